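"""Independent reference implementations used as oracles.

Literal, loop-based transcriptions of the published formulas for the
spatial statistics, written without reference to the vectorized package
code.  They are deliberately slow and explicit.
"""

import math

import numpy as np


def moran_i_loop(x, w):
    """Global Moran's I and randomization moments, by explicit double loops."""
    x = [float(v) for v in x]
    n = len(x)
    xbar = sum(x) / n
    z = [v - xbar for v in x]
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s0 += w[i][j]
            num += w[i][j] * z[i] * z[j]
    den = sum(v * v for v in z)
    stat = n / s0 * num / den
    # randomization moments
    s1 = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                s1 += 0.5 * (w[i][j] + w[j][i]) ** 2
    s2 = 0.0
    for i in range(n):
        wi_ = sum(w[i][j] for j in range(n) if j != i)
        w_i = sum(w[j][i] for j in range(n) if j != i)
        s2 += (wi_ + w_i) ** 2
    b2 = n * sum(v**4 for v in z) / den**2
    e = -1.0 / (n - 1)
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e**2
    zscore = (stat - e) / math.sqrt(var)
    return stat, e, var, zscore


def general_g_loop(x, w):
    """Getis-Ord General G and randomization moments, by explicit loops."""
    x = [float(v) for v in x]
    n = len(x)
    num = den = s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num += w[i][j] * x[i] * x[j]
            den += x[i] * x[j]
            s0 += w[i][j]
    g = num / den
    e = s0 / (n * (n - 1))
    s1 = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                s1 += 0.5 * (w[i][j] + w[j][i]) ** 2
    s2 = 0.0
    for i in range(n):
        wi_ = sum(w[i][j] for j in range(n) if j != i)
        w_i = sum(w[j][i] for j in range(n) if j != i)
        s2 += (wi_ + w_i) ** 2
    m1 = sum(x)
    m2 = sum(v**2 for v in x)
    m3 = sum(v**3 for v in x)
    m4 = sum(v**4 for v in x)
    b0 = (n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2
    b1 = -((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    b2_ = -(2 * n * s1 - (n + 3) * s2 + 6 * s0**2)
    b3 = 4 * (n - 1) * s1 - 2 * (n + 1) * s2 + 8 * s0**2
    b4 = s1 - s2 + s0**2
    eg2 = (b0 * m2**2 + b1 * m4 + b2_ * m1**2 * m2 + b3 * m1 * m3 + b4 * m1**4) / (
        (m1**2 - m2) ** 2 * n * (n - 1) * (n - 2) * (n - 3)
    )
    var = eg2 - e**2
    zscore = (g - e) / math.sqrt(var)
    return g, e, var, zscore


def local_moran_loop(x, w):
    """Anselin local I_i with m2 = Σz²/n, plus exact conditional moments."""
    x = [float(v) for v in x]
    n = len(x)
    xbar = sum(x) / n
    z = [v - xbar for v in x]
    m2 = sum(v * v for v in z) / n
    stats = []
    es = []
    vars_ = []
    for i in range(n):
        lag = sum(w[i][j] * z[j] for j in range(n) if j != i)
        stats.append(z[i] / m2 * lag)
        wi = sum(w[i][j] for j in range(n) if j != i)
        wi2 = sum(w[i][j] ** 2 for j in range(n) if j != i)
        s1 = -z[i]  # sum of the remaining values
        s2 = sum(v * v for v in z) - z[i] ** 2
        sigma2 = s2 / (n - 1) - (s1 / (n - 1)) ** 2
        var_lag = sigma2 * (wi2 - (wi**2 - wi2) / (n - 2))
        es.append(z[i] / m2 * wi * s1 / (n - 1))
        vars_.append((z[i] / m2) ** 2 * var_lag)
    return stats, es, vars_


def gi_star_loop(x, w_self):
    """Ord-Getis Gi* z-scores (self-inclusive weights), by explicit loops."""
    x = [float(v) for v in x]
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar**2)
    out = []
    for i in range(n):
        wi = sum(w_self[i][j] for j in range(n))
        wi2 = sum(w_self[i][j] ** 2 for j in range(n))
        num = sum(w_self[i][j] * x[j] for j in range(n)) - xbar * wi
        den = s * math.sqrt((n * wi2 - wi**2) / (n - 1))
        out.append(num / den)
    return out


def nearest_site_index(point, sites):
    """Index of the nearest site (brute force), for partition oracles."""
    best, besti = float("inf"), -1
    for i, (sx, sy) in enumerate(sites):
        d = (point[0] - sx) ** 2 + (point[1] - sy) ** 2
        if d < best:
            best, besti = d, i
    return besti


def shoelace_area(ring):
    """Polygon area by the shoelace formula, written by hand."""
    s = 0.0
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def regular_polygon(k, side=1.0):
    """Vertices of a regular k-gon with the given side length."""
    r = side / (2.0 * math.sin(math.pi / k))
    return [
        (r * math.cos(2 * math.pi * i / k), r * math.sin(2 * math.pi * i / k))
        for i in range(k)
    ]
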