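"""Per-slice analysis orchestration and cross-group comparison.

``analyze_slice`` runs the two arms — Voronoi cellular sociology and the
hexbin GIS statistics — on one point pattern with a single shared
configuration, returning a JSON-serializable SliceReport.  ``compare_groups``
assembles per-slice summaries into group tables and applies the inference
chain (ROUT outlier check → KS normality → ANOVA suite).  Group comparisons
are refused unless every report was produced with identical hexagon size and
weight settings, since the hexbin statistics are scale-dependent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ComparabilityError, VorogisError
from .geodist import distribution_summary
from .globalstats import ann, general_g, morans_i, ripleys_k
from .hexgrid import default_edge_length, frame_cells, generate_hex_grid, occupied_cells, spatial_join
from .inference import anova_suite, ks_normality, rout_outliers
from .localstats import class_area_percentages, gi_star, local_morans
from .points import PointPattern
from .voronoi import sociology
from .weights import build_weights


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters shared by every slice in a comparison."""

    hex_edge: float | None = None  # None → ~400 hexagons over the frame
    weight_conceptualization: str = "inverse_distance"
    weight_standardization: str = "row"
    gi_band: float | None = None  # None → ensure-neighbor threshold
    n_perm_local: int = 999
    n_perm_ripley: int = 99
    alpha: float = 0.05
    fdr: bool = False
    seed: int = 0
    sd_ddof: int = 1

    def validate(self):
        if self.hex_edge is not None and self.hex_edge <= 0:
            raise VorogisError("config: hex_edge must be > 0")
        if not 0 < self.alpha < 1:
            raise VorogisError("config: alpha must lie in (0, 1)")
        if self.n_perm_local < 0 or self.n_perm_ripley < 0:
            raise VorogisError("config: permutation counts must be >= 0")

    def comparability_key(self) -> tuple:
        return (
            self.hex_edge,
            self.weight_conceptualization,
            self.weight_standardization,
            self.gi_band,
            self.alpha,
            self.fdr,
        )


def analyze_slice(pattern: PointPattern, config: AnalysisConfig | None = None) -> dict:
    """Run both analysis arms on one slice; deterministic given config.seed."""
    config = config or AnalysisConfig()
    config.validate()
    edge = config.hex_edge or default_edge_length(pattern.frame)

    indices, retained = sociology(pattern, ddof=config.sd_ddof)
    dist = distribution_summary(pattern)

    grid = spatial_join(generate_hex_grid(pattern.frame, edge), pattern)
    raster = frame_cells(grid)
    occ = occupied_cells(grid)
    # global statistics see the full in-frame count raster (empty hexagons
    # carry the dispersion signal); local statistics run on the occupied
    # cells only, with the tessellation kept as the area-percentage denominator
    full_counts = raster.counts.astype(float)
    occ_counts = occ.counts.astype(float)
    w_full_row = build_weights(
        raster.centers,
        conceptualization=config.weight_conceptualization,
        standardization=config.weight_standardization,
    )
    w_full_none = build_weights(
        raster.centers, conceptualization=config.weight_conceptualization, standardization="none"
    )
    w_occ_row = build_weights(
        occ.centers,
        conceptualization=config.weight_conceptualization,
        standardization=config.weight_standardization,
    )
    w_occ_self = build_weights(
        occ.centers,
        conceptualization="fixed_band",
        threshold=config.gi_band,
        include_self=True,
    )

    ann_res = ann(pattern)
    g_res = general_g(full_counts, w_full_none)
    i_res = morans_i(full_counts, w_full_row)
    k_res = ripleys_k(
        pattern, n_perm=config.n_perm_ripley, seed=config.seed + 101
    )
    lisa = local_morans(
        occ_counts,
        w_occ_row,
        alpha=config.alpha,
        fdr=config.fdr,
        n_perm=config.n_perm_local,
        seed=config.seed + 202,
        total_cells=grid.total_cells,
    )
    gi = gi_star(occ_counts, w_occ_self, fdr=config.fdr, total_cells=grid.total_cells)

    above = k_res.l - k_res.distances
    report = {
        "slice_id": pattern.slice_id,
        "group": pattern.group,
        "n_points": pattern.n,
        "sociology": asdict(indices),
        "geo_distribution": {
            "central_feature_index": dist.central_feature_index,
            "mean_center": dist.mean_center,
            "median_center": dist.median_center,
            "standard_distance": dist.standard_distance,
            "ellipse": asdict(dist.ellipse),
        },
        "global": {
            "ann": {
                "R": ann_res.statistic,
                "omd": ann_res.meta["omd"],
                "emd": ann_res.meta["emd"],
                "z": ann_res.z_score,
                "p": ann_res.p_value,
            },
            "general_g": {
                "G": g_res.statistic,
                "expected": g_res.expected,
                "z": g_res.z_score,
                "p": g_res.p_value,
            },
            "morans_i": {
                "I": i_res.statistic,
                "expected": i_res.expected,
                "z": i_res.z_score,
                "p": i_res.p_value,
            },
            "ripley": {
                "distances": k_res.distances.tolist(),
                "l_minus_d": above.tolist(),
                "n_above_envelope": int(
                    np.count_nonzero(k_res.l > k_res.envelope_hi)
                )
                if k_res.envelope_hi is not None
                else None,
            },
        },
        "local": {
            "lisa_percent": class_area_percentages(lisa),
            "gi_percent": class_area_percentages(gi),
        },
        "provenance": {
            "version": __version__,
            "hex_edge": edge,
            "total_hexagons": grid.total_cells,
            "occupied_hexagons": occ.n_cells,
            "config": asdict(config),
        },
    }
    return report


#: per-slice summaries extracted into group tables for comparison
SUMMARY_EXTRACTORS = {
    "mean_area": lambda r: r["sociology"]["mean_area"],
    "rf_av": lambda r: r["sociology"]["rf_av"],
    "area_disorder": lambda r: r["sociology"]["area_disorder"],
    "rf_homogeneity": lambda r: r["sociology"]["rf_homogeneity"],
    "ann_r": lambda r: r["global"]["ann"]["R"],
    "ann_omd": lambda r: r["global"]["ann"]["omd"],
    "general_g_z": lambda r: r["global"]["general_g"]["z"],
    "morans_i_z": lambda r: r["global"]["morans_i"]["z"],
    "lisa_hh_percent": lambda r: r["local"]["lisa_percent"]["HH"],
    "lisa_ll_percent": lambda r: r["local"]["lisa_percent"]["LL"],
}


def group_table(reports: Sequence[dict], summary: str) -> pd.DataFrame:
    extract = SUMMARY_EXTRACTORS[summary]
    return pd.DataFrame(
        {
            "slice_id": [r["slice_id"] for r in reports],
            "group": [r["group"] for r in reports],
            "value": [extract(r) for r in reports],
        }
    )


def compare_groups(
    reports: Sequence[dict],
    summaries: Sequence[str] | None = None,
    rout_q: float | None = 0.01,
) -> dict:
    """Group-comparison report across slices.

    For each summary: optional ROUT cleaning per group, KS normality per
    group, then the full ANOVA suite.  Raises ComparabilityError if the
    reports were produced with different hexbin/weight parameters.
    """
    keys = {json.dumps(r["provenance"]["config"], sort_keys=True, default=str) for r in reports}
    hex_edges = {round(r["provenance"]["hex_edge"], 9) for r in reports}
    if len(hex_edges) > 1:
        raise ComparabilityError(f"mixed hexagon edge lengths across reports: {hex_edges}")
    if len(keys) > 1:
        raise ComparabilityError("mixed analysis configurations across reports")
    groups = sorted({r["group"] for r in reports})
    if len(groups) < 2:
        raise ComparabilityError("comparison requires >= 2 groups")
    summaries = summaries or list(SUMMARY_EXTRACTORS)
    out = {"groups": groups, "n_slices": len(reports), "summaries": {}}
    for summary in summaries:
        table = group_table(reports, summary)
        cleaned_rows = []
        n_outliers = 0
        for g in groups:
            vals = table.loc[table["group"] == g, "value"].to_numpy()
            if rout_q is not None and vals.size >= 5:
                flags, vals = rout_outliers(vals, q=rout_q)
                n_outliers += int(flags.sum())
            cleaned_rows.append(pd.DataFrame({"group": g, "value": vals}))
        cleaned = pd.concat(cleaned_rows, ignore_index=True)
        normality = {}
        for g in groups:
            vals = cleaned.loc[cleaned["group"] == g, "value"].to_numpy()
            try:
                normality[g] = ks_normality(vals).p_value
            except VorogisError:
                normality[g] = None
        suite = anova_suite(cleaned)
        out["summaries"][summary] = {
            "group_means": {
                g: float(cleaned.loc[cleaned["group"] == g, "value"].mean()) for g in groups
            },
            "n_outliers_removed": n_outliers,
            "ks_normality_p": normality,
            "anova": {
                "F": suite.ordinary.statistic,
                "df": suite.ordinary.df,
                "p": suite.ordinary.p_value,
            },
            "welch": {"W": suite.welch.statistic, "df": suite.welch.df, "p": suite.welch.p_value},
            "brown_forsythe": {
                "F*": suite.brown_forsythe.statistic,
                "df": suite.brown_forsythe.df,
                "p": suite.brown_forsythe.p_value,
            },
            "tukey": suite.tukey.to_dict(orient="records"),
            "dunnett_t3": suite.dunnett_t3.to_dict(orient="records"),
        }
    return out
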