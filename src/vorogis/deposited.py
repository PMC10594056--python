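"""Optional re-analysis of the deposited per-polygon tables.

The study deposited per-polygon Area/Perimeter/Circularity tables and
per-slice AD/RFH/RFav summaries for the three culture groups on Figshare
(DOIs 10.6084/m9.figshare.21063616.v1, .21063517.v1, .21063280.v1).  This
module recomputes the group comparison from such tables when the files are
available locally; nothing here downloads anything, and no offline test
depends on it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .inference import anova_suite, rout_outliers


def load_polygon_table(path: str | Path) -> pd.DataFrame:
    """Read a per-polygon table with Area/Perimeter/Circularity columns
    (case-insensitive; CSV or Excel)."""
    path = Path(path)
    df = pd.read_excel(path) if path.suffix.lower() in (".xlsx", ".xls") else pd.read_csv(path)
    cols = {str(c).strip().lower(): c for c in df.columns}
    missing = [k for k in ("area", "perimeter") if k not in cols]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = pd.DataFrame({"area": df[cols["area"]], "perimeter": df[cols["perimeter"]]})
    circ = cols.get("circ.") or cols.get("circularity") or cols.get("circ")
    if circ is not None:
        out["circularity"] = df[circ]
    else:
        out["circularity"] = 4.0 * np.pi * out["area"] / out["perimeter"] ** 2
    return out


def per_slice_summary(df: pd.DataFrame, ddof: int = 1) -> dict:
    """RFav/AD/RFH and the mean polygon area of one deposited slice table."""
    a, rf = df["area"].to_numpy(float), df["circularity"].to_numpy(float)
    a_av, sd_a = a.mean(), a.std(ddof=ddof)
    rf_av, sd_rf = rf.mean(), rf.std(ddof=ddof)
    return {
        "n_polygons": a.size,
        "mean_area": float(a_av),
        "rf_av": float(rf_av),
        "area_disorder": float(1 - 1 / (1 + sd_a / a_av)),
        "rf_homogeneity": float(1 / (1 + sd_rf / rf_av)),
    }


def compare_deposited(slice_tables: dict[str, list[pd.DataFrame]], rout_q: float = 0.01) -> dict:
    """Group comparison of per-slice mean areas and RFav from deposited tables.

    ``slice_tables`` maps group label → list of per-slice polygon tables.
    ROUT (Q) cleaning is applied per group before the ANOVA suite, matching
    the published analysis chain.
    """
    out = {}
    for summary in ("mean_area", "rf_av"):
        rows = []
        for group, tables in slice_tables.items():
            vals = np.array([per_slice_summary(t)[summary] for t in tables])
            if vals.size >= 5:
                _, vals = rout_outliers(vals, q=rout_q)
            rows.append(pd.DataFrame({"group": group, "value": vals}))
        table = pd.concat(rows, ignore_index=True)
        suite = anova_suite(table)
        out[summary] = {
            "group_means": table.groupby("group")["value"].mean().to_dict(),
            "anova_F": suite.ordinary.statistic,
            "anova_df": suite.ordinary.df,
            "welch_W": suite.welch.statistic,
            "brown_forsythe_Fstar": suite.brown_forsythe.statistic,
        }
    return out
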