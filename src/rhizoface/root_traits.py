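"""Morphological and chemical root traits from scanner-exported tables.

Consumes the trait table an image-analysis scanner exports for each root
system (total length, branch points, surface area) together with combustion
C/N percentages, and derives the three traits used for treatment
comparison: specific root length (SRL, m g-1), branching frequency
(branch points mm-1), and tissue C:N (mass basis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical column names; scanner exports are remapped onto these
CANONICAL_COLUMNS = (
    "sample_id",
    "total_length_mm",
    "branch_points",
    "dry_mass_g",
    "surface_area_mm2",
    "tissue_C_pct",
    "tissue_N_pct",
)

MM_PER_M = 1000.0


def specific_root_length(total_length_mm, dry_mass_g):
    """SRL = root length / root dry mass, in m per g."""
    length = np.asarray(total_length_mm, dtype=float)
    mass = np.asarray(dry_mass_g, dtype=float)
    if np.any(mass <= 0) or np.any(np.isnan(mass)):
        raise ValueError("root dry mass must be positive")
    return length / MM_PER_M / mass


def branching_frequency(branch_points, total_length_mm):
    """Branch points per mm of root."""
    bp = np.asarray(branch_points, dtype=float)
    length = np.asarray(total_length_mm, dtype=float)
    if np.any(length <= 0):
        raise ValueError("total root length must be positive")
    if np.any(bp < 0):
        raise ValueError("branch-point counts must be non-negative")
    return bp / length


def tissue_cn(tissue_C_pct, tissue_N_pct):
    """Tissue C:N on a mass basis; NaN where %N is zero."""
    c = np.asarray(tissue_C_pct, dtype=float)
    n = np.asarray(tissue_N_pct, dtype=float)
    for arr, name in ((c, "%C"), (n, "%N")):
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError(f"{name} outside [0, 100]")
    return np.where(n > 0, c / np.where(n > 0, n, np.nan), np.nan)


def derive_traits(scans: pd.DataFrame, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Append srl_m_per_g, branching_per_mm and tissue_cn to a scan table.

    ``column_map`` maps canonical names to the caller's column names, so the
    exports of common scanner software can be consumed without renaming.
    Rows with %N = 0 get a NaN C:N and a ``cn_undefined`` flag.
    """
    df = scans.copy()
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "sample_id"]
    if missing:
        raise ValueError(f"scan table missing columns {missing}")
    df["srl_m_per_g"] = specific_root_length(df["total_length_mm"], df["dry_mass_g"])
    df["branching_per_mm"] = branching_frequency(df["branch_points"], df["total_length_mm"])
    df["tissue_cn"] = tissue_cn(df["tissue_C_pct"], df["tissue_N_pct"])
    df["cn_undefined"] = ~(df["tissue_N_pct"] > 0)
    return df
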