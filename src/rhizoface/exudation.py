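"""Net root exudation fluxes from syringe-incubation records.

Each record is one 24-h in-situ incubation of an intact fine-root system in
a glass syringe; the recovered solution (collection plus washes, pooled) is
assayed for dissolved organic C and total dissolved N. One rootless blank
syringe per root box corrects for background C/N. Because roots both release
and re-absorb compounds, the blank-corrected flux is *net* exudation and may
legitimately be negative; negatives are flagged, never floored.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

#: Expected columns of an incubation table, with units.
INCUBATION_COLUMNS = {
    "sample_id": "unique identifier",
    "array_id": "experimental array",
    "treatment": "ambient|elevated",
    "timepoint": "season label",
    "collection_date": "ISO date of the campaign",
    "box_id": "root box within the array",
    "is_blank": "True for rootless blank syringes",
    "solution_C_ug": "ug DOC recovered (collection + washes pooled)",
    "solution_N_ug": "ug TDN recovered",
    "root_dry_mass_g": "g dry root (NaN for blanks)",
    "root_surface_area_mm2": "mm2 (NaN for blanks)",
    "duration_d": "incubation length, days",
}


def blank_correct(incubations: pd.DataFrame) -> pd.DataFrame:
    """Subtract matched blank means from each root sample's C and N masses.

    Blank matching hierarchy: same box and timepoint, else mean blank of the
    same array and timepoint, else the global mean blank for the timepoint.
    The level used is recorded in ``blank_level``; corrected masses that go
    negative (net reuptake) are flagged, not clipped.

    Raises ``ValueError`` naming the orphaned sample if no blank exists at
    any level for its timepoint.
    """
    df = incubations.copy()
    blanks = df[df["is_blank"]]
    samples = df[~df["is_blank"]].copy()

    by_box = blanks.groupby(["timepoint", "box_id"])[["solution_C_ug", "solution_N_ug"]].mean()
    by_array = blanks.groupby(["timepoint", "array_id"])[["solution_C_ug", "solution_N_ug"]].mean()
    by_tp = blanks.groupby("timepoint")[["solution_C_ug", "solution_N_ug"]].mean()

    levels, c_corr, n_corr = [], [], []
    for row in samples.itertuples():
        key_box = (row.timepoint, row.box_id)
        key_arr = (row.timepoint, row.array_id)
        if key_box in by_box.index:
            ref, level = by_box.loc[key_box], "box"
        elif key_arr in by_array.index:
            ref, level = by_array.loc[key_arr], "array"
        elif row.timepoint in by_tp.index:
            ref, level = by_tp.loc[row.timepoint], "global"
        else:
            raise ValueError(
                f"no blank at any matching level for sample {row.sample_id!r} "
                f"(timepoint {row.timepoint!r})"
            )
        levels.append(level)
        c_corr.append(row.solution_C_ug - ref["solution_C_ug"])
        n_corr.append(row.solution_N_ug - ref["solution_N_ug"])

    samples["corrected_C_ug"] = c_corr
    samples["corrected_N_ug"] = n_corr
    samples["blank_level"] = levels
    samples["negative_after_blank"] = (samples["corrected_C_ug"] < 0) | (
        samples["corrected_N_ug"] < 0
    )
    return samples


def specific_rates(corrected: pd.DataFrame) -> pd.DataFrame:
    """Mass- and area-specific net exudation rates, plus exudate C:N.

    C_rate and N_rate are ug per g root per day; area rates are ug per mm2
    per day. C:N is the ratio of rates (equivalently of masses, since the
    duration cancels) and is undefined (NaN) when the N rate is not positive.
    """
    df = corrected.copy()
    if (df["duration_d"] <= 0).any():
        raise ValueError("incubation duration must be positive")
    if (df["root_dry_mass_g"] <= 0).any() or df["root_dry_mass_g"].isna().any():
        bad = df.loc[
            (df["root_dry_mass_g"] <= 0) | df["root_dry_mass_g"].isna(), "sample_id"
        ].tolist()
        raise ValueError(f"non-positive root dry mass for samples {bad}")
    denom = df["root_dry_mass_g"] * df["duration_d"]
    df["C_rate_ug_g_d"] = df["corrected_C_ug"] / denom
    df["N_rate_ug_g_d"] = df["corrected_N_ug"] / denom
    area_denom = df["root_surface_area_mm2"] * df["duration_d"]
    df["C_rate_ug_mm2_d"] = df["corrected_C_ug"] / area_denom
    df["N_rate_ug_mm2_d"] = df["corrected_N_ug"] / area_denom
    df["CN_ratio"] = np.where(
        df["N_rate_ug_g_d"] > 0, df["C_rate_ug_g_d"] / df["N_rate_ug_g_d"], np.nan
    )
    return df


def _nearest_census(census_dates: pd.Series, target: dt.date) -> dt.date:
    """Closest census to the target date; ties resolved to the later census."""
    dates = sorted(pd.unique(census_dates))
    best = min(dates, key=lambda d: (abs((pd.Timestamp(d) - pd.Timestamp(target)).days), -pd.Timestamp(d).toordinal()))
    return best


def areal_rate(rates: pd.DataFrame, standing_biomass: pd.DataFrame) -> pd.DataFrame:
    """Scale mass-specific rates to forest area using standing root stock.

    ``standing_biomass`` has one row per array and census date with the
    <1 mm and 1-2 mm fine-root biomass classes (g m-2); the two classes are
    summed, and each sample is matched to its array's census nearest in time
    to the collection date (later census on a tie). Output rates are
    ug m-2 d-1.

    Raises ``ValueError`` if an array has no biomass record at all.
    """
    bio = standing_biomass.copy()
    bio["census_date"] = pd.to_datetime(bio["census_date"]).dt.date
    bio["standing_g_m2"] = bio["biomass_lt1mm_g_m2"] + bio["biomass_1to2mm_g_m2"]
    df = rates.copy()
    df["collection_date"] = pd.to_datetime(df["collection_date"]).dt.date

    stock = []
    for row in df.itertuples():
        arr = bio[bio["array_id"] == row.array_id]
        if arr.empty:
            raise ValueError(
                f"no standing-biomass record for array {row.array_id!r} "
                f"(sample {row.sample_id!r}) in exudation.areal_rate"
            )
        census = _nearest_census(arr["census_date"], row.collection_date)
        stock.append(float(arr.loc[arr["census_date"] == census, "standing_g_m2"].mean()))
    df["standing_root_g_m2"] = stock
    df["C_rate_ug_m2_d"] = df["C_rate_ug_g_d"] * df["standing_root_g_m2"]
    df["N_rate_ug_m2_d"] = df["N_rate_ug_g_d"] * df["standing_root_g_m2"]
    return df


def exudation_rates(
    incubations: pd.DataFrame, standing_biomass: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Blank-correct and derive all exudation rates in one pass."""
    out = specific_rates(blank_correct(incubations))
    if standing_biomass is not None:
        out = areal_rate(out, standing_biomass)
    return out
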