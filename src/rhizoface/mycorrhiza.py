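"""Ectomycorrhizal biomass production and turnover from sand ingrowth bags.

Root-excluding mesh bags of sand accrue extramatrical hyphae; the fungal
sterol ergosterol measured in each bag indexes fungal biomass via a fixed
conversion factor (3.3 ug ergosterol per mg biomass). Quarterly (3-mo) bags
give seasonal net production rates. Staggered 6- and 12-month bags give the
annual turnover coefficient: writing B6a for biomass accrued over the first
six months (collected at t1), B6b for a bag covering the second six months
(collected at t2), and B12 for the full-year bag, first-order loss at rate
``mu`` implies

    B12 = B6a * exp(-mu * (t2 - t1)) + B6b

so

    mu = -ln((B12 - B6b) / B6a) / (t2 - t1)        [per year]

The fraction (B12 - B6b)/B6a is the surviving share of first-half biomass.
Bags where B12 <= B6b carry no turnover information (the log argument is
non-positive) and propagate as missing, with the reason recorded.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ERGOSTEROL_PER_MG_BIOMASS

DAYS_PER_YEAR = 365.25


def ergosterol_to_biomass(ergosterol_ug, factor: float = ERGOSTEROL_PER_MG_BIOMASS):
    """Convert ergosterol mass (ug) to fungal biomass (mg)."""
    erg = np.asarray(ergosterol_ug, dtype=float)
    if np.any(erg < 0):
        raise ValueError("ergosterol mass cannot be negative")
    out = erg / factor
    return float(out) if out.ndim == 0 else out


def production_rate(bags: pd.DataFrame, factor: float = ERGOSTEROL_PER_MG_BIOMASS) -> pd.DataFrame:
    """Seasonal production from quarterly bags: ug biomass per g sand per day.

    Only 3-month bags measure seasonal production; passing any other duration
    class is an error. The rate divides per-gram fungal biomass by the exact
    number of installed days.
    """
    df = bags.copy()
    wrong = df.loc[df["duration_class"] != "3mo", "bag_id"].tolist()
    if wrong:
        raise ValueError(f"production_rate expects 3mo bags only; got {wrong}")
    install = pd.to_datetime(df["install_date"])
    collect = pd.to_datetime(df["collect_date"])
    days = (collect - install).dt.days.astype(float)
    if (days <= 0).any():
        raise ValueError("collection must postdate installation")
    biomass_ug_per_g = ergosterol_to_biomass(df["ergosterol_ug_per_g"].to_numpy(), factor) * 1000.0
    df["biomass_ug_per_g"] = biomass_ug_per_g
    df["production_ug_g_d"] = biomass_ug_per_g / days.to_numpy()
    return df


@dataclass(frozen=True)
class TurnoverEstimate:
    mu: float  # per year; NaN when undefined
    B6a: float
    B6b: float
    B12: float
    t1: dt.date
    t2: dt.date
    survival_fraction: float
    reason: str = ""  # non-empty when mu is missing or negative

    @property
    def dt_years(self) -> float:
        if isinstance(self.t1, dt.date):
            return (self.t2 - self.t1).days / DAYS_PER_YEAR
        return float(self.t2 - self.t1)


def turnover(B6a: float, B6b: float, B12: float, t1, t2) -> TurnoverEstimate:
    """Annual turnover coefficient from one staggered bag triple.

    ``t1``/``t2`` are the two staggered collection dates (or plain floats in
    years for closed-form use). B6a must be positive and t2 after t1.
    B12 <= B6b yields a missing estimate (surviving biomass non-positive);
    survival fractions above 1 give a negative mu, reported with a warning
    reason rather than clamped.
    """
    if B6a <= 0:
        raise ValueError("B6a must be positive")
    if t2 <= t1:
        raise ValueError("t2 must be after t1")
    if isinstance(t1, dt.date):
        dt_years = (t2 - t1).days / DAYS_PER_YEAR
    else:
        dt_years = float(t2 - t1)
    survival = (B12 - B6b) / B6a
    if survival <= 0:
        return TurnoverEstimate(
            float("nan"), B6a, B6b, B12, t1, t2, survival,
            reason="B12 <= B6b: surviving first-half biomass non-positive",
        )
    mu = -np.log(survival) / dt_years
    reason = "survival fraction > 1: negative turnover" if survival > 1 else ""
    return TurnoverEstimate(float(mu), B6a, B6b, B12, t1, t2, float(survival), reason)


def _bag_biomass_ug_per_g(df: pd.DataFrame, factor: float) -> pd.Series:
    return ergosterol_to_biomass(df["ergosterol_ug_per_g"].to_numpy(), factor) * 1000.0


def estimate_turnover(
    bags: pd.DataFrame, factor: float = ERGOSTEROL_PER_MG_BIOMASS
) -> dict:
    """Treatment-level turnover from a full ingrowth-bag table.

    Per array, the 6- and 12-month bags are averaged over locations first
    (B6a = earlier-collected 6-mo bags, B6b = later-collected, B12 = 12-mo),
    and one turnover estimate is made per array; treatments are then
    summarized as mean +/- SE over arrays (n = number of arrays). Because the
    proper replication level of the SE is debatable at this design, an SE
    over per-location estimates is reported alongside.
    """
    df = bags.copy()
    df["install_date"] = pd.to_datetime(df["install_date"]).dt.date
    df["collect_date"] = pd.to_datetime(df["collect_date"]).dt.date
    df["biomass_ug_per_g"] = _bag_biomass_ug_per_g(df, factor)

    six = df[df["duration_class"] == "6mo"]
    twelve = df[df["duration_class"] == "12mo"]
    if six.empty or twelve.empty:
        raise ValueError("need both 6mo and 12mo bags for turnover")
    t1 = min(six["collect_date"])
    t2 = max(six["collect_date"])
    if t2 <= t1:
        raise ValueError("6mo bags must span two staggered collections")

    per_array, per_location = [], []
    for (arr, trt), grp in df.groupby(["array_id", "treatment"], sort=True):
        g6 = grp[grp["duration_class"] == "6mo"]
        b6a = g6.loc[g6["collect_date"] == t1, "biomass_ug_per_g"]
        b6b = g6.loc[g6["collect_date"] == t2, "biomass_ug_per_g"]
        b12 = grp.loc[grp["duration_class"] == "12mo", "biomass_ug_per_g"]
        if b6a.empty or b6b.empty or b12.empty:
            raise ValueError(f"array {arr!r} missing a staggered bag class")
        est = turnover(b6a.mean(), b6b.mean(), b12.mean(), t1, t2)
        per_array.append(
            {"array_id": arr, "treatment": trt, "mu": est.mu,
             "survival_fraction": est.survival_fraction, "reason": est.reason}
        )
        # per-location estimates, for the alternative SE
        for loc, lg in grp.groupby("location_id"):
            l6 = lg[lg["duration_class"] == "6mo"]
            la = l6.loc[l6["collect_date"] == t1, "biomass_ug_per_g"]
            lb = l6.loc[l6["collect_date"] == t2, "biomass_ug_per_g"]
            l12 = lg.loc[lg["duration_class"] == "12mo", "biomass_ug_per_g"]
            if la.empty or lb.empty or l12.empty or la.mean() <= 0:
                continue
            lest = turnover(la.mean(), lb.mean(), l12.mean(), t1, t2)
            per_location.append({"array_id": arr, "treatment": trt, "location_id": loc, "mu": lest.mu})

    arrays = pd.DataFrame(per_array)
    locations = pd.DataFrame(per_location)
    summary = {}
    for trt, grp in arrays.groupby("treatment"):
        mus = grp["mu"].dropna()
        loc_mus = locations.loc[locations["treatment"] == trt, "mu"].dropna()
        summary[trt] = {
            "mu_mean": float(mus.mean()) if len(mus) else float("nan"),
            "mu_se_arrays": float(mus.std(ddof=1) / np.sqrt(len(mus))) if len(mus) > 1 else float("nan"),
            "mu_se_locations": float(loc_mus.std(ddof=1) / np.sqrt(len(loc_mus))) if len(loc_mus) > 1 else float("nan"),
            "n_arrays": int(len(mus)),
            "n_locations": int(len(loc_mus)),
            "n_missing_arrays": int(grp["mu"].isna().sum()),
        }
    return {"per_array": arrays, "per_location": locations, "summary": summary, "t1": t1, "t2": t2}
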