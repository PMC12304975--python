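"""Synthetic FACE-study dataset generator with known ground truth.

Emulates the geometry and statistical structure of a six-array forest FACE
experiment: 2 treatments x 3 arrays, four seasonal campaigns, six exudation
pseudoreplicates (three root boxes x two root systems) per array, five
ingrowth-bag locations per array with staggered 3/6/12-month bags, and
paired root/exudate metabolomics feature tables.

Every measured variable follows the multiplicative model

    observation = baseline * seasonal_multiplier
                  * exp(treatment_indicator * true_RR + array_effect)
                  * lognormal noise (mean 1, given CV)

with array effects drawn once per (variable, array) and shared across
timepoints — the repeated-measures structure of the design. Ingrowth-bag
biomass follows the production-decay model

    B(collect) = integral of P(t) * exp(-mu * (collect - t)) dt

with production P piecewise-constant over each quarterly window, so the
staggered-bag turnover estimator is exactly self-consistent on noiseless
data. Ergosterol, not biomass, is written to the output table, so the
downstream conversion step is always exercised.

One global integer seed drives an independent, named substream per table;
adding a table never perturbs the others. Identical (specs, seed) give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    AMBIENT,
    BAG_3MO_COLLECTIONS,
    BAG_INSTALL_DATE,
    BAG_SEASONS,
    BAG_T1,
    BAG_T2,
    ELEVATED,
    ERGOSTEROL_PER_MG_BIOMASS,
    TIMEPOINT_DATES,
    TREATMENTS,
    DesignSpec,
    EffectSpec,
    MetabolomeSpec,
)
from .metabolomics import FeatureMatrix

DAYS_PER_YEAR = 365.25

#: fixed substream keys; never renumber (would silently reshuffle datasets)
_STREAM_KEYS = {
    "array_effects": 1,
    "exudates": 2,
    "root_geometry": 3,
    "biomass": 4,
    "bags": 5,
    "metabolome_roots": 6,
    "metabolome_exudates": 7,
    "metabolome_truth": 8,
}

MEAN_ROOT_MASS_G = 0.4  # median of the root-system dry-mass distribution
ROOT_MASS_SD_LOG = 0.3
ROOT_DIAMETER_MM = 0.3  # drives surface area ~ pi * d * length
SAND_MASS_G = 45.0


def _rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_KEYS[table]]))


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1 + cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def _array_ids(design: DesignSpec) -> dict[str, list[str]]:
    n = design.n_arrays_per_treatment
    return {AMBIENT: [f"A{i + 1}" for i in range(n)], ELEVATED: [f"E{i + 1}" for i in range(n)]}


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth serialized alongside each synthetic dataset."""

    true_rr: dict[str, float] = dataclasses.field(default_factory=dict)
    true_mu: dict[str, float] = dataclasses.field(default_factory=dict)
    affected_features: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    array_effects: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            {**self.true_rr, **other.true_rr},
            {**self.true_mu, **other.true_mu},
            {**self.affected_features, **other.affected_features},
            {**self.array_effects, **other.array_effects},
        )


# ---------------------------------------------------------------------------
# measurement tables (exudation, root traits, standing biomass)
# ---------------------------------------------------------------------------

_PRIMITIVES = ("c_exudation", "n_exudation", "srl", "branching", "tissue_c", "tissue_n",
               "fine_root_biomass")


def _draw_array_effects(design: DesignSpec, effects: EffectSpec) -> dict[str, dict[str, float]]:
    rng = _rng(design.seed, "array_effects")
    ids = _array_ids(design)
    out: dict[str, dict[str, float]] = {}
    for var in _PRIMITIVES:
        out[var] = {}
        for trt in TREATMENTS:
            for arr in ids[trt]:
                out[var][arr] = float(rng.normal(0.0, effects.array_sd))
    return out


def _model_value(
    effects: EffectSpec,
    var: str,
    trt: str,
    arr: str,
    timepoint: str,
    array_effects: dict,
    noise: float,
) -> float:
    base = effects.baseline_mean[var]
    seas = effects.seasonal(var, timepoint)
    treat = effects.true_rr.get(var, 0.0) if trt == ELEVATED else 0.0
    return base * seas * math.exp(treat + array_effects[var][arr]) * noise


def generate_measurements(
    design: DesignSpec, effects: EffectSpec
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Exudate incubations, root-trait scans, and standing fine-root biomass.

    Root-system geometry (dry mass, and hence length and surface area) is
    drawn once per sampling slot and shared between the two treatments, so
    that with zero noise and zero effect the treatments are exactly equal
    observation for observation.
    """
    array_effects = _draw_array_effects(design, effects)
    rng_ex = _rng(design.seed, "exudates")
    rng_geom = _rng(design.seed, "root_geometry")
    rng_bio = _rng(design.seed, "biomass")
    ids = _array_ids(design)
    tps = list(design.timepoints)
    n_boxes = design.n_boxes_per_array
    cv = effects.residual_cv

    # paired auxiliary geometry: one draw per (array slot, timepoint, rep)
    n_slots = design.n_arrays_per_treatment * len(tps) * design.n_exudate_pseudoreps
    masses = np.exp(rng_geom.normal(math.log(MEAN_ROOT_MASS_G), ROOT_MASS_SD_LOG, n_slots))

    ex_rows, trait_rows = [], []
    slot = 0
    for ai in range(design.n_arrays_per_treatment):
        for tp in tps:
            date = TIMEPOINT_DATES.get(tp, BAG_INSTALL_DATE)
            for rep in range(design.n_exudate_pseudoreps):
                mass = float(masses[slot])
                slot += 1
                box = rep // 2 + 1
                for trt in TREATMENTS:
                    arr = ids[trt][ai]
                    noise = {v: float(_lognoise(rng_ex, cv, ())) for v in
                             ("c_exudation", "n_exudation", "srl", "branching",
                              "tissue_c", "tissue_n")}
                    val = {v: _model_value(effects, v, trt, arr, tp, array_effects, noise[v])
                           for v in noise}
                    srl = val["srl"]  # m per g
                    length_mm = srl * mass * 1000.0
                    branch_points = int(round(val["branching"] * length_mm))
                    area_mm2 = math.pi * ROOT_DIAMETER_MM * length_mm
                    tissue_c = min(val["tissue_c"], 100.0)
                    tissue_n = min(val["tissue_n"], 100.0)
                    sid = f"{arr}-{tp}-B{box}-R{rep % 2 + 1}"
                    blank_c = effects.blank_fraction * (
                        effects.baseline_mean["c_exudation"]
                        * effects.seasonal("c_exudation", tp) * MEAN_ROOT_MASS_G
                    )
                    blank_n = effects.blank_fraction * (
                        effects.baseline_mean["n_exudation"]
                        * effects.seasonal("n_exudation", tp) * MEAN_ROOT_MASS_G
                    )
                    ex_rows.append({
                        "sample_id": sid, "array_id": arr, "treatment": trt,
                        "timepoint": tp, "collection_date": date.isoformat(),
                        "box_id": f"{arr}-B{box}", "is_blank": False,
                        "solution_C_ug": val["c_exudation"] * mass * 1.0 + blank_c,
                        "solution_N_ug": val["n_exudation"] * mass * 1.0 + blank_n,
                        "root_dry_mass_g": mass,
                        "root_surface_area_mm2": area_mm2,
                        "duration_d": 1.0,
                    })
                    trait_rows.append({
                        "sample_id": sid, "array_id": arr, "treatment": trt,
                        "timepoint": tp, "total_length_mm": length_mm,
                        "branch_points": branch_points, "dry_mass_g": mass,
                        "surface_area_mm2": area_mm2,
                        "tissue_C_pct": tissue_c, "tissue_N_pct": tissue_n,
                    })

    # blanks: one rootless syringe per box and timepoint, background only
    blank_rows = []
    for trt in TREATMENTS:
        for arr in ids[trt]:
            for tp in tps:
                date = TIMEPOINT_DATES.get(tp, BAG_INSTALL_DATE)
                for box in range(1, n_boxes + 1):
                    blank_c = effects.blank_fraction * (
                        effects.baseline_mean["c_exudation"]
                        * effects.seasonal("c_exudation", tp) * MEAN_ROOT_MASS_G
                    )
                    blank_n = effects.blank_fraction * (
                        effects.baseline_mean["n_exudation"]
                        * effects.seasonal("n_exudation", tp) * MEAN_ROOT_MASS_G
                    )
                    blank_rows.append({
                        "sample_id": f"{arr}-{tp}-B{box}-blank", "array_id": arr,
                        "treatment": trt, "timepoint": tp,
                        "collection_date": date.isoformat(),
                        "box_id": f"{arr}-B{box}", "is_blank": True,
                        "solution_C_ug": blank_c, "solution_N_ug": blank_n,
                        "root_dry_mass_g": np.nan, "root_surface_area_mm2": np.nan,
                        "duration_d": 1.0,
                    })

    exudates = pd.DataFrame(ex_rows + blank_rows)
    traits = pd.DataFrame(trait_rows)

    bio_rows = []
    for trt in TREATMENTS:
        for arr in ids[trt]:
            for tp in tps:
                date = TIMEPOINT_DATES.get(tp, BAG_INSTALL_DATE)
                total = _model_value(
                    effects, "fine_root_biomass", trt, arr, tp, array_effects,
                    float(_lognoise(rng_bio, cv, ())),
                )
                bio_rows.append({
                    "array_id": arr, "treatment": trt, "timepoint": tp,
                    "census_date": date.isoformat(),
                    "biomass_lt1mm_g_m2": 0.6 * total,
                    "biomass_1to2mm_g_m2": 0.4 * total,
                })
    biomass = pd.DataFrame(bio_rows)

    truth = SyntheticTruth(
        true_rr={
            "c_exudation": effects.true_rr["c_exudation"],
            "n_exudation": effects.true_rr["n_exudation"],
            "srl": effects.true_rr["srl"],
            "branching": effects.true_rr["branching"],
            "fine_root_biomass": effects.true_rr["fine_root_biomass"],
            "exudate_cn": effects.true_rr["c_exudation"] - effects.true_rr["n_exudation"],
            "root_cn": effects.true_rr["tissue_c"] - effects.true_rr["tissue_n"],
        },
        array_effects=array_effects,
    )
    return {"exudates": exudates, "root_traits": traits, "biomass": biomass}, truth


# ---------------------------------------------------------------------------
# ingrowth bags
# ---------------------------------------------------------------------------

def _quarter_bounds() -> list[tuple[dt.date, dt.date]]:
    bounds = [BAG_INSTALL_DATE, *BAG_3MO_COLLECTIONS]
    return list(zip(bounds[:-1], bounds[1:]))


def bag_biomass(
    install: dt.date, collect: dt.date, mu: float, production: dict[str, float]
) -> float:
    """Forward production-decay model: ug biomass per g sand at collection.

    ``production`` maps each quarterly season label to P (ug biomass per g
    sand per day), piecewise-constant over the quarter; ``mu`` is the annual
    first-order loss rate. In the mu -> 0 limit biomass is the plain
    integral of production.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    mu_d = mu / DAYS_PER_YEAR
    total = 0.0
    for season, (q0, q1) in zip(BAG_SEASONS, _quarter_bounds()):
        a, b = max(q0, install), min(q1, collect)
        if b <= a:
            continue
        p = production[season]
        if mu_d < 1e-12:
            total += p * (b - a).days
        else:
            total += (p / mu_d) * (
                math.exp(-mu_d * (collect - b).days) - math.exp(-mu_d * (collect - a).days)
            )
    return total


def measured_production_rr(effects: EffectSpec) -> float:
    """The estimand of the quarterly-bag production measurement.

    Net accrual over a quarter reflects production discounted by within-bag
    decay, so the measured-production response ratio depends on both P and
    mu; this computes it exactly from the generating parameters.
    """
    rates = {t: [] for t in TREATMENTS}
    for trt, mu in ((AMBIENT, effects.true_mu_ambient), (ELEVATED, effects.true_mu_elevated)):
        for season, (q0, q1) in zip(BAG_SEASONS, _quarter_bounds()):
            prod = {s: effects.true_production[s][trt] for s in BAG_SEASONS}
            b = bag_biomass(q0, q1, mu, prod)
            rates[trt].append(b / (q1 - q0).days)
    return math.log(np.mean(rates[ELEVATED]) / np.mean(rates[AMBIENT]))


def generate_bags(
    design: DesignSpec, effects: EffectSpec
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Staggered ingrowth-bag table: 3-mo x4, 6-mo x2, 12-mo x1 per location.

    Biomass follows the production-decay model; multiplicative lognormal
    noise (CV = residual_cv) is applied last; the output records ergosterol
    (ug per g sand), the inverse of the biomass conversion, so downstream
    code always exercises the conversion step.
    """
    if effects.true_mu_ambient <= 0 or effects.true_mu_elevated <= 0:
        raise ValueError("turnover coefficients must be positive")
    rng = _rng(design.seed, "bags")
    ids = _array_ids(design)
    mu_by_trt = {AMBIENT: effects.true_mu_ambient, ELEVATED: effects.true_mu_elevated}
    rows = []
    for trt in TREATMENTS:
        prod = {s: effects.true_production[s][trt] for s in BAG_SEASONS}
        mu = mu_by_trt[trt]
        for arr in ids[trt]:
            for loc in range(1, design.n_bag_locations + 1):
                schedule = []
                prev = BAG_INSTALL_DATE
                for c in BAG_3MO_COLLECTIONS:
                    schedule.append(("3mo", prev, c))
                    prev = c
                schedule.append(("6mo", BAG_INSTALL_DATE, BAG_T1))
                schedule.append(("6mo", BAG_T1, BAG_T2))
                schedule.append(("12mo", BAG_INSTALL_DATE, BAG_T2))
                for k, (cls, install, collect) in enumerate(schedule):
                    b = bag_biomass(install, collect, mu, prod)
                    b *= float(_lognoise(rng, effects.residual_cv, ()))
                    erg = b / 1000.0 * ERGOSTEROL_PER_MG_BIOMASS  # ug erg per g sand
                    rows.append({
                        "bag_id": f"{arr}-L{loc}-{cls}-{collect.isoformat()}",
                        "array_id": arr, "treatment": trt, "location_id": f"L{loc}",
                        "duration_class": cls,
                        "install_date": install.isoformat(),
                        "collect_date": collect.isoformat(),
                        "ergosterol_ug_per_g": erg,
                        "sand_mass_g": SAND_MASS_G,
                    })
    bags = pd.DataFrame(rows)
    truth = SyntheticTruth(
        true_rr={
            "ecm_turnover": math.log(effects.true_mu_elevated / effects.true_mu_ambient),
            "ecm_production": measured_production_rr(effects),
        },
        true_mu={AMBIENT: effects.true_mu_ambient, ELEVATED: effects.true_mu_elevated},
    )
    return bags, truth


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------

def _feature_meta(rng: np.random.Generator, ids: list[str]) -> pd.DataFrame:
    n = len(ids)
    return pd.DataFrame({
        "feature_id": ids,
        "mz": np.round(rng.uniform(80.0, 1200.0, n), 4),
        "rt": np.round(rng.uniform(0.5, 12.0, n), 3),
        "mode": rng.choice(["positive", "negative"], n),
    })


def _draw_effects(
    rng: np.random.Generator, spec: MetabolomeSpec, feature_ids: list[str]
) -> dict[str, float]:
    n_aff = int(round(spec.affected_fraction * len(feature_ids)))
    if spec.affected_fraction > 0 and n_aff < 1:
        warnings.warn("affected_fraction rounds below one feature; using 1")
        n_aff = 1
    chosen = rng.choice(len(feature_ids), size=n_aff, replace=False)
    lo, hi = spec.fold_range
    out = {}
    for i in chosen:
        mag = math.exp(rng.uniform(math.log(lo), math.log(hi))) if hi > lo else lo
        sign = 1.0 if rng.random() < spec.prob_accumulated else -1.0
        out[feature_ids[int(i)]] = mag if sign > 0 else -mag
    return out


def _compartment_matrix(
    rng: np.random.Generator,
    spec: MetabolomeSpec,
    features: pd.DataFrame,
    compartment: str,
    assigned: dict[str, float],
) -> FeatureMatrix:
    n = len(features)
    ns = spec.n_samples_per_group
    treatments = [AMBIENT] * ns + [ELEVATED] * ns
    sample_ids = [f"{compartment[:2]}-{t[:1]}{i + 1:02d}" for i, t in enumerate(treatments)]
    masses = np.exp(rng.normal(math.log(MEAN_ROOT_MASS_G), ROOT_MASS_SD_LOG, 2 * ns))
    base = np.exp(rng.normal(math.log(1e4), 1.0, n))
    effect = np.ones(n)
    for idx, fid in enumerate(features["feature_id"]):
        f = assigned.get(fid)
        if f is not None:
            effect[idx] = f if f >= 1 else -1.0 / f
    noise = np.exp(rng.normal(0.0, spec.noise_sd_log, (n, 2 * ns)))
    elevated = np.array([t == ELEVATED for t in treatments])
    normalized = base[:, None] * noise * np.where(elevated[None, :], effect[:, None], 1.0)
    abundance = normalized * masses[None, :]
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "treatment": treatments,
        "compartment": compartment,
        "root_dry_mass_g": masses,
    })
    return FeatureMatrix(features.reset_index(drop=True), samples, abundance)


def generate_feature_matrices(
    spec: MetabolomeSpec, seed: int
) -> tuple[FeatureMatrix, FeatureMatrix, SyntheticTruth]:
    """Paired (roots, exudates) feature matrices with shared-ion structure.

    The first ``round(shared_fraction * n_features)`` exudate features also
    occur in roots with identical (m/z, RT, mode) keys; the root matrix is
    topped up with root-exclusive ions to the same total. Affected features
    are drawn independently per compartment, without replacement, with
    signed folds log-uniform over ``fold_range``.
    """
    rng_truth = _rng(seed, "metabolome_truth")
    n = spec.n_features
    n_shared = int(round(spec.shared_fraction * n))
    ex_ids = [f"F{i:05d}" for i in range(n)]
    root_ids = ex_ids[:n_shared] + [f"R{i:05d}" for i in range(n - n_shared)]
    ex_meta = _feature_meta(rng_truth, ex_ids)
    root_meta = pd.concat(
        [ex_meta.iloc[:n_shared], _feature_meta(rng_truth, root_ids[n_shared:])],
        ignore_index=True,
    )
    aff_ex = _draw_effects(rng_truth, spec, ex_ids)
    aff_root = _draw_effects(rng_truth, spec, root_ids)
    roots = _compartment_matrix(_rng(seed, "metabolome_roots"), spec, root_meta, "root", aff_root)
    exudates = _compartment_matrix(
        _rng(seed, "metabolome_exudates"), spec, ex_meta, "exudate", aff_ex
    )
    truth = SyntheticTruth(affected_features={"root": aff_root, "exudate": aff_ex})
    return roots, exudates, truth


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------

def generate_dataset(
    design: DesignSpec, effects: EffectSpec, metabolome: MetabolomeSpec
) -> tuple[dict, SyntheticTruth]:
    """All five input tables plus merged ground truth."""
    tables, truth_m = generate_measurements(design, effects)
    bags, truth_b = generate_bags(design, effects)
    roots_fm, exudates_fm, truth_f = generate_feature_matrices(metabolome, design.seed)
    tables["bags"] = bags
    tables["metabolome_roots"] = roots_fm
    tables["metabolome_exudates"] = exudates_fm
    return tables, truth_m.merge(truth_b).merge(truth_f)


def write_dataset(tables: dict, truth: SyntheticTruth, outdir: str | Path) -> None:
    """Serialize the dataset: CSV tables, CSV feature matrices, JSON truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("exudates", "root_traits", "biomass", "bags"):
        tables[name].to_csv(out / f"{name}.csv", index=False)
    for name in ("metabolome_roots", "metabolome_exudates"):
        tables[name].to_csv(out / f"{name}_features.csv", out / f"{name}_samples.csv")
    truth.to_json(out / "truth.json")
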