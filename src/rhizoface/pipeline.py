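"""End-to-end orchestration: generate or load tables, run every stage,
write per-stage CSVs and one deterministic JSON summary.

Stage order: synthetic generation (optional) -> exudation fluxes -> root
traits -> ectomycorrhizal production and turnover -> annual response ratios
-> metabolomics -> correlation networks and treatment tests. Any stage
failure aborts with the stage name attached. Reruns with the same config
and seed produce byte-identical summaries (no timestamps enter outputs).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AMBIENT, ELEVATED, RR_VARIABLES, RunConfig
from . import exudation, mycorrhiza, root_traits, stats, synthetic
from . import metabolomics as metab
from .response_ratio import annual_rr_table

NETWORK_VARIABLES = ("c_exudation", "n_exudation", "srl", "branching", "ecm_production")
KEY_PAIRS = (
    ("c_exudation", "ecm_production"),
    ("branching", "ecm_production"),
    ("branching", "c_exudation"),
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_tables(indir: Path) -> dict:
    tables = {
        name: pd.read_csv(indir / f"{name}.csv")
        for name in ("exudates", "root_traits", "biomass", "bags")
    }
    for name in ("metabolome_roots", "metabolome_exudates"):
        tables[name] = metab.FeatureMatrix.from_csv(
            indir / f"{name}_features.csv", indir / f"{name}_samples.csv"
        )
    return tables


def _treatment_split(df: pd.DataFrame, col: str) -> tuple[np.ndarray, np.ndarray]:
    e = df.loc[df["treatment"] == ELEVATED, col].dropna().to_numpy()
    a = df.loc[df["treatment"] == AMBIENT, col].dropna().to_numpy()
    return e, a


def assemble_rr_samples(
    rates: pd.DataFrame,
    traits: pd.DataFrame,
    biomass: pd.DataFrame,
    production: pd.DataFrame,
    turnover_result: dict,
    pooling: str = "pseudoreplicate",
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Annual (elevated, ambient) pools for each forest-plot variable.

    Default pooling is the grand pool of pseudoreplicate observations across
    timepoints within each treatment; ``array_mean`` pools array means
    instead (one value per array). Turnover is always at array level — that
    is the native resolution of the estimator.
    """
    sources = {
        "c_exudation": (rates, "C_rate_ug_g_d"),
        "n_exudation": (rates, "N_rate_ug_g_d"),
        "exudate_cn": (rates, "CN_ratio"),
        "srl": (traits, "srl_m_per_g"),
        "branching": (traits, "branching_per_mm"),
        "root_cn": (traits, "tissue_cn"),
        "ecm_production": (production, "production_ug_g_d"),
    }
    bio = biomass.copy()
    bio["total_g_m2"] = bio["biomass_lt1mm_g_m2"] + bio["biomass_1to2mm_g_m2"]
    sources["fine_root_biomass"] = (bio, "total_g_m2")

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for var, (df, col) in sources.items():
        if pooling == "array_mean":
            grouped = df.groupby(["treatment", "array_id"])[col].mean().reset_index()
            out[var] = _treatment_split(grouped, col)
        else:
            out[var] = _treatment_split(df, col)
    per_array = turnover_result["per_array"]
    out["ecm_turnover"] = _treatment_split(per_array, "mu")
    return out


def array_mean_table(samples_by_var: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Array-level annual means of the network variables, one row per array."""
    frames = []
    for var, (df, col) in samples_by_var.items():
        g = df.groupby(["array_id", "treatment"])[col].mean().rename(var)
        frames.append(g)
    return pd.concat(frames, axis=1).reset_index()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle as a dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    try:
        if config.input_dir is None:
            design = config.design.model_copy(update={"seed": config.seed})
            tables, truth = synthetic.generate_dataset(
                design, config.effects, config.metabolome
            )
            synthetic.write_dataset(tables, truth, outdir / "inputs")
        else:
            tables = _load_tables(Path(config.input_dir))
            truth = None
    except Exception as e:  # noqa: BLE001
        raise StageError("synthetic_data", e) from e

    # --- exudation --------------------------------------------------------
    try:
        rates = exudation.exudation_rates(tables["exudates"], tables["biomass"])
    except Exception as e:  # noqa: BLE001
        raise StageError("exudation.areal_rate" if "biomass" in str(e) else "exudation", e) from e

    # --- root traits ------------------------------------------------------
    try:
        traits = root_traits.derive_traits(tables["root_traits"])
    except Exception as e:  # noqa: BLE001
        raise StageError("root_traits", e) from e

    # --- mycorrhiza -------------------------------------------------------
    try:
        bags = tables["bags"]
        production = mycorrhiza.production_rate(
            bags[bags["duration_class"] == "3mo"], config.ergosterol_conversion
        )
        turn = mycorrhiza.estimate_turnover(bags, config.ergosterol_conversion)
    except Exception as e:  # noqa: BLE001
        raise StageError("mycorrhiza", e) from e

    # --- response ratios --------------------------------------------------
    try:
        samples = assemble_rr_samples(
            rates, traits, tables["biomass"], production, turn, config.rr_pooling
        )
        rr = annual_rr_table(samples, required=RR_VARIABLES)
        rr = rr.set_index("variable").loc[list(RR_VARIABLES)].reset_index()
    except Exception as e:  # noqa: BLE001
        raise StageError("response_ratio", e) from e

    # --- per-timepoint treatment tests ------------------------------------
    try:
        wilcoxon = []
        for tp, grp in production.groupby(
            production["collect_date"].astype(str), sort=True
        ):
            e, a = _treatment_split(grp, "production_ug_g_d")
            res = stats.wilcoxon_rank_sum(e, a)
            wilcoxon.append({"collection": tp, "p": res.p_value, "method": res.method})
        perm = {}
        for var in ("c_exudation", "branching", "srl"):
            src = rates if var == "c_exudation" else traits
            col = {"c_exudation": "C_rate_ug_g_d", "branching": "branching_per_mm",
                   "srl": "srl_m_per_g"}[var]
            g = src.groupby(["treatment", "array_id"])[col].mean().reset_index()
            e, a = _treatment_split(g, col)
            r = stats.array_permutation_test(e, a)
            perm[var] = {"p": r.p_value, "note": r.note}
    except Exception as e:  # noqa: BLE001
        raise StageError("stats_core.tests", e) from e

    # --- correlation networks ---------------------------------------------
    try:
        net_sources = {
            "c_exudation": (rates, "C_rate_ug_g_d"),
            "n_exudation": (rates, "N_rate_ug_g_d"),
            "srl": (traits, "srl_m_per_g"),
            "branching": (traits, "branching_per_mm"),
            "ecm_production": (production, "production_ug_g_d"),
        }
        arr_tab = array_mean_table(net_sources)
        networks = {"pooled": stats.correlation_network(
            arr_tab[list(NETWORK_VARIABLES)], config.correlation_threshold)}
        for trt in (AMBIENT, ELEVATED):
            sub = arr_tab[arr_tab["treatment"] == trt]
            networks[trt] = stats.correlation_network(
                sub[list(NETWORK_VARIABLES)], config.correlation_threshold
            )
        slopes = [stats.pairwise_slope(arr_tab, x, y) for x, y in KEY_PAIRS]
    except Exception as e:  # noqa: BLE001
        raise StageError("stats_core.network", e) from e

    # --- metabolomics ------------------------------------------------------
    try:
        fm_roots = tables["metabolome_roots"]
        fm_ex = tables["metabolome_exudates"]
        res_roots = metab.per_feature_test(
            fm_roots, config.alpha, config.fdr, config.pseudocount
        )
        res_ex = metab.per_feature_test(fm_ex, config.alpha, config.fdr, config.pseudocount)
        shared = metab.shared_features(
            fm_roots, fm_ex, config.mz_tol_ppm, config.rt_tol_min, res_roots, res_ex
        )
        ordinations = {}
        for name, fm in (("root", fm_roots), ("exudate", fm_ex)):
            for mode in sorted(fm.features["mode"].unique()):
                keep = (fm.features["mode"] == mode).to_numpy()
                sub = metab.FeatureMatrix(
                    fm.features[keep].reset_index(drop=True), fm.samples,
                    fm.abundance[keep],
                )
                transformed, dropped = metab.normalize_and_scale(sub, config.pseudocount)
                ord_ = metab.pca_ordination(transformed, n_components=2)
                ordinations[f"{name}_{mode}"] = {
                    "explained_pct": [float(x) for x in ord_["explained_pct"][:2]],
                    "n_features_dropped": dropped,
                }
    except Exception as e:  # noqa: BLE001
        raise StageError("metabolomics", e) from e

    # --- outputs -----------------------------------------------------------
    rates.to_csv(outdir / "exudation_rates.csv", index=False)
    traits.to_csv(outdir / "root_traits_derived.csv", index=False)
    production.to_csv(outdir / "ecm_production.csv", index=False)
    turn["per_array"].to_csv(outdir / "ecm_turnover_arrays.csv", index=False)
    rr.to_csv(outdir / "annual_response_ratios.csv", index=False)
    res_roots.to_csv(outdir / "metabolome_root_results.csv", index=False)
    res_ex.to_csv(outdir / "metabolome_exudate_results.csv", index=False)
    for name, net in networks.items():
        net.to_edge_csv(outdir / f"network_{name}.csv")

    summary = {
        "response_ratios": {
            row["variable"]: {
                "rr": row["rr"], "v": row["v"], "fold": row["fold"],
                "ci": [row["ci_low"], row["ci_high"]],
                "significant": bool(row["significant"]),
            }
            for _, row in rr.iterrows()
        },
        "turnover": turn["summary"],
        "wilcoxon_production_by_timepoint": wilcoxon,
        "array_permutation": perm,
        "metabolome": {
            "exudate": metab.classification_summary(res_ex),
            "root": metab.classification_summary(res_roots),
            "n_shared": shared["n_shared"],
            "n_shared_significant": shared.get("n_shared_significant"),
            "ordination": ordinations,
        },
        "networks": {
            name: {"n_edges": int(len(net.edges)),
                   "edges": net.edges.to_dict("records")}
            for name, net in networks.items()
        },
        "key_pair_slopes": slopes,
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "note": "array_permutation is an exact array-level permutation test, "
                    "not a mixed-model fit; RR significance uses a normal CI from sqrt(v)",
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)

    return {
        "rates": rates, "traits": traits, "production": production,
        "turnover": turn, "rr": rr, "networks": networks, "summary": summary,
        "truth": truth, "metabolome": {"root": res_roots, "exudate": res_ex, "shared": shared},
    }


def demo(output_dir, seed: int = 0) -> dict:
    """One-command demonstration at study-like parameter values."""
    config = RunConfig(output_dir=Path(output_dir), seed=seed)
    return run_pipeline(config)
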