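"""Untargeted metabolomics feature-table analysis.

Works on feature-by-sample abundance matrices (LC-MS ions with m/z,
retention time and ionization mode) for two compartments, roots and root
exudates. The stages mirror the standard workflow for such tables:
normalization to the root dry mass behind each sample, log transform and
unit-variance scaling for ordination, a rank-based (Kruskal-Wallis) test
per feature for the CO2 treatment effect, signed-fold classification into
accumulated / depleted / unchanged, and tolerance-based matching of shared
ions between compartments.

No multiplicity correction is applied by default — feature counts are
reported at raw p < alpha — with Benjamini-Hochberg FDR available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

FEATURE_META = ("feature_id", "mz", "rt", "mode")
SAMPLE_META = ("sample_id", "treatment", "compartment", "root_dry_mass_g")


@dataclass
class FeatureMatrix:
    """Features x samples abundance with ion and sample metadata."""

    features: pd.DataFrame  # columns FEATURE_META
    samples: pd.DataFrame  # columns SAMPLE_META
    abundance: np.ndarray  # shape (n_features, n_samples), non-negative

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        nf, ns = self.abundance.shape
        if nf != len(self.features) or ns != len(self.samples):
            raise ValueError("abundance shape does not match metadata")
        if not np.all(np.isfinite(self.abundance)):
            raise ValueError("abundance must be finite")
        dup = self.features.duplicated(["feature_id", "mode"])
        if dup.any():
            raise ValueError("feature ids must be unique within an ionization mode")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        trt = self.samples["treatment"].to_numpy()
        return trt == "elevated", trt == "ambient"

    def to_csv(self, features_path, samples_path) -> None:
        wide = self.features.copy()
        for j, sid in enumerate(self.samples["sample_id"]):
            wide[sid] = self.abundance[:, j]
        wide.to_csv(features_path, index=False)
        self.samples.to_csv(samples_path, index=False)

    @classmethod
    def from_csv(cls, features_path, samples_path) -> "FeatureMatrix":
        wide = pd.read_csv(features_path)
        samples = pd.read_csv(samples_path)
        meta = wide[list(FEATURE_META)]
        abundance = wide[samples["sample_id"].tolist()].to_numpy(dtype=float)
        return cls(meta, samples, abundance)


def mass_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each sample's abundances by its root dry mass (g)."""
    mass = fm.samples["root_dry_mass_g"].to_numpy(dtype=float)
    if np.any(mass <= 0) or np.any(np.isnan(mass)):
        raise ValueError("every sample needs a positive root dry mass")
    return replace(fm, abundance=fm.abundance / mass[None, :])


def normalize_and_scale(
    fm: FeatureMatrix, pseudocount: float = 1.0
) -> tuple[FeatureMatrix, int]:
    """Mass-normalize, ln(x + pseudocount), then unit-variance scale.

    Scaling is per feature (center to zero mean, divide by SD across
    samples). Zero-variance features carry no contrast and are dropped;
    the count of dropped features is returned.
    """
    normed = mass_normalize(fm)
    logged = np.log(normed.abundance + pseudocount)
    sd = logged.std(axis=1, ddof=0)
    # tolerance absorbs float residue of constant features after the log
    keep = sd > 1e-10 * np.maximum(1.0, np.abs(logged).max(axis=1))
    n_dropped = int((~keep).sum())
    logged = logged[keep]
    scaled = (logged - logged.mean(axis=1, keepdims=True)) / logged.std(
        axis=1, ddof=0, keepdims=True
    )
    out = FeatureMatrix(normed.features[keep].reset_index(drop=True), normed.samples, scaled)
    return out, n_dropped


def pca_ordination(fm: FeatureMatrix, n_components: int | None = None) -> dict:
    """Sample ordination of a transformed matrix (samples as observations).

    Returns per-sample scores and the percent variance explained by each
    component; component count is capped by the matrix rank.
    """
    if fm.n_samples < 3 or fm.n_features < 2:
        raise ValueError("need >= 3 samples and >= 2 features for ordination")
    X = fm.abundance.T  # samples x features
    rank_cap = min(fm.n_samples - 1, fm.n_features)
    k = rank_cap if n_components is None else min(n_components, rank_cap)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    pct = 100.0 * pca.explained_variance_ratio_
    out = fm.samples.copy()
    for i in range(scores.shape[1]):
        out[f"Dim{i + 1}"] = scores[:, i]
    return {"scores": out, "explained_pct": pct}


def _kruskal_h_two_groups(abundance: np.ndarray, mask_e: np.ndarray, mask_a: np.ndarray):
    """Vectorized tie-corrected Kruskal-Wallis H for a two-group design."""
    X = abundance[:, mask_e | mask_a]
    ne, na = int(mask_e.sum()), int(mask_a.sum())
    n = ne + na
    # ranks per feature across the pooled samples
    ranks = sps.rankdata(X, axis=1)
    # reorder columns so elevated come first
    order = np.concatenate([np.where(mask_e[mask_e | mask_a])[0], np.where(mask_a[mask_e | mask_a])[0]])
    ranks = ranks[:, order]
    r_e = ranks[:, :ne].sum(axis=1)
    r_a = ranks[:, ne:].sum(axis=1)
    h = 12.0 / (n * (n + 1)) * (r_e**2 / ne + r_a**2 / na) - 3 * (n + 1)
    # tie correction per feature
    tie = np.ones(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(X[i], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            tie[i] = 1.0 - float(np.sum(t**3 - t)) / (n**3 - n)
    degenerate = tie <= 0  # all observations tied
    h = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, tie))
    p = np.where(degenerate, 1.0, sps.chi2.sf(h, df=1))
    return h, p


def signed_fold(mean_e: float, mean_a: float) -> float:
    """mean_e/mean_a as a signed fold: r if r >= 1 else -1/r."""
    if mean_a <= 0 or mean_e <= 0:
        raise ValueError("signed_fold needs positive group summaries")
    r = mean_e / mean_a
    return r if r >= 1 else -1.0 / r


def per_feature_test(
    fm: FeatureMatrix,
    alpha: float = 0.05,
    fdr: bool = False,
    pseudocount: float = 1.0,
    use_median: bool = False,
) -> pd.DataFrame:
    """Kruskal-Wallis treatment test and fold classification per feature.

    Runs on mass-normalized (not log/unit-scaled) abundances — the test is
    rank-based, so any monotone transform gives identical p-values. A
    feature is 'accumulated' (signed fold >= 1) or 'depleted' (<= -1) when
    its (raw or, with ``fdr``, BH-adjusted) p-value is below ``alpha``,
    otherwise 'unchanged'. Group summaries are means by default; the
    pseudocount only rescues zero group means in the fold.
    """
    normed = mass_normalize(fm)
    mask_e, mask_a = normed.group_masks()
    if mask_e.sum() < 2 or mask_a.sum() < 2:
        raise ValueError("need >= 2 samples per treatment group")
    h, p = _kruskal_h_two_groups(normed.abundance, mask_e, mask_a)
    center = np.median if use_median else np.mean
    m_e = center(normed.abundance[:, mask_e], axis=1)
    m_a = center(normed.abundance[:, mask_a], axis=1)
    folds = np.array(
        [signed_fold(me if me > 0 else pseudocount, ma if ma > 0 else pseudocount)
         for me, ma in zip(m_e, m_a)]
    )
    p_eff = p
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p_eff = multipletests(p, method="fdr_bh")[1]
    cls = np.where(p_eff < alpha, np.where(folds >= 1, "accumulated", "depleted"), "unchanged")
    out = normed.features.copy()
    out["H"] = h
    out["p_value"] = p
    if fdr:
        out["p_adjusted"] = p_eff
    out["mean_elevated"] = m_e
    out["mean_ambient"] = m_a
    out["signed_fold"] = folds
    out["class"] = cls
    return out


def classification_summary(results: pd.DataFrame) -> dict:
    """Counts and fold ranges of accumulated/depleted features."""
    sig = results[results["class"] != "unchanged"]
    acc = sig[sig["class"] == "accumulated"]
    dep = sig[sig["class"] == "depleted"]
    return {
        "n_features": int(len(results)),
        "n_significant": int(len(sig)),
        "pct_significant": 100.0 * len(sig) / len(results) if len(results) else float("nan"),
        "n_accumulated": int(len(acc)),
        "n_depleted": int(len(dep)),
        "accumulated_fold_range": [float(acc["signed_fold"].min()), float(acc["signed_fold"].max())] if len(acc) else None,
        "depleted_fold_range": [float(dep["signed_fold"].max()), float(dep["signed_fold"].min())] if len(dep) else None,
    }


def shared_features(
    roots: FeatureMatrix,
    exudates: FeatureMatrix,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.1,
    root_results: pd.DataFrame | None = None,
    exudate_results: pd.DataFrame | None = None,
) -> dict:
    """Match ions between compartments within m/z and RT tolerances.

    Only features of the same ionization mode are compared. Matching is
    greedy one-to-one on the smallest combined (ppm, RT) distance. When
    per-feature test results are supplied, the cross-classification of
    significance classes over shared ions is tabulated.
    """
    pairs = []
    for mode in sorted(set(roots.features["mode"]) | set(exudates.features["mode"])):
        rf = roots.features[roots.features["mode"] == mode]
        ef = exudates.features[exudates.features["mode"] == mode]
        if rf.empty or ef.empty:
            continue
        rmz = rf["mz"].to_numpy()[:, None]
        emz = ef["mz"].to_numpy()[None, :]
        ppm = np.abs(rmz - emz) / rmz * 1e6
        drt = np.abs(rf["rt"].to_numpy()[:, None] - ef["rt"].to_numpy()[None, :])
        ok = (ppm <= mz_tol_ppm) & (drt <= rt_tol_min)
        ii, jj = np.where(ok)
        dist = ppm[ii, jj] / mz_tol_ppm + drt[ii, jj] / rt_tol_min
        order = np.argsort(dist, kind="stable")
        used_r, used_e = set(), set()
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if i in used_r or j in used_e:
                continue
            used_r.add(i)
            used_e.add(j)
            pairs.append(
                {"root_feature": rf.iloc[i]["feature_id"],
                 "exudate_feature": ef.iloc[j]["feature_id"],
                 "mode": mode,
                 "ppm": float(ppm[i, j]),
                 "d_rt": float(drt[i, j])}
            )
    matched = pd.DataFrame(pairs, columns=["root_feature", "exudate_feature", "mode", "ppm", "d_rt"])
    out = {
        "matched": matched,
        "n_shared": int(len(matched)),
        "n_root_exclusive": roots.n_features - len(matched),
        "n_exudate_exclusive": exudates.n_features - len(matched),
    }
    if root_results is not None and exudate_results is not None:
        rc = root_results.set_index("feature_id")["class"]
        ec = exudate_results.set_index("feature_id")["class"]
        tab = matched.assign(
            root_class=rc.reindex(matched["root_feature"]).to_numpy(),
            exudate_class=ec.reindex(matched["exudate_feature"]).to_numpy(),
        )
        out["cross_classification"] = (
            tab.groupby(["root_class", "exudate_class"]).size().rename("n").reset_index()
        )
        out["n_shared_significant"] = int(
            ((tab["root_class"] != "unchanged") | (tab["exudate_class"] != "unchanged")).sum()
        )
    return out
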