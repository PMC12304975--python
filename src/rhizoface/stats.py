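"""Nonparametric and correlation machinery shared by the analysis stages.

Small-sample treatment comparisons in a FACE design have very few true
replicates (three arrays per treatment), so the workhorses here are exact:
a tie-aware exact Wilcoxon rank-sum test, and an exact permutation test over
array means used in place of a mixed-model fit. With 3 vs 3 arrays the
permutation p-value cannot go below 2/20 = 0.1; that floor is reported
explicitly rather than hidden.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_LIMIT = 12  # pooled n at or below which the rank-sum test enumerates


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "approximate" | "exact-permutation"
    n: tuple[int, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_rank_sum(x, y, two_sided: bool = True) -> TestResult:
    """Wilcoxon rank-sum test of two independent samples.

    For pooled sizes up to 12 the p-value is computed by tie-aware exhaustive
    enumeration over all C(n, n_x) assignments of the pooled mid-ranks; larger
    samples use the normal approximation with tie and continuity corrections.
    The statistic is the rank sum W of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks under ties
    w_obs = ranks[:nx].sum()

    if n <= EXACT_LIMIT:
        # doubled ranks are integers even with mid-ranks; exact comparison safe
        r2 = np.rint(2 * ranks).astype(np.int64)
        w2_obs = int(np.rint(2 * w_obs))
        lo = hi = 0
        total = 0
        for comb in itertools.combinations(range(n), nx):
            w2 = int(r2[list(comb)].sum())
            lo += w2 <= w2_obs
            hi += w2 >= w2_obs
            total += 1
        if two_sided:
            p = min(1.0, 2.0 * min(lo, hi) / total)
        else:
            p = hi / total
        return TestResult(float(w_obs), p, "exact", (nx, ny))

    mean_w = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:  # every observation tied
        return TestResult(float(w_obs), 1.0, "approximate", (nx, ny), note="all ties")
    d = w_obs - mean_w
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var_w)  # continuity correction
    if two_sided:
        p = float(2 * sps.norm.sf(abs(z)))
    else:
        p = float(sps.norm.sf(z))
    return TestResult(float(w_obs), min(1.0, p), "approximate", (nx, ny))


def array_permutation_test(array_means_e, array_means_a) -> TestResult:
    """Exact two-sided permutation test of a treatment effect over array means.

    Stand-in for a mixed-model treatment test: the replicate unit is the
    array, the statistic is the difference of treatment means, and all
    C(n_e + n_a, n_e) relabellings are enumerated. With 3 vs 3 arrays the
    attainable p-value floor is 0.1 (= 2/20), recorded in ``note``.
    """
    e = np.asarray(array_means_e, dtype=float)
    a = np.asarray(array_means_a, dtype=float)
    if e.size < 2 or a.size < 2:
        raise ValueError("need at least 2 arrays per treatment")
    pooled = np.concatenate([e, a])
    n, ne = pooled.size, e.size
    obs = abs(e.mean() - a.mean())
    count = total = 0
    for comb in itertools.combinations(range(n), ne):
        idx = np.zeros(n, dtype=bool)
        idx[list(comb)] = True
        stat = abs(pooled[idx].mean() - pooled[~idx].mean())
        count += stat >= obs - 1e-12
        total += 1
    floor = 2.0 / total if ne == n - ne else 1.0 / total
    return TestResult(
        float(e.mean() - a.mean()),
        count / total,
        "exact-permutation",
        (e.size, a.size),
        note=f"p-value floor {floor:g} at this design",
    )


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: var_a, var_b, r, p, n
    threshold: float
    excluded: list[str] = field(default_factory=list)  # constant variables

    def to_edge_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)

    def to_dot(self, path) -> None:
        lines = ["graph correlation_network {"]
        lines += [f'  "{n}";' for n in self.nodes]
        for row in self.edges.itertuples():
            style = "dashed" if row.r < 0 else "solid"
            lines.append(
                f'  "{row.var_a}" -- "{row.var_b}" [label="{row.r:.2f}", style={style}];'
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples():
            g.add_edge(row.var_a, row.var_b, r=row.r, p=row.p)
        return g


def correlation_network(table: pd.DataFrame, threshold: float = 0.5) -> CorrelationNetwork:
    """Pearson correlation network over paired observations (array means).

    ``table`` holds one column per variable, one row per paired observation.
    An edge is retained iff |r| >= threshold (absolute value, so negative
    trade-off relationships are kept). Constant variables cannot be
    correlated and are excluded with a log entry in ``excluded``.
    """
    cols = list(table.columns)
    excluded = [c for c in cols if table[c].dropna().nunique() <= 1]
    usable = [c for c in cols if c not in excluded]
    rows = []
    for va, vb in itertools.combinations(usable, 2):
        pair = table[[va, vb]].dropna()
        if len(pair) < 3:
            continue
        r, p = sps.pearsonr(pair[va], pair[vb])
        if abs(r) >= threshold:
            rows.append({"var_a": va, "var_b": vb, "r": float(r), "p": float(p), "n": len(pair)})
    edges = pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "n"])
    return CorrelationNetwork(usable, edges, threshold, excluded)


def pairwise_slope(table: pd.DataFrame, x: str, y: str) -> dict:
    """OLS slope of y on x (array means), for sign checks on key trade-offs."""
    pair = table[[x, y]].dropna()
    if len(pair) < 3:
        raise ValueError(f"need >= 3 paired observations for {x} vs {y}")
    fit = sps.linregress(pair[x], pair[y])
    return {
        "x": x,
        "y": y,
        "slope": float(fit.slope),
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "n": len(pair),
    }


def skew_kurtosis(sample) -> tuple[float, float]:
    """Bias-corrected skewness and excess kurtosis, the normality screen."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        return float("nan"), float("nan")
    g1 = float(sps.skew(x, bias=False))
    g2 = float(sps.kurtosis(x, fisher=True, bias=False))
    return g1, g2
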