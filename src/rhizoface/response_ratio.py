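"""Log response ratios of elevated vs ambient CO2 — the cross-variable currency.

For a response with treatment means Re (elevated) and Ra (ambient),

    RR = ln(Re / Ra),
    v  = sd_e^2 / (n_e * Re^2) + sd_a^2 / (n_a * Ra^2),

with a normal-approximation 95% CI of RR +/- 1.96 sqrt(v). RR = 0 means no
response; RR = 1 an e-fold (~2.7-fold) increase. Folds use the signed
convention: exp(RR) when >= 1, else -1/exp(RR), so a halving is -2.0.

Forest-plot outputs mirror the source figure's convention of +/- v error
bars (an unconventional choice — v is a variance, not an SE); the CI is
emitted alongside and carries the significance call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Z95 = 1.96

#: deviations below this ratio display as fold 1.0 (raw value retained)
FOLD_DISPLAY_EPS = math.log(1.005)


def rr_to_fold(rr: float) -> float:
    """Signed fold change for a log response ratio."""
    if not np.isfinite(rr):
        raise ValueError("RR must be finite")
    r = math.exp(rr)
    return r if r >= 1 else -1.0 / r


@dataclass(frozen=True)
class ResponseRatio:
    variable: str
    rr: float
    re: float
    ra: float
    sd_e: float
    sd_a: float
    n_e: int
    n_a: int
    v: float
    ci_low: float
    ci_high: float
    fold: float
    significant: bool
    display_fold: float = field(default=float("nan"))

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "variable", "rr", "re", "ra", "sd_e", "sd_a", "n_e", "n_a",
            "v", "ci_low", "ci_high", "fold", "significant", "display_fold")}
        return d


def response_ratio_from_stats(
    variable: str, re: float, ra: float, sd_e: float, sd_a: float, n_e: int, n_a: int
) -> ResponseRatio:
    """RR, variance, CI and signed fold from treatment summary statistics."""
    if re <= 0 or ra <= 0:
        raise ValueError(f"{variable}: treatment means must be positive for a log ratio")
    rr = math.log(re / ra)
    v = sd_e**2 / (n_e * re**2) + sd_a**2 / (n_a * ra**2)
    half = Z95 * math.sqrt(v)
    fold = rr_to_fold(rr)
    display = 1.0 if abs(rr) < FOLD_DISPLAY_EPS else fold
    return ResponseRatio(
        variable, rr, re, ra, sd_e, sd_a, n_e, n_a, v,
        rr - half, rr + half, fold, not (rr - half <= 0 <= rr + half), display
    )


def response_ratio(values_e, values_a, variable: str = "") -> ResponseRatio:
    """RR of two samples of positive-mean observations.

    SDs use ddof=1 (0 for singleton samples, making v = 0 a noiseless case
    rather than an error).
    """
    e = np.asarray(values_e, dtype=float)
    a = np.asarray(values_a, dtype=float)
    e, a = e[~np.isnan(e)], a[~np.isnan(a)]
    if e.size == 0 or a.size == 0:
        raise ValueError(f"{variable or 'response_ratio'}: both samples must be non-empty")
    sd_e = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    sd_a = float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    return response_ratio_from_stats(
        variable, float(e.mean()), float(a.mean()), sd_e, sd_a, e.size, a.size
    )


def annual_rr_table(
    variable_samples: dict[str, tuple[np.ndarray, np.ndarray]],
    required: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One RR per variable, in forest-plot order.

    ``variable_samples`` maps a variable name to its (elevated, ambient)
    annual pools — all pseudoreplicate observations across timepoints within
    a treatment (or array means if the caller pooled that way). Variables in
    ``required`` but absent from the mapping are listed in an error rather
    than silently skipped.
    """
    missing = [v for v in required if v not in variable_samples]
    if missing:
        raise ValueError(f"annual_rr_table missing required variables: {missing}")
    rows = [
        response_ratio(e, a, variable=name).as_dict()
        for name, (e, a) in variable_samples.items()
    ]
    return pd.DataFrame(rows)
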