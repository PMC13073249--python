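"""Fixed-effects meta-analysis of hazard ratios across cohorts.

Per-cohort hazard ratios arrive with 95% confidence intervals; standard
errors on the log scale are recovered from the CI width,
SE_i = (ln U_i - ln L_i) / (2 * 1.96), each study is weighted by
w_i = 1/SE_i^2, and the pooled log hazard ratio is the weighted mean with
pooled SE 1/sqrt(sum w_i). Fixed effects (one common true effect) is the
intended regime: with very few cohorts the between-study variance of a
random-effects model cannot be estimated stably.

Two-tailed per-cohort p-values are combined by the weighted Stouffer
Z-method with each p converted to a signed normal quantile so the effect
direction is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: Supported weighting schemes for Stouffer pooling of HR p-values.
STOUFFER_SCHEMES = ("sqrt-n", "n", "inverse-variance")


@dataclass
class PooledHR:
    """Inverse-variance fixed-effects summary of k hazard-ratio studies."""

    pooled_hr: float
    ci_low: float
    ci_high: float
    pooled_se_log: float
    weights_pct: np.ndarray
    k: int
    pooled_p: float | None = None
    stouffer_z: float | None = None


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error of ln(HR) recovered from a 95% CI: (ln U - ln L)/3.92."""
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError(f"CI bounds must be positive, got ({ci_low}, {ci_high})")
    if ci_high < ci_low:
        raise ValueError(f"upper CI bound {ci_high} below lower bound {ci_low}")
    return (np.log(ci_high) - np.log(ci_low)) / (2 * 1.96)


def pool_fixed_effects(studies: Sequence[tuple[float, float, float]]) -> PooledHR:
    """Pool (hr, ci_low, ci_high) triples on the log-HR scale.

    w_i = 1/SE_i^2; pooled lnHR = sum(w_i lnHR_i)/sum(w_i); pooled
    SE = 1/sqrt(sum w_i); the pooled HR and its 95% CI are the
    exponentials. ``weights_pct`` gives each study's share of the total
    weight in percent.
    """
    if len(studies) == 0:
        raise ValueError("at least one study required")
    hrs = np.array([s[0] for s in studies], dtype=float)
    ses = np.array([se_from_ci(s[1], s[2]) for s in studies])
    if np.any(ses == 0):
        raise ValueError("degenerate CI (zero width) gives infinite weight")
    w = 1.0 / ses**2
    log_hr = np.log(hrs)
    pooled_log = float(np.sum(w * log_hr) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    return PooledHR(
        pooled_hr=float(np.exp(pooled_log)),
        ci_low=float(np.exp(pooled_log - 1.96 * pooled_se)),
        ci_high=float(np.exp(pooled_log + 1.96 * pooled_se)),
        pooled_se_log=pooled_se,
        weights_pct=100.0 * w / np.sum(w),
        k=len(studies),
    )


def stouffer_pool(p_values, directions, weights) -> tuple[float, float]:
    """Weighted Stouffer Z combination of two-tailed p-values.

    z_i = sign_i * Phi^-1(1 - p_i/2); Z = sum(w_i z_i)/sqrt(sum w_i^2);
    pooled two-tailed p = 2(1 - Phi(|Z|)). Returns (pooled_p, Z); the
    combined direction is sign(Z).
    """
    p = np.asarray(p_values, dtype=float)
    d = np.sign(np.asarray(directions, dtype=float))
    w = np.asarray(weights, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any(d == 0):
        raise ValueError("each study needs a nonzero direction sign")
    z = d * stats.norm.isf(p / 2)
    Z = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    pooled_p = float(2 * stats.norm.sf(abs(Z)))
    return pooled_p, Z


def pool_hazard_ratios(
    studies: Sequence,
    stouffer_weights: str = "sqrt-n",
) -> PooledHR:
    """Full pooled summary from per-cohort :class:`~stratmeta.survival.HRStudyResult`-like objects.

    Each study must expose ``hr``, ``ci_low``, ``ci_high``, ``p_two_tailed``
    and ``n``. Effect pooling is inverse-variance on ln(HR); p-values are
    Stouffer-combined with the chosen weight scheme (default sqrt(n)),
    directions taken from sign(ln HR_i).
    """
    if stouffer_weights not in STOUFFER_SCHEMES:
        raise ValueError(f"stouffer_weights must be one of {STOUFFER_SCHEMES}")
    pooled = pool_fixed_effects([(s.hr, s.ci_low, s.ci_high) for s in studies])
    n = np.array([s.n for s in studies], dtype=float)
    if stouffer_weights == "sqrt-n":
        w = np.sqrt(n)
    elif stouffer_weights == "n":
        w = n
    else:
        w = 1.0 / np.array([se_from_ci(s.ci_low, s.ci_high) for s in studies]) ** 2
    directions = np.sign(np.log([s.hr for s in studies]))
    directions[directions == 0] = 1.0  # HR exactly 1 contributes z=0 either way
    pooled_p, Z = stouffer_pool([s.p_two_tailed for s in studies], directions, w)
    pooled.pooled_p = pooled_p
    pooled.stouffer_z = Z
    return pooled
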