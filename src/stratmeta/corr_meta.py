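"""Stratum-wise Spearman correlation meta-analysis.

Within each cohort and each marker stratum (LOW/HIGH), the Spearman rank
correlation between the marker gene and every candidate gene is computed
on pairwise-complete observations. Cohort coefficients are pooled on the
Fisher z' scale, z' = atanh(rho) = 0.5*ln((1+rho)/(1-rho)), with weights
n_i - 3 (the reciprocal of the large-sample variance of z'), and the
pooled z' is mapped back with tanh. The pooled standard error is
1/sqrt(sum(n_i - 3)) and the 95% CI is formed on the z' scale then
back-transformed endpoint-wise. Per-cohort two-tailed p-values are
combined by the weighted Stouffer Z-method with the same n-3 weights and
direction signs taken from the cohort rho. Between-cohort heterogeneity
is summarized by Cochran's Q (weighted squared deviations of z' around
the pooled z'), its chi-square p on k-1 df, and I^2 = max(0, (Q-df)/Q)*100.

Coefficients of exactly +/-1 have undefined z'-variance and are excluded
from pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hr_meta import stouffer_pool


@dataclass
class StratumCorrelation:
    """Spearman correlation of one gene with the marker in one cohort stratum."""

    cohort_id: str
    gene: str
    stratum: str
    rho: float
    n: int
    z_prime: float
    weight: float  # n - 3
    p_two_tailed: float


@dataclass
class PooledCorrelation:
    """Fisher-z pooled Spearman coefficient for one gene/stratum across cohorts."""

    gene: str
    stratum: str
    pooled_rho: float
    ci_low: float
    ci_high: float
    pooled_p: float
    k: int
    q_stat: float | None = None
    q_p: float | None = None
    i_squared: float | None = None
    df: int | None = None


def spearman_rho(x, y) -> tuple[float, int, float] | None:
    """Spearman rho with pairwise deletion; returns (rho, n, p) or None.

    Ranks use midranks for ties; the two-tailed p comes from the
    t-approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df. Fewer than 4
    complete pairs, or zero rank variance in either variable, yields None
    (a flagged missing result) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        return None
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return None
    rho, p = stats.spearmanr(xs, ys)
    if not np.isfinite(rho):
        return None
    if abs(rho) > 1 - 1e-12:  # identical rank vectors up to float noise
        rho = float(np.sign(rho))
    return float(rho), n, float(p)


def fisher_z(rho: float) -> float:
    """Fisher's variance-stabilizing transform z' = 0.5*ln((1+r)/(1-r))."""
    if abs(rho) >= 1:
        raise ValueError(f"|rho| = 1 has undefined variance under the Fisher transform (got {rho})")
    return float(np.arctanh(rho))


def inverse_fisher_z(z: float) -> float:
    """Back-transform z' to a correlation coefficient: r = tanh(z')."""
    return float(np.tanh(z))


def heterogeneity(z_values, weights) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p, and I^2 (%) for k study-level z' values."""
    z = np.asarray(z_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    k = len(z)
    if k < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    zbar = np.sum(w * z) / np.sum(w)
    q = float(np.sum(w * (z - zbar) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df=df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return q, q_p, i2


def pool_z(correlations: Sequence[StratumCorrelation]) -> PooledCorrelation:
    """Pool one gene/stratum's cohort correlations on the Fisher z' scale.

    Cohorts with |rho| = 1 or n < 4 must already have been excluded by the
    caller (``cohort_correlations`` never emits them). Heterogeneity fields
    are filled when k >= 2.
    """
    valid = [c for c in correlations if c.n >= 4 and abs(c.rho) < 1]
    if not valid:
        raise ValueError("no valid cohort correlations to pool")
    gene = valid[0].gene
    stratum = valid[0].stratum
    z = np.array([c.z_prime for c in valid])
    w = np.array([c.weight for c in valid], dtype=float)
    pooled_z = float(np.sum(w * z) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    pooled_p, _ = stouffer_pool(
        [c.p_two_tailed for c in valid],
        [1.0 if c.rho >= 0 else -1.0 for c in valid],
        w,
    )
    out = PooledCorrelation(
        gene=gene,
        stratum=stratum,
        pooled_rho=inverse_fisher_z(pooled_z),
        ci_low=inverse_fisher_z(pooled_z - 1.96 * se),
        ci_high=inverse_fisher_z(pooled_z + 1.96 * se),
        pooled_p=pooled_p,
        k=len(valid),
    )
    if len(valid) >= 2:
        out.q_stat, out.q_p, out.i_squared = heterogeneity(z, w)
        out.df = len(valid) - 1
    return out


def stouffer_pool_corr(correlations: Sequence[StratumCorrelation]) -> float:
    """Weighted Stouffer pooled two-tailed p with weights n-3, signs from rho."""
    pooled_p, _ = stouffer_pool(
        [c.p_two_tailed for c in correlations],
        [1.0 if c.rho >= 0 else -1.0 for c in correlations],
        [c.weight for c in correlations],
    )
    return pooled_p


def cohort_correlations(
    cohort_id: str,
    expression: pd.DataFrame,
    labels: pd.Series,
    marker_gene: str,
    genes: Sequence[str],
) -> list[StratumCorrelation]:
    """Per-stratum marker-vs-gene Spearman correlations for one cohort.

    Samples are restricted to those with a stratum label; missing values are
    deleted pairwise per gene, so n (and hence the n-3 weight) can differ
    between genes within one cohort. Genes absent from the cohort, strata
    with fewer than 4 complete pairs, and |rho| = 1 results are skipped.
    """
    out: list[StratumCorrelation] = []
    marker = expression[marker_gene]
    for stratum in sorted(labels.unique()):
        ids = labels.index[labels == stratum]
        m = marker.loc[ids]
        for gene in genes:
            if gene not in expression.columns:
                continue
            res = spearman_rho(m, expression.loc[ids, gene])
            if res is None:
                continue
            rho, n, p = res
            if abs(rho) >= 1:
                continue  # undefined Fisher variance
            out.append(
                StratumCorrelation(
                    cohort_id=cohort_id,
                    gene=gene,
                    stratum=stratum,
                    rho=rho,
                    n=n,
                    z_prime=fisher_z(rho),
                    weight=float(n - 3),
                    p_two_tailed=p,
                )
            )
    return out


def pool_panel(
    per_cohort: Sequence[StratumCorrelation],
) -> dict[tuple[str, str], PooledCorrelation]:
    """Group per-cohort stratum correlations by (gene, stratum) and pool each."""
    groups: dict[tuple[str, str], list[StratumCorrelation]] = {}
    for c in per_cohort:
        groups.setdefault((c.gene, c.stratum), []).append(c)
    return {key: pool_z(vals) for key, vals in groups.items()}
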