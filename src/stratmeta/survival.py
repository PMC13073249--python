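"""Per-cohort survival statistics on stratified samples.

Implements the survival-window filter (records with 0 months or more than
30 months of follow-up removed), Kaplan-Meier curves, the Mantel-Haenszel
log-rank comparison of the HIGH vs LOW marker strata with its
HR = exp((O-E)/V) effect estimate, and a single-covariate Cox
proportional-hazards model for the continuous (non-dichotomized) marker.

The log-rank machinery sums, over distinct event times, the observed
events in the HIGH group (O), their conditional expectation under the
null (E) and the hypergeometric variance (V); the hazard ratio and its
95% CI follow as exp((O-E)/V) and exp((O-E)/V +/- 1.96/sqrt(V)). This is
the classic Mantel-Haenszel/Peto formulation rather than a Cox fit, so
per-cohort results are reproducible from the risk tables alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stratification import HIGH, LOW


@dataclass
class WindowFilterResult:
    """Outcome of the survival-window filter: retained records + removal tallies."""

    records: pd.DataFrame
    n_removed_zero: int
    n_removed_over: int

    @property
    def n_removed(self) -> int:
        return self.n_removed_zero + self.n_removed_over


@dataclass
class HRStudyResult:
    """Mantel-Haenszel hazard ratio (group_a vs group_b) for one cohort."""

    cohort_id: str
    n: int
    hr: float
    ci_low: float
    ci_high: float
    p_two_tailed: float  # from the log-rank chi-square (1 df)
    o_minus_e: float
    variance_v: float
    n_events: int


@dataclass
class CoxResult:
    """Single-covariate Cox fit: log-hazard slope per unit of the covariate."""

    beta: float
    se: float
    hr_per_unit: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    n_iter: int
    flag: str | None = None


def filter_survival_window(
    records: pd.DataFrame, min_months: float = 0.0, max_months: float = 30.0
) -> WindowFilterResult:
    """Retain records with min_months < time <= max_months.

    Zero-month records (events or censorings alike) and records beyond the
    window are removed; the boundary itself (exactly ``max_months``) is
    retained. Removal counts are reported by reason.
    """
    t = records["os_months"].to_numpy(dtype=float)
    at_floor = t <= min_months
    over = (~at_floor) & (t > max_months)
    keep = ~(at_floor | over)
    return WindowFilterResult(
        records=records.loc[keep],
        n_removed_zero=int(at_floor.sum()),
        n_removed_over=int(over.sum()),
    )


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) estimate with a risk table.

    Returns one row per distinct observed time with columns ``at_risk``,
    ``events``, ``censored`` and ``survival`` (the estimate just after that
    time). Tied events are processed before censorings at the same time, so
    S(0) = 1 and the curve is non-increasing.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_estimate requires at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    # event_table always contains a t=0 row; drop it unless data sit at 0
    table = kmf.event_table.loc[kmf.event_table.index > 0] if (t > 0).all() else kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "at_risk": table["at_risk"].astype(int),
            "events": table["observed"].astype(int),
            "censored": table["censored"].astype(int),
            "survival": surv.reindex(table.index).to_numpy(),
        }
    )
    out.index.name = "time"
    return out


def logrank_mh(
    times, events, groups, group_a: str = HIGH, group_b: str = LOW, cohort_id: str = ""
) -> HRStudyResult:
    """Mantel-Haenszel log-rank comparison of two strata.

    At each distinct event time the 2x2 table of (group x event) over the
    risk set contributes observed events in ``group_a`` (O), the
    hypergeometric expectation (E) and variance (v). The chi-square
    statistic (O-E)^2/V on 1 df gives the two-tailed p; the hazard ratio is
    exp((O-E)/V) with 95% CI exp((O-E)/V +/- 1.96/sqrt(V)).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    in_a = g == group_a
    in_b = g == group_b
    if not in_a.any() or not in_b.any():
        raise ValueError("both groups must be non-empty")
    mask = in_a | in_b
    t, e, in_a = t[mask], e[mask], in_a[mask]
    if not e.any():
        raise ValueError("at least one event is required")

    O = E = V = 0.0
    for u in np.unique(t[e]):
        at_risk = t >= u
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        now = e & (t == u)
        d = now.sum()
        d_a = (now & in_a).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if V <= 0:
        raise ValueError("zero log-rank variance: no comparable risk sets")

    log_hr = (O - E) / V
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    half = 1.96 / np.sqrt(V)
    return HRStudyResult(
        cohort_id=cohort_id,
        n=int(mask.sum()),
        hr=float(np.exp(log_hr)),
        ci_low=float(np.exp(log_hr - half)),
        ci_high=float(np.exp(log_hr + half)),
        p_two_tailed=p,
        o_minus_e=float(O - E),
        variance_v=float(V),
        n_events=int(e.sum()),
    )


def _cox_loglik(beta: float, t, e, x, ties: str):
    """Log partial likelihood, score and information for a scalar Cox model."""
    order = np.argsort(-t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    w = np.exp(eta)
    # cumulative sums over the risk set: records sorted by descending time
    cs0 = np.cumsum(w)
    cs1 = np.cumsum(w * x)
    cs2 = np.cumsum(w * x * x)
    ll = u = info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # block [i, j) shares this time; risk set = all records with index < j
        ev = np.arange(i, j)[e[i:j]]
        d = len(ev)
        if d > 0:
            s0, s1, s2 = cs0[j - 1], cs1[j - 1], cs2[j - 1]
            wd = w[ev]
            xd = x[ev]
            ll += float(np.sum(beta * xd))
            u += float(np.sum(xd))
            if ties == "breslow":
                ll -= d * np.log(s0)
                u -= d * s1 / s0
                info += d * (s2 / s0 - (s1 / s0) ** 2)
            else:  # efron
                d0, d1, d2 = wd.sum(), (wd * xd).sum(), (wd * xd * xd).sum()
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    ll -= np.log(a0)
                    u -= a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
        i = j
    return ll, u, info


def cox_continuous(
    times, events, covariate, ties: str = "efron", max_iter: int = 50, tol: float = 1e-9
) -> CoxResult:
    """Fit hazard(t) = h0(t) * exp(beta * x) by Newton iteration on beta.

    Ties among event times are handled by the Efron approximation by
    default (Breslow available). Non-convergence or a monotone partial
    likelihood (covariate perfectly ordering the events) is flagged rather
    than raised; the Wald CI and p use the observed information.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if len(np.unique(x[e])) < 2:
        return CoxResult(
            beta=np.nan, se=np.nan, hr_per_unit=np.nan, ci_low=np.nan, ci_high=np.nan,
            p=np.nan, converged=False, n_iter=0, flag="no information: covariate constant among events",
        )

    beta = 0.0
    flag = None
    converged = False
    it = 0
    ll, u, info = _cox_loglik(beta, t, e, x, ties)
    for it in range(1, max_iter + 1):
        if info <= 1e-12:
            flag = "singular information"
            break
        step = u / info
        new_beta = beta + step
        new_ll, new_u, new_info = _cox_loglik(new_beta, t, e, x, ties)
        halvings = 0
        while not np.isfinite(new_ll) or (new_ll < ll - 1e-12 and halvings < 20):
            step /= 2
            new_beta = beta + step
            new_ll, new_u, new_info = _cox_loglik(new_beta, t, e, x, ties)
            halvings += 1
        beta, ll, u, info = new_beta, new_ll, new_u, new_info
        if abs(u) < tol and abs(step) < 1e-8:
            converged = True
            break
        if abs(beta) > 50:
            flag = "monotone likelihood: |beta| diverging"
            break
    if not converged and flag is None:
        flag = f"did not converge in {max_iter} iterations"

    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    z = beta / se if np.isfinite(se) and se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    with np.errstate(over="ignore"):  # divergent beta: CI bounds may overflow to inf
        return CoxResult(
            beta=float(beta),
            se=float(se),
            hr_per_unit=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.96 * se)),
            ci_high=float(np.exp(beta + 1.96 * se)),
            p=p,
            converged=converged,
            n_iter=it,
            flag=flag,
        )
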