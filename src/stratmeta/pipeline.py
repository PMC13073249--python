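"""End-to-end orchestration: stratify, per-cohort statistics, pooled reports.

Produces the two summary tables the analysis is built around: a pooled
hazard-ratio report (one row per cohort plus a pooled row) and a
differential-correlation report (one row per panel gene with pooled
stratum correlations, delta, heterogeneity and labels, sorted by delta
descending). Both reports are plain DataFrames; the CLI layer handles
formatting and serialization. Re-running with identical inputs and
configuration yields identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import corr_meta, delta_classify, hr_meta, survival
from .cohort_io import CohortData, GenePanel
from .stratification import HIGH, LOW, TRIM_BOTH, assign_strata

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated knobs for a full pipeline run."""

    marker_gene: str = "PROS1"
    trim_fraction: float = 0.05
    trim_mode: str = TRIM_BOTH
    drop_trimmed: bool = False
    window_min_months: float = 0.0
    window_max_months: float = 30.0
    stouffer_weights: str = "sqrt-n"

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.window_max_months <= self.window_min_months:
            raise ValueError("survival window must be non-empty")
        if self.stouffer_weights not in hr_meta.STOUFFER_SCHEMES:
            raise ValueError(f"stouffer_weights must be one of {hr_meta.STOUFFER_SCHEMES}")

    def to_dict(self) -> dict:
        return asdict(self)


def _stratify_all(cohorts: Sequence[CohortData], config: PipelineConfig) -> dict:
    return {
        c.cohort_id: assign_strata(
            c,
            config.marker_gene,
            fraction=config.trim_fraction,
            mode=config.trim_mode,
            drop_trimmed=config.drop_trimmed,
        )
        for c in cohorts
    }


def cohort_hr(cohort: CohortData, labels: pd.Series, config: PipelineConfig) -> survival.HRStudyResult:
    """Window-filter one cohort's survival records and compute its MH hazard ratio."""
    shared = labels.index.intersection(cohort.clinical.index)
    records = cohort.clinical.loc[shared].copy()
    records["stratum"] = labels.loc[shared]
    filt = survival.filter_survival_window(
        records, config.window_min_months, config.window_max_months
    )
    logger.info(
        "cohort %s: removed %d zero-month and %d over-window records",
        cohort.cohort_id, filt.n_removed_zero, filt.n_removed_over,
    )
    kept = filt.records
    return survival.logrank_mh(
        kept["os_months"], kept["event"], kept["stratum"],
        group_a=HIGH, group_b=LOW, cohort_id=cohort.cohort_id,
    )


def run_survival_pipeline(
    cohorts: Sequence[CohortData], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, hr_meta.PooledHR]:
    """Pooled hazard-ratio report: per-cohort rows plus the pooled row.

    Cohorts without survival data are skipped with a warning. Returns the
    report table and the PooledHR object.
    """
    config = config or PipelineConfig()
    usable = []
    for c in cohorts:
        if not c.has_survival:
            logger.warning("cohort %s lacks survival data; skipped from HR pooling", c.cohort_id)
            continue
        usable.append(c)
    if not usable:
        raise ValueError("no cohort with survival data")
    strata = _stratify_all(usable, config)
    studies = [cohort_hr(c, strata[c.cohort_id].labels, config) for c in usable]
    pooled = hr_meta.pool_hazard_ratios(studies, stouffer_weights=config.stouffer_weights)

    rows = [
        {
            "cohort": s.cohort_id,
            "n": s.n,
            "hr": s.hr,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "p": s.p_two_tailed,
            "weight_pct": w,
        }
        for s, w in zip(studies, pooled.weights_pct)
    ]
    rows.append(
        {
            "cohort": "Pooled",
            "n": sum(s.n for s in studies),
            "hr": pooled.pooled_hr,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "p": pooled.pooled_p,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows), pooled


def run_corr_pipeline(
    cohorts: Sequence[CohortData], panel: GenePanel, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Differential-correlation report: one row per panel gene.

    Columns: pooled rho per stratum, delta, direction, pooled p per
    stratum, heterogeneity (Q, Q p, I^2 per stratum reported for the HIGH
    stratum alongside LOW), and the interpretation label. Genes missing a
    stratum are emitted with NaNs and left unclassified. Sorted by delta
    descending.
    """
    config = config or PipelineConfig()
    strata = _stratify_all(cohorts, config)
    per_cohort: list[corr_meta.StratumCorrelation] = []
    for c in cohorts:
        per_cohort.extend(
            corr_meta.cohort_correlations(
                c.cohort_id, c.expression, strata[c.cohort_id].labels,
                config.marker_gene, panel.candidate_genes,
            )
        )
    pooled = corr_meta.pool_panel(per_cohort)

    rows = []
    for gene in panel.candidate_genes:
        low = pooled.get((gene, LOW))
        high = pooled.get((gene, HIGH))
        row: dict = {"gene": gene}
        for stratum, res in (("low", low), ("high", high)):
            row[f"rho_{stratum}"] = res.pooled_rho if res else np.nan
            row[f"p_{stratum}"] = res.pooled_p if res else np.nan
            row[f"q_{stratum}"] = res.q_stat if res else np.nan
            row[f"q_p_{stratum}"] = res.q_p if res else np.nan
            row[f"i2_{stratum}"] = res.i_squared if res else np.nan
        if low is not None and high is not None:
            rec = delta_classify.classify_gene(gene, low.pooled_rho, high.pooled_rho)
            row.update(
                delta_rho=rec.delta_rho,
                direction=rec.direction,
                interpretation=rec.interpretation,
                gate_passed=rec.gate_passed,
            )
        else:
            logger.warning("gene %s missing a stratum in all cohorts; left unclassified", gene)
            row.update(delta_rho=np.nan, direction=None, interpretation=None, gate_passed=None)
        rows.append(row)
    columns = [
        "gene", "rho_low", "rho_high", "delta_rho", "direction", "interpretation",
        "gate_passed", "p_low", "p_high", "q_low", "q_p_low", "i2_low",
        "q_high", "q_p_high", "i2_high",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)[columns]
    return df.sort_values("delta_rho", ascending=False, kind="stable").reset_index(drop=True)
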