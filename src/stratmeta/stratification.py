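"""Low/high stratification of samples by marker-gene expression.

Each cohort is split at its own trimmed mean of marker expression: tail
outliers (default 5% per tail) are removed before averaging so that the
cut-point is robust to extreme values, then every sample with a finite
marker measurement — including the trimmed ones — is labelled HIGH when
its expression is greater than or equal to the threshold and LOW
otherwise. Trimming robustifies the mean; it does not by itself exclude
samples from analysis (a >95th-percentile sample is genuinely "high"),
though callers can opt to drop trimmed samples downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import CohortData

LOW = "LOW"
HIGH = "HIGH"

TRIM_BOTH = "both-tails"
TRIM_UPPER = "upper-tail"


@dataclass
class StratumAssignment:
    """Result of stratifying one cohort by marker expression.

    ``threshold`` is the arithmetic mean of marker expression over the
    retained (non-trimmed) samples. ``labels`` maps each labelled sample to
    LOW/HIGH; with the default policy trimmed samples are labelled too.
    """

    threshold: float
    labels: pd.Series
    trimmed_ids: list
    missing_ids: list
    trim_mode: str
    trim_fraction: float

    @property
    def n_low(self) -> int:
        return int((self.labels == LOW).sum())

    @property
    def n_high(self) -> int:
        return int((self.labels == HIGH).sum())


def trim_outliers(
    values: pd.Series, fraction: float, mode: str = TRIM_BOTH
) -> tuple[pd.Index, pd.Index]:
    """Split samples into (retained, trimmed) by percentile tail trimming.

    Values strictly above the (1-fraction) quantile are trimmed; in
    ``both-tails`` mode values strictly below the ``fraction`` quantile are
    trimmed as well. Quantiles use linear interpolation of order statistics
    (the common spreadsheet percentile convention). Only finite values are
    considered; non-finite entries are excluded from both sets.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError(f"trim fraction must be in [0, 0.5), got {fraction}")
    if mode not in (TRIM_BOTH, TRIM_UPPER):
        raise ValueError(f"unknown trim mode {mode!r}")
    finite = values[np.isfinite(values)]
    if len(finite) < 3:
        raise ValueError(f"need at least 3 finite values to trim, got {len(finite)}")
    arr = finite.to_numpy(dtype=float)
    hi = np.quantile(arr, 1.0 - fraction)
    keep = arr <= hi
    if mode == TRIM_BOTH:
        lo = np.quantile(arr, fraction)
        keep &= arr >= lo
    retained = finite.index[keep]
    trimmed = finite.index[~keep]
    return retained, trimmed


def assign_strata(
    cohort: CohortData,
    marker_gene: str,
    fraction: float = 0.05,
    mode: str = TRIM_BOTH,
    drop_trimmed: bool = False,
) -> StratumAssignment:
    """Compute the trimmed-mean threshold and label every sample LOW/HIGH.

    The threshold is the mean of marker expression over retained samples;
    a sample is HIGH iff its marker expression >= threshold (ties go HIGH).
    Samples with missing marker expression are excluded and recorded.
    With ``drop_trimmed`` the trimmed samples are left unlabelled as well.
    """
    if marker_gene not in cohort.expression.columns:
        raise ValueError(f"marker gene {marker_gene!r} absent from cohort {cohort.cohort_id!r}")
    marker = cohort.expression[marker_gene]
    finite = marker[np.isfinite(marker)]
    missing = marker.index.difference(finite.index)
    retained, trimmed = trim_outliers(finite, fraction, mode)
    threshold = float(finite.loc[retained].mean())
    to_label = retained if drop_trimmed else finite.index
    labels = pd.Series(
        np.where(finite.loc[to_label] >= threshold, HIGH, LOW),
        index=to_label,
        name="stratum",
    )
    return StratumAssignment(
        threshold=threshold,
        labels=labels,
        trimmed_ids=list(trimmed),
        missing_ids=list(missing),
        trim_mode=mode,
        trim_fraction=fraction,
    )
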