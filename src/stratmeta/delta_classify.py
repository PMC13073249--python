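"""Classification of differential correlation between marker strata.

For each candidate gene the statistic is the change in pooled Spearman
correlation between the two marker-expression states,
delta_rho = rho_high - rho_low. Two label sets are assigned:

Direction of change
    |delta| < 0.29 -> "Negligible"; delta <= -0.29 -> "Decreased";
    delta >= 0.29 -> "Increased".

Biological interpretation
    Correlations below 0.3 in magnitude are conventionally read as no/weak
    relationships, so delta bands are interpretable only when at least one
    stratum shows |rho| >= 0.3 (the interpretability gate). When the gate
    fails, or |delta| < 0.60, the gene is labelled "Independent
    correlation". Otherwise the magnitude bands are [0.60, 0.70) "Lower",
    [0.70, 0.80) "Intermediate" and [0.80, 1.00] "High" magnitude change;
    a positive delta >= 0.60 through the gate is labelled "Strengthened".
    Magnitudes above 1 are clamped into the High band (logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

logger = logging.getLogger(__name__)

NEGLIGIBLE = "Negligible"
DECREASED = "Decreased"
INCREASED = "Increased"

INDEPENDENT = "Independent correlation"
STRENGTHENED = "Strengthened"
LOWER = "Lower magnitude Δρ"
INTERMEDIATE = "Intermediate magnitude Δρ"
HIGH_MAG = "High magnitude Δρ"

#: |delta| below this is a negligible direction of change.
DIRECTION_THRESHOLD = 0.29
#: at least one stratum must reach this |rho| for delta bands to be interpretable.
GATE_RHO = 0.30
#: |delta| below this is an independent correlation even through the gate.
BAND_FLOOR = 0.60


@dataclass
class DeltaRhoRecord:
    """One gene's differential-correlation summary (one output-table row)."""

    gene: str
    rho_low: float
    rho_high: float
    delta_rho: float
    direction: str
    interpretation: str
    gate_passed: bool


def delta_rho(rho_low: float, rho_high: float) -> float:
    """delta = rho_high - rho_low (exact subtraction, no rounding)."""
    if not (math.isfinite(rho_low) and math.isfinite(rho_high)):
        raise ValueError(f"rho values must be finite, got ({rho_low}, {rho_high})")
    return rho_high - rho_low


def classify_direction(delta: float) -> str:
    """Direction of change from delta alone."""
    if abs(delta) < DIRECTION_THRESHOLD:
        return NEGLIGIBLE
    return DECREASED if delta < 0 else INCREASED


def classify_interpretation(rho_low: float, rho_high: float, delta: float | None = None) -> str:
    """Interpretation band from the stratum coefficients and delta."""
    if delta is None:
        delta = delta_rho(rho_low, rho_high)
    gate = abs(rho_low) >= GATE_RHO or abs(rho_high) >= GATE_RHO
    m = abs(delta)
    if not gate or m < BAND_FLOOR:
        return INDEPENDENT
    if delta >= BAND_FLOOR:
        return STRENGTHENED
    if m > 1.0:
        logger.warning("delta magnitude %.3f exceeds 1; clamped to the high band", m)
        return HIGH_MAG
    if m < 0.70:
        return LOWER
    if m < 0.80:
        return INTERMEDIATE
    return HIGH_MAG


def classify_gene(gene: str, rho_low: float, rho_high: float) -> DeltaRhoRecord:
    """Full record for one gene."""
    d = delta_rho(rho_low, rho_high)
    return DeltaRhoRecord(
        gene=gene,
        rho_low=rho_low,
        rho_high=rho_high,
        delta_rho=d,
        direction=classify_direction(d),
        interpretation=classify_interpretation(rho_low, rho_high, d),
        gate_passed=abs(rho_low) >= GATE_RHO or abs(rho_high) >= GATE_RHO,
    )


def classify_table(pairs: Sequence[tuple[str, float, float]]) -> list[DeltaRhoRecord]:
    """Classify a panel of (gene, rho_low, rho_high), sorted by delta descending."""
    records = [classify_gene(g, lo, hi) for g, lo, hi in pairs]
    records.sort(key=lambda r: -r.delta_rho)
    return records
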