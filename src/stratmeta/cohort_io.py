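"""Reading, validation and joining of cohort expression and clinical survival tables.

Cohorts arrive as two tab-separated files in the cBioPortal export style:
an expression matrix (either samples-in-rows or the transposed
genes-in-rows layout with a gene-symbol column) and a clinical table with
one row per sample carrying overall-survival months and vital status.
This module parses both, normalizes the vital-status dialects, and joins
them into the :class:`CohortData` container the rest of the pipeline
consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Accepted vital-status tokens (upper-cased) -> event flag (True = deceased).
STATUS_TOKENS = {
    "0:LIVING": False,
    "1:DECEASED": True,
    "LIVING": False,
    "DECEASED": True,
    "ALIVE": False,
    "0": False,
    "1": True,
}

#: Metadata columns that may precede the sample columns in genes-in-rows exports.
_GENE_META_COLUMNS = {"ENTREZ_GENE_ID", "ENTREZ_ID"}


class CohortParseError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class GenePanel:
    """A marker gene plus an ordered panel of candidate genes to correlate with it."""

    marker_gene: str
    candidate_genes: list[str]

    def __post_init__(self) -> None:
        if self.marker_gene in self.candidate_genes:
            raise ValueError(f"marker gene {self.marker_gene!r} must not appear in the candidate panel")
        dupes = _duplicates(self.candidate_genes)
        if dupes:
            raise ValueError(f"duplicate candidate genes: {sorted(dupes)}")


@dataclass
class CohortData:
    """One cohort: expression matrix (samples x genes) joined with clinical survival.

    ``expression`` is indexed by sample ID with gene symbols as columns; missing
    measurements stay as NaN and are handled pairwise downstream. ``clinical``
    is indexed by sample ID with ``os_months`` (non-negative float, months) and
    ``event`` (True = deceased). After :func:`assemble_cohort` the two indices
    are identical. ``n_dropped_expression`` / ``n_dropped_clinical`` record how
    many samples each side lost in the inner join.
    """

    cohort_id: str
    expression: pd.DataFrame
    clinical: pd.DataFrame | None = None
    n_dropped_expression: int = 0
    n_dropped_clinical: int = 0

    @property
    def samples(self) -> pd.Index:
        return self.expression.index

    @property
    def has_survival(self) -> bool:
        return self.clinical is not None and len(self.clinical) > 0


def _duplicates(items: Iterable) -> set:
    seen: set = set()
    dup: set = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def read_expression(path: str | Path, dialect: str = "samples-in-rows") -> pd.DataFrame:
    """Read a TSV expression matrix and return it with samples as rows.

    Parameters
    ----------
    path
        Tab-separated file with a header row. One axis is labelled by gene
        symbols, the other by sample IDs.
    dialect
        ``"samples-in-rows"`` (first column = sample ID, remaining columns =
        genes) or ``"genes-in-rows"`` (cBioPortal style: first column = gene
        symbol, optional Entrez ID column, remaining columns = samples).
        The orientation is never guessed silently.
    """
    if dialect not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.index.name is None and df.index.isna().any():
        raise CohortParseError(f"{path}: malformed header or missing row labels")
    if dialect == "genes-in-rows":
        drop = [c for c in df.columns if c.upper() in _GENE_META_COLUMNS]
        if drop:
            df = df.drop(columns=drop)
        df = df.T
    logger.info("read_expression(%s): orientation=%s, %d samples x %d genes",
                path, dialect, df.shape[0], df.shape[1])

    dup_samples = _duplicates(df.index)
    if dup_samples:
        raise CohortParseError(f"{path}: duplicate sample IDs: {sorted(dup_samples)}")
    dup_genes = _duplicates(df.columns)
    if dup_genes:
        raise CohortParseError(f"{path}: duplicate gene symbols: {sorted(dup_genes)}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = df.notna() & numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise CohortParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at sample {df.index[r]!r}, gene {df.columns[c]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "sample_id"
    numeric.columns = numeric.columns.astype(str)
    return numeric


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a TSV clinical table into (sample_id -> os_months, event).

    Expects columns SAMPLE_ID, OS_MONTHS, OS_STATUS (case-insensitive). Vital
    status is accepted in the cBioPortal dialect (``0:LIVING``/``1:DECEASED``)
    or as bare ``0/1`` / ``LIVING/ALIVE/DECEASED`` tokens.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    cols = {c.upper(): c for c in df.columns}
    missing = [c for c in ("SAMPLE_ID", "OS_MONTHS", "OS_STATUS") if c not in cols]
    if missing:
        raise CohortParseError(f"{path}: missing required columns {missing}; found {list(df.columns)}")

    sample_ids = df[cols["SAMPLE_ID"]].astype(str)
    dup = _duplicates(sample_ids)
    if dup:
        raise CohortParseError(f"{path}: duplicate sample IDs: {sorted(dup)}")

    months = pd.to_numeric(df[cols["OS_MONTHS"]], errors="coerce")
    bad_months = months.isna() & df[cols["OS_MONTHS"]].notna()
    if bad_months.any():
        i = bad_months.idxmax()
        raise CohortParseError(f"{path}: non-numeric OS_MONTHS {df[cols['OS_MONTHS']][i]!r} for sample {sample_ids[i]!r}")
    if (months < 0).any():
        i = (months < 0).idxmax()
        raise CohortParseError(f"{path}: negative OS_MONTHS {months[i]} for sample {sample_ids[i]!r}")

    events = []
    for i, raw in enumerate(df[cols["OS_STATUS"]]):
        token = str(raw).strip().upper()
        if token not in STATUS_TOKENS:
            raise CohortParseError(f"{path}: unrecognized OS_STATUS token {raw!r} for sample {sample_ids[i]!r}")
        events.append(STATUS_TOKENS[token])

    out = pd.DataFrame(
        {"os_months": months.astype(float).to_numpy(), "event": np.asarray(events, dtype=bool)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return out


def assemble_cohort(expression: pd.DataFrame, clinical: pd.DataFrame, cohort_id: str) -> CohortData:
    """Inner-join expression and clinical tables on sample ID into a CohortData.

    Samples present on only one side are dropped (counted and logged).
    An empty intersection is an error.
    """
    shared = expression.index.intersection(clinical.index)
    if len(shared) == 0:
        raise ValueError(f"cohort {cohort_id!r}: expression and clinical tables share no sample IDs")
    n_drop_expr = len(expression.index) - len(shared)
    n_drop_clin = len(clinical.index) - len(shared)
    if n_drop_expr:
        logger.warning("cohort %s: dropped %d expression-only samples", cohort_id, n_drop_expr)
    if n_drop_clin:
        logger.warning("cohort %s: dropped %d clinical-only samples", cohort_id, n_drop_clin)
    return CohortData(
        cohort_id=cohort_id,
        expression=expression.loc[shared],
        clinical=clinical.loc[shared],
        n_dropped_expression=n_drop_expr,
        n_dropped_clinical=n_drop_clin,
    )


def write_expression(df: pd.DataFrame, path: str | Path, dialect: str = "samples-in-rows") -> None:
    """Write an expression matrix as TSV in either orientation (round-trip safe)."""
    if dialect == "samples-in-rows":
        out = df.copy()
        out.index.name = "SAMPLE_ID"
    elif dialect == "genes-in-rows":
        out = df.T.copy()
        out.index.name = "HUGO_SYMBOL"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t")


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    """Write a clinical table as TSV in the cBioPortal status dialect."""
    out = pd.DataFrame(
        {
            "SAMPLE_ID": df.index,
            "OS_MONTHS": df["os_months"].to_numpy(),
            "OS_STATUS": np.where(df["event"].to_numpy(), "1:DECEASED", "0:LIVING"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path, marker_gene: str) -> GenePanel:
    """Read a candidate-gene panel (one symbol per line; '#' comments allowed)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        g = line.split("#", 1)[0].strip()
        if g:
            genes.append(g)
    return GenePanel(marker_gene=marker_gene, candidate_genes=genes)
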