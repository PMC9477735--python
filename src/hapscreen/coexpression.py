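"""Single-query co-expression screening over a tissue expression atlas.

The procedure is deliberately simple: drop low-variance genes (sample
variance below a threshold, default 1 in squared expression units), compute
the Pearson correlation of every remaining gene with a query gene across
samples, and keep partners at or above a correlation cut-off (default
r >= 0.7). The selected list is what downstream ontology-enrichment tools
consume; ontology statistics themselves are out of scope here.

Atlas values are used as provided (no log transform). Duplicate gene
identifiers are collapsed before analysis — by mean by default, optionally
by max — and rows with missing values are dropped and logged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError

__all__ = [
    "ExpressionMatrix",
    "CoexpressionResult",
    "load_expression_matrix",
    "filter_low_variance",
    "correlate_to_gene",
    "select_coexpressed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples expression matrix in the source atlas's units."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidInputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


@dataclass(frozen=True)
class CoexpressionResult:
    """Correlations of all genes to one query gene, plus the selection."""

    query_gene: str
    correlations: dict[str, float]
    selected: list[str] = field(default_factory=list)
    variance_threshold: float = 1.0
    cutoff: float = 0.7


def load_expression_matrix(
    path: str | Path, collapse: str = "mean"
) -> ExpressionMatrix:
    """Parse a delimited atlas file: first column gene ids, rest numeric.

    Rows with missing values are dropped (and logged); duplicate gene ids
    are collapsed by ``collapse`` ("mean" or "max").
    """
    if collapse not in ("mean", "max"):
        raise InvalidInputError(
            f"collapse must be 'mean' or 'max', got {collapse!r}"
        )
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error):
        raise FormatError(f"{path}: empty or undelimited expression file") from None
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise FormatError(f"{path}: no expression rows/columns found")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    introduced = numeric.isna() & frame.notna()
    if introduced.any().any():
        row, col = np.argwhere(introduced.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value at gene {frame.index[row]!r}, "
            f"sample {frame.columns[col]!r}"
        )
    missing = numeric.isna().any(axis=1)
    if missing.any():
        logger.info(
            "%s: dropping %d row(s) with missing values", path, missing.sum()
        )
        numeric = numeric.loc[~missing]
    duplicated = numeric.index.duplicated()
    if duplicated.any():
        logger.info(
            "%s: collapsing %d duplicate gene id(s) by %s",
            path,
            duplicated.sum(),
            collapse,
        )
        grouped = numeric.groupby(level=0, sort=False)
        numeric = grouped.mean() if collapse == "mean" else grouped.max()
    return ExpressionMatrix(
        gene_ids=[str(g) for g in numeric.index],
        sample_ids=[str(s) for s in numeric.columns],
        values=numeric.to_numpy(dtype=float),
    )


def filter_low_variance(
    matrix: ExpressionMatrix, threshold: float = 1.0
) -> ExpressionMatrix:
    """Keep genes whose sample variance (n-1 denominator) is >= threshold."""
    if threshold < 0:
        raise InvalidInputError("variance threshold must be >= 0")
    if len(matrix.sample_ids) < 2:
        raise InvalidInputError("variance filter needs >= 2 samples")
    variances = matrix.values.var(axis=1, ddof=1)
    keep = variances >= threshold
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        sample_ids=matrix.sample_ids,
        values=matrix.values[keep],
    )


def correlate_to_gene(
    matrix: ExpressionMatrix, query_gene: str
) -> CoexpressionResult:
    """Pearson correlation of every gene's row with the query gene's row.

    Genes with zero variance across samples have no defined correlation and
    are excluded (they cannot occur after the variance filter). The query
    correlates with itself at exactly 1.
    """
    if query_gene not in matrix.gene_ids:
        raise KeyError(f"query gene {query_gene!r} not in the matrix")
    if len(matrix.sample_ids) < 3:
        raise InvalidInputError("correlation needs >= 3 samples")
    values = matrix.values
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    q = matrix.gene_ids.index(query_gene)
    if norms[q] == 0.0:
        raise InvalidInputError(
            f"query gene {query_gene!r} has zero variance"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ centered[q]) / (norms * norms[q])
    correlations = {
        gene: float(np.clip(r_i, -1.0, 1.0))
        for gene, r_i, norm in zip(matrix.gene_ids, r, norms)
        if norm > 0.0
    }
    correlations[query_gene] = 1.0
    return CoexpressionResult(query_gene=query_gene, correlations=correlations)


def select_coexpressed(
    result: CoexpressionResult, cutoff: float = 0.7
) -> list[str]:
    """Partners with r >= cutoff, query excluded, by descending r then id."""
    if not -1.0 <= cutoff <= 1.0:
        raise InvalidInputError("cutoff must lie in [-1, 1]")
    chosen = [
        (gene, r)
        for gene, r in result.correlations.items()
        if gene != result.query_gene and r >= cutoff
    ]
    chosen.sort(key=lambda item: (-item[1], item[0]))
    return [gene for gene, _ in chosen]
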