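"""Per-gene enrichment statistics for a reporter-sorted insertion screen.

For every gene the screen compares the count of unique sense insertions
between the two sorted populations against all remaining gene-mapped
insertions, as a 2x2 table

    =============  =========  =========
    .              high bin   low bin
    =============  =========  =========
    in gene        a          c
    all others     b          d
    =============  =========  =========

and asks, by a two-sided Fisher's exact test, whether insertions in the gene
are unequally distributed between the bins. P values are adjusted across all
tested genes with the Benjamini-Hochberg step-up procedure (one family per
screen). The "fishtail" coordinates of a gene are its combined unique
insertion count ``a + c`` (x) and its mutation ratio (y)

    ratio = (a / (a + b)) / (c / (c + d)),

the in-gene insertion fraction of the high bin over that of the low bin.
A significant gene with ratio < 1 is a positive regulator of the reporter
(its disruption depletes insertions from the high bin); ratio > 1 marks a
negative regulator.

The Fisher test uses the minimum-likelihood two-sided rule — the p-value
sums hypergeometric point probabilities of all tables (at fixed margins)
no more probable than the observed one — which is the convention of
mainstream statistical software. Point probabilities are computed in log
space via ``lgamma`` so tables with totals of order 1e6 do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTableError,
    FormatError,
    InvalidInputError,
)
from .models import NEGATIVE_REGULATOR, NO_DIRECTION, POSITIVE_REGULATOR

__all__ = [
    "GeneContingency",
    "EnrichmentResult",
    "fisher_two_sided",
    "benjamini_hochberg",
    "mutation_ratio",
    "analyze_screen",
    "read_supplementary_table",
    "write_results",
]

#: Relative tolerance when comparing hypergeometric point probabilities,
#: so that exact ties computed in floating point are still treated as ties.
TIE_RTOL = 1e-7


@dataclass(frozen=True, slots=True)
class GeneContingency:
    """Per-gene 2x2 insertion counts (the unit of the screen statistic)."""

    gene_id: str
    a: int  # unique sense insertions in the gene, high population
    b: int  # all other unique sense insertions, high population
    c: int  # in the gene, low population
    d: int  # all other, low population

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidInputError(
                f"gene {self.gene_id!r}: negative count in "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )

    @property
    def combined(self) -> int:
        return self.a + self.c


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One gene's screen statistics and hit call."""

    gene_id: str
    a: int
    b: int
    c: int
    d: int
    p: float
    p_adj: float
    ratio: float  # may be math.inf; NaN when a == c == 0 (unplottable)
    combined: int
    direction: str


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value of one 2x2 table.

    Minimum-likelihood rule: with margins fixed, sum the point probabilities
    of every admissible table whose probability is at most that of the
    observed table (within :data:`TIE_RTOL` relative tolerance). Both row
    sums must be positive.
    """
    for value in (a, b, c, d):
        if value < 0 or value != int(value):
            raise InvalidInputError(
                f"counts must be non-negative integers, got ({a},{b},{c},{d})"
            )
    row1, row2 = a + b, c + d
    if row1 == 0 or row2 == 0:
        raise DegenerateTableError(
            f"table ({a},{b},{c},{d}) has an empty population"
        )
    k = a + c  # column margin of the in-gene counts
    n = row1 + row2
    lo = max(0, k - row2)
    hi = min(k, row1)
    support = np.arange(lo, hi + 1)
    log_pmf = (
        _log_binom(row1, support)
        + _log_binom(row2, k - support)
        - _log_binom(n, np.full_like(support, k))
    )
    log_obs = log_pmf[a - lo]
    keep = log_pmf <= log_obs + math.log1p(TIE_RTOL)
    if keep.all():  # the observed table is the mode
        return 1.0
    p = float(np.exp(log_pmf[keep]).sum())
    return min(p, 1.0)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    For order statistics ``p_(1) <= ... <= p_(m)`` the adjusted value is
    ``adj_(j) = min_{k >= j} min(1, m p_(k) / k)``; rejecting ``adj < alpha``
    reproduces the classic step-up rejection set at level ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("p_values must be a non-empty 1-d sequence")
    if np.any(~(p > 0.0) | (p > 1.0)):
        raise InvalidInputError("all p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(m, dtype=float)
    adj[order] = adj_sorted
    # mathematically adj >= p; guard against one-ulp rounding in p*m/k
    return np.maximum(adj, p)


def mutation_ratio(a: int, b: int, c: int, d: int) -> float:
    """High-bin in-gene insertion fraction over the low-bin fraction.

    Returns ``inf`` when the gene has insertions only in the high bin and
    ``nan`` (undefined; excluded from fishtail output) when it has none in
    either bin.
    """
    if a + b == 0 or c + d == 0:
        raise InvalidInputError("both populations need a positive total")
    if a == 0 and c == 0:
        return math.nan
    frac_high = a / (a + b)
    frac_low = c / (c + d)
    if frac_low == 0.0:
        return math.inf
    return frac_high / frac_low


def analyze_screen(
    tables: Sequence[GeneContingency], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Run the full per-gene screen statistic over all testable genes.

    Genes with ``a == c == 0`` are excluded before testing (they cannot be
    observed in insertion data and carry no information). BH adjustment is
    applied jointly across all tested genes. A direction is assigned only at
    ``p_adj < alpha``: positive regulator for ratio < 1, negative for
    ratio > 1. Results are sorted by ``(p_adj, gene_id)``.
    """
    if len(tables) == 0:
        raise InvalidInputError("analyze_screen needs at least one gene")
    tested = [t for t in tables if t.a + t.c > 0]
    if not tested:
        raise InvalidInputError("no testable gene (all have a == c == 0)")
    p = np.array([fisher_two_sided(t.a, t.b, t.c, t.d) for t in tested])
    p_adj = benjamini_hochberg(p)
    results = []
    for t, p_i, q_i in zip(tested, p, p_adj):
        ratio = mutation_ratio(t.a, t.b, t.c, t.d)
        if q_i < alpha and ratio < 1.0:
            direction = POSITIVE_REGULATOR
        elif q_i < alpha and ratio > 1.0:
            direction = NEGATIVE_REGULATOR
        else:
            direction = NO_DIRECTION
        results.append(
            EnrichmentResult(
                gene_id=t.gene_id,
                a=t.a,
                b=t.b,
                c=t.c,
                d=t.d,
                p=float(p_i),
                p_adj=float(q_i),
                ratio=ratio,
                combined=t.combined,
                direction=direction,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.gene_id))
    return results


#: Column order of the published processed screen table: the low-bin counts
#: precede the high-bin counts.
_SUPP_COLUMNS = [
    "gene_id",
    "low_in_gene",
    "low_other",
    "high_in_gene",
    "high_other",
    "p",
    "p_adj",
]


def read_supplementary_table(
    path: str | Path,
) -> tuple[list[GeneContingency], pd.DataFrame]:
    """Read a processed per-gene screen count table.

    Expects seven delimited columns: gene symbol, in-gene and other counts
    for the low population, in-gene and other counts for the high
    population, then the reported P and FDR-corrected P. Returns the
    contingency tables (``a``/``b`` from the high columns, ``c``/``d`` from
    the low columns) plus the raw frame with the reported p-value columns
    retained for cross-validation.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else None
    if sep is None:
        frame = pd.read_csv(path, sep=None, engine="python")
    else:
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if frame.shape[1] < 7:
        raise FormatError(
            f"{path}: expected 7 columns "
            f"(gene, low in-gene, low other, high in-gene, high other, "
            f"P, adjusted P), got {frame.shape[1]}"
        )
    frame = frame.iloc[:, :7]
    frame.columns = _SUPP_COLUMNS
    for column in _SUPP_COLUMNS[1:5]:
        values = pd.to_numeric(frame[column], errors="coerce")
        if values.isna().any() or (values % 1 != 0).any():
            bad = frame.loc[
                values.isna() | (values % 1 != 0), "gene_id"
            ].iloc[0]
            raise FormatError(
                f"{path}: non-integer count in column {column!r} "
                f"(gene {bad!r})"
            )
        frame[column] = values.astype(np.int64)
    tables = [
        GeneContingency(
            gene_id=str(row.gene_id),
            a=int(row.high_in_gene),
            b=int(row.high_other),
            c=int(row.low_in_gene),
            d=int(row.low_other),
        )
        for row in frame.itertuples(index=False)
    ]
    return tables, frame


def write_results(
    results: Sequence[EnrichmentResult], path: str | Path
) -> Path:
    """Write screen results as a TSV; infinite ratios serialise as ``inf``."""
    if len(results) == 0:
        raise InvalidInputError("write_results needs at least one result")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "gene_id\ta\tb\tc\td\tp\tp_adj\tratio\tcombined\tdirection\n"
        )
        for r in results:
            ratio = "nan" if math.isnan(r.ratio) else repr(float(r.ratio))
            if math.isinf(r.ratio):
                ratio = "inf"
            fh.write(
                f"{r.gene_id}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{r.p:.6g}\t"
                f"{r.p_adj:.6g}\t{ratio}\t{r.combined}\t{r.direction}\n"
            )
    return path


def fishtail_coordinates(
    results: Sequence[EnrichmentResult],
) -> pd.DataFrame:
    """Plot coordinates: x = combined unique insertions, y = mutation ratio.

    Genes with an undefined ratio are dropped; infinite ratios are mapped to
    the largest finite ratio in the result set (the plot-axis maximum).
    """
    finite = [
        r.ratio
        for r in results
        if math.isfinite(r.ratio) and r.ratio > 0
    ]
    ceiling = max(finite) if finite else 1.0
    rows = []
    for r in results:
        if math.isnan(r.ratio):
            continue
        ratio = ceiling if math.isinf(r.ratio) else r.ratio
        rows.append(
            {
                "gene_id": r.gene_id,
                "combined": r.combined,
                "ratio": ratio,
                "p_adj": r.p_adj,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
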