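"""Shared domain records for the screen pipeline.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
A gene "body" is the full annotated span including introns, because gene-trap
vectors inactivate a gene from intronic as well as exonic integrations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidAnnotationError, InvalidInputError

STRANDS = ("+", "-")
POPULATIONS = ("high", "low")

POSITIVE_REGULATOR = "positive_regulator"
NEGATIVE_REGULATOR = "negative_regulator"
NO_DIRECTION = "none"
DIRECTIONS = (POSITIVE_REGULATOR, NEGATIVE_REGULATOR)


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One annotated gene body.

    ``start``/``end`` are 0-based half-open base-pair coordinates; ``strand``
    is the transcriptional orientation used for the sense-insertion filter.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise InvalidAnnotationError(
                f"gene {self.gene_id!r}: invalid interval "
                f"[{self.start}, {self.end}) (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise InvalidAnnotationError(
                f"gene {self.gene_id!r}: strand must be one of {STRANDS}, "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chromosome: str, position: int) -> bool:
        """Half-open containment test on this gene's chromosome."""
        return (
            chromosome == self.chromosome and self.start <= position < self.end
        )


@dataclass(frozen=True, slots=True)
class InsertionSite:
    """One gene-trap integration event recovered from a sorted population."""

    chromosome: str
    position: int
    strand: str
    population: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise InvalidInputError(
                f"insertion position must be >= 0, got {self.position}"
            )
        if self.strand not in STRANDS:
            raise InvalidInputError(
                f"insertion strand must be one of {STRANDS}, got {self.strand!r}"
            )
        if self.population not in POPULATIONS:
            raise InvalidInputError(
                f"population must be one of {POPULATIONS}, got {self.population!r}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """Uniqueness key of an integration: (chromosome, position, strand)."""
        return (self.chromosome, self.position, self.strand)
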