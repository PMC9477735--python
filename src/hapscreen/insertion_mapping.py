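"""From insertion coordinates to per-gene, per-population count tables.

The pipeline deliberately starts at mapped insertion coordinates — raw-read
alignment and insertion calling are upstream, external steps. What this
module owns:

* reading BED-like per-population insertion files and BED6/GTF/GFF gene
  annotations (all coordinates normalised to 0-based half-open),
* deduplicating insertions to unique integration sites, keyed by
  ``(chromosome, position, strand)``,
* assigning each unique insertion to the gene bodies that contain it in the
  sense orientation (insertion strand equal to gene strand), and
* assembling per-gene 2x2 contingency tables against the population totals.

Population totals follow the screen's own accounting: "all other mutations"
means all *gene-mapped sense* insertions of that population, so intergenic
and antisense insertions contribute neither to any gene nor to the total.
A sense insertion inside k overlapping genes counts once for each gene but
only once toward the population total.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np

from .errors import (
    FormatError,
    InconsistencyError,
    InvalidAnnotationError,
    InvalidInputError,
)
from .models import GeneModel, InsertionSite, POPULATIONS, STRANDS

__all__ = [
    "InsertionSite",
    "read_insertions",
    "read_annotation",
    "deduplicate",
    "map_to_genes",
    "build_contingencies",
]


def _data_lines(path: Path):
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_insertions(path: str | Path, population: str) -> list[InsertionSite]:
    """Read one sorted population's insertions from a BED-like file.

    Expects at least six tab-separated columns (chrom, start, end, name,
    score, strand); the insertion coordinate is the 0-based ``start``.
    """
    path = Path(path)
    if population not in POPULATIONS:
        raise InvalidInputError(
            f"population must be one of {POPULATIONS}, got {population!r}"
        )
    sites: list[InsertionSite] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise FormatError(
                f"{path}:{lineno}: expected >= 6 BED columns including "
                f"strand, got {len(fields)}"
            )
        chrom, start_s, end_s = fields[0], fields[1], fields[2]
        strand = fields[5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-integer coordinates "
                f"{start_s!r}/{end_s!r}"
            ) from None
        if start < 0 or start >= end:
            raise FormatError(
                f"{path}:{lineno}: invalid interval [{start}, {end})"
            )
        if strand not in STRANDS:
            raise FormatError(
                f"{path}:{lineno}: missing or invalid strand {strand!r}"
            )
        sites.append(
            InsertionSite(
                chromosome=chrom,
                position=start,
                strand=strand,
                population=population,
            )
        )
    return sites


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a gene annotation from BED6 or from GTF/GFF ``gene`` features.

    BED input is taken as-is (0-based half-open). GTF/GFF input (detected by
    a ``.gtf``/``.gff``/``.gff3`` suffix or a 9-column layout with a feature
    type in column 3) is converted from 1-based inclusive coordinates, and
    only ``gene`` features are kept; the gene id is taken from the first
    ``gene_id`` or ``ID`` attribute.
    """
    path = Path(path)
    gff_suffix = path.suffix.lower() in {".gtf", ".gff", ".gff3"}
    genes: list[GeneModel] = []
    for lineno, fields in _data_lines(path):
        is_gff = gff_suffix or (
            len(fields) >= 9 and not fields[3].lstrip("-").isdigit()
        )
        try:
            if is_gff:
                if len(fields) < 9:
                    raise FormatError(
                        f"{path}:{lineno}: expected 9 GFF columns"
                    )
                if fields[2] != "gene":
                    continue
                chrom, start, end, strand = (
                    fields[0],
                    int(fields[3]) - 1,
                    int(fields[4]),
                    fields[6],
                )
                gene_id = _gff_gene_id(fields[8], path, lineno)
            else:
                if len(fields) < 6:
                    raise FormatError(
                        f"{path}:{lineno}: expected >= 6 BED columns"
                    )
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                gene_id, strand = fields[3], fields[5]
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-integer coordinates"
            ) from None
        if start >= end:
            raise InvalidAnnotationError(
                f"{path}:{lineno}: gene {gene_id!r} has start >= end"
            )
        genes.append(GeneModel(gene_id, chrom, start, end, strand))
    return genes


def _gff_gene_id(attributes: str, path: Path, lineno: int) -> str:
    for chunk in attributes.replace(";", " ; ").split(";"):
        chunk = chunk.strip()
        for key in ("gene_id", "ID"):
            if chunk.startswith(key):
                value = chunk[len(key):].strip(" =\"")
                if value:
                    return value.strip('"')
    raise FormatError(
        f"{path}:{lineno}: no gene_id/ID attribute in {attributes!r}"
    )


def deduplicate(sites: list[InsertionSite]) -> list[InsertionSite]:
    """Collapse to unique integration sites, sorted by (chrom, pos, strand).

    All sites must come from a single population; idempotent.
    """
    populations = {s.population for s in sites}
    if len(populations) > 1:
        raise InvalidInputError(
            f"deduplicate expects one population, got {sorted(populations)}"
        )
    unique = {s.key: s for s in sites}
    return [unique[k] for k in sorted(unique)]


def map_to_genes(
    sites: list[InsertionSite], annotation: list[GeneModel]
) -> tuple[dict[str, int], int]:
    """Count unique sense insertions per gene body.

    A site is counted for gene ``g`` iff ``g.start <= position < g.end`` on
    ``g``'s chromosome and the site strand equals the gene strand. Returns
    ``(counts, total_mapped)`` where ``total_mapped`` counts each site at
    most once even if it lies in several overlapping genes.
    """
    for gene in annotation:
        if gene.start >= gene.end:  # unreachable via GeneModel, kept for ducks
            raise InvalidAnnotationError(
                f"gene {gene.gene_id!r} has start >= end"
            )
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in annotation:
        by_chrom.setdefault(gene.chromosome, []).append(gene)

    counts: Counter[str] = Counter()
    total_mapped = 0
    index: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel], bool]] = {}
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
        starts = np.array([g.start for g in genes], dtype=np.int64)
        ends = np.array([g.end for g in genes], dtype=np.int64)
        overlapping = bool(np.any(ends[:-1] > starts[1:])) if len(genes) > 1 else False
        index[chrom] = (starts, ends, genes, overlapping)

    for site in sites:
        entry = index.get(site.chromosome)
        if entry is None:
            continue
        starts, ends, genes, overlapping = entry
        hit_any = False
        if overlapping:
            # All genes starting at or before the site are candidates.
            j = int(np.searchsorted(starts, site.position, side="right"))
            for gene in genes[:j]:
                if site.position < gene.end and site.strand == gene.strand:
                    counts[gene.gene_id] += 1
                    hit_any = True
        else:
            j = int(np.searchsorted(starts, site.position, side="right")) - 1
            if j >= 0:
                gene = genes[j]
                if site.position < gene.end and site.strand == gene.strand:
                    counts[gene.gene_id] += 1
                    hit_any = True
        if hit_any:
            total_mapped += 1
    return dict(counts), total_mapped


def build_contingencies(
    high_counts: dict[str, int],
    low_counts: dict[str, int],
    total_high: int,
    total_low: int,
) -> list:
    """Assemble per-gene 2x2 tables ``(a, b, c, d)``.

    ``a`` = in-gene high, ``b`` = all other high, ``c`` = in-gene low,
    ``d`` = all other low. Genes absent from one population get a zero count
    there. Rows are ordered by gene id.
    """
    from .enrichment_stats import GeneContingency

    tables = []
    for gene_id in sorted(set(high_counts) | set(low_counts)):
        a = high_counts.get(gene_id, 0)
        c = low_counts.get(gene_id, 0)
        if a > total_high:
            raise InconsistencyError(
                f"gene {gene_id!r}: high count {a} exceeds total {total_high}"
            )
        if c > total_low:
            raise InconsistencyError(
                f"gene {gene_id!r}: low count {c} exceeds total {total_low}"
            )
        tables.append(
            GeneContingency(
                gene_id=gene_id, a=a, b=total_high - a, c=c, d=total_low - c
            )
        )
    return tables
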