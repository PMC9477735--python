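"""Synthetic haploid gene-trap screens with known ground truth.

The generative model mirrors a reporter-sorted insertional-mutagenesis screen
in near-haploid cells:

1. A toy genome of non-overlapping gene bodies is laid out on one (or more)
   pseudo-chromosomes, with a configurable intergenic fraction.
2. Every simulated cell carries exactly one gene-trap integration at a
   uniformly random genomic position with a uniformly random strand — the
   single-integration idealisation of a near-haploid mutagenesis library,
   which keeps the ground truth per cell unambiguous.
3. An insertion disrupts a gene only when it falls inside the gene body in
   the sense orientation (classic gene-trap behaviour).
4. Reporter intensity is log-normal: each cell draws a Gaussian log-intensity
   ``N(reporter_log_mean, reporter_log_sd)``. Disrupting a planted hit gene
   shifts the log-intensity by ``-effect_log_shift`` (positive regulator) or
   ``+effect_log_shift`` (negative regulator) with probability ``penetrance``.
5. Cells are ranked by reporter (ties broken by cell index); the bottom
   ``sort_fraction`` become the "low" population and the top ``sort_fraction``
   the "high" population — by default the top/bottom 4% bins of a FACS sort.
6. Each sorted cell's insertion is recovered with probability
   ``recovery_rate``, emulating incomplete library recovery by sequencing.

All randomness flows through one ``numpy`` generator seeded from
``ScreenSimConfig.seed``; identical configs give bit-identical screens.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateSortError, InvalidConfigError
from .models import (
    DIRECTIONS,
    GeneModel,
    InsertionSite,
    NEGATIVE_REGULATOR,
    POSITIVE_REGULATOR,
)

__all__ = [
    "GeneModel",
    "ScreenSimConfig",
    "SimulatedScreen",
    "simulate_genome",
    "simulate_screen",
    "write_fixture",
]


@dataclass(frozen=True)
class ScreenSimConfig:
    """All generative parameters of a simulated screen.

    Parameters
    ----------
    n_genes
        Number of gene bodies in the toy genome.
    gene_length_bp
        Either a fixed length or an inclusive ``(min, max)`` range sampled
        uniformly per gene.
    intergenic_fraction
        Fraction of the genome that is intergenic; each gene is followed by a
        gap so that ``gap / (gene + gap) = intergenic_fraction``.
    n_cells
        Number of mutagenised cells, one integration each.
    hit_genes
        Mapping ``gene_id -> direction`` of planted regulators
        (``"positive_regulator"`` or ``"negative_regulator"``).
    penetrance
        Probability that a sense insertion in a hit gene actually shifts the
        reporter.
    reporter_log_mean, reporter_log_sd
        Location and scale of the per-cell log reporter intensity.
    effect_log_shift
        Magnitude of the log-scale reporter shift for affected cells.
    sort_fraction
        Fraction of cells taken into each of the low and high bins
        (default 0.04, i.e. top/bottom 4%).
    recovery_rate
        Probability that a sorted cell's insertion is recovered.
    n_chromosomes
        Genome layout switch: genes are split into this many contiguous
        pseudo-chromosome blocks (default one chromosome).
    """

    n_genes: int = 500
    gene_length_bp: int | tuple[int, int] = 10_000
    intergenic_fraction: float = 0.5
    n_cells: int = 100_000
    hit_genes: dict[str, str] = field(default_factory=dict)
    penetrance: float = 0.9
    reporter_log_mean: float = 0.0
    reporter_log_sd: float = 1.0
    effect_log_shift: float = 3.0
    sort_fraction: float = 0.04
    recovery_rate: float = 1.0
    n_chromosomes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        lo, hi = self._length_range()
        if lo <= 0 or hi < lo:
            raise InvalidConfigError(
                f"gene_length_bp must be positive (got {self.gene_length_bp!r})"
            )
        if not 0.0 <= self.intergenic_fraction < 1.0:
            raise InvalidConfigError("intergenic_fraction must be in [0, 1)")
        if self.n_cells < 1:
            raise InvalidConfigError("n_cells must be >= 1")
        for prob_name in ("penetrance", "recovery_rate"):
            value = getattr(self, prob_name)
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{prob_name} must be in [0, 1]")
        if not 0.0 < self.sort_fraction <= 1.0:
            raise InvalidConfigError("sort_fraction must be in (0, 1]")
        if self.recovery_rate <= 0.0:
            raise InvalidConfigError("recovery_rate must be in (0, 1]")
        if self.reporter_log_sd <= 0.0:
            raise InvalidConfigError("reporter_log_sd must be > 0")
        if self.n_chromosomes < 1 or self.n_chromosomes > self.n_genes:
            raise InvalidConfigError(
                "n_chromosomes must be in [1, n_genes]"
            )
        for gene_id, direction in self.hit_genes.items():
            if direction not in DIRECTIONS:
                raise InvalidConfigError(
                    f"hit gene {gene_id!r}: direction must be one of "
                    f"{DIRECTIONS}, got {direction!r}"
                )

    def _length_range(self) -> tuple[int, int]:
        if isinstance(self.gene_length_bp, (tuple, list)):
            lo, hi = self.gene_length_bp
            return int(lo), int(hi)
        return int(self.gene_length_bp), int(self.gene_length_bp)

    def replace(self, **changes) -> "ScreenSimConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SimulatedScreen:
    """A fully simulated screen: annotation, sorted insertions and truth."""

    annotation: list[GeneModel]
    insertions_high: list[InsertionSite]
    insertions_low: list[InsertionSite]
    truth: dict[str, str]


def _rng_for(config: ScreenSimConfig, stream: int) -> np.random.Generator:
    """Independent child generator for one stage of the simulation.

    ``simulate_genome`` always uses stream 0, so the annotation built inside
    ``simulate_screen`` is identical to a standalone ``simulate_genome`` call
    with the same config.
    """
    seq = np.random.SeedSequence(config.seed, spawn_key=(stream,))
    return np.random.default_rng(seq)


def simulate_genome(config: ScreenSimConfig) -> list[GeneModel]:
    """Lay out ``n_genes`` non-overlapping gene bodies.

    Each gene occupies the first ``length`` bp of a block whose total span is
    ``length / (1 - intergenic_fraction)``; blocks are concatenated, so genes
    never overlap. Gene strands are uniformly random. Genes are assigned to
    ``n_chromosomes`` contiguous, near-equal chromosome blocks named
    ``chr1 .. chrN``.
    """
    rng = _rng_for(config, 0)
    lo, hi = config._length_range()
    if lo == hi:
        lengths = np.full(config.n_genes, lo, dtype=np.int64)
    else:
        lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)

    spans = np.ceil(lengths / (1.0 - config.intergenic_fraction)).astype(
        np.int64
    )
    width = max(1, len(str(config.n_genes)))
    chrom_of = np.minimum(
        (np.arange(config.n_genes) * config.n_chromosomes) // config.n_genes,
        config.n_chromosomes - 1,
    )

    genes: list[GeneModel] = []
    cursor = 0
    current_chrom = -1
    for i in range(config.n_genes):
        if chrom_of[i] != current_chrom:
            current_chrom = int(chrom_of[i])
            cursor = 0
        start = cursor
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:0{width}d}",
                chromosome=f"chr{current_chrom + 1}",
                start=start,
                end=start + int(lengths[i]),
                strand=str(strands[i]),
            )
        )
        cursor += int(spans[i])
    return genes


def _chromosome_lengths(genes: list[GeneModel], config: ScreenSimConfig):
    """Total span per chromosome, including the trailing intergenic gap."""
    lengths: dict[str, int] = {}
    frac = 1.0 - config.intergenic_fraction
    for gene in genes:
        span = int(np.ceil(gene.length / frac))
        lengths[gene.chromosome] = max(
            lengths.get(gene.chromosome, 0), gene.start + span
        )
    return lengths


def simulate_screen(config: ScreenSimConfig) -> SimulatedScreen:
    """Run the full generative model and return both populations plus truth."""
    genes = simulate_genome(config)
    gene_ids = {g.gene_id for g in genes}
    unknown = set(config.hit_genes) - gene_ids
    if unknown:
        raise InvalidConfigError(
            f"hit_genes not in the simulated genome: {sorted(unknown)}"
        )

    n_sorted = int(np.floor(config.n_cells * config.sort_fraction))
    if n_sorted < 1:
        raise DegenerateSortError(
            f"sort_fraction {config.sort_fraction} of {config.n_cells} cells "
            "yields an empty sort bin"
        )

    rng = _rng_for(config, 1)
    chrom_lengths = _chromosome_lengths(genes, config)
    chrom_names = sorted(chrom_lengths, key=lambda c: int(c[3:]))
    sizes = np.array([chrom_lengths[c] for c in chrom_names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    genome_size = int(offsets[-1])

    # One integration per cell: global linear coordinate + strand.
    linear = rng.integers(0, genome_size, size=config.n_cells)
    cell_chrom_idx = np.searchsorted(offsets, linear, side="right") - 1
    cell_pos = linear - offsets[cell_chrom_idx]
    cell_strand = rng.integers(0, 2, size=config.n_cells)  # 0 = '+', 1 = '-'

    # Sense-disruption lookup per cell via the global linear coordinate.
    gene_starts = np.empty(len(genes), dtype=np.int64)
    gene_ends = np.empty(len(genes), dtype=np.int64)
    gene_strand = np.empty(len(genes), dtype=np.int64)
    chrom_index = {c: i for i, c in enumerate(chrom_names)}
    for j, gene in enumerate(genes):
        off = offsets[chrom_index[gene.chromosome]]
        gene_starts[j] = off + gene.start
        gene_ends[j] = off + gene.end
        gene_strand[j] = 0 if gene.strand == "+" else 1
    # Genes are non-overlapping and sorted along the linear genome.
    slot = np.searchsorted(gene_starts, linear, side="right") - 1
    slot_valid = slot >= 0
    slot_clip = np.clip(slot, 0, None)
    in_gene = slot_valid & (linear < gene_ends[slot_clip])
    sense = in_gene & (cell_strand == gene_strand[slot_clip])

    # Reporter intensities with hit-gene shifts.
    log_intensity = rng.normal(
        config.reporter_log_mean, config.reporter_log_sd, size=config.n_cells
    )
    if config.hit_genes and config.penetrance > 0:
        direction_of = np.zeros(len(genes), dtype=np.int64)
        for j, gene in enumerate(genes):
            d = config.hit_genes.get(gene.gene_id)
            if d == POSITIVE_REGULATOR:
                direction_of[j] = -1
            elif d == NEGATIVE_REGULATOR:
                direction_of[j] = 1
        cell_dir = np.where(sense, direction_of[slot_clip], 0)
        affected = cell_dir != 0
        if config.penetrance < 1.0:
            affected &= rng.random(config.n_cells) < config.penetrance
        log_intensity = log_intensity + np.where(
            affected, cell_dir * config.effect_log_shift, 0.0
        )

    # Stable sort: reporter ties broken by cell index, for determinism.
    order = np.argsort(log_intensity, kind="stable")
    low_cells = order[:n_sorted]
    high_cells = order[-n_sorted:]

    def _recover(cells: np.ndarray, population: str) -> list[InsertionSite]:
        if config.recovery_rate < 1.0:
            keep = rng.random(cells.size) < config.recovery_rate
            cells = cells[keep]
        return [
            InsertionSite(
                chromosome=chrom_names[cell_chrom_idx[i]],
                position=int(cell_pos[i]),
                strand="+" if cell_strand[i] == 0 else "-",
                population=population,
            )
            for i in cells
        ]

    # Fixed draw order (low then high) keeps the output reproducible.
    insertions_low = _recover(low_cells, "low")
    insertions_high = _recover(high_cells, "high")
    return SimulatedScreen(
        annotation=genes,
        insertions_high=insertions_high,
        insertions_low=insertions_low,
        truth=dict(config.hit_genes),
    )


def write_fixture(
    screen: SimulatedScreen, directory: str | Path, config: ScreenSimConfig | None = None
) -> dict[str, Path]:
    """Write a screen to BED/TSV files that round-trip through the readers.

    Emits ``insertions_high.bed`` and ``insertions_low.bed`` (BED6: chrom,
    start, start+1, population, 0, strand), ``annotation.bed`` (BED6 with the
    gene id in the name column), ``truth.tsv`` and, when a config is given,
    ``config.txt`` as flat ``key = value`` lines.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for population, sites in (
        ("high", screen.insertions_high),
        ("low", screen.insertions_low),
    ):
        path = directory / f"insertions_{population}.bed"
        with path.open("w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for s in sites:
                fh.write(
                    f"{s.chromosome}\t{s.position}\t{s.position + 1}\t"
                    f"{s.population}\t0\t{s.strand}\n"
                )
        paths[f"insertions_{population}"] = path

    annot = directory / "annotation.bed"
    with annot.open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for g in screen.annotation:
            fh.write(
                f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )
    paths["annotation"] = annot

    truth = directory / "truth.tsv"
    with truth.open("w") as fh:
        fh.write("gene_id\tdirection\n")
        for gene_id in sorted(screen.truth):
            fh.write(f"{gene_id}\t{screen.truth[gene_id]}\n")
    paths["truth"] = truth

    if config is not None:
        cfg = directory / "config.txt"
        with cfg.open("w") as fh:
            for f_ in dataclasses.fields(config):
                fh.write(f"{f_.name} = {getattr(config, f_.name)!r}\n")
        paths["config"] = cfg
    return paths
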