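# hapscreen

Analysis toolkit for **reporter-sorted haploid gene-trap screens** — the
forward-genetic screen design in which near-haploid cells (e.g. KBM-7) are
mutagenised with a gene-trap retrovirus, sorted by FACS into the top and
bottom tails (by default 4%) of a fluorescent pathway reporter, and the
recovered integration sites of the two populations are compared per gene to
find pathway regulators. It is written for computational biologists who
have mapped insertion coordinates in hand (read alignment and insertion
calling are upstream of this package) and want a tested, reproducible path
from coordinates to ranked hits.

For each gene the screen statistic is a two-sided Fisher's exact test on
the 2×2 table

|            | high tail | low tail |
|------------|-----------|----------|
| in gene    | *a*       | *c*      |
| all others | *b*       | *d*      |

of unique sense gene-body insertions, Benjamini–Hochberg adjusted across
all genes, with hits at *P*_adj < 0.05. Genes are placed on the classic
"fishtail" plot by their combined count *a + c* and mutation ratio
(*a*/(*a*+*b*)) / (*c*/(*c*+*d*)): a significant ratio < 1 is a positive
regulator of the reporter, ratio > 1 a negative regulator.

The package contains five modules:

* `synthetic_screen` — a generative simulator (toy genome, one gene-trap
  insertion per cell, log-normal reporter shifted by planted hit genes with
  configurable penetrance, 4% tail sorting, sequencing recovery) so every
  downstream stage is testable against known ground truth;
* `insertion_mapping` — BED/GFF readers, deduplication to unique
  integration sites, sense-orientation assignment to gene bodies, and 2×2
  table construction;
* `enrichment_stats` — the Fisher/BH screen statistic, mutation ratios,
  hit calling, fishtail coordinates, and I/O for published per-gene count
  tables;
* `coexpression` — variance-filtered Pearson co-expression screening of a
  tissue expression atlas against a query gene with an *r* ≥ 0.7 cut-off;
* `assay_stats` — relative response ratio (RRR) normalisation for
  split-luciferase assays and four-parameter logistic (4PL) EC50 fitting.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Simulate a 250-gene screen of 10⁵ cells with one planted positive and one
planted negative regulator (penetrance 0.9, reporter shift 3σ), then map
and test:

```sh
$ cat config.txt
n_genes = 250
n_cells = 100000
hit_genes = {'gene025': 'positive_regulator', 'gene225': 'negative_regulator'}
penetrance = 0.9
effect_log_shift = 3.0
seed = 1

$ hapscreen simulate --config config.txt --out screen
simulated 250 genes, 4000 high / 4000 low insertions -> screen

$ hapscreen map --high screen/insertions_high.bed --low screen/insertions_low.bed \
    --annotation screen/annotation.bed --out counts.tsv
250 genes with insertions (totals: high=1072, low=1077) -> counts.tsv

$ hapscreen test --counts counts.tsv --out results.tsv
250 genes tested; at P_adj < 0.05: 1 positive regulators, 1 negative regulators

$ head -3 results.tsv
gene_id a     b     c     d     p           p_adj       ratio      combined  direction
gene025 1     1071  78    999   6.54716e-23 1.63679e-20 0.0128803  79        positive_regulator
gene225 78    994   2     1075  5.80975e-22 7.26219e-20 39.1819    80        negative_regulator
```

Both planted regulators are recovered as the only two hits: the positive
regulator's insertions pile into the low tail (1 high vs 78 low, mutation
ratio 0.013), the negative regulator's into the high tail (ratio 39.2), and
the 248 neutral genes stay above *P*_adj = 0.05.

The same pipeline runs on real data: point `hapscreen map` at your
per-population BED files and gene annotation, or feed a published per-gene
count table directly to `hapscreen test --supp-table table.tsv --validate`
to recompute *P* and *P*_adj and compare them against the table's reported
columns. `hapscreen coexpress`, `hapscreen fit-ec50` and `hapscreen rrr`
expose the remaining modules.

Every command is a thin wrapper over importable functions:

```python
import hapscreen as hs

config = hs.ScreenSimConfig(n_genes=250, n_cells=100_000,
                            hit_genes={"gene025": hs.POSITIVE_REGULATOR},
                            penetrance=0.9, effect_log_shift=3.0, seed=1)
screen = hs.simulate_screen(config)
high, _ = hs.map_to_genes(hs.deduplicate(screen.insertions_high), screen.annotation)
```

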