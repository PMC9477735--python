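# Methods

## The screen model

`hapscreen` analyses reporter-sorted haploid gene-trap screens. In such a
screen, near-haploid cells are mutagenised with a gene-trap retrovirus so
that (ideally) each cell carries one inactivating integration; the
population is stimulated, and cells are FACS-sorted into the extreme tails
(by default the top and bottom 4%) of a fluorescent pathway reporter.
Integration sites recovered by sequencing from the two tails are compared
per gene: a gene whose disruption blunts the reporter accumulates
insertions in the low tail, and a gene whose disruption de-represses the
reporter accumulates insertions in the high tail.

The per-gene statistic is a two-sided Fisher's exact test on

|            | high tail | low tail |
|------------|-----------|----------|
| in gene    | a         | c        |
| all others | b         | d        |

where "all others" are all remaining unique gene-mapped sense insertions of
that tail. P values are Benjamini–Hochberg adjusted across all tested genes
as a single family, and hits are called at P_adj < 0.05. Each gene also
gets its fishtail coordinates: the combined unique insertion count `a + c`
and the mutation ratio `(a/(a+b)) / (c/(c+d))`. A significant ratio < 1
marks a positive regulator of the reporter, ratio > 1 a negative regulator.

### Counting conventions

* Coordinates are BED-style 0-based half-open throughout; GTF/GFF
  annotations are converted on ingestion.
* An insertion's identity is `(chromosome, position, strand)`; duplicates
  (e.g. PCR siblings mapping to one base) collapse to one unique site.
* Only *sense* insertions within the full annotated gene body (introns
  included) disrupt a gene — the classic gene-trap mechanism. Antisense and
  intergenic insertions count neither for any gene nor toward the
  population totals.
* A sense insertion inside k overlapping genes counts once per gene but
  once toward the total. With the default non-overlapping simulated
  annotation this case never arises; with real annotations it is rare and
  documented here rather than hidden.
* No minimum-insertion prefilter is applied by default; genes with
  `a == c == 0` are untestable and excluded (they cannot appear in
  insertion data).

### The exact test

`fisher_two_sided` uses the minimum-likelihood two-sided rule: with margins
fixed, the p-value is the sum of hypergeometric point probabilities of all
tables no more probable than the observed one. This is the convention of
mainstream statistical software (R's `fisher.test`, SciPy). Point
probabilities are computed in log space via log-gamma so screen-scale
totals (~10⁶) do not overflow; probability ties are compared with a
relative tolerance of 1e-7. The implementation agrees with exact
integer-arithmetic enumeration to < 1e-12 over every 2×2 table with both
margins ≤ 30 (245,025 tables, checked exhaustively in the test suite) and
with an independent implementation to ~1e-9 relative at 10⁶-scale margins,
the accuracy limit of double-precision log-gamma.

`benjamini_hochberg` implements the step-up adjustment
`adj_(j) = min_{k≥j} min(1, m p_(k) / k)` in input order. A one-ulp guard
(`max(adj, p)`) enforces the mathematical invariant `adj ≥ p` against
floating-point rounding of `p·m/k`.

## The simulator

`synthetic_screen` generates screens with known ground truth:

* **Genome** — `n_genes` non-overlapping gene bodies on one pseudo-
  chromosome (optionally several), each followed by an intergenic gap so a
  fraction `intergenic_fraction` of the genome is intergenic. Defaults: 500
  genes of 10 kb, half the genome intergenic — a miniature of a mammalian
  genome's gene density, small enough that 10⁵ cells give a few unique
  insertions per gene per tail.
* **Cells** — one integration per cell, uniform position and strand. The
  multi-round transduction of real libraries (multi-insertion clones) is
  deliberately not modelled so that ground truth per cell is unambiguous.
* **Reporter** — log-normal: log-intensity `N(reporter_log_mean,
  reporter_log_sd)`, matching the roughly log-normal shape of flow-
  cytometry intensities. A sense insertion in a planted hit gene shifts the
  log-intensity by `∓effect_log_shift` (down for positive regulators) with
  probability `penetrance`.
* **Sorting** — cells ranked by reporter (ties broken by cell index for
  determinism); bottom and top `sort_fraction` (default 0.04) become the
  low and high tails. Each sorted cell's insertion is recovered with
  probability `recovery_rate` (default 1: recovery losses are a thinning
  that changes no distributional property of the counts).
* **Randomness** — a single seeded NumPy generator threaded through all
  draws; identical config + seed gives bit-identical screens.

What the simulator does *not* emulate — integration-site bias of the
retrovirus, multi-insertion clones, PCR duplication structure, sorter
impurity, and gene-length-correlated expression — means passing tests
demonstrate the correctness of the statistics pipeline under the idealised
generative model, not robustness of the screen design to those real-data
artefacts.

### Calibration under the null

With `penetrance = 0` every gene is null, and per-gene exact-test p-values
must be *valid*: P(p ≤ u) ≤ u. They are not exactly uniform — Fisher
p-values are discrete, and at the default depth (~4 combined insertions per
gene) strongly so, with a large atom at p = 1. The calibration check
therefore tests uniformity in the direction the statistic guarantees: a
one-sided Kolmogorov–Smirnov test for anti-conservative excess of small
p-values (α = 0.01, pooled over 20 replicate screens), plus the empirical
screen-wide false-positive fraction at P_adj < 0.05, required to be within
2 SE of zero. Measured: KS D⁺ = 0, zero false positives in 20 replicates.

### Power at the planted-hit conditions

With 5 planted positive regulators at penetrance 0.9 and a reporter shift
of 3σ among 500 genes and 10⁵ cells, a hit gene contributes ≈ 100
sense-disrupted cells of which ≈ 80 land in the bottom-4% tail versus ≈ 4
expected under the null, so recovery of all hits at P_adj < 0.05 with
ratio < 1 in every replicate is expected and observed (10/10 replicates,
empirical FDR 0).

## Co-expression screening

`coexpression` reproduces the standard atlas workflow: drop genes with
sample variance < 1 (n−1 denominator, in squared atlas units — the
convention of the statistical environments these atlases are analysed in),
correlate all remaining genes to a query gene (Pearson, across tissues),
and keep partners at r ≥ 0.7 sorted by descending r (ties
lexicographically). Atlas values are used untransformed; duplicate
identifiers collapse by mean (optionally max) — on probe-level matrices
the collapse rule can change the selected-partner count, which is why it is
exposed. On synthetic data where a partner row is the query plus
independent noise, the measured r matches the analytic attenuation
`1/√(1 + σ²_noise/σ²_signal)` within simulation tolerance.

## Assay statistics

**RRR.** Split-luciferase complementation signals are normalised between
plate controls: `RRR(%) = (value − negative)/(positive − negative) × 100`.
Affine-invariant by construction (gain and offset of the luminometer drop
out).

**4PL.** Dose-response data are fitted with
`y = bottom + (top − bottom)/(1 + (ec50/x)^hill)`, so `y(ec50) =
(top + bottom)/2` identically. The fit is least squares over
`(bottom, top, log ec50, hill)` — log-dose internally for conditioning —
with bounds keeping `log ec50` within ±5 natural-log units of the dosed
range (an EC50 further out is unidentifiable; such fits are flagged
`extrapolated`). Initialisation: bottom/top from the response extremes,
hill sign from the rank correlation of dose and response, log ec50 from
linear interpolation of the half-range crossing. The baseline is free by
default (NF-κB reporters have nonzero background); `fix_bottom` pins it.
Flat data raise `FlatCurveError`; a non-converged optimiser raises
`FitFailureError` carrying the best iterate.

**Synthetic titration design.** `simulate_titration` defaults to a 12-dose
1:3 serial dilution centred on the EC50, in triplicate (one 96-well plate
row, three biological replicates), with homoscedastic Gaussian noise of 5%
of the dynamic range. The design was chosen by an identifiability
analysis: at 5% noise the Cramér–Rao bound puts the median relative EC50
error of an 8-point triplicate titration at ~12% no matter the fitter,
while the 12-point design bounds it at ~7%; measured recovery matches
(~6.8% median over 100 replicates, and < 1e-6 relative on noiseless
curves). Sparser designs are still fittable — they simply estimate EC50
less precisely.

## Problem sizes

Default verification scales, chosen to characterise the statistics well at
interactive runtimes: exhaustive exact-test verification over margins ≤ 30;
20 null replicates and 10 planted-hit replicates of 500-gene / 10⁵-cell
screens; 1,000 random p-vectors for the step-up equivalence; 100 noisy
titration fits. The published-data checks (hit count of the real screen
table; partner count of the real tissue atlas) run only when those external
files are supplied under `data/external/` — see the test suite's
acceptance module.

## Known limitations

* The one-insertion-per-cell idealisation understates the background of
  real multi-integration libraries.
* Promoter/5′-region insertions are not assigned to genes (gene-body only);
  antisense trapping is not scored.
* The two-sided tie tolerance (1e-7 relative) can, in principle, differ
  from another implementation's tie handling in the last digits of extreme
  p-values.
* The 4PL fitter reports a flagged estimate rather than refusing when the
  EC50 sits outside the dosed range; confidence intervals are not computed.
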