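# Methods

## The triangulation model

The pipeline assumes three statistically independent views of the same gene
universe:

- a stable-cell RNA-seq comparison in which true targets are depleted
  (miRNA-mediated degradation),
- a RISC pulldown pair in which true targets are enriched in the
  miRNA-of-interest capture (direct binding), and
- sequence-based prediction calls that fire on true targets with high
  sensitivity and on non-targets rarely.

Because the three error processes are independent, intersecting the three
gene sets suppresses false positives multiplicatively while costing only
the product of the three per-stream sensitivities in recall. No statistical
test or FDR correction is applied within a stream; each stream is a plain
threshold rule, and the guarantees come from the intersection.

## Stream 1: expression screen

Raw counts are filtered before any normalization: a gene is kept only if it
has at least `min_count` (default 2) reads in *every* library. The phrase
"at least N across all libraries" is ambiguous between per-library and
summed readings; the stricter per-library reading is the default
(`low_count_mode="each"`), and the summed reading is available
(`"total"`).

Filtered counts are quantile-normalized: each column is mapped onto the
across-sample mean of order statistics. Tied values within a column receive
the mean of the reference values spanned by their ranks. Conventions for
ties differ between implementations and change results, so this one is
fixed and tested. Two consequences worth knowing: (i) after normalization
all columns have identical sorted value vectors *exactly* when no column
has ties, and up to tie-averaging otherwise; (ii) the transform is
idempotent to numerical precision on tie-free data.

The screen computes `FC = (mean_mir + pseudocount)/(mean_control +
pseudocount)` on normalized condition means and selects `FC <
fc_threshold` strictly, so a gene at exactly a 2-fold drop is not selected
("more than 2-fold"). The pseudocount (default 1) guards against zero
denominators on normalized values; with a single library per condition —
the default study design — the condition mean is the single column.

## Stream 2: pulldown enrichment (R_RC)

`R_RC = log2((n2+f)/(n1+f)) + log2((t1−n1+f)/(t2−n2+f))`, with sample 1 the
control-miRNA pulldown and sample 2 the miRNA of interest, so positive
values mean enrichment by the miRNA of interest. Totals are computed on the
same low-count-filtered matrix the per-gene counts come from. The
pseudocount `f` defaults to 0.5, the conventional half-count used in
log-odds-type read-count ratios; it is configurable and echoed into
provenance because published cutoff values cannot be reproduced without
knowing it.

The implementation evaluates the formula as
`(log2(n2+f) − log2(n1+f)) + (log2(t1−n1+f) − log2(t2−n2+f))` —
algebraically identical, but with the property that swapping the two
samples negates the result *exactly* in IEEE floating point, which the test
suite asserts on random inputs.

The cutoff is always data-derived: the empirical `q`-quantile (default
0.95, linear-interpolation definition at order-statistic position
`1 + q(n−1)`) of the R_RC values from a control-context pulldown pair in
which no true enrichment is expected. Selection in the cancer context is
strictly greater-than. The quantile convention matters at this table size
and is therefore pinned and tested against hand-computed values.

## Stream 3: prediction consensus

The call table is boolean gene-by-predictor; genes absent from the table
are explicit negatives (zero votes) rather than missing data, because the
pipeline makes no attempt to model database coverage. A gene passes with at
least `min_votes` (default 4) of the predictors (default 5). With
per-predictor sensitivity `s` the consensus sensitivity is
`C(5,4) s⁴(1−s) + s⁵` (0.91854 at `s = 0.9`), which is a hard ceiling on
end-to-end recall: a target the predictors miss can never be recovered by
the other two streams.

## Synthetic studies

The generator emulates the study designs the pipeline consumes, not the
sequencing process. Per-gene baseline means are drawn log-normally (log2
mean 6, log2 sd 2 — a realistic bulk RNA-seq dynamic range) and scaled to
the library size (default 5×10⁶ expected reads). Counts are
negative-binomial in the mean–dispersion parameterization (variance
`μ + dμ²`), with dispersion 0 handled as Poisson; the default dispersion
0.1 is typical of biological variability in bulk RNA-seq. Defaults follow
the validated study conditions: 2,000 genes, 50 planted targets, planted
log2 fold change −2 in the stable cell, planted log2 enrichment +3 in the
cancer-context pulldown, predictor sensitivity 0.9 and specificity 0.98,
one library per condition.

The control pulldown is generated at 0.7× the depth of the miRNA pulldown
so the totals-correction term of R_RC does real work; the two library
totals are deliberately unequal. All randomness derives from one master
seed, with each table consuming a sub-stream keyed by a stable hash of the
table label, so regenerating one table never perturbs another and adding a
table never shifts existing ones.

What the generator does *not* emulate — read-level artifacts, mapping
bias, isoform structure, correlated predictor errors, gene–gene count
correlation — bounds what passing tests show: they validate the decision
logic and its calibration under the stated noise model, not robustness to
every artifact of real libraries.

## Validation results the suite computes

- With no planted effects, the fraction of genes in an independent null
  pulldown exceeding the 0.95-quantile threshold calibrated on another
  null pulldown averages 5% (±1% over 20 runs at 2,000 genes).
- Under the default conditions over ten independent studies, the final
  target set recovers a mean ≈ 0.83 of planted targets at precision ≈ 1.0;
  per-seed recall never exceeds the realized consensus rate, whose mean
  matches the binomial closed form 0.91854 within ±0.02.
- Reported problem sizes: recovery and null-calibration runs use 2,000
  genes; the consensus-rate check pools 500 planted targets.

## EV quantification arithmetic

`aggregate_trps` implements the top-k replicate rule for tunable resistive
pulse sensing: a partially clogged nanopore undercounts particles without
tripping quality-control flags, so replicate error is biased downward and
the mean of the k = 3 highest technical replicates is the robust location
estimate. Fewer than k replicates is an error by default; an explicit
fallback averages all replicates with a logged warning.

`copies_per_vesicle` divides absolute cargo copies (e.g. from ddPCR) by a
particle count, with a paired-difference helper for comparing EV classes.

The qPCR standard curve is the standard model: quantification cycle linear
in log10(concentration), fitted by least squares; concentrations are molar,
TRPS concentrations particles/mL, and unit labels are carried in outputs.
Amplification efficiency (`10^(−1/slope) − 1`) is reported as a diagnostic
only. Inversion outside the calibrated concentration range returns a value
flagged `extrapolated=True` (tolerance 10⁻⁹ of the range width at the
edges) and leaves any normalization — to plasma volume, to EV count — to
the caller.

## Numerical and design choices

- Strict inequalities at both selection boundaries (`FC < 0.5`,
  `R_RC > threshold`), matching "more than"/"greater than".
- Report ordering: descending R_RC, ties by ascending log2 fold change,
  then lexicographic gene id; intersections themselves are order-free.
- A user-supplied annotation gene list (e.g. vesicle-trafficking genes)
  only *flags* report rows; it never filters, because such prioritization
  is a judgment call outside the reproducible pipeline.
- Provenance (thresholds, calibrated cutoff, seeds, SHA-256 input digests)
  is written with every file-based run; reruns with identical inputs and
  configuration are byte-identical.
- Empty results are legal everywhere (an empty evidence set empties the
  intersection with a warning, not an error); an empty calibration table
  is an error because no cutoff can be defined.

## Known limitations

- Single-library-per-condition designs (the default) make the fold-change
  screen a point estimate; the pipeline deliberately mirrors that design
  rather than adding a dispersion-modelled test.
- The consensus ceiling means overall recall is capped by predictor
  quality regardless of sequencing depth.
- Gene identifiers are matched case-sensitively with no mapping layer;
  inputs must share a namespace.
- Published cutoffs from real studies cannot be regenerated without the
  original pseudocount `f` and the exact filtered gene universe; this
  package therefore always recalibrates its own cutoff.
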