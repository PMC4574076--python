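# Methods

## Windowing and signal definitions

All coordinates are 0-based, half-open (BED convention). The genome is tiled
per chromosome into consecutive, non-overlapping windows of one odd width N;
the trailing partial window is dropped so all windows are directly
comparable, and excluded chromosomes (chrY by default, because read sets
disagree on whether they carry it) contribute no windows. Odd widths are
used so every window has a centre base; the multiscale driver uses
N = 2ᵏ + 1.

A read contributes a single stranded 5′ position (BED start on '+', end − 1
on '−') and is assigned to the one window containing that position; reads in
the dropped remainder are ignored. Duplicates — identical (chromosome,
strand, position) — are collapsed to one representative before counting, so
a window of width N holds at most 2N reads. Mappability and GC are per-base
0/1 tracks (1 = uniquely mappable / G-or-C); their window value is the exact
fraction of 1-bases. The mappability binarization threshold defaults to 1.0
(uniquely mappable only) and is configurable; uncovered bases and ambiguous
FASTA symbols (N etc.) score 0, the conservative choice.

## The staged decomposition

Stage 0 is the intercept-only model, whose MSE (with the n−1 denominator
used throughout) equals the sample variance of the regressand. Stage i adds
the i-th predictor in the priority order — mappability, GC, DNase
(accessibility), input-DNA, IgG — and refits *all* coefficients by ordinary
least squares. The percentage of variance credited to the stage-i predictor
is POVᵢ = 100·(MSEᵢ₋₁ − MSEᵢ)/var(y). Because var(y) uses the same n−1
denominator, the POVs telescope exactly to 100·R² of the full model, and
each POVᵢ equals the incremental R² of adding that column. The priority
order encodes an attribution convention for shared variance (cell-state-
independent tracks first, then accessibility, then the controls); permuting
the order changes per-stage POVs but never the total, and affine rescaling
of any predictor changes nothing — both are asserted as invariants in the
test suite.

Numerical choices: least-squares solves use a rank-tolerant minimum-norm
solver, so a predictor collinear with earlier columns gets POV 0 rather
than crashing the fit. POVs in (−10⁻⁸, 0) are numerical round-off and are
clipped to 0 in reports; anything more negative raises an
internal-consistency error, since RSS cannot grow when a column is added.
Standard errors of the final-stage coefficients use the homoskedastic OLS
formula with RSS/(n−p); they are reporting aids, not inputs to the POV
accounting. A zero-variance regressand is rejected rather than fitted.
Predictor read counts are not depth-normalized by default — POV is
invariant to per-column rescaling, so normalization would only relabel
coefficients.

## Background subtraction for peaks

Peaks are rebuilt as symmetric summit ± h windows (h = 64, i.e. 129 bp,
matching the training width); a peak whose window would cross a chromosome
edge is excluded rather than truncated, so the feature definitions match
the trained model exactly. Features are recomputed on each exact peak
window, and the purified estimate is B = R − ŷ, never clamped (negative B
means "fewer reads than the background model expects"). The caller score S
is ingested as an opaque larger-is-better number (summit-BED score column
or narrowPeak signalValue; configurable) — no attempt is made to recompute
caller statistics, since any monotone transform leaves rank-based outputs
unchanged. Motif occurrences count toward a peak only if fully contained in
its window, on either strand. The best-estimator tally across datasets is
tested with an exact upper-tail binomial ("ratio test"): under the null
that the m compared methods are interchangeable, one method's win count is
Binomial(datasets, 1/m). Ties in rankings break by stable sort with genomic
coordinate as the final key, for reproducibility.

## Expression association and the confounder audit

Expression is the raw CAGE 5′-tag count in TSS ± 64 bp (no log transform by
default; a log1p flag exists). TSSs sharing a position are collapsed with
concatenated ids. Prediction is OLS with intercept under tenfold
cross-validation: folds are a seeded random partition with sizes differing
by at most one; the headline accuracy is the Pearson correlation of pooled
out-of-fold predictions with observed expression (lower-variance than
fold-averaging; both are reported, the fold PCCs giving a
t-based 95 % interval). ΔPCC for a candidate signal is the pooled-PCC gain
of core + signal over the core predictors alone, computed on identical fold
assignments so the difference is not fold noise. The same operations accept
arbitrary intervals, so gene-body analyses need no new code.

## The synthetic-data generator

The generator is the package's test bed: every emitted file round-trips
through the package's own readers, and all randomness flows from one
integer-seeded PCG64 stream consumed in a fixed order, so output is
bit-reproducible under a fixed seed.

Per-window expected ChIP count is *linear* in the realized predictors —
λ = β₀ + β₁·map + β₂·gc + β₃·dnase + β₄·idna + β₅·igg, counts Poisson — so
the fitted model is correctly specified and planted coefficients are
recoverable; negative rates would be clamped to zero before the draw (the
one deliberate mis-specification knob, inactive under the default
coefficients (0.5, 1.5, 1.0, 0.2, 0.25, 0.15), which keep rates positive).
Mappability alternates geometric mappable/unmappable runs (means 600/60 bp);
GC is per-base Bernoulli around a smoothly drifting probability
(0.41 ± 0.08); accessibility is a baseline (0.1) plus Gaussian bumps
(density 1/5 kb, sd 300 bp, exponential amplitudes) saturating at 1.2 — a
region cannot be more than fully open, and the cap also keeps the
log-linear expression link from producing a handful of extreme counts that
would dominate Pearson statistics. The DNase rate is deep by design
(100·(0.1 + a) reads per open 129-bp window, the regime of well-sequenced
DNase libraries at regulatory regions): the confounder audit requires the
core predictor set to carry a low-noise measurement of accessibility, which
is what "conditioning on accessibility" means operationally.

Window-level counts are the regression test bed; read *placement* is a
separate downstream step that drops each count uniformly onto mappable
base/strand slots (suppressing, with a log message, reads in fully
unmappable windows). Placement samples slots with replacement, so
coincident 5′ duplicates arise and deduplication trims dense windows
(≈5–10 % inside strong peaks) exactly as with real libraries. Recovery
tests therefore fit the window-level counts (the correctly specified
generator), while read-level tests exercise the full file → dedup → count
pipeline and tolerate the resulting small attenuation.

Peaks (default 300, enrichment Gamma-distributed with mean 20 reads per
129-bp window) and TSSs are placed on mappable positions preferentially in
open chromatin — peaks because TF binding concentrates there (which is
precisely why raw counts R are a biased binding estimate the purified B
improves on), TSSs because promoters sit in open chromatin (which is why
accessibility confounds TSS-signal associations). TSS windows are kept
non-overlapping: overlapping windows would share placed reads between the
expression and factor signals, a hidden "TSS density" coupling that
violates the planted conditional-independence structure. Motif counts per
peak are Poisson with mean increasing in the planted enrichment; occurrences
are emitted as FIMO-format rows. Expression is Poisson(exp(0.5 + 2a)); the
"specific TF" read rate (2 + 8a) depends only on accessibility, making it
conditionally independent of expression given a by construction, while the
"general factor" can receive a direct coupling to realized expression.

What the generator does not emulate: fragment-length/shift geometry, PCR
duplication, sequencing error, copy-number variation, diploid genomes, and
inter-dataset depth heterogeneity. Passing tests therefore demonstrate the
estimators' behaviour under the composition model they assume, with
realistic Poisson noise and mappability/accessibility structure — not
robustness to artifacts outside that model.

## Problem sizes used in tests and the acceptance script

Oracle-agreement checks use 50 random instances of 200 windows × 5
predictors. Coefficient recovery uses 20 simulated genomes of 50,000
windows of 129 bp (≈6.45 Mb each). The read-level fixture study uses a
1.29-Mb chromosome (10,000 windows) with 200 peaks; the purification
comparison uses ten replicates of 2.58 Mb with 500 peaks each; the
confounder audit uses 2,000 TSSs on 2.58 Mb; the multiscale trend uses a
300-kb smooth-rate genome across widths 2³+1 … 2⁹+1. These sizes give
stable statistics (recovery and ranking results are reproducible across
seeds) while keeping any single analysis under a minute on one CPU.

## Known limitations

- The linear-rate model is the estimator's own assumption; on real data the
  count–predictor relationship is only approximately linear, and POVs are
  attribution under that approximation.
- The staged attribution is order-dependent by design; only the total POV
  is order-free.
- B is an unbiased background subtraction, not a probability or an
  enrichment ratio; comparing B across datasets of very different depth
  requires the caller to normalize depth first.
- The CV confidence interval treats fold PCCs as approximately independent,
  which understates dependence between folds sharing training data.
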