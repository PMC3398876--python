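# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
design decisions taken where the published analysis convention leaves the
procedure open.

## Copy-number model

Input is a matrix of probe-level log2 ratios (tumour vs a normal-diploid
reference), ordered by genome position, with a flagged subset of
amplified-normal control samples. The ratio scale is log2(copies/2): a
hemizygous deletion sits at −1, a single-copy gain at log2(3/2) ≈ 0.585.

**Amplification correction.** Whole-genome amplification before SNP-array
hybridisation introduces a reproducible probe-specific bias. Because the
same protocol applied to normal-diploid DNA carries the same bias, the
per-probe median over the amplified-normal controls is an estimate of it
and is subtracted from every tumour column. Controls pass through unchanged
and are marked consumed. Probes with no control value get correction 0 and
a warning (never imputed). Each sample is then recentred to median log2
ratio zero, making the modal (neutral) state the reference point; note that
correction-then-centring equals centring of (input − control medians), an
identity used as a test.

**Segmentation (CBS).** Each (sample, chromosome) series is segmented by a
deliberately transparent reimplementation of circular binary segmentation:

* statistic: over all arcs x[i:j] of the circularised window, the pooled
  two-sample *t* comparing the arc with its complement; the best split is
  the arc maximising |t|;
* significance: the window's values are randomly permuted; the split is
  accepted when p = (1 + #{permuted max ≥ observed max})/(n_perm + 1) ≤ α.
  The loop stops early once significance is unreachable, which makes null
  windows cheap;
* recursion: accepted cuts partition the window (an interior arc yields
  three pieces) and each piece is re-tested;
* `min_width` (default 2 probes) constrains candidate arcs so every piece a
  split would produce spans at least that many probes;
* determinism: a single seed spawns one child generator per (sample,
  chromosome) series, so results do not depend on iteration order.

Defaults α = 0.01 and n_perm = 200 (add-one smoothing needs
n_perm ≥ 1/α − 1 for a split to be acceptable at all; 200 leaves headroom).
There is no hybrid tail approximation and no MAD-based undo step: on the
cohort sizes this package targets, correctness is anchored instead on an
exhaustive maximal-t oracle (tests enumerate every single breakpoint on
short series and require agreement whenever a split is accepted), not on
bit-compatibility with any particular CBS release.

Degenerate inputs: a chromosome with fewer than two probes (or shorter than
2×min_width) is returned as a single trivial segment; a constant window has
max |t| = 0 and is never split; a zero-variance window with a non-zero mean
difference gets an infinite statistic and splits whenever the permutation
test supports it.

**Gene assignment and calls.** Each gene receives the mean log2 ratio of
the segment with the largest base-pair overlap (1-based inclusive
coordinates throughout, on disk and in memory). Ties are broken toward the
segment containing the gene midpoint, then leftmost. Genes overlapping no
probed segment are MISSING, and missing values propagate — they are never
imputed. Status thresholds are strict inequalities; a ratio exactly at a
boundary stays NEUTRAL. The deletion and gain boundaries log2(1.5/2) and
log2(2.5/2) are the conventional 1.5-/2.5-copy boundaries; the homozygous-
deletion boundary (−2, i.e. < 0.5 copies) and high-level-amplification
boundary (log2(5/2), i.e. ≥ 5 copies) are this package's defaults, both
configurable, chosen to be biologically literal on the ratio scale.

**Concordance** between two call vectors collapses
{HOMDEL, DEL} → deleted, {GAIN, AMP} → gained, NEUTRAL → normal, and
reports the matched fraction with its numerator and denominator.

## Class enrichment

The background is the full universe of genes with copy-number information:
a class of n_class genes in a universe of n_total gives p₀. For a selected
set of n genes containing k class members the statistic is the exact
one-sided upper tail P(X ≥ k), X ~ Binomial(n, p₀), evaluated through the
regularised incomplete beta function, which remains accurate far below
1e-15. One-sidedness matters: the test asks only about over-representation,
and a selection at the background rate gives p near 1, not near 0.5 both
ways. The background is fixed at the universe, not recomputed per cutoff or
per sample. No multiple-testing correction is applied across cutoffs or
samples (raw p-values are reported; a Fisher-exact cross-check utility
exists but is not the headline statistic).

The frequency profile applies the test at increasing recurrence cutoffs
(genes aberrant in ≥ c samples); the per-sample variant tests each sample's
own aberrant gene set; the subset variant serves peak gene sets and
homozygous-deletion sets.

## Recurrent peaks (simplified GISTIC)

Per gene and direction, G = f × ā where f is the fraction of aberrant
samples and ā the mean |log2 ratio| among them — algebraically the
sample-mean of the aberrant-masked amplitude, so G ≤ max |ratio|. The null
permutes each sample's markers independently *within chromosomes*,
preserving each sample's aberration load and per-chromosome marker counts
while destroying cross-sample recurrence. The default marker-wise null
pools permuted G values across markers and permutations; a genome-wide-max
null is available behind a flag for a more conservative, FWER-flavoured
comparison. P-values use add-one smoothing and are BH-corrected; runs of
markers with q ≤ 0.25 (the conventional threshold, configurable) are
reduced to the contiguous sub-interval attaining the run's maximum G (a
plateau of equal maxima spans the plateau). There is no peel-off of
secondary peaks within a run and no peak-boundary confidence interval —
one run yields one peak.

## Expression calls and their false-positive rate

Signals are assumed normalised to a common target (≈100); calls are
scale-invariant in any case (a property test multiplies all signals by a
constant). Marginal (M) detection calls are treated as not-present under a
strict reading of "present". The DOWN rule conditions on the *normals*
(all present, tumour more than twofold below their mean) and does not
require the tumour itself to be present — genes absent everywhere are
thereby not callable, and a config switch can additionally require tumour
presence. The fold factor defaults to 2 and is configurable.

The false-positive rate is estimated from normals only by leave-one-out:
each normal in turn plays the pseudo-tumour against the mean (and
all-present requirement) of the remaining normals, mirroring the
tumour-vs-normal-mean comparison without sample reuse; at least three
normals are required so the baseline never degenerates. The estimator is
validated against an independent Monte-Carlo evaluation of the same tail
probability for i.i.d. log-normal signals.

IHC validation scores are intensity (0–3) × proportion class (1–3),
giving 0–9; paired tumour:normal ratios are log2 with zero-score pairs
clamped to ±4 (both zero → NA), and the paired test is the exact two-sided
Wilcoxon signed-rank on score differences with ties dropped (the package's
choice of paired test; ≥ 5 informative pairs required for a meaningful
exact p).

## Copy-number / expression integration

Spearman's ρ (average ranks for ties) is computed per gene across samples
matched by name, using complete pairs only (no imputation) and requiring
≥ 3 pairs; constant vectors give NA. The summary counts genes with
ρ strictly below 0.65, excluding NAs from numerator and denominator and
reporting the NA tally. The cross-tab counts a gene as "deleted and down"
if deleted in ≥ 1 sample and down-called in ≥ k tumours (k configurable;
4 corresponds to the 25% tier of a 16-tumour cohort).

## qPCR quantification

Standard curves are ordinary least squares of Ct on log10(copies) over the
calibrator dilutions (≥ 3 distinct levels required); r² is reported and a
slope outside [−3.6, −3.1] — efficiency outside roughly 90–110%, where
efficiency = 10^(−1/slope) − 1 — triggers a warning. Duplicate wells are
averaged on the Ct scale by default (geometric mean on the copies scale),
with a copies-scale option. Undetermined Ct propagates as NA, never imputed
to the final cycle. Copy-number estimates are
reference_ploidy × target/reference copies, which cancels any common
multiplicative bias; the mass convention (6.6 pg per diploid cell, 2 copies
per autosomal locus per cell) converts input mass to expected copies and is
exposed as constants because the "gene copies" convention (per cell vs per
allele) is ambiguous in common usage — downstream ratios do not depend on
it.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a two-platform microdissection
study at reduced scale: by default 3 chromosomes (150 Mb), 200
non-overlapping genes (20 TSG, 10 TPG labels), a uniform 200 kb probe grid
alternating between two enzyme sets, 8 tumours, 4 normals, and 5
amplified-normal controls. Planted events follow a carcinoma-like pattern:
a recurrent hemizygous deletion (~75% of tumours) with a nested homozygous
deletion in a quarter of those, a recurrent gain (~50%), and exactly one
≥5-copy amplification in one tumour. Tumour probe ratios are
log2(copies/2) + probe bias + Gaussian noise; controls carry the *same*
per-probe bias vector, so the correction step can cancel it exactly — an
identity the tests exploit. Homozygous deletions are floored at 0.05 copies
(configurable) so log2 stays finite, as array ratios do in practice. The
probe-noise default (sd 0.15) and the amplification-bias spread (sd 0.3)
are free parameters of the simulation, chosen as plausible array-scale
magnitudes, not estimates of any particular dataset.

Expression baselines are per-gene log-normal around the target signal 100;
coupled genes scale tumour means by 2^(assigned log2 ratio); planted
UP/DOWN genes scale by fold 4 / 0.25 in a random ~80% of tumours. The truth
table records the call implied by the *deterministic* planted factor
(> 2 → UP, < 0.5 → DOWN), so recovery at zero noise is exact even when a
coupled gene sits inside a deep deletion. Detection calls drop to absent
with a configurable probability only below a signal floor of 20.

Not emulated: raw probe intensities and PM/MM pairs, allele-specific
signal, linkage disequilibrium, tumour purity and subclonality, GC waves or
other spatially correlated noise, and batch structure. Passing tests
therefore demonstrate correctness of the algorithms under the stated noise
model, not performance on any real cohort.

Problem sizes in the test suite and acceptance script (750-probe genomes,
8–16 tumours, 100–200 permutations, 1000-replicate calibrations, 20k-gene
FPR matrices) were chosen as the smallest scales at which each property is
statistically sharp; all complete in well under a minute apiece on one CPU.
The calibration check uses a 300-gene selection from the 714/21204
background because the binomial test's discreteness makes the attained
level closest to the nominal 5% there (exact attained level 4.8%).

## Known limitations

* CBS here has no undo step and no tail approximation; very long
  chromosomes (tens of thousands of probes) would need the O(n²) arc scan
  to be windowed.
* The peak caller reports one peak per significant run; two nearby true
  events inside one run merge.
* The per-sample enrichment test treats genes as independent draws, which
  real genomes violate (genes travel in segments); its p-values are
  well-calibrated only under the shuffled-label null.
* qPCR modelling covers the log-linear regime only; no plateau or
  inhibition effects.
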