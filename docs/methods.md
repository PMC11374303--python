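# Methods

## Scope and model

`proxiscore` analyzes proximity-labeling (BioID / miniTurbo) pull-down
experiments at the protein-report level. A promiscuous biotin ligase fused
to a bait protein biotinylates neighbors within roughly 10 nm; streptavidin
capture followed by quantitative mass spectrometry yields a proteins ×
samples intensity table for the bait line and a ligase-only control line.
The package turns such tables into false-positive-rate-controlled
interactor calls, corroborates them with SEC-MS co-elution, identifies
substrate candidates from inhibitor contrasts, and validates labeling
specificity on a 3-D structure. Raw spectra, spectral-library search and
peptide-to-protein rollup are upstream of this package and out of scope.

## Differential abundance

Intensities are analyzed on the log2 scale; zero intensities are treated
as missing before the transform (log2(0) is undefined, and zero in a DIA
protein report means "not quantified", not "absent at zero copies").

**Normalization.** Global median normalization: each sample's nonmissing
log2 values are shifted so every sample median equals the median of the
pre-normalization sample medians. The operation is idempotent. Note one
real property it inherits from the field's convention: when enrichment is
one-sided (bait samples contain genuinely enriched proteins), the bait
medians rise and normalization subtracts one global constant from all
ratios. With a few percent of proteins enriched this constant is small;
the noise-free consistency tests therefore run with normalization off.

**Paired test.** Bait and control replicates are paired by `pair_id`
(replicate batches processed together). Per protein, d_i = log2(bait_i) −
log2(control_i) over complete pairs; the mean of d is the reported log2
ratio, and a two-sided paired t-test with df = n_pairs − 1 gives the
p-value. Proteins with fewer than two complete pairs carry no p-value.
Degenerate variance is resolved by convention rather than NaN: all d_i = 0
gives p = 1, all d_i equal and nonzero gives p = 0, both flagged
`degenerate`. Optional global-minimum imputation substitutes the smallest
observed intensity for missing values; the default is no imputation.

**q-values.** The proportion of true nulls is estimated as
pi0 = #{p > λ} / (m(1 − λ)) with λ = 0.5 by default, clamped to [1/m, 1];
the q-value of the i-th ordered p is min_{j≥i} pi0·m·p_(j)/j. With
pi0 = 1 this is exactly the step-up FDR adjustment (verified against a
brute-force oracle). An `auto` mode estimates pi0 on a λ grid
(0.05…0.90, step 0.05) with a cubic polynomial smoother evaluated at the
top of the grid; the fixed-λ default is preferred for reproducibility.

## Enrichment classifier

The per-protein enrichment score is S = (mean log2 ratio) × (−log10 q).
Base 10 follows volcano/MA-plot convention and is configurable. Proteins
missing either factor are dropped and counted. q = 0 (possible under the
degenerate-variance convention) is clamped to the smallest positive normal
double so that S stays finite while q = 0 proteins remain strictly the
most significant; the clamp is recorded in the score metadata.

A one-dimensional logistic regression P(positive | S) = expit(a + bS) is
fit on curated anchor sets — positives that must be near the bait (e.g.
complex co-members) and negatives that must not be (e.g.
mitochondrial-matrix proteins for a cytosolic bait). A tiny ridge penalty
(C = 10^6) keeps separable anchors finite; because the model is monotone
in S, probability and score thresholds are interchangeable and the score
threshold is canonical.

Performance is estimated by stratified 10-fold cross-validation repeated
30 times (fold assignments drawn from child seeds of one master seed),
reporting the mean and SD of held-out ROC AUC. AUC uses the rank
(Mann–Whitney) formula with ties counted ½. CV estimates performance
only; the deployed threshold is then selected on the full anchor set:
candidate thresholds are the distinct anchor scores plus +∞, the
anchor-negative FPR of each is #{neg ≥ t}/#neg, and the candidate
minimizing |FPR − target| wins. Ties break toward the higher threshold
(fewer calls); +∞ is chosen only when no finite candidate attains the
minimum, since the top finite score always matches +∞'s FPR and a rule
that defaulted to +∞ could never call anything. FPR is computed on anchor
negatives only — they are the only proteins whose negativity is known.

A fixed-cutoff alternative (log2FC strictly > 1 and q strictly < 0.05) is
provided for cross-checking classifier calls.

## SEC co-elution

Elution profiles over ordered fractions are normalized to their fraction
sums (missing counts as zero for the sum; zero-total proteins are
excluded and counted). Co-elution with the bait is summarized by Pearson
r over fractions where both profiles are quantified (pairwise deletion;
zero-filling available as a flag), requiring at least 5 overlapping
fractions and non-constant profiles. Whether classifier-enriched proteins
co-elute better than the rest is tested with a two-sided Wilcoxon
rank-sum test: midranks and a tie-corrected normal variance with ±0.5
continuity correction, switching to exact enumeration of all label
assignments when the combined sample size is ≤ 12 and tie-free. Signal
fractions inside assembly-state windows (e.g. 30S/26S/20S peaks) are sums
of normalized quantities over the union of user-supplied fraction ranges;
a helper proposes windows from local maxima of the mean anchor-positive
profile but is explicitly heuristic — peak-to-assembly assignment is a
judgement call on real data.

## Substrate calling

A substrate signature is exclusive enrichment: called enriched under
proteasome inhibition but not under vehicle, computed as a set difference
of per-condition calls (each condition thresholded against its own
matched control; a global-threshold mode exists). Candidates are
annotated against reference lists in a fixed priority order —
proteasome/ubiquitin-related, then known substrate, then unannotated
candidate, with ubiquitylation-responsive membership flagged within the
remainder — so counts always partition the set. Percentages are rounded
half-up to integer percent. A distribution-shift test (Wilcoxon rank-sum
of candidate log2 ratios vs the rest, with group medians and their
difference as effect size) distinguishes abundance increases from
recruitment when run on total-proteome and proximity-labeling contrasts
separately.

Degrader (PROTAC) experiments over the four arms {untreated, inhibitor,
PROTAC, PROTAC+inhibitor} are classified per protein in priority order:
`constitutive` (enriched untreated) > `degrader-induced` (enriched under
the degrader even without inhibitor — the induced-target signature) >
`inhibition-dependent` (enriched only in inhibitor arms — substrate-like)
> `none`. The order matters only for proteins enriched in multiple arms
and is the package's own convention.

## Structural proximity

Structures are read from PDB or mmCIF (via gemmi); alternate locations
resolve to the highest-occupancy conformer, ties to file order. The
anchor is the Cα of the last resolved residue of the bait chain — fusion
C-termini are typically unresolved in deposited models, so distances
slightly underestimate the ligase's true reach. Site distances default to
the lysine side-chain NZ (the biotinylated atom), falling back to Cα. A
site is within the labeling radius iff its Euclidean distance is strictly
less than the radius (default 100 Å = 10 nm); sites absent from the model
are reported as unresolved, not errors, and excluded from the fraction.

## Synthetic data generator

The generator provides planted ground truth for every stage. Its design,
and what it does and does not emulate:

* **Abundance**: per-protein baseline log2 intensity ~ N(20, 2), a
  typical DIA protein-report scale. Real reports have heavier tails and
  abundance-dependent variance; the generator does not model either.
* **Pairing**: bait and control replicate i share a batch offset
  ~ N(0, 0.5²) drawn once per pair, so the paired test genuinely gains
  power over an unpaired one. The offset cancels in paired differences.
* **Effects**: planted log2 enrichments added to bait samples only —
  anchor positives +4 by default, planted interactors/substrates per
  condition spec. Replicate noise is i.i.d. N(0, rep_noise_sd²) per cell.
* **Missingness**: uniform at random, or biased toward low abundance via
  a logistic curve in baseline log2 abundance rescaled so the marginal
  missing fraction matches the configured rate.
* **SEC**: profiles are mixtures of shared Gaussian complex peaks plus a
  late free-monomer peak, scaled by a log-normal abundance and optional
  multiplicative log-normal noise (CV-parameterized, mean 1). Real SEC
  has asymmetric peaks, column carryover and fraction-to-fraction
  normalization artifacts; none are modeled.
* **Structure fixtures**: a short bait chain whose C-terminal Cα is the
  anchor plus lysine sites placed strictly inside/outside the radius
  (uniform in direction; radii uniform in [0.10, 0.95]·r and
  [1.05, 2.00]·r). Site CA and NZ coordinates coincide — these are
  geometric fixtures, not physical models, and are labeled synthetic.

Default calibration conditions (5,000 background nulls, 40 anchor
positives at +4, 200 training negatives, 300 held-out negatives, 4 paired
replicates, noise SD 0.5) are package choices for a realistic deep BioID
experiment; passing tests under them demonstrates correctness of the
machinery, not performance on any particular real dataset.

Two numerical notes on the noise-free regime used by the consistency
tests. First, "noise-free" sets the pair-batch offset to zero as well:
the offset cancels exactly in infinite precision but not bitwise through
the linear-scale round-trip, and only with it zeroed do zero-variance
differences trigger the degenerate p ∈ {0, 1} convention exactly.
Second, planted effects in noise-free runs are set at or above the anchor
effect (+5 vs +4): with p degenerate, scores are proportional to the
log2 ratio and the FPR threshold sits at the top anchor score, so exact
set recovery requires planted scores to clear it.

## Reproducibility

Every stochastic component takes an explicit seed; one master seed fans
out to stages (and to CV repeats) through `numpy.random.SeedSequence`
with fixed indices, so stages can be rerun in isolation. Identical
config + seed reproduces every output file byte for byte; tabular outputs
carry a header comment with the package version and a hash of the
configuration (excluding the output path, which must not affect content).

## Problem sizes

The shipped test suite and the calibration script use simulation sizes
chosen to exercise every code path at full statistical fidelity —
thousands of null proteins where a law-of-large-numbers or calibration
claim is tested, hundreds otherwise; the full calibration study (30
datasets of ~5,540 proteins) completes in about a second on one core.

## Known limitations

* The classifier is deliberately one-dimensional; multivariate
  extensions (e.g. adding detection counts) are out of scope.
* pi0 estimation at fixed λ is conservative on strongly non-uniform
  p-value distributions.
* The exclusive-enrichment logic is binary per condition; graded
  dose-response designs are not modeled.
* Median normalization assumes most proteins are unchanged; heavily
  asymmetric designs violate this (see above).
* The structural check measures straight-line distance, ignoring
  intervening mass and linker flexibility.
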