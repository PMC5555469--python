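# Methods

This note documents the statistical models behind `chronofly`, the
defaults and why they were chosen, and what the synthetic-data generators
do and do not emulate.

## Locomotor activity

### Data model

Beam-break counts arrive in 5-min bins (288/day), one channel per fly.
Day boundaries and Zeitgeber time are anchored at lights-on of the
entrainment schedule; under constant darkness (DD) projected ZT continues
from the last LD cycle.  Counts are nonnegative integers on a strictly
uniform time axis; monitor rows with a bad status flag are counted and
excluded at parse time.

### Daily profiles and activity levels

Display profiles use a centered moving average of width 2f+1 bins
(default f = 2, i.e. 25 min), with the window shrinking symmetrically at
the edges so the filter is phase-preserving and maps constant series to
themselves.  Profiles are folded by day after per-fly smoothing and
summarized as mean ± SEM over fly-days.  Activity level is the mean of
within-day sums of *raw* counts — smoothing redistributes but a permutation
of bins within a day cannot change the total, which several tests exploit.
The default analysis window drops the trailing days of a recording, which
serve as a survival control in this protocol.

### Chi-square periodogram

For a candidate period of P bins the series x₁..x_N folds into P columns
with means M_h (column sizes K_h) and grand mean M̄.  Two scalings of the
folded-variance ratio are kept:

* `qp = N·Σ_h (M_h − M̄)² / Σ_i (x_i − M̄)²` — a normalized ratio with
  convenient closed forms: exactly P on a noiseless P-periodic series
  (between-column and total sums of squares coincide up to the fold count)
  and 0 on a constant series.  Because between-SS ≤ total-SS, qp is bounded
  by P and is *not* chi-square distributed for multi-cycle recordings.
* `chi2_stat = N·Σ_h K_h (M_h − M̄)² / Σ_i (x_i − M̄)²` — the
  Sokolove–Bushell test statistic, approximately χ²(P−1) under the
  no-rhythm null.  This is the quantity rhythm calls are based on; the
  significance line is the χ²(P−1) quantile at 1 − α (α = 0.05 default).

Candidate periods run at the native bin resolution over 16–32 h by
default (~193 candidates at 5-min bins).  A day-resolution scan performs
~200 correlated tests; with an uncorrected pointwise line essentially
every white-noise series crosses it somewhere (measured 100% familywise
false-rhythmicity on Poisson noise, versus 4.4% for a single candidate).
`classify_rhythmicity` therefore Bonferroni-corrects the threshold across
the scanned candidates by default; the measured familywise rate drops
below 1%, while genuinely rhythmic series at realistic count levels exceed
even the corrected line by three orders of magnitude, so period recovery
is unaffected (mean absolute error < 0.05 h at the simulated conditions;
the period grid itself quantizes at 1/12 h).  The liberal pointwise rule
remains available (`correction="none"`).  The periodogram always runs on
raw counts: display smoothing correlates neighboring bins and inflates
the statistic.

Period estimates are reported only for rhythmic flies; exact ties in the
peak excess break toward the candidate closest to 24 h.  Cohort summaries
give percent rhythmic over all flies and period mean ± SD over rhythmic
flies only.

## qPCR quantification

### Relative expression

Technical replicates are averaged into one Cq per biological sample; a
sample whose technical spread exceeds 0.5 cycles is flagged but kept —
there is no principled exclusion rule, and silent dropping would bias
dispersion estimates downward.  Relative expression per biological
replicate is E^−(Cq_gene − Cq_ref) with amplification efficiency E = 2.0
(perfect doubling, the classic ΔCq assumption; configurable).  Gene series
are normalized to the sample with the highest mean expression *jointly
across conditions*, so curves recorded at several temperatures share one
relative axis with a single global maximum of 1 — required for
cross-temperature amplitude comparisons; per-condition normalization is
available by flag.  Normalization is idempotent, and with zero simulated
noise the round trip through the generator recovers the generator's
relative-abundance function exactly up to that one global scale factor.

### Phase

The acrophase is estimated either as the argmax of the per-timepoint means
(ties to the earliest ZT; granularity = the sampling interval, 2 h in the
standard design) or by a single-harmonic cosinor, the least-squares fit of
m + a·cos(2π(t − φ)/24) via the linear cos/sin parameterization, with
a ≥ 0 enforced by the phase convention and R² reported as fit quality.
Under the default noise model the cosinor lands within ±1 h of the true
acrophase in ~95% of runs, while the argmax wobbles by its 2-h step —
the cosine is flat near its peak, so neighboring timepoints differ by only
a few percent.  Phase shifts between conditions are minimal signed
circular differences mapped to (−12, +12] h; negative = advance.

### Cycling and splicing statistics

Cycling is tested by a one-way F test of timepoint effect on log relative
expression across biological replicates (log because Cq noise is additive
in cycle units, hence multiplicative in expression), BH-corrected across
genes.  A zero-variance series has no defined F statistic and is flagged
non-cycling.  Splicing efficiency is spliced/(spliced+unspliced) per
replicate; condition contrasts are reported as differences in percentage
points with Welch t-tests on the log isoform ratio log(spliced/unspliced)
(the efficiency's logit, where group variances are comparable), BH-corrected
across pairs.  These tests are the package's own choices of standard
procedure, not reconstructions of any particular published analysis.

## Motif enrichment

IUPAC consensi are scanned with overlapping matches on both strands;
minus-strand sites are recorded at the forward coordinate of their 5′ end.
Palindromic sites (e.g. the canonical E-box CACGTG) count once per strand,
i.e. twice per location, in both the observed and the expected count, so
the fold ratio stays consistent.  The expected count in random DNA is

    strands · (L − k + 1) · Π_j Σ_{b ∈ allowed_j} p(b)

with the uniform background p = 1/4 by default (an observed-composition
background is available for sensitivity analysis).  `N` bases never match
and their windows are subtracted from the scannable offsets.  Regions of
kind `ups_plus` are stored as separate pieces (upstream sequence + first
intron); matches never span the junction because the pieces are not
contiguous genomic DNA, and each piece contributes its own L_part − k + 1
offsets.  Worked example: 4 sites of an 8-mer in 5,000 bp on both strands
give 4 / (2 · 4993 · 4⁻⁸) ≈ 26-fold enrichment.  The default motif set
ships the E-box family (CACGTG, CACGTH, AACGTG) and the 8-bp D-box
TTATGTAA; other circadian elements (RRE, Adf1, ...) have no single
canonical consensus and must be supplied by the user.

## Synthetic data

The generators reproduce the statistical structure the analyses assume,
at the standard experimental scales: 5-min bins, ≥ 10–14 recording days,
2-h qPCR sampling with 3 biological × 3 technical replicates, triplicate
splice assays, kb-scale promoters.

* **Activity**: Poisson counts (optionally negative-binomial via a gamma
  mixing parameter, off by default) with rate = baseline + circular-
  Gaussian bouts recurring every τ hours from lights-on; under LD the
  scotophase rate is multiplied by a dark-attenuation factor.  Defaults —
  baseline 2 counts/bin, one bout of height 10 and SD 2 h at ZT 10, dark
  attenuation 0.3 — give day totals and signal-to-noise in the range of
  real monitor recordings of large flies.  Arrhythmic flies are generated
  by permuting the rate vector within fly, destroying periodicity while
  preserving expected total activity, so activity-level analyses see no
  difference.  The long-run per-bin mean converges to the rate function.
* **qPCR**: Cq = ref_Cq − log_E(rel(t)) + biological + technical Gaussian
  noise in cycle units (bio shared across a sample's technical wells);
  rel(t) = mesor·(1 + A·cos(2π(t − peak)/24)), A < 1.  Default noise
  (bio 0.25, tech 0.15 cycles) matches routine SYBR-green head-RNA assays.
  A flat reference gene is always emitted.
* **Splice assays**: independent multiplicative log-normal noise on
  spliced and unspliced levels around a requested efficiency in (0, 1).
* **Promoters**: i.i.d. bases at a requested GC fraction with
  non-overlapping planted motif instances (degenerate positions
  concretized at random; minus-strand plants reverse-complemented); the
  ground-truth plant map is returned and is always a subset of the
  scanner's output.

All generators are bit-reproducible for a fixed seed.  What they do *not*
emulate: within-day temperature cycles, bout/burst autocorrelation in
activity (real beam breaks cluster), sex or individual differences beyond
the arrhythmic fraction, non-sinusoidal expression waveforms, or
primer-specific amplification efficiencies.  Passing tests therefore show
the estimators recover the truth under the assumed noise laws — they do
not certify behavior on data violating those laws.

## Numerical and design choices

* Periodogram candidates are integer bin counts; a 5-min grid quantizes
  periods at 1/12 h, well inside the ±0.25 h recovery target.
* Zero-variance series short-circuit to statistic 0 (nothing significant).
* Simulation sizes in the test suite (200 flies per τ, 500-series noise
  panels, 1,000-replicate calibration loops, 20,000-draw motif nulls) were
  chosen so Monte-Carlo error is several times smaller than each asserted
  tolerance.
* The pipeline runs stages sequentially, communicating only through files,
  and writes a manifest of config hash, seed and per-file SHA-256 checksums;
  timestamps are recorded but excluded from determinism comparisons.

## Known limitations

* The chi-square periodogram tests only for *some* periodicity in the
  scanned band; it does not separate multiple simultaneous periods.
* Argmax phase estimates are quantized to the sampling interval and
  unstable for low-amplitude genes; prefer the cosinor for shift analyses.
* Fold enrichment carries no significance measure by design (observed
  counts of rare motifs are small; a fold of 26 can rest on 4 sites) —
  treat large folds as hypotheses, not detections.
* Monitor parsing requires a uniform time axis and rejects files with
  interior gaps rather than imputing.
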