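# Methods

## Sleep scoring

Sleep is scored behaviourally from uniformly sampled velocity traces.  A
frame is *immobile* iff its velocity is strictly below the mobility
cut-off (default 6 mm/s, separating active swimming from passive drift); a
velocity exactly at the cut-off counts as active swimming.  A *sleep bout*
is a maximal run of immobility of at least `min_bout_s` (default 60 s,
"60 s or more"), with durations measured in whole frames times the frame
period so the boundary case (exactly 60 frames at 1 Hz) qualifies.
"Consolidated" is read as uninterrupted: `max_gap_s` defaults to 0, and a
positive value merges immobile runs across mobile gaps up to that length.

Missing frames are conservative against inflating sleep: under the default
`break` policy a missing frame counts as mobile and interrupts any bout;
under `fill_short`, missing runs of at most 1 s inherit the previous
frame's state and longer runs still break.

Window conventions: total sleep counts each bout's *overlap* with the
window (this conserves time — profile bins and windowed totals agree
exactly), while the bout count and mean bout length use bouts whose *onset*
falls in the window, with the full duration entering the mean (counts stay
integral).  Sleep profiles apportion bout time to bins by overlap; the bin
axis is Zeitgeber time ((t − lights-on)/3600, not wrapped at 24 h so the
axis stays monotone), with day = ZT0–14 and night = ZT14–24 under the
husbandry 14:10 light:dark schedule.

### Transition probabilities

Two estimators are provided, with different purposes:

* `transition_probabilities` labels 1-s epochs *sleep* iff they lie wholly
  inside a scored sleep bout and estimates P(doze) = (# wake epochs whose
  successor is sleep) / (# wake epochs with a successor), and P(wake)
  symmetrically.  This is the sleep-pressure / sleep-depth readout used for
  group comparisons; because the sleep label embeds the 60-s rule, it is a
  *conditional* quantity, not an estimate of any generative rate.
* `estimate_epoch_transition_rates` labels epochs directly by quiescence
  (all frames immobile) and counts epoch-to-epoch transitions.  For a
  two-state chain whose dwell times may be shorter than a sleep bout this
  is the estimator that recovers the generative per-epoch probabilities;
  the bout-conditioned one is severely biased whenever mean dwell times are
  comparable to 60 s (the censoring removes most short quiescent runs).

A state contributing no epoch with a successor yields a missing value
(NaN), never zero.  Epoch length defaults to 1 s, the resolution at which
the sleep rule is defined.

## Synthetic locomotor model

The hidden state is a two-state Markov chain (active/quiescent) on 1-s
epochs with per-epoch transition probabilities `p_doze_true` and
`p_wake_true`; defining dynamics on epochs rather than frames keeps the
probabilities frame-rate independent.  Dwell times are therefore geometric;
the generator samples dwell lengths directly (exactly equivalent to
per-epoch stepping, and checked against an independent per-epoch stepping
oracle in the tests), making the long-run quiescent fraction
`p_doze/(p_doze+p_wake)`.  States expand to the frame grid by epoch index;
velocities are emitted per frame from a state-specific normal truncated at
zero (velocities are non-negative), sampled by inverse CDF.

Default emissions are active 20 ± 4 mm/s and quiescent 1 ± 1 mm/s: a
realistic burst-swim vs drift contrast in which each state sits several
standard deviations from the 6 mm/s cut-off, so per-frame misclassification
(~2×10⁻⁴ for active frames) stays small relative to the default transition
probabilities.  Parameters that do not straddle the cut-off trigger a
warning (the scenario is ill-posed for velocity-threshold scoring), not an
error.  Cohorts derive per-subject seeds from (master seed, subject index)
via a seed sequence, giving independent, reproducible streams.

What the generator does **not** emulate: circadian modulation of the
transition probabilities, bout-length distributions heavier-tailed than
geometric, tracking artefacts (reflections, dropped frames in bursts), or
arena-position effects.  Passing tests therefore validate the scoring
arithmetic and estimator calibration, not robustness to those real-data
features.

## HCR %RE

Per sample, over live-gated events, `F = N × MFI / S`; `%RE = 100 F_t/F_u`.
Conventions: live gating uses the viability-dye channel (live iff dye <
threshold); scatter channels are generated but not used for gating, as the
dye is the quantitative criterion.  The GFP-positive threshold is either
manual or the q-quantile (default q = 0.999, linear-interpolation /type-7
convention) of an untransfected control's live-gated GFP intensities — a
reproducible stand-in for a hand-drawn positivity line.  N = 0 gives
MFI = NaN but F = 0; F_u = 0 leaves %RE missing with a warning.  %RE is
invariant under a common rescaling of both samples' intensities (with the
threshold rescaled alike), and on simulated pairs with equal GFP⁺ intensity
distributions it estimates the ratio of transfection/repair efficiencies.

The flow generator draws each intensity component log-normally with the
`*_mean` parameter as the component median and `*_sd` as the log-scale
sigma; defaults separate the components by >5 log-sd, so gates recover
truth labels at the >99% level.  Spectral unmixing, compensation and FCS
binary parsing are out of scope; events arrive as exported CSV tables.

## Image quantification

The z-projection is the pixelwise arithmetic mean over slices (the ImageJ
"Average Intensity" projection); a max projection is available and
selectable for the per-nucleus path (default mean, mirroring the
ROS-imaging pipeline).  ROI membership uses pixel centers — pixel (row r,
col c) has center (c, r) — inside the polygon, matching common ImageJ
behaviour; for the simple polygons required, even-odd and winding rules
coincide.  A polygon containing no pixel center is an error naming the ROI.
Per-nucleus means average the projected intensity over each label's pixels;
background subtraction (median of label-0 pixels) is off by default since
the fluorescence figures report raw means, and available as a policy.

The image generator places non-overlapping uniform-intensity disks (value =
background + planted intensity inside the disk) with bounded rejection
sampling, then adds independent per-slice Gaussian read noise clipped at
zero.  Uniform disks were chosen over soft-edged profiles so that, at zero
noise, per-nucleus means equal the planted intensities *exactly* after
median-background subtraction — an identity the tests exploit.  Real nuclei
have soft edges, chromatin texture and partial-volume effects; the
generator validates the measurement arithmetic, not segmentation quality.

## Expression response

* **BH adjustment** delegates to statsmodels' step-up implementation
  (checked against an explicit step-up loop in the tests); NaN inputs are
  an error.
* **Classification**: a gene responds in a population iff padj < α
  (default 0.05); shared iff significant in both, population-specific iff
  in exactly one; direction is the sign of log2FC.  Tables are outer-joined
  on gene, with absence treated as non-significance; duplicate gene ids are
  an error.
* **Ranking**: score = −log10(p) × sign(log2FC) (multiplication by sign; the
  "/sign" form is identical for sign ±1).  p = 0 is clamped to the smallest
  positive p in the table, floored at 1e-300; log2FC = 0 maps to score 0
  (the only direction-free value).  Ties break lexicographically by gene id
  so the ranking is a strict total order.
* **Preranked GSEA**: the running sum increments by |score|^weight
  (normalised over hits) at hits and decrements by 1/#misses at misses;
  ES is the signed extreme, so |ES| ≤ 1, and weight 0 recovers the
  classical Kolmogorov–Smirnov form.  A set covering the whole universe has
  ES = 1 by convention.  The null permutes gene labels (hit positions),
  since preranked summaries carry no phenotype labels to permute; the null
  distribution is shared across sets of equal size within one call.  The
  two-sided p-value is (1 + #{|ES_null| ≥ |ES|}) / (n_perm + 1); NES
  divides ES by the mean |null ES| of matching sign; p-values are
  BH-adjusted across reported sets.  Sets are filtered to intersection
  sizes in [10, 500] by default (configurable).  This permutation scheme is
  a statistic-family match to, not a numerical clone of, adaptive
  multilevel split implementations.
* **ΔΔCt**: technical replicates are averaged on the Ct scale (the
  conventional choice); ΔCt = Ct_target − Ct_housekeeping per sample
  (housekeeping default *rpl13a*; a sample without it is an error naming
  the sample); ΔΔCt = mean ΔCt(condition) − mean ΔCt(reference); fold
  change = 2^(−ΔΔCt), exactly 1 for the reference condition.

The DE generator draws each gene's observed log2FC as planted effect
(default ±2, sign split evenly) plus N(0, se) noise (se = 0.4) and converts
the z-score to a two-sided normal p-value, so null p-values are uniform and
BH behaves as designed; planted responders at the defaults are detected
with high power while the false-discovery proportion among
population-specific calls stays at the nominal level.  Real DE statistics
have gene-wise dispersions, filtering and independent-filtering artefacts
that this generator deliberately omits.

## Group statistics

One-way ANOVA and the unpaired t-test are computed from their closed-form
sums of squares (scipy supplies only tail probabilities), making them
directly checkable by hand and against library oracles to 1e-10.  Both
p-values are two-sided; the t-test defaults to Welch with a pooled-variance
flag (the classical two-group identity F = t² holds for the pooled form).
Degenerate inputs: zero within-group variance with unequal means reports
F = ∞ with p = 0; all-identical observations are an error; zero-variance
equal-mean t-tests return t = 0, p = 1.  SEM uses the n−1 sample standard
deviation and is undefined (NaN) for n = 1.  Mixed-effects and repeated-
measures designs are intentionally not re-derived here; they are routine
fits for standard libraries and outside this package's scope.

## Problem sizes and determinism

All quantifications are deterministic given inputs; all simulations take
explicit integer seeds, and `scripts/acceptance.py` threads its single
`--seed` through every stage.  The acceptance script uses 2,000 random
flag sequences for the bout oracle, a 50-subject × 24-h × 1-Hz cohort for
parameter recovery, 20 × 50,000 events for %RE, 100 × 2,000-gene
replicates for classification calibration, and 100 null sets × 1,000
permutations for enrichment-p uniformity — sizes at which the Monte-Carlo
error of each reported rate is well below the margins being checked.
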