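# Methods

`ramplux` analyzes calcium-imaging recordings of visual neurons driven by
slow, whole-field luminance ramps, of the kind used to characterize
tectal pyramidal neurons (PyrNs), their retinal-ganglion-cell (RGC)
inputs, and torus-longitudinalis feedback neurons (SMTLs) in larval
zebrafish. This note describes the models, the defaults and their units,
the synthetic-data generators, and the numerical choices made where the
underlying analysis conventions were open.

## Stimulus model

The luminance ramp is a triangular wave: a linear rise from `min_lux`
(default 0.4 LUX, a dim-adapted background) to `max_lux` (32 LUX) over
one ramp leg of `ramp_s` seconds, then a linear fall, repeated for
`n_cycles` cycles. Standard legs are 10 s and 30 s, i.e. 20 s and 60 s
cycles. Cycles start at the luminance minimum; the phase tag uses
half-open legs (cycle time 0 is RISING, the apex is FALLING) so every
sample has an unambiguous phase. The receptive-field stimulus is a
6 x 4 grid of 15° squares per hemifield (90° x 60° span), each shown for
10 s with a 10 s gap, in a pseudorandom order drawn from an explicit
seed that is recorded with every output.

## Trace preprocessing

Traces are z-scored as z = (x − μ)/σ with μ and σ computed from stimulus
onset to stimulus end and applied to all samples. σ uses the population
(N) denominator; the sample convention is available via `ddof=1`. A
constant window is flagged rather than divided (the flag propagates to a
NONRESPONSIVE call). Traces whose z-score never exceeds ±0.5 over the
stimulus window are gated out as unresponsive; the boundary value itself
does not count as a response.

A practical property of this gate is worth stating: after z-scoring, any
trace has unit variance over the window, so a pure-noise trace with
independent samples will essentially always exceed ±0.5 somewhere. The
gate therefore catches near-constant traces (its stated purpose — cells
with "no obvious change in fluorescence"), while noise-only units are
identified downstream by the classifier and by the absence of a
significant peak. Correlated, drifting real-world noise can behave
differently; passing the gate on synthetic i.i.d. noise says nothing
about that regime.

Cycle averaging folds the windowed samples onto a canonical grid of
`round(period × rate)` points by index (equivalent to nearest folded
time for uniform sampling) and averages pointwise; partial trailing
cycles are discarded, and the first (indicator-transient) cycle is
included by default. No resampling or interpolation happens at this
stage.

## Peak kinetics

A significant peak has topographic prominence strictly greater than 0.75
z-units (lowest-contour-line definition). Detection runs on a
three-period tiling of the cycle response, so peaks straddling the cycle
seam are found exactly once; the implementation (scipy's peak finder on
the tiling) is verified exactly against a brute-force circular-walk
oracle over an exhaustive grid of ~14,000 short signals.

Half-height is `baseline + (height − baseline)/2` with the baseline
taken as the minimum of the cycle-averaged trace; a
prominence-referenced alternative is switchable
(`baseline="prominence"`). Crossing times are linearly interpolated
between samples.

* **LUX-at-half-max** maps the rising (pre-peak) half-height crossing
  through the triangular luminance trajectory: "reached 50% of the peak"
  is read as response onset. For multi-peak (DUAL) responses the most
  prominent falling-leg peak — the OFF peak — is used; if no peak lies on
  the falling leg the most prominent peak is used with a warning.
* **Width-at-half-max** is the time between the two half-height
  crossings; responses with several significant peaks report the mean of
  the per-peak widths. A crossing not found within one cycle truncates
  at the cycle bound and flags the peak.

Because firing kernels live in luminance space, the same kernel played
on a 30 s leg produces three-fold wider temporal responses than on a
10 s leg; the measured ratio converges to 3.0 in the fast-indicator
limit and falls slightly below 3 with slow-indicator smearing. No
deconvolution is attempted: with a slow indicator these statistics
describe the fluorescence signal, not underlying firing onset/duration.

## Classification

Features are the cycle-averaged z-trace resampled to L = 40
phase-aligned points (linear interpolation on the closed cycle). The
supervised route is a linear multiclass SVM (one-vs-one, C = 1) with
stratified 5-fold cross-validation (shuffled folds under a fixed seed);
per-fold accuracies and the confusion matrix pooled over held-out folds
are reported, and the final model is refit on all data. Items failing
the responsiveness gate are forced NONRESPONSIVE after prediction.

The unsupervised route runs K-means for k = 2..8, keeping the best of
1000 random initializations per k (tests use fewer replicates for
speed; the default matches the study condition), scores each k with the
Calinski-Harabasz criterion, and takes the knee of the score-vs-k curve
(maximum perpendicular distance from the chord joining the curve's
endpoints — a simple, deterministic elbow rule; the original MATLAB
utility's internals are not reproduced). Clusters are binned to classes
by pushing each centroid through the peak detector: no significant peak
is NONRESPONSIVE; peaks on both ramp legs are DUAL; otherwise the most
prominent peak's luminance decides ON (upper half of the range) versus
OFF (lower half).

Population summaries report per-class fractions among responsive units,
with SEM across animals when animal identifiers are supplied.

## Movie segmentation

A pixel is active when its temporal maximum reaches 175% of its temporal
mean (a minimum change of 75% over that pixel's average). The rule
presumes background-subtracted input; a ΔF/F-style reading is available
via `mode="dff"`, and non-positive-mean pixels are excluded with a
warning. Active pixels form 8-connected components, which are
recursively split where a subgroup's mean trace correlates below
`corr_min = 0.7` with the rest — but a subgroup whose mean still tracks
the component is merged back, so single-pixel noise does not fragment
ROIs. Fragments under `min_size_px = 4` are discarded. Both `corr_min`
and `min_size_px` are free parameters of an unpublished original tool
and are exposed as options. The active-area fraction is the summed ROI
area over the area of a user-supplied total-label mask; layer tallies
assign each ROI to the anatomical layer under its centroid (majority
pixel as tiebreak, `unassigned` when no layer overlaps). Anatomy is
never inferred — layer masks are user input.

## Receptive-field mapping

Each trial's response is the maximum z within the presentation window
plus a 2 s lag (the slow indicator peaks after square offset; the lag is
configurable and covers readings with or without the inter-stimulus
gap). z uses the mean and SD of the entire recording — and since both
hemifield presentations belong to one session of the same unit, the
statistics are pooled across both sides (`rf.binocular_maps`).
Normalizing each hemifield against only its own trace makes a silent
hemifield's z-scores pure noise in units of its own SD, and the
max-over-trial statistic then crosses any fixed threshold spuriously;
pooling scores silence against the unit's genuine response variance.

RF size counts positions with z ≥ 1.5 (inclusive). A unit is binocular
when both hemifields hold at least one suprathreshold position; the
contra/ipsi size ratio is undefined for monocular units, and
8-connected suprathreshold components per hemifield describe compound
(discontiguous) RFs. Tier comparisons report mean size ± SEM per tier
and whether mean(PyrN) > mean(SMTL) ≥ mean(RGC) — the signature of
union convergence.

## Synthetic data

The generators provide every input modality with ground truth attached.

**Ramp traces.** Firing kernels are Gaussians in (luminance, phase)
space: ON centered at the luminance maximum, OFF at the minimum (width
18% of the luminance span), DUAL as two phase-gated Gaussians at
mid-range (width 15% of span) with the falling-phase (OFF) peak stronger
(`dual_ratio = 0.6` scales the rising peak). Defining kernels over
luminance rather than time makes LUX-at-half-max invariant to ramp
duration, mirroring the consistency of class kinetics across 10 s and
30 s ramps. Firing is convolved with a causal double-exponential
indicator kernel (rise 0.2 s, decay 1.8 s — slow GCaMP6s), simulated on
a 50 ms grid, sampled at 2 Hz (the 1–2 Hz acquisition regime), and
corrupted with additive i.i.d. Gaussian noise, by default 20% of the
unit's amplitude. Datasets draw per-unit jitter on center, width, and
amplitude and are byte-reproducible under a seed. Ground-truth
LUX-at-half-max is computed independently of the analysis path, on a
10 ms grid over a steady-state cycle by direct argmax/half-crossing
walking. Photon shot noise, drift, and motion are out of scope.

**Movies.** Active regions share a noiseless kernel-driven trace
(amplitude = SNR × pixel noise SD over a baseline of 50 with noise SD
10) plus per-pixel noise. Movie fixtures use brief-firing kernels
(width 6% of the luminance span): sparse ramp-responsive terminals spend
most of the recording near baseline, which is precisely the regime in
which a max-over-mean threshold is informative. With i.i.d. pixel noise
at SNR 5 the 175% rule recovers region counts exactly and area within a
few percent, but a strict per-pixel superset of the truth mask is not a
stable property — an individual pixel misses whenever its few apex-time
noise samples are all slightly negative (~10⁻³ per pixel).

**RF scenes.** RGCs get compact 1–2 position footprints placed
retinotopically in one hemifield; each SMTL is the union of 3 RGC
footprints drawn from both hemifields; each PyrN is the union of 3 SMTL
footprints plus one direct RGC. Trial traces fire at unit amplitude
whenever the presented square lies in the footprint, convolved and
sampled as above, with a noise floor of 5% of amplitude — the
ROI-averaged strong-responder regime. At substantially higher noise the
Z ≥ 1.5 rule saturates through max-statistic bias (24 windowed maxima
per hemifield) regardless of footprint, which is a property of the rule
rather than of the generator.

What passing these tests shows — and does not. The suite demonstrates
that the implementation recovers known parameters under the stated
synthetic regimes (Gaussian kernels, additive i.i.d. noise, perfect
registration). It does not certify behavior under real-data features the
generators omit: correlated noise, bleaching and drift, motion residue,
overlapping sources, or non-Gaussian response shapes.

## Numerical choices and degenerate inputs

Constant traces are flagged, never divided. Peaks at the cycle seam are
reported once in [0, period). Half-max crossings failing within a cycle
truncate with a flag. Classes with fewer examples than folds, empty
groups/tiers, schedule mismatches, overlapping movie regions, and
movies shorter than two cycles raise errors. All randomness flows
through explicit seeds; K-means, fold shuffling, and every generator are
deterministic under a fixed seed.

## Problem sizes

Default analysis and acceptance runs use 50 units per class for
classification, twenty 240 x 64 x 64 movies, and 50 convergence scenes
(12 RGC, 6 SMTL, 4 PyrN each) — population sizes comparable to the
recordings the pipeline is modeled on, and the full suite completes in
well under a minute.
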