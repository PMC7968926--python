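# Methods

This note documents the models, estimation procedures and design
choices behind `cytoquant`, and what the synthetic-data generators do
and do not emulate.

## Ca²⁺ flux scoring

Each reporter cell's raw intensity series is min–max normalized:
`v_i = 100·(x_i − min x)/(max x − min x)`. Normalization is per cell, so
the threshold is expressed on a common [0, 100] scale; constant traces
raise a degenerate-trace error. A **flux event** is a maximal contiguous
run of samples with `v ≥ threshold` (default 50, configurable); runs
whose end-to-start gap is shorter than the merge window (default 20 s)
are merged, so fluorescence maintained — or briefly interrupted — over
20 s counts as a single flux. The "~20 s" window is resolved to exactly
20.0 s and exposed as a parameter. Event membership uses `≥ threshold`
while total-flux-time uses strictly `> threshold`, mirroring the two
phrasings of the protocol ("minimum peak fluorescence of 50" vs
"greater than 50"); both comparisons are configurable. The peak
criterion is implemented as threshold runs with merging; no additional
local-maximum shape requirement is imposed.

Per-cell metrics: event count, rate per minute (`n / (duration/60)`,
duration = samples × dt), total flux time (supra-threshold samples ×
dt), and — when deposit times are known — the proportion of flux time
inside the union of `[d, d + 20 s]` response windows vs over its
complement. Empty window sets or complements yield flagged undefined
proportions rather than silent zeros. Cells that never flux are excluded
and reported, matching the assay's exclusion rule.

**Threshold validation.** All timepoint values of all control cells are
pooled and the 90th/95th percentiles computed with linear interpolation
between order statistics (the most common convention; the method is
recorded in output metadata). The configured threshold is validated iff
it lies within that bracket. A per-cell alternative to pooling is
available behind a flag.

**Inference.** The condition contrast (proportion of time in flux,
case vs control) uses the two-sided Wilcoxon rank-sum test; the deposit
contrast pairs each cell with itself (in-window vs out-of-window
proportion) and uses the two-sided Wilcoxon signed-rank test. Zero
differences are dropped; ties among |differences| use midranks. Exact
null distributions are used for combined n ≤ 25 without ties, the
normal approximation with tie correction otherwise. With 15 pairs all
in one direction the exact two-sided p is 2/2¹⁵ ≈ 6.1 × 10⁻⁵.

## Deposit calling from kymographs

A kymograph is a time × position intensity matrix along a cytoneme
(`dt` s/frame, `dx` µm/pixel, tip column known). **Background** is the
median of the line-scan intensities excluding detected puncta
(two-pass), a robust choice since puncta are sparse. **Puncta** are
local maxima strictly above 1.5× background (the >50%-above-background
rule; factor configurable), with maxima closer than 3 pixels merged to
the brighter — a single diffraction-limited spot can otherwise
double-detect under noise. **Tracks** are formed by greedy
nearest-neighbour linking within a per-frame step bound (default
max(2 µm, 4·dx)); a candidate detection dimmer than 0.55× the track's
median intensity is not linked (genuine puncta keep their brightness;
barely-threshold noise does not). Broken trajectories are stitched when
one track ends within 2 frames and 1 step-bound of another's start.
Track direction is classified by net displacement toward the tip with a
0.5 µm dead-band (anterograde / retrograde / stationary).

A **deposit** is called when an anterograde track of ≥ 5 frames ends
within the tip zone (default 1 µm) before the end of the recording —
the punctum is absent in the successive frame — with no retrograde step
exceeding the dead-band over its final three frames. One dangling
trailing sample that jumps away from the tip right before disappearance
is trimmed as detection noise (true retraction persists as a track).
The anterograde and minimum-length requirements operationalize the
definition of a deposit as a punctum that *traversed* the cytoneme to
the tip; they also make the caller robust to noise tracks. Absence is
judged over a single successive frame. Called times are in seconds and
feed the flux pipeline's deposit windows unchanged.

Detection operates on a hard intensity threshold, so its margin is
`(peak − 1.5·background)/σ`. With the default generator settings (peak
3× background, noise σ = background/5, i.e. peak SNR 10) recall and
precision exceed 0.95; they remain so at peak SNR 5. At peak SNR 3 the
margin at the 1.5× rule is below 0.5 σ per frame and recall degrades to
≈ 0.9 — an intrinsic limit of thresholded detection, noted here rather
than hidden by smoothing that would change the rule's semantics.

## FRAP transport velocity

Recovery at a region of interest a known distance `d` from the cell
body reports directed transport: `v = d / τ½`. The pipeline:

1. **Bleach correction** — `corrected_i = frap_i · (ref_pre / ref_i)`
   with a matched unbleached reference region; a multiplicative
   mono-exponential acquisition loss cancels exactly.
2. **Normalization** — 100% is the mean of the pre-bleach window
   (default 5 s baseline), 0% the first post-bleach frame.
3. **Halftime fit** — least squares of `R(t) = P·(1 − 2^(−t/τ))` on the
   post-bleach samples (t rebased to 0 at the bleach); τ is the
   halftime by construction. This single-exponential is the minimal
   model consistent with one τ½ per ROI; a model-free 50%-crossing
   estimate is provided as a cross-check (`halftime_by_crossing`).
   Initial values come from the curve itself (tail mean, first
   half-maximum crossing); bounds keep P ∈ [0, 300]% and τ > 0.
4. **Classification** — a curve is non-recovered when the fit fails or
   when `min(P, achieved recovery at the end of acquisition)` is below
   the plateau cutoff (default 20%). Classifying on achieved recovery
   matters: noise can be fit by a huge plateau with τ far beyond the
   recording, which is not a recovery. The 20% cutoff cleanly separates
   the simulated transport-blocked (ionomycin) and vehicle regimes and
   is configurable.
5. **Aggregation** — ROI velocities `d/τ½` are averaged per cytoneme
   over its recovered ROIs (2–3 ROIs per cytoneme typical); condition
   summaries report mean ± SD over cytonemes, the non-recovery
   fraction, and a two-tailed t-test between two conditions. Averaging
   at ROI level instead is available. The time-averaged-velocity
   integral formulation reduces to the per-ROI quotient under constant
   per-ROI velocity, which is how it is implemented.

All analysis is 1-D: a cytoneme is thinner than the diffraction limit,
so the recovery is a single vector from the cell body and no 2-D
diffusion model is fit.

## Masked colocalization

Cytonemes are segmented from the membrane channel: global Otsu
threshold (overridable) → 3×3 binary opening (removes single-pixel
speckle while preserving ridges ≥ 3 px wide) → removal of
cell-body-scale blobs (area cap, default 25 µm²) and fragments below
half the minimum length → per-object skeletonization. Object length is
the geodesic skeleton length (unit steps plus √2 diagonals) × pixel
size; width is `2·(mean distance transform along the skeleton) − 1 px`,
the −1 correcting the EDT's centre-to-first-background offset. Objects
are retained when length ≥ 10 µm and width ≤ 0.2 µm (both configurable;
on real diffraction-limited images the apparent width exceeds the
physical 200 nm criterion, so the cap must be adjusted to the imaging
system — a caveat that does not apply to the synthetic fields, which
are generated at ground-truth scale). Masking requires the minimum
length to span at least 20 px.

Pearson's r between two channels is computed over mask pixels only;
it is location- and scale-invariant, so no background subtraction is
applied. Constant-in-mask channels yield a flagged undefined result;
fewer than 10 pixels flags under-powered. The puncta-referenced variant
segments reference-channel pixels above `puncta_factor ×` (in-mask
median) — the same 1.5× rule as deposit detection — dilates by one
pixel to capture pixels "in contact with" the ligand, intersects with
the mask, and correlates the other two channels there. Batch analysis
yields one r per cytoneme object and per-condition box-plot statistics
(median, quartiles, min/max, n); field-level errors are recorded
without aborting the batch. The original imaging workflow used
CellProfiler pipelines that are not published; this module reproduces
the stated measurements (masked Pearson, puncta-referenced Pearson),
not any particular pipeline bit-for-bit.

## Morphometry and occurrence

A projection is a cytoneme iff length ≥ 10 µm, width ≤ 0.2 µm
("approximately < 200 nm" resolved to ≤ 0.2 µm inclusive,
configurable), and not substrate-attached (basal protrusions in
continuous coverslip contact are excluded). Live-imaging motility is
carried as metadata, not computed from movies. Occurrence = 100 ×
positives/scored, reported with a Wilson 95% interval — an addition to
the conventional mean ± SD over coverslips, both of which are emitted;
scoring fewer than 100 cells per condition triggers a warning.
Cytoneme-to-cell-body intensity ratios are ratios of pixel means (≥ 10
px each; zero body mean flags the ratio undefined). Group comparisons
follow the field's convention: two-tailed Student t-test for two
groups, one-way ANOVA with Tukey HSD post-test for more, with stars at
0.05/0.01/0.001/0.0001. Where replicate structure is ambiguous
(coverslips vs biological replicates), across-coverslip dispersion is
the default and replicate-level aggregation is left to the caller.

## Synthetic data

Generators are pure functions of (parameters, seed) and always emit
ground truth; the defaults are the study conditions of the assays they
emulate.

**Calcium traces** (15 min at 1.7 s/frame): baseline 100 AU with
Gaussian noise (σ 3), transients with a 2 s linear rise and exponential
decay (visible duration 35–70 s), amplitudes U(60, 120). The summed
transient signal passes through `sat·tanh(S/sat)` (sat = 150):
overlapping transients saturate the indicator rather than stacking,
which keeps per-event peaks comparable within a cell — real GECIs
saturate, and without this a cell's largest overlap would set the
normalization max and push single events below the relative threshold.
Spontaneous events arrive as a Poisson process (0.3/min → effective
scored rate ≈ 0.27/min in controls after merging); deposit-coupled events fire with
probability 0.9 at a U(10, 20) s latency after their deposit, per the
observed response delay. These rates and shapes were set so the control
condition reproduces two stated properties of the real control data —
the pooled normalized distribution brackets the threshold of 50 between
its 90th and 95th percentiles, and ligand-contacted cells flux at more
than twice the control rate (12 deposits per case cell per 15 min) —
and then frozen. The generator does not model photobleaching of the
reporter, cell movement, focus drift, or amplitude run-down; the
amplitude distribution is a parameter, not an assertion about R-GECO
photophysics. Passing tests therefore demonstrate correctness of the
scoring pipeline under the stated statistical structure, not robustness
to every artifact of live imaging.

**FRAP** (5 s baseline + 120 s recovery at 277 ms/frame): each ROI at
distance d recovers as `plateau·(1 − 2^(−t/τ))` with `τ = d/v_true`
(constant tip-ward velocity; default plateau 0.9, noise σ 4% of
pre-bleach), multiplied by `exp(−b·t)` (default b = 0.002/s) to emulate
acquisition loss, with a matched reference trace for correction.
`recovery=False` emulates transport blockade: post-bleach values
fluctuate about zero. Default ROI distances 2.5/5/7.5 µm give three
τ values per cytoneme.

**Kymographs**: puncta are Gaussian spots (σ 0.3 µm) on a constant
background (default peak 3× background, noise σ = background/5) that
depart the cell body, move at constant velocity, and vanish on the
frame after tip arrival; retrograde distractors start near the tip,
move backward and vanish mid-cytoneme, flagged in ground truth.

**Colocalization fields**: 3-px-wide, ≥ 15 µm ridges at 0.05 µm/px; the
channel pair has identical marginals (mean 100, σ 20) across the whole
field with population correlation ρ (shared + independent white noise
mixture), so a few misassigned boundary pixels in a recovered mask do
not bias the in-mask correlation. With `puncta_density > 0` a
reference channel carries bright 3×3 puncta and the pair's correlation
on a 5×5 patch around each punctum is `rho_puncta`, letting
ligand-confined correlation be designed independently of the
background. Fields are white-noise (no spatial autocorrelation), so
pixel counts equal effective sample sizes; real images are smoother and
their r estimates correspondingly noisier.

**Occurrence**: positives ~ Binomial(n, p) per condition; counts per
positive cell ~ 1 + Poisson(mean − 1).

## Problem sizes and numerical choices

The test and acceptance computations use sizes chosen to keep
Monte-Carlo error well inside the tolerances they check: 5 replicate
simulated assays for the fold change (27 control + 15 case cells each),
27 cells for percentile bracketing, 10⁴ random traces for the
detector/oracle sweep, 50 cytonemes per velocity for FRAP recovery, 100
kymographs (alternating peak SNR 10 and 5, one retrograde distractor
each, deposits ≥ 15 s apart so concurrent puncta stay resolvable at the
line-scan pitch) for deposit calling, 100 seeds per designed ρ for
colocalization, and 500–1000 replicates for type-I calibration.
Exact Wilcoxon nulls are verified against full enumeration (2ⁿ sign
patterns; C(n+m, n) rank assignments) up to n = 10–15. Percentiles use
linear interpolation; curve fits use analytic-free least squares with
data-driven starts; all randomness flows through
`numpy.random.default_rng` seeds, and identical inputs with identical
seeds produce byte-identical output tables.

## Known limitations

- Trace analysis assumes uniform sampling (dt = median step); heavily
  irregular time bases would bias time-in-flux accounting.
- Deposit calling assumes the line-scan path is given and puncta
  separated by more than the detection merge radius; two releases
  closer than ~2 s at 0.25 µm/s are reported as one.
- The width criterion on real images measures apparent
  (diffraction-limited) width, not physical diameter.
- The rank-based tests' discreteness makes small-sample type-I rates
  slightly conservative (observed ≈ 3.5–4% at a nominal 5%).
- No imaging-to-trace extraction, 2-D+t particle tracking, Manders/
  Costes coefficients, deconvolution, or 3-D analysis.
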