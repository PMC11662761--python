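# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, the parameters a user may want to adjust, what
the synthetic-data generators do and do not emulate, and the known
limitations.

## Pose calibration and ingestion

Pose CSVs use the three-header-row dialect of markerless pose-estimation
software (scorer / bodyparts / coords, with x, y and optional likelihood
per landmark). Bodypart names are matched case-insensitively onto the six
canonical hindlimb landmarks (iliac crest, hip, knee, ankle,
metatarsophalangeal joint, toe); a missing landmark, a non-numeric cell or
an empty file is a fatal error that names the offender.

Calibration uses one frame showing four markers at the corners of an
axis-aligned rectangle of known size (7 cm wide × 4 cm high on the
treadmill). Corners are matched by lexicographic sort; the horizontal and
vertical cm-per-pixel scales are averaged into a single scalar coefficient,
mirroring the single conversion coefficient used in practice. The scales'
fractional disagreement (anisotropy) is recorded, and anisotropy above 5%
(default `anisotropy_tol`) is an error rather than being silently averaged:
it indicates a tilted camera or mis-placed markers, which a scalar
coefficient cannot represent. Rotated calibration rectangles are rejected
for the same reason.

Frames where a landmark's likelihood falls below `likelihood_min` (default
0.9, a common working threshold for pose-estimation output; the filter is
our convention and can be disabled by passing 0) are treated as dropouts
and filled by linear interpolation between the nearest confident frames,
with nearest-value extension at the edges. Interpolated values therefore
never leave the convex hull of their bounding samples. A landmark confident
in fewer than half the frames aborts the recording ("tracking quality
insufficient"). Coordinates are emitted in a y-up centimetre frame
(y_cm = (image_height − y_px) × coefficient) so joint heights are positive
upward.

## Joint angles

The angle at joint B flanked by neighbours A and C is the interior angle
arccos of the normalized dot product, in [0°, 180°]; no signed or reflex
angles. Hip uses (iliac crest, hip, knee), knee (hip, knee, ankle), ankle
(knee, ankle, MTP). Frames with coincident adjacent landmarks yield an
undefined angle and are interpolated; more than 10% such frames is fatal.

## Phase detection

The segmentation rule is a package design choice (treadmill-kinematics
convention): on a treadmill the belt carries the planted foot rearward, so
with the animal facing +x, stance frames have negative toe x-velocity and
swing frames positive. Toe x is smoothed with a centred moving average
(`smooth_window`, default 9 frames = 36 ms at 250 fps) and differentiated
by central differences. A hysteresis dead band `v_min` (default 0.5 cm/s)
absorbs jitter: frames inside the band inherit the previous label. Runs
shorter than `min_phase` (default 10 frames = 40 ms) are merged into their
neighbours. Because the hysteresis rule fires only once |v| exceeds
`v_min` — a systematic lag of a few frames — each detected transition is
then refined to the toe-x extremum in a ±`min_phase`/2 window: touch-down
is the foremost toe position, lift-off the rearmost (v = 0 exactly there).
Only stance→swing pairs flanked by valid phases on both sides are emitted,
so partial cycles at the recording edges are discarded. The animal's facing
direction is auto-detected from the velocity sign structure (stance
occupies the majority of the cycle, so the majority-time sign is the stance
sign); this assumes a duty factor above 0.5, which holds for walking gaits.

## Representative cycle and gait metrics

Each stance and each swing is linearly resampled onto `n_phase` (default
100) uniform points with endpoints preserved; all resampled stances are
averaged pointwise, likewise swings, and the representative cycle
concatenates mean stance then mean swing — 200 samples at the defaults,
independent of cadence, duty factor or cycle count. Stance-first order
follows the conventional presentation; it is a configuration choice.

The average joint angle is the plain mean over the 200 samples (stance and
swing therefore weigh equally regardless of duty factor). The RMS
difference between two cycles is the root mean squared sample-wise angle
difference — a scaled Euclidean metric, hence symmetric and satisfying the
triangle inequality.

Two RMS reference modes exist because the variability metric can be
defined either longitudinally or within a recording. The default
references each recording to the same animal's baseline (pre-induction)
representative cycle, matching a longitudinal study design in which per-
timepoint RMS values are tracked over weeks. The alternative
(`rms_within_recording`) measures cycle-to-cycle variability inside one
recording: mean RMS of each normalized cycle against the recording's mean
cycle. Both are exposed; the default is documented rather than guessed
silently at run time.

Hip angles are computed alongside knee and ankle but the headline metrics
are the knee and ankle values, which are the sensitive deficit measures in
this preparation.

## eYFP transection quantification

Grey-matter fluorescence is unaffected by disease, so thresholds are
anchored to it. Per image, the ratio of mean intensity in visually healthy
white matter to mean grey-matter intensity is computed; the cohort mean of
these ratios is the standardized ratio R. The per-image threshold is
R × (grey-matter mean) × f with f = 1.5 by default — f is an empirical
multiplier exposed as configuration, not a constant. The transection
measure is the percent of white-matter pixels strictly above threshold
("suprathreshold"), which makes the result invariant under any global
intensity rescaling. The scope of the cohort average (which images share
one R) is a configuration decision; the pipeline computes it once per run
batch. Healthy-white-matter ROIs are inputs, not computed.

## Neutral-Red white-matter loss

Demyelinated tissue loses the blue Eriochrome-Cyanine stain and takes the
red Neutral-Red counterstain. A pixel inside the white-matter mask is
NR-positive when red / (blue + 1e−6) > 1.2 (`red_blue_ratio_min`,
configurable — the original image-analysis settings for this stain are not
standardized, so the rule is a stated default). The readout is the percent
of white-matter area that is NR-positive.

## g-ratios and remyelination

Axon and myelin label masks come from an external segmentation tool and
share integer labels. The g-ratio is area-equivalent:
g = √(A_axon / (A_axon + A_myelin)) from pixel counts scaled by the pixel
size. This is robust to non-circular fibre profiles and is the standard
definition in automated segmentation practice, rather than a diameter
measured along a chord. Axons touching the image border are excluded
(their areas are underestimated), as are axons below `min_axon_area_px`
(default 10 px, suppressing segmentation specks). An unmyelinated axon has
g = 1 exactly. Myelinated axons with g **strictly above** 0.8
(`g_cutoff`) are classified remyelinating — thin sheaths relative to axon
calibre — and summarized as counts, density per µm² of field area, and
percentage. The percentage's headline denominator is all retained axons;
the myelinated-only percentage is reported alongside, since either
denominator is defensible.

## qPCR

Technical replicates are averaged arithmetically per (sample, gene); an
optional outlier rule (drop replicates > 0.5 cycles from the replicate
median) exists but is off by default, matching plain averaging practice.
geNorm stability: for candidate genes j, k the per-sample log₂ expression
ratio is Cq_k − Cq_j (amplification efficiency fixed at 2); V_jk is its
sample SD (ddof = 1) and M_j the mean of V_jk over k ≠ j. Accept thresholds
are 1.0 for tissue and 0.5 for cell culture. Only per-gene M values and
threshold flags are computed; the full iterative geNorm exclusion procedure
is not, as reference selection here only requires the stability check.

ddCq: ΔCq = Cq_target − mean(Cq of references) per sample (arithmetic mean
of Cq equals geometric-mean expression normalization); ΔΔCq centres ΔCq on
the control group's mean, so the control group's geometric-mean fold is 1
by construction; fold = 2^(−ΔΔCq). A single-calibrator-sample mode is
available behind a flag for designs anchored to one reference sample.
Efficiency-corrected variants (per-gene efficiencies ≠ 2) are out of scope.

## Clinical scores and the rank test

Scores live on the 0–5 grid in 0.5 steps. The cumulative clinical score
sums daily scores over an inclusive window, DPI 16–44 by default (both
endpoints included; treatment onset at peak disease through study end).
Missing days are fatal unless interpolation is explicitly requested.

The one-tailed Mann–Whitney U test uses midranks for ties. For pooled
sizes n + m ≤ 20 the p-value is exact: the null distribution of U over all
C(n+m, n) equally likely group assignments of the observed pooled values,
computed by a dynamic program over (doubled) midrank subset sums — integer
counts, so the result is identical to literal enumeration, which the test
suite verifies against an independent enumeration oracle. Exactness
matters here because half-point scores generate heavy ties and n = 10 per
group is typical, where the normal approximation is unreliable. Larger
samples use the normal approximation with tie and continuity corrections,
and the method used is recorded on the result. Gait analysis is restricted
to days the animal scored ≤ 2.5 (able to walk); the pipeline applies this
filter and logs every exclusion with a reason code.

## Synthetic-data generators

All generators are pure functions of parameters + seed and export ground
truth at the level the pipeline measures.

*Gait*: the hindlimb is a five-segment forward-kinematic chain hanging
from a quasi-fixed iliac crest (small vertical oscillation only). The
thigh's absolute angle sweeps ±25° about the vertical with a cosine ease
so its angular velocity is zero exactly at touch-down and lift-off; knee
and ankle interior angles are constant during stance and flex during swing
by a sin² bump with zero value and slope at the boundaries. During stance
every segment angle is the thigh sweep plus a constant, so the leg rotates
rigidly about the hip and the toe moves strictly rearward — phase
boundaries coincide with toe-x extrema, which is the property the detector
uses. The construction is checked post-hoc for this velocity-sign pattern
and raises if a parameter combination violates it. Deficits are injected
as a constant knee-angle offset; step-to-step variability as per-cycle
constant angle offsets (σ_c); pose jitter as white coordinate noise (σ_t).
Defaults: 250 fps, 4 s, cadence 1.5 Hz, duty factor 0.6, segment lengths at
adult-mouse scale (0.8 / 1.6 / 1.8 / 1.0 / 0.5 cm), 100 px/cm camera —
values chosen once as realistic for a mouse on a treadmill. The generator
does not model muscle dynamics, ground contact compliance, out-of-plane
motion or perspective; passing tests demonstrate correct measurement of
angle waveforms and phase structure, not robustness to those effects.

*eYFP*: slab regions (grey matter at 100 units, white matter at 1.25×, a
healthy-WM ROI kept free of puncta so the standardized ratio stays exact),
puncta disks painted at 2× the analytic threshold and trimmed to an exact
pixel count, optional Gaussian noise as a fraction of the grey-matter
mean. True percent is exact by construction at zero noise. Real sections'
intensity gradients, autofluorescence and ROI-drawing variability are not
emulated.

*Axon fields*: non-overlapping elliptical annuli (radii 8–20 px at
0.02 µm/px, ellipticity up to 1.3, target g from a mixture around 0.70 and
0.85 or an explicit list). True g is computed from the same pixel counts
used to rasterize, so the truth is exact under the area definition;
discretization moves realized g away from the target by ~1/r, which is why
classification tests use targets away from the cutoff or compare against
the pixel-count truth.

*Clinical cohorts*: zero until a per-animal onset day (DPI 9–12), linear
ramp to a per-animal peak (2.5–4.0) at DPI 16, then a group-specific
linear recovery (score points per week), daily Gaussian jitter, rounding
to the 0.5 grid and clipping to [0, 5]. Defaults (vehicle 0.35, treated
0.9 points/week) produce the qualitative treated-recovers-faster pattern.

*qPCR plates*: Cq = per-gene baseline (20–26 cycles) + per-sample loading
shift − log₂(expression fold for targets in the treated group) +
biological jitter + per-replicate noise, three technical replicates. With
all SDs zero the ddCq pipeline inverts the construction exactly.

## Numerical choices and degenerate inputs

- Linear interpolation everywhere a gap is filled or a phase resampled;
  endpoints preserved exactly in resampling.
- Strict `>` at both classification thresholds (eYFP suprathreshold,
  g-cutoff), so boundary values are negative cases.
- arccos arguments clipped to [−1, 1] before conversion to degrees.
- Zero complete step cycles is a warning and an empty segmentation;
  asking for a representative cycle from it is fatal.
- Empty axon record lists produce a summary of zeros with a warning.
- The exact Mann–Whitney dynamic program doubles midranks to integers, so
  no floating-point accumulation affects the tail count; p-values are
  clamped to (0, 1].
- The null-calibration study uses continuous (normal) null samples: with
  the exact test, heavily tied ordinal data makes the attainable p-values
  so discrete that the rejection rate at a nominal α reflects the tie
  structure rather than test calibration.

## Problem sizes used in the test and acceptance runs

Recordings of 4–6 s at 250 fps (4–8 complete cycles), image fields of
256²–1024² px with 20–30 axons, cohorts of 10 animals per group, plates of
7 samples per group × 3 replicates, 2000 replicates for the null-
calibration study and 200 tie-laden cases for the enumeration-oracle
check. These sizes exercise every code path with comfortable margins while
keeping the full suite under a minute.

## Known limitations

- 2-D sagittal kinematics only; no stride-length/cadence statistics, no
  forelimb, no lens-distortion correction.
- Phase detection assumes treadmill locomotion with duty factor > 0.5;
  overground or running gaits would need a different orientation heuristic.
- The eYFP and NR rules are intensity-ratio heuristics with stated
  defaults, not learned classifiers; stain normalization is out of scope.
- Axon/myelin segmentation itself is external; label masks are trusted
  inputs apart from border/size filters.
- Two-way repeated-measures ANOVA, Dunnett and Dunn post-hoc procedures
  are deliberately not reimplemented: the pipeline emits tidy long-format
  tables for standard statistics packages.
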