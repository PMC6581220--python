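# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `awakepet`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

World coordinates are millimetres in the scanner frame: z along the
bore, x/y transaxial, origin at the centre of the field of view. A head
pose maps head-frame coordinates into the scanner frame,
`x_scanner = R x_head + t`, with `R` stored as a unit quaternion
(w, x, y, z). Voxel grids follow the corner convention: the centre of
voxel `i` is `origin + (i + 0.5) · voxel_size`. Event timestamps are
integer microseconds so that 32-ms framing is exact.

## Scanner model and simulator

The scanner is a cylinder of crystals. Two presets exist: the
`inveon-like` preset with a 10 cm transaxial diameter and 12.7 cm axial
FOV (the full-scale instrument), and the default `desk` preset
(radius 50 mm, 192 crystals/ring × 16 rings, 1.6 mm transaxial / 2.0 mm
axial pitch) sized so every experiment runs in seconds-to-minutes on one
CPU. The desk crystal pitch is deliberately kept close to a real
small-animal scanner's: with much coarser pitches the discrete set of
lines of response aliases against the reconstruction grid and biases
regional means differently for static and moving acquisitions, an
artifact of the sampling rather than of motion correction.

The simulator draws emission times from a homogeneous Poisson process at
a configurable emission rate, emission sites proportionally to the
current activity (phantom voxels plus the four marker point sources,
both rigid with the head), an isotropic photon-pair direction, and keeps
events whose line intersects the detector cylinder at two distinct
crystals inside the axial FOV with the emission point between them.
Markers are sampled as Gaussian blobs of FWHM equal to their 1-mm
diameter to avoid sub-voxel aliasing. With an attenuation map, events
are thinned with survival `exp(−∫ μ dl)` along the head-frame line.
Poses are interpolated continuously between the 32-ms trajectory knots
(linear translation, quaternion slerp) — the same interpolation the
motion correction uses. Not modelled: scatter, randoms, positron range,
crystal depth of interaction (parallax), dead time, and decay during the
scan. Crystal quantisation (hits snapped to crystal centres) is the only
resolution-degrading effect, so simulated data are *sharper* than real
data; resolution modelling is therefore off (σ = 0) in all
simulator-based comparisons, while the `ReconConfig` default resolves to
half the transaxial crystal pitch for use on data with genuine detector
blur.

### Phantom

A soft-tissue ellipsoid (semi-axes 12 × 16 × 9 mm, μ = 0.097 cm⁻¹)
contains an ellipsoidal brain partitioned into five schematic regions —
cortex (shell), caudate putamen (two lateral spheres), thalamus (central
ellipsoid), hippocampus (band), cerebellum (posterior slab). Geometry is
schematic by design: downstream code needs disjoint, nonempty labelled
regions with known activities, not anatomy. Default concentrations
(cortex 1.5, caudate 1.8, thalamus 2.0, hippocampus 1.7, cerebellum 1.6,
body 0.4 MBq/cm³) correspond to SUV ≈ 2–3 after an ~18.5 MBq injection
in a ~25 g mouse, so the four 296–370 kBq markers contribute a realistic
~24% of counts.

### Marker model

Two markers sit under the ears on the head surface, one on the nasal
bridge, one elevated ~10 mm on a lightweight spacer; the elevated and
peripheral placement keeps marker spill away from the cortex, mirroring
the experimental practice. The tetrahedron is asymmetric with all six
pairwise distances distinct by ≥ 1.4 mm — a validated requirement,
because the distance-based matcher needs a unique ordering.

### Trajectories

Head motion is an Ornstein–Uhlenbeck-style bounded random walk:
AR(1)-correlated planar velocity (τ = 0.5 s) rescaled so the mean speed
equals the requested regime speed exactly before wall folding;
exponential move/rest bouts implement the rest fraction (the 2 cm/s
test–retest regime uses 35% rest, the 4 cm/s memantine regime 5%);
small z bobbing (SD 1 mm) and yaw-dominant angular random walk
(45°/s RMS yaw, quarter of that in pitch/roll) complete the 6-DOF pose.
Positions fold at the 10 × 9 cm platform walls and, by default, at a
35-mm radius — the physical reach of the head centre inside the bore.
Because the marker centroid sits ~3 mm from the head origin, yaw sweep
adds ~0.2–0.3 cm/s to the *centroid* speed on top of the calibrated
translation speed.

## Tracking

Each 32-ms frame is reconstructed on a coarse grid (1.5-mm voxels
covering the bore) with a fast configuration (3 plain MLEM iterations,
no PSF). Candidates are local maxima of the lightly smoothed frame
(0.6-voxel Gaussian, which stabilises sources whose counts split across
voxel corners) above 0.3 × the frame maximum, refined by an
intensity-weighted centroid of the raw counts in the 3³ neighbourhood;
at most 10 are kept, brightest first. Matching evaluates the similarity
score — the sum over the six unordered pairs of squared differences
between candidate and model inter-point distances — for every ordered
4-arrangement (≤ 5040 at defaults) and takes the global minimum; a
frame with fewer than 4 candidates, or whose best score exceeds
`4 · (2 mm)²`, yields no pose. The rigid pose is the Kabsch SVD solution
with det(R) = +1; a frame is accepted iff every marker residual is
≤ 2 mm (inclusive). Poses are stamped at frame centres. No pose
smoothing is applied. Three-marker fallback poses are not computed: a
frame in which any source fails detection is discarded.

Centroid detection carries a small (~0.1 mm) bias toward the body mass,
because background counts enter the centroid window; it is far below the
2-mm acceptance scale and the half-millimetre accuracy level.

## Reconstruction and motion correction

List-mode OSEM uses subsets formed by event index modulo the subset
count (deterministic, time-balanced), the Siddon exact-intersection
system model, an optional isotropic image-space Gaussian PSF applied on
both sides of the update, and the standard multiplicative step. With the
PSF off, one full iteration preserves `Σ x·s` equal to the event count
exactly, and the update matches a dense-matrix EM to machine precision.

Attenuation enters through the sensitivity image: in the list-mode
update a per-event attenuation factor cancels between the numerator and
denominator of the event ratio, so multiplying each event's ratio by its
ACF is algebraically identical to using the attenuated sensitivity; the
implementation does the latter. ACFs are `exp(∫ μ dl)` by the same ray
tracer. For awake scans the μ-map is derived from the body activity
outline of an uncorrected reconstruction: largest connected component
above 10% of the robust (99.5th-percentile) maximum, morphologically
closed and hole-filled, filled with 0.097 cm⁻¹.

Motion correction is event-by-event: endpoints are transformed by the
inverse of the pose interpolated at the event time. Events inside
tracking gaps longer than 5 frames are dropped; events within the frame
of an accepted pose bordering such a gap keep that frame's pose. The
sensitivity under motion is the exposure-weighted average over accepted
poses of the scanner-frame sensitivity sampled at each head voxel's
world position. That field is computed once on a bore-covering grid at
the reconstruction voxel size and resampled per pose (trilinear); with
attenuation, the head-frame survival factor (attenuated / geometric
static sensitivity) multiplies the average. Per-pose exact recomputation
of the discrete-pair sensitivity was evaluated and rejected: at
affordable pair subsampling its aliasing noise exceeds the interpolation
error of the field approach.

## Quantification and statistics

Regional means are arithmetic means over atlas labels. At desk scale the
regions hold only 50–450 voxels, so a fully converged OSEM's voxel noise
leaves ±3–5% noise on small-region means even in static-vs-static null
comparisons; regional quantification therefore applies a common 1-mm
Gaussian post-filter to every image entering a comparison (the real
study's regions are orders of magnitude larger in voxel count, which
averages this noise away by itself).

SUV divides concentration by injected dose per body weight (density
1 g/cm³), with optional decay correction of the dose to scan start
(F-18 half-life 109.77 min, on by default). TACs come from independent
dynamic frames (2-min default) reconstructed with the same
configuration; the slope test is ordinary least squares with a two-sided
*t*-test on n−2 degrees of freedom. The ICC defaults to the two-way
absolute-agreement single-measurement form ICC(A,1) computed from ANOVA
mean squares — variants differ substantially on the same data, so the
variant is selectable ("C,1", "1,1"). Bland–Altman operates on percent
differences `100 (test − retest) / pair mean`, so a retest exceeding the
test gives a negative bias. The variability metric is the mean absolute
percent difference — one concrete choice among several in circulation.
The challenge percent change uses the mean of test and retest as
baseline (a test-only baseline gives visibly different region averages)
and averages the five regional percentages without weighting. The
blur-equivalence σ minimises the mean squared difference between the
Gaussian-blurred reference and the degraded image by a bounded 1-D
search on [0, 2] mm, returning 0 when no blur improves the match.

## Problem sizes

Defaults used by the test suite and the acceptance script: quantification
scans of 25 s at a 2.5 × 10⁵ cps emission rate (~1.5 M detected events),
tracking-accuracy scans of 12 s (~7 × 10⁵ events), the desk geometry and
a 64 × 64 × 24 grid at 1 mm. The end-to-end experiment runner defaults
to the protocol's 20-min scan duration but is routinely exercised at
these shorter sizes; all sizes are configuration, not code.

## What passing tests do and do not show

The simulator emulates the geometry and statistics of the acquisition,
not its physics: no scatter, randoms or parallax, and ideal (constant,
known) marker activities. Passing tests therefore demonstrate that the
tracking-and-correction chain is internally correct — poses are
recovered to sub-millimetre accuracy at the behavioural speed regimes
and corrected regional quantification matches a motionless acquisition —
but they do not certify performance on real scanner data, where detector
physics, scatter backgrounds and the quality of the marker attachment
dominate. Real-animal quantities (absolute SUVs, ICC values of a
biological cohort, speeds and distances of actual mice) depend on the
cohort and are outside what synthetic data can reproduce; the published
group-mean SUV table is used only as tabular input to the percent-change
computation.

## Known limitations

* Emission is static (trapped-tracer); no kinetics beyond an optional
  linear ramp for TAC testing.
* The pose-averaged sensitivity is an approximation; its residual error
  is small compared with count noise at desk scale but has not been
  characterised at full scale.
* The outline-based μ-map assumes a single soft-tissue coefficient and a
  connected body.
* `run_experiment` always simulates a separate matched-count static
  reference, so its motion-corrected and static images differ by count
  noise even for a motionless configuration; the exact moco/static
  identity holds at the function level (identity trajectory reproduces
  the plain reconstruction bit for bit).
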