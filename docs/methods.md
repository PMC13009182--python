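# Methods

## Problem and approach

Patients with hydrocephalus often carry a programmable CSF shunt whose
valve (here the Codman Certas Plus, 8 settings) is adjusted externally
with a magnetic tool. On head CT the valve's metal components are
visible as small very-bright structures, and the current setting is
encoded in the orientation of the rotating magnet pair (the setting
indicator) relative to the valve body. Reading that orientation off a
3D volume by eye is hard — metal artefacts, sub-millimetre components,
oblique valve poses — which motivates an automated geometric readout
downstream of a marker segmentation.

This package implements everything downstream of segmentation. Given a
label map of the five radiopaque markers —

| label | marker |
|---|---|
| 1 | magnet with tantalum ball (pointer end of the rotor) |
| 2 | magnet without ball |
| 3 | rotating construct (ring) |
| 4 | right-hand-side (RHS) marker |
| 5 | distal tip |

— the pipeline is:

1. **Centres of mass.** Each marker's centroid is the unweighted mean
   of its voxels' physical coordinates (the NIfTI affine applied to
   voxel indices; the affine is linear so this equals the affine image
   of the mean index). Binary, not intensity-weighted: the input is a
   segmentation.
2. **Valve frame.** The valve plane passes through the rotating
   construct (RC), RHS marker and distal tip. The reference axis is
   `r = unit(RHS − RC)`; the plane normal is
   `n = unit((RHS − RC) × (TIP − RC))`, whose sign carries the
   valve's chirality.
3. **Indicator angle.** The indicator direction
   `d = centroid(magnet_with_ball) − centroid(magnet_without_ball)` is
   projected into the plane and the signed angle is
   `θ = atan2((r × d)·(−n), r·d)`, i.e. positive angles run clockwise
   about `n`. θ is reported in [−90°, 270°).
4. **Setting.** The dial is divided into eight 45° zones with 0° the
   cutoff between settings 2 and 3: zone(s) = [(s−3)·45, (s−2)·45),
   half-open and lower-inclusive, expected (zone-centre) angle
   (s−2.5)·45, i.e. −67.5° for setting 1 through 247.5° for setting 8.

### Why this is pose- and face-invariant

The angle is a function of dot/cross products of centroid differences,
so any rigid motion of the head leaves it unchanged (tested to 1e-6°
over random poses). Under a mirror reflection the indicator direction
flips handedness, but so does the RHS/TIP-derived normal, and the two
flips cancel: the angle is unchanged. This is what makes the readout
independent of which valve face points toward the scanner.

### Conventions and degenerate inputs

- The clockwise-positive algebraic convention is not uniquely fixed by
  the physical description ("settings increase clockwise"); this
  implementation fixes it jointly with the phantom generator and
  validates the pair by round-trip tests. Flipping both conventions is
  equivalent.
- The angle is measured in 3D after projection into the valve plane
  (rather than on a reformatted 2D slice); for exact geometry the two
  are identical, and 3D projection avoids a resampling step.
- Zone boundaries are assigned upward (0.0° → setting 3). The boundary
  is a measure-zero event; some deterministic rule is required for
  reproducibility.
- Missing RC/RHS/TIP or magnet centroids raise a typed
  "setting undeterminable: missing <marker>" error, which the pipeline
  converts to an `undeterminable` outcome (a data result, exit code 0
  in the CLI) — never a silent default.
- A defining triangle with minimum altitude < 0.1 mm (below voxel
  scale) is rejected as a degenerate plane; an indicator within ~0.1%
  of perpendicular to the plane is rejected as a degenerate direction.

## Synthetic phantoms

`shuntvalve.phantom` rasterises the five-marker constellation into a
small CT-like volume (default 96³ voxels at 0.6 mm isotropic — a
sub-volume around a retroauricular valve at typical head-CT
resolution) with a crisp ground-truth label map and a truth record.

Canonical geometry (valve plane z = 0, RC at origin, RHS along +x,
flow along +y): magnets are 2.0 mm-radius spheres at ±3.5 mm from RC
along the indicator direction; the rotating construct is a ring (torus)
of radius 8.0 mm, tube radius 0.8 mm; the RHS marker a 0.9 mm sphere at
12 mm; the distal tip a 0.8 mm × 4 mm capsule at 30 mm along the flow
axis. These millimetre dimensions are plausible, configuration-exposed
stand-ins (`ValveDimensions`), not manufacturer drawings — only the
angular relationships matter to the method. The ring radius and RHS
offset are chosen so that blurred, thresholded components never merge
(magnet outer extent 5.5 mm vs ring inner radius 7.2 mm); markers in
physical contact would defeat any connected-component segmenter by
construction, not by measurement difficulty.

Intensity model: background 40, markers 2000 (soft tissue vs metal, HU-like),
Gaussian blur σ = 0.4 mm, additive Gaussian noise SD 15, optional
cosmetic radial streaks (stressors for the segmenter, not a physical
scanner model). The sub-voxel tantalum ball (radius 0.4 mm < one voxel)
is modelled as a Gaussian partial-volume intensity bump inside the ball
magnet rather than as rasterised voxels — a binary rasterisation of a
sub-voxel sphere frequently yields zero voxels, which would erase the
ball/no-ball distinction entirely. Labels are assigned pre-blur, so
ground truth stays crisp where intensities overlap, mirroring manual
segmentation of artefact-degraded CT.

Rasterisation uses 2× sub-voxel supersampling with majority vote, which
keeps rasterised volumes and centroids close to their analytic values;
with it, rasterisation alone perturbs the recovered angle by ≲0.2° at
identity pose and ≲1.5° in the worst random pose.

Cohorts (`plan_cohort`) draw settings from skewed weights
(3, 8, 12, 25, 15, 9, 5, 3 — mode at setting 4 and rare extremes, as in
clinical series), then a **continuous** uniform angle within the drawn
setting's 45° zone: the physical dial rotates continuously rather than
clicking into detents, and this is the dominant source of "adjacent
setting" confusions. Poses are uniform over SO(3) with ±3 mm
translation jitter; ~25% of cases reuse the previous patient id so the
grouped 80:20 train/test split (`grouped_split`, never splitting a
patient across partitions) has real groups to respect.

What the phantoms do **not** emulate: skull and anatomy, beam
hardening, reconstruction kernels, genuine metal-artefact physics, and
segmentation behaviour of a learned model. Passing phantom tests
therefore demonstrates the correctness of the geometry→angle→setting
chain and the robustness of the classical segmenter to blur/noise — not
clinical performance on patient scans.

## Threshold segmenter

`segment_markers` binarises at 800 (between tissue and metal), takes
26-connected components (diagonal connectivity keeps thin rings whole),
drops components under 3 voxels, and assigns labels geometrically: the
largest-extent component is the ring; the two components nearest the
ring centre are the magnets (the one containing the brightest voxel is
the ball magnet); of the remainder, nearest = RHS marker, farthest =
distal tip. Unassignable scenes produce a partial label map and the
case is reported undeterminable downstream. The peak-intensity ball
test is a phantom-compatible proxy; on clinical data a learned
segmenter would output labels 1 vs 2 directly.

## Evaluation statistics

- Dice `2|A∩B|/(|A|+|B|)` and IoU `|A∩B|/|A∪B|` per label, with the
  both-empty = 1.0 convention (empty vs non-empty = 0); the identity
  IoU = DSC/(2−DSC) is property-tested.
- Confusion matrix is 8×8 over determinable cases only; undeterminable
  cases are tallied separately but **count against** exact/adjacent
  accuracy, whose denominator is all cases — a clinician receives no
  usable prediction for them.
- Adjacent accuracy accepts |Δsetting| ≤ 1; non-circular by default
  (pressure adjacency), with a circular mode treating 1 and 8 — dial
  neighbours — as adjacent.
- Per-setting angle summaries report mean and SD (n−1 denominator; SD
  undefined, not 0, for singletons) next to the expected angle, and
  flag settings whose expected angle falls outside mean ± 2 SD.
- Confidence intervals are Clopper–Pearson exact binomial intervals
  from beta quantiles (lower = Beta(k, n−k+1) at α/2, upper =
  Beta(k+1, n−k) at 1−α/2, with the k = 0 / k = n endpoints exactly 0
  and 1). Exact intervals are conservative: simulated coverage at
  p = 0.8, n = 75 sits slightly above the nominal 95%.

## Problem sizes and numerical choices

The package's standard experiment sizes — 8 settings × 100 poses for
the exact-geometry round trip, 200 noiseless phantoms for rasterised
recovery, a 75-case noisy cohort for the end-to-end rate, 2000
replicates for CI coverage — were chosen as the smallest sizes at which
the checked rates are stable across seeds. Angle comparisons near the
reporting-range boundary use circular differences. All randomness flows
from explicit integer seeds (`numpy.random.default_rng`); cohorts store
per-case child seeds in the manifest so any case is reproducible in
isolation.

## Known limitations

- No intensity-only angle estimation: a label map (from this package's
  threshold segmenter or an external model) is required.
- Marker dimensions are invented; absolute Dice/IoU values on phantoms
  do not transfer to clinical segmentations.
- The segmenter's geometric heuristics assume a single valve in the
  field of view and spatially separated markers.
- Settings-to-opening-pressure mapping (mmH₂O) is out of scope.
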