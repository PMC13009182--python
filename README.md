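# shuntvalve

Geometric readout of **Codman Certas Plus** programmable shunt-valve
settings from head-CT marker segmentations — with a synthetic phantom
generator, a classical fallback segmenter and the full evaluation
stack, so the whole method is testable without patient data or a
trained network.

## Who this is for

Hydrocephalus patients carry CSF shunts whose adjustable valve setting
(1–8 on the Certas Plus) must be verified when malfunction is
suspected; head CT is usually the first scan available, but reading the
setting off a 3D volume is error-prone. Groups building automated
shunt-reading pipelines typically train a segmentation model for the
valve's five radiopaque markers; this package provides everything
downstream of that segmentation, plus the synthetic data to validate
it.

## The measurement

Given centroids (unweighted centres of mass, in mm) of the five
markers — ball magnet, plain magnet, rotating construct (RC), RHS
marker, distal tip (TIP) — the valve frame is

```
r = unit(RHS − RC)                 # in-plane reference axis
n = unit((RHS − RC) × (TIP − RC))  # plane normal, carries chirality
```

and the indicator angle is the signed, clockwise-positive angle between
the magnet axis `d = ball_magnet − plain_magnet` (projected into the
plane) and `r`:

```
θ = atan2((r × d)·(−n), r·d),   θ ∈ [−90°, 270°)
```

The dial covers 360° in eight 45° zones with θ = 0° the cutoff between
settings 2 and 3, so zone(s) = [(s−3)·45°, (s−2)·45°) and the nominal
angle of setting *s* is (s−2.5)·45° (setting 1: −67.5° … setting 8:
247.5°). The construction is invariant to rigid motion and to
mirroring (the normal flips with the chirality), so the readout does
not depend on patient pose or on which valve face points at the
scanner. See `docs/methods.md` for details and conventions.

## Worked example

Simulate one phantom at setting 5 (nominal angle 112.5°) in an oblique
pose, then run the full volume → segmentation → angle → setting
pipeline:

```python
from shuntvalve import PhantomSpec, make_phantom, predict_from_volume

grid, labels, truth = make_phantom(
    PhantomSpec(setting=5, rotation_deg=(25, -40, 10), seed=42)
)
result = predict_from_volume(grid)
print(truth.truth_angle_deg, result.angle_deg, result.setting)
# 112.5 112.72307456454837 5
```

The measured angle (112.72°) differs from truth by 0.22° —
rasterisation, blur and noise — and lands in zone [90°, 135°), i.e.
setting 5. The same run from the shell:

```bash
shuntvalve predict --volume demo_ct.nii.gz
```

prints a JSON record with `status`, `angle_deg` (112.72…), `setting`
(5), the zone, per-marker centroids/voxel counts and the valve frame.
A case with a missing marker returns `status: "undeterminable"` naming
the marker (exit code 0 — that is a data outcome a clinician should
review, not a program error).

Cohort-scale use:

```bash
shuntvalve simulate cohort/ --n 75 --seed 7 --predict   # NIfTIs + manifest + predictions
shuntvalve evaluate cohort/manifest.csv cohort/predictions.csv --out-dir report/
shuntvalve zones                                        # the setting/zone/angle table
```

`evaluate` writes the 8×8 confusion matrix, exact/adjacent accuracy and
determinability rate with Clopper–Pearson 95% CIs, and per-setting
angle summaries (mean, SD, expected angle).

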