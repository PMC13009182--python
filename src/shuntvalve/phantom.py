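"""Synthetic CT phantoms of the five-marker Certas Plus constellation.

Generates small head-CT-like sub-volumes containing the valve's five
radiopaque markers at a known rigid pose and indicator angle, together
with crisp ground-truth label maps and truth records.  This is the
test-bed for the angle/setting pipeline: only the angular relationships
between markers matter to the method, so the millimetre dimensions below
are plausible, configuration-exposed stand-ins, not manufacturer
drawings.

Canonical frame: valve plane is z = 0, rotating construct (RC) centred
at the origin, right-hand-side (RHS) marker along +x, distal tip (TIP)
along +y.  In this frame the plane normal is +z and a clockwise
indicator angle theta places the magnet axis along (cos theta,
-sin theta, 0), so the ball magnet of a valve at angle theta sits at
+magnet_offset along that direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .geometry import MarkerSet
from .settings import angle_to_setting, setting_to_expected_angle, zone_bounds
from .volumes_io import LabelMap, VoxelGrid


class PhantomOutOfBoundsError(ValueError):
    """Some marker geometry falls outside the simulated volume."""


@dataclass(frozen=True)
class ValveDimensions:
    """Marker sizes and offsets of the simulated valve, in mm.

    The rotor magnets sit inside the rotating-construct ring; the ring
    radius and RHS offset are chosen so that, after CT-like blurring,
    thresholded components stay separable (magnets, ring, RHS marker and
    distal tip never merge).
    """

    magnet_offset: float = 3.5
    magnet_radius: float = 2.0
    ring_radius: float = 8.0
    ring_tube_radius: float = 0.8
    rhs_offset: float = 12.0
    rhs_radius: float = 0.9
    tip_offset: float = 30.0
    tip_axis_deg: float = 90.0  # flow direction, off the RC-RHS line by design
    tip_radius: float = 0.8
    tip_length: float = 4.0
    ball_offset: float = 1.0  # tantalum ball centre, along the magnet axis
    ball_radius: float = 0.4


DEFAULT_DIMENSIONS = ValveDimensions()


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one simulated case.

    Exactly one of ``setting`` (expanded to its zone-centre angle) or
    ``angle_deg`` fixes the indicator; the pose is a rigid transform
    (xyz Euler angles + translation) applied to the canonical valve,
    which is then re-centred in the volume before the translation
    offset is added.  Intensity defaults mimic soft tissue (40) versus
    metal (2000) with mild blur and noise.
    """

    setting: int | None = None
    angle_deg: float | None = None
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.6)
    volume_shape: tuple[int, int, int] = (96, 96, 96)
    blur_sigma: float = 0.4
    noise_sd: float = 15.0
    background_level: float = 40.0
    marker_level: float = 2000.0
    ball_level_factor: float = 1.6
    streak_artefacts: bool = False
    supersample: int = 2
    seed: int = 0

    def resolve_angle(self) -> float:
        if (self.setting is None) == (self.angle_deg is None):
            raise ValueError("specify exactly one of setting or angle_deg")
        if self.setting is not None:
            return setting_to_expected_angle(self.setting)
        if not math.isfinite(self.angle_deg):
            raise ValueError("angle_deg must be finite")
        return float(self.angle_deg)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.marker_level <= self.background_level:
            raise ValueError("marker_level must exceed background_level")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth carried alongside each phantom."""

    truth_angle_deg: float
    truth_setting: int
    rotation_deg: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    markers: MarkerSet  # exact posed centroids, physical mm
    seed: int
    spec: PhantomSpec


def canonical_markers(
    angle_deg: float, dims: ValveDimensions = DEFAULT_DIMENSIONS
) -> MarkerSet:
    """Exact marker centroids in the canonical frame for a given angle."""
    if not math.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    theta = math.radians(angle_deg)
    d = np.array([math.cos(theta), -math.sin(theta), 0.0])  # clockwise about +z
    alpha = math.radians(dims.tip_axis_deg)
    return MarkerSet.from_points(
        {
            "magnet_with_ball": dims.magnet_offset * d,
            "magnet_without_ball": -dims.magnet_offset * d,
            "rotating_construct": np.zeros(3),
            "rhs_marker": np.array([dims.rhs_offset, 0.0, 0.0]),
            "distal_tip": dims.tip_offset
            * np.array([math.cos(alpha), math.sin(alpha), 0.0]),
        }
    )


# ---------------------------------------------------------------------------
# rasterisation


def _shape_list(angle_deg: float, dims: ValveDimensions):
    """Geometric primitives (label, kind, params) in the canonical frame."""
    m = canonical_markers(angle_deg, dims)
    tip = m.get("distal_tip")
    flow = tip / np.linalg.norm(tip)
    half = 0.5 * dims.tip_length * flow
    return [
        (3, "torus", dict(center=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
                          ring_radius=dims.ring_radius, tube_radius=dims.ring_tube_radius)),
        (1, "sphere", dict(center=m.get("magnet_with_ball"), radius=dims.magnet_radius)),
        (2, "sphere", dict(center=m.get("magnet_without_ball"), radius=dims.magnet_radius)),
        (4, "sphere", dict(center=m.get("rhs_marker"), radius=dims.rhs_radius)),
        (5, "capsule", dict(a=tip - half, b=tip + half, radius=dims.tip_radius)),
    ]


def _transform_shape(kind: str, params: dict, R: np.ndarray, t: np.ndarray) -> dict:
    out = dict(params)
    for key in ("center", "a", "b"):
        if key in out:
            out[key] = R @ out[key] + t
    if "axis" in out:
        out["axis"] = R @ out["axis"]
    return out


def _shape_bbox(kind: str, p: dict) -> tuple[np.ndarray, np.ndarray]:
    if kind == "sphere":
        r = p["radius"]
        return p["center"] - r, p["center"] + r
    if kind == "torus":
        r = p["ring_radius"] + p["tube_radius"]
        return p["center"] - r, p["center"] + r
    if kind == "capsule":
        lo = np.minimum(p["a"], p["b"]) - p["radius"]
        hi = np.maximum(p["a"], p["b"]) + p["radius"]
        return lo, hi
    raise ValueError(kind)


def _inside(kind: str, p: dict, pts: np.ndarray) -> np.ndarray:
    """Membership test for an (..., 3) array of physical points."""
    if kind == "sphere":
        return np.linalg.norm(pts - p["center"], axis=-1) <= p["radius"]
    if kind == "torus":
        q = pts - p["center"]
        z = q @ p["axis"]
        rho = np.linalg.norm(q - z[..., None] * p["axis"], axis=-1)
        return (rho - p["ring_radius"]) ** 2 + z**2 <= p["tube_radius"] ** 2
    if kind == "capsule":
        ab = p["b"] - p["a"]
        denom = float(ab @ ab)
        s = np.clip((pts - p["a"]) @ ab / denom, 0.0, 1.0)
        closest = p["a"] + s[..., None] * ab
        return np.linalg.norm(pts - closest, axis=-1) <= p["radius"]
    raise ValueError(kind)


def _rasterise_shape(
    target: np.ndarray,
    value: int | float,
    kind: str,
    params: dict,
    spacing: np.ndarray,
    supersample: int,
) -> None:
    """Paint a shape into ``target`` (axis-aligned diagonal geometry).

    Voxel (i,j,k) is centred at i*spacing; a voxel belongs to the shape
    when at least half of its ``supersample**3`` sub-sample points fall
    inside, which keeps rasterised volumes and centroids close to their
    analytic values even for markers only a couple of voxels across.
    """
    lo_mm, hi_mm = _shape_bbox(kind, params)
    lo = np.maximum(np.floor(lo_mm / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(hi_mm / spacing).astype(int) + 2, target.shape)
    if np.any(lo >= hi):
        return
    axes = [np.arange(lo[i], hi[i]) * spacing[i] for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    if supersample == 1:
        mask = _inside(kind, params, grid)
    else:
        offsets = (np.arange(supersample) + 0.5) / supersample - 0.5
        frac = np.zeros(grid.shape[:-1])
        for ox in offsets:
            for oy in offsets:
                for oz in offsets:
                    shift = np.array([ox, oy, oz]) * spacing
                    frac += _inside(kind, params, grid + shift)
        mask = frac >= (supersample**3) / 2.0
    view = target[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    view[mask] = value


def _add_streaks(
    data: np.ndarray, centers: list[np.ndarray], spacing: np.ndarray, rng: np.random.Generator
) -> None:
    """Cosmetic radial streaks from marker centres (not a scanner model)."""
    shape = np.asarray(data.shape)
    for c in centers:
        for _ in range(4):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            amp = rng.uniform(-250.0, 250.0)
            ts = np.arange(1.0, 25.0, 0.3)
            pts = c[None, :] + ts[:, None] * v[None, :]
            idx = np.round(pts / spacing).astype(int)
            ok = np.all((idx >= 0) & (idx < shape), axis=1)
            idx = idx[ok]
            decay = np.exp(-ts[ok] / 12.0)
            data[idx[:, 0], idx[:, 1], idx[:, 2]] += amp * decay


def make_phantom(
    spec: PhantomSpec, dims: ValveDimensions = DEFAULT_DIMENSIONS
) -> tuple[VoxelGrid, LabelMap, TruthRecord]:
    """Rasterise one phantom: intensity volume, truth label map, truth record.

    The label map holds the exact pre-blur rasterised markers, so the
    ground truth stays crisp even where blurred intensities overlap —
    mirroring manual segmentation of artefact-degraded CT.  The whole
    construction is deterministic given ``spec.seed``.
    """
    angle = spec.resolve_angle()
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = tuple(int(s) for s in spec.volume_shape)

    R = Rotation.from_euler("xyz", spec.rotation_deg, degrees=True).as_matrix()
    shapes = [
        (label, kind, _transform_shape(kind, p, R, np.zeros(3)))
        for label, kind, p in _shape_list(angle, dims)
    ]
    # centre the posed constellation's bounding box in the volume, then jitter
    boxes = [_shape_bbox(kind, p) for _, kind, p in shapes]
    bbox_lo = np.min([b[0] for b in boxes], axis=0)
    bbox_hi = np.max([b[1] for b in boxes], axis=0)
    vol_center = (np.asarray(shape) - 1) * spacing / 2.0
    shift = vol_center - (bbox_lo + bbox_hi) / 2.0 + np.asarray(spec.translation_mm)
    shapes = [
        (label, kind, _transform_shape(kind, p, np.eye(3), shift))
        for label, kind, p in shapes
    ]

    extent_hi = (np.asarray(shape) - 1) * spacing
    for _, kind, p in shapes:
        lo, hi = _shape_bbox(kind, p)
        if np.any(lo < 0) or np.any(hi > extent_hi):
            raise PhantomOutOfBoundsError(
                "phantom out of bounds: marker geometry exceeds the volume extent"
            )

    labels = np.zeros(shape, dtype=np.int16)
    for label, kind, p in shapes:
        _rasterise_shape(labels, label, kind, p, spacing, spec.supersample)

    data = np.full(shape, spec.background_level, dtype=float)
    data[labels > 0] = spec.marker_level
    # tantalum ball: the sub-voxel ball cannot be rasterised reliably, so its
    # partial-volume bloom is modelled as a Gaussian intensity bump inside the
    # ball magnet, making that magnet carry the brightest voxel
    theta = math.radians(angle)
    ball_dir = R @ np.array([math.cos(theta), -math.sin(theta), 0.0])
    posed = canonical_markers(angle, dims).transformed(R, shift)
    ball_center = posed.get("magnet_with_ball") + dims.ball_offset * ball_dir
    ball_sigma = max(dims.ball_radius, spacing.max())
    lo = np.maximum(np.floor((ball_center - 4 * ball_sigma) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((ball_center + 4 * ball_sigma) / spacing).astype(int) + 1, shape)
    axes = [np.arange(lo[i], hi[i]) * spacing[i] for i in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    r2 = np.sum((pts - ball_center) ** 2, axis=-1)
    amp = spec.marker_level * (spec.ball_level_factor - 1.0)
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * np.exp(
        -r2 / (2.0 * ball_sigma**2)
    )

    if spec.blur_sigma > 0:
        ndimage.gaussian_filter(data, sigma=spec.blur_sigma / spacing, output=data)
    if spec.streak_artefacts:
        centers = [posed.get(n) for n in ("magnet_with_ball", "magnet_without_ball",
                                          "rotating_construct")]
        _add_streaks(data, centers, spacing, rng)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=shape)

    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    grid = VoxelGrid(data=data, affine=affine)
    labelmap = LabelMap(labels=labels, affine=affine.copy())
    truth = TruthRecord(
        truth_angle_deg=angle,
        truth_setting=angle_to_setting(angle).setting,
        rotation_deg=tuple(spec.rotation_deg),
        translation_mm=tuple(spec.translation_mm),
        markers=posed,
        seed=spec.seed,
        spec=spec,
    )
    return grid, labelmap, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class PoseJitter:
    """Random-pose model for cohort cases.

    ``max_rotation_deg >= 180`` draws orientations uniformly over SO(3);
    smaller values draw each xyz Euler angle uniformly in its +/- range.
    Translations are uniform per axis within +/- ``max_translation_mm``
    (applied after the constellation is centred in the volume).
    """

    max_rotation_deg: float = 180.0
    max_translation_mm: float = 3.0


#: Skewed setting frequencies emulating a clinical cohort in which
#: setting 4 is by far the most common and the extremes are rare.
DEFAULT_SETTING_WEIGHTS: tuple[float, ...] = (3, 8, 12, 25, 15, 9, 5, 3)


def plan_cohort(
    n: int,
    setting_weights=None,
    pose_jitter: PoseJitter | None = None,
    seed: int = 0,
    base: PhantomSpec | None = None,
) -> list[dict]:
    """Draw the specs (settings, continuous angles, poses, seeds) of a cohort.

    Settings are drawn from the normalised weights; within its 45-degree
    zone each case gets a continuous uniform angle, reflecting the fact
    that the physical dial rotates continuously rather than clicking
    into eight detents.  Patients are assigned so that some contribute
    more than one scan, giving the grouped train/test split something to
    group by.  Fully reproducible from ``seed``.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    w = np.asarray(
        DEFAULT_SETTING_WEIGHTS if setting_weights is None else setting_weights,
        dtype=float,
    )
    if w.shape != (8,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("setting_weights must be 8 nonnegative values with positive sum")
    w = w / w.sum()
    jitter = pose_jitter or PoseJitter()
    base = base or PhantomSpec(setting=4)
    rng = np.random.default_rng(seed)

    plans: list[dict] = []
    patient = -1
    for i in range(n):
        if patient < 0 or rng.random() >= 0.25:  # ~25% repeat scans per patient
            patient += 1
        s = int(rng.choice(8, p=w)) + 1
        lo, hi = zone_bounds(s)
        angle = float(rng.uniform(lo, hi))
        if jitter.max_rotation_deg >= 180.0:
            rot = tuple(
                Rotation.random(random_state=rng).as_euler("xyz", degrees=True)
            )
        else:
            rot = tuple(rng.uniform(-jitter.max_rotation_deg, jitter.max_rotation_deg, 3))
        trans = tuple(rng.uniform(-jitter.max_translation_mm, jitter.max_translation_mm, 3))
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base,
            setting=None,
            angle_deg=angle,
            rotation_deg=tuple(float(x) for x in rot),
            translation_mm=tuple(float(x) for x in trans),
            seed=case_seed,
        )
        plans.append(
            {
                "case_id": f"case_{i:03d}",
                "patient_id": f"P{patient:03d}",
                "truth_setting": s,
                "truth_angle_deg": angle,
                "seed": case_seed,
                "spec": spec,
            }
        )
    return plans


def cohort_manifest(plans: list[dict]) -> pd.DataFrame:
    """Flatten cohort plans into a manifest table (one row per case)."""
    rows = []
    for p in plans:
        spec: PhantomSpec = p["spec"]
        rows.append(
            {
                "case_id": p["case_id"],
                "patient_id": p["patient_id"],
                "truth_setting": p["truth_setting"],
                "truth_angle_deg": p["truth_angle_deg"],
                "seed": p["seed"],
                "rot_x_deg": spec.rotation_deg[0],
                "rot_y_deg": spec.rotation_deg[1],
                "rot_z_deg": spec.rotation_deg[2],
                "trans_x_mm": spec.translation_mm[0],
                "trans_y_mm": spec.translation_mm[1],
                "trans_z_mm": spec.translation_mm[2],
                "noise_sd": spec.noise_sd,
                "blur_sigma": spec.blur_sigma,
            }
        )
    return pd.DataFrame(rows)


def make_cohort(
    n: int,
    setting_weights=None,
    pose_jitter: PoseJitter | None = None,
    seed: int = 0,
    base: PhantomSpec | None = None,
    dims: ValveDimensions = DEFAULT_DIMENSIONS,
):
    """Materialise a cohort: list of (VoxelGrid, LabelMap, TruthRecord) + manifest.

    For large cohorts prefer :func:`plan_cohort` + :func:`make_phantom`
    case by case to keep memory flat.
    """
    plans = plan_cohort(n, setting_weights, pose_jitter, seed, base)
    cases = [make_phantom(p["spec"], dims) for p in plans]
    return cases, cohort_manifest(plans)


def grouped_split(
    manifest: pd.DataFrame,
    train_fraction: float = 0.8,
    group_col: str = "patient_id",
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each case to 'train' or 'test', never splitting a group.

    Groups (patients) are shuffled and accumulated into the training set
    until it holds at least ``train_fraction`` of the cases; remaining
    groups form the test set.  Grouping prevents scans of one patient
    leaking across the split.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    groups = manifest[group_col].unique()
    order = rng.permutation(len(groups))
    sizes = manifest[group_col].value_counts()
    target = train_fraction * len(manifest)
    train_groups = set()
    total = 0
    for gi in order:
        if total >= target:
            break
        g = groups[gi]
        train_groups.add(g)
        total += int(sizes[g])
    out = manifest.copy()
    out["split"] = np.where(out[group_col].isin(train_groups), "train", "test")
    return out
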