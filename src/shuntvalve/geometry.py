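"""Core valve geometry: marker centroids, valve frame, signed indicator angle.

The measurement chain is: unweighted centre of mass (in mm) for each of
the five segmented markers; a valve plane through the rotating construct
(RC), right-hand-side marker (RHS) and distal tip (TIP); and the signed
angle, in that plane, between the RC->RHS reference axis and the line
through the two rotor magnets.  Positive angles run clockwise when the
valve is viewed from the side on which the RHS marker defines a
right-handed frame, so settings increase with angle.

The sign convention is fixed jointly with the phantom generator: with
normal ``n = unit((RHS-RC) x (TIP-RC))`` the angle is
``atan2((r x d) . (-n), r . d)``.  Flipping both conventions together is
equivalent; mirroring the whole constellation leaves the angle unchanged
(the normal flips with the chirality), which is what makes the
measurement independent of which valve face points toward the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes_io import LABEL_NAMES, LabelMap, indices_to_world


class SettingUndeterminableError(ValueError):
    """A marker required for the angle computation is absent.

    Mirrors the clinical pipeline's observed failure mode, where a missing
    right-hand-side marker makes the setting undeterminable.
    """

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__("setting undeterminable: missing " + ", ".join(self.missing))


class DegenerateGeometryError(ValueError):
    """Marker constellation does not define a usable plane or direction."""


@dataclass(eq=False)
class MarkerSet:
    """Physical-space centroids (mm) and voxel counts for labels 1..5.

    A centroid is present iff its voxel count is positive; absence is
    data (a segmentation miss), not an error.
    """

    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_counts: dict[str, int] = field(default_factory=dict)

    def get(self, name: str) -> np.ndarray | None:
        return self.centroids.get(name)

    def present(self, name: str) -> bool:
        return name in self.centroids

    @property
    def missing(self) -> list[str]:
        return [n for n in LABEL_NAMES.values() if n not in self.centroids]

    @classmethod
    def from_points(cls, points: dict[str, np.ndarray]) -> "MarkerSet":
        """Build a MarkerSet from exact mathematical centroids (count 1 each)."""
        return cls(
            centroids={k: np.asarray(v, dtype=float) for k, v in points.items()},
            voxel_counts={k: 1 for k in points},
        )

    def transformed(self, rotation: np.ndarray, translation) -> "MarkerSet":
        """Apply a rigid motion ``p -> R p + t`` to every centroid."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return MarkerSet(
            centroids={k: R @ v + t for k, v in self.centroids.items()},
            voxel_counts=dict(self.voxel_counts),
        )


@dataclass(eq=False)
class ValveFrame:
    """Orthonormal frame of the valve plane.

    origin    -- rotating-construct centroid (mm)
    ref_axis  -- unit vector RC->RHS (lies in the plane by construction)
    normal    -- unit((RHS-RC) x (TIP-RC)); sign carries the chirality
    flow_axis -- unit vector RC->TIP, reported for orientation context
    """

    origin: np.ndarray
    ref_axis: np.ndarray
    normal: np.ndarray
    flow_axis: np.ndarray


@dataclass(eq=False)
class AngleResult:
    """Signed indicator angle in degrees, normalised into [-90, 270)."""

    angle_deg: float
    frame: ValveFrame
    markers: MarkerSet


def wrap_angle(angle_deg: float) -> float:
    """Normalise an angle into the reporting range [-90, 270)."""
    return float(((angle_deg + 90.0) % 360.0) - 90.0)


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Signed difference a-b wrapped into (-180, 180]."""
    return float(-(((b_deg - a_deg) + 180.0) % 360.0 - 180.0))


def marker_centroids(labelmap: LabelMap) -> MarkerSet:
    """Unweighted binary centroid of each marker's voxels, in mm.

    The centroid of label L is the mean of the physical coordinates of
    all voxels carrying L.  Since the affine is linear this equals the
    affine image of the mean voxel index.
    """
    centroids: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for label, name in LABEL_NAMES.items():
        idx = np.argwhere(labelmap.labels == label)
        counts[name] = int(idx.shape[0])
        if idx.shape[0] == 0:
            continue
        mean_index = idx.mean(axis=0)
        centroids[name] = indices_to_world(labelmap.affine, mean_index[None, :])[0]
    return MarkerSet(centroids=centroids, voxel_counts=counts)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length direction vector")
    return v / n


def valve_frame(markers: MarkerSet, *, min_altitude_mm: float = 0.1) -> ValveFrame:
    """Valve plane and orientation from RC, RHS and TIP centroids.

    Rejects constellations whose defining triangle has minimum altitude
    below ``min_altitude_mm`` (default 0.1 mm): below voxel scale the
    plane normal is dominated by noise.
    """
    required = ("rotating_construct", "rhs_marker", "distal_tip")
    missing = [n for n in required if not markers.present(n)]
    if missing:
        raise SettingUndeterminableError(missing)

    rc = markers.get("rotating_construct")
    rhs = markers.get("rhs_marker")
    tip = markers.get("distal_tip")
    v_ref = rhs - rc
    v_flow = tip - rc
    cross = np.cross(v_ref, v_flow)
    area2 = np.linalg.norm(cross)  # twice the triangle area
    longest = max(
        np.linalg.norm(v_ref), np.linalg.norm(v_flow), np.linalg.norm(tip - rhs)
    )
    if longest < 1e-12 or area2 / longest < min_altitude_mm:
        raise DegenerateGeometryError(
            "degenerate valve plane: rotating construct, RHS marker and distal "
            "tip are collinear within tolerance"
        )
    return ValveFrame(
        origin=np.asarray(rc, dtype=float),
        ref_axis=_unit(v_ref),
        normal=_unit(cross),
        flow_axis=_unit(v_flow),
    )


def indicator_angle(
    markers: MarkerSet,
    frame: ValveFrame | None = None,
    *,
    min_projection: float = 1e-6,
) -> AngleResult:
    """Signed angle between the magnet axis and the RC->RHS reference axis.

    The indicator direction points from the magnet WITHOUT the tantalum
    ball to the magnet WITH it — the ball marks the pointer end of the
    otherwise nearly symmetric rotor, resolving the 180-degree ambiguity
    between opposing settings.  The direction is projected into the
    valve plane before the angle is taken.
    """
    missing = [
        n for n in ("magnet_with_ball", "magnet_without_ball") if not markers.present(n)
    ]
    if missing:
        raise SettingUndeterminableError(missing)
    if frame is None:
        frame = valve_frame(markers)

    d = markers.get("magnet_with_ball") - markers.get("magnet_without_ball")
    n = frame.normal
    d_plane = d - np.dot(d, n) * n
    norm = np.linalg.norm(d_plane)
    if norm < min_projection or norm < 1e-3 * np.linalg.norm(d):
        raise DegenerateGeometryError(
            "degenerate indicator direction: magnet axis is perpendicular to "
            "the valve plane"
        )
    d_plane = d_plane / norm
    r = frame.ref_axis
    # Clockwise-positive about n: y-component measured along -n.
    angle = np.degrees(np.arctan2(np.dot(np.cross(r, d_plane), -n), np.dot(r, d_plane)))
    return AngleResult(angle_deg=wrap_angle(angle), frame=frame, markers=markers)
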