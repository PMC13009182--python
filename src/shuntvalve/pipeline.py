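"""End-to-end prediction: label map (or raw volume) -> indicator angle -> setting.

A case whose required markers are missing yields status "undeterminable"
with the missing markers named — that is a reported data outcome, not a
program error, so the clinician can fall back to reading the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import (
    AngleResult,
    DegenerateGeometryError,
    MarkerSet,
    SettingUndeterminableError,
    indicator_angle,
    marker_centroids,
    valve_frame,
)
from .segment import NoMarkersFoundError, SegParams, segment_markers
from .settings import angle_to_setting
from .volumes_io import LABEL_NAMES, LabelMap, VoxelGrid


@dataclass
class PredictionResult:
    """Outcome of one case: setting + angle, or why none could be derived."""

    status: str  # "ok" | "undeterminable"
    angle_deg: float | None = None
    setting: int | None = None
    zone: tuple[float, float] | None = None
    missing_markers: list[str] = field(default_factory=list)
    reason: str | None = None
    markers: MarkerSet | None = None
    angle_result: AngleResult | None = None

    def to_dict(self) -> dict:
        out = {
            "status": self.status,
            "angle_deg": self.angle_deg,
            "setting": self.setting,
            "zone": list(self.zone) if self.zone else None,
            "missing_markers": self.missing_markers,
            "reason": self.reason,
        }
        if self.markers is not None:
            out["marker_centroids"] = {
                k: [float(x) for x in v] for k, v in self.markers.centroids.items()
            }
            out["voxel_counts"] = dict(self.markers.voxel_counts)
        if self.angle_result is not None:
            f = self.angle_result.frame
            out["frame"] = {
                "origin": [float(x) for x in f.origin],
                "ref_axis": [float(x) for x in f.ref_axis],
                "normal": [float(x) for x in f.normal],
                "flow_axis": [float(x) for x in f.flow_axis],
            }
        return out


def predict_from_markers(markers: MarkerSet) -> PredictionResult:
    """Angle + setting from already-computed marker centroids."""
    try:
        frame = valve_frame(markers)
        result = indicator_angle(markers, frame)
    except SettingUndeterminableError as err:
        return PredictionResult(
            status="undeterminable",
            missing_markers=err.missing,
            reason=str(err),
            markers=markers,
        )
    except DegenerateGeometryError as err:
        return PredictionResult(
            status="undeterminable", reason=str(err), markers=markers
        )
    pred = angle_to_setting(result.angle_deg)
    return PredictionResult(
        status="ok",
        angle_deg=result.angle_deg,
        setting=pred.setting,
        zone=(pred.zone_lo, pred.zone_hi),
        markers=markers,
        angle_result=result,
    )


def predict_from_labelmap(labelmap: LabelMap) -> PredictionResult:
    """Centroids -> valve frame -> signed angle -> 45-degree-zone setting."""
    return predict_from_markers(marker_centroids(labelmap))


def predict_from_volume(
    volume: VoxelGrid, params: SegParams | None = None
) -> PredictionResult:
    """Full pipeline from a raw intensity volume via the threshold segmenter."""
    try:
        labelmap = segment_markers(volume, params)
    except NoMarkersFoundError as err:
        return PredictionResult(
            status="undeterminable",
            missing_markers=list(LABEL_NAMES.values()),
            reason=str(err),
        )
    return predict_from_labelmap(labelmap)
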