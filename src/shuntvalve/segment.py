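"""Classical threshold segmenter for the five valve markers.

Lets the full pipeline (intensity volume -> label map -> setting) run on
phantoms without any trained network: metal markers are far brighter
than soft tissue, so a global intensity threshold plus 26-connected
component analysis recovers them, and simple geometric heuristics assign
the five labels.  The ball-magnet disambiguation by per-component peak
intensity is a phantom-compatible proxy for the sub-millimetre tantalum
ball; on clinical data a learned segmenter would provide labels 1 vs 2
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes_io import LabelMap, VoxelGrid, indices_to_world


class NoMarkersFoundError(ValueError):
    """No component above threshold — nothing to label."""


@dataclass(frozen=True)
class SegParams:
    """Tunables of the fallback segmenter.

    hu_threshold         -- intensity cutoff separating metal from tissue
                            (default 800, far above soft tissue, well
                            below unblurred metal)
    min_component_voxels -- components smaller than this are noise
    max_components       -- keep at most this many largest components
    """

    hu_threshold: float = 800.0
    min_component_voxels: int = 3
    max_components: int = 12

    def __post_init__(self) -> None:
        if not np.isfinite(self.hu_threshold):
            raise ValueError("hu_threshold must be finite")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")


@dataclass
class _Component:
    comp_id: int
    voxel_count: int
    centroid_mm: np.ndarray
    extent_mm: float  # bounding-box diagonal in physical mm
    max_intensity: float


def _components(volume: VoxelGrid, params: SegParams) -> tuple[np.ndarray, list[_Component]]:
    mask = volume.data >= params.hu_threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity keeps thin rings whole
    comp_map, n = ndimage.label(mask, structure=structure)
    if n == 0:
        raise NoMarkersFoundError("no markers found above intensity threshold")
    spacing = volume.spacing
    comps: list[_Component] = []
    objects = ndimage.find_objects(comp_map)
    counts = np.bincount(comp_map.ravel())
    for cid in range(1, n + 1):
        count = int(counts[cid])
        if count < params.min_component_voxels:
            comp_map[comp_map == cid] = 0
            continue
        sl = objects[cid - 1]
        idx = np.argwhere(comp_map[sl] == cid) + np.array([s.start for s in sl])
        centroid = indices_to_world(volume.affine, idx.mean(axis=0)[None, :])[0]
        span = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing
        comps.append(
            _Component(
                comp_id=cid,
                voxel_count=count,
                centroid_mm=centroid,
                extent_mm=float(np.linalg.norm(span)),
                max_intensity=float(volume.data[sl][comp_map[sl] == cid].max()),
            )
        )
    if not comps:
        raise NoMarkersFoundError("no markers found above minimum component size")
    comps.sort(key=lambda c: c.voxel_count, reverse=True)
    for dropped in comps[params.max_components :]:
        comp_map[comp_map == dropped.comp_id] = 0
    return comp_map, comps[: params.max_components]


def segment_markers(volume: VoxelGrid, params: SegParams | None = None) -> LabelMap:
    """Threshold + connected components + geometric label assignment.

    Heuristics: the rotating-construct ring is the component of largest
    spatial extent; the two remaining components nearest the ring centre
    are the rotor magnets (the one containing the brightest voxel is the
    ball magnet); of the rest, the component nearest the ring is the RHS
    marker and the farthest is the distal tip.  Scenes in which some
    markers cannot be assigned yield a partial label map — missing
    labels stay empty and the downstream geometry reports the case as
    undeterminable rather than guessing.
    """
    params = params or SegParams()
    comp_map, comps = _components(volume, params)

    assignment: dict[int, int] = {}  # comp_id -> marker label
    ring = max(comps, key=lambda c: c.extent_mm)
    assignment[ring.comp_id] = 3
    rest = [c for c in comps if c.comp_id != ring.comp_id]
    rest.sort(key=lambda c: float(np.linalg.norm(c.centroid_mm - ring.centroid_mm)))

    if len(rest) >= 2:
        magnets, rest = rest[:2], rest[2:]
        ball = max(magnets, key=lambda c: c.max_intensity)
        other = magnets[0] if magnets[1] is ball else magnets[1]
        assignment[ball.comp_id] = 1
        assignment[other.comp_id] = 2

    if len(rest) >= 2:
        assignment[rest[0].comp_id] = 4  # nearest leftover: RHS marker
        assignment[rest[-1].comp_id] = 5  # farthest leftover: distal tip
    elif len(rest) == 1:
        # single leftover: near the ring it can only be the RHS marker,
        # far out along the catheter it is the distal tip
        dist = float(np.linalg.norm(rest[0].centroid_mm - ring.centroid_mm))
        assignment[rest[0].comp_id] = 4 if dist <= 1.5 * ring.extent_mm / 2.0 else 5

    labels = np.zeros(volume.shape, dtype=np.int16)
    for comp_id, label in assignment.items():
        labels[comp_map == comp_id] = label
    return LabelMap(labels=labels, affine=volume.affine.copy())
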