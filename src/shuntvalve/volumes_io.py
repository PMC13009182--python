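"""NIfTI input/output for CT volumes and marker label maps.

All downstream geometry is computed in physical millimetres using the
NIfTI affine exactly as stored in the header (voxel indices are 0-based
and map to voxel centres).  No reorientation pass is performed: the
indicator-angle measurement is rotation invariant, so only internal
consistency of the frame matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Canonical label dictionary for the five radiopaque Certas Plus markers.
LABEL_NAMES: dict[int, str] = {
    1: "magnet_with_ball",
    2: "magnet_without_ball",
    3: "rotating_construct",
    4: "rhs_marker",
    5: "distal_tip",
}

NAME_TO_LABEL: dict[str, int] = {v: k for k, v in LABEL_NAMES.items()}

_VALID_LABELS = frozenset(range(6))


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("singular affine: voxel axes do not span 3D space")
    return affine


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass(eq=False)
class VoxelGrid:
    """A scalar 3D image (Hounsfield-unit-like) with voxel->mm geometry."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D array")
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def meets_resolution(self, max_spacing_mm: float = 1.0) -> bool:
        """Whether every axis is sampled at least as finely as ``max_spacing_mm``.

        Mirrors the study-inclusion requirement of sub-millimetre-ish CT
        resolution; deliberately an advisory check, not enforced on load.
        """
        return bool(np.all(self.spacing <= max_spacing_mm + 1e-9))


@dataclass(eq=False)
class LabelMap:
    """Integer 3D volume with labels 0 (background) and 1..5 (markers)."""

    labels: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected 3D label map, got {labels.ndim}D array")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.rint(labels), atol=1e-6):
                raise ValueError("label map contains non-integer voxel values")
            labels = np.rint(labels).astype(np.int16)
        present = set(np.unique(labels).tolist())
        unknown = sorted(present - _VALID_LABELS)
        if unknown:
            raise ValueError(f"unknown labels in label map: {unknown}")
        self.labels = labels.astype(np.int16, copy=False)
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def mask(self, label: int | str) -> np.ndarray:
        """Boolean mask for a label given by number or canonical name."""
        if isinstance(label, str):
            label = NAME_TO_LABEL[label]
        return self.labels == label

    def same_geometry(self, other: "LabelMap | VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a 3D NIfTI intensity volume.

    Intensities are returned as float64 with scl_slope/inter applied by
    nibabel; the affine is taken verbatim from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(path)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D image in {path}")
    return VoxelGrid(data=data, affine=np.asarray(img.affine))


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a VoxelGrid as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_labelmap(path: str | Path) -> LabelMap:
    """Read a marker label map; values must be integral and within 0..5."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label map: {path}")
    img = nib.load(path)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise ValueError(f"expected 3D label map, got {data.ndim}D image in {path}")
    return LabelMap(labels=data, affine=np.asarray(img.affine))


def write_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    """Write a LabelMap as int16 NIfTI-1, re-readable bit-exactly."""
    img = nib.Nifti1Image(labelmap.labels.astype(np.int16), labelmap.affine)
    nib.save(img, str(path))


def write_label_names(path: str | Path, label_names: dict[int, str] | None = None) -> None:
    """Emit the label dictionary as a JSON sidecar ``{label: name}``."""
    names = label_names if label_names is not None else LABEL_NAMES
    Path(path).write_text(json.dumps({str(k): v for k, v in names.items()}, indent=2))


def voxel_to_world(index, grid: VoxelGrid | LabelMap) -> np.ndarray:
    """Map a 0-based voxel index to its physical mm coordinate (voxel centre)."""
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise ValueError("index must be a triple")
    shape = grid.shape
    if np.any(idx < 0) or np.any(idx > np.asarray(shape) - 1):
        raise IndexError(f"index {tuple(index)} outside volume of shape {shape}")
    return grid.affine[:3, :3] @ idx + grid.affine[:3, 3]


def indices_to_world(affine: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Vectorised voxel->mm mapping for an (N, 3) index array."""
    indices = np.asarray(indices, dtype=float)
    return indices @ affine[:3, :3].T + affine[:3, 3]
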