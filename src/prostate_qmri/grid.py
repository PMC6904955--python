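"""Core imaging containers: axis-aligned 3D scalar fields and acquisition series.

All volumes in this package live on axis-aligned grids: the mapping from a
voxel index ``(i, j, k)`` to a physical point in mm is
``origin + index * spacing``.  This is sufficient for the phantom cohorts the
package simulates and keeps the registration/resampling algebra transparent;
oblique acquisitions are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "VolumeGrid",
    "AcquisitionSeries",
    "QuantMap",
    "load_volume",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an axis-aligned voxel grid (shape, spacing in mm, origin in mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def center(self) -> np.ndarray:
        """Physical coordinate of the grid center (mm)."""
        return np.array(
            [
                self.origin[a] + 0.5 * (self.shape[a] - 1) * self.spacing[a]
                for a in range(3)
            ]
        )

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def approx_equal(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing and origin; the unit of all imaging I/O."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid requires 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.data.shape), self.spacing, self.origin)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same geometry, new voxel values."""
        return VolumeGrid(data, self.spacing, self.origin)

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


def load_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI volume into a :class:`VolumeGrid` (axis-aligned affines only)."""
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-4):
        raise ValueError(f"{path}: only axis-aligned NIfTI volumes are supported")
    spacing = tuple(float(d) for d in np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: negative/zero voxel spacing in affine")
    data = np.asarray(img.dataobj)
    if data.dtype not in (np.float32, np.float64):
        data = data.astype(np.float64)
    return VolumeGrid(data, spacing, tuple(float(t) for t in aff[:3, 3]))


@dataclass
class AcquisitionSeries:
    """An ordered set of volumes indexed by an acquisition parameter.

    ``index`` holds echo times in ms (kind='echo') or b-values in s/mm^2
    (kind='dwi'); all member volumes share one grid.
    """

    volumes: list[VolumeGrid]
    index: np.ndarray
    kind: str  # 'echo' | 'dwi'

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        if len(self.volumes) != len(self.index):
            raise ValueError("series index length must match number of volumes")
        if self.kind not in ("echo", "dwi"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if len(self.volumes) > 1:
            g0 = self.volumes[0].grid
            for v in self.volumes[1:]:
                if not g0.approx_equal(v.grid):
                    raise ValueError("all volumes in a series must share one grid")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def grid(self) -> GridSpec:
        return self.volumes[0].grid

    def stack(self) -> np.ndarray:
        """Voxel data as a 4D array (x, y, z, acquisition)."""
        return np.stack([v.data for v in self.volumes], axis=-1)

    def volume_at(self, value: float) -> VolumeGrid:
        """The member volume whose index parameter equals ``value`` exactly."""
        hits = np.nonzero(np.isclose(self.index, value))[0]
        if hits.size == 0:
            raise KeyError(f"no volume with index value {value} in series {self.index}")
        return self.volumes[int(hits[0])]

    def save(self, directory: str | Path, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, vol in enumerate(self.volumes):
            vol.save(directory / f"{stem}_{i:02d}.nii.gz")
        sidecar = {"kind": self.kind, "index": [float(x) for x in self.index]}
        (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path, stem: str) -> "AcquisitionSeries":
        directory = Path(directory)
        meta = json.loads((directory / f"{stem}.json").read_text())
        vols = [
            load_volume(directory / f"{stem}_{i:02d}.nii.gz")
            for i in range(len(meta["index"]))
        ]
        return cls(vols, np.asarray(meta["index"]), meta["kind"])


INVALID_SENTINEL = -1.0


@dataclass
class QuantMap:
    """A volume of physical values (T2 in ms or ADC in mm^2/s) with a validity mask.

    Invalid voxels carry a sentinel value and must never enter statistics; all
    extraction helpers in this package intersect with ``valid`` first.
    """

    values: VolumeGrid
    valid: np.ndarray
    map_type: str  # 'T2' | 'ADC'
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.data.shape:
            raise ValueError("validity mask shape must match value volume")
        if self.map_type not in ("T2", "ADC"):
            raise ValueError(f"unknown map_type {self.map_type!r}")

    @property
    def grid(self) -> GridSpec:
        return self.values.grid

    def masked_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid voxel values, optionally restricted to a boolean mask."""
        sel = self.valid if mask is None else (self.valid & np.asarray(mask, bool))
        return self.values.data[sel]

    def save(self, path_values: str | Path, path_valid: str | Path | None = None) -> None:
        out = np.where(self.valid, self.values.data, INVALID_SENTINEL)
        self.values.with_data(out).save(path_values)
        if path_valid is not None:
            self.values.with_data(self.valid.astype(np.uint8)).save(path_valid)

    @classmethod
    def load(
        cls,
        path_values: str | Path,
        path_valid: str | Path,
        map_type: str,
        fit_meta: dict | None = None,
    ) -> "QuantMap":
        vol = load_volume(path_values)
        valid = load_volume(path_valid).data > 0.5
        return cls(vol, valid, map_type, fit_meta or {})
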