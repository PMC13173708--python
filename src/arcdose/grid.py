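"""Volumetric containers shared by every stage of the pipeline.

A :class:`VolumeGrid` is a 3D scalar field (CT in HU, dose in Gy, or a
binary mask) on a regular grid with array axes ordered ``(slice, row,
column)``; ``spacing`` is given as ``(dx, dy, dz)`` in mm, so the array
axis ``k`` of shape ``(nz, ny, nx)`` maps to ``spacing[2 - k]``.

A :class:`StructureSet` bundles the nine canonical region-of-interest
masks of a pelvic plan (PTV, seven organs at risk, and the external body
contour) on one shared grid.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Canonical ROI order used throughout the package.
ROI_NAMES: Tuple[str, ...] = (
    "PTV",
    "Bladder",
    "Rectum",
    "SmallIntestine",
    "SpinalCord",
    "Marrow",
    "FemoralHeadL",
    "FemoralHeadR",
    "Body",
)

OAR_NAMES: Tuple[str, ...] = tuple(n for n in ROI_NAMES if n not in ("PTV", "Body"))


class GridError(ValueError):
    """Raised on inconsistent grids or invalid grid parameters."""


@dataclass
class VolumeGrid:
    """A scalar field on a regular 3D grid.

    Parameters
    ----------
    values
        Array of shape ``(nz, ny, nx)`` — axes (slice, row, column).
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, strictly positive.
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float] = (2.5, 2.5, 5.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GridError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be three positive numbers, got {self.spacing}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.values.shape)

    @property
    def spacing_zyx(self) -> Tuple[float, float, float]:
        """Spacing reordered to match the array axes (dz, dy, dx)."""
        dx, dy, dz = self.spacing
        return (dz, dy, dx)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridError(
                f"{what} are not on the same grid: "
                f"{self.shape}/{self.spacing} vs {other.shape}/{other.spacing}"
            )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.spacing, self.origin)

    # -- mask helpers ------------------------------------------------------
    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def is_binary(self) -> bool:
        v = self.values
        return bool(np.isin(np.unique(v), (0, 1)).all())


def _affine(spacing: Tuple[float, float, float], origin: Tuple[float, float, float]) -> np.ndarray:
    # Array axes are (z, y, x); NIfTI data axes are written as (x, y, z).
    dx, dy, dz = spacing
    aff = np.diag([dx, dy, dz, 1.0]).astype(float)
    aff[:3, 3] = origin
    return aff


def save_nifti(vol: VolumeGrid, path: str | Path) -> None:
    """Write a gzipped NIfTI file with a reproducible byte stream.

    The gzip member is written with ``mtime=0`` so identical volumes give
    bitwise-identical files regardless of when they are saved.
    """
    path = Path(path)
    data = np.asarray(vol.values).transpose(2, 1, 0)  # (x, y, z) on disk
    img = nib.Nifti1Image(np.ascontiguousarray(data), _affine(vol.spacing, vol.origin))
    raw = img.to_bytes()
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".gz":
        buf = io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
            gz.write(raw)
        path.write_bytes(buf.getvalue())
    else:
        path.write_bytes(raw)


def load_nifti(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GridError(f"{path}: expected a 3D volume, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VolumeGrid(np.asarray(data).transpose(2, 1, 0), spacing, origin)


@dataclass
class StructureSet:
    """Named binary masks (the nine canonical ROIs) on one shared grid."""

    masks: Dict[str, VolumeGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [n for n in ROI_NAMES if n not in self.masks]
        if missing:
            raise GridError(f"StructureSet missing ROIs: {missing}")
        extra = [n for n in self.masks if n not in ROI_NAMES]
        if extra:
            raise GridError(f"StructureSet has unknown ROIs: {extra}")
        # keep canonical order
        self.masks = {n: self.masks[n] for n in ROI_NAMES}
        body = self.masks["Body"]
        body_b = body.as_bool()
        for name, m in self.masks.items():
            body.require_same_grid(m, f"mask {name!r} and Body")
            if not m.is_binary():
                raise GridError(f"mask {name!r} is not binary")
            if name != "Body" and not np.all(body_b[m.as_bool()]):
                raise GridError(f"mask {name!r} is not contained in Body")
        if not self.masks["PTV"].as_bool().any():
            raise GridError("PTV mask is empty")

    def __getitem__(self, name: str) -> VolumeGrid:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def grid(self) -> VolumeGrid:
        return self.masks["Body"]

    def names(self) -> Iterable[str]:
        return self.masks.keys()

    def bool_masks(self) -> Dict[str, np.ndarray]:
        return {n: m.as_bool() for n, m in self.masks.items()}


def resample_to_shape(vol: VolumeGrid, shape: Tuple[int, int, int], *, order: int = 1) -> VolumeGrid:
    """Resample a volume to a fixed grid shape, scaling the spacing.

    Utility for standardizing external volumes to the model's input size;
    masks should be resampled with ``order=0``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise GridError(f"invalid target shape {shape}")
    zoom = [t / s for t, s in zip(shape, vol.shape)]
    out = ndimage.zoom(vol.values.astype(float), zoom, order=order, grid_mode=True, mode="nearest")
    out = out[: shape[0], : shape[1], : shape[2]]
    dz, dy, dx = vol.spacing_zyx
    new_zyx = (dz / zoom[0], dy / zoom[1], dx / zoom[2])
    return VolumeGrid(out, (new_zyx[2], new_zyx[1], new_zyx[0]), vol.origin)


# -- case I/O ---------------------------------------------------------------

def save_case(
    path: str | Path,
    ct: VolumeGrid,
    structures: StructureSet,
    dose: VolumeGrid | None = None,
    meta: Mapping | None = None,
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    save_nifti(ct, path / "ct.nii.gz")
    for name, m in structures.masks.items():
        save_nifti(m.with_values(m.values.astype(np.uint8)), path / f"mask_{name}.nii.gz")
    if dose is not None:
        save_nifti(dose, path / "dose.nii.gz")
    if meta is not None:
        (path / "meta.json").write_text(json.dumps(dict(meta), indent=2, sort_keys=True))


def load_case(path: str | Path) -> Dict[str, object]:
    path = Path(path)
    ct = load_nifti(path / "ct.nii.gz")
    masks = {n: load_nifti(path / f"mask_{n}.nii.gz") for n in ROI_NAMES}
    structures = StructureSet({n: m.with_values(m.values.astype(np.uint8)) for n, m in masks.items()})
    out: Dict[str, object] = {"ct": ct, "structures": structures}
    dose_path = path / "dose.nii.gz"
    if dose_path.exists():
        out["dose"] = load_nifti(dose_path)
    meta_path = path / "meta.json"
    if meta_path.exists():
        out["meta"] = json.loads(meta_path.read_text())
    return out
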