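"""Directional beam-band masks: geometric priors for arc-therapy dose.

A beam band at angle θ is, on each axial slice, the corridor between
the two lines parallel to the beam direction and tangent to the PTV —
the region a parallel beam at that angle sweeps through the target.
With k directions at ``i * 180/k`` degrees (k=4 gives 0°, 45°, 90°,
135°) the band union marks where entrance dose is expected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .grid import VolumeGrid
from .phantom import direction_vector


class BandError(ValueError):
    """Invalid band construction parameters."""


@dataclass
class BandMaskSet:
    """k directional band masks plus their voxelwise union."""

    k: int
    angles: List[float]
    bands: List[VolumeGrid]
    union: VolumeGrid

    def __post_init__(self) -> None:
        if self.k != len(self.bands) or self.k != len(self.angles):
            raise BandError("k must match the number of angles and bands")

    def stacked(self) -> np.ndarray:
        """Bands as a (k, nz, ny, nx) binary array (network input order)."""
        return np.stack([b.values.astype(np.uint8) for b in self.bands])


def band_angles(k: int) -> List[float]:
    """The k band angles ``i * 180 / k`` for i = 0..k-1 (degrees)."""
    if k < 1:
        raise BandError(f"k must be >= 1, got {k}")
    return [i * 180.0 / k for i in range(k)]


def band_mask_slice(
    ptv_slice: np.ndarray,
    angle: float,
    spacing: Tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """The tangent-line corridor of a single slice.

    Pixels whose center projects, along the normal of the beam
    direction, into the closed interval spanned by the PTV pixel-center
    projections.  An empty PTV slice yields an empty band.

    Parameters
    ----------
    ptv_slice : 2D binary array (rows, columns)
    angle : beam angle in degrees, taken mod 180
    spacing : (dy, dx) pixel spacing in mm
    """
    ptv_slice = np.asarray(ptv_slice).astype(bool)
    if ptv_slice.ndim != 2:
        raise BandError("ptv_slice must be 2D")
    dy, dx = spacing
    if dy <= 0 or dx <= 0:
        raise BandError("spacing must be positive")
    if not ptv_slice.any():
        return np.zeros_like(ptv_slice)
    d_row, d_col = direction_vector(angle)
    # normal of the beam direction (rotate d by 90°)
    n_row, n_col = d_col, -d_row
    ny, nx = ptv_slice.shape
    yy = (np.arange(ny) * dy)[:, None]
    xx = (np.arange(nx) * dx)[None, :]
    proj = yy * n_row + xx * n_col
    p = proj[ptv_slice]
    lo, hi = p.min(), p.max()
    eps = 1e-9 * max(1.0, abs(lo), abs(hi))
    return (proj >= lo - eps) & (proj <= hi + eps)


def make_band_set(
    ptv: VolumeGrid,
    k: int,
    *,
    angles: Optional[Sequence[float]] = None,
    clip_body: Optional[VolumeGrid] = None,
) -> BandMaskSet:
    """Build the k-direction band set of a PTV, slice by slice.

    ``angles`` overrides the default ``i * 180/k`` spacing (used by the
    nested-subset ablation harness).  ``clip_body`` optionally restricts
    bands to the body contour; by default bands span the full slice.
    """
    if angles is None:
        angles = band_angles(k)
    else:
        angles = [float(a) for a in angles]
        if len(angles) != k:
            raise BandError("len(angles) must equal k")
    if k < 1:
        raise BandError(f"k must be >= 1, got {k}")
    ptv_vals = ptv.as_bool()
    dz, dy, dx = ptv.spacing_zyx
    body = clip_body.as_bool() if clip_body is not None else None
    bands = []
    for ang in angles:
        m = np.zeros(ptv_vals.shape, dtype=bool)
        for z in range(ptv_vals.shape[0]):
            if ptv_vals[z].any():
                m[z] = band_mask_slice(ptv_vals[z], ang, (dy, dx))
        if body is not None:
            m &= body
        bands.append(ptv.with_values(m.astype(np.uint8)))
    union = ptv.with_values(
        np.logical_or.reduce([b.as_bool() for b in bands]).astype(np.uint8)
    )
    return BandMaskSet(k=k, angles=list(angles), bands=bands, union=union)


def band_dose_coverage(
    dose: VolumeGrid,
    bands: BandMaskSet,
    threshold_fraction: float = 0.5,
) -> float:
    """Fraction of above-threshold dose mass falling inside the band union.

    The thresholded region is ``dose >= threshold_fraction * max(dose)``;
    the statistic is the dose sum inside (union ∩ region) over the dose
    sum in the region, 1.0 when the region is empty.
    """
    if not (0 <= threshold_fraction < 1):
        raise BandError(f"threshold_fraction must be in [0, 1), got {threshold_fraction}")
    dose.require_same_grid(bands.union, "dose and band union")
    d = dose.values
    dmax = float(d.max())
    region = d >= threshold_fraction * dmax if dmax > 0 else np.zeros(d.shape, bool)
    denom = float(d[region].sum())
    if denom <= 0:
        return 1.0
    num = float(d[region & bands.union.as_bool()].sum())
    return num / denom
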