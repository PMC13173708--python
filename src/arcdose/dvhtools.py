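"""DVH computation, dose-volume endpoints, plan-quality scores, and
gamma analysis.

Endpoint grammar (Table-style metric names):

* ``Dmax`` / ``Dmean`` — hottest / mean ROI voxel dose (Gy);
* ``D{p}%`` — dose received by the hottest p% of the ROI volume (Gy),
  linear interpolation of the empirical dose quantile;
* ``V{d}`` — percent of the ROI receiving at least d Gy;
* ``V{p}%`` — percent of the ROI receiving at least p% of prescription;
* ``HI`` — homogeneity index ``(D2% - D98%) / D50%``;
* ``CI`` — Paddick conformity index ``TV_PIV^2 / (TV * PIV)`` at the
  prescription isodose (the RTOG ratio ``PIV / TV`` is available via
  ``ci_variant="rtog"``).

Scores: the dose score is the body-restricted mean absolute voxel
difference (Gy); the DVH score averages absolute endpoint differences
over a configurable (roi, metric) spec (Gy); the scale-normalized DVH
score divides each endpoint difference by a per-metric scale
(prescription for dose-type, 100 points for volume-type metrics) and so
mixes Gy and % endpoints into one dimensionless number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import OAR_NAMES, StructureSet, VolumeGrid


class MetricError(ValueError):
    """Unknown or malformed DVH metric name."""


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of ROI volume receiving >= each bin dose."""

    dose_bins: np.ndarray
    cum_volume: np.ndarray

    def volume_at(self, dose: float) -> float:
        """Fraction of ROI volume at or above a dose, by interpolation."""
        return float(np.interp(dose, self.dose_bins, self.cum_volume))


def compute_dvh(dose: VolumeGrid, mask: VolumeGrid, bin_width: float = 0.1) -> DVHCurve:
    """Exact voxel-counting cumulative DVH on a uniform dose-bin grid."""
    if bin_width <= 0:
        raise MetricError(f"bin_width must be > 0, got {bin_width}")
    dose.require_same_grid(mask, "dose and mask")
    m = mask.as_bool()
    if not m.any():
        raise MetricError("DVH requested for an empty ROI mask")
    d = dose.values[m].astype(float)
    top = max(float(d.max()), bin_width)
    bins = np.arange(0.0, top + 2 * bin_width, bin_width)
    counts = (d[None, :] >= bins[:, None]).mean(axis=1)
    return DVHCurve(dose_bins=bins, cum_volume=counts)


_D_PCT = re.compile(r"^D(\d+(?:\.\d+)?)%$")
_V_PCT = re.compile(r"^V(\d+(?:\.\d+)?)%$")
_V_GY = re.compile(r"^V(\d+(?:\.\d+)?)$")


def metric_units(metric: str) -> str:
    """'Gy' for dose-type metrics, '%' for volume-type, '' for indices."""
    if metric in ("Dmax", "Dmean") or _D_PCT.match(metric):
        return "Gy"
    if _V_PCT.match(metric) or _V_GY.match(metric):
        return "%"
    if metric in ("HI", "CI"):
        return ""
    raise MetricError(f"unknown metric {metric!r}")


def endpoint(
    dose: VolumeGrid,
    mask: VolumeGrid,
    metric: str,
    prescription: float = 45.0,
    *,
    ci_variant: str = "paddick",
) -> float:
    """Evaluate one DVH endpoint for an ROI."""
    dose.require_same_grid(mask, "dose and mask")
    m = mask.as_bool()
    if not m.any():
        raise MetricError(f"empty ROI mask for metric {metric!r}")
    d = dose.values[m].astype(float)
    if metric == "Dmax":
        return float(d.max())
    if metric == "Dmean":
        return float(d.mean())
    mm = _D_PCT.match(metric)
    if mm:
        p = float(mm.group(1))
        if not (0 <= p <= 100):
            raise MetricError(f"volume percentage out of range in {metric!r}")
        # dose to the hottest p% == (1 - p/100) quantile, linear interpolation
        return float(np.quantile(d, 1.0 - p / 100.0, method="linear"))
    mm = _V_PCT.match(metric)
    if mm:
        thr = float(mm.group(1)) / 100.0 * prescription
        return float((d >= thr).mean() * 100.0)
    mm = _V_GY.match(metric)
    if mm:
        thr = float(mm.group(1))
        return float((d >= thr).mean() * 100.0)
    if metric == "HI":
        d2 = float(np.quantile(d, 0.98, method="linear"))
        d98 = float(np.quantile(d, 0.02, method="linear"))
        d50 = float(np.quantile(d, 0.50, method="linear"))
        if d50 == 0:
            raise MetricError("HI undefined: D50% is zero")
        return (d2 - d98) / d50
    if metric == "CI":
        piv = dose.values >= prescription
        tv = int(m.sum())
        n_piv = int(piv.sum())
        inter = int((piv & m).sum())
        if ci_variant == "paddick":
            if n_piv == 0:
                return 0.0
            return inter**2 / (tv * n_piv)
        if ci_variant == "rtog":
            return n_piv / tv
        raise MetricError(f"unknown CI variant {ci_variant!r}")
    raise MetricError(f"unknown metric {metric!r}")


# -- endpoint tables -------------------------------------------------------

#: (roi, metrics) spec used for the DVH score by default.
DEFAULT_DVH_SPEC: Dict[str, Tuple[str, ...]] = {
    "PTV": ("D2%", "D98%", "Dmean"),
    **{oar: ("Dmean", "Dmax") for oar in OAR_NAMES},
}

#: OpenKBP-style endpoint set (target quantiles + OAR mean/max).
OPENKBP_DVH_SPEC: Dict[str, Tuple[str, ...]] = {
    "PTV": ("D1%", "D95%", "D99%"),
    **{oar: ("Dmean", "Dmax") for oar in OAR_NAMES},
}

#: Protocol-style table of target and organ endpoints (mixed D and V).
PROTOCOL_SPEC: Dict[str, Tuple[str, ...]] = {
    "PTV": ("Dmax", "Dmean", "V95%", "V100%", "D98%", "D2%", "CI", "HI"),
    "Bladder": ("Dmean", "V30", "V40", "V45"),
    "Rectum": ("Dmean", "V30", "V40", "V45"),
    "SmallIntestine": ("Dmax", "Dmean", "V30"),
    "SpinalCord": ("Dmax", "Dmean"),
    "Marrow": ("Dmean", "V30"),
    "FemoralHeadL": ("Dmean", "V30", "V40"),
    "FemoralHeadR": ("Dmean", "V30", "V40"),
}

NAMED_SPECS = {
    "default": DEFAULT_DVH_SPEC,
    "openkbp": OPENKBP_DVH_SPEC,
    "protocol": PROTOCOL_SPEC,
}


def endpoint_table(
    dose: VolumeGrid,
    structures: StructureSet,
    spec: Mapping[str, Sequence[str]] | str = "default",
    prescription: float = 45.0,
) -> pd.DataFrame:
    """Evaluate a (roi, metric) spec into a tidy endpoint table."""
    if isinstance(spec, str):
        spec = NAMED_SPECS[spec]
    rows = []
    for roi, metrics in spec.items():
        if roi not in structures:
            raise MetricError(f"ROI {roi!r} not present in the structure set")
        for metric in metrics:
            val = endpoint(dose, structures[roi], metric, prescription)
            rows.append((roi, metric, val, metric_units(metric)))
    return pd.DataFrame(rows, columns=["roi", "metric", "value", "units"])


def save_endpoint_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_endpoint_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- scores ----------------------------------------------------------------

def dose_score(pred: VolumeGrid, ref: VolumeGrid, body: VolumeGrid) -> float:
    """Mean absolute voxel difference inside the body (Gy)."""
    pred.require_same_grid(ref, "pred and ref")
    pred.require_same_grid(body, "pred and body")
    m = body.as_bool()
    if not m.any():
        raise MetricError("empty body mask")
    return float(np.abs(pred.values[m] - ref.values[m]).mean())


def _spec_pairs(spec) -> List[Tuple[str, str]]:
    if isinstance(spec, str):
        spec = NAMED_SPECS[spec]
    pairs = [(roi, metric) for roi, metrics in spec.items() for metric in metrics]
    if not pairs:
        raise MetricError("endpoint spec is empty")
    return pairs


def dvh_score(
    pred: VolumeGrid,
    ref: VolumeGrid,
    structures: StructureSet,
    endpoint_spec: Mapping[str, Sequence[str]] | str = "default",
    prescription: float = 45.0,
) -> float:
    """Mean absolute endpoint difference over the spec (dose metrics, Gy)."""
    pairs = _spec_pairs(endpoint_spec)
    missing = sorted({roi for roi, _ in pairs if roi not in structures})
    if missing:
        raise MetricError(f"ROIs missing from structure set: {missing}")
    diffs = [
        abs(
            endpoint(pred, structures[roi], metric, prescription)
            - endpoint(ref, structures[roi], metric, prescription)
        )
        for roi, metric in pairs
    ]
    return float(np.mean(diffs))


def default_scales(pairs: Sequence[Tuple[str, str]], prescription: float) -> Dict[Tuple[str, str], float]:
    """Prescription Gy for dose-type metrics, 100 points for volume-type."""
    scales = {}
    for roi, metric in pairs:
        u = metric_units(metric)
        scales[(roi, metric)] = prescription if u == "Gy" else 100.0 if u == "%" else 1.0
    return scales


def sn_dvh_score(
    pred: VolumeGrid,
    ref: VolumeGrid,
    structures: StructureSet,
    endpoint_spec: Mapping[str, Sequence[str]] | str = "default",
    scales: Optional[Mapping[Tuple[str, str], float]] = None,
    prescription: float = 45.0,
) -> float:
    """Scale-normalized DVH score: mean of |Δendpoint| / scale (dimensionless)."""
    pairs = _spec_pairs(endpoint_spec)
    if scales is None:
        scales = default_scales(pairs, prescription)
    vals = []
    for roi, metric in pairs:
        s = float(scales[(roi, metric)])
        if s <= 0:
            raise MetricError(f"scale for ({roi}, {metric}) must be positive, got {s}")
        diff = abs(
            endpoint(pred, structures[roi], metric, prescription)
            - endpoint(ref, structures[roi], metric, prescription)
        )
        vals.append(diff / s)
    return float(np.mean(vals))


# -- gamma analysis --------------------------------------------------------

def _upsample(values: np.ndarray, refine: int) -> np.ndarray:
    """Trilinear upsampling onto the grid of fractional steps 1/refine."""
    from scipy.ndimage import map_coordinates

    fine_axes = [np.arange((n - 1) * refine + 1) / refine for n in values.shape]
    coords = np.meshgrid(*fine_axes, indexing="ij")
    return map_coordinates(values.astype(float), coords, order=1, mode="nearest")


def gamma_pass_rate(
    ref: VolumeGrid,
    eval_dose: VolumeGrid,
    dd_percent: float = 3.0,
    dta_mm: float = 3.0,
    low_dose_threshold: float = 0.1,
    *,
    refine: int = 3,
    search_factor: float = 3.0,
    return_gamma: bool = False,
):
    """Global-normalization gamma pass rate (percent).

    The dose-difference criterion is ``dd_percent`` of the reference
    maximum; gamma is evaluated at reference voxels at or above
    ``low_dose_threshold`` of the reference maximum.  For each such
    voxel, displacements on a ``refine``-times-refined voxel grid within
    a radius of ``search_factor * dta_mm`` are searched, with the
    evaluated dose trilinearly interpolated; a voxel passes when
    ``min sqrt((Δd/dd)^2 + (|r|/dta)^2) <= 1``.  The reference volume is
    the normalization source, so the statistic is not symmetric under
    swapping the two doses.
    """
    ref.require_same_grid(eval_dose, "ref and eval doses")
    if dd_percent <= 0 or dta_mm <= 0:
        raise MetricError("dd and dta criteria must be positive")
    ref_max = float(ref.values.max())
    if ref_max <= 0:
        raise MetricError("reference dose is empty (max <= 0)")
    evaluable = ref.values >= low_dose_threshold * ref_max
    if not evaluable.any():
        raise MetricError("no evaluable voxels above the low-dose threshold")
    dd_abs = dd_percent / 100.0 * ref_max

    spacing_zyx = np.asarray(ref.spacing_zyx)
    fine_step = spacing_zyx / refine
    radius = search_factor * dta_mm
    max_off = np.floor(radius / fine_step).astype(int)

    # enumerate fine-grid displacements inside the search sphere, sorted
    # by their spatial gamma term so the scan can stop early
    offs = np.stack(
        np.meshgrid(
            *[np.arange(-m, m + 1) for m in max_off],
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    dist = np.linalg.norm(offs * fine_step, axis=1)
    keep = dist <= radius + 1e-9
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    offs, dist = offs[order], dist[order]

    fine = _upsample(eval_dose.values, refine)
    idx = np.argwhere(evaluable)
    fine_idx = idx * refine
    ref_vals = ref.values[evaluable]
    shape = np.asarray(fine.shape)

    gamma_sq = np.full(ref_vals.shape, np.inf)
    for off, r in zip(offs, dist):
        space_term = (r / dta_mm) ** 2
        if space_term >= gamma_sq.max():
            break  # no remaining displacement can improve any voxel
        pos = fine_idx + off
        valid = np.all((pos >= 0) & (pos < shape), axis=1)
        if not valid.any():
            continue
        dvals = fine[pos[valid, 0], pos[valid, 1], pos[valid, 2]]
        cand = ((dvals - ref_vals[valid]) / dd_abs) ** 2 + space_term
        cur = gamma_sq[valid]
        gamma_sq[valid] = np.minimum(cur, cand)
    gamma = np.sqrt(gamma_sq)
    rate = float((gamma <= 1.0).mean() * 100.0)
    if return_gamma:
        gmap = np.full(ref.shape, np.nan)
        gmap[tuple(idx.T)] = gamma
        return rate, gmap
    return rate
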