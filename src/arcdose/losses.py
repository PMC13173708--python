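"""Training objectives for the refinement stage.

The composite second-stage objective is a weighted sum of four terms,

    L_total = λ_body·L_body + λ_band·L_band + λ_grad·L_grad + λ_dvh·L_dvh,

all computed on prescription-normalized dose: a body-restricted MAE
(global accuracy), a band-union-restricted MAE (fidelity where arc dose
enters), an L1 mismatch of spacing-aware dose gradients inside the band
union (gradient consistency at fall-offs), and an L1 distance between
soft (sigmoid-relaxed) cumulative DVHs per ROI (endpoint agreement).
The first-stage objective is L_body alone.

Each term has a hand-derived gradient with respect to the prediction —
this is what the numpy network trainer backpropagates — and every
gradient is finite-difference checked in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np


class LossError(ValueError):
    """Invalid loss inputs (empty masks, bad weights)."""


@dataclass
class LossWeights:
    """Non-negative weights of the four composite-loss terms.

    The auxiliary terms default to quarter weight: their per-voxel
    gradients are intrinsically larger than the global body MAE's (the
    band term averages over a smaller region, and the soft-DVH term is
    sharpened by 1/temperature inside small ROIs), so subordinate
    weights keep the global term the dominant driver while the
    auxiliaries refine band fidelity, fall-off gradients, and endpoint
    agreement.
    """

    lambda_body: float = 1.0
    lambda_band: float = 0.25
    lambda_grad: float = 0.25
    lambda_dvh: float = 0.25

    def __post_init__(self) -> None:
        vals = (self.lambda_body, self.lambda_band, self.lambda_grad, self.lambda_dvh)
        if any(v < 0 for v in vals):
            raise LossError(f"loss weights must be >= 0, got {vals}")
        if not any(v > 0 for v in vals):
            raise LossError("at least one loss weight must be positive")


@dataclass
class LossBreakdown:
    """Per-term values and the weighted total (normalized-dose units)."""

    l_body: float
    l_band: float
    l_grad: float
    l_dvh: float
    l_total: float


DEFAULT_DVH_BINS = np.linspace(0.0, 1.2, 25)
DEFAULT_TEMPERATURE = 0.02  # ~1 Gy softness at a 45 Gy prescription


def _masked_mae(pred, ref, mask):
    diff = pred[mask] - ref[mask]
    n = diff.size
    value = float(np.abs(diff).mean())
    grad = np.zeros_like(pred, dtype=float)
    grad[mask] = np.sign(diff) / n
    return value, grad


def loss_body(pred: np.ndarray, ref: np.ndarray, body_mask: np.ndarray) -> float:
    """MAE over body voxels (normalized dose)."""
    return loss_body_grad(pred, ref, body_mask)[0]


def loss_body_grad(pred, ref, body_mask):
    body_mask = np.asarray(body_mask, bool)
    if not body_mask.any():
        raise LossError("body mask is empty")
    return _masked_mae(np.asarray(pred, float), np.asarray(ref, float), body_mask)


def loss_band(pred: np.ndarray, ref: np.ndarray, band_union: np.ndarray) -> float:
    """MAE restricted to the beam-band union."""
    return loss_band_grad(pred, ref, band_union)[0]


def loss_band_grad(pred, ref, band_union):
    band_union = np.asarray(band_union, bool)
    if not band_union.any():
        raise LossError("band union is empty")
    return _masked_mae(np.asarray(pred, float), np.asarray(ref, float), band_union)


def _gradient_op(f: np.ndarray, spacing_zyx: Sequence[float]) -> list[np.ndarray]:
    """Spacing-aware finite-difference gradient (central interior,
    one-sided edges — same stencil as ``np.gradient``)."""
    return list(np.gradient(f, *spacing_zyx))


def _gradient_adjoint(gs: Sequence[np.ndarray], spacing_zyx: Sequence[float]) -> np.ndarray:
    """Exact adjoint of :func:`_gradient_op` (needed for backprop)."""
    out = np.zeros_like(gs[0], dtype=float)
    for axis, (g, h) in enumerate(zip(gs, spacing_zyx)):
        g = np.moveaxis(g, axis, 0)
        o = np.moveaxis(out, axis, 0)
        n = g.shape[0]
        if n < 2:
            raise LossError("gradient loss needs >= 2 voxels per axis")
        # forward: d[0] = (f1-f0)/h ; d[i] = (f[i+1]-f[i-1])/2h ; d[-1] = (f[-1]-f[-2])/h
        o[0] += -g[0] / h
        o[1] += g[0] / h
        if n > 2:
            o[2:] += g[1:-1] / (2 * h)
            o[:-2] += -g[1:-1] / (2 * h)
        o[-1] += g[-1] / h
        o[-2] += -g[-1] / h
    return out


def loss_grad(
    pred: np.ndarray,
    ref: np.ndarray,
    band_union: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Mean L1 difference of dose-gradient vectors inside the band union.

    ``spacing`` is given axis-ordered ``(dz, dy, dx)`` to match the
    arrays; gradients are in normalized dose per mm.
    """
    return loss_grad_grad(pred, ref, band_union, spacing)[0]


def loss_grad_grad(pred, ref, band_union, spacing=(1.0, 1.0, 1.0)):
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    band_union = np.asarray(band_union, bool)
    if not band_union.any():
        raise LossError("band union is empty")
    if any(s < 3 for s in pred.shape):
        raise LossError(f"gradient loss needs >= 3 voxels per axis, got shape {pred.shape}")
    gp = _gradient_op(pred, spacing)
    gr = _gradient_op(ref, spacing)
    n = int(band_union.sum())
    value = 0.0
    sens = []
    for a in range(3):
        d = gp[a] - gr[a]
        value += float(np.abs(d[band_union]).sum()) / n
        s = np.zeros_like(d)
        s[band_union] = np.sign(d[band_union]) / n
        sens.append(s)
    grad = _gradient_adjoint(sens, spacing)
    return value, grad


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def loss_dvh(
    pred: np.ndarray,
    ref: np.ndarray,
    structures: Mapping[str, np.ndarray],
    temperature: float = DEFAULT_TEMPERATURE,
    bin_grid: Optional[np.ndarray] = None,
) -> float:
    """L1 distance between soft cumulative DVHs, averaged over ROIs and bins.

    The soft curve of an ROI is ``s(b) = mean_v sigmoid((d_v - b)/T)``,
    a smooth relaxation of the fraction of the ROI at or above dose b;
    as T → 0 it recovers the hard DVH.
    """
    return loss_dvh_grad(pred, ref, structures, temperature, bin_grid)[0]


def loss_dvh_grad(pred, ref, structures, temperature=DEFAULT_TEMPERATURE, bin_grid=None):
    if temperature <= 0:
        raise LossError(f"temperature must be > 0, got {temperature}")
    bins = DEFAULT_DVH_BINS if bin_grid is None else np.asarray(bin_grid, float)
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    rois = []
    for name, mask in structures.items():
        mask = np.asarray(mask, bool)
        if not mask.any():
            warnings.warn(f"DVH loss: skipping empty ROI {name!r}")
            continue
        rois.append(mask)
    if not rois:
        raise LossError("all ROIs empty in DVH loss")
    value = 0.0
    grad = np.zeros_like(pred)
    nb = bins.size
    nr = len(rois)
    for mask in rois:
        dp = pred[mask][:, None]  # (N, 1)
        dr = ref[mask][:, None]
        nvox = dp.shape[0]
        sp = _sigmoid((dp - bins[None, :]) / temperature).mean(axis=0)  # (B,)
        sr = _sigmoid((dr - bins[None, :]) / temperature).mean(axis=0)
        diff = sp - sr
        value += float(np.abs(diff).sum()) / (nb * nr)
        # d|diff_b|/d pred_v = sign(diff_b) * σ'((p_v - b)/T) / (T * nvox)
        sig = _sigmoid((dp - bins[None, :]) / temperature)
        dsig = sig * (1.0 - sig) / temperature
        gvox = (dsig * np.sign(diff)[None, :]).sum(axis=1) / (nvox * nb * nr)
        g = np.zeros_like(pred)
        g[mask] = gvox
        grad += g
    return value, grad


def total_loss(
    pred: np.ndarray,
    ref: np.ndarray,
    body: np.ndarray,
    band_union: Optional[np.ndarray],
    structures: Optional[Mapping[str, np.ndarray]],
    weights: LossWeights,
    *,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    temperature: float = DEFAULT_TEMPERATURE,
    bin_grid: Optional[np.ndarray] = None,
    return_grad: bool = False,
):
    """The weighted composite objective; zero-weight terms are skipped
    entirely (they are neither computed nor required to be well-posed)."""
    w = weights
    terms = {"l_body": 0.0, "l_band": 0.0, "l_grad": 0.0, "l_dvh": 0.0}
    grad = np.zeros_like(np.asarray(pred, float)) if return_grad else None

    def acc(lam, key, fn, *args, **kw):
        if lam == 0:
            return
        v, g = fn(*args, **kw)
        terms[key] = v
        if return_grad:
            np.add(grad, lam * g, out=grad)

    acc(w.lambda_body, "l_body", loss_body_grad, pred, ref, body)
    acc(w.lambda_band, "l_band", loss_band_grad, pred, ref, band_union)
    acc(w.lambda_grad, "l_grad", loss_grad_grad, pred, ref, band_union, spacing)
    acc(w.lambda_dvh, "l_dvh", loss_dvh_grad, pred, ref, structures, temperature, bin_grid)

    total = (
        w.lambda_body * terms["l_body"]
        + w.lambda_band * terms["l_band"]
        + w.lambda_grad * terms["l_grad"]
        + w.lambda_dvh * terms["l_dvh"]
    )
    breakdown = LossBreakdown(
        l_body=terms["l_body"],
        l_band=terms["l_band"],
        l_grad=terms["l_grad"],
        l_dvh=terms["l_dvh"],
        l_total=float(total),
    )
    if return_grad:
        return breakdown, grad
    return breakdown
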