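"""The two-stage cascaded dose-prediction models and their training.

Stage 1 is a 3D U-Net mapping CT + nine structure masks (10 channels)
to a coarse dose, trained with body-masked MAE.  Stage 2 is a 3D
residual U-Net that sees the CT, structure masks, the coarse dose, and
the four directional beam-band masks (15 channels) and predicts a
correction on top of the coarse dose (clipped at zero), trained with
the composite objective of :mod:`arcdose.losses` while stage 1 stays
frozen.  Doses are prescription-normalized inside the networks and
returned in Gy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import losses
from .bandgeom import make_band_set
from .grid import ROI_NAMES, StructureSet, VolumeGrid
from .losses import LossWeights
from .nn import Adam, ShapeError, UNet3D, load_checkpoint, save_checkpoint
from .phantom import cohort_cases, load_cohort_case

HU_CLIP = (-1000.0, 1000.0)
STAGE1_CHANNELS = 1 + len(ROI_NAMES)  # CT + 9 masks = 10
N_BANDS = 4
STAGE2_CHANNELS = STAGE1_CHANNELS + 1 + N_BANDS  # + coarse dose + 4 bands = 15


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 1
    learning_rate: float = 3e-4
    seed: int = 0
    width: int = 16
    depth: int = 3
    prescription: float = 45.0
    n_bands: int = N_BANDS
    loss_weights: LossWeights = field(default_factory=LossWeights)
    dvh_temperature: float = losses.DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size/learning_rate must be positive")


def normalize_ct(ct: VolumeGrid) -> np.ndarray:
    lo, hi = HU_CLIP
    return ((np.clip(ct.values, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def stage1_input(ct: VolumeGrid, structures: StructureSet) -> np.ndarray:
    """(10, nz, ny, nx): normalized CT plus the nine binary masks."""
    chans = [normalize_ct(ct)]
    chans += [structures[n].values.astype(np.float32) for n in ROI_NAMES]
    return np.stack(chans)


def stage2_input(
    ct: VolumeGrid,
    structures: StructureSet,
    coarse_norm: np.ndarray,
    band_stack: np.ndarray,
) -> np.ndarray:
    """(15, ...): CT, masks, prescription-normalized coarse dose, 4 bands."""
    if band_stack.shape[0] != N_BANDS:
        raise ShapeError(f"expected {N_BANDS} band channels, got {band_stack.shape[0]}")
    x1 = stage1_input(ct, structures)
    return np.concatenate(
        [x1, coarse_norm[None].astype(np.float32), band_stack.astype(np.float32)]
    )


def build_stage1(config: TrainConfig) -> UNet3D:
    """3D U-Net, 10 -> 1 channels, softplus output (dose is non-negative)."""
    return UNet3D(
        cin=STAGE1_CHANNELS, width=config.width, depth=config.depth,
        final_activation="softplus", seed=config.seed,
    )


def build_stage2(config: TrainConfig) -> UNet3D:
    """3D residual U-Net, 15 -> 1 channels; zero-initialized output so
    the cascade starts exactly at the coarse dose."""
    return UNet3D(
        cin=STAGE2_CHANNELS, width=config.width, depth=config.depth,
        residual=True, final_zero=True, final_activation="none",
        seed=config.seed + 1,
    )


# -- dataset handling ------------------------------------------------------

@dataclass
class Case:
    case_id: str
    ct: VolumeGrid
    structures: StructureSet
    dose: VolumeGrid  # reference dose, Gy


def load_split(cohort_dir, split: str) -> List[Case]:
    ids = cohort_cases(cohort_dir, split)
    out = []
    for cid in ids:
        data = load_cohort_case(cohort_dir, cid)
        out.append(Case(cid, data["ct"], data["structures"], data["dose"]))
    return out


def _val_mae(net: UNet3D, cases: Sequence[Case], rx: float) -> float:
    errs = []
    for c in cases:
        pred = net.forward(stage1_input(c.ct, c.structures))[0]
        body = c.structures["Body"].as_bool()
        errs.append(float(np.abs(pred[body] - c.dose.values[body] / rx).mean()))
    return float(np.mean(errs))


def _write_history(path: Optional[Path], history: List[dict]) -> None:
    if path is None or not history:
        return
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0]))
        writer.writeheader()
        writer.writerows(history)


def train_stage1(
    cohort_dir,
    config: TrainConfig,
    checkpoint_path,
    *,
    history_path=None,
) -> Path:
    """Train the coarse-dose U-Net with body-masked MAE; keep the
    best-validation parameters.  Deterministic for a given seed."""
    train_cases = load_split(cohort_dir, "train")
    val_cases = load_split(cohort_dir, "val")
    if not train_cases or not val_cases:
        raise ValueError("cohort must have non-empty train and val splits")
    rx = config.prescription
    net = build_stage1(config)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    best = (np.inf, None)
    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_cases))
        train_losses = []
        for i in order:
            c = train_cases[i]
            x = stage1_input(c.ct, c.structures)
            pred = net.forward(x)
            body = c.structures["Body"].as_bool()
            value, grad = losses.loss_body_grad(pred[0], c.dose.values / rx, body)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"NaN/inf stage-1 loss at epoch {epoch}, case {c.case_id}"
                )
            net.zero_grads()
            net.backward(grad[None].astype(np.float32))
            opt.step(net.gradients())
            train_losses.append(value)
        val = _val_mae(net, val_cases, rx)
        history.append(
            {"epoch": epoch, "train_mae": float(np.mean(train_losses)), "val_mae": val}
        )
        if val < best[0]:
            best = (val, {k: v.copy() for k, v in net.parameters().items()})
    net.load_parameters(best[1])
    save_checkpoint(
        checkpoint_path, net,
        extra={"stage": 1, "config": _cfg_dict(config), "best_val_mae": best[0],
               "history": history},
    )
    _write_history(Path(history_path) if history_path else None, history)
    return Path(checkpoint_path)


def _cfg_dict(config: TrainConfig) -> dict:
    d = dict(vars(config))
    d["loss_weights"] = vars(config.loss_weights)
    return d


def _case_bands(c: Case, n_bands: int) -> np.ndarray:
    bs = make_band_set(c.structures["PTV"], n_bands)
    return bs.stacked()


def _coarse_norm(net1: UNet3D, c: Case) -> np.ndarray:
    return net1.forward(stage1_input(c.ct, c.structures))[0].astype(np.float32)


def train_stage2(
    cohort_dir,
    stage1_checkpoint,
    config: TrainConfig,
    checkpoint_path,
    *,
    history_path=None,
) -> Path:
    """Train the refinement ResU-Net with the composite objective.

    Stage 1 is frozen; its coarse doses and the per-case band masks are
    computed once up front.  The refined output is
    ``max(coarse + correction, 0)`` and the loss gradient flows through
    that clip into the correction network only.
    """
    net1, _ = load_checkpoint(stage1_checkpoint)
    train_cases = load_split(cohort_dir, "train")
    val_cases = load_split(cohort_dir, "val")
    if not train_cases or not val_cases:
        raise ValueError("cohort must have non-empty train and val splits")
    rx = config.prescription
    spacing_zyx = train_cases[0].ct.spacing_zyx

    def prep(cases):
        out = []
        for c in cases:
            coarse = _coarse_norm(net1, c)
            bands = _case_bands(c, config.n_bands)
            x = stage2_input(c.ct, c.structures, coarse, bands)
            rois = {
                n: c.structures[n].as_bool()
                for n in ROI_NAMES
                if n != "Body" and c.structures[n].as_bool().any()
            }
            out.append(
                dict(case=c, x=x, coarse=coarse, union=np.logical_or.reduce(bands.astype(bool)),
                     body=c.structures["Body"].as_bool(), rois=rois,
                     ref=(c.dose.values / rx).astype(np.float32))
            )
        return out

    train_prep = prep(train_cases)
    val_prep = prep(val_cases)

    net2 = build_stage2(config)
    opt = Adam(net2.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    best = (np.inf, {k: v.copy() for k, v in net2.parameters().items()})
    history = []

    def refined_of(item, net):
        delta = net.forward(item["x"])[0]
        raw = item["coarse"] + delta
        return np.maximum(raw, 0.0), raw

    def val_metric():
        errs = [
            float(np.abs(refined_of(it, net2)[0][it["body"]] - it["ref"][it["body"]]).mean())
            for it in val_prep
        ]
        return float(np.mean(errs))

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_prep))
        epoch_losses = []
        for i in order:
            it = train_prep[i]
            refined, raw = refined_of(it, net2)
            breakdown, grad = losses.total_loss(
                refined, it["ref"], it["body"], it["union"], it["rois"],
                config.loss_weights, spacing=spacing_zyx,
                temperature=config.dvh_temperature, return_grad=True,
            )
            if not np.isfinite(breakdown.l_total):
                raise FloatingPointError(
                    f"NaN/inf stage-2 loss at epoch {epoch}, case {it['case'].case_id}"
                )
            grad = grad * (raw > 0)  # through the non-negativity clip
            net2.zero_grads()
            net2.backward(grad[None].astype(np.float32))
            opt.step(net2.gradients())
            epoch_losses.append(breakdown.l_total)
        val = val_metric()
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), "val_mae": val}
        )
        if val < best[0]:
            best = (val, {k: v.copy() for k, v in net2.parameters().items()})
    net2.load_parameters(best[1])
    save_checkpoint(
        checkpoint_path, net2,
        extra={"stage": 2, "config": _cfg_dict(config), "best_val_mae": best[0],
               "history": history, "stage1_checkpoint": str(stage1_checkpoint)},
    )
    _write_history(Path(history_path) if history_path else None, history)
    return Path(checkpoint_path)


def predict(
    ct: VolumeGrid,
    structures: StructureSet,
    stage1_checkpoint,
    stage2_checkpoint=None,
    *,
    prescription: float = 45.0,
    n_bands: int = N_BANDS,
) -> Dict[str, VolumeGrid]:
    """Run the cascade on one case; returns coarse and refined doses in Gy,
    both zeroed outside the body."""
    net1, _ = load_checkpoint(stage1_checkpoint)
    body = structures["Body"].as_bool()
    coarse = net1.forward(stage1_input(ct, structures))[0].astype(np.float32)
    out: Dict[str, VolumeGrid] = {}
    coarse_gy = coarse * prescription
    coarse_gy[~body] = 0.0
    out["coarse"] = ct.with_values(coarse_gy.astype(float))
    if stage2_checkpoint is not None:
        net2, _ = load_checkpoint(stage2_checkpoint)
        bands = make_band_set(structures["PTV"], n_bands).stacked()
        x2 = stage2_input(ct, structures, coarse, bands)
        delta = net2.forward(x2)[0]
        refined = np.maximum(coarse + delta, 0.0) * prescription
        refined[~body] = 0.0
        out["refined"] = ct.with_values(refined.astype(float))
    return out
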