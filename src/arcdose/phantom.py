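"""Synthetic pelvic phantom generator and surrogate beam dose engine.

Every downstream component (band geometry, dose prediction, inverse
planning, evaluation) is exercised on cases produced here: a CT-like
volume, the nine canonical structure masks, and a reference dose with
the directional, multi-beam character of an arc plan.

The dose engine is a parallel-ray exponential-attenuation model: for a
gantry angle θ (axial plane, mod 180°), unit-fluence rays traverse the
body and deposit ``exp(-mu * depth)`` at each voxel, where ``depth`` is
the radiological path length inside the body.  Dose is linear in the
per-angle weights and optional per-ray beamlet weights, which is what
the inverse-planning surrogate optimizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import (
    ROI_NAMES,
    GridError,
    StructureSet,
    VolumeGrid,
    load_case,
    save_case,
)


class ConfigurationError(ValueError):
    """Invalid phantom or beam configuration."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic pelvic case generator.

    ``shape`` is ``(nz, ny, nx)`` — slices, rows, columns; ``spacing`` is
    ``(dx, dy, dz)`` mm.  ``seed`` fixes all randomness (geometry jitter
    and CT noise).  ``prescription`` is the plan prescription in Gy.
    """

    shape: Tuple[int, int, int] = (32, 64, 64)
    spacing: Tuple[float, float, float] = (2.5, 2.5, 5.0)
    seed: int = 0
    prescription: float = 45.0
    pos_jitter: float = 0.04   # organ-center jitter, fraction of axis length
    size_jitter: float = 0.10  # organ-size jitter, fractional
    hu_noise: float = 20.0     # CT additive Gaussian noise, HU
    beam_angles: Tuple[float, ...] = tuple(float(i) * 22.5 for i in range(8))
    attenuation_mu: float = 0.004  # per mm, megavoltage-like

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ConfigurationError(f"grid shape must be >= 16 per axis, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be positive, got {self.spacing}")
        if self.prescription <= 0:
            raise ConfigurationError("prescription must be > 0")
        if self.pos_jitter < 0 or self.size_jitter < 0 or self.hu_noise < 0:
            raise ConfigurationError("jitter/noise ranges must be >= 0")


def _ellipsoid(shape: Tuple[int, int, int], center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = (max(s, 1e-6) for s in semi)
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig) -> Tuple[VolumeGrid, StructureSet]:
    """Generate one pelvic-like case: CT volume plus nine structure masks.

    Layout (axial plane): elliptical body; ellipsoidal PTV near the
    center; bladder anterior and rectum posterior, abutting the PTV;
    spinal-cord column on the posterior midline; femoral heads lateral;
    a bony pelvic-ring shell standing in for marrow; small-intestine
    blobs superior/anterior.  Deterministic for a given config.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2

    def jit_pos(n: int) -> float:
        return float(rng.uniform(-1, 1) * config.pos_jitter * n)

    def jit_size() -> float:
        return float(1.0 + rng.uniform(-1, 1) * config.size_jitter)

    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]

    # Body: per-slice ellipse with a mild superior/inferior taper.
    taper = 1.0 - 0.08 * ((zz - cz) / max(nz / 2, 1)) ** 2
    body = (((yy - cy) / (0.40 * ny * taper)) ** 2 + ((xx - cx) / (0.46 * nx * taper)) ** 2) <= 1.0

    # PTV — central, slightly posterior of mid-plane.
    s = jit_size()
    ptv_c = (cz + jit_pos(nz), cy + 0.04 * ny + jit_pos(ny), cx + jit_pos(nx))
    ptv_semi = (0.30 * nz * s, 0.17 * ny * s, 0.17 * nx * s)
    ptv = _ellipsoid(config.shape, ptv_c, ptv_semi)

    # Bladder — anterior to the PTV, abutting it.
    s = jit_size()
    bl_c = (cz + jit_pos(nz), ptv_c[1] - ptv_semi[1] - 0.09 * ny + jit_pos(ny), cx + jit_pos(nx))
    bladder = _ellipsoid(config.shape, bl_c, (0.20 * nz * s, 0.11 * ny * s, 0.13 * nx * s))

    # Rectum — posterior midline tube.
    s = jit_size()
    re_c = (cz + jit_pos(nz), ptv_c[1] + ptv_semi[1] + 0.05 * ny + jit_pos(ny), cx + jit_pos(nx) * 0.5)
    rectum = _ellipsoid(config.shape, re_c, (0.30 * nz * s, 0.055 * ny * s, 0.05 * nx * s))

    # Spinal cord — thin posterior midline column through all slices.
    r_cord = 0.035 * min(ny, nx) * jit_size()
    cord_y = cy + 0.33 * ny + jit_pos(ny) * 0.3
    cord_x = cx + jit_pos(nx) * 0.3
    cord = ((yy - cord_y) ** 2 + (xx - cord_x) ** 2 <= r_cord**2) & np.ones((nz, 1, 1), bool)

    # Femoral heads — lateral spheres.
    fem = {}
    for name, sx in (("FemoralHeadL", -1.0), ("FemoralHeadR", 1.0)):
        s = jit_size()
        c = (cz + jit_pos(nz) * 0.5, cy + 0.02 * ny + jit_pos(ny) * 0.5, cx + sx * 0.34 * nx + jit_pos(nx) * 0.5)
        fem[name] = _ellipsoid(config.shape, c, (0.16 * nz * s, 0.10 * ny * s, 0.10 * nx * s))

    # Marrow — bony pelvic-ring shell (annulus of the body ellipse) over
    # the central slices; the same mask doubles as the bone compartment.
    rr = ((yy - cy) / (0.40 * ny)) ** 2 + ((xx - cx) / (0.46 * nx)) ** 2
    ring = (rr <= 0.90**2) & (rr >= 0.74**2)
    marrow = ring & (np.abs(zz - cz) <= 0.38 * nz) & np.ones((1, ny, nx), bool)

    # Small intestine — a few superior/anterior blobs at fixed anchor
    # points, each independently jittered.
    intestine = np.zeros(config.shape, bool)
    anchors = [(0.28, -0.12, -0.18), (0.36, -0.20, 0.10), (0.22, -0.08, 0.20), (0.33, -0.16, -0.02)]
    for fz, fy, fx in anchors:
        c = (cz + fz * nz + jit_pos(nz), cy + fy * ny + jit_pos(ny), cx + fx * nx + jit_pos(nx))
        s = jit_size()
        intestine |= _ellipsoid(config.shape, c, (0.11 * nz * s, 0.09 * ny * s, 0.09 * nx * s))

    masks_raw: Dict[str, np.ndarray] = {
        "PTV": ptv & body,
        "Bladder": bladder,
        "Rectum": rectum,
        "SmallIntestine": intestine,
        "SpinalCord": cord,
        "Marrow": marrow,
        "FemoralHeadL": fem["FemoralHeadL"],
        "FemoralHeadR": fem["FemoralHeadR"],
        "Body": body,
    }
    ptv_final = masks_raw["PTV"]
    for name in masks_raw:
        if name in ("PTV", "Body"):
            continue
        masks_raw[name] = masks_raw[name] & body & ~ptv_final

    bone = masks_raw["Marrow"] | masks_raw["FemoralHeadL"] | masks_raw["FemoralHeadR"]
    ct_vals = np.full(config.shape, -1000.0)
    ct_vals[body] = 0.0
    ct_vals[bone] = 700.0
    if config.hu_noise > 0:
        noise = rng.normal(0.0, config.hu_noise, size=config.shape)
        ct_vals[body] += noise[body]
    ct_vals = np.clip(ct_vals, -1000.0, 1500.0)

    ct = VolumeGrid(ct_vals, config.spacing)
    structures = StructureSet(
        {n: VolumeGrid(masks_raw[n].astype(np.uint8), config.spacing) for n in ROI_NAMES}
    )
    return ct, structures


# -- beam geometry and the forward dose model ------------------------------

def direction_vector(angle_deg: float) -> Tuple[float, float]:
    """Unit beam direction ``(d_row, d_col)`` for an axial-plane angle.

    Angles are taken mod 180° (a parallel beam at θ equals θ+180°);
    θ=0 travels along the column axis, θ=90 along the row axis.  The
    band-mask construction uses the same convention, so bands align with
    the dose corridors this engine produces.
    """
    t = np.deg2rad(angle_deg % 180.0)
    return (float(np.sin(t)), float(np.cos(t)))


def _rot_coords(shape_yx: Tuple[int, int], angle_deg: float, inverse: bool = False) -> np.ndarray:
    """Sampling coordinates mapping the beam-aligned frame to the image frame.

    In the beam frame of angle θ, rays run along the second (column)
    axis.  ``inverse=True`` gives the coordinates for rotating back.
    """
    ny, nx = shape_yx
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    t = np.deg2rad(angle_deg % 180.0)
    if inverse:
        t = -t
    sin, cos = np.sin(t), np.cos(t)
    yp, xp = np.meshgrid(np.arange(ny) - cy, np.arange(nx) - cx, indexing="ij")
    # point = y' * n + x' * d, with d = (sin, cos), n = (cos, -sin)
    y = yp * cos + xp * sin + cy
    x = -yp * sin + xp * cos + cx
    return np.stack([y, x])


@lru_cache(maxsize=256)
def _coords3d(shape: Tuple[int, int, int], angle: float, inverse: bool) -> np.ndarray:
    nz, ny, nx = shape
    yx = _rot_coords((ny, nx), angle, inverse)
    z = np.broadcast_to(np.arange(nz, dtype=float)[:, None, None], shape)
    y = np.broadcast_to(yx[0][None], shape)
    x = np.broadcast_to(yx[1][None], shape)
    return np.stack([z, y, x])


def _rotate_stack(vol: np.ndarray, angle: float, inverse: bool = False) -> np.ndarray:
    """Rotate every axial slice by the same in-plane angle (trilinear,
    zero fill outside the grid)."""
    coords = _coords3d(tuple(vol.shape), float(angle), bool(inverse))
    return ndimage.map_coordinates(vol.astype(float), coords, order=1, cval=0.0)


def angle_deposits(
    structures: StructureSet,
    angles: Sequence[float],
    attenuation_mu: float,
) -> Dict[float, np.ndarray]:
    """Per-angle unit-fluence deposit volumes in each beam-aligned frame."""
    body = structures["Body"].values.astype(float)
    dx, dy, _ = structures.grid.spacing
    if abs(dx - dy) > 1e-9:
        raise ConfigurationError("forward dose model requires isotropic in-plane spacing")
    deposits = {}
    for ang in angles:
        a = float(ang) % 180.0
        if a == 0.0:
            body_rot = body.copy()
        else:
            body_rot = _rotate_stack(body, a)
        depth = (np.cumsum(body_rot, axis=2) - 0.5 * body_rot) * dx
        deposits[float(ang)] = body_rot * np.exp(-attenuation_mu * depth)
    return deposits


def forward_dose(
    structures: StructureSet,
    beam_weights: Sequence[float],
    angles: Sequence[float],
    attenuation_mu: float = 0.004,
    beamlet_weights: Optional[Sequence[Optional[np.ndarray]]] = None,
    _deposits: Optional[Dict[float, np.ndarray]] = None,
) -> VolumeGrid:
    """Dose from parallel-ray beams: linear in all weights, zero outside Body.

    ``beam_weights`` is one non-negative scalar per angle; optional
    ``beamlet_weights[i]`` of shape ``(nz, ny)`` modulates individual
    rays of angle ``i`` (lateral position indexed in the beam frame).
    """
    angles = [float(a) for a in angles]
    if len(angles) == 0:
        raise ConfigurationError("at least one beam angle is required")
    beam_weights = np.asarray(beam_weights, dtype=float)
    if beam_weights.shape != (len(angles),):
        raise ConfigurationError("one weight per angle is required")
    if np.any(beam_weights < 0):
        raise ConfigurationError("beam weights must be non-negative")
    deposits = _deposits if _deposits is not None else angle_deposits(structures, angles, attenuation_mu)
    body = structures["Body"].as_bool()
    shape = structures.grid.shape
    dose = np.zeros(shape, dtype=float)
    for i, ang in enumerate(angles):
        contrib = deposits[ang]
        if beamlet_weights is not None and beamlet_weights[i] is not None:
            w = np.asarray(beamlet_weights[i], dtype=float)
            if w.shape != (shape[0], shape[1]):
                raise ConfigurationError(
                    f"beamlet weights for angle {ang} must have shape (nz, ny)={shape[:2]}, got {w.shape}"
                )
            if np.any(w < 0):
                raise ConfigurationError("beamlet weights must be non-negative")
            contrib = contrib * w[:, :, None]
        a = ang % 180.0
        if a != 0.0:
            contrib = _rotate_stack(contrib, a, inverse=True)
        dose += beam_weights[i] * contrib
    dose[~body] = 0.0
    np.clip(dose, 0.0, None, out=dose)
    return structures.grid.with_values(dose)


def default_protocol(prescription: float) -> List[dict]:
    """Clinical-style planning goals used for reference-plan generation.

    Dose goals are in Gy at the given prescription; the PTV goals
    dominate so that target coverage is ensured before organ sparing.
    """
    rx = prescription
    return [
        dict(roi="PTV", kind="target_uniformity", metric="Dmean", goal=rx, weight=60.0),
        dict(roi="PTV", kind="target_min_dvh", metric="D98%", goal=0.97 * rx, weight=200.0),
        dict(roi="PTV", kind="oar_max", metric="Dmax", goal=1.06 * rx, weight=60.0),
        dict(roi="Body", kind="oar_max", metric="Dmax", goal=1.08 * rx, weight=20.0),
        dict(roi="Bladder", kind="oar_mean", metric="Dmean", goal=0.67 * rx, weight=2.0),
        dict(roi="Rectum", kind="oar_mean", metric="Dmean", goal=0.63 * rx, weight=2.0),
        dict(roi="SmallIntestine", kind="oar_mean", metric="Dmean", goal=0.45 * rx, weight=2.0),
        dict(roi="SpinalCord", kind="oar_max", metric="Dmax", goal=0.78 * rx, weight=4.0),
        dict(roi="Marrow", kind="oar_mean", metric="Dmean", goal=0.78 * rx, weight=1.0),
        dict(roi="FemoralHeadL", kind="oar_mean", metric="Dmean", goal=0.56 * rx, weight=2.0),
        dict(roi="FemoralHeadR", kind="oar_mean", metric="Dmean", goal=0.56 * rx, weight=2.0),
    ]


def generate_reference_plan(
    ct: VolumeGrid,
    structures: StructureSet,
    config: PhantomConfig,
    *,
    max_iters: int = 80,
) -> Tuple[VolumeGrid, dict]:
    """Optimize a reference dose for a phantom with the surrogate planner.

    Runs the beamlet optimizer against the default clinical-style
    protocol and renormalizes the result so that PTV Dmean equals the
    prescription.  Returns the dose plus an info dict (weights applied,
    normalization scale, convergence flag); non-convergence is flagged,
    never silent.
    """
    from .planner import BeamGeometry, Objective, optimize

    objectives = [Objective(**o) for o in default_protocol(config.prescription)]
    geometry = BeamGeometry(angles=config.beam_angles, attenuation_mu=config.attenuation_mu)
    dose, weights, info = optimize(objectives, structures, geometry, max_iters=max_iters)
    ptv = structures["PTV"].as_bool()
    mean = float(dose.values[ptv].mean())
    if mean <= 0:
        raise RuntimeError("reference plan optimization produced zero PTV dose")
    scale = config.prescription / mean
    dose = dose.with_values(dose.values * scale)
    info = dict(info)
    info.update(normalization_scale=scale, prescription=config.prescription)
    info["beamlet_weights"] = [ (w * scale).tolist() for w in weights]
    info["angles"] = list(config.beam_angles)
    return dose, info


def split_cohort(n: int) -> List[str]:
    """Deterministic train/val/test assignment at an 8:1:1 ratio.

    Validation and test each receive ``max(1, round(n/10))`` cases (the
    last cases in index order), so n=10 gives (8, 1, 1) and n=3 gives
    (1, 1, 1).
    """
    if n < 3:
        raise ConfigurationError("cohort needs n >= 3 for a non-empty 8:1:1 split")
    n_val = max(1, round(n * 0.1))
    n_test = max(1, round(n * 0.1))
    labels = ["train"] * (n - n_val - n_test) + ["val"] * n_val + ["test"] * n_test
    return labels


def generate_cohort(n: int, config: PhantomConfig, out_dir: str | Path) -> Path:
    """Write an n-case synthetic cohort (CT, masks, reference dose, manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = split_cohort(n)
    cases = {}
    for i in range(n):
        case_id = f"case_{i:03d}"
        case_cfg_kwargs = asdict(config)
        case_cfg_kwargs["seed"] = int((config.seed * 1009 + i) % (2**31 - 1))
        case_cfg = PhantomConfig(**case_cfg_kwargs)
        ct, structures = generate_phantom(case_cfg)
        dose, info = generate_reference_plan(ct, structures, case_cfg)
        meta = {
            "seed": case_cfg.seed,
            "prescription": case_cfg.prescription,
            "converged": bool(info["converged"]),
            "normalization_scale": info["normalization_scale"],
            "angles": info["angles"],
        }
        save_case(out_dir / case_id, ct, structures, dose, meta)
        cases[case_id] = {"split": labels[i], "seed": case_cfg.seed}
    manifest = {
        "n": n,
        "seed": config.seed,
        "prescription": config.prescription,
        "shape": list(config.shape),
        "spacing": list(config.spacing),
        "cases": cases,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir


def read_manifest(cohort_dir: str | Path) -> dict:
    return json.loads((Path(cohort_dir) / "manifest.json").read_text())


def cohort_cases(cohort_dir: str | Path, split: Optional[str] = None) -> List[str]:
    manifest = read_manifest(cohort_dir)
    ids = sorted(manifest["cases"])
    if split is not None:
        ids = [c for c in ids if manifest["cases"][c]["split"] == split]
    return ids


def load_cohort_case(cohort_dir: str | Path, case_id: str) -> Dict[str, object]:
    return load_case(Path(cohort_dir) / case_id)
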