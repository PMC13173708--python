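"""DVH-driven iterative inverse planning against the surrogate dose engine.

The auto-planning loop: extract goal DVH endpoints (M0) from a refined
predicted dose, assemble one optimization objective per endpoint, run a
projected-gradient beamlet optimizer on the parallel-ray dose engine,
compare the achieved endpoints (Mc) with M0, nudge every unmet
objective's dose goal by 2% toward compliance, and re-optimize — at
most five iterations, keeping the iteration closest to the goals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dvhtools import endpoint_table, metric_units, _D_PCT, _V_GY, _V_PCT
from .grid import StructureSet, VolumeGrid
from .phantom import ConfigurationError, angle_deposits, forward_dose


class PlannerError(ValueError):
    """Invalid objectives or misaligned endpoint tables."""


OBJECTIVE_KINDS = (
    "target_min_dvh",   # metric >= goal
    "oar_max_dvh",      # DVH-point metric <= goal
    "oar_mean",         # Dmean <= goal
    "oar_max",          # Dmax <= goal
    "target_uniformity",  # Dmean == goal (two-sided)
)

#: objective kinds for which a larger achieved value is better
LOWER_BOUND_KINDS = ("target_min_dvh",)


@dataclass
class Objective:
    roi: str
    kind: str
    metric: str
    goal: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise PlannerError(f"unknown objective kind {self.kind!r}")
        if self.goal <= 0 and self.kind != "oar_max_dvh":
            raise PlannerError(f"dose goal must be > 0 for {self.roi}/{self.metric}")
        if self.goal < 0:
            raise PlannerError(f"goal must be >= 0 for {self.roi}/{self.metric}")
        if self.weight <= 0:
            raise PlannerError(f"objective weight must be > 0 for {self.roi}/{self.metric}")


@dataclass
class BeamGeometry:
    """Parallel-beam arrangement used by the surrogate optimizer."""

    angles: Sequence[float] = tuple(float(i) * 22.5 for i in range(8))
    attenuation_mu: float = 0.004

    def __post_init__(self) -> None:
        if len(self.angles) < 1:
            raise ConfigurationError("beam geometry needs at least one angle")


#: Default (roi, metric) endpoint spec for planning targets M0 — only
#: metrics that translate into one of the five objective kinds.
PLAN_SPEC: Dict[str, Tuple[str, ...]] = {
    "PTV": ("Dmean", "D98%", "D2%", "V95%"),
    "Bladder": ("Dmean", "V40"),
    "Rectum": ("Dmean", "V40"),
    "SmallIntestine": ("Dmean",),
    "SpinalCord": ("Dmax",),
    "Marrow": ("Dmean",),
    "FemoralHeadL": ("Dmean",),
    "FemoralHeadR": ("Dmean",),
}

DEFAULT_WEIGHTS = {"target_uniformity": 60.0, "target_min_dvh": 200.0,
                   "oar_max": 20.0, "oar_mean": 2.0, "oar_max_dvh": 2.0}


def extract_targets(
    refined_dose: VolumeGrid,
    structures: StructureSet,
    endpoint_spec: Mapping[str, Sequence[str]] | str | None = None,
    prescription: float = 45.0,
) -> pd.DataFrame:
    """Goal endpoint table M0, read off the refined predicted dose."""
    spec = PLAN_SPEC if endpoint_spec is None else endpoint_spec
    return endpoint_table(refined_dose, structures, spec, prescription)


def default_kind(roi: str, metric: str) -> str:
    """Map an endpoint to an objective kind: PTV coverage metrics become
    lower bounds, PTV hot-spot metrics and all OAR metrics upper bounds."""
    if roi == "PTV":
        if metric == "Dmean":
            return "target_uniformity"
        if metric in ("Dmax", "D2%", "D1%", "D5%"):
            return "oar_max"
        if _V_PCT.match(metric) or _V_GY.match(metric) or _D_PCT.match(metric):
            return "target_min_dvh"
        raise PlannerError(f"cannot map PTV metric {metric!r} to an objective kind")
    if metric == "Dmean":
        return "oar_mean"
    if metric == "Dmax":
        return "oar_max"
    if _V_PCT.match(metric) or _V_GY.match(metric) or _D_PCT.match(metric):
        return "oar_max_dvh"
    raise PlannerError(f"cannot map {roi} metric {metric!r} to an objective kind")


def assemble_objectives(
    m0: pd.DataFrame,
    protocol_spec: Optional[Mapping[Tuple[str, str], Mapping]] = None,
) -> List[Objective]:
    """One objective per M0 row, goals equal to the M0 values.

    ``protocol_spec`` may override ``kind`` and ``weight`` per
    (roi, metric); defaults come from :func:`default_kind` and
    per-kind default weights.
    """
    protocol_spec = protocol_spec or {}
    objectives = []
    for row in m0.itertuples():
        over = dict(protocol_spec.get((row.roi, row.metric), {}))
        kind = over.get("kind", default_kind(row.roi, row.metric))
        weight = over.get("weight", DEFAULT_WEIGHTS[kind])
        objectives.append(
            Objective(roi=row.roi, kind=kind, metric=row.metric,
                      goal=float(row.value), weight=float(weight))
        )
    return objectives


# -- the surrogate optimizer ----------------------------------------------

def _metric_threshold(metric: str, goal: float, prescription: float) -> Tuple[float, Optional[float]]:
    """Translate a DVH-point objective into (dose threshold Gy, volume goal %).

    D{p}% <= g  <=>  V_g <= p ; V{d} and V{p}% keep their own threshold.
    """
    m = _D_PCT.match(metric)
    if m:
        return goal, float(m.group(1))
    m = _V_PCT.match(metric)
    if m:
        return float(m.group(1)) / 100.0 * prescription, goal
    m = _V_GY.match(metric)
    if m:
        return float(m.group(1)), goal
    raise PlannerError(f"{metric!r} is not a DVH-point metric")


def _penalty_and_grad(
    dose: np.ndarray,
    objectives: Sequence[Objective],
    masks: Mapping[str, np.ndarray],
    prescription: float,
    soft_tau: float = 0.75,
) -> Tuple[float, np.ndarray]:
    """Weighted quadratic one-sided penalties and their dose gradient."""
    rx2 = prescription**2
    total = 0.0
    grad = np.zeros_like(dose)
    for obj in objectives:
        m = masks[obj.roi]
        d = dose[m]
        n = d.size
        w = obj.weight
        if obj.kind == "target_uniformity":
            diff = d - obj.goal
            total += w * float(np.mean(diff**2)) / rx2
            grad[m] += w * 2.0 * diff / (n * rx2)
        elif obj.kind == "target_min_dvh":
            if metric_units(obj.metric) == "Gy":
                t = obj.goal
            else:
                t, _ = _metric_threshold(obj.metric, obj.goal, prescription)
            under = np.maximum(t - d, 0.0)
            total += w * float(np.mean(under**2)) / rx2
            grad[m] += w * (-2.0) * under / (n * rx2)
        elif obj.kind == "oar_max":
            over = np.maximum(d - obj.goal, 0.0)
            total += w * float(np.mean(over**2)) / rx2
            grad[m] += w * 2.0 * over / (n * rx2)
        elif obj.kind == "oar_mean":
            over = max(float(d.mean()) - obj.goal, 0.0)
            total += w * (over / prescription) ** 2
            if over > 0:
                grad[m] += w * 2.0 * over / (n * rx2)
        elif obj.kind == "oar_max_dvh":
            t, vol_goal = _metric_threshold(obj.metric, obj.goal, prescription)
            s = 0.5 * (1.0 + np.tanh(0.5 * (d - t) / soft_tau))
            v_soft = float(s.mean()) * 100.0
            over = max(v_soft - vol_goal, 0.0)
            total += w * (over / 100.0) ** 2
            if over > 0:
                dsig = s * (1.0 - s) / soft_tau
                grad[m] += w * 2.0 * over * dsig / (100.0 * n)
    return total, grad


def optimize(
    objectives: Sequence[Objective],
    structures: StructureSet,
    geometry: BeamGeometry,
    *,
    init_weights: Optional[List[np.ndarray]] = None,
    max_iters: int = 80,
    tol: float = 1e-6,
    prescription: float = 45.0,
    _deposits=None,
) -> Tuple[VolumeGrid, List[np.ndarray], dict]:
    """Projected gradient descent over non-negative per-ray beamlet weights.

    Deterministic: a fixed zero (or given) start, backtracking line
    search on the penalty, and a fixed iteration budget.  Returns the
    optimized dose, the per-angle beamlet weight maps, and an info dict
    with the penalty trace and a convergence flag.
    """
    missing = sorted({o.roi for o in objectives} - set(structures.names()))
    if missing:
        raise PlannerError(f"objective ROIs missing from structures: {missing}")
    angles = [float(a) for a in geometry.angles]
    deposits = _deposits if _deposits is not None else angle_deposits(
        structures, angles, geometry.attenuation_mu
    )
    from .phantom import _rotate_stack  # adjoint pieces of the dose engine

    masks = {o.roi: structures[o.roi].as_bool() for o in objectives}
    nz, ny, _ = structures.grid.shape
    if init_weights is None:
        weights = [np.zeros((nz, ny)) for _ in angles]
    else:
        weights = [np.asarray(w, float).copy() for w in init_weights]

    ones = np.ones(len(angles))

    def dose_of(ws):
        return forward_dose(
            structures, ones, angles, geometry.attenuation_mu,
            beamlet_weights=ws, _deposits=deposits,
        ).values

    def weight_grad(gvol):
        gws = []
        for ang in angles:
            a = ang % 180.0
            g_rot = gvol if a == 0.0 else _rotate_stack(gvol, a)
            gws.append((deposits[ang] * g_rot).sum(axis=2))
        return gws

    dose = dose_of(weights)
    penalty, gvol = _penalty_and_grad(dose, objectives, masks, prescription)
    trace = [penalty]
    lr = 10.0 * prescription
    converged = False
    for _ in range(max_iters):
        if not np.isfinite(penalty):
            raise FloatingPointError(f"optimizer diverged; penalty trace: {trace}")
        gws = weight_grad(gvol)
        accepted = False
        for _bt in range(30):
            cand = [np.maximum(w - lr * g, 0.0) for w, g in zip(weights, gws)]
            cand_dose = dose_of(cand)
            cand_penalty, cand_gvol = _penalty_and_grad(cand_dose, objectives, masks, prescription)
            if cand_penalty <= penalty:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            converged = True
            break
        rel_drop = (penalty - cand_penalty) / max(penalty, 1e-30)
        weights, dose, penalty, gvol = cand, cand_dose, cand_penalty, cand_gvol
        trace.append(penalty)
        lr *= 1.3
        if rel_drop < tol:
            converged = True
            break
    info = {"penalty_trace": trace, "converged": bool(converged or penalty <= tol),
            "final_penalty": penalty, "n_iters": len(trace) - 1}
    return structures.grid.with_values(dose), weights, info


# -- the closed loop -------------------------------------------------------

def _metric_scale(metric: str, prescription: float) -> float:
    u = metric_units(metric)
    return prescription if u == "Gy" else 100.0 if u == "%" else 1.0


def aggregate_violation(
    mc: pd.DataFrame,
    m0: pd.DataFrame,
    *,
    directions: Optional[Mapping[Tuple[str, str], str]] = None,
    prescription: float = 45.0,
) -> float:
    """Sum of normalized positive shortfalls of Mc against M0.

    The shortfall of a lower-bound metric is ``goal - achieved``; of an
    upper-bound metric ``achieved - goal``; each divided by the
    prescription (dose metrics) or 100 points (volume metrics).  Zero
    iff every metric is met.
    """
    key = ["roi", "metric"]
    a = m0.set_index(key)["value"]
    b = mc.set_index(key)["value"]
    if not a.index.equals(b.index):
        raise PlannerError("Mc and M0 tables are not aligned (roi, metric)")
    total = 0.0
    for (roi, metric), goal in a.items():
        achieved = float(b[(roi, metric)])
        if directions is not None and (roi, metric) in directions:
            direction = directions[(roi, metric)]
        else:
            kind = default_kind(roi, metric)
            direction = "lower" if kind in LOWER_BOUND_KINDS else (
                "both" if kind == "target_uniformity" else "upper"
            )
        if direction == "lower":
            short = max(goal - achieved, 0.0)
        elif direction == "upper":
            short = max(achieved - goal, 0.0)
        else:  # two-sided
            short = abs(achieved - goal)
        total += short / _metric_scale(metric, prescription)
    return float(total)


@dataclass
class PlanIteration:
    index: int  # 1-based
    goals: Dict[Tuple[str, str], float]
    mc: pd.DataFrame
    aggregate_violation: float
    met: Dict[Tuple[str, str], bool]
    dose: VolumeGrid
    weights: List[np.ndarray]
    optimizer_info: dict


@dataclass
class PlanResult:
    iterations: List[PlanIteration]
    retained: int  # 1-based index into iterations
    final_dose: VolumeGrid
    m0: pd.DataFrame
    failed: bool = False
    failure: Optional[str] = None

    @property
    def retained_iteration(self) -> PlanIteration:
        return self.iterations[self.retained - 1]


def iterate_plan(
    m0: pd.DataFrame,
    structures: StructureSet,
    geometry: BeamGeometry,
    *,
    max_iter: int = 5,
    step: float = 0.02,
    prescription: float = 45.0,
    protocol_spec: Optional[Mapping[Tuple[str, str], Mapping]] = None,
    met_tol: float = 0.005,
    optimizer_iters: int = 60,
) -> PlanResult:
    """The objective-adjustment loop.

    Each iteration optimizes the current objectives, evaluates Mc, and
    marks a metric met when its normalized shortfall against M0 is at
    most ``met_tol`` (0.005 ≈ 0.23 Gy or 0.5 volume points at 45 Gy).
    Unmet upper-bound goals are multiplied by ``1 - step`` and unmet
    lower-bound goals by ``1 + step``; met objectives are left alone.
    Stops early when everything is met, else after ``max_iter`` rounds,
    and retains the minimum-violation iteration (ties: earliest).
    """
    if max_iter < 1:
        raise PlannerError("max_iter must be >= 1")
    objectives = assemble_objectives(m0, protocol_spec)
    spec: Dict[str, List[str]] = {}
    for row in m0.itertuples():
        spec.setdefault(row.roi, []).append(row.metric)
    m0_vals = {(r.roi, r.metric): float(r.value) for r in m0.itertuples()}

    deposits = angle_deposits(structures, [float(a) for a in geometry.angles],
                              geometry.attenuation_mu)
    iterations: List[PlanIteration] = []
    weights = None
    failure = None
    for it in range(1, max_iter + 1):
        try:
            dose, weights, info = optimize(
                objectives, structures, geometry, init_weights=weights,
                max_iters=optimizer_iters, prescription=prescription,
                _deposits=deposits,
            )
        except FloatingPointError as exc:
            failure = f"optimizer failure at iteration {it}: {exc}"
            break
        mc = endpoint_table(dose, structures, spec, prescription)
        agg = aggregate_violation(mc, m0, prescription=prescription)
        met: Dict[Tuple[str, str], bool] = {}
        mc_vals = {(r.roi, r.metric): float(r.value) for r in mc.itertuples()}
        for obj in objectives:
            key = (obj.roi, obj.metric)
            goal0, achieved = m0_vals[key], mc_vals[key]
            scale = _metric_scale(obj.metric, prescription)
            if obj.kind in LOWER_BOUND_KINDS:
                short = max(goal0 - achieved, 0.0)
            elif obj.kind == "target_uniformity":
                short = abs(achieved - goal0)
            else:
                short = max(achieved - goal0, 0.0)
            met[key] = bool(short / scale <= met_tol)
        iterations.append(
            PlanIteration(index=it, goals={(o.roi, o.metric): o.goal for o in objectives},
                          mc=mc, aggregate_violation=agg, met=met, dose=dose,
                          weights=[w.copy() for w in weights], optimizer_info=info)
        )
        if all(met.values()):
            break
        if it == max_iter:
            break
        # tighten only the unmet objectives by the fixed 2% step
        for obj in objectives:
            key = (obj.roi, obj.metric)
            if met[key]:
                continue
            if obj.kind in LOWER_BOUND_KINDS:
                obj.goal *= 1.0 + step
            elif obj.kind == "target_uniformity":
                achieved = mc_vals[key]
                obj.goal *= (1.0 + step) if achieved < m0_vals[key] else (1.0 - step)
            else:
                obj.goal *= 1.0 - step
    if not iterations:
        raise PlannerError(failure or "planning produced no iterations")
    aggs = [i.aggregate_violation for i in iterations]
    retained = int(np.argmin(aggs)) + 1  # argmin takes the earliest tie
    return PlanResult(
        iterations=iterations, retained=retained,
        final_dose=iterations[retained - 1].dose, m0=m0,
        failed=failure is not None, failure=failure,
    )
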