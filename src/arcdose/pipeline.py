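"""End-to-end workflow and ablation harnesses.

``run_pipeline`` chains the stages — simulate, bands, train (both
stages), predict, plan, score, gamma — with file-level resumability:
a stage re-executes when its outputs are missing or any upstream stage
re-ran, so deleting one intermediate re-runs only the downstream part.
All randomness flows from the single root seed in the config, which is
recorded in every report.

``ablate_bands`` sweeps the number of band directions k over nested
angle subsets (so coverage is monotone by construction); ``ablate_losses``
retrains the refinement stage under the four cumulative loss
configurations — MAE baseline, +band, +gradient, +DVH — with shared
seeds and splits, and summarizes seed-paired scores.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import yaml

from . import dvhtools, nets, planner
from .bandgeom import band_angles, band_dose_coverage, make_band_set
from .grid import save_nifti
from .losses import LossWeights
from .nets import TrainConfig, load_split
from .phantom import PhantomConfig, generate_cohort, read_manifest

log = logging.getLogger("arcdose")


@dataclass
class PipelineConfig:
    out_dir: str = "arcdose_run"
    n_cases: int = 10
    seed: int = 0
    k_bands: int = 4
    gamma_dd: float = 3.0
    gamma_dta: float = 3.0
    endpoint_spec: str = "default"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        # one root seed drives the cohort and both training stages
        self.phantom = dataclasses.replace(self.phantom, seed=self.seed)
        self.train = dataclasses.replace(self.train, seed=self.seed,
                                         prescription=self.phantom.prescription)

    # -- round-trip through YAML ------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["train"]["loss_weights"] = dataclasses.asdict(self.train.loss_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom" in d:
            d["phantom"] = PhantomConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in d["phantom"].items()
            })
        if "train" in d:
            t = dict(d["train"])
            if "loss_weights" in t:
                t["loss_weights"] = LossWeights(**t["loss_weights"])
            d["train"] = TrainConfig(**t)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _jsonl_log(run_dir: Path, stage: str, message: str) -> None:
    log.info("[%s] %s", stage, message)
    with open(run_dir / "run.log.jsonl", "a") as fh:
        fh.write(json.dumps({"t": time.time(), "stage": stage, "msg": message}) + "\n")


def run_pipeline(config: PipelineConfig, *, force: bool = False) -> dict:
    """Execute (or resume) the full workflow; returns the score report."""
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run / "config.yaml")
    cohort = run / "cohort"
    ck1 = run / "checkpoints" / "stage1.npz"
    ck2 = run / "checkpoints" / "stage2.npz"
    pred_dir = run / "predictions"
    plan_dir = run / "plans"
    report_path = run / "report.json"
    rx = config.phantom.prescription

    upstream_ran = force

    def stage(name: str, outputs: Sequence[Path], fn) -> None:
        nonlocal upstream_ran
        missing = [p for p in outputs if not p.exists()]
        if upstream_ran or missing:
            _jsonl_log(run, name, "running")
            try:
                fn()
            except Exception as exc:
                _jsonl_log(run, name, f"FAILED: {exc}")
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            upstream_ran = True
            _jsonl_log(run, name, "done")
        else:
            _jsonl_log(run, name, "up to date, skipped")

    stage("simulate", [cohort / "manifest.json"],
          lambda: generate_cohort(config.n_cases, config.phantom, cohort))

    test_ids = [c for c, v in read_manifest(cohort)["cases"].items() if v["split"] == "test"]

    def do_bands():
        for case in load_split(cohort, "test"):
            bs = make_band_set(case.structures["PTV"], config.k_bands)
            out = run / "bands" / case.case_id
            out.mkdir(parents=True, exist_ok=True)
            for ang, b in zip(bs.angles, bs.bands):
                save_nifti(b, out / f"band_{ang:05.1f}.nii.gz")
            save_nifti(bs.union, out / "union.nii.gz")

    stage("bands", [run / "bands" / t / "union.nii.gz" for t in test_ids], do_bands)
    stage("train1", [ck1], lambda: nets.train_stage1(
        cohort, config.train, ck1, history_path=run / "checkpoints" / "stage1_history.csv"))
    stage("train2", [ck2], lambda: nets.train_stage2(
        cohort, ck1, config.train, ck2,
        history_path=run / "checkpoints" / "stage2_history.csv"))

    def do_predict():
        for case in load_split(cohort, "test"):
            out = nets.predict(case.ct, case.structures, ck1, ck2,
                               prescription=rx, n_bands=config.k_bands)
            d = pred_dir / case.case_id
            save_nifti(out["coarse"], d / "coarse.nii.gz")
            save_nifti(out["refined"], d / "refined.nii.gz")

    stage("predict", [pred_dir / t / "refined.nii.gz" for t in test_ids], do_predict)

    def do_plan():
        geometry = planner.BeamGeometry(angles=config.phantom.beam_angles,
                                        attenuation_mu=config.phantom.attenuation_mu)
        for case in load_split(cohort, "test"):
            from .grid import load_nifti

            refined = load_nifti(pred_dir / case.case_id / "refined.nii.gz")
            m0 = planner.extract_targets(refined, case.structures, prescription=rx)
            result = planner.iterate_plan(m0, case.structures, geometry, prescription=rx)
            d = plan_dir / case.case_id
            d.mkdir(parents=True, exist_ok=True)
            save_nifti(result.final_dose, d / "final_dose.nii.gz")
            dvhtools.save_endpoint_table(m0, d / "m0.csv")
            dvhtools.save_endpoint_table(result.retained_iteration.mc, d / "mc.csv")
            summary = {
                "retained": result.retained,
                "n_iterations": len(result.iterations),
                "failed": result.failed,
                "aggregate_violation": [i.aggregate_violation for i in result.iterations],
                "met": {f"{r}/{m}": bool(v)
                        for (r, m), v in result.retained_iteration.met.items()},
            }
            (d / "plan.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    stage("plan", [plan_dir / t / "plan.json" for t in test_ids], do_plan)

    def do_score():
        from .grid import load_nifti

        per_case = {}
        for case in load_split(cohort, "test"):
            refined = load_nifti(pred_dir / case.case_id / "refined.nii.gz")
            coarse = load_nifti(pred_dir / case.case_id / "coarse.nii.gz")
            plan_dose = load_nifti(plan_dir / case.case_id / "final_dose.nii.gz")
            body = case.structures["Body"]
            spec = config.endpoint_spec
            entry = {
                "dose_score_coarse": dvhtools.dose_score(coarse, case.dose, body),
                "dose_score_refined": dvhtools.dose_score(refined, case.dose, body),
                "dvh_score_refined": dvhtools.dvh_score(refined, case.dose, case.structures, spec, rx),
                "sndvh_score_refined": dvhtools.sn_dvh_score(refined, case.dose, case.structures, spec, prescription=rx),
                "dose_score_plan": dvhtools.dose_score(plan_dose, case.dose, body),
                "gamma_plan_vs_ref": dvhtools.gamma_pass_rate(
                    case.dose, plan_dose, config.gamma_dd, config.gamma_dta),
                "gamma_refined_vs_ref": dvhtools.gamma_pass_rate(
                    case.dose, refined, config.gamma_dd, config.gamma_dta),
                "plan": json.loads((plan_dir / case.case_id / "plan.json").read_text()),
            }
            per_case[case.case_id] = entry
        keys = [k for k in next(iter(per_case.values())) if k != "plan"]
        report = {
            "seed": config.seed,
            "n_cases": config.n_cases,
            "prescription": rx,
            "per_case": per_case,
            "summary": {k: float(np.median([c[k] for c in per_case.values()])) for k in keys},
        }
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))

    stage("score", [report_path], do_score)
    return json.loads(report_path.read_text())


# -- ablations -------------------------------------------------------------

def nested_angle_sets(k_values: Sequence[int]) -> Dict[int, List[float]]:
    """Angle subsets that nest along increasing k (prefixes of a
    bit-reversal ordering of the finest set), so band-union coverage is
    monotone by construction.  For powers of two the subsets coincide
    with the uniform ``i*180/k`` spacing."""
    k_values = sorted(set(int(k) for k in k_values))
    if not k_values or k_values[0] < 1:
        raise ValueError("k_values must be positive")
    k_max = k_values[-1]
    base = band_angles(k_max)
    # stable ordering whose prefixes are maximally spread
    def bitrev_rank(i: int, n: int) -> float:
        r, x = 0.0, 0.5
        while i:
            if i & 1:
                r += x
            i >>= 1
            x /= 2
        return r
    order = sorted(range(k_max), key=lambda i: (bitrev_rank(i, k_max), i))
    ordered = [base[i] for i in order]
    return {k: sorted(ordered[:k]) for k in k_values}


def ablate_bands(
    config: PipelineConfig,
    k_values: Sequence[int] = (1, 2, 4, 8),
    *,
    threshold_fraction: float = 0.5,
) -> dict:
    """Coverage-vs-k curve on the cohort's test cases.

    Uses the reference doses (arc-structured by construction) and
    nested angle subsets; also reports the band-mask storage per k,
    which grows linearly in k.
    """
    cohort = Path(config.out_dir) / "cohort"
    if not (cohort / "manifest.json").exists():
        generate_cohort(config.n_cases, config.phantom, cohort)
    cases = load_split(cohort, "test")
    subsets = nested_angle_sets(k_values)
    arms = {}
    for k, angles in subsets.items():
        covs, nbytes = [], 0
        for case in cases:
            bs = make_band_set(case.structures["PTV"], k, angles=angles)
            covs.append(band_dose_coverage(case.dose, bs, threshold_fraction))
            nbytes = sum(b.values.nbytes for b in bs.bands)
        arms[k] = {
            "angles": angles,
            "coverage_median": float(np.median(covs)),
            "coverage": [float(c) for c in covs],
            "band_storage_bytes": int(nbytes),
        }
    report = {"seed": config.seed, "threshold_fraction": threshold_fraction, "arms": arms}
    out = Path(config.out_dir) / "ablation_bands.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _loss_arms() -> List[tuple]:
    """The four cumulative arms, activating each term at its default weight."""
    w = LossWeights()
    return [
        ("baseline", LossWeights(w.lambda_body, 0, 0, 0)),
        ("+L_band", LossWeights(w.lambda_body, w.lambda_band, 0, 0)),
        ("+L_grad", LossWeights(w.lambda_body, w.lambda_band, w.lambda_grad, 0)),
        ("+L_dvh", LossWeights(w.lambda_body, w.lambda_band, w.lambda_grad, w.lambda_dvh)),
    ]


LOSS_ARMS: List[tuple] = _loss_arms()


def ablate_losses(
    config: PipelineConfig,
    seeds: Sequence[int] = (0, 1, 2),
) -> dict:
    """Retrain the refinement stage under the four cumulative loss arms.

    Every arm shares the cohort, split, and per-seed initialization /
    data order; only the loss weights differ.  Per-arm scores are
    summarized as median and IQR over (seed, test case) pairs, plus
    seed-paired sign counts of each arm against the previous one.
    """
    run = Path(config.out_dir)
    cohort = run / "cohort"
    if not (cohort / "manifest.json").exists():
        generate_cohort(config.n_cases, config.phantom, cohort)
    test = load_split(cohort, "test")
    rx = config.phantom.prescription
    results: Dict[str, Dict[int, dict]] = {name: {} for name, _ in LOSS_ARMS}
    for seed in seeds:
        tcfg = dataclasses.replace(config.train, seed=int(seed))
        ck1 = run / "ablation" / f"seed{seed}" / "stage1.npz"
        if not ck1.exists():
            nets.train_stage1(cohort, tcfg, ck1)
        for name, weights in LOSS_ARMS:
            acfg = dataclasses.replace(tcfg, loss_weights=weights)
            ck2 = run / "ablation" / f"seed{seed}" / f"stage2_{name}.npz"
            if not ck2.exists():
                nets.train_stage2(cohort, ck1, acfg, ck2)
            scores = {"dose_score": [], "dvh_score": [], "sndvh_score": []}
            for case in test:
                out = nets.predict(case.ct, case.structures, ck1, ck2, prescription=rx,
                                   n_bands=config.k_bands)
                pred = out["refined"]
                scores["dose_score"].append(
                    dvhtools.dose_score(pred, case.dose, case.structures["Body"]))
                scores["dvh_score"].append(
                    dvhtools.dvh_score(pred, case.dose, case.structures,
                                       config.endpoint_spec, rx))
                scores["sndvh_score"].append(
                    dvhtools.sn_dvh_score(pred, case.dose, case.structures,
                                          config.endpoint_spec, prescription=rx))
            results[name][int(seed)] = {k: float(np.mean(v)) for k, v in scores.items()}

    def summary(name):
        per_seed = results[name]
        out = {}
        for k in ("dose_score", "dvh_score", "sndvh_score"):
            vals = [per_seed[s][k] for s in per_seed]
            out[k] = {"median": float(np.median(vals)),
                      "iqr": [float(np.percentile(vals, 25)), float(np.percentile(vals, 75))],
                      "per_seed": vals}
        return out

    arms = {name: summary(name) for name, _ in LOSS_ARMS}
    # seed-paired comparison of consecutive arms (small-n sign summary)
    paired = {}
    for (a, _), (b, _) in zip(LOSS_ARMS, LOSS_ARMS[1:]):
        diffs = [results[b][s]["dose_score"] - results[a][s]["dose_score"] for s in results[a]]
        paired[f"{a}->{b}"] = {
            "dose_score_diffs": [float(d) for d in diffs],
            "n_improved": int(sum(d < 0 for d in diffs)),
        }
    report = {"seed_root": config.seed, "seeds": [int(s) for s in seeds],
              "arms": arms, "order": [n for n, _ in LOSS_ARMS], "paired": paired}
    (run / "ablation_losses.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
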