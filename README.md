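# arcdose

Desk-scale, end-to-end VMAT auto-planning in pure scientific Python:
from anatomy to a deliverable-style dose distribution, with every stage
testable on synthetic pelvic phantoms.

Automated treatment planning for arc radiotherapy usually splits into
two problems: *predicting* a clinically plausible 3D dose distribution
from a patient's CT and contours, and *realizing* that prediction as an
optimized plan inside a treatment planning system. `arcdose` implements
both halves of such a workflow for a pelvic (cervical-cancer-like)
setting, at a scale that runs on one CPU:

1. **Beam-band priors** — per-slice corridors between the two lines
   tangent to the PTV and parallel to a beam direction; with k
   directions at `i·180/k` degrees (k = 4 gives 0°/45°/90°/135°) they
   encode where arc dose enters the patient.
2. **Cascaded dose prediction** — a 3D U-Net predicts a coarse dose
   from CT + 9 structure masks (10 channels); a residual 3D U-Net sees
   those plus the coarse dose and the 4 band masks (15 channels) and
   refines it, trained with the composite objective

   `L_total = λ_body·L_body + λ_band·L_band + λ_grad·L_grad + λ_dvh·L_dvh`

   (body MAE, band-union MAE, L1 gradient-vector consistency, and a
   differentiable soft-DVH distance; all on prescription-normalized
   dose, all with analytic, finite-difference-checked gradients —
   the networks and backprop are implemented directly in numpy).
3. **DVH-driven inverse planning** — goal endpoints **M0** are read off
   the refined dose, turned into objectives, and optimized over
   non-negative beamlet weights on a parallel-ray surrogate dose
   engine; achieved endpoints **Mc** are compared with M0 and unmet
   dose goals are nudged by 2 % (×0.98 for upper bounds, ×1.02 for
   lower bounds), for at most five iterations, keeping the iteration
   closest to the goals.
4. **Evaluation** — dose score (body MAE, Gy), DVH score (mean
   |Δendpoint|, Gy), a scale-normalized dimensionless DVH score,
   DVH endpoints (Dmax, Dmean, D{p}%, V{d}, V{p}%, HI, CI), and global
   3 %/3 mm gamma analysis.

A built-in phantom generator produces the inputs — CT-like volumes,
nine structure masks (PTV, bladder, rectum, small intestine, spinal
cord, marrow, femoral heads, body), and arc-structured reference doses
optimized by the package's own planner at a 45 Gy prescription — so the
whole pipeline is reproducible without clinical data. See
`docs/methods.md` for the models, defaults, and limitations.

## Worked example

```python
from arcdose import PhantomConfig, generate_phantom, generate_reference_plan
from arcdose.planner import extract_targets, iterate_plan, BeamGeometry
from arcdose.dvhtools import endpoint

cfg = PhantomConfig(shape=(16, 32, 32), seed=3)
ct, structures = generate_phantom(cfg)
reference, info = generate_reference_plan(ct, structures, cfg)

m0 = extract_targets(reference, structures)          # goal endpoints
result = iterate_plan(m0, structures, BeamGeometry())
it = result.retained_iteration
print(f"iterations: {len(result.iterations)}, retained: {result.retained}, "
      f"aggregate violation: {it.aggregate_violation:.4f}")
for roi, metric in [("PTV", "Dmean"), ("PTV", "V95%"),
                    ("Bladder", "Dmean"), ("SpinalCord", "Dmax")]:
    goal = float(m0[(m0.roi == roi) & (m0.metric == metric)].value.iloc[0])
    achieved = endpoint(result.final_dose, structures[roi], metric)
    print(f"{roi:11s} {metric:5s}  goal {goal:7.2f}   achieved {achieved:7.2f}")
```

prints

```
iterations: 1, retained: 1, aggregate violation: 0.0047
PTV         Dmean  goal   45.00   achieved   44.98
PTV         V95%   goal  100.00   achieved  100.00
Bladder     Dmean  goal   20.64   achieved   19.62
SpinalCord  Dmax   goal   18.12   achieved   16.27
```

i.e. the planning loop met every goal on the first optimization (early
stop), reproducing the target coverage (PTV mean within 0.02 Gy of the
45 Gy goal, V95% = 100 %) while staying below the organ-at-risk goals.

The same workflow is available from the shell:

```bash
arcdose simulate --n 10 --seed 0 --out cohort/
arcdose train --stage 1 --cohort cohort/ --out ck/stage1.npz
arcdose train --stage 2 --cohort cohort/ --stage1-checkpoint ck/stage1.npz --out ck/stage2.npz
arcdose pipeline --out run/ --n 10 --seed 0     # or everything at once
arcdose gamma --ref run/cohort/case_009/dose.nii.gz \
              --eval run/plans/case_009/final_dose.nii.gz --dd 3 --dta 3
```

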