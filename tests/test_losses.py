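import numpy as np
import pytest

from arcdose.losses import (
    LossError,
    LossWeights,
    loss_band,
    loss_band_grad,
    loss_body,
    loss_body_grad,
    loss_dvh,
    loss_dvh_grad,
    loss_grad,
    loss_grad_grad,
    total_loss,
)

SHAPE = (8, 8, 8)
SPACING = (5.0, 2.5, 2.5)


@pytest.fixture()
def toy(rng):
    return dict(
        pred=rng.uniform(0, 1, SHAPE),
        ref=rng.uniform(0, 1, SHAPE),
        body=np.ones(SHAPE, bool),
        union=rng.uniform(size=SHAPE) > 0.4,
        rois={"A": rng.uniform(size=SHAPE) > 0.5, "B": rng.uniform(size=SHAPE) > 0.6},
    )


def finite_diff_max_err(fn, pred, indices, eps=1e-6):
    v, g = fn(pred)
    errs = []
    for i in indices:
        p2 = pred.copy()
        p2[i] += eps
        v2, _ = fn(p2)
        num = (v2 - v) / eps
        errs.append(abs(num - g[i]) / max(abs(num), abs(g[i]), 1e-12))
    return max(errs)


def test_losses_zero_on_identical(toy):
    p = toy["ref"]
    assert loss_body(p, p, toy["body"]) == 0.0
    assert loss_band(p, p, toy["union"]) == 0.0
    assert loss_grad(p, p, toy["union"], SPACING) == 0.0
    assert loss_dvh(p, p, toy["rois"]) == pytest.approx(0.0, abs=1e-15)


def test_constant_offset_closed_forms(toy):
    p = toy["ref"] + 0.07
    assert loss_body(p, toy["ref"], toy["body"]) == pytest.approx(0.07, rel=1e-12)
    assert loss_band(p, toy["ref"], toy["union"]) == pytest.approx(0.07, rel=1e-12)
    # gradients kill constants
    assert loss_grad(p, toy["ref"], toy["union"], SPACING) == pytest.approx(0.0, abs=1e-12)


def test_band_restriction(toy):
    """Error placed entirely outside the band union is invisible to it."""
    p = toy["ref"].copy()
    p[~toy["union"]] += 0.5
    assert loss_band(p, toy["ref"], toy["union"]) == 0.0
    assert loss_band(p, toy["ref"], np.ones(SHAPE, bool)) == pytest.approx(
        loss_body(p, toy["ref"], np.ones(SHAPE, bool))
    )


def test_ramp_gradient_closed_form():
    """Linear ramp vs flat: the loss equals the ramp slope."""
    slope = 0.01  # per mm along the column axis
    xx = np.arange(SHAPE[2]) * SPACING[2]
    ramp = np.broadcast_to(slope * xx, SHAPE).copy()
    v = loss_grad(ramp, np.zeros(SHAPE), np.ones(SHAPE, bool), SPACING)
    assert v == pytest.approx(slope, rel=1e-12)


def test_gradient_checks_all_terms(toy):
    """Analytic vs finite-difference gradients, 1e-4 relative, 8^3 inputs."""
    idx = [(2, 3, 4), (0, 0, 0), (7, 6, 5), (4, 4, 4), (1, 7, 2)]
    assert finite_diff_max_err(
        lambda p: loss_body_grad(p, toy["ref"], toy["body"]), toy["pred"], idx) < 1e-4
    assert finite_diff_max_err(
        lambda p: loss_band_grad(p, toy["ref"], toy["union"]), toy["pred"], idx) < 1e-4
    assert finite_diff_max_err(
        lambda p: loss_grad_grad(p, toy["ref"], toy["union"], SPACING), toy["pred"], idx) < 1e-4
    assert finite_diff_max_err(
        lambda p: loss_dvh_grad(p, toy["ref"], toy["rois"], 0.05), toy["pred"], idx) < 1e-4


def test_total_loss_gradient_check(toy):
    idx = [(2, 3, 4), (5, 1, 6), (4, 4, 4)]

    def fn(p):
        br, g = total_loss(p, toy["ref"], toy["body"], toy["union"], toy["rois"],
                           LossWeights(1, 0.5, 0.3, 0.2), spacing=SPACING, return_grad=True)
        return br.l_total, g

    assert finite_diff_max_err(fn, toy["pred"], idx) < 1e-4


def test_dvh_loss_temperature_limit():
    """As T -> 0 the soft curve recovers the hard DVH on a 2-voxel toy."""
    pred = np.array([[[0.40, 0.50]]])
    ref = np.array([[[0.45, 0.55]]])
    rois = {"R": np.ones_like(pred, bool)}
    bins = np.linspace(0.0, 1.0, 21)  # bin centers avoid the voxel values
    bins += 0.012
    soft = loss_dvh(pred, ref, rois, temperature=1e-3, bin_grid=bins)
    hard_p = (pred.ravel()[None, :] > bins[:, None]).mean(axis=1)
    hard_r = (ref.ravel()[None, :] > bins[:, None]).mean(axis=1)
    hard = np.abs(hard_p - hard_r).mean()
    assert soft == pytest.approx(hard, abs=1e-6)


def test_weights_validation():
    with pytest.raises(LossError):
        LossWeights(-1, 0, 0, 0)
    with pytest.raises(LossError):
        LossWeights(0, 0, 0, 0)


def test_total_loss_linearity_in_lambdas(toy):
    """The composite is a weighted sum: linear in each lambda."""
    args = (toy["pred"], toy["ref"], toy["body"], toy["union"], toy["rois"])
    base = total_loss(*args, LossWeights(1, 1, 1, 1), spacing=SPACING)
    comps = np.array([base.l_body, base.l_band, base.l_grad, base.l_dvh])
    for lams in [(1, 0, 0, 0), (2, 0.5, 0, 3), (0.1, 0.2, 0.3, 0.4)]:
        br = total_loss(*args, LossWeights(*lams), spacing=SPACING)
        assert br.l_total == pytest.approx(float(np.dot(lams, comps)), rel=1e-9)
    only_body = total_loss(*args, LossWeights(1, 0, 0, 0), spacing=SPACING)
    assert only_body.l_total == only_body.l_body
    ident = total_loss(toy["ref"], toy["ref"], toy["body"], toy["union"], toy["rois"],
                       LossWeights(3, 2, 1, 5), spacing=SPACING)
    assert ident.l_total == pytest.approx(0.0, abs=1e-12)


def test_empty_mask_errors(toy):
    with pytest.raises(LossError):
        loss_body(toy["pred"], toy["ref"], np.zeros(SHAPE, bool))
    with pytest.raises(LossError):
        loss_band(toy["pred"], toy["ref"], np.zeros(SHAPE, bool))
    with pytest.raises(LossError):
        loss_dvh(toy["pred"], toy["ref"], {"A": np.zeros(SHAPE, bool)})
    with pytest.warns(UserWarning, match="empty ROI"):
        loss_dvh(toy["pred"], toy["ref"],
                 {"A": np.zeros(SHAPE, bool), "B": np.ones(SHAPE, bool)})
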