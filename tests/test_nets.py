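import numpy as np
import pytest

from arcdose.nets import (
    STAGE1_CHANNELS,
    STAGE2_CHANNELS,
    TrainConfig,
    build_stage1,
    build_stage2,
    load_split,
    predict,
    stage1_input,
    stage2_input,
)
from arcdose.nn import Adam, Conv3d, ShapeError, UNet3D, load_checkpoint, save_checkpoint


def test_conv_backward_matches_finite_differences(rng):
    conv = Conv3d(2, 3, 3, np.random.default_rng(0), dtype=np.float64)
    x = rng.uniform(-1, 1, (2, 5, 5, 5))
    y = conv.forward(x)
    dy = rng.normal(size=y.shape)
    dx = conv.backward(dy)
    eps = 1e-6
    for i in [(0, 1, 2, 3), (1, 4, 4, 4)]:
        x2 = x.copy()
        x2[i] += eps
        num = ((conv.forward(x2) - y) * dy).sum() / eps
        assert num == pytest.approx(dx[i], rel=1e-5)
    w = conv.params["W"]
    gw = conv.grads["W"]
    conv.forward(x)
    conv.backward(dy)  # grads accumulate; compare against doubled value
    i = (2, 1, 0, 1, 2)
    w[i] += eps
    num = ((conv.forward(x) - y) * dy).sum() / eps
    assert num == pytest.approx(gw[i] / 2.0, rel=1e-4)


def test_stage1_shape_and_nonnegativity(rng):
    cfg = TrainConfig(width=4, depth=2)
    net = build_stage1(cfg)
    x = rng.uniform(0, 1, (STAGE1_CHANNELS, 8, 16, 16)).astype(np.float32)
    y = net.forward(x)
    assert y.shape == (1, 8, 16, 16)
    assert (y >= 0).all()


def test_build_determinism():
    cfg = TrainConfig(width=4, depth=2, seed=3)
    p1 = build_stage1(cfg).parameters()
    p2 = build_stage1(cfg).parameters()
    assert all(np.array_equal(p1[k], p2[k]) for k in p1)
    n1 = build_stage2(cfg).n_parameters()
    n2 = build_stage2(cfg).n_parameters()
    assert n1 == n2 > 0


def test_grid_not_divisible_raises():
    net = UNet3D(cin=2, width=4, depth=3)
    with pytest.raises(ShapeError, match="divisible"):
        net.forward(np.zeros((2, 12, 12, 12), np.float32))


def test_stage2_identity_at_init(rng):
    """Zero-initialized output layer: refined == coarse at initialization."""
    cfg = TrainConfig(width=4, depth=2)
    net = build_stage2(cfg)
    x = rng.uniform(0, 1, (STAGE2_CHANNELS, 8, 16, 16)).astype(np.float32)
    delta = net.forward(x)
    assert np.abs(delta).max() == 0.0


def test_stage2_channel_count_enforced(rng):
    cfg = TrainConfig(width=4, depth=2)
    net = build_stage2(cfg)
    with pytest.raises(ShapeError, match=r"expected input of shape \(15"):
        net.forward(np.zeros((STAGE2_CHANNELS - 1, 8, 16, 16), np.float32))


def test_input_assembly(phantom_case):
    ct, st_ = phantom_case
    x1 = stage1_input(ct, st_)
    assert x1.shape[0] == STAGE1_CHANNELS == 10
    assert 0.0 <= x1[0].min() and x1[0].max() <= 1.0  # CT normalized
    assert set(np.unique(x1[1:])) <= {0.0, 1.0}
    from arcdose.bandgeom import make_band_set

    bands = make_band_set(st_["PTV"], 4).stacked()
    x2 = stage2_input(ct, st_, np.zeros(ct.shape, np.float32), bands)
    assert x2.shape[0] == STAGE2_CHANNELS == 15


def test_checkpoint_round_trip(tmp_path, rng):
    net = UNet3D(cin=3, width=4, depth=1, residual=True, final_activation="none", seed=9)
    x = rng.uniform(size=(3, 4, 4, 4)).astype(np.float32)
    y = net.forward(x)
    path = tmp_path / "ck.npz"
    save_checkpoint(path, net, extra={"stage": 2})
    net2, extra = load_checkpoint(path)
    assert extra["stage"] == 2
    assert np.array_equal(net2.forward(x), y)


def test_training_learns_and_is_deterministic(cohort_dir, stage1_ckpt, train_config):
    """Stage-1 validation MAE drops well below both the untrained network
    and the zero-dose predictor; retraining with the same seed is identical."""
    _, extra = load_checkpoint(stage1_ckpt)
    hist = extra["history"]
    assert len(hist) == train_config.epochs
    first, best = hist[0]["val_mae"], extra["best_val_mae"]
    assert best <= 0.7 * first  # >= 30% reduction vs epoch 1
    val = load_split(cohort_dir, "val")
    zero = float(np.mean([
        np.abs(c.dose.values[c.structures["Body"].as_bool()] / 45.0).mean() for c in val
    ]))
    assert best <= 0.7 * zero  # >= 30% better than predicting zero dose
    from arcdose.nets import train_stage1

    again = stage1_ckpt.parent / "stage1_again.npz"
    train_stage1(cohort_dir, train_config, again)
    _, extra2 = load_checkpoint(again)
    assert [h["val_mae"] for h in extra2["history"]] == [h["val_mae"] for h in hist]


def test_predict_contract(cohort_dir, stage1_ckpt, stage2_ckpt):
    case = load_split(cohort_dir, "test")[0]
    out = predict(case.ct, case.structures, stage1_ckpt, stage2_ckpt)
    body = case.structures["Body"].as_bool()
    for name in ("coarse", "refined"):
        vol = out[name]
        assert vol.shape == case.ct.shape
        assert not vol.values[~body].any()
        assert (vol.values >= 0).all()
    out2 = predict(case.ct, case.structures, stage1_ckpt, stage2_ckpt)
    assert np.array_equal(out["refined"].values, out2["refined"].values)


def test_stage2_refinement_not_harmful(cohort_dir, stage1_ckpt, stage2_ckpt):
    """The cascade must not degrade the test dose score by more than 5%."""
    from arcdose.dvhtools import dose_score

    cases = load_split(cohort_dir, "test")
    coarse, refined = [], []
    for c in cases:
        out = predict(c.ct, c.structures, stage1_ckpt, stage2_ckpt)
        coarse.append(dose_score(out["coarse"], c.dose, c.structures["Body"]))
        refined.append(dose_score(out["refined"], c.dose, c.structures["Body"]))
    assert np.median(refined) <= 1.05 * np.median(coarse)


def test_adam_moves_toward_minimum():
    p = {"x": np.array([5.0])}
    opt = Adam(p, lr=0.1)
    for _ in range(200):
        opt.step({"x": 2 * p["x"]})  # d/dx x^2
    assert abs(p["x"][0]) < 0.1
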