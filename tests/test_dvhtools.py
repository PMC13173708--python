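import numpy as np
import pytest

from arcdose.dvhtools import (
    MetricError,
    compute_dvh,
    dose_score,
    dvh_score,
    endpoint,
    endpoint_table,
    gamma_pass_rate,
    metric_units,
    sn_dvh_score,
)
from arcdose.grid import VolumeGrid

SP = (2.5, 2.5, 5.0)


def vol(arr):
    return VolumeGrid(np.asarray(arr, float), SP)


def two_voxel_roi():
    d = np.zeros((1, 1, 4))
    d[0, 0, 0], d[0, 0, 1] = 40.0, 50.0
    m = np.zeros((1, 1, 4))
    m[0, 0, :2] = 1
    return vol(d), vol(m)


# -- oracle: sort-based endpoint computation ------------------------------

def oracle_d_pct(doses, p):
    """Dose to the hottest p%: linear interpolation of the sorted sample."""
    s = np.sort(doses)
    q = 1.0 - p / 100.0
    pos = q * (len(s) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


def oracle_v(doses, thr):
    return float((doses >= thr).sum()) / len(doses) * 100.0


def test_dvh_step_curve_uniform_dose():
    d = vol(np.full((2, 3, 4), 20.0))
    m = vol(np.ones((2, 3, 4)))
    curve = compute_dvh(d, m, bin_width=1.0)
    assert curve.cum_volume[0] == 1.0
    assert np.all(np.diff(curve.cum_volume) <= 0)
    assert curve.volume_at(20.0) == 1.0
    assert curve.volume_at(20.6) == pytest.approx(0.4)  # interpolated step


def test_two_voxel_v45_and_d50():
    d, m = two_voxel_roi()
    assert endpoint(d, m, "V45") == pytest.approx(50.0)
    # linear interpolation between the two sorted voxel doses
    assert endpoint(d, m, "D50%") == pytest.approx(45.0)


def test_empty_roi_raises():
    d, _ = two_voxel_roi()
    with pytest.raises(MetricError, match="empty"):
        endpoint(d, vol(np.zeros((1, 1, 4))), "Dmean")
    with pytest.raises(MetricError):
        endpoint(d, vol(np.ones((1, 1, 4))), "Dwhatever")


def test_uniform_dose_hi_zero_ci_one():
    shape = (4, 8, 8)
    ptv = np.zeros(shape)
    ptv[1:3, 2:6, 2:6] = 1
    d = vol(45.0 * ptv)
    assert endpoint(d, vol(ptv), "HI") == pytest.approx(0.0)
    assert endpoint(d, vol(ptv), "CI", prescription=45.0) == pytest.approx(1.0)
    assert endpoint(d, vol(ptv), "CI", prescription=45.0, ci_variant="rtog") == pytest.approx(1.0)


def test_endpoints_match_sort_oracle(rng):
    """Every endpoint family vs an independent sort/count oracle."""
    for _ in range(20):
        shape = (4, 6, 6)
        d = rng.uniform(0, 60, shape)
        m = rng.uniform(size=shape) > 0.4
        if not m.any():
            continue
        dv, mv = vol(d), vol(m.astype(float))
        doses = d[m]
        assert endpoint(dv, mv, "Dmax") == pytest.approx(doses.max(), rel=1e-12)
        assert endpoint(dv, mv, "Dmean") == pytest.approx(doses.mean(), rel=1e-12)
        for p in (2, 50, 98):
            assert endpoint(dv, mv, f"D{p}%") == pytest.approx(oracle_d_pct(doses, p), rel=1e-9)
        for t in (10, 30, 45):
            assert endpoint(dv, mv, f"V{t}") == pytest.approx(oracle_v(doses, t), rel=1e-12)
        assert endpoint(dv, mv, "V95%") == pytest.approx(oracle_v(doses, 0.95 * 45), rel=1e-12)
        hi = (oracle_d_pct(doses, 2) - oracle_d_pct(doses, 98)) / oracle_d_pct(doses, 50)
        assert endpoint(dv, mv, "HI") == pytest.approx(hi, rel=1e-9)


def test_endpoint_monotonicity(rng):
    d = rng.uniform(0, 60, (4, 6, 6))
    m = np.ones_like(d)
    dv, mv = vol(d), vol(m)
    vs = [endpoint(dv, mv, f"V{t}") for t in (5, 15, 25, 35, 45)]
    assert all(a >= b for a, b in zip(vs, vs[1:]))
    ds = [endpoint(dv, mv, f"D{p}%") for p in (2, 25, 50, 75, 98)]
    assert all(a >= b - 1e-12 for a, b in zip(ds, ds[1:]))


def test_dose_score_matches_loop_oracle(rng):
    shape = (3, 4, 5)
    a, b = rng.uniform(0, 50, shape), rng.uniform(0, 50, shape)
    body = rng.uniform(size=shape) > 0.3
    expected, n = 0.0, 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if body[i, j, k]:
                    expected += abs(a[i, j, k] - b[i, j, k])
                    n += 1
    expected /= n
    assert dose_score(vol(a), vol(b), vol(body.astype(float))) == pytest.approx(expected, abs=1e-12)
    assert dose_score(vol(a), vol(a), vol(body.astype(float))) == 0.0


def test_dvh_score_translation_equivariance(phantom_case, rng):
    _, st_ = phantom_case
    shape = st_.grid.shape
    ref = VolumeGrid(rng.uniform(0, 50, shape), st_.grid.spacing)
    pred = ref.with_values(ref.values + 2.0)
    # pure D-metric spec: every quantile shifts by exactly the offset
    spec = {roi: ("Dmean", "Dmax", "D2%", "D98%") for roi in ("PTV", "Bladder", "Rectum")}
    assert dvh_score(pred, ref, st_, spec) == pytest.approx(2.0, rel=1e-9)
    assert dvh_score(ref, ref, st_, spec) == 0.0


def test_dvh_score_matches_endpoint_oracle(phantom_case, rng):
    _, st_ = phantom_case
    shape = st_.grid.shape
    ref = VolumeGrid(rng.uniform(0, 50, shape), st_.grid.spacing)
    pred = VolumeGrid(rng.uniform(0, 50, shape), st_.grid.spacing)
    spec = {"PTV": ("D2%", "Dmean"), "Bladder": ("Dmax",)}
    expected = np.mean([
        abs(endpoint(pred, st_["PTV"], "D2%") - endpoint(ref, st_["PTV"], "D2%")),
        abs(endpoint(pred, st_["PTV"], "Dmean") - endpoint(ref, st_["PTV"], "Dmean")),
        abs(endpoint(pred, st_["Bladder"], "Dmax") - endpoint(ref, st_["Bladder"], "Dmax")),
    ])
    assert dvh_score(pred, ref, st_, spec) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(MetricError, match="Missing|missing"):
        dvh_score(pred, ref, st_, {"NotAnOrgan": ("Dmean",)})


def test_sn_dvh_score_hand_computed(phantom_case):
    _, st_ = phantom_case
    ref = st_.grid.with_values(np.full(st_.grid.shape, 10.0))
    pred = ref.with_values(ref.values + 4.5)
    # single D metric off by 4.5 Gy, scale 45 -> 0.1
    assert sn_dvh_score(pred, ref, st_, {"PTV": ("Dmean",)}) == pytest.approx(0.1, rel=1e-12)
    # 3-endpoint toy, hand-computed weighted sum:
    # D off by 4.5 (scale 45 -> 0.1), V45 differs by 100 points (scale 100 -> 1.0)
    spec = {"PTV": ("Dmean", "Dmax", "V45")}
    v_ref = endpoint(ref, st_["PTV"], "V45")    # 0 %
    v_pred = endpoint(pred, st_["PTV"], "V45")  # 0 % (14.5 Gy < 45)
    expected = np.mean([0.1, 0.1, abs(v_pred - v_ref) / 100.0])
    assert sn_dvh_score(pred, ref, st_, spec) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(MetricError):
        sn_dvh_score(pred, ref, st_, {"PTV": ("Dmean",)}, scales={("PTV", "Dmean"): 0.0})


def test_metric_units():
    assert metric_units("Dmean") == "Gy" and metric_units("D2%") == "Gy"
    assert metric_units("V30") == "%" and metric_units("V95%") == "%"
    assert metric_units("HI") == "" and metric_units("CI") == ""


def test_endpoint_table_layout(phantom_case):
    _, st_ = phantom_case
    dose = st_.grid.with_values(np.full(st_.grid.shape, 30.0))
    table = endpoint_table(dose, st_, "default")
    assert list(table.columns) == ["roi", "metric", "value", "units"]
    assert len(table) == 3 + 7 * 2  # PTV three metrics, seven OARs two each


# -- gamma -----------------------------------------------------------------

def test_gamma_identity_is_100(rng):
    from scipy.ndimage import gaussian_filter

    d = gaussian_filter(rng.uniform(0, 60, (8, 12, 12)), 1.5)
    v = vol(d)
    assert gamma_pass_rate(v, v) == 100.0


def test_gamma_uniform_offset_fails_everywhere():
    """A flat 4%-of-max offset cannot be rescued by distance: gamma = 4/3."""
    ref = vol(np.full((8, 10, 10), 50.0))
    ev = vol(np.full((8, 10, 10), 52.0))
    rate, gmap = gamma_pass_rate(ref, ev, 3.0, 3.0, return_gamma=True)
    assert rate == 0.0
    assert np.nanmin(gmap) == pytest.approx(4.0 / 3.0, rel=1e-6)


def test_gamma_errors():
    ref = vol(np.zeros((4, 4, 4)))
    with pytest.raises(MetricError):
        gamma_pass_rate(ref, ref)
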