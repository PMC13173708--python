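import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arcdose.bandgeom import (
    BandError,
    band_angles,
    band_dose_coverage,
    band_mask_slice,
    make_band_set,
)
from arcdose.grid import VolumeGrid


def brute_force_band(ptv, angle, spacing):
    """Independent slab construction: project every pixel center onto the
    band normal and compare with the PTV projection extremes."""
    dy, dx = spacing
    t = np.deg2rad(angle % 180.0)
    d = np.array([np.sin(t), np.cos(t)])
    n = np.array([d[1], -d[0]])
    ny, nx = ptv.shape
    pts = np.stack(np.meshgrid(np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"), -1)
    proj = pts @ n
    sel = proj[ptv]
    return (proj >= sel.min() - 1e-9) & (proj <= sel.max() + 1e-9)


def test_rectangle_angle0_full_rows():
    m = np.zeros((24, 30), bool)
    m[6:11, 12:20] = True
    band = band_mask_slice(m, 0.0, (1.0, 1.0))
    expected = np.zeros_like(m)
    expected[6:11, :] = True
    assert np.array_equal(band, expected)
    assert np.array_equal(band, brute_force_band(m, 0.0, (1.0, 1.0)))


def test_single_pixel_line():
    m = np.zeros((15, 15), bool)
    m[7, 7] = True
    for ang in (0.0, 90.0):
        band = band_mask_slice(m, ang, (1.0, 1.0))
        assert band.sum() == 15
        assert band[7, 7]


def test_disk_band_width_angle_invariant():
    yy, xx = np.mgrid[0:41, 0:41]
    disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
    # the slab interval is the projection extent, so its width is the
    # normal extent of the disk: 2r for every angle up to discretization
    widths = [brute_force_width(disk, ang) for ang in (0, 30, 45, 60, 90, 120, 135, 150)]
    assert max(widths) - min(widths) <= 2.0
    assert all(abs(w - 20.0) <= 1.0 for w in widths)


def brute_force_width(ptv, angle):
    t = np.deg2rad(angle % 180.0)
    n = np.array([np.cos(t), -np.sin(t)])
    pts = np.argwhere(ptv).astype(float)
    proj = pts @ n
    return proj.max() - proj.min()


def test_empty_ptv_empty_band():
    assert not band_mask_slice(np.zeros((10, 10), bool), 45.0).any()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    r0=st.integers(2, 10), c0=st.integers(2, 10),
    h=st.integers(1, 8), w=st.integers(1, 8),
    angle=st.floats(0, 179.9),
)
def test_band_matches_brute_force_projection(r0, c0, h, w, angle):
    m = np.zeros((22, 22), bool)
    m[r0:r0 + h, c0:c0 + w] = True
    band = band_mask_slice(m, angle, (2.0, 2.0))
    assert np.array_equal(band, brute_force_band(m, angle, (2.0, 2.0)))
    assert band[m].all()  # tangency interval always covers the PTV


def test_make_band_set_angles_and_union(phantom_case):
    _, structures = phantom_case
    ptv = structures["PTV"]
    bs = make_band_set(ptv, 4)
    assert bs.angles == [0.0, 45.0, 90.0, 135.0]
    assert band_angles(1) == [0.0]
    union = np.logical_or.reduce([b.as_bool() for b in bs.bands])
    assert np.array_equal(bs.union.as_bool(), union)
    p = ptv.as_bool()
    for b in bs.bands:
        assert b.as_bool()[p].all()
    # slices without PTV have empty bands
    empty_slices = ~p.any(axis=(1, 2))
    assert not bs.union.as_bool()[empty_slices].any()
    with pytest.raises(BandError):
        make_band_set(ptv, 0)


def test_tangency_shrinking_excludes_ptv(phantom_case):
    """Shrinking the slab by one pixel on either side drops >=1 PTV pixel."""
    _, structures = phantom_case
    p3d = structures["PTV"].as_bool()
    z = int(np.argwhere(p3d.any(axis=(1, 2)))[0, 0])
    ptv = p3d[z]
    for ang in (0.0, 45.0, 90.0, 137.5):
        t = np.deg2rad(ang)
        n = np.array([np.cos(t), -np.sin(t)])
        pts = np.stack(np.meshgrid(np.arange(ptv.shape[0]), np.arange(ptv.shape[1]),
                                   indexing="ij"), -1).astype(float)
        proj = pts @ n
        sel = proj[ptv]
        lo, hi = sel.min(), sel.max()
        for shrunk in [(lo + 1.0, hi), (lo, hi - 1.0)]:
            inside = (sel >= shrunk[0] - 1e-9) & (sel <= shrunk[1] + 1e-9)
            assert (~inside).sum() >= 1


def test_coverage_definition_and_bounds(phantom_case, cohort_dir):
    from arcdose.phantom import cohort_cases, load_cohort_case

    cid = cohort_cases(cohort_dir, "test")[0]
    data = load_cohort_case(cohort_dir, cid)
    dose, st_ = data["dose"], data["structures"]
    bs1 = make_band_set(st_["PTV"], 1)
    bs4 = make_band_set(st_["PTV"], 4)
    c1 = band_dose_coverage(dose, bs1)
    c4 = band_dose_coverage(dose, bs4)
    assert 0.0 <= c1 <= 1.0 and 0.0 <= c4 <= 1.0
    # dose fully inside the union -> coverage 1
    inside = dose.with_values(dose.values * bs1.union.values)
    assert band_dose_coverage(inside, bs1) == pytest.approx(1.0)
    with pytest.raises(BandError):
        band_dose_coverage(dose, bs1, threshold_fraction=1.5)


def test_coverage_monotone_on_nested_subsets(cohort_dir):
    from arcdose.phantom import cohort_cases, load_cohort_case
    from arcdose.pipeline import nested_angle_sets

    cid = cohort_cases(cohort_dir, "test")[0]
    data = load_cohort_case(cohort_dir, cid)
    dose, st_ = data["dose"], data["structures"]
    subsets = nested_angle_sets([1, 2, 4, 8])
    # the subsets nest and match the uniform spacing at powers of two
    assert subsets[4] == [0.0, 45.0, 90.0, 135.0]
    assert set(subsets[1]) <= set(subsets[2]) <= set(subsets[4]) <= set(subsets[8])
    covs = [
        band_dose_coverage(dose, make_band_set(st_["PTV"], k, angles=subsets[k]))
        for k in (1, 2, 4, 8)
    ]
    assert all(a <= b + 1e-12 for a, b in zip(covs, covs[1:]))
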