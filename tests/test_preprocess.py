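import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal

from ifcpipe import (
    Grid,
    MotionTrace,
    VolumeSeries,
    bandpass,
    compute_tsnr,
    discard_initial,
    extract_roi_timecourse,
    qc_motion,
    regress_nuisance,
)
from ifcpipe.preprocess import bandpass_sos
from ifcpipe.rois import RoiMask, RoiSpec


def make_series(data, tr=2.0):
    data = np.atleast_2d(np.asarray(data, float))
    grid = Grid.from_spacing((data.shape[0], 1, 1), 1.0, (0, 0, 0))
    return VolumeSeries(data=data, grid=grid, tr_seconds=tr)


def make_mask(indices, n_vox):
    grid = Grid.from_spacing((n_vox, 1, 1), 1.0, (0, 0, 0))
    spec = RoiSpec("roi", "mtl", "L", (0, 0, 0), radius_mm=1.0)
    return RoiMask(spec=spec, indices=np.asarray(indices), grid=grid)


# -- volume discard ---------------------------------------------------------

def test_discard_three_of_three_hundred():
    s = make_series(np.random.default_rng(0).normal(size=(4, 300)))
    assert discard_initial(s, 3).n_volumes == 297


def test_discard_zero_is_identity():
    s = make_series(np.arange(12.0).reshape(3, 4))
    out = discard_initial(s, 0)
    assert np.array_equal(out.data, s.data)


def test_discard_all_raises():
    s = make_series(np.ones((2, 5)))
    with pytest.raises(ValueError):
        discard_initial(s, 5)


# -- motion QC --------------------------------------------------------------

def test_zero_trace_all_metrics_zero():
    tr = MotionTrace(np.zeros((3, 50)), np.zeros((3, 50)))
    rep = qc_motion(tr)
    assert rep.cumulative_translation_mm == 0
    assert rep.mean_p2p_translation_mm == 0
    assert rep.mean_p2p_rotation_deg == 0
    assert rep.rms_translation_mm == 0
    assert not rep.excluded


def test_alternating_translation_trips_p2p_threshold():
    x = np.zeros((3, 40))
    x[0, 1::2] = 0.2  # p2p steps of 0.2 mm every volume
    rep = qc_motion(MotionTrace(x, np.zeros_like(x)))
    assert rep.mean_p2p_translation_mm == pytest.approx(0.2, rel=1e-3)
    assert rep.excluded
    assert any("point-to-point translation" in r for r in rep.reasons)


def test_monotone_drift_trips_cumulative_threshold():
    x = np.zeros((3, 100))
    x[0] = np.linspace(0, 3.5, 100)  # slow drift: small p2p, large excursion
    rep = qc_motion(MotionTrace(x, np.zeros_like(x)))
    assert rep.cumulative_translation_mm == pytest.approx(3.5)
    assert rep.excluded
    assert any("cumulative" in r for r in rep.reasons)


def test_rotation_threshold_in_degrees():
    r = np.zeros((3, 40))
    r[2, 1::2] = 0.12  # degrees
    rep = qc_motion(MotionTrace(np.zeros_like(r), r))
    assert rep.mean_p2p_rotation_deg > 0.1
    assert rep.excluded


@given(offset=st.floats(-5, 5, allow_nan=False))
def test_metrics_invariant_to_constant_offset(offset):
    rng = np.random.default_rng(7)
    t = rng.normal(0, 0.02, size=(3, 60)).cumsum(axis=1)
    r = rng.normal(0, 0.01, size=(3, 60)).cumsum(axis=1)
    base = qc_motion(MotionTrace(t, r))
    shifted = qc_motion(MotionTrace(t + offset, r))
    assert shifted.cumulative_translation_mm == pytest.approx(
        base.cumulative_translation_mm
    )
    assert shifted.mean_p2p_translation_mm == pytest.approx(
        base.mean_p2p_translation_mm
    )
    assert shifted.mean_p2p_rotation_deg == pytest.approx(base.mean_p2p_rotation_deg)


def test_length_mismatch_raises():
    tr = MotionTrace(np.zeros((3, 10)), np.zeros((3, 10)))
    s = make_series(np.ones((2, 12)) + np.arange(12))
    with pytest.raises(ValueError):
        qc_motion(tr, s)


def test_spm_file_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    tr = MotionTrace(rng.normal(size=(3, 20)), rng.normal(size=(3, 20)))
    path = tmp_path / "rp_sub.txt"
    np.savetxt(path, tr.to_spm_array(), fmt="%.10e")
    back = MotionTrace.from_spm_file(path)
    np.testing.assert_allclose(back.translations_mm, tr.translations_mm, rtol=1e-8)
    np.testing.assert_allclose(back.rotations_deg, tr.rotations_deg, rtol=1e-8)


# -- tSNR -------------------------------------------------------------------

def test_tsnr_constant_ratio():
    rng = np.random.default_rng(0)
    data = 100 + 10 * rng.standard_normal((50, 2000))
    # rescale each voxel to exactly mean 100, sd 10
    data = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
    data = 100 + 10 * data
    res = compute_tsnr(make_series(data))
    assert res.tsnr == pytest.approx(10.0)
    assert res.n_constant_voxels == 0


def test_constant_voxel_excluded_and_counted():
    rng = np.random.default_rng(1)
    data = 50 + rng.standard_normal((5, 100))
    data[2] = 7.0
    res = compute_tsnr(make_series(data))
    assert res.n_constant_voxels == 1
    assert np.isfinite(res.tsnr)


def test_all_constant_raises():
    with pytest.raises(ValueError):
        compute_tsnr(make_series(np.full((3, 10), 5.0)))


def test_tsnr_monte_carlo_matches_mu_over_sigma():
    mu, sigma = 80.0, 4.0
    rng = np.random.default_rng(42)
    data = mu + sigma * rng.standard_normal((20, 10_000))
    res = compute_tsnr(make_series(data))
    assert res.tsnr == pytest.approx(mu / sigma, rel=0.02)


# -- band-pass --------------------------------------------------------------

def analytic_gain(f_hz, tr=2.0, order=4, low=0.009, high=0.08):
    """Squared magnitude of the single-pass filter = zero-phase filter gain."""
    sos = bandpass_sos(low, high, tr, order)
    _, h = signal.sosfreqz(sos, worN=[f_hz], fs=1.0 / tr)
    return float(np.abs(h[0]) ** 2)


@pytest.mark.parametrize(
    "f_hz,bound,kind",
    [(0.04, 0.9, "ge"), (0.2, 0.1, "le")],
)
def test_sinusoid_gain_against_analytic_oracle(f_hz, bound, kind):
    tr = 2.0
    t = np.arange(4096) * tr
    x = np.sin(2 * np.pi * f_hz * t)
    y = bandpass(x, tr_seconds=tr)
    # steady-state amplitude away from the edges
    mid = slice(1024, 3072)
    amp = np.abs(y[mid]).max()
    gain = analytic_gain(f_hz, tr)
    assert amp == pytest.approx(gain, abs=0.02)
    if kind == "ge":
        assert amp >= bound
    else:
        assert amp <= bound


def test_constant_series_suppressed():
    x = np.full(600, 37.5)
    y = bandpass(x, tr_seconds=2.0)
    assert np.max(np.abs(y)) < 1e-8 * 37.5


def test_band_outside_nyquist_raises():
    with pytest.raises(ValueError):
        bandpass(np.ones(100), low_hz=0.01, high_hz=0.3, tr_seconds=2.0)
    with pytest.raises(ValueError):
        bandpass(np.ones(100), low_hz=0.0, high_hz=0.1, tr_seconds=2.0)


def test_filter_and_regression_are_linear(rng):
    x = rng.standard_normal(400)
    y = rng.standard_normal(400)
    a, b = 2.3, -0.7
    lhs = bandpass(a * x + b * y, tr_seconds=2.0)
    rhs = a * bandpass(x, tr_seconds=2.0) + b * bandpass(y, tr_seconds=2.0)
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)
    R = rng.standard_normal((400, 4))
    lhs = regress_nuisance(a * x + b * y, R)
    rhs = a * regress_nuisance(x, R) + b * regress_nuisance(y, R)
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)


# -- nuisance regression ----------------------------------------------------

def test_regressing_out_self_gives_zero(rng):
    r = rng.standard_normal(200)
    resid = regress_nuisance(3.0 * r + 1.0, r[:, None])
    np.testing.assert_allclose(resid, 0, atol=1e-10)


def test_orthogonal_tc_unchanged(rng):
    R = rng.standard_normal((300, 3))
    tc = rng.standard_normal(300)
    # project tc away from [1 | R] exactly, then it must be a fixed point
    X = np.column_stack([np.ones(300), R])
    tc = tc - X @ np.linalg.lstsq(X, tc, rcond=None)[0]
    resid = regress_nuisance(tc, R)
    np.testing.assert_allclose(resid, tc, atol=1e-10)


def test_matches_pseudoinverse_oracle(rng):
    tc = rng.standard_normal(250)
    R = rng.standard_normal((250, 9))
    X = np.column_stack([np.ones(250), R])
    oracle = tc - X @ (np.linalg.pinv(X) @ tc)
    resid = regress_nuisance(tc, R)
    np.testing.assert_allclose(resid, oracle, atol=1e-10)
    assert np.max(np.abs(resid @ R)) / len(tc) < 1e-8


def test_collinear_regressors_named(rng):
    r = rng.standard_normal(100)
    R = np.column_stack([r, 2 * r])
    with pytest.raises(ValueError, match="collinear"):
        regress_nuisance(rng.standard_normal(100), R)


# -- SVD seed reduction -----------------------------------------------------

def test_identical_voxels_recover_shared_course(rng):
    s = rng.standard_normal(150)
    data = np.tile(s, (12, 1))
    series = make_series(data)
    tc = extract_roi_timecourse(series, make_mask(np.arange(12), 12))
    z = (s - s.mean()) / s.std()
    np.testing.assert_allclose(tc.values, z, atol=1e-8)


def test_rank_one_block_recovers_v(rng):
    a = rng.random(20) + 0.5  # positive loadings so the mean keeps the sign
    v = rng.standard_normal(90)
    series = make_series(np.outer(a, v))
    tc = extract_roi_timecourse(series, make_mask(np.arange(20), 20))
    vz = (v - v.mean()) / v.std()
    np.testing.assert_allclose(tc.values, vz, atol=1e-8)


def test_matches_eigendecomposition_oracle(rng):
    data = rng.standard_normal((30, 120))
    series = make_series(data)
    tc = extract_roi_timecourse(series, make_mask(np.arange(30), 30))
    # oracle: first PC score from the time x time covariance eigenproblem
    Xc = data - data.mean(axis=1, keepdims=True)
    evals, evecs = np.linalg.eigh(Xc.T @ Xc)
    pc = evecs[:, np.argmax(evals)]
    r = abs(np.corrcoef(tc.values, pc)[0, 1])
    assert r > 1 - 1e-10
    assert tc.values.mean() == pytest.approx(0, abs=1e-12)
    assert tc.values.std() == pytest.approx(1)


def test_voxel_order_invariance(rng):
    data = rng.standard_normal((25, 80))
    series = make_series(data)
    perm = rng.permutation(25)
    t1 = extract_roi_timecourse(series, make_mask(np.arange(25), 25))
    t2 = extract_roi_timecourse(series, make_mask(perm, 25))
    np.testing.assert_allclose(t1.values, t2.values, atol=1e-8)


def test_all_zero_block_raises():
    series = make_series(np.zeros((4, 50)) + 3.0)  # constant rows, zero after centring
    with pytest.raises(ValueError, match="roi"):
        extract_roi_timecourse(series, make_mask(np.arange(4), 4))
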