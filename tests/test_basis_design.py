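"""Basis sets, HRF convolution, design assembly, temporal preprocessing."""

import numpy as np
import pytest

import probcode as pc
from probcode.design import (dct_drift_basis, n_scans_for,
                             posterior_expectation_modulators,
                             session_design_raw)
from probcode.errors import ConfigurationError
from probcode.hrf import HrfSpec


def test_center_spacing_rule():
    b = pc.make_basis("gaussian", 10, (0.0, 1.0), 0.04)
    assert b.centers[0] == pytest.approx(1.0 / 11.0)
    np.testing.assert_allclose(np.diff(b.centers), 1.0 / 11.0)
    bc = pc.EncodingSpec.default("versatile", "confidence").basis
    np.testing.assert_allclose(np.diff(bc.centers), 1.5 / 11.0)
    assert bc.centers[0] == pytest.approx(1.1 + 1.5 / 11.0)


def test_basis_sum_ripple_matches_fine_grid_oracle():
    """Sum of the K = 10 sigma = 0.04 Gaussians is nearly flat between the
    outer centers; ripple checked against an independent evaluation."""
    b = pc.make_basis("gaussian", 10, (0.0, 1.0), 0.04)
    x = np.linspace(b.centers[0], b.centers[-1], 10001)
    total = b(x).sum(axis=1)
    # independent oracle: direct formula, no BasisSet machinery
    mu = np.array([(i + 1) / 11 for i in range(10)])
    oracle = np.exp(-(x[:, None] - mu) ** 2 / (2 * 0.04 ** 2)).sum(axis=1)
    np.testing.assert_allclose(total, oracle, rtol=1e-12)
    ripple = total.max() / total.min()
    assert ripple == pytest.approx(oracle.max() / oracle.min(), rel=1e-12)


def test_sigmoid_basis_shape():
    b = pc.make_basis("sigmoid", 3, (0.0, 1.0), 0.05)
    v = b(np.array([0.0, 0.5, 1.0]))
    assert v.shape == (3, 3)
    assert np.all(np.diff(b(np.linspace(0, 1, 50)), axis=0) > 0)
    assert b(np.array([b.centers[1]]))[0, 1] == pytest.approx(0.5)


@pytest.mark.parametrize("kwargs", [
    {"kind": "spline", "K": 3, "domain": (0, 1), "width": 0.1},
    {"kind": "gaussian", "K": 0, "domain": (0, 1), "width": 0.1},
    {"kind": "gaussian", "K": 3, "domain": (1, 0), "width": 0.1},
    {"kind": "gaussian", "K": 3, "domain": (0, 1), "width": 0.0},
])
def test_make_basis_errors(kwargs):
    with pytest.raises(ConfigurationError):
        pc.make_basis(**kwargs)


def test_hrf_matches_nilearn_canonical():
    """Our double-gamma agrees with nilearn's SPM HRF up to scale."""
    from nilearn.glm.first_level import hemodynamic_models as hm
    ours = HrfSpec(dt=0.1).kernel()
    ref = hm.spm_hrf(1.0, oversampling=10, time_length=32.0)
    n = min(ours.size, ref.size)
    c = np.corrcoef(ours[:n], ref[:n])[0, 1]
    assert c > 0.999


def test_unit_impulse_column_is_sampled_hrf(short_task_config, obs_config):
    """One stimulus with modulator 1: raw column equals the HRF at TR grid."""
    cfg = short_task_config
    seq = pc.generate_sequence(cfg, seed=0)
    # single stimulus at t=0, others far: easier to build a 1-trial session
    seq.values = seq.values[:1]
    seq.hidden_p = seq.hidden_p[:1]
    seq.onsets = np.array([0.0])
    seq.report_trials = np.array([], dtype=int)
    seq.report_onsets = np.array([])
    seq.duration = 40.0
    trace, est = pc.run_ideal_observer(seq, obs_config)
    from probcode.design import SessionData
    sess = SessionData(seq=seq, trace=trace, est=est)
    spec = pc.EncodingSpec("linear", "probability", None)
    hrf = HrfSpec()
    X, labels, mask = session_design_raw(sess, spec, hrf, tr=2.0)
    kernel = hrf.kernel()
    scan_idx = np.round(np.arange(n_scans_for(seq, 2.0)) * 2.0 / hrf.dt).astype(int)
    expected = np.zeros(scan_idx.size)
    within = scan_idx < kernel.size
    expected[within] = kernel[scan_idx[within]] * est.p_hat[0]
    np.testing.assert_allclose(X[:, 0], expected, atol=1e-12)


def test_interest_columns_match_direct_summation(obs_config):
    """3-stimulus toy: each basis column equals the explicit sum of shifted,
    scaled HRF copies."""
    from probcode.design import SessionData
    cfg = pc.TaskConfig(n_stimuli_per_session=3)
    seq = pc.generate_sequence(cfg, seed=1)
    seq.onsets = np.array([0.0, 3.0, 7.1])
    seq.report_trials = np.array([], dtype=int)
    seq.report_onsets = np.array([])
    seq.duration = 60.0
    trace, est = pc.run_ideal_observer(seq, obs_config)
    sess = SessionData(seq=seq, trace=trace, est=est)
    spec = pc.EncodingSpec.default("versatile", "probability", K=4)
    hrf = HrfSpec()
    X, _, mask = session_design_raw(sess, spec, hrf, tr=2.0)
    kernel = hrf.kernel()
    F = spec.basis(est.p_hat)                       # (3, 4)
    n_fine = int(np.ceil(seq.duration / hrf.dt)) + 1
    scan_idx = np.round(np.arange(n_scans_for(seq, 2.0)) * 2.0 / hrf.dt).astype(int)
    for i in range(4):
        fine = np.zeros(n_fine + kernel.size)
        for t in range(3):
            start = int(round(seq.onsets[t] / hrf.dt))
            fine[start:start + kernel.size] += F[t, i] * kernel
        np.testing.assert_allclose(X[:, i], fine[:n_fine][scan_idx], atol=1e-10)


def test_zero_modulator_gives_zero_column(sessions_with_data):
    sess = sessions_with_data[0]
    est = sess.est
    zero_est = pc.NormativeEstimates(p_hat=np.zeros_like(est.p_hat),
                                     confidence=est.confidence,
                                     surprise=est.surprise, entropy=est.entropy)
    from probcode.design import SessionData
    s2 = SessionData(seq=sess.seq, trace=sess.trace, est=zero_est,
                     reports=sess.reports)
    X, _, mask = session_design_raw(s2, pc.EncodingSpec("linear", "probability", None),
                                    HrfSpec(), tr=2.0)
    assert np.allclose(X[:, 0], 0.0)


def test_posterior_expectation_modulators_quadrature(obs_config):
    basis = pc.EncodingSpec.default("versatile", "probability").basis
    grid = obs_config.grid
    G = grid.size
    # delta posterior at one grid point
    delta = np.zeros((1, G))
    delta[0, 37] = 1.0
    trace = pc.PosteriorTrace(grid=grid, posterior=delta, predictive=delta)
    mods = posterior_expectation_modulators(trace, basis)
    np.testing.assert_allclose(mods[0], basis(grid[37]), atol=1e-14)
    # uniform posterior -> grid mean of each basis function
    uni = np.full((1, G), 1.0 / G)
    trace = pc.PosteriorTrace(grid=grid, posterior=uni, predictive=uni)
    np.testing.assert_allclose(posterior_expectation_modulators(trace, basis)[0],
                               basis(grid).mean(axis=0), atol=1e-14)
    # bell-shaped posterior vs independent quadrature
    bell = np.exp(-(grid - 0.4) ** 2 / (2 * 0.05 ** 2))
    bell /= bell.sum()
    trace = pc.PosteriorTrace(grid=grid, posterior=bell[None], predictive=bell[None])
    expected = np.array([float(np.sum(bell * basis(grid)[:, i])) for i in range(10)])
    np.testing.assert_allclose(posterior_expectation_modulators(trace, basis)[0],
                               expected, atol=1e-10)


def test_preprocess_constant_series_to_zeros():
    sessions = [np.full((50, 2), 3.7), np.full((40, 2), -1.2)]
    out, sd = pc.preprocess_timeseries(sessions, tr=2.0)
    for y in out:
        np.testing.assert_allclose(y, 0.0, atol=1e-12)


def test_preprocess_removes_linear_trend():
    t = np.arange(100, dtype=float)
    out, _ = pc.preprocess_timeseries([2.0 + 0.3 * t], tr=2.0)
    assert np.max(np.abs(out[0])) < 1e-8


def test_preprocess_single_scan_session_errors():
    with pytest.raises(ConfigurationError):
        pc.preprocess_timeseries([np.ones((1, 2))], tr=2.0)


def test_highpass_attenuation_matches_projection_oracle():
    """A 1/256 Hz sinusoid is attenuated exactly as predicted by direct
    least-squares projection onto the detrend + drift basis."""
    from scipy.signal import detrend
    n, tr = 300, 2.0
    t = np.arange(n) * tr
    sig = np.sin(2 * np.pi * t / 256.0)
    # our filter: detrend followed by DCT drift-basis projection
    y = detrend(sig, type="linear")
    B = dct_drift_basis(n, tr)
    ours = y - B @ (B.T @ y)
    # independent oracle: sequential lstsq projections (line, then drift)
    k_max = int(np.floor(2 * n * tr / 128.0))
    drift = np.column_stack([np.cos(np.pi * k * (np.arange(n) + 0.5) / n)
                             for k in range(1, k_max + 1)])
    line = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(line, sig, rcond=None)
    resid = sig - line @ beta
    gamma, *_ = np.linalg.lstsq(drift, resid, rcond=None)
    resid = resid - drift @ gamma
    np.testing.assert_allclose(ours, resid, atol=1e-8)
    attenuation = np.linalg.norm(resid) / np.linalg.norm(sig - sig.mean())
    assert attenuation < 0.5   # 1/256 Hz lies below the 1/128 Hz cutoff


def test_design_columns_session_demeaned(sessions_with_data):
    spec = pc.EncodingSpec.default("versatile", "probability")
    d = pc.build_design_matrix(sessions_with_data, spec)
    for i in range(d.n_sessions):
        block = d.X[d.session_rows(i)]
        np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-10)
    assert int(d.interest_mask.sum()) == 10
    assert d.X.shape[1] == len(d.labels)


def test_design_session_permutation_equivariance(sessions_with_data):
    spec = pc.EncodingSpec.default("versatile", "probability")
    d = pc.build_design_matrix(sessions_with_data, spec)
    perm = [2, 0, 3, 1]
    d2 = pc.build_design_matrix([sessions_with_data[i] for i in perm], spec)
    blocks = [d.X[d.session_rows(i)] for i in range(4)]
    blocks2 = [d2.X[d2.session_rows(i)] for i in range(4)]
    for j, i in enumerate(perm):
        np.testing.assert_allclose(blocks2[j], blocks[i], atol=1e-10)


def test_confidence_values_clamped_with_warning(sessions_with_data):
    spec = pc.EncodingSpec.default("versatile", "confidence",)
    narrow = pc.EncodingSpec(spec.model_class, spec.estimate,
                             pc.make_basis("gaussian", 10, (1.5, 2.0), 0.02))
    with pytest.warns(UserWarning, match="clamped"):
        pc.build_design_matrix(sessions_with_data, narrow)
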