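"""Correlation-distance decoding and RDM geometry."""

import numpy as np
import pytest

import probcode as pc
from probcode.decoding import (average_rdm, bin_validity, compute_rdm,
                               decode_bins, regress_rdm)
from probcode.decoding import BinPatterns, Rdm
from probcode.errors import ConfigurationError


def patterns(test, train, fold=0):
    return BinPatterns(train=np.asarray(train, float),
                       test=np.asarray(test, float),
                       selected_units=np.arange(len(test)), fold_id=fold)


def test_rdm_hand_example_three_units():
    test = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 0.5]])
    train = np.array([[1.0, 3.0], [2.0, 1.0], [3.0, 2.0]])
    rdm = compute_rdm(patterns(test, train))
    for j in range(2):
        for k in range(2):
            r = np.corrcoef(test[:, j], train[:, k])[0, 1]
            assert rdm.D[j, k] == pytest.approx(1 - r, abs=1e-12)


def test_rdm_identity_and_anticorrelation_limits():
    v = np.array([1.0, 2.0, 4.0])
    rdm = compute_rdm(patterns(np.column_stack([v, -v]), np.column_stack([v, -v])))
    assert rdm.D[0, 0] == pytest.approx(0.0, abs=1e-12)
    assert rdm.D[0, 1] == pytest.approx(2.0, abs=1e-12)
    assert np.all((rdm.D >= -1e-12) & (rdm.D <= 2 + 1e-12))


def test_rdm_affine_invariance_per_unit():
    rng = np.random.default_rng(0)
    test = rng.normal(size=(8, 3))
    train = rng.normal(size=(8, 3))
    base = compute_rdm(patterns(test, train)).D
    scaled = compute_rdm(patterns(test * 2.0 + 1.0, train)).D
    # correlation distance over units is invariant to common affine maps of
    # the bin axis applied per pattern column-wise: scaling all units of a
    # pattern together leaves correlations unchanged
    np.testing.assert_allclose(scaled, base, atol=1e-12)


def test_rdm_needs_two_units_and_flags_constant_patterns():
    with pytest.raises(ConfigurationError):
        compute_rdm(patterns(np.ones((1, 2)), np.ones((1, 2))))
    with pytest.warns(UserWarning, match="zero-variance"):
        rdm = compute_rdm(patterns(np.ones((4, 2)), np.random.default_rng(0).normal(size=(4, 2))))
    assert np.isnan(rdm.D).all()


def test_decode_diagonal_minimum_gives_accuracy_one():
    D = np.ones((5, 5)) - 0.5 * np.eye(5)
    acc, _, assign = decode_bins([Rdm(D=D, valid_rows=np.ones(5, bool), fold_id=0)])
    assert acc == 1.0
    np.testing.assert_array_equal(assign[0], np.arange(5))


def test_decode_tie_breaks_to_lowest_bin():
    D = np.ones((3, 3))
    _, _, assign = decode_bins([Rdm(D=D, valid_rows=np.ones(3, bool), fold_id=0)])
    np.testing.assert_array_equal(assign[0], np.zeros(3))


def test_invalid_rows_excluded_from_accuracy():
    D = np.ones((4, 4)) - 0.5 * np.eye(4)
    D[0] = [0.1, 0.0, 0.9, 0.9]           # would decode wrongly
    valid = np.array([False, True, True, True])
    acc, _, assign = decode_bins([Rdm(D=D, valid_rows=valid, fold_id=0)])
    assert acc == 1.0
    assert assign[0][0] == -1


def test_fold_without_valid_bins_omitted():
    good = Rdm(D=np.ones((3, 3)) - np.eye(3), valid_rows=np.ones(3, bool), fold_id=0)
    bad = Rdm(D=np.ones((3, 3)), valid_rows=np.zeros(3, bool), fold_id=1)
    with pytest.warns(UserWarning, match="omitted"):
        acc, fold_acc, _ = decode_bins([good, bad])
    assert acc == 1.0 and len(fold_acc) == 1
    with pytest.raises(ConfigurationError):
        decode_bins([bad])


def test_bin_validity_activation_rule():
    basis = pc.EncodingSpec.default("versatile", "probability", K=5).basis
    x = np.full(100, basis.centers[2])     # all stimuli at the middle bin
    valid = bin_validity(x, basis)
    assert valid[2]
    assert not valid[0] and not valid[4]


def test_average_rdm_ignores_invalid_rows():
    D1 = np.zeros((3, 3))
    D2 = np.ones((3, 3))
    r1 = Rdm(D=D1, valid_rows=np.array([True, True, False]), fold_id=0)
    r2 = Rdm(D=D2, valid_rows=np.array([True, False, False]), fold_id=1)
    mean, valid = average_rdm([r1, r2])
    assert mean[0, 0] == pytest.approx(0.5)
    assert mean[1, 0] == pytest.approx(0.0)
    np.testing.assert_array_equal(valid, [True, True, False])


def test_rdm_regression_exact_recovery():
    """Constructed RDM 0.7 z(graded) + 0.3 z(identity) + 1 recovers its
    coefficients exactly."""
    n = 5
    J, K = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ident = (J != K).astype(float)
    grad = np.abs(J - K).astype(float)
    z = lambda v: (v - v.mean()) / v.std()
    D = 0.7 * z(grad) + 0.3 * z(ident) + 1.0
    reg = regress_rdm(D, np.ones(n, bool))
    assert reg.coef_graded == pytest.approx(0.7, abs=1e-10)
    assert reg.coef_identity == pytest.approx(0.3, abs=1e-10)
    assert reg.intercept == pytest.approx(1.0, abs=1e-10)
    assert reg.winner == "graded"


def test_rdm_regression_winner_constructions():
    n = 5
    J, K = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    reg_i = regress_rdm(2.0 + (J != K).astype(float), np.ones(n, bool))
    assert reg_i.winner == "identity"
    assert reg_i.coef_graded == pytest.approx(0.0, abs=1e-10)
    reg_g = regress_rdm(np.abs(J - K).astype(float), np.ones(n, bool))
    assert reg_g.winner == "graded"


def test_rdm_regression_requires_rows():
    with pytest.raises(ConfigurationError):
        regress_rdm(np.ones((4, 4)), np.array([True, False, False, False]))


def test_n_top_clamps_with_warning(sessions_with_data, task_config, obs_config):
    rng = np.random.default_rng(0)
    spec5 = pc.EncodingSpec.default("versatile", "probability", K=5)
    d = pc.build_design_matrix(sessions_with_data, spec5)
    for i, s in enumerate(sessions_with_data):
        a, b = d.session_bounds[i]
        s.y = rng.normal(size=(b - a, 6))
    with pytest.warns(UserWarning, match="using all units"):
        pats, _ = pc.estimate_bin_patterns(sessions_with_data, "probability",
                                           task_config=task_config,
                                           observer_config=obs_config,
                                           n_top=100, rng=rng)
    assert all(p.selected_units.size == 6 for p in pats)
    assert pats[0].train.shape == (6, 5)


def test_selection_uses_training_sessions_only(sessions_with_data, task_config,
                                               obs_config):
    """Replacing test-session data must not change the selected units."""
    rng = np.random.default_rng(1)
    spec5 = pc.EncodingSpec.default("versatile", "probability", K=5)
    d = pc.build_design_matrix(sessions_with_data, spec5)
    X_int = d.X[:, d.interest_mask]
    W = np.column_stack([pc.draw_bump_weights(5, rng) for _ in range(8)])
    sig = X_int @ W
    Y = sig + rng.normal(size=sig.shape) * np.sqrt(3 * sig.var(0))
    for i, s in enumerate(sessions_with_data):
        s.y = Y[d.session_rows(i)].copy()
    kwargs = dict(task_config=task_config, observer_config=obs_config,
                  n_top=4, n_null=25)
    pats_a, _ = pc.estimate_bin_patterns(sessions_with_data, "probability",
                                         rng=np.random.default_rng(7), **kwargs)
    sessions_with_data[0].y = np.random.default_rng(99).normal(
        size=sessions_with_data[0].y.shape)
    pats_b, _ = pc.estimate_bin_patterns(sessions_with_data, "probability",
                                         rng=np.random.default_rng(7), **kwargs)
    np.testing.assert_array_equal(pats_a[0].selected_units,
                                  pats_b[0].selected_units)


def test_noiseless_bump_code_decodes_perfectly(sessions_with_data, task_config,
                                               obs_config):
    rng = np.random.default_rng(2)
    spec5 = pc.EncodingSpec.default("versatile", "probability", K=5)
    d = pc.build_design_matrix(sessions_with_data, spec5)
    W = np.column_stack([pc.draw_bump_weights(5, rng) for _ in range(15)])
    Y = d.X[:, d.interest_mask] @ W
    for i, s in enumerate(sessions_with_data):
        s.y = Y[d.session_rows(i)]
    res = pc.decode_participant(sessions_with_data, "probability",
                                task_config=task_config,
                                observer_config=obs_config, rng=rng)
    assert res.accuracy == 1.0
    assert res.regression.winner == "identity"
    # per-bin train/test pattern correlation near 1
    for pat in res.patterns:
        for j in range(5):
            r = np.corrcoef(pat.train[:, j], pat.test[:, j])[0, 1]
            assert r > 0.99


def test_group_decoding_stats_chance_and_errors():
    # all accuracies exactly at chance: t = 0 per region
    out0 = pc.group_decoding_stats(np.full((4, 3), 0.2))
    assert all(t.t == 0.0 for t in out0["region_tests"])
    # off-chance with zero variance is undefined
    with pytest.raises(ConfigurationError):
        pc.group_decoding_stats(np.full((4, 3), 0.4))
    rng = np.random.default_rng(0)
    acc = 0.2 + rng.normal(0, 0.01, (4, 3))
    wins = rng.random((4, 3)) > 0.5
    out = pc.group_decoding_stats(acc, graded_wins=wins)
    assert out["p_fdr"].shape == (3,)
    np.testing.assert_allclose(out["graded_fraction"], wins.mean(axis=1))
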