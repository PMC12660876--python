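"""Ridge fitting and cross-validated z-R2 evaluation of encoding models.

Models are fitted by closed-form ridge regression (no intercept; data and
regressors are demeaned by preprocessing) with one penalty shared across
units. Evaluation is leave-one-session-out: the model is fitted on the
other sessions, and predictions on the held-out session use only the
regressors of interest. The resulting sums-of-squares R2 is standardized
against a null distribution obtained by rebuilding the interest regressors
from replacement sequences drawn from the same task process, keeping the
fitted weights:  z-R2 = (R2 - mu0) / sigma0, averaged over folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .basis import EncodingSpec
from .design import (DesignMatrix, SessionData, build_design_matrix,
                     null_interest_columns, preprocess_timeseries)
from .errors import ConfigurationError
from .hrf import HrfSpec
from .observer import ObserverConfig, batch_observer_estimates
from .task import TaskConfig, generate_value_matrix

__all__ = ["EncodingFit", "CvScore", "fit_encoding", "evaluate_encoding",
           "cross_validated_r2", "r2_score_ss", "optimize_ridge_lambda"]

DEFAULT_LAMBDA = 1.0
DEFAULT_N_NULL = 100


@dataclass
class EncodingFit:
    """Fitted weights (n_regressors, n_units) and the shared ridge penalty."""

    weights: np.ndarray
    penalty: float
    labels: list[str] | None = None
    interest_mask: np.ndarray | None = None

    @property
    def interest_weights(self) -> np.ndarray:
        if self.interest_mask is None:
            return self.weights
        return self.weights[self.interest_mask]


@dataclass
class CvScore:
    """Cross-validated scores per unit.

    ``r2`` and ``z_r2_folds`` have shape (n_units, n_folds); ``z_r2`` is the
    fold average. ``null_mean``/``null_sd`` are the per-fold moments of the
    null R2 distribution. Units whose null R2 distribution degenerates
    (sigma0 = 0 in any fold) are flagged in ``excluded``.
    """

    r2: np.ndarray
    z_r2_folds: np.ndarray
    z_r2: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_null: int
    excluded: np.ndarray


def fit_encoding(X: np.ndarray, y: np.ndarray, penalty: float = DEFAULT_LAMBDA,
                 labels=None, interest_mask=None) -> EncodingFit:
    """Closed-form ridge solve: w = (X'X + lambda I)^-1 X'y.

    ``y`` may hold many units as columns; the penalty is shared.
    """
    if penalty < 0:
        raise ConfigurationError(f"ridge penalty must be >= 0, got {penalty}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ConfigurationError("non-finite values in regression inputs")
    G = X.T @ X + penalty * np.eye(X.shape[1])
    W = cho_solve(cho_factor(G), X.T @ Y)
    return EncodingFit(weights=W, penalty=float(penalty), labels=labels,
                       interest_mask=interest_mask)


def r2_score_ss(y: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Sums-of-squares R2, computed per column; may be negative."""
    resid = y - pred
    ss_res = np.sum(resid ** 2, axis=0)
    ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    return 1.0 - ss_res / ss_tot


def cross_validated_r2(design: DesignMatrix, Y: np.ndarray,
                       penalty: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Leave-one-session-out R2 with interest-only test predictions.

    Returns (n_units, n_folds). ``Y`` must already be preprocessed and row
    aligned with ``design.X``.
    """
    n_folds = design.n_sessions
    out = np.empty((Y.shape[1], n_folds))
    mask = design.interest_mask
    for f in range(n_folds):
        rows = design.train_rows(f)
        fit = fit_encoding(design.X[rows], Y[rows], penalty)
        test = design.session_rows(f)
        pred = design.X[test][:, mask] @ fit.weights[mask]
        out[:, f] = r2_score_ss(Y[test], pred)
    return out


def _null_estimates(task_config: TaskConfig, obs: ObserverConfig, n_null: int,
                    rng: np.random.Generator, need_traces: bool):
    values = generate_value_matrix(task_config, n_null, rng)
    est, traces = batch_observer_estimates(values, obs, keep_trace=need_traces)
    return est, traces


def evaluate_encoding(sessions: list[SessionData], spec: EncodingSpec,
                      task_config: TaskConfig, observer_config: ObserverConfig,
                      *, hrf: HrfSpec | None = None, tr: float = 2.0,
                      penalty: float = DEFAULT_LAMBDA,
                      n_null: int = DEFAULT_N_NULL,
                      rng: np.random.Generator | int | None = None,
                      preprocess_y: bool = True,
                      design: DesignMatrix | None = None,
                      null_cols_per_fold: list[np.ndarray] | None = None
                      ) -> CvScore:
    """Leave-one-session-out z-R2 of one encoding model.

    The null sequences are drawn once per evaluation from the task process
    and shared across folds and units; ``rng`` seeds that draw. Precomputed
    ``design`` and ``null_cols_per_fold`` may be supplied to share work
    across models evaluated on the same data (as in the recovery
    simulation).
    """
    if len(sessions) < 2:
        raise ConfigurationError("evaluation needs at least 2 sessions")
    hrf = hrf or HrfSpec()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if design is None:
        design = build_design_matrix(sessions, spec, hrf, tr)
    Y_sessions = [s.y for s in sessions]
    if any(y is None for y in Y_sessions):
        raise ConfigurationError("every session needs a data array y")
    if preprocess_y:
        Y_sessions, _ = preprocess_timeseries(Y_sessions, tr)
    Y = np.concatenate([np.atleast_2d(y.T).T for y in Y_sessions], axis=0)

    if null_cols_per_fold is None:
        need_traces = spec.model_class == "posterior_expectation"
        null_est, null_traces = _null_estimates(task_config, observer_config,
                                                n_null, rng, need_traces)
        sd_int = design.col_sd[design.interest_mask]
        null_cols_per_fold = [
            null_interest_columns(sess, null_est, spec, hrf, sd_int, tr,
                                  null_traces=null_traces)
            for sess in sessions]
    n_null = null_cols_per_fold[0].shape[1]

    n_folds = design.n_sessions
    V = Y.shape[1]
    mask = design.interest_mask
    r2 = np.empty((V, n_folds))
    z_folds = np.empty((V, n_folds))
    mu0 = np.empty((V, n_folds))
    sd0 = np.empty((V, n_folds))
    for f in range(n_folds):
        rows = design.train_rows(f)
        fit = fit_encoding(design.X[rows], Y[rows], penalty)
        W_int = fit.weights[mask]
        test = design.session_rows(f)
        y_test = Y[test]
        pred = design.X[test][:, mask] @ W_int
        r2[:, f] = r2_score_ss(y_test, pred)
        # null predictions: (n_scans, n_null, K) x (K, V) -> (n_scans, n_null, V)
        pred_null = np.einsum("snk,kv->snv", null_cols_per_fold[f], W_int,
                              optimize=True)
        ss_tot = np.sum((y_test - y_test.mean(axis=0)) ** 2, axis=0)
        ss_res = np.sum((y_test[:, None, :] - pred_null) ** 2, axis=0)
        r2_null = 1.0 - ss_res / ss_tot          # (n_null, V)
        mu0[:, f] = r2_null.mean(axis=0)
        sd0[:, f] = r2_null.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_folds[:, f] = (r2[:, f] - mu0[:, f]) / sd0[:, f]
    excluded = np.any(sd0 == 0.0, axis=1)
    if excluded.any():
        warnings.warn(f"{int(excluded.sum())} unit(s) had a degenerate null "
                      "R2 distribution (sigma0 = 0) and were flagged")
    z = np.where(excluded[:, None], np.nan, z_folds).mean(axis=1)
    return CvScore(r2=r2, z_r2_folds=z_folds, z_r2=z, null_mean=mu0,
                   null_sd=sd0, n_null=n_null, excluded=excluded)


def optimize_ridge_lambda(sessions: list[SessionData], spec: EncodingSpec,
                          task_config: TaskConfig,
                          observer_config: ObserverConfig,
                          grid=(0.01, 0.1, 1.0, 10.0, 100.0),
                          **kwargs) -> float:
    """Simulation-style grid search: the penalty maximizing mean z-R2."""
    best, best_val = None, -np.inf
    for lam in grid:
        score = evaluate_encoding(sessions, spec, task_config, observer_config,
                                  penalty=lam, **kwargs)
        val = np.nanmean(score.z_r2)
        if val > best_val:
            best, best_val = lam, val
    return float(best)
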