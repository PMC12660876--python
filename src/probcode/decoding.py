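"""Multivariate decoding from bin patterns and RDM geometry analysis.

The decoder works on patterns of unit responses to (overlapping) bins of
the encoded estimate: the versatile model refitted with 5 basis functions,
whose per-unit weights form a units x bins pattern matrix. Per
leave-one-session-out fold, patterns are estimated separately on the three
training sessions (jointly) and on the test session; the test pattern of
bin j is assigned the training bin k minimizing the correlation distance
D(j,k) = 1 - Pearson r. A bin counts a stimulus when the estimate drives
its basis function above 10% of that function's maximum; a bin is valid in
a fold only when at least 5% of the test-session stimuli fall in it.

Fold-averaged RDMs (asymmetric, nonzero diagonal) are regressed on two
z-scored theoretical RDMs: the identity model (equal off-diagonal
dissimilarity, the signature of a highly non-monotonic code) and the graded
model (dissimilarity growing with bin distance, the signature of a
monotonic code); the larger coefficient classifies the code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import BasisSet, EncodingSpec
from .design import SessionData, build_design_matrix, preprocess_timeseries
from .encoding import (DEFAULT_LAMBDA, DEFAULT_N_NULL, evaluate_encoding,
                       fit_encoding)
from .errors import ConfigurationError
from .hrf import HrfSpec
from .observer import ObserverConfig
from .stats import fdr_bh, ttest
from .task import TaskConfig

__all__ = ["BinPatterns", "Rdm", "RdmRegression", "DecodingResult",
           "estimate_bin_patterns", "bin_validity", "compute_rdm",
           "decode_bins", "average_rdm", "regress_rdm", "decode_participant",
           "group_decoding_stats"]

DEFAULT_N_BINS = 5
DEFAULT_N_TOP = 100
BIN_ACTIVATION_FRACTION = 0.1
BIN_MIN_STIM_FRACTION = 0.05
CHANCE_LEVEL = 1.0 / DEFAULT_N_BINS


@dataclass
class BinPatterns:
    """Units x bins weight patterns of one cross-validation fold."""

    train: np.ndarray
    test: np.ndarray
    selected_units: np.ndarray
    fold_id: int


@dataclass
class Rdm:
    """Correlation-distance matrix D(j, k) between test bin j and train bin k."""

    D: np.ndarray
    valid_rows: np.ndarray
    fold_id: int


@dataclass
class RdmRegression:
    coef_identity: float
    coef_graded: float
    intercept: float
    winner: str


@dataclass
class DecodingResult:
    accuracy: float
    fold_accuracies: list[float]
    assignments: list[np.ndarray]
    rdms: list[Rdm]
    mean_rdm: np.ndarray
    mean_valid_rows: np.ndarray
    regression: RdmRegression
    patterns: list[BinPatterns]


def _select_units(train_sessions: list[SessionData], spec: EncodingSpec,
                  n_top: int, n_units: int, task_config, observer_config,
                  hrf, tr, penalty, n_null, rng) -> np.ndarray:
    if n_top >= n_units:
        if n_top > n_units:
            warnings.warn(f"n_top = {n_top} exceeds the {n_units} available "
                          "units; using all units")
        return np.arange(n_units)
    score = evaluate_encoding(train_sessions, spec, task_config,
                              observer_config, hrf=hrf, tr=tr, penalty=penalty,
                              n_null=n_null, rng=rng)
    z = np.where(np.isnan(score.z_r2), -np.inf, score.z_r2)
    return np.sort(np.argsort(z)[::-1][:n_top])


def estimate_bin_patterns(sessions: list[SessionData], estimate: str,
                          *, task_config: TaskConfig,
                          observer_config: ObserverConfig,
                          n_top: int = DEFAULT_N_TOP,
                          n_bins: int = DEFAULT_N_BINS,
                          hrf: HrfSpec | None = None, tr: float = 2.0,
                          penalty: float = DEFAULT_LAMBDA,
                          n_null: int = DEFAULT_N_NULL,
                          rng: np.random.Generator | int | None = None,
                          ) -> tuple[list[BinPatterns], EncodingSpec]:
    """Per-fold bin patterns from the 5-basis versatile model.

    Unit selection (top ``n_top`` by z-R2) uses the training sessions only,
    via an inner leave-one-session-out among them; the pattern fits are the
    joint fit on the training sessions and a separate fit on the test
    session.
    """
    if len(sessions) < 2:
        raise ConfigurationError("decoding needs at least 2 sessions")
    hrf = hrf or HrfSpec()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    spec = EncodingSpec.default("versatile", estimate, K=n_bins)
    design = build_design_matrix(sessions, spec, hrf, tr)
    Y_sessions, _ = preprocess_timeseries([s.y for s in sessions], tr)
    n_units = Y_sessions[0].shape[1]
    mask = design.interest_mask

    folds = []
    for f in range(len(sessions)):
        train_ids = [i for i in range(len(sessions)) if i != f]
        train_sessions = [SessionData(seq=sessions[i].seq, trace=sessions[i].trace,
                                      est=sessions[i].est, reports=sessions[i].reports,
                                      y=Y_sessions[i])
                          for i in train_ids]
        selected = _select_units(train_sessions, spec, n_top, n_units,
                                 task_config, observer_config, hrf, tr,
                                 penalty, n_null, rng)
        rows_train = design.train_rows(f)
        Y = np.concatenate(Y_sessions, axis=0)
        fit_train = fit_encoding(design.X[rows_train], Y[rows_train][:, selected],
                                 penalty)
        rows_test = design.session_rows(f)
        fit_test = fit_encoding(design.X[rows_test], Y[rows_test][:, selected],
                                penalty)
        folds.append(BinPatterns(train=fit_train.weights[mask].T,
                                 test=fit_test.weights[mask].T,
                                 selected_units=selected, fold_id=f))
    return folds, spec


def bin_validity(x_test: np.ndarray, basis: BasisSet,
                 activation_fraction: float = BIN_ACTIVATION_FRACTION,
                 min_stim_fraction: float = BIN_MIN_STIM_FRACTION) -> np.ndarray:
    """Which bins see enough test stimuli to be decoded reliably.

    A stimulus falls in bin j when f_j(x) exceeds ``activation_fraction``
    of that basis function's maximum; the bin is valid when at least
    ``min_stim_fraction`` of the test stimuli fall in it.
    """
    x = np.clip(np.asarray(x_test, dtype=float), *basis.domain)
    F = basis(x)                                  # (T, K)
    hits = F > activation_fraction * basis.max_values()
    return hits.mean(axis=0) >= min_stim_fraction


def compute_rdm(patterns: BinPatterns, valid_rows: np.ndarray | None = None) -> Rdm:
    """Correlation distances between test and train bin patterns."""
    test, train = patterns.test, patterns.train
    if test.shape[0] < 2:
        raise ConfigurationError("correlation distance needs >= 2 units")
    n_bins = test.shape[1]
    sd_test = test.std(axis=0)
    sd_train = train.std(axis=0)
    if np.any(sd_test == 0) or np.any(sd_train == 0):
        warnings.warn("zero-variance bin pattern; affected distances are NaN")
    tc = test - test.mean(axis=0)
    rc = train - train.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (tc.T @ rc) / (test.shape[0] * np.outer(sd_test, sd_train))
    D = 1.0 - C
    if valid_rows is None:
        valid_rows = np.ones(n_bins, dtype=bool)
    return Rdm(D=D, valid_rows=np.asarray(valid_rows, dtype=bool),
               fold_id=patterns.fold_id)


def decode_bins(rdms: list[Rdm]):
    """Nearest-pattern assignments and accuracy over valid bins and folds.

    For each valid row j the decoded bin is argmin_k D(j, k) (ties to the
    lowest k); fold accuracy is the fraction of valid bins decoded
    correctly, and the final accuracy averages over folds that have at
    least one valid bin.
    """
    fold_acc, assignments = [], []
    for rdm in rdms:
        valid = rdm.valid_rows & ~np.any(np.isnan(rdm.D), axis=1)
        assign = np.full(rdm.D.shape[0], -1)
        if not valid.any():
            warnings.warn(f"fold {rdm.fold_id}: no valid bins; fold omitted")
            assignments.append(assign)
            continue
        assign[valid] = np.argmin(rdm.D[valid], axis=1)
        assignments.append(assign)
        fold_acc.append(float(np.mean(assign[valid] == np.flatnonzero(valid))))
    if not fold_acc:
        raise ConfigurationError("no fold had a valid bin")
    return float(np.mean(fold_acc)), fold_acc, assignments


def average_rdm(rdms: list[Rdm]) -> tuple[np.ndarray, np.ndarray]:
    """Fold-averaged RDM; rows invalid in a fold are ignored in the average."""
    n = rdms[0].D.shape[0]
    acc = np.zeros((n, n))
    cnt = np.zeros((n, 1))
    for rdm in rdms:
        rows = rdm.valid_rows & ~np.any(np.isnan(rdm.D), axis=1)
        acc[rows] += rdm.D[rows]
        cnt[rows, 0] += 1
    valid = cnt[:, 0] > 0
    with np.errstate(invalid="ignore"):
        mean = acc / cnt
    return mean, valid


def _zscore_cells(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ConfigurationError("constant model RDM over included cells")
    return (v - v.mean()) / sd


def regress_rdm(mean_rdm: np.ndarray, valid_rows: np.ndarray,
                graded: str = "abs") -> RdmRegression:
    """OLS of the fold-averaged RDM on z-scored identity and graded models.

    All cells of valid rows enter (diagonal included); the winner is the
    model with the larger coefficient.
    """
    n = mean_rdm.shape[0]
    if valid_rows.sum() < 2:
        raise ConfigurationError("need at least 2 valid rows for RDM regression")
    J, K = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    cells = np.repeat(valid_rows, n).reshape(n, n)
    y = mean_rdm[cells]
    ident = (J != K).astype(float)[cells]
    dist = np.abs(J - K) if graded == "abs" else (J - K) ** 2
    grad = dist.astype(float)[cells]
    X = np.column_stack([np.ones_like(y), _zscore_cells(ident), _zscore_cells(grad)])
    if np.linalg.matrix_rank(X) < 3:
        raise ConfigurationError("collinear model RDMs after row exclusion")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    winner = "identity" if beta[1] >= beta[2] else "graded"
    return RdmRegression(coef_identity=float(beta[1]), coef_graded=float(beta[2]),
                         intercept=float(beta[0]), winner=winner)


def decode_participant(sessions: list[SessionData], estimate: str = "probability",
                       *, task_config: TaskConfig,
                       observer_config: ObserverConfig,
                       n_top: int = DEFAULT_N_TOP, n_bins: int = DEFAULT_N_BINS,
                       hrf: HrfSpec | None = None, tr: float = 2.0,
                       penalty: float = DEFAULT_LAMBDA,
                       n_null: int = DEFAULT_N_NULL,
                       rng: np.random.Generator | int | None = None,
                       graded: str = "abs") -> DecodingResult:
    """Full decoding pipeline for one participant (or unit group)."""
    patterns, spec = estimate_bin_patterns(
        sessions, estimate, task_config=task_config,
        observer_config=observer_config, n_top=n_top, n_bins=n_bins, hrf=hrf,
        tr=tr, penalty=penalty, n_null=n_null, rng=rng)
    rdms = []
    for pat in patterns:
        est = sessions[pat.fold_id].est
        x = est.p_hat if estimate == "probability" else est.confidence
        valid = bin_validity(x, spec.basis)
        rdms.append(compute_rdm(pat, valid))
    accuracy, fold_acc, assignments = decode_bins(rdms)
    mean_rdm, mean_valid = average_rdm(rdms)
    regression = regress_rdm(mean_rdm, mean_valid, graded)
    return DecodingResult(accuracy=accuracy, fold_accuracies=fold_acc,
                          assignments=assignments, rdms=rdms,
                          mean_rdm=mean_rdm, mean_valid_rows=mean_valid,
                          regression=regression, patterns=patterns)


def group_decoding_stats(accuracies: np.ndarray,
                         graded_wins: np.ndarray | None = None,
                         chance: float = CHANCE_LEVEL, q: float = 0.05) -> dict:
    """Group-level decoding statistics.

    ``accuracies`` is participants x regions; per region a two-sided
    one-sample t-test against chance with BH-FDR across regions. When
    ``graded_wins`` (participants x regions, boolean) is given, the
    per-participant fraction of regions classified "graded" is tested
    against 0.5.
    """
    acc = np.atleast_2d(np.asarray(accuracies, dtype=float))
    if acc.shape[0] < 2:
        raise ConfigurationError("need at least 2 participants")
    region_tests = [ttest(acc[:, r], kind="one_sample", popmean=chance)
                    for r in range(acc.shape[1])]
    pvals = np.array([t.p for t in region_tests])
    reject, p_adj = fdr_bh(pvals, q)
    out = {"region_tests": region_tests, "p_fdr": p_adj,
           "significant": reject, "mean_accuracy": acc.mean(axis=0)}
    if graded_wins is not None:
        frac = np.atleast_2d(np.asarray(graded_wins, dtype=float)).mean(axis=1)
        out["graded_fraction"] = frac
        out["graded_vs_half"] = ttest(frac, kind="one_sample", popmean=0.5)
    return out
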