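"""Design-matrix construction and temporal preprocessing.

Regressors of interest are the encoding-model modulators (the estimate
itself for the linear class, the basis responses f_i(x_t) for the versatile
class) placed as impulses at stimulus onsets on a sub-TR grid, convolved
with the HRF and sampled at the scan times. Regressors of no interest model
stimulus onsets (constant), Shannon surprise, outcome entropy, and the
report screens (constant, normative value, reported value), plus optional
motion confounds.

All regressors then go through exactly the temporal preprocessing applied
to the data: per-session linear detrend, discrete-cosine high-pass at
1/128 Hz, z-scoring over the concatenated sessions, and per-session
demeaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _detrend
from scipy.signal import fftconvolve

from .basis import BasisSet, EncodingSpec
from .errors import ConfigurationError
from .hrf import HrfSpec
from .observer import NormativeEstimates, PosteriorTrace
from .task import StimulusSequence

__all__ = ["ReportBlock", "SessionData", "DesignMatrix", "build_design_matrix",
           "preprocess_timeseries", "posterior_expectation_modulators",
           "interest_modulators", "null_interest_columns", "dct_drift_basis"]

DEFAULT_TR = 2.0
HIGHPASS_CUTOFF_HZ = 1.0 / 128.0


@dataclass
class ReportBlock:
    """Response-screen events of one session (two screens per report period)."""

    screen_onsets: np.ndarray
    normative: np.ndarray       # normative estimate shown screen-by-screen
    reported: np.ndarray        # simulated (or actual) report values


@dataclass
class SessionData:
    """Everything one session contributes to an encoding analysis."""

    seq: StimulusSequence
    trace: PosteriorTrace | None
    est: NormativeEstimates
    reports: ReportBlock | None = None
    y: np.ndarray | None = None     # (n_scans, n_units)


@dataclass
class DesignMatrix:
    """Concatenated, preprocessed design over all sessions."""

    X: np.ndarray                   # (n_scans_total, n_regressors)
    labels: list[str]
    interest_mask: np.ndarray       # boolean per column
    session_bounds: list[tuple[int, int]]
    tr: float
    col_sd: np.ndarray              # z-scoring scale used per column
    spec: EncodingSpec | None = field(default=None, repr=False)

    @property
    def n_sessions(self) -> int:
        return len(self.session_bounds)

    def session_rows(self, i: int) -> slice:
        a, b = self.session_bounds[i]
        return slice(a, b)

    def train_rows(self, holdout: int) -> np.ndarray:
        idx = [np.arange(a, b) for i, (a, b) in enumerate(self.session_bounds)
               if i != holdout]
        return np.concatenate(idx)


# ---------------------------------------------------------------------------
# modulators

def _estimate_values(spec: EncodingSpec, est: NormativeEstimates) -> np.ndarray:
    if spec.estimate == "probability":
        return est.p_hat
    if spec.estimate == "confidence":
        return est.confidence
    return est.entropy


def _clamp_to_domain(x: np.ndarray, basis: BasisSet) -> np.ndarray:
    a, b = basis.domain
    n_out = int(np.sum((x < a) | (x > b)))
    if n_out:
        warnings.warn(f"{n_out} estimate value(s) outside basis domain "
                      f"[{a}, {b}]; clamped to the boundary", stacklevel=3)
    return np.clip(x, a, b)


def interest_modulators(spec: EncodingSpec, est: NormativeEstimates,
                        trace: PosteriorTrace | None = None) -> np.ndarray:
    """Per-trial modulator matrix (T, n_interest) for an encoding spec."""
    spec.validate()
    if spec.model_class == "posterior_expectation":
        if trace is None:
            raise ConfigurationError("posterior_expectation needs a posterior trace")
        return posterior_expectation_modulators(trace, spec.basis)
    x = _estimate_values(spec, est)
    if spec.model_class == "linear":
        return x[:, None]
    return spec.basis(_clamp_to_domain(x, spec.basis))


def posterior_expectation_modulators(trace: PosteriorTrace,
                                     basis: BasisSet,
                                     which: str = "predictive") -> np.ndarray:
    """Modulators int f_i(x) p(x) dx as grid sums under the trial posteriors."""
    P = trace.predictive if which == "predictive" else trace.posterior
    F = basis(trace.grid)                # (G, K)
    return P @ F


# ---------------------------------------------------------------------------
# convolution machinery

def _fine_grid(duration: float, dt: float) -> int:
    return int(np.ceil(duration / dt)) + 1


def _impulse_convolve(n_fine: int, idx: np.ndarray, amps: np.ndarray,
                      kernel: np.ndarray) -> np.ndarray:
    """HRF-convolve impulses of amplitudes ``amps`` (n_events, C) at sample
    indices ``idx``; returns the fine-grid series (n_fine, C)."""
    imp = np.zeros((n_fine, amps.shape[1]))
    np.add.at(imp, idx, amps)
    out = fftconvolve(imp, kernel[:, None], axes=0)
    return out[:n_fine]


def n_scans_for(seq: StimulusSequence, tr: float = DEFAULT_TR) -> int:
    return int(np.ceil(seq.duration / tr))


def _scan_sample_idx(n_scans: int, tr: float, dt: float) -> np.ndarray:
    return np.round(np.arange(n_scans) * tr / dt).astype(int)


def session_design_raw(sess: SessionData, spec: EncodingSpec, hrf: HrfSpec,
                       tr: float = DEFAULT_TR,
                       motion: np.ndarray | None = None):
    """Unpreprocessed design of one session, sampled at the TR grid.

    Returns (X_raw, labels, interest_mask).
    """
    spec.validate()
    hrf.validate()
    seq, est = sess.seq, sess.est
    dt = hrf.dt
    kernel = hrf.kernel()
    n_fine = _fine_grid(seq.duration, dt)
    n_scans = n_scans_for(seq, tr)
    scan_idx = _scan_sample_idx(n_scans, tr, dt)
    stim_idx = np.round(seq.onsets / dt).astype(int)

    M = interest_modulators(spec, est, sess.trace)
    labels = [f"interest_{i}" for i in range(M.shape[1])]

    # No-interest stimulus modulations: constant, surprise, entropy. Entropy
    # is dropped when it is itself the factor of interest.
    blocks = [M, np.ones((seq.n_trials, 1)), est.surprise[:, None]]
    labels += ["stim_constant", "surprise"]
    if spec.estimate != "entropy":
        blocks.append(est.entropy[:, None])
        labels.append("entropy")
    stim_amps = np.hstack(blocks)
    X_fine = _impulse_convolve(n_fine, stim_idx, stim_amps, kernel)

    cols = [X_fine[scan_idx]]
    if sess.reports is not None and sess.reports.screen_onsets.size:
        rep = sess.reports
        rep_idx = np.round(rep.screen_onsets / dt).astype(int)
        rep_amps = np.column_stack([np.ones_like(rep.normative),
                                    rep.normative, rep.reported])
        R_fine = _impulse_convolve(n_fine, rep_idx, rep_amps, kernel)
        cols.append(R_fine[scan_idx])
        labels += ["report_constant", "report_normative", "report_reported"]

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise ConfigurationError("motion confounds must have one row per scan")
        cols.append(motion)
        labels += [f"motion_{i}" for i in range(motion.shape[1])]

    X_raw = np.hstack(cols)
    interest_mask = np.zeros(X_raw.shape[1], dtype=bool)
    interest_mask[:M.shape[1]] = True
    return X_raw, labels, interest_mask


# ---------------------------------------------------------------------------
# temporal preprocessing

def dct_drift_basis(n_scans: int, tr: float,
                    cutoff: float = HIGHPASS_CUTOFF_HZ) -> np.ndarray:
    """Orthonormal DCT-II drift regressors with frequencies below ``cutoff``.

    Component k has frequency k / (2 * n_scans * tr) Hz; the constant term
    is excluded (handled by detrending/demeaning).
    """
    k_max = int(np.floor(2.0 * n_scans * tr * cutoff))
    n = np.arange(n_scans)
    B = np.array([np.cos(np.pi * k * (n + 0.5) / n_scans)
                  for k in range(1, k_max + 1)]).T
    if B.size == 0:
        return np.zeros((n_scans, 0))
    B = B / np.linalg.norm(B, axis=0)
    return B


def preprocess_timeseries(sessions: list[np.ndarray], tr: float = DEFAULT_TR,
                          cutoff: float = HIGHPASS_CUTOFF_HZ,
                          scale: np.ndarray | None = None):
    """Apply the study's temporal pipeline to per-session series.

    Per session: linear detrend, then DCT high-pass at ``cutoff``; then the
    sessions are concatenated and z-scored (per column, across sessions);
    finally each session is demeaned. Constant columns come out as zeros.

    ``scale`` optionally freezes the z-scoring standard deviations (used to
    put null-model regressors on the same scale as the true design).
    Returns (list of processed arrays, scale used).
    """
    proc = []
    raw_mag = 0.0
    for y in sessions:
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] < 2:
            raise ConfigurationError("each session needs at least 2 scans")
        raw_mag = np.maximum(raw_mag, np.abs(y).max(axis=0))
        y = _detrend(y, axis=0, type="linear")
        B = dct_drift_basis(y.shape[0], tr, cutoff)
        if B.shape[1]:
            y = y - B @ (B.T @ y)
        proc.append(y)
    full = np.concatenate(proc, axis=0)
    # columns reduced to float-epsilon residue (e.g. constant input) are dead
    dead = np.abs(full).max(axis=0) <= 1e-10 * (raw_mag + 1.0)
    full[:, dead] = 0.0
    if scale is None:
        sd = full.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        sd = np.asarray(scale, dtype=float)
    full = (full - full.mean(axis=0)) / sd
    out = []
    start = 0
    for y in proc:
        stop = start + y.shape[0]
        block = full[start:stop]
        out.append(block - block.mean(axis=0))
        start = stop
    return out, sd


def build_design_matrix(sessions: list[SessionData], spec: EncodingSpec,
                        hrf: HrfSpec | None = None, tr: float = DEFAULT_TR,
                        motion: list[np.ndarray] | None = None,
                        cutoff: float = HIGHPASS_CUTOFF_HZ) -> DesignMatrix:
    """Build and preprocess the full multi-session design for one model."""
    hrf = hrf or HrfSpec()
    raws = []
    labels = interest_mask = None
    for i, sess in enumerate(sessions):
        X_raw, labels_i, mask_i = session_design_raw(
            sess, spec, hrf, tr, None if motion is None else motion[i])
        raws.append(X_raw)
        if labels is None:
            labels, interest_mask = labels_i, mask_i
        elif labels_i != labels:
            raise ConfigurationError("sessions produced inconsistent regressor sets")
    proc, sd = preprocess_timeseries(raws, tr, cutoff)
    bounds = []
    start = 0
    for p in proc:
        bounds.append((start, start + p.shape[0]))
        start += p.shape[0]
    return DesignMatrix(X=np.concatenate(proc, axis=0), labels=labels,
                        interest_mask=interest_mask, session_bounds=bounds,
                        tr=tr, col_sd=sd, spec=spec)


def null_interest_columns(sess: SessionData, null_est: NormativeEstimates,
                          spec: EncodingSpec, hrf: HrfSpec,
                          interest_sd: np.ndarray, tr: float = DEFAULT_TR,
                          cutoff: float = HIGHPASS_CUTOFF_HZ,
                          null_traces: np.ndarray | None = None) -> np.ndarray:
    """Interest regressors rebuilt from replacement sequences.

    ``null_est`` holds (n_null, T) estimate arrays from sequences generated
    by the task process; the true session supplies the stimulus timing and
    report schedule. The columns go through the same preprocessing as the
    true design, with the z-scoring scale frozen to ``interest_sd``.

    Returns an array of shape (n_scans, n_null, n_interest).
    """
    spec.validate()
    seq = sess.seq
    dt = hrf.dt
    kernel = hrf.kernel()
    n_fine = _fine_grid(seq.duration, dt)
    n_scans = n_scans_for(seq, tr)
    scan_idx = _scan_sample_idx(n_scans, tr, dt)
    stim_idx = np.round(seq.onsets / dt).astype(int)

    if spec.model_class == "posterior_expectation":
        if null_traces is None:
            raise ConfigurationError("posterior_expectation nulls need predictive traces")
        mods = np.einsum("ntg,gk->ntk", null_traces, spec.basis(sess.trace.grid))
    else:
        x = null_est.p_hat if spec.estimate == "probability" else (
            null_est.confidence if spec.estimate == "confidence" else null_est.entropy)
        if spec.model_class == "linear":
            mods = x[:, :, None]
        else:
            mods = spec.basis(np.clip(x, *spec.basis.domain))
    n_null, T, K = mods.shape

    amps = mods.transpose(1, 0, 2).reshape(T, n_null * K)
    X_fine = _impulse_convolve(n_fine, stim_idx, amps, kernel)
    X = X_fine[scan_idx]
    X = _detrend(X, axis=0, type="linear")
    B = dct_drift_basis(n_scans, tr, cutoff)
    if B.shape[1]:
        X = X - B @ (B.T @ X)
    X = X / np.tile(interest_sd, n_null)
    X = X - X.mean(axis=0)
    return X.reshape(n_scans, n_null, K)
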