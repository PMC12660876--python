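"""Synthetic experiments and the model-recovery simulation.

A synthetic experiment mirrors the study design: four sessions of 420
stimuli from the change-point Bernoulli process, ideal-observer estimates,
simulated report periods, and voxel time series generated as a weighted sum
of the (HRF-convolved, preprocessed) regressors of a chosen generative
encoding model plus Gaussian white noise with nine times the signal power
(10% signal / 90% noise).

The recovery analysis crosses generative models with fitted models: each
simulated data set is evaluated with every fitted model through the full
leave-one-session-out z-R2 pipeline, and scores are averaged over voxels
and experiments into a generative x fitted matrix, together with the
fraction of experiments in which each fitted model scored best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import EncodingSpec
from .design import (ReportBlock, SessionData, build_design_matrix,
                     null_interest_columns)
from .encoding import (DEFAULT_LAMBDA, DEFAULT_N_NULL, evaluate_encoding)
from .errors import ConfigurationError
from .hrf import HrfSpec
from .observer import ObserverConfig, batch_observer_estimates, run_ideal_observer
from .task import TaskConfig, generate_sequence, generate_value_matrix

__all__ = ["GenerativeVoxelSpec", "SyntheticExperiment", "RecoveryMatrix",
           "simulate_reports", "simulate_voxel", "generate_participant_sessions",
           "simulate_experiment", "model_recovery_matrix",
           "draw_random_weights", "draw_monotone_weights", "draw_bump_weights"]

DEFAULT_NOISE_RATIO = 9.0
WEIGHT_RANGE = (-0.5, 0.5)


@dataclass
class GenerativeVoxelSpec:
    """Ground truth of one simulated voxel."""

    spec: EncodingSpec
    weights: np.ndarray
    noise_ratio: float = DEFAULT_NOISE_RATIO


@dataclass
class SyntheticExperiment:
    """Four sessions plus simulated voxels with stored ground truth."""

    task_config: TaskConfig
    observer_config: ObserverConfig
    sessions: list[SessionData]
    gspecs: list[GenerativeVoxelSpec]
    seed: int | None = None


@dataclass
class RecoveryMatrix:
    """Generative x fitted score summary of the recovery simulation."""

    gen_labels: list[str]
    fit_labels: list[str]
    mean_z_r2: np.ndarray            # (G, F), averaged over voxels and experiments
    frac_best: np.ndarray            # (G, F), rows sum to 1
    per_experiment: np.ndarray       # (n_experiments, G, F) voxel-mean z-R2


# ---------------------------------------------------------------------------
# report simulation (regressors of no interest only)

def _discretize(v: float, edges: np.ndarray) -> float:
    """Map a value to the center of its bin."""
    idx = np.clip(np.searchsorted(edges, v) - 1, 0, len(edges) - 2)
    return float((edges[idx] + edges[idx + 1]) / 2.0)


def simulate_reports(seq, trace, rng: np.random.Generator,
                     noise_sd: float = 0.1,
                     confidence_domain: tuple[float, float] = (1.1, 2.6)
                     ) -> ReportBlock:
    """Simulated probability and confidence reports at the response screens.

    Reported value = normative value + Gaussian noise (sd 0.1 on the unit
    scale), discretized to the report scale (3- or 5-range for probability,
    chosen at random per period as in the task; 5 levels for confidence).
    The first screen of each period carries the probability report, the
    second the confidence report.
    """
    if seq.report_trials.size == 0:
        return ReportBlock(screen_onsets=np.empty(0), normative=np.empty(0),
                           reported=np.empty(0))
    grid = trace.grid
    post = trace.posterior[seq.report_trials]
    p_norm = post @ grid
    sd = np.sqrt(np.maximum(post @ grid ** 2 - p_norm ** 2, 1e-300))
    c_norm = np.clip(-np.log(sd), *confidence_domain)
    lo, hi = confidence_domain

    onsets, normative, reported = [], [], []
    half = seq.config.report_period_duration / 2.0
    for i, t0 in enumerate(seq.report_onsets):
        n_ranges = int(rng.choice([3, 5]))
        p_edges = np.linspace(0.0, 1.0, n_ranges + 1)
        p_rep = _discretize(np.clip(p_norm[i] + rng.normal(0.0, noise_sd), 0, 1),
                            p_edges)
        c_unit = (c_norm[i] - lo) / (hi - lo)
        c_rep_unit = _discretize(np.clip(c_unit + rng.normal(0.0, noise_sd), 0, 1),
                                 np.linspace(0.0, 1.0, 6))
        c_rep = lo + c_rep_unit * (hi - lo)
        onsets += [t0, t0 + half]
        normative += [p_norm[i], c_norm[i]]
        reported += [p_rep, c_rep]
    return ReportBlock(screen_onsets=np.asarray(onsets),
                       normative=np.asarray(normative),
                       reported=np.asarray(reported))


# ---------------------------------------------------------------------------
# voxel simulation

def simulate_voxel(X_interest: np.ndarray, weights: np.ndarray,
                   noise_ratio: float = DEFAULT_NOISE_RATIO,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Signal X w plus white noise with ``noise_ratio`` times its power."""
    if noise_ratio < 0:
        raise ConfigurationError(f"noise_ratio must be >= 0, got {noise_ratio}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    signal = np.asarray(X_interest) @ np.asarray(weights)
    var = signal.var()
    if var == 0.0 and noise_ratio > 0:
        raise ConfigurationError("zero-variance signal: noise scaling undefined")
    noise = rng.normal(0.0, np.sqrt(noise_ratio * var), size=signal.shape)
    return signal + noise


def draw_random_weights(K: int, rng: np.random.Generator) -> np.ndarray:
    """Study default: each weight uniform in [-0.5, 0.5]."""
    return rng.uniform(*WEIGHT_RANGE, size=K)


def draw_monotone_weights(basis, rng: np.random.Generator) -> np.ndarray:
    """Weights of a random monotone (sigmoid-shaped) tuning curve.

    Sampled at the basis centers, with random threshold, slope scale, and
    sign, then scaled into the study weight range.
    """
    a, b = basis.domain
    theta = rng.uniform(a + 0.2 * (b - a), b - 0.2 * (b - a))
    slope = rng.uniform(0.05, 0.3) * (b - a)
    sign = rng.choice([-1.0, 1.0])
    w = sign / (1.0 + np.exp(-(basis.centers - theta) / slope))
    return 0.5 * (w - w.mean()) / max(np.abs(w - w.mean()).max(), 1e-12)


def draw_bump_weights(K: int, rng: np.random.Generator) -> np.ndarray:
    """One-hot weights: a single positive bump at a random basis index."""
    w = np.zeros(K)
    w[rng.integers(K)] = 0.5
    return w


# ---------------------------------------------------------------------------
# experiment assembly

def generate_participant_sessions(task_config: TaskConfig,
                                  observer_config: ObserverConfig,
                                  rng: np.random.Generator,
                                  include_reports: bool = True,
                                  timing: str = "predictive") -> list[SessionData]:
    """Sequences, observer traces/estimates, and simulated reports."""
    sessions = []
    for i in range(task_config.n_sessions):
        seq = generate_sequence(task_config, rng, session_id=i)
        trace, est = run_ideal_observer(seq, observer_config, timing=timing)
        reports = simulate_reports(seq, trace, rng) if include_reports else None
        sessions.append(SessionData(seq=seq, trace=trace, est=est,
                                    reports=reports))
    return sessions


def simulate_experiment(task_config: TaskConfig | None = None,
                        observer_config: ObserverConfig | None = None,
                        gen_spec: EncodingSpec | None = None,
                        n_voxels: int = 20,
                        seed: int | np.random.Generator | None = None,
                        *, hrf: HrfSpec | None = None, tr: float = 2.0,
                        noise_ratio: float = DEFAULT_NOISE_RATIO,
                        weight_sampler=None,
                        include_reports: bool = True) -> SyntheticExperiment:
    """Simulate one participant under a single generative encoding model.

    ``weight_sampler(rng) -> weights`` overrides the default uniform draw
    (per voxel, constant across sessions).
    """
    task_config = task_config or TaskConfig()
    observer_config = observer_config or ObserverConfig.default(
        task_config.p_support, hazard=task_config.hazard)
    gen_spec = gen_spec or EncodingSpec.default("versatile", "probability")
    hrf = hrf or HrfSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sessions = generate_participant_sessions(task_config, observer_config, rng,
                                             include_reports)
    design = build_design_matrix(sessions, gen_spec, hrf, tr)
    X_int = design.X[:, design.interest_mask]
    K = gen_spec.n_interest
    gspecs = []
    Y = np.empty((design.X.shape[0], n_voxels))
    for v in range(n_voxels):
        w = weight_sampler(rng) if weight_sampler else draw_random_weights(K, rng)
        gspecs.append(GenerativeVoxelSpec(spec=gen_spec, weights=w,
                                          noise_ratio=noise_ratio))
        Y[:, v] = simulate_voxel(X_int, w, noise_ratio, rng)
    for i, sess in enumerate(sessions):
        sess.y = Y[design.session_rows(i)]
    return SyntheticExperiment(task_config=task_config,
                               observer_config=observer_config,
                               sessions=sessions, gspecs=gspecs,
                               seed=None if isinstance(seed, np.random.Generator) else seed)


def default_model_set(include_entropy: bool = False) -> list[EncodingSpec]:
    specs = [EncodingSpec.default("linear", "probability"),
             EncodingSpec.default("versatile", "probability"),
             EncodingSpec.default("linear", "confidence"),
             EncodingSpec.default("versatile", "confidence")]
    if include_entropy:
        specs.append(EncodingSpec("linear", "entropy", None))
    return specs


def model_recovery_matrix(n_experiments: int = 10, n_voxels: int = 20,
                          gen_specs: list[EncodingSpec] | None = None,
                          fit_specs: list[EncodingSpec] | None = None,
                          *, task_config: TaskConfig | None = None,
                          observer_config: ObserverConfig | None = None,
                          hrf: HrfSpec | None = None, tr: float = 2.0,
                          penalty: float = DEFAULT_LAMBDA,
                          n_null: int = DEFAULT_N_NULL,
                          noise_ratio: float = DEFAULT_NOISE_RATIO,
                          seed: int | np.random.Generator | None = 0,
                          include_reports: bool = True) -> RecoveryMatrix:
    """Model-recovery simulation: every generative model crossed with every
    fitted model through the full z-R2 pipeline.

    Null sequences and the fitted-model designs are shared across
    generative models within an experiment (they depend only on the
    session data), which keeps the desk-scale default (10 experiments x
    20 voxels) tractable.
    """
    task_config = task_config or TaskConfig()
    observer_config = observer_config or ObserverConfig.default(
        task_config.p_support, hazard=task_config.hazard)
    gen_specs = gen_specs or default_model_set()
    fit_specs = fit_specs or default_model_set()
    hrf = hrf or HrfSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    G, F = len(gen_specs), len(fit_specs)
    per_exp = np.empty((n_experiments, G, F))
    for e in range(n_experiments):
        sessions = generate_participant_sessions(task_config, observer_config,
                                                 rng, include_reports)
        # one design per distinct model label (generative and fitted share)
        designs: dict[str, object] = {}
        for spec in list(gen_specs) + list(fit_specs):
            if spec.label not in designs:
                designs[spec.label] = build_design_matrix(sessions, spec, hrf, tr)

        # null estimates shared by all fitted models of this experiment
        null_values = generate_value_matrix(task_config, n_null, rng)
        need_traces = any(s.model_class == "posterior_expectation" for s in fit_specs)
        null_est, null_traces = batch_observer_estimates(
            null_values, observer_config, keep_trace=need_traces)
        null_cols: dict[str, list[np.ndarray]] = {}
        for spec in fit_specs:
            if spec.label in null_cols:
                continue
            d = designs[spec.label]
            sd_int = d.col_sd[d.interest_mask]
            null_cols[spec.label] = [
                null_interest_columns(sess, null_est, spec, hrf, sd_int, tr,
                                      null_traces=null_traces)
                for sess in sessions]

        for g, gspec in enumerate(gen_specs):
            dg = designs[gspec.label]
            X_int = dg.X[:, dg.interest_mask]
            W = np.column_stack([draw_random_weights(gspec.n_interest, rng)
                                 for _ in range(n_voxels)])
            signal = X_int @ W
            noise = rng.normal(size=signal.shape) * np.sqrt(
                noise_ratio * signal.var(axis=0))
            Y = signal + noise
            for i, sess in enumerate(sessions):
                sess.y = Y[dg.session_rows(i)]
            for f, fspec in enumerate(fit_specs):
                score = evaluate_encoding(
                    sessions, fspec, task_config, observer_config, hrf=hrf,
                    tr=tr, penalty=penalty, rng=rng,
                    design=designs[fspec.label],
                    null_cols_per_fold=null_cols[fspec.label])
                per_exp[e, g, f] = np.nanmean(score.z_r2)

    best = per_exp.argmax(axis=2)                    # (n_experiments, G)
    frac_best = np.stack([(best == f).mean(axis=0) for f in range(F)], axis=1)
    return RecoveryMatrix(gen_labels=[s.label for s in gen_specs],
                          fit_labels=[s.label for s in fit_specs],
                          mean_z_r2=per_exp.mean(axis=0),
                          frac_best=frac_best, per_experiment=per_exp)
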