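"""Generative task process: change-point Bernoulli sequences with report periods.

A session is a sequence of binary stimuli (A/B) drawn from a hidden Bernoulli
probability ``h_t`` that occasionally undergoes abrupt change points. At each
step the probability is redrawn with a fixed hazard rate, under two
constraints: the odds of A must change by at least a fixed factor, and a
change is forced if a run ever reaches ``max_run`` trials. Report periods,
during which the observer would report a probability estimate and a
confidence level on two response screens, interrupt the stimulus stream on
average every ``report_mean_interval`` trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["TaskConfig", "StimulusSequence", "generate_sequence",
           "generate_session_set", "sequence_to_events", "sequence_from_events"]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the generative task process.

    Defaults reproduce the study design: 4 sessions of 420 stimuli, hazard
    1/75 on the hidden probability with support [0.1, 0.9], odds-change
    factor >= 4 at change points, a forced change after 300 trials without
    one, reports every 22 +/- 3 trials, stimuli of 1 s every 1.3 s (SOA),
    and 10-s report periods (two 5-s response screens).
    """

    n_stimuli_per_session: int = 420
    n_sessions: int = 4
    hazard: float = 1.0 / 75.0
    p_support: tuple[float, float] = (0.1, 0.9)
    min_odds_factor: float = 4.0
    max_run: int = 300
    report_mean_interval: int = 22
    report_jitter: int = 3
    soa: float = 1.3
    stimulus_duration: float = 1.0
    report_period_duration: float = 10.0
    rest_tail: float = 16.0
    seed: int | None = None

    def validate(self) -> None:
        lo, hi = self.p_support
        if not 0.0 < self.hazard < 1.0:
            raise ConfigurationError(f"hazard must lie in (0, 1), got {self.hazard}"
                                     if self.hazard != 0.0 else
                                     "hazard must lie in (0, 1), got 0")
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(f"p_support must lie within (0, 1), got {self.p_support}")
        if self.min_odds_factor < 1.0:
            raise ConfigurationError(f"min_odds_factor must be >= 1, got {self.min_odds_factor}")
        if self.max_run < 1:
            raise ConfigurationError(f"max_run must be >= 1, got {self.max_run}")
        if not self.report_mean_interval > self.report_jitter >= 0:
            raise ConfigurationError(
                "report_mean_interval must exceed report_jitter and jitter must be >= 0, "
                f"got interval={self.report_mean_interval}, jitter={self.report_jitter}")
        if self.n_stimuli_per_session < 1 or self.n_sessions < 1:
            raise ConfigurationError("session and stimulus counts must be >= 1")
        if self.soa <= 0 or self.stimulus_duration <= 0:
            raise ConfigurationError("soa and stimulus_duration must be positive")

    # hazard = 0 is allowed for the observer but not for the generator, which
    # needs it to define a run-length distribution; allow it explicitly via a
    # permissive validator used by generate_sequence.
    def _validate_generator(self) -> None:
        cfg = self if self.hazard != 0.0 else replace(self, hazard=0.5)
        cfg.validate()
        if not 0.0 <= self.hazard < 1.0:
            raise ConfigurationError(f"hazard must lie in [0, 1) for generation, got {self.hazard}")


@dataclass
class StimulusSequence:
    """One session of the task.

    ``values`` is the binary stimulus stream (1 = A, 0 = B); ``hidden_p`` the
    hidden probability of A on each trial; ``change_points`` the trial
    indices at which a new probability takes effect; ``report_trials`` the
    indices of trials followed by a report period; ``onsets`` stimulus onset
    times in seconds.
    """

    values: np.ndarray
    hidden_p: np.ndarray
    change_points: np.ndarray
    report_trials: np.ndarray
    onsets: np.ndarray
    report_onsets: np.ndarray
    duration: float
    session_id: int = 0
    config: TaskConfig = field(default_factory=TaskConfig)

    @property
    def n_trials(self) -> int:
        return self.values.size

    def screen_onsets(self) -> np.ndarray:
        """Onsets of the two response screens of every report period."""
        half = self.config.report_period_duration / 2.0
        return np.sort(np.concatenate([self.report_onsets, self.report_onsets + half]))


def _odds(p: np.ndarray | float) -> np.ndarray | float:
    return p / (1.0 - p)


def _draw_new_p(rng: np.random.Generator, p_old: float | None,
                cfg: TaskConfig) -> float:
    """Resample the hidden probability, enforcing the odds-factor constraint."""
    lo, hi = cfg.p_support
    while True:
        p_new = rng.uniform(lo, hi)
        if p_old is None:
            return p_new
        ratio = _odds(p_new) / _odds(p_old)
        if max(ratio, 1.0 / ratio) >= cfg.min_odds_factor:
            return p_new


def _run_length(rng: np.random.Generator, cfg: TaskConfig) -> int:
    if cfg.hazard == 0.0:
        return cfg.max_run if np.isfinite(cfg.max_run) else 10 ** 9
    return int(min(rng.geometric(cfg.hazard), cfg.max_run))


def generate_sequence(config: TaskConfig, seed: int | np.random.Generator | None = None,
                      session_id: int = 0) -> StimulusSequence:
    """Generate one session of the change-point Bernoulli task.

    The hidden probability is piecewise constant with per-step change
    probability ``config.hazard``; run lengths are drawn geometrically and
    capped at ``max_run`` (a change is forced there). Identical seeds yield
    bit-identical sequences.
    """
    config._validate_generator()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed)
    T = config.n_stimuli_per_session

    hidden = np.empty(T)
    change_points: list[int] = []
    pos = 0
    p = _draw_new_p(rng, None, config)
    while pos < T:
        run = _run_length(rng, config)
        end = min(pos + run, T)
        hidden[pos:end] = p
        pos = end
        if pos < T:
            change_points.append(pos)
            p = _draw_new_p(rng, p, config)

    values = (rng.random(T) < hidden).astype(np.int8)

    # Report schedule: cumulative sums of (mean interval + integer jitter).
    intervals = []
    total = 0
    while total < T:
        step = config.report_mean_interval + int(
            rng.integers(-config.report_jitter, config.report_jitter + 1))
        intervals.append(step)
        total += step
    report_after = np.cumsum(intervals) - 1          # index of trial preceding the period
    report_after = report_after[report_after < T - 1]

    onsets = np.empty(T)
    t = 0.0
    report_set = set(int(r) for r in report_after)
    report_onsets = []
    for i in range(T):
        onsets[i] = t
        t += config.soa
        if i in report_set:
            report_onsets.append(t)
            t += config.report_period_duration
    duration = t + config.rest_tail

    return StimulusSequence(
        values=values, hidden_p=hidden,
        change_points=np.asarray(change_points, dtype=int),
        report_trials=np.asarray(report_after, dtype=int),
        onsets=onsets, report_onsets=np.asarray(report_onsets),
        duration=float(duration), session_id=session_id, config=config)


def generate_session_set(config: TaskConfig,
                         seed: int | np.random.Generator | None = None
                         ) -> list[StimulusSequence]:
    """Generate all sessions of one simulated participant."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed)
    return [generate_sequence(config, rng, session_id=i) for i in range(config.n_sessions)]


def generate_value_matrix(config: TaskConfig, n_sequences: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_sequences`` stimulus-value rows from the task process.

    Used for the sequence-permutation null: only the binary values matter
    there (timing is taken from the session being scored).
    """
    T = config.n_stimuli_per_session
    out = np.empty((n_sequences, T), dtype=np.int8)
    for i in range(n_sequences):
        out[i] = generate_sequence(config, rng).values
    return out


# ---------------------------------------------------------------------------
# BIDS-style events table round trip

def sequence_to_events(seq: StimulusSequence) -> pd.DataFrame:
    cfg = seq.config
    is_change = np.zeros(seq.n_trials, dtype=bool)
    is_change[seq.change_points] = True
    is_report = np.zeros(seq.n_trials, dtype=bool)
    is_report[seq.report_trials] = True
    return pd.DataFrame({
        "onset": seq.onsets,
        "duration": np.full(seq.n_trials, cfg.stimulus_duration),
        "trial_index": np.arange(seq.n_trials),
        "stimulus": np.where(seq.values == 1, "A", "B"),
        "hidden_p": seq.hidden_p,
        "is_change_point": is_change.astype(int),
        "is_report": is_report.astype(int),
    })


def sequence_from_events(df: pd.DataFrame, config: TaskConfig | None = None,
                         session_id: int = 0) -> StimulusSequence:
    """Rebuild a :class:`StimulusSequence` from an events table.

    Report-period onsets are reconstructed from the task timing parameters.
    """
    cfg = config or TaskConfig()
    df = df.sort_values("trial_index")
    onsets = df["onset"].to_numpy(float)
    report_trials = np.flatnonzero(df["is_report"].to_numpy(int))
    report_onsets = onsets[report_trials] + cfg.soa
    duration = float(onsets[-1] + cfg.soa
                     + (cfg.report_period_duration if (report_trials.size and
                                                       report_trials[-1] == len(df) - 1) else 0.0)
                     + cfg.rest_tail)
    return StimulusSequence(
        values=(df["stimulus"].to_numpy() == "A").astype(np.int8),
        hidden_p=df["hidden_p"].to_numpy(float),
        change_points=np.flatnonzero(df["is_change_point"].to_numpy(int)),
        report_trials=report_trials,
        onsets=onsets, report_onsets=report_onsets,
        duration=duration, session_id=session_id, config=cfg)
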