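"""Bayes-optimal (ideal observer) estimation of the hidden probability.

The observer tracks a posterior distribution over the hidden Bernoulli
probability ``h_t`` on a fixed grid, updating it iteratively: the previous
posterior is mixed with the resampling prior according to the hazard rate
(the change-point transition kernel), then multiplied by the Bernoulli
likelihood of the new stimulus and renormalized.

Two scalar summaries drive the encoding models downstream:

* the probability estimate ``p_hat``, the mean of the distribution, and
* the confidence, defined as ``-log SD`` of the distribution (log precision
  up to a factor of two), in natural-log units.

By default both are read out from the *predictive* distribution held before
observing the trial's stimulus, so that the Shannon surprise
``-log p(s_t)`` of that stimulus is defined from the same quantity. The
post-update (filtered) convention is available via ``timing="posterior"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError, NumericalError
from .task import StimulusSequence

__all__ = ["ObserverConfig", "PosteriorTrace", "NormativeEstimates",
           "run_ideal_observer", "batch_observer_estimates",
           "compute_event_quantities", "brute_force_posterior"]


@dataclass(frozen=True)
class ObserverConfig:
    """Grid, hazard rate, and resampling prior of the ideal observer."""

    grid: np.ndarray
    hazard: float = 1.0 / 75.0
    resample_prior: np.ndarray | None = None

    @classmethod
    def default(cls, p_support: tuple[float, float] = (0.1, 0.9),
                n_points: int = 100, hazard: float = 1.0 / 75.0) -> "ObserverConfig":
        """Uniform prior on ``n_points`` equally spaced values spanning the support."""
        grid = np.linspace(p_support[0], p_support[1], n_points)
        return cls(grid=grid, hazard=hazard)

    def prior(self) -> np.ndarray:
        if self.resample_prior is None:
            return np.full(self.grid.size, 1.0 / self.grid.size)
        return np.asarray(self.resample_prior, dtype=float)

    def validate(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ConfigurationError("grid must contain >= 2 strictly increasing values")
        if not 0.0 <= self.hazard < 1.0:
            raise ConfigurationError(f"hazard must lie in [0, 1), got {self.hazard}")
        p = self.prior()
        if p.shape != g.shape or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ConfigurationError("resample_prior must be a distribution over the grid")


@dataclass
class PosteriorTrace:
    """Grid posteriors per trial.

    ``posterior[t]`` is p(h_t | s_1:t) (after observing trial t);
    ``predictive[t]`` is the distribution held before observing trial t,
    i.e. the hazard-mixed carry-over of ``posterior[t-1]`` (the prior itself
    for t = 0).
    """

    grid: np.ndarray
    posterior: np.ndarray
    predictive: np.ndarray


@dataclass
class NormativeEstimates:
    """Per-trial scalar read-outs of the observer (natural-log units)."""

    p_hat: np.ndarray
    confidence: np.ndarray
    surprise: np.ndarray
    entropy: np.ndarray


def _moments(dist: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = dist @ grid
    var = dist @ grid ** 2 - mean ** 2
    return mean, np.sqrt(np.maximum(var, 0.0))


def _filter(values: np.ndarray, obs: ObserverConfig, keep_trace: bool):
    """Vectorized grid filter over a batch of sequences (batch, T)."""
    obs.validate()
    grid = np.asarray(obs.grid, dtype=float)
    prior = obs.prior()
    h = obs.hazard
    B, T = values.shape
    post = np.broadcast_to(prior, (B, grid.size)).copy()
    p_pred = np.empty((B, T))
    sd_pred = np.empty((B, T))
    p_filt = np.empty((B, T))
    sd_filt = np.empty((B, T))
    posts = np.empty((B, T, grid.size)) if keep_trace else None
    preds = np.empty((B, T, grid.size)) if keep_trace else None
    lik_a = grid
    lik_b = 1.0 - grid
    for t in range(T):
        pred = (1.0 - h) * post + h * prior
        p_pred[:, t], sd_pred[:, t] = _moments(pred, grid)
        lik = np.where(values[:, t, None] == 1, lik_a, lik_b)
        post = pred * lik
        z = post.sum(axis=1, keepdims=True)
        if np.any(z <= 0.0):
            bad = int(np.argmax(z.ravel() <= 0.0))
            raise NumericalError(f"posterior degenerated to zero at trial {t} (sequence {bad})")
        post = post / z
        p_filt[:, t], sd_filt[:, t] = _moments(post, grid)
        if keep_trace:
            preds[:, t] = pred
            posts[:, t] = post
    return grid, p_pred, sd_pred, p_filt, sd_filt, posts, preds


def _estimates(values, p_pred, sd_pred, p_use, sd_use):
    p_stim = np.where(values == 1, p_pred, 1.0 - p_pred)
    surprise = -np.log(p_stim)
    entropy = -p_pred * np.log(p_pred) - (1.0 - p_pred) * np.log(1.0 - p_pred)
    confidence = -np.log(sd_use)
    return NormativeEstimates(p_hat=p_use, confidence=confidence,
                              surprise=surprise, entropy=entropy)


def run_ideal_observer(seq: StimulusSequence | np.ndarray, obs: ObserverConfig,
                       timing: str = "predictive"
                       ) -> tuple[PosteriorTrace, NormativeEstimates]:
    """Run the grid filter on one sequence.

    ``timing`` selects the read-out convention for ``p_hat`` and
    ``confidence``: ``"predictive"`` (before observing s_t, default) or
    ``"posterior"`` (after the update). Surprise and entropy are always
    computed from the predictive distribution, which is what makes
    ``-log p(s_t)`` well defined.
    """
    if timing not in ("predictive", "posterior"):
        raise ConfigurationError(f"unknown timing convention {timing!r}")
    values = seq.values if isinstance(seq, StimulusSequence) else np.asarray(seq)
    values = np.atleast_1d(values).astype(int)
    grid, p_pred, sd_pred, p_filt, sd_filt, posts, preds = _filter(
        values[None, :], obs, keep_trace=True)
    use_pred = timing == "predictive"
    est = _estimates(values[None, :], p_pred, sd_pred,
                     p_pred if use_pred else p_filt,
                     sd_pred if use_pred else sd_filt)
    trace = PosteriorTrace(grid=grid, posterior=posts[0], predictive=preds[0])
    return trace, NormativeEstimates(p_hat=est.p_hat[0], confidence=est.confidence[0],
                                     surprise=est.surprise[0], entropy=est.entropy[0])


def batch_observer_estimates(values: np.ndarray, obs: ObserverConfig,
                             timing: str = "predictive",
                             keep_trace: bool = False):
    """Observer estimates for many sequences at once (rows of ``values``).

    Returns a :class:`NormativeEstimates` whose fields are (batch, T)
    arrays, plus the predictive traces when ``keep_trace`` is set (needed by
    the posterior-expectation encoding variant).
    """
    values = np.asarray(values, dtype=int)
    grid, p_pred, sd_pred, p_filt, sd_filt, posts, preds = _filter(
        values, obs, keep_trace=keep_trace)
    use_pred = timing == "predictive"
    est = _estimates(values, p_pred, sd_pred,
                     p_pred if use_pred else p_filt,
                     sd_pred if use_pred else sd_filt)
    return (est, preds) if keep_trace else (est, None)


def compute_event_quantities(p_prev, stimulus):
    """Shannon surprise and outcome entropy implied by an estimate.

    ``surprise = -ln p(s)`` with ``p(s) = p_prev`` for A (1) and
    ``1 - p_prev`` for B (0); ``entropy`` is the binary entropy of
    ``p_prev``. Natural-log units (nats).
    """
    p = np.asarray(p_prev, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise DomainError("p_prev must lie strictly inside (0, 1)")
    s = np.asarray(stimulus)
    p_s = np.where(s == 1, p, 1.0 - p)
    surprise = -np.log(p_s)
    entropy = -p * np.log(p) - (1.0 - p) * np.log(1.0 - p)
    if surprise.ndim == 0:
        return float(surprise), float(entropy)
    return surprise, entropy


def brute_force_posterior(values: np.ndarray, obs: ObserverConfig) -> np.ndarray:
    """Exact posterior over the grid by change-point enumeration.

    Sums over all 2^(T-1) change-point configurations, weighting each by
    hazard^(#changes) * (1-hazard)^(#non-changes) and marginalizing each
    completed segment's probability over the resampling prior. Reference
    implementation for tests; refuses prefixes longer than 12 trials.
    """
    values = np.asarray(values, dtype=int).ravel()
    T = values.size
    if T > 12:
        raise DomainError("brute-force enumeration limited to sequences of length <= 12")
    if T == 0:
        raise DomainError("need at least one observation")
    obs.validate()
    grid = np.asarray(obs.grid, dtype=float)
    prior = obs.prior()
    h = obs.hazard
    lik = np.where(values[:, None] == 1, grid, 1.0 - grid)   # (T, G)

    # segment likelihood products for every (start, stop)
    seg = {}
    for i in range(T):
        prod = np.ones_like(grid)
        for j in range(i, T):
            prod = prod * lik[j]
            seg[(i, j + 1)] = prod.copy()

    acc = np.zeros_like(grid)
    for mask in range(1 << (T - 1)):
        changes = [t + 1 for t in range(T - 1) if (mask >> t) & 1]
        bounds = [0] + changes + [T]
        c = len(changes)
        w = (h ** c) * ((1.0 - h) ** (T - 1 - c))
        for a, b in zip(bounds[:-2], bounds[1:-1]):
            w *= float(prior @ seg[(a, b)])
        acc += w * prior * seg[(bounds[-2], bounds[-1])]
    total = acc.sum()
    if total <= 0.0:
        raise NumericalError("enumeration produced an all-zero posterior")
    return acc / total
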