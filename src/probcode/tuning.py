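"""Tuning-curve reconstruction and shape characterization.

A unit's tuning curve is the weighted sum of the basis functions with the
fitted interest weights. Three shape measures describe each curve:

* location of the maximum, classed non-extreme when it falls at least 20%
  of the domain span away from either bound;
* non-monotonicity n(f) = 1 - |f(b) - f(a)| / (f_max - f_min), which is 0
  exactly for monotonic curves (m(f) = 1 - n(f) is the monotonicity index);
* nonlinearity nu(f) = 1 - R2 of an ordinary least-squares line, the
  fraction of curve variance a linear fit leaves unexplained.

Peaks are counted on the min-max-normalized curve with minimum height 0.7
and minimum topographic prominence 0.125 (endpoints are not peaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .basis import BasisSet
from .encoding import DEFAULT_LAMBDA, fit_encoding
from .errors import ConfigurationError
from .stats import TestResult, fdr_bh, ttest

__all__ = ["TuningCurve", "CurveCharacterization", "reconstruct_tuning_curve",
           "characterize_curve", "select_units_of_interest",
           "split_half_reliability", "summarize_participant",
           "group_characterization_summary"]

DEFAULT_GRID_POINTS = 201
PEAK_MIN_HEIGHT = 0.7
PEAK_MIN_PROMINENCE = 0.125
EXTREME_MARGIN = 0.2


@dataclass
class TuningCurve:
    grid: np.ndarray
    values: np.ndarray
    domain: tuple[float, float]


@dataclass
class CurveCharacterization:
    argmax_x: float
    non_extreme: bool
    non_monotonicity: float
    monotonicity: float
    nonlinearity: float
    ss_lin_res: float
    ss_tot: float
    r2_lin: float
    n_peaks: int
    degenerate: bool


def reconstruct_tuning_curve(weights: np.ndarray, basis: BasisSet,
                             n_grid: int = DEFAULT_GRID_POINTS) -> TuningCurve:
    """Curve values sum_i w_i f_i(x) on an evaluation grid over the domain."""
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != basis.K:
        raise ConfigurationError(
            f"got {w.size} weights for a basis of K = {basis.K}")
    grid = np.linspace(basis.domain[0], basis.domain[1], n_grid)
    return TuningCurve(grid=grid, values=basis(grid) @ w, domain=basis.domain)


def characterize_curve(curve: TuningCurve) -> CurveCharacterization:
    f = np.asarray(curve.values, dtype=float)
    x = np.asarray(curve.grid, dtype=float)
    a, b = curve.domain
    span = b - a
    f_min, f_max = f.min(), f.max()
    degenerate = f_max == f_min
    i_max = int(np.argmax(f))                 # ties resolve to lowest x
    argmax_x = float(x[i_max])
    non_extreme = (a + EXTREME_MARGIN * span <= argmax_x
                   <= b - EXTREME_MARGIN * span) and not degenerate

    if degenerate:
        return CurveCharacterization(argmax_x=argmax_x, non_extreme=False,
                                     non_monotonicity=0.0, monotonicity=1.0,
                                     nonlinearity=0.0, ss_lin_res=0.0,
                                     ss_tot=0.0, r2_lin=1.0, n_peaks=0,
                                     degenerate=True)

    n = 1.0 - abs(f[-1] - f[0]) / (f_max - f_min)

    slope, intercept = np.polyfit(x, f, 1)
    resid = f - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2_lin = 1.0 - ss_res / ss_tot
    nu = min(max(1.0 - r2_lin, 0.0), 1.0)

    norm = (f - f_min) / (f_max - f_min)
    peaks, _ = find_peaks(norm, height=PEAK_MIN_HEIGHT,
                          prominence=PEAK_MIN_PROMINENCE)

    return CurveCharacterization(argmax_x=argmax_x, non_extreme=bool(non_extreme),
                                 non_monotonicity=float(n),
                                 monotonicity=float(1.0 - n),
                                 nonlinearity=float(nu), ss_lin_res=ss_res,
                                 ss_tot=ss_tot, r2_lin=float(r2_lin),
                                 n_peaks=int(peaks.size), degenerate=False)


def select_units_of_interest(r2_observed: np.ndarray, r2_null: np.ndarray,
                             alpha: float = 0.05):
    """Empirical-null p-values with BH-FDR selection.

    p = (1 + #{null >= observed}) / (1 + n_null), then Benjamini-Hochberg
    at level ``alpha``. Returns (selected mask, raw p-values).
    """
    null = np.sort(np.asarray(r2_null, dtype=float).ravel())
    if null.size == 0:
        raise ConfigurationError("empirical null distribution is empty")
    obs = np.asarray(r2_observed, dtype=float)
    n_ge = null.size - np.searchsorted(null, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + null.size)
    mask, _ = fdr_bh(p, alpha)
    return mask, p


def split_half_reliability(design, Y: np.ndarray, unit_mask: np.ndarray,
                           penalty: float = DEFAULT_LAMBDA,
                           halves=((0, 1), (2, 3))) -> float:
    """Pearson r between interest weights fitted on two session halves.

    ``design`` is the full preprocessed :class:`DesignMatrix`; ``Y`` the row
    aligned preprocessed data. Default halves are sessions {1,2} vs {3,4}.
    """
    if design.n_sessions < len(halves[0]) + len(halves[1]):
        raise ConfigurationError("need at least 2 sessions per half")
    mask = design.interest_mask
    ws = []
    for half in halves:
        rows = np.concatenate([np.arange(*design.session_bounds[i]) for i in half])
        fit = fit_encoding(design.X[rows], Y[rows][:, unit_mask], penalty)
        ws.append(fit.weights[mask].ravel(order="F"))
    return float(pearsonr(ws[0], ws[1]).statistic)


def summarize_participant(chars: list[CurveCharacterization]) -> dict:
    """Participant-level summary of curve characterizations.

    Degenerate (constant) curves are excluded.
    """
    ok = [c for c in chars if not c.degenerate]
    if not ok:
        raise ConfigurationError("no non-degenerate curves to summarize")
    return {
        "prop_non_extreme": float(np.mean([c.non_extreme for c in ok])),
        "mean_non_monotonicity": float(np.mean([c.non_monotonicity for c in ok])),
        "mean_nonlinearity": float(np.mean([c.nonlinearity for c in ok])),
        "prop_multipeak": float(np.mean([c.n_peaks > 1 for c in ok])),
        "n_units": len(ok),
    }


def group_characterization_summary(group_a: list[list[CurveCharacterization]],
                                   group_b: list[list[CurveCharacterization]]
                                   ) -> dict:
    """Two-sample comparison of tuning-curve shape between conditions.

    ``group_a``/``group_b`` hold per-participant characterization lists
    (e.g. probability vs confidence). Returns per-participant summaries
    and independent two-tailed t-tests on each measure.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ConfigurationError("need at least 2 participants per condition")
    sa = [summarize_participant(c) for c in group_a]
    sb = [summarize_participant(c) for c in group_b]
    tests: dict[str, TestResult] = {}
    for key in ("prop_non_extreme", "mean_non_monotonicity",
                "mean_nonlinearity", "prop_multipeak"):
        xa = np.array([s[key] for s in sa])
        xb = np.array([s[key] for s in sb])
        tests[key] = ttest(xa, kind="two_sample", other=xb)
    return {"group_a": sa, "group_b": sb, "tests": tests}
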