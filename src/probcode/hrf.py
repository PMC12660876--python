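"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .errors import ConfigurationError

__all__ = ["HrfSpec"]


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma HRF: a positive peak minus a scaled undershoot.

    Defaults are the canonical shape (peak at 6 s, undershoot at 16 s, unit
    dispersions, undershoot ratio 1/6, 32-s support) sampled at ``dt``
    seconds, the sub-TR resolution on which event impulses are placed.
    The kernel is normalized to unit peak; overall scale is absorbed by the
    regression weights.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0
    dt: float = 0.1

    def validate(self) -> None:
        if self.length < 24.0:
            raise ConfigurationError(f"HRF length must be >= 24 s, got {self.length}")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if np.trapezoid(self.kernel(), dx=self.dt) <= 0:
            raise ConfigurationError("HRF kernel must integrate to a positive value")

    def kernel(self) -> np.ndarray:
        t = np.arange(0.0, self.length, self.dt)
        peak = gamma_dist.pdf(t, self.peak_delay / self.peak_dispersion,
                              scale=self.peak_dispersion)
        under = gamma_dist.pdf(t, self.undershoot_delay / self.undershoot_dispersion,
                               scale=self.undershoot_dispersion)
        h = peak - self.undershoot_ratio * under
        return h / h.max()
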