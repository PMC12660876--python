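"""Basis sets and encoding-model specifications.

The versatile encoding model expresses a unit's tuning curve as a weighted
sum of K basis functions of the encoded estimate (Gaussian by default,
sigmoid as an alternative). Centers are placed with equal spacing between
consecutive centers and between the domain bounds and the outermost
centers, i.e. mu_i = a + i*(b-a)/(K+1) for i = 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["BasisSet", "make_basis", "EncodingSpec"]

PROBABILITY_DOMAIN = (0.0, 1.0)
CONFIDENCE_DOMAIN = (1.1, 2.6)
# Widths quoted for K = 10; for other K the width is scaled with the center
# spacing so that the sum of the basis functions stays approximately flat
# over the domain (translation invariance).
SIGMA_10 = {"probability": 0.04, "confidence": 0.06}


@dataclass(frozen=True)
class BasisSet:
    """A family of K equally spaced basis functions on [a, b]."""

    kind: str                      # "gaussian" or "sigmoid"
    K: int
    domain: tuple[float, float]
    width: float                   # sigma (gaussian) or slope scale (sigmoid)
    amplitude: float = 1.0

    @property
    def centers(self) -> np.ndarray:
        a, b = self.domain
        return a + (b - a) * np.arange(1, self.K + 1) / (self.K + 1)

    @property
    def spacing(self) -> float:
        a, b = self.domain
        return (b - a) / (self.K + 1)

    def __call__(self, x) -> np.ndarray:
        """Evaluate all K functions at x; returns shape x.shape + (K,)."""
        x = np.asarray(x, dtype=float)
        d = x[..., None] - self.centers
        if self.kind == "gaussian":
            return self.amplitude * np.exp(-d ** 2 / (2.0 * self.width ** 2))
        return self.amplitude / (1.0 + np.exp(-d / self.width))

    def max_values(self) -> np.ndarray:
        """Maximum of each basis function over the domain (for bin validity)."""
        grid = np.linspace(self.domain[0], self.domain[1], 2001)
        return self(grid).max(axis=0)


def make_basis(kind: str, K: int, domain: tuple[float, float], width: float,
               amplitude: float = 1.0) -> BasisSet:
    if kind not in ("gaussian", "sigmoid"):
        raise ConfigurationError(f"unknown basis kind {kind!r}")
    if K < 1:
        raise ConfigurationError(f"K must be >= 1, got {K}")
    a, b = domain
    if not a < b:
        raise ConfigurationError(f"domain must satisfy a < b, got {domain}")
    if width <= 0:
        raise ConfigurationError(f"width must be positive, got {width}")
    return BasisSet(kind=kind, K=K, domain=(float(a), float(b)),
                    width=float(width), amplitude=float(amplitude))


@dataclass(frozen=True)
class EncodingSpec:
    """Which quantity a model encodes and with what tuning-curve family.

    ``model_class``: "linear" (activity proportional to the estimate),
    "versatile" (weighted sum of basis functions of the estimate), or
    "posterior_expectation" (basis responses averaged under the full
    posterior instead of evaluated at the point estimate).
    ``estimate``: "probability", "confidence", or "entropy".
    """

    model_class: str
    estimate: str
    basis: BasisSet | None = None

    def validate(self) -> None:
        if self.model_class not in ("linear", "versatile", "posterior_expectation"):
            raise ConfigurationError(f"unknown model class {self.model_class!r}")
        if self.estimate not in ("probability", "confidence", "entropy"):
            raise ConfigurationError(f"unknown estimate {self.estimate!r}")
        if self.model_class == "linear" and self.basis is not None:
            raise ConfigurationError("linear models take no basis set")
        if self.model_class != "linear" and self.basis is None:
            raise ConfigurationError(f"{self.model_class} models require a basis set")
        if self.model_class == "posterior_expectation" and self.estimate != "probability":
            raise ConfigurationError(
                "posterior_expectation applies to the posterior over probability only")

    @property
    def n_interest(self) -> int:
        return 1 if self.model_class == "linear" else self.basis.K

    @property
    def label(self) -> str:
        return f"{self.model_class}-{self.estimate}"

    @classmethod
    def default(cls, model_class: str, estimate: str, K: int = 10,
                kind: str = "gaussian") -> "EncodingSpec":
        """Study defaults: K = 10 Gaussian bases, sigma 0.04 on [0, 1] for
        probability and 0.06 on [1.1, 2.6] for confidence (scaled with the
        center spacing for other K)."""
        if model_class == "linear":
            spec = cls(model_class, estimate, None)
        else:
            if estimate == "probability":
                domain, sigma10 = PROBABILITY_DOMAIN, SIGMA_10["probability"]
            elif estimate == "confidence":
                domain, sigma10 = CONFIDENCE_DOMAIN, SIGMA_10["confidence"]
            else:
                raise ConfigurationError("versatile entropy models are not defined here")
            width = sigma10 * 11.0 / (K + 1)
            spec = cls(model_class, estimate,
                       make_basis(kind, K, domain, width))
        spec.validate()
        return spec
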