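"""Maximum-likelihood fits for the selection-free movement kernel.

A movement kernel is a gamma distribution for step lengths paired with a
von Mises distribution (mean fixed at 0) for turning angles. Both MLEs are
functions of sufficient statistics only:

* gamma: the mean and the mean log of the observations; the shape solves
  ``log k - digamma(k) = log(mean) - mean(log)`` (Newton iteration), and
  the scale is ``mean / k``.
* von Mises with known mean 0: the mean cosine ``R = mean(cos theta)``;
  the concentration solves ``I1(kappa)/I0(kappa) = R``. ``R <= 0`` gives
  ``kappa = 0`` (no concentration); ``R`` near 1 is capped at
  ``KAPPA_MAX`` to keep the degenerate all-same-angle case finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, i0e, i1e, polygamma

#: Documented cap on the von Mises concentration (degenerate samples).
KAPPA_MAX: float = 500.0


@dataclass(frozen=True)
class GammaParams:
    """Gamma step-length distribution: shape ``k`` and scale ``theta``."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"gamma shape must be finite and > 0, got {self.shape}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"gamma scale must be finite and > 0, got {self.scale}")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass(frozen=True)
class VonMisesParams:
    """Von Mises turning-angle distribution with mean fixed at 0."""

    kappa: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= KAPPA_MAX):
            raise ValueError(f"kappa must be in [0, {KAPPA_MAX}], got {self.kappa}")


@dataclass(frozen=True)
class MovementKernel:
    """Selection-free movement kernel: gamma step lengths, von Mises turns."""

    gamma: GammaParams
    vonmises: VonMisesParams


def fit_gamma_from_stats(mean: float, mean_log: float) -> GammaParams:
    """Gamma MLE from the sufficient statistics (mean, mean of logs)."""
    s = np.log(mean) - mean_log
    if not np.isfinite(s) or s <= 0:
        raise ValueError(
            "degenerate sufficient statistics (zero sample variance?): "
            f"log(mean) - mean(log) = {s}"
        )
    # Standard closed-form starting value, then Newton on the shape equation.
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        f = np.log(k) - digamma(k) - s
        if abs(f) < 1e-12:
            break
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        k = k_new
    if abs(np.log(k) - digamma(k) - s) > 1e-10:
        raise RuntimeError("gamma shape iteration did not converge")
    return GammaParams(shape=float(k), scale=float(mean / k))


def fit_gamma(values) -> GammaParams:
    """Gamma MLE for positive observations (n >= 10)."""
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("gamma fit requires strictly positive finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: gamma shape is unbounded")
    return fit_gamma_from_stats(float(np.mean(x)), float(np.mean(np.log(x))))


def mean_resultant_length(angles) -> float:
    """Mean cosine about mean 0 (the von Mises sufficient statistic)."""
    return float(np.mean(np.cos(np.asarray(angles, dtype=float))))


def _A(kappa: float) -> float:
    """Ratio I1(kappa)/I0(kappa), computed with exponentially scaled Bessels."""
    return i1e(kappa) / i0e(kappa)


def fit_vonmises_from_stats(r_bar: float) -> VonMisesParams:
    """Von Mises (mean 0) MLE from the mean cosine."""
    if r_bar <= 0.0:
        return VonMisesParams(kappa=0.0)
    if _A(KAPPA_MAX) <= r_bar:
        return VonMisesParams(kappa=KAPPA_MAX)
    kappa = brentq(lambda k: _A(k) - r_bar, 0.0, KAPPA_MAX, xtol=1e-12, rtol=1e-14)
    return VonMisesParams(kappa=float(kappa))


def fit_vonmises(angles) -> VonMisesParams:
    """Von Mises (mean fixed at 0) MLE for angles in radians (n >= 10)."""
    theta = np.asarray(angles, dtype=float)
    if theta.size < 10:
        raise ValueError(f"need at least 10 observations, got {theta.size}")
    return fit_vonmises_from_stats(mean_resultant_length(theta))


def sample_kernel(kernel: MovementKernel, n: int, rng: np.random.Generator):
    """Draw ``n`` (step length, turning angle) pairs from a kernel."""
    sl = rng.gamma(kernel.gamma.shape, kernel.gamma.scale, size=n)
    if kernel.vonmises.kappa == 0.0:
        ta = rng.uniform(-np.pi, np.pi, size=n)
    else:
        ta = rng.vonmises(0.0, kernel.vonmises.kappa, size=n)
    return sl, ta
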