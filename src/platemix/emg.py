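"""Exponentially-modified Gaussian (EMG) density, moments and sampling.

The EMG is the convolution of a Normal(mu, sigma^2) with an Exponential of
rate lam, a right-skewed family that fits forward-scatter (FSC) event
distributions of platelet subpopulations well: the Gaussian part captures
instrument/size spread, the exponential tail the skew toward larger objects.

Parameterization is (mu, sigma, lam) with lam the *rate* of the exponential
part, so the component mean is mu + 1/lam and its variance sigma^2 + 1/lam^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import special, stats

from .errors import InputError, ParameterError

__all__ = [
    "EMGComponent",
    "emg_logpdf",
    "emg_pdf",
    "emg_moments",
    "emg_rvs",
    "moment_init",
]


@dataclass(frozen=True)
class EMGComponent:
    """One EMG component: Gaussian location/scale plus exponential rate.

    Attributes
    ----------
    mu : float
        Gaussian location, FSC arbitrary units.
    sigma : float
        Gaussian scale, FSC a.u.; must be positive and finite.
    lam : float
        Exponential rate, 1/a.u.; must be positive and finite.
    """

    mu: float
    sigma: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"EMG parameter {name!r} must be finite, got {v}")
        if self.sigma <= 0:
            raise ParameterError(f"EMG sigma must be > 0, got {self.sigma}")
        if self.lam <= 0:
            raise ParameterError(f"EMG lam must be > 0, got {self.lam}")

    @property
    def mean(self) -> float:
        return self.mu + 1.0 / self.lam

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.mu, self.sigma, self.lam)


def emg_logpdf(x, comp: EMGComponent):
    """Log-density of the EMG, stable over the whole (mu, sigma, lam) range.

    Uses the scaled complementary error function (erfcx) in the regime where
    erfc underflows, which keeps the evaluation accurate up to lam*sigma of
    order 1e3 (near-Gaussian limit) and far into both tails.
    """
    return _emg_logpdf_raw(np.asarray(x, dtype=float), comp.mu, comp.sigma, comp.lam)


def _emg_logpdf_raw(x: np.ndarray, mu: float, sigma: float, lam: float) -> np.ndarray:
    # f(x) = lam/2 * exp[(lam/2)(2 mu + lam sigma^2 - 2 x)] * erfc(z),
    # z = (mu + lam sigma^2 - x) / (sqrt(2) sigma).
    # For z >= 0: log f = log(lam/2) - (x-mu)^2/(2 sigma^2) + log erfcx(z)
    # (the exp and the e^{z^2} inside erfcx cancel analytically).
    z = (mu + lam * sigma * sigma - x) / (np.sqrt(2.0) * sigma)
    out = np.empty_like(z)
    pos = z >= 0
    if np.any(pos):
        out[pos] = (
            np.log(lam / 2.0)
            - (x[pos] - mu) ** 2 / (2.0 * sigma * sigma)
            + np.log(special.erfcx(z[pos]))
        )
    if np.any(~pos):
        # erfc(z) in (1, 2]: evaluate directly; the exponent stays in log space.
        a = lam * (mu - x[~pos]) + 0.5 * (lam * sigma) ** 2
        out[~pos] = np.log(lam / 2.0) + a + np.log(special.erfc(z[~pos]))
    return out


def emg_pdf(x, comp: EMGComponent):
    """EMG probability density at ``x`` (1/a.u.)."""
    return np.exp(emg_logpdf(x, comp))


def emg_moments(comp: EMGComponent) -> Tuple[float, float, float]:
    """Return (mean, variance, skewness) of the EMG in closed form."""
    m = comp.mu + 1.0 / comp.lam
    v = comp.sigma**2 + 1.0 / comp.lam**2
    sl = comp.sigma * comp.lam
    skew = (2.0 / sl**3) * (1.0 + 1.0 / sl**2) ** -1.5
    return (m, v, skew)


def emg_rvs(comp: EMGComponent, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` EMG variates: Normal(mu, sigma) + Exponential(1/lam)."""
    return comp.mu + comp.sigma * rng.standard_normal(size) + rng.exponential(
        1.0 / comp.lam, size
    )


def moment_init(values) -> EMGComponent:
    """Method-of-moments EMG estimate used to initialize EM.

    With sample SD ``s`` and skewness ``g1``, set k = (g1/2)^(1/3); then
    lam = 1/(s k), sigma^2 = s^2 (1 - k^2), mu = mean - s k. When the sample
    is left-skewed or the inversion leaves no Gaussian variance (k >= 1), a
    neutral half-and-half split of the variance is returned instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise InputError(f"moment_init needs >= 10 values, got {x.size}")
    mean = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    if s <= 0:
        raise InputError("moment_init needs non-constant values")
    g1 = float(stats.skew(x, bias=True))
    if g1 > 0:
        k = (g1 / 2.0) ** (1.0 / 3.0)
        if k < 1.0:
            return EMGComponent(mu=mean - s * k, sigma=s * np.sqrt(1.0 - k * k), lam=1.0 / (s * k))
    return EMGComponent(mu=mean - s / 2.0, sigma=s / np.sqrt(2.0), lam=2.0 / s)
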