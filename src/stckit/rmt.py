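"""Random-matrix-theory predictions for sample-covariance spectra.

These closed forms describe the sampling structure that makes significance
testing hard with strongly correlated stimuli: the Marčenko–Pastur bulk of a
white sample covariance, the bias/variance/eigenvector-mixing of outstanding
("spiked") eigenvalues of a spiked-Wishart sample covariance, the shifted
Wigner semicircle with an outstanding mode for element-shuffled matrices, and
the resulting fold-improvement in required spike counts when the coherent
mode is projected out before testing.

Notation: ``c = D/N`` is the aspect ratio (stimulus dimensionality over
sample count); ``ell`` denotes a population eigenvalue on the scale where the
bulk is 1.  A spike is *supercritical* (detectable above the bulk) when
``ell > 1 + sqrt(c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "SpikedWishartParams",
    "MarchenkoPastur",
    "WignerShifted",
    "SpikedEigStats",
    "mp_density",
    "wigner_shifted_spectrum",
    "spiked_eigenvalue_stats",
    "eigenvector_overlap",
    "sensitivity_improvement",
    "bbp_threshold",
]


@dataclass(frozen=True)
class SpikedWishartParams:
    """Spiked-Wishart ensemble: identity population plus a few spikes.

    ``spikes`` are population eigenvalues > 1 (relative to the unit bulk);
    their count is assumed small compared with D.
    """

    D: int
    N: int
    spikes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.D < 2 or self.N < 1:
            raise ValueError("need D >= 2 and N >= 1")
        if any(s <= 1 for s in self.spikes):
            raise ValueError("spike eigenvalues must exceed the unit bulk")

    @property
    def c(self) -> float:
        return self.D / self.N


def bbp_threshold(c: float) -> float:
    """Detectability threshold: spikes below 1 + sqrt(c) merge with the bulk."""
    return 1.0 + np.sqrt(c)


@dataclass(frozen=True)
class MarchenkoPastur:
    """Marčenko–Pastur law at aspect ratio c (bulk variance 1)."""

    c: float

    @property
    def support(self) -> tuple[float, float]:
        lm = (1.0 - np.sqrt(self.c)) ** 2
        lp = (1.0 + np.sqrt(self.c)) ** 2
        return lm, lp

    def pdf(self, x):
        """Density of the absolutely continuous part (mass 1 for c <= 1)."""
        x = np.asarray(x, dtype=float)
        lm, lp = self.support
        out = np.zeros_like(x)
        inside = (x > lm) & (x < lp) & (x > 0)
        xi = x[inside]
        out[inside] = np.sqrt((lp - xi) * (xi - lm)) / (2.0 * np.pi * self.c * xi)
        if self.c > 1:
            # renormalize continuous part; a point mass 1 - 1/c sits at zero
            out /= self.c
        return out

    def cdf(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lm, lp = self.support
        out = np.empty_like(x)
        for i, xi in enumerate(x):
            if xi <= lm:
                out[i] = 0.0
            elif xi >= lp:
                out[i] = 1.0
            else:
                out[i], _ = integrate.quad(self.pdf, lm, xi, limit=200)
        if self.c > 1:
            out = (1.0 - 1.0 / self.c) + out
            out = np.clip(out, 0.0, 1.0)
        return out if out.size > 1 else float(out[0])


def mp_density(c: float) -> MarchenkoPastur:
    """Marčenko–Pastur density and support edges for aspect ratio ``c``.

    The limiting eigenvalue law of a sample covariance when the population
    covariance is the identity.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    return MarchenkoPastur(c)


@dataclass(frozen=True)
class WignerShifted:
    """Semicircle bulk plus outstanding mode for mean-shifted Wigner matrices.

    For a D x D symmetric matrix with i.i.d. elements of mean ``mu`` and
    variance ``sigma**2``, the bulk follows the semicircle of radius
    ``2 sigma sqrt(D)``; once ``mu`` exceeds ``sigma/sqrt(D)`` an outstanding
    eigenvalue detaches at ``D mu + sigma**2/mu`` whose eigenvector is the
    uniform vector (1, ..., 1)/sqrt(D).
    """

    mu: float
    sigma: float
    D: int

    @property
    def radius(self) -> float:
        return 2.0 * self.sigma * np.sqrt(self.D)

    @property
    def has_outlier(self) -> bool:
        return self.mu > self.sigma / np.sqrt(self.D)

    @property
    def outlier(self) -> float | None:
        if not self.has_outlier:
            return None
        return self.D * self.mu + self.sigma**2 / self.mu

    @property
    def outlier_vector(self) -> np.ndarray:
        return np.ones(self.D) / np.sqrt(self.D)

    def pdf(self, x):
        """Semicircle bulk density; total bulk mass (D-1)/D when the
        outstanding mode exists, 1 otherwise."""
        x = np.asarray(x, dtype=float)
        R = self.radius
        out = np.zeros_like(x)
        inside = np.abs(x) < R
        out[inside] = 2.0 * np.sqrt(R**2 - x[inside] ** 2) / (np.pi * R**2)
        if self.has_outlier:
            out *= (self.D - 1) / self.D
        return out


def wigner_shifted_spectrum(mu: float, sigma: float, D: int) -> WignerShifted:
    """Spectrum prediction for element-shuffled (mean-shifted Wigner) matrices."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if D < 2:
        raise ValueError("D must be >= 2")
    return WignerShifted(mu=mu, sigma=sigma, D=D)


@dataclass(frozen=True)
class SpikedEigStats:
    mean: float
    variance: float
    subcritical: bool


def spiked_eigenvalue_stats(params: SpikedWishartParams, r: int = 0) -> SpikedEigStats:
    """Mean and variance of the r-th outstanding sample eigenvalue.

    Supercritical spikes (``ell > 1 + sqrt(c)``) have a positively biased
    sample eigenvalue

        mean = ell * (1 + c / (ell - 1)),

    with Gaussian fluctuations of variance

        var = (2 / N) * ell**2 * (1 - c / (ell - 1)**2),

    growing with the square of the eigenvalue and inversely with the sample
    count.  Below the detectability threshold the prediction reverts to the
    bulk edge (1 + sqrt(c))**2 and is flagged ``subcritical``; the formula
    above is invalid there.
    """
    ell = sorted(params.spikes, reverse=True)[r]
    c = params.c
    if ell <= bbp_threshold(c):
        return SpikedEigStats(mean=(1.0 + np.sqrt(c)) ** 2, variance=np.nan,
                              subcritical=True)
    mean = ell * (1.0 + c / (ell - 1.0))
    var = 2.0 * ell**2 * (1.0 - c / (ell - 1.0) ** 2) / params.N
    return SpikedEigStats(mean=mean, variance=var, subcritical=False)


def eigenvector_overlap(params: SpikedWishartParams, r: int = 0) -> float:
    """Limiting squared dot product between population and sample eigenvectors.

    For a supercritical spike ``ell``,

        |<u_r, u_hat_r>|^2 -> (1 - c/(ell-1)**2) / (1 + c/(ell-1)),

    approaching 1 as c -> 0 and 0 at the detectability threshold.
    """
    ell = sorted(params.spikes, reverse=True)[r]
    c = params.c
    if ell <= bbp_threshold(c):
        return 0.0
    t = ell - 1.0
    return (1.0 - c / t**2) / (1.0 + c / t)


def sensitivity_improvement(lambda1: float, lambda2: float) -> float:
    """Predicted fold-change in the spike count needed for full recovery.

    The extremal null eigenvalues inherit the sampling variance of the
    leading stimulus eigenvalue, var ~ lambda**2 / N_s, so the minimal
    sufficient spike count scales as lambda**2.  Removing the coherent mode
    replaces lambda1 by lambda2 and the required N_s drops by

        (lambda1 / lambda2)**2.
    """
    if not (lambda1 >= lambda2 > 0):
        raise ValueError("require lambda1 >= lambda2 > 0")
    return (lambda1 / lambda2) ** 2
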