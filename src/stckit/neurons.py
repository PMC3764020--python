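"""Logistic model neurons for generating simulated spike trains.

Three linear-nonlinear model cells, each spiking as an independent Bernoulli
draw per stimulus frame:

``or2``
    Two relevant features; spike probability increases when the projection on
    *either* feature is large in absolute value (a logical OR of two logistic
    functions of |k_i . s|).  Symmetric under s -> -s.
``mono1``
    One relevant feature with a monotonic logistic nonlinearity of k . s.
``coherent1``
    Same monotonic form, but the feature carries a large component along the
    coherent mode of the stimulus ensemble.

The logistic nonlinearity maximizes noise entropy, i.e. makes the fewest
assumptions about the cell's response given the mean constraint.  Width ``w``
and soft threshold ``theta`` are expressed in units of the standard deviation
of the stimulus projection on each feature, so the same parameters describe
matched cells across stimulus ensembles with different variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .stimuli import StimulusEnsemble

__all__ = [
    "ModelNeuron",
    "spike_probability",
    "generate_spike_train",
    "match_firing_rate",
    "orthogonalize_feature",
    "save_spikes",
    "load_spikes",
]

#: default nonlinearity width and threshold, in units of projection SD
DEFAULT_W = 0.5
DEFAULT_THETA = 2.0


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ModelNeuron:
    """A logistic LN model cell.

    Parameters
    ----------
    model_type : {"or2", "mono1", "coherent1"}
    features : (K, D) ndarray
        Unit-norm relevant features; K = 2 for ``or2``, else 1.
    w, theta : float
        Nonlinearity width and soft threshold in projection-SD units.
    p_max : float
        Per-frame spike probability cap in (0, 1].
    proj_scale : (K,) ndarray or None
        Standard deviation of the stimulus projection on each feature; set
        by :meth:`calibrate` (defaults to 1, i.e. raw projections).
    """

    model_type: str
    features: np.ndarray
    w: float = DEFAULT_W
    theta: float = DEFAULT_THETA
    p_max: float = 1.0
    proj_scale: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.model_type not in {"or2", "mono1", "coherent1"}:
            raise ValueError(f"unknown model type {self.model_type!r}")
        F = np.atleast_2d(np.asarray(self.features, dtype=float))
        K_expected = 2 if self.model_type == "or2" else 1
        if F.shape[0] != K_expected:
            raise ValueError(
                f"{self.model_type} requires {K_expected} feature(s), got {F.shape[0]}"
            )
        norms = np.linalg.norm(F, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            F = F / norms[:, None]
        self.features = F
        if self.w <= 0:
            raise ValueError("w must be positive")
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError("p_max must be in (0, 1]")
        if self.proj_scale is not None:
            self.proj_scale = np.asarray(self.proj_scale, dtype=float)

    @property
    def K(self) -> int:
        return self.features.shape[0]

    @property
    def D(self) -> int:
        return self.features.shape[1]

    def calibrate(self, stimuli) -> "ModelNeuron":
        """Return a copy with proj_scale set to the empirical projection SD."""
        X = stimuli.X if isinstance(stimuli, StimulusEnsemble) else np.asarray(stimuli)
        proj = X @ self.features.T
        scale = proj.std(axis=0)
        if np.any(scale <= 0):
            raise ValueError("degenerate projection variance; cannot calibrate")
        return replace(self, proj_scale=scale)


def spike_probability(neuron: ModelNeuron, frames: np.ndarray) -> np.ndarray:
    """Per-frame spike probability; accepts a single frame or an (N, D) array."""
    X = np.atleast_2d(np.asarray(frames, dtype=float))
    if X.shape[1] != neuron.D:
        raise ValueError(f"frame dimension {X.shape[1]} != feature dimension {neuron.D}")
    scale = neuron.proj_scale if neuron.proj_scale is not None else np.ones(neuron.K)
    z = (X @ neuron.features.T) / scale  # (N, K) projections in SD units

    if neuron.model_type == "or2":
        f1 = _logistic((np.abs(z[:, 0]) - neuron.theta) / neuron.w)
        f2 = _logistic((np.abs(z[:, 1]) - neuron.theta) / neuron.w)
        p = neuron.p_max * (1.0 - (1.0 - f1) * (1.0 - f2))
    else:  # mono1, coherent1
        p = neuron.p_max * _logistic((z[:, 0] - neuron.theta) / neuron.w)
    p = np.clip(p, 0.0, 1.0)
    return p if np.asarray(frames).ndim > 1 else float(p[0])


def generate_spike_train(neuron: ModelNeuron, stimuli, seed: int | None = None) -> np.ndarray:
    """One Bernoulli draw per frame at p = spike_probability; 0/1 counts."""
    X = stimuli.X if isinstance(stimuli, StimulusEnsemble) else np.atleast_2d(stimuli)
    p = spike_probability(neuron, X)
    rng = np.random.default_rng(seed)
    return (rng.random(X.shape[0]) < p).astype(np.int64)


def match_firing_rate(neuron: ModelNeuron, stimuli, target_rate: float,
                      *, rtol: float = 1e-3) -> float:
    """Threshold theta at which the expected rate over the ensemble matches.

    The mean of spike_probability over the frames is continuous and strictly
    decreasing in theta, so the root is found by bracketing + Brent.  Returns
    theta; the caller applies it via ``replace(neuron, theta=theta)``.
    Raises if ``target_rate`` is not achievable (e.g. above p_max).
    """
    if not (0.0 < target_rate < 1.0):
        raise ValueError("target_rate must be in (0, 1)")
    X = stimuli.X if isinstance(stimuli, StimulusEnsemble) else np.atleast_2d(stimuli)

    def rate(theta: float) -> float:
        return float(np.mean(spike_probability(replace(neuron, theta=theta), X)))

    lo, hi = -10.0, 10.0
    while rate(hi) > target_rate:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError(f"target rate {target_rate} unreachable (too low)")
    while rate(lo) < target_rate:
        lo *= 2.0
        if lo < -1e4:
            raise ValueError(
                f"target rate {target_rate} unreachable for p_max={neuron.p_max}"
            )
    theta = brentq(lambda t: rate(t) - target_rate, lo, hi, xtol=1e-10, rtol=1e-12)
    achieved = rate(theta)
    if abs(achieved - target_rate) > rtol * target_rate:
        raise ValueError(
            f"rate matching failed: achieved {achieved:.5f} vs target {target_rate:.5f}"
        )
    return float(theta)


def orthogonalize_feature(v: np.ndarray, *modes: np.ndarray) -> np.ndarray:
    """Project the given directions out of v and renormalize.

    Used to build model features exactly orthogonal to the coherent mode.
    """
    v = np.asarray(v, dtype=float).copy()
    for u in modes:
        u = np.asarray(u, dtype=float)
        u = u / np.linalg.norm(u)
        v -= (u @ v) * u
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("feature lies entirely in the projected-out subspace")
    return v / n


def save_spikes(spikes: np.ndarray, path: str | Path) -> None:
    """One integer count per line; line i corresponds to frame i (0-based)."""
    np.savetxt(path, np.asarray(spikes, dtype=np.int64), fmt="%d")


def load_spikes(path: str | Path) -> np.ndarray:
    n = np.loadtxt(path, dtype=np.int64, ndmin=1)
    if np.any(n < 0):
        raise ValueError("spike counts must be nonnegative")
    return n
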