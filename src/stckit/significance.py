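"""Null distributions and significance tests for STC eigenvalues.

The null hypothesis is that spiking is independent of the stimulus.  It is
simulated by recomputing the STC difference matrix with randomized spike
trains — by default circular shifts with periodic boundary conditions, which
preserve both the total spike count and the spike train's internal temporal
structure.  Eigenvalues of the real difference matrix are then compared with
the eigenvalues pooled over many randomized realizations (the *global* test)
or with rank-ordered null distributions in an iterative projection scheme
(the *nested* test).

Two formulations are supported.  In the *zero-centered* formulation the
difference matrix dC = C_s - C_p is tested against zero.  In the
*one-centered* (pre-whitened) formulation each frame is whitened by the
inverse square root of the sample prior covariance (optionally a
pseudoinverse of order m) and the whitened spike-triggered covariance is
tested against the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stc import EigenSpectrum, covariance_pair, eigendecompose
from .stimuli import StimulusEnsemble

__all__ = [
    "NullDistribution",
    "SignificanceResult",
    "randomize_spike_train",
    "null_distribution",
    "global_test",
    "nested_test",
    "prewhitened_delta",
    "sidak_level",
    "feature_variance_test",
]


def _frames(stimuli) -> np.ndarray:
    if isinstance(stimuli, StimulusEnsemble):
        return stimuli.X
    return np.atleast_2d(np.asarray(stimuli, dtype=float))


def _spike_cov(Xc: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Spike-triggered covariance of pre-centered frames (weights = counts)."""
    idx = np.flatnonzero(n)
    w = n[idx].astype(float)
    N_s = w.sum()
    Xs = Xc[idx]
    sta = (w @ Xs) / N_s
    Xsc = Xs - sta
    if np.all(w == 1.0):
        return (Xsc.T @ Xsc) / N_s
    return (Xsc.T * w) @ Xsc / N_s


def _whitening_matrix(C_p: np.ndarray, m: int) -> np.ndarray:
    """Inverse square root of C_p restricted to its top-m eigenpairs."""
    spec = eigendecompose(C_p)
    if m < 1 or m > spec.values.shape[0]:
        raise ValueError(f"pinv order must be in 1..D, got {m}")
    w = spec.values[:m]
    if np.any(w <= 0):
        raise ValueError("retained prior-covariance eigenvalue is not positive")
    V = spec.vectors[:, :m]
    return (V / np.sqrt(w)) @ V.T


@dataclass
class NullDistribution:
    """Eigenvalues of many stimulus-independent realizations of the STC matrix.

    ``pooled`` holds all R*D eigenvalues; ``by_rank`` is (R, D) with column r
    the null series for descending rank r.  ``center`` is 0 for the
    zero-centered formulation, 1 for the pre-whitened one.
    """

    pooled: np.ndarray
    by_rank: np.ndarray
    R: int
    mode: str
    seed: int | None
    center: float = 0.0


@dataclass
class SignificanceResult:
    """Outcome of a significance test on an STC spectrum.

    ``signs[i] = +1`` marks a variance increase (eigenvalue above center),
    ``-1`` a decrease.  ``vectors[:, i]`` is the flagged eigenvector.
    """

    indices: np.ndarray
    signs: np.ndarray
    values: np.ndarray
    vectors: np.ndarray
    lower: float | np.ndarray
    upper: float | np.ndarray
    alpha: float
    method: str
    formulation: str
    n_iterations: int = 1

    @property
    def n_significant(self) -> int:
        return int(len(self.indices))


def randomize_spike_train(spikes, mode: str = "circular_shift",
                          seed=None) -> np.ndarray:
    """Randomized spike train with no stimulus association.

    ``circular_shift``: n_rnd(t) = n((t + r) mod N) for a random integer
    shift r drawn uniformly from 1..N-1 (0 and N are excluded as identity
    shifts); the spike count and the multiset of inter-spike intervals (up
    to one wrap-around interval) are exactly preserved.

    ``poisson_rate``: i.i.d. Bernoulli at the empirical spike rate; the count
    is preserved only in expectation.
    """
    n = np.asarray(spikes, dtype=np.int64)
    N = n.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "circular_shift":
        if N < 2:
            raise ValueError("circular shift requires at least 2 frames")
        r = int(rng.integers(1, N))
        return np.roll(n, -r)
    if mode == "poisson_rate":
        rate = min(n.sum() / N, 1.0)
        return (rng.random(N) < rate).astype(np.int64)
    raise ValueError(f"unknown randomization mode {mode!r}")


def null_distribution(stimuli, spikes, R: int = 1000,
                      mode: str = "circular_shift", seed=None, *,
                      formulation: str = "zero_centered",
                      pinv_order: int | None = None) -> NullDistribution:
    """Eigenvalue null distribution from R randomized spike trains.

    Each realization recomputes the spike-triggered covariance with a
    randomized spike train (the prior covariance does not depend on the
    spikes and is computed once) and eigendecomposes the corresponding
    difference (or whitened) matrix.
    """
    X = _frames(stimuli)
    N, D = X.shape
    n = np.asarray(spikes, dtype=np.int64)
    if n.shape[0] != N:
        raise ValueError("spike train length does not match frame count")
    if n.sum() < 2:
        raise ValueError("need at least 2 spikes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Xc = X - X.mean(axis=0)
    C_p = (Xc.T @ Xc) / N
    if formulation == "one_centered":
        m = D if pinv_order is None else pinv_order
        W = _whitening_matrix(C_p, m)
        center = 1.0
    elif formulation == "zero_centered":
        W = None
        center = 0.0
    else:
        raise ValueError(f"unknown formulation {formulation!r}")

    by_rank = np.empty((R, D))
    for r_i in range(R):
        n_rnd = randomize_spike_train(n, mode=mode, seed=rng)
        C_s = _spike_cov(Xc, n_rnd)
        M = W @ C_s @ W if W is not None else C_s - C_p
        by_rank[r_i] = np.linalg.eigvalsh(M)[::-1]
    return NullDistribution(
        pooled=by_rank.ravel().copy(), by_rank=by_rank, R=R, mode=mode,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        center=center,
    )


def global_test(spectrum: EigenSpectrum, null: NullDistribution,
                alpha: float = 0.01) -> SignificanceResult:
    """Flag eigenvalues outside the pooled null's central (1-alpha) interval.

    Exceedance is strict; an eigenvalue exactly at a percentile bound is
    conservatively not significant.
    """
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    pool = null.pooled
    if alpha / 2 * pool.size < 1.0:
        raise ValueError(
            f"alpha={alpha} needs more null realizations: the alpha/2 "
            f"percentile of a pool of {pool.size} is not an interior point"
        )
    lower = float(np.quantile(pool, alpha / 2))
    upper = float(np.quantile(pool, 1.0 - alpha / 2))
    vals = spectrum.values
    flagged = np.flatnonzero((vals > upper) | (vals < lower))
    return SignificanceResult(
        indices=flagged,
        signs=np.sign(vals[flagged] - null.center).astype(int),
        values=vals[flagged],
        vectors=spectrum.vectors[:, flagged],
        lower=lower, upper=upper, alpha=alpha,
        method="global",
        formulation="one_centered" if null.center == 1.0 else "zero_centered",
    )


def nested_test(stimuli, spikes, R: int = 1000, alpha: float = 0.01,
                formulation: str = "zero_centered",
                mode: str = "circular_shift", seed=None,
                pinv_order: int | None = None) -> SignificanceResult:
    """Iterative rank-ordered significance test.

    At each iteration rank-ordered null distributions are built on the
    current (possibly projected) frames.  Only the extremal ranks can
    trigger: the largest eigenvalue is flagged if it exceeds the upper bound
    of the rank-1 null, and the smallest (smallest retained, for the
    pre-whitened formulation) if it falls below its rank's lower bound.  An
    interior eigenvalue outside its rank interval is *not* flagged unless an
    extremal criterion fires.  Flagged eigenvectors are projected out of all
    frames, the prior covariance is re-estimated, and the analysis repeats
    until nothing new is flagged (at most D iterations).
    """
    X = _frames(stimuli).copy()
    N, D = X.shape
    n = np.asarray(spikes, dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    found_vecs: list[np.ndarray] = []
    found_vals: list[float] = []
    found_signs: list[int] = []
    center = 1.0 if formulation == "one_centered" else 0.0
    lower_used = upper_used = np.nan
    n_iter = 0

    for n_iter in range(1, D + 1):
        n_removed = len(found_vecs)
        Xc = X - X.mean(axis=0)
        C_p = (Xc.T @ Xc) / N
        C_s = _spike_cov(Xc, n)
        if formulation == "one_centered":
            m = (D - n_removed) if pinv_order is None else min(pinv_order, D - n_removed)
            W = _whitening_matrix(C_p, m)
            spec = eigendecompose(W @ C_s @ W)
            bottom = m - 1
        else:
            W = None
            spec = eigendecompose(C_s - C_p)
            bottom = D - 1
        null = null_distribution(
            X, n, R=R, mode=mode, seed=rng, formulation=formulation,
            pinv_order=None if W is None else m,
        )
        lo = np.quantile(null.by_rank, alpha / 2, axis=0)
        hi = np.quantile(null.by_rank, 1.0 - alpha / 2, axis=0)
        lower_used, upper_used = lo, hi

        flags = []
        if spec.values[0] > hi[0]:
            flags.append((0, +1))
        if bottom > 0 and spec.values[bottom] < lo[bottom]:
            flags.append((bottom, -1))
        if not flags:
            break
        for idx, sign in flags:
            v = spec.vectors[:, idx]
            found_vecs.append(v)
            found_vals.append(float(spec.values[idx]))
            found_signs.append(sign)
            X = X - np.outer(X @ v, v)

    K = len(found_vecs)
    return SignificanceResult(
        indices=np.arange(K),
        signs=np.array(found_signs, dtype=int),
        values=np.array(found_vals),
        vectors=np.column_stack(found_vecs) if K else np.empty((D, 0)),
        lower=lower_used, upper=upper_used, alpha=alpha,
        method="nested", formulation=formulation, n_iterations=n_iter,
    )


def prewhitened_delta(stimuli, spikes, pinv_order: int | None = None) -> np.ndarray:
    """Whitened spike-triggered covariance W C_s W, W = pinv(C_p)^(1/2).

    Equivalent to whitening each (mean-subtracted) frame by the inverse
    square root of the sample prior covariance restricted to its top
    ``pinv_order`` eigenpairs, then computing the spike-triggered
    covariance.  Under the null with infinite data this equals the identity
    on the retained subspace, so eigenvalues are compared to 1, not 0.
    """
    X = _frames(stimuli)
    N, D = X.shape
    n = np.asarray(spikes, dtype=np.int64)
    if n.shape[0] != N:
        raise ValueError("spike train length does not match frame count")
    Xc = X - X.mean(axis=0)
    C_p = (Xc.T @ Xc) / N
    m = D if pinv_order is None else pinv_order
    W = _whitening_matrix(C_p, m)
    C_s = _spike_cov(Xc, n)
    return W @ C_s @ W


def sidak_level(alpha_family: float, n_tests: int) -> float:
    """Dunn-Šidák per-test level: 1 - (1 - alpha)^(1/n).

    The family-wise error over ``n_tests`` independent tests at the returned
    level equals ``alpha_family``; for small alpha it approaches alpha/n.
    """
    if not (0.0 < alpha_family < 1.0):
        raise ValueError("alpha_family must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 1.0 - (1.0 - alpha_family) ** (1.0 / n_tests)


def feature_variance_test(stimuli, spikes, feature: np.ndarray, R: int = 1000,
                          mode: str = "circular_shift", seed=None):
    """Percentile of the spike-triggered projection variance within its null.

    Projects all frames onto a unit-norm candidate feature, computes the
    variance of the spike-triggered projections (count-weighted, about the
    spike-triggered mean), and locates it within R values obtained from
    randomized spike trains.  Returns ``(percentile, null_series)``; a
    percentile near 0 or 100 indicates the spike train carries signal about
    the feature even when no eigenvalue clears the spectrum-wide test.
    """
    feature = np.asarray(feature, dtype=float)
    if abs(np.linalg.norm(feature) - 1.0) > 1e-8:
        raise ValueError("feature must be unit-norm")
    X = _frames(stimuli)
    n = np.asarray(spikes, dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = (X - X.mean(axis=0)) @ feature

    def spike_var(counts: np.ndarray) -> float:
        idx = np.flatnonzero(counts)
        w = counts[idx].astype(float)
        xi = x[idx]
        mu = (w @ xi) / w.sum()
        return float((w @ (xi - mu) ** 2) / w.sum())

    value = spike_var(n)
    null_series = np.array([
        spike_var(randomize_spike_train(n, mode=mode, seed=rng)) for _ in range(R)
    ])
    below = np.count_nonzero(null_series < value)
    ties = np.count_nonzero(null_series == value)
    percentile = 100.0 * (below + 0.5 * ties) / R
    return percentile, null_series
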