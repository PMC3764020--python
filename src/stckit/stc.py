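"""Core spike-triggered covariance computations.

The STC method compares the covariance of stimuli that elicited a spike,
C_s, with the covariance of all stimuli, C_p; eigenvectors of the difference
dC = C_s - C_p whose eigenvalues differ significantly from zero span the
neuron's relevant subspace.  This module computes the covariance pair, the
difference matrix and its second-moment variant, the coherent-mode
projection used by the correction scheme, and a sign-conventioned
eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import StimulusEnsemble

__all__ = [
    "CovariancePair",
    "EigenSpectrum",
    "covariance_pair",
    "delta_c",
    "second_moment_difference",
    "project_out_coherent_mode",
    "eigendecompose",
]


def _as_frames(stimuli) -> np.ndarray:
    if isinstance(stimuli, StimulusEnsemble):
        return stimuli.X
    X = np.atleast_2d(np.asarray(stimuli, dtype=float))
    return X


def _as_counts(spikes, N: int) -> np.ndarray:
    n = np.asarray(spikes)
    if n.ndim != 1 or n.shape[0] != N:
        raise ValueError(
            f"spike train length {n.shape} does not match frame count {N}"
        )
    if np.any(n < 0) or not np.all(n == np.floor(n)):
        raise ValueError("spike counts must be nonnegative integers")
    return n.astype(np.int64)


@dataclass
class CovariancePair:
    """Prior and spike-triggered covariance with the spike-triggered average.

    ``sta`` is relative to the ensemble mean.  Normalization is 1/N and
    1/N_s (population-style averages); the choice is immaterial to
    eigenvectors.
    """

    C_p: np.ndarray
    C_s: np.ndarray
    sta: np.ndarray
    N: int
    N_s: int


@dataclass
class EigenSpectrum:
    """Eigenvalues (descending) with matched orthonormal eigenvectors.

    ``vectors[:, j]`` is the unit eigenvector for ``values[j]``; the sign of
    each vector is fixed by making its largest-magnitude component positive.
    """

    values: np.ndarray
    vectors: np.ndarray


def covariance_pair(stimuli, spikes) -> CovariancePair:
    """Compute C_p, C_s and the spike-triggered average.

    C_p is the covariance over all N frames (mean-subtracted, 1/N).  C_s is
    the covariance of spike-triggered frames weighted by spike count (a frame
    with n spikes contributes n times), mean-subtracted by the spike-
    triggered average, normalized by N_s.  The returned ``sta`` is the
    spike-triggered mean minus the ensemble mean.
    """
    X = _as_frames(stimuli)
    N = X.shape[0]
    n = _as_counts(spikes, N)
    N_s = int(n.sum())
    if N_s < 2:
        raise ValueError(f"need at least 2 spikes for a covariance, got {N_s}")

    mean_all = X.mean(axis=0)
    Xc = X - mean_all
    C_p = (Xc.T @ Xc) / N

    idx = np.flatnonzero(n)
    w = n[idx].astype(float)
    Xs = Xc[idx]
    sta = (w @ Xs) / N_s
    Xs_centered = Xs - sta
    C_s = (Xs_centered.T * w) @ Xs_centered / N_s
    return CovariancePair(C_p=C_p, C_s=C_s, sta=sta, N=N, N_s=N_s)


def delta_c(pair: CovariancePair) -> np.ndarray:
    """The STC difference matrix dC = C_s - C_p."""
    return pair.C_s - pair.C_p


def second_moment_difference(stimuli, spikes) -> np.ndarray:
    """Difference of second moments about the ensemble mean.

    After subtracting the ensemble mean stimulus from every frame, this is
    the spike-triggered second moment minus the prior second moment; it
    equals dC + sta sta^T, so it differs from dC only by a rank-1 PSD term
    and the *significant* eigenvectors of both agree at the subspace level.
    """
    pair = covariance_pair(stimuli, spikes)
    return delta_c(pair) + np.outer(pair.sta, pair.sta)


def project_out_coherent_mode(stimuli, u1: np.ndarray):
    """Replace every frame s by s - (u1 . s) u1.

    Output frames are exactly orthogonal to ``u1``; the operation is a
    projector, hence idempotent.  Accepts and returns the same container
    type it was given (ensemble in, ensemble out; array in, array out).
    """
    u1 = np.asarray(u1, dtype=float)
    norm = np.linalg.norm(u1)
    if norm < 1e-300:
        raise ValueError("u1 has zero norm")
    if abs(norm - 1.0) > 1e-8:
        u1 = u1 / norm
    X = _as_frames(stimuli)
    if u1.shape[0] != X.shape[1]:
        raise ValueError("u1 dimension does not match frames")
    Xp = X - np.outer(X @ u1, u1)
    if isinstance(stimuli, StimulusEnsemble):
        return StimulusEnsemble(Xp, seed=stimuli.seed, source=stimuli.source)
    return Xp


def eigendecompose(M: np.ndarray, *, sym_tol: float = 1e-8) -> EigenSpectrum:
    """Symmetric eigendecomposition, eigenvalues sorted descending.

    Sign convention: each eigenvector's largest-magnitude component is made
    positive, so decompositions are reproducible across LAPACK builds.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    scale = max(np.abs(M).max(), 1.0)
    if np.abs(M - M.T).max() > sym_tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return EigenSpectrum(values=w, vectors=V)
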