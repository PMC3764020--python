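"""From significant STC eigenvectors to relevant stimulus features.

With correlated stimuli the significant eigenvectors of dC are the relevant
features filtered by the stimulus covariance (each eigenvector is a
covariance-weighted mixture of the true features), so stimulus correlations
must be removed by multiplying with the (pseudo)inverse of the prior
covariance.  The pseudoinverse order m trades decorrelation fidelity against
noise amplification in low-variance stimulus directions; it can be chosen by
cross-validated mutual information between feature projections and spiking.

When significance is evaluated in the subspace orthogonal to the coherent
mode, the flagged eigenvectors lack their coherent-mode components.  Because
full-space and projected-space eigenvectors of dC differ *only* in their
components along the coherent mode, each projected eigenvector can be
matched to the full-space eigenvector whose non-coherent component block is
proportional to it, restoring the coherent component before decorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stc import EigenSpectrum, eigendecompose
from .stimuli import StimulusEnsemble

__all__ = [
    "FeatureSet",
    "pseudoinverse",
    "decorrelate_features",
    "select_pinv_order",
    "match_full_space_feature",
    "subspace_overlap",
    "projection_information",
]


@dataclass
class FeatureSet:
    """Raw significant eigenvectors and their decorrelated counterparts."""

    raw: np.ndarray               # (D, K)
    decorrelated: np.ndarray      # (D, K), unit-norm columns
    pinv_order: int
    space: str = "full"           # or "coherent_orthogonal"
    degenerate: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def K(self) -> int:
        return self.raw.shape[1]


def pseudoinverse(C: np.ndarray, m: int) -> np.ndarray:
    """Pseudoinverse of order m: sum over the top m eigenpairs of (1/l) u u^T."""
    C = np.asarray(C, dtype=float)
    spec = eigendecompose(C)
    D = C.shape[0]
    if not (1 <= m <= D):
        raise ValueError(f"pinv order must be in 1..{D}, got {m}")
    w = spec.values[:m]
    if np.any(w <= 0):
        raise ValueError("retained eigenvalue is not positive")
    V = spec.vectors[:, :m]
    return (V / w) @ V.T


def decorrelate_features(raw_features: np.ndarray, C_p: np.ndarray, m: int,
                         *, space: str = "full",
                         degenerate_tol: float = 1e-10) -> FeatureSet:
    """Multiply each raw eigenvector by pinv(C_p, m) and renormalize.

    A feature whose image under the pseudoinverse is (numerically) zero lies
    entirely in the discarded (D-m)-dimensional subspace; it is kept as-is
    and reported in ``degenerate`` rather than silently dropped.
    """
    raw = np.asarray(raw_features, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    P = pseudoinverse(C_p, m)
    dec = P @ raw
    norms = np.linalg.norm(dec, axis=0)
    scale = np.linalg.norm(P, ord=2) * np.linalg.norm(raw, axis=0)
    degenerate = np.flatnonzero(norms <= degenerate_tol * np.maximum(scale, 1.0))
    ok = norms > degenerate_tol * np.maximum(scale, 1.0)
    dec[:, ok] /= norms[ok]
    dec[:, ~ok] = raw[:, ~ok]
    return FeatureSet(raw=raw, decorrelated=dec, pinv_order=m, space=space,
                      degenerate=degenerate)


def _hist_info(proj: np.ndarray, spikes: np.ndarray, n_bins: int) -> float:
    """Binned mutual-information-per-spike between projections and spiking.

    I = sum_x P(x|spike) log2[P(x|spike)/P(x)] over quantile bins per
    dimension (K <= 3).  Quantile bins equalize occupancy of P(x), which
    stabilizes the tails of strongly correlated projections.
    """
    proj = np.atleast_2d(proj.T).T  # (N, K)
    N, K = proj.shape
    edges = []
    for k in range(K):
        qs = np.quantile(proj[:, k], np.linspace(0, 1, n_bins + 1))
        qs[0], qs[-1] = -np.inf, np.inf
        qs = np.unique(qs)
        edges.append(qs)
    idx = np.zeros(N, dtype=np.int64)
    stride = 1
    for k in range(K):
        b = np.searchsorted(edges[k], proj[:, k], side="right") - 1
        b = np.clip(b, 0, len(edges[k]) - 2)
        idx += stride * b
        stride *= len(edges[k]) - 1
    n_cells = stride
    p_all = np.bincount(idx, minlength=n_cells).astype(float)
    p_all /= p_all.sum()
    p_spk = np.bincount(idx, weights=spikes.astype(float), minlength=n_cells)
    tot = p_spk.sum()
    if tot <= 0:
        return 0.0
    p_spk /= tot
    nz = p_spk > 0
    return float(np.sum(p_spk[nz] * np.log2(p_spk[nz] / p_all[nz])))


def projection_information(proj: np.ndarray, spikes: np.ndarray,
                           n_bins: int, n_shuffles: int = 10,
                           rng=None) -> tuple[float, float]:
    """Shuffle-corrected information and the shuffle standard deviation.

    The raw binned estimate carries an upward sampling bias; the mean
    information of spike trains shuffled against the projections estimates
    that bias and is subtracted.  The shuffle SD doubles as the estimate's
    standard error for the plateau rule.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    raw = _hist_info(proj, spikes, n_bins)
    shuffled = np.array([
        _hist_info(proj, rng.permutation(spikes), n_bins)
        for _ in range(n_shuffles)
    ])
    return raw - float(shuffled.mean()), float(shuffled.std())


_DEFAULT_BINS = {1: 15, 2: 8, 3: 5}


def select_pinv_order(stimuli_train, spikes_train, stimuli_test, spikes_test,
                      features: np.ndarray, *, orders=None,
                      n_bins: int | None = None, n_shuffles: int = 10,
                      min_spikes_per_bin: int = 5, seed=None):
    """Cross-validated pseudoinverse order for feature decorrelation.

    For each candidate order m the raw features are decorrelated with the
    *training* prior covariance, test frames are projected onto them, and
    the binned information between projections and the test spike train is
    estimated (shuffle-corrected).  Returns ``(m_star, info_curve)`` where
    ``info_curve`` maps order -> (information, standard error).  ``m_star``
    is the smallest order within one standard error of the maximum (plateau
    rule), which is conservative when the informative band of orders is
    broad and flat.
    """
    Xtr = stimuli_train.X if isinstance(stimuli_train, StimulusEnsemble) else np.asarray(stimuli_train)
    Xte = stimuli_test.X if isinstance(stimuli_test, StimulusEnsemble) else np.asarray(stimuli_test)
    n_te = np.asarray(spikes_test, dtype=np.int64)
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    K = F.shape[1]
    if K > 3:
        raise ValueError("information estimation supports at most 3 features")
    D = Xtr.shape[1]
    if n_bins is None:
        n_bins = _DEFAULT_BINS[K]
    # coarsen binning if the test spike count cannot populate the histogram
    while n_bins > 2 and n_te.sum() < min_spikes_per_bin * n_bins**K:
        n_bins -= 1
    rng = np.random.default_rng(seed)

    Xtr_c = Xtr - Xtr.mean(axis=0)
    C_tr = (Xtr_c.T @ Xtr_c) / Xtr.shape[0]
    Xte_c = Xte - Xte.mean(axis=0)

    if orders is None:
        orders = range(1, D + 1)
    curve: dict[int, tuple[float, float]] = {}
    for m in orders:
        fs = decorrelate_features(F, C_tr, m)
        proj = Xte_c @ fs.decorrelated
        curve[m] = projection_information(proj, n_te, n_bins,
                                          n_shuffles=n_shuffles, rng=rng)
    ms = sorted(curve)
    infos = np.array([curve[m][0] for m in ms])
    best = int(np.argmax(infos))
    threshold = infos[best] - curve[ms[best]][1]
    m_star = next(m for m, i in zip(ms, infos) if i >= threshold)
    return m_star, curve


def match_full_space_feature(v_perp: np.ndarray,
                             spectrum_full: EigenSpectrum,
                             u1: np.ndarray, *,
                             min_cosine: float = 0.7,
                             exclude: set[int] | None = None,
                             value_perp: float | None = None,
                             center: float = 0.0,
                             magnitude_slack: float = 0.8):
    """Restore the coherent-mode component of a projected-space eigenvector.

    ``v_perp`` is a significant eigenvector found in the subspace orthogonal
    to the coherent mode ``u1``; ``spectrum_full`` holds the eigenvectors of
    dC in the full space.  The matching candidate is the full-space
    eigenvector whose component block orthogonal to u1 has the largest
    absolute cosine with v_perp (the two differ only along u1); a match
    below ``min_cosine`` returns ``(None, index, cosine)`` so unmatched
    features are reported, never silently dropped.

    When ``value_perp`` (the projected eigenvalue) is given, candidates are
    restricted to full-space eigenvalues of the same sign and at least
    ``magnitude_slack`` times its magnitude (relative to ``center``):
    restoring the coherent component can only add signal, so the true
    counterpart's eigenvalue is at least as extreme, whereas the projected
    noise eigenvectors — which also reappear almost unchanged in the full
    spectrum and would otherwise shadow the true match — sit strictly
    inside it.

    Returns ``(matched_vector_or_None, full_space_index, cosine)``.
    """
    u1 = np.asarray(u1, dtype=float)
    u1 = u1 / np.linalg.norm(u1)
    v = np.asarray(v_perp, dtype=float)
    v = v - (u1 @ v) * u1
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("v_perp is parallel to the coherent mode")
    v /= nv
    exclude = exclude or set()

    best_j, best_cos = -1, 0.0
    V = spectrum_full.vectors
    vals = spectrum_full.values
    for j in range(V.shape[1]):
        if j in exclude:
            continue
        if value_perp is not None:
            dv, dj = value_perp - center, vals[j] - center
            if dv * dj <= 0 or abs(dj) < magnitude_slack * abs(dv):
                continue
        w = V[:, j] - (u1 @ V[:, j]) * u1
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            continue
        cos = abs(v @ w) / nw
        if cos > best_cos:
            best_cos, best_j = cos, j
    if best_j < 0 or best_cos < min_cosine:
        return None, best_j, best_cos
    return V[:, best_j].copy(), best_j, best_cos


def subspace_overlap(U: np.ndarray, V: np.ndarray) -> float:
    """Determinant-based overlap between the column spans of U and V.

        overlap = |det(U^T V)| / sqrt(det(U^T U) det(V^T V))

    Lies in [0, 1]; equals 1 iff the spans coincide, 0 iff some direction of
    one span is orthogonal to all of the other.  Invariant to invertible
    recombination of either basis and symmetric in its arguments.  For K = 1
    it reduces to the absolute cosine of the two vectors.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float).T).T
    V = np.atleast_2d(np.asarray(V, dtype=float).T).T
    if U.shape != V.shape:
        raise ValueError("U and V must have the same shape (D, K)")
    gU = np.linalg.det(U.T @ U)
    gV = np.linalg.det(V.T @ V)
    if gU <= 1e-300 or gV <= 1e-300:
        raise ValueError("rank-deficient basis")
    return float(np.abs(np.linalg.det(U.T @ V)) / np.sqrt(gU * gV))
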