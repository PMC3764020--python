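"""Synthetic Gaussian stimulus ensembles with natural-scene-like covariance.

Natural images have a characteristic second-order structure: one outstanding
"coherent" mode (approximately the zero-spatial-frequency pattern, eigenvector
with all-positive components, eigenvalue far above the rest) on top of a
heavy, power-law eigenvalue tail.  This module builds population covariance
matrices with that structure, samples zero-mean multivariate Gaussian frame
ensembles from them, and provides the element-shuffling construction used to
connect sample covariances to shifted-Wigner random matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import h5py

__all__ = [
    "PopulationCovariance",
    "StimulusEnsemble",
    "build_population_covariance",
    "sample_stimuli",
    "shuffle_covariance_entries",
    "load_stimuli",
    "save_stimuli",
]

#: default patch geometry, a 16x16 pixel patch
DEFAULT_D = 256

#: refuse to materialize ensembles larger than this many scalar entries
MAX_ELEMENTS = int(2e8)


class SizeError(ValueError):
    """Requested ensemble exceeds the configured memory budget."""


def _householder_basis(u1: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal basis whose first column is ``u1``.

    Uses the Householder reflector mapping e1 -> u1, so the completion is
    reproducible with no hidden randomness.
    """
    D = u1.shape[0]
    u1 = u1 / np.linalg.norm(u1)
    e1 = np.zeros(D)
    e1[0] = 1.0
    v = e1 - u1
    nv = np.linalg.norm(v)
    if nv < 1e-14:
        return np.eye(D)
    v /= nv
    return np.eye(D) - 2.0 * np.outer(v, v)


@dataclass
class PopulationCovariance:
    """A population (true) stimulus covariance matrix.

    Attributes
    ----------
    C : (D, D) ndarray
        Symmetric positive-semidefinite covariance, units of illumination^2.
    kind : str
        One of ``{"white", "spiked", "powerlaw_spiked", "from_file"}``.
    """

    C: np.ndarray
    kind: str
    _eigvals: np.ndarray | None = field(default=None, repr=False)
    _eigvecs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"covariance must be square, got shape {C.shape}")
        if C.shape[0] < 2:
            raise ValueError("dimensionality must be at least 2")
        scale = max(np.abs(C).max(), 1.0)
        if np.abs(C - C.T).max() > 1e-12 * scale:
            raise ValueError("covariance must be symmetric")
        self.C = 0.5 * (C + C.T)

    @property
    def D(self) -> int:
        return self.C.shape[0]

    def _decompose(self) -> None:
        if self._eigvals is None:
            w, V = np.linalg.eigh(self.C)
            order = np.argsort(w)[::-1]
            w, V = w[order], V[:, order]
            if w.min() < -1e-10 * max(w.max(), 1.0):
                raise ValueError(
                    f"covariance is not PSD (min eigenvalue {w.min():.3e})"
                )
            w = np.clip(w, 0.0, None)
            # sign convention: leading component of largest magnitude positive
            for j in range(V.shape[1]):
                k = np.argmax(np.abs(V[:, j]))
                if V[k, j] < 0:
                    V[:, j] = -V[:, j]
            self._eigvals, self._eigvecs = w, V

    @property
    def eigvals(self) -> np.ndarray:
        self._decompose()
        return self._eigvals

    @property
    def eigvecs(self) -> np.ndarray:
        self._decompose()
        return self._eigvecs

    @property
    def coherent_mode(self) -> np.ndarray:
        """Leading population eigenvector."""
        return self.eigvecs[:, 0]

    def sqrt(self) -> np.ndarray:
        """Symmetric PSD square root via the eigendecomposition.

        Preferred over Cholesky so that exactly singular covariances
        (common for near-natural spectra) are handled.
        """
        w, V = self.eigvals, self.eigvecs
        return (V * np.sqrt(w)) @ V.T


@dataclass
class StimulusEnsemble:
    """N stimulus frames of dimension D drawn from a Gaussian ensemble."""

    X: np.ndarray
    seed: int | None = None
    source: PopulationCovariance | str = "external"

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] < 1 or X.shape[1] < 2:
            raise ValueError(f"need N >= 1 frames of dimension D >= 2, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("stimulus frames must be finite")
        self.X = X

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]


def build_population_covariance(
    kind: str,
    D: int = DEFAULT_D,
    *,
    lambda1: float = 100.0,
    lambda2: float = 10.0,
    gamma: float = 2.0,
    bulk: float = 1.0,
    file_path: str | Path | None = None,
) -> PopulationCovariance:
    """Construct a population covariance of the requested family.

    Parameters
    ----------
    kind : {"white", "spiked", "powerlaw_spiked", "from_file"}
        ``white``: the identity.  ``spiked``: eigenvalues
        ``(lambda1, lambda2, bulk, ..., bulk)`` with the coherent mode
        u1 = (1, ..., 1)/sqrt(D) as leading eigenvector — the spiked-Wishart
        population.  ``powerlaw_spiked``: u1 with eigenvalue ``lambda1`` and
        the remaining spectrum proportional to k**(-gamma), scaled so its
        mean equals ``bulk`` — a natural-scene-like heavy tail.
        ``from_file``: dense matrix from NPZ (key "C") or whitespace CSV.
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    if kind == "white":
        return PopulationCovariance(np.eye(D), kind)
    if kind == "from_file":
        if file_path is None:
            raise ValueError("from_file requires file_path")
        path = Path(file_path)
        if path.suffix == ".npz":
            C = np.load(path)["C"]
        else:
            C = np.loadtxt(path)
        C = np.asarray(C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"file must contain a square matrix, got {C.shape}")
        pc = PopulationCovariance(0.5 * (C + C.T), kind)
        pc._decompose()  # validates PSD, clips round-off negatives
        return pc

    if not (bulk > 0):
        raise ValueError("bulk must be positive")
    u1 = np.ones(D) / np.sqrt(D)
    basis = _householder_basis(u1)
    if kind == "spiked":
        if not (lambda1 >= lambda2 >= bulk):
            raise ValueError("require lambda1 >= lambda2 >= bulk")
        w = np.full(D, bulk)
        w[0], w[1] = lambda1, lambda2
    elif kind == "powerlaw_spiked":
        if gamma <= 0:
            raise ValueError("gamma must be positive for powerlaw_spiked")
        if lambda1 < bulk:
            raise ValueError("lambda1 must be >= bulk")
        tail = np.arange(1, D, dtype=float) ** (-gamma)
        tail *= bulk / tail.mean()
        if lambda1 < tail.max():
            raise ValueError(
                f"lambda1={lambda1} must exceed the largest tail eigenvalue "
                f"{tail.max():.3g} for the coherent mode to be leading"
            )
        w = np.concatenate([[lambda1], tail])
    else:
        raise ValueError(f"unknown covariance kind {kind!r}")
    C = (basis * w) @ basis.T
    pc = PopulationCovariance(C, kind)
    return pc


def sample_stimuli(
    C_pop: PopulationCovariance,
    N: int,
    seed: int | None = None,
    *,
    max_elements: int = MAX_ELEMENTS,
) -> StimulusEnsemble:
    """Draw N i.i.d. zero-mean Gaussian frames with covariance ``C_pop``.

    Deterministic given ``seed``; the transform z -> C^(1/2) z uses the
    symmetric square root so singular covariances sample correctly.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    D = C_pop.D
    if N * D > max_elements:
        raise SizeError(
            f"requested ensemble of {N}x{D} = {N * D} values exceeds the "
            f"budget of {max_elements} (raise max_elements to override)"
        )
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((N, D))
    if C_pop.kind == "white":
        X = Z
    else:
        X = Z @ C_pop.sqrt()
    return StimulusEnsemble(X, seed=seed, source=C_pop)


def shuffle_covariance_entries(C: np.ndarray, seed: int | None = None) -> np.ndarray:
    """Shuffle covariance entries while preserving their multiset.

    Off-diagonal entries of the upper triangle are randomly permuted then
    mirrored; diagonal entries are permuted separately (so the trace is
    exactly preserved).  The result is symmetric but generally indefinite:
    its spectrum follows the shifted Wigner semicircle, with the outstanding
    eigenvalue preserved when the element mean exceeds the element
    fluctuation scale.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("input must be square")
    if np.abs(C - C.T).max() > 1e-10 * max(np.abs(C).max(), 1.0):
        raise ValueError("input must be symmetric")
    D = C.shape[0]
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(D, k=1)
    off = rng.permutation(C[iu, ju])
    diag = rng.permutation(np.diag(C))
    S = np.zeros_like(C)
    S[iu, ju] = off
    S = S + S.T
    S[np.diag_indices(D)] = diag
    return S


def save_stimuli(ensemble: StimulusEnsemble, path: str | Path) -> None:
    """Write an ensemble to HDF5 (dataset "stimuli") or NPZ (key "X")."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("stimuli", data=ensemble.X)
            if ensemble.seed is not None:
                f.attrs["seed"] = ensemble.seed
    elif path.suffix == ".npz":
        np.savez(path, X=ensemble.X)
    else:
        np.savetxt(path, ensemble.X)


def load_stimuli(path: str | Path) -> StimulusEnsemble:
    """Read an ensemble from HDF5 (dataset "stimuli"), NPZ (key "X"), or text."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            X = f["stimuli"][...]
    elif path.suffix == ".npz":
        X = np.load(path)["X"]
    else:
        X = np.loadtxt(path)
    return StimulusEnsemble(X, source="external")
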