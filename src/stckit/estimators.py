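"""Scikit-learn estimator wrapping the full STC analysis.

``SpikeTriggeredCovariance`` is a supervised transformer: ``fit(X, y)``
takes an (N, D) array of stimulus frames and a length-N vector of spike
counts, runs covariance estimation, optional coherent-mode projection,
significance testing, full-space matching and decorrelation, and exposes
the recovered relevant features; ``transform(X)`` projects frames onto
them.  It composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import significance as sig
from .decorrelation import (decorrelate_features, match_full_space_feature,
                            select_pinv_order)
from .stc import covariance_pair, delta_c, eigendecompose, project_out_coherent_mode

__all__ = ["SpikeTriggeredCovariance"]


class SpikeTriggeredCovariance(TransformerMixin, BaseEstimator):
    """Spike-triggered covariance analysis with coherent-mode correction.

    Parameters
    ----------
    method : {"global", "nested"}
        Pooled-null percentile test, or iterative rank-ordered testing with
        projection of flagged eigenvectors.
    formulation : {"zero_centered", "one_centered"}
        Test dC = C_s - C_p against zero, or the pre-whitened C_s against
        the identity.
    alpha : float
        Two-sided significance level for the null eigenvalue interval.
    n_null : int
        Number of randomized spike trains building the null distribution.
    randomization : {"circular_shift", "poisson_rate"}
        How null spike trains are generated; circular shifts preserve the
        spike count and temporal structure exactly.
    project_coherent : int
        Number of leading stimulus modes projected out before significance
        testing (the correction scheme; 0 disables it).
    coherent_mode : "sample" or ndarray
        Use the leading eigenvector(s) of the sample prior covariance (what
        an experimenter has) or externally supplied mode(s) of shape (D,) or
        (q, D).
    pinv_order : "full", int, or "auto"
        Pseudoinverse order for decorrelating features; "auto" selects it by
        cross-validated information (requires <= 3 significant features).
    train_fraction : float
        Contiguous train/test split used only by pinv_order="auto".
    match_threshold : float
        Minimum absolute cosine for matching a projected-space eigenvector
        to its full-space counterpart; unmatched features are kept in the
        projected space and listed in ``unmatched_``.
    random_state : int or None
        Seed for every internal source of randomness.

    Attributes
    ----------
    prior_cov_, spike_cov_, sta_ : sample covariances and spike-triggered
        average (relative to the ensemble mean).
    delta_ : dC in the full stimulus space.
    eigenvalues_, eigenvectors_ : spectrum of the tested matrix (in the
        projected space when ``project_coherent > 0``).
    coherent_modes_ : (q, D) projected-out modes.
    null_ : the null eigenvalue distribution (global method).
    significance_ : the full test result.
    features_raw_ : (D, K) significant eigenvectors as tested.
    features_ : (K, D) decorrelated relevant features, unit-norm rows, in
        the full stimulus space (coherent components restored when matched).
    m_star_ : pseudoinverse order actually used.
    """

    def __init__(self, *, method="global", formulation="zero_centered",
                 alpha=0.01, n_null=1000, randomization="circular_shift",
                 project_coherent=0, coherent_mode="sample",
                 pinv_order="full", train_fraction=0.75,
                 match_threshold=0.7, random_state=None):
        self.method = method
        self.formulation = formulation
        self.alpha = alpha
        self.n_null = n_null
        self.randomization = randomization
        self.project_coherent = project_coherent
        self.coherent_mode = coherent_mode
        self.pinv_order = pinv_order
        self.train_fraction = train_fraction
        self.match_threshold = match_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be an (N, D) array of frames")
        y = np.asarray(y)
        N, D = X.shape
        if y.shape != (N,):
            raise ValueError("y must be a length-N spike-count vector")
        rng = np.random.default_rng(self.random_state)

        pair = covariance_pair(X, y)
        self.prior_cov_, self.spike_cov_ = pair.C_p, pair.C_s
        self.sta_ = pair.sta
        self.n_spikes_ = pair.N_s
        self.mean_ = X.mean(axis=0)
        self.delta_ = delta_c(pair)
        self.full_spectrum_ = eigendecompose(self.delta_)

        # --- coherent-mode projection -------------------------------------
        q = int(self.project_coherent)
        if q > 0:
            if isinstance(self.coherent_mode, str) and self.coherent_mode == "sample":
                prior_spec = eigendecompose(self.prior_cov_)
                modes = prior_spec.vectors[:, :q].T
            else:
                modes = np.atleast_2d(np.asarray(self.coherent_mode, dtype=float))
                if modes.shape[0] != q:
                    raise ValueError(
                        f"coherent_mode provides {modes.shape[0]} mode(s), "
                        f"project_coherent={q}"
                    )
            X_work = X
            for u in modes:
                X_work = project_out_coherent_mode(X_work, u)
            self.coherent_modes_ = modes
        else:
            X_work = X
            self.coherent_modes_ = np.empty((0, D))

        # --- significance --------------------------------------------------
        whiten_m = D - q if self.formulation == "one_centered" else None
        if self.method == "global":
            if self.formulation == "one_centered":
                tested = sig.prewhitened_delta(X_work, y, pinv_order=whiten_m)
            else:
                tested = delta_c(covariance_pair(X_work, y))
            spectrum = eigendecompose(tested)
            self.null_ = sig.null_distribution(
                X_work, y, R=self.n_null, mode=self.randomization, seed=rng,
                formulation=self.formulation, pinv_order=whiten_m,
            )
            result = sig.global_test(spectrum, self.null_, alpha=self.alpha)
        elif self.method == "nested":
            result = sig.nested_test(
                X_work, y, R=self.n_null, alpha=self.alpha,
                formulation=self.formulation, mode=self.randomization,
                seed=rng, pinv_order=whiten_m,
            )
            self.null_ = None
            spectrum = result  # eigen info lives in the result
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.significance_ = result
        if self.method == "global":
            self.eigenvalues_ = spectrum.values
            self.eigenvectors_ = spectrum.vectors
        else:
            self.eigenvalues_ = result.values
            self.eigenvectors_ = result.vectors
        self.features_raw_ = result.vectors

        # --- match back to the full space ----------------------------------
        unmatched = []
        if q > 0 and result.vectors.shape[1] > 0:
            matched_cols = []
            used: set[int] = set()
            for j in range(result.vectors.shape[1]):
                vec, idx, cos = match_full_space_feature(
                    result.vectors[:, j], self.full_spectrum_,
                    self.coherent_modes_[0],
                    min_cosine=self.match_threshold, exclude=used,
                    # eigenvalue-magnitude screening is only meaningful when
                    # projected and full spectra share the dC scale
                    value_perp=(float(result.values[j])
                                if self.formulation == "zero_centered" else None),
                )
                if vec is None:
                    unmatched.append(j)
                    matched_cols.append(result.vectors[:, j])
                else:
                    used.add(idx)
                    matched_cols.append(vec)
            full_feats = np.column_stack(matched_cols)
        else:
            full_feats = result.vectors
        self.unmatched_ = np.array(unmatched, dtype=int)

        # --- decorrelation -------------------------------------------------
        K = full_feats.shape[1]
        if K == 0:
            self.m_star_ = D
            self.info_curve_ = None
            self.features_ = np.empty((0, D))
            return self

        if isinstance(self.pinv_order, str) and self.pinv_order == "auto":
            if K > 3:
                raise ValueError("pinv_order='auto' supports at most 3 features")
            split = int(round(self.train_fraction * N))
            m_star, curve = select_pinv_order(
                X[:split], y[:split], X[split:], y[split:], full_feats,
                seed=rng.integers(2**31),
            )
            self.m_star_, self.info_curve_ = m_star, curve
        elif isinstance(self.pinv_order, str) and self.pinv_order == "full":
            self.m_star_, self.info_curve_ = D, None
        elif isinstance(self.pinv_order, numbers.Integral):
            self.m_star_, self.info_curve_ = int(self.pinv_order), None
        else:
            raise ValueError(f"invalid pinv_order {self.pinv_order!r}")

        fs = decorrelate_features(
            full_feats, self.prior_cov_, self.m_star_,
            space="coherent_orthogonal" if (q > 0 and len(unmatched)) else "full",
        )
        self.feature_set_ = fs
        self.features_ = fs.decorrelated.T
        return self

    # ------------------------------------------------------------------
    def transform(self, X):
        """Project mean-subtracted frames onto the recovered features."""
        check_is_fitted(self, "features_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.features_.T

    @property
    def n_significant_(self) -> int:
        check_is_fitted(self, "significance_")
        return self.significance_.n_significant
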