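"""Pseudoinverse decorrelation, information-based order selection,
full-space matching, and the subspace overlap metric."""

import numpy as np
import pytest

import stckit as sk
from stckit.decorrelation import projection_information


class TestPseudoinverse:
    def test_full_order_is_inverse(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 6))
        C = A @ A.T + 0.5 * np.eye(6)
        P = sk.pseudoinverse(C, 6)
        np.testing.assert_allclose(P @ C, np.eye(6), atol=1e-8)

    def test_rank_truncation(self):
        P = sk.pseudoinverse(np.diag([4.0, 1.0]), 1)
        np.testing.assert_allclose(P, np.diag([0.25, 0.0]), atol=1e-14)

    def test_moore_penrose_on_retained_subspace(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((8, 8))
        C = A @ A.T
        for m in (3, 8):
            P = sk.pseudoinverse(C, m)
            np.testing.assert_allclose(P @ C @ P, P, atol=1e-8)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            sk.pseudoinverse(np.eye(3), 0)
        with pytest.raises(ValueError):
            sk.pseudoinverse(np.diag([1.0, 0.0]), 2)  # zero retained eigenvalue


class TestDecorrelateFeatures:
    def test_white_noop(self, white_or2_data):
        ens, spikes, _ = white_or2_data
        pair = sk.covariance_pair(ens.X, spikes)
        rng = np.random.default_rng(2)
        raw = rng.standard_normal((32, 2))
        raw /= np.linalg.norm(raw, axis=0)
        fs = sk.decorrelate_features(raw, pair.C_p, 32)
        cos = np.abs(np.sum(fs.decorrelated * raw, axis=0))
        assert np.all(cos > 0.99)  # N/D > 300, C_p ~ identity

    def test_correlated_decorrelation_improves_recovery(
            self, correlated_mono1_data):
        """The raw dC eigenvector is the covariance-filtered feature; the
        decorrelated version is closer to the model's k."""
        ens, spikes, k = correlated_mono1_data
        # analyze in the coherent-orthogonal subspace where the signal is
        # visible (k itself is orthogonal to the coherent mode)
        pair_full = sk.covariance_pair(ens.X, spikes)
        u1 = sk.eigendecompose(pair_full.C_p).vectors[:, 0]
        Xp = sk.project_out_coherent_mode(ens.X, u1)
        spec = sk.eigendecompose(sk.delta_c(sk.covariance_pair(Xp, spikes)))
        # signal eigenvalue is the most extreme one
        j = np.argmax(np.abs(spec.values))
        raw = spec.vectors[:, [j]]
        fs = sk.decorrelate_features(raw, pair_full.C_p, 48)
        assert abs(fs.decorrelated[:, 0] @ k) > abs(raw[:, 0] @ k)
        assert abs(fs.decorrelated[:, 0] @ k) > 0.9

    def test_feature_in_discarded_subspace_flagged(self):
        C = np.diag([4.0, 2.0, 1.0])
        v = np.array([[0.0], [0.0], [1.0]])
        fs = sk.decorrelate_features(v, C, 2)
        assert 0 in fs.degenerate
        np.testing.assert_allclose(fs.decorrelated, v)  # kept, not dropped

    def test_round_trip_identity_on_retained_subspace(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((10, 10))
        C = A @ A.T + np.eye(10)
        spec = sk.eigendecompose(C)
        m = 6
        v = spec.vectors[:, :m] @ rng.standard_normal(m)  # inside retained span
        v /= np.linalg.norm(v)
        fs = sk.decorrelate_features((C @ v)[:, None], C, m)
        got = fs.decorrelated[:, 0]
        np.testing.assert_allclose(np.abs(got @ v), 1.0, atol=1e-8)


class TestSelectPinvOrder:
    def test_independent_spikes_give_no_information(self, spiked_cov):
        ens = sk.sample_stimuli(spiked_cov, 8000, seed=10)
        spikes = np.zeros(8000, dtype=np.int64)
        spikes[np.random.default_rng(11).choice(8000, 800, replace=False)] = 1
        rng = np.random.default_rng(12)
        feat = rng.standard_normal((48, 1))
        feat /= np.linalg.norm(feat)
        m_star, curve = sk.select_pinv_order(
            ens.X[:6000], spikes[:6000], ens.X[6000:], spikes[6000:], feat,
            orders=[1, 4, 16, 48], seed=13)
        for m, (info, se) in curve.items():
            assert info <= 3 * se + 0.05

    def test_information_nonnegative_and_plateau_rule(
            self, correlated_mono1_data):
        ens, spikes, k = correlated_mono1_data
        split = 15_000
        m_star, curve = sk.select_pinv_order(
            ens.X[:split], spikes[:split], ens.X[split:], spikes[split:],
            k[:, None], orders=[1, 2, 4, 8, 16, 32, 48], seed=14)
        infos = {m: i for m, (i, _) in curve.items()}
        # true feature carries real information at full order
        assert infos[48] > 0.05
        # m_star is the smallest order within one SE of the maximum
        best = max(infos.values())
        se_at_best = [s for m, (i, s) in curve.items() if i == best][0]
        eligible = [m for m, i in sorted(infos.items()) if i >= best - se_at_best]
        assert m_star == eligible[0]

    def test_too_many_features_rejected(self, spiked_cov):
        ens = sk.sample_stimuli(spiked_cov, 100, seed=15)
        with pytest.raises(ValueError):
            sk.select_pinv_order(ens.X, np.ones(100, dtype=int), ens.X,
                                 np.ones(100, dtype=int), np.eye(48)[:, :4])

    def test_histogram_information_positive_for_dependent_data(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(5000)
        spikes = (rng.random(5000) < 1 / (1 + np.exp(-2 * x))).astype(np.int64)
        info, se = projection_information(x[:, None], spikes, n_bins=15,
                                          rng=rng)
        assert info > 0.1


class TestMatchFullSpaceFeature:
    def test_orthogonal_feature_matches_itself(self):
        """Infinite-data limit with a feature exactly orthogonal to u1: the
        matched full-space vector has zero coherent component."""
        D = 12
        u1 = np.ones(D) / np.sqrt(D)
        rng = np.random.default_rng(20)
        v = sk.orthogonalize_feature(rng.standard_normal(D), u1)
        # full-space spectrum whose first vector IS v (plus unrelated ones)
        others = np.linalg.qr(rng.standard_normal((D, D)))[0]
        vecs = np.column_stack([v] + [sk.orthogonalize_feature(others[:, i], v)
                                      for i in range(3)])
        spec = sk.EigenSpectrum(values=np.arange(vecs.shape[1], 0, -1.0),
                                vectors=vecs)
        matched, idx, cos = sk.match_full_space_feature(v, spec, u1)
        assert idx == 0 and cos > 0.999
        assert abs(matched @ u1) < 1e-10

    def test_injectivity_via_exclusion(self, spiked_cov):
        rng = np.random.default_rng(21)
        u1 = spiked_cov.coherent_mode
        spec = sk.eigendecompose(spiked_cov.C)
        v = sk.orthogonalize_feature(spec.vectors[:, 1], u1)
        _, idx1, _ = sk.match_full_space_feature(v, spec, u1)
        _, idx2, _ = sk.match_full_space_feature(v, spec, u1, exclude={idx1})
        assert idx1 != idx2

    def test_unmatched_below_threshold_reported(self):
        D = 6
        u1 = np.ones(D) / np.sqrt(D)
        rng = np.random.default_rng(22)
        v = sk.orthogonalize_feature(rng.standard_normal(D), u1)
        # spectrum of vectors orthogonal to v (and generic): no good match
        w = sk.orthogonalize_feature(rng.standard_normal(D), u1, v)
        spec = sk.EigenSpectrum(values=np.array([1.0]), vectors=w[:, None])
        matched, idx, cos = sk.match_full_space_feature(v, spec, u1,
                                                        min_cosine=0.7)
        assert matched is None and cos < 0.7

    def test_magnitude_screening_skips_noise_twins(self):
        """A projected noise eigenvector's near-identical full-space twin is
        excluded when its eigenvalue is less extreme than the projected one."""
        D = 8
        u1 = np.ones(D) / np.sqrt(D)
        rng = np.random.default_rng(23)
        v = sk.orthogonalize_feature(rng.standard_normal(D), u1)
        twin = v.copy()                      # identical, tiny eigenvalue
        real = 0.8 * u1 + 0.6 * v            # true counterpart, big eigenvalue
        spec = sk.EigenSpectrum(values=np.array([-0.1, -5.0]),
                                vectors=np.column_stack([twin, real]))
        matched, idx, _ = sk.match_full_space_feature(
            v, spec, u1, value_perp=-1.0)
        assert idx == 1
        np.testing.assert_allclose(matched, real)


class TestSubspaceOverlap:
    def test_identical_and_orthogonal(self):
        rng = np.random.default_rng(30)
        U = np.linalg.qr(rng.standard_normal((10, 3)))[0]
        assert sk.subspace_overlap(U, U) == pytest.approx(1.0)
        V = np.linalg.qr(rng.standard_normal((10, 10)))[0][:, 3:6]
        V = V - U @ (U.T @ V)
        assert sk.subspace_overlap(U, V) == pytest.approx(0.0, abs=1e-10)

    def test_k1_equals_absolute_cosine(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            u = rng.standard_normal(7)
            v = rng.standard_normal(7)
            expected = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            assert sk.subspace_overlap(u[:, None], v[:, None]) == \
                pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_basis_invariance(self):
        rng = np.random.default_rng(32)
        U = rng.standard_normal((9, 2))
        V = rng.standard_normal((9, 2))
        a = sk.subspace_overlap(U, V)
        assert sk.subspace_overlap(V, U) == pytest.approx(a, abs=1e-12)
        A = rng.standard_normal((2, 2)) + 2 * np.eye(2)  # invertible recombination
        assert sk.subspace_overlap(U @ A, V) == pytest.approx(a, abs=1e-10)

    def test_rank_deficient_rejected(self):
        U = np.ones((5, 2))
        with pytest.raises(ValueError):
            sk.subspace_overlap(U, U)
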