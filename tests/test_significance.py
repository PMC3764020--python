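"""Null distributions, global/nested tests, pre-whitening, Šidák."""

import numpy as np
import pytest

import stckit as sk
from stckit.significance import NullDistribution
from stckit.stc import EigenSpectrum


def _random_spikes(N, N_s, seed):
    sp = np.zeros(N, dtype=np.int64)
    sp[np.random.default_rng(seed).choice(N, N_s, replace=False)] = 1
    return sp


class TestRandomizeSpikeTrain:
    def test_circular_preserves_count_and_intervals(self):
        rng = np.random.default_rng(0)
        spikes = (rng.random(500) < 0.1).astype(np.int64)
        shifted = sk.randomize_spike_train(spikes, "circular_shift", seed=1)
        assert shifted.sum() == spikes.sum()
        # inter-spike intervals preserved up to one wrap-around interval
        def isi(s):
            t = np.flatnonzero(s)
            return np.diff(t)
        a = np.sort(isi(spikes))
        b = np.sort(isi(shifted))
        assert np.sum(~np.isin(b, a)) <= 1 or np.array_equal(a, b)

    def test_never_identity_shift(self):
        """Shift 0 (and N) are excluded, so a delta train always moves."""
        spikes = np.zeros(20, dtype=np.int64)
        spikes[5] = 1
        moved = [sk.randomize_spike_train(spikes, seed=s).argmax() != 5
                 for s in range(40)]
        # the identity outcome would put the spike back at index 5
        assert all(np.roll(spikes, -r).argmax() != 5 or r % 20 == 0
                   for r in range(1, 20))
        assert any(moved)

    def test_shift_composition(self):
        spikes = np.arange(10, dtype=np.int64) % 3
        r1, r2 = 3, 8
        once = np.roll(np.roll(spikes, -r1), -r2)
        np.testing.assert_array_equal(once, np.roll(spikes, -((r1 + r2) % 10)))

    def test_poisson_rate_mode(self):
        spikes = np.zeros(10_000, dtype=np.int64)
        spikes[:1000] = 1
        rnd = sk.randomize_spike_train(spikes, "poisson_rate", seed=2)
        assert abs(rnd.mean() - 0.1) < 0.02

    def test_short_train_rejected(self):
        with pytest.raises(ValueError):
            sk.randomize_spike_train(np.array([1]), "circular_shift", seed=0)


class TestNullDistribution:
    def test_symmetric_about_zero_for_white(self, white_cov):
        ens = sk.sample_stimuli(white_cov, 5000, seed=50)
        spikes = _random_spikes(5000, 500, 51)
        nd = sk.null_distribution(ens, spikes, R=300, seed=52)
        assert nd.pooled.size == 300 * 32
        se = nd.pooled.std() / np.sqrt(300)  # realizations are the unit
        assert abs(nd.pooled.mean()) < 2 * se

    def test_coherent_projection_shrinks_null_spread(self, spiked_cov):
        """Projecting the coherent mode shrinks the extremal null spread by
        roughly lambda1/lambda2."""
        ens = sk.sample_stimuli(spiked_cov, 5000, seed=53)
        spikes = _random_spikes(5000, 500, 54)
        nd_full = sk.null_distribution(ens, spikes, R=200, seed=55)
        Xp = sk.project_out_coherent_mode(ens.X, spiked_cov.coherent_mode)
        nd_proj = sk.null_distribution(Xp, spikes, R=200, seed=56)
        spread_full = nd_full.by_rank[:, 0].std()
        spread_proj = nd_proj.by_rank[:, 0].std()
        ratio = spread_full / spread_proj
        assert ratio == pytest.approx(50.0 / 5.0, rel=0.5)

    def test_spike_count_scaling(self, spiked_cov):
        """Doubling N_s halves the variance of the top-rank null series."""
        ens = sk.sample_stimuli(spiked_cov, 40_000, seed=57)
        variances = []
        counts = [500, 1000, 2000, 4000]
        for i, N_s in enumerate(counts):
            v = [sk.null_distribution(ens, _random_spikes(40_000, N_s, 60 + j),
                                      R=120, seed=70 + 10 * i + j).by_rank[:, 0].var()
                 for j in range(3)]
            variances.append(np.mean(v))
        slope = np.polyfit(np.log(counts), np.log(variances), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_determinism(self, white_cov):
        ens = sk.sample_stimuli(white_cov, 1000, seed=58)
        spikes = _random_spikes(1000, 100, 59)
        a = sk.null_distribution(ens, spikes, R=20, seed=60)
        b = sk.null_distribution(ens, spikes, R=20, seed=60)
        np.testing.assert_array_equal(a.by_rank, b.by_rank)


class TestGlobalTest:
    def test_empty_and_clear_exceedance(self):
        rng = np.random.default_rng(61)
        pool = rng.uniform(-1, 1, size=2000)
        null = NullDistribution(pooled=pool, by_rank=pool.reshape(100, 20),
                                R=100, mode="circular_shift", seed=0)
        spec = EigenSpectrum(values=np.array([2.0, 0.1, -1.5]),
                             vectors=np.eye(3))
        res = sk.global_test(spec, null, alpha=0.01)
        assert set(res.indices) == {0, 2}
        assert list(res.signs) == [1, -1]
        zero = EigenSpectrum(values=np.zeros(3), vectors=np.eye(3))
        assert sk.global_test(zero, null, alpha=0.01).n_significant == 0

    def test_percentile_bounds_match_sorted_pool(self):
        """Bounds agree with a brute-force sort-and-index computation."""
        rng = np.random.default_rng(62)
        pool = rng.standard_normal(1000)
        null = NullDistribution(pooled=pool, by_rank=pool.reshape(50, 20),
                                R=50, mode="circular_shift", seed=0)
        spec = EigenSpectrum(values=np.zeros(20), vectors=np.eye(20))
        res = sk.global_test(spec, null, alpha=0.1)
        s = np.sort(pool)
        # linear-interpolation quantile, computed by hand
        def quant(q):
            pos = q * (len(s) - 1)
            lo = int(np.floor(pos))
            return s[lo] + (pos - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
        assert res.lower == pytest.approx(quant(0.05), abs=1e-12)
        assert res.upper == pytest.approx(quant(0.95), abs=1e-12)

    def test_alpha_incompatible_with_pool_size(self):
        pool = np.arange(100.0)
        null = NullDistribution(pooled=pool, by_rank=pool.reshape(10, 10),
                                R=10, mode="circular_shift", seed=0)
        spec = EigenSpectrum(values=np.zeros(10), vectors=np.eye(10))
        with pytest.raises(ValueError):
            sk.global_test(spec, null, alpha=0.001)


class TestNestedTest:
    def test_null_gives_empty_result_usually(self, white_cov):
        """Type-I contract at reduced scale: stimulus-independent spikes
        yield no significant dimensions in most runs."""
        hits = 0
        n_runs = 12
        for s in range(n_runs):
            ens = sk.sample_stimuli(white_cov, 2000, seed=80 + s)
            spikes = _random_spikes(2000, 200, 90 + s)
            res = sk.nested_test(ens, spikes, R=150, alpha=0.02, seed=100 + s)
            hits += res.n_significant > 0
        assert hits <= 3  # ~2*alpha expected per run; allow slack

    def test_or2_agreement_with_global(self, white_or2_data):
        ens, spikes, _ = white_or2_data
        res = sk.nested_test(ens, spikes, R=200, alpha=0.01, seed=110)
        assert res.n_significant == 2
        assert res.n_iterations <= 32

    def test_termination_bound(self, white_cov):
        ens = sk.sample_stimuli(white_cov, 1500, seed=120)
        spikes = _random_spikes(1500, 150, 121)
        res = sk.nested_test(ens, spikes, R=100, alpha=0.05, seed=122)
        assert res.n_iterations <= 32


class TestPrewhitenedDelta:
    def test_identity_prior_reduces_to_shifted_delta(self, white_cov):
        """With C_p = I (exactly), the whitened C_s equals dC + I."""
        rng = np.random.default_rng(130)
        X = rng.standard_normal((4000, 16))
        spikes = _random_spikes(4000, 400, 131)
        M = sk.prewhitened_delta(X, spikes)
        pair = sk.covariance_pair(X, spikes)
        dC = sk.delta_c(pair)
        w_m = np.sort(np.linalg.eigvalsh(M))
        w_d = np.sort(np.linalg.eigvalsh(dC + np.eye(16)))
        assert np.abs(w_m - w_d).max() < 0.2

    def test_whitened_prior_is_identity(self, spiked_cov):
        ens = sk.sample_stimuli(spiked_cov, 5000, seed=132)
        M = sk.prewhitened_delta(ens, np.ones(5000, dtype=int))
        # spikes on every frame: whitened C_s = whitened C_p = identity
        np.testing.assert_allclose(M, np.eye(48), atol=1e-8)

    def test_null_eigenvalues_cluster_near_one(self, spiked_cov):
        ens = sk.sample_stimuli(spiked_cov, 48 * 60, seed=133)
        spikes = _random_spikes(48 * 60, 1200, 134)
        M = sk.prewhitened_delta(ens, spikes)
        assert np.linalg.eigvalsh(M).mean() == pytest.approx(1.0, abs=0.05)

    def test_truncated_order(self, spiked_cov):
        ens = sk.sample_stimuli(spiked_cov, 3000, seed=135)
        spikes = _random_spikes(3000, 300, 136)
        M = sk.prewhitened_delta(ens, spikes, pinv_order=10)
        assert np.linalg.matrix_rank(M, tol=1e-8) <= 10
        with pytest.raises(ValueError):
            sk.prewhitened_delta(ens, spikes, pinv_order=0)


class TestSidak:
    def test_single_test_unchanged(self):
        assert sk.sidak_level(0.05, 1) == pytest.approx(0.05)

    def test_first_order_approximation(self):
        assert sk.sidak_level(0.01, 10) == pytest.approx(0.001, rel=0.02)

    def test_reference_value(self):
        assert sk.sidak_level(0.05, 10) == pytest.approx(0.005116, abs=5e-7)


class TestFeatureVarianceTest:
    def test_null_percentile_calibration(self, white_cov):
        """Percentile of a stimulus-independent spike train is uniform."""
        from scipy.stats import kstest
        C = sk.build_population_covariance("white", 10)
        ens = sk.sample_stimuli(C, 2000, seed=140)
        feature = np.zeros(10)
        feature[0] = 1.0
        pcts = []
        for s in range(200):
            spikes = _random_spikes(2000, 100, 150 + s)
            pct, _ = sk.feature_variance_test(ens, spikes, feature, R=100,
                                              seed=400 + s)
            pcts.append(pct / 100.0)
        assert kstest(pcts, "uniform").pvalue > 0.01

    def test_detects_signal_below_spectrum_threshold(self):
        """With too few spikes for any eigenvalue to clear the (coherent-
        widened) null band, the variance along the true feature is still
        extreme within its own randomized-spike-train null."""
        strong = sk.build_population_covariance("spiked", 48, lambda1=100.0,
                                                lambda2=5.0, bulk=1.0)
        ens = sk.sample_stimuli(strong, 10_000, seed=141)
        rng = np.random.default_rng(142)
        k = sk.orthogonalize_feature(rng.standard_normal(48),
                                     strong.coherent_mode)
        cell = sk.ModelNeuron("mono1", k[None, :], w=0.5).calibrate(ens)
        cell.theta = sk.match_firing_rate(cell, ens, 0.1)
        spikes = sk.generate_spike_train(cell, ens, seed=143)
        # full-space analysis is blind at this spike count
        nd = sk.null_distribution(ens, spikes, R=200, seed=144)
        spec = sk.eigendecompose(sk.delta_c(sk.covariance_pair(ens.X, spikes)))
        assert sk.global_test(spec, nd, 0.01).n_significant == 0
        pct, _ = sk.feature_variance_test(ens, spikes, k, R=200, seed=145)
        assert pct < 1.0 or pct > 99.0

    def test_orthogonal_feature_not_flagged(self, spiked_cov,
                                            correlated_mono1_data):
        ens, spikes, k = correlated_mono1_data
        extremes = 0
        for s in range(10):
            rng = np.random.default_rng(160 + s)
            probe = sk.orthogonalize_feature(rng.standard_normal(48),
                                             spiked_cov.coherent_mode, k)
            pct, _ = sk.feature_variance_test(ens.X[:5000], spikes[:5000],
                                              probe, R=100, seed=170 + s)
            extremes += (pct < 1.0) or (pct > 99.0)
        assert extremes <= 1
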