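"""Ensemble analyses: motor split, connectivity, states, contrasts, TCA."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import rewardmap as rm
from rewardmap.errors import InvalidInputError


class TestBinarizeMovement:
    def test_rules(self):
        assert not rm.binarize_movement(np.zeros(10), 1.0).any()
        v = np.array([0.0, 0.5, 2.0])
        np.testing.assert_array_equal(rm.binarize_movement(v, 0.0),
                                      [False, True, True])
        with pytest.raises(InvalidInputError):
            rm.binarize_movement(v, -1.0)

    def test_moving_fraction_matches_count(self, rng):
        v = rng.random(500) * 10
        flags = rm.binarize_movement(v, 3.0)
        assert flags.sum() == int(np.sum(v > 3.0))


class TestClassifyMotor:
    def test_planted_lag_recovered(self, rng):
        n = 1000
        movement = rng.random(n) < 0.3
        # ensure both states well represented
        movement[:30] = True
        movement[30:60] = False
        lag = 3
        trace = np.zeros(n)
        trace[lag:] = movement[:-lag].astype(float)
        trace += 0.01 * rng.standard_normal(n)
        traces = np.vstack([trace, rng.standard_normal(n)])
        labels = rm.classify_motor(traces, movement)
        assert labels.labels[0] == "motor"
        assert labels.best_lag[0] == lag

    def test_noise_neurons_rarely_motor(self, rng):
        movement = rng.random(2000) < 0.3
        traces = rng.standard_normal((200, 2000))
        labels = rm.classify_motor(traces, movement)
        assert (labels.labels == "motor").mean() <= 0.01

    def test_planted_population_recovery(self, consumption_session):
        session, truth = consumption_session
        z = rm.consumption_preprocess(session)
        movement = rm.binarize_movement(session.velocity, 1.0)
        labels = rm.classify_motor(z, movement)
        is_motor_true = truth.neuron_populations == "motor"
        assert (labels.labels[is_motor_true] == "motor").mean() >= 0.9
        assert (labels.labels[~is_motor_true] == "motor").mean() <= 0.1

    def test_joint_time_reversal_preserves_labels(self, consumption_session):
        session, truth = consumption_session
        z = rm.consumption_preprocess(session)
        movement = rm.binarize_movement(session.velocity, 1.0)
        fwd = rm.classify_motor(z, movement)
        rev = rm.classify_motor(z[:, ::-1], movement[::-1])
        np.testing.assert_array_equal(fwd.labels, rev.labels)

    def test_constant_movement_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            rm.classify_motor(rng.standard_normal((2, 100)),
                              np.ones(100, dtype=bool))


class TestConnectivityIndex:
    def test_baseline_index_is_one(self, rng):
        segs = [rng.standard_normal((6, 100)) for _ in range(3)]
        segs[0][1] = segs[0][0] + 0.01 * rng.standard_normal(100)  # one pair
        series = rm.connectivity_index(segs, baseline_index=0)
        assert series.index[0] == 1.0

    def test_identical_traces_complete_graph(self, rng):
        base = rng.standard_normal(80)
        seg = np.tile(base, (7, 1))
        assert rm.count_synchronized_pairs(seg) == 7 * 6 // 2

    def test_counts_match_pairwise_oracle(self, rng):
        for n in (5, 20, 100):
            seg = rng.standard_normal((n, 60))
            # plant some correlated pairs
            for i in range(0, n - 1, 3):
                seg[i + 1] = 0.7 * seg[i] + 0.3 * rng.standard_normal(60)
            count = rm.count_synchronized_pairs(seg)
            oracle = sum(
                stats.pearsonr(seg[i], seg[j]).statistic > 0.3
                for i, j in itertools.combinations(range(n), 2)
            )
            assert count == oracle

    def test_invariant_to_relabeling(self, rng):
        segs = [rng.standard_normal((10, 50)) for _ in range(3)]
        perm = rng.permutation(10)
        s1 = rm.connectivity_index(segs, 0, baseline_pseudocount=True)
        s2 = rm.connectivity_index([s[perm] for s in segs], 0,
                                   baseline_pseudocount=True)
        np.testing.assert_array_equal(s1.counts, s2.counts)

    def test_zero_baseline_requires_pseudocount(self, rng):
        segs = [rng.standard_normal((8, 2000)) for _ in range(2)]
        if rm.count_synchronized_pairs(segs[0]) == 0:
            with pytest.raises(InvalidInputError):
                rm.connectivity_index(segs, 0)
            series = rm.connectivity_index(segs, 0, baseline_pseudocount=True)
            assert series.index[0] == 1.0


class TestClusterStates:
    @staticmethod
    def prototypes(rng, n_per=30, t=120):
        """Meal-start / sustained / meal-end response shapes."""
        time = np.arange(t)
        shapes = [
            np.exp(-0.5 * ((time - 20) / 8.0) ** 2),
            np.clip((time - 30) / 40.0, 0, 1),
            np.exp(-0.5 * ((time - 100) / 8.0) ** 2),
        ]
        X, truth = [], []
        for c, shape in enumerate(shapes):
            for _ in range(n_per):
                X.append(5 * shape + 0.3 * rng.standard_normal(t))
                truth.append(c)
        return np.array(X), np.array(truth)

    def test_recovery_and_determinism(self, rng):
        X, truth = self.prototypes(rng)
        sm1 = rm.cluster_states(X, k=3, seed=0)
        sm2 = rm.cluster_states(X, k=3, seed=0)
        assert adjusted_rand_score(truth, sm1.labels) >= 0.9
        np.testing.assert_array_equal(sm1.labels, sm2.labels)
        np.testing.assert_allclose(sm1.nmf_coords, sm2.nmf_coords)
        np.testing.assert_allclose(sm1.tsne_coords, sm2.tsne_coords)
        assert np.all(sm1.nmf_coords >= 0)

    def test_k_validation(self, rng):
        with pytest.raises(InvalidInputError):
            rm.cluster_states(rng.random((5, 10)), k=1)
        with pytest.raises(InvalidInputError):
            rm.cluster_states(rng.random((2, 10)), k=3)


class TestActivationContrast:
    def test_identical_counts(self):
        (p1, p2), odds, p = rm.activation_contrast((10, 100), (10, 100))
        assert p1 == p2 == 10.0
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_empty_sets(self):
        (_, _), odds, p = rm.activation_contrast((0, 50), (0, 60))
        assert np.isnan(odds)
        assert p == pytest.approx(1.0)

    @staticmethod
    def fisher_oracle(a, b, c, d):
        """Two-sided Fisher p by explicit hypergeometric enumeration."""
        n, K, nn = a + b + c + d, a + b, a + c
        lo, hi = max(0, K + nn - n), min(K, nn)
        ks = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(ks, n, K, nn)
        p_obs = stats.hypergeom.pmf(a, n, K, nn)
        return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())

    def test_example_table_matches_enumeration(self):
        (_, _), _, p = rm.activation_contrast((10, 100), (30, 100))
        assert p == pytest.approx(self.fisher_oracle(10, 90, 30, 70),
                                  abs=1e-10)

    def test_all_small_tables_match_enumeration(self):
        """Every 2x2 table with total n <= 25 agrees with the exhaustive
        hypergeometric oracle (the full n <= 40 sweep runs in acceptance)."""
        for n in range(2, 26):
            for n1 in range(1, n):
                n2 = n - n1
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        (_, _), _, p = rm.activation_contrast((a, n1), (c, n2))
                        oracle = self.fisher_oracle(a, n1 - a, c, n2 - c)
                        assert abs(p - oracle) < 1e-10


class TestVarianceTopPcs:
    def test_exact_rank_three(self, rng):
        X = rng.standard_normal((50, 3)) @ rng.standard_normal((3, 200))
        assert rm.variance_top_pcs(X, 3) > 0.999

    def test_isotropic_noise_low_ratio(self, rng):
        X = rng.standard_normal((100, 500))
        ratio = rm.variance_top_pcs(X, 3)
        # Marchenko-Pastur-inflated bound for p/n = 100/500
        assert 3 / 100 < ratio < 3 * ((1 + np.sqrt(100 / 500)) ** 2) / 100

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((30, 80))
        r1 = rm.variance_top_pcs(X)
        r2 = rm.variance_top_pcs(X[rng.permutation(30)])
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestTCA:
    def test_factors_nonnegative_and_rank_one_exact(self, rng):
        a, b, c = rng.random(6) + 0.5, rng.random(8) + 0.5, rng.random(10) + 0.5
        X = np.einsum("i,j,k->ijk", a, b, c)
        res = rm.tca_fit(X, rank=1, restarts=3, seed=0)
        assert res.rel_error < 1e-6
        for f in (res.neuron_factors, res.time_factors, res.trial_factors):
            assert np.all(f >= 0)

    def test_error_nonincreasing_in_rank(self, rng):
        X, _, _ = rm.gen_multisession_tensor(
            rm.CalciumSimSpec(seed=9, n_neurons=30,
                              populations={"silent": (30, 0.0)}),
            gain_per_session=1.3, n_sessions=4,
        )
        errs = [rm.tca_fit(X, rank=r, restarts=4, seed=0).rel_error
                for r in range(1, 5)]
        assert all(e2 <= e1 + 1e-6 for e1, e2 in zip(errs, errs[1:]))

    def test_planted_rank_two_recovery(self):
        X, _, truth = rm.gen_multisession_tensor(
            rm.CalciumSimSpec(seed=10, n_neurons=45,
                              populations={"silent": (45, 0.0)}),
            gain_per_session=1.5, n_sessions=5,
        )
        res = rm.tca_fit(X, rank=2, restarts=5, seed=1)
        assert rm.factor_congruence(res, truth.tca_factors) >= 0.9

    def test_rank_validation(self, rng):
        X = rng.random((3, 4, 5))
        with pytest.raises(InvalidInputError):
            rm.tca_fit(X, rank=4)


@pytest.fixture(scope="module")
def planted():
    spec = rm.CalciumSimSpec(seed=11, n_neurons=45,
                             populations={"silent": (45, 0.0)})
    X, labels, truth = rm.gen_multisession_tensor(
        spec, gain_per_session=1.5, n_sessions=5)
    res = rm.tca_fit(X, rank=2, restarts=5, seed=2)
    return X, labels, truth, res


class TestTrendAndContrast:

    def test_amplifying_component_has_positive_trend(self, planted):
        X, labels, truth, res = planted
        trend = rm.tca_trend_and_contrast(res, labels, X)
        # amplifying component: the one matching the planted gain profile
        j = int(np.argmax(np.abs(trend.slopes)))
        assert trend.slopes[j] > 0
        assert trend.slope_pvalues[j] < 0.05
        assert trend.contrast_pvalue < 0.05

    def test_stationary_gain_has_flat_trend(self):
        X, labels, _ = rm.gen_multisession_tensor(
            rm.CalciumSimSpec(seed=12, n_neurons=45,
                              populations={"silent": (45, 0.0)}),
            gain_per_session=1.0, n_sessions=5,
        )
        res = rm.tca_fit(X, rank=2, restarts=5, seed=3)
        trend = rm.tca_trend_and_contrast(res, labels, X)
        scale = np.abs(res.trial_factors).mean(axis=0)
        rel = np.abs(trend.slopes) / scale
        assert rel.max() < 0.05  # slope small relative to factor magnitude

    def test_contributing_set_matches_sign_oracle(self, planted):
        X, labels, truth, res = planted
        trend = rm.tca_trend_and_contrast(res, labels, X)
        diff = res.neuron_factors[:, 0] - res.neuron_factors[:, 1]
        np.testing.assert_array_equal(trend.contributing, diff > 0)
        # equal loadings are excluded (strict positivity)
        res2 = rm.TCAResult(
            rank=2,
            neuron_factors=np.array([[0.5, 0.5], [0.7, 0.2]]),
            time_factors=np.ones((4, 2)),
            trial_factors=np.ones((6, 2)),
            rel_error=0.0, seed=0, restarts=1,
        )
        t2 = rm.tca_trend_and_contrast(res2)
        np.testing.assert_array_equal(t2.contributing, [False, True])
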