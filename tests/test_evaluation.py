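import numpy as np
import pytest

from dart import (
    benchmark_simulation,
    compare_methods_V,
    consistency_score_V,
    ground_state_accuracy,
    interpathway_correlation,
    paired_wilcoxon,
    phenotype_association,
    vb_cluster_1d,
)
from dart.evaluation import ClusteringResult


class TestVbCluster:
    def test_two_point_masses_two_components(self, rng):
        x = np.concatenate([rng.normal(0, 0.01, 50), rng.normal(10, 0.01, 50)])
        res = vb_cluster_1d(x, seed=0)
        assert res.n_effective_components == 2
        # ground state = the low mass (means shrink slightly toward the prior)
        assert res.in_ground_state[:50].all() and not res.in_ground_state[50:].any()
        assert res.component_means[res.ground_state] < 1.0

    def test_constant_profile_single_ground_state(self):
        res = vb_cluster_1d(np.full(20, 3.5), seed=0)
        assert res.n_effective_components == 1
        assert res.in_ground_state.all()

    def test_two_gaussian_mixture_low_misassignment(self):
        # 0.4 N(0,0.1) + 0.6 N(3,0.1): Bayes-optimal boundary misassigns ~0
        mis = []
        for s in range(10):
            r = np.random.default_rng(s)
            x = np.concatenate([r.normal(0, 0.1, 40), r.normal(3, 0.1, 60)])
            truth = np.r_[np.zeros(40, bool), np.ones(60, bool)]
            res = vb_cluster_1d(x, seed=s)
            mis.append(1.0 - ground_state_accuracy(res, truth))
        assert np.mean(mis) < 0.01

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(60)
        a = vb_cluster_1d(x, seed=11)
        b = vb_cluster_1d(x, seed=11)
        assert (a.assignments == b.assignments).all()


class TestGroundStateAccuracy:
    def test_perfect_separation(self):
        res = ClusteringResult(
            assignments=np.r_[np.zeros(40, int), np.ones(60, int)],
            component_means={0: 0.0, 1: 2.0},
            ground_state=0,
            n_effective_components=2,
        )
        truth = np.r_[np.zeros(40, bool), np.ones(60, bool)]
        assert ground_state_accuracy(res, truth) == 1.0

    def test_single_component_collapse_scores_inactive_fraction(self):
        res = ClusteringResult(
            assignments=np.zeros(100, int),
            component_means={0: 1.0},
            ground_state=0,
            n_effective_components=1,
        )
        truth = np.r_[np.zeros(40, bool), np.ones(60, bool)]
        assert ground_state_accuracy(res, truth) == pytest.approx(0.40)

    def test_invariant_to_component_relabelling(self, rng):
        labels = rng.integers(0, 3, 50)
        truth = rng.random(50) > 0.5
        means = {0: -1.0, 1: 0.5, 2: 2.0}
        a = ClusteringResult(labels, means, 0, 3)
        relabelled = {0: 2, 1: 0, 2: 1}
        b = ClusteringResult(
            np.vectorize(relabelled.get)(labels),
            {relabelled[k]: v for k, v in means.items()},
            relabelled[0],
            3,
        )
        assert ground_state_accuracy(a, truth) == ground_state_accuracy(b, truth)

    def test_random_two_way_assignment_near_half(self, rng):
        truth = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        accs = []
        for _ in range(200):
            res = ClusteringResult(rng.integers(0, 2, 100), {0: 0.0, 1: 1.0}, 0, 2)
            accs.append(ground_state_accuracy(res, truth))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.02)


class TestWilcoxonHelpers:
    def test_identical_vectors_p_one(self):
        assert paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
        assert compare_methods_V([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_constant_shift_significant_at_n20(self, rng):
        v2 = rng.standard_normal(20)
        assert compare_methods_V(v2 + 1.0, v2) < 0.01

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(15)
        assert paired_wilcoxon(a, b) == pytest.approx(paired_wilcoxon(b, a))


class TestInterpathwayCorrelation:
    def test_identical_profiles_max_association(self, rng):
        x = rng.standard_normal(50)
        t, p = interpathway_correlation(x, x)
        assert t >= 1e6 and p == 0.0

    def test_anticorrelated_profiles_negative_t(self, rng):
        x = rng.standard_normal(100)
        t, p = interpathway_correlation(x, -x + rng.normal(0, 0.05, 100))
        assert t < -20 and p < 1e-10

    def test_independent_profiles_rarely_extreme(self):
        extreme = 0
        for s in range(200):
            r = np.random.default_rng(s)
            t, _ = interpathway_correlation(r.standard_normal(200), r.standard_normal(200))
            extreme += abs(t) >= 3
        assert extreme <= 4  # P(|t| >= 3) ~ 0.003 at 198 df

    def test_needs_four_samples(self):
        with pytest.raises(ValueError):
            interpathway_correlation(np.ones(3), np.ones(3))


class TestVScore:
    def test_direct_evaluation(self):
        assert consistency_score_V(2.0, 0.01, [(3.0, 0.01)]) == pytest.approx(3.0)
        assert consistency_score_V(2.0, 0.01, [(3.0, 0.06)]) == 0.0
        assert consistency_score_V(2.0, 0.01, [(-2.5, 0.02)]) == pytest.approx(-2.5)
        assert consistency_score_V(2.0, 0.01, []) == 0.0

    def test_additive_over_validation_sets(self):
        sets = [(3.0, 0.01), (-2.5, 0.02), (1.5, 0.2)]
        total = consistency_score_V(2.0, 0.01, sets)
        parts = sum(consistency_score_V(2.0, 0.01, [s]) for s in sets)
        assert total == pytest.approx(parts)

    def test_non_hypothesis_rejected(self):
        with pytest.raises(ValueError):
            consistency_score_V(2.0, 0.2, [(3.0, 0.01)])


class TestPhenotypeAssociation:
    def test_separated_groups_tiny_p(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        groups = np.r_[np.zeros(30), np.ones(30)]
        p = phenotype_association(scores, groups, test="t_one_tailed", direction="greater")
        assert p < 1e-6
        # wrong direction: association invisible
        p_wrong = phenotype_association(scores, groups, test="t_one_tailed", direction="less")
        assert p_wrong > 0.99

    def test_permutation_resolution_add_one(self, rng):
        scores = np.arange(30, dtype=float)
        cov = scores + rng.normal(0, 0.01, 30)
        p = phenotype_association(scores, cov, test="permutation_regression",
                                  n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self, rng):
        scores = rng.standard_normal(40)
        cov = rng.standard_normal(40)
        kw = dict(test="permutation_regression", n_perm=200, seed=8)
        assert phenotype_association(scores, cov, **kw) == phenotype_association(scores, cov, **kw)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            phenotype_association(rng.standard_normal(10), np.ones(10))


class TestBenchmark:
    def test_small_benchmark_shapes_and_determinism(self):
        r1 = benchmark_simulation("simset2", n_reps=3, seed=0)
        r2 = benchmark_simulation("simset2", n_reps=3, seed=0)
        assert r1.accuracies.shape == (3, 3)
        assert list(r1.accuracies.columns) == ["UPR-AV", "PR-AV", "DART"]
        assert r1.accuracies.equals(r2.accuracies)
        assert set(r1.wilcoxon) == {
            ("UPR-AV", "PR-AV"), ("UPR-AV", "DART"), ("PR-AV", "DART")
        }
        assert ((r1.accuracies >= 0) & (r1.accuracies <= 1)).all().all()

    def test_noise_free_limit_all_methods_perfect(self):
        from dart.simulate import SimConfig

        cfg = SimConfig(sigma1=1e-6, sigma2=1e-6, noise_sd=1e-6)
        r = benchmark_simulation("simset1", n_reps=3, seed=1, cfg=cfg)
        assert (r.accuracies.to_numpy() == 1.0).all()
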