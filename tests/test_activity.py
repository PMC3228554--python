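import numpy as np
import pandas as pd
import pytest

from dart import (
    EmptyComponentError,
    PathwaySignature,
    activity_unweighted,
    activity_weighted,
    estimate_activity,
    max_connected_component,
    run_dart,
    simset2,
    zscore,
)
from dart.simulate import SimConfig

from conftest import make_network


class TestZscore:
    def test_hand_population_zscore(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"])
        Z, stats = zscore(X)
        np.testing.assert_allclose(Z.loc["A"], [-1.224744871, 0.0, 1.224744871], atol=1e-9)
        assert stats.loc["A", "mean"] == 2.0

    def test_idempotent_on_standardised_rows(self, rng):
        x = rng.standard_normal(50)
        x = (x - x.mean()) / x.std()
        X = pd.DataFrame([x], index=["A"])
        Z, _ = zscore(X)
        np.testing.assert_allclose(Z.loc["A"], x, atol=1e-12)

    def test_constant_gene_dropped(self, rng):
        X = pd.DataFrame({"A": rng.standard_normal(10), "B": np.ones(10)}).T
        Z, _ = zscore(X)
        assert list(Z.index) == ["A"]

    def test_sample_sd_option(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"])
        Z, _ = zscore(X, ddof=1)
        assert Z.loc["A"].std(ddof=1) == pytest.approx(1.0)


class TestUnweightedMetric:
    def test_single_up_gene_is_its_z_profile(self, rng):
        X = pd.DataFrame([rng.standard_normal(20)], index=["A"])
        Z, _ = zscore(X)
        prof = activity_unweighted(Z, {"A": 1})
        np.testing.assert_allclose(prof.scores, Z.loc["A"])

    def test_opposed_pair_averages_to_up_profile(self, rng):
        zup = rng.standard_normal(30)
        zup = (zup - zup.mean()) / zup.std()
        Z = pd.DataFrame({"up": zup, "down": -zup}).T
        prof = activity_unweighted(Z, {"up": 1, "down": -1})
        np.testing.assert_allclose(prof.scores, zup, atol=1e-12)  # (z - (-z))/2

    def test_flipping_signs_negates_scores(self, rng):
        Z = pd.DataFrame(rng.standard_normal((4, 25)), index=list("ABCD"))
        signs = {"A": 1, "B": 1, "C": -1, "D": 1}
        s1 = activity_unweighted(Z, signs).scores
        s2 = activity_unweighted(Z, {g: -s for g, s in signs.items()}).scores
        np.testing.assert_allclose(s1, -s2)


class TestWeightedMetric:
    def _component(self, edges, signs):
        sig = PathwaySignature("s", signs)
        return max_connected_component(make_network(edges), sig)

    def test_equal_degrees_proportional_to_average(self, rng):
        signs = {"A": 1, "B": 1, "C": -1}
        comp = self._component([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)], signs)
        Z = pd.DataFrame(rng.standard_normal((3, 40)), index=["A", "B", "C"])
        weighted = activity_weighted(Z, comp).scores
        unweighted = activity_unweighted(Z, signs).scores
        # all degrees k: norm = k*sqrt(M) so weighted = sqrt(M) * average
        np.testing.assert_allclose(weighted, np.sqrt(3) * unweighted, atol=1e-12)

    def test_star_weights(self, rng):
        signs = {"H": 1, "L1": 1, "L2": 1, "L3": 1}
        comp = self._component([("H", "L1", 1), ("H", "L2", 1), ("H", "L3", 1)], signs)
        Z = pd.DataFrame(rng.standard_normal((4, 10)), index=["H", "L1", "L2", "L3"])
        prof = activity_weighted(Z, comp)
        expected = (3 * Z.loc["H"] + Z.loc["L1"] + Z.loc["L2"] + Z.loc["L3"]) / np.sqrt(12)
        np.testing.assert_allclose(prof.scores, expected, atol=1e-12)
        assert prof.weights["H"] == 3

    def test_unit_variance_for_independent_inputs(self, rng):
        # the 1/sqrt(sum k^2) normalisation keeps the score unit-variance
        signs = {g: 1 for g in "ABCDE"}
        comp = self._component(
            [("A", "B", 1), ("B", "C", 1), ("C", "D", 1), ("D", "E", 1), ("A", "C", 1)],
            signs,
        )
        n = 10_000
        Z = pd.DataFrame(rng.standard_normal((5, n)), index=list("ABCDE"))
        var = activity_weighted(Z, comp).scores.var()
        assert 0.8 < var < 1.2


class TestRunDart:
    def test_recovers_faithful_genes_and_separates_samples(self):
        data = simset2(SimConfig(seed=0))
        res = run_dart(data.X, data.signature(), seed=0)
        assert {"g01", "g02", "g03"} <= set(res.component.nodes)
        active_scores = res.activity.scores[data.active]
        inactive_scores = res.activity.scores[~data.active]
        assert active_scores.mean() > inactive_scores.mean() + 1.0
        assert res.consistency.p_value <= 0.05

    def test_uncorrelated_genes_error_then_fallback(self, rng):
        X = pd.DataFrame(rng.standard_normal((2, 40)), index=["A", "B"])
        sig = PathwaySignature("s", {"A": 1, "B": 1})
        with pytest.raises(EmptyComponentError):
            run_dart(X, sig, p_threshold=1e-6)
        res = run_dart(X, sig, p_threshold=1e-6, fallback_unpruned=True)
        assert res.fallback_used
        assert res.activity.method == "UPR-AV"

    def test_test_cohort_equal_to_train_gives_identical_scores(self):
        data = simset2(SimConfig(seed=1))
        sig = data.signature()
        train_only = run_dart(data.X, sig, seed=5)
        both = run_dart(data.X, sig, X_test=data.X.copy(), seed=5)
        np.testing.assert_allclose(both.test_activity.scores, train_only.activity.scores)

    def test_methods_dispatch(self):
        data = simset2(SimConfig(seed=2))
        sig = data.signature()
        res = run_dart(data.X, sig, seed=2)
        pr = estimate_activity(data.X, sig, "PR-AV", comp=res.component)
        upr = estimate_activity(data.X, sig, "UPR-AV")
        assert set(pr.genes_used) == set(res.component.nodes)
        assert set(upr.genes_used) == set(data.X.index)
        with pytest.raises(ValueError):
            estimate_activity(data.X, sig, "PR-AV")  # needs a component

    def test_scores_invariant_to_gene_and_sample_order(self):
        data = simset2(SimConfig(seed=3))
        sig = data.signature()
        base = run_dart(data.X, sig, seed=0).activity
        shuffled = data.X.iloc[::-1, ::-1]
        perm = run_dart(shuffled, sig, seed=0).activity
        s1 = base.to_series().sort_index()
        s2 = perm.to_series().sort_index()
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)
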