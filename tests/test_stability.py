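import numpy as np
import pytest

from destab import (
    CountMatrix,
    PerturbationConfig,
    SelectionSet,
    SimulationConfig,
    aucor,
    aucor_stratified,
    ave_curve,
    compute_aucor,
    constant_set,
    phi_similarity,
    proportion_intersection,
    simulate_dataset,
)
from destab.stability import CorrelationCurve


def sel(G, members):
    ind = np.zeros(G, dtype=bool)
    ind[list(members)] = True
    return SelectionSet(ind)


class TestPhiSimilarity:
    def test_self_similarity_is_one(self):
        s = sel(10, [0, 1, 2])
        assert phi_similarity(s, s) == pytest.approx(1.0)

    def test_disjoint_sets_truncate_to_zero(self):
        assert phi_similarity(sel(10, [0, 1, 2]), sel(10, [3, 4, 5])) == 0.0

    def test_worked_example_eleven_over_twentyone(self):
        # G=10, k1=k2=3, intersection 2: (2 - 9/10) / (10 * 0.21) = 11/21
        val = phi_similarity(sel(10, [0, 1, 2]), sel(10, [1, 2, 3]))
        assert val == pytest.approx(11 / 21, abs=1e-12)

    def test_degenerate_sets_give_zero(self):
        assert phi_similarity(sel(10, []), sel(10, [1])) == 0.0
        assert phi_similarity(sel(10, range(10)), sel(10, [1])) == 0.0

    def test_matches_pearson_on_random_pairs(self, rng):
        """Brute-force oracle: phi == max(0, corrcoef of indicator vectors)."""
        for _ in range(1000):
            G = int(rng.integers(2, 51))
            a = rng.random(G) < rng.random()
            b = rng.random(G) < rng.random()
            s1, s2 = SelectionSet(a), SelectionSet(b)
            k1, k2 = a.sum(), b.sum()
            if k1 in (0, G) or k2 in (0, G):
                expected = 0.0
            else:
                expected = max(0.0, np.corrcoef(a, b)[0, 1])
            assert phi_similarity(s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_relabeling_invariant(self, rng):
        G = 30
        a = rng.random(G) < 0.3
        b = rng.random(G) < 0.3
        perm = rng.permutation(G)
        assert phi_similarity(SelectionSet(a), SelectionSet(b)) == pytest.approx(
            phi_similarity(SelectionSet(b), SelectionSet(a))
        )
        assert phi_similarity(SelectionSet(a[perm]), SelectionSet(b[perm])) == pytest.approx(
            phi_similarity(SelectionSet(a), SelectionSet(b))
        )

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            phi_similarity(sel(10, [1]), sel(12, [1]))


class TestProportionIntersection:
    def test_worked_example(self):
        val = proportion_intersection(sel(20, range(4)), sel(20, [0, 1, 2, 10, 11, 12]))
        assert val == pytest.approx(0.6)

    def test_identical_sets(self):
        s = sel(10, [1, 2])
        assert proportion_intersection(s, s) == 1.0

    def test_disjoint_and_empty(self):
        assert proportion_intersection(sel(10, [0]), sel(10, [1])) == 0.0
        assert proportion_intersection(sel(10, []), sel(10, [])) == 0.0


class TestAucorArithmetic:
    def _curve(self, alphas, ave):
        return CorrelationCurve(
            alphas=np.asarray(alphas, dtype=float),
            ave=np.asarray(ave, dtype=float),
            per_replicate=np.empty((0, len(alphas) - 1)),
            M=0,
        )

    def test_trapezoid_example(self):
        assert aucor(self._curve([0, 0.05, 0.1], [1, 0.8, 0.6])) == pytest.approx(0.8)

    def test_constant_one(self):
        assert aucor(self._curve([0, 0.05, 0.1], [1, 1, 1])) == pytest.approx(1.0)

    def test_single_grid_point(self):
        assert aucor(self._curve([0, 0.1], [1, 0])) == pytest.approx(0.5)

    def test_non_monotone_alphas_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            aucor(self._curve([0, 0.1, 0.05], [1, 1, 1]))

    def test_refining_a_linear_curve_is_exact(self):
        coarse = self._curve([0, 0.1], [1.0, 0.4])
        fine_alphas = np.linspace(0, 0.1, 11)
        fine = self._curve(fine_alphas, 1.0 - 6.0 * fine_alphas)
        assert aucor(coarse) == pytest.approx(aucor(fine))


@pytest.fixture(scope="module")
def dataset():
    cfg = SimulationConfig(n_features=2000, n_per_group=3, seed=1)
    cm, design, truth, _ = simulate_dataset(cfg)
    return cm, design, truth


class TestAveCurve:
    def test_anchor_and_range(self, dataset):
        cm, design, _ = dataset
        config = PerturbationConfig(n_grid=3, M=2, seed=0)
        curve = ave_curve(cm, design, "nb_wald", config)
        assert curve.alphas[0] == 0.0 and curve.ave[0] == 1.0
        assert np.all((curve.ave >= 0) & (curve.ave <= 1))
        assert np.all((curve.per_replicate >= 0) & (curve.per_replicate <= 1))
        assert np.allclose(curve.ave[1:], curve.per_replicate.mean(axis=0))

    def test_empty_selection_gives_all_zero_curve(self, dataset, caplog):
        cm, design, _ = dataset
        config = PerturbationConfig(n_grid=2, M=2, seed=0)
        # Welch at 3v3 cannot clear BH here: the SAMseq regime
        with caplog.at_level("WARNING"):
            curve = ave_curve(cm, design, "logcpm_welch", config)
        assert np.all(curve.ave == 0.0)
        assert aucor(curve) == 0.0

    def test_small_alpha_more_similar_than_large(self, dataset):
        cm, design, _ = dataset
        config = PerturbationConfig(n_grid=10, M=5, seed=3)
        curve = ave_curve(cm, design, "nb_wald", config)
        assert curve.ave[1] > curve.ave[-1]  # Ave(0.01) > Ave(0.10)


class TestComputeAucor:
    def test_constant_method_is_fixed_point(self, dataset):
        """A data-ignoring method has Ave == 1 and AUCOR == 1; use a set of
        well-expressed features so the universal zero-count filter never
        touches it."""
        cm, design, _ = dataset
        means = cm.counts.mean(axis=1)
        k = 100
        idx = np.argsort(-means)[:k]

        def method(cm_, design_, rng_):
            p = np.ones(cm_.n_features)
            p[idx] = 1e-12
            return p

        method.name = "constant_highexpr"
        res = compute_aucor(cm, design, method, PerturbationConfig(n_grid=5, M=3, seed=0))
        assert res.aucor == pytest.approx(1.0)
        assert np.all(res.curve.ave == 1.0)

    def test_random_k_near_floor(self):
        cfg = SimulationConfig(n_features=10_000, n_per_group=3, seed=4)
        cm, design, _, _ = simulate_dataset(cfg)
        res = compute_aucor(
            cm, design, "random_k:100", PerturbationConfig(n_grid=10, M=5, seed=4)
        )
        assert res.aucor < 0.2

    def test_insensitive_to_alpha_max_near_default(self, dataset):
        cm, design, _ = dataset
        a_low = compute_aucor(
            cm, design, "nb_wald", PerturbationConfig(alpha_max=0.08, n_grid=8, M=3, seed=7)
        ).aucor
        a_high = compute_aucor(
            cm, design, "nb_wald", PerturbationConfig(alpha_max=0.12, n_grid=8, M=3, seed=7)
        ).aucor
        assert abs(a_low - a_high) < 0.1


class TestStratified:
    def test_quartile_sizes_and_range(self, dataset):
        cm, design, _ = dataset
        res = aucor_stratified(cm, design, "nb_wald", PerturbationConfig(n_grid=3, M=2, seed=0))
        assert set(res) == {"Q1", "Q2", "Q3", "Q4"}
        for r in res.values():
            assert 0.0 <= r.aucor <= 1.0

    def test_high_abundance_more_stable(self, dataset):
        cm, design, _ = dataset
        res = aucor_stratified(cm, design, "nb_wald", PerturbationConfig(n_grid=5, M=3, seed=2))
        assert res["Q4"].aucor > res["Q1"].aucor

    def test_degenerate_quartiles_rejected(self):
        counts = np.ones((20, 4), dtype=int)
        cm = CountMatrix(counts, [f"g{i}" for i in range(20)], ["a1", "a2", "b1", "b2"])
        from destab import GroupDesign

        with pytest.raises(ValueError, match="quartile"):
            aucor_stratified(
                cm, GroupDesign(["A", "A", "B", "B"]), "nb_wald", PerturbationConfig()
            )
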