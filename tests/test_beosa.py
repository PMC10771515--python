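"""Binary optimizer: population contract, update arithmetic, transfer-based
binarization, wrapper fitness, and end-to-end search behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinfuse import beosa
from twinfuse.beosa import BeosaConfig, BinaryIndividual


def _ind(pos):
    pos = np.asarray(pos)
    return BinaryIndividual(index=0, pos=pos, shadow=pos.astype(float))


class TestInitPopulation:
    def test_binary_contract(self):
        pop = beosa.init_population(2, 4, seed=0)
        assert len(pop) == 2
        for ind in pop:
            assert set(np.unique(ind.pos)) <= {0, 1}
            assert ind.pos.shape == ind.shadow.shape == (4,)
            assert ind.fitness == beosa.UNSET_FITNESS

    def test_deterministic_under_seed(self):
        a = beosa.init_population(3, 1, seed=7)
        b = beosa.init_population(3, 1, seed=7)
        assert all((x.pos == y.pos).all() for x, y in zip(a, b))

    def test_one_bit_fraction_near_half(self):
        pop = beosa.init_population(200, 10, seed=1)
        frac = np.mean([ind.pos.mean() for ind in pop])
        assert 0.45 <= frac <= 0.55

    @pytest.mark.parametrize("pop_size,dim", [(1, 4), (0, 4), (3, 0)])
    def test_invalid_sizes(self, pop_size, dim):
        with pytest.raises(ValueError):
            beosa.init_population(pop_size, dim, seed=0)


class TestPositionUpdate:
    def test_zero_when_equal(self):
        ind, best = _ind([1, 0, 1]), _ind([1, 0, 1])
        out = beosa.position_update(ind, best, delta=0.7, rand=0.3)
        assert np.allclose(out, 0.0)

    def test_identity_scaling(self):
        out = beosa.position_update(_ind([1, 0]), _ind([0, 1]), delta=1.0, rand=0.0)
        assert np.allclose(out, [1.0, -1.0])  # e^0 cos 0 = 1

    def test_closed_form(self):
        ind, best = _ind([1, 0, 0]), _ind([0, 0, 1])
        out = beosa.position_update(ind, best, delta=0.5, rand=0.25)
        expected = 0.5 * np.exp(0.25) * np.cos(np.pi / 2) * np.array([1.0, 0.0, -1.0])
        assert np.allclose(out, expected, atol=1e-12)
        assert np.allclose(out, 0.0, atol=1e-12)  # cos(pi/2) kills the move

    def test_stores_shadow(self):
        ind = _ind([1, 0])
        out = beosa.position_update(ind, _ind([0, 0]), delta=2.0, rand=0.0)
        assert (ind.shadow == out).all()

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            beosa.position_update(_ind([1, 0]), _ind([1, 0, 0]), 1.0, 0.0)


class TestBinarize:
    def test_sigmoid_limit(self):
        rng = np.random.default_rng(0)
        bits = beosa.binarize(np.full(100, -60.0), "S", rng)
        assert (bits == 1).all()  # S(-inf) -> 0 so r > S almost surely

    def test_zero_shadow_is_fair_coin(self):
        rng = np.random.default_rng(1)
        draws = np.concatenate(
            [beosa.binarize(np.zeros(100), "S", rng) for _ in range(100)])
        assert 0.48 <= draws.mean() <= 0.52

    def test_v_zero_point(self):
        rng = np.random.default_rng(2)
        bits = np.array([beosa.binarize(np.zeros(1), "V", rng)[0] for _ in range(50)])
        assert (bits == 1).all()  # V(0)=0 and r > 0 almost surely

    def test_flipped_rule(self):
        rng = np.random.default_rng(3)
        bits = beosa.binarize(np.full(200, -60.0), "S", rng, printed_rule=False)
        assert (bits == 0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            beosa.binarize(np.array([0.0, np.nan]), "S", np.random.default_rng(0))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=16),
           st.sampled_from(["S", "V"]))
    def test_always_binary(self, shadow, transfer):
        bits = beosa.binarize(np.asarray(shadow), transfer, np.random.default_rng(0))
        assert set(np.unique(bits)) <= {0, 1}


class TestFeatureFitness:
    def test_perfect_classifier_all_features(self):
        # one feature fully determines the label -> CV accuracy 1.0
        y = np.array([0] * 30 + [1] * 30)
        X = y[:, None].astype(float)
        fit = beosa.feature_fitness(np.ones(1, dtype=int), X, y, seed=0)
        assert fit == pytest.approx(0.99 * 0.0 + 0.01 * 1.0)

    def test_arithmetic_midpoint(self):
        # acc 0.5 with half the features selected -> 0.99*0.5 + 0.01*0.5
        assert 0.99 * 0.5 + 0.01 * 0.5 == 0.5

    def test_all_zero_mask_is_worst_case(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        y = np.array([0, 1] * 10)
        assert beosa.feature_fitness(np.zeros(4, dtype=int), X, y) == 1.0

    def test_oracle_mask_beats_all_ones(self):
        fm, y, mask = __import__("twinfuse").synthetic.gen_feature_matrix(
            n=120, dim=8, informative=[1, 6], effect=3.0, seed=2)
        f_oracle = beosa.feature_fitness(mask, fm, y, seed=0)
        f_full = beosa.feature_fitness(np.ones(8, dtype=int), fm, y, seed=0)
        assert f_oracle < f_full

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            beosa.feature_fitness(np.ones(3, dtype=int), np.zeros((5, 4)),
                                  np.zeros(5))


class TestApplyMask:
    def test_identity(self):
        X = np.arange(12.0).reshape(3, 4)
        assert (beosa.apply_mask(X, np.ones(4)) == X).all()

    def test_empty_selection(self):
        out = beosa.apply_mask(np.zeros((3, 4)), np.zeros(4))
        assert out.shape == (3, 0)

    def test_column_order_preserved(self):
        X = np.array([[1.0, 2.0, 3.0]])
        assert (beosa.apply_mask(X, [1, 0, 1]) == [[1.0, 3.0]]).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            beosa.apply_mask(np.zeros((2, 3)), [1, 0])


class TestOptimize:
    def test_constant_objective_flat_history(self):
        res = beosa.optimize(5, lambda p: 1.25, BeosaConfig(pop_size=6, max_iter=10, seed=0))
        assert res.history == [1.25] * 10
        assert res.best.fitness == 1.25

    def test_recovers_hidden_hamming_target(self):
        target = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1])
        res = beosa.optimize(
            12, lambda p: int(np.sum(p != target)),
            BeosaConfig(pop_size=20, max_iter=50, seed=3))
        assert res.best.fitness == 0  # exhaustive minimum over 2^12 masks
        assert (res.best.pos == target).all()

    def test_binary_closure_every_evaluation(self):
        seen = []

        def fit(pos):
            seen.append(set(np.unique(pos)) <= {0, 1})
            return float(pos.sum())

        beosa.optimize(6, fit, BeosaConfig(pop_size=4, max_iter=8, seed=1))
        assert seen and all(seen)

    def test_history_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=10)
        res = beosa.optimize(10, lambda p: float(p @ w),
                             BeosaConfig(pop_size=10, max_iter=25, seed=5))
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))
        assert len(res.history) == 25

    def test_bit_identical_determinism(self):
        cfg = BeosaConfig(pop_size=8, max_iter=15, seed=11)
        f = lambda p: float(p.sum())
        r1 = beosa.optimize(7, f, cfg)
        r2 = beosa.optimize(7, f, cfg)
        assert (r1.best.pos == r2.best.pos).all()
        assert r1.best.fitness == r2.best.fitness
        assert r1.history == r2.history
        assert r1.evaluations == r2.evaluations

    def test_beats_random_search_baseline(self, informative_matrix):
        fm, y, _ = informative_matrix
        fitness = lambda m: beosa.feature_fitness(m, fm, y, seed=0)
        res = beosa.optimize(10, fitness, BeosaConfig(pop_size=20, max_iter=20, seed=6))
        rng = np.random.default_rng(7)
        random_best = min(
            fitness(rng.integers(0, 2, size=10)) for _ in range(res.evaluations))
        assert res.best.fitness <= random_best

    def test_fitness_error_carries_context(self):
        def bad(pos):
            raise ValueError("boom")

        with pytest.raises((RuntimeError, ValueError)):
            beosa.optimize(4, bad, BeosaConfig(pop_size=4, max_iter=3, seed=0))

    @pytest.mark.parametrize("kwargs", [
        dict(pop_size=1), dict(max_iter=0), dict(srate=1.5), dict(transfer="X"),
    ])
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            BeosaConfig(**kwargs)
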