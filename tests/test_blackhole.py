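"""Black-hole optimizer: move/horizon arithmetic, elitism, convergence."""

from __future__ import annotations

import numpy as np
import pytest

from emobh.blackhole import (
    BlackHoleOptions,
    EvalContext,
    SearchSpace,
    Star,
    absorb_or_keep,
    evaluate,
    event_horizon,
    init_population,
    move_star,
    optimize,
)
from emobh.classifier import SvmConfig, accuracy, train


def unit_space(dim=3, mode="feature_perturbation"):
    return SearchSpace(
        mode=mode, lower=np.zeros(dim), upper=np.full(dim, 10.0), n_features=dim
    )


def toy_objective(space, c):
    """f(x) = 1 - min(1, ||x - c|| / ||bounds||): maximal at the hidden c."""
    scale = np.linalg.norm(space.width)

    def fit(star: Star) -> float:
        star.fitness = 1.0 - min(1.0, np.linalg.norm(star.position - c) / scale)
        return star.fitness

    return fit


class TestMoveStar:
    def test_absorption_arithmetic(self):
        class FixedAlpha:
            def uniform(self, low=0.0, high=1.0, size=None):
                return 0.5

        out = move_star(np.array([0.0]), np.array([10.0]), FixedAlpha())
        assert out[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("alpha, expected", [(0.0, 0.0), (1.0, 10.0)])
    def test_alpha_extremes(self, alpha, expected):
        class Fixed:
            def uniform(self, low=0.0, high=1.0, size=None):
                return alpha

        out = move_star(np.array([0.0]), np.array([10.0]), Fixed())
        assert out[0] == pytest.approx(expected)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            move_star(np.zeros(3), np.zeros(4), rng)

    def test_single_alpha_moves_collinearly(self, rng):
        # One scalar alpha: the move stays on the segment star -> black hole.
        x = np.array([0.0, 0.0, 0.0])
        bh = np.array([2.0, 4.0, 8.0])
        out = move_star(x, bh, rng)
        ratios = out / bh
        assert np.allclose(ratios, ratios[0])


class TestEventHorizon:
    def test_worked_example(self):
        assert event_horizon(0.9, [0.9, 0.1, 0.8]) == pytest.approx(0.5)

    def test_equal_fitnesses_give_one_over_n(self):
        for n in (2, 5, 30):
            assert event_horizon(0.7, [0.7] * n) == pytest.approx(1.0 / n)

    def test_radius_in_unit_interval(self, rng):
        for _ in range(50):
            f = rng.uniform(0.01, 1.0, size=10)
            r = event_horizon(f.max(), f.tolist())
            assert 0.0 < r <= 1.0

    def test_exclude_bh_variant(self):
        assert event_horizon(0.9, [0.9, 0.1, 0.8], exclude_bh=True) == pytest.approx(1.0)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            event_horizon(0.0, [0.0, 0.0])


class TestInitPopulation:
    def test_zero_error_collapses_to_base(self, rng):
        space = unit_space()
        base = np.full(3, 5.0)
        stars = init_population(base, 10, 0.0, rng, space)
        assert len(stars) == 10
        for s in stars:
            np.testing.assert_array_equal(s.position, base)

    def test_thirty_stars(self, rng):
        stars = init_population(np.full(3, 5.0), 30, 0.3, rng, unit_space())
        assert len(stars) == 30

    def test_star_zero_is_base_and_rest_in_bounds(self, rng):
        space = unit_space()
        base = np.full(3, 5.0)
        stars = init_population(base, 20, 0.5, rng, space)
        np.testing.assert_array_equal(stars[0].position, base)
        for s in stars[1:]:
            assert np.all(s.position >= space.lower) and np.all(s.position <= space.upper)

    def test_seeded_determinism(self):
        space = unit_space()
        base = np.full(3, 5.0)
        p1 = init_population(base, 10, 0.4, np.random.default_rng(3), space)
        p2 = init_population(base, 10, 0.4, np.random.default_rng(3), space)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.position, b.position)

    def test_tiny_population_rejected(self, rng):
        with pytest.raises(ValueError):
            init_population(np.zeros(3), 1, 0.1, rng, unit_space())


class TestAbsorbOrKeep:
    def test_star_at_bh_position_replaced(self, rng):
        space = unit_space()
        star = Star(position=np.full(3, 5.0), fitness=0.5)
        bh = Star(position=np.full(3, 5.0), fitness=0.9)
        out = absorb_or_keep(star, bh, R=0.1, rng=rng, space=space)
        assert out is not star

    def test_zero_radius_never_replaces(self, rng):
        space = unit_space()
        star = Star(position=np.full(3, 4.0), fitness=0.5)
        bh = Star(position=np.full(3, 5.0), fitness=0.9)
        out = absorb_or_keep(star, bh, R=0.0, rng=rng, space=space)
        assert out is star

    def test_replacement_reproducible_per_seed(self):
        space = unit_space()
        star = Star(position=np.full(3, 5.0), fitness=0.5)
        bh = Star(position=np.full(3, 5.0), fitness=0.9)
        o1 = absorb_or_keep(star, bh, 0.5, np.random.default_rng(1), space)
        o2 = absorb_or_keep(star, bh, 0.5, np.random.default_rng(1), space)
        np.testing.assert_array_equal(o1.position, o2.position)

    def test_probability_rule(self):
        space = unit_space()
        star = Star(position=np.full(3, 0.0), fitness=0.5)
        bh = Star(position=np.full(3, 10.0), fitness=0.9)
        # R = 1: any u < 1 absorbs regardless of the (large) distance.
        out = absorb_or_keep(star, bh, 1.0, np.random.default_rng(0), space, rule="probability")
        assert out is not star


class TestOptimize:
    def test_toy_convergence_and_monotone_trace(self):
        space = unit_space(dim=4)
        c = np.array([7.0, 2.0, 9.0, 4.0])
        wins = 0
        for seed in range(5):
            res = optimize(
                space,
                ctx=None,
                n=30,
                T=100,
                seed=seed,
                fitness_fn=toy_objective(space, c),
                base=np.full(4, 5.0),
                error0=0.5,
            )
            assert res.trace.size == 100
            assert np.all(np.diff(res.trace) >= 0)
            if res.best_fitness >= 0.95:
                wins += 1
        assert wins >= 4

    def test_t_zero_returns_initial_best(self):
        space = unit_space(dim=2)
        c = np.array([5.0, 5.0])
        res = optimize(
            space, ctx=None, n=10, T=0, seed=0,
            fitness_fn=toy_objective(space, c), base=np.full(2, 1.0), error0=0.5,
        )
        assert res.trace.size == 0
        assert res.best_fitness > 0.0

    def test_trace_determinism(self):
        space = unit_space(dim=3)
        c = np.array([1.0, 2.0, 3.0])
        kwargs = dict(ctx=None, n=15, T=30, seed=11,
                      fitness_fn=toy_objective(space, c), base=np.full(3, 5.0), error0=0.5)
        r1 = optimize(space, **kwargs)
        r2 = optimize(space, **kwargs)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_final_best_at_least_base_fitness(self):
        space = unit_space(dim=3)
        c = np.array([8.0, 8.0, 8.0])
        fit = toy_objective(space, c)
        base = np.full(3, 2.0)
        base_fitness = fit(Star(position=base.copy()))
        res = optimize(space, ctx=None, n=10, T=20, seed=2,
                       fitness_fn=fit, base=base, error0=0.3)
        assert res.best_fitness >= base_fitness


class TestClassifierEvaluation:
    def test_base_star_fitness_equals_baseline_accuracy(self, blobs):
        X, y = blobs
        ctx = EvalContext(X_train=X[::2], y_train=y[::2], X_eval=X[1::2], y_eval=y[1::2])
        space = SearchSpace.for_features(ctx.X_train, mode="both")
        base = space.base_position(ctx.base_config, ctx.X_train)
        baseline_model = train(ctx.X_train, ctx.y_train, SvmConfig())
        baseline_acc = accuracy(baseline_model, ctx.X_eval, ctx.y_eval)
        star = Star(position=base)
        assert evaluate(star, space, ctx) == pytest.approx(baseline_acc)

    def test_evaluation_deterministic(self, blobs, rng):
        X, y = blobs
        ctx = EvalContext(X_train=X[::2], y_train=y[::2], X_eval=X[1::2], y_eval=y[1::2])
        space = SearchSpace.for_features(ctx.X_train, mode="both")
        pos = space.lower + rng.uniform(size=space.dimension) * space.width
        f1 = evaluate(Star(position=pos.copy()), space, ctx)
        f2 = evaluate(Star(position=pos.copy()), space, ctx)
        assert f1 == f2

    def test_out_of_bounds_position_rejected(self, blobs):
        X, y = blobs
        ctx = EvalContext(X_train=X[::2], y_train=y[::2], X_eval=X[1::2], y_eval=y[1::2])
        space = SearchSpace.for_features(ctx.X_train, mode="both")
        bad = space.upper + 1.0
        with pytest.raises(ValueError):
            evaluate(Star(position=bad), space, ctx)

    def test_population_matches_or_beats_base_quickly(self, blobs):
        # Elitist search on separable blobs: within 10 iterations some star
        # reaches at least the baseline fitness, for every seed tried.
        X, y = blobs
        ctx = EvalContext(X_train=X[::2], y_train=y[::2], X_eval=X[1::2], y_eval=y[1::2])
        space = SearchSpace.for_features(ctx.X_train, mode="both")
        base = space.base_position(ctx.base_config, ctx.X_train)
        base_fit = evaluate(Star(position=base.copy()), space, ctx)
        for seed in range(5):
            res = optimize(space, ctx, n=10, T=10, seed=seed)
            assert res.best_fitness >= base_fit
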