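"""Genetic operators and the evolutionary loop: structure, determinism,
selection statistics, and monotone best-fitness tracking."""

import math

import numpy as np
import pandas as pd
import pytest

from figp2.engine import (
    GPConfig,
    crossover,
    evolve,
    initialize_population,
    mutate,
    preset_config,
    structure_key,
    tournament_select,
)
from figp2.filters import DomainSpec, d2_filter, f_filter, v_filter
from figp2.fitness import StabilityConfig
from figp2.trees import ExpressionTree, Var, parse_formula, render_formula

from conftest import random_trees


@pytest.fixture
def small_dataset(rng):
    X = pd.DataFrame({"x": rng.uniform(0, 3, 30)})
    y = 1.5 * X["x"].to_numpy() + 4.0 + rng.normal(0, 0.05, 30)
    return X, y


def small_cfg(**kw):
    defaults = dict(population_size=20, n_generations=4, seed=0)
    defaults.update(kw)
    return GPConfig(**defaults)


class TestGPConfig:
    def test_defaults_match_standard_operating_point(self):
        cfg = GPConfig()
        assert cfg.population_size == 200
        assert cfg.n_generations == 200
        assert cfg.init_depth == (1, 2)
        assert cfg.crossover_prob == 0.7
        assert cfg.mutation_prob == 0.2
        assert cfg.mutation_depth == (0, 2)
        assert cfg.max_depth == 4
        assert cfg.tournament_size == 5
        assert set(cfg.operators) == {
            "+", "-", "*", "/", "sqrt", "square", "cube", "exp", "ln",
        }
        assert cfg.f_filter_groups == (
            frozenset({"sqrt"}),
            frozenset({"square", "cube"}),
            frozenset({"ln", "exp"}),
        )

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            GPConfig(crossover_prob=0.9, mutation_prob=0.2)
        with pytest.raises(ValueError):
            GPConfig(crossover_prob=-0.1)

    def test_presets(self):
        assert preset_config("GP").active_filters == ()
        assert preset_config("FIGP").active_filters == ("V", "F", "D")
        assert preset_config("FIGP2_D2").active_filters == ("V", "F", "D2")
        figp2 = preset_config("FIGP2")
        assert figp2.active_filters == ("V", "F", "D2")
        assert figp2.stability.metric_kind == "fitness_xc"
        assert figp2.stability.lambdas == (0.5, 0.5)


class TestCrossover:
    def test_identical_parents_give_structurally_equal_offspring(self, rng):
        t = parse_formula("square(x) + 1.0")
        c1, c2 = crossover(t, t, rng)
        assert structure_key(c1) == structure_key(t)
        assert structure_key(c2) == structure_key(t)

    def test_depth_zero_parents_swap_to_same_pair(self, rng):
        a, b = ExpressionTree(Var("x")), ExpressionTree(Var("y"))
        c1, c2 = crossover(a, b, rng)
        assert {render_formula(c1), render_formula(c2)} == {"x", "y"}

    def test_offspring_respect_depth_and_arity(self):
        gen = np.random.default_rng(17)
        pool = random_trees(40, ["a", "b"], (1, 4), 18)
        for _ in range(1000):
            i, j = gen.integers(len(pool), size=2)
            c1, c2 = crossover(pool[i], pool[j], gen, max_depth=4)
            assert c1.depth <= 4 and c2.depth <= 4
            # arity is enforced by construction: re-render to validate
            render_formula(c1), render_formula(c2)

    def test_parents_unmodified(self, rng):
        a = parse_formula("square(x) + 1.0")
        b = parse_formula("ln(x) - 2.0")
        sa, sb = render_formula(a), render_formula(b)
        crossover(a, b, rng)
        assert render_formula(a) == sa and render_formula(b) == sb


class TestMutate:
    def test_single_terminal_tree_fully_replaced(self, rng):
        cfg = small_cfg(mutation_depth=(1, 2))
        m = mutate(ExpressionTree(Var("x")), cfg, ["x", "y"], rng)
        assert m.depth >= 1

    def test_reproducible_under_seed(self, small_dataset):
        t = parse_formula("square(x) + 1.0")
        cfg = small_cfg()
        m1 = mutate(t, cfg, ["x"], np.random.default_rng(3))
        m2 = mutate(t, cfg, ["x"], np.random.default_rng(3))
        assert render_formula(m1) == render_formula(m2)

    def test_mutants_respect_structural_invariants(self):
        gen = np.random.default_rng(19)
        cfg = small_cfg()
        pool = random_trees(30, ["a", "b"], (0, 4), 20)
        for _ in range(1000):
            m = mutate(pool[int(gen.integers(len(pool)))], cfg, ["a", "b"], gen)
            assert m.depth <= cfg.max_depth
            render_formula(m)


class TestTournament:
    def test_full_size_tournament_returns_global_best(self, rng):
        pop = random_trees(10, ["x"], (0, 1), 33)
        fits = list(range(10))
        # tournament over the whole population with unique fitnesses
        picks = tournament_select(pop, fits, 20, size=10 * 50, rng=rng)
        assert all(p is pop[0] for p in picks)

    def test_size_one_is_uniform(self):
        pop = random_trees(4, ["x"], (0, 1), 34)
        fits = [3.0, 2.0, 1.0, 0.5]
        gen = np.random.default_rng(0)
        picks = tournament_select(pop, fits, 4000, size=1, rng=gen)
        counts = np.array([sum(p is q for p in picks) for q in pop])
        assert (counts > 800).all() and (counts < 1200).all()

    def test_pick_distribution_matches_order_statistics(self):
        n, k, draws = 20, 5, 10000
        pop = random_trees(n, ["x"], (0, 1), 35)
        fits = [float(i) for i in range(n)]  # rank == index
        gen = np.random.default_rng(1)
        picks = tournament_select(pop, fits, draws, size=k, rng=gen)
        index_of = {id(q): i for i, q in enumerate(pop)}
        ranks = np.array([index_of[id(p)] for p in picks])
        # P(winner rank <= r) = 1 - ((n-1-r)/n)^k for draws with replacement
        for r in (0, 4, 9, 14):
            p = 1.0 - ((n - 1 - r) / n) ** k
            observed = np.mean(ranks <= r)
            sigma = math.sqrt(p * (1 - p) / draws)
            assert abs(observed - p) < 3 * sigma + 1e-12


class TestInitialization:
    def test_population_size_and_filters(self, small_dataset):
        X, y = small_dataset
        cfg = small_cfg(active_filters=("V",))
        spec = DomainSpec.from_training(X, y)
        pop = initialize_population(cfg, (X, y), spec)
        assert len(pop) == cfg.population_size
        assert all(v_filter(t).passed for t in pop)

    def test_structural_filters_respected(self, small_dataset):
        X, y = small_dataset
        cfg = small_cfg(active_filters=("V", "F"))
        spec = DomainSpec.from_training(X, y)
        for t in initialize_population(cfg, (X, y), spec):
            assert v_filter(t).passed and f_filter(t).passed

    def test_reproducible_under_seed(self, small_dataset):
        X, y = small_dataset
        cfg = small_cfg(active_filters=())
        spec = DomainSpec.from_training(X, y)
        a = initialize_population(cfg, (X, y), spec)
        b = initialize_population(cfg, (X, y), spec)
        assert [render_formula(t) for t in a] == [render_formula(t) for t in b]


class TestEvolve:
    def test_zero_generations_returns_best_of_initial_population(self, small_dataset):
        X, y = small_dataset
        cfg = small_cfg(n_generations=0, active_filters=())
        res = evolve((X, y), cfg=cfg)
        assert len(res.generation_log) == 1
        assert res.best_fitness.combined == res.generation_log[0]["best_combined"]

    def test_full_determinism(self, small_dataset):
        X, y = small_dataset
        cfg = small_cfg(
            active_filters=("V", "F", "D2"),
            stability=StabilityConfig(metric_kind="fitness_xc"),
        )
        r1 = evolve((X, y), cfg=cfg)
        r2 = evolve((X, y), cfg=cfg)
        assert r1.formula == r2.formula
        assert r1.generation_log == r2.generation_log

    def test_best_fitness_monotone_nonincreasing(self, small_dataset):
        X, y = small_dataset
        cfg = small_cfg(n_generations=8)
        res = evolve((X, y), cfg=cfg)
        bests = [g["best_combined"] for g in res.generation_log]
        assert all(a >= b for a, b in zip(bests, bests[1:]))

    def test_best_tree_passes_active_filters(self, small_dataset):
        X, y = small_dataset
        cfg = small_cfg(
            n_generations=6,
            active_filters=("V", "F", "D2"),
        )
        res = evolve((X, y), cfg=cfg)
        assert v_filter(res.best_tree).passed
        assert f_filter(res.best_tree).passed
        assert d2_filter(
            res.best_tree, res.domain_spec, rng=np.random.default_rng(0)
        ).passed

    def test_test_rmse_reported(self, small_dataset, rng):
        X, y = small_dataset
        Xt = pd.DataFrame({"x": rng.uniform(0, 3, 10)})
        yt = 1.5 * Xt["x"].to_numpy() + 4.0
        res = evolve((X, y), (Xt, yt), cfg=small_cfg())
        assert res.test_rmse is not None and res.test_rmse < 2.0

    def test_empty_training_set_rejected(self):
        X = pd.DataFrame({"x": []})
        with pytest.raises(ValueError):
            evolve((X, np.array([])), cfg=small_cfg())
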