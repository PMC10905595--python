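"""V-, F-, D-, and D2-filter behaviour against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from figp2.filters import (
    DomainSpec,
    RangeEstimationError,
    d2_filter,
    d_filter,
    estimate_range,
    f_filter,
    v_filter,
)
from figp2.trees import (
    OPERATORS,
    Const,
    ExpressionTree,
    Op,
    Var,
    evaluate,
    parse_formula,
)

from conftest import random_trees


def enumerate_trees(features, max_depth):
    """Every tree shape up to max_depth over the features plus one constant."""
    terminals = [Var(f) for f in features] + [Const(1.5)]

    def clones(node):
        from figp2.trees import _clone

        return _clone(node)

    def at_depth(d):
        if d == 0:
            return [t for t in terminals]
        subs = all_up_to(d - 1)
        out = []
        for name, spec in OPERATORS.items():
            if spec.arity == 1:
                out.extend(Op(name, [clones(s)]) for s in subs)
            else:
                out.extend(
                    Op(name, [clones(a), clones(b)])
                    for a in subs
                    for b in subs
                )
        return out

    def all_up_to(d):
        nodes = [t for t in terminals]
        for k in range(1, d + 1):
            nodes.extend(at_depth(k))
        return nodes

    return [ExpressionTree(n) for n in all_up_to(max_depth)]


class TestVFilter:
    def test_examples(self):
        assert v_filter(parse_formula("0.5*logp + 6.9")).passed
        rep = v_filter(parse_formula("logp + ln(logp)"))
        assert not rep.passed
        assert "logp" in rep.detail

    def test_exhaustive_against_occurrence_count(self):
        for t in enumerate_trees(["a", "b"], 2):
            counts = t.variables()
            expected = all(k <= 1 for k in counts.values())
            assert v_filter(t).passed == expected

    def test_invariant_to_constant_values(self, rng):
        for t in random_trees(100, ["a", "b"], (0, 3), 51):
            before = v_filter(t).passed
            for c in t.constants():
                c.value = rng.normal() * 100
            assert v_filter(t).passed == before


class TestFFilter:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("sqrt(sqrt(x))", False),
            ("square(x) + cube(y)", True),
            ("ln(1 + exp(x))", False),
            ("square(cube(x))", False),
            ("exp(x) * ln(y)", True),
            ("sqrt(square(x))", True),  # different groups may nest
        ],
    )
    def test_examples(self, formula, expected):
        assert f_filter(parse_formula(formula)).passed == expected

    def test_exhaustive_against_ancestor_scan(self):
        groups = [{"sqrt"}, {"square", "cube"}, {"ln", "exp"}]

        def oracle(node, active=()):
            if not isinstance(node, Op):
                return True
            for i, g in enumerate(groups):
                if node.name in g and i in active:
                    return False
            mine = tuple(
                set(active) | {i for i, g in enumerate(groups) if node.name in g}
            )
            return all(oracle(c, mine) for c in node.children)

        trees = enumerate_trees(["a"], 2)
        assert any(not oracle(t.root) for t in trees)
        for t in trees:
            assert f_filter(t).passed == oracle(t.root)


class TestDFilter:
    def test_constant_in_range_passes(self):
        probes = pd.DataFrame({"logp": np.linspace(0, 5, 11)})
        assert d_filter(ExpressionTree(Const(7.0)), probes, (5, 10)).passed

    def test_invalid_probe_fails(self):
        t = parse_formula("1/(logp - 2)")
        probes = pd.DataFrame({"logp": [1.0, 2.0, 3.0]})
        rep = d_filter(t, probes, (-100, 100))
        assert not rep.passed

    def test_sparse_grid_misses_pole_that_d2_catches(self):
        # pole at x = 0.5 sits between integer probe points
        t = parse_formula("1/(x - 0.5) + 7")
        probes = pd.DataFrame({"x": np.arange(-2.0, 3.0)})  # -2..2 integers
        spec = DomainSpec({"x": (-2.0, 2.0)}, (0.0, 14.0))
        assert d_filter(t, probes, spec.target_range).passed
        assert not d2_filter(t, spec, rng=np.random.default_rng(0)).passed


class TestEstimateRange:
    def test_monotone_square_on_positive_box(self):
        est = estimate_range(
            parse_formula("square(x)"), {"x": (0.0, 3.0)},
            rng=np.random.default_rng(1),
        )
        assert est.min_value == pytest.approx(0.0, abs=1e-9)
        assert est.max_value == pytest.approx(9.0, abs=1e-9)

    def test_global_quadratic_minimum(self):
        est = estimate_range(
            parse_formula("square(x - 1) + square(y + 2)"),
            {"x": (-5.0, 5.0), "y": (-5.0, 5.0)},
            rng=np.random.default_rng(2),
        )
        assert est.min_value == pytest.approx(0.0, abs=1e-8)
        assert est.argmin["x"] == pytest.approx(1.0, abs=1e-4)
        assert est.argmin["y"] == pytest.approx(-2.0, abs=1e-4)

    def test_monotone_single_variable_equals_endpoints(self):
        box = {"x": (0.5, 4.0)}
        for formula in ["2*x + 1", "exp(x)", "ln(x)", "1/x"]:
            t = parse_formula(formula)
            est = estimate_range(t, box, rng=np.random.default_rng(3))
            ends = [
                evaluate(t, {"x": np.array([box["x"][0]])}).values[0],
                evaluate(t, {"x": np.array([box["x"][1]])}).values[0],
            ]
            assert est.min_value == pytest.approx(min(ends), rel=1e-9)
            assert est.max_value == pytest.approx(max(ends), rel=1e-9)

    def test_brackets_grid_oracle_on_random_trees(self):
        box = {"a": (-2.0, 2.0), "b": (0.5, 5.0)}
        g = np.meshgrid(
            np.linspace(*box["a"], 200), np.linspace(*box["b"], 200)
        )
        grid = {"a": g[0].ravel(), "b": g[1].ravel()}
        checked = 0
        gen = np.random.default_rng(61)
        while checked < 20:
            t = random_trees(1, ["a", "b"], (1, 3), int(gen.integers(2**31)))[0]
            res = evaluate(t, grid)
            if not res.all_valid:
                continue  # compare only where the whole box is in-domain
            lo, hi = res.values.min(), res.values.max()
            span = max(hi - lo, 1e-9)
            est = estimate_range(t, box, rng=np.random.default_rng(checked))
            assert est.min_value <= lo + 0.01 * span
            assert est.max_value >= hi - 0.01 * span
            checked += 1

    def test_everywhere_invalid_raises(self):
        t = parse_formula("ln(0 - square(x))")  # ln of a nonpositive value
        with pytest.raises(RangeEstimationError):
            estimate_range(t, {"x": (1.0, 2.0)}, rng=np.random.default_rng(4))


class TestD2Filter:
    def test_pole_inside_box_rejected(self):
        spec = DomainSpec({"logp": (1.4, 4.2)}, (5.1, 9.0))
        rep = d2_filter(
            parse_formula("1/(logp - 2.65)"), spec, rng=np.random.default_rng(0)
        )
        assert not rep.passed

    def test_constant_within_target_passes(self):
        spec = DomainSpec({"logp": (1.4, 4.2)}, (5.57, 9.30))
        assert d2_filter(
            ExpressionTree(Const(7.0)), spec, rng=np.random.default_rng(0)
        ).passed

    def test_bounded_sigmoid_passes(self):
        # a/(1 + b*exp(-acc)) with a,b > 0: denominator > 1 for acc >= 0
        t = parse_formula("7/(1 + 0.5*exp(0 - acc))")
        spec = DomainSpec({"acc": (0.0, 8.0)}, (4.0, 8.0))
        assert d2_filter(t, spec, rng=np.random.default_rng(0)).passed

    def test_d2_pass_implies_d_pass_on_box_samples(self):
        spec = DomainSpec({"a": (-1.0, 1.0), "b": (0.5, 2.0)}, (-5.0, 15.0))
        gen = np.random.default_rng(71)
        probes = pd.DataFrame(
            {k: gen.uniform(lo, hi, 500) for k, (lo, hi) in spec.variable_box.items()}
        )
        for t in random_trees(40, ["a", "b"], (1, 3), 72):
            if d2_filter(t, spec, rng=np.random.default_rng(1)).passed:
                assert d_filter(t, probes, spec.target_range).passed


class TestDomainSpec:
    def test_dict_round_trip(self):
        spec = DomainSpec({"logp": (-1.0, 5.0)}, (5.0, 9.0), source="user_supplied")
        assert DomainSpec.from_dict(spec.to_dict()) == spec

    def test_from_training_covers_data(self, rational_dataset):
        X, y = rational_dataset
        spec = DomainSpec.from_training(X, y)
        assert spec.source == "from_training"
        for c in X.columns:
            lo, hi = spec.variable_box[c]
            assert lo == X[c].min() and hi == X[c].max()
        assert spec.target_range == (y.min(), y.max())

    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            DomainSpec({"x": (2.0, 1.0)}, (0.0, 1.0))
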