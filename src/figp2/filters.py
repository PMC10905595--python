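"""Candidate-expression filters for the GP search.

Four filters reject undesirable expressions:

* **V-filter** — a variable may appear at most once anywhere in the tree.
* **F-filter** — operators from the same functional group ({sqrt},
  {square, cube}, {ln, exp}) may not be nested along a root-to-leaf path.
* **D-filter** — sample-based domain check: the expression must evaluate
  validly and inside the target range on a set of probe points.
* **D2-filter** — optimization-based domain check: the expression's
  minimum and maximum over the descriptor domain box, found by multi-start
  bounded minimization, must lie inside the target range.

The D2-filter certifies the whole box rather than a finite probe sample,
so it catches poles and divergences that slip between probe points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .trees import ExpressionTree, Op, eval_scalar, evaluate

__all__ = [
    "DomainSpec",
    "FilterReport",
    "RangeEstimate",
    "RangeEstimationError",
    "DEFAULT_F_GROUPS",
    "v_filter",
    "f_filter",
    "d_filter",
    "estimate_range",
    "d2_filter",
]

DEFAULT_F_GROUPS: tuple[frozenset, ...] = (
    frozenset({"sqrt"}),
    frozenset({"square", "cube"}),
    frozenset({"ln", "exp"}),
)

_FAIL_VALUE = 1e15  # objective value at invalid optimizer query points


@dataclass
class DomainSpec:
    """Per-variable domain box and the admissible output range.

    ``variable_box`` maps each feature to a closed ``[lo, hi]`` interval in
    descriptor units; ``target_range`` is the closed admissible interval
    for the response (pKi units).  ``source`` records how the spec was
    derived: deriving it from training data alone avoids information
    leakage, while ``from_training_and_test`` mirrors protocols that use
    both splits.
    """

    variable_box: dict[str, tuple[float, float]]
    target_range: tuple[float, float]
    source: str = "user_supplied"

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.variable_box.items():
            if not lo <= hi:
                raise ValueError(f"variable_box[{name!r}] has lower > upper")
        if not self.target_range[0] <= self.target_range[1]:
            raise ValueError("target_range has lower > upper")

    @classmethod
    def from_training(cls, X, y) -> "DomainSpec":
        box = {
            str(c): (float(np.min(X[c])), float(np.max(X[c])))
            for c in X.columns
        }
        y = np.asarray(y, dtype=float)
        return cls(box, (float(y.min()), float(y.max())), source="from_training")

    @classmethod
    def from_training_and_test(cls, X_tr, y_tr, X_te, y_te) -> "DomainSpec":
        box = {}
        for c in X_tr.columns:
            lo = min(float(np.min(X_tr[c])), float(np.min(X_te[c])))
            hi = max(float(np.max(X_tr[c])), float(np.max(X_te[c])))
            box[str(c)] = (lo, hi)
        y = np.concatenate([np.asarray(y_tr, float), np.asarray(y_te, float)])
        return cls(
            box, (float(y.min()), float(y.max())), source="from_training_and_test"
        )

    @property
    def target_width(self) -> float:
        return self.target_range[1] - self.target_range[0]

    def to_dict(self) -> dict:
        return {
            "variables": {k: list(v) for k, v in self.variable_box.items()},
            "target": list(self.target_range),
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainSpec":
        return cls(
            {k: (float(v[0]), float(v[1])) for k, v in d["variables"].items()},
            (float(d["target"][0]), float(d["target"][1])),
            d.get("source", "user_supplied"),
        )


@dataclass
class FilterReport:
    passed: bool
    filter_name: str
    detail: str = ""

    def __post_init__(self) -> None:
        if not self.passed and not self.detail:
            raise ValueError("a failing FilterReport must carry a detail")

    def __bool__(self) -> bool:  # convenience: `if report:`
        return self.passed


@dataclass
class RangeEstimate:
    """Estimated output range of an expression over a domain box."""

    min_value: float
    max_value: float
    argmin: dict[str, float] = field(default_factory=dict)
    argmax: dict[str, float] = field(default_factory=dict)
    n_restarts_used: int = 0
    #: True when any optimizer query point inside the box evaluated
    #: invalidly — the expression is undefined somewhere in the domain
    hit_invalid: bool = False


class RangeEstimationError(RuntimeError):
    """Every optimization restart failed in both directions."""


def v_filter(tree: ExpressionTree) -> FilterReport:
    """Pass iff no feature occurs more than once anywhere in the tree."""
    repeated = sorted(n for n, k in tree.variables().items() if k > 1)
    if repeated:
        return FilterReport(False, "V", f"repeated variable(s): {', '.join(repeated)}")
    return FilterReport(True, "V")


def f_filter(tree: ExpressionTree, groups=None) -> FilterReport:
    """Pass iff no operator is nested under a same-group operator."""
    groups = tuple(frozenset(g) for g in groups) if groups is not None else DEFAULT_F_GROUPS

    def scan(node, active: frozenset) -> str | None:
        if not isinstance(node, Op):
            return None
        hit = [i for i in active if node.name in groups[i]]
        if hit:
            members = ", ".join(sorted(groups[hit[0]]))
            return f"nested operator {node.name!r} within group {{{members}}}"
        mine = frozenset(i for i, g in enumerate(groups) if node.name in g)
        nxt = active | mine
        for child in node.children:
            msg = scan(child, nxt)
            if msg:
                return msg
        return None

    msg = scan(tree.root, frozenset())
    if msg:
        return FilterReport(False, "F", msg)
    return FilterReport(True, "F")


def d_filter(tree: ExpressionTree, probe_points, target_range) -> FilterReport:
    """Sample-based domain check over explicit probe points.

    Pass iff every probe evaluates validly and every output lies within
    ``target_range``.
    """
    res = evaluate(tree, probe_points)
    if res.values.size == 0:
        raise ValueError("probe_points must be nonempty")
    if not res.all_valid:
        i = int(np.argmin(res.valid_mask))
        return FilterReport(False, "D", f"invalid evaluation at probe row {i}")
    lo, hi = target_range
    out = (res.values < lo) | (res.values > hi)
    if out.any():
        i = int(np.argmax(out))
        return FilterReport(
            False,
            "D",
            f"output {res.values[i]:.6g} at probe row {i} outside "
            f"target range [{lo:g}, {hi:g}]",
        )
    return FilterReport(True, "D")


def _scalar_objective(tree, names):
    root = tree.root
    state = {"hit_invalid": False}

    def f(x: np.ndarray) -> float:
        v = eval_scalar(root, dict(zip(names, x)))
        if v is None:
            state["hit_invalid"] = True
            return _FAIL_VALUE
        return v

    return f, state


def estimate_range(
    tree: ExpressionTree,
    box: dict[str, tuple[float, float]],
    n_restarts: int = 5,
    rng: np.random.Generator | None = None,
    start_points=None,
    n_probes: int = 256,
) -> RangeEstimate:
    """Estimate min/max of ``tree`` over ``box`` by multi-start bounded
    local minimization of f and of -f.

    Starts are rows sampled without replacement from ``start_points``
    (clipped into the box) when given, else uniform in the box.  Query
    points where evaluation is invalid receive a large sentinel objective,
    and a restart whose final point is invalid does not count.  A seeded
    uniform probe sample of ``n_probes`` points is folded into the
    estimate, which tightens it near discontinuities the local optimizer
    can stall on.  Raises :class:`RangeEstimationError` when every restart
    fails in either direction.
    """
    rng = rng if rng is not None else np.random.default_rng()
    names = sorted(tree.variables())
    if not names:
        res = evaluate(tree, {"_": np.zeros(1)})
        if not res.valid_mask[0]:
            raise RangeEstimationError("constant expression is invalid")
        v = float(res.values[0])
        return RangeEstimate(v, v, {}, {}, 0)
    missing = [n for n in names if n not in box]
    if missing:
        raise ValueError(f"box does not cover variable(s): {missing}")
    bounds = [box[n] for n in names]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    if start_points is not None:
        pts = np.column_stack(
            [np.asarray(start_points[n], dtype=float) for n in names]
        )
        k = min(n_restarts, len(pts))
        idx = rng.choice(len(pts), size=k, replace=False)
        starts = np.clip(pts[idx], lo, hi)
        if k < n_restarts:
            extra = rng.uniform(lo, hi, size=(n_restarts - k, len(names)))
            starts = np.vstack([starts, extra])
    else:
        starts = rng.uniform(lo, hi, size=(n_restarts, len(names)))

    f, state = _scalar_objective(tree, names)
    best_min = np.inf
    best_max = -np.inf
    arg_min = arg_max = None
    used = 0
    if n_probes > 0:
        probes = rng.uniform(lo, hi, size=(n_probes, len(names)))
        cols = {n_: probes[:, j] for j, n_ in enumerate(names)}
        res = evaluate(tree, cols)
        if not res.all_valid:
            state["hit_invalid"] = True
        if res.valid_mask.any():
            vals = res.values[res.valid_mask]
            pts = probes[res.valid_mask]
            i_min, i_max = int(np.argmin(vals)), int(np.argmax(vals))
            best_min, arg_min = float(vals[i_min]), pts[i_min]
            best_max, arg_max = float(vals[i_max]), pts[i_max]
    for x0 in starts:
        v0 = f(x0)
        if v0 < _FAIL_VALUE:
            if v0 < best_min:
                best_min, arg_min = v0, x0
            if v0 > best_max:
                best_max, arg_max = v0, x0
        for sign in (1.0, -1.0):
            res = minimize(
                lambda x: sign * f(x),
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-9, "gtol": 1e-8},
            )
            used += 1
            val = f(res.x)
            if val >= _FAIL_VALUE:
                continue
            if val < best_min:
                best_min, arg_min = val, res.x
            if val > best_max:
                best_max, arg_max = val, res.x
    if arg_min is None or arg_max is None:
        raise RangeEstimationError(
            "all restarts failed: expression invalid throughout the searched box"
        )
    return RangeEstimate(
        float(best_min),
        float(best_max),
        dict(zip(names, (float(v) for v in arg_min))),
        dict(zip(names, (float(v) for v in arg_max))),
        used,
        hit_invalid=state["hit_invalid"],
    )


def d2_filter(
    tree: ExpressionTree,
    spec: DomainSpec,
    n_restarts: int = 5,
    rng: np.random.Generator | None = None,
    start_points=None,
) -> FilterReport:
    """Optimization-based domain check.

    Pass iff range estimation succeeds and the estimated ``[min, max]`` of
    the expression over ``spec.variable_box`` is contained in
    ``spec.target_range``.  An expression undefined somewhere the optimizer
    queried, or whose extrema escape the target range, is rejected.
    """
    try:
        est = estimate_range(
            tree, spec.variable_box, n_restarts=n_restarts, rng=rng,
            start_points=start_points,
        )
    except RangeEstimationError as exc:
        return FilterReport(False, "D2", f"range estimation failed: {exc}")
    if est.hit_invalid:
        return FilterReport(
            False,
            "D2",
            "expression is undefined at an optimizer query point inside the box",
        )
    lo, hi = spec.target_range
    if est.min_value < lo:
        return FilterReport(
            False,
            "D2",
            f"minimum {est.min_value:.6g} at {est.argmin} below target range "
            f"[{lo:g}, {hi:g}]",
        )
    if est.max_value > hi:
        return FilterReport(
            False,
            "D2",
            f"maximum {est.max_value:.6g} at {est.argmax} above target range "
            f"[{lo:g}, {hi:g}]",
        )
    return FilterReport(True, "D2")
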