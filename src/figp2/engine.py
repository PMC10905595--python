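"""The filter-induced genetic-programming loop.

Evolution proceeds in four steps: generate an initial population, select
survivors by tournament, apply crossover/mutation, and score the offspring.
Structural filters (V, F) act on every generated tree; the domain filters
(D or D2) and the stability-weighted fitness act at scoring time, after the
tree's constants have been refined by least squares — so the domain
certificate applies to the final expression, not a pre-fit draft.

The module exposes the individual genetic operators plus a functional
``evolve`` entry point; :class:`figp2.estimator.SymbolicRegressor` is the
scikit-learn-style surface over the same loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .filters import (
    DEFAULT_F_GROUPS,
    DomainSpec,
    d2_filter,
    d_filter,
    f_filter,
    v_filter,
)
from .fitness import FitnessBreakdown, StabilityConfig, WORST_FITNESS, compute_fitness
from .fitting import fit_constants
from .trees import (
    OPERATORS,
    ExpressionTree,
    Op,
    Var,
    build_random_tree,
    evaluate,
    render_formula,
)

__all__ = [
    "GPConfig",
    "RunResult",
    "InitializationError",
    "initialize_population",
    "tournament_select",
    "crossover",
    "mutate",
    "evolve",
    "preset_config",
]

VALID_FILTERS = ("V", "F", "D", "D2")


class InitializationError(RuntimeError):
    """The initial population could not be filled under the active filters."""


@dataclass
class GPConfig:
    """All hyperparameters of a GP run.

    Defaults are the standard operating point: population 200, 200
    generations, initial tree depth 1-2, crossover/mutation probabilities
    0.7/0.2, mutation subtree depth 0-2, maximum depth 4, tournament size
    5, and the nine-operator function set.
    """

    population_size: int = 200
    n_generations: int = 200
    init_depth: tuple[int, int] = (1, 2)
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    mutation_depth: tuple[int, int] = (0, 2)
    max_depth: int = 4
    tournament_size: int = 5
    operators: tuple[str, ...] = tuple(OPERATORS)
    f_filter_groups: tuple[frozenset, ...] = DEFAULT_F_GROUPS
    active_filters: tuple[str, ...] = ("V", "F", "D2")
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    seed: int = 0
    max_regen_attempts: int = 50
    elitism: int = 1
    d_probe_count: int = 10000
    d_probe_scale: float = 1.5
    p_const: float = 0.2
    const_range: tuple[float, float] = (-10.0, 10.0)
    #: least-squares iteration cap per individual; constants of the small
    #: trees searched here converge in far fewer steps
    fit_max_iter: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_prob <= 1 or not 0 <= self.mutation_prob <= 1:
            raise ValueError("crossover/mutation probabilities must be in [0, 1]")
        if self.crossover_prob + self.mutation_prob > 1:
            raise ValueError("crossover_prob + mutation_prob must be <= 1")
        bad = [f for f in self.active_filters if f not in VALID_FILTERS]
        if bad:
            raise ValueError(f"unknown filters: {bad}")
        if self.max_depth < max(self.init_depth[1], 0):
            raise ValueError("init_depth exceeds max_depth")


_PRESETS = {
    # conventional GP: no filters, plain RMSE fitness
    "GP": ((), "fitness_0"),
    # previously proposed method: structural filters + sample-based D-filter
    "FIGP": (("V", "F", "D"), "fitness_0"),
    # optimization-based domain filter only
    "FIGP2_D2": (("V", "F", "D2"), "fitness_0"),
    # full method: D2-filter + stability-weighted fitness
    "FIGP2": (("V", "F", "D2"), "fitness_xc"),
}


def preset_config(name: str, seed: int = 0, **overrides) -> GPConfig:
    """Named method presets: GP, FIGP, FIGP2_D2, FIGP2."""
    filters, metric = _PRESETS[name]
    stability = overrides.pop("stability", StabilityConfig(metric_kind=metric))
    return GPConfig(
        active_filters=filters, stability=stability, seed=seed, **overrides
    )


@dataclass
class RunResult:
    best_tree: ExpressionTree
    best_fitness: FitnessBreakdown
    test_rmse: float | None
    generation_log: list
    seed: int
    domain_spec: DomainSpec

    @property
    def formula(self) -> str:
        return render_formula(self.best_tree)


# ---------------------------------------------------------------------------
# Structural helpers
# ---------------------------------------------------------------------------


def structure_key(tree: ExpressionTree) -> str:
    """Constant-blind structural signature of a tree.

    Two trees with the same shape and variables but different constant
    values share a key, and any variable-free subtree collapses to a single
    constant marker: least-squares fitting maps all such variants to the
    same expression family, so they are duplicates for search purposes.
    """

    def walk(node):
        if isinstance(node, Op):
            inner = [walk(c) for c in node.children]
            if all(k == "C" for k in inner):
                return "C"
            return f"({node.name} {' '.join(inner)})"
        if isinstance(node, Var):
            return node.name
        return "C"

    return walk(tree.root)


def _shape_key(tree: ExpressionTree) -> str:
    """Exact tree shape with constant values masked (no folding)."""

    def walk(node):
        if isinstance(node, Op):
            return f"({node.name} {' '.join(walk(c) for c in node.children)})"
        return node.name if isinstance(node, Var) else "C"

    return walk(tree.root)


def _structural_ok(tree: ExpressionTree, cfg: GPConfig) -> bool:
    if "V" in cfg.active_filters and not v_filter(tree):
        return False
    if "F" in cfg.active_filters and not f_filter(tree, cfg.f_filter_groups):
        return False
    return True


def _all_nodes(tree: ExpressionTree):
    """Preorder list of (parent, child_index, node, depth_from_root)."""
    out = []

    def walk(node, parent, idx, depth):
        out.append((parent, idx, node, depth))
        if isinstance(node, Op):
            for i, c in enumerate(node.children):
                walk(c, node, i, depth + 1)

    walk(tree.root, None, -1, 0)
    return out


def _splice(tree: ExpressionTree, parent, idx, new_node) -> None:
    if parent is None:
        tree.root = new_node
    else:
        parent.children[idx] = new_node


# ---------------------------------------------------------------------------
# Genetic operators
# ---------------------------------------------------------------------------


def crossover(
    a: ExpressionTree,
    b: ExpressionTree,
    rng: np.random.Generator,
    max_depth: int = 4,
    max_attempts: int = 50,
) -> tuple[ExpressionTree, ExpressionTree]:
    """One-point subtree exchange at uniformly chosen nodes.

    Offspring deeper than ``max_depth`` are rejected and the swap points
    re-drawn; after ``max_attempts`` failures the parents are returned
    unchanged (as clones).  Structurally identical parents exchange the
    subtree at the *same* position (homologous swap), so their offspring
    keep the parents' shape.
    """
    homologous = _shape_key(a) == _shape_key(b)
    for _ in range(max_attempts):
        c1, c2 = a.clone(), b.clone()
        n1 = _all_nodes(c1)
        n2 = _all_nodes(c2)
        k1 = int(rng.integers(len(n1)))
        k2 = k1 if homologous else int(rng.integers(len(n2)))
        p1, i1, s1, _ = n1[k1]
        p2, i2, s2, _ = n2[k2]
        _splice(c1, p1, i1, s2)
        _splice(c2, p2, i2, s1)
        if c1.depth <= max_depth and c2.depth <= max_depth:
            return c1, c2
    return a.clone(), b.clone()


def mutate(
    tree: ExpressionTree,
    cfg: GPConfig,
    feature_names,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> ExpressionTree:
    """Replace a uniformly chosen node's subtree by a fresh random tree.

    The replacement depth is drawn from ``cfg.mutation_depth``, capped so
    the mutant respects ``cfg.max_depth``.
    """
    attempts = max_attempts if max_attempts is not None else cfg.max_regen_attempts
    mlo, mhi = cfg.mutation_depth
    for _ in range(attempts):
        mutant = tree.clone()
        nodes = _all_nodes(mutant)
        parent, idx, _, depth = nodes[int(rng.integers(len(nodes)))]
        allowed = cfg.max_depth - depth
        hi = min(mhi, allowed)
        if hi < mlo:
            continue
        sub = build_random_tree(
            feature_names,
            (mlo, hi),
            rng,
            operators=cfg.operators,
            p_const=cfg.p_const,
            const_range=cfg.const_range,
        )
        _splice(mutant, parent, idx, sub.root)
        if mutant.depth <= cfg.max_depth:
            return mutant
    return tree.clone()


def tournament_select(
    population,
    fitnesses,
    k: int,
    size: int = 5,
    rng: np.random.Generator | None = None,
    node_counts=None,
) -> list:
    """Pick ``k`` individuals, each the best of ``size`` uniform draws.

    Draws are with replacement, both within a tournament and across picks.
    Ties on combined fitness break toward the smaller tree, then randomly.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if not population:
        raise ValueError("population must be nonempty")
    if node_counts is None:
        node_counts = [t.node_count for t in population]
    picks = []
    for _ in range(k):
        idx = rng.integers(len(population), size=size)
        best = min(idx, key=lambda i: (fitnesses[i], node_counts[i], rng.random()))
        picks.append(population[int(best)])
    return picks


# ---------------------------------------------------------------------------
# Evaluation pipeline
# ---------------------------------------------------------------------------


def _make_probes(X, cfg: GPConfig, rng: np.random.Generator):
    """Uniform probe cloud for the D-filter: per-feature box scaled to
    ``d_probe_scale`` times the training span, centered on the data."""
    cols = {}
    for c in X.columns:
        v = np.asarray(X[c], dtype=float)
        mid = (v.max() + v.min()) / 2.0
        half = (v.max() - v.min()) / 2.0 * cfg.d_probe_scale
        cols[str(c)] = rng.uniform(mid - half, mid + half, size=cfg.d_probe_count)
    return cols


def _evaluate_individual(tree, X, y, cols, cfg, spec, probes, rng, counters):
    """Fit constants, apply active domain filters, compute fitness."""
    fitres = fit_constants(tree, cols, y, max_iter=cfg.fit_max_iter)
    fitted = fitres.fitted_tree
    if "D" in cfg.active_filters and probes is not None:
        rep = d_filter(fitted, probes, spec.target_range)
        if not rep:
            counters["D"] += 1
            return fitted, FitnessBreakdown(
                WORST_FITNESS, 0.0, 0.0, WORST_FITNESS, True
            )
    if "D2" in cfg.active_filters:
        rep = d2_filter(fitted, spec, rng=rng, start_points=X)
        if not rep:
            counters["D2"] += 1
            return fitted, FitnessBreakdown(
                WORST_FITNESS, 0.0, 0.0, WORST_FITNESS, True
            )
    return fitted, compute_fitness(fitted, cols, y, cfg.stability, rng)


def _random_structural(cfg, feature_names, rng, depth_range):
    """A random tree passing the structural filters, or None."""
    for _ in range(cfg.max_regen_attempts):
        t = build_random_tree(
            feature_names,
            depth_range,
            rng,
            operators=cfg.operators,
            p_const=cfg.p_const,
            const_range=cfg.const_range,
        )
        if _structural_ok(t, cfg):
            return t
    return None


def initialize_population(cfg: GPConfig, dataset, spec: DomainSpec):
    """Generate ``population_size`` trees passing the active filters.

    Domain filters (D/D2) are checked on the constant-fitted tree so the
    certificate applies to the expression that will actually be scored.
    A slot whose draws keep failing a domain filter falls back to a
    structurally valid tree (which will then receive worst fitness if it
    still fails at scoring time); a slot that cannot even pass the
    structural filters raises :exc:`InitializationError`.
    """
    X, y = dataset
    rng = np.random.default_rng(cfg.seed)
    return _initialize(cfg, X, y, spec, rng, counters={"V/F": 0, "D": 0, "D2": 0})


def _initialize(cfg, X, y, spec, rng, counters, probes=None):
    cols = {str(c): np.asarray(X[c], dtype=float) for c in X.columns}
    feature_names = list(cols)
    domain_active = any(f in cfg.active_filters for f in ("D", "D2"))
    population = []
    seen: set[str] = set()
    for slot in range(cfg.population_size):
        accepted = None
        for _ in range(cfg.max_regen_attempts):
            t = build_random_tree(
                feature_names,
                cfg.init_depth,
                rng,
                operators=cfg.operators,
                p_const=cfg.p_const,
                const_range=cfg.const_range,
            )
            if not _structural_ok(t, cfg):
                counters["V/F"] += 1
                continue
            if structure_key(t) in seen:
                continue  # keep the initial population structurally diverse
            if domain_active:
                fitted = fit_constants(t, cols, y, max_iter=cfg.fit_max_iter).fitted_tree
                if "D" in cfg.active_filters and probes is not None:
                    if not d_filter(fitted, probes, spec.target_range):
                        counters["D"] += 1
                        continue
                if "D2" in cfg.active_filters:
                    if not d2_filter(fitted, spec, rng=rng, start_points=X):
                        counters["D2"] += 1
                        continue
                t = fitted
            accepted = t
            break
        if accepted is None:
            accepted = _random_structural(cfg, feature_names, rng, cfg.init_depth)
        if accepted is None:
            raise InitializationError(
                f"could not fill population slot {slot}: rejections {counters}"
            )
        seen.add(structure_key(accepted))
        population.append(accepted)
    return population


# ---------------------------------------------------------------------------
# The generational loop
# ---------------------------------------------------------------------------


def _coerce_xy(data):
    if data is None:
        return None
    if hasattr(data, "X") and hasattr(data, "y"):
        return data.X, np.asarray(data.y, dtype=float)
    X, y = data
    return X, np.asarray(y, dtype=float)


def evolve(train, test=None, cfg: GPConfig | None = None, spec: DomainSpec | None = None) -> RunResult:
    """Run the full evolutionary loop and report the best expression found.

    ``train``/``test`` are ``(X, y)`` pairs (DataFrame + vector) or any
    object with ``.X``/``.y``.  When ``spec`` is omitted it is derived from
    the training split (per-feature min/max box, observed response range).
    Returns the all-time best filter-passing individual, its fitness
    breakdown, the per-generation log, and the test RMSE when a test split
    is given.
    """
    cfg = cfg or GPConfig()
    X, y = _coerce_xy(train)
    if len(y) == 0:
        raise ValueError("training set is empty")
    if spec is None:
        spec = DomainSpec.from_training(X, y)
    if cfg.stability.invalid_displacement == StabilityConfig().invalid_displacement:
        cfg = replace(
            cfg,
            stability=replace(
                cfg.stability, invalid_displacement=max(spec.target_width, 1e-12)
            ),
        )

    rng = np.random.default_rng(cfg.seed)
    cols = {str(c): np.asarray(X[c], dtype=float) for c in X.columns}
    feature_names = list(cols)
    probes = (
        _make_probes(X, cfg, rng) if "D" in cfg.active_filters else None
    )
    counters = {"V/F": 0, "D": 0, "D2": 0}
    population = _initialize(cfg, X, y, spec, rng, counters, probes)

    def score(tree):
        return _evaluate_individual(tree, X, y, cols, cfg, spec, probes, rng, counters)

    scored = [score(t) for t in population]

    best_tree = None
    best_fit = None

    def update_best():
        nonlocal best_tree, best_fit
        for t, b in scored:
            if b.combined == WORST_FITNESS:
                continue
            if best_fit is None or (b.combined, t.node_count) < (
                best_fit.combined,
                best_tree.node_count,
            ):
                best_tree, best_fit = t.clone(), b

    log = []

    def log_generation(gen):
        combined = [b.combined for _, b in scored]
        finite = [c for c in combined if math.isfinite(c)]
        log.append(
            {
                "generation": gen,
                "best_combined": best_fit.combined if best_fit else WORST_FITNESS,
                "median_combined": float(np.median(finite)) if finite else WORST_FITNESS,
                "n_penalized": sum(1 for c in combined if not math.isfinite(c)),
                "rejections": dict(counters),
            }
        )

    update_best()
    log_generation(0)

    for gen in range(1, cfg.n_generations + 1):
        trees = [t for t, _ in scored]
        fits = [b.combined for _, b in scored]
        node_counts = [t.node_count for t in trees]

        def pick(k):
            return tournament_select(
                scored, fits, k, cfg.tournament_size, rng, node_counts
            )

        offspring = []
        seen: set[str] = set()

        def admit(tree, breakdown, force=False) -> bool:
            # duplicate structures are redrawn to preserve search diversity;
            # after repeated failures the duplicate is admitted anyway
            key = structure_key(tree)
            if key in seen and not force:
                return False
            seen.add(key)
            offspring.append((tree, breakdown))
            return True

        def structural_crossover(t1, t2):
            """Crossover that re-draws swap points until both children pass
            the structural filters; falls back to the parents."""
            for _ in range(cfg.max_regen_attempts):
                c1, c2 = crossover(t1, t2, rng, cfg.max_depth)
                if _structural_ok(c1, cfg) and _structural_ok(c2, cfg):
                    return c1, c2, True
                counters["V/F"] += 1
            return t1.clone(), t2.clone(), False

        def structural_mutate(t):
            for _ in range(cfg.max_regen_attempts):
                m = mutate(t, cfg, feature_names, rng)
                if _structural_ok(m, cfg):
                    return m, True
                counters["V/F"] += 1
            return t.clone(), False

        if best_tree is not None and cfg.elitism > 0:
            admit(best_tree.clone(), best_fit, force=True)
        # variation: select a pair, recombine with probability crossover_prob,
        # then mutate each child independently with probability mutation_prob
        stale = 0
        while len(offspring) < cfg.population_size:
            force = stale >= cfg.max_regen_attempts
            (t1, b1), (t2, b2) = pick(2)
            pair = [(t1.clone(), b1), (t2.clone(), b2)]
            if rng.random() < cfg.crossover_prob:
                c1, c2, changed = structural_crossover(t1, t2)
                if changed:
                    pair = [(c1, None), (c2, None)]
            out = []
            for t, b in pair:
                if rng.random() < cfg.mutation_prob:
                    m, changed = structural_mutate(t)
                    out.append((m, None) if changed else (t, b))
                else:
                    out.append((t, b))
            added = False
            for t, b in out:
                if len(offspring) >= cfg.population_size:
                    break
                added |= admit(t, b, force)
            stale = 0 if added else stale + 1

        scored = [(t, b) if b is not None else score(t) for t, b in offspring]
        update_best()
        log_generation(gen)

    if best_tree is None:
        # every individual failed a domain filter in every generation:
        # return the least-bad structural individual
        best_tree, best_fit = min(scored, key=lambda tb: tb[1].combined)
        best_tree = best_tree.clone()

    test_rmse = None
    if test is not None:
        Xt, yt = _coerce_xy(test)
        res = evaluate(best_tree, Xt)
        preds = np.where(res.valid_mask, res.values, float(np.mean(y)))
        test_rmse = float(np.sqrt(np.mean((preds - yt) ** 2)))

    return RunResult(best_tree, best_fit, test_rmse, log, cfg.seed, spec)
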