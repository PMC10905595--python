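"""Scikit-learn-style interface to the symbolic regressor."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .engine import GPConfig, evolve
from .filters import DomainSpec
from .fitness import StabilityConfig
from .trees import evaluate, render_formula

__all__ = ["SymbolicRegressor"]

_FITNESS_ALIASES = {
    "0": "fitness_0",
    "x": "fitness_x",
    "c": "fitness_c",
    "xc": "fitness_xc",
}


class SymbolicRegressor(RegressorMixin, BaseEstimator):
    """Interpretable symbolic regression by filtered genetic programming.

    Searches the space of small closed-form expressions over the input
    features, fitting each candidate's constants by nonlinear least
    squares.  Structural filters keep expressions readable (each variable
    at most once, no nested functionals from the same group); the
    optimization-based domain filter (``"D2"``) certifies that the fitted
    expression stays inside the observed response range over the whole
    training domain box; and the stability terms penalize expressions that
    are hypersensitive to small descriptor or coefficient perturbations.

    Parameters
    ----------
    population_size, n_generations, init_depth, crossover_prob,
    mutation_prob, mutation_depth, max_depth, tournament_size :
        Genetic-programming hyperparameters (see :class:`figp2.engine.GPConfig`).
    filters : tuple of {"V", "F", "D", "D2"}
        Active candidate filters.  Default ``("V", "F", "D2")``.
    fitness : {"0", "x", "c", "xc"}
        Fitness variant: plain training RMSE, or RMSE plus the descriptor
        (``x``), coefficient (``c``), or both (``xc``) stability penalties.
    lambda_x, lambda_c : float or None
        Stability weights; ``None`` selects the conventional defaults
        (1.0 for single-penalty variants, 0.5 each for ``"xc"``).
    delta_x_scale, delta_c_scale : float
        Perturbation sizes as fractions of the feature standard deviation
        and of each coefficient's magnitude.
    domain : DomainSpec or None
        Domain box and admissible output range; derived from the training
        split when omitted.
    random_state : int
        Seed for every stochastic component of the run.

    Attributes
    ----------
    best_tree_ : ExpressionTree
        The best filter-passing expression found.
    formula_ : str
        Human-readable rendering of ``best_tree_``.
    fitness_breakdown_ : FitnessBreakdown
        Training RMSE, stability terms, and combined fitness of the best.
    generation_log_ : list of dict
        Per-generation best/median fitness and filter-rejection counts.
    domain_spec_ : DomainSpec
        The domain specification the run certified against.

    Examples
    --------
    >>> import numpy as np, pandas as pd
    >>> rng = np.random.default_rng(0)
    >>> X = pd.DataFrame({"logp": rng.uniform(-1, 4, 60)})
    >>> y = 0.5 * X["logp"] + 6.9
    >>> model = SymbolicRegressor(population_size=30, n_generations=10)
    >>> rmse = np.sqrt(np.mean((model.fit(X, y).predict(X) - y) ** 2))
    """

    def __init__(
        self,
        population_size: int = 200,
        n_generations: int = 200,
        init_depth: tuple[int, int] = (1, 2),
        crossover_prob: float = 0.7,
        mutation_prob: float = 0.2,
        mutation_depth: tuple[int, int] = (0, 2),
        max_depth: int = 4,
        tournament_size: int = 5,
        operators: tuple[str, ...] | None = None,
        filters: tuple[str, ...] = ("V", "F", "D2"),
        fitness: str = "xc",
        lambda_x: float | None = None,
        lambda_c: float | None = None,
        delta_x_scale: float = 0.1,
        delta_c_scale: float = 0.1,
        domain: DomainSpec | None = None,
        max_regen_attempts: int = 50,
        d_probe_count: int = 10000,
        d_probe_scale: float = 1.5,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.n_generations = n_generations
        self.init_depth = init_depth
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.mutation_depth = mutation_depth
        self.max_depth = max_depth
        self.tournament_size = tournament_size
        self.operators = operators
        self.filters = filters
        self.fitness = fitness
        self.lambda_x = lambda_x
        self.lambda_c = lambda_c
        self.delta_x_scale = delta_x_scale
        self.delta_c_scale = delta_c_scale
        self.domain = domain
        self.max_regen_attempts = max_regen_attempts
        self.d_probe_count = d_probe_count
        self.d_probe_scale = d_probe_scale
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"x{i}" for i in range(arr.shape[1])]
        return pd.DataFrame(arr, columns=list(names))

    def _config(self) -> GPConfig:
        metric = _FITNESS_ALIASES.get(str(self.fitness).lower(), str(self.fitness))
        stability = StabilityConfig(
            delta_x_scale=self.delta_x_scale,
            delta_c_scale=self.delta_c_scale,
            lambda_x=self.lambda_x,
            lambda_c=self.lambda_c,
            metric_kind=metric,
        )
        kwargs = {}
        if self.operators is not None:
            kwargs["operators"] = tuple(self.operators)
        return GPConfig(
            population_size=self.population_size,
            n_generations=self.n_generations,
            init_depth=tuple(self.init_depth),
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            mutation_depth=tuple(self.mutation_depth),
            max_depth=self.max_depth,
            tournament_size=self.tournament_size,
            active_filters=tuple(self.filters),
            stability=stability,
            seed=int(self.random_state),
            max_regen_attempts=self.max_regen_attempts,
            d_probe_count=self.d_probe_count,
            d_probe_scale=self.d_probe_scale,
            **kwargs,
        )

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        """Evolve an expression for ``y`` as a function of the columns of ``X``."""
        Xf = self._as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(Xf) != len(y):
            raise ValueError("X and y have inconsistent numbers of rows")
        if len(y) < 2:
            raise ValueError("need at least 2 training rows")
        if not np.all(np.isfinite(Xf.to_numpy())) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite")
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]

        result = evolve((Xf, y), cfg=self._config(), spec=self.domain)
        self.best_tree_ = result.best_tree
        self.formula_ = render_formula(result.best_tree)
        self.fitness_breakdown_ = result.best_fitness
        self.generation_log_ = result.generation_log
        self.domain_spec_ = result.domain_spec
        self.run_result_ = result
        self.train_mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        """Evaluate the best expression row-wise.

        Rows where the expression is undefined (outside its valid domain)
        fall back to the training-mean prediction.
        """
        check_is_fitted(self, "best_tree_")
        Xf = self._as_frame(X)
        res = evaluate(self.best_tree_, Xf)
        return np.where(res.valid_mask, res.values, self.train_mean_)
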