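"""Stability metrics and the combined fitness functions.

Overfit expressions tend to be hypersensitive to small changes in their
inputs or coefficients.  The stability metric STBL quantifies that
sensitivity as the root-mean-square displacement (RMSD) between the fitted
expression f(x; c) and a perturbed copy:

* ``STBL_x`` perturbs every descriptor simultaneously by a fraction
  (default 0.1) of its training standard deviation;
* ``STBL_c`` perturbs every constant simultaneously by a fraction
  (default 0.1) of its absolute value.

The perturbation magnitudes are deterministic; the reported value is the
mean of the +delta and -delta displacements, which keeps GP selection
reproducible and removes sign bias.  A seeded stochastic variant (random
sign vectors) is available for sensitivity checks.

Four fitness functions combine training RMSE with the metrics (lower is
better)::

    FITNESS_0  = RMSE
    FITNESS_X  = RMSE + lambda_x * STBL_x
    FITNESS_C  = RMSE + lambda_c * STBL_c
    FITNESS_XC = RMSE + lambda_x * STBL_x + lambda_c * STBL_c

with default weights (1.0, 1.0) for the single-metric variants and
(0.5, 0.5) for FITNESS_XC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import ExpressionTree, _as_columns, _eval_node

__all__ = [
    "StabilityConfig",
    "FitnessBreakdown",
    "stbl_x",
    "stbl_c",
    "compute_fitness",
    "WORST_FITNESS",
    "METRIC_KINDS",
]

METRIC_KINDS = ("fitness_0", "fitness_x", "fitness_c", "fitness_xc")

#: Sentinel combined fitness for individuals whose training evaluation is
#: invalid or that fail an active domain filter.
WORST_FITNESS = math.inf

_DEFAULT_LAMBDAS = {
    "fitness_0": (0.0, 0.0),
    "fitness_x": (1.0, 0.0),
    "fitness_c": (0.0, 1.0),
    "fitness_xc": (0.5, 0.5),
}


@dataclass
class StabilityConfig:
    """Perturbation scales, metric weights, and the metric selector.

    ``lambda_x``/``lambda_c`` default (``None``) to the conventional
    weights of the selected metric; the weight of an inactive metric is 0.
    ``invalid_displacement`` is the displacement charged to a row whose
    perturbed evaluation is invalid — the GP engine sets it to the width
    of the target range.  ``scheme='stochastic'`` replaces the symmetric
    deterministic perturbation by ``n_sign_samples`` random sign vectors.
    """

    delta_x_scale: float = 0.1
    delta_c_scale: float = 0.1
    lambda_x: float | None = None
    lambda_c: float | None = None
    metric_kind: str = "fitness_0"
    invalid_displacement: float = 4.0
    scheme: str = "symmetric"
    n_sign_samples: int = 8

    def __post_init__(self) -> None:
        if self.metric_kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric_kind {self.metric_kind!r}")
        if self.delta_x_scale <= 0 or self.delta_c_scale <= 0:
            raise ValueError("delta scales must be > 0")
        if self.scheme not in ("symmetric", "stochastic"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def lambdas(self) -> tuple[float, float]:
        dx, dc = _DEFAULT_LAMBDAS[self.metric_kind]
        lx = self.lambda_x if self.lambda_x is not None else dx
        lc = self.lambda_c if self.lambda_c is not None else dc
        if self.metric_kind in ("fitness_0", "fitness_c"):
            lx = 0.0
        if self.metric_kind in ("fitness_0", "fitness_x"):
            lc = 0.0
        return lx, lc


@dataclass
class FitnessBreakdown:
    rmse_train: float
    stbl_x: float
    stbl_c: float
    combined: float
    penalized: bool = False

    def as_dict(self) -> dict:
        return {
            "rmse_train": self.rmse_train,
            "stbl_x": self.stbl_x,
            "stbl_c": self.stbl_c,
            "combined": self.combined,
            "penalized": self.penalized,
        }


def _rmsd(base: np.ndarray, pert_vals, pert_valid, penalty: float) -> float:
    disp = np.where(pert_valid, pert_vals - base, penalty)
    return float(np.sqrt(np.mean(disp * disp)))


def _sign_vectors(cfg: StabilityConfig, dim: int, rng) -> np.ndarray:
    if cfg.scheme == "symmetric":
        return np.array([np.ones(dim), -np.ones(dim)])
    if rng is None:
        rng = np.random.default_rng(0)
    return rng.choice([-1.0, 1.0], size=(cfg.n_sign_samples, dim))


def stbl_x(
    tree: ExpressionTree,
    X,
    cfg: StabilityConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Descriptor-perturbation stability of a fitted tree over training rows.

    Every feature is shifted simultaneously by ``delta_x_scale`` times its
    training standard deviation (ddof=1; a degenerate feature with zero
    spread gets delta 0).  Rows whose perturbed evaluation is invalid
    contribute ``cfg.invalid_displacement``.
    """
    cfg = cfg or StabilityConfig()
    cols, n = _as_columns(X)
    base, base_valid = _eval_node(tree.root, cols, n)
    if not base_valid.all():
        raise ValueError("tree must evaluate validly on X to measure stability")
    names = sorted(tree.variables())
    if not names:
        return 0.0
    deltas = {}
    for name in names:
        col = cols[name]
        s = float(np.std(col, ddof=1)) if len(col) > 1 else 0.0
        deltas[name] = cfg.delta_x_scale * s
    rmsds = []
    for signs in _sign_vectors(cfg, len(names), rng):
        pcols = dict(cols)
        for name, s in zip(names, signs):
            pcols[name] = cols[name] + s * deltas[name]
        vals, valid = _eval_node(tree.root, pcols, n)
        rmsds.append(_rmsd(base, vals, valid, cfg.invalid_displacement))
    return float(np.mean(rmsds))


def stbl_c(
    tree: ExpressionTree,
    X,
    cfg: StabilityConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Coefficient-perturbation stability of a fitted tree.

    Every constant ``c_j`` is shifted simultaneously by
    ``delta_c_scale * |c_j|``; trees without constants return 0.
    """
    cfg = cfg or StabilityConfig()
    cols, n = _as_columns(X)
    base, base_valid = _eval_node(tree.root, cols, n)
    if not base_valid.all():
        raise ValueError("tree must evaluate validly on X to measure stability")
    work = tree.clone()
    consts = work.constants()
    if not consts:
        return 0.0
    c0 = np.array([node.value for node in consts])
    deltas = cfg.delta_c_scale * np.abs(c0)
    rmsds = []
    for signs in _sign_vectors(cfg, len(consts), rng):
        for node, v, s, d in zip(consts, c0, signs, deltas):
            node.value = float(v + s * d)
        vals, valid = _eval_node(work.root, cols, n)
        rmsds.append(_rmsd(base, vals, valid, cfg.invalid_displacement))
    return float(np.mean(rmsds))


def compute_fitness(
    tree: ExpressionTree,
    X,
    y,
    cfg: StabilityConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FitnessBreakdown:
    """Score a fitted, filter-passing tree on training data.

    Returns training RMSE plus the weighted stability terms of the
    configured metric.  If any training row evaluates invalidly the
    individual is penalized with the worst-fitness sentinel.
    """
    cfg = cfg or StabilityConfig()
    y = np.asarray(y, dtype=float)
    cols, n = _as_columns(X)
    vals, valid = _eval_node(tree.root, cols, n)
    if not valid.all():
        return FitnessBreakdown(WORST_FITNESS, 0.0, 0.0, WORST_FITNESS, True)
    rmse = float(np.sqrt(np.mean((vals - y) ** 2)))
    lx, lc = cfg.lambdas
    sx = stbl_x(tree, X, cfg, rng) if lx > 0 else 0.0
    sc = stbl_c(tree, X, cfg, rng) if lc > 0 else 0.0
    return FitnessBreakdown(rmse, sx, sc, rmse + lx * sx + lc * sc, False)
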