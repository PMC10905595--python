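"""Nonlinear least-squares optimization of a tree's constant nodes.

Every candidate expression carries real-valued constant nodes (its
coefficient vector ``c``).  Before an expression is scored, the constants
are refined against the training data by damped least squares
(scipy ``least_squares``), started from the tree's current constants.
Rows where the expression evaluates invalidly contribute a large finite
penalty residual so the optimizer is steered away from invalid regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .trees import ExpressionTree, evaluate, _as_columns

__all__ = ["FitResult", "fit_constants", "INVALID_ROW_RESIDUAL"]

#: Residual assigned to a training row whose evaluation is invalid.
INVALID_ROW_RESIDUAL = 1e6


@dataclass
class FitResult:
    """Outcome of a constant fit: same tree structure, updated constants."""

    fitted_tree: ExpressionTree
    sse: float
    converged: bool
    n_iterations: int


def _residuals(tree, consts, cols, n, y, c):
    for node, v in zip(consts, c):
        node.value = float(v)
    values, valid = _eval(tree, cols, n)
    # residuals are capped at the invalid-row penalty so the squared
    # objective stays finite even for wildly divergent candidate constants
    r = np.where(valid, values - y, INVALID_ROW_RESIDUAL)
    return np.clip(r, -INVALID_ROW_RESIDUAL, INVALID_ROW_RESIDUAL)


def _eval(tree, cols, n):
    from .trees import _eval_node

    return _eval_node(tree.root, cols, n)


def fit_constants(
    tree: ExpressionTree,
    X,
    y,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> FitResult:
    """Fit the tree's constants to minimize the sum of squared residuals.

    Returns a :class:`FitResult` whose tree is a structural copy of the
    input with optimized constants.  The fit never worsens the objective:
    if the optimizer fails or ends above the starting objective, the
    initial constants are kept.  Trees with no tunable constants are
    returned unchanged with their residual sum computed directly.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response vector y contains non-finite values")
    cols, n = _as_columns(X)
    if n != len(y):
        raise ValueError(f"X has {n} rows but y has {len(y)}")
    work = tree.clone()
    consts = work.constants()
    if not consts:
        values, valid = _eval(work, cols, n)
        r = np.clip(
            np.where(valid, values - y, INVALID_ROW_RESIDUAL),
            -INVALID_ROW_RESIDUAL,
            INVALID_ROW_RESIDUAL,
        )
        return FitResult(work, float(r @ r), True, 0)

    c0 = np.array([node.value for node in consts], dtype=float)
    r0 = _residuals(work, consts, cols, n, y, c0)
    sse0 = float(r0 @ r0)

    try:
        result = least_squares(
            lambda c: _residuals(work, consts, cols, n, y, c),
            c0,
            method="trf",
            xtol=tol,
            ftol=tol,
            gtol=tol,
            max_nfev=max_iter * (len(c0) + 1),
        )
    except ValueError:
        # optimizer wandered into a non-finite region; keep the start
        for node, v in zip(consts, c0):
            node.value = float(v)
        return FitResult(work, sse0, False, 0)
    sse1 = float(2.0 * result.cost)
    if result.status > 0 and sse1 <= sse0 and np.all(np.isfinite(result.x)):
        c_best, sse, converged = result.x, sse1, True
    else:
        c_best, sse, converged = c0, sse0, False
    for node, v in zip(consts, c_best):
        node.value = float(v)
    return FitResult(work, sse, converged, int(result.nfev))
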