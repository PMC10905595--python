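"""Symbolic expression trees: construction, evaluation, rendering, parsing.

An expression tree is the individual of the genetic-programming search and
the model form of the symbolic regressor.  Nodes are operators (unary or
binary), named variables (descriptor columns), or real constants.  Depth
uses the terminal-depth-0 convention: a bare variable or constant has
depth 0.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OperatorSpec",
    "OPERATORS",
    "Const",
    "Var",
    "Op",
    "ExpressionTree",
    "EvaluationResult",
    "build_random_tree",
    "evaluate",
    "render_formula",
    "parse_formula",
    "tree_metrics",
    "to_prefix",
    "from_prefix",
    "trees_equal",
]

#: Any intermediate value above this magnitude is treated as an invalid
#: (overflowing) evaluation for that row.
OVERFLOW_LIMIT = 1e300


@dataclass(frozen=True)
class OperatorSpec:
    """An operator symbol together with its arity."""

    name: str
    arity: int


#: The default function set: four binary arithmetic operators and five
#: unary functionals.
OPERATORS: dict[str, OperatorSpec] = {
    "+": OperatorSpec("+", 2),
    "-": OperatorSpec("-", 2),
    "*": OperatorSpec("*", 2),
    "/": OperatorSpec("/", 2),
    "sqrt": OperatorSpec("sqrt", 1),
    "square": OperatorSpec("square", 1),
    "cube": OperatorSpec("cube", 1),
    "exp": OperatorSpec("exp", 1),
    "ln": OperatorSpec("ln", 1),
}

_BINARY = ("+", "-", "*", "/")
_UNARY = ("sqrt", "square", "cube", "exp", "ln")


@dataclass
class Const:
    """A real-valued constant leaf; ``fit=True`` marks it tunable."""

    value: float
    fit: bool = True


@dataclass
class Var:
    """A named variable leaf referring to a descriptor column."""

    name: str


@dataclass
class Op:
    """An operator node with ``arity`` children."""

    name: str
    children: list = field(default_factory=list)


Node = Const | Var | Op


@dataclass
class ExpressionTree:
    """A rooted expression tree."""

    root: Node

    def clone(self) -> "ExpressionTree":
        return ExpressionTree(_clone(self.root))

    @property
    def depth(self) -> int:
        return _depth(self.root)

    @property
    def node_count(self) -> int:
        return _count(self.root)

    def variables(self) -> Counter:
        c: Counter = Counter()
        _vars(self.root, c)
        return c

    def constants(self) -> list[Const]:
        """Tunable constant nodes in preorder (the coefficient vector c)."""
        out: list[Const] = []
        _consts(self.root, out)
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return render_formula(self)


@dataclass
class EvaluationResult:
    """Row-wise outputs plus a mask of rows that evaluated validly."""

    values: np.ndarray
    valid_mask: np.ndarray

    @property
    def all_valid(self) -> bool:
        return bool(self.valid_mask.all())


def _clone(node: Node) -> Node:
    if isinstance(node, Const):
        return Const(node.value, node.fit)
    if isinstance(node, Var):
        return Var(node.name)
    return Op(node.name, [_clone(c) for c in node.children])


def _depth(node: Node) -> int:
    if isinstance(node, Op):
        return 1 + max(_depth(c) for c in node.children)
    return 0


def _count(node: Node) -> int:
    if isinstance(node, Op):
        return 1 + sum(_count(c) for c in node.children)
    return 1


def _vars(node: Node, acc: Counter) -> None:
    if isinstance(node, Var):
        acc[node.name] += 1
    elif isinstance(node, Op):
        for c in node.children:
            _vars(c, acc)


def _consts(node: Node, acc: list[Const]) -> None:
    if isinstance(node, Const):
        if node.fit:
            acc.append(node)
    elif isinstance(node, Op):
        for c in node.children:
            _consts(c, acc)


def tree_metrics(tree: ExpressionTree) -> tuple[int, int, Counter, int]:
    """Return ``(depth, node_count, variables_used, constant_count)``.

    ``variables_used`` is a multiset counting every occurrence.
    """
    return (
        tree.depth,
        tree.node_count,
        tree.variables(),
        len(tree.constants()),
    )


# ---------------------------------------------------------------------------
# Random construction
# ---------------------------------------------------------------------------


def build_random_tree(
    feature_names,
    depth_range,
    rng: np.random.Generator,
    operators=None,
    p_const: float = 0.2,
    const_range: tuple[float, float] = (-10.0, 10.0),
) -> ExpressionTree:
    """Grow a random tree whose depth lies in ``depth_range`` (inclusive).

    A target depth is drawn uniformly from the range and the tree is grown
    to exactly that depth: at least one root-to-leaf path reaches it, no
    path exceeds it.  Constants are drawn uniformly from ``const_range``;
    terminals are constants with probability ``p_const``, else a uniformly
    chosen feature.
    """
    feature_names = list(feature_names)
    if not feature_names:
        raise ValueError("feature_names must be nonempty")
    lo, hi = int(depth_range[0]), int(depth_range[1])
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid depth_range {depth_range!r}")
    ops = [OPERATORS[n] for n in (operators or list(OPERATORS))]

    def terminal() -> Node:
        if rng.random() < p_const:
            return Const(float(rng.uniform(*const_range)))
        return Var(feature_names[int(rng.integers(len(feature_names)))])

    def grow(depth: int) -> Node:
        if depth == 0:
            return terminal()
        spec = ops[int(rng.integers(len(ops)))]
        if spec.arity == 1:
            return Op(spec.name, [grow(depth - 1)])
        spine = int(rng.integers(2))
        children = []
        for i in range(2):
            d = depth - 1 if i == spine else int(rng.integers(depth))
            children.append(grow(d))
        return Op(spec.name, children)

    target = int(rng.integers(lo, hi + 1))
    return ExpressionTree(grow(target))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


class MissingFeatureError(KeyError):
    """A variable in the tree has no matching input column."""


def _as_columns(X) -> tuple[dict[str, np.ndarray], int]:
    if hasattr(X, "columns"):  # pandas DataFrame
        cols = {str(c): np.asarray(X[c], dtype=float) for c in X.columns}
    elif isinstance(X, dict):
        cols = {k: np.asarray(v, dtype=float) for k, v in X.items()}
    else:
        raise TypeError("X must be a DataFrame or a mapping of named columns")
    n = len(next(iter(cols.values()))) if cols else 0
    return cols, n


def _eval_node(node: Node, cols: dict, n: int):
    """Evaluate with numpy floating-point warnings suppressed."""
    with np.errstate(all="ignore"):
        return _eval_raw(node, cols, n)


def _eval_raw(node: Node, cols: dict, n: int):
    if isinstance(node, Const):
        return np.full(n, node.value), np.ones(n, dtype=bool)
    if isinstance(node, Var):
        if node.name not in cols:
            raise MissingFeatureError(
                f"input is missing feature column {node.name!r}"
            )
        v = cols[node.name]
        return v, np.isfinite(v)
    a, va = _eval_raw(node.children[0], cols, n)
    name = node.name
    if name in _UNARY:
        if name == "sqrt":
            valid = va & (a >= 0)
            out = np.sqrt(np.where(valid, a, 0.0))
        elif name == "square":
            valid = va
            out = a * a
        elif name == "cube":
            valid = va
            out = a * a * a
        elif name == "exp":
            valid = va
            out = np.exp(np.minimum(a, 709.0))
        else:  # ln
            valid = va & (a > 0)
            out = np.log(np.where(valid, a, 1.0))
    else:
        b, vb = _eval_raw(node.children[1], cols, n)
        valid = va & vb
        if name == "+":
            out = a + b
        elif name == "-":
            out = a - b
        elif name == "*":
            out = a * b
        else:  # /
            valid = valid & (b != 0)
            out = np.divide(a, np.where(b != 0, b, 1.0))
    valid = valid & np.isfinite(out) & (np.abs(out) <= OVERFLOW_LIMIT)
    return np.where(valid, out, 0.0), valid


def eval_scalar(node: Node, env: dict[str, float]) -> float | None:
    """Evaluate a tree at a single point; ``None`` marks an invalid operation.

    Fast path for optimizers that query one point at a time (the
    domain-filter range search); semantics match :func:`evaluate`.
    """
    if isinstance(node, Const):
        return node.value
    if isinstance(node, Var):
        v = env[node.name]
        return v if math.isfinite(v) else None
    a = eval_scalar(node.children[0], env)
    if a is None:
        return None
    name = node.name
    if name in _UNARY:
        if name == "sqrt":
            out = math.sqrt(a) if a >= 0 else None
        elif name == "square":
            out = a * a
        elif name == "cube":
            out = a * a * a
        elif name == "exp":
            out = math.exp(min(a, 709.0))
        else:  # ln
            out = math.log(a) if a > 0 else None
    else:
        b = eval_scalar(node.children[1], env)
        if b is None:
            return None
        if name == "+":
            out = a + b
        elif name == "-":
            out = a - b
        elif name == "*":
            out = a * b
        else:
            out = a / b if b != 0 else None
    if out is None or not math.isfinite(out) or abs(out) > OVERFLOW_LIMIT:
        return None
    return out


def evaluate(tree: ExpressionTree, X) -> EvaluationResult:
    """Evaluate ``tree`` row-wise over named columns.

    Rows hitting an invalid operation (division by zero, ln/sqrt out of
    domain, overflow beyond 1e300) are flagged in ``valid_mask`` instead of
    raising; their ``values`` entry is 0.
    """
    cols, n = _as_columns(X)
    values, valid = _eval_node(tree.root, cols, n)
    return EvaluationResult(np.asarray(values, dtype=float), valid)


# ---------------------------------------------------------------------------
# Rendering / parsing
# ---------------------------------------------------------------------------

_PREC = {"+": 1, "-": 1, "*": 2, "/": 2}
_COMMUTATIVE = ("+", "*")


def to_prefix(node_or_tree, precision: int = 17) -> str:
    """Exact prefix serialization, e.g. ``(+ (var logp) (const 6.9))``."""
    node = node_or_tree.root if isinstance(node_or_tree, ExpressionTree) else node_or_tree
    if isinstance(node, Const):
        return f"(const {node.value:.{precision}g})"
    if isinstance(node, Var):
        return f"(var {node.name})"
    inner = " ".join(to_prefix(c, precision) for c in node.children)
    return f"({node.name} {inner})"


_PREFIX_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def from_prefix(text: str) -> ExpressionTree:
    """Parse the prefix serialization produced by :func:`to_prefix`."""
    tokens = _PREFIX_TOKEN.findall(text)
    pos = 0

    def parse() -> Node:
        nonlocal pos
        if tokens[pos] != "(":
            raise ValueError(f"expected '(' at token {pos}")
        pos += 1
        head = tokens[pos]
        pos += 1
        if head == "const":
            node: Node = Const(float(tokens[pos]))
            pos += 1
        elif head == "var":
            node = Var(tokens[pos])
            pos += 1
        else:
            spec = OPERATORS[head]
            node = Op(head, [parse() for _ in range(spec.arity)])
        if tokens[pos] != ")":
            raise ValueError(f"expected ')' at token {pos}")
        pos += 1
        return node

    tree = ExpressionTree(parse())
    if pos != len(tokens):
        raise ValueError("trailing tokens in prefix expression")
    return tree


def _canonical(node: Node) -> Node:
    """Sort operands of commutative operators by their serialized form."""
    if isinstance(node, Op):
        kids = [_canonical(c) for c in node.children]
        if node.name in _COMMUTATIVE:
            kids.sort(key=to_prefix)
        return Op(node.name, kids)
    return _clone(node)


def canonicalize(tree: ExpressionTree) -> ExpressionTree:
    """A copy with commutative operands in canonical order."""
    return ExpressionTree(_canonical(tree.root))


def trees_equal(a: ExpressionTree, b: ExpressionTree) -> bool:
    """Structural equality up to commutative operand order."""
    return to_prefix(canonicalize(a)) == to_prefix(canonicalize(b))


def _render(node: Node, sig: int) -> str:
    if isinstance(node, Const):
        return f"{node.value:.{sig}g}"
    if isinstance(node, Var):
        return node.name
    name = node.name
    if name in _UNARY:
        return f"{name}({_render(node.children[0], sig)})"
    prec = _PREC[name]
    parts = []
    for i, child in enumerate(node.children):
        s = _render(child, sig)
        if isinstance(child, Op) and child.name in _PREC:
            cp = _PREC[child.name]
            # a same-precedence right operand keeps parentheses so the
            # rendered string re-parses to the identical tree shape
            if cp < prec or (cp == prec and i == 1):
                s = f"({s})"
        elif isinstance(child, Const) and child.value < 0 and not (i == 0 and prec == 1):
            s = f"({s})"
        parts.append(s)
    sep = f" {name} " if prec == 1 else name
    return sep.join(parts)


def render_formula(tree: ExpressionTree, sig: int = 3) -> str:
    """Human-readable infix formula with minimal parentheses.

    Commutative operands are put in a canonical order so structurally equal
    trees render identically; constants print with ``sig`` significant
    digits.
    """
    return _render(_canonical(tree.root), sig)


# --- infix parser ----------------------------------------------------------

_TOKEN = re.compile(
    r"\s*(?:(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*/()]))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    out = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise ValueError(f"cannot tokenize formula at {text[pos:]!r}")
        pos = m.end()
        for kind in ("num", "name", "op"):
            if m.group(kind) is not None:
                out.append((kind, m.group(kind)))
                break
    return out


def parse_formula(text: str) -> ExpressionTree:
    """Parse an infix formula produced by :func:`render_formula`."""
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    def expr() -> Node:
        nonlocal pos
        node = term()
        while peek() == ("op", "+") or peek() == ("op", "-"):
            opname = tokens[pos][1]
            pos += 1
            node = Op(opname, [node, term()])
        return node

    def term() -> Node:
        nonlocal pos
        node = factor()
        while peek() == ("op", "*") or peek() == ("op", "/"):
            opname = tokens[pos][1]
            pos += 1
            node = Op(opname, [node, factor()])
        return node

    def factor() -> Node:
        nonlocal pos
        if peek() == ("op", "-"):
            pos += 1
            inner = factor()
            if isinstance(inner, Const):
                return Const(-inner.value)
            return Op("-", [Const(0.0, fit=False), inner])
        return atom()

    def atom() -> Node:
        nonlocal pos
        kind, val = peek()
        if kind == "num":
            pos += 1
            return Const(float(val))
        if kind == "name":
            pos += 1
            if val in _UNARY and peek() == ("op", "("):
                pos += 1
                inner = expr()
                if peek() != ("op", ")"):
                    raise ValueError(f"missing ')' after {val}(...")
                pos += 1
                return Op(val, [inner])
            return Var(val)
        if (kind, val) == ("op", "("):
            pos += 1
            inner = expr()
            if peek() != ("op", ")"):
                raise ValueError("unbalanced parentheses")
            pos += 1
            return inner
        raise ValueError(f"unexpected token {val!r}")

    root = expr()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens: {tokens[pos:]!r}")
    return ExpressionTree(root)
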