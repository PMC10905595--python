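"""Dataset I/O, feature sets, splitting, and synthetic ground-truth data.

A :class:`Dataset` is a named descriptor matrix plus a potency vector
(pKi).  The standard substituent-descriptor vocabulary has ten names:
arings, acc, don, a_heavy, logp, rbc, rings, tpsa, vdw_vol, mw; three
preset feature subsets (FEAT10/FEAT7/FEAT4) are provided.

The synthetic generator draws descriptors uniformly from a per-feature box
and computes the response from a known ground-truth expression plus
additive Gaussian noise, so recovery of the generating formula can be
tested exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trees import ExpressionTree, evaluate, parse_formula

__all__ = [
    "DESCRIPTOR_NAMES",
    "FEATURE_SETS",
    "FeatureSet",
    "Dataset",
    "SyntheticSpec",
    "read_table",
    "write_table",
    "split_train_test",
    "generate_synthetic",
    "ground_truth_presets",
]

logger = logging.getLogger(__name__)

DESCRIPTOR_NAMES = (
    "arings",
    "acc",
    "don",
    "a_heavy",
    "logp",
    "rbc",
    "rings",
    "tpsa",
    "vdw_vol",
    "mw",
)


@dataclass(frozen=True)
class FeatureSet:
    name: str
    members: tuple[str, ...]


FEATURE_SETS: dict[str, FeatureSet] = {
    "FEAT10": FeatureSet("FEAT10", DESCRIPTOR_NAMES),
    "FEAT7": FeatureSet(
        "FEAT7", ("arings", "acc", "don", "logp", "rbc", "tpsa", "mw")
    ),
    "FEAT4": FeatureSet("FEAT4", ("logp", "rbc", "tpsa", "mw")),
}


@dataclass
class Dataset:
    """Descriptor matrix ``X`` (named columns) and potency vector ``y``."""

    X: pd.DataFrame
    y: pd.Series
    ids: pd.Series | None = None
    smiles: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y have different numbers of rows")
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("Dataset may not contain missing values")

    def __len__(self) -> int:
        return len(self.y)

    def __iter__(self):
        # allows unpacking as (X, y)
        yield self.X
        yield np.asarray(self.y, dtype=float)

    @property
    def features(self) -> list[str]:
        return [str(c) for c in self.X.columns]

    def subset(self, features) -> "Dataset":
        members = list(features.members) if isinstance(features, FeatureSet) else list(features)
        missing = [f for f in members if f not in self.X.columns]
        if missing:
            raise KeyError(f"dataset is missing feature(s): {missing}")
        return Dataset(self.X[members].copy(), self.y.copy(), self.ids, self.smiles)

    def take(self, idx) -> "Dataset":
        return Dataset(
            self.X.iloc[idx].reset_index(drop=True),
            self.y.iloc[idx].reset_index(drop=True),
            None if self.ids is None else self.ids.iloc[idx].reset_index(drop=True),
            None if self.smiles is None else self.smiles.iloc[idx].reset_index(drop=True),
        )


def read_table(path, target_column: str = "pKi", feature_columns=None) -> Dataset:
    """Read a delimited text table (or spreadsheet) into a Dataset.

    Rows with any missing value in the selected columns are dropped with a
    logged count.  ``feature_columns=None`` selects every numeric column
    except the target (and the conventional ``id``/``smiles`` columns).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if target_column not in df.columns:
        raise ValueError(f"table {path} has no target column {target_column!r}")
    if feature_columns is None:
        feature_columns = [
            c
            for c in df.columns
            if c not in (target_column, "id", "smiles")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    missing = [c for c in feature_columns if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} is missing column(s): {missing}")
    cols = list(feature_columns) + [target_column]
    for c in cols:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(f"non-numeric cell in column {c!r} at row {row}")
        df[c] = pd.to_numeric(df[c])
    keep = df[cols].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_table: dropped %d row(s) with missing values", dropped)
    df = df[keep].reset_index(drop=True)
    return Dataset(
        df[list(feature_columns)].astype(float),
        df[target_column].astype(float),
        ids=df["id"] if "id" in df.columns else None,
        smiles=df["smiles"] if "smiles" in df.columns else None,
    )


def write_table(ds: Dataset, path, target_column: str = "pKi") -> None:
    """Write a Dataset as CSV (full float precision, round-trip safe)."""
    df = ds.X.copy()
    df[target_column] = np.asarray(ds.y, dtype=float)
    if ds.ids is not None:
        df.insert(0, "id", ds.ids)
    if ds.smiles is not None:
        df.insert(1 if ds.ids is not None else 0, "smiles", ds.smiles)
    df.to_csv(path, index=False)


def split_train_test(ds: Dataset, train_ratio: float, seed: int = 0):
    """Uniform random partition into (train, test).

    The training size is ``round(n * train_ratio)``; reproducible per seed.
    """
    if not 0 < train_ratio < 1:
        raise ValueError("train_ratio must be in (0, 1)")
    n = len(ds)
    n_train = int(round(n * train_ratio))
    if n_train < 2 or n - n_train < 2:
        raise ValueError(
            f"split of {n} rows at ratio {train_ratio} leaves a side below 2 rows"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return ds.take(np.sort(perm[:n_train])), ds.take(np.sort(perm[n_train:]))


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic dataset with a known generating formula."""

    ground_truth: ExpressionTree
    variable_box: dict[str, tuple[float, float]]
    n_samples: int
    noise_sigma: float = 0.0
    seed: int = 0


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw X uniformly over the box and set y = f(X) + N(0, sigma^2).

    The generating spec is attached to the returned dataset as
    ``ds.synthetic_spec`` so recovery tests can compare against the truth.
    """
    rng = np.random.default_rng(spec.seed)
    X = pd.DataFrame(
        {
            name: rng.uniform(lo, hi, size=spec.n_samples)
            for name, (lo, hi) in spec.variable_box.items()
        }
    )
    res = evaluate(spec.ground_truth, X)
    if not res.all_valid:
        bad = int(np.argmin(res.valid_mask))
        raise ValueError(
            f"ground truth evaluates invalidly at sampled row {bad}; "
            "shrink the variable box"
        )
    y = res.values + rng.normal(0.0, spec.noise_sigma, size=spec.n_samples)
    ds = Dataset(X, pd.Series(y, name="pKi"))
    ds.synthetic_spec = spec
    return ds


def ground_truth_presets() -> dict[str, ExpressionTree]:
    """Representative generating formulas: linear, rational, saturating
    exponential — the shapes a substituent-potency model typically takes."""
    return {
        "linear": parse_formula("0.5*logp + 6.9"),
        "rational": parse_formula("0.5*logp + 2/(tpsa + 1) + 6.5"),
        "saturating_exp": parse_formula("7.5 - 2*exp(-0.8*acc)"),
    }
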