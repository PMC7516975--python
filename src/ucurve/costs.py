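"""Concrete cost functions for the U-curve problem.

Two substantive criteria are provided:

* the **subset-sum cost** c(X) = |t − Σ_{x∈X} w_x|, the polynomial reduction
  from subset sum that makes U-curve instances provably hard while remaining
  decomposable in U-shaped curves — used to generate benchmark instances;
* the **penalized mean conditional entropy** (MCE), an information-theoretic
  wrapper criterion for classifier design: the expected conditional entropy
  of the label given the realization of the selected features, with
  realizations observed exactly once charged the maximal entropy (the
  small-sample penalty N/t).

Also here: the projected (wrapper) cost c_X(Y) = c(X ∪ Y) used to restrict a
cost to an inner Boolean lattice, an explicit-table cost for hand-crafted
fixtures, and readers/writers for the discrete sample-table formats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lattice import (
    CostFunction,
    EvaluationLedger,
    FeatureSet,
    GroundSet,
)


# ---------------------------------------------------------------------------
# Subset-sum cost (hard-instance reduction)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetSumInstance:
    """A subset-sum instance: one non-negative integer weight per feature
    plus a non-negative target t."""

    weights: Mapping[str, int]
    target: int

    def __post_init__(self):
        for name, w in self.weights.items():
            if int(w) < 0:
                raise ValueError(f"weight of {name!r} must be non-negative, got {w}")
        if int(self.target) < 0:
            raise ValueError(f"target must be non-negative, got {self.target}")

    @property
    def ground(self) -> GroundSet:
        return GroundSet(self.weights.keys())

    def cost(self) -> "SubsetSumCost":
        return SubsetSumCost(self)

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {"weights": {k: int(v) for k, v in sorted(self.weights.items())},
             "target": int(self.target)}
        )

    @classmethod
    def from_json(cls, text: str) -> "SubsetSumInstance":
        obj = json.loads(text)
        return cls(weights={k: int(v) for k, v in obj["weights"].items()},
                   target=int(obj["target"]))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "SubsetSumInstance":
        return cls.from_json(Path(path).read_text())


class SubsetSumCost(CostFunction):
    """c(X) = |t − Σ_{x∈X} w_x|: integer-valued, decomposable in U-shaped
    curves, and zero exactly on subsets summing to the target."""

    name = "subset-sum"

    def __init__(self, instance: SubsetSumInstance):
        ground = instance.ground
        super().__init__(ground)
        self.instance = instance
        self._w = [int(instance.weights[f]) for f in ground.features]
        self._t = int(instance.target)

    def evaluate_mask(self, mask: int) -> int:
        s = 0
        w = self._w
        m = mask
        while m:
            b = m & -m
            s += w[b.bit_length() - 1]
            m ^= b
        return abs(self._t - s)


def subset_sum_cost(inst: SubsetSumInstance, X: FeatureSet) -> int:
    """Evaluate the subset-sum cost of ``X`` under ``inst``."""
    return SubsetSumCost(inst)(X)


# ---------------------------------------------------------------------------
# Discrete labelled sample tables and the penalized MCE criterion
# ---------------------------------------------------------------------------

class SampleTable:
    """Discrete labelled samples with multiplicities.

    Rows are feature vectors of discrete (integer) values over the ground
    set, each with a class label from the alphabet L and a multiplicity;
    identical (vector, label) rows are aggregated.  ``t`` is the total sample
    count Σ multiplicities.
    """

    def __init__(self, features: Sequence[str], X: np.ndarray, y: np.ndarray,
                 mult: np.ndarray | None = None,
                 labels: Sequence[int] | None = None,
                 planted: FeatureSet | None = None):
        order = np.argsort(np.asarray(features, dtype=object))
        self.features = tuple(np.asarray(features, dtype=object)[order])
        X = np.asarray(X, dtype=np.int64)
        if X.ndim != 2 or X.shape[1] != len(self.features):
            raise ValueError("feature matrix shape does not match feature names")
        X = X[:, order]
        y = np.asarray(y, dtype=np.int64)
        if y.shape != (X.shape[0],):
            raise ValueError("label vector length does not match sample count")
        mult = (np.ones(X.shape[0], dtype=np.int64) if mult is None
                else np.asarray(mult, dtype=np.int64))
        if mult.shape != y.shape or (mult < 1).any():
            raise ValueError("multiplicities must be positive, one per row")
        if X.shape[0] == 0:
            raise ValueError("sample table must contain at least one sample")
        # aggregate duplicated (vector, label) rows
        key = np.concatenate([X, y[:, None]], axis=1)
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        agg = np.bincount(inverse, weights=mult).astype(np.int64)
        self.X = uniq[:, :-1]
        self.y = uniq[:, -1]
        self.mult = agg
        self.labels = (tuple(sorted(set(int(v) for v in self.y)))
                       if labels is None else tuple(sorted(set(int(v) for v in labels))))
        if set(self.y.tolist()) - set(self.labels):
            raise ValueError("sample labels outside the declared alphabet")
        self.planted = planted

    @property
    def t(self) -> int:
        return int(self.mult.sum())

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def ground(self) -> GroundSet:
        return GroundSet(self.features)

    def cost(self) -> "PenalizedMCECost":
        return PenalizedMCECost(self)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read_dat(cls, path) -> "SampleTable":
        """Whitespace-separated integers, one sample per line, last column
        the class label.  Feature names are positional (f00, f01, ...)."""
        arr = np.loadtxt(path, dtype=np.int64, ndmin=2)
        if arr.shape[1] < 2:
            raise ValueError("sample table needs at least one feature and a label")
        n = arr.shape[1] - 1
        width = max(2, len(str(n - 1)))
        names = [f"f{i:0{width}d}" for i in range(n)]
        return cls(names, arr[:, :-1], arr[:, -1])

    @classmethod
    def read_csv(cls, path, label_column: str = "label") -> "SampleTable":
        df = pd.read_csv(path)
        if label_column not in df.columns:
            raise ValueError(f"CSV sample table must have a {label_column!r} column")
        y = df[label_column].to_numpy()
        Xdf = df.drop(columns=[label_column])
        return cls(list(Xdf.columns), Xdf.to_numpy(), y)

    def to_dat(self, path) -> None:
        rows = np.repeat(
            np.concatenate([self.X, self.y[:, None]], axis=1), self.mult, axis=0
        )
        np.savetxt(path, rows, fmt="%d")

    def to_csv(self, path, label_column: str = "label") -> None:
        rows = np.repeat(
            np.concatenate([self.X, self.y[:, None]], axis=1), self.mult, axis=0
        )
        df = pd.DataFrame(rows, columns=list(self.features) + [label_column])
        df.to_csv(path, index=False)


def project_counts(table: SampleTable, X: FeatureSet) -> dict:
    """Aggregate the table by the X-restricted feature vector.

    Returns a mapping from each observed realization x of X (a tuple of
    feature values, in the ground set's lexicographic feature order) to an
    integer array of per-label counts, ordered as ``table.labels``.  The
    counts total the table's sample count t.
    """
    if X.ground != table.ground:
        raise ValueError("subset is over a different ground set than the table")
    return _project_counts_mask(table, X.mask)


def _project_counts_mask(table: SampleTable, mask: int) -> dict:
    idx = [i for i in range(len(table.features)) if mask >> i & 1]
    label_pos = {lab: j for j, lab in enumerate(table.labels)}
    ycol = np.array([label_pos[int(v)] for v in table.y])
    if not idx:
        counts = np.zeros(table.n_labels, dtype=np.int64)
        np.add.at(counts, ycol, table.mult)
        return {(): counts}
    sub = table.X[:, idx]
    uniq, inverse = np.unique(sub, axis=0, return_inverse=True)
    counts = np.zeros((uniq.shape[0], table.n_labels), dtype=np.int64)
    np.add.at(counts, (inverse, ycol), table.mult)
    return {tuple(int(v) for v in uniq[g]): counts[g] for g in range(uniq.shape[0])}


def conditional_entropy(label_counts, n_labels: int) -> float:
    """Empirical conditional entropy −Σ_y p_y log_{|L|} p_y of the label
    histogram ``label_counts``, in [0, 1].

    The logarithm base is the alphabet size |L|, so the uniform distribution
    has entropy exactly 1 (0·log 0 ≡ 0 by convention).
    """
    if n_labels < 2:
        raise ValueError("entropy needs a label alphabet of size >= 2")
    if isinstance(label_counts, Mapping):
        counts = np.asarray(list(label_counts.values()), dtype=float)
    else:
        counts = np.asarray(label_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("label counts must sum to at least 1")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(n_labels))).sum())


class PenalizedMCECost(CostFunction):
    """Penalized mean conditional entropy estimator, in [0, 1].

    c(X) = N/t + Σ_{x : count(x) ≥ 2} Ĥ(Y | X = x) · count(x)/t, where N is
    the number of samples whose X-projected realization occurs exactly once.
    Singleton realizations are treated as following the uniform label
    distribution (maximal entropy 1 in base |L|), hence contribute 1/t each.
    """

    name = "mce"

    def __init__(self, table: SampleTable):
        if table.n_labels < 2:
            raise ValueError("penalized MCE needs at least two classes")
        super().__init__(table.ground)
        self.table = table
        self._log_base = math.log(table.n_labels)

    def evaluate_mask(self, mask: int) -> float:
        table = self.table
        t = table.t
        idx = [i for i in range(len(table.features)) if mask >> i & 1]
        label_pos = {lab: j for j, lab in enumerate(table.labels)}
        ycol = np.array([label_pos[int(v)] for v in table.y])
        if not idx:
            inverse = np.zeros(len(table.y), dtype=np.int64)
            n_groups = 1
        else:
            _, inverse = np.unique(table.X[:, idx], axis=0, return_inverse=True)
            n_groups = int(inverse.max()) + 1
        counts = np.zeros((n_groups, table.n_labels), dtype=np.int64)
        np.add.at(counts, (inverse, ycol), table.mult)
        totals = counts.sum(axis=1)
        singletons = totals == 1
        cost = float(singletons.sum()) / t
        big = counts[~singletons]
        if big.size:
            tot = big.sum(axis=1, keepdims=True).astype(float)
            p = big / tot
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = np.where(p > 0, np.log(p), 0.0)
            h = -(p * logp).sum(axis=1) / self._log_base
            cost += float((h * tot[:, 0] / t).sum())
        return cost


def penalized_mce(table: SampleTable, X: FeatureSet) -> float:
    """Evaluate the penalized MCE of ``X`` on ``table``."""
    return PenalizedMCECost(table)(X)


# ---------------------------------------------------------------------------
# Projected (wrapper) cost over an inner Boolean lattice
# ---------------------------------------------------------------------------

class ProjectedCost(CostFunction):
    """The wrapper cost c_X(Y) = c(X ∪ Y) over the free coordinates.

    ``anchor`` is an element X of the outer lattice (a subset of the fixed
    set S′); evaluation embeds a free-coordinate subset Y into the full
    space, unions it with the anchor and delegates to the base cost through
    the shared ledger, so memoization and distinct-call accounting stay
    global.
    """

    name = "projected"

    def __init__(self, base: CostFunction, anchor_mask: int,
                 free_idx: Sequence[int],
                 ledger: EvaluationLedger | None = None):
        free_idx = tuple(sorted(int(i) for i in free_idx))
        n = base.ground.n
        if any(i < 0 or i >= n for i in free_idx):
            raise ValueError("free coordinate index out of range")
        fixed_mask_all = base.ground.full_mask
        self._free_embed = free_idx
        self._free_mask_full = 0
        for i in free_idx:
            self._free_mask_full |= 1 << i
        self._fixed_mask_full = fixed_mask_all ^ self._free_mask_full
        if anchor_mask & self._free_mask_full:
            raise ValueError("anchor overlaps the free coordinates")
        self.base = base
        self.base_ledger = ledger
        self.anchor_mask = int(anchor_mask)
        free_names = [base.ground.features[i] for i in free_idx]
        super().__init__(GroundSet(free_names))

    def full_mask_of(self, free_space_mask: int) -> int:
        full = self.anchor_mask
        for j, i in enumerate(self._free_embed):
            if free_space_mask >> j & 1:
                full |= 1 << i
        return full

    def evaluate_mask(self, free_space_mask: int):
        full = self.full_mask_of(free_space_mask)
        if self.base_ledger is not None:
            return self.base_ledger.evaluate_mask(self.base, full)
        return self.base.evaluate_mask(full)

    def evaluate_full(self, Y: FeatureSet):
        """Evaluate on a full-space subset Y ⊆ S′¯ (error if Y touches S′)."""
        if Y.ground != self.base.ground:
            raise ValueError("subset is over a different ground set than the base cost")
        if Y.mask & self._fixed_mask_full:
            raise ValueError("subset overlaps the fixed set S'")
        full = self.anchor_mask | Y.mask
        if self.base_ledger is not None:
            return self.base_ledger.evaluate_mask(self.base, full)
        return self.base.evaluate_mask(full)


def projected_cost(pc: ProjectedCost, Y: FeatureSet):
    """Evaluate the wrapper cost c_X(Y) = c(anchor ∪ Y).

    ``Y`` may be given either over the projected (free) ground set or as a
    full-space subset of the free coordinates.
    """
    if Y.ground == pc.ground:
        return pc(Y)
    return pc.evaluate_full(Y)


# ---------------------------------------------------------------------------
# Explicit-table cost (fixture support)
# ---------------------------------------------------------------------------

class ExplicitTableCost(CostFunction):
    """Lookup cost over a complete table of all 2^n subsets."""

    name = "table"

    def __init__(self, ground: GroundSet, values: Mapping[int, float]):
        super().__init__(ground)
        expected = 1 << ground.n
        missing = [m for m in range(expected) if m not in values]
        if missing:
            raise ValueError(
                f"explicit cost table is missing {len(missing)} of {expected} subsets "
                f"(first missing mask: {missing[0]:b})"
            )
        self._values = {int(m): values[m] for m in range(expected)}

    def evaluate_mask(self, mask: int):
        try:
            return self._values[mask]
        except KeyError:
            raise ValueError(f"subset mask {mask:b} not in explicit cost table") from None


def explicit_table_cost(values: Mapping) -> ExplicitTableCost:
    """Build a lookup cost from {FeatureSet | bit-string: cost}.

    All 2^n subsets of a common ground set must be present.
    """
    if not values:
        raise ValueError("explicit cost table is empty")
    first = next(iter(values))
    if isinstance(first, FeatureSet):
        ground = first.ground
        table = {fs.mask: v for fs, v in values.items()}
    else:
        n = len(str(first))
        width = max(2, len(str(n - 1)))
        ground = GroundSet([f"f{i:0{width}d}" for i in range(n)])
        table = {FeatureSet.from_string(str(k), ground).mask: v for k, v in values.items()}
    return ExplicitTableCost(ground, table)


def load_explicit_table(path) -> ExplicitTableCost:
    """Read an explicit cost table from JSON: {"01001": 0.5, ...}."""
    obj = json.loads(Path(path).read_text())
    if "costs" in obj and isinstance(obj["costs"], dict):
        obj = obj["costs"]
    return explicit_table_cost({k: float(v) for k, v in obj.items()})
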