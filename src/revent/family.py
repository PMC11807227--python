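"""Parameterized edge-partition families with affine class counts.

Polymer repeat structures give rise to graph families indexed by the degree
of polymerization s: each reverse-degree edge class has a count that is
affine in s (slope*s + intercept). Every topological index here is linear in
the class counts, so each index of the family is itself an affine closed
form slope*s + intercept — `affine_index` computes it symbolically.
Entropies are *not* affine in s and are tabulated numerically
(`entropy_table`).

The packaged fixture `haptx_partition()` is the nine-class family of the
hyaluronic acid-paclitaxel (HA-PTX) polymer-drug conjugate, e.g. class
(3,3) occurs 19s-1 times and q(s) = 96s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .entropy import displayed_form_entropy, edge_weight_entropy
from .errors import ParameterRangeError, PartitionError
from .molgraph import EdgePartition
from .weights import WeightSpec, edge_weight

__all__ = [
    "AffineCount",
    "ParameterizedPartition",
    "AffineForm",
    "haptx_partition",
    "evaluate_at",
    "affine_index",
    "entropy_table",
    "read_partition_csv",
    "write_partition_csv",
]


@dataclass(frozen=True)
class AffineCount:
    """Edge-class count slope*s + intercept, nonnegative for all s >= s_min."""

    slope: int
    intercept: int

    def __call__(self, s: int) -> int:
        return self.slope * s + self.intercept


@dataclass(frozen=True)
class AffineForm:
    """An index closed form slope*s + intercept."""

    slope: float
    intercept: float

    def __call__(self, s: float) -> float:
        return self.slope * s + self.intercept

    def round(self, ndigits: int) -> "AffineForm":
        return AffineForm(round(self.slope, ndigits), round(self.intercept, ndigits))


@dataclass(frozen=True)
class ParameterizedPartition:
    """Edge classes keyed by reverse-degree pair, counts affine in s.

    Validated so that every count is nonnegative for all integer s >= s_min
    (i.e. count(s_min) >= 0 and slope >= 0).
    """

    classes: tuple[tuple[tuple[int, int], AffineCount], ...]
    s_min: int = 1

    def __init__(
        self,
        classes: Iterable[tuple[tuple[int, int], AffineCount | tuple[int, int]]],
        s_min: int = 1,
    ):
        norm = []
        seen = set()
        for (a, b), count in classes:
            if a < 1 or b < a:
                raise PartitionError(f"invalid class pair {(a, b)!r}")
            if (a, b) in seen:
                raise PartitionError(f"duplicate class {(a, b)!r}")
            seen.add((a, b))
            if not isinstance(count, AffineCount):
                count = AffineCount(*count)
            if count.slope < 0 or count(s_min) < 0:
                raise PartitionError(
                    f"count {count.slope}*s+{count.intercept} of class {(a, b)} "
                    f"goes negative for s >= {s_min}"
                )
            norm.append(((a, b), count))
        if not norm:
            raise PartitionError("parameterized partition needs at least one class")
        object.__setattr__(self, "classes", tuple(norm))
        object.__setattr__(self, "s_min", s_min)

    @property
    def q_form(self) -> AffineForm:
        """q(s) as an affine form: sum of the class-count slopes/intercepts."""
        return AffineForm(
            sum(c.slope for _, c in self.classes),
            sum(c.intercept for _, c in self.classes),
        )

    def evaluate_at(self, s: int) -> EdgePartition:
        return evaluate_at(self, s)


def haptx_partition() -> ParameterizedPartition:
    """The packaged nine-class HA-PTX reverse-degree edge partition."""
    path = resources.files("revent.data") / "haptx_edge_partition.csv"
    with resources.as_file(path) as p:
        return read_partition_csv(p)


def read_partition_csv(path) -> ParameterizedPartition:
    """Read a partition CSV with header ``a,b,slope,intercept`` ('#' comments)."""
    df = pd.read_csv(path, comment="#")
    required = {"a", "b", "slope", "intercept"}
    if not required.issubset(df.columns):
        raise PartitionError(
            f"partition CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    return ParameterizedPartition(
        ((int(r.a), int(r.b)), AffineCount(int(r.slope), int(r.intercept)))
        for r in df.itertuples()
    )


def write_partition_csv(pp: ParameterizedPartition, path) -> None:
    pd.DataFrame(
        [(a, b, c.slope, c.intercept) for (a, b), c in pp.classes],
        columns=["a", "b", "slope", "intercept"],
    ).to_csv(path, index=False)


def evaluate_at(pp: ParameterizedPartition, s: int) -> EdgePartition:
    """Concrete edge partition at integer repeat parameter s."""
    if s < pp.s_min:
        raise ParameterRangeError(f"s={s} below s_min={pp.s_min}")
    counts = {}
    for (a, b), c in pp.classes:
        n = c(s)
        if n < 0:  # defensive; construction already forbids this
            raise ParameterRangeError(f"class {(a, b)} count {n} negative at s={s}")
        counts[(a, b)] = n
    return EdgePartition(counts)


def affine_index(pp: ParameterizedPartition, spec: WeightSpec) -> AffineForm:
    """Symbolic closed form of an index over the family.

    slope = sum class_slope * F(a,b) and intercept = sum class_intercept *
    F(a,b); exact because indices are linear in class counts. The
    context-dependent Balaban weight has no affine context here and is
    rejected.
    """
    if spec.resolve().needs_context:
        raise PartitionError(
            "balaban index needs (p, q) context, which a parameterized "
            "partition does not carry"
        )
    slope = 0.0
    intercept = 0.0
    for (a, b), c in pp.classes:
        w = edge_weight(spec, a, b)
        slope += c.slope * w
        intercept += c.intercept * w
    return AffineForm(slope, intercept)


def entropy_table(
    pp: ParameterizedPartition,
    specs: Sequence[WeightSpec],
    s_values: Sequence[int],
    base: float = math.e,
    displayed_form: bool = False,
) -> pd.DataFrame:
    """Entropy of the family at each s, one column per weight.

    With ``displayed_form=True`` the cells use the class-aggregated
    diagnostic variant instead of the Shannon edge-weight entropy.
    """
    rows = {}
    for s in s_values:
        part = evaluate_at(pp, s)
        row = {}
        for spec in specs:
            if displayed_form:
                row[spec.label] = displayed_form_entropy(part, spec, base=base)
            else:
                row[spec.label] = edge_weight_entropy(part, spec, base=base).value
        rows[s] = row
    cols = [sp.label for sp in specs]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "s"
    return df
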