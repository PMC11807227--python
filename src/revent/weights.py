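"""Registry of reverse-degree edge-weight functions and index computation.

Each topological index used here is a sum of an edge-weight function
F(a, b) over all edges, where (a, b) are the reverse degrees of the edge's
endpoints. Because the sum only depends on how many edges fall in each
reverse-degree class, indices are computed from the edge partition; a
brute-force per-edge oracle (`brute_force_index`) is provided for testing.

Weight functions:

    randic(alpha)   (a*b)^alpha          alpha in {1, -1, 1/2, -1/2} by default
    abc             sqrt((a+b-2)/(a*b))  0 at (1,1) by convention
    ga              2*sqrt(a*b)/(a+b)
    m1              a+b                  first Zagreb
    m2              a*b                  second Zagreb
    hm              (a+b)^2              hyper Zagreb
    forgotten       a^2+b^2
    azi             (a*b/(a+b-2))^3      undefined at (1,1)
    balaban         q/(q-p+2) * (a*b)^(-1/2)   needs graph context (p, q)
    rezg1           (a+b)/(a*b)
    rezg2           a*b/(a+b)
    rezg3           a*b*(a+b)
    harmonic        2/(a+b)
    sdd             (a^2+b^2)/(a*b)      symmetric division degree
    mm2             alias of randic(-1)  modified second Zagreb
    isi             alias of rezg2       inverse sum indeg
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .errors import ContextRequiredError, UnknownWeightError, WeightDomainError
from .molgraph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "WeightSpec",
    "IndexValue",
    "UndefinedIndex",
    "WEIGHT_NAMES",
    "DEFAULT_RANDIC_ALPHAS",
    "default_weight_specs",
    "parse_weight",
    "edge_weight",
    "index_from_partition",
    "index_from_graph",
    "all_indices",
    "brute_force_index",
]

WEIGHT_NAMES = (
    "randic", "abc", "ga", "m1", "m2", "hm", "forgotten", "azi", "balaban",
    "rezg1", "rezg2", "rezg3", "mm2", "harmonic", "sdd", "isi",
)

#: alpha exponents of the Randic weight used throughout the package
DEFAULT_RANDIC_ALPHAS = (1.0, -1.0, 0.5, -0.5)

_ALIASES = {"mm2": ("randic", -1.0), "isi": ("rezg2", None)}


@dataclass(frozen=True)
class WeightSpec:
    """A named edge-weight function, optionally parameterized.

    ``alpha`` is required iff ``name == "randic"`` and restricted to
    {1, -1, 1/2, -1/2} unless ``allow_any_alpha`` is set.
    """

    name: str
    alpha: float | None = None
    allow_any_alpha: bool = False

    def __post_init__(self):
        if self.name not in WEIGHT_NAMES:
            raise UnknownWeightError(
                f"unknown weight {self.name!r}; choose from {', '.join(WEIGHT_NAMES)}"
            )
        if self.name == "randic":
            if self.alpha is None:
                raise UnknownWeightError("randic weight requires an alpha exponent")
            if not self.allow_any_alpha and float(self.alpha) not in DEFAULT_RANDIC_ALPHAS:
                raise UnknownWeightError(
                    f"randic alpha {self.alpha} outside the default set "
                    f"{DEFAULT_RANDIC_ALPHAS}; pass allow_any_alpha=True to override"
                )
        elif self.alpha is not None:
            raise UnknownWeightError(f"weight {self.name!r} takes no alpha")

    @property
    def needs_context(self) -> bool:
        return self.name == "balaban"

    @property
    def label(self) -> str:
        """Stable string key used in tables and CLI output."""
        if self.name == "randic":
            return f"randic_{Fraction(self.alpha).limit_denominator(1000)}"
        return self.name

    def resolve(self) -> "WeightSpec":
        """Replace an alias (mm2, isi) by its target; identity otherwise."""
        if self.name in _ALIASES:
            target, alpha = _ALIASES[self.name]
            return WeightSpec(target, alpha)
        return self


@dataclass(frozen=True)
class IndexValue:
    """A finite index value together with the weight that produced it."""

    weight: WeightSpec
    value: float


@dataclass(frozen=True)
class UndefinedIndex:
    """Recorded in batch output when a weight is undefined on the graph."""

    weight: WeightSpec
    reason: str


def parse_weight(token: str) -> WeightSpec:
    """Parse a CLI/CSV weight token, e.g. ``m1``, ``abc``, ``randic_-1/2``."""
    token = token.strip().lower()
    if token.startswith("randic_") or token.startswith("randic("):
        frag = token[7:].rstrip(")")
        try:
            alpha = float(Fraction(frag))
        except (ValueError, ZeroDivisionError):
            raise UnknownWeightError(f"cannot parse randic alpha from {token!r}")
        return WeightSpec("randic", alpha)
    if token == "randic":
        raise UnknownWeightError("randic requires an alpha, e.g. randic_1/2")
    return WeightSpec(token)


def default_weight_specs(include_aliases: bool = False) -> list[WeightSpec]:
    """The registry: Randic at the four default alphas plus the named weights."""
    specs = [WeightSpec("randic", a) for a in DEFAULT_RANDIC_ALPHAS]
    for name in WEIGHT_NAMES:
        if name == "randic" or (not include_aliases and name in _ALIASES):
            continue
        specs.append(WeightSpec(name))
    return specs


def edge_weight(
    spec: WeightSpec,
    a: int,
    b: int,
    context: tuple[int, int] | None = None,
) -> float:
    """Evaluate F(a, b) for one reverse-degree pair.

    ``context = (p, q)`` is required for (and only for) the Balaban weight.
    """
    if a < 1 or b < 1:
        raise WeightDomainError(f"reverse degrees must be >= 1, got ({a}, {b})")
    spec = spec.resolve()
    name = spec.name
    if name == "randic":
        return float((a * b) ** spec.alpha)
    if name == "abc":
        return math.sqrt((a + b - 2) / (a * b))  # 0 at (1,1): numerator vanishes
    if name == "ga":
        return 2.0 * math.sqrt(a * b) / (a + b)
    if name == "m1":
        return float(a + b)
    if name == "m2":
        return float(a * b)
    if name == "hm":
        return float((a + b) ** 2)
    if name == "forgotten":
        return float(a * a + b * b)
    if name == "azi":
        if a + b == 2:
            raise WeightDomainError(
                "augmented-Zagreb weight undefined on class (1,1): "
                "zero denominator a+b-2"
            )
        return (a * b / (a + b - 2)) ** 3
    if name == "balaban":
        if context is None:
            raise ContextRequiredError("balaban weight needs graph context (p, q)")
        p, q = context
        return q / (q - p + 2) / math.sqrt(a * b)
    if name == "rezg1":
        return (a + b) / (a * b)
    if name == "rezg2":
        return a * b / (a + b)
    if name == "rezg3":
        return float(a * b * (a + b))
    if name == "harmonic":
        return 2.0 / (a + b)
    if name == "sdd":
        return (a * a + b * b) / (a * b)
    raise UnknownWeightError(name)  # pragma: no cover


def index_from_partition(partition: EdgePartition, spec: WeightSpec) -> IndexValue:
    """Sum count * F(a, b) over the partition classes."""
    ctx = partition.context if spec.resolve().needs_context else None
    if spec.resolve().needs_context and partition.context is None:
        raise ContextRequiredError(
            "balaban index needs a partition with (p, q) context"
        )
    total = 0.0
    for (a, b), n in partition.items():
        if n:
            total += n * edge_weight(spec, a, b, context=ctx)
    return IndexValue(weight=spec, value=total)


def index_from_graph(graph: MolecularGraph, spec: WeightSpec) -> IndexValue:
    """Index of a graph; equal to the partition-based computation by construction."""
    return index_from_partition(edge_partition(graph), spec)


def all_indices(graph: MolecularGraph) -> dict[str, IndexValue | UndefinedIndex]:
    """Every registered weight on one graph; per-entry failures are captured
    as `UndefinedIndex` instead of aborting the batch."""
    part = edge_partition(graph)
    out: dict[str, IndexValue | UndefinedIndex] = {}
    for spec in default_weight_specs(include_aliases=True):
        try:
            out[spec.label] = index_from_partition(part, spec)
        except WeightDomainError as exc:
            out[spec.label] = UndefinedIndex(weight=spec, reason=str(exc))
    return out


def brute_force_index(graph: MolecularGraph, spec: WeightSpec) -> float:
    """Independent per-edge oracle: recomputes reverse degrees from raw edges
    with no partition or caching. Intended for tests."""
    deg: dict[str, int] = {}
    for u, v in graph.edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    delta = max(deg.values())
    ctx = (len(deg), len(graph.edges)) if spec.resolve().needs_context else None
    total = 0.0
    for u, v in graph.edges:
        a = delta - deg[u] + 1
        b = delta - deg[v] + 1
        if a > b:
            a, b = b, a
        total += edge_weight(spec, a, b, context=ctx)
    return total
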