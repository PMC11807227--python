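"""Shannon-type entropies over edge weights and vertex information functions.

The edge-weight entropy of a graph Z with weight function F is the Shannon
entropy of the probability distribution obtained by normalizing the per-edge
weights by their sum T = sum_{rs} F(rs):

    E_F(Z) = - sum_{rs} (F/T) log(F/T) = log T - (1/T) sum_{rs} F log F,

with the 0*log 0 = 0 convention for zero weights. The vertex version uses an
information function f(v) > 0 in place of F (reverse degree by default).

Computation is carried out in natural log and converted, so changing base
from e to b divides the value by ln b exactly.

`displayed_form_entropy` additionally replicates a class-aggregated variant
in which each reverse-degree class contributes log(count * F**F) once, rather
than count * F * log F. That variant is NOT mathematically equivalent to the
Shannon form above (the class count enters the logarithm instead of
multiplying it); it is provided purely as a diagnostic for comparison with
published per-class tabulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .errors import EntropyDomainError
from .molgraph import EdgePartition, MolecularGraph, reverse_degrees
from .weights import WeightSpec, edge_weight

__all__ = [
    "EntropyResult",
    "edge_weight_entropy",
    "vertex_information_entropy",
    "displayed_form_entropy",
    "VERTEX_INFO_FUNCTIONS",
]


@dataclass(frozen=True)
class EntropyResult:
    """An entropy value with the bookkeeping needed to interpret it.

    value          entropy in log-base units
    base           logarithm base (> 1)
    weight         label of the edge weight / vertex info function
    total_weight   the normalizer T = sum of weights
    n_outcomes     q for edge entropy, p for vertex entropy; the entropy is
                   bounded by log_base(n_outcomes)
    """

    value: float
    base: float
    weight: str
    total_weight: float
    n_outcomes: int

    @property
    def max_value(self) -> float:
        return math.log(self.n_outcomes) / math.log(self.base)


def _check_base(base: float) -> float:
    if base <= 1:
        raise EntropyDomainError(f"log base must exceed 1, got {base}")
    return math.log(base)


def edge_weight_entropy(
    partition: EdgePartition,
    spec: WeightSpec,
    base: float = math.e,
) -> EntropyResult:
    """Shannon entropy of the weight distribution over edges.

    Classes with zero weight (e.g. the atom-bond-connectivity weight on a
    (1,1) class) contribute nothing, by the 0*log 0 convention.
    """
    ln_base = _check_base(base)
    ctx = partition.context if spec.resolve().needs_context else None
    terms = []  # (count, weight)
    for (a, b), n in partition.items():
        if n == 0:
            continue
        w = edge_weight(spec, a, b, context=ctx)
        if w < 0:
            raise EntropyDomainError(
                f"negative weight {w} on class {(a, b)}; entropy undefined"
            )
        terms.append((n, w))
    total = sum(n * w for n, w in terms)
    if total <= 0:
        raise EntropyDomainError("all weights vanish; entropy undefined")
    acc = sum(n * w * math.log(w) for n, w in terms if w > 0)
    value_nats = math.log(total) - acc / total
    return EntropyResult(
        value=value_nats / ln_base,
        base=base,
        weight=spec.label,
        total_weight=total,
        n_outcomes=partition.q,
    )


def _info_reverse_degree(graph: MolecularGraph) -> dict[str, float]:
    return dict(reverse_degrees(graph).upsilon)


def _info_degree(graph: MolecularGraph) -> dict[str, float]:
    return {v: float(d) for v, d in graph.degrees().items()}


VERTEX_INFO_FUNCTIONS: dict[str, Callable[[MolecularGraph], dict[str, float]]] = {
    "reverse_degree": _info_reverse_degree,
    "degree": _info_degree,
}


def vertex_information_entropy(
    graph: MolecularGraph,
    info: str | Callable[[MolecularGraph], dict[str, float]] = "reverse_degree",
    base: float = math.e,
) -> EntropyResult:
    """Shannon entropy of a positive vertex information function.

    The normalizer is the true sum of the information values. (For reverse
    degrees that sum is p*(Delta+1) - 2q; the familiar degree-sum shortcut
    2q does not apply to reverse degrees.)
    """
    ln_base = _check_base(base)
    fn = VERTEX_INFO_FUNCTIONS[info] if isinstance(info, str) else info
    values = fn(graph)
    if any(x <= 0 for x in values.values()):
        raise EntropyDomainError("vertex information values must be positive")
    total = sum(values.values())
    acc = sum(x * math.log(x) for x in values.values())
    value_nats = math.log(total) - acc / total
    label = info if isinstance(info, str) else getattr(info, "__name__", "custom")
    return EntropyResult(
        value=value_nats / ln_base,
        base=base,
        weight=label,
        total_weight=total,
        n_outcomes=graph.p,
    )


def displayed_form_entropy(
    partition: EdgePartition,
    spec: WeightSpec,
    base: float = math.e,
) -> float:
    """Class-aggregated diagnostic variant: log T - (1/T) sum_k log(n_k * F_k**F_k).

    T is the index value (the same normalizer as `edge_weight_entropy`), but
    each class contributes a single log(count * F**F) term, so the result is
    NOT the Shannon entropy; see the module docstring.
    """
    ln_base = _check_base(base)
    ctx = partition.context if spec.resolve().needs_context else None
    terms = []
    for (a, b), n in partition.items():
        if n == 0:
            continue
        w = edge_weight(spec, a, b, context=ctx)
        if w < 0:
            raise EntropyDomainError(f"negative weight {w} on class {(a, b)}")
        terms.append((n, w))
    total = sum(n * w for n, w in terms)
    if total <= 0:
        raise EntropyDomainError("all weights vanish")
    # log(n * w**w) = log n + w log w, with w**w -> 1 as w -> 0
    acc = sum(math.log(n) + (w * math.log(w) if w > 0 else 0.0) for n, w in terms)
    return (math.log(total) - acc / total) / ln_base
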