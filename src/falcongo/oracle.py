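"""Exhaustive enumeration of consistent labelings for small DAGs.

Ancestrally closed subsets of a DAG with |V| terms can be enumerated by
walking the terms parents-before-children and branching only where every
parent is already positive: a child under a negative parent is forced to 0,
so whole inconsistent subtrees are pruned without being generated.  For the
graph sizes where this is tractable (the default cap is 20 terms) the
enumeration gives the exact most-probable labeling, which serves as the
ground truth the differential-evolution search is measured against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .dag import GoDag, Labeling
from .objectives import ObjectiveSpec, score

__all__ = ["EnumerationResult", "enumerate_consistent", "exhaustive_best"]

DEFAULT_CAP = 20


@dataclass
class EnumerationResult:
    best: Labeling
    best_score: float
    n_consistent: int
    ranked: Optional[list[tuple[float, Labeling]]] = None


def enumerate_consistent(
    dag: GoDag, cap: int = DEFAULT_CAP
) -> Iterator[Labeling]:
    """Yield every TPR-consistent labeling of ``dag`` exactly once."""
    if dag.n_terms > cap:
        raise ValueError(
            f"{dag.n_terms} terms exceeds the enumeration cap of {cap}; "
            "use the FALCON optimizer for graphs this large"
        )
    order = dag.topological_order()
    parents = dag.parent_indices()
    x = np.zeros(dag.n_terms, dtype=bool)

    def rec(pos: int) -> Iterator[Labeling]:
        if pos == len(order):
            yield x.copy()
            return
        g = order[pos]
        pa = parents[g]
        x[g] = False
        yield from rec(pos + 1)
        if pa.size == 0 or bool(np.all(x[pa])):
            x[g] = True
            yield from rec(pos + 1)
            x[g] = False

    yield from rec(0)


def exhaustive_best(
    dag: GoDag,
    theta: np.ndarray,
    priors: np.ndarray,
    spec: ObjectiveSpec,
    cap: int = DEFAULT_CAP,
    keep_ranked: bool = False,
) -> EnumerationResult:
    """Argmax of the objective over all consistent labelings.

    Ties are broken toward the lexicographically smallest bit vector so the
    result is deterministic.
    """
    best: Optional[Labeling] = None
    best_score = float("-inf")
    n = 0
    ranked: list[tuple[float, Labeling]] = [] if keep_ranked else None
    for x in enumerate_consistent(dag, cap=cap):
        s = score(x, theta, priors, dag, spec)
        if ranked is not None:
            ranked.append((s, x))
        n += 1
        if (
            best is None
            or s > best_score
            or (s == best_score and tuple(x) < tuple(best))
        ):
            best, best_score = x, s
    if ranked is not None:
        ranked.sort(key=lambda t: (-t[0], tuple(t[1])))
    return EnumerationResult(
        best=best, best_score=best_score, n_consistent=n, ranked=ranked
    )
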