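"""Gene Ontology DAG representation and True-Path-Rule machinery.

The GO is modelled as a directed acyclic graph ``G = (V, E)`` whose nodes are
term identifiers and whose edges point from child to parent (``is_a`` and,
optionally, ``part_of``).  A protein's annotation is a binary labeling ``x``
over ``V``; the True Path Rule (TPR) requires that a positively labeled child
implies positively labeled parents, i.e. the positive set is ancestrally
closed.  Everything downstream — the Bayesian-network density, the
differential-evolution moves, the exhaustive oracle — operates on labelings
that satisfy this rule, and the set algebra implemented here (element-wise
OR / AND) is closed under it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "Labeling",
    "load_dag",
    "is_consistent",
    "up_propagate",
    "labeling_union",
    "labeling_intersection",
    "random_ancestral_subgraph",
]

#: A labeling is a dense boolean vector indexed identically to ``GoDag.terms``.
Labeling = np.ndarray


@dataclass(frozen=True)
class GoDag:
    """A GO DAG with precomputed ancestor closure.

    Terms are held in a fixed lexicographic order; every vector quantity in
    the package (labelings, probability vectors, priors) is indexed by this
    order.  ``ancestor_closure`` row ``i`` is the boolean mask of term ``i``
    itself plus all of its ancestors, which makes up-propagation of a term
    set a single row-wise OR.
    """

    terms: tuple[str, ...]
    edges: frozenset[tuple[str, str]]  # (child, parent)
    parents_of: Mapping[str, frozenset[str]]
    ancestors_of: Mapping[str, frozenset[str]]
    index: Mapping[str, int] = field(repr=False)
    # edge arrays for vectorized TPR checks
    edge_child: np.ndarray = field(repr=False)
    edge_parent: np.ndarray = field(repr=False)
    # (|V|, |V|) boolean; row g = {g} ∪ ancestors(g)
    ancestor_closure: np.ndarray = field(repr=False)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if not self.parents_of[t])

    @property
    def leaves(self) -> tuple[str, ...]:
        has_child = {p for _, p in self.edges}
        return tuple(t for t in self.terms if t not in has_child)

    def topological_order(self) -> list[int]:
        """Indices ordered parents-before-children."""
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_terms))
        g.add_edges_from(
            zip(self.edge_parent.tolist(), self.edge_child.tolist())
        )
        return list(nx.topological_sort(g))

    def parent_indices(self) -> list[np.ndarray]:
        """Per-term integer arrays of parent positions (empty for roots)."""
        out: list[list[int]] = [[] for _ in range(self.n_terms)]
        for c, p in zip(self.edge_child.tolist(), self.edge_parent.tolist()):
            out[c].append(p)
        return [np.asarray(v, dtype=np.intp) for v in out]


class CycleError(ValueError):
    """Raised when the edge source contains a directed cycle."""


def load_dag(edge_source: Iterable[tuple[str, str]]) -> GoDag:
    """Build a :class:`GoDag` from an iterable of ``(child, parent)`` pairs.

    Duplicate edges are dropped silently (with a log entry); a cycle aborts
    the load and the error message names one offending cycle path.  Term
    order is lexicographic, fixed at load time.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dupes = 0
    for child, parent in edge_source:
        child, parent = str(child), str(parent)
        if not child or not parent:
            raise ValueError("term identifiers must be non-empty strings")
        if (child, parent) in seen:
            dupes += 1
            continue
        seen.add((child, parent))
        pairs.append((child, parent))
    if dupes:
        logger.info("deduplicated %d repeated edges", dupes)
    if not pairs:
        raise ValueError("edge source is empty")

    g = nx.DiGraph()
    for child, parent in pairs:
        g.add_edge(child, parent)  # direction: child -> parent
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle is not None:
        path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise CycleError(f"cycle detected in ontology edges: {path}")

    terms = tuple(sorted(g.nodes))
    index = {t: i for i, t in enumerate(terms)}
    parents_of = {
        t: frozenset(g.successors(t)) for t in terms
    }  # successors along child->parent = parents
    # nx.descendants along child->parent edges yields all ancestors
    ancestors_of = {t: frozenset(nx.descendants(g, t)) for t in terms}

    n = len(terms)
    edge_child = np.asarray([index[c] for c, _ in pairs], dtype=np.intp)
    edge_parent = np.asarray([index[p] for _, p in pairs], dtype=np.intp)
    closure = np.zeros((n, n), dtype=bool)
    for t, i in index.items():
        closure[i, i] = True
        for a in ancestors_of[t]:
            closure[i, index[a]] = True

    return GoDag(
        terms=terms,
        edges=frozenset(pairs),
        parents_of=parents_of,
        ancestors_of=ancestors_of,
        index=index,
        edge_child=edge_child,
        edge_parent=edge_parent,
        ancestor_closure=closure,
    )


def _check_length(x: np.ndarray, dag: GoDag) -> np.ndarray:
    x = np.asarray(x, dtype=bool)
    if x.shape != (dag.n_terms,):
        raise ValueError(
            f"labeling has length {x.shape}, expected ({dag.n_terms},)"
        )
    return x


def is_consistent(x: Labeling, dag: GoDag) -> bool:
    """True iff no edge carries child=1 with parent=0 (the TPR)."""
    x = _check_length(x, dag)
    if dag.edge_child.size == 0:
        return True
    return not np.any(x[dag.edge_child] & ~x[dag.edge_parent])


def up_propagate(positive_terms: Iterable[str], dag: GoDag) -> Labeling:
    """Close a term set under the ancestor relation.

    Returns the labeling with 1 exactly on ``positive_terms`` and all their
    ancestors; the result is consistent by construction.
    """
    rows = []
    for t in positive_terms:
        if t not in dag.index:
            raise KeyError(f"unknown term {t!r}")
        rows.append(dag.index[t])
    x = np.zeros(dag.n_terms, dtype=bool)
    if rows:
        x = dag.ancestor_closure[rows].any(axis=0)
    return x


def up_propagate_mask(mask: np.ndarray, dag: GoDag) -> Labeling:
    """Vectorized :func:`up_propagate` for a boolean seed mask."""
    mask = _check_length(mask, dag)
    if not mask.any():
        return np.zeros(dag.n_terms, dtype=bool)
    return dag.ancestor_closure[mask].any(axis=0)


def labeling_union(x1: Labeling, x2: Labeling) -> Labeling:
    """Element-wise OR; the union of two consistent labelings is consistent."""
    x1, x2 = np.asarray(x1, bool), np.asarray(x2, bool)
    if x1.shape != x2.shape:
        raise ValueError("labelings differ in length")
    return x1 | x2


def labeling_intersection(x1: Labeling, x2: Labeling) -> Labeling:
    """Element-wise AND; closed over consistent labelings like the union."""
    x1, x2 = np.asarray(x1, bool), np.asarray(x2, bool)
    if x1.shape != x2.shape:
        raise ValueError("labelings differ in length")
    return x1 & x2


def random_ancestral_subgraph(dag: GoDag, rng: np.random.Generator) -> Labeling:
    """A uniformly drawn term together with all its ancestors.

    This is the ergodicity term ``e`` of the optimizer's proposal moves: it
    guarantees every consistent configuration is reachable.
    """
    u = int(rng.integers(dag.n_terms))
    return dag.ancestor_closure[u].copy()
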