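"""Synthetic GO-like DAGs, probability vectors and planted-truth datasets.

Real inputs to a consistency decoder are the per-term membership
probabilities produced upstream by a network-propagation or classification
method; such methods characteristically return high probabilities for
general (shallow) terms and attenuated ones for detailed (deep) terms.  The
generators here emulate that structure so the whole pipeline — DAG loading,
objective scoring, optimization, evaluation — can be exercised end-to-end
without any external download, and so the simulation protocol (uniform
probability vectors on a small fixed DAG, exhaustive search as ground
truth) is a single function call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .dag import GoDag, load_dag, up_propagate
from .objectives import EPS, ObjectiveSpec, estimate_priors
from .optimizer import OptimizerConfig, evolve
from .oracle import exhaustive_best

__all__ = [
    "SyntheticDataset",
    "SimulationSummary",
    "random_dag",
    "uniform_theta",
    "planted_truth_dataset",
    "run_simulation_protocol",
    "term_depths",
]

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_dag(
    n_terms: int, max_parents: int = 2, seed: RngLike = None
) -> GoDag:
    """A connected rooted random DAG grown term by term.

    Term ``k`` (zero-padded name, so lexicographic order equals creation
    order) receives 1..max_parents parents drawn uniformly among earlier
    terms; the first term is the root.  For n_terms >= 4 and
    max_parents >= 2 at least one multi-parent term is guaranteed (an extra
    parent edge is added to the last term if the draw produced none), so
    the diamond configurations that make consistency non-trivial are always
    present.
    """
    if n_terms < 1 or max_parents < 1:
        raise ValueError("n_terms and max_parents must be >= 1")
    rng = _rng(seed)
    width = len(str(n_terms))
    names = [f"t{k:0{width}d}" for k in range(1, n_terms + 1)]
    if n_terms == 1:
        # degenerate single-root graph; load_dag needs >=1 edge, so build
        # the GoDag record directly
        return GoDag(
            terms=(names[0],),
            edges=frozenset(),
            parents_of={names[0]: frozenset()},
            ancestors_of={names[0]: frozenset()},
            index={names[0]: 0},
            edge_child=np.empty(0, dtype=np.intp),
            edge_parent=np.empty(0, dtype=np.intp),
            ancestor_closure=np.ones((1, 1), dtype=bool),
        )
    edges: list[tuple[str, str]] = []
    multi = False
    for k in range(1, n_terms):
        n_par = int(rng.integers(1, min(max_parents, k) + 1))
        parents = rng.choice(k, size=n_par, replace=False)
        multi = multi or n_par >= 2
        for p in parents:
            edges.append((names[k], names[int(p)]))
    if not multi and n_terms >= 4 and max_parents >= 2:
        existing = {p for c, p in edges if c == names[-1]}
        pool = [n for n in names[:-1] if n not in existing]
        extra = pool[int(rng.integers(len(pool)))]
        edges.append((names[-1], extra))
    return load_dag(edges)


def uniform_theta(
    dag: GoDag, n_vectors: int, seed: RngLike = None
) -> np.ndarray:
    """i.i.d. U(0,1) membership probabilities, one row per simulated protein."""
    if n_vectors < 1:
        raise ValueError("n_vectors must be >= 1")
    return _rng(seed).random((n_vectors, dag.n_terms))


def term_depths(dag: GoDag) -> np.ndarray:
    """Longest-path depth from a root (roots are depth 0)."""
    depth = np.zeros(dag.n_terms, dtype=int)
    parents = dag.parent_indices()
    for g in dag.topological_order():
        if parents[g].size:
            depth[g] = depth[parents[g]].max() + 1
    return depth


@dataclass
class SyntheticDataset:
    dag: GoDag
    truth: np.ndarray  # (n_proteins, |V|) bool, each row consistent
    theta: np.ndarray  # (n_proteins, |V|) in [0,1]
    priors: np.ndarray
    proteins: tuple[str, ...]
    seed: Optional[int]

    def truth_terms(self, protein: str) -> set[str]:
        i = self.proteins.index(protein)
        return {t for t, v in zip(self.dag.terms, self.truth[i]) if v}


# depth attenuation and Beta concentration for the planted-truth generator:
# the separation between true- and false-term probability means shrinks
# geometrically with term depth (emulating upstream methods' weak signal on
# detailed terms), and kappa controls sampling spread around those means
DEPTH_DECAY = 0.85
BETA_KAPPA = 30.0


def planted_truth_dataset(
    dag: GoDag,
    n_proteins: int,
    noise: float,
    seed: RngLike = None,
    max_leaves: int = 3,
) -> SyntheticDataset:
    """Proteins with known consistent labelings and noisy probabilities.

    Each protein's truth is the up-propagation of a small random non-empty
    leaf set.  At ``noise = 0`` the probability vector is deterministic and
    maximally informative (1-eps on true terms, eps elsewhere).  For
    ``noise > 0`` probabilities are Beta draws whose means sit at
    ``0.5 ± (0.5 - noise) * DEPTH_DECAY**depth`` for true/false terms: the
    separation collapses as noise approaches 0.5 and is weaker for deeper
    terms.  Priors are estimated from the planted truths themselves.
    """
    if not 0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = _rng(seed)
    leaves = list(dag.leaves)
    width = len(str(n_proteins))
    proteins = tuple(f"P{k:0{width}d}" for k in range(1, n_proteins + 1))

    truth = np.zeros((n_proteins, dag.n_terms), dtype=bool)
    for i in range(n_proteins):
        k = int(rng.integers(1, min(max_leaves, len(leaves)) + 1))
        chosen = rng.choice(len(leaves), size=k, replace=False)
        truth[i] = up_propagate([leaves[int(j)] for j in chosen], dag)

    depth = term_depths(dag)
    sep = (0.5 - noise) * DEPTH_DECAY ** depth
    theta = np.empty((n_proteins, dag.n_terms))
    if noise == 0:
        theta[:] = np.where(truth, 1.0 - EPS, EPS)
    else:
        mean = np.where(truth, 0.5 + sep, 0.5 - sep)
        a = mean * BETA_KAPPA
        b = (1.0 - mean) * BETA_KAPPA
        theta = rng.beta(a, b)

    annotations = {
        p: [t for t, v in zip(dag.terms, truth[i]) if v]
        for i, p in enumerate(proteins)
    }
    priors = estimate_priors(annotations, dag)
    return SyntheticDataset(
        dag=dag,
        truth=truth,
        theta=theta,
        priors=priors,
        proteins=proteins,
        seed=seed if isinstance(seed, (int, type(None))) else None,
    )


@dataclass
class SimulationSummary:
    """Outcome of the uniform-θ retrieval experiment on one fixed DAG."""

    n_instances: int
    n_retrieved: int
    matches: np.ndarray  # per-instance bool
    falcon_scores: np.ndarray
    optimal_scores: np.ndarray
    objective: str

    @property
    def retrieval_rate(self) -> float:
        return self.n_retrieved / self.n_instances


def run_simulation_protocol(
    dag: GoDag,
    n_vectors: int = 100,
    spec: Optional[ObjectiveSpec] = None,
    cfg: Optional[OptimizerConfig] = None,
    seed: RngLike = None,
    prior_value: float = 0.5,
) -> SimulationSummary:
    """Uniform probability vectors, flat priors, FALCON vs exhaustive search.

    For each of ``n_vectors`` simulated proteins the probability of every
    term is drawn U(0,1); all priors are fixed at ``prior_value``; the
    optimizer's best score is compared to the exhaustive optimum over all
    consistent labelings, and an instance counts as retrieved when they
    agree (to floating-point tolerance).
    """
    spec = spec or ObjectiveSpec(kind="eq1")
    cfg = cfg or OptimizerConfig()
    rng = _rng(seed)
    theta = uniform_theta(dag, n_vectors, rng)
    priors = np.full(dag.n_terms, prior_value)
    falcon = np.empty(n_vectors)
    optimal = np.empty(n_vectors)
    for i in range(n_vectors):
        falcon[i] = evolve(theta[i], priors, dag, spec, cfg, rng).best_score
        optimal[i] = exhaustive_best(dag, theta[i], priors, spec).best_score
    matches = np.isclose(falcon, optimal, rtol=1e-9, atol=1e-9)
    return SimulationSummary(
        n_instances=n_vectors,
        n_retrieved=int(matches.sum()),
        matches=matches,
        falcon_scores=falcon,
        optimal_scores=optimal,
        objective=spec.kind,
    )
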