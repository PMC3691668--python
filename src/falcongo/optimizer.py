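"""Discrete differential evolution over consistent labelings (FALCON).

The search space is the set of ancestrally closed binary labelings of the
GO DAG.  A population of N = 2|V| consistent labelings is evolved with four
proposal strategies built from the union/intersection algebra, which is
closed under TPR consistency — so every candidate ever constructed is
consistent and no repair step is needed:

* S1, global union:         R1 ∨ R2 ∨ e
* S2, global intersection:  (R1 ∧ R2) ∨ e
* S3, local union:          Ri ∨ R1 ∨ R2 ∨ e
* S4, local intersection:   (Ri ∧ R1) ∨ R2 ∨ e

R1, R2 are population members distinct from the target Ri, and ``e`` is a
fresh random ancestral subgraph (a uniformly drawn term plus its ancestors)
that guarantees every consistent labeling remains reachable.  A candidate
replaces Ri only if it scores strictly higher.  The run stops after a fixed
generation budget or when the population best has not improved for a
plateau of consecutive generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .dag import GoDag, Labeling, random_ancestral_subgraph, up_propagate_mask
from .objectives import ObjectiveSpec, calibrate, clip_probabilities

__all__ = [
    "OptimizerConfig",
    "Population",
    "EvolveResult",
    "initialize_population",
    "propose_candidate",
    "evolve",
    "predict_protein",
    "make_scorer",
]

STRATEGIES = ("S1", "S2", "S3", "S4")


@dataclass(frozen=True)
class OptimizerConfig:
    """Search budget and move configuration.

    ``max_generations`` is the total generation budget across all restarts.
    A run proceeds in rounds: when the population best stalls for
    ``plateau_generations`` the round ends and, budget permitting, the
    population is re-initialized from fresh random draws (the best-ever
    labeling is kept across rounds).  Restarts matter because the proposal
    algebra can only add terms on top of what the population jointly
    carries — the element-wise AND of all members never loses a term — so a
    round whose initial draws overshoot the optimum can never shrink back
    to it.  ``stale_rounds`` bounds how many consecutive rounds may end
    without improving the best-ever score before the run stops early.
    """

    max_generations: int = 10_000
    plateau_generations: int = 100
    stale_rounds: int = 10
    population_size: Optional[int] = None  # default 2|V| (floor 4)
    strategy_weights: tuple[float, float, float, float] = (
        0.25,
        0.25,
        0.25,
        0.25,
    )
    s4_grouping: str = "and_first"  # or "local_pair": (Ri ∧ (R1∨R2)) ∨ e
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if (
            self.max_generations <= 0
            or self.plateau_generations <= 0
            or self.stale_rounds <= 0
        ):
            raise ValueError("generation counts must be positive")
        if self.population_size is not None and self.population_size < 4:
            raise ValueError("population must have at least 4 members")
        w = np.asarray(self.strategy_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("strategy_weights must be 4 non-negatives summing to 1")
        if self.s4_grouping not in ("and_first", "local_pair"):
            raise ValueError("s4_grouping must be 'and_first' or 'local_pair'")

    def resolve_population_size(self, n_terms: int) -> int:
        if self.population_size is not None:
            return self.population_size
        return max(2 * n_terms, 4)


@dataclass
class Population:
    members: np.ndarray  # (N, |V|) bool; every row consistent
    scores: np.ndarray  # (N,) float
    generation: int = 0

    @property
    def size(self) -> int:
        return self.members.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.scores))


@dataclass
class EvolveResult:
    best: Labeling
    best_score: float
    history: list[float] = field(repr=False)
    n_generations: int = 0
    termination: str = ""

    def __iter__(self):
        # allow  best, score, history = evolve(...)
        return iter((self.best, self.best_score, self.history))


def make_scorer(
    theta: np.ndarray,
    priors: np.ndarray,
    dag: GoDag,
    spec: ObjectiveSpec,
) -> Callable[[np.ndarray], float]:
    """Fast objective evaluator valid for *consistent* labelings only.

    For the density-based objectives a consistent labeling can only have
    x_g = 1 where all parents are 1, so the -inf branch never triggers and
    the score reduces to sums over the positive set and the "active
    frontier" of negative terms whose parents are all positive.
    """
    priors = clip_probabilities(priors)
    if spec.kind == "deltal":
        theta = clip_probabilities(theta)
        neg = np.log1p(-theta) - np.log1p(-priors)
        w = (np.log(theta) - np.log(priors)) - neg
        base = float(neg.sum())

        def score_deltal(x: np.ndarray) -> float:
            return base + float(w[x].sum())

        return score_deltal

    if spec.kind == "logitr":
        theta = calibrate(theta, priors, spec.alpha)
    else:
        theta = clip_probabilities(theta)
    logt = np.log(theta)
    log1mt = np.log1p(-theta)
    echild, eparent = dag.edge_child, dag.edge_parent

    def score_density(x: np.ndarray) -> float:
        ok = np.ones(x.shape[0], dtype=bool)
        if echild.size:
            ok[echild[~x[eparent]]] = False
        return float(logt[x].sum() + log1mt[~x & ok].sum())

    return score_density


def inclusion_probabilities(
    theta: np.ndarray,
    priors: np.ndarray,
    spec: ObjectiveSpec,
) -> np.ndarray:
    """Per-term Bernoulli probabilities used to seed the population.

    eq1 uses θ directly, logitr the calibrated θc; deltal turns the
    per-term score difference between the positive and negative label,
    logit(θ) - logit(θ*), back into a probability via the logistic, which
    reduces to θ itself when all priors are 0.5.
    """
    theta = clip_probabilities(theta)
    priors = clip_probabilities(priors)
    if spec.kind == "eq1":
        return theta
    if spec.kind == "logitr":
        return calibrate(theta, priors, spec.alpha)
    d = (np.log(theta) - np.log1p(-theta)) - (
        np.log(priors) - np.log1p(-priors)
    )
    return 1.0 / (1.0 + np.exp(-d))


def initialize_population(
    theta: np.ndarray,
    priors: np.ndarray,
    dag: GoDag,
    spec: ObjectiveSpec,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
) -> Population:
    """Seed N consistent labelings by Bernoulli sampling + up-propagation."""
    n = cfg.resolve_population_size(dag.n_terms)
    p = inclusion_probabilities(theta, priors, spec)
    scorer = make_scorer(theta, priors, dag, spec)
    members = np.zeros((n, dag.n_terms), dtype=bool)
    # member 0 is the empty labeling — the bottom of the consistent lattice.
    # Every proposal ORs in a non-empty ancestral subgraph, so the
    # no-annotation solution can be kept from initialization but never
    # regenerated; seeding it makes that solution always representable.
    for i in range(1, n):
        seeds = rng.random(dag.n_terms) < p
        members[i] = up_propagate_mask(seeds, dag)
    scores = np.array([scorer(m) for m in members])
    return Population(members=members, scores=scores)


def propose_candidate(
    i: int,
    pop: Population,
    dag: GoDag,
    strategy: str,
    rng: np.random.Generator,
    s4_grouping: str = "and_first",
) -> Labeling:
    """One DE move: combine donors R1, R2, the target Ri and the random
    ancestral subgraph ``e`` according to the chosen strategy."""
    if pop.size < 3:
        raise ValueError("population must have at least 3 members to propose")
    if not 0 <= i < pop.size:
        raise IndexError(f"member index {i} out of range")
    others = [j for j in range(pop.size) if j != i]
    j1, j2 = rng.choice(len(others), size=2, replace=False)
    r1, r2 = pop.members[others[j1]], pop.members[others[j2]]
    ri = pop.members[i]
    e = random_ancestral_subgraph(dag, rng)
    if strategy == "S1":
        return r1 | r2 | e
    if strategy == "S2":
        return (r1 & r2) | e
    if strategy == "S3":
        return ri | r1 | r2 | e
    if strategy == "S4":
        if s4_grouping == "local_pair":
            return (ri & (r1 | r2)) | e
        return (ri & r1) | r2 | e
    raise ValueError(f"unknown strategy {strategy!r}")


def evolve(
    theta: np.ndarray,
    priors: np.ndarray,
    dag: GoDag,
    spec: ObjectiveSpec,
    cfg: Optional[OptimizerConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> EvolveResult:
    """Run the full differential-evolution search; returns the best-ever
    labeling, its score, and the per-generation best-score history."""
    cfg = cfg or OptimizerConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scorer = make_scorer(theta, priors, dag, spec)
    weights = np.asarray(cfg.strategy_weights)

    best: Optional[Labeling] = None
    best_score = float("-inf")
    history: list[float] = []
    total_gen = 0
    stale_rounds = 0
    termination = "max_generations"
    while total_gen < cfg.max_generations:
        pop = initialize_population(theta, priors, dag, spec, cfg, rng)
        round_best = float(pop.scores.max())
        if best is None or round_best > best_score:
            b = pop.best_index
            best = pop.members[b].copy()
            best_score = round_best
        history.append(best_score)
        improved_ever = False
        plateau = 0
        while plateau < cfg.plateau_generations and total_gen < cfg.max_generations:
            total_gen += 1
            strategies = rng.choice(4, size=pop.size, p=weights)
            for i in range(pop.size):
                cand = propose_candidate(
                    i, pop, dag, STRATEGIES[strategies[i]], rng, cfg.s4_grouping
                )
                s = scorer(cand)
                if s > pop.scores[i]:  # strict: ties rejected
                    pop.members[i] = cand
                    pop.scores[i] = s
            pop.generation = total_gen
            round_best = float(pop.scores.max())
            if round_best > best_score:
                b = pop.best_index
                best = pop.members[b].copy()
                best_score = round_best
                improved_ever = True
                plateau = 0
            else:
                plateau += 1
            history.append(best_score)
        stale_rounds = 0 if improved_ever else stale_rounds + 1
        if stale_rounds >= cfg.stale_rounds:
            termination = "stale_restarts"
            break
    return EvolveResult(
        best=best,
        best_score=best_score,
        history=history,
        n_generations=total_gen,
        termination=termination,
    )


@dataclass
class ProteinPrediction:
    protein: str
    terms: tuple[str, ...]
    labeling: Labeling
    score: float
    theta: np.ndarray
    theta_calibrated: Optional[np.ndarray]
    termination: str
    n_generations: int


def predict_protein(
    theta: np.ndarray,
    priors: np.ndarray,
    dag: GoDag,
    spec: ObjectiveSpec,
    cfg: Optional[OptimizerConfig] = None,
    rng: Optional[np.random.Generator] = None,
    protein: str = "",
) -> ProteinPrediction:
    """Decode one protein's probability vector into a consistent term set."""
    res = evolve(theta, priors, dag, spec, cfg, rng)
    terms = tuple(t for t, v in zip(dag.terms, res.best) if v)
    theta_c = (
        calibrate(theta, priors, spec.alpha) if spec.kind == "logitr" else None
    )
    return ProteinPrediction(
        protein=protein,
        terms=terms,
        labeling=res.best,
        score=res.best_score,
        theta=np.asarray(theta, float),
        theta_calibrated=theta_c,
        termination=res.termination,
        n_generations=res.n_generations,
    )
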