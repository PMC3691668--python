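"""Model/Results surface for consistent GO-term assignment.

:class:`FalconModel` bundles the inputs of the decoding problem — the GO
DAG, one or more per-protein probability vectors, the per-term priors and
the objective — and :meth:`FalconModel.fit` runs the differential-evolution
search, returning a :class:`FalconResults` that carries the consistent term
assignments, their objective scores, convergence diagnostics and a
``summary()`` table.

Randomness is controlled by a single seed: each protein's search stream is
derived by stable hashing of the protein identifier, so results are
independent of the order in which proteins are processed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dag import GoDag
from .evaluate import EvalReport, PredictionSet, evaluate
from .objectives import ObjectiveSpec, estimate_priors
from .optimizer import OptimizerConfig, ProteinPrediction, predict_protein

__all__ = ["FalconModel", "FalconResults", "protein_seed"]


def protein_seed(seed: Optional[int], protein: str) -> int:
    """Stable per-protein seed below 2**31, derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{protein}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class FalconModel:
    """Most-probable consistent GO-term assignment for a set of proteins.

    Parameters
    ----------
    theta
        Mapping of protein id → probability vector aligned with
        ``dag.terms`` (a single unnamed vector may be passed directly).
    dag
        The ontology as a :class:`~falcongo.dag.GoDag`.
    priors
        Per-term prior membership probabilities θ*; defaults to 0.5
        everywhere (a flat prior under which the DeltaL and density
        objectives agree on per-term preferences).
    objective, alpha
        One of ``eq1``, ``deltal``, ``logitr``; α is the calibration slope
        used by ``logitr``.
    """

    def __init__(
        self,
        theta: Mapping[str, np.ndarray] | np.ndarray,
        dag: GoDag,
        priors: Optional[np.ndarray] = None,
        objective: str = "logitr",
        alpha: float = 2.0,
    ) -> None:
        if isinstance(theta, np.ndarray):
            theta = {"protein": theta}
        self.theta = {p: np.asarray(v, float) for p, v in theta.items()}
        for p, v in self.theta.items():
            if v.shape != (dag.n_terms,):
                raise ValueError(
                    f"theta for {p!r} has shape {v.shape}, expected ({dag.n_terms},)"
                )
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"theta for {p!r} contains values outside [0,1]")
        self.dag = dag
        self.priors = (
            np.full(dag.n_terms, 0.5) if priors is None else np.asarray(priors, float)
        )
        self.spec = ObjectiveSpec(kind=objective, alpha=alpha)

    @classmethod
    def from_dataframe(
        cls,
        theta: pd.DataFrame,
        dag: GoDag,
        priors: Optional[np.ndarray] = None,
        **kwargs,
    ) -> "FalconModel":
        """Build from a protein × term DataFrame (columns = term ids)."""
        missing = [t for t in dag.terms if t not in theta.columns]
        fill = priors if priors is not None else np.full(dag.n_terms, 0.5)
        rows = {}
        for prot, row in theta.iterrows():
            v = fill.astype(float).copy()
            for t in theta.columns:
                if t in dag.index:
                    v[dag.index[t]] = row[t]
            rows[str(prot)] = v
        model = cls(rows, dag, priors=priors, **kwargs)
        model._imputed_terms = tuple(missing)
        return model

    @classmethod
    def from_annotated_priors(
        cls,
        theta: Mapping[str, np.ndarray],
        dag: GoDag,
        annotations: Mapping[str, Sequence[str]],
        **kwargs,
    ) -> "FalconModel":
        """Estimate θ* from an annotation corpus, then build the model."""
        return cls(theta, dag, priors=estimate_priors(annotations, dag), **kwargs)

    def fit(
        self,
        seed: Optional[int] = None,
        config: Optional[OptimizerConfig] = None,
    ) -> "FalconResults":
        """Run the FALCON search for every protein."""
        cfg = config or OptimizerConfig()
        preds = {}
        for prot in sorted(self.theta):
            rng = np.random.default_rng(protein_seed(seed, prot))
            preds[prot] = predict_protein(
                self.theta[prot],
                self.priors,
                self.dag,
                self.spec,
                cfg,
                rng,
                protein=prot,
            )
        return FalconResults(model=self, config=cfg, seed=seed, predictions=preds)


@dataclass
class FalconResults:
    """Fitted consistent assignments plus diagnostics."""

    model: FalconModel
    config: OptimizerConfig
    seed: Optional[int]
    predictions: dict[str, ProteinPrediction]

    @property
    def prediction_set(self) -> PredictionSet:
        return PredictionSet(
            terms={p: set(r.terms) for p, r in self.predictions.items()},
            scores={p: r.score for p, r in self.predictions.items()},
        )

    def predicted_terms(self, protein: Optional[str] = None):
        if protein is not None:
            return set(self.predictions[protein].terms)
        return {p: set(r.terms) for p, r in self.predictions.items()}

    def frame(self) -> pd.DataFrame:
        """Tidy protein/term/score table of all positive assignments."""
        rows = [
            {"protein": p, "term": t, "score": r.score}
            for p, r in sorted(self.predictions.items())
            for t in sorted(r.terms)
        ]
        return pd.DataFrame(rows, columns=["protein", "term", "score"])

    def score_against(
        self, truth: Mapping[str, Sequence[str]], **kwargs
    ) -> EvalReport:
        """Precision/recall/F against up-propagated truth annotations."""
        return evaluate(self.prediction_set, truth, self.model.dag, **kwargs)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "FALCON consistent GO-term assignment",
            "====================================",
            f"objective: {spec.kind}"
            + (f" (alpha={spec.alpha:g})" if spec.kind == "logitr" else ""),
            f"terms: {self.model.dag.n_terms}   proteins: {len(self.predictions)}"
            f"   seed: {self.seed}",
            f"population: {self.config.resolve_population_size(self.model.dag.n_terms)}"
            f"   budget: {self.config.max_generations} generations"
            f" (plateau {self.config.plateau_generations})",
            "",
            f"{'protein':<16}{'n_terms':>8}{'score':>14}{'generations':>13}  termination",
        ]
        for p, r in sorted(self.predictions.items()):
            lines.append(
                f"{p:<16}{len(r.terms):>8}{r.score:>14.4f}"
                f"{r.n_generations:>13}  {r.termination}"
            )
        return "\n".join(lines)
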