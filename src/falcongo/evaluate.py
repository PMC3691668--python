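"""Precision/recall/F evaluation and the maxF per-term threshold baseline.

maxF is the supervised comparator: for every GO term independently, pick the
probability cutoff that maximizes that term's F-score on training data and
predict ``θ ≥ cutoff``.  Because terms are thresholded independently, the
resulting per-protein term lists are not guaranteed to respect the True
Path Rule — unlike anything the FALCON optimizer emits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dag import GoDag, is_consistent, up_propagate

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionSet",
    "EvalReport",
    "maxf_thresholds",
    "maxf_predict",
    "precision_recall_f",
    "evaluate",
]


@dataclass
class PredictionSet:
    """Per-protein predicted term sets with optional scores."""

    terms: dict[str, set[str]]
    scores: dict[str, float] = field(default_factory=dict)

    def consistency_flags(self, dag: GoDag) -> dict[str, bool]:
        out = {}
        for prot, ts in self.terms.items():
            x = np.zeros(dag.n_terms, dtype=bool)
            x[[dag.index[t] for t in ts if t in dag.index]] = True
            out[prot] = is_consistent(x, dag)
        return out


def _fscore(p: float, r: float, mean: str) -> float:
    if mean == "harmonic":
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)
    if mean == "geometric":
        return math.sqrt(p * r)
    raise ValueError(f"unknown F mean {mean!r}")


def precision_recall_f(
    predicted: set[str],
    truth: set[str],
    mean: str = "harmonic",
) -> tuple[float, float, float]:
    """Set-overlap precision, recall and F for one protein.

    ``truth`` must already be up-propagated.  An empty prediction has
    undefined precision and is reported as (0, 0, 0); an empty truth set is
    an error (the caller excludes such proteins).
    """
    if not truth:
        raise ValueError("truth set is empty; protein cannot be scored")
    if not predicted:
        return (0.0, 0.0, 0.0)
    tp = len(predicted & truth)
    p = tp / len(predicted)
    r = tp / len(truth)
    return (p, r, _fscore(p, r, mean))


def maxf_thresholds(
    train_theta: pd.DataFrame,
    train_labels: pd.DataFrame,
    mean: str = "harmonic",
) -> pd.Series:
    """Training-F-optimal probability cutoff per term (columns of the frame).

    The exact optimum is found by scanning the midpoints between consecutive
    distinct observed θ values (plus the minimum itself, i.e. predict-all);
    ties go to the smallest cutoff.  A term with no positive training
    example gets +inf (never predicted) and is logged.
    """
    if not train_theta.columns.equals(train_labels.columns) or not (
        train_theta.index.equals(train_labels.index)
    ):
        raise ValueError("theta and label frames must be aligned")
    cuts = {}
    for term in train_theta.columns:
        theta = train_theta[term].to_numpy(dtype=float)
        y = train_labels[term].to_numpy(dtype=bool)
        if not y.any():
            logger.info("term %s has no positives; threshold set to +inf", term)
            cuts[term] = math.inf
            continue
        u = np.unique(theta)
        candidates = np.concatenate([[u[0]], (u[:-1] + u[1:]) / 2.0])
        best_f, best_t = -1.0, math.inf
        for t in candidates:
            pred = theta >= t
            tp = int((pred & y).sum())
            p = tp / pred.sum() if pred.any() else 0.0
            r = tp / y.sum()
            f = _fscore(p, r, mean)
            if f > best_f:
                best_f, best_t = f, float(t)
        cuts[term] = best_t
    return pd.Series(cuts, name="threshold")


def maxf_predict(
    theta: pd.DataFrame, thresholds: pd.Series
) -> PredictionSet:
    """Apply per-term cutoffs: predict term g for a protein iff θ_g ≥ cutoff."""
    terms: dict[str, set[str]] = {}
    common = [c for c in theta.columns if c in thresholds.index]
    cut = thresholds[common].to_numpy()
    mat = theta[common].to_numpy(dtype=float) >= cut
    for i, prot in enumerate(theta.index):
        terms[str(prot)] = {common[j] for j in np.flatnonzero(mat[i])}
    return PredictionSet(terms=terms)


@dataclass
class EvalReport:
    per_protein: pd.DataFrame
    per_term: pd.DataFrame
    macro_protein: dict[str, float]
    macro_term: dict[str, float]
    n_proteins_with_predictions: int
    n_proteins_scored: int
    inconsistent_proteins: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            "-----------------",
            f"proteins with >=1 prediction: {self.n_proteins_with_predictions}",
            f"proteins entering per-protein means: {self.n_proteins_scored}",
            "per-protein macro: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.macro_protein.items()),
            "per-term macro:    "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.macro_term.items()),
        ]
        if self.inconsistent_proteins:
            lines.append(
                f"TPR-inconsistent predictions for {len(self.inconsistent_proteins)} protein(s)"
            )
        return "\n".join(lines)


def evaluate(
    predictions: PredictionSet | Mapping[str, set[str]],
    truth: Mapping[str, Sequence[str]],
    dag: GoDag,
    exclude_roots: bool = True,
    mean: str = "harmonic",
) -> EvalReport:
    """Macro-averaged per-protein and per-term metrics.

    Truth annotations are up-propagated before scoring.  Per-protein means
    run over proteins with at least one prediction and non-empty truth;
    per-term metrics cover every term appearing in either side.  Root terms
    are excluded by default (predicting a root is vacuous).
    """
    if isinstance(predictions, PredictionSet):
        pred_sets = predictions.terms
        flags = predictions.consistency_flags(dag)
    else:
        pred_sets = {k: set(v) for k, v in predictions.items()}
        flags = PredictionSet(terms=pred_sets).consistency_flags(dag)
    roots = set(dag.roots) if exclude_roots else set()

    truth_sets: dict[str, set[str]] = {}
    for prot, terms in truth.items():
        x = up_propagate(terms, dag)
        truth_sets[prot] = {
            t for t, v in zip(dag.terms, x) if v and t not in roots
        }

    rows = []
    n_with_pred = 0
    for prot in sorted(set(pred_sets) | set(truth_sets)):
        pred = pred_sets.get(prot, set()) - roots
        if pred:
            n_with_pred += 1
        tru = truth_sets.get(prot, set())
        if not tru:
            logger.info("protein %s has empty truth; excluded", prot)
            continue
        if not pred:
            continue  # per-protein means run over proteins with predictions
        p, r, f = precision_recall_f(pred, tru, mean=mean)
        rows.append(
            {"protein": prot, "precision": p, "recall": r, "f": f,
             "n_predicted": len(pred), "n_truth": len(tru)}
        )
    per_protein = pd.DataFrame(
        rows, columns=["protein", "precision", "recall", "f",
                       "n_predicted", "n_truth"]
    ).set_index("protein")

    all_terms = sorted(
        (set().union(*pred_sets.values()) if pred_sets else set())
        | (set().union(*truth_sets.values()) if truth_sets else set())
    )
    all_terms = [t for t in all_terms if t not in roots]
    trows = []
    proteins = sorted(set(pred_sets) | set(truth_sets))
    for term in all_terms:
        tp = fp = fn = 0
        for prot in proteins:
            in_pred = term in pred_sets.get(prot, set())
            in_true = term in truth_sets.get(prot, set())
            tp += in_pred and in_true
            fp += in_pred and not in_true
            fn += in_true and not in_pred
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        trows.append(
            {"term": term, "precision": p, "recall": r,
             "f": _fscore(p, r, mean), "tp": tp, "fp": fp, "fn": fn}
        )
    per_term = pd.DataFrame(
        trows, columns=["term", "precision", "recall", "f", "tp", "fp", "fn"]
    ).set_index("term")

    def macro(df: pd.DataFrame) -> dict[str, float]:
        if df.empty:
            return {"precision": 0.0, "recall": 0.0, "f": 0.0}
        return {
            k: float(df[k].mean()) for k in ("precision", "recall", "f")
        }

    return EvalReport(
        per_protein=per_protein,
        per_term=per_term,
        macro_protein=macro(per_protein),
        macro_term=macro(per_term),
        n_proteins_with_predictions=n_with_pred,
        n_proteins_scored=len(per_protein),
        inconsistent_proteins=tuple(
            sorted(p for p, ok in flags.items() if not ok)
        ),
    )
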