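"""Objective functions scored over TPR-consistent labelings.

Three objectives are supported, all maximized:

``eq1``
    The log of the Bayesian-network density ``p(x | G, θ) = Π_g p(x_g |
    x_pa(g))`` with the conditional probability table: when every parent of
    ``g`` is positive (vacuously true for roots), ``x_g = 1`` with
    probability ``θ_g``; when any parent is 0, ``x_g`` is forced to 0.
    Inconsistent labelings therefore have probability zero (log-density
    ``-inf``).

``deltal``
    The difference of log-likelihoods under the input probabilities θ and
    the prior membership probabilities θ*: each term contributes
    ``log(θ_g/θ*_g)`` when positive and ``log((1-θ_g)/(1-θ*_g))`` when
    negative.  A term is worth switching on exactly when θ_g > θ*_g.

``logitr``
    The ``eq1`` log-density evaluated on probabilities calibrated on the
    logit scale: ``logit θc_g = logit θ*_g + α (logit θ_g - logit θ*_g)``.
    α > 1 pushes probabilities away from the prior, making terms whose
    posterior exceeds their prior stand out; θ = θ* is a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .dag import GoDag, Labeling, up_propagate

logger = logging.getLogger(__name__)

__all__ = [
    "EPS",
    "ObjectiveSpec",
    "clip_probabilities",
    "log_density",
    "delta_l",
    "calibrate",
    "score",
    "estimate_priors",
]

#: Probabilities are clipped into [EPS, 1-EPS] before any log or logit.
EPS = 1e-6

OBJECTIVES = ("eq1", "deltal", "logitr")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which objective to maximize and the calibration slope α (logitr)."""

    kind: str = "logitr"
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVES:
            raise ValueError(
                f"unknown objective {self.kind!r}; expected one of {OBJECTIVES}"
            )
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


def clip_probabilities(theta: np.ndarray, warn: bool = False) -> np.ndarray:
    """Clip into [EPS, 1-EPS]; logs a warning if exact 0/1 entries occur."""
    theta = np.asarray(theta, dtype=float)
    if warn and np.any((theta <= 0.0) | (theta >= 1.0)):
        logger.warning(
            "probabilities at {0,1} clipped into [%g, %g]", EPS, 1 - EPS
        )
    return np.clip(theta, EPS, 1.0 - EPS)


def _parents_all_positive(x: np.ndarray, dag: GoDag) -> np.ndarray:
    """Boolean vector: min over parents of x is 1 (vacuously true at roots)."""
    ok = np.ones(dag.n_terms, dtype=bool)
    if dag.edge_child.size:
        off = dag.edge_child[~x[dag.edge_parent]]
        ok[off] = False
    return ok


def log_density(x: Labeling, theta: np.ndarray, dag: GoDag) -> float:
    """Log Bayesian-network density of a labeling; -inf if inconsistent."""
    x = np.asarray(x, dtype=bool)
    theta = np.asarray(theta, dtype=float)
    if x.shape != (dag.n_terms,) or theta.shape != (dag.n_terms,):
        raise ValueError("labeling/theta length must equal the number of terms")
    ok = _parents_all_positive(x, dag)
    if np.any(x & ~ok):
        return float("-inf")
    theta = clip_probabilities(theta)
    # active terms contribute log θ (x=1) or log(1-θ) (x=0);
    # terms under a negative parent contribute log 1 = 0
    return float(
        np.sum(np.where(x, np.log(theta), ok * np.log1p(-theta)))
    )


def delta_l(
    x: Labeling,
    theta: np.ndarray,
    priors: np.ndarray,
    dag: GoDag,
    conditional: bool = False,
) -> float:
    """Log-likelihood difference between input and prior probabilities.

    By default the per-term log-ratio scores are summed over every term.
    With ``conditional=True`` the CPT-conditional reading is used instead:
    ``log_density(x; θ) - log_density(x; θ*)``, in which terms below a
    negative parent contribute nothing.
    """
    x = np.asarray(x, dtype=bool)
    theta = clip_probabilities(theta, warn=True)
    priors = clip_probabilities(priors)
    if conditional:
        return log_density(x, theta, dag) - log_density(x, priors, dag)
    pos = np.log(theta) - np.log(priors)
    neg = np.log1p(-theta) - np.log1p(-priors)
    return float(np.sum(np.where(x, pos, neg)))


def calibrate(
    theta: np.ndarray, priors: np.ndarray, alpha: float
) -> np.ndarray:
    """Logit-scale calibration of θ toward/away from the prior θ*.

    ``logit θc = logit θ* + α (logit θ - logit θ*)``.  α = 1 is the
    identity; θ = θ* is a fixed point for every α; the map is strictly
    increasing in θ for fixed prior and α.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    theta = clip_probabilities(theta)
    priors = clip_probabilities(priors)
    logit = lambda p: np.log(p) - np.log1p(-p)  # noqa: E731
    z = logit(priors) + alpha * (logit(theta) - logit(priors))
    # numerically stable inverse logit
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def score(
    x: Labeling,
    theta: np.ndarray,
    priors: np.ndarray,
    dag: GoDag,
    spec: ObjectiveSpec,
) -> float:
    """Dispatch to the configured objective; higher is better."""
    if spec.kind == "eq1":
        return log_density(x, theta, dag)
    if spec.kind == "deltal":
        return delta_l(x, theta, priors, dag)
    if spec.kind == "logitr":
        return log_density(x, calibrate(theta, priors, spec.alpha), dag)
    raise ValueError(f"unknown objective {spec.kind!r}")


def estimate_priors(
    annotations: Mapping[str, Iterable[str]], dag: GoDag
) -> np.ndarray:
    """Prior membership probability per term from a protein→terms map.

    Each protein's term set is up-propagated first (the TPR applies to the
    annotations themselves); θ*_g is the fraction of proteins whose closed
    set contains g, clipped into [EPS, 1-EPS].
    """
    if not annotations:
        raise ValueError("annotation map is empty")
    counts = np.zeros(dag.n_terms, dtype=float)
    for terms in annotations.values():
        counts += up_propagate(terms, dag)
    return clip_probabilities(counts / len(annotations))
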