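"""Readers and writers for the TSV/OBO formats and the run manifest.

All tabular formats are UTF-8 tab-separated text with ``#`` comment lines
and no quoting:

* edge list: ``child<TAB>parent`` (header optional);
* θ matrix: header row of term identifiers, first column protein IDs,
  values in [0, 1];
* priors: ``term<TAB>prior``;
* annotations: ``protein<TAB>term``, one pair per line;
* predictions: ``protein<TAB>term<TAB>score``.

Ontologies may alternatively be given as OBO 1.2 files; ``is_a`` edges are
always honored, ``part_of`` optionally, any other relationship is ignored
with a logged count, and obsolete term stanzas are skipped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import obonet
import pandas as pd

from .dag import GoDag, load_dag

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_tsv",
    "load_dag_tsv",
    "load_dag_obo",
    "read_theta_matrix",
    "write_theta_matrix",
    "read_priors_tsv",
    "write_priors_tsv",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "write_predictions_tsv",
    "read_predictions_tsv",
    "RunManifest",
]


def _data_lines(path: str | Path) -> list[list[str]]:
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def read_edge_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read ``child<TAB>parent`` pairs; a ``child/parent`` header is skipped."""
    rows = _data_lines(path)
    if rows and [c.lower() for c in rows[0][:2]] == ["child", "parent"]:
        rows = rows[1:]
    pairs = []
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"malformed edge line: {row!r}")
        pairs.append((row[0], row[1]))
    return pairs


def load_dag_tsv(path: str | Path) -> GoDag:
    return load_dag(read_edge_tsv(path))


def load_dag_obo(path: str | Path, include_part_of: bool = False) -> GoDag:
    """Load an OBO 1.2 ontology restricted to is_a (and optionally part_of)."""
    graph = obonet.read_obo(str(path))  # skips is_obsolete stanzas
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    pairs = []
    skipped: dict[str, int] = {}
    for child, parent, key in graph.edges(keys=True):
        if key in keep:
            pairs.append((child, parent))
        else:
            skipped[key] = skipped.get(key, 0) + 1
    for rel, n in sorted(skipped.items()):
        logger.info("ignored %d %s relationship(s)", n, rel)
    return load_dag(pairs)


def read_theta_matrix(
    path: str | Path,
    dag: GoDag,
    priors: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Protein × term probability matrix, validated against the DAG.

    Values outside [0, 1] raise with the offending cell named; matrix terms
    not in the DAG raise listing them; DAG terms missing from the matrix
    are imputed with the prior θ* (0.5 if no priors are given) and logged —
    the neutral value under every objective.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.columns = df.columns.astype(str)
    unknown = [t for t in df.columns if t not in dag.index]
    if unknown:
        raise ValueError(f"terms not present in the DAG: {unknown}")
    bad = np.argwhere((df.values < 0) | (df.values > 1) | ~np.isfinite(df.values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"probability out of [0,1] at protein {df.index[i]!r}, "
            f"term {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    missing = [t for t in dag.terms if t not in df.columns]
    fill = priors if priors is not None else np.full(dag.n_terms, 0.5)
    if missing:
        logger.info(
            "imputing %d term(s) absent from the matrix with priors", len(missing)
        )
    out = {}
    for prot, row in df.iterrows():
        theta = fill.astype(float).copy()
        idx = [dag.index[t] for t in df.columns]
        theta[idx] = row.to_numpy(dtype=float)
        out[str(prot)] = theta
    return out


def write_theta_matrix(
    path: str | Path, theta: Mapping[str, np.ndarray], dag: GoDag
) -> None:
    df = pd.DataFrame(
        {p: np.asarray(v, float) for p, v in theta.items()}, index=dag.terms
    ).T
    df.index.name = "protein"
    df.to_csv(path, sep="\t")


def read_priors_tsv(path: str | Path, dag: GoDag) -> np.ndarray:
    """``term<TAB>prior`` into a vector aligned with ``dag.terms``."""
    rows = _data_lines(path)
    if rows and rows[0][0].lower() == "term":
        rows = rows[1:]
    values = {}
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"malformed prior line: {row!r}")
        if row[0] not in dag.index:
            raise ValueError(f"prior for unknown term {row[0]!r}")
        values[row[0]] = float(row[1])
    missing = [t for t in dag.terms if t not in values]
    if missing:
        raise ValueError(f"priors missing for terms: {missing[:10]}")
    return np.array([values[t] for t in dag.terms])


def write_priors_tsv(path: str | Path, priors: np.ndarray, dag: GoDag) -> None:
    with open(path, "w") as fh:
        fh.write("term\tprior\n")
        for t, v in zip(dag.terms, priors):
            fh.write(f"{t}\t{v:.10g}\n")


def read_annotations_tsv(path: str | Path) -> dict[str, set[str]]:
    """``protein<TAB>term`` pairs into a protein → term-set map."""
    rows = _data_lines(path)
    if rows and [c.lower() for c in rows[0][:2]] == ["protein", "term"]:
        rows = rows[1:]
    out: dict[str, set[str]] = {}
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"malformed annotation line: {row!r}")
        out.setdefault(row[0], set()).add(row[1])
    return out


def write_annotations_tsv(
    path: str | Path, annotations: Mapping[str, Sequence[str]]
) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tterm\n")
        for prot in sorted(annotations):
            for term in sorted(annotations[prot]):
                fh.write(f"{prot}\t{term}\n")


def write_predictions_tsv(
    path: str | Path,
    predictions: Mapping[str, Sequence[str]],
    scores: Optional[Mapping[str, float]] = None,
) -> None:
    """``protein<TAB>term<TAB>score`` (score = the protein's objective value)."""
    with open(path, "w") as fh:
        fh.write("protein\tterm\tscore\n")
        for prot in sorted(predictions):
            s = scores.get(prot, float("nan")) if scores else float("nan")
            for term in sorted(predictions[prot]):
                fh.write(f"{prot}\t{term}\t{s:.10g}\n")


def read_predictions_tsv(path: str | Path) -> dict[str, set[str]]:
    rows = _data_lines(path)
    if rows and rows[0][0].lower() == "protein":
        rows = rows[1:]
    out: dict[str, set[str]] = {}
    for row in rows:
        out.setdefault(row[0], set()).add(row[1])
    return out


@dataclass
class RunManifest:
    """Everything needed to replay a run bit-exactly."""

    command: str
    inputs: dict[str, str]
    objective: str
    alpha: float
    optimizer: dict[str, object]
    seed: Optional[int]
    version: str = ""
    termination: dict[str, str] = field(default_factory=dict)
    n_generations: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
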