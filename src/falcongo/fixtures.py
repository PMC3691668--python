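"""Frozen small fixture DAGs used by the simulation protocol and tests.

Both graphs are synthetic stand-ins: small rooted DAGs with multi-parent
terms, generated once with :func:`falcongo.synthetic.random_dag` (seed 11)
and frozen here as literal edge lists so the retrieval experiments are
reproducible byte-for-byte.  At these sizes the retrieval behaviour of the
optimizer is robust to the exact topology; what matters is that diamonds
(terms with two or more parents) are present, since those are the
configurations where term-independent thresholding breaks the True Path
Rule.
"""

from __future__ import annotations

from .dag import GoDag, load_dag

__all__ = ["fixture_dag_6", "fixture_dag_15", "EDGES_6", "EDGES_15"]

# 6 terms, single root t1, two multi-parent terms (t4, t5); 15 consistent
# labelings out of 2^6 = 64 binary vectors
EDGES_6: tuple[tuple[str, str], ...] = (
    ("t2", "t1"),
    ("t3", "t1"),
    ("t4", "t1"),
    ("t4", "t2"),
    ("t5", "t1"),
    ("t5", "t2"),
    ("t6", "t5"),
)

# 15 terms, single root t01, seven multi-parent terms; 243 consistent
# labelings out of 2^15 = 32768 binary vectors
EDGES_15: tuple[tuple[str, str], ...] = (
    ("t02", "t01"),
    ("t03", "t01"),
    ("t04", "t01"),
    ("t04", "t02"),
    ("t05", "t01"),
    ("t05", "t02"),
    ("t06", "t05"),
    ("t07", "t01"),
    ("t07", "t04"),
    ("t08", "t06"),
    ("t08", "t07"),
    ("t09", "t02"),
    ("t09", "t03"),
    ("t10", "t06"),
    ("t11", "t03"),
    ("t11", "t09"),
    ("t12", "t09"),
    ("t13", "t09"),
    ("t14", "t07"),
    ("t15", "t11"),
    ("t15", "t12"),
)


def fixture_dag_6() -> GoDag:
    """The 6-term fixture DAG (single root, two diamond terms)."""
    return load_dag(EDGES_6)


def fixture_dag_15() -> GoDag:
    """The 15-term fixture DAG (single root, seven multi-parent terms)."""
    return load_dag(EDGES_15)
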