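"""Disease semantic similarity and lncRNA functional similarity.

Disease side (Wang-style DAG measure): each disease is placed in the MeSH
hierarchy by its tree numbers.  The disease plus all ancestors (obtained by
dot-segment prefix truncation) form a DAG; the disease's own positions
contribute 1 and every ancestor contributes a decay-factor-damped maximum over
its children.  The semantic similarity of two diseases is the summed shared
contribution relative to their total semantic values.

lncRNA side (LNCSIM group-wise measure): the functional similarity of two
lncRNAs is the best-match average of disease semantic similarities between
their associated disease groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_io import AssociationDataset, SimilarityMatrix

__all__ = [
    "DiseaseDAG",
    "build_dag",
    "build_dags",
    "disease_similarity",
    "all_disease_similarities",
    "group_similarity",
    "lncrna_similarity",
]


def _ancestors(code: str) -> list[str]:
    """All prefixes of a dot-delimited tree code, including the code itself."""
    parts = code.split(".")
    return [".".join(parts[: k + 1]) for k in range(len(parts))]


@dataclass(frozen=True)
class DiseaseDAG:
    """One disease's ancestor DAG with per-term semantic contributions.

    ``terms`` is the disease's tree positions plus every ancestor;
    ``edges`` are parent->child prefix links; ``contributions`` maps each term
    to its semantic contribution: exactly 1 on the disease's own positions,
    decayed max-over-children elsewhere.
    """

    disease_id: str
    codes: frozenset
    terms: frozenset
    edges: frozenset
    contributions: dict
    decay: float

    @property
    def semantic_value(self) -> float:
        """Total semantic value T(D): the sum of all term contributions."""
        return float(sum(self.contributions.values()))


def build_dag(disease_id: str, tree_codes, decay: float = 0.5) -> DiseaseDAG:
    """Build the ancestor DAG of one disease from its tree numbers.

    Parameters
    ----------
    disease_id:
        Disease identifier.
    tree_codes:
        One or more dot-delimited tree numbers locating the disease.
    decay:
        Semantic contribution decay factor in [0, 1]; each step from a node to
        its parent multiplies the contribution by this factor, and a term
        reachable along several paths keeps the maximum.
    """
    codes = {str(c) for c in tree_codes}
    if not codes:
        raise ValueError(f"disease {disease_id!r} has no tree codes")
    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must be in [0, 1], got {decay}")

    terms: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for code in codes:
        chain = _ancestors(code)
        terms.update(chain)
        edges.update(zip(chain[:-1], chain[1:]))

    # Prefix truncation cannot create a cycle (every edge strictly increases
    # segment count), but guard anyway per the type contract.
    depth = {t: t.count(".") for t in terms}
    if any(depth[p] >= depth[c] for p, c in edges):
        raise ValueError("cyclic edge set in disease DAG")

    children: dict[str, list[str]] = {t: [] for t in terms}
    for p, c in edges:
        children[p].append(c)

    contributions: dict[str, float] = {}
    for term in sorted(terms, key=lambda t: -depth[t]):  # deepest first
        if term in codes:
            contributions[term] = 1.0
        else:
            contributions[term] = max(
                decay * contributions[c] for c in children[term]
            )
    return DiseaseDAG(
        disease_id=disease_id,
        codes=frozenset(codes),
        terms=frozenset(terms),
        edges=frozenset(edges),
        contributions=contributions,
        decay=decay,
    )


def build_dags(tree_numbers: Mapping[str, set], decay: float = 0.5,
               order: Sequence[str] | None = None) -> dict[str, DiseaseDAG]:
    """Build DAGs for every disease in ``tree_numbers`` (optionally in a given
    order); a disease missing from the map raises KeyError."""
    ids = list(order) if order is not None else list(tree_numbers)
    return {d: build_dag(d, tree_numbers[d], decay) for d in ids}


def disease_similarity(a: DiseaseDAG, b: DiseaseDAG) -> float:
    """Semantic similarity of two diseases from their shared DAG terms.

    The score is the sum of both diseases' contributions over the shared terms
    divided by the sum of their semantic values; it is symmetric, lies in
    [0, 1], is 1 for identical DAGs and 0 for disjoint ones.
    """
    if a.decay != b.decay:
        raise ValueError("DAGs were built with different decay factors")
    shared = a.terms & b.terms
    if not shared:
        return 0.0
    num = sum(a.contributions[t] + b.contributions[t] for t in shared)
    return float(num / (a.semantic_value + b.semantic_value))


def all_disease_similarities(dags: Sequence[DiseaseDAG]) -> SimilarityMatrix:
    """Pairwise disease semantic similarity matrix (symmetric, unit diagonal)."""
    ids = [d.disease_id for d in dags]
    n = len(dags)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = disease_similarity(dags[i], dags[j])
    return SimilarityMatrix(ids, values)


def group_similarity(d: int, group, DD: SimilarityMatrix | np.ndarray) -> float:
    """Best-match similarity between disease ``d`` and a disease group: the
    maximum of DD(d, g) over g in the group.  Raises on an empty group."""
    group = list(group)
    if not group:
        raise ValueError("disease group is empty")
    values = DD.values if isinstance(DD, SimilarityMatrix) else np.asarray(DD)
    return float(values[d, group].max())


def lncrna_similarity(AS: np.ndarray | AssociationDataset,
                      DD: SimilarityMatrix | np.ndarray,
                      lncrna_ids: Sequence[str] | None = None) -> SimilarityMatrix:
    """LNCSIM functional similarity between lncRNAs.

    For lncRNAs u, v with associated disease groups D(u), D(v),

        LL(u, v) = [ sum_{d in D(u)} max_{d' in D(v)} DD(d, d')
                   + sum_{d in D(v)} max_{d' in D(u)} DD(d, d') ]
                   / ( |D(u)| + |D(v)| ).

    If either group is empty the similarity is defined as 0 — including the
    diagonal of an empty-profile lncRNA — encoding "no functional evidence".
    DD must be indexed consistently with the columns of ``AS``.
    """
    if isinstance(AS, AssociationDataset):
        if lncrna_ids is None:
            lncrna_ids = AS.lncrna_ids
        AS = AS.AS
    AS = np.asarray(AS)
    dd = DD.values if isinstance(DD, SimilarityMatrix) else np.asarray(DD)
    nl, nd = AS.shape
    if dd.shape != (nd, nd):
        raise ValueError("DD must be square over the disease axis of AS")
    if lncrna_ids is None:
        lncrna_ids = [f"L{i}" for i in range(nl)]

    groups = [np.flatnonzero(AS[u]) for u in range(nl)]
    deg = np.array([len(g) for g in groups], dtype=float)
    # best[u, d] = max_{d' in D(u)} DD(d, d'); zero row for empty profiles
    best = np.zeros((nl, nd))
    for u, g in enumerate(groups):
        if len(g):
            best[u] = dd[:, g].max(axis=1)
    # cross[u, v] = sum_{d in D(u)} best[v, d]
    cross = AS.astype(float) @ best.T
    denom = deg[:, None] + deg[None, :]
    nonempty = (deg[:, None] > 0) & (deg[None, :] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        LL = np.where(nonempty, (cross + cross.T) / denom, 0.0)
    np.clip(LL, 0.0, 1.0, out=LL)
    LL = (LL + LL.T) / 2.0  # exact symmetry against float round-off
    return SimilarityMatrix(list(lncrna_ids), LL)
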