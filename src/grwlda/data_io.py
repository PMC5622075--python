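"""Reading and writing of association tables, tree-number records, similarity
matrices and ranked prediction tables.

All formats are plain tab-separated text:

* **Association edge list** — one ``lncRNA<TAB>disease`` pair per line, ``#``
  comments allowed.  Two optional directive comments, ``#@lncrnas`` and
  ``#@diseases``, carry the full identifier order so that a written file
  round-trips exactly (including entities whose association profile is empty).
  Files without directives are read in first-appearance order.
* **Tree-number records** — ``disease<TAB>code[<TAB>code ...]``, codes being
  dot-delimited MeSH-style tree numbers such as ``C04.588.274``.  Repeated
  disease identifiers union their codes.
* **Labeled similarity matrix** — square TSV with a header row and a first
  column of identifiers.
* **Ranked predictions** — ``rank / query / candidate / score`` TSV.
"""

from __future__ import annotations

import difflib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "AssociationDataset",
    "SimilarityMatrix",
    "read_associations",
    "write_associations",
    "read_tree_numbers",
    "write_tree_numbers",
    "read_similarity",
    "write_similarity",
    "ranked_candidates",
    "write_ranked_predictions",
    "write_metrics",
]

_CODE_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class AssociationDataset:
    """Known lncRNA-disease associations as an adjacency matrix.

    ``AS`` has one row per lncRNA and one column per disease; ``AS[i, j] == 1``
    iff lncRNA ``lncrna_ids[i]`` is associated with disease ``disease_ids[j]``.
    """

    lncrna_ids: list[str]
    disease_ids: list[str]
    AS: np.ndarray

    def __post_init__(self) -> None:
        self.lncrna_ids = list(self.lncrna_ids)
        self.disease_ids = list(self.disease_ids)
        self.AS = np.asarray(self.AS, dtype=np.int8)
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if self.AS.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValueError(
                f"AS shape {self.AS.shape} does not match "
                f"({len(self.lncrna_ids)}, {len(self.disease_ids)}) identifiers"
            )
        if not np.isin(self.AS, (0, 1)).all():
            raise ValueError("AS entries must be 0 or 1")

    @property
    def nl(self) -> int:
        return len(self.lncrna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.AS.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """Known (lncRNA, disease) pairs in row-major matrix order."""
        return [
            (self.lncrna_ids[i], self.disease_ids[j])
            for i, j in zip(*np.nonzero(self.AS))
        ]

    def lncrna_index(self, lncrna: str) -> int:
        return self.lncrna_ids.index(lncrna)

    def disease_index(self, disease: str) -> int:
        return self.disease_ids.index(disease)

    def copy_with(self, AS: np.ndarray) -> "AssociationDataset":
        return AssociationDataset(self.lncrna_ids, self.disease_ids, AS)


@dataclass
class SimilarityMatrix:
    """Square labeled similarity matrix with scores in [0, 1].

    The diagonal is 1 for any entity with a nonempty profile; an entity whose
    profile is empty (no DAG terms / no associated diseases) carries an
    all-zero row and column, including its own diagonal.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate identifiers")
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity scores must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy restricted/reordered to ``ids`` (all must be present)."""
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# association edge lists
# ---------------------------------------------------------------------------

def read_associations(path: str | Path) -> AssociationDataset:
    """Read an edge-list TSV of lncRNA-disease pairs.

    Identifier order is first-appearance order unless ``#@lncrnas`` /
    ``#@diseases`` directives fix it.  Duplicate pairs are collapsed.
    """
    path = Path(path)
    lnc_order: dict[str, None] = {}
    dis_order: dict[str, None] = {}
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#@lncrnas"):
            for name in line.split("\t")[1:]:
                lnc_order.setdefault(name, None)
            continue
        if line.startswith("#@diseases"):
            for name in line.split("\t")[1:]:
                dis_order.setdefault(name, None)
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"{path}:{lineno}: expected at least 2 tab-separated fields "
                f"(lncRNA, disease), got {line!r}"
            )
        lnc, dis = fields[0].strip(), fields[1].strip()
        lnc_order.setdefault(lnc, None)
        dis_order.setdefault(dis, None)
        pairs.append((lnc, dis))
    if not pairs and not (lnc_order and dis_order):
        raise ParseError(f"{path}: no associations found")
    lncrna_ids = list(lnc_order)
    disease_ids = list(dis_order)
    AS = np.zeros((len(lncrna_ids), len(disease_ids)), dtype=np.int8)
    li = {name: i for i, name in enumerate(lncrna_ids)}
    di = {name: j for j, name in enumerate(disease_ids)}
    for lnc, dis in pairs:
        AS[li[lnc], di[dis]] = 1
    return AssociationDataset(lncrna_ids, disease_ids, AS)


def write_associations(dataset: AssociationDataset, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "# lncRNA-disease association edge list",
        "#@lncrnas\t" + "\t".join(dataset.lncrna_ids),
        "#@diseases\t" + "\t".join(dataset.disease_ids),
    ]
    lines += [f"{l}\t{d}" for l, d in dataset.pairs()]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tree-number records
# ---------------------------------------------------------------------------

def read_tree_numbers(path: str | Path) -> dict[str, set[str]]:
    """Read ``disease -> tree codes`` records; repeated diseases union codes."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    seen_any = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"{path}:{lineno}: disease record needs at least one tree code"
            )
        disease = fields[0].strip()
        codes = [c.strip() for c in fields[1:]]
        if not disease or any(not c for c in codes):
            raise ParseError(f"{path}:{lineno}: empty disease id or tree code")
        for code in codes:
            if not _CODE_RE.match(code):
                raise ParseError(
                    f"{path}:{lineno}: malformed tree code {code!r} "
                    "(expected dot-delimited alphanumeric segments)"
                )
        out.setdefault(disease, set()).update(codes)
        seen_any = True
    if not seen_any:
        raise ParseError(f"{path}: no tree-number records found")
    return out


def write_tree_numbers(tree_numbers: Mapping[str, Iterable[str]],
                       path: str | Path) -> None:
    path = Path(path)
    lines = ["# disease tree numbers"]
    for disease, codes in tree_numbers.items():
        lines.append(disease + "\t" + "\t".join(sorted(codes)))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# labeled similarity / score matrices
# ---------------------------------------------------------------------------

def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if list(map(str, df.columns)) != ids:
        raise ParseError(f"{path}: row and column labels differ")
    return SimilarityMatrix(ids, df.to_numpy(dtype=float))


def write_similarity(matrix: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def write_scores(scores: np.ndarray, dataset: AssociationDataset,
                 path: str | Path) -> None:
    """Write an lncRNA x disease score matrix as labeled TSV."""
    pd.DataFrame(
        scores, index=dataset.lncrna_ids, columns=dataset.disease_ids
    ).to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# ranked predictions
# ---------------------------------------------------------------------------

def _resolve_query(dataset: AssociationDataset, query: str) -> tuple[str, int]:
    if query in dataset.disease_ids:
        return "disease", dataset.disease_index(query)
    if query in dataset.lncrna_ids:
        return "lncrna", dataset.lncrna_index(query)
    near = difflib.get_close_matches(
        query, dataset.disease_ids + dataset.lncrna_ids, n=5, cutoff=0.4
    )
    hint = f"; closest matches: {', '.join(near)}" if near else ""
    raise KeyError(f"unknown query identifier {query!r}{hint}")


def ranked_candidates(scores: np.ndarray, dataset: AssociationDataset,
                      query: str) -> list[tuple[str, float]]:
    """Candidate partners of ``query`` not already associated, ordered by
    descending score then ascending identifier (deterministic tie-break)."""
    axis, idx = _resolve_query(dataset, query)
    if axis == "disease":
        mask = dataset.AS[:, idx] == 0
        names = [n for n, m in zip(dataset.lncrna_ids, mask) if m]
        vals = scores[mask, idx]
    else:
        mask = dataset.AS[idx, :] == 0
        names = [n for n, m in zip(dataset.disease_ids, mask) if m]
        vals = scores[idx, mask]
    order = sorted(range(len(names)), key=lambda k: (-vals[k], names[k]))
    return [(names[k], float(vals[k])) for k in order]


def write_ranked_predictions(scores: np.ndarray, dataset: AssociationDataset,
                             query: str, top_k: int,
                             path: str | Path | None = None) -> pd.DataFrame:
    """Rank unknown partners of ``query`` by score; known pairs are excluded."""
    ranked = ranked_candidates(scores, dataset, query)[:top_k]
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "query": query,
            "candidate": [n for n, _ in ranked],
            "score": [s for _, s in ranked],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df


def write_metrics(metrics: Mapping, path: str | Path) -> None:
    """Write a JSON metrics report (AUC/AUPR, params, seed, mode...)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(metrics, indent=2, default=_default) + "\n")
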