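"""Cross-validation protocols, ROC/PR metrics and case-study ranking.

Three leave-one-out masking modes mirror the prediction settings:

* ``overall`` — each known association is zeroed in turn (one cell);
* ``novel_lncrna`` — the held-out lncRNA's whole association row is zeroed,
  so it carries no known disease at prediction time;
* ``isolated_disease`` — the held-out disease's whole association column is
  zeroed, so it carries no known lncRNA at prediction time.

In every fold the lncRNA functional similarity LL is recomputed from the
masked association matrix (functional similarity is derived from the
associations, so reusing the unmasked LL would leak the held-out evidence);
``static_ll=True`` restores the naive variant.  Held-out associations supply
the positive scores; the negatives are all never-known pairs scored once
under the full unmasked model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .data_io import AssociationDataset, SimilarityMatrix, ranked_candidates
from .propagation import GrwParams, grwlda_scores
from .similarity import DiseaseDAG, all_disease_similarities, lncrna_similarity

__all__ = [
    "CvResult",
    "MODES",
    "roc_auc",
    "pr_aupr",
    "loocv",
    "kfold_cv",
    "rank_of_pairs",
]

MODES = ("overall", "novel_lncrna", "isolated_disease")

# scorer(AS_masked, LL, DD, params) -> nl x nd score matrix; the default runs
# the propagation model, tests may inject stubs
Scorer = Callable[[np.ndarray, SimilarityMatrix, SimilarityMatrix, GrwParams],
                  np.ndarray]


def _default_scorer(AS, LL, DD, params) -> np.ndarray:
    return grwlda_scores(AS, LL, DD, params).FS


@dataclass
class CvResult:
    """Pooled cross-validation scores, curves and areas."""

    mode: str
    positive_scores: list  # [((lncrna, disease), score), ...]
    negative_scores: list
    roc_points: np.ndarray  # (n, 2) of (FPR, TPR)
    pr_points: np.ndarray   # (n, 2) of (recall, precision)
    auc: float
    aupr: float
    per_rep_auc: list | None = None

    def to_metrics(self, params: GrwParams | None = None,
                   seed: int | None = None) -> dict:
        out = {
            "mode": self.mode,
            "auc": self.auc,
            "aupr": self.aupr,
            "n_positives": len(self.positive_scores),
            "n_negatives": len(self.negative_scores),
        }
        if self.per_rep_auc is not None:
            out["per_rep_auc"] = list(self.per_rep_auc)
        if params is not None:
            out["params"] = {
                "gamma": params.gamma, "alpha": params.alpha,
                "beta": params.beta, "eta": params.eta, "tol": params.tol,
                "max_iter": params.max_iter,
                "laplacian_form": params.laplacian_form,
                "engine": params.engine,
            }
        if seed is not None:
            out["seed"] = seed
        return out


# ---------------------------------------------------------------------------
# threshold-sweep metrics
# ---------------------------------------------------------------------------

def roc_auc(positives: Sequence[float],
            negatives: Sequence[float]) -> tuple[np.ndarray, float]:
    """ROC points and area from pooled positive/negative scores.

    Sweeps every distinct score as a threshold; the area (trapezoidal rule)
    equals the Mann-Whitney statistic with 0.5 credit for ties.
    """
    positives, negatives = list(positives), list(negatives)
    if not positives or not negatives:
        raise ValueError("ROC needs at least one positive and one negative")
    y = np.r_[np.ones(len(positives)), np.zeros(len(negatives))]
    s = np.r_[positives, negatives]
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(np.trapezoid(tpr, fpr))


def pr_aupr(positives: Sequence[float],
            negatives: Sequence[float]) -> tuple[np.ndarray, float]:
    """Precision-recall points and area (step-wise rule, no interpolation)."""
    positives, negatives = list(positives), list(negatives)
    if not positives:
        raise ValueError("PR curve needs at least one positive")
    if not negatives:
        # precision is identically 1 at every threshold
        return np.array([[0.0, 1.0], [1.0, 1.0]]), 1.0
    y = np.r_[np.ones(len(positives)), np.zeros(len(negatives))]
    s = np.r_[positives, negatives]
    precision, recall, _ = precision_recall_curve(y, s)
    pts = np.column_stack([recall, precision])[::-1]  # increasing recall
    return pts, float(average_precision_score(y, s))


def _result(mode: str, positives: list, negatives: list,
            per_rep_auc: list | None = None) -> CvResult:
    pos = [s for _, s in positives]
    neg = [s for _, s in negatives]
    roc_points, auc = roc_auc(pos, neg)
    pr_points, aupr = pr_aupr(pos, neg)
    return CvResult(
        mode=mode, positive_scores=positives, negative_scores=negatives,
        roc_points=roc_points, pr_points=pr_points, auc=auc, aupr=aupr,
        per_rep_auc=per_rep_auc,
    )


# ---------------------------------------------------------------------------
# cross-validation drivers
# ---------------------------------------------------------------------------

def _disease_matrix(dataset: AssociationDataset,
                    dags: Mapping[str, DiseaseDAG] | Sequence[DiseaseDAG] | None,
                    dd: SimilarityMatrix | None) -> SimilarityMatrix:
    if dd is not None:
        return dd.reindex(dataset.disease_ids) if dd.ids != dataset.disease_ids else dd
    if dags is None:
        raise ValueError("either disease DAGs or a precomputed DD is required")
    if isinstance(dags, Mapping):
        ordered = [dags[d] for d in dataset.disease_ids]
    else:
        by_id = {d.disease_id: d for d in dags}
        ordered = [by_id[d] for d in dataset.disease_ids]
    return all_disease_similarities(ordered)


def _fold_scores(AS_masked: np.ndarray, dataset: AssociationDataset,
                 DD: SimilarityMatrix, LL_full: SimilarityMatrix,
                 params: GrwParams, static_ll: bool,
                 scorer: Scorer) -> np.ndarray:
    LL = LL_full if static_ll else lncrna_similarity(
        AS_masked, DD, dataset.lncrna_ids)
    return scorer(AS_masked, LL, DD, params)


def loocv(dataset: AssociationDataset,
          dags: Mapping[str, DiseaseDAG] | Sequence[DiseaseDAG] | None = None,
          params: GrwParams | None = None,
          mode: str = "overall",
          *,
          dd: SimilarityMatrix | None = None,
          static_ll: bool = False,
          scorer: Scorer | None = None) -> CvResult:
    """Leave-one-out cross validation in one of the three masking modes.

    Every known association is held out in turn: its evidence is masked per
    ``mode`` (single cell, the lncRNA's whole row, or the disease's whole
    column), LL is recomputed from the masked matrix, the model is rerun and
    the held-out pair's score is recorded as a positive.

    In ``overall`` mode the negatives (all never-known pairs) are scored once
    under the full model, which differs from any single-cell-masked model only
    in that one cell.  In the row/column modes both the knowns and the
    unknowns of the masked entity are scored from the same masked run — the
    run that would rank candidates for that entity were it genuinely novel or
    isolated — so positives and negatives face identical evidence.
    """
    if mode not in MODES:
        raise ValueError(f"unknown LOOCV mode {mode!r}; expected one of {MODES}")
    if params is None:
        params = GrwParams()
    if scorer is None:
        scorer = _default_scorer
    if dataset.n_associations < 2:
        raise ValueError("LOOCV needs at least 2 known associations")

    DD = _disease_matrix(dataset, dags, dd)
    AS = dataset.AS.astype(float)
    LL_full = lncrna_similarity(AS, DD, dataset.lncrna_ids)

    known = list(zip(*np.nonzero(dataset.AS)))
    positives: list[tuple[tuple[str, str], float]] = []
    negatives: list[tuple[tuple[str, str], float]] = []

    def run(AS_masked: np.ndarray) -> np.ndarray:
        return _fold_scores(AS_masked, dataset, DD, LL_full, params,
                            static_ll, scorer)

    def pair(i: int, j: int) -> tuple[str, str]:
        return dataset.lncrna_ids[i], dataset.disease_ids[j]

    if mode == "overall":
        # negatives once under the full model; each positive from its own
        # single-cell-masked run
        FS_full = scorer(AS, LL_full, DD, params)
        negatives += [
            (pair(i, j), float(FS_full[i, j]))
            for i, j in zip(*np.nonzero(dataset.AS == 0))
        ]
        for i, j in known:
            AS_m = AS.copy()
            AS_m[i, j] = 0.0
            FS = run(AS_m)
            positives.append((pair(i, j), float(FS[i, j])))
    elif mode == "novel_lncrna":
        # one run per lncRNA with its whole row masked; that run scores the
        # row's knowns (positives) and unknowns (negatives) alike, exactly as
        # candidates of a truly novel lncRNA would be ranked
        for i in range(dataset.nl):
            AS_m = AS.copy()
            AS_m[i, :] = 0.0
            FS = run(AS_m)
            for j in range(dataset.nd):
                bucket = positives if dataset.AS[i, j] else negatives
                bucket.append((pair(i, j), float(FS[i, j])))
    else:  # isolated_disease: one run per disease with its column masked
        for j in range(dataset.nd):
            AS_m = AS.copy()
            AS_m[:, j] = 0.0
            FS = run(AS_m)
            for i in range(dataset.nl):
                bucket = positives if dataset.AS[i, j] else negatives
                bucket.append((pair(i, j), float(FS[i, j])))

    return _result(mode, positives, negatives)


def kfold_cv(dataset: AssociationDataset,
             dags: Mapping[str, DiseaseDAG] | Sequence[DiseaseDAG] | None = None,
             params: GrwParams | None = None,
             k: int = 5,
             reps: int = 10,
             seed: int | None = None,
             *,
             dd: SimilarityMatrix | None = None,
             static_ll: bool = False,
             scorer: Scorer | None = None) -> CvResult:
    """Repeated k-fold cross validation at the association (cell) level.

    Per repetition the known associations are randomly partitioned into k
    folds; each fold's cells are zeroed jointly, the model rerun, and the
    fold's scores recorded as positives.  Pooling the repetition's folds
    against the full-model negatives gives one AUC per repetition; ``auc`` is
    their mean.  ``seed`` is mandatory: the partition must be reproducible.
    """
    if seed is None:
        raise ValueError("kfold_cv requires an explicit seed")
    if k < 2:
        raise ValueError("k must be at least 2")
    if params is None:
        params = GrwParams()
    if scorer is None:
        scorer = _default_scorer
    n_assoc = dataset.n_associations
    if n_assoc < k:
        raise ValueError(f"need at least k={k} associations, have {n_assoc}")

    DD = _disease_matrix(dataset, dags, dd)
    AS = dataset.AS.astype(float)
    LL_full = lncrna_similarity(AS, DD, dataset.lncrna_ids)
    FS_full = scorer(AS, LL_full, DD, params)
    negatives = [
        ((dataset.lncrna_ids[i], dataset.disease_ids[j]), float(FS_full[i, j]))
        for i, j in zip(*np.nonzero(dataset.AS == 0))
    ]
    neg_vals = [s for _, s in negatives]

    known = np.array(list(zip(*np.nonzero(dataset.AS))))
    rng = np.random.default_rng(seed)
    per_rep_auc: list[float] = []
    positives: list[tuple[tuple[str, str], float]] = []

    for _ in range(reps):
        order = rng.permutation(n_assoc)
        folds = np.array_split(order, k)
        rep_pos: list[tuple[tuple[str, str], float]] = []
        for fold in folds:
            AS_m = AS.copy()
            cells = known[fold]
            AS_m[cells[:, 0], cells[:, 1]] = 0.0
            FS = _fold_scores(AS_m, dataset, DD, LL_full, params,
                              static_ll, scorer)
            for i, j in cells:
                rep_pos.append(
                    ((dataset.lncrna_ids[i], dataset.disease_ids[j]),
                     float(FS[i, j])))
        _, rep_auc = roc_auc([s for _, s in rep_pos], neg_vals)
        per_rep_auc.append(rep_auc)
        positives.extend(rep_pos)

    result = _result("kfold", positives, negatives, per_rep_auc=per_rep_auc)
    result.auc = float(np.mean(per_rep_auc))
    return result


# ---------------------------------------------------------------------------
# case-study ranking
# ---------------------------------------------------------------------------

def rank_of_pairs(FS: np.ndarray, dataset: AssociationDataset,
                  pairs: Sequence[tuple[str, str]]) -> tuple[list[int], float]:
    """Rank of each unknown (lncRNA, disease) pair among all unknown pairs of
    the same disease (1 = best score), plus the mean rank.

    Ties are broken by ascending lncRNA identifier, matching the ranked
    prediction tables.  A pair already known under the training matrix is an
    error: its rank among candidates is undefined.
    """
    ranks: list[int] = []
    for lnc, dis in pairs:
        i, j = dataset.lncrna_index(lnc), dataset.disease_index(dis)
        if dataset.AS[i, j]:
            raise ValueError(f"pair ({lnc}, {dis}) is a known association")
        candidates = ranked_candidates(FS, dataset, dis)
        ranks.append(1 + [n for n, _ in candidates].index(lnc))
    return ranks, float(np.mean(ranks))
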