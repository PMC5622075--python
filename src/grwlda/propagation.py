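"""The GrwLDA propagation core.

Scores every lncRNA-disease pair by two restart random walks on a
heterogeneous network built from the lncRNA functional similarity matrix LL,
the disease semantic similarity matrix DD and the binary association matrix
AS:

1. column-normalize LL, DD, AS and AS^T into transfer matrices WL, WD, WA1,
   WA2 (zero columns stay zero);
2. for every disease j, smooth its indicator over the disease network into a
   Laplacian relevance vector, project it through WA1 together with disease
   j's own seed column, normalize, and run a restart walk on the lncRNA
   network to a steady state — its i-th entry is s1(i, j);
3. symmetrically, for every lncRNA i a walk on the disease network yields
   s2(i, j);
4. blend: FS = eta * S1 + (1 - eta) * S2.

Because every disease's seed construction is linear, the per-entity walks are
run as one matrix iteration over all columns at once; this is numerically
identical to the per-vector walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data_io import AssociationDataset, SimilarityMatrix

__all__ = [
    "GrwParams",
    "ScorePair",
    "ConvergenceError",
    "column_normalize",
    "laplacian_score",
    "initial_vector",
    "rwr",
    "rwr_solve",
    "grwlda_scores",
]


class ConvergenceError(RuntimeError):
    """Random walk failed to reach its steady state within max_iter."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class GrwParams:
    """Parameters of the propagation model.

    gamma : restart probability of both walks, in (0, 1).
    alpha : disease-side Laplacian balance, in (0, 1).
    beta  : lncRNA-side Laplacian balance, in (0, 1).
    eta   : blend weight of the lncRNA-side walk in the final score, in [0, 1].
    tol   : L1 convergence threshold between successive probability vectors.
    max_iter : iteration cap for the walks.
    laplacian_form : "inverse" (default) smooths the indicator with
        (1-balance)(I - balance W)^-1, the standard graph-regularization
        score; "literal" evaluates the plain product (1-balance)(I - balance W)
        instead, kept for fidelity experiments.
    engine : "iterative" runs the walk to its fixed point; "solve" evaluates
        the closed form gamma (I - (1-gamma) W)^-1 p0 directly.
    """

    gamma: float = 0.9
    alpha: float = 0.1
    beta: float = 0.1
    eta: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000
    laplacian_form: str = "inverse"
    engine: str = "iterative"

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.laplacian_form not in ("inverse", "literal"):
            raise ValueError(f"unknown laplacian_form {self.laplacian_form!r}")
        if self.engine not in ("iterative", "solve"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass(frozen=True)
class ScorePair:
    """Scores of the two walks and their blend, all nl x nd."""

    S1: np.ndarray
    S2: np.ndarray
    FS: np.ndarray


def _as_array(M) -> np.ndarray:
    if isinstance(M, SimilarityMatrix):
        return M.values
    return np.asarray(M, dtype=float)


def column_normalize(M) -> np.ndarray:
    """Normalize each column of a nonnegative matrix to sum 1; all-zero
    columns are left all-zero."""
    M = np.array(_as_array(M), dtype=float)
    if M.min(initial=0.0) < 0:
        raise ValueError("column_normalize requires nonnegative entries")
    sums = M.sum(axis=0)
    nz = sums > 0
    M[:, nz] /= sums[nz]
    return M


def _normalize_columns_signed(M: np.ndarray) -> np.ndarray:
    """Column normalization without the nonnegativity guard (literal
    Laplacian form only, whose seed columns may carry negative entries)."""
    M = np.array(M, dtype=float)
    sums = M.sum(axis=0)
    nz = sums != 0
    M[:, nz] /= sums[nz]
    M[:, ~nz] = 0.0
    return M


def _laplacian_all(W: np.ndarray, balance: float, form: str) -> np.ndarray:
    """Laplacian relevance vectors of every entity, as matrix columns."""
    n = W.shape[0]
    A = np.eye(n) - balance * W
    if form == "inverse":
        return (1.0 - balance) * scipy.linalg.solve(A, np.eye(n))
    if form == "literal":
        return (1.0 - balance) * A
    raise ValueError(f"unknown laplacian_form {form!r}")


def laplacian_score(W, index: int, balance: float,
                    form: str = "inverse") -> np.ndarray:
    """Relevance of all entities to the entity at ``index`` after smoothing
    its indicator over the similarity network ``W``.

    ``form="inverse"`` returns (1-balance)(I - balance W)^-1 e_index, which is
    nonnegative for column-stochastic W and balance < 1; ``form="literal"``
    returns the plain product (1-balance)(I - balance W) e_index.
    """
    W = _as_array(W)
    if W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not 0.0 < balance < 1.0:
        raise ValueError(f"balance must be in (0, 1), got {balance}")
    e = np.zeros(W.shape[0])
    e[index] = 1.0
    A = np.eye(W.shape[0]) - balance * W
    if form == "inverse":
        return (1.0 - balance) * scipy.linalg.solve(A, e)
    if form == "literal":
        return (1.0 - balance) * (A @ e)
    raise ValueError(f"unknown laplacian_form {form!r}")


def initial_vector(WA: np.ndarray, lap: np.ndarray, index: int) -> np.ndarray:
    """Seed distribution of one walk: WA @ lap + WA[:, index], normalized to
    sum 1 (an all-zero result stays all-zero: an entity with no associations
    and no similar neighbors simply seeds nothing)."""
    WA = _as_array(WA)
    v = WA @ np.asarray(lap, dtype=float) + WA[:, index]
    s = v.sum()
    return v / s if s > 0 else np.zeros_like(v)


def rwr(W, p0: np.ndarray, gamma: float, tol: float = 1e-6,
        max_iter: int = 1000) -> np.ndarray:
    """Random walk with restart to the steady state.

    Iterates p <- (1-gamma) W p + gamma p0 until the L1 change between
    successive vectors is at most ``tol``.  An all-zero seed returns an
    all-zero steady state.
    """
    W = _as_array(W)
    p0 = np.asarray(p0, dtype=float)
    p = p0.copy()
    residual = np.inf
    for _ in range(max_iter):
        p_next = (1.0 - gamma) * (W @ p) + gamma * p0
        residual = float(np.abs(p_next - p).sum())
        if residual <= tol:
            return p_next
        p = p_next
    raise ConvergenceError(
        f"walk did not converge in {max_iter} iterations "
        f"(last L1 residual {residual:.3e})",
        residual,
    )


def rwr_solve(W, p0: np.ndarray, gamma: float) -> np.ndarray:
    """Closed-form steady state gamma (I - (1-gamma) W)^-1 p0 of the walk."""
    W = _as_array(W)
    p0 = np.asarray(p0, dtype=float)
    n = W.shape[0]
    rhs = gamma * p0
    return scipy.linalg.solve(np.eye(n) - (1.0 - gamma) * W, rhs)


def _rwr_matrix(W: np.ndarray, P0: np.ndarray, params: GrwParams) -> np.ndarray:
    """All-columns-at-once walk; stops when every column's L1 change is
    within tol.  Identical fixed point as per-column :func:`rwr`."""
    if params.engine == "solve":
        n = W.shape[0]
        return scipy.linalg.solve(
            np.eye(n) - (1.0 - params.gamma) * W, params.gamma * P0
        )
    P = P0.copy()
    residual = np.inf
    for _ in range(params.max_iter):
        P_next = (1.0 - params.gamma) * (W @ P) + params.gamma * P0
        residual = float(np.abs(P_next - P).sum(axis=0).max())
        if residual <= params.tol:
            return P_next
        P = P_next
    raise ConvergenceError(
        f"walk did not converge in {params.max_iter} iterations "
        f"(worst column L1 residual {residual:.3e})",
        residual,
    )


def grwlda_scores(dataset: AssociationDataset | np.ndarray,
                  LL, DD, params: GrwParams | None = None) -> ScorePair:
    """Score every lncRNA-disease pair with the dual restart walks.

    Returns a :class:`ScorePair` with the lncRNA-side walk scores S1 (columns
    are steady distributions over lncRNAs, one per disease), the disease-side
    walk scores S2, and the blend FS = eta S1 + (1-eta) S2, all indexed like
    the association matrix (rows lncRNAs, columns diseases).
    """
    if params is None:
        params = GrwParams()
    AS = dataset.AS if isinstance(dataset, AssociationDataset) else dataset
    AS = np.asarray(AS, dtype=float)
    LLv, DDv = _as_array(LL), _as_array(DD)
    nl, nd = AS.shape
    if LLv.shape != (nl, nl) or DDv.shape != (nd, nd):
        raise ValueError("LL/DD dimensions inconsistent with AS")

    WL = column_normalize(LLv)
    WD = column_normalize(DDv)
    WA1 = column_normalize(AS)
    WA2 = column_normalize(AS.T)

    norm = (column_normalize if params.laplacian_form == "inverse"
            else _normalize_columns_signed)

    # lncRNA-side walk: one seed column per disease
    LPD = _laplacian_all(WD, params.alpha, params.laplacian_form)
    PL0 = norm(WA1 @ LPD + WA1)
    S1 = _rwr_matrix(WL, PL0, params)

    # disease-side walk: one seed column per lncRNA
    LPL = _laplacian_all(WL, params.beta, params.laplacian_form)
    PD0 = norm(WA2 @ LPL + WA2)
    S2 = _rwr_matrix(WD, PD0, params).T

    FS = params.eta * S1 + (1.0 - params.eta) * S2
    return ScorePair(S1=S1, S2=S2, FS=FS)
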