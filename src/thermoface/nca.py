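"""Feature weighting and selection by Neighborhood Component Analysis.

A diagonal, regularized NCA: sample x_i picks neighbour x_j softly with

    p_ij = exp(-d(x_i, x_j) / sigma) / sum_{k != i} exp(-d(x_i, x_k) / sigma)

using the weighted absolute-difference distance

    d(x_i, x_j) = sum_l  w_l^2 |x_il - x_jl|,

and the fitted weights maximise the expected leave-one-out accuracy
penalised by an L2 term:

    xi(w) = sum_i p_i - lambda * sum_l w_l^2,      p_i = sum_j y_ij p_ij,

where y_ij = 1 when x_i and x_j share a class label.  The analytic
gradient is

    d xi / d w_l = 2 w_l [ (1/sigma) sum_i ( p_i sum_j p_ij |x_il-x_jl|
                                            - sum_j y_ij p_ij |x_il-x_jl| )
                           - lambda ].

Fitting is deterministic gradient ascent from w = 1 with backtracking
step halving.  Because the objective depends on w only through w^2, the
weight vector is folded to |w| after each step, keeping weights
nonnegative without altering the objective.  Features are expected to
be standardized beforehand (sigma defaults to 1 on that scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .roi import ROI_NAMES
from .features import FEATURE_IDS

_CHUNK = 32  # feature-chunk size for the (N, N, d) |diff| tensor


@dataclass
class NCAWeights:
    """Fitted per-feature NCA weights plus fit metadata."""

    w: np.ndarray
    sigma: float
    lam: float
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def objective(self) -> float:
        return self.objective_trace[-1] if self.objective_trace else np.nan


def _check_inputs(X: np.ndarray, w: np.ndarray, sigma: float) -> tuple:
    X = np.asarray(X, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"need a (N>=2, d) sample matrix, got shape {X.shape}")
    if w.shape != (X.shape[1],):
        raise ValueError(f"weight length {w.shape} != feature count {X.shape[1]}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return X, w


def _weighted_distances(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """D_ij = sum_l w_l^2 |x_il - x_jl|, computed in feature chunks."""
    n, d = X.shape
    w2 = w * w
    D = np.zeros((n, n))
    for c in range(0, d, _CHUNK):
        block = np.abs(X[:, None, c:c + _CHUNK] - X[None, :, c:c + _CHUNK])
        D += block @ w2[c:c + _CHUNK]
    return D


def nca_probabilities(X: np.ndarray, w: np.ndarray, sigma: float,
                      y: np.ndarray | None = None):
    """Soft neighbour probabilities p_ij (rows sum to 1, p_ii = 0).

    If labels ``y`` are given, also returns p_i, the probability that
    each sample is correctly classified by its soft neighbour.
    """
    X, w = _check_inputs(X, w, sigma)
    D = _weighted_distances(X, w)
    S = -D / sigma
    np.fill_diagonal(S, -np.inf)
    S -= S.max(axis=1, keepdims=True)  # shift for numerical stability
    P = np.exp(S)
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    if y is None:
        return P
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("label vector length does not match sample count")
    Y = (y[:, None] == y[None, :])
    return P, (P * Y).sum(axis=1)


def nca_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                  sigma: float = 1.0, lam: float = 0.0) -> float:
    """Regularized objective xi(w) = sum_i p_i - lambda * sum_l w_l^2."""
    _, p = nca_probabilities(X, w, sigma, y)
    w = np.asarray(w, dtype=np.float64)
    return float(p.sum() - lam * (w * w).sum())


def nca_gradient(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                 sigma: float = 1.0, lam: float = 0.0) -> np.ndarray:
    """Analytic gradient of :func:`nca_objective` with respect to w."""
    X, w = _check_inputs(X, w, sigma)
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("label vector length does not match sample count")
    P, p = nca_probabilities(X, w, sigma, y)
    Y = (y[:, None] == y[None, :]).astype(np.float64)
    PY = P * Y
    pP = p[:, None] * P  # p_i * p_ij
    n, d = X.shape
    grad = np.empty(d)
    for c in range(0, d, _CHUNK):
        A = np.abs(X[:, None, c:c + _CHUNK] - X[None, :, c:c + _CHUNK])
        term1 = np.einsum("ij,ijl->l", pP, A)
        term2 = np.einsum("ij,ijl->l", PY, A)
        grad[c:c + _CHUNK] = (term1 - term2) / sigma
    return 2.0 * w * (grad - lam)


class _NCAEvaluator:
    """Objective/gradient evaluator caching the (N, N, d) |diff| tensor.

    Caching is worthwhile for the iterative fit; the public
    :func:`nca_objective` / :func:`nca_gradient` rebuild it per call and
    serve as the memory-light reference path.
    """

    _BUDGET_BYTES = 400 * 2**20

    def __init__(self, X: np.ndarray, y: np.ndarray, sigma: float,
                 lam: float) -> None:
        self.X, self.y, self.sigma, self.lam = X, y, sigma, lam
        self.Y = (y[:, None] == y[None, :]).astype(np.float64)
        n, d = X.shape
        self.A = (np.abs(X[:, None, :] - X[None, :, :])
                  if n * n * d * 8 <= self._BUDGET_BYTES else None)

    def _probs(self, w: np.ndarray):
        if self.A is not None:
            D = self.A @ (w * w)
        else:
            D = _weighted_distances(self.X, w)
        S = -D / self.sigma
        np.fill_diagonal(S, -np.inf)
        S -= S.max(axis=1, keepdims=True)
        P = np.exp(S)
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        return P, (P * self.Y).sum(axis=1)

    def objective(self, w: np.ndarray) -> float:
        _, p = self._probs(w)
        return float(p.sum() - self.lam * (w * w).sum())

    def gradient(self, w: np.ndarray) -> np.ndarray:
        if self.A is None:
            return nca_gradient(self.X, self.y, w, self.sigma, self.lam)
        P, p = self._probs(w)
        PY = P * self.Y
        pP = p[:, None] * P
        term1 = np.einsum("ij,ijl->l", pP, self.A)
        term2 = np.einsum("ij,ijl->l", PY, self.A)
        return 2.0 * w * ((term1 - term2) / self.sigma - self.lam)


def fit_nca(X: np.ndarray, y: np.ndarray, sigma: float = 1.0,
            lam: float | None = None, step: float = 1.0,
            max_iter: int = 100, tol: float = 1e-6,
            max_backtracks: int = 30) -> NCAWeights:
    """Fit diagonal NCA weights by backtracking gradient ascent.

    ``lam=None`` defaults to 1/N.  The fit starts from the
    uninformative w = 1 vector and is fully deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to fit NCA")
    n, d = X.shape
    lam = 1.0 / n if lam is None else float(lam)
    ev = _NCAEvaluator(X, y, float(sigma) if sigma > 0 else sigma, lam)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    w = np.ones(d)
    obj = ev.objective(w)
    if not np.isfinite(obj):
        raise FloatingPointError(f"non-finite NCA objective at start: {obj}")
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = ev.gradient(w)
        s = step
        accepted = False
        for _ in range(max_backtracks):
            w_new = np.abs(w + s * g)
            obj_new = ev.objective(w_new)
            if np.isfinite(obj_new) and obj_new >= obj:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            converged = True
            break
        delta = obj_new - obj
        w, obj = w_new, obj_new
        trace.append(obj)
        step = min(s * 1.5, 1e6)
        if delta < tol:
            converged = True
            break
    return NCAWeights(w=w, sigma=float(sigma), lam=lam,
                      objective_trace=trace, n_iter=it, converged=converged)


def select_features(weights: NCAWeights | np.ndarray, tau: float = 0.1,
                    top_n: int | None = None) -> np.ndarray:
    """Indices of selected features.

    Default rule: w_l > tau * max(w).  With ``top_n`` the largest-weight
    top_n features are taken instead.  The selection is never empty: it
    falls back to the argmax feature.
    """
    w = weights.w if isinstance(weights, NCAWeights) else np.asarray(weights)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if top_n is not None:
        order = np.argsort(-w, kind="stable")
        return np.sort(order[:max(1, top_n)])
    sel = np.nonzero(w > tau * w.max())[0]
    if sel.size == 0:
        sel = np.array([int(np.argmax(w))])
    return sel


def tune_lambda(X: np.ndarray, y: np.ndarray, sigma: float = 1.0,
                grid: Sequence[float] | None = None, k: int = 3,
                seed: int = 0, **fit_kw) -> float:
    """Pick lambda by inner k-fold CV, scoring weighted 1-NN accuracy.

    The default grid is {0.25, 0.5, 1, 2, 4}/N.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = X.shape[0]
    if grid is None:
        grid = [g / n for g in (0.25, 0.5, 1.0, 2.0, 4.0)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    best_lam, best_score = grid[0], -np.inf
    for lam in grid:
        score = 0.0
        for f in range(k):
            val = folds[f]
            tr = np.concatenate([folds[g] for g in range(k) if g != f])
            fit = fit_nca(X[tr], y[tr], sigma=sigma, lam=lam, **fit_kw)
            w2 = fit.w * fit.w
            # weighted-|.|-distance 1-NN vote from the training part
            d = np.abs(X[val][:, None, :] - X[tr][None, :, :]) @ w2
            score += float((y[tr][d.argmin(axis=1)] == y[val]).mean())
        if score > best_score:
            best_score, best_lam = score, lam
    return best_lam


def selection_frequency(runs: Sequence[Sequence[int]],
                        names: Sequence[str] | None = None) -> pd.DataFrame:
    """Tally how often each (ROI, feature) index was selected across runs.

    Returns an ROI x feature-id count matrix (rows in canonical ROI
    order); ``names`` defaults to the canonical 154 feature names.
    """
    if len(runs) == 0:
        raise ValueError("need at least one selection run")
    if names is None:
        from .features import feature_names
        names = feature_names()
    counts = np.zeros(len(names), dtype=int)
    for run in runs:
        for i in set(int(j) for j in run):
            counts[i] += 1
    table = pd.DataFrame(0, index=list(ROI_NAMES), columns=list(FEATURE_IDS))
    for name, c in zip(names, counts):
        roi, fid = name.rsplit("_", 1)
        table.loc[roi, fid] += c
    table.attrs["n_runs"] = len(runs)
    return table
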