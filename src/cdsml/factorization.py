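"""Similarity-regularized matrix factorization of the binary response.

The binary response B (m cell lines x n drugs) is decomposed as
B ~ X Y^T with latent dimension K = floor(k' * min(m, n)).  The loss is

    1/2 sum_{(i,j) not in Missing} (B_ij - X_i . Y_j)^2
    + alpha/2 (||X||_F^2 + ||Y||_F^2)
    + beta/2 (sum_{i,j} ||X_i - X_j||^2 SC_ij
              + sum_{i,j} ||Y_i - Y_j||^2 SD_ij)

where SC / SD are the prepared cell-line and drug similarity weight
matrices and Missing is the set of unobserved pairs (empty when the
matrix has been imputed).  X and Y alternate entry-wise (diagonal
Hessian) Newton updates with step halving, which keeps the loss trace
non-increasing.  A second, independently initialized fit decomposes B^T
with the similarity roles swapped, and the two reconstructions are
averaged into the predicted score matrix.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import BinaryResponseMatrix, ScoreMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

_CURV_FLOOR = 1e-8
_MAX_HALVINGS = 20


@dataclass
class Hyperparameters:
    """Learning hyper-parameters.

    alpha and beta are the regularization and similarity-conservation
    coefficients; k_prime fixes the latent dimension through
    K = floor(k' * min(m, n)).  Defaults are the grid-search optimum on
    the GDSC screen (alpha=3.5, beta=4.5, k'=0.7).
    """

    alpha: float = 3.5
    beta: float = 4.5
    k_prime: float = 0.7
    max_iter: int = 500
    tol: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not 0 < self.k_prime <= 1:
            raise ValueError("k_prime must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def latent_dim(self, m: int, n: int) -> int:
        return max(1, math.floor(self.k_prime * min(m, n)))


@dataclass
class Scenario:
    """Which similarity-conservation terms enter the loss, and whether
    unobserved pairs are excluded from the reconstruction error."""

    use_sc: bool = True
    use_sd: bool = True
    missing_aware: bool = False

    @classmethod
    def from_name(cls, name: str, missing_aware: bool = False) -> "Scenario":
        table = {"both": (True, True), "sc": (True, False),
                 "sd": (False, True), "none": (False, False)}
        if name not in table:
            raise ValueError(f"unknown scenario {name!r}; choose from {sorted(table)}")
        sc, sd = table[name]
        return cls(use_sc=sc, use_sd=sd, missing_aware=missing_aware)


@dataclass
class FitResult:
    X: np.ndarray
    Y: np.ndarray
    loss_trace: list[float]
    iterations_run: int
    converged: bool

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]


@dataclass
class LatentFactors:
    """The four factor matrices of the double decomposition."""

    X: np.ndarray
    Y: np.ndarray
    W: np.ndarray
    Z: np.ndarray
    fit_b: FitResult = None  # type: ignore[assignment]
    fit_bt: FitResult = None  # type: ignore[assignment]


def _graph_laplacian(W: np.ndarray) -> np.ndarray:
    """Laplacian of the weight matrix W: diag(W 1) - W.

    For any symmetric W, sum_{i,j} ||X_i - X_j||^2 W_ij = 2 tr(X^T L X).
    """
    return np.diag(W.sum(axis=1)) - W


def _weight_matrix(sim: SimilarityMatrix | np.ndarray | None) -> np.ndarray | None:
    if sim is None:
        return None
    return sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)


def loss(B: np.ndarray, mask_observed: np.ndarray, X: np.ndarray, Y: np.ndarray,
         SC: np.ndarray | None, SD: np.ndarray | None,
         hp: Hyperparameters, scenario: Scenario) -> float:
    """Evaluate the scenario-selected loss at (X, Y)."""
    with np.errstate(over="ignore", invalid="ignore"):
        R = (X @ Y.T - B) * mask_observed
        value = 0.5 * float((R * R).sum())
        value += 0.5 * hp.alpha * (float((X * X).sum()) + float((Y * Y).sum()))
        if scenario.use_sc:
            if SC is None:
                raise ValueError("scenario requires SC but none was given")
            L = _graph_laplacian(SC)
            value += hp.beta * float(np.einsum("ik,ij,jk->", X, L, X))
        if scenario.use_sd:
            if SD is None:
                raise ValueError("scenario requires SD but none was given")
            L = _graph_laplacian(SD)
            value += hp.beta * float(np.einsum("ik,ij,jk->", Y, L, Y))
    # an overflowing candidate is "infinitely bad" for the damping search
    return value if np.isfinite(value) else float("inf")


def gradients(B: np.ndarray, mask_observed: np.ndarray, X: np.ndarray, Y: np.ndarray,
              SC: np.ndarray | None, SD: np.ndarray | None,
              hp: Hyperparameters, scenario: Scenario
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients and entry-wise curvatures for X and Y.

    For the conservation term beta/2 sum ||X_i - X_j||^2 W_ij the
    gradient is 2 beta L X and the curvature of entry (i, k) is
    2 beta L_ii, with L the Laplacian of the weight matrix.
    """
    R = (X @ Y.T - B) * mask_observed
    gX = R @ Y + hp.alpha * X
    gY = R.T @ X + hp.alpha * Y
    hX = mask_observed @ (Y * Y) + hp.alpha
    hY = mask_observed.T @ (X * X) + hp.alpha
    if scenario.use_sc:
        L = _graph_laplacian(SC)
        gX = gX + 2.0 * hp.beta * (L @ X)
        hX = hX + 2.0 * hp.beta * np.diag(L)[:, None]
    if scenario.use_sd:
        L = _graph_laplacian(SD)
        gY = gY + 2.0 * hp.beta * (L @ Y)
        hY = hY + 2.0 * hp.beta * np.diag(L)[:, None]
    return gX, gY, hX, hY


def newton_step(factor: np.ndarray, gradient: np.ndarray, curvature: np.ndarray,
                loss_fn, current_loss: float) -> tuple[np.ndarray, float]:
    """Entry-wise damped Newton update of one factor matrix.

    The raw step is g / max(h, eps); if it raises the loss it is halved
    up to 20 times and the best candidate (including the unchanged
    factor) is kept, so the loss never increases.
    """
    if not np.all(np.isfinite(gradient)):
        raise FloatingPointError("non-finite gradient: optimization diverged")
    step = gradient / np.maximum(curvature, _CURV_FLOOR)
    best, best_loss = factor, current_loss
    scale = 1.0
    for _ in range(_MAX_HALVINGS + 1):
        candidate = factor - scale * step
        candidate_loss = loss_fn(candidate)
        if candidate_loss < best_loss:
            best, best_loss = candidate, candidate_loss
        if candidate_loss <= current_loss:
            break
        scale *= 0.5
    return best, best_loss


def fit_one(B: BinaryResponseMatrix,
            SC: SimilarityMatrix | np.ndarray | None,
            SD: SimilarityMatrix | np.ndarray | None,
            hp: Hyperparameters, scenario: Scenario) -> FitResult:
    """Fit one decomposition B ~ X Y^T by alternating damped Newton updates.

    X and Y start from seeded uniform(0, 1) draws; iteration stops when
    ||X^{t+1} - X^t||_F + ||Y^{t+1} - Y^t||_F < tol or max_iter is hit.
    """
    Bv = np.asarray(B.labels, dtype=float)
    m, n = Bv.shape
    if m == 0 or n == 0:
        raise ValueError("response matrix is empty")
    mask_obs = (~B.missing_mask).astype(float) if scenario.missing_aware \
        else np.ones_like(Bv)
    Bv = Bv * mask_obs  # masked entries contribute nothing either way
    SCw = _weight_matrix(SC) if scenario.use_sc else None
    SDw = _weight_matrix(SD) if scenario.use_sd else None
    if SCw is not None and SCw.shape != (m, m):
        raise ValueError("SC shape does not match the cell-line axis")
    if SDw is not None and SDw.shape != (n, n):
        raise ValueError("SD shape does not match the drug axis")

    K = hp.latent_dim(m, n)
    rng = np.random.default_rng(hp.seed)
    X = rng.uniform(0.0, 1.0, size=(m, K))
    Y = rng.uniform(0.0, 1.0, size=(n, K))

    current = loss(Bv, mask_obs, X, Y, SCw, SDw, hp, scenario)
    trace = [current]
    converged = False
    iterations = 0
    for iterations in range(1, hp.max_iter + 1):
        X_prev, Y_prev = X, Y
        gX, _, hX, _ = gradients(Bv, mask_obs, X, Y, SCw, SDw, hp, scenario)
        X, current = newton_step(
            X, gX, hX,
            lambda Xc: loss(Bv, mask_obs, Xc, Y, SCw, SDw, hp, scenario),
            current,
        )
        _, gY, _, hY = gradients(Bv, mask_obs, X, Y, SCw, SDw, hp, scenario)
        Y, current = newton_step(
            Y, gY, hY,
            lambda Yc: loss(Bv, mask_obs, X, Yc, SCw, SDw, hp, scenario),
            current,
        )
        trace.append(current)
        delta = np.linalg.norm(X - X_prev) + np.linalg.norm(Y - Y_prev)
        if delta < hp.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fit_one: no convergence after {hp.max_iter} iterations "
            f"(last update norm above tol={hp.tol})"
        )
    if len(trace) > 1 and trace[-1] == trace[0]:
        warnings.warn(
            "fit_one: no loss decrease from the initialization; the "
            "objective may be unbounded below (e.g. Laplacian-weighted "
            "conservation at large beta) — consider similarity "
            "weights='standardized' or a smaller beta"
        )
    return FitResult(X, Y, trace, iterations, converged)


def fit_predict(B: BinaryResponseMatrix,
                SC: SimilarityMatrix | np.ndarray | None,
                SD: SimilarityMatrix | np.ndarray | None,
                hp: Hyperparameters, scenario: Scenario,
                return_factors: bool = False):
    """Double decomposition: average the fits of B and B^T.

    The transpose fit swaps the similarity roles (drugs become rows) and
    uses a fresh seeded initialization (seed + 1) so the two fits are
    independent draws.  Returns the averaged score matrix
    B~ = 1/2 (X Y^T + (Z W^T)^T).
    """
    fit_b = fit_one(B, SC, SD, hp, scenario)
    hp_t = Hyperparameters(hp.alpha, hp.beta, hp.k_prime, hp.max_iter,
                           hp.tol, hp.seed + 1)
    # drugs are rows of B^T, so the similarity roles AND the scenario
    # flags swap for the transpose fit
    scenario_t = Scenario(use_sc=scenario.use_sd, use_sd=scenario.use_sc,
                          missing_aware=scenario.missing_aware)
    fit_bt = fit_one(B.transpose(), SD, SC, hp_t, scenario_t)
    scores = 0.5 * (fit_b.X @ fit_b.Y.T + (fit_bt.X @ fit_bt.Y.T).T)
    score_matrix = ScoreMatrix(scores, list(B.row_ids), list(B.col_ids))
    if return_factors:
        factors = LatentFactors(X=fit_b.X, Y=fit_b.Y,
                                W=fit_bt.Y, Z=fit_bt.X,
                                fit_b=fit_b, fit_bt=fit_bt)
        return score_matrix, factors
    return score_matrix


def _pr_points(scores: np.ndarray, labels: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision/recall at every distinct threshold t (predict 1 iff score >= t)."""
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    precision = np.empty(thresholds.size)
    recall = np.empty(thresholds.size)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp_cum = np.cumsum(sorted_labels)
    # last index with score >= t, per threshold
    counts = np.searchsorted(-sorted_scores, -thresholds, side="right")
    for idx, cnt in enumerate(counts):
        tp = tp_cum[cnt - 1]
        precision[idx] = tp / cnt
        recall[idx] = tp / n_pos
    return thresholds, precision, recall


def threshold_scores(scores: ScoreMatrix, labels_known: BinaryResponseMatrix
                     ) -> tuple[BinaryResponseMatrix, float]:
    """Pick the precision-recall elbow threshold and binarize the scores.

    The threshold is the score at the PR-curve point closest (Euclidean)
    to the ideal corner (recall=1, precision=1); pairs score >= threshold
    are labeled sensitive.  Only known (non-missing) pairs inform the
    curve.
    """
    obs = ~labels_known.missing_mask
    s = scores.scores[obs]
    y = labels_known.labels[obs]
    if y.min() == y.max():
        raise ValueError("known labels contain a single class; cannot build a PR curve")
    if np.unique(s).size == 1:
        warnings.warn("all scores identical; every threshold yields the same labeling")
        thr = float(s[0])
    else:
        thresholds, precision, recall = _pr_points(s, y)
        dist2 = (1.0 - precision) ** 2 + (1.0 - recall) ** 2
        thr = float(thresholds[int(np.argmin(dist2))])
    labels = (scores.scores >= thr).astype(float)
    out = BinaryResponseMatrix(labels, list(scores.row_ids), list(scores.col_ids),
                               labels_known.missing_mask.copy())
    return out, thr


def rank_unknown(scores: ScoreMatrix, B: BinaryResponseMatrix,
                 top_n: int = 10) -> list[tuple[str, str, float]]:
    """Rank the unobserved pairs by predicted score, descending.

    Ties break by (cell id, drug id).  Returns at most ``top_n`` triples
    (cell_line, drug, score); an empty list (with a warning) when B has
    no missing pairs.
    """
    rows, cols = np.nonzero(B.missing_mask)
    if rows.size == 0:
        warnings.warn("rank_unknown: no missing pairs to rank")
        return []
    entries = [
        (B.row_ids[i], B.col_ids[j], float(scores.scores[i, j]))
        for i, j in zip(rows, cols)
    ]
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    return entries[:top_n]
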