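"""Stratified pairwise cross-validation, classification metrics and
hyper-parameter grid search.

Folding partitions cell line-drug PAIRS (not cell lines): the sensitive
and resistant pair lists are shuffled independently and dealt
round-robin into folds, so each fold preserves the global class ratio.
Test pairs are masked as missing and the model is fitted missing-aware
on the remaining pairs; the score-to-label threshold is learned on the
training pairs only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import BinaryResponseMatrix, SimilarityMatrix
from .factorization import (
    Hyperparameters,
    Scenario,
    fit_predict,
    threshold_scores,
)


@dataclass
class FoldPlan:
    """Assignment of every observed pair to one of ``n_folds`` folds."""

    assignments: dict[tuple[int, int], int]
    n_folds: int
    seed: int

    def test_pairs(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in self.assignments.items() if f == fold]

    def to_file(self, path) -> None:
        """Export as TSV (row, col, fold) for reproducibility."""
        with open(path, "w") as fh:
            fh.write(f"# n_folds: {self.n_folds}\n# seed: {self.seed}\n")
            fh.write("row\tcol\tfold\n")
            for (i, j), fold in sorted(self.assignments.items()):
                fh.write(f"{i}\t{j}\t{fold}\n")

    @classmethod
    def from_file(cls, path) -> "FoldPlan":
        n_folds, seed = 0, 0
        assignments: dict[tuple[int, int], int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# n_folds:"):
                    n_folds = int(line.split(":")[1])
                elif line.startswith("# seed:"):
                    seed = int(line.split(":")[1])
                elif line and not line.startswith(("#", "row\t")):
                    i, j, fold = (int(x) for x in line.split("\t"))
                    assignments[(i, j)] = fold
        return cls(assignments, n_folds, seed)


def make_folds(B: BinaryResponseMatrix, n_folds: int = 5,
               seed: int = 0) -> FoldPlan:
    """Stratified partition of observed pairs into ``n_folds`` folds.

    Pairs of each class are shuffled (seeded) and dealt round-robin, so
    per-class fold sizes differ by at most one.
    """
    rows, cols = np.nonzero(~B.missing_mask)
    labels = B.labels[rows, cols]
    pos = [(int(i), int(j)) for i, j, y in zip(rows, cols, labels) if y == 1]
    neg = [(int(i), int(j)) for i, j, y in zip(rows, cols, labels) if y == 0]
    if len(pos) < n_folds or len(neg) < n_folds:
        raise ValueError(
            f"each class needs at least {n_folds} pairs "
            f"(sensitive={len(pos)}, resistant={len(neg)})"
        )
    rng = np.random.default_rng(seed)
    assignments: dict[tuple[int, int], int] = {}
    for pairs in (pos, neg):
        order = rng.permutation(len(pairs))
        for rank, idx in enumerate(order):
            assignments[pairs[idx]] = rank % n_folds + 1
    return FoldPlan(assignments, n_folds, seed)


def confusion_metrics(pred, truth) -> dict[str, float]:
    """Accuracy, F1, Precision, Recall from the sensitive/resistant
    confusion table (sensitive = positive class)."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    tp = float(np.sum((pred == 1) & (truth == 1)))
    tn = float(np.sum((pred == 0) & (truth == 0)))
    fp = float(np.sum((pred == 1) & (truth == 0)))
    fn = float(np.sum((pred == 0) & (truth == 1)))
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("no predicted positives; precision reported as 0")
        precision = 0.0
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        warnings.warn("precision + recall = 0; F1 reported as 0")
        f1 = 0.0
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    return {"accuracy": accuracy, "f1": f1, "precision": precision, "recall": recall}


def rank_metrics(scores, truth) -> tuple[float, float]:
    """(AUC, AUPR) of a score vector against binary truth.

    AUC uses the Mann-Whitney pairwise formulation (ties count 1/2);
    AUPR integrates the precision step-curve over recall, evaluated at
    every distinct threshold.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rank_metrics needs both classes present")
    ranks = rankdata(scores)
    auc = (ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp_cum = np.cumsum(truth[order])
    # indices where the threshold changes (last occurrence of each score)
    last = np.nonzero(np.r_[sorted_scores[1:] != sorted_scores[:-1], True])[0]
    precision = tp_cum[last] / (last + 1)
    recall = tp_cum[last] / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    aupr = float(np.sum((recall - prev_recall) * precision))
    return float(auc), aupr


@dataclass
class EvaluationReport:
    """Per repetition x fold metric table plus aggregated means."""

    records: pd.DataFrame
    n_folds: int
    n_reps: int

    METRICS = ("auc", "aupr", "accuracy", "f1", "precision", "recall")

    @property
    def means(self) -> dict[str, float]:
        per_rep = self.records.groupby("repetition")[list(self.METRICS)].mean()
        return {k: float(v) for k, v in per_rep.mean().items()}

    def summary_json(self) -> dict:
        return {"n_folds": self.n_folds, "n_reps": self.n_reps, **self.means}


def cross_validate(B: BinaryResponseMatrix,
                   SC: SimilarityMatrix | np.ndarray | None,
                   SD: SimilarityMatrix | np.ndarray | None,
                   hp: Hyperparameters, scenario: Scenario,
                   n_folds: int = 5, n_reps: int = 30,
                   seed: int = 0) -> EvaluationReport:
    """Repeated stratified pairwise cross-validation.

    For each repetition and fold the test pairs are masked as missing,
    the model is fitted missing-aware on the training pairs, the elbow
    threshold is learned on training pairs, and all six metrics are
    computed on the test pairs.
    """
    rows: list[dict] = []
    for rep in range(n_reps):
        plan = make_folds(B, n_folds, seed=seed + rep)
        for fold in range(1, n_folds + 1):
            test = plan.test_pairs(fold)
            ti = np.array([p[0] for p in test])
            tj = np.array([p[1] for p in test])
            B_train = B.copy()
            B_train.missing_mask[ti, tj] = True
            fit_seed = (seed + rep) * n_folds + fold
            hp_fold = Hyperparameters(hp.alpha, hp.beta, hp.k_prime,
                                      hp.max_iter, hp.tol, fit_seed)
            fold_scenario = Scenario(scenario.use_sc, scenario.use_sd,
                                     missing_aware=True)
            scores = fit_predict(B_train, SC, SD, hp_fold, fold_scenario)
            _, thr = threshold_scores(scores, B_train)
            test_scores = scores.scores[ti, tj]
            test_truth = B.labels[ti, tj]
            test_pred = (test_scores >= thr).astype(float)
            auc, aupr = rank_metrics(test_scores, test_truth)
            rows.append({
                "repetition": rep + 1, "fold": fold, "threshold": thr,
                "auc": auc, "aupr": aupr,
                **confusion_metrics(test_pred, test_truth),
            })
    return EvaluationReport(pd.DataFrame(rows), n_folds, n_reps)


def grid_search(B: BinaryResponseMatrix,
                SC: SimilarityMatrix | np.ndarray | None,
                SD: SimilarityMatrix | np.ndarray | None,
                scenario: Scenario,
                alpha_grid, beta_grid, kprime_grid,
                seed: int = 0, n_folds: int = 5, n_reps: int = 3,
                max_iter: int = 500,
                ) -> tuple[Hyperparameters, pd.DataFrame]:
    """Exhaustive grid search maximizing mean cross-validated AUC.

    Ties break toward lexicographically smaller (alpha, beta, k').
    ``n_reps`` defaults to 3 for desk-scale runtime; the full protocol
    uses 30.
    """
    alpha_grid = list(alpha_grid)
    beta_grid = list(beta_grid)
    kprime_grid = list(kprime_grid)
    if not alpha_grid or not beta_grid or not kprime_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    best: tuple | None = None
    for alpha, beta, kp in itertools.product(alpha_grid, beta_grid, kprime_grid):
        hp = Hyperparameters(alpha, beta, kp, max_iter=max_iter, seed=seed)
        report = cross_validate(B, SC, SD, hp, scenario,
                                n_folds=n_folds, n_reps=n_reps, seed=seed)
        means = report.means
        rows.append({"alpha": alpha, "beta": beta, "k_prime": kp, **means})
        key = (-means["auc"], alpha, beta, kp)
        if best is None or key < best[0]:
            best = (key, hp)
    table = pd.DataFrame(rows)
    return best[1], table


def heldout_recovery_auc(spec, scenario_name: str,
                         hp: Hyperparameters | None = None,
                         weights: str = "standardized") -> float:
    """Parameter-recovery experiment on one synthetic bundle.

    Generates a bundle, fits missing-aware on the observed (noisy)
    labels, predicts the bundle's own masked entries and returns the AUC
    of those predictions against the noiseless planted labels from the
    truth record.
    """
    from .synthetic import generate
    from .transform import prepare_similarity

    bundle = generate(spec)
    B = bundle.binary_response
    SC = prepare_similarity(bundle.sc_raw, weights)
    SD = prepare_similarity(bundle.sd_raw, weights)
    hp = hp or Hyperparameters(seed=spec.seed)
    scenario = Scenario.from_name(scenario_name, missing_aware=True)
    scores = fit_predict(B, SC, SD, hp, scenario)
    held_out = B.missing_mask
    auc, _ = rank_metrics(scores.scores[held_out],
                          bundle.truth["B_clean"][held_out])
    return auc


def vector_compare(X, Y, binary: bool | None = None) -> dict[str, float]:
    """Vector-agreement metrics: Jaccard, cosine, binary cross-entropy,
    RMSE, range-normalized RMSE (both normalizations) and MAE.

    Jaccard and cross-entropy are only meaningful when X is binary; for
    cross-entropy Y is clipped to [1e-7, 1 - 1e-7] so exactly-binary
    probability vectors stay finite.  A zero range makes the matching
    NRMSE variant NaN.
    """
    X = np.asarray(X, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    if X.shape != Y.shape:
        raise ValueError("vectors must have the same length")
    n = X.size
    out: dict[str, float] = {}

    inter = float((X * Y).sum())
    union = float((X + Y).sum()) - inter
    out["jaccard"] = inter / union if union > 0 else 0.0

    nx, ny = np.linalg.norm(X), np.linalg.norm(Y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    out["cosine"] = float((X * Y).sum() / (nx * ny))

    Yc = np.clip(Y, 1e-7, 1.0 - 1e-7)
    out["cross_entropy"] = float(-np.mean(X * np.log(Yc) + (1 - X) * np.log(1 - Yc)))

    diff = X - Y
    rmse = float(np.sqrt((diff * diff).sum() / n))
    out["rmse"] = rmse
    range_x = float(X.max() - X.min())
    range_y = float(Y.max() - Y.min())
    out["nrmse_x"] = rmse / range_x if range_x > 0 else float("nan")
    out["nrmse_y"] = rmse / range_y if range_y > 0 else float("nan")
    out["mae"] = float(np.abs(diff).mean())
    return out
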