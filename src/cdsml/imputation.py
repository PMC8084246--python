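"""Expression-distance-weighted KNN imputation of missing matrix entries.

The distance between two cell lines is the squared Euclidean norm of
their expression profiles; a missing entry is replaced by the weighted
mean of its k nearest neighbours' values in that column, each neighbour
weighted by its DISTANCE to the query cell line.  Distance weighting
(rather than the conventional inverse-distance weighting) is the
published form of the update and is the default here; an
``inverse-distance`` mode provides the conventional variant.  See
docs/methods.md for the discussion.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import DistanceMatrix, FeatureMatrix, ResponseMatrix

logger = logging.getLogger(__name__)

WEIGHTINGS = ("distance", "inverse-distance")


def expression_distance(expr: FeatureMatrix) -> DistanceMatrix:
    """Pairwise squared-Euclidean distances between expression profiles.

    The expression matrix must be fully observed (it anchors the
    distances used to impute every other matrix).
    """
    if expr.missing_mask.any():
        raise ValueError("expression matrix must not contain missing entries")
    E = expr.values
    sq = (E * E).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (E @ E.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(D, list(expr.row_ids))


def knn_impute(target, dist: DistanceMatrix, k: int = 10,
               weighting: str = "distance"):
    """Fill every missing entry of ``target`` by the weighted k-NN mean.

    Neighbours missing the value in the queried column are skipped and
    replaced by the next nearest cell line, so each missing entry uses k
    usable neighbours whenever that many exist.  Distance ties break by
    cell-line id.  If every usable neighbour sits at distance zero the
    unweighted mean is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    if weighting == "distance":
        logger.info(
            "knn_impute: using literal distance weighting (farther neighbours "
            "weigh more); pass weighting='inverse-distance' for the "
            "conventional variant"
        )
    pos = {cid: i for i, cid in enumerate(dist.ids)}
    try:
        order_in_dist = [pos[r] for r in target.row_ids]
    except KeyError as exc:
        raise ValueError(f"cell line {exc.args[0]!r} absent from distance matrix") from None
    D = dist.values[np.ix_(order_in_dist, order_in_dist)]

    m = len(target.row_ids)
    if k > m - 1:
        warnings.warn(f"k={k} exceeds available cell lines; truncated to {m - 1}")
        k = max(1, m - 1)

    values = target.values.copy()
    mask = target.missing_mask
    # per-row neighbour order: by (distance, id), excluding the row itself
    ids = np.array(target.row_ids)
    orders = []
    for i in range(m):
        cand = [j for j in range(m) if j != i]
        cand.sort(key=lambda j: (D[i, j], ids[j]))
        orders.append(cand)

    for i, j in zip(*np.nonzero(mask)):
        usable = [nb for nb in orders[i] if not mask[nb, j]][:k]
        if not usable:
            raise ValueError(
                f"no usable neighbours to impute entry "
                f"({target.row_ids[i]!r}, {target.col_ids[j]!r})"
            )
        d = D[i, usable]
        v = values[usable, j]
        if weighting == "distance":
            if d.sum() <= 0:
                values[i, j] = v.mean()  # duplicate profiles: unweighted mean
            else:
                values[i, j] = float((v * d).sum() / d.sum())
        else:
            w = 1.0 / np.maximum(d, 1e-12)
            values[i, j] = float((v * w).sum() / w.sum())

    empty = np.zeros(values.shape, dtype=bool)
    if isinstance(target, ResponseMatrix):
        return ResponseMatrix(values, list(target.row_ids), list(target.col_ids), empty)
    return FeatureMatrix(values, list(target.row_ids), list(target.col_ids),
                         kind=target.kind, missing_mask=empty)
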