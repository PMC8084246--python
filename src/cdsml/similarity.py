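"""Cell-line and drug similarity constructors.

Cell lines: Pearson correlation of expression (SC_E) or copy-number
(SC_V) profiles, and the Jaccard index of mutation profiles (SC_M).
Drugs: Jaccard index of chemical fingerprints (SD_S), Jaccard index of
the immediate neighbourhoods in a chemical-protein interaction network
(SD_N), and the total weight of a maximum-weight bipartite matching
between the two drugs' target-protein sets over a protein-protein
interaction network (SD_P).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import (
    DrugTargetMap,
    FeatureMatrix,
    SimilarityMatrix,
    WeightedNetwork,
)

logger = logging.getLogger(__name__)

_KIND_TO_SOURCE = {"expression": "SC_E", "cnv": "SC_V",
                   "mutation": "SC_M", "fingerprint": "SD_S"}


def pearson_similarity(features: FeatureMatrix) -> SimilarityMatrix:
    """Pearson correlation between row profiles; diagonal forced to 1."""
    if features.missing_mask.any():
        raise ValueError("feature matrix must be fully observed")
    if features.shape[1] < 2:
        raise ValueError("need at least 2 feature columns for correlation")
    X = features.values
    std = X.std(axis=1)
    for i in np.flatnonzero(std == 0):
        raise ValueError(f"constant row {features.row_ids[i]!r} has zero variance")
    S = np.corrcoef(X)
    np.fill_diagonal(S, 1.0)
    np.clip(S, -1.0, 1.0, out=S)
    source = _KIND_TO_SOURCE.get(features.kind, "SC_E")
    entity = "drug" if features.kind == "fingerprint" else "cell_line"
    return SimilarityMatrix(S, list(features.row_ids), entity, source, "raw")


def _jaccard_from_binary(B: np.ndarray) -> np.ndarray:
    inter = B @ B.T
    sums = B.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    return S


def jaccard_similarity(features: FeatureMatrix) -> SimilarityMatrix:
    """Jaccard index |A∩B| / |A∪B| of binary row profiles.

    Two all-zero profiles give 0 (no evidence of similarity); the
    diagonal is fixed at 1.
    """
    if features.missing_mask.any():
        raise ValueError("feature matrix must be fully observed")
    bad = np.argwhere(~np.isin(features.values, (0.0, 1.0)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-binary value at row {features.row_ids[i]!r}, "
            f"column {features.col_ids[j]!r}"
        )
    S = _jaccard_from_binary(features.values)
    source = _KIND_TO_SOURCE.get(features.kind, "SD_S")
    entity = "drug" if features.kind == "fingerprint" else "cell_line"
    return SimilarityMatrix(S, list(features.row_ids), entity, source, "raw")


def neighbor_jaccard(network: WeightedNetwork, drugs: list[str],
                     min_weight: float = 0.0) -> SimilarityMatrix:
    """Jaccard index of immediate network neighbourhoods (weights ignored).

    Drugs absent from the network have an empty neighbourhood; two empty
    neighbourhoods score 0, including on the diagonal.
    """
    hoods = [network.neighbors(d, min_weight) for d in drugs]
    n = len(drugs)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            union = hoods[i] | hoods[j]
            S[i, j] = S[j, i] = len(hoods[i] & hoods[j]) / len(union) if union else 0.0
    return SimilarityMatrix(S, list(drugs), "drug", "SD_N", "raw")


def max_weight_matching_value(left: list[str], right: list[str],
                              ppi: WeightedNetwork) -> float:
    """Total weight of a maximum-weight matching in the bipartite graph
    with parts ``left``/``right`` and edge weights from the PPI network.

    The two parts keep shared proteins as distinct nodes; since the PPI
    network has no self-loops, a protein facing its own copy contributes
    nothing.  Solved as a zero-padded assignment problem (all weights are
    positive, so padding with zeros never forces a worse matching).
    """
    if not left or not right:
        return 0.0
    W = np.zeros((len(left), len(right)))
    for a, p in enumerate(left):
        for b, q in enumerate(right):
            if p == q:
                continue
            w = ppi.weight(p, q)
            if w is not None:
                W[a, b] = w
    rows, cols = linear_sum_assignment(W, maximize=True)
    return float(W[rows, cols].sum())


def matching_similarity(targets: DrugTargetMap, ppi: WeightedNetwork,
                        drugs: list[str]) -> SimilarityMatrix:
    """PPI-based drug similarity: maximum-weight bipartite matching value
    between the two drugs' target-protein sets.  The diagonal is computed
    the same way on TP_i vs its own copy."""
    missing = set()
    for d in drugs:
        missing |= targets[d] - ppi.nodes
    if missing:
        logger.warning(
            "matching_similarity: %d target protein(s) absent from the PPI "
            "network: %s", len(missing), ", ".join(sorted(missing)[:5]),
        )
    sets = [sorted(targets[d]) for d in drugs]
    n = len(drugs)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            S[i, j] = S[j, i] = max_weight_matching_value(sets[i], sets[j], ppi)
    return SimilarityMatrix(S, list(drugs), "drug", "SD_P", "raw")


def rescale_matching(similarity: SimilarityMatrix) -> SimilarityMatrix:
    """Scale the matching similarity onto [0, 1] by its maximum entry.

    Matching values are sums of positive PPI weights and are unbounded
    above; dividing by the maximum entry puts them on the same scale as
    the Jaccard/Pearson similarities before standardization.  An all-zero
    matrix passes through unchanged.
    """
    if similarity.source != "SD_P" or similarity.stage != "raw":
        raise ValueError("rescale_matching expects a raw SD_P matrix")
    if np.any(similarity.values < 0):
        raise ValueError("matching similarities must be non-negative")
    peak = similarity.values.max()
    values = similarity.values if peak == 0 else similarity.values / peak
    return SimilarityMatrix(values.copy(), list(similarity.ids), "drug", "SD_P", "raw")
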