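"""Similarity standardization and symmetric normalized Laplacian.

Raw similarities live in [-1, 1] (Pearson) or [0, 1] (Jaccard, rescaled
matching).  Standardization maps them linearly onto [0, 1] via
(S + 1) / 2; normalization then forms D^{-1/2} (D - S) D^{-1/2} with
D_ii = sum_j S_ij, a symmetric positive semidefinite operator with
spectrum in [0, 2].
"""

from __future__ import annotations

import numpy as np

from .containers import SimilarityMatrix

_RANGE_TOL = 1e-9


def standardize(similarity: SimilarityMatrix) -> SimilarityMatrix:
    """Map a raw similarity entry-wise through (S + 1) / 2.

    Strictly monotone, so entry ordering is preserved.  Entries outside
    [-1, 1] signal an un-rescaled matching similarity and raise.
    """
    if similarity.stage != "raw":
        raise ValueError(f"standardize expects stage 'raw', got {similarity.stage!r}")
    S = similarity.values
    bad = np.argwhere((S < -1.0 - _RANGE_TOL) | (S > 1.0 + _RANGE_TOL))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"entry ({similarity.ids[i]!r}, {similarity.ids[j]!r}) = {S[i, j]:g} "
            "outside [-1, 1]; rescale the matching similarity first"
        )
    out = (np.clip(S, -1.0, 1.0) + 1.0) / 2.0
    return SimilarityMatrix(out, list(similarity.ids), similarity.entity,
                            similarity.source, "standardized")


def laplacian_normalize(similarity: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric normalized Laplacian D^{-1/2} (D - S) D^{-1/2}.

    D is the diagonal of row sums of the standardized matrix (diagonal
    included).  Every row sum must be strictly positive.
    """
    if similarity.stage != "standardized":
        raise ValueError(
            f"laplacian_normalize expects stage 'standardized', got {similarity.stage!r}"
        )
    S = similarity.values
    d = S.sum(axis=1)
    for i in np.flatnonzero(d <= 0):
        raise ValueError(f"zero row sum for {similarity.ids[i]!r}")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = (np.diag(d) - S) * inv_sqrt[:, None] * inv_sqrt[None, :]
    L = 0.5 * (L + L.T)
    return SimilarityMatrix(L, list(similarity.ids), similarity.entity,
                            similarity.source, "normalized")


def prepare_similarity(similarity: SimilarityMatrix,
                       weights: str = "standardized") -> SimilarityMatrix:
    """Prepare a raw similarity for use as conservation weights.

    ``weights='standardized'`` (default) standardizes onto [0, 1] and
    feeds that similarity into the conservation penalty, which keeps the
    penalty a positive-semidefinite graph-Laplacian quadratic form.
    ``weights='laplacian'`` additionally applies the symmetric
    normalized Laplacian and uses the resulting operator itself as the
    pairwise weights; with that choice the conservation term is
    indefinite and the loss can be unbounded below at large beta (see
    docs/methods.md), so it is not the default.
    """
    if weights not in ("laplacian", "standardized"):
        raise ValueError("weights must be 'laplacian' or 'standardized'")
    std = standardize(similarity)
    return laplacian_normalize(std) if weights == "laplacian" else std
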