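"""In-memory containers shared by all pipeline stages.

Matrices are stored row-major with cell lines on rows and drugs (or
features) on columns.  Missing entries are tracked with an explicit
boolean mask (``True`` = unknown) rather than with NaN so that binary
matrices keep an integer dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

FeatureKind = Literal["expression", "cnv", "mutation", "fingerprint"]
SimilaritySource = Literal["SC_E", "SC_V", "SC_M", "SD_S", "SD_N", "SD_P"]
SimilarityStage = Literal["raw", "standardized", "normalized"]

_SYM_TOL = 1e-10


def _check_unique(ids: list[str], axis: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {axis} id: {i!r}")
        seen.add(i)


def _as_mask(mask: np.ndarray | None, shape: tuple[int, int]) -> np.ndarray:
    if mask is None:
        return np.zeros(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"missing_mask shape {mask.shape} != values shape {shape}")
    return mask


@dataclass
class ResponseMatrix:
    """Continuous drug-response matrix (ln IC50, molar) over cell lines x drugs."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        m, n = self.values.shape
        if len(self.row_ids) != m or len(self.col_ids) != n:
            raise ValueError("id lengths do not match matrix shape")
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        self.missing_mask = _as_mask(self.missing_mask, self.values.shape)
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-missing entries must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ResponseMatrix":
        return replace(
            self,
            values=self.values.copy(),
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
            missing_mask=self.missing_mask.copy(),
        )


@dataclass
class FeatureMatrix:
    """Cell-line (or drug) feature matrix: expression, CNV, mutation or fingerprint."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    kind: FeatureKind = "expression"
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("expression", "cnv", "mutation", "fingerprint"):
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if len(self.row_ids) != m or len(self.col_ids) != n:
            raise ValueError("id lengths do not match matrix shape")
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        self.missing_mask = _as_mask(self.missing_mask, self.values.shape)
        if self.kind in ("mutation", "fingerprint"):
            # {0,1} at read time; KNN imputation may introduce fractional
            # values, which stay inside [0,1] (convex combinations).
            observed = self.values[~self.missing_mask]
            if observed.size and (observed.min() < 0.0 or observed.max() > 1.0):
                raise ValueError(f"{self.kind} matrix entries must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "FeatureMatrix":
        return replace(
            self,
            values=self.values.copy(),
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
            missing_mask=self.missing_mask.copy(),
        )


@dataclass
class BinaryResponseMatrix:
    """Sensitive(1)/resistant(0) labels over cell lines x drugs."""

    labels: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        m, n = self.labels.shape
        if len(self.row_ids) != m or len(self.col_ids) != n:
            raise ValueError("id lengths do not match matrix shape")
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        self.missing_mask = _as_mask(self.missing_mask, self.labels.shape)
        observed = self.labels[~self.missing_mask]
        if not np.all(np.isin(observed, (0.0, 1.0))):
            raise ValueError("labels must be 0/1 where observed")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def values(self) -> np.ndarray:  # uniform access for IO helpers
        return self.labels

    def sensitive_fraction(self) -> float:
        obs = self.labels[~self.missing_mask]
        return float(obs.mean()) if obs.size else float("nan")

    def copy(self) -> "BinaryResponseMatrix":
        return replace(
            self,
            labels=self.labels.copy(),
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
            missing_mask=self.missing_mask.copy(),
        )

    def transpose(self) -> "BinaryResponseMatrix":
        return BinaryResponseMatrix(
            labels=self.labels.T.copy(),
            row_ids=list(self.col_ids),
            col_ids=list(self.row_ids),
            missing_mask=self.missing_mask.T.copy(),
        )


@dataclass
class DistanceMatrix:
    """Squared-Euclidean distances between cell-line expression profiles."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square over ids")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=_SYM_TOL):
            raise ValueError("distance matrix must have zero diagonal")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over cell lines or drugs, tagged by source and stage."""

    values: np.ndarray
    ids: list[str]
    entity: Literal["cell_line", "drug"]
    source: SimilaritySource
    stage: SimilarityStage = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        # keep it exactly symmetric downstream
        self.values = 0.5 * (self.values + self.values.T)

    def copy(self) -> "SimilarityMatrix":
        return replace(self, values=self.values.copy(), ids=list(self.ids))


@dataclass
class CmaxTable:
    """Per-drug maximum plasma concentration, same scale as the response values."""

    cmax: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, value in self.cmax.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite c_max for drug {drug!r}")

    def __getitem__(self, drug: str) -> float:
        if drug not in self.cmax:
            raise KeyError(f"drug {drug!r} absent from C_max table")
        return self.cmax[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.cmax


@dataclass
class WeightedNetwork:
    """Undirected weighted graph over proteins and/or chemicals (no self-loops)."""

    edges: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_edge_list(cls, triples) -> "WeightedNetwork":
        net = cls()
        for a, b, w in triples:
            net.add_edge(str(a), str(b), float(w))
        return net

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on node {a!r} not allowed")
        if weight <= 0:
            raise ValueError(f"edge ({a!r}, {b!r}) must have positive weight")
        self.edges[frozenset((a, b))] = weight

    def weight(self, a: str, b: str) -> float | None:
        return self.edges.get(frozenset((a, b)))

    def neighbors(self, node: str, min_weight: float = 0.0) -> set[str]:
        out = set()
        for key, w in self.edges.items():
            if node in key and w >= min_weight:
                (other,) = key - {node}
                out.add(other)
        return out

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for key in self.edges:
            out |= set(key)
        return out


@dataclass
class DrugTargetMap:
    """drug id -> set of target-protein ids (may be empty)."""

    targets: dict[str, set] = field(default_factory=dict)

    def __getitem__(self, drug: str) -> set:
        return self.targets.get(drug, set())


@dataclass
class ScoreMatrix:
    """Predicted continuous sensitivity scores over cell lines x drugs."""

    scores: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        m, n = self.scores.shape
        if len(self.row_ids) != m or len(self.col_ids) != n:
            raise ValueError("id lengths do not match matrix shape")

    @property
    def values(self) -> np.ndarray:  # uniform access for IO helpers
        return self.scores
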