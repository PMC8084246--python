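"""Delimited-text IO, sparse-sample filtering and C_max binarization.

All matrices travel as delimited text (TSV by default, comma accepted):
first row = column ids, first column = row ids.  The C_max table is a
two-column file (drug_id, c_max).  Networks are 3-column edge lists and
drug-target maps are 2-column pair lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import (
    BinaryResponseMatrix,
    CmaxTable,
    DrugTargetMap,
    FeatureMatrix,
    ResponseMatrix,
    WeightedNetwork,
)

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKEN = "NA"


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _read_table(path) -> tuple[list[str], list[str], list[list[str]]]:
    """Parse a delimited file into (col_ids, row_ids, string cells)."""
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    sep = _sniff_delimiter(lines[0])
    header = lines[0].split(sep)
    col_ids = [c.strip() for c in header[1:]]
    row_ids: list[str] = []
    cells: list[list[str]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split(sep)
        if len(parts) != len(col_ids) + 1:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(parts)} fields, expected {len(col_ids) + 1})"
            )
        row_ids.append(parts[0].strip())
        cells.append([c.strip() for c in parts[1:]])
    return col_ids, row_ids, cells


def read_matrix(path, kind: str | None = None,
                missing_token: str = DEFAULT_MISSING_TOKEN):
    """Read a labeled matrix; ``kind=None`` yields a :class:`ResponseMatrix`.

    Cells equal to ``missing_token`` or empty are masked as missing.
    Duplicate ids, ragged rows and non-numeric cells raise ``ValueError``
    with enough context to locate the offence.
    """
    col_ids, row_ids, cells = _read_table(path)
    m, n = len(row_ids), len(col_ids)
    values = np.zeros((m, n))
    mask = np.zeros((m, n), dtype=bool)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            if cell == "" or cell == missing_token:
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row "
                        f"{row_ids[i]!r}, column {col_ids[j]!r}"
                    ) from None
    if kind is None:
        return ResponseMatrix(values, row_ids, col_ids, mask)
    if kind == "binary_response":
        return BinaryResponseMatrix(values, row_ids, col_ids, mask)
    return FeatureMatrix(values, row_ids, col_ids, kind=kind, missing_mask=mask)


def write_matrix(matrix, path, missing_token: str = DEFAULT_MISSING_TOKEN,
                 sep: str = "\t", fmt: str = "%.10g") -> None:
    """Write any labeled matrix; inverse of :func:`read_matrix` up to float format."""
    values = matrix.values
    mask = getattr(matrix, "missing_mask", None)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    with open(path, "w") as fh:
        fh.write(sep.join(["id", *matrix.col_ids]) + "\n")
        for i, rid in enumerate(matrix.row_ids):
            cells = [
                missing_token if mask[i, j] else fmt % values[i, j]
                for j in range(values.shape[1])
            ]
            fh.write(sep.join([rid, *cells]) + "\n")


def write_similarity(sim, path, sep: str = "\t") -> None:
    """Write a similarity matrix with its stage recorded in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# stage: {sim.stage}\n# source: {sim.source}\n")
        fh.write(sep.join(["id", *sim.ids]) + "\n")
        for i, rid in enumerate(sim.ids):
            fh.write(sep.join([rid, *("%.10g" % v for v in sim.values[i])]) + "\n")


def read_cmax(path) -> CmaxTable:
    """Two-column file (drug_id, c_max); a header row is detected and skipped."""
    table: dict[str, float] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, ln in enumerate(lines, start=1):
        if not ln or ln.startswith("#"):
            continue
        sep = _sniff_delimiter(ln)
        parts = [p.strip() for p in ln.split(sep)]
        if len(parts) != 2:
            raise ValueError(f"{path}: expected 2 columns at line {lineno}")
        try:
            value = float(parts[1])
        except ValueError:
            if lineno == 1:  # header
                continue
            raise ValueError(
                f"{path}: non-numeric c_max {parts[1]!r} at line {lineno}"
            ) from None
        table[parts[0]] = value
    return CmaxTable(table)


def write_cmax(table: CmaxTable, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["drug_id", "c_max"]) + "\n")
        for drug, value in table.cmax.items():
            fh.write(sep.join([drug, "%.10g" % value]) + "\n")


def read_network(path) -> WeightedNetwork:
    """3-column edge list (node_a, node_b, weight), undirected."""
    net = WeightedNetwork()
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln or ln.startswith("#"):
            continue
        sep = _sniff_delimiter(ln)
        parts = [p.strip() for p in ln.split(sep)]
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 3 columns at line {lineno}")
        try:
            w = float(parts[2])
        except ValueError:
            if lineno == 1:
                continue
            raise
        net.add_edge(parts[0], parts[1], w)
    return net


def write_network(net: WeightedNetwork, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["node_a", "node_b", "weight"]) + "\n")
        for key, w in sorted(net.edges.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(key)
            fh.write(sep.join([a, b, "%.10g" % w]) + "\n")


def read_target_map(path) -> DrugTargetMap:
    """2-column pair list (drug_id, protein_id), one row per pair."""
    targets: dict[str, set] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln or ln.startswith("#"):
            continue
        sep = _sniff_delimiter(ln)
        parts = [p.strip() for p in ln.split(sep)]
        if len(parts) != 2:
            raise ValueError(f"{path}: expected 2 columns at line {lineno}")
        if lineno == 1 and parts[0].lower() in ("drug", "drug_id"):
            continue
        targets.setdefault(parts[0], set()).add(parts[1])
    return DrugTargetMap(targets)


def write_target_map(tmap: DrugTargetMap, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["drug_id", "protein_id"]) + "\n")
        for drug in sorted(tmap.targets):
            for protein in sorted(tmap.targets[drug]):
                fh.write(sep.join([drug, protein]) + "\n")


@dataclass
class Removal:
    axis: str         # "drug" | "feature" | "cell_line"
    entity_id: str
    missing_fraction: float
    rule: str

    def as_line(self) -> str:
        return f"{self.axis}\t{self.entity_id}\t{self.missing_fraction:.4f}\t{self.rule}"


@dataclass
class RemovalLog:
    removals: list[Removal] = field(default_factory=list)

    def add(self, axis: str, entity_id: str, fraction: float, rule: str) -> None:
        self.removals.append(Removal(axis, entity_id, float(fraction), rule))

    def __len__(self) -> int:
        return len(self.removals)

    def as_text(self) -> str:
        return "\n".join(r.as_line() for r in self.removals)


def filter_sparse(response: ResponseMatrix,
                  features: list[FeatureMatrix] | None = None,
                  drug_threshold: float = 0.5,
                  cell_threshold: float = 0.5,
                  feature_threshold: float = 0.5,
                  ) -> tuple[ResponseMatrix, list[FeatureMatrix], RemovalLog]:
    """Drop under-observed drugs, feature columns, then cell lines.

    Order: (1) response columns (drugs) with missing fraction strictly
    above ``drug_threshold``; (2) feature columns strictly above
    ``feature_threshold``; (3) cell lines whose missing fraction exceeds
    ``cell_threshold`` in the response or in any feature matrix.  The
    cell-line axis stays identical across all outputs.
    """
    features = features or []
    for fm in features:
        if fm.row_ids != response.row_ids:
            raise ValueError("feature matrices must share the response cell-line axis")
    log = RemovalLog()

    # (1) drugs
    drug_frac = response.missing_mask.mean(axis=0)
    keep_drugs = drug_frac <= drug_threshold
    for j, keep in enumerate(keep_drugs):
        if not keep:
            log.add("drug", response.col_ids[j], drug_frac[j],
                    f"missing_fraction>{drug_threshold}")
    if not keep_drugs.any():
        raise ValueError("empty matrix after filtering: all drugs removed")
    response = ResponseMatrix(
        response.values[:, keep_drugs],
        list(response.row_ids),
        [c for c, k in zip(response.col_ids, keep_drugs) if k],
        response.missing_mask[:, keep_drugs],
    )

    # (2) feature columns
    filtered_features: list[FeatureMatrix] = []
    for fm in features:
        col_frac = fm.missing_mask.mean(axis=0)
        keep_cols = col_frac <= feature_threshold
        for j, keep in enumerate(keep_cols):
            if not keep:
                log.add("feature", f"{fm.kind}:{fm.col_ids[j]}", col_frac[j],
                        f"missing_fraction>{feature_threshold}")
        filtered_features.append(FeatureMatrix(
            fm.values[:, keep_cols],
            list(fm.row_ids),
            [c for c, k in zip(fm.col_ids, keep_cols) if k],
            kind=fm.kind,
            missing_mask=fm.missing_mask[:, keep_cols],
        ))

    # (3) cell lines, judged on the already-filtered columns
    keep_cells = np.ones(len(response.row_ids), dtype=bool)
    reasons: dict[int, tuple[float, str]] = {}
    matrices = [("response", response)] + [(fm.kind, fm) for fm in filtered_features]
    for name, mat in matrices:
        if mat.values.shape[1] == 0:
            continue
        row_frac = mat.missing_mask.mean(axis=1)
        over = row_frac > cell_threshold
        for i in np.flatnonzero(over):
            keep_cells[i] = False
            reasons.setdefault(i, (row_frac[i], f"missing_fraction>{cell_threshold} in {name}"))
    for i, (frac, rule) in sorted(reasons.items()):
        log.add("cell_line", response.row_ids[i], frac, rule)
    if not keep_cells.any():
        raise ValueError("empty matrix after filtering: all cell lines removed")

    kept_rows = [r for r, k in zip(response.row_ids, keep_cells) if k]
    response = ResponseMatrix(
        response.values[keep_cells], kept_rows, list(response.col_ids),
        response.missing_mask[keep_cells],
    )
    filtered_features = [
        FeatureMatrix(fm.values[keep_cells], list(kept_rows), list(fm.col_ids),
                      kind=fm.kind, missing_mask=fm.missing_mask[keep_cells])
        for fm in filtered_features
    ]
    for r in log.removals:
        logger.info("filter_sparse removed %s", r.as_line())
    return response, filtered_features, log


def binarize_ic50(response: ResponseMatrix, cmax: CmaxTable) -> BinaryResponseMatrix:
    """Label each pair sensitive (1) iff IC50 < C_max(drug), strictly.

    Equality falls to the resistant (0) side; missing entries stay missing.
    """
    thresholds = np.array([cmax[d] for d in response.col_ids])
    labels = (response.values < thresholds[None, :]).astype(float)
    labels[response.missing_mask] = 0.0
    out = BinaryResponseMatrix(
        labels, list(response.row_ids), list(response.col_ids),
        response.missing_mask.copy(),
    )
    frac = out.sensitive_fraction()
    logger.info("binarize_ic50: sensitive fraction over observed pairs = %.4f", frac)
    return out
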