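"""Shared data types, TSV/GMT readers and writers, and expression preprocessing.

Expression data is carried as log2-scale matrices (genes x samples).  Cell-line
data (Illumina-style) additionally carries per-cell detection p-values used for
the expression filter; clinical cohort matrices (Affymetrix-style) do not and
bypass that filter.  All matrices are log2-scale by contract: no automatic
log-detection is attempted.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("muenv")

#: Canonical subtype keys used throughout the package.
SUBTYPES = ("luminal", "her2", "basal")

#: Display labels for the clinical subtype partition.
SUBTYPE_LABELS = {
    "luminal": "ER+/HER2-",
    "her2": "HER2+",
    "basal": "ER-/HER2-",
}

#: Treatment conditions of the cell-line experiment.
CONDITIONS = ("CAF_CM", "NAF_CM", "CTRL")


class ParseError(ValueError):
    """Raised when an input file violates its documented layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with optional detection p-values.

    Parameters
    ----------
    values
        DataFrame indexed by gene/probe id with one column per sample.
        Duplicate row ids are permitted at probe level (resolved by
        :func:`collapse_probes`); sample ids must be unique.
    detection_p
        Optional DataFrame of detection p-values with the same shape and
        labels as ``values``.
    platform_tag
        Free-text platform annotation.
    """

    values: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    platform_tag: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection_p shape differs from values")
            dp = self.detection_p.to_numpy()
            if np.any((dp < 0) | (dp > 1)):
                raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        det = None if self.detection_p is None else self.detection_p[sample_ids]
        return ExpressionMatrix(self.values[sample_ids], det, self.platform_tag)


@dataclass
class ProbeMap:
    """probe_id -> (gene_id, detection_rate, iqr) used for probe collapse."""

    entries: Mapping[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        for probe, (gene, rate, iqr) in self.entries.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"probe {probe}: detection rate {rate} outside [0,1]")
            if iqr < 0:
                raise ValueError(f"probe {probe}: negative IQR {iqr}")


@dataclass
class ExperimentDesign:
    """Sample annotation for the cell-line treatment experiment.

    ``table`` is indexed by sample id with columns ``cell_line``, ``subtype``
    (one of :data:`SUBTYPES`), ``condition`` (one of :data:`CONDITIONS`) and
    ``replicate`` (integer >= 1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_line", "subtype", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in design")
        bad = set(self.table["subtype"]) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtypes in design: {sorted(bad)}")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions in design: {sorted(bad)}")

    def samples(self, subtype: str | None = None, condition: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if subtype is not None:
            mask &= self.table["subtype"] == subtype
        if condition is not None:
            mask &= self.table["condition"] == condition
        return list(self.table.index[mask])


@dataclass
class CohortAnnotation:
    """Per-patient clinical annotation.

    ``table`` is indexed by sample id.  Required columns: ``time_months``
    (> 0) and ``event`` (0/1).  Optional: ``age_years``, ``size_cm``, ``ggi``,
    ``treatment`` (none/tam/chemo) and ``subtype`` (filled by
    :func:`muenv.signature.assign_subtype`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time_months", "event"):
            if col not in self.table.columns:
                raise ValueError(f"annotation missing required column {col!r}")
        t = self.table["time_months"].to_numpy(dtype=float)
        if np.any(t <= 0):
            raise ValueError("time_months must be strictly positive")
        ev = self.table["event"].to_numpy()
        if not set(np.unique(ev)) <= {0, 1}:
            raise ValueError("event must be 0/1")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style)."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_matrix_text(handle: io.TextIOBase, what: str) -> pd.DataFrame:
    reader = csv.reader(handle, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError(f"{what}: file is empty") from None
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{what}: duplicate sample ids {dup}")
    n = len(sample_ids)
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != n + 1:
            raise ParseError(
                f"{what}: line {lineno} has {len(row)} fields, expected {n + 1}"
            )
        ids.append(row[0])
        try:
            rows.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise ParseError(f"{what}: non-numeric value on line {lineno}: {exc}") from None
    return pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=sample_ids)


def read_expression_tsv(
    path: str,
    detection_path: str | None = None,
    platform_tag: str = "",
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (first column ids, header of samples).

    ``detection_path``, when given, names a companion detection-p file with an
    identical layout (same row and column order).
    """
    with open(path) as fh:
        values = _parse_matrix_text(fh, path)
    detection = None
    if detection_path is not None:
        with open(detection_path) as fh:
            detection = _parse_matrix_text(fh, detection_path)
        if list(detection.index) != list(values.index) or list(detection.columns) != list(
            values.columns
        ):
            raise ParseError(
                f"{detection_path}: layout differs from expression matrix {path}"
            )
    return ExpressionMatrix(values, detection, platform_tag)


def write_expression_tsv(matrix: ExpressionMatrix, path: str, fmt: str = "%.17g") -> None:
    """Write the matrix (and any detection p-values to ``path + '.detection'``).

    The default float format preserves float64 exactly, so write/read
    round-trips are bit-equal.
    """
    _write_frame(matrix.values, path, fmt)
    if matrix.detection_p is not None:
        _write_frame(matrix.detection_p, path + ".detection", fmt)


def _write_frame(frame: pd.DataFrame, path: str, fmt: str = "%.17g") -> None:
    with open(path, "w", newline="") as fh:
        fh.write("id\t" + "\t".join(map(str, frame.columns)) + "\n")
        arr = frame.to_numpy()
        for i, gid in enumerate(frame.index):
            fh.write(str(gid) + "\t" + "\t".join(fmt % v for v in arr[i]) + "\n")


def read_gmt(path: str) -> GeneSetCollection:
    """Read a standard GMT file: name TAB description TAB gene ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: duplicate gene set name {name!r} (line {lineno})")
            sets[name] = set(fields[2:])
    return GeneSetCollection(sets, source=path)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w", newline="") as fh:
        for name, genes in collection:
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")


def read_cohort_annotation(path: str) -> CohortAnnotation:
    """Read a clinical annotation TSV (columns sample_id, time_months, event, ...)."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in table.columns:
        raise ParseError(f"{path}: missing sample_id column")
    table = table.set_index("sample_id")
    return CohortAnnotation(table)


def write_cohort_annotation(ann: CohortAnnotation, path: str) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) quantile distribution.

    Each column's values are replaced by the across-sample mean of the
    column-wise sorted values at the corresponding rank; ties receive the
    average of their reference values.  After the call all columns share an
    identical sorted value multiset, and the transform is idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    if n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    order = np.argsort(vals, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(vals, order, axis=0), axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        col = vals[:, j]
        ranks = np.empty(n_genes, dtype=float)
        ranks[order[:, j]] = reference
        # average reference values over tied input values
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < n_genes:
            sums = np.bincount(inverse, weights=ranks)
            ranks = (sums / counts)[inverse]
        out[:, j] = ranks
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.detection_p, matrix.platform_tag)


def filter_probes(matrix: ExpressionMatrix, p_cut: float = 0.01) -> ExpressionMatrix:
    """Keep probes detected (p < ``p_cut``) in at least one sample.

    Requires detection p-values; cohort matrices without them should skip this
    step entirely.
    """
    if matrix.detection_p is None:
        raise ValueError(
            "no detection p-values present: skip detection filtering for this matrix"
        )
    keep = (matrix.detection_p.to_numpy() < p_cut).any(axis=1)
    values = matrix.values.iloc[keep]
    detection = matrix.detection_p.iloc[keep]
    logger.info("detection filter: %d of %d probes retained", keep.sum(), len(keep))
    return ExpressionMatrix(values, detection, matrix.platform_tag)


def collapse_probes(matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse probes to one row per gene.

    The surviving probe per gene is the one with the highest detection rate;
    ties are broken by the highest IQR of the log2 signal, residual ties by
    lexicographically smallest probe id (reproducible, otherwise arbitrary).
    """
    entries = probe_map.entries
    unmapped = [p for p in matrix.values.index if p not in entries]
    if unmapped:
        raise ValueError(f"probes missing from probe map: {sorted(set(unmapped))}")
    best: dict[str, tuple[float, float, str]] = {}
    for probe in matrix.values.index:
        gene, rate, iqr = entries[probe]
        # max by (rate, iqr), then min by probe id
        key = (rate, iqr, _NegStr(probe))
        if gene not in best or key > best[gene]:
            best[gene] = key
    chosen = {gene: str(key[2]) for gene, key in best.items()}
    probes = list(chosen.values())
    genes = list(chosen.keys())
    values = matrix.values.loc[probes]
    values.index = genes
    detection = None
    if matrix.detection_p is not None:
        detection = matrix.detection_p.loc[probes]
        detection.index = genes
    return ExpressionMatrix(values, detection, matrix.platform_tag)


class _NegStr(str):
    """String with reversed ordering, so max() picks the lexicographic minimum."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
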