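"""Plain-text readers/writers and container types for the pipeline.

The native interchange formats are deliberately simple and diff-able:

* expression / detection matrices — tab-separated, one header row of sample
  ids, first column gene (or probe) ids;
* sample metadata — CSV with one row per sample;
* gene sets — GMT (set name, description, tab-separated members);
* probe-to-gene maps — two-column TSV.

Matrices travel as :class:`pandas.DataFrame` (genes x samples).  Gene sets
use :class:`GeneSet` / :class:`GeneSetCollection`, which carry GMT semantics
(unique set names, unique members within a set, member order irrelevant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParseError

logger = logging.getLogger(__name__)

DIAGNOSIS_LEVELS = ("control", "autism")
SEX_LEVELS = ("M", "F")
REGION_LEVELS = ("frontal", "temporal")

#: Columns every sample-metadata table must carry (besides the sample_id index).
METADATA_COLUMNS = ("subject_id", "diagnosis", "RIN", "PMI", "age", "sex", "region")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named, unordered collection of unique gene identifiers."""

    name: str
    genes: frozenset
    description: str = ""

    @classmethod
    def from_members(cls, name: str, members: Iterable[str], description: str = "") -> "GeneSet":
        """Build a set from an iterable, deduplicating with a logged warning."""
        members = list(members)
        unique = frozenset(members)
        if len(unique) < len(members):
            logger.warning("gene set %r: %d duplicate members removed",
                           name, len(members) - len(unique))
        return cls(name=name, genes=unique, description=description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))


class GeneSetCollection:
    """An ordered mapping of set name -> :class:`GeneSet` with unique names."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {s.name: s.genes for s in self} == {s.name: s.genes for s in other}


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line)."""
    collection = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}")
            name, description = fields[0], fields[1]
            gene_set = GeneSet.from_members(name, fields[2:], description)
            try:
                collection.add(gene_set)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene_set in collection:
            fields = [gene_set.name, gene_set.description, *sorted(gene_set.genes)]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# expression / detection matrices
# ---------------------------------------------------------------------------

def _check_unique(labels, kind: str, where: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ParseError(f"{where}: duplicate {kind} label {lab!r}")
        seen.add(lab)


def read_expression(path, has_detection: bool = False,
                    detection_suffix: str = ".Detection"):
    """Read a genes x samples TSV matrix.

    When ``has_detection`` is true, columns whose header ends with
    ``detection_suffix`` are split into a second, identically-labelled
    detection p-value matrix and the suffix is stripped.

    Returns ``(expr, detection)`` where ``detection`` is ``None`` unless
    requested.  Ragged rows, duplicate labels and non-numeric cells raise
    :class:`ParseError` with row/column coordinates.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header must name at least one sample")
        columns = header[1:]
        _check_unique(columns, "sample", f"{path}: header")
        ncol = len(columns)
        index: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncol + 1} fields, got {len(fields)}")
            index.append(fields[0])
            rows.append(fields[1:])
    _check_unique(index, "gene", f"{path}: first column")
    values = np.empty((len(rows), ncol), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: row {index[i]!r}, column {columns[j]!r}: "
                    f"non-numeric cell {cell!r}") from None
    df = pd.DataFrame(values, index=pd.Index(index, name="gene_id"), columns=columns)
    if not has_detection:
        return df, None
    det_cols = [c for c in df.columns if c.endswith(detection_suffix)]
    expr_cols = [c for c in df.columns if not c.endswith(detection_suffix)]
    detection = df[det_cols].copy()
    detection.columns = [c[: -len(detection_suffix)] for c in det_cols]
    expr = df[expr_cols]
    missing = set(expr.columns) ^ set(detection.columns)
    if missing:
        raise ParseError(f"{path}: unpaired expression/detection columns: {sorted(missing)}")
    detection = detection[expr.columns.tolist()]
    return expr, detection


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def write_expression_with_detection(expr: pd.DataFrame, detection: pd.DataFrame,
                                    path, detection_suffix: str = ".Detection") -> None:
    """Write expression and detection p-values interleaved into one TSV."""
    if not expr.index.equals(detection.index) or list(expr.columns) != list(detection.columns):
        raise AlignmentError("expression and detection matrices are not aligned")
    det = detection.copy()
    det.columns = [c + detection_suffix for c in det.columns]
    pd.concat([expr, det], axis=1).to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (sample_id index, required columns)."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"metadata missing columns: {missing}")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise ParseError(f"metadata: duplicate sample_id {dup!r}")
    for col, levels in (("diagnosis", DIAGNOSIS_LEVELS), ("sex", SEX_LEVELS),
                        ("region", REGION_LEVELS)):
        bad = set(meta[col].unique()) - set(levels)
        if bad:
            raise ParseError(f"metadata column {col!r}: invalid levels {sorted(bad)}")
    for col, lower in (("RIN", 0.0), ("PMI", 0.0), ("age", 0.0)):
        vals = pd.to_numeric(meta[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"metadata column {col!r}: non-numeric value")
        if col == "RIN":
            if (vals <= lower).any():
                raise ParseError(f"metadata column 'RIN': values must be > 0")
        elif (vals < lower).any():
            raise ParseError(f"metadata column {col!r}: values must be >= {lower}")
    return meta


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col="sample_id")
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# probe -> gene maps
# ---------------------------------------------------------------------------

def read_gene_map(path) -> pd.DataFrame:
    """Read a two-column probe_id/gene_id TSV; fully duplicated rows dropped."""
    gm = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["probe_id", "gene_id"]
    if list(gm.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(gm.columns)}")
    before = len(gm)
    gm = gm.drop_duplicates().reset_index(drop=True)
    if len(gm) < before:
        logger.warning("gene map %s: %d fully duplicated rows dropped", path, before - len(gm))
    return gm


def write_gene_map(gene_map: pd.DataFrame, path) -> None:
    gene_map.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align(matrix: pd.DataFrame, meta: pd.DataFrame):
    """Restrict a matrix and metadata to their common samples, matrix order.

    Returns the aligned ``(matrix, meta)`` pair.  Raises
    :class:`AlignmentError` when no samples are shared.  Dropped samples on
    either side are logged.
    """
    common = [s for s in matrix.columns if s in meta.index]
    if not common:
        raise AlignmentError("expression matrix and metadata share no sample ids")
    dropped_expr = [s for s in matrix.columns if s not in meta.index]
    dropped_meta = [s for s in meta.index if s not in set(matrix.columns)]
    if dropped_expr:
        logger.info("align: dropped %d expression samples without metadata: %s",
                    len(dropped_expr), dropped_expr[:10])
    if dropped_meta:
        logger.info("align: dropped %d metadata rows without expression: %s",
                    len(dropped_meta), dropped_meta[:10])
    return matrix[common], meta.loc[common]
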