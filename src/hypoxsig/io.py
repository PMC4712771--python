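"""Readers, writers and in-memory containers for every tabular artifact.

All files are tab-delimited UTF-8 with a header row; gene and sample
identifiers are opaque strings (no ID translation is attempted). Matrices
are stored genes-in-rows; a transposed file is a user error, not
auto-detected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSet",
    "GeneSetCollection",
    "read_count_matrix",
    "read_gmt",
    "read_cohort",
    "write_count_matrix",
    "write_expression_matrix",
    "write_gmt",
]

TISSUES = ("tumour", "normal")
OUTCOMES = ("disease_free", "recurred_progressed", "unknown")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} IDs: {dups[:5]}")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with a condition label per sample.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``condition_of`` maps every sample ID to its condition label.
    """

    counts: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise FormatError("count matrix has no genes")
        if self.counts.shape[1] == 0:
            raise FormatError("count matrix has no samples")
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        if not all(np.issubdtype(dt, np.integer) for dt in self.counts.dtypes):
            raise FormatError("count matrix must contain integer counts only")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("count matrix contains negative counts")
        missing = [s for s in self.counts.columns if s not in self.condition_of]
        if missing:
            raise ConsistencyError(
                f"samples missing from sample sheet: {missing}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> pd.Series:
        """Condition label per sample, in column order."""
        return pd.Series(
            [self.condition_of[s] for s in self.counts.columns],
            index=self.counts.columns,
            name="condition",
        )

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]


@dataclass
class ExpressionMatrix:
    """Non-negative real gene x sample matrix of normalized expression."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0:
            raise FormatError("expression matrix has no genes")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise FormatError("expression matrix contains NaN or infinite values")
        if (arr < 0).any():
            raise FormatError("expression matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-sample tissue (tumour/normal) and outcome annotation."""

    table: pd.DataFrame  # index: sample_id; columns: tissue, outcome

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for col in ("tissue", "outcome"):
            if col not in self.table.columns:
                raise FormatError(f"clinical table lacks column {col!r}")
        bad_t = set(self.table["tissue"]) - set(TISSUES)
        if bad_t:
            raise FormatError(f"unknown tissue labels: {sorted(bad_t)}")
        bad_o = set(self.table["outcome"]) - set(OUTCOMES)
        if bad_o:
            raise FormatError(f"unknown outcome labels: {sorted(bad_o)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_with_outcome(self, outcome: str) -> list[str]:
        return list(self.table.index[self.table["outcome"] == outcome])


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named pathway -> member gene-ID sets, as parsed from GMT."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def read_count_matrix(path, sample_sheet_path) -> CountMatrix:
    """Read a TSV count matrix plus a ``sample<TAB>condition`` sheet.

    Rejects non-integer or negative cells (naming the offending row and
    column), duplicate IDs, and samples absent from the sheet.
    """
    raw = _read_tsv(path)
    if raw.shape[0] == 0:
        raise FormatError(f"{path}: no gene rows")
    _check_unique(raw.index, "gene")
    _check_unique(raw.columns, "sample")
    counts = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            as_float = raw[col].astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in column {col!r}: {exc}") from exc
        frac = as_float != np.floor(as_float)
        if frac.any() or not np.isfinite(as_float).all():
            gene = raw.index[frac.argmax()]
            raise FormatError(
                f"{path}: non-integer count at gene {gene!r}, sample {col!r}"
            )
        if (as_float < 0).any():
            gene = raw.index[(as_float < 0).argmax()]
            raise FormatError(
                f"{path}: negative count at gene {gene!r}, sample {col!r}"
            )
        counts[col] = as_float.astype(np.int64)

    sheet = pd.read_csv(sample_sheet_path, sep="\t", header=0, dtype=str)
    if sheet.shape[1] < 2:
        raise FormatError(f"{sample_sheet_path}: expected sample<TAB>condition")
    sheet.columns = [c.strip() for c in sheet.columns]
    scol, ccol = sheet.columns[:2]
    _check_unique(sheet[scol], "sample-sheet sample")
    condition_of = dict(zip(sheet[scol], sheet[ccol]))
    return CountMatrix(counts=counts, condition_of=condition_of)


def write_count_matrix(cm: CountMatrix, path, sample_sheet_path=None) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")
    if sample_sheet_path is not None:
        cm.conditions.rename_axis("sample").to_frame().to_csv(
            sample_sheet_path, sep="\t"
        )


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_matrix(path) -> ExpressionMatrix:
    raw = _read_tsv(path)
    try:
        vals = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell: {exc}") from exc
    return ExpressionMatrix(values=vals)


def read_gmt(path) -> GeneSetCollection:
    """Parse standard GMT: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a set are removed; a line with fewer than three
    fields is a format error naming the line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and "
                    f"at least one gene, got {len(fields)} fields"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = GeneSet(name=name, description=desc, genes=genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def read_cohort(expr_path, clinical_path) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Read a cohort expression matrix and its clinical annotation.

    Clinical rows for samples absent from the matrix are retained with a
    warning (cohorts are routinely subset), and matrix samples lacking a
    clinical row are likewise flagged with a warning.
    """
    expr = read_expression_matrix(expr_path)
    raw = pd.read_csv(clinical_path, sep="\t", header=0, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    if raw.shape[1] < 3:
        raise FormatError(
            f"{clinical_path}: expected sample<TAB>tissue<TAB>outcome"
        )
    raw = raw.set_index(raw.columns[0])
    annot = raw.iloc[:, :2].copy()
    annot.columns = ["tissue", "outcome"]
    clinical = ClinicalTable(table=annot)
    extra = set(clinical.sample_ids) - set(expr.sample_ids)
    if extra:
        warnings.warn(
            f"{len(extra)} clinical rows refer to samples absent from the "
            f"expression matrix (retained): {sorted(extra)[:5]}",
            stacklevel=2,
        )
    unannotated = set(expr.sample_ids) - set(clinical.sample_ids)
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} expression samples have no clinical row: "
            f"{sorted(unannotated)[:5]}",
            stacklevel=2,
        )
    return expr, clinical
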