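"""Containers and readers for matched miRNA/mRNA expression profiles.

The anti-correlation screen downstream operates on two feature × sample
matrices profiled on the same patients: probe-level mRNA signal from a
microarray (one gene may be represented by one to three probe sets) and
miRNA abundance from qPCR-style assays. This module reads those matrices
from plain TSV (or GEO series-matrix-style) files, attaches probe → gene
annotation, restricts both platforms to their shared samples in a common
order, and applies the optional log2 transform.

Missing values are carried as NaN and handled pairwise-complete downstream;
they are never silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionIOError",
    "DuplicateIdError",
    "NonNumericCellError",
    "ExpressionMatrix",
    "SampleMetadata",
    "MatchedCohort",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_annotation",
    "read_sample_metadata",
    "attach_probe_annotation",
    "match_samples",
    "log_transform",
    "ct_to_log2_abundance",
]

LINEAR = "linear"
LOG2 = "log2"

GROUP_VOCABULARY = frozenset({"tumor", "normal"})


class ExpressionIOError(ValueError):
    """Malformed expression input."""


class DuplicateIdError(ExpressionIOError):
    """A feature or sample identifier occurs more than once."""


class NonNumericCellError(ExpressionIOError):
    """A matrix cell is neither numeric nor empty."""


@dataclass
class ExpressionMatrix:
    """A feature × sample numeric expression table.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (probe-set id or miRNA name) with
        one column per sample. NaN marks an explicitly missing cell.
    scale
        ``"linear"`` or ``"log2"``.
    platform
        Free-text platform tag (e.g. ``"affymetrix-u133a-mas5"``).
    gene_symbols
        Optional Series mapping a subset of feature ids to upper-cased gene
        symbols. Features absent from the Series are *unmapped*, which is a
        state, not an error.
    """

    values: pd.DataFrame
    scale: str = LINEAR
    platform: str = ""
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_f = idx[idx.duplicated()].unique().tolist()
        if dup_f:
            raise DuplicateIdError(f"duplicate feature id(s): {dup_f}")
        dup_s = cols[cols.duplicated()].unique().tolist()
        if dup_s:
            raise DuplicateIdError(f"duplicate sample id(s): {dup_s}")
        if self.scale not in (LINEAR, LOG2):
            raise ExpressionIOError(f"unknown scale {self.scale!r}")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise NonNumericCellError(str(exc)) from exc
        if np.isinf(self.values.to_numpy()).any():
            raise ExpressionIOError("infinite value in expression matrix")
        if self.gene_symbols is not None:
            extra = self.gene_symbols.index.difference(idx).tolist()
            if extra:
                raise ExpressionIOError(
                    f"annotation refers to unknown feature(s): {extra}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def symbol_of(self, feature_id: str) -> str | None:
        """Gene symbol for a feature, or None if unmapped."""
        if self.gene_symbols is None or feature_id not in self.gene_symbols.index:
            return None
        return str(self.gene_symbols.loc[feature_id])

    def unmapped_features(self) -> list[str]:
        if self.gene_symbols is None:
            return self.feature_ids
        return [f for f in self.feature_ids if f not in self.gene_symbols.index]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in self.values.columns]
        if missing:
            raise ExpressionIOError(f"unknown sample id(s): {missing}")
        return replace(self, values=self.values.loc[:, wanted])


@dataclass
class SampleMetadata:
    """sample id → group label, labels drawn from {tumor, normal}."""

    groups: Mapping[str, str]
    cohort: str = ""

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in GROUP_VOCABULARY}
        if bad:
            raise ExpressionIOError(
                f"group label(s) {sorted(bad)} outside vocabulary {sorted(GROUP_VOCABULARY)}"
            )
        self.groups = dict(self.groups)

    def group_of(self, sample_id: str) -> str:
        return self.groups[sample_id]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def restrict(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        keep = {s: self.groups[s] for s in sample_ids if s in self.groups}
        return SampleMetadata(groups=keep, cohort=self.cohort)


@dataclass
class MatchedCohort:
    """mRNA and miRNA matrices over the same samples in the same order."""

    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    metadata: SampleMetadata | None = None

    def __post_init__(self) -> None:
        if self.mrna.sample_ids != self.mirna.sample_ids:
            raise ExpressionIOError(
                "matched cohort requires identical sample ids in identical order"
            )
        if self.n < 3:
            raise ExpressionIOError(
                f"cohort has {self.n} shared samples; need at least 3 for correlation"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.mrna.sample_ids

    @property
    def n(self) -> int:
        return self.mrna.n_samples


def _parse_table_lines(lines: list[list[str]], path: str) -> pd.DataFrame:
    header = lines[0]
    sample_ids = header[1:]
    dup = pd.Index(sample_ids)
    dup = dup[dup.duplicated()].unique().tolist()
    if dup:
        raise DuplicateIdError(f"{path}: duplicate sample id(s) in header: {dup}")
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for row_no, fields in enumerate(lines[1:], start=2):
        if not fields or (len(fields) == 1 and fields[0] == ""):
            continue
        fid = fields[0]
        if fid in seen:
            raise DuplicateIdError(f"{path}: duplicate feature id {fid!r} at row {row_no}")
        seen.add(fid)
        cells = fields[1:]
        if len(cells) != len(sample_ids):
            raise ExpressionIOError(
                f"{path}: row {row_no} has {len(cells)} cells, expected {len(sample_ids)}"
            )
        parsed: list[float] = []
        for col_no, cell in enumerate(cells):
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN", "NULL"}:
                parsed.append(math.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise NonNumericCellError(
                    f"{path}: non-numeric cell {cell!r} at row {row_no} "
                    f"(feature {fid!r}), column {col_no + 2} (sample {sample_ids[col_no]!r})"
                ) from None
        feature_ids.append(fid)
        rows.append(parsed)
    values = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=float)
    return values


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv_matrix",
    scale: str = LINEAR,
    platform: str = "",
) -> ExpressionMatrix:
    """Read a feature × sample matrix from TSV.

    Dialects
    --------
    ``tsv_matrix``
        Row 1 is ``feature_id`` followed by sample ids; one feature per
        subsequent row; the empty string marks a missing cell.
    ``series_matrix``
        GEO series-matrix style: lines starting with ``!`` (metadata and
        table delimiters) are skipped and identifiers may be double-quoted.
    """
    path = Path(path)
    if dialect not in ("tsv_matrix", "series_matrix"):
        raise ExpressionIOError(f"unknown dialect {dialect!r}")
    raw = path.read_text(encoding="utf-8").splitlines()
    lines: list[list[str]] = []
    for line in raw:
        if dialect == "series_matrix":
            if line.startswith("!") or not line.strip():
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
        else:
            if not line.strip():
                continue
            fields = line.split("\t")
        lines.append(fields)
    if not lines:
        raise ExpressionIOError(f"{path}: no table content")
    values = _parse_table_lines(lines, str(path))
    return ExpressionMatrix(values=values, scale=scale, platform=platform)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the canonical TSV dialect (empty string for missing cells)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in matrix.values.iterrows():
            cells = ["" if pd.isna(v) else repr(float(v)) for v in row.to_numpy()]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def read_probe_annotation(path: str | Path) -> dict[str, str]:
    """TSV with columns probe_id, gene_symbol → mapping (symbols upper-cased)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_symbol"}
    if not required.issubset(table.columns):
        raise ExpressionIOError(
            f"annotation file needs columns {sorted(required)}, got {list(table.columns)}"
        )
    mapping: dict[str, str] = {}
    for probe, symbol in zip(table["probe_id"], table["gene_symbol"]):
        if pd.isna(symbol) or not str(symbol).strip():
            continue
        if probe in mapping and mapping[probe] != str(symbol).strip().upper():
            raise ExpressionIOError(f"probe {probe!r} maps to more than one symbol")
        mapping[str(probe)] = str(symbol).strip().upper()
    return mapping


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """TSV with columns sample_id, group."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(table.columns):
        raise ExpressionIOError(
            f"metadata file needs columns {sorted(required)}, got {list(table.columns)}"
        )
    return SampleMetadata(
        groups={str(s): str(g).strip().lower() for s, g in zip(table["sample_id"], table["group"])}
    )


def attach_probe_annotation(
    matrix: ExpressionMatrix, annotation: Mapping[str, str]
) -> ExpressionMatrix:
    """Attach probe → gene-symbol annotation to a probe-level matrix.

    Probe ids match case-sensitively; symbols are canonicalised to upper
    case (public tables mix cases). Probes absent from the annotation are
    retained and flagged unmapped.
    """
    mapped: dict[str, str] = {}
    for fid in matrix.feature_ids:
        if fid in annotation:
            symbol = str(annotation[fid]).strip()
            if not symbol:
                raise ExpressionIOError(f"empty gene symbol for probe {fid!r}")
            mapped[fid] = symbol.upper()
    series = pd.Series(mapped, dtype=object) if mapped else pd.Series(dtype=object)
    return replace(matrix, gene_symbols=series)


def match_samples(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    meta: SampleMetadata | None = None,
) -> MatchedCohort:
    """Restrict both platforms to their shared samples, mRNA order first.

    Idempotent: matching an already-matched cohort changes nothing.
    """
    if mrna.n_samples == 0 or mirna.n_samples == 0:
        raise ExpressionIOError("cannot match empty expression matrices")
    mirna_set = set(mirna.sample_ids)
    shared = [s for s in mrna.sample_ids if s in mirna_set]
    if len(shared) < 3:
        raise ExpressionIOError(
            f"only {len(shared)} shared sample(s) between platforms; "
            "need at least 3 for correlation"
        )
    cohort_meta = meta.restrict(shared) if meta is not None else None
    return MatchedCohort(
        mrna=mrna.subset_samples(shared),
        mirna=mirna.subset_samples(shared),
        metadata=cohort_meta,
    )


def log_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset) on a linear-scale matrix.

    Strictly monotone, so within-row value ordering is preserved. Refuses
    to double-transform and names the first offending cell when
    value + offset ≤ 0.
    """
    if matrix.scale == LOG2:
        raise ExpressionIOError("matrix is already on the log2 scale")
    vals = matrix.values.to_numpy()
    bad = np.argwhere((vals + offset <= 0) & ~np.isnan(vals))
    if bad.size:
        i, j = bad[0]
        raise ExpressionIOError(
            f"value {vals[i, j]} + offset {offset} is not positive at "
            f"feature {matrix.feature_ids[i]!r}, sample {matrix.sample_ids[j]!r}"
        )
    out = matrix.values.copy()
    out.loc[:, :] = np.log2(vals + offset)
    return replace(matrix, values=out, scale=LOG2)


def ct_to_log2_abundance(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a Ct-valued miRNA matrix to a log2-abundance-like scale.

    Ct is the qPCR cycle at which fluorescence crosses threshold and is
    inversely related to template abundance; negating it gives values that
    increase with abundance (up to an additive constant), which fixes the
    sign convention of every downstream correlation.
    """
    out = matrix.values.copy() * -1.0
    return replace(matrix, values=out, scale=LOG2)
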