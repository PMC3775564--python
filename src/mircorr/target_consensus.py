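"""Consensus miRNA target nomination from predictions plus anti-correlation.

A (miRNA, gene) pair becomes a candidate target when at least one of the
four sequence-based prediction sources (TargetScan, PicTar, miRDB,
microRNA.org) lists it AND at least one probe of that gene shows a
significant NEGATIVE expression correlation with the miRNA in the matched
cohort. Pairs whose only significant correlations are positive are
excluded. Experimental-validation status (TarBase-style catalogue) is an
annotation, never an inclusion gate.

3′UTR binding-site records (miRNA, gene, UTR interval, mirSVR score,
PhastCons conservation) are filtered with inclusive cutoffs — the default
keeps sites with mirSVR <= 0 and PhastCons >= 0 — and counted per pair
after collapsing records at identical coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .correlation_engine import CorrelationResult

__all__ = [
    "PREDICTION_SOURCES",
    "PredictionRecord",
    "ValidatedTargetRecord",
    "BindingSiteThresholds",
    "BindingSiteRecord",
    "ConsensusTarget",
    "normalize_mirna_id",
    "normalize_prediction_table",
    "read_validated_targets",
    "read_binding_sites",
    "build_candidate_pairs",
    "annotate_validation_status",
    "filter_binding_sites",
    "count_binding_sites",
    "attach_binding_site_counts",
    "consensus_to_frame",
]

logger = logging.getLogger(__name__)

PREDICTION_SOURCES = ("targetscan", "pictar", "mirdb", "microrna_org")

# per-source column aliases for exported tables; the canonical schema is
# (source, mirna_id, gene_symbol, score)
_COLUMN_ALIASES: dict[str, str] = {
    "mirna_id": "mirna_id",
    "mirna": "mirna_id",
    "mirna_name": "mirna_id",
    "mir_family": "mirna_id",
    "microrna": "mirna_id",
    "gene_symbol": "gene_symbol",
    "gene": "gene_symbol",
    "symbol": "gene_symbol",
    "target_gene": "gene_symbol",
    "gene_name": "gene_symbol",
    "score": "score",
    "context_score": "score",
    "pictar_score": "score",
    "target_score": "score",
    "mirsvr_score": "score",
}

_MIR_RE = re.compile(r"^(?P<prefix>[a-z]{3}-)?(?P<kind>mir|let)-?(?P<rest>.+)$")


def normalize_mirna_id(name: str) -> str:
    """Canonicalise a miRNA name to the ``hsa-miR-…`` / ``hsa-let-…`` form.

    ``miR-200a``, ``hsa-mir-200b``, ``MIR200C`` all map to their
    ``hsa-miR-200x`` spelling; unparsable names are returned stripped but
    otherwise untouched.
    """
    raw = name.strip()
    m = _MIR_RE.match(raw.lower())
    if m is None:
        return raw
    prefix = m.group("prefix") or "hsa-"
    kind = "miR" if m.group("kind") == "mir" else "let"
    return f"{prefix}{kind}-{m.group('rest')}"


@dataclass(frozen=True)
class PredictionRecord:
    """One (source, miRNA, gene) prediction after normalization."""

    source: str
    mirna_id: str
    gene_symbol: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in PREDICTION_SOURCES:
            raise ValueError(
                f"unknown prediction source {self.source!r}; "
                f"expected one of {PREDICTION_SOURCES}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_symbol)


@dataclass(frozen=True)
class ValidatedTargetRecord:
    """One experimentally supported (miRNA, gene) interaction."""

    mirna_id: str
    gene_symbol: str
    evidence: str = ""


@dataclass(frozen=True)
class BindingSiteThresholds:
    """Inclusive cutoffs for 3′UTR site retention.

    Defaults keep sites with mirSVR score <= 0 (predicted repression) and
    PhastCons conservation >= 0 (i.e. no conservation floor).
    """

    mirsvr_max: float = 0.0
    phastcons_min: float = 0.0


@dataclass(frozen=True)
class BindingSiteRecord:
    """A predicted miRNA site in a gene's 3′UTR (1-based inclusive coords)."""

    mirna_id: str
    gene_symbol: str
    utr_start: int
    utr_end: int
    mirsvr: float
    phastcons: float
    duplex: str | None = None

    def __post_init__(self) -> None:
        if self.utr_start > self.utr_end:
            raise ValueError(
                f"utr_start {self.utr_start} > utr_end {self.utr_end} "
                f"for {self.mirna_id}/{self.gene_symbol}"
            )
        if not 0.0 <= self.phastcons <= 1.0:
            raise ValueError(f"phastcons must be in [0, 1], got {self.phastcons}")


@dataclass
class ConsensusTarget:
    """A nominated (miRNA, gene) pair with its supporting evidence."""

    mirna_id: str
    gene_symbol: str
    supporting_sources: tuple[str, ...]
    supporting_probes: tuple[str, ...]
    min_r: float
    validated: bool = False
    binding_site_count: int = 0

    def __post_init__(self) -> None:
        if not self.supporting_sources:
            raise ValueError("consensus target needs at least one prediction source")
        if not self.supporting_probes:
            raise ValueError("consensus target needs at least one supporting probe")
        if not self.min_r < 0:
            raise ValueError(f"min_r must be negative, got {self.min_r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_symbol)


def normalize_prediction_table(
    path: str | Path, source: str
) -> list[PredictionRecord]:
    """Read one source's export and normalise to canonical records.

    Column names are mapped through per-source aliases, miRNA names through
    :func:`normalize_mirna_id`, gene symbols are upper-cased, and duplicate
    (source, miRNA, gene) rows collapse to the first occurrence. Rows with
    a missing miRNA or gene are skipped and counted in a warning.
    """
    if source not in PREDICTION_SOURCES:
        raise ValueError(
            f"unknown prediction source {source!r}; expected one of {PREDICTION_SOURCES}"
        )
    table = pd.read_csv(path, sep="\t", dtype=str)
    renames = {
        col: _COLUMN_ALIASES[col.strip().lower()]
        for col in table.columns
        if col.strip().lower() in _COLUMN_ALIASES
    }
    table = table.rename(columns=renames)
    if "mirna_id" not in table.columns or "gene_symbol" not in table.columns:
        raise ValueError(
            f"{path}: cannot locate miRNA/gene columns in {list(table.columns)}"
        )
    records: list[PredictionRecord] = []
    seen: set[tuple[str, str]] = set()
    skipped = 0
    for row in table.itertuples(index=False):
        mirna = getattr(row, "mirna_id")
        gene = getattr(row, "gene_symbol")
        if pd.isna(mirna) or pd.isna(gene) or not str(mirna).strip() or not str(gene).strip():
            skipped += 1
            continue
        score_raw = getattr(row, "score", None)
        score: float | None = None
        if score_raw is not None and not pd.isna(score_raw) and str(score_raw).strip():
            try:
                score = float(score_raw)
            except ValueError:
                skipped += 1
                continue
        rec = PredictionRecord(
            source=source,
            mirna_id=normalize_mirna_id(str(mirna)),
            gene_symbol=str(gene).strip().upper(),
            score=score,
        )
        if rec.key in seen:
            continue
        seen.add(rec.key)
        records.append(rec)
    if skipped:
        logger.warning("%s: skipped %d unmappable row(s)", path, skipped)
    return records


def read_validated_targets(path: str | Path) -> list[ValidatedTargetRecord]:
    """TSV with columns mirna_id, gene_symbol[, evidence] → catalogue records."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "mirna_id" not in table.columns or "gene_symbol" not in table.columns:
        raise ValueError(f"{path}: needs columns mirna_id, gene_symbol")
    out: list[ValidatedTargetRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in table.itertuples(index=False):
        rec = ValidatedTargetRecord(
            mirna_id=normalize_mirna_id(str(row.mirna_id)),
            gene_symbol=str(row.gene_symbol).strip().upper(),
            evidence=str(getattr(row, "evidence", "") or ""),
        )
        key = (rec.mirna_id, rec.gene_symbol)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def read_binding_sites(path: str | Path) -> list[BindingSiteRecord]:
    """TSV columns mirna_id, gene_symbol, utr_start, utr_end, mirsvr, phastcons."""
    table = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "gene_symbol", "utr_start", "utr_end", "mirsvr", "phastcons"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    return [
        BindingSiteRecord(
            mirna_id=normalize_mirna_id(str(row.mirna_id)),
            gene_symbol=str(row.gene_symbol).strip().upper(),
            utr_start=int(row.utr_start),
            utr_end=int(row.utr_end),
            mirsvr=float(row.mirsvr),
            phastcons=float(row.phastcons),
        )
        for row in table.itertuples(index=False)
    ]


def build_candidate_pairs(
    predictions: Iterable[PredictionRecord],
    correlations: Iterable[CorrelationResult],
) -> list[ConsensusTarget]:
    """Intersect predictions with significant negative probe correlations.

    ``correlations`` must already have passed the significance filter. A
    pair is emitted iff >=1 source predicts it and >=1 probe of the gene
    correlates negatively (significantly) with the miRNA; the supporting
    source set and probe set are recorded, along with the most negative
    supporting r. Matching is case-insensitive on gene symbols.
    """
    support: dict[tuple[str, str], dict[str, float]] = {}
    for res in correlations:
        if res.gene_symbol is None or res.r >= 0:
            continue
        key = (res.mirna_id, res.gene_symbol.upper())
        probes = support.setdefault(key, {})
        if res.probe_id not in probes or res.r < probes[res.probe_id]:
            probes[res.probe_id] = res.r

    by_pair: dict[tuple[str, str], set[str]] = {}
    for pred in predictions:
        key = (pred.mirna_id, pred.gene_symbol.upper())
        by_pair.setdefault(key, set()).add(pred.source)

    out: list[ConsensusTarget] = []
    for key in sorted(by_pair):
        probes = support.get(key)
        if not probes:
            continue
        out.append(
            ConsensusTarget(
                mirna_id=key[0],
                gene_symbol=key[1],
                supporting_sources=tuple(
                    s for s in PREDICTION_SOURCES if s in by_pair[key]
                ),
                supporting_probes=tuple(sorted(probes)),
                min_r=min(probes.values()),
            )
        )
    return out


def annotate_validation_status(
    pairs: Iterable[ConsensusTarget],
    validated: Iterable[ValidatedTargetRecord],
) -> list[ConsensusTarget]:
    """Flag pairs present in the validated-target catalogue.

    Annotation only — it never gates inclusion. Symbol matching is
    case-insensitive.
    """
    catalogue = {
        (rec.mirna_id, rec.gene_symbol.upper()) for rec in validated
    }
    return [
        replace(p, validated=(p.mirna_id, p.gene_symbol.upper()) in catalogue)
        for p in pairs
    ]


def filter_binding_sites(
    records: Iterable[BindingSiteRecord],
    thresholds: BindingSiteThresholds = BindingSiteThresholds(),
) -> list[BindingSiteRecord]:
    """Keep sites with mirsvr <= mirsvr_max AND phastcons >= phastcons_min.

    Both cutoffs are inclusive, so the (0, 0) boundary site is kept under
    the defaults. Tightening either threshold never increases any count.
    """
    return [
        rec
        for rec in records
        if rec.mirsvr <= thresholds.mirsvr_max
        and rec.phastcons >= thresholds.phastcons_min
    ]


def count_binding_sites(
    gene_symbol: str,
    mirna_id: str,
    records: Iterable[BindingSiteRecord],
) -> int:
    """Number of retained sites for (gene, miRNA).

    Records at identical (start, end) coordinates collapse to one;
    overlapping-but-distinct sites count separately.
    """
    gene = gene_symbol.strip().upper()
    mirna = normalize_mirna_id(mirna_id)
    intervals = {
        (rec.utr_start, rec.utr_end)
        for rec in records
        if rec.gene_symbol.upper() == gene and rec.mirna_id == mirna
    }
    return len(intervals)


def attach_binding_site_counts(
    pairs: Iterable[ConsensusTarget],
    records: Iterable[BindingSiteRecord],
    thresholds: BindingSiteThresholds = BindingSiteThresholds(),
) -> list[ConsensusTarget]:
    """Filter site records once, then stamp per-pair counts on the targets."""
    retained = filter_binding_sites(records, thresholds)
    return [
        replace(
            p,
            binding_site_count=count_binding_sites(p.gene_symbol, p.mirna_id, retained),
        )
        for p in pairs
    ]


def consensus_to_frame(pairs: Iterable[ConsensusTarget]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": p.mirna_id,
            "gene_symbol": p.gene_symbol,
            "sources": ",".join(p.supporting_sources),
            "n_sources": len(p.supporting_sources),
            "supporting_probes": ",".join(p.supporting_probes),
            "min_r": p.min_r,
            "validated": p.validated,
            "binding_site_count": p.binding_site_count,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "gene_symbol", "sources", "n_sources",
            "supporting_probes", "min_r", "validated", "binding_site_count",
        ],
    )
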