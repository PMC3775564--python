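"""Quantification arithmetic for wet-lab target validation.

Implements the Livak relative-quantification chain for qPCR,

    ΔCt   = Ct(target gene) − Ct(endogenous control gene)
    ΔΔCt  = mean ΔCt(treated) − mean ΔCt(control)
    fold  = 2^(−ΔΔCt),

western-blot densitometry normalised to a loading control and expressed
relative to the scrambled-miRNA reference condition, tumor-vs-normal fold
change with an unpaired t-test, and the confirmed-target decision: a
predicted gene counts as confirmed when its mRNA is significantly
downregulated OR its protein drops by at least 15% relative to the
negative control.

Endogenous controls are parameters throughout (the study used U47 for
miRNA and UBC for mRNA), never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, SampleMetadata, LOG2

__all__ = [
    "QuantError",
    "DEFAULT_MAX_CYCLES",
    "read_ct_table",
    "read_band_table",
    "FoldChangeResult",
    "ProteinLevelResult",
    "ConfirmationThresholds",
    "ConfirmationCall",
    "delta_delta_ct",
    "relative_protein_level",
    "confirm_target",
    "group_fold_change",
]

DEFAULT_MAX_CYCLES = 40.0


class QuantError(ValueError):
    """Malformed or incomplete quantification input."""


@dataclass
class FoldChangeResult:
    """2^−ΔΔCt relative expression of one gene under one treatment."""

    gene: str
    condition: str
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    fold: float
    p: float | None
    n_replicates: int
    censored: bool = False  # a Ct at the detection limit entered the fold


@dataclass
class ProteinLevelResult:
    """Densitometry level relative to the reference condition."""

    protein: str
    condition: str
    relative_level: float
    percent_change: float  # 100 * (1 - relative_level); positive = down


@dataclass(frozen=True)
class ConfirmationThresholds:
    """Decision rule parameters for the confirmed-target call."""

    mrna_alpha: float = 0.05
    protein_down_min: float = 0.15  # fractional decrease

    def __post_init__(self) -> None:
        if not 0 < self.mrna_alpha < 1:
            raise ValueError(f"mrna_alpha must be in (0, 1), got {self.mrna_alpha}")
        if not 0 < self.protein_down_min < 1:
            raise ValueError(
                f"protein_down_min must be in (0, 1), got {self.protein_down_min}"
            )


@dataclass
class ConfirmationCall:
    """Outcome of the mRNA-or-protein confirmation rule for one pair."""

    gene: str
    mirna: str
    predicted: bool
    mrna_down_significant: bool
    protein_down_meets_threshold: bool
    confirmed: bool


def read_ct_table(path: str | Path, max_cycles: float = DEFAULT_MAX_CYCLES) -> pd.DataFrame:
    """TSV with columns replicate_id, condition, gene, ct."""
    table = pd.read_csv(path, sep="\t", dtype={"replicate_id": str, "condition": str, "gene": str})
    return validate_ct_table(table, max_cycles=max_cycles)


def validate_ct_table(table: pd.DataFrame, max_cycles: float = DEFAULT_MAX_CYCLES) -> pd.DataFrame:
    required = {"replicate_id", "condition", "gene", "ct"}
    if not required.issubset(table.columns):
        raise QuantError(f"Ct table needs columns {sorted(required)}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any():
        raise QuantError("non-numeric Ct value in table")
    if ((ct <= 0) | (ct > max_cycles)).any():
        bad = table.loc[(ct <= 0) | (ct > max_cycles)].iloc[0]
        raise QuantError(
            f"Ct {bad['ct']} for gene {bad['gene']!r} outside (0, {max_cycles}]"
        )
    out = table.copy()
    out["ct"] = ct.astype(float)
    return out


def read_band_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns protein, condition, raw_intensity, loading_control_intensity."""
    table = pd.read_csv(path, sep="\t", dtype={"protein": str, "condition": str})
    required = {"protein", "condition", "raw_intensity", "loading_control_intensity"}
    if not required.issubset(table.columns):
        raise QuantError(f"band table needs columns {sorted(required)}")
    return table


def _replicate_delta_ct(
    table: pd.DataFrame, target_gene: str, control_gene: str, condition: str
) -> np.ndarray:
    """Per-replicate ΔCt = Ct(target) − Ct(control gene) within a condition."""
    sub = table[table["condition"] == condition]
    tgt = sub[sub["gene"] == target_gene].set_index("replicate_id")["ct"]
    ctl = sub[sub["gene"] == control_gene].set_index("replicate_id")["ct"]
    if tgt.empty:
        raise QuantError(f"missing Ct cell: gene {target_gene!r}, condition {condition!r}")
    if ctl.empty:
        raise QuantError(f"missing Ct cell: gene {control_gene!r}, condition {condition!r}")
    shared = tgt.index.intersection(ctl.index)
    if len(shared) == 0:
        raise QuantError(
            f"no replicate measures both {target_gene!r} and {control_gene!r} "
            f"in condition {condition!r}"
        )
    return (tgt.loc[shared] - ctl.loc[shared]).to_numpy(dtype=float)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    control_gene: str,
    treated_condition: str,
    control_condition: str,
    max_cycles: float = DEFAULT_MAX_CYCLES,
    equal_var: bool = False,
) -> FoldChangeResult:
    """Livak 2^−ΔΔCt fold change of ``target_gene`` under treatment.

    ΔCt is computed per replicate (replicate ids pair target and control
    gene wells), averaged per condition; ΔΔCt is the treated-minus-control
    difference of those means. The p-value is an unpaired t-test (Welch by
    default; ``equal_var=True`` pools variances) over the two replicate
    ΔCt sets; with a single replicate on either side the fold is still
    returned and p is flagged unavailable (None).

    Ct values sitting exactly at ``max_cycles`` are at the detection
    limit; the result is then flagged ``censored`` and its fold should be
    read as a bound, not a point value.
    """
    table = validate_ct_table(ct_table, max_cycles=max_cycles)
    d_treated = _replicate_delta_ct(table, target_gene, control_gene, treated_condition)
    d_control = _replicate_delta_ct(table, target_gene, control_gene, control_condition)
    involved = table[
        table["gene"].isin([target_gene, control_gene])
        & table["condition"].isin([treated_condition, control_condition])
    ]
    censored = bool((involved["ct"] == max_cycles).any())
    ddct = float(d_treated.mean() - d_control.mean())
    fold = 2.0 ** (-ddct)
    if len(d_treated) >= 2 and len(d_control) >= 2:
        p = float(stats.ttest_ind(d_treated, d_control, equal_var=equal_var).pvalue)
    else:
        p = None
    return FoldChangeResult(
        gene=target_gene,
        condition=treated_condition,
        delta_ct_treated=float(d_treated.mean()),
        delta_ct_control=float(d_control.mean()),
        delta_delta_ct=ddct,
        fold=fold,
        p=p,
        n_replicates=min(len(d_treated), len(d_control)),
        censored=censored,
    )


def relative_protein_level(
    bands: pd.DataFrame, reference_condition: str
) -> list[ProteinLevelResult]:
    """Loading-control-normalised band intensity relative to the reference.

    relative_level = (raw/loading) ÷ (raw/loading of the reference
    condition for the same protein); percent_change = 100·(1 − relative).
    Scale-invariant per lane: multiplying a lane's raw and loading
    intensities by any positive constant changes nothing. Multiple bands
    per (protein, condition) are averaged after normalization.
    """
    required = {"protein", "condition", "raw_intensity", "loading_control_intensity"}
    if not required.issubset(bands.columns):
        raise QuantError(f"band table needs columns {sorted(required)}")
    raw = pd.to_numeric(bands["raw_intensity"], errors="coerce")
    loading = pd.to_numeric(bands["loading_control_intensity"], errors="coerce")
    if raw.isna().any() or loading.isna().any():
        raise QuantError("non-numeric band intensity")
    if (raw <= 0).any() or (loading <= 0).any():
        raise QuantError("band intensities must be positive")
    work = bands.assign(normalized=raw / loading)
    results: list[ProteinLevelResult] = []
    for protein, group in work.groupby("protein", sort=True):
        ref = group[group["condition"] == reference_condition]
        if ref.empty:
            raise QuantError(
                f"reference condition {reference_condition!r} missing for protein {protein!r}"
            )
        ref_level = float(ref["normalized"].mean())
        for condition, sub in group.groupby("condition", sort=True):
            rel = float(sub["normalized"].mean()) / ref_level
            results.append(
                ProteinLevelResult(
                    protein=str(protein),
                    condition=str(condition),
                    relative_level=rel,
                    percent_change=100.0 * (1.0 - rel),
                )
            )
    return results


def confirm_target(
    mrna: FoldChangeResult | None,
    protein: ProteinLevelResult | None,
    thresholds: ConfirmationThresholds = ConfirmationThresholds(),
    gene: str | None = None,
    mirna: str = "",
    predicted: bool = True,
) -> ConfirmationCall:
    """Apply the confirmed-target rule to one (gene, miRNA) pair.

    mRNA arm: fold < 1 AND t-test p <= mrna_alpha. Protein arm:
    percent_change >= 100·protein_down_min (so exactly 15% passes the
    default, 14.9% does not). Confirmed is their disjunction; at least one
    arm must be provided.
    """
    if mrna is None and protein is None:
        raise QuantError("confirm_target needs an mRNA result, a protein result, or both")
    mrna_down = bool(
        mrna is not None
        and mrna.fold < 1.0
        and mrna.p is not None
        and mrna.p <= thresholds.mrna_alpha
    )
    protein_down = bool(
        protein is not None
        and protein.percent_change >= 100.0 * thresholds.protein_down_min
    )
    name = gene or (mrna.gene if mrna is not None else protein.protein)
    return ConfirmationCall(
        gene=name,
        mirna=mirna,
        predicted=predicted,
        mrna_down_significant=mrna_down,
        protein_down_meets_threshold=protein_down,
        confirmed=mrna_down or protein_down,
    )


def group_fold_change(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    feature_id: str,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Tumor-vs-normal fold change of one feature with an unpaired t-test.

    The fold is the ratio of group means on the linear scale (log2 values
    are back-transformed first); the two-sided t-test runs on the matrix's
    analysis scale as given (Welch by default). Both groups need at least
    2 samples.
    """
    if feature_id not in matrix.values.index:
        raise QuantError(f"unknown feature {feature_id!r}")
    row = matrix.values.loc[feature_id]
    tumor_ids = [s for s in matrix.sample_ids if meta.groups.get(s) == "tumor"]
    normal_ids = [s for s in matrix.sample_ids if meta.groups.get(s) == "normal"]
    tumor = row.loc[tumor_ids].dropna().to_numpy(dtype=float)
    normal = row.loc[normal_ids].dropna().to_numpy(dtype=float)
    if len(tumor) < 2 or len(normal) < 2:
        raise QuantError(
            f"need >=2 samples per group, got tumor={len(tumor)}, normal={len(normal)}"
        )
    if matrix.scale == LOG2:
        fold = float(np.mean(2.0 ** tumor) / np.mean(2.0 ** normal))
    else:
        fold = float(tumor.mean() / normal.mean())
    p = float(stats.ttest_ind(tumor, normal, equal_var=equal_var).pvalue)
    return fold, p
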