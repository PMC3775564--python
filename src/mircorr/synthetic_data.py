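"""Synthetic matched cohorts with planted miRNA→target repression.

The generator emulates the statistical structure the screen assumes — not
array chemistry. On the log2 scale:

* each miRNA's abundance is Normal(baseline + tumor_shift·[tumor], mirna_sd²)
  per sample; tumor shifts apply only to designated miRNAs (the three
  miR-200s by default, at the magnitudes seen in squamous-cell tumors);
* each gene has a latent signal of fixed variance ``gene_sd²``. For a
  planted (miRNA, gene) pair the signal borrows a slope
  β = r·sqrt(gene_sd² + noise_sd²)/mirna_sd from the miRNA and sheds the
  matching residual variance, so the PROBE-level population Pearson
  correlation equals the requested ``target_population_r`` exactly;
* every gene is measured by 1–3 probes, each adding independent
  Normal(0, noise_sd²) measurement noise to the shared gene signal.

Because the gene-signal variance is fixed, the attainable probe-level
correlation magnitude is bounded by gene_sd/sqrt(gene_sd² + noise_sd²);
requests beyond that raise with the bound. One seed drives everything via
deterministically spawned child streams, so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    MatchedCohort,
    SampleMetadata,
    attach_probe_annotation,
)
from .target_consensus import ConsensusTarget, PredictionRecord, PREDICTION_SOURCES

__all__ = [
    "DEFAULT_TUMOR_SHIFTS",
    "SimulationConfig",
    "PlantedTruth",
    "RecoveryMetrics",
    "mirna_names",
    "gene_names",
    "plant_random_pairs",
    "simulate_cohort",
    "simulate_prediction_tables",
    "simulate_ct_table",
    "recovery_metrics",
]

# Tumor-vs-normal linear fold changes of the three miR-200s in squamous-cell
# lung tumors, expressed as log2 mean shifts of the simulated miRNA signal.
DEFAULT_TUMOR_SHIFTS: dict[str, float] = {
    "hsa-miR-200a": math.log2(2.56),
    "hsa-miR-200b": math.log2(2.94),
    "hsa-miR-200c": math.log2(3.16),
}


def mirna_names(n: int) -> list[str]:
    """The first three names are the miR-200s; the rest are synthetic."""
    fixed = ["hsa-miR-200a", "hsa-miR-200b", "hsa-miR-200c"]
    names = fixed[:n]
    names += [f"hsa-miR-9{i:03d}" for i in range(1, n - len(names) + 1)]
    return names


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped cohort simulation parameters.

    Defaults mirror the screening cohort: 57 matched tumor samples (the
    screen ran on tumors only, so ``n_normal`` defaults to 0; set it
    positive to exercise tumor-vs-normal fold changes), 1–3 probes per
    gene drawn uniformly, and tumor shifts for the miR-200s.
    """

    n_samples: int = 57          # tumor samples (the matched screen cohort)
    n_normal: int = 0            # additional normal-tissue samples
    n_genes: int = 200
    n_mirnas: int = 20
    probes_per_gene: tuple[int, ...] = (1, 2, 3)
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    tumor_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TUMOR_SHIFTS)
    )
    mirna_sd: float = 0.7
    gene_sd: float = 1.0
    noise_sd: float = 0.3
    gene_baseline_mean: float = 8.0
    gene_baseline_sd: float = 1.5
    mirna_baseline_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError(f"n_samples must be >= 3, got {self.n_samples}")
        if self.n_normal < 0:
            raise ValueError("n_normal must be >= 0")
        if not self.probes_per_gene or any(k < 1 for k in self.probes_per_gene):
            raise ValueError("probes_per_gene must contain positive counts")
        for sd_name in ("mirna_sd", "gene_sd"):
            if getattr(self, sd_name) <= 0:
                raise ValueError(f"{sd_name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def attainable_r(self) -> float:
        """Largest probe-level |correlation| the noise model permits."""
        return self.gene_sd / math.sqrt(self.gene_sd**2 + self.noise_sd**2)


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort, for recovery scoring."""

    pairs: frozenset[tuple[str, str]]
    target_r: dict[tuple[str, str], float]
    mirna_ids: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    fp_rates: dict[str, float] = field(default_factory=dict)
    fn_rates: dict[str, float] = field(default_factory=dict)


@dataclass
class RecoveryMetrics:
    """Sensitivity/precision of a consensus output against planted truth."""

    sensitivity: float
    precision: float | None  # None (undefined) when the output is empty
    true_positives: int
    false_positives: int
    false_negatives: int


def plant_random_pairs(
    n_genes: int,
    n_mirnas: int,
    n_pairs: int,
    target_r: float,
    seed: int,
) -> tuple[tuple[str, str, float], ...]:
    """Draw distinct (miRNA, gene) pairs, at most one planted miRNA per gene.

    One regulator per gene keeps each planted probe-level correlation
    exactly at ``target_r`` (multiple regulators split a gene's variance
    budget).
    """
    if n_pairs > n_genes:
        raise ValueError("cannot plant more pairs than genes under one-per-gene")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 17)))
    genes = rng.choice(gene_names(n_genes), size=n_pairs, replace=False)
    mirs = rng.choice(mirna_names(n_mirnas), size=n_pairs, replace=True)
    return tuple((str(m), str(g), float(target_r)) for m, g in zip(mirs, genes))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MatchedCohort, SampleMetadata, PlantedTruth]:
    """Generate a matched miRNA/mRNA cohort with planted repression."""
    genes = gene_names(config.n_genes)
    mirnas = mirna_names(config.n_mirnas)
    gene_set = set(genes)
    mirna_set = set(mirnas)

    planted_by_gene: dict[str, list[tuple[str, float]]] = {}
    for mirna, gene, r in config.planted_pairs:
        if gene not in gene_set:
            raise ValueError(f"planted gene {gene!r} outside the simulated universe")
        if mirna not in mirna_set:
            raise ValueError(f"planted miRNA {mirna!r} outside the simulated universe")
        if not -1.0 < r < 0.0:
            raise ValueError(
                f"target_population_r must be in (-1, 0), got {r} for {mirna}/{gene}"
            )
        if abs(r) > config.attainable_r:
            raise ValueError(
                f"target_population_r {r} for {mirna}/{gene} is infeasible: "
                f"with noise_sd={config.noise_sd} the attainable bound is "
                f"|r| <= {config.attainable_r:.4f}"
            )
        planted_by_gene.setdefault(gene, []).append((mirna, r))

    ss = np.random.SeedSequence(entropy=(config.seed, 0))
    rng_mir, rng_gene, rng_probe = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    n_total = config.n_samples + config.n_normal
    sample_ids = [f"T{i:03d}" for i in range(1, config.n_samples + 1)] + [
        f"N{i:03d}" for i in range(1, config.n_normal + 1)
    ]
    is_tumor = np.array([1.0] * config.n_samples + [0.0] * config.n_normal)
    groups = {s: ("tumor" if t else "normal") for s, t in zip(sample_ids, is_tumor)}
    meta = SampleMetadata(groups=groups, cohort="synthetic")

    # miRNA matrix: baseline + tumor shift + noise, log2 scale
    shifts = np.array([config.tumor_shift.get(m, 0.0) for m in mirnas])
    M = (
        config.mirna_baseline_mean
        + shifts[:, None] * is_tumor[None, :]
        + rng_mir.normal(0.0, config.mirna_sd, size=(config.n_mirnas, n_total))
    )
    mirna_matrix = ExpressionMatrix(
        values=pd.DataFrame(M, index=mirnas, columns=sample_ids),
        scale="log2",
        platform="synthetic-taqman",
    )

    # gene signals: fixed variance gene_sd^2, slope traded against residual
    probe_var = config.gene_sd**2 + config.noise_sd**2
    baselines = rng_gene.normal(
        config.gene_baseline_mean, config.gene_baseline_sd, size=config.n_genes
    )
    mir_index = {m: i for i, m in enumerate(mirnas)}
    # deviations of miRNA signal from its structural mean, per sample
    M_dev = M - (config.mirna_baseline_mean + shifts[:, None] * is_tumor[None, :])
    residual_noise = rng_gene.normal(0.0, 1.0, size=(config.n_genes, n_total))

    probe_counts = rng_probe.choice(
        config.probes_per_gene, size=config.n_genes, replace=True
    )
    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    annotation: dict[str, str] = {}
    for gi, gene in enumerate(genes):
        signal = np.full(n_total, baselines[gi])
        beta_var = 0.0
        for mirna, r in planted_by_gene.get(gene, ()):  # repression slopes
            beta = r * math.sqrt(probe_var) / config.mirna_sd
            contrib_var = beta**2 * config.mirna_sd**2
            beta_var += contrib_var
            signal = signal + beta * M_dev[mir_index[mirna]]
        # slopes spend the gene's fixed variance budget: probe total
        # variance stays at gene_sd^2 + noise_sd^2, so probe-level r hits
        # the planted target exactly
        resid_var = config.gene_sd**2 - beta_var
        if resid_var < -1e-12:
            raise ValueError(
                f"gene {gene!r}: planted regulators exhaust the variance budget "
                f"(residual variance {resid_var:.4f} < 0); lower |target_population_r| "
                f"or plant fewer miRNAs on this gene"
            )
        signal = signal + math.sqrt(max(resid_var, 0.0)) * residual_noise[gi]
        for k in range(1, int(probe_counts[gi]) + 1):
            pid = f"{gene}_P{k}"
            probe_ids.append(pid)
            annotation[pid] = gene
            probe_rows.append(
                signal + rng_probe.normal(0.0, config.noise_sd, size=n_total)
            )

    mrna_matrix = ExpressionMatrix(
        values=pd.DataFrame(np.vstack(probe_rows), index=probe_ids, columns=sample_ids),
        scale="log2",
        platform="synthetic-array",
    )
    mrna_matrix = attach_probe_annotation(mrna_matrix, annotation)

    truth = PlantedTruth(
        pairs=frozenset((m, g) for m, g, _ in config.planted_pairs),
        target_r={(m, g): r for m, g, r in config.planted_pairs},
        mirna_ids=tuple(mirnas),
        gene_symbols=tuple(genes),
    )
    cohort = MatchedCohort(mrna=mrna_matrix, mirna=mirna_matrix, metadata=meta)
    return cohort, meta, truth


def simulate_prediction_tables(
    truth: PlantedTruth,
    fp_rate: float | Mapping[str, float] = 0.01,
    fn_rate: float | Mapping[str, float] = 0.2,
    seed: int = 0,
    sources: Sequence[str] = PREDICTION_SOURCES,
) -> dict[str, list[PredictionRecord]]:
    """Per-source prediction tables with controlled error rates.

    Each source contains each truth pair with probability 1 − fn_rate and
    each non-truth pair of the universe with probability fp_rate, all
    independently. Rates may be scalars or per-source mappings.
    """
    def rate_for(rates: float | Mapping[str, float], source: str) -> float:
        value = rates.get(source, 0.0) if isinstance(rates, Mapping) else float(rates)
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"rate for {source!r} must be in [0, 1], got {value}")
        return value

    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 1)))
    universe = [
        (m, g) for m in truth.mirna_ids for g in truth.gene_symbols
    ]
    tables: dict[str, list[PredictionRecord]] = {}
    for source in sources:
        fp = rate_for(fp_rate, source)
        fn = rate_for(fn_rate, source)
        truth.fp_rates[source] = fp
        truth.fn_rates[source] = fn
        draws = rng.random(len(universe))
        records: list[PredictionRecord] = []
        for (mirna, gene), u in zip(universe, draws):
            keep = (u >= fn) if (mirna, gene) in truth.pairs else (u < fp)
            if keep:
                records.append(
                    PredictionRecord(source=source, mirna_id=mirna, gene_symbol=gene)
                )
        tables[source] = records
    return tables


def simulate_ct_table(
    true_fold: float,
    replicate_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    target_gene: str = "TARGET",
    control_gene: str = "UBC",
    treated_condition: str = "miR-200",
    control_condition: str = "miR-scr",
    base_target_ct: float = 26.0,
    base_control_ct: float = 20.0,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table whose expected ΔΔCt is −log2(true_fold).

    Treated-condition target wells sit ``−log2(true_fold)`` cycles away
    from the control-condition baseline (a repressed target needs more
    cycles); every well gets independent Normal(0, replicate_sd²) noise.
    """
    if true_fold <= 0:
        raise ValueError(f"true_fold must be positive, got {true_fold}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 2)))
    rows: list[dict[str, object]] = []
    shift = -math.log2(true_fold)
    for rep in range(1, n_replicates + 1):
        rep_id = f"R{rep}"
        wells = {
            (treated_condition, target_gene): base_target_ct + shift,
            (treated_condition, control_gene): base_control_ct,
            (control_condition, target_gene): base_target_ct,
            (control_condition, control_gene): base_control_ct,
        }
        for (condition, gene), mean_ct in wells.items():
            rows.append(
                {
                    "replicate_id": rep_id,
                    "condition": condition,
                    "gene": gene,
                    "ct": mean_ct + float(rng.normal(0.0, replicate_sd)),
                }
            )
    return pd.DataFrame(rows, columns=["replicate_id", "condition", "gene", "ct"])


def recovery_metrics(
    consensus: Iterable[ConsensusTarget | tuple[str, str]],
    truth: PlantedTruth,
) -> RecoveryMetrics:
    """Score a consensus output against the planted truth.

    Precision is reported as None (undefined — neither 0 nor 1) when the
    output is empty; an empty truth set is an error.
    """
    if not truth.pairs:
        raise ValueError("recovery metrics undefined for empty truth")
    output: set[tuple[str, str]] = set()
    for item in consensus:
        if isinstance(item, ConsensusTarget):
            output.add(item.key)
        else:
            output.add((str(item[0]), str(item[1])))
    tp = len(output & truth.pairs)
    fp = len(output - truth.pairs)
    fn = len(truth.pairs - output)
    return RecoveryMetrics(
        sensitivity=tp / len(truth.pairs),
        precision=(tp / len(output)) if output else None,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
    )
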