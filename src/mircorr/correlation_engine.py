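"""Pearson anti-correlation screen over a matched miRNA/mRNA cohort.

Every marker probe is correlated with every miRNA across the matched
samples (pairwise-complete when cells are missing). Each pair gets the
product-moment coefficient r, its t-transform statistic

    t = r * sqrt(n - 2) / sqrt(1 - r^2),  df = n - 2,

a two-sided p-value from Student's t, an optional Benjamini–Hochberg
adjusted p across the whole probe × miRNA grid, and a significance flag.

The screening rule is configurable: the default profile flags a pair when
|r| >= 0.258 AND p <= 0.05 (the conjunction of the study thresholds).
Note that at n = 57 inverting the t transform at alpha = 0.05 gives
|r| ≈ 0.2609, slightly above 0.258, so the two clauses are not redundant;
``critical_r`` exposes the exact inversion and ``alpha_only`` / ``r_only``
modes support sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import MatchedCohort

__all__ = [
    "UndefinedCorrelationError",
    "AnalysisThresholds",
    "CorrelationResult",
    "SkippedPair",
    "CorrelationScreen",
    "pearson_r",
    "correlation_pvalue",
    "critical_r",
    "correlate_pairs",
    "filter_significant",
    "results_to_frame",
    "results_from_frame",
]

MODES = ("both", "alpha_only", "r_only")


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (constant vector or n < 3)."""


@dataclass(frozen=True)
class AnalysisThresholds:
    """Screening rule for the probe × miRNA grid.

    ``mode="both"`` requires |r| >= r_min AND p <= alpha (the study
    profile); ``alpha_only`` and ``r_only`` apply a single clause.
    """

    alpha: float = 0.05
    r_min: float = 0.258
    mode: str = "both"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 <= self.r_min < 1:
            raise ValueError(f"r_min must be in [0, 1), got {self.r_min}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def is_significant(self, r: float, p: float) -> bool:
        by_alpha = p <= self.alpha
        by_r = abs(r) >= self.r_min
        if self.mode == "alpha_only":
            return by_alpha
        if self.mode == "r_only":
            return by_r
        return by_alpha and by_r


#: the study screening profile: |r| >= 0.258 and p <= 0.05, conjunction.
STUDY_PROFILE = AnalysisThresholds()


@dataclass
class CorrelationResult:
    """One (miRNA, probe) pair from the screen."""

    mirna_id: str
    probe_id: str
    gene_symbol: str | None
    r: float
    n: int
    t_stat: float
    p: float
    significant: bool
    adj_p: float | None = None
    p_exact: bool = False  # True when |r| == 1 forced p = 0 exactly


@dataclass
class SkippedPair:
    """A pair excluded from the screen, with the reason."""

    mirna_id: str
    probe_id: str
    reason: str
    n: int


@dataclass
class CorrelationScreen:
    """Screen output: emitted results plus the skip log."""

    results: list[CorrelationResult]
    skipped: list[SkippedPair]

    def to_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient, pairwise-complete.

    Raises :class:`UndefinedCorrelationError` for constant input or fewer
    than 3 complete pairs — never a silent NaN or r = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    xa, ya = _pairwise_complete(xa, ya)
    n = xa.size
    if n < 3:
        raise UndefinedCorrelationError(
            f"only {n} complete pair(s); need at least 3"
        )
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            "zero variance in " + ("x" if sx == 0.0 else "y")
        )
    r = float(dx @ dy) / (sx * sy)
    return max(-1.0, min(1.0, r))


def _t_from_r(r: float, n: int) -> float:
    denom = 1.0 - r * r
    if denom <= 0.0:
        return math.inf if r > 0 else -math.inf
    return r * math.sqrt(n - 2) / math.sqrt(denom)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r at sample size n.

    Uses the t transform t = r·sqrt(n−2)/sqrt(1−r²) with n−2 degrees of
    freedom. |r| = 1 returns exactly 0 (see ``p_exact`` on screen results).
    """
    if n < 3:
        raise UndefinedCorrelationError(f"n must be >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r must be in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = _t_from_r(r, n)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| whose two-sided p-value is <= alpha at sample size n.

    Inverts the t transform at the two-sided alpha quantile of Student's t
    with n−2 degrees of freedom: r* = t* / sqrt(t*² + n − 2).
    """
    if n < 3:
        raise UndefinedCorrelationError(f"n must be >= 3, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 2))
    return t_crit / math.sqrt(t_crit * t_crit + n - 2)


def _vector_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    denom = np.clip(1.0 - r * r, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * math.sqrt(n - 2) / np.sqrt(denom)
    t = np.where(denom == 0.0, np.sign(r) * np.inf, t)
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2), t


def correlate_pairs(
    cohort: MatchedCohort,
    marker_probes: Sequence[str] | None = None,
    thresholds: AnalysisThresholds = STUDY_PROFILE,
    adjust: bool = True,
) -> CorrelationScreen:
    """Correlate every marker probe with every miRNA in the cohort.

    Pairs with fewer than 3 pairwise-complete samples or a constant vector
    are not emitted; they land in the skip log. ``adjust`` adds
    Benjamini–Hochberg adjusted p-values across all emitted pairs (the
    significance flag is gated on the raw p, per the default profile).
    """
    mrna = cohort.mrna
    if marker_probes is None:
        probes = mrna.feature_ids
    else:
        probes = [str(p) for p in marker_probes]
        unknown = [p for p in probes if p not in mrna.values.index]
        if unknown:
            raise KeyError(f"unknown marker probe id(s): {unknown}")
    mirnas = cohort.mirna.feature_ids
    results: list[CorrelationResult] = []
    skipped: list[SkippedPair] = []
    if not probes or not mirnas:
        return CorrelationScreen(results=results, skipped=skipped)

    X = mrna.values.loc[probes].to_numpy(dtype=float)
    Y = cohort.mirna.values.to_numpy(dtype=float)
    n_samples = cohort.n
    symbols = [mrna.symbol_of(p) for p in probes]

    complete = not (np.isnan(X).any() or np.isnan(Y).any())
    if complete:
        dx = X - X.mean(axis=1, keepdims=True)
        dy = Y - Y.mean(axis=1, keepdims=True)
        sx = np.sqrt((dx * dx).sum(axis=1))
        sy = np.sqrt((dy * dy).sum(axis=1))
        ok_x = sx > 0
        ok_y = sy > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            R = (dx @ dy.T) / np.outer(sx, sy)
        R = np.clip(R, -1.0, 1.0)
        P, T = _vector_pvalues(R, n_samples)
        for i, probe in enumerate(probes):
            for j, mir in enumerate(mirnas):
                if not (ok_x[i] and ok_y[j]):
                    skipped.append(
                        SkippedPair(mir, probe, "zero variance", n_samples)
                    )
                    continue
                r = float(R[i, j])
                exact = abs(r) == 1.0
                results.append(
                    CorrelationResult(
                        mirna_id=mir,
                        probe_id=probe,
                        gene_symbol=symbols[i],
                        r=r,
                        n=n_samples,
                        t_stat=float(T[i, j]),
                        p=0.0 if exact else float(P[i, j]),
                        significant=False,
                        p_exact=exact,
                    )
                )
    else:
        for i, probe in enumerate(probes):
            for j, mir in enumerate(mirnas):
                xa, ya = _pairwise_complete(X[i], Y[j])
                n = xa.size
                if n < 3:
                    skipped.append(
                        SkippedPair(mir, probe, f"only {n} complete samples", n)
                    )
                    continue
                try:
                    r = pearson_r(xa, ya)
                except UndefinedCorrelationError as exc:
                    skipped.append(SkippedPair(mir, probe, str(exc), n))
                    continue
                exact = abs(r) == 1.0
                results.append(
                    CorrelationResult(
                        mirna_id=mir,
                        probe_id=probe,
                        gene_symbol=symbols[i],
                        r=r,
                        n=n,
                        t_stat=_t_from_r(r, n),
                        p=correlation_pvalue(r, n),
                        significant=False,
                        p_exact=exact,
                    )
                )

    for res in results:
        res.significant = thresholds.is_significant(res.r, res.p)
    if adjust and results:
        _, adj, _, _ = multipletests([res.p for res in results], method="fdr_bh")
        for res, q in zip(results, adj):
            res.adj_p = float(q)
    return CorrelationScreen(results=results, skipped=skipped)


def filter_significant(
    results: Iterable[CorrelationResult],
    thresholds: AnalysisThresholds = STUDY_PROFILE,
) -> list[CorrelationResult]:
    """Retain pairs meeting the configured rule; order is preserved.

    Monotone in the thresholds: relaxing alpha or r_min never removes a
    previously retained pair.
    """
    out: list[CorrelationResult] = []
    for res in results:
        if thresholds.is_significant(res.r, res.p):
            out.append(replace(res, significant=True))
    return out


_COLUMNS = [
    "mirna_id", "probe_id", "gene_symbol", "r", "n", "t", "p", "adj_p", "significant",
]


def results_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": r.mirna_id,
            "probe_id": r.probe_id,
            "gene_symbol": r.gene_symbol if r.gene_symbol is not None else "",
            "r": r.r,
            "n": r.n,
            "t": r.t_stat,
            "p": r.p,
            "adj_p": r.adj_p if r.adj_p is not None else "",
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def results_from_frame(frame: pd.DataFrame) -> list[CorrelationResult]:
    out: list[CorrelationResult] = []
    for row in frame.itertuples(index=False):
        symbol = getattr(row, "gene_symbol", "")
        adj = getattr(row, "adj_p", "")
        out.append(
            CorrelationResult(
                mirna_id=str(row.mirna_id),
                probe_id=str(row.probe_id),
                gene_symbol=None if (pd.isna(symbol) or symbol == "") else str(symbol),
                r=float(row.r),
                n=int(row.n),
                t_stat=float(row.t),
                p=float(row.p),
                significant=bool(row.significant),
                adj_p=None if (isinstance(adj, str) and adj == "") or pd.isna(adj) else float(adj),
            )
        )
    return out
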