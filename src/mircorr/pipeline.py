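"""End-to-end screen: correlations → significance filter → consensus."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .correlation_engine import (
    AnalysisThresholds,
    CorrelationScreen,
    CorrelationResult,
    STUDY_PROFILE,
    correlate_pairs,
    filter_significant,
)
from .expression_io import MatchedCohort
from .target_consensus import (
    BindingSiteRecord,
    BindingSiteThresholds,
    ConsensusTarget,
    PredictionRecord,
    ValidatedTargetRecord,
    annotate_validation_status,
    attach_binding_site_counts,
    build_candidate_pairs,
)

__all__ = ["ScreenOutput", "screen_targets"]


@dataclass
class ScreenOutput:
    """Everything the screen produced, from raw correlations to targets."""

    screen: CorrelationScreen
    significant: list[CorrelationResult]
    targets: list[ConsensusTarget]


def screen_targets(
    cohort: MatchedCohort,
    predictions: Iterable[PredictionRecord] | Mapping[str, Sequence[PredictionRecord]],
    thresholds: AnalysisThresholds = STUDY_PROFILE,
    marker_probes: Sequence[str] | None = None,
    validated: Iterable[ValidatedTargetRecord] | None = None,
    binding_sites: Iterable[BindingSiteRecord] | None = None,
    site_thresholds: BindingSiteThresholds = BindingSiteThresholds(),
) -> ScreenOutput:
    """Run the full nomination pipeline on a matched cohort.

    Correlates every marker probe with every miRNA, keeps pairs passing
    the significance rule, intersects with the prediction sources under
    the negative-probe rule, then (optionally) annotates validation status
    and filtered binding-site counts.
    """
    if isinstance(predictions, Mapping):
        flat: list[PredictionRecord] = []
        for records in predictions.values():
            flat.extend(records)
        predictions = flat
    screen = correlate_pairs(cohort, marker_probes=marker_probes, thresholds=thresholds)
    significant = filter_significant(screen.results, thresholds)
    targets = build_candidate_pairs(predictions, significant)
    if validated is not None:
        targets = annotate_validation_status(targets, validated)
    if binding_sites is not None:
        targets = attach_binding_site_counts(targets, binding_sites, site_thresholds)
    return ScreenOutput(screen=screen, significant=significant, targets=targets)
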