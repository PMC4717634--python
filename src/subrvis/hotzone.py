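"""Hot-zone analysis of de novo mutations.

A "hot zone" mutation combines a damaging variant-level effect score
(PolyPhen-2 HumVar >= 0.95; synonymous variants score 0, canonical
splice / stop gain / stop loss score 1) with an intolerant regional
context (region score at or below the 25th percentile of the genome-wide
distribution). Case/control enrichment of hot-zone mutations is assessed
with a two-sided Fisher's exact test. Also included: the rule converting
MutationTaster's four-way predictions and probabilities onto a single
[0, 1] scale (0 = predicted pathogenic, 1 = predicted harmless).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DeNovoMutation",
    "MTPrediction",
    "variant_effect_score",
    "classify_hot_zone",
    "hotzone_enrichment",
    "mutationtaster_score",
    "filter_denovo",
    "score_percentiles",
    "DAMAGING_EFFECT_THRESHOLD",
    "INTOLERANT_PERCENTILE",
]

DAMAGING_EFFECT_THRESHOLD = 0.95
INTOLERANT_PERCENTILE = 25.0

_LOF_LIKE = {"canonical_splice", "stop_gain", "stop_loss"}


@dataclass(frozen=True)
class DeNovoMutation:
    """A single-nucleotide de novo mutation with effect annotation and,
    for cohorts that need it, cross-center validation metadata."""

    chrom: str
    pos: int
    consequence: str  # synonymous | missense | canonical_splice | stop_gain | stop_loss | other
    polyphen2_humvar: float | None
    cohort: str  # case | control
    in_both_siblings: bool = False
    validated_by: frozenset[str] = frozenset()
    call_labels: Mapping[str, str] | None = None  # institute -> strong/weak/not_called/...


@dataclass(frozen=True)
class MTPrediction:
    prediction: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("probability must be in (0, 1]")


def variant_effect_score(m: DeNovoMutation) -> float | None:
    """Variant-level effect score in [0, 1]: 0 for synonymous, 1 for
    canonical splice / stop gain / stop loss, the PolyPhen-2 HumVar score
    for missense. Missense without a HumVar score returns None (excluded
    downstream)."""
    if m.consequence == "synonymous":
        return 0.0
    if m.consequence in _LOF_LIKE:
        return 1.0
    if m.consequence == "missense":
        if m.polyphen2_humvar is None:
            logger.info("missense at %s:%d lacks a HumVar score; excluded", m.chrom, m.pos)
            return None
        return float(m.polyphen2_humvar)
    return None


def classify_hot_zone(
    effect_score: float | None,
    region_score_percentile: float | None,
    damaging_threshold: float = DAMAGING_EFFECT_THRESHOLD,
    percentile_threshold: float = INTOLERANT_PERCENTILE,
) -> bool:
    """True iff the effect score is damaging (>= 0.95, inclusive) and the
    region percentile is intolerant (<= 25, inclusive). Missing inputs
    classify as False."""
    if effect_score is None or region_score_percentile is None:
        logger.debug("hot-zone classification with missing input -> False")
        return False
    if math.isnan(effect_score) or math.isnan(region_score_percentile):
        return False
    return effect_score >= damaging_threshold and region_score_percentile <= percentile_threshold


def hotzone_enrichment(
    case_hot: int,
    case_total: int,
    control_hot: int,
    control_total: int,
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of hot-zone enrichment in cases.

    Returns (odds ratio, p). A table with a zero margin has no evidence
    either way: p = 1 and the odds ratio is NaN.
    """
    if case_hot > case_total or control_hot > control_total:
        raise ValueError("hot counts exceed totals")
    table = np.array(
        [
            [case_hot, case_total - case_hot],
            [control_hot, control_total - control_hot],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return (float("nan"), 1.0)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def mutationtaster_score(pred: MTPrediction) -> float:
    """Map a MutationTaster prediction to a [0, 1] score.

    polymorphism -> probability (always >= 0.5); disease_causing ->
    1 - probability (always <= 0.5). The *_automatic labels reflect a
    database lookup; when the Bayes classifier disagrees (probability
    < 0.5) the prediction is flipped and the probability replaced by
    1 - probability before applying the non-automatic rule.
    """
    prediction, prob = pred.prediction, pred.probability
    if prediction.endswith("_automatic"):
        base = prediction[: -len("_automatic")]
        if prob < 0.5:
            base = "polymorphism" if base == "disease_causing" else "disease_causing"
            prob = 1.0 - prob
        prediction = base
    if prediction == "polymorphism":
        return prob
    if prediction == "disease_causing":
        return 1.0 - prob
    raise ValueError(f"unknown MutationTaster prediction {pred.prediction!r}")


def filter_denovo(
    mutations: Iterable[DeNovoMutation],
    population_variant_positions: set[tuple[str, int]],
    autism_validation_rules: bool = False,
) -> list[DeNovoMutation]:
    """Exclude de novo calls seen as standing variants in the population
    cohort and, when ``autism_validation_rules`` is set, apply the
    cross-center validation logic: the call must not appear in both
    siblings, and either (1) at least one institute validated it, or
    (2) at least one institute labelled it a 'strong' call while no
    institute labelled it 'not_called' or 'weak'."""
    out = []
    for m in mutations:
        if (m.chrom, m.pos) in population_variant_positions:
            continue
        if autism_validation_rules:
            if m.in_both_siblings:
                continue
            labels = set((m.call_labels or {}).values())
            validated = bool(m.validated_by)
            strong_uncontested = "strong" in labels and not labels & {"not_called", "weak"}
            if not (validated or strong_uncontested):
                continue
        out.append(m)
    return out


def score_percentiles(scores: Sequence[float]) -> np.ndarray:
    """Percentile of each score within the full distribution, computed as
    100 * (proportion of scores <= value); lower scores sit at lower
    percentiles, so intolerant regions fall toward 0."""
    s = np.asarray(scores, dtype=float)
    order = np.sort(s)
    ranks = np.searchsorted(order, s, side="right")
    return 100.0 * ranks / len(s)
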