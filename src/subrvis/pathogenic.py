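"""Pathogenic-variant test set construction and per-region tallies.

The test set combines clinical databases (ClinVar entries labelled
"Pathogenic", HGMD entries tagged "DM") and keeps canonical-transcript
missense variants that are not annotated with any loss-of-function or
splice-adjacent consequence, since loss-of-function variants damage the
whole protein regardless of where they fall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import GeneModel, SubRegion
from .scores import RegionIndex, region_key

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalVariant",
    "RegionPathogenicity",
    "filter_pathogenic",
    "tally_pathogenic",
    "domain_type_risk_table",
    "EXCLUDED_CONSEQUENCE_TERMS",
]

#: consequence annotations that disqualify a missense variant from the
#: localization test set
EXCLUDED_CONSEQUENCE_TERMS = frozenset(
    {
        "incomplete_terminal_codon_variant",
        "splice_region_variant",
        "stop_gained",
        "stop_lost",
    }
)

_QUALIFYING_LABELS = {"clinvar": "Pathogenic", "hgmd": "DM"}


@dataclass(frozen=True)
class ClinicalVariant:
    """One reported clinical variant with its annotation terms."""

    chrom: str
    pos: int
    ref: str
    alt: str
    source: str  # clinvar | hgmd | other
    clinical_label: str
    canonical: bool
    consequence_terms: frozenset[str]


@dataclass(frozen=True)
class RegionPathogenicity:
    """Pathogenic tally and presence flag for one sub-region."""

    gene_id: str
    region_index: int
    count: int
    present: int

    def __post_init__(self) -> None:
        if self.present != int(self.count >= 1):
            raise ValueError("present flag must equal (count >= 1)")


def filter_pathogenic(variants: Iterable[ClinicalVariant]) -> list[ClinicalVariant]:
    """Apply the pathogenic test-set filter.

    Keeps variants that (a) come from ClinVar with label "Pathogenic" or
    from HGMD with label "DM", (b) are on the canonical transcript, (c)
    carry the "missense_variant" consequence, and (d) carry none of the
    excluded terms. Variants at the same (chrom, pos, alt) across sources
    are deduplicated, keeping the first seen. Idempotent.
    """
    seen: set[tuple[str, int, str]] = set()
    out = []
    for v in variants:
        required = _QUALIFYING_LABELS.get(v.source)
        if required is None or v.clinical_label != required:
            continue
        if not v.canonical:
            continue
        if "missense_variant" not in v.consequence_terms:
            continue
        if v.consequence_terms & EXCLUDED_CONSEQUENCE_TERMS:
            continue
        key = (v.chrom, v.pos, v.alt)
        if key in seen:
            continue
        seen.add(key)
        out.append(v)
    return out


def tally_pathogenic(
    variants: Iterable[ClinicalVariant],
    regions: Sequence[SubRegion],
    genes: Mapping[str, GeneModel],
) -> list[RegionPathogenicity]:
    """Count filtered pathogenic variants per sub-region of one division.

    Variants falling outside every region are logged and not counted; the
    counts over all regions therefore sum to the number of assigned
    variants.
    """
    index = RegionIndex(genes, regions)
    counts: dict[tuple[str, int], int] = {region_key(r): 0 for r in regions}
    unassigned = 0
    for v in variants:
        region = index.locate(v.chrom, v.pos)
        if region is None:
            unassigned += 1
            continue
        counts[region_key(region)] += 1
    if unassigned:
        logger.info("%d pathogenic variants fell outside every sub-region", unassigned)
    return [
        RegionPathogenicity(r.gene_id, r.index, counts[region_key(r)], int(counts[region_key(r)] >= 1))
        for r in regions
    ]


def domain_type_risk_table(
    regions: Sequence[SubRegion],
    pathogenicity: Sequence[RegionPathogenicity],
    mutation_rates: pd.Series,
) -> pd.DataFrame:
    """Approximate disease risk per domain type.

    Aggregates, across genes, the pathogenic tally and the cumulative
    mutation rate for each domain label (unaligned stretches aggregate
    under their own label), and reports tally / cumulative rate — a rough
    count of reported pathogenic mutations after controlling for sequence
    mutability. Zero-rate types get a missing ratio.
    """
    counts = {(p.gene_id, p.region_index): p.count for p in pathogenicity}
    rows = []
    for r in regions:
        key = region_key(r)
        rows.append(
            {
                "domain_id": r.label,
                "tally": counts.get(key, 0),
                "cumulative_rate": float(mutation_rates.get(key, 0.0)),
            }
        )
    df = pd.DataFrame(rows).groupby("domain_id", as_index=False).sum()
    df["risk_ratio"] = df["tally"] / df["cumulative_rate"].where(df["cumulative_rate"] > 0)
    return df.sort_values("risk_ratio", ascending=False, ignore_index=True)
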