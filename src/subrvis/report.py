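"""Per-gene score-profile report: the plot-ready table of a gene's
sub-regions, their labels and scores, and where its reported pathogenic
variants fall (one row per region, one row per variant with its region
assignment)."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .pathogenic import ClinicalVariant
from .regions import GeneModel, SubRegion
from .scores import RegionIndex

__all__ = ["gene_profile_report"]


def gene_profile_report(
    gene_id: str,
    regions: Sequence[SubRegion],
    scores: pd.Series,
    variants: Sequence[ClinicalVariant],
    genes: Mapping[str, GeneModel],
) -> pd.DataFrame:
    """Ordered region and variant records for one gene.

    Region rows carry (row_type="region", cds_start, cds_end, label,
    score); variant rows carry (row_type="variant", position and the index
    of the half-open region containing it). Suitable for step plots of the
    score profile with variant markers.
    """
    gene_regions = sorted((r for r in regions if r.gene_id == gene_id), key=lambda r: r.cds_start)
    if not gene_regions:
        raise KeyError(f"unknown or unscored gene {gene_id!r}")
    index = RegionIndex(genes, gene_regions)
    rows = []
    for r in gene_regions:
        rows.append(
            {
                "row_type": "region",
                "gene_id": gene_id,
                "region_index": r.index,
                "label": r.label,
                "cds_start": r.cds_start,
                "cds_end": r.cds_end,
                "score": scores.get((gene_id, r.index), float("nan")),
                "pos": pd.NA,
            }
        )
    for v in variants:
        hit = index.locate(v.chrom, v.pos)
        if hit is None or hit.gene_id != gene_id:
            continue
        rows.append(
            {
                "row_type": "variant",
                "gene_id": gene_id,
                "region_index": hit.index,
                "label": hit.label,
                "cds_start": pd.NA,
                "cds_end": pd.NA,
                "score": scores.get((gene_id, hit.index), float("nan")),
                "pos": v.pos,
            }
        )
    return pd.DataFrame(rows)
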