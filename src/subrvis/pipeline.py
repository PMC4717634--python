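"""End-to-end wiring: from raw inputs to scored region tables and test
inputs, including the full rescore-per-shuffle loop of the division
permutation test.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genome_test
from .gene_test import GeneTestInput
from .genome_test import GenomeTestInput
from .pathogenic import ClinicalVariant, filter_pathogenic, tally_pathogenic
from .regions import GeneModel, SubRegion, build_domain_regions, build_exon_regions, permute_region_sizes
from .scores import (
    SiteRecord,
    compute_subgerp,
    compute_subrvis,
    qualify_sites,
    region_mutation_rates,
    tally_region_counts,
)

__all__ = [
    "build_division",
    "score_division",
    "gene_test_inputs",
    "genome_test_input",
    "division_effect_null",
]


def build_division(cohort, division: str = "domain") -> list[SubRegion]:
    """Construct one division's sub-regions for every gene of a cohort."""
    if division == "domain":
        return list(cohort.domain_regions)
    if division == "exon":
        out = []
        for gene in cohort.genes.values():
            out.extend(build_exon_regions(gene))
        return out
    raise ValueError(f"unknown division {division!r}; choose 'domain' or 'exon'")


def score_division(
    regions: Sequence[SubRegion],
    genes: Mapping[str, GeneModel],
    sites: Sequence[SiteRecord],
    pathogenic: Sequence[ClinicalVariant],
    flanked_cds: Mapping[str, str],
    rate_table: Mapping[tuple[str, str], float],
    conservation: Mapping[str, Mapping[int, float]] | None = None,
    min_coverage: float = 10.0,
    already_filtered: bool = False,
) -> pd.DataFrame:
    """Score one division end to end.

    Qualifies sites, tallies counts, fits the subRVIS regression, computes
    mutation rates (and subGERP when a conservation track is given), and
    attaches pathogenic tallies. Returns a region table indexed by
    (gene_id, region_index) with columns label, length, total_variants,
    common_functional, subrvis, mutation_rate, path_count, present
    [, subgerp].
    """
    qualified = qualify_sites(sites, min_coverage=min_coverage)
    counts = tally_region_counts(qualified, regions, genes)
    subrvis = compute_subrvis(counts)
    rates = region_mutation_rates(regions, flanked_cds, rate_table)
    kept = pathogenic if already_filtered else filter_pathogenic(pathogenic)
    tallies = tally_pathogenic(kept, regions, genes)

    idx = subrvis.index
    df = pd.DataFrame(
        {
            "label": [r.label for r in regions],
            "length": [r.length for r in regions],
            "total_variants": [c.total_variants for c in counts],
            "common_functional": [c.common_functional for c in counts],
            "subrvis": subrvis.to_numpy(),
            "mutation_rate": rates.to_numpy(),
            "path_count": [t.count for t in tallies],
            "present": [t.present for t in tallies],
        },
        index=idx,
    )
    if conservation is not None:
        df["subgerp"] = compute_subgerp(conservation, regions, genes).to_numpy()
    return df


def gene_test_inputs(table: pd.DataFrame, score: str = "subrvis") -> list[GeneTestInput]:
    """Per-gene test inputs from a scored region table. Genes whose
    regions include a missing score or a non-positive mutation rate are
    still emitted (the test itself records the skip reason)."""
    out = []
    for gid, sub in table.groupby(level="gene_id", sort=True):
        out.append(
            GeneTestInput(
                gene_id=str(gid),
                Y=sub["path_count"].to_numpy(dtype=float),
                Z=sub["mutation_rate"].to_numpy(dtype=float),
                X=sub[score].to_numpy(dtype=float),
            )
        )
    return out


def genome_test_input(
    table: pd.DataFrame,
    score_columns: Sequence[str] = ("subrvis",),
    restrict_to_pathogenic_genes: bool = True,
) -> GenomeTestInput:
    """Genome-wide test input from a scored region table, restricted (by
    default) to genes carrying at least one reported pathogenic variant,
    and dropping regions with missing scores."""
    df = table
    if restrict_to_pathogenic_genes:
        has = df.groupby(level="gene_id")["path_count"].transform("sum") > 0
        df = df[has]
    df = df.dropna(subset=list(score_columns))
    df = df[df["mutation_rate"] > 0]
    return GenomeTestInput(
        Y=df["present"].to_numpy(dtype=np.int8),
        Z=df["mutation_rate"].to_numpy(dtype=float),
        scores={c: df[c].to_numpy(dtype=float) for c in score_columns},
    )


def division_effect_null(
    cohort,
    n_permutations: int = 100,
    seed: int = 0,
    score: str = "subrvis",
    division: str = "domain",
) -> np.ndarray:
    """Null distribution of score effect sizes over shuffled divisions.

    Each iteration re-lays every gene's sub-regions in a random order
    (preserving each gene's region count and size multiset), re-tallies
    variants and pathogenic counts against the new boundaries, refits the
    subRVIS regression and mutation rates, and records the genome-wide
    logistic score effect size.
    """
    rng = np.random.default_rng(seed)
    base_regions = build_division(cohort, division)
    by_gene: dict[str, list] = {}
    for r in base_regions:
        by_gene.setdefault(r.gene_id, []).append(r)
    kept_pathogenic = filter_pathogenic(cohort.pathogenic)
    betas = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted: list[SubRegion] = []
        for gid, regs in by_gene.items():
            permuted.extend(permute_region_sizes(cohort.genes[gid], regs, rng))
        table = score_division(
            permuted,
            cohort.genes,
            cohort.sites,
            kept_pathogenic,
            cohort.flanked_cds,
            cohort.rate_table,
            already_filtered=True,
        )
        fit = genome_test.fit_region_model(genome_test_input(table, (score,)))
        betas[i] = fit.beta2[score]
    return betas
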