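"""Regional intolerance and conservation scores.

subRVIS: all qualifying variants in a sub-region are tallied and the count
of common (minor allele frequency > 0.1%) non-synonymous variants is
regressed on the total count by ordinary least squares, jointly across all
sub-regions of a division. Each sub-region's score is its studentized
residual — the departure of its observed common functional variation from
the expectation given its total variation. Lower scores mark more
intolerant regions. The raw residuals are, by construction, orthogonal to
the total variant tally.

subGERP: the arithmetic mean of per-base evolutionary-constraint scores
(e.g. GERP++) over a sub-region's genomic footprint; higher means more
conserved.

Mutation rate: a sequence-composition expectation summing a
trinucleotide-context substitution-rate table over every position and
every possible single-nucleotide change; it serves as the mutability
covariate in the localization tests.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .regions import GeneModel, SubRegion, map_genomic_to_cds

logger = logging.getLogger(__name__)

__all__ = [
    "SiteRecord",
    "RegionCounts",
    "RegionIndex",
    "qualify_sites",
    "tally_region_counts",
    "compute_subrvis",
    "compute_subgerp",
    "compute_mutation_rate",
    "region_mutation_rates",
    "gene_variability_score",
    "region_key",
]

COMMON_MAF = 0.001  # strict lower bound for a "common" variant

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SiteRecord:
    """One genomic site from a population sequencing cohort."""

    chrom: str
    pos: int
    mean_coverage: float
    filter_status: str
    is_variant: bool
    alt_allele_frequency: float  # folded minor allele frequency
    consequence: str  # synonymous | nonsynonymous | other

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError("negative coverage")
        if not 0.0 <= self.alt_allele_frequency <= 0.5:
            raise ValueError(
                f"alt_allele_frequency {self.alt_allele_frequency} outside [0, 0.5]; "
                "fold to minor allele frequency first"
            )


@dataclass(frozen=True)
class RegionCounts:
    """Variant tallies for one sub-region."""

    gene_id: str
    region_index: int
    total_variants: int
    common_functional: int

    def __post_init__(self) -> None:
        if not 0 <= self.common_functional <= self.total_variants:
            raise ValueError("common_functional must lie in [0, total_variants]")


def region_key(region: SubRegion) -> tuple[str, int]:
    return (region.gene_id, region.index)


def qualify_sites(
    sites: Iterable[SiteRecord],
    min_coverage: float = 10.0,
    required_filter: str = "PASS",
) -> list[SiteRecord]:
    """Keep sites with adequate coverage whose variant calls pass filtering.

    Non-variant sites only need the coverage threshold; variant sites must
    additionally carry the required filter status. Input order is preserved.
    """
    out = []
    for s in sites:
        if s.mean_coverage < min_coverage:
            continue
        if s.is_variant and s.filter_status != required_filter:
            continue
        out.append(s)
    return out


class RegionIndex:
    """Genomic-position -> sub-region lookup for one division.

    Positions are first mapped into each gene's CDS coordinate space and
    then assigned by binary search on the division's CDS boundaries, so a
    site on a region's start position lands in that region (half-open
    intervals).
    """

    def __init__(self, genes: Mapping[str, GeneModel], regions: Iterable[SubRegion]):
        self._genes = dict(genes)
        self._bounds: dict[str, list[int]] = {}
        self._by_gene: dict[str, list[SubRegion]] = {}
        for r in regions:
            self._by_gene.setdefault(r.gene_id, []).append(r)
        for gid, regs in self._by_gene.items():
            regs.sort(key=lambda r: r.cds_start)
            self._bounds[gid] = [r.cds_start for r in regs]
        # chrom -> sorted (start, end, gene_id) exon blocks for gene lookup
        self._chrom_blocks: dict[str, list[tuple[int, int, str]]] = {}
        for gid in self._by_gene:
            gene = self._genes[gid]
            for s, e in gene.coding_exons:
                self._chrom_blocks.setdefault(gene.chrom, []).append((s, e, gid))
        for blocks in self._chrom_blocks.values():
            blocks.sort()
        self._chrom_starts = {c: [b[0] for b in blocks] for c, blocks in self._chrom_blocks.items()}

    def locate_gene(self, chrom: str, pos: int) -> str | None:
        blocks = self._chrom_blocks.get(chrom)
        if not blocks:
            return None
        i = bisect.bisect_right(self._chrom_starts[chrom], pos) - 1
        if i >= 0:
            s, e, gid = blocks[i]
            if s <= pos < e:
                return gid
        return None

    def locate(self, chrom: str, pos: int) -> SubRegion | None:
        gid = self.locate_gene(chrom, pos)
        if gid is None:
            return None
        cds_pos = map_genomic_to_cds(self._genes[gid], pos)
        if cds_pos is None:
            return None
        return self.locate_cds(gid, cds_pos)

    def locate_cds(self, gene_id: str, cds_pos: int) -> SubRegion | None:
        regs = self._by_gene.get(gene_id)
        if not regs:
            return None
        i = bisect.bisect_right(self._bounds[gene_id], cds_pos) - 1
        if i >= 0 and regs[i].cds_start <= cds_pos < regs[i].cds_end:
            return regs[i]
        return None


def tally_region_counts(
    sites: Iterable[SiteRecord],
    regions: Sequence[SubRegion],
    genes: Mapping[str, GeneModel],
    maf_threshold: float = COMMON_MAF,
) -> list[RegionCounts]:
    """Count qualifying variants per sub-region.

    ``total_variants`` counts every variant site in the region;
    ``common_functional`` the non-synonymous subset with MAF strictly above
    ``maf_threshold``. Sites falling outside every region are logged and
    not counted.
    """
    index = RegionIndex(genes, regions)
    totals: dict[tuple[str, int], int] = {region_key(r): 0 for r in regions}
    common: dict[tuple[str, int], int] = {region_key(r): 0 for r in regions}
    unassigned = 0
    for s in sites:
        if not s.is_variant:
            continue
        region = index.locate(s.chrom, s.pos)
        if region is None:
            unassigned += 1
            continue
        key = region_key(region)
        totals[key] += 1
        if s.consequence == "nonsynonymous" and s.alt_allele_frequency > maf_threshold:
            common[key] += 1
    if unassigned:
        logger.info("%d variant sites fell outside every sub-region", unassigned)
    return [
        RegionCounts(r.gene_id, r.index, totals[region_key(r)], common[region_key(r)])
        for r in regions
    ]


def compute_subrvis(
    counts: Sequence[RegionCounts],
    studentization: str = "external",
) -> pd.Series:
    """subRVIS scores: studentized residuals of the genome-wide regression
    of common functional counts on total variant counts.

    One regression line (with intercept) is fitted jointly over all
    sub-regions of the division; the score of each sub-region is its
    externally studentized residual (leave-one-out error variance), or the
    internally studentized residual when ``studentization="internal"``.

    Returns a float Series indexed by ``(gene_id, region_index)``.
    """
    if studentization not in ("external", "internal"):
        raise ValueError(f"unknown studentization {studentization!r}")
    if len(counts) < 3:
        raise ValueError("need at least 3 regions with data to fit the regression")
    total = np.array([c.total_variants for c in counts], dtype=float)
    common = np.array([c.common_functional for c in counts], dtype=float)
    if np.ptp(total) == 0:
        raise ValueError("degenerate design: total_variants has zero variance")
    exog = sm.add_constant(total)
    fit = sm.OLS(common, exog).fit()
    infl = OLSInfluence(fit)
    if studentization == "external":
        scores = np.asarray(infl.resid_studentized_external)
    else:
        scores = np.asarray(infl.resid_studentized_internal)
    # a residual of (numerically) zero studentizes to 0; under a perfect
    # fit the error variance is 0 too and the ratio degenerates to 0/0
    scale = max(1.0, float(np.abs(common).max()))
    exact = np.abs(fit.resid) < 1e-10 * scale
    scores = np.where(exact, 0.0, scores)
    idx = pd.MultiIndex.from_tuples(
        [(c.gene_id, c.region_index) for c in counts], names=["gene_id", "region_index"]
    )
    return pd.Series(scores, index=idx, name="subrvis")


def compute_subgerp(
    conservation: Mapping[str, Mapping[int, float]],
    regions: Sequence[SubRegion],
    genes: Mapping[str, GeneModel] | None = None,
) -> pd.Series:
    """Mean per-base conservation score over each sub-region's genomic
    blocks, using whichever bases the (possibly sparse) track covers.
    Regions with no covered base get NaN.

    ``conservation`` maps chrom -> {position: score}. Each region's
    chromosome is resolved through ``genes``; when omitted the track must
    cover a single chromosome.
    """
    if genes is None:
        if len(conservation) != 1:
            raise ValueError("pass gene models to resolve chromosomes for a multi-chrom track")
        only = next(iter(conservation))
        chrom_of = {r.gene_id: only for r in regions}
    else:
        chrom_of = {gid: g.chrom for gid, g in genes.items()}
    values = []
    keys = []
    for r in regions:
        track = conservation.get(chrom_of[r.gene_id], {})
        acc = [track[p] for s, e in r.genomic_blocks for p in range(s, e) if p in track]
        values.append(float(np.mean(acc)) if acc else np.nan)
        keys.append(region_key(r))
    idx = pd.MultiIndex.from_tuples(keys, names=["gene_id", "region_index"])
    return pd.Series(values, index=idx, name="subgerp")


def compute_mutation_rate(
    flanked_sequence: str,
    rate_table: Mapping[tuple[str, str], float],
) -> float:
    """Sequence-composition mutation rate of one region.

    ``flanked_sequence`` is the region's nucleotide sequence with one extra
    base on each side so every region position has a full trinucleotide
    context. The rate sums, over region positions and each of the three
    possible substitutions, the table rate for ``(context, alt)``.
    Positions whose context contains ``N`` are skipped with a log message;
    a region shorter than one base returns 0.
    """
    seq = flanked_sequence.upper()
    if len(seq) < 3:
        return 0.0
    rate = 0.0
    for i in range(1, len(seq) - 1):
        ctx = seq[i - 1 : i + 2]
        if "N" in ctx:
            logger.debug("context %s at offset %d contains N; skipped", ctx, i)
            continue
        ref = seq[i]
        for alt in NUCLEOTIDES:
            if alt != ref:
                rate += rate_table.get((ctx, alt), 0.0)
    return rate


def region_mutation_rates(
    regions: Sequence[SubRegion],
    flanked_cds_sequences: Mapping[str, str],
    rate_table: Mapping[tuple[str, str], float],
) -> pd.Series:
    """Mutation rate per sub-region from each gene's flanked CDS sequence.

    ``flanked_cds_sequences[gene_id]`` has length ``cds_length_nt + 2``:
    the CDS with one flanking base on each side, so region contexts at CDS
    boundaries are well defined.
    """
    values = []
    keys = []
    for r in regions:
        seq = flanked_cds_sequences[r.gene_id]
        values.append(compute_mutation_rate(seq[r.cds_start : r.cds_end + 2], rate_table))
        keys.append(region_key(r))
    idx = pd.MultiIndex.from_tuples(keys, names=["gene_id", "region_index"])
    return pd.Series(values, index=idx, name="mutation_rate")


def gene_variability_score(scores: pd.Series, min_regions: int = 3) -> pd.Series:
    """Per-gene intolerance variability: the sample standard deviation of a
    gene's sub-region scores. Genes with fewer than ``min_regions`` scored
    sub-regions get NaN.

    ``scores`` is indexed by ``(gene_id, region_index)``.
    """
    def _sd(x: pd.Series) -> float:
        x = x.dropna()
        if len(x) < min_regions:
            return np.nan
        return float(x.std(ddof=1))

    return scores.groupby(level="gene_id").apply(_sd).rename("variability")
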