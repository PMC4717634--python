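"""Synthetic cohorts with planted regional-intolerance structure.

The generator emulates every input the pipeline consumes — gene models,
domain alignments, population site records, a per-base conservation
track, clinical pathogenic variants, de novo mutation sets and a
trinucleotide substitution-rate table — on a single synthetic chromosome.
A designated fraction of domain sub-regions is "intolerant": their common
non-synonymous variants are thinned by a suppression factor (so they earn
low subRVIS scores), their conservation is elevated, and pathogenic
variants are placed multinomially with probabilities proportional to the
regional mutation rate times an enrichment factor. With suppression and
enrichment both 1 the cohort is exactly the multinomial null of the
gene-specific test.

All randomness flows from a single seed; identical seeds give identical
cohorts (and byte-identical output files through :mod:`subrvis.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .gene_test import GeneTestInput
from .genome_test import GenomeTestInput
from .pathogenic import ClinicalVariant
from .regions import DomainAlignment, GeneModel, SubRegion, build_domain_regions, map_cds_to_genomic
from .scores import NUCLEOTIDES, SiteRecord, region_key, region_mutation_rates
from .hotzone import DeNovoMutation

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_null_scores",
    "simulate_presence_data",
    "simulate_null_gene_inputs",
    "synthetic_rate_table",
    "preset_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults describe a cohort of ordinary
    protein-coding genes averaging about five domain sub-regions each.

    ``suppression`` thins common functional variants in intolerant regions
    (1 = no planted intolerance signal); ``pathogenic_enrichment``
    multiplies the multinomial placement weight of intolerant regions
    (1 = the mutability-only null).
    """

    n_genes: int = 500
    chrom: str = "chr1"
    cds_aa_min: int = 120
    cds_aa_max: int = 500
    mean_exons: float = 4.0
    mean_domains: float = 1.8
    domain_aa_min: int = 30
    domain_aa_max: int = 120
    intron_length: int = 200
    intergenic_gap: int = 1000
    fraction_intolerant: float = 0.2
    suppression: float = 5.0
    pathogenic_enrichment: float = 5.0
    variant_density: float = 0.03  # variant sites per CDS base
    p_nonsynonymous: float = 0.7
    p_common: float = 0.3  # pre-suppression probability a variant is common
    mean_pathogenic_per_gene: float = 2.0
    decoy_pathogenic_fraction: float = 0.15
    coverage_mean: float = 50.0
    low_coverage_fraction: float = 0.05
    fail_filter_fraction: float = 0.05
    conservation_coverage: float = 0.9
    conserved_mean: float = 3.0
    neutral_mean: float = 0.5
    n_denovo_case: int = 300
    n_denovo_control: int = 1000
    case_signal: float = 0.3  # fraction of case de novos forced into hot zones

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.cds_aa_min < 10 or self.cds_aa_max < self.cds_aa_min:
            raise ValueError("infeasible gene-size configuration")
        if self.suppression < 1 or self.pathogenic_enrichment < 1:
            raise ValueError("suppression and enrichment factors must be >= 1")
        if self.variant_density < 0 or self.mean_pathogenic_per_gene < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SyntheticCohort:
    """Everything the pipeline reads, plus the planted truth."""

    config: SimConfig
    genes: dict[str, GeneModel]
    alignments: dict[str, list[DomainAlignment]]
    flanked_cds: dict[str, str]  # gene_id -> CDS sequence with 1-nt flanks
    domain_regions: list[SubRegion]
    sites: list[SiteRecord]
    conservation: dict[str, dict[int, float]]
    pathogenic: list[ClinicalVariant]
    denovo: list[DeNovoMutation]
    rate_table: dict[tuple[str, str], float]
    intolerant_keys: set[tuple[str, int]] = field(default_factory=set)

    def gene_regions(self, gene_id: str) -> list[SubRegion]:
        return [r for r in self.domain_regions if r.gene_id == gene_id]


def synthetic_rate_table(seed: int | np.random.Generator = 0) -> dict[tuple[str, str], float]:
    """A synthetic trinucleotide-context substitution-rate table: one
    strictly positive lognormal rate per (context, alt) pair, around 1e-8
    per base per generation. A stand-in with the same shape and scale as
    empirically calibrated context tables, not a calibrated table itself.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table: dict[tuple[str, str], float] = {}
    for a in NUCLEOTIDES:
        for ref in NUCLEOTIDES:
            for b in NUCLEOTIDES:
                ctx = a + ref + b
                for alt in NUCLEOTIDES:
                    if alt != ref:
                        table[(ctx, alt)] = float(1e-8 * rng.lognormal(0.0, 0.8))
    return table


def _random_gene(
    rng: np.random.Generator,
    cfg: SimConfig,
    gene_id: str,
    cursor: int,
) -> tuple[GeneModel, int]:
    cds_len = 3 * int(rng.integers(cfg.cds_aa_min, cfg.cds_aa_max + 1))
    max_exons = max(1, cds_len // 30)
    n_exons = min(1 + rng.poisson(max(cfg.mean_exons - 1, 0)), max_exons)
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False))
    else:
        cuts = np.array([], dtype=int)
    bounds = np.concatenate(([0], cuts, [cds_len]))
    lengths = np.diff(bounds)
    strand = "+" if rng.random() < 0.5 else "-"
    blocks = []
    pos = cursor
    for ln in lengths:
        blocks.append((pos, pos + int(ln)))
        pos += int(ln) + cfg.intron_length
    end = blocks[-1][1]
    exons = tuple(blocks) if strand == "+" else tuple(reversed(blocks))
    return GeneModel(gene_id=gene_id, chrom=cfg.chrom, strand=strand, coding_exons=exons), end


def _random_alignments(
    rng: np.random.Generator, cfg: SimConfig, gene: GeneModel
) -> list[DomainAlignment]:
    aa_len = gene.cds_length_nt // 3
    out: list[DomainAlignment] = []
    for _ in range(rng.poisson(cfg.mean_domains)):
        dom_len = int(rng.integers(cfg.domain_aa_min, cfg.domain_aa_max + 1))
        if dom_len >= aa_len:
            continue
        start = int(rng.integers(1, aa_len - dom_len + 1))
        end = start + dom_len - 1
        if any(start <= a.aa_end and a.aa_start <= end for a in out):
            continue
        out.append(
            DomainAlignment(
                gene_id=gene.gene_id,
                domain_id=f"cd{int(rng.integers(0, 5000)):05d}",
                aa_start=start,
                aa_end=end,
                evalue=float(10.0 ** -rng.uniform(3, 10)),
                score=float(rng.uniform(50, 250)),
            )
        )
    return out


def _genomic_positions(gene: GeneModel) -> np.ndarray:
    """Genomic coordinate of every CDS base, indexed by CDS position."""
    parts = []
    for s, e in gene.coding_exons:
        if gene.strand == "+":
            parts.append(np.arange(s, e))
        else:
            parts.append(np.arange(e - 1, s - 1, -1))
    return np.concatenate(parts)


def simulate_cohort(cfg: SimConfig, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``cfg``; deterministic for a
    fixed seed."""
    rng = np.random.default_rng(seed)
    rate_table = synthetic_rate_table(np.random.default_rng(seed + 1))

    genes: dict[str, GeneModel] = {}
    alignments: dict[str, list[DomainAlignment]] = {}
    flanked: dict[str, str] = {}
    cursor = 1000
    for i in range(cfg.n_genes):
        gid = f"G{i:04d}"
        gene, end = _random_gene(rng, cfg, gid, cursor)
        genes[gid] = gene
        alignments[gid] = _random_alignments(rng, cfg, gene)
        seq = rng.choice(list(NUCLEOTIDES), size=gene.cds_length_nt + 2)
        flanked[gid] = "".join(seq)
        cursor = end + cfg.intergenic_gap

    regions: list[SubRegion] = []
    for gid, gene in genes.items():
        regions.extend(build_domain_regions(gene, alignments[gid]))

    intolerant = {
        region_key(r) for r in regions if rng.random() < cfg.fraction_intolerant
    }

    rates = region_mutation_rates(regions, flanked, rate_table)

    sites: list[SiteRecord] = []
    for r in regions:
        gene = genes[r.gene_id]
        n_var = rng.poisson(r.length * cfg.variant_density)
        n_var = min(n_var, r.length)
        if n_var == 0:
            continue
        cds_pos = rng.choice(r.length, size=n_var, replace=False) + r.cds_start
        hot = region_key(r) in intolerant
        for cp in np.sort(cds_pos):
            block = map_cds_to_genomic(gene, int(cp), int(cp) + 1)[0]
            nonsyn = rng.random() < cfg.p_nonsynonymous
            p_common = cfg.p_common / (cfg.suppression if (hot and nonsyn) else 1.0)
            common = rng.random() < p_common
            maf = float(rng.uniform(0.0011, 0.05)) if common else float(rng.uniform(1e-5, 0.0009))
            low = rng.random() < cfg.low_coverage_fraction
            cov = float(rng.uniform(1.0, 9.5)) if low else float(max(10.0, rng.normal(cfg.coverage_mean, 10.0)))
            status = "LowQual" if rng.random() < cfg.fail_filter_fraction else "PASS"
            sites.append(
                SiteRecord(
                    chrom=gene.chrom,
                    pos=block[0],
                    mean_coverage=round(cov, 2),
                    filter_status=status,
                    is_variant=True,
                    alt_allele_frequency=round(maf, 6),
                    consequence="nonsynonymous" if nonsyn else "synonymous",
                )
            )

    conservation: dict[str, dict[int, float]] = {cfg.chrom: {}}
    track = conservation[cfg.chrom]
    for gid, gene in genes.items():
        gpos = _genomic_positions(gene)
        hot_mask = np.zeros(gene.cds_length_nt, dtype=bool)
        for r in regions:
            if r.gene_id == gid and region_key(r) in intolerant:
                hot_mask[r.cds_start : r.cds_end] = True
        covered = rng.random(gene.cds_length_nt) < cfg.conservation_coverage
        values = np.where(
            hot_mask,
            rng.normal(cfg.conserved_mean, 1.0, gene.cds_length_nt),
            rng.normal(cfg.neutral_mean, 1.5, gene.cds_length_nt),
        )
        for p, v in zip(gpos[covered], values[covered]):
            track[int(p)] = round(float(v), 3)

    pathogenic: list[ClinicalVariant] = []
    by_gene: dict[str, list[SubRegion]] = {}
    for r in regions:
        by_gene.setdefault(r.gene_id, []).append(r)
    for gid, gene in genes.items():
        gregs = by_gene[gid]
        m = rng.poisson(cfg.mean_pathogenic_per_gene)
        if m == 0:
            continue
        w = np.array(
            [
                rates[region_key(r)]
                * (cfg.pathogenic_enrichment if region_key(r) in intolerant else 1.0)
                for r in gregs
            ]
        )
        counts = rng.multinomial(m, w / w.sum())
        for r, c in zip(gregs, counts):
            if c == 0:
                continue
            cds_pos = rng.choice(r.length, size=min(c, r.length), replace=False) + r.cds_start
            for cp in np.sort(cds_pos):
                block = map_cds_to_genomic(gene, int(cp), int(cp) + 1)[0]
                source = "clinvar" if rng.random() < 0.5 else "hgmd"
                decoy = rng.random() < cfg.decoy_pathogenic_fraction
                if decoy:
                    label = "Likely pathogenic" if source == "clinvar" else "DM?"
                else:
                    label = "Pathogenic" if source == "clinvar" else "DM"
                terms = {"missense_variant"}
                if decoy and rng.random() < 0.5:
                    terms.add("splice_region_variant")
                ref = flanked[gid][int(cp) + 1]
                alt = NUCLEOTIDES[(NUCLEOTIDES.index(ref) + 1) % 4]
                pathogenic.append(
                    ClinicalVariant(
                        chrom=gene.chrom,
                        pos=int(block[0]),
                        ref=ref,
                        alt=alt,
                        source=source,
                        clinical_label=label,
                        canonical=True,
                        consequence_terms=frozenset(terms),
                    )
                )

    denovo = _simulate_denovo(rng, cfg, genes, by_gene, intolerant)

    return SyntheticCohort(
        config=cfg,
        genes=genes,
        alignments=alignments,
        flanked_cds=flanked,
        domain_regions=regions,
        sites=sites,
        conservation=conservation,
        pathogenic=pathogenic,
        denovo=denovo,
        rate_table=rate_table,
        intolerant_keys=intolerant,
    )


def _simulate_denovo(
    rng: np.random.Generator,
    cfg: SimConfig,
    genes: Mapping[str, GeneModel],
    by_gene: Mapping[str, list[SubRegion]],
    intolerant: set[tuple[str, int]],
) -> list[DeNovoMutation]:
    gene_ids = list(genes)
    out: list[DeNovoMutation] = []
    for cohort, n in (("case", cfg.n_denovo_case), ("control", cfg.n_denovo_control)):
        for _ in range(n):
            gid = gene_ids[int(rng.integers(len(gene_ids)))]
            gene = genes[gid]
            hot_regions = [r for r in by_gene[gid] if region_key(r) in intolerant]
            force_hot = cohort == "case" and hot_regions and rng.random() < cfg.case_signal
            if force_hot:
                r = hot_regions[int(rng.integers(len(hot_regions)))]
                cp = int(rng.integers(r.cds_start, r.cds_end))
                consequence = "missense"
                polyphen = float(rng.uniform(0.95, 1.0))
            else:
                cp = int(rng.integers(0, gene.cds_length_nt))
                u = rng.random()
                if u < 0.15:
                    consequence, polyphen = "synonymous", None
                elif u < 0.2:
                    consequence, polyphen = "stop_gain", None
                else:
                    consequence, polyphen = "missense", float(rng.beta(0.6, 0.6))
            block = map_cds_to_genomic(gene, cp, cp + 1)[0]
            out.append(
                DeNovoMutation(
                    chrom=gene.chrom,
                    pos=int(block[0]),
                    consequence=consequence,
                    polyphen2_humvar=None if polyphen is None else round(polyphen, 3),
                    cohort=cohort,
                    in_both_siblings=False,
                    validated_by=frozenset({"center_a"}),
                    call_labels={"center_a": "strong"},
                )
            )
    return out


def simulate_null_scores(n_regions: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Standard-normal score vector, independent of everything else — the
    null input for calibration checks."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal(n_regions)


def simulate_presence_data(
    n_regions: int,
    alpha: float,
    beta1: float,
    beta2: float,
    seed: int | np.random.Generator = 0,
    score_name: str = "score",
) -> GenomeTestInput:
    """Draw (Y, Z, X) directly from the genome-wide logistic model with
    known coefficients — the parameter-recovery oracle's data source.

    Z is lognormal (so log Z is standard normal), X standard normal with
    unit SD, and Y_i ~ Bernoulli(logit^{-1}(alpha + beta1 log Z_i +
    beta2 X_i)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_z = rng.standard_normal(n_regions)
    x = rng.standard_normal(n_regions)
    eta = alpha + beta1 * log_z + beta2 * x
    y = (rng.random(n_regions) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
    return GenomeTestInput(Y=y, Z=np.exp(log_z), scores={score_name: x})


def simulate_null_gene_inputs(
    n_genes: int,
    seed: int | np.random.Generator = 0,
    mean_regions: float = 5.0,
    mean_pathogenic: float = 4.0,
) -> list[GeneTestInput]:
    """Gene-test inputs drawn exactly from the multinomial null: pathogenic
    counts follow the mutation rates, scores are independent noise. Used
    for type-I-error calibration."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n_genes):
        n = 2 + rng.poisson(max(mean_regions - 2, 0))
        Z = rng.lognormal(0.0, 0.7, n)
        total = 1 + rng.poisson(max(mean_pathogenic - 1, 0))
        Y = rng.multinomial(total, Z / Z.sum()).astype(float)
        X = rng.standard_normal(n)
        out.append(GeneTestInput(gene_id=f"N{i:05d}", Y=Y, Z=Z, X=X))
    return out


def preset_config(name: str, **overrides) -> SimConfig:
    """Named demonstration scenarios.

    ``"concentrated"`` — most of a gene is tolerant but a small fraction of
    regions is strongly intolerant and carries nearly all pathogenic
    variants (the pattern of genes like MAPT). ``"graded"`` — intolerance
    is spread over roughly half the regions with milder contrast (the
    pattern of genes like ATP1A3). ``"null"`` — no planted signal.
    """
    presets = {
        "concentrated": SimConfig(fraction_intolerant=0.15, suppression=8.0, pathogenic_enrichment=10.0),
        "graded": SimConfig(fraction_intolerant=0.5, suppression=2.5, pathogenic_enrichment=3.0),
        "null": SimConfig(suppression=1.0, pathogenic_enrichment=1.0),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return replace(presets[name], **overrides)
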