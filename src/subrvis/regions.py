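"""Sub-region construction for protein-coding genes.

A gene's coding sequence (CDS) is the concatenation of its coding exons in
transcription order, giving a 0-based nucleotide coordinate space
``[0, cds_length_nt)``. Two divisions of that space into contiguous
sub-regions are supported:

* **domain division** — intervals aligned to conserved protein-domain
  models (e.g. RPS-BLAST hits against CDD) plus the unaligned stretches
  between, before and after them;
* **exon division** — one sub-region per coding exon.

Both divisions tile the CDS exactly, which is what the size-preserving
region-shuffle permutation test relies on. Genomic intervals follow the
BED convention (0-based, half-open); protein alignment coordinates follow
the BLAST convention (1-based, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "DomainAlignment",
    "SubRegion",
    "build_domain_regions",
    "build_exon_regions",
    "map_cds_to_genomic",
    "map_genomic_to_cds",
    "permute_region_sizes",
    "select_canonical",
    "UNALIGNED_LABEL",
]

UNALIGNED_LABEL = "unaligned"


@dataclass(frozen=True)
class GeneModel:
    """A gene's ordered coding exons, defining its CDS coordinate system.

    ``coding_exons`` are genomic half-open intervals listed in
    *transcription* order: ascending genomic start for ``+`` strand genes,
    descending for ``-`` strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    coding_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.coding_exons:
            raise ValueError(f"gene {self.gene_id}: at least one coding exon required")
        exons = tuple((int(s), int(e)) for s, e in self.coding_exons)
        object.__setattr__(self, "coding_exons", exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon interval ({s}, {e})")
        starts = [s for s, _ in exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(
                f"gene {self.gene_id}: exons must be in transcription order for strand {self.strand}"
            )
        genomic_sorted = sorted(exons)
        for (_, e1), (s2, _) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping coding exons")
        if self.cds_length_nt % 3 != 0:
            # tolerated: CCDS-style annotations occasionally carry
            # incomplete terminal codons
            logger.warning(
                "gene %s: CDS length %d not divisible by 3", self.gene_id, self.cds_length_nt
            )

    @property
    def cds_length_nt(self) -> int:
        return sum(e - s for s, e in self.coding_exons)

    @property
    def has_incomplete_codon(self) -> bool:
        return self.cds_length_nt % 3 != 0


@dataclass(frozen=True)
class DomainAlignment:
    """One profile-search hit: a protein-coordinate alignment of a gene to
    a conserved-domain model. ``aa_start``/``aa_end`` are 1-based inclusive."""

    gene_id: str
    domain_id: str
    aa_start: int
    aa_end: int
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise ValueError(f"{self.domain_id}: aa_start {self.aa_start} > aa_end {self.aa_end}")
        if self.aa_start < 1:
            raise ValueError(f"{self.domain_id}: aa_start must be >= 1")
        if self.evalue < 0:
            raise ValueError(f"{self.domain_id}: negative evalue")

    @property
    def cds_interval(self) -> tuple[int, int]:
        """The alignment's footprint in 0-based half-open CDS nucleotides."""
        return (self.aa_start - 1) * 3, self.aa_end * 3


@dataclass(frozen=True)
class SubRegion:
    """One contiguous CDS interval of a gene, with its genomic projection."""

    gene_id: str
    index: int
    label: str
    cds_start: int
    cds_end: int
    genomic_blocks: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.cds_end <= self.cds_start:
            raise ValueError(f"empty sub-region [{self.cds_start}, {self.cds_end})")
        if self.genomic_blocks:
            blen = sum(e - s for s, e in self.genomic_blocks)
            if blen != self.length:
                raise ValueError(
                    f"genomic blocks cover {blen} nt, CDS interval covers {self.length} nt"
                )

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start


def map_cds_to_genomic(gene: GeneModel, cds_start: int, cds_end: int) -> tuple[tuple[int, int], ...]:
    """Project a CDS interval onto genomic coordinates.

    Returns half-open genomic blocks in transcription order (descending
    genomic coordinate for minus-strand genes); their lengths sum to the
    interval length. An interval spanning an exon junction splits into one
    block per exon.
    """
    if not (0 <= cds_start < cds_end <= gene.cds_length_nt):
        raise ValueError(
            f"CDS interval [{cds_start}, {cds_end}) out of range for gene "
            f"{gene.gene_id} (CDS length {gene.cds_length_nt})"
        )
    blocks: list[tuple[int, int]] = []
    offset = 0
    for ex_start, ex_end in gene.coding_exons:
        ex_len = ex_end - ex_start
        lo = max(cds_start, offset)
        hi = min(cds_end, offset + ex_len)
        if lo < hi:
            if gene.strand == "+":
                blocks.append((ex_start + (lo - offset), ex_start + (hi - offset)))
            else:
                blocks.append((ex_end - (hi - offset), ex_end - (lo - offset)))
        offset += ex_len
    return tuple(blocks)


def map_genomic_to_cds(gene: GeneModel, position: int) -> int | None:
    """Inverse projection: genomic position -> CDS coordinate, or None if the
    position does not fall in a coding exon."""
    offset = 0
    for ex_start, ex_end in gene.coding_exons:
        if ex_start <= position < ex_end:
            if gene.strand == "+":
                return offset + (position - ex_start)
            return offset + (ex_end - 1 - position)
        offset += ex_end - ex_start
    return None


def _region(gene: GeneModel, index: int, label: str, start: int, end: int) -> SubRegion:
    return SubRegion(
        gene_id=gene.gene_id,
        index=index,
        label=label,
        cds_start=start,
        cds_end=end,
        genomic_blocks=map_cds_to_genomic(gene, start, end),
    )


def build_domain_regions(
    gene: GeneModel,
    alignments: Iterable[DomainAlignment],
    max_evalue: float = 1e-2,
) -> list[SubRegion]:
    """Divide a gene's CDS into domain-aligned and unaligned sub-regions.

    Alignments above ``max_evalue`` are discarded. Overlaps are resolved
    greedily: alignments are considered in descending bit score (ties by
    lower E-value, then domain id) and any alignment overlapping an
    already-kept one is dropped entirely. Every maximal unaligned stretch —
    including before the first and after the last kept alignment — becomes
    a sub-region labelled ``"unaligned"``, so the output tiles the CDS.

    Alignments extending past the CDS end are rejected with a warning.
    """
    candidates = []
    for aln in alignments:
        if aln.gene_id != gene.gene_id:
            raise ValueError(f"alignment for {aln.gene_id} passed with gene {gene.gene_id}")
        if aln.evalue > max_evalue:
            continue
        _, nt_end = aln.cds_interval
        if nt_end > gene.cds_length_nt:
            logger.warning(
                "gene %s: alignment %s (aa %d-%d) extends past CDS end; rejected",
                gene.gene_id, aln.domain_id, aln.aa_start, aln.aa_end,
            )
            continue
        candidates.append(aln)

    candidates.sort(key=lambda a: (-a.score, a.evalue, a.domain_id))
    kept: list[DomainAlignment] = []
    for aln in candidates:
        s, e = aln.cds_interval
        if any(s < ke and ks < e for ks, ke in (k.cds_interval for k in kept)):
            continue
        kept.append(aln)
    kept.sort(key=lambda a: a.cds_interval[0])

    regions: list[SubRegion] = []
    cursor = 0
    for aln in kept:
        s, e = aln.cds_interval
        if s > cursor:
            regions.append(_region(gene, len(regions), UNALIGNED_LABEL, cursor, s))
        regions.append(_region(gene, len(regions), aln.domain_id, s, e))
        cursor = e
    if cursor < gene.cds_length_nt:
        regions.append(_region(gene, len(regions), UNALIGNED_LABEL, cursor, gene.cds_length_nt))
    return regions


def build_exon_regions(gene: GeneModel) -> list[SubRegion]:
    """One sub-region per coding exon, in transcription order."""
    regions = []
    offset = 0
    for i, (s, e) in enumerate(gene.coding_exons):
        regions.append(_region(gene, i, f"exon_{i + 1}", offset, offset + (e - s)))
        offset += e - s
    return regions


def permute_region_sizes(
    gene: GeneModel,
    gene_regions: Sequence[SubRegion],
    seed: int | np.random.Generator,
) -> list[SubRegion]:
    """Randomly reorder a gene's sub-regions, re-laying them contiguously
    from CDS position 0.

    The output has the same number of regions and the same size multiset
    as the input (each region keeps its label), so the permuted division
    tiles the CDS exactly like the biological one.
    """
    if not gene_regions:
        raise ValueError("gene has no regions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(gene_regions))
    out = []
    cursor = 0
    for new_index, old_index in enumerate(order):
        src = gene_regions[old_index]
        out.append(_region(gene, new_index, src.label, cursor, cursor + src.length))
        cursor += src.length
    return out


def select_canonical(transcripts: Sequence[GeneModel]) -> GeneModel:
    """Pick a gene's canonical transcript: the longest CDS, ties broken by
    lexicographically smallest gene/transcript id."""
    if not transcripts:
        raise ValueError("no transcripts supplied")
    return min(transcripts, key=lambda g: (-g.cds_length_nt, g.gene_id))
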