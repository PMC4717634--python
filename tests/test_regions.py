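"""Sub-region construction: domain/exon divisions, coordinate projection,
and size-preserving permutation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from subrvis.regions import (
    DomainAlignment,
    GeneModel,
    build_domain_regions,
    build_exon_regions,
    map_cds_to_genomic,
    map_genomic_to_cds,
    permute_region_sizes,
    select_canonical,
)
from conftest import make_alignment


def intervals(regions):
    return [(r.cds_start, r.cds_end) for r in regions]


def assert_tiles(regions, cds_length):
    """Every division must partition [0, cds_length) exactly."""
    assert regions[0].cds_start == 0
    assert regions[-1].cds_end == cds_length
    for a, b in zip(regions, regions[1:]):
        assert a.cds_end == b.cds_start
    for r in regions:
        assert sum(e - s for s, e in r.genomic_blocks) == r.length


class TestDomainRegions:
    def test_two_alignments_give_five_tiling_regions(self, gene_900):
        alns = [
            make_alignment(domain_id="d1", aa_start=10, aa_end=50, score=100),
            make_alignment(domain_id="d2", aa_start=120, aa_end=200, score=80),
        ]
        regions = build_domain_regions(gene_900, alns)
        assert intervals(regions) == [(0, 27), (27, 150), (150, 357), (357, 600), (600, 900)]
        assert [r.label for r in regions] == ["unaligned", "d1", "unaligned", "d2", "unaligned"]
        assert_tiles(regions, 900)

    def test_no_alignments_single_unaligned_region(self, gene_900):
        regions = build_domain_regions(gene_900, [])
        assert intervals(regions) == [(0, 900)]
        assert regions[0].label == "unaligned"

    def test_lower_scoring_overlap_dropped_entirely(self, gene_900):
        alns = [
            make_alignment(domain_id="d1", aa_start=10, aa_end=50, score=100),
            make_alignment(domain_id="d2", aa_start=40, aa_end=90, score=60),
        ]
        regions = build_domain_regions(gene_900, alns)
        assert [r.label for r in regions] == ["unaligned", "d1", "unaligned"]
        assert intervals(regions) == [(0, 27), (27, 150), (150, 900)]

    def test_score_tie_broken_by_lower_evalue_then_domain_id(self, gene_900):
        alns = [
            make_alignment(domain_id="zzz", aa_start=10, aa_end=50, evalue=1e-9, score=100),
            make_alignment(domain_id="aaa", aa_start=40, aa_end=90, evalue=1e-6, score=100),
        ]
        regions = build_domain_regions(gene_900, alns)
        assert "zzz" in [r.label for r in regions]
        assert "aaa" not in [r.label for r in regions]

    def test_weak_evalue_discarded(self, gene_900):
        alns = [make_alignment(evalue=0.5)]
        assert intervals(build_domain_regions(gene_900, alns)) == [(0, 900)]

    def test_alignment_past_cds_end_rejected_with_warning(self, gene_900, caplog):
        alns = [make_alignment(aa_start=250, aa_end=350)]  # 350*3 > 900
        with caplog.at_level("WARNING"):
            regions = build_domain_regions(gene_900, alns)
        assert intervals(regions) == [(0, 900)]
        assert "rejected" in caplog.text

    def test_adjacent_alignments_leave_no_zero_length_gap(self, gene_900):
        alns = [
            make_alignment(domain_id="d1", aa_start=1, aa_end=50, score=100),
            make_alignment(domain_id="d2", aa_start=51, aa_end=300, score=90),
        ]
        regions = build_domain_regions(gene_900, alns)
        assert [r.label for r in regions] == ["d1", "d2"]
        assert_tiles(regions, 900)

    def test_foreign_gene_alignment_raises(self, gene_900):
        with pytest.raises(ValueError, match="passed with gene"):
            build_domain_regions(gene_900, [make_alignment(gene_id="OTHER")])


class TestExonRegions:
    def test_three_exons_tile_in_order(self, three_exon_gene):
        regions = build_exon_regions(three_exon_gene)
        assert intervals(regions) == [(0, 100), (100, 300), (300, 350)]
        assert_tiles(regions, 350)

    def test_single_exon_gene_is_whole_cds(self, gene_900):
        regions = build_exon_regions(gene_900)
        assert intervals(regions) == [(0, 900)]

    def test_minus_strand_blocks_descend_genomically(self, minus_gene):
        regions = build_exon_regions(minus_gene)
        assert intervals(regions) == [(0, 50), (50, 250), (250, 350)]
        # first region in transcription order is the 3'-most genomic exon
        assert regions[0].genomic_blocks == ((700, 750),)
        assert regions[2].genomic_blocks == ((0, 100),)
        # round trip through the coordinate map
        for r in regions:
            for s, e in r.genomic_blocks:
                for gpos in (s, e - 1):
                    cds = map_genomic_to_cds(minus_gene, gpos)
                    assert r.cds_start <= cds < r.cds_end


class TestCoordinateMap:
    def test_interval_inside_one_exon_is_one_block(self, three_exon_gene):
        assert map_cds_to_genomic(three_exon_gene, 10, 40) == ((10, 40),)

    def test_interval_spanning_intron_splits(self, three_exon_gene):
        blocks = map_cds_to_genomic(three_exon_gene, 90, 120)
        assert blocks == ((90, 100), (300, 320))

    def test_out_of_range_errors(self, three_exon_gene):
        with pytest.raises(ValueError):
            map_cds_to_genomic(three_exon_gene, 0, 351)
        with pytest.raises(ValueError):
            map_cds_to_genomic(three_exon_gene, 40, 40)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_map_unmap_roundtrip_on_random_genes(self, seed):
        rng = np.random.default_rng(seed)
        n_exons = int(rng.integers(1, 6))
        lengths = rng.integers(10, 200, n_exons)
        strand = "+" if rng.random() < 0.5 else "-"
        blocks, pos = [], 0
        for ln in lengths:
            blocks.append((pos, pos + int(ln)))
            pos += int(ln) + int(rng.integers(50, 300))
        exons = tuple(blocks) if strand == "+" else tuple(reversed(blocks))
        gene = GeneModel("R", "chrR", strand, exons)
        L = gene.cds_length_nt
        start = int(rng.integers(0, L))
        end = int(rng.integers(start + 1, L + 1))
        mapped = map_cds_to_genomic(gene, start, end)
        assert sum(e - s for s, e in mapped) == end - start
        covered = sorted(
            map_genomic_to_cds(gene, g) for s, e in mapped for g in range(s, e)
        )
        assert covered == list(range(start, end))


class TestPermutation:
    def test_single_region_unchanged(self, gene_900):
        regions = build_domain_regions(gene_900, [])
        out = permute_region_sizes(gene_900, regions, seed=3)
        assert intervals(out) == intervals(regions)

    def test_size_multiset_and_count_conserved(self, gene_900):
        alns = [
            make_alignment(domain_id="d1", aa_start=10, aa_end=50, score=100),
            make_alignment(domain_id="d2", aa_start=120, aa_end=200, score=80),
        ]
        regions = build_domain_regions(gene_900, alns)
        out = permute_region_sizes(gene_900, regions, seed=7)
        assert sorted(r.length for r in out) == sorted(r.length for r in regions)
        assert sorted(r.label for r in out) == sorted(r.label for r in regions)
        assert len(out) == len(regions)
        assert_tiles(out, 900)

    def test_seed_reproducibility_and_variation(self, gene_900):
        alns = [
            make_alignment(domain_id="d1", aa_start=10, aa_end=50, score=100),
            make_alignment(domain_id="d2", aa_start=120, aa_end=200, score=80),
        ]
        regions = build_domain_regions(gene_900, alns)
        a = permute_region_sizes(gene_900, regions, seed=5)
        b = permute_region_sizes(gene_900, regions, seed=5)
        assert intervals(a) == intervals(b)
        layouts = {tuple(intervals(permute_region_sizes(gene_900, regions, seed=s))) for s in range(20)}
        assert len(layouts) > 1


def test_select_canonical_longest_then_lexicographic():
    a = GeneModel("tx_b", "chr1", "+", ((0, 300),))
    b = GeneModel("tx_a", "chr1", "+", ((0, 300),))
    c = GeneModel("tx_c", "chr1", "+", ((0, 600),))
    assert select_canonical([a, b, c]).gene_id == "tx_c"
    assert select_canonical([a, b]).gene_id == "tx_a"


def test_gene_model_invariants():
    with pytest.raises(ValueError, match="strand"):
        GeneModel("X", "chr1", "*", ((0, 10),))
    with pytest.raises(ValueError, match="transcription order"):
        GeneModel("X", "chr1", "-", ((0, 10), (20, 30)))
    with pytest.raises(ValueError, match="overlap"):
        GeneModel("X", "chr1", "+", ((0, 10), (5, 30)))
    # non-multiple-of-3 CDS tolerated, flagged
    g = GeneModel("X", "chr1", "+", ((0, 10),))
    assert g.has_incomplete_codon
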