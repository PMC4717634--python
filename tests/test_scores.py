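"""Intolerance scoring: site qualification, count tallies, the subRVIS
regression against an independent studentization oracle, subGERP means,
mutation rates, and the per-gene variability score."""

import numpy as np
import pandas as pd
import pytest

from subrvis.regions import GeneModel, build_domain_regions, build_exon_regions
from subrvis.scores import (
    RegionCounts,
    SiteRecord,
    compute_mutation_rate,
    compute_subgerp,
    compute_subrvis,
    gene_variability_score,
    qualify_sites,
    region_mutation_rates,
    tally_region_counts,
)


def site(pos, cov=50.0, status="PASS", variant=True, maf=0.01, csq="nonsynonymous", chrom="chr1"):
    return SiteRecord(chrom, pos, cov, status, variant, maf, csq)


def ols_studentized_external(x, y):
    """Independent oracle: simple linear regression + leave-one-out
    (externally) studentized residuals from first principles."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    e = y - X @ beta
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    h = np.diag(H)
    sse = float(e @ e)
    p = 2
    out = np.empty(n)
    for i in range(n):
        s2_i = (sse - e[i] ** 2 / (1 - h[i])) / (n - p - 1)
        out[i] = e[i] / np.sqrt(s2_i * (1 - h[i]))
    return out


class TestQualifySites:
    def test_coverage_threshold_and_filter_status(self):
        sites = [site(1, cov=9.9), site(2, cov=10.0), site(3, status="LowQual"), site(4)]
        kept = qualify_sites(sites)
        assert [s.pos for s in kept] == [2, 4]

    def test_nonvariant_site_needs_only_coverage(self):
        s = site(1, variant=False, status=".", maf=0.0)
        assert qualify_sites([s]) == [s]

    def test_empty_input(self):
        assert qualify_sites([]) == []


class TestTally:
    def test_common_functional_uses_strict_maf_threshold(self):
        gene = GeneModel("G", "chr1", "+", ((0, 300),))
        regions = build_exon_regions(gene)
        sites = [
            site(10, maf=0.0005),                      # nonsyn, rare
            site(20, maf=0.002),                       # nonsyn, common
            site(30, maf=0.002, csq="synonymous"),     # common but synonymous
            site(40, maf=0.001),                       # exactly at threshold: not common
        ]
        counts = tally_region_counts(sites, regions, {"G": gene})
        assert counts[0].total_variants == 4
        assert counts[0].common_functional == 1

    def test_no_qualifying_sites_zero_counts(self):
        gene = GeneModel("G", "chr1", "+", ((0, 300),))
        counts = tally_region_counts([], build_exon_regions(gene), {"G": gene})
        assert (counts[0].total_variants, counts[0].common_functional) == (0, 0)

    def test_site_outside_all_regions_uncounted(self):
        gene = GeneModel("G", "chr1", "+", ((0, 300),))
        counts = tally_region_counts(
            [site(5000)], build_exon_regions(gene), {"G": gene}
        )
        assert counts[0].total_variants == 0


class TestSubrvis:
    TOY = [(10, 1), (20, 2), (30, 3), (10, 3), (20, 0), (30, 5)]

    def _counts(self, pairs):
        return [RegionCounts("G", i, t, c) for i, (t, c) in enumerate(pairs)]

    def test_matches_independent_studentization_oracle(self):
        scores = compute_subrvis(self._counts(self.TOY))
        expected = ols_studentized_external(
            [t for t, _ in self.TOY], [c for _, c in self.TOY]
        )
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-8)

    def test_counts_on_exact_line_score_zero(self):
        pairs = [(t, 2 + t // 10) for t in (10, 20, 30, 40)]
        scores = compute_subrvis(self._counts(pairs))
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_intercept_absorbs_constant_shift(self):
        s1 = compute_subrvis(self._counts(self.TOY))
        shifted = [(t, c + 7) for t, c in self.TOY]
        s2 = compute_subrvis(self._counts(shifted))
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_residuals_orthogonal_to_totals(self):
        rng = np.random.default_rng(4)
        total = rng.integers(5, 100, 500)
        common = rng.binomial(total, 0.2)
        counts = [RegionCounts("G", i, int(t), int(c)) for i, (t, c) in enumerate(zip(total, common))]
        # orthogonality holds for the raw residuals of the fitted line
        import statsmodels.api as sm

        fit = sm.OLS(common.astype(float), sm.add_constant(total.astype(float))).fit()
        corr = np.corrcoef(fit.resid, total)[0, 1]
        assert abs(corr) < 1e-10
        # and the studentized scores stay essentially uncorrelated too
        scores = compute_subrvis(counts)
        assert abs(np.corrcoef(scores, total)[0, 1]) < 1e-2

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_subrvis(self._counts([(10, 1), (10, 2), (10, 3)]))
        with pytest.raises(ValueError, match="at least 3"):
            compute_subrvis(self._counts([(10, 1), (20, 2)]))


class TestSubgerp:
    def test_constant_track_scores_constant(self):
        gene = GeneModel("G", "chr1", "+", ((0, 30), (50, 80)))
        regions = build_exon_regions(gene)
        track = {"chr1": {p: 1.5 for p in list(range(0, 30)) + list(range(50, 80))}}
        scores = compute_subgerp(track, regions, {"G": gene})
        np.testing.assert_allclose(scores.to_numpy(), 1.5)

    def test_mean_over_available_bases_only(self):
        gene = GeneModel("G", "chr1", "+", ((0, 3),))
        regions = build_exon_regions(gene)
        scores = compute_subgerp({"chr1": {0: 2.0, 1: 4.0}}, regions, {"G": gene})
        assert scores.iloc[0] == pytest.approx(3.0)

    def test_uncovered_region_is_missing(self):
        gene = GeneModel("G", "chr1", "+", ((0, 3),))
        scores = compute_subgerp({"chr1": {}}, build_exon_regions(gene), {"G": gene})
        assert np.isnan(scores.iloc[0])

    def test_random_sparse_track_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        gene = GeneModel("G", "chr1", "+", ((0, 120), (200, 260)))
        regions = build_exon_regions(gene)
        track = {
            "chr1": {
                int(p): float(rng.normal())
                for p in list(range(0, 120)) + list(range(200, 260))
                if rng.random() < 0.6
            }
        }
        scores = compute_subgerp(track, regions, {"G": gene})
        for r, got in zip(regions, scores):
            vals = [track["chr1"][p] for s, e in r.genomic_blocks for p in range(s, e) if p in track["chr1"]]
            assert got == pytest.approx(np.mean(vals))


class TestMutationRate:
    def test_uniform_table_closed_form(self):
        r = 2e-8
        table = {
            (a + b + c, alt): r
            for a in "ACGT" for b in "ACGT" for c in "ACGT" for alt in "ACGT" if alt != b
        }
        L = 8
        seq = "A" * (L + 2)
        assert compute_mutation_rate(seq, table) == pytest.approx(3 * L * r)

    def test_toy_sequence_hand_summed(self):
        # region = "CG" with flanks A...T; contexts ACG (ref C) and CGT (ref G)
        table = {("ACG", "T"): 1e-8, ("CGT", "A"): 3e-8}
        assert compute_mutation_rate("ACGT", table) == pytest.approx(4e-8)

    def test_linearity_in_table(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 50))
        table = {
            (a + b + c, alt): float(rng.random())
            for a in "ACGT" for b in "ACGT" for c in "ACGT" for alt in "ACGT" if alt != b
        }
        doubled = {k: 2 * v for k, v in table.items()}
        assert compute_mutation_rate(seq, doubled) == pytest.approx(
            2 * compute_mutation_rate(seq, table)
        )

    def test_n_context_skipped_and_short_sequence_zero(self):
        table = {("ACG", "T"): 1e-8}
        assert compute_mutation_rate("ANGT", table) == 0.0
        assert compute_mutation_rate("AT", table) == 0.0

    def test_region_rates_positive_on_synthetic_gene(self, small_cohort):
        rates = region_mutation_rates(
            small_cohort.domain_regions, small_cohort.flanked_cds, small_cohort.rate_table
        )
        assert (rates > 0).all()


class TestVariability:
    def _series(self, gene_scores):
        tuples = [(g, i) for g, vals in gene_scores.items() for i in range(len(vals))]
        values = [v for vals in gene_scores.values() for v in vals]
        idx = pd.MultiIndex.from_tuples(tuples, names=["gene_id", "region_index"])
        return pd.Series(values, index=idx)

    def test_min_region_rule_and_sample_sd(self):
        s = self._series({"A": [1.0, 1.0, 1.0], "B": [-1.0, 0.0, 1.0], "C": [1.0, 2.0]})
        out = gene_variability_score(s)
        assert out["A"] == pytest.approx(0.0)
        assert out["B"] == pytest.approx(1.0)
        assert np.isnan(out["C"])
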