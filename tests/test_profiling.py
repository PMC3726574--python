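"""Density profiles, enrichment statistics, expression calls and smRNA
mapping."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ltrsurvey.profiling import (
    ExpressionEvidence, call_expressed, centromere_enrichment,
    density_profile, expression_divergence, smrna_unique_hits,
    term_enrichment,
)


def el(start, end, chrom="chr1"):
    return type("El", (), {"start": start, "end": end, "chrom": chrom})()


class TestDensity:
    def test_single_window_concentration(self):
        elements = [el(i * 100, i * 100 + 50) for i in range(10)]
        profiles = density_profile(elements, {"chr1": 5_000_000},
                                   window_bp=1_000_000)
        assert profiles[0].fractions[0] == 1.0
        assert sum(profiles[0].fractions) == pytest.approx(1.0)

    def test_uniform_planting(self):
        rng = np.random.default_rng(1)
        mids = rng.integers(0, 10_000_000, size=2000)
        elements = [el(int(m), int(m) + 10) for m in mids]
        profiles = density_profile(elements, {"chr1": 10_000_000},
                                   window_bp=1_000_000)
        assert np.allclose(profiles[0].fractions, 0.1, atol=0.03)

    def test_fractions_sum_to_one_multichrom(self):
        elements = [el(100, 200, "chr1"), el(100, 200, "chr2"),
                    el(5000, 6000, "chr2")]
        profiles = density_profile(elements, {"chr1": 10_000, "chr2": 10_000},
                                   window_bp=1000)
        total = sum(sum(p.fractions) for p in profiles)
        assert total == pytest.approx(1.0)

    def test_element_beyond_chromosome(self):
        with pytest.raises(ValueError):
            density_profile([el(2_000_000, 2_000_100)], {"chr1": 100_000},
                            window_bp=10_000)


class TestCentromereEnrichment:
    def test_concentrated_elements_significant(self):
        elements = [el(500_000 + i * 100, 500_100 + i * 100) for i in range(50)]
        frac, p = centromere_enrichment(elements, centromere=505_000,
                                        chrom_length=5_000_000,
                                        radius_bp=100_000, seed=1)
        assert frac == 1.0 and p <= 0.01

    def test_uniform_fraction_matches_geometry(self):
        rng = np.random.default_rng(2)
        elements = [el(int(m), int(m) + 10)
                    for m in rng.integers(0, 4_000_000, size=3000)]
        frac, p = centromere_enrichment(elements, centromere=2_000_000,
                                        chrom_length=4_000_000,
                                        radius_bp=400_000, seed=3)
        assert abs(frac - 0.2) < 0.03  # 2 * radius / length
        assert p > 0.01

    def test_empty_elements_error(self):
        with pytest.raises(ValueError):
            centromere_enrichment([], 100, 10_000, 10)

    def test_radius_precondition(self):
        with pytest.raises(ValueError):
            centromere_enrichment([el(1, 2)], 100, 1000, 600)


class TestTermEnrichment:
    def test_perfectly_enriched_term(self):
        bg = {f"g{i}" for i in range(40)}
        table = {f"g{i}": {"T"} for i in range(8)}
        fg = {f"g{i}" for i in range(8)}
        res = term_enrichment(fg, bg, table, mode="go")
        r = res[0]
        # p equals the hypergeometric point mass of drawing all carriers
        expected = 1.0 / math.comb(40, 8) * math.comb(8, 8) * math.comb(32, 0)
        assert r.p_value == pytest.approx(expected, rel=1e-9)
        assert r.direction == "over" and r.significant

    def test_hypergeometric_matches_brute_force(self):
        """Tail sum over the hypergeometric pmf on small margins."""
        M, K, n = 50, 12, 15
        bg = {f"g{i}" for i in range(M)}
        table = {f"g{i}": {"T"} for i in range(K)}
        fg = {f"g{i}" for i in range(5, 5 + n)}
        k = len({g for g in fg if g in table})
        res = term_enrichment(fg, bg, table, mode="go")
        brute = sum(math.comb(K, x) * math.comb(M - K, n - x)
                    for x in range(k, min(K, n) + 1)) / math.comb(M, n)
        assert res[0].p_value == pytest.approx(brute, rel=1e-9)

    def test_domain_chi2_direction_and_p(self):
        """Table (10,90 / 10,890): 10% vs 1.1% -> over-represented."""
        bg = {f"g{i}" for i in range(1000)}
        fg = {f"g{i}" for i in range(100)}
        carriers = {f"g{i}" for i in range(10)} | \
                   {f"g{i}" for i in range(100, 110)}
        table = {g: {"D"} for g in carriers}
        res = term_enrichment(fg, bg, table, mode="domain")
        r = res[0]
        assert r.direction == "over"
        # expected count in the smallest cell is 2 (< 5), so the exact
        # test replaces the chi-square here
        t = np.array([[10, 90], [10, 890]])
        _, p_exact = stats.fisher_exact(t, alternative="two-sided")
        assert r.p_value == pytest.approx(p_exact)
        assert r.significant  # p < 0.01

    def test_domain_chi2_used_for_large_counts(self):
        bg = {f"g{i}" for i in range(1000)}
        fg = {f"g{i}" for i in range(200)}
        carriers = {f"g{i}" for i in range(60)} | \
                   {f"g{i}" for i in range(200, 260)}
        table = {g: {"D"} for g in carriers}
        r = term_enrichment(fg, bg, table, mode="domain")[0]
        t = np.array([[60, 140], [60, 740]])
        _, p_ref, _, _ = stats.chi2_contingency(t, correction=False)
        assert r.p_value == pytest.approx(p_ref)
        assert r.direction == "over" and r.significant

    def test_domain_small_counts_use_exact_test(self):
        bg = {f"g{i}" for i in range(30)}
        fg = {f"g{i}" for i in range(6)}
        table = {"g0": {"D"}, "g1": {"D"}, "g10": {"D"}}
        res = term_enrichment(fg, bg, table, mode="domain")
        t = np.array([[2, 4], [1, 23]])
        _, p_ref = stats.fisher_exact(t, alternative="two-sided")
        assert res[0].p_value == pytest.approx(p_ref)

    def test_fg_not_subset_raises(self):
        with pytest.raises(ValueError):
            term_enrichment({"a"}, {"b"}, {}, mode="go")

    def test_bh_fdr_monotone(self):
        rng = np.random.default_rng(5)
        bg = {f"g{i}" for i in range(200)}
        table = {}
        for t in range(20):
            for g in rng.choice(sorted(bg), size=30, replace=False):
                table.setdefault(g, set()).add(f"T{t}")
        fg = set(rng.choice(sorted(bg), size=40, replace=False))
        res = term_enrichment(fg, bg, table, mode="go")
        ordered = sorted(res, key=lambda r: r.p_value)
        for a, b in zip(ordered, ordered[1:]):
            assert a.fdr <= b.fdr + 1e-12
            assert a.fdr >= a.p_value - 1e-12

    def test_type_one_error_calibrated(self):
        """Random foregrounds: <= 7% of terms nominally significant."""
        rng = np.random.default_rng(6)
        bg = {f"g{i}" for i in range(300)}
        table = {}
        for t in range(25):
            for g in rng.choice(sorted(bg), size=40, replace=False):
                table.setdefault(g, set()).add(f"T{t}")
        n_tests = n_sig = 0
        for _ in range(10):
            fg = set(rng.choice(sorted(bg), size=50, replace=False))
            for r in term_enrichment(fg, bg, table, mode="go"):
                n_tests += 1
                n_sig += r.p_value < 0.05
        assert n_sig / n_tests <= 0.07


class TestExpression:
    def test_est_hit_fires(self):
        ev = ExpressionEvidence("g", est_hits=[(0.96, 0.92)])
        assert call_expressed(ev)

    def test_mpss_requires_both_signatures(self):
        assert not call_expressed(ExpressionEvidence("g", mpss_17=5, mpss_20=4))
        assert call_expressed(ExpressionEvidence("g", mpss_17=5, mpss_20=5))

    def test_no_evidence_not_expressed(self):
        assert not call_expressed(ExpressionEvidence("g"))

    def test_weak_est_does_not_fire(self):
        assert not call_expressed(
            ExpressionEvidence("g", est_hits=[(0.94, 0.99), (0.99, 0.85)]))

    @given(st.floats(0, 1), st.floats(0, 1),
           st.booleans(), st.booleans())
    def test_monotone_in_evidence(self, ident, cov, arr, rna):
        """Adding evidence never flips expressed -> not expressed."""
        base = ExpressionEvidence("g", est_hits=[(ident, cov)])
        more = ExpressionEvidence("g", est_hits=[(ident, cov), (0.99, 0.99)],
                                  mpss_17=9, mpss_20=9,
                                  array_expressed=arr, rnaseq_expressed=rna)
        assert not call_expressed(base) or call_expressed(more)

    def test_divergence_discordant_status(self):
        a = ExpressionEvidence("a", array_expressed=True)
        b = ExpressionEvidence("b")
        assert expression_divergence(a, b)

    def test_divergence_equal_abundance(self):
        a = ExpressionEvidence("a", mpss_17=10, mpss_20=10)
        b = ExpressionEvidence("b", mpss_17=10, mpss_20=10)
        assert not expression_divergence(a, b)

    def test_divergence_fold_change(self):
        a = ExpressionEvidence("a", mpss_17=40, mpss_20=40)
        b = ExpressionEvidence("b", mpss_17=10, mpss_20=10)
        assert expression_divergence(a, b)


class TestSmRNA:
    def test_unique_hit_reported(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=5000))
        gene = genome[1000:1600]
        smrna = gene[100:121]  # 21-mer
        hits, counts = smrna_unique_hits({"g1": gene}, {"s1": smrna}, genome)
        assert len(hits) == 1 and hits[0].genome_hit_count == 1
        assert counts["g1"] == 1

    def test_multimapper_excluded(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=21))
        genome = core + "".join(rng.choice(list("ACGT"), size=500)) + core
        hits, counts = smrna_unique_hits({"g1": core}, {"s1": core}, genome)
        assert hits == [] and counts["g1"] == 0

    def test_single_mismatch_excluded(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=3000))
        gene = genome[500:900]
        smrna = list(gene[50:71])
        smrna[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[smrna[10]]
        hits, _ = smrna_unique_hits({"g1": gene}, {"s1": "".join(smrna)}, genome)
        assert hits == []

    def test_length_bounds_enforced(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        gene = genome[100:400]
        hits, _ = smrna_unique_hits(
            {"g1": gene}, {"short": gene[10:25], "long": gene[10:45]}, genome)
        assert hits == []

    def test_reverse_strand_match(self, rng):
        from ltrsurvey.align import revcomp
        genome = "".join(rng.choice(list("ACGT"), size=3000))
        gene = genome[800:1200]
        smrna = revcomp(gene[200:222])
        hits, _ = smrna_unique_hits({"g1": gene}, {"s1": smrna}, genome)
        assert len(hits) == 1
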