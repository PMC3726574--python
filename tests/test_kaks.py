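"""NG86 Ka/Ks: codon alignment, site/difference counting against a
brute-force oracle, pairing, and distribution summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ng86_oracle import ng86_counts
from ltrsurvey.kaks import (
    CodonAlignment, CodonAlignmentError, codon_align, kaks_for_pair, ng86,
    pair_elements, pair_genes, summarize,
)
from ltrsurvey.simulate import (
    STOP_CODONS, random_cds, simulate_codon_pairs, translate,
)

SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in STOP_CODONS]

codon_pairs = st.lists(
    st.tuples(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS)),
    min_size=10, max_size=40)


class TestCodonAlign:
    def test_identical_cds(self, rng):
        cds = random_cds(60, rng)
        aln = codon_align(cds, cds)
        assert aln.n_codons == 59  # final stop codon is not aligned
        assert all(a == b for a, b in aln.codons)

    def test_gap_column_dropped(self, rng):
        cds = random_cds(60, rng)
        shorter = cds[:30] + cds[33:]  # remove one internal codon
        aln = codon_align(cds, shorter)
        assert aln.n_codons == 58

    def test_internal_stop_rejected(self, rng):
        cds = random_cds(60, rng)
        bad = cds[:30] + "TAA" + cds[33:]
        with pytest.raises(CodonAlignmentError):
            codon_align(cds, bad)

    def test_length_not_multiple_of_three(self, rng):
        cds = random_cds(60, rng)
        with pytest.raises(CodonAlignmentError):
            codon_align(cds, cds + "A")

    def test_mismatched_protein_alignment_rejected(self, rng):
        from ltrsurvey.align import global_protein_alignment
        cds_a = random_cds(60, rng)
        cds_b = random_cds(60, rng)
        wrong = global_protein_alignment("M" * 59, "K" * 59)
        with pytest.raises(CodonAlignmentError):
            codon_align(cds_a, cds_b, wrong)


class TestNG86:
    def test_hand_worked_example(self):
        """ATG AAA GGG TTT vs ATG AAG GGG TTT: one synonymous Lys change."""
        pairs = list(zip(["ATG", "AAA", "GGG", "TTT"],
                         ["ATG", "AAG", "GGG", "TTT"])) * 3
        r = ng86(CodonAlignment(codons=pairs))
        # per codon set: ATG 0, AAA 1/3, GGG 1, TTT 1/3 -> 5/3 sites
        assert r.S_sites == pytest.approx(5.0, abs=1e-12)
        assert r.Sd == pytest.approx(3.0) and r.Nd == 0.0
        assert r.Ka == 0.0
        assert r.Ks > 0

    def test_identical_sequences(self):
        pairs = [(c, c) for c in SENSE_CODONS[:12]]
        r = ng86(CodonAlignment(codons=pairs))
        assert r.Sd == r.Nd == 0.0
        assert r.Ka == 0.0 and r.Ks == 0.0
        assert math.isnan(r.ratio)

    def test_oracle_equivalence_random_pairs(self, rng):
        for _ in range(25):
            pairs = [(SENSE_CODONS[rng.integers(61)],
                      SENSE_CODONS[rng.integers(61)]) for _ in range(10)]
            r = ng86(CodonAlignment(codons=pairs))
            S, N, Sd, Nd = ng86_counts(pairs)
            assert abs(r.S_sites - S) < 1e-9
            assert abs(r.N_sites - N) < 1e-9
            assert abs(r.Sd - Sd) < 1e-9
            assert abs(r.Nd - Nd) < 1e-9

    @given(codon_pairs)
    def test_site_conservation(self, pairs):
        r = ng86(CodonAlignment(codons=pairs))
        assert r.S_sites + r.N_sites == pytest.approx(3 * len(pairs))

    @given(codon_pairs)
    def test_symmetry(self, pairs):
        r1 = ng86(CodonAlignment(codons=pairs))
        r2 = ng86(CodonAlignment(codons=[(b, a) for a, b in pairs]))
        assert r1.S_sites == pytest.approx(r2.S_sites)
        assert r1.Sd == pytest.approx(r2.Sd)
        assert r1.Nd == pytest.approx(r2.Nd)

    def test_saturated_proportion_undefined(self):
        # ps >= 3/4 puts Ks outside the Jukes-Cantor domain
        from ltrsurvey.kaks import KaKsResult
        r = KaKsResult(S_sites=10, N_sites=20, Sd=8.0, Nd=1.0)
        assert math.isnan(r.Ks)
        assert math.isnan(r.ratio)

    def test_too_few_codons(self):
        with pytest.raises(ValueError):
            ng86(CodonAlignment(codons=[("ATG", "ATG")] * 5))


class TestPairing:
    def test_expansion_pairs_found(self, small_sim, small_detection):
        _, genome, truth = small_sim
        pairs = pair_elements(small_detection, genome)
        # every planted parent/child lineage with both members detected
        # must appear among the called pairs
        by_truth = {}
        for e in truth.planted:
            det = next((d for d in small_detection
                        if abs(d.start - e.start) <= 10), None)
            if det:
                by_truth[e.id] = det.id
        expected = {frozenset((by_truth[e.id], by_truth[e.parent_element_id]))
                    for e in truth.planted
                    if e.parent_element_id in by_truth and e.id in by_truth}
        called = {frozenset((p.element_a, p.element_b)) for p in pairs}
        assert expected <= called
        for p in pairs:
            assert p.ltr5_identity >= 0.80 and p.ltr3_identity >= 0.80

    def test_single_element_no_pairs(self, small_detection, small_sim):
        _, genome, _ = small_sim
        assert pair_elements(small_detection[:1], genome) == []

    def test_gene_pairs_reciprocal(self, small_sim, small_detection):
        from ltrsurvey.capture import call_captured, load_annotation
        from ltrsurvey.simulate import write_truth_gff3
        import tempfile, os
        _, genome, truth = small_sim
        with tempfile.TemporaryDirectory() as td:
            path = os.path.join(td, "t.gff3")
            write_truth_gff3(truth, path)
            genes = load_annotation(path, {"chr1": genome})
        captured = call_captured(genes, small_detection)
        eps = pair_elements(small_detection, genome)
        gps = pair_genes(captured, eps, genes)
        seen_a = [g.gene_a for g in gps]
        assert len(seen_a) == len(set(seen_a))  # reciprocal best pairs only
        for gp in gps:
            assert gp.protein_identity >= 0.50


class TestSummarize:
    def test_all_identical(self, rng):
        cds = random_cds(60, rng)
        results = [kaks_for_pair(cds, cds) for _ in range(3)]
        s = summarize(results)
        assert s["mean_ka"] == 0.0 and s["mean_ks"] == 0.0
        assert s["n_defined"] == 0

    def test_frequencies_sum_to_one(self):
        pairs = simulate_codon_pairs(20, 100, omega=0.5, n_events=30, seed=2)
        s = summarize([kaks_for_pair(a, b) for a, b in pairs])
        assert sum(s["frequencies"]) == pytest.approx(1.0)

    def test_neutral_recovery(self):
        """Neutral simulation (omega=1) recovers mean Ka/Ks ~ 1 +/- 0.15."""
        pairs = simulate_codon_pairs(200, 300, omega=1.0, n_events=90, seed=4)
        s = summarize([kaks_for_pair(a, b) for a, b in pairs])
        assert abs(s["mean_ratio"] - 1.0) < 0.15

    def test_empty(self):
        assert summarize([]) == {"n": 0}
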