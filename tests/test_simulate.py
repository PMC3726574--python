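"""Simulator correctness: backgrounds, element structure, planting,
pseudogenization, truth round-trips and determinism."""

import numpy as np
import pytest

from ltrsurvey.simulate import (
    SimulationConfig, SimulationError, build_element, diverge_copy,
    generate_background, make_solo, mutate_cds, plant, pseudogenize,
    random_cds, read_truth_gff3, simulate_genome, translate,
    write_truth_gff3,
)


def gc_fraction(seq):
    return (seq.count("G") + seq.count("C")) / len(seq)


class TestBackground:
    def test_length_and_gc(self):
        seq = generate_background(10_000, 0.5, 1)
        assert len(seq) == 10_000
        assert abs(gc_fraction(seq) - 0.5) < 0.03  # binomial CI at n=1e4

    def test_extreme_gc(self):
        seq = generate_background(1000, 0.99, 2)
        assert gc_fraction(seq) >= 0.97

    def test_deterministic(self):
        assert generate_background(2000, 0.4, 7) == generate_background(2000, 0.4, 7)

    @pytest.mark.parametrize("length,gc", [(10, 0.5), (5000, 0.0), (5000, 1.0)])
    def test_invalid_inputs(self, length, gc):
        with pytest.raises(SimulationError):
            generate_background(length, gc, 0)


class TestBuildElement:
    def test_zero_divergence_ltrs_identical(self, rng):
        cfg = SimulationConfig(ltr_divergence=0.0)
        el = build_element(cfg, rng, with_gene=False)
        assert el.ltr5_seq == el.ltr3_seq

    def test_divergence_matches_identity(self, rng):
        """Observed LTR-LTR identity ~ 1 - divergence (Fig 3-style pairs)."""
        cfg = SimulationConfig(ltr_divergence=0.08)
        idents = []
        for _ in range(30):
            el = build_element(cfg, rng, with_gene=False)
            a, b = el.ltr5_seq, el.ltr3_seq
            idents.append(sum(x == y for x, y in zip(a, b)) / len(a))
        assert abs(np.mean(idents) - 0.92) < 0.02

    def test_structure_invariants(self, rng):
        cfg = SimulationConfig()
        el = build_element(cfg, rng, with_gene=True)
        for ltr in (el.ltr5_seq, el.ltr3_seq):
            assert ltr.startswith("TG") and ltr.endswith("CA")
        # PBS right after the 5'-LTR, PPT right before the 3'-LTR
        assert el.pbs_offset - el.ltr5_span[1] <= 20
        assert el.ltr3_span[0] - (el.ppt_offset + len(el.ppt_seq)) <= 20
        purines = sum(c in "AG" for c in el.ppt_seq) / len(el.ppt_seq)
        assert len(el.ppt_seq) >= 10 and purines >= 0.8

    def test_captured_gene_is_clean_orf(self, rng):
        cfg = SimulationConfig(capture_fraction=1.0)
        el = build_element(cfg, rng, with_gene=True)
        prot = translate(el.gene_cds)
        assert prot.startswith("M")
        assert "*" not in prot[:-1] and prot.endswith("*")

    def test_ltr_identity_mean_within_three_sd(self, rng):
        """E[identity] = 1 - d within 3 binomial SD over >= 50 elements."""
        d = 0.10
        cfg = SimulationConfig(ltr_divergence=d)
        total_sites = 0
        total_matches = 0
        for _ in range(50):
            el = build_element(cfg, rng, with_gene=False)
            a, b = el.ltr5_seq, el.ltr3_seq
            total_sites += len(a)
            total_matches += sum(x == y for x, y in zip(a, b))
        p = 1 - d
        sd = np.sqrt(p * (1 - p) / total_sites)
        # terminal dinucleotides are forced identical: allow for that bias
        assert abs(total_matches / total_sites - p) < 3 * sd + 4 / (total_sites / 50)


class TestPlant:
    def test_conservation_and_roundtrip(self, small_sim):
        cfg, genome, truth = small_sim
        planted_len = sum(len(e.seq) for e in truth.planted)
        planted_len += sum(len(s.seq) for s in truth.solos)
        tsd_len = sum(len(e.tsd_seq) for e in truth.planted)
        tsd_len += sum(len(s.tsd_seq) for s in truth.solos)
        assert len(genome) == cfg.genome_length + planted_len + tsd_len
        for e in truth.planted:
            assert genome[e.start:e.end] == e.seq
            L = len(e.tsd_seq)
            assert genome[e.start - L:e.start] == e.tsd_seq
            assert genome[e.end:e.end + L] == e.tsd_seq

    def test_solos_do_not_overlap_elements(self, small_sim):
        _, genome, truth = small_sim
        spans = truth.element_spans()
        for s in truth.solos:
            assert genome[s.span[0]:s.span[1]] == s.seq
            assert all(s.span[1] <= a or s.span[0] >= b for a, b in spans)

    def test_overfull_genome_rejected(self, rng):
        cfg = SimulationConfig(genome_length=10_000, n_full_elements=2)
        elements = [build_element(cfg, rng, f"e{i}", with_gene=False)
                    for i in range(2)]
        with pytest.raises(SimulationError):
            plant("A" * 10_000, elements, [], cfg, rng)


class TestPseudogenize:
    def test_identity_when_no_disablements(self, rng):
        cds = random_cds(60, rng)
        out, events = pseudogenize(cds, 0, 0, 1)
        assert out == cds and events == []

    def test_frameshift_changes_downstream_frame(self, rng):
        cds = random_cds(80, rng)
        out, events = pseudogenize(cds, 1, 0, 2)
        assert abs(len(out) - len(cds)) in (1, 2)
        assert events[0]["kind"] == "frameshift"
        codon = events[0]["codon"]
        # translation downstream of the indel no longer matches the parent
        parent_prot = translate(cds)
        child_prot = translate(out[:len(out) - len(out) % 3])
        assert child_prot[codon + 2:] != parent_prot[codon + 2:len(child_prot)]

    def test_premature_stop_created(self, rng):
        cds = random_cds(80, rng)
        out, events = pseudogenize(cds, 0, 1, 3)
        assert events[0]["kind"] == "premature_stop"
        assert "*" in translate(out)[:-1]

    def test_first_and_last_codons_untouched(self, rng):
        cds = random_cds(40, rng)
        for seed in range(5):
            out, _ = pseudogenize(cds, 1, 1, seed)
            assert out[:3] == cds[:3]
            assert out[-3:] == cds[-3:]

    def test_errors(self, rng):
        with pytest.raises(SimulationError):
            pseudogenize("ATGAAA", 1, 0, 0)  # too short
        with pytest.raises(SimulationError):
            pseudogenize(random_cds(30, rng) + "A", 0, 1, 0)  # not codon-sized
        with pytest.raises(SimulationError):
            pseudogenize(random_cds(30, rng), 20, 20, 0)  # too many events


class TestLineage:
    def test_diverge_copy_tracks_parent(self, rng):
        cfg = SimulationConfig()
        parent = build_element(cfg, rng, "p", with_gene=True)
        child = diverge_copy(parent, cfg, rng, "c")
        assert child.parent_element_id == "p"
        assert child.pbs_seq == parent.pbs_seq
        ident = sum(x == y for x, y in zip(child.ltr5_seq, parent.ltr5_seq)) \
            / len(parent.ltr5_seq)
        assert ident > 1 - cfg.copy_divergence - 0.05

    def test_mutate_cds_never_creates_stop(self, rng):
        cds = random_cds(120, rng)
        for _ in range(10):
            out = mutate_cds(cds, 0.1, rng)
            assert "*" not in translate(out)[:-1]

    def test_solo_comes_from_five_prime_ltr(self, rng):
        cfg = SimulationConfig(solo_divergence=0.05)
        el = build_element(cfg, rng, "src", with_gene=False)
        solo = make_solo(el, cfg, rng, "s1")
        ident = sum(x == y for x, y in zip(solo.seq, el.ltr5_seq)) / len(solo.seq)
        assert ident > 0.90 and solo.source_element_id == "src"


class TestTruthIO:
    def test_gff3_roundtrip(self, small_sim, tmp_path):
        _, genome, truth = small_sim
        path = tmp_path / "truth.gff3"
        write_truth_gff3(truth, path)
        back = read_truth_gff3(path, genome)
        assert back.as_records() == truth.as_records()

    def test_determinism(self):
        cfg = SimulationConfig(genome_length=50_000, n_full_elements=2,
                               n_solo=1, seed=9)
        g1, t1 = simulate_genome(cfg)
        g2, t2 = simulate_genome(cfg)
        assert g1 == g2
        assert t1.as_records() == t2.as_records()
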