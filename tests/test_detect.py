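"""Structural detector: seed pairing, identity, feature validation,
scoring and span limits."""

import numpy as np
import pytest

from ltrsurvey.align import revcomp
from ltrsurvey.detect import (
    CandidateRepeatPair, DetectionParams, LTRElement, StructuralFeatures,
    align_pair, detect, element_score, find_seed_pairs, score_and_filter,
    validate_structure,
)
from ltrsurvey.simulate import (
    SimulationConfig, build_element, generate_background, mutate_sequence,
)


def plant_at(background, element_seq, pos, tsd="ACGTA"):
    """Manual insertion with a fixed TSD; returns (genome, start, end)."""
    genome = background[:pos] + tsd + element_seq + tsd + background[pos:]
    start = pos + len(tsd)
    return genome, start, start + len(element_seq)


@pytest.fixture(scope="module")
def one_element_genome():
    rng = np.random.default_rng(21)
    cfg = SimulationConfig(ltr_divergence=0.05)
    el = build_element(cfg, rng, with_gene=False)
    bg = generate_background(100_000, 0.44, 22)
    genome, start, end = plant_at(bg, el.seq, 40_000)
    ltr_len = len(el.ltr5_seq)
    return genome, el, start, end, ltr_len


class TestSeedPairs:
    def test_planted_element_found(self, one_element_genome):
        genome, el, start, end, ltr_len = one_element_genome
        cands = find_seed_pairs(genome)
        true_left = (start, start + ltr_len)
        hits = []
        for c in cands:
            o = min(c.left_span[1], true_left[1]) - max(c.left_span[0], true_left[0])
            hits.append(o / ltr_len)
        assert max(hits) >= 0.9

    def test_random_genome_has_no_candidates(self):
        genome = generate_background(100_000, 0.44, 33)
        assert find_seed_pairs(genome) == []

    def test_no_cross_element_pairs_beyond_span_limit(self):
        """Same-family copies 30 kb apart never pair (20 kb limit)."""
        from ltrsurvey.simulate import diverge_copy
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(ltr_divergence=0.05)
        el_a = build_element(cfg, rng, "a", with_gene=False)
        el_b = diverge_copy(el_a, cfg, rng, "b")
        bg = generate_background(100_000, 0.44, 4)
        genome, a_start, a_end = plant_at(bg, el_a.seq, 20_000)
        genome, b_start, b_end = plant_at(genome, el_b.seq,
                                          50_000 + len(el_a.seq))
        params = DetectionParams()
        for c in find_seed_pairs(genome, params):
            assert c.right_span[1] - c.left_span[0] <= params.max_element_span + 100
        found = detect(genome)
        assert len(found) == 2
        starts = sorted(e.start for e in found)
        assert abs(starts[0] - a_start) <= 5 and abs(starts[1] - b_start) <= 5

    def test_n_only_sequence_is_empty_not_error(self):
        assert find_seed_pairs("N" * 5000) == []


class TestAlignPair:
    def test_identical_copies(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        genome = seq + "TTTT" + seq
        cand = CandidateRepeatPair("chr1", (0, 500), (504, 1004))
        assert align_pair(cand, genome).identity == 1.0

    def test_diverged_copies(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        other = mutate_sequence(seq, 0.08, rng)
        genome = seq + "TTTT" + other
        cand = CandidateRepeatPair("chr1", (0, 1000), (1004, 2004))
        assert abs(align_pair(cand, genome).identity - 0.92) < 0.02

    def test_reverse_complement_scores_near_background(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        genome = seq + "TTTT" + revcomp(seq)
        cand = CandidateRepeatPair("chr1", (0, 600), (604, 1204))
        assert align_pair(cand, genome).identity < 0.6


class TestValidateStructure:
    def test_planted_tsd_recovered(self, one_element_genome):
        genome, el, start, end, ltr_len = one_element_genome
        cand = CandidateRepeatPair("chr1", (start, start + ltr_len),
                                   (end - ltr_len, end))
        cand, feats = validate_structure(cand, genome)
        assert feats.tsd == "ACGTA"
        assert feats.tg_ca_5 and feats.tg_ca_3
        assert feats.pbs is not None and feats.ppt is not None

    def test_tandem_duplication_lacks_te_features(self):
        """A duplicated non-TE segment has no TSD/PBS/PPT."""
        rng = np.random.default_rng(8)
        seg = "".join(rng.choice(list("ACGT"), size=800))
        bg = generate_background(20_000, 0.44, 9)
        genome = bg[:10_000] + seg + "TT" + seg + bg[10_000:]
        cand = CandidateRepeatPair("chr1", (10_000, 10_800),
                                   (10_802, 11_602))
        cand, feats = validate_structure(cand, genome)
        absent = sum([feats.tsd is None, feats.pbs is None,
                      feats.ppt is None,
                      not (feats.tg_ca_5 and feats.tg_ca_3)])
        assert absent >= 2

    def test_out_of_genome_candidate_raises(self):
        cand = CandidateRepeatPair("chr1", (0, 200), (900, 1200))
        with pytest.raises(ValueError):
            validate_structure(cand, "ACGT" * 100)


class TestScoring:
    def full_features(self):
        return StructuralFeatures(tsd="ACGTA", tg_ca_5=True, tg_ca_3=True,
                                  pbs=(0, "X", "p"), ppt=(0, "X", 0.9),
                                  has_orf=True)

    def test_full_featured_score(self):
        params = DetectionParams()
        assert element_score(0.95, self.full_features(), params) == 7.5

    def test_identity_only_rejected(self):
        params = DetectionParams()
        cand = CandidateRepeatPair("chr1", (0, 300), (1000, 1300),
                                   identity=0.95)
        feats = StructuralFeatures(tg_ca_5=True, tg_ca_3=True)
        kept = score_and_filter([(cand, feats)], params)
        assert kept == []  # 2 + 1 = 3 < 6

    def test_overlap_resolution_keeps_higher_score(self):
        params = DetectionParams(require_tg_ca=False)
        c1 = CandidateRepeatPair("chr1", (0, 300), (5000, 5300), identity=0.95)
        f1 = self.full_features()
        c2 = CandidateRepeatPair("chr1", (100, 400), (4000, 4300),
                                 identity=0.95)
        f2 = self.full_features()
        f2.has_orf = False  # 6.5
        kept = score_and_filter([(c1, f1), (c2, f2)], params)
        assert len(kept) == 1 and kept[0].score == 7.5

    def test_output_spans_non_overlapping(self, small_detection):
        spans = sorted(e.span for e in small_detection)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_monotone_in_threshold(self, small_sim):
        _, genome, _ = small_sim
        n_default = len(detect(genome, DetectionParams(score_threshold=6.0)))
        n_high = len(detect(genome, DetectionParams(score_threshold=7.0)))
        assert n_high <= n_default


class TestDetectEndToEnd:
    def test_recall_and_boundaries(self, small_sim, small_detection):
        _, _, truth = small_sim
        recovered = 0
        for e in truth.planted:
            ok = any(abs(d.start - e.start) <= 5 and abs(d.end - e.end) <= 5
                     for d in small_detection)
            recovered += ok
        assert recovered / len(truth.planted) >= 0.85

    def test_background_only_genome_clean(self):
        for seed in range(3):
            genome = generate_background(300_000, 0.44, 50 + seed)
            assert detect(genome) == []

    def test_oversized_element_not_reported(self):
        """An LTR pair spanning 26 kb exceeds the 20 kb distance limit."""
        rng = np.random.default_rng(11)
        ltr = "TG" + "".join(rng.choice(list("ACGT"), size=996)) + "CA"
        internal = "".join(rng.choice(list("ACGT"), size=24_000))
        element = ltr + internal + ltr
        bg = generate_background(60_000, 0.44, 12)
        genome, start, end = plant_at(bg, element, 15_000)
        assert end - start == 26_000
        assert detect(genome) == []
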