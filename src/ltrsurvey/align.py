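"""Shared pairwise-alignment helpers.

All pairwise alignment in the package goes through Biopython's
``PairwiseAligner`` with the fixed parameter sets documented here:

* nucleotide: match +1, mismatch -1, gap open -2, gap extend -0.5
  (global for identity estimates, local for repeat-extent refinement);
* protein: BLOSUM62, gap open -10, gap extend -0.5 (global Needleman-Wunsch).

Identity is always computed as matched columns / total alignment columns,
so gap columns count as mismatches.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def _nt_aligner(mode: str, strict: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    if strict:
        # repeat-extent refinement: expected score on random DNA must be
        # negative, or local alignments drift into unrelated flanks
        aligner.mismatch_score = -2.0
        aligner.open_gap_score = -4.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -0.5
    return aligner


@lru_cache(maxsize=None)
def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity_from_alignment(alignment) -> tuple[float, int, int]:
    """Return (identity, n_matches, n_columns) for one pairwise alignment."""
    a, b = alignment.sequences
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        seg_a = a[a0:a1]
        seg_b = b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        aligned_cols += a1 - a0
    columns = alignment.length
    return (matches / columns if columns else 0.0), matches, columns


def global_nt_identity(a: str, b: str) -> float:
    """Global nucleotide identity; gaps count as mismatched columns."""
    if not a or not b:
        return 0.0
    alignment = _nt_aligner("global").align(a, b)[0]
    return _identity_from_alignment(alignment)[0]


def local_nt_alignment(a: str, b: str, strict: bool = False):
    """Best local (Smith-Waterman) alignment between two DNA strings.

    Returns the Biopython alignment object, or None when no positive-scoring
    alignment exists.
    """
    if not a or not b:
        return None
    alignments = _nt_aligner("local", strict).align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    return best


def local_alignment_extents(a: str, b: str):
    """Spans of the max-scoring core of the best local alignment.

    Returns ((a0, a1), (b0, b1)) or None. Smith-Waterman tracebacks can
    carry zero-net-score co-optimal tails (alternating match/mismatch or
    cheap gap runs), so the column path is re-scored and trimmed to its
    maximum-sum contiguous segment before reporting extents.
    """
    best = local_nt_alignment(a, b, strict=True)
    if best is None:
        return None
    a_blocks, b_blocks = best.aligned
    if len(a_blocks) == 0:
        return None
    # column list: (a_pos_before, b_pos_before, score)
    cols: list[tuple[int, int, float]] = []
    prev_a = int(a_blocks[0][0])
    prev_b = int(b_blocks[0][0])
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        a0, a1, b0, b1 = int(a0), int(a1), int(b0), int(b1)
        for run, is_a in ((a0 - prev_a, True), (b0 - prev_b, False)):
            for g in range(run):
                s = -4.0 if g == 0 else -1.0
                cols.append((prev_a + g if is_a else prev_a,
                             prev_b if is_a else prev_b + g, s))
        for off in range(a1 - a0):
            s = 1.0 if a[a0 + off] == b[b0 + off] else -2.0
            cols.append((a0 + off, b0 + off, s))
        prev_a, prev_b = a1, b1
    # maximum-sum contiguous segment (shortest among ties)
    best_sum = cur = 0.0
    best_seg = None
    seg_start = 0
    for i, (_, _, s) in enumerate(cols):
        if cur <= 0:
            cur = s
            seg_start = i
        else:
            cur += s
        if cur > best_sum:
            best_sum = cur
            best_seg = (seg_start, i)
    if best_seg is None:
        return None
    i0, i1 = best_seg
    a0 = cols[i0][0]
    b0 = cols[i0][1]
    a1 = cols[i1][0] + 1
    b1 = cols[i1][1] + 1
    return ((a0, a1), (b0, b1))


def global_protein_alignment(a: str, b: str):
    """Global BLOSUM62 protein alignment (Biopython alignment object)."""
    return _protein_aligner().align(a, b)[0]


def protein_identity(a: str, b: str) -> float:
    """Identity of the global protein alignment, gaps as mismatched columns."""
    if not a or not b:
        return 0.0
    return _identity_from_alignment(global_protein_alignment(a, b))[0]
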