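"""De novo structural detection of full-length LTR retrotransposons.

The detector mirrors the feature set classic structural annotators key on:
a pair of direct long terminal repeats within a bounded element span,
flanking target-site duplication (TSD), TG...CA LTR termini, a primer
binding site (PBS) just inside the 5'-LTR, a polypurine tract (PPT) just
upstream of the 3'-LTR, and an internal open reading frame.

Stages (each exposed separately, composed by :func:`detect`):

1. ``find_seed_pairs`` -- exact k-mer anchors chained on a shared diagonal
   into candidate direct-repeat pairs, refined by local alignment;
2. ``align_pair`` -- global alignment of the two repeat copies for an
   identity estimate;
3. ``validate_structure`` -- TSD / TG...CA / PBS / PPT / internal-ORF
   checks with small boundary-adjustment windows;
4. ``score_and_filter`` -- additive feature score, threshold, and greedy
   resolution of overlapping survivors.

Default limits follow standard practice for plant genomes: at most 20 kb
between LTR starts and ends, LTRs of 100 bp - 3.5 kb, minimum LTR-LTR
identity 0.80, and an acceptance score of 6.0 under the weights in
``score_and_filter``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import global_nt_identity, local_alignment_extents, revcomp
from .simulate import TRNA_PRIMERS

PURINES = frozenset("AG")
_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass
class DetectionParams:
    max_element_span: int = 20_000
    max_ltr_len: int = 3500
    min_ltr_len: int = 100
    min_ltr_identity: float = 0.80
    seed_k: int = 20
    score_threshold: float = 6.0
    require_tg_ca: bool = True
    tsd_len_range: tuple[int, int] = (4, 6)
    # chaining knobs
    diagonal_band: int = 30
    max_anchor_gap: int = 400
    max_kmer_occurrence: int = 50
    refine_pad: int = 40
    terminus_window: int = 20
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.min_ltr_len < self.max_ltr_len <= self.max_element_span // 2:
            raise ValueError("require min_ltr_len < max_ltr_len <= span/2")
        if not 0 < self.min_ltr_identity <= 1:
            raise ValueError("min_ltr_identity must be in (0, 1]")


@dataclass
class CandidateRepeatPair:
    chrom: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    n_anchors: int = 0
    identity: float | None = None

    @property
    def element_span(self) -> tuple[int, int]:
        return self.left_span[0], self.right_span[1]


@dataclass
class StructuralFeatures:
    tsd: str | None = None
    tg_ca_5: bool = False
    tg_ca_3: bool = False
    pbs: tuple[int, str, str] | None = None   # (offset, seq, primer name)
    ppt: tuple[int, str, float] | None = None  # (offset, seq, purine fraction)
    has_orf: bool = False


@dataclass
class LTRElement:
    id: str
    chrom: str
    start: int
    end: int
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int]
    ltr_identity: float
    score: float
    features: StructuralFeatures = field(default_factory=StructuralFeatures)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


# ---------------------------------------------------------------------------
# stage 1: seed pairs
# ---------------------------------------------------------------------------


def _kmer_codes(genome: str, k: int) -> np.ndarray:
    """2-bit packed codes of all k-mers; -1 where the window contains non-ACGT."""
    arr = _BASE_CODE[np.frombuffer(genome.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        window = arr[t:t + n]
        codes = codes * 4 + np.where(window < 4, window, 0)
        bad |= window >= 4
    codes[bad] = -1
    return codes


def _anchor_pairs(genome: str, params: DetectionParams) -> np.ndarray:
    """All (i, j) same-strand exact k-mer matches with 0 < j-i <= max span."""
    k = params.seed_k
    codes = _kmer_codes(genome, k)
    if codes.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    boundaries = np.nonzero(np.diff(sorted_codes))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [codes.size]])
    pairs = []
    for s, e in zip(starts, ends):
        if sorted_codes[s] < 0:
            continue
        count = e - s
        if count < 2 or count > params.max_kmer_occurrence:
            continue
        pos = np.sort(order[s:e])
        for a in range(count - 1):
            for b in range(a + 1, count):
                gap = pos[b] - pos[a]
                if gap > params.max_element_span:
                    break
                if gap >= params.min_ltr_len:
                    pairs.append((pos[a], pos[b]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(sorted(pairs), dtype=np.int64)


def _chain_anchors(pairs: np.ndarray, params: DetectionParams) -> list[tuple[int, int, int, int, int]]:
    """Group anchors by diagonal proximity into (i0, i1, j0, j1, n) chains."""
    if pairs.size == 0:
        return []
    diag = pairs[:, 1] - pairs[:, 0]
    order = np.lexsort((pairs[:, 0], diag))
    chains = []
    cur = None
    for idx in order:
        i, j = int(pairs[idx, 0]), int(pairs[idx, 1])
        d = j - i
        if (cur is not None
                and abs(d - cur["d"]) <= params.diagonal_band
                and -params.diagonal_band <= i - cur["i1"] <= params.max_anchor_gap):
            cur["i1"] = max(cur["i1"], i)
            cur["j1"] = max(cur["j1"], j)
            cur["n"] += 1
        else:
            if cur is not None:
                chains.append(cur)
            cur = {"i0": i, "i1": i, "j0": j, "j1": j, "d": d, "n": 1}
    if cur is not None:
        chains.append(cur)
    return [(c["i0"], c["i1"], c["j0"], c["j1"], c["n"]) for c in chains]


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 1.0


def find_seed_pairs(genome: str, params: DetectionParams | None = None,
                    chrom: str = "chr1") -> list[CandidateRepeatPair]:
    """Candidate direct-repeat pairs from chained exact k-mer anchors.

    Chains are refined by a local alignment of the two padded repeat
    regions so candidate spans track the true repeat extents; candidates
    shorter than ``min_ltr_len`` or violating the span limits are dropped.
    """
    params = params or DetectionParams()
    genome = genome.upper()
    k = params.seed_k
    candidates: list[CandidateRepeatPair] = []
    for i0, i1, j0, j1, n in _chain_anchors(_anchor_pairs(genome, params), params):
        left = (i0, i1 + k)
        right = (j0, j1 + k)
        if left[1] > right[0]:  # overlapping copies: tandem, not an LTR pair
            continue
        if right[1] - left[0] > params.max_element_span + 100:
            continue
        cand = _refine_candidate(genome, left, right, params, chrom, n)
        if cand is not None:
            candidates.append(cand)
    candidates.sort(key=lambda c: (c.left_span, c.right_span))
    return _merge_duplicate_candidates(candidates)


def _refine_candidate(genome: str, left: tuple[int, int], right: tuple[int, int],
                      params: DetectionParams, chrom: str,
                      n_anchors: int) -> CandidateRepeatPair | None:
    pad = params.refine_pad
    for _ in range(5):
        l0 = max(0, left[0] - pad)
        l1 = min(len(genome), left[1] + pad)
        r0 = max(0, right[0] - pad)
        r1 = min(len(genome), right[1] + pad)
        if l1 > r0:  # keep windows disjoint
            l1 = r0 = (l1 + r0) // 2
        a, b = genome[l0:l1], genome[r0:r1]
        if (_n_fraction(a) > params.max_n_fraction
                or _n_fraction(b) > params.max_n_fraction):
            return None
        ext = local_alignment_extents(a, b)
        if ext is None:
            return None
        (a0, a1), (b0, b1) = ext
        new_left = (l0 + a0, l0 + a1)
        new_right = (r0 + b0, r0 + b1)
        # alignment pinned at a window edge: the repeat probably continues
        edge = (a0 == 0 and l0 > 0) or (b0 == 0 and r0 > 0) \
            or (a1 == len(a) and l1 < r0) or (b1 == len(b) and r1 < len(genome))
        left, right = new_left, new_right
        if not edge or pad >= 640:
            break
        pad *= 2
    if (left[1] - left[0] < params.min_ltr_len
            or right[1] - right[0] < params.min_ltr_len):
        return None
    if (left[1] - left[0] > params.max_ltr_len
            or right[1] - right[0] > params.max_ltr_len):
        return None
    if right[1] - left[0] > params.max_element_span + 100:
        return None
    if left[1] > right[0]:
        return None
    return CandidateRepeatPair(chrom=chrom, left_span=left, right_span=right,
                               n_anchors=n_anchors)


def _merge_duplicate_candidates(cands: list[CandidateRepeatPair]
                                ) -> list[CandidateRepeatPair]:
    """Collapse chains that refined to essentially the same repeat pair."""
    out: list[CandidateRepeatPair] = []
    for c in cands:
        dup = False
        for o in out:
            if (abs(c.left_span[0] - o.left_span[0]) <= 20
                    and abs(c.right_span[1] - o.right_span[1]) <= 20):
                o.n_anchors = max(o.n_anchors, c.n_anchors)
                dup = True
                break
        if dup:
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# stage 2: identity
# ---------------------------------------------------------------------------


def align_pair(candidate: CandidateRepeatPair, genome: str) -> CandidateRepeatPair:
    """Global alignment of the two repeat copies; identity = matches/columns."""
    a = genome[slice(*candidate.left_span)]
    b = genome[slice(*candidate.right_span)]
    candidate.identity = global_nt_identity(a, b)
    return candidate


# ---------------------------------------------------------------------------
# stage 3: structural validation
# ---------------------------------------------------------------------------


def _dinuc_shifts(genome: str, pos: int, dinuc: str, anchor: str,
                  window: int) -> list[int]:
    """Shifts within +/-window placing the boundary on `dinuc`, nearest first.

    ``anchor`` is 'start' (dinucleotide begins at pos+shift) or 'end'
    (dinucleotide ends at pos+shift).
    """
    out = []
    for shift in sorted(range(-window, window + 1), key=abs):
        p = pos + shift
        if anchor == "start":
            if 0 <= p and genome[p:p + 2] == dinuc:
                out.append(shift)
        else:
            if p >= 2 and genome[p - 2:p] == dinuc:
                out.append(shift)
    return out


def _find_tsd(genome: str, start: int, end: int,
              len_range: tuple[int, int]) -> str | None:
    """Longest 4-6 bp host duplication immediately flanking the element."""
    lo, hi = len_range
    for L in range(hi, lo - 1, -1):
        if start - L < 0 or end + L > len(genome):
            continue
        if genome[start - L:start] == genome[end:end + L]:
            return genome[start - L:start]
    return None


def _match_count(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def _find_pbs(genome: str, ltr5_end: int, search: int = 20,
              min_match: int = 14) -> tuple[int, str, str] | None:
    """>=14/18 complement match to a library tRNA primer just inside the LTR."""
    best = None
    for name, primer in TRNA_PRIMERS.items():
        target = revcomp(primer)
        L = len(target)
        for off in range(search + 1):
            window = genome[ltr5_end + off:ltr5_end + off + L]
            if len(window) < L:
                break
            m = _match_count(window, target)
            if m >= min_match and (best is None or m > best[3]):
                best = (ltr5_end + off, window, name, m)
    if best is None:
        return None
    return best[0], best[1], best[2]


def _find_ppt(genome: str, ltr3_start: int, search: int = 30,
              min_len: int = 10, min_purine: float = 0.80
              ) -> tuple[int, str, float] | None:
    """Purine-rich window (>=10 nt, >=80% A/G) just upstream of the 3'-LTR."""
    region_start = max(0, ltr3_start - search - min_len)
    region = genome[region_start:ltr3_start]
    best = None
    for L in range(min(len(region), 20), min_len - 1, -1):
        for s in range(len(region) - L + 1):
            window = region[s:s + L]
            frac = sum(c in PURINES for c in window) / L
            if frac >= min_purine:
                cand = (region_start + s, window, frac)
                if best is None or len(window) > len(best[1]):
                    best = cand
        if best is not None:
            break
    return best


def _has_internal_orf(internal: str, min_len: int = 300) -> bool:
    """ATG-to-stop ORF of >= min_len bases on either strand, any frame."""
    for seq in (internal, revcomp(internal)):
        for frame in range(3):
            start = None
            for p in range(frame, len(seq) - 2, 3):
                codon = seq[p:p + 3]
                if codon == "ATG" and start is None:
                    start = p
                elif codon in ("TAA", "TAG", "TGA"):
                    if start is not None and p + 3 - start >= min_len:
                        return True
                    start = None
            if start is not None and len(seq) - start >= min_len:
                return True
    return False


def validate_structure(candidate: CandidateRepeatPair, genome: str,
                       params: DetectionParams | None = None
                       ) -> tuple[CandidateRepeatPair, StructuralFeatures]:
    """TSD / TG...CA / PBS / PPT / internal-ORF checks for one candidate.

    Boundaries are first nudged (<= ``boundary_adjust`` bp) onto TG / CA
    dinucleotides where possible; the candidate spans are updated in place
    so downstream coordinates reflect the adjusted termini.
    """
    params = params or DetectionParams()
    if candidate.left_span[0] < 0 or candidate.right_span[1] > len(genome):
        raise ValueError("candidate spans fall outside the genome")
    w = params.terminus_window
    l0, l1 = candidate.left_span
    r0, r1 = candidate.right_span

    feats = StructuralFeatures()
    # outer termini: element start must begin TG, element end must end CA;
    # among candidate shifts prefer the pair supported by an exact TSD
    start_shifts = _dinuc_shifts(genome, l0, "TG", "start", w) or [0]
    end_shifts = _dinuc_shifts(genome, r1, "CA", "end", w) or [0]
    best = None
    for ds in start_shifts:
        for de in end_shifts:
            tsd = _find_tsd(genome, l0 + ds, r1 + de, params.tsd_len_range)
            key = (tsd is not None, -(abs(ds) + abs(de)))
            if best is None or key > best[0]:
                best = (key, ds, de, tsd)
    _, ds, de, tsd = best
    l0 += ds
    r1 += de
    feats.tsd = tsd
    # inner termini: 5'-LTR must end CA, 3'-LTR must begin TG
    in_end = _dinuc_shifts(genome, l1, "CA", "end", w)
    in_start = _dinuc_shifts(genome, r0, "TG", "start", w)
    if in_end:
        l1 += in_end[0]
    if in_start:
        r0 += in_start[0]
    feats.tg_ca_5 = genome[l0:l0 + 2] == "TG" and genome[l1 - 2:l1] == "CA"
    feats.tg_ca_3 = genome[r0:r0 + 2] == "TG" and genome[r1 - 2:r1] == "CA"
    candidate.left_span, candidate.right_span = (l0, l1), (r0, r1)
    feats.pbs = _find_pbs(genome, l1)
    feats.ppt = _find_ppt(genome, r0)
    internal = genome[l1:r0]
    feats.has_orf = _has_internal_orf(internal)
    return candidate, feats


# ---------------------------------------------------------------------------
# stage 4: scoring and overlap resolution
# ---------------------------------------------------------------------------

SCORE_WEIGHTS = {
    "ltr_identity": 2.0,
    "tsd": 1.5,
    "tg_ca": 1.0,
    "pbs": 1.0,
    "ppt": 1.0,
    "orf": 1.0,
}


def element_score(identity: float, feats: StructuralFeatures,
                  params: DetectionParams) -> float:
    score = 0.0
    if identity >= params.min_ltr_identity:
        score += SCORE_WEIGHTS["ltr_identity"]
    if feats.tsd is not None:
        score += SCORE_WEIGHTS["tsd"]
    if feats.tg_ca_5 and feats.tg_ca_3:
        score += SCORE_WEIGHTS["tg_ca"]
    if feats.pbs is not None:
        score += SCORE_WEIGHTS["pbs"]
    if feats.ppt is not None:
        score += SCORE_WEIGHTS["ppt"]
    if feats.has_orf:
        score += SCORE_WEIGHTS["orf"]
    return score


def score_and_filter(candidates_with_features:
                     list[tuple[CandidateRepeatPair, StructuralFeatures]],
                     params: DetectionParams | None = None) -> list[LTRElement]:
    """Additive feature score; keep score >= threshold, resolve overlaps.

    Overlapping survivors are resolved by keeping the higher score, ties by
    smaller span, then leftmost start.
    """
    params = params or DetectionParams()
    kept: list[LTRElement] = []
    for cand, feats in candidates_with_features:
        identity = cand.identity if cand.identity is not None else 0.0
        if identity < params.min_ltr_identity:
            continue
        if params.require_tg_ca and not (feats.tg_ca_5 and feats.tg_ca_3):
            continue
        score = element_score(identity, feats, params)
        if score < params.score_threshold:
            continue
        start, end = cand.element_span
        kept.append(LTRElement(
            id="", chrom=cand.chrom, start=start, end=end,
            ltr5_span=cand.left_span, ltr3_span=cand.right_span,
            ltr_identity=identity, score=score, features=feats))
    kept.sort(key=lambda e: (-e.score, e.end - e.start, e.start))
    resolved: list[LTRElement] = []
    for e in kept:
        if any(not (e.end <= o.start or e.start >= o.end) for o in resolved):
            continue
        resolved.append(e)
    resolved.sort(key=lambda e: (e.chrom, e.start))
    for i, e in enumerate(resolved, 1):
        e.id = f"LTRRT_{i:04d}"
    return resolved


def detect(genome: str, params: DetectionParams | None = None,
           chrom: str = "chr1") -> list[LTRElement]:
    """Full detection pass over one sequence; output sorted by (chrom, start)."""
    params = params or DetectionParams()
    genome = genome.upper()
    cands = find_seed_pairs(genome, params, chrom)
    scored = []
    for cand in cands:
        align_pair(cand, genome)
        if cand.identity is None or cand.identity < params.min_ltr_identity:
            continue
        cand, feats = validate_structure(cand, genome, params)
        align_pair(cand, genome)  # identity over the adjusted spans
        scored.append((cand, feats))
    return score_and_filter(scored, params)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_elements_gff3(elements: list[LTRElement], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for e in elements:
        attrs = (f"ID={e.id};ltr_identity={e.ltr_identity:.4f};"
                 f"score={e.score:.1f};tsd={e.features.tsd or '.'}")
        lines.append("\t".join([e.chrom, "ltrsurvey", "LTR_retrotransposon",
                                str(e.start + 1), str(e.end), f"{e.score:.1f}",
                                "+", ".", attrs]))
        for tag, span in (("ltr5", e.ltr5_span), ("ltr3", e.ltr3_span)):
            lines.append("\t".join([
                e.chrom, "ltrsurvey", "long_terminal_repeat",
                str(span[0] + 1), str(span[1]), ".", "+", ".",
                f"ID={e.id}_{tag};Parent={e.id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_elements_tsv(elements: list[LTRElement], path: str | Path) -> None:
    import pandas as pd
    rows = []
    for e in elements:
        f = e.features
        rows.append({
            "id": e.id, "chrom": e.chrom, "start": e.start, "end": e.end,
            "ltr5_start": e.ltr5_span[0], "ltr5_end": e.ltr5_span[1],
            "ltr3_start": e.ltr3_span[0], "ltr3_end": e.ltr3_span[1],
            "ltr_identity": round(e.ltr_identity, 4), "score": e.score,
            "tsd": f.tsd or "", "tg_ca": f.tg_ca_5 and f.tg_ca_3,
            "pbs_offset": f.pbs[0] if f.pbs else -1,
            "pbs": f.pbs[1] if f.pbs else "",
            "ppt_offset": f.ppt[0] if f.ppt else -1,
            "ppt": f.ppt[1] if f.ppt else "",
            "internal_orf": f.has_orf,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_elements_tsv(path: str | Path) -> list[LTRElement]:
    """Reload detector output written by :func:`write_elements_tsv`."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        feats = StructuralFeatures(
            tsd=(r["tsd"] or None),
            tg_ca_5=bool(r["tg_ca"]), tg_ca_3=bool(r["tg_ca"]),
            pbs=((int(r["pbs_offset"]), r["pbs"], "")
                 if r["pbs"] else None),
            ppt=((int(r["ppt_offset"]), r["ppt"], 1.0)
                 if r["ppt"] else None),
            has_orf=bool(r["internal_orf"]))
        out.append(LTRElement(
            id=r["id"], chrom=r["chrom"], start=int(r["start"]),
            end=int(r["end"]),
            ltr5_span=(int(r["ltr5_start"]), int(r["ltr5_end"])),
            ltr3_span=(int(r["ltr3_start"]), int(r["ltr3_end"])),
            ltr_identity=float(r["ltr_identity"]), score=float(r["score"]),
            features=feats))
    return out
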