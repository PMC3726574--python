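"""Solo-LTR discovery by family profiles.

Solo LTRs are single long terminal repeats left behind when unequal
recombination between the two LTRs of a full-length element deletes the
internal region. They carry no internal features, so they are found by
sequence profile rather than by structure:

1. LTR sequences harvested from detected full-length elements are
   clustered into families (greedy centroid clustering at >= 80% identity
   over >= 80% of the representative's length);
2. each family is summarized as a position-weight log-odds matrix built
   from a star alignment of the members to the representative (pseudocount
   0.5 per base, log-odds against the genome's base composition);
3. the genome is scanned on both strands with the profile; hit
   significance is calibrated empirically against length-matched windows
   of a dinucleotide-shuffled genome (Gumbel tail fit), and hits are kept
   at E <= 1.0e-9;
4. hits overlapping any full-length element are removed and the rest must
   realign to the family representative at >= 70% identity (gaps counted
   as mismatches).

The E-value cutoff and the 70% identity floor are the thresholds used for
solo-LTR calling in genome surveys of rice and sorghum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree
from scipy import signal, stats

from .align import global_nt_identity, revcomp

E_VALUE_CUTOFF = 1.0e-9
MIN_SOLO_IDENTITY = 0.70

_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class LTRCluster:
    id: str
    members: list[str]
    representative: str  # longest member

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class LTRProfile:
    cluster_id: str
    matrix: np.ndarray           # (length, 4) log-odds
    background: np.ndarray       # genome base frequencies used
    null_loc: float = 0.0        # Gumbel location of null block maxima
    null_scale: float = 1.0      # Gumbel scale
    null_block: int = 1          # windows per block in the maxima fit

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def evalue(self, score: float, n_windows: int) -> float:
        """Expected number of null windows scoring >= `score`.

        The Gumbel is fitted to block maxima, so the per-window exceedance
        probability is the fitted survival divided by the block size.
        """
        sf = stats.gumbel_r.sf(score, loc=self.null_loc, scale=self.null_scale)
        return float(sf / max(1, self.null_block) * n_windows)


@dataclass
class ProfileHit:
    chrom: str
    span: tuple[int, int]
    strand: str
    cluster_id: str
    score: float
    e_value: float


@dataclass
class SoloLTR:
    chrom: str
    span: tuple[int, int]
    strand: str
    cluster_id: str
    score: float
    e_value: float
    identity_to_representative: float
    has_tsd: bool = False


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_ltrs(ltr_seqs: list[str], cluster_identity: float = 0.80,
                 min_coverage: float = 0.80) -> list[LTRCluster]:
    """Greedy centroid clustering of LTR sequences.

    Sequences are sorted by length (descending); each joins the first
    cluster whose representative it matches at >= `cluster_identity` over
    >= `min_coverage` of the shorter/longer length ratio, else founds a
    new cluster. The representative is the founding (longest) member.
    """
    clusters: list[LTRCluster] = []
    for seq in sorted(ltr_seqs, key=len, reverse=True):
        placed = False
        for cl in clusters:
            rep = cl.representative
            if min(len(seq), len(rep)) / max(len(seq), len(rep)) < min_coverage:
                continue
            if global_nt_identity(seq, rep) >= cluster_identity:
                cl.members.append(seq)
                placed = True
                break
        if not placed:
            clusters.append(LTRCluster(id=f"fam_{len(clusters) + 1:03d}",
                                       members=[seq], representative=seq))
    return clusters


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------


def _star_columns(cluster: LTRCluster) -> np.ndarray:
    """Per-column base counts from a star alignment to the representative.

    Insertions relative to the representative are ignored; deletions leave
    the column's count row untouched (gap). Returns (rep_len, 5) counts,
    the 5th column counting gaps.
    """
    from .align import local_nt_alignment

    rep = cluster.representative
    counts = np.zeros((len(rep), 5))
    for i, b in enumerate(rep):
        counts[i, _IDX[b]] += 1.0
    for member in cluster.members:
        if member is cluster.representative:
            continue
        aln = local_nt_alignment(rep, member, strict=False)
        if aln is None:
            counts[:, 4] += 1.0
            continue
        covered = np.zeros(len(rep), dtype=bool)
        rep_blocks, mem_blocks = aln.aligned
        for (r0, r1), (m0, m1) in zip(rep_blocks, mem_blocks):
            for off in range(r1 - r0):
                counts[r0 + off, _IDX[member[m0 + off]]] += 1.0
                covered[r0 + off] = True
        counts[~covered, 4] += 1.0
    return counts


def genome_base_frequencies(genome: str) -> np.ndarray:
    arr = np.array([genome.count(b) for b in "ACGT"], dtype=float)
    total = arr.sum()
    if total == 0:
        return np.full(4, 0.25)
    return arr / total


def build_profile(cluster: LTRCluster, genome_background: np.ndarray | str,
                  pseudocount: float = 0.5,
                  max_gap_fraction: float = 0.5) -> LTRProfile:
    """Position-weight log-odds matrix for one LTR family.

    Columns with more than `max_gap_fraction` gaps are removed; remaining
    per-column probabilities use `pseudocount` per base and are log-odds
    scored against the genome base composition.
    """
    if isinstance(genome_background, str):
        genome_background = genome_base_frequencies(genome_background)
    counts = _star_columns(cluster)
    n = len(cluster.members)
    keep = counts[:, 4] <= max_gap_fraction * n
    base_counts = counts[keep, :4] + pseudocount
    probs = base_counts / base_counts.sum(axis=1, keepdims=True)
    if probs.size == 0:
        raise ValueError("cluster alignment has no usable columns")
    matrix = np.log(probs / genome_background[None, :])
    return LTRProfile(cluster_id=cluster.id, matrix=matrix,
                      background=np.asarray(genome_background, dtype=float))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _encode_onehot(genome: str) -> np.ndarray:
    arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    onehot = np.zeros((4, len(arr)))
    for b, i in _IDX.items():
        onehot[i] = arr == ord(b)
    return onehot


class GenomeScanner:
    """Cached per-strand base-indicator spectra for fast profile scans.

    Scanning k profiles over the same genome shares the expensive forward
    FFTs of the four base-indicator tracks; each profile then costs four
    small kernel FFTs plus one inverse transform per strand.
    """

    def __init__(self, genome: str, max_profile_len: int = 4000):
        from scipy.fft import next_fast_len, rfft
        self.n = len(genome)
        self.nfft = next_fast_len(self.n + max_profile_len)
        self.spectra: dict[str, np.ndarray] = {}
        for strand, seq in (("+", genome), ("-", revcomp(genome))):
            onehot = _encode_onehot(seq)
            self.spectra[strand] = rfft(onehot, self.nfft, axis=1)

    def window_scores(self, profile: LTRProfile, strand: str) -> np.ndarray:
        from scipy.fft import irfft, rfft
        L = profile.length
        if self.n < L:
            return np.empty(0)
        kernels = rfft(profile.matrix[::-1, :].T, self.nfft, axis=1)
        spec = (self.spectra[strand] * kernels).sum(axis=0)
        full = irfft(spec, self.nfft)
        return full[L - 1:self.n]


def _window_scores(genome: str, profile: LTRProfile) -> np.ndarray:
    """Profile score of every window start (FFT cross-correlation)."""
    L = profile.length
    if len(genome) < L:
        return np.empty(0)
    onehot = _encode_onehot(genome)
    scores = np.zeros(len(genome) - L + 1)
    for i in range(4):
        scores += signal.fftconvolve(onehot[i], profile.matrix[::-1, i],
                                     mode="valid")
    return scores


def dinucleotide_shuffle(genome: str, seed: int) -> str:
    """Composition-preserving shuffle of the genome's dinucleotide list."""
    rng = np.random.default_rng(seed)
    pairs = [genome[i:i + 2] for i in range(0, len(genome) - 1, 2)]
    rng.shuffle(pairs)
    tail = genome[-1] if len(genome) % 2 else ""
    return "".join(pairs) + tail


def calibrate_null(profile: LTRProfile, genome: str, n_blocks: int = 1000,
                   seed: int = 0,
                   shuffled_scanner: "GenomeScanner | None" = None) -> LTRProfile:
    """Empirical extreme-value null from a dinucleotide-shuffled genome.

    The profile is scored at every position of a shuffled copy of the
    genome; the score track is cut into `n_blocks` blocks and a right
    Gumbel is fitted to the block maxima. Fitting maxima (rather than bulk
    scores) captures the tail that an E-value actually depends on; the
    block size is stored so exceedance converts back to per-window terms.
    """
    if shuffled_scanner is None:
        shuffled_scanner = GenomeScanner(dinucleotide_shuffle(genome, seed),
                                         profile.length + 10)
    scores = shuffled_scanner.window_scores(profile, "+")
    if scores.size == 0:
        raise ValueError("genome shorter than profile")
    n_blocks = min(n_blocks, max(1, scores.size // 50))
    block = scores.size // n_blocks
    maxima = scores[:block * n_blocks].reshape(n_blocks, block).max(axis=1)
    loc, scale = stats.gumbel_r.fit(maxima)
    profile.null_loc = float(loc)
    profile.null_scale = float(max(scale, 1e-6))
    profile.null_block = block
    return profile




def scan_genome(genome: str, profile: LTRProfile,
                e_cutoff: float = E_VALUE_CUTOFF, chrom: str = "chr1",
                calibrate_seed: int = 0,
                scanner: GenomeScanner | None = None) -> list[ProfileHit]:
    """Both-strand profile scan; hits at E <= `e_cutoff`, overlaps merged.

    E = Gumbel exceedance probability of the window score under the
    shuffled-genome null, multiplied by the number of windows scanned
    (both strands).
    """
    genome = genome.upper()
    if profile.null_scale == 1.0 and profile.null_loc == 0.0:
        calibrate_null(profile, genome, seed=calibrate_seed)
    L = profile.length
    n_windows = max(1, 2 * (len(genome) - L + 1))
    hits: list[ProfileHit] = []
    for strand in ("+", "-"):
        if scanner is not None:
            scores = scanner.window_scores(profile, strand)
        else:
            seq = genome if strand == "+" else revcomp(genome)
            scores = _window_scores(seq, profile)
        if scores.size == 0:
            continue
        # minimum score reaching the cutoff under the fitted null
        idx = np.nonzero(stats.gumbel_r.sf(
            scores, loc=profile.null_loc, scale=profile.null_scale)
            * n_windows <= e_cutoff)[0]
        for i in idx:
            if strand == "+":
                span = (int(i), int(i) + L)
            else:
                span = (len(genome) - int(i) - L, len(genome) - int(i))
            hits.append(ProfileHit(
                chrom=chrom, span=span, strand=strand,
                cluster_id=profile.cluster_id, score=float(scores[i]),
                e_value=profile.evalue(float(scores[i]), n_windows)))
    return merge_hits(hits)


def merge_hits(hits: list[ProfileHit]) -> list[ProfileHit]:
    """Collapse overlapping hits, keeping the best score per locus."""
    kept: list[ProfileHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        if any(h.chrom == k.chrom
               and h.span[0] < k.span[1] and k.span[0] < h.span[1]
               for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.span))
    return kept


# ---------------------------------------------------------------------------
# solo calling
# ---------------------------------------------------------------------------


def call_solos(hits: list[ProfileHit], full_elements, genome: str,
               representatives: dict[str, str],
               min_identity: float = MIN_SOLO_IDENTITY,
               tsd_len_range: tuple[int, int] = (4, 6)) -> list[SoloLTR]:
    """Filter profile hits into solo-LTR calls.

    Hits overlapping a full-length element by >= 1 bp are removed (those
    are the elements' own LTRs); the rest must realign to the family
    representative at >= `min_identity` (gap columns count as mismatches).
    TSD presence is recorded but not required.
    """
    tree = IntervalTree()
    for el in full_elements:
        start, end = (el.span if hasattr(el, "span") else el)
        if end > start:
            tree[start:end] = True
    solos: list[SoloLTR] = []
    for h in hits:
        if tree.overlap(h.span[0], h.span[1]):
            continue
        seq = genome[h.span[0]:h.span[1]]
        if h.strand == "-":
            seq = revcomp(seq)
        rep = representatives[h.cluster_id]
        identity = global_nt_identity(seq, rep)
        if identity < min_identity:
            continue
        has_tsd = _flank_tsd(genome, h.span, tsd_len_range)
        solos.append(SoloLTR(
            chrom=h.chrom, span=h.span, strand=h.strand,
            cluster_id=h.cluster_id, score=h.score, e_value=h.e_value,
            identity_to_representative=identity, has_tsd=has_tsd))
    return solos


def _flank_tsd(genome: str, span: tuple[int, int],
               len_range: tuple[int, int]) -> bool:
    s, e = span
    for L in range(len_range[1], len_range[0] - 1, -1):
        if s - L >= 0 and e + L <= len(genome) \
                and genome[s - L:s] == genome[e:e + L]:
            return True
    return False


def find_solos(genome: str, full_elements, chrom: str = "chr1",
               e_cutoff: float = E_VALUE_CUTOFF,
               min_identity: float = MIN_SOLO_IDENTITY,
               calibrate_seed: int = 0) -> list[SoloLTR]:
    """Cluster element LTRs, build/calibrate profiles, scan, call solos."""
    ltr_seqs = []
    for el in full_elements:
        ltr_seqs.append(genome[el.ltr5_span[0]:el.ltr5_span[1]])
        ltr_seqs.append(genome[el.ltr3_span[0]:el.ltr3_span[1]])
    if not ltr_seqs:
        return []
    clusters = cluster_ltrs(ltr_seqs)
    background = genome_base_frequencies(genome)
    max_len = max(len(s) for s in ltr_seqs) + 10
    scanner = GenomeScanner(genome, max_len)
    shuffled_scanner = GenomeScanner(
        dinucleotide_shuffle(genome, calibrate_seed), max_len)
    hits: list[ProfileHit] = []
    reps: dict[str, str] = {}
    for cl in clusters:
        profile = build_profile(cl, background)
        calibrate_null(profile, genome, seed=calibrate_seed,
                       shuffled_scanner=shuffled_scanner)
        hits.extend(scan_genome(genome, profile, e_cutoff, chrom,
                                calibrate_seed, scanner=scanner))
        reps[cl.id] = cl.representative
    return call_solos(hits, full_elements, genome, reps, min_identity)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_solos_bed(solos: list[SoloLTR], path: str | Path) -> None:
    lines = []
    for i, s in enumerate(solos, 1):
        lines.append("\t".join([
            s.chrom, str(s.span[0]), str(s.span[1]), f"solo_{i:04d}",
            f"{s.score:.1f}", s.strand]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_solos_tsv(solos: list[SoloLTR], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "chrom": s.chrom, "start": s.span[0], "end": s.span[1],
        "strand": s.strand, "cluster_id": s.cluster_id,
        "score": round(s.score, 2), "e_value": s.e_value,
        "identity": round(s.identity_to_representative, 4),
        "has_tsd": s.has_tsd,
    } for s in solos]).to_csv(path, sep="\t", index=False)
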