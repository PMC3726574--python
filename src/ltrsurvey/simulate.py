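"""Synthetic genomes with planted LTR retrotransposons and ground truth.

The simulator emulates the structure an LTR-retrotransposon annotation
pipeline keys on: paired long terminal repeats at a configurable divergence,
TG...CA termini, a 4-6 bp target-site duplication (TSD) flanking every
insertion, a primer-binding site (PBS) immediately downstream of the 5'-LTR,
a polypurine tract (PPT) immediately upstream of the 3'-LTR, optional
captured protein-coding genes inside the internal region, recombination-
derived solo LTRs, diverged element copies (expansion pairs), and
pseudogenized gene copies with known disablement counts.

Every planted object is recorded in a :class:`TruthSet` with exact
coordinates so detector recall, boundary accuracy, solo recovery, capture
calling and pseudogene classification can all be scored against ground
truth.

Divergence model: the 3'-LTR is derived from the 5'-LTR by per-site
Bernoulli substitutions at the configured rate, each hit site guaranteed to
change base, so expected LTR-LTR identity is exactly ``1 - divergence``.
No indels are introduced unless requested, keeping identity analytically
predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote, unquote

import numpy as np

from .align import revcomp

BASES = np.array(["A", "C", "G", "T"])
STOP_CODONS = ("TAA", "TAG", "TGA")

# Built-in tRNA primer 3'-end library (18 nt each). The PBS planted in an
# element is the reverse complement of one of these. Real retroelements
# prime minus-strand synthesis on host tRNAs (most often initiator Met);
# the precise set is a free choice here.
TRNA_PRIMERS = {
    "tRNA-iMet": "TGGCGCCCAACGTGGGGC",
    "tRNA-Trp": "TGGTGACCCCGACGTGAT",
    "tRNA-Pro": "TGGGGTCTCCCCGCGCAG",
}


class SimulationError(ValueError):
    """Raised for invalid simulator configuration or impossible layouts."""


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Defaults describe a 2 Mb chromosome carrying 20 full-length elements
    (half of them gene-carrying, half of the gene carriers arranged in
    parent/child expansion pairs) and 10 solo LTRs, with 5% LTR-LTR
    divergence -- young, fully featured insertions of the kind a structural
    detector is expected to recover.
    """

    genome_length: int = 2_000_000
    gc_content: float = 0.44  # rice-like background
    n_full_elements: int = 20
    n_solo: int = 10
    ltr_length_range: tuple[int, int] = (250, 1200)
    internal_length_range: tuple[int, int] = (2500, 6000)
    ltr_divergence: float = 0.05
    tsd_length_range: tuple[int, int] = (4, 6)
    capture_fraction: float = 0.5
    pseudogene_fraction: float = 0.5
    # fraction of gene-carrying elements that are diverged copies of another
    # gene-carrying element (expansion pairs); effective maximum 0.5
    expansion_fraction: float = 0.5
    # divergence of a planted solo LTR from its source element's 5'-LTR
    solo_divergence: float = 0.10
    # divergence between a child copy and its parent element
    copy_divergence: float = 0.08
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise SimulationError("genome_length must be >= 1000")
        if not 0.0 < self.gc_content < 1.0:
            raise SimulationError("gc_content must be in (0, 1)")
        for name in ("ltr_divergence", "capture_fraction", "pseudogene_fraction",
                     "expansion_fraction", "solo_divergence", "copy_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.ltr_divergence > 0.3:
            raise SimulationError("ltr_divergence above 0.3 is not supported")
        lo, hi = self.ltr_length_range
        if not 50 <= lo <= hi:
            raise SimulationError("invalid ltr_length_range")
        if hi > 3500:
            raise SimulationError("ltr_length_range.max must be <= 3500 bp")
        ilo, ihi = self.internal_length_range
        if not 100 <= ilo <= ihi:
            raise SimulationError("invalid internal_length_range")
        if 2 * hi + ihi > 20_000:
            raise SimulationError(
                "2*max LTR + max internal exceeds the 20 kb detectable span")
        tlo, thi = self.tsd_length_range
        if not 1 <= tlo <= thi:
            raise SimulationError("invalid tsd_length_range")


@dataclass
class PlantedElement:
    """One planted full-length element.

    Coordinates are 0-based half-open. Before :func:`plant` is called,
    ``start`` is None and the span fields are element-relative; planting
    shifts them to genome coordinates.
    """

    id: str
    seq: str
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int]
    pbs_offset: int
    pbs_seq: str
    ppt_offset: int
    ppt_seq: str
    ltr_divergence: float
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    tsd_seq: str = ""
    captured_gene_id: str | None = None
    gene_span: tuple[int, int] | None = None  # CDS span, same frame as spans
    gene_cds: str | None = None
    parent_element_id: str | None = None
    is_pseudogenized: bool = False

    def _rel(self, span: tuple[int, int]) -> tuple[int, int]:
        if self.start is None:
            return span
        return span[0] - self.start, span[1] - self.start

    @property
    def ltr5_seq(self) -> str:
        s, e = self._rel(self.ltr5_span)
        return self.seq[s:e]

    @property
    def ltr3_seq(self) -> str:
        s, e = self._rel(self.ltr3_span)
        return self.seq[s:e]


@dataclass
class PlantedSolo:
    id: str
    seq: str
    source_element_id: str
    chrom: str | None = None
    span: tuple[int, int] | None = None
    tsd_seq: str = ""


@dataclass
class GeneModelTruth:
    gene_id: str
    cds: str
    protein: str
    chrom: str | None = None
    span: tuple[int, int] | None = None
    strand: str = "+"
    parent_gene_id: str | None = None
    description: str = "hypothetical protein"


@dataclass
class TruthSet:
    """Ground truth for one simulated genome."""

    chrom: str
    genome_length: int
    planted: list[PlantedElement] = field(default_factory=list)
    solos: list[PlantedSolo] = field(default_factory=list)
    gene_models: list[GeneModelTruth] = field(default_factory=list)

    def element_spans(self) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.planted]

    def as_records(self) -> list[dict]:
        """GFF-visible fields of every planted object, for round-trip tests."""
        recs: list[dict] = []
        for e in self.planted:
            recs.append({
                "kind": "element", "id": e.id, "chrom": e.chrom,
                "start": e.start, "end": e.end,
                "ltr5": e.ltr5_span, "ltr3": e.ltr3_span,
                "tsd": e.tsd_seq, "pbs": (e.pbs_offset, e.pbs_seq),
                "ppt": (e.ppt_offset, e.ppt_seq),
                "captured_gene": e.captured_gene_id,
                "parent_element": e.parent_element_id,
                "pseudogenized": e.is_pseudogenized,
            })
        for s in self.solos:
            recs.append({
                "kind": "solo", "id": s.id, "chrom": s.chrom,
                "start": s.span[0], "end": s.span[1],
                "source_element": s.source_element_id, "tsd": s.tsd_seq,
            })
        for g in self.gene_models:
            recs.append({
                "kind": "gene", "id": g.gene_id, "chrom": g.chrom,
                "start": g.span[0], "end": g.span[1], "strand": g.strand,
                "parent_gene": g.parent_gene_id,
                "description": g.description,
            })
        return sorted(recs, key=lambda r: (r["kind"], r["id"]))


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------


def generate_background(length: int, gc: float, seed: int) -> str:
    """I.i.d. random genome of `length` bases with expected GC fraction `gc`."""
    if length < 1000:
        raise SimulationError("background length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise SimulationError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator,
                    protect: frozenset[int] | set[int] = frozenset()) -> str:
    """Per-site Bernoulli substitutions; every hit site changes base."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in protect:
            continue
        old = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != old]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons-2) random sense codons + one stop codon."""
    if n_codons < 10:
        raise SimulationError("CDS must have >= 10 codons")
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


def mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only CDS mutation that never creates an internal stop.

    The ATG start and the terminal stop codon are left untouched; any
    substitution that would turn an internal codon into a stop is skipped.
    """
    out = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for ci in range(1, len(out) - 1):
        codon = out[ci]
        new = list(codon)
        for pos in range(3):
            if rng.random() < rate:
                choices = [b for b in "ACGT" if b != codon[pos]]
                new[pos] = choices[rng.integers(3)]
        cand = "".join(new)
        if cand not in STOP_CODONS:
            out[ci] = cand
    return "".join(out)


def translate(cds: str) -> str:
    """Translate, silently dropping a trailing partial codon."""
    from Bio.Seq import Seq
    usable = cds[:len(cds) - len(cds) % 3]
    return str(Seq(usable).translate())


def pseudogenize(cds: str, n_frameshift: int, n_premature_stop: int,
                 seed: int | np.random.Generator) -> tuple[str, list[dict]]:
    """Disable a CDS with exact counts of frameshifts and premature stops.

    Frameshifts are 1-2 bp insertions or deletions; premature stops are
    codon substitutions to TAA/TAG/TGA. Neither touches the first or last
    codon, and stop substitutions are confined to the first 85% of the CDS
    so they are unambiguously premature. Returns the mutated CDS and a list
    of event records ``{"kind", "codon", "detail"}``.
    """
    if len(cds) % 3 != 0:
        raise SimulationError("CDS length must be a multiple of 3")
    n_codons = len(cds) // 3
    if n_codons < 30:
        raise SimulationError("CDS must have >= 30 codons")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stop_limit = max(2, int(n_codons * 0.85))
    avail_stop = list(range(1, stop_limit))
    avail_fs = list(range(1, n_codons - 1))
    if n_premature_stop > len(avail_stop) or n_frameshift + n_premature_stop > len(avail_fs):
        raise SimulationError("requested disablements exceed available positions")

    events: list[dict] = []
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    stop_sites = sorted(rng.choice(avail_stop, size=n_premature_stop, replace=False)) \
        if n_premature_stop else []
    for ci in stop_sites:
        codons[int(ci)] = STOP_CODONS[rng.integers(3)]
        events.append({"kind": "premature_stop", "codon": int(ci),
                       "detail": codons[int(ci)]})

    seq = "".join(codons)
    fs_codons = [c for c in avail_fs if c not in set(stop_sites)]
    chosen = sorted(rng.choice(fs_codons, size=n_frameshift, replace=False),
                    reverse=True) if n_frameshift else []
    for ci in chosen:
        ci = int(ci)
        size = int(rng.integers(1, 3))  # 1 or 2 bp
        pos = 3 * ci + int(rng.integers(3))
        if rng.random() < 0.5:
            seq = seq[:pos] + seq[pos + size:]
            events.append({"kind": "frameshift", "codon": ci,
                           "detail": f"del{size}"})
        else:
            ins = "".join(rng.choice(BASES, size=size))
            seq = seq[:pos] + ins + seq[pos:]
            events.append({"kind": "frameshift", "codon": ci,
                           "detail": f"ins{size}"})
    return seq, events


# ---------------------------------------------------------------------------
# element construction
# ---------------------------------------------------------------------------


def _force_termini(ltr: str) -> str:
    return "TG" + ltr[2:-2] + "CA"


def _assemble(rng: np.random.Generator, ltr5: str, ltr3: str, internal_len: int,
              pbs: str, ppt: str, cds: str | None, element_id: str,
              divergence: float) -> PlantedElement:
    """Lay out LTR5|sp|PBS|fill|[CDS]|fill|PPT|sp|LTR3 and record offsets."""
    sp1, sp2 = 2, 2
    core = internal_len - len(pbs) - len(ppt) - sp1 - sp2
    cds_len = len(cds) if cds else 0
    if core < cds_len + 40:
        raise SimulationError("internal region too small to host requested CDS")
    if cds:
        lead = int(rng.integers(20, core - cds_len - 19))
    else:
        lead = core
    fill_a = _random_seq(rng, lead)
    fill_b = _random_seq(rng, core - lead - cds_len)
    parts = [ltr5, _random_seq(rng, sp1), pbs, fill_a]
    pbs_off = len(ltr5) + sp1
    gene_span = None
    if cds:
        gene_start = pbs_off + len(pbs) + lead
        gene_span = (gene_start, gene_start + cds_len)
        parts.append(cds)
    parts += [fill_b, ppt, _random_seq(rng, sp2), ltr3]
    seq = "".join(parts)
    ppt_off = len(seq) - len(ltr3) - sp2 - len(ppt)
    return PlantedElement(
        id=element_id, seq=seq,
        ltr5_span=(0, len(ltr5)),
        ltr3_span=(len(seq) - len(ltr3), len(seq)),
        pbs_offset=pbs_off, pbs_seq=pbs,
        ppt_offset=ppt_off, ppt_seq=ppt,
        ltr_divergence=divergence,
        gene_span=gene_span, gene_cds=cds,
    )


def build_element(cfg: SimulationConfig, rng: np.random.Generator,
                  element_id: str = "elem_1",
                  with_gene: bool | None = None,
                  gene_id: str | None = None) -> PlantedElement:
    """Build one fully featured element (sequence + metadata, unplaced)."""
    if with_gene is None:
        with_gene = rng.random() < cfg.capture_fraction
    ltr_len = int(rng.integers(cfg.ltr_length_range[0], cfg.ltr_length_range[1] + 1))
    internal_len = int(rng.integers(cfg.internal_length_range[0],
                                    cfg.internal_length_range[1] + 1))
    ltr5 = _force_termini(_random_seq(rng, ltr_len))
    protect = {0, 1, ltr_len - 2, ltr_len - 1}
    ltr3 = _force_termini(mutate_sequence(ltr5, cfg.ltr_divergence, rng, protect))
    primer = TRNA_PRIMERS[list(TRNA_PRIMERS)[rng.integers(len(TRNA_PRIMERS))]]
    pbs = revcomp(primer)
    ppt = "".join(rng.choice(np.array(["A", "G"]), size=12, p=[0.4, 0.6]))
    cds = None
    if with_gene:
        max_codons = min(300, (internal_len - len(pbs) - len(ppt) - 50) // 3)
        n_codons = int(rng.integers(100, max(101, max_codons)))
        cds = random_cds(n_codons, rng)
    elem = _assemble(rng, ltr5, ltr3, internal_len, pbs, ppt, cds,
                     element_id, cfg.ltr_divergence)
    if with_gene:
        elem.captured_gene_id = gene_id or f"{element_id}_gene"
    return elem


def diverge_copy(parent: PlantedElement, cfg: SimulationConfig,
                 rng: np.random.Generator, element_id: str,
                 pseudogenize_gene: bool = False,
                 gene_id: str | None = None) -> PlantedElement:
    """Diverged copy of `parent`: an expansion product of one template.

    LTRs, filler and PPT are mutated at ``cfg.copy_divergence``; the PBS is
    kept identical (primer choice is a property of the family); the captured
    CDS, if any, is mutated without disablements and then optionally
    pseudogenized with exactly one frameshift or one premature stop.
    """
    d = cfg.copy_divergence
    p5 = parent.ltr5_seq
    protect = {0, 1, len(p5) - 2, len(p5) - 1}
    ltr5 = _force_termini(mutate_sequence(p5, d, rng, protect))
    ltr3 = _force_termini(mutate_sequence(ltr5, cfg.ltr_divergence, rng, protect))
    internal_len = len(parent.seq) - len(parent.ltr5_seq) - len(parent.ltr3_seq)
    ppt = mutate_sequence(parent.ppt_seq, d / 2, rng)
    cds = None
    if parent.gene_cds:
        cds = mutate_cds(parent.gene_cds, d / 2, rng)
        if pseudogenize_gene:
            kind = int(rng.integers(2))
            cds, _ = pseudogenize(cds, 1 - kind, kind, rng)
    elem = _assemble(rng, ltr5, ltr3, internal_len, parent.pbs_seq, ppt, cds,
                     element_id, cfg.ltr_divergence)
    elem.parent_element_id = parent.id
    elem.is_pseudogenized = pseudogenize_gene and parent.gene_cds is not None
    if cds:
        elem.captured_gene_id = gene_id or f"{element_id}_gene"
    return elem


def make_solo(source: PlantedElement, cfg: SimulationConfig,
              rng: np.random.Generator, solo_id: str) -> PlantedSolo:
    """Single-LTR recombination product of `source` (keeps the 5'-LTR)."""
    ltr = source.ltr5_seq
    protect = {0, 1, len(ltr) - 2, len(ltr) - 1}
    seq = _force_termini(mutate_sequence(ltr, cfg.solo_divergence, rng, protect))
    return PlantedSolo(id=solo_id, seq=seq, source_element_id=source.id)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def plant(genome: str, elements: list[PlantedElement],
          solos: list[PlantedSolo], cfg: SimulationConfig,
          rng: np.random.Generator) -> tuple[str, TruthSet]:
    """Insert elements and solos at non-overlapping sites with TSDs.

    Each insertion duplicates the 4-6 bp of host sequence at the insertion
    point so the planted object is flanked by an exact TSD on both sides.
    Coordinates in the returned TruthSet are exact genome coordinates.
    """
    items: list = list(elements) + list(solos)
    total = sum(len(getattr(it, "seq")) for it in items)
    if total >= len(genome) / 2:
        raise SimulationError("planted length must stay below half the genome")
    margin, min_gap = 2000, 300
    positions: list[int] = []
    for _ in range(2000):
        if len(positions) == len(items):
            break
        p = int(rng.integers(margin, len(genome) - margin))
        if all(abs(p - q) >= min_gap for q in positions):
            positions.append(p)
    if len(positions) < len(items):
        raise SimulationError("could not place insertions without overlap")

    order = np.argsort(positions)
    pieces: list[str] = []
    prev = 0
    out_len = 0
    truth = TruthSet(chrom=cfg.chrom, genome_length=0)
    tlo, thi = cfg.tsd_length_range
    for idx in order:
        it = items[int(idx)]
        p = positions[int(idx)]
        tsd_len = int(rng.integers(tlo, thi + 1))
        tsd = genome[p:p + tsd_len]
        pieces.append(genome[prev:p])
        out_len += p - prev
        pieces.append(tsd)
        out_len += tsd_len
        start = out_len
        pieces.append(it.seq)
        out_len += len(it.seq)
        prev = p
        it.chrom = cfg.chrom
        it.tsd_seq = tsd
        if isinstance(it, PlantedElement):
            it.start, it.end = start, start + len(it.seq)
            it.ltr5_span = (start + it.ltr5_span[0], start + it.ltr5_span[1])
            it.ltr3_span = (start + it.ltr3_span[0], start + it.ltr3_span[1])
            it.pbs_offset += start
            it.ppt_offset += start
            if it.gene_span is not None:
                it.gene_span = (start + it.gene_span[0], start + it.gene_span[1])
            truth.planted.append(it)
        else:
            it.span = (start, start + len(it.seq))
            truth.solos.append(it)
    pieces.append(genome[prev:])
    out_len += len(genome) - prev
    new_genome = "".join(pieces)
    truth.genome_length = out_len
    truth.planted.sort(key=lambda e: e.start)
    truth.solos.sort(key=lambda s: s.span[0])

    for e in truth.planted:
        if e.captured_gene_id:
            truth.gene_models.append(GeneModelTruth(
                gene_id=e.captured_gene_id, cds=e.gene_cds,
                protein=translate(e.gene_cds).rstrip("*"),
                chrom=cfg.chrom, span=e.gene_span, strand="+",
                parent_gene_id=(f"{e.parent_element_id}_gene"
                                if e.parent_element_id else None),
                description=("pseudogene fragment" if e.is_pseudogenized
                             else "hypothetical protein"),
            ))
    return new_genome, truth


def simulate_genome(cfg: SimulationConfig) -> tuple[str, TruthSet]:
    """End-to-end simulation under `cfg`: background + elements + solos."""
    # background and element streams must be decorrelated: seeding both
    # with cfg.seed would make planted sequences echo the genome's start
    rng = np.random.default_rng([cfg.seed, 0x1e7e])
    background = generate_background(cfg.genome_length, cfg.gc_content, cfg.seed)

    n_capture = round(cfg.n_full_elements * cfg.capture_fraction)
    n_child = min(round(n_capture * cfg.expansion_fraction),
                  n_capture - round(n_capture * cfg.expansion_fraction))
    n_child = max(0, n_child)
    n_parent_captured = n_capture - n_child
    n_plain = cfg.n_full_elements - n_capture

    elements: list[PlantedElement] = []
    captured_parents: list[PlantedElement] = []
    k = 0
    for _ in range(n_parent_captured):
        k += 1
        e = build_element(cfg, rng, f"elem_{k:03d}", with_gene=True)
        elements.append(e)
        captured_parents.append(e)
    n_pseudo = round(n_child * cfg.pseudogene_fraction)
    for i in range(n_child):
        k += 1
        parent = captured_parents[i % len(captured_parents)]
        elements.append(diverge_copy(parent, cfg, rng, f"elem_{k:03d}",
                                     pseudogenize_gene=(i < n_pseudo)))
    for _ in range(n_plain):
        k += 1
        elements.append(build_element(cfg, rng, f"elem_{k:03d}", with_gene=False))

    solos = []
    sources = elements[:max(1, len(elements))]
    for i in range(cfg.n_solo):
        src = sources[int(rng.integers(len(sources)))]
        solos.append(make_solo(src, cfg, rng, f"solo_{i + 1:03d}"))

    return plant(background, elements, solos, cfg, rng)


# ---------------------------------------------------------------------------
# codon-pair simulators for Ka/Ks and pseudogene benchmarks
# ---------------------------------------------------------------------------


def evolve_cds(cds: str, omega: float, n_events: int,
               rng: np.random.Generator) -> str:
    """Evolve a CDS under uniform mutation with selection intensity `omega`.

    Proposals are uniform single-base changes at uniform positions (first
    and last codon excluded). A synonymous proposal is always accepted, a
    nonsynonymous one with probability `omega`, and a stop-creating one
    never, so the realized nonsynonymous/synonymous rate ratio per
    opportunity equals `omega`. Exactly `n_events` accepted substitutions
    are applied.
    """
    from Bio.Seq import Seq

    arr = list(cds)
    n = len(arr)
    accepted = 0
    while accepted < n_events:
        pos = int(rng.integers(3, n - 3))
        old = arr[pos]
        new = "ACGT".replace(old, "")[rng.integers(3)]
        ci = pos // 3
        codon = "".join(arr[3 * ci:3 * ci + 3])
        cand = codon[:pos % 3] + new + codon[pos % 3 + 1:]
        if cand in STOP_CODONS:
            continue
        syn = str(Seq(codon).translate()) == str(Seq(cand).translate())
        if syn or rng.random() < omega:
            arr[pos] = new
            accepted += 1
    return "".join(arr)


def simulate_codon_pairs(n_pairs: int, n_codons: int, omega: float,
                         n_events: int, seed: int) -> list[tuple[str, str]]:
    """Independent CDS pairs diverged from a common ancestor at ratio `omega`."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        anc = random_cds(n_codons, rng)
        a = evolve_cds(anc, omega, n_events // 2, rng)
        b = evolve_cds(anc, omega, n_events - n_events // 2, rng)
        pairs.append((a, b))
    return pairs


def simulate_parent_child_cds(n_pairs: int, frac_disabled: float, seed: int,
                              n_codons_range: tuple[int, int] = (120, 250),
                              background_rate: float = 0.02,
                              ) -> list[tuple[str, str, bool, str]]:
    """Parent/child CDS pairs, a fraction of children disabled.

    Returns tuples ``(parent_cds, child_cds, is_disabled, kind)`` where kind
    is 'intact', 'frameshift' or 'premature_stop'. Intact children carry
    only neutral substitutions; disabled children additionally carry exactly
    one disablement of the named kind.
    """
    rng = np.random.default_rng(seed)
    n_disabled = round(n_pairs * frac_disabled)
    out = []
    for i in range(n_pairs):
        n_codons = int(rng.integers(*n_codons_range))
        parent = random_cds(n_codons, rng)
        child = mutate_cds(parent, background_rate, rng)
        if i < n_disabled:
            if i % 2 == 0:
                child, _ = pseudogenize(child, 1, 0, rng)
                kind = "frameshift"
            else:
                child, _ = pseudogenize(child, 0, 1, rng)
                kind = "premature_stop"
            out.append((parent, child, True, kind))
        else:
            out.append((parent, child, False, "intact"))
    return out


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def write_genome_fasta(genome: str, path: str | Path, chrom: str = "chr1") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    rec = SeqRecord(Seq(genome), id=chrom, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _attrs(**kv) -> str:
    parts = []
    for k, v in kv.items():
        if v is None:
            continue
        parts.append(f"{k}={quote(str(v), safe=' _.-')}")
    return ";".join(parts)


def write_truth_gff3(truth: TruthSet, path: str | Path) -> None:
    """Truth as GFF3 (1-based inclusive), gene models as gene/mRNA/CDS."""
    lines = ["##gff-version 3",
             f"##sequence-region {truth.chrom} 1 {truth.genome_length}"]

    def row(ftype, start, end, attrs, strand="+"):
        lines.append("\t".join([
            truth.chrom, "ltrsurvey_sim", ftype, str(start + 1), str(end),
            ".", strand, ".", attrs]))

    for e in truth.planted:
        row("LTR_retrotransposon", e.start, e.end, _attrs(
            ID=e.id, ltr_divergence=e.ltr_divergence, tsd=e.tsd_seq,
            captured_gene=e.captured_gene_id,
            parent_element=e.parent_element_id,
            pseudogenized=str(e.is_pseudogenized).lower()))
        row("long_terminal_repeat", *e.ltr5_span,
            _attrs(ID=f"{e.id}_ltr5", Parent=e.id))
        row("long_terminal_repeat", *e.ltr3_span,
            _attrs(ID=f"{e.id}_ltr3", Parent=e.id))
        row("target_site_duplication", e.start - len(e.tsd_seq), e.start,
            _attrs(ID=f"{e.id}_tsd5", Parent=e.id))
        row("target_site_duplication", e.end, e.end + len(e.tsd_seq),
            _attrs(ID=f"{e.id}_tsd3", Parent=e.id))
        row("primer_binding_site", e.pbs_offset, e.pbs_offset + len(e.pbs_seq),
            _attrs(ID=f"{e.id}_pbs", Parent=e.id, seq=e.pbs_seq))
        row("RR_tract", e.ppt_offset, e.ppt_offset + len(e.ppt_seq),
            _attrs(ID=f"{e.id}_ppt", Parent=e.id, seq=e.ppt_seq))
    for s in truth.solos:
        row("long_terminal_repeat", s.span[0], s.span[1], _attrs(
            ID=s.id, solo="true", source_element=s.source_element_id,
            tsd=s.tsd_seq))
    for g in truth.gene_models:
        row("gene", g.span[0], g.span[1], _attrs(
            ID=g.gene_id, description=g.description,
            parent_gene=g.parent_gene_id), g.strand)
        row("mRNA", g.span[0], g.span[1], _attrs(
            ID=f"{g.gene_id}.1", Parent=g.gene_id), g.strand)
        row("CDS", g.span[0], g.span[1], _attrs(
            ID=f"{g.gene_id}.1.cds", Parent=f"{g.gene_id}.1"), g.strand)
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_gff3(path: str | Path, genome: str | None = None) -> TruthSet:
    """Re-parse a truth GFF3 written by :func:`write_truth_gff3`."""
    chrom = "chr1"
    glen = 0
    elems: dict[str, PlantedElement] = {}
    solos: list[PlantedSolo] = []
    genes: dict[str, GeneModelTruth] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            _, chrom, _, glen = line.split()
            glen = int(glen)
            continue
        if not line or line.startswith("#"):
            continue
        c, _, ftype, s, e, _, strand, _, attr_s = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if kv)
        attrs = {k: unquote(v) for k, v in attrs.items()}
        rows.append((c, ftype, int(s) - 1, int(e), strand, attrs))
    for c, ftype, s, e, strand, a in rows:
        if ftype == "LTR_retrotransposon":
            seq = genome[s:e] if genome else ""
            elems[a["ID"]] = PlantedElement(
                id=a["ID"], seq=seq, ltr5_span=(0, 0), ltr3_span=(0, 0),
                pbs_offset=0, pbs_seq="", ppt_offset=0, ppt_seq="",
                ltr_divergence=float(a.get("ltr_divergence", 0)),
                chrom=c, start=s, end=e, tsd_seq=a.get("tsd", ""),
                captured_gene_id=a.get("captured_gene"),
                parent_element_id=a.get("parent_element"),
                is_pseudogenized=a.get("pseudogenized") == "true")
        elif ftype == "long_terminal_repeat" and a.get("solo") == "true":
            solos.append(PlantedSolo(
                id=a["ID"], seq=genome[s:e] if genome else "",
                source_element_id=a.get("source_element", ""),
                chrom=c, span=(s, e), tsd_seq=a.get("tsd", "")))
        elif ftype == "gene":
            genes[a["ID"]] = GeneModelTruth(
                gene_id=a["ID"], cds=genome[s:e] if genome else "",
                protein="", chrom=c, span=(s, e), strand=strand,
                parent_gene_id=a.get("parent_gene"),
                description=a.get("description", ""))
    for c, ftype, s, e, strand, a in rows:
        parent = a.get("Parent", "")
        if ftype == "long_terminal_repeat" and parent in elems:
            el = elems[parent]
            if a["ID"].endswith("_ltr5"):
                el.ltr5_span = (s, e)
            else:
                el.ltr3_span = (s, e)
        elif ftype == "primer_binding_site" and parent in elems:
            elems[parent].pbs_offset = s
            elems[parent].pbs_seq = a.get("seq", "")
        elif ftype == "RR_tract" and parent in elems:
            elems[parent].ppt_offset = s
            elems[parent].ppt_seq = a.get("seq", "")
    for el in elems.values():
        if el.captured_gene_id and el.captured_gene_id in genes:
            el.gene_span = genes[el.captured_gene_id].span
            if genome:
                el.gene_cds = genome[el.gene_span[0]:el.gene_span[1]]
    if genome:
        for g in genes.values():
            g.protein = translate(g.cds).rstrip("*")
    truth = TruthSet(chrom=chrom, genome_length=glen,
                     planted=sorted(elems.values(), key=lambda x: x.start),
                     solos=sorted(solos, key=lambda x: x.span[0]),
                     gene_models=sorted(genes.values(), key=lambda x: x.span[0]))
    return truth


def write_truth_tsv(truth: TruthSet, path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame(truth.as_records()).to_csv(path, sep="\t", index=False)


def write_gene_fastas(truth: TruthSet, cds_path: str | Path,
                      protein_path: str | Path) -> None:
    with open(cds_path, "w") as cf, open(protein_path, "w") as pf:
        for g in truth.gene_models:
            cf.write(f">{g.gene_id}\n{g.cds}\n")
            pf.write(f">{g.gene_id}\n{g.protein}\n")
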