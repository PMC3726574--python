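"""Captured-gene calling and pseudogene classification.

A captured gene is an annotated, non-TE gene lying entirely within a
full-length LTR retrotransposon. Capture is strict containment: a gene
straddling an element boundary is not captured. Genes whose functional
description matches transposon keywords (gag, pol, reverse transcriptase,
integrase, ...) are excluded, since those are the element's own coding
capacity rather than cargo.

Pseudogene calls compare a gene's genomic CDS region against its parent
protein through a three-frame translated alignment: the child sequence is
translated in all three frames, frame segments (split at stop codons) are
locally aligned to the parent protein, and the best collinear chain of
blocks is inspected for disablements. A frameshift is a frame change
along the chain (including a first block out of the annotated frame 0); a
premature stop is a stop codon interrupting the chain before the final 5%
of the parent. The call requires >= 70% parent-protein coverage plus at
least one disablement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .simulate import translate

logger = logging.getLogger(__name__)

MIN_PARENT_COVERAGE = 0.70
PREMATURE_STOP_MARGIN = 0.05  # stops in the final 5% of the parent are natural
DEFAULT_TE_KEYWORDS = (
    "retrotransposon", "transposon", "transposable", "gag", "pol ",
    "polyprotein", "reverse transcriptase", "integrase", "rnase h",
)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    span: tuple[int, int]  # 0-based half-open
    strand: str
    cds_segments: list[tuple[int, int]]
    cds_seq: str
    protein: str
    descriptor: str = ""
    is_te_related: bool = False

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass
class CapturedGene:
    gene_id: str
    element_id: str
    offset: int  # gene start relative to element start


@dataclass
class PseudogeneCall:
    gene_id: str
    parent_gene_id: str
    parent_coverage: float
    n_frameshifts: int
    n_premature_stops: int
    is_pseudogene: bool
    blocks: list[dict] = field(default_factory=list)


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------


def load_annotation(gff3_path: str | Path,
                    genome: dict[str, str] | None = None,
                    cds_fasta: str | Path | None = None,
                    protein_fasta: str | Path | None = None) -> list[GeneModel]:
    """Gene models from a GFF3 gene/mRNA/CDS hierarchy.

    When a gene has several mRNAs, the splice form with the longest total
    CDS is kept. CDS and protein sequences are taken from the FASTA files
    when given (keyed by gene id, then mRNA id), otherwise spliced out of
    `genome`. GFF3 1-based inclusive coordinates become 0-based half-open.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except EmptyInputError:
        return []
    cds_by_id = _read_fasta_dict(cds_fasta)
    prot_by_id = _read_fasta_dict(protein_fasta)

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_span = (gene.start - 1, gene.end)
        best: tuple[int, list, str] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = []
            for cds in db.children(mrna, featuretype="CDS"):
                if cds.seqid != gene.seqid:
                    raise AnnotationError(
                        f"CDS on wrong chromosome: {cds.seqid} vs {gene.seqid}"
                        f" (gene {gene.id})")
                if cds.start - 1 < gene_span[0] or cds.end > gene_span[1]:
                    raise AnnotationError(
                        f"CDS outside gene span for {gene.id}: "
                        f"{cds.start}-{cds.end}")
                segs.append((cds.start - 1, cds.end))
            segs.sort()
            total = sum(e - s for s, e in segs)
            if segs and (best is None or total > best[0]):
                best = (total, segs, mrna.id)
        if best is None:
            continue
        _, segs, mrna_id = best
        cds_seq = (cds_by_id.get(gene.id) or cds_by_id.get(mrna_id) or "")
        if not cds_seq and genome is not None:
            chrom_seq = genome.get(gene.seqid)
            if chrom_seq is None:
                raise AnnotationError(f"unknown chromosome {gene.seqid}")
            cds_seq = "".join(chrom_seq[s:e] for s, e in segs)
            if gene.strand == "-":
                from .align import revcomp
                cds_seq = revcomp(cds_seq)
        protein = (prot_by_id.get(gene.id) or prot_by_id.get(mrna_id) or "")
        if not protein and cds_seq and len(cds_seq) % 3 == 0:
            protein = translate(cds_seq).rstrip("*")
        descriptor = (gene.attributes.get("description", [""])[0]
                      or gene.attributes.get("Note", [""])[0])
        models.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, span=gene_span,
            strand=gene.strand or "+", cds_segments=segs, cds_seq=cds_seq,
            protein=protein, descriptor=descriptor))
    models.sort(key=lambda m: (m.chrom, m.span))
    return models


def _read_fasta_dict(path) -> dict[str, str]:
    if path is None:
        return {}
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# capture calling
# ---------------------------------------------------------------------------


def call_captured(genes: list[GeneModel], elements) -> list[CapturedGene]:
    """Genes lying strictly within an element span.

    A gene contained in two overlapping elements is assigned to the
    higher-scoring one.
    """
    captured: list[CapturedGene] = []
    for gene in genes:
        hosts = [el for el in elements
                 if getattr(el, "chrom", "chr1") == gene.chrom
                 and gene.start >= el.start and gene.end <= el.end]
        if not hosts:
            continue
        host = max(hosts, key=lambda el: getattr(el, "score", 0.0))
        captured.append(CapturedGene(gene_id=gene.gene_id,
                                     element_id=host.id,
                                     offset=gene.start - host.start))
    return captured


def filter_te_genes(captured: list[CapturedGene], genes: list[GeneModel],
                    te_keywords: tuple[str, ...] = DEFAULT_TE_KEYWORDS
                    ) -> list[CapturedGene]:
    """Drop captured genes whose descriptor matches a TE keyword."""
    if not te_keywords:
        return list(captured)
    by_id = {g.gene_id: g for g in genes}
    kept = []
    for cg in captured:
        gene = by_id.get(cg.gene_id)
        desc = (gene.descriptor if gene else "").lower()
        if any(kw in desc for kw in te_keywords):
            if gene:
                gene.is_te_related = True
            continue
        kept.append(cg)
    return kept


# ---------------------------------------------------------------------------
# pseudogene classification
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    frame: int
    parent_span: tuple[int, int]   # aa coords on parent
    child_nt_span: tuple[int, int]  # nt coords on child region
    score: float
    preceded_by_stop: bool


def _frame_segments(child: str, frame: int) -> list[tuple[int, str, bool]]:
    """(child_nt_offset, peptide, preceded_by_stop) segments of one frame."""
    usable = child[frame:]
    usable = usable[:len(usable) - len(usable) % 3]
    if not usable:
        return []
    pep = translate(usable)
    segments = []
    start = 0
    for i, aa in enumerate(list(pep) + ["*"]):
        if aa == "*":
            if i > start:
                segments.append((frame + 3 * start, pep[start:i], start > 0))
            start = i + 1
    return segments


def _align_segment(peptide: str, parent: str, child_nt_offset: int,
                   frame: int, preceded: bool,
                   min_block_aa: int = 8) -> _Block | None:
    from Bio import Align
    from Bio.Align import substitution_matrices

    if len(peptide) < min_block_aa:
        return None
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    try:
        aln = aligner.align(peptide, parent)[0]
    except IndexError:
        return None
    pep_blocks, par_blocks = aln.aligned
    if len(pep_blocks) == 0:
        return None
    p0, p1 = int(par_blocks[0][0]), int(par_blocks[-1][1])
    c0, c1 = int(pep_blocks[0][0]), int(pep_blocks[-1][1])
    if p1 - p0 < min_block_aa:
        return None
    matches = 0
    for (a0, a1), (b0, b1) in zip(pep_blocks, par_blocks):
        matches += sum(x == y for x, y in
                       zip(peptide[a0:a1], parent[b0:b1]))
    if matches / (p1 - p0) < 0.3:
        return None
    return _Block(frame=frame, parent_span=(p0, p1),
                  child_nt_span=(child_nt_offset + 3 * c0,
                                 child_nt_offset + 3 * c1),
                  score=float(aln.score), preceded_by_stop=preceded)


def _chain_blocks(blocks: list[_Block],
                  parent_overlap_aa: int = 30,
                  child_overlap_nt: int = 90,
                  min_block_score: float = 40.0) -> list[_Block]:
    """Best-scoring collinear chain of solid blocks (simple DP).

    Local alignments on either side of a disablement typically overrun the
    junction by several residues, so generous overlaps on both the parent
    and the child are tolerated; each step must still advance along both.
    Low-scoring blocks (chance matches of out-of-frame translations) are
    excluded before chaining so they can neither pad coverage nor fake a
    frame change.
    """
    blocks = [b for b in blocks if b.score >= min_block_score]
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: (b.parent_span, b.child_nt_span))
    n = len(blocks)
    best_score = [b.score for b in blocks]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            bi, bj = blocks[i], blocks[j]
            if (bj.parent_span[1] <= bi.parent_span[0] + parent_overlap_aa
                    and bj.parent_span[1] < bi.parent_span[1]
                    and bj.child_nt_span[1] <= bi.child_nt_span[0] + child_overlap_nt
                    and bj.child_nt_span[1] < bi.child_nt_span[1]
                    and best_score[j] + bi.score > best_score[i]):
                best_score[i] = best_score[j] + bi.score
                prev[i] = j
    end = max(range(n), key=lambda i: best_score[i])
    chain = []
    while end != -1:
        chain.append(blocks[end])
        end = prev[end]
    return chain[::-1]


def classify_pseudogene(child_region: str, parent_protein: str,
                        gene_id: str = "", parent_gene_id: str = "",
                        min_coverage: float = MIN_PARENT_COVERAGE
                        ) -> PseudogeneCall:
    """Disablement call for a child genomic CDS region vs a parent protein.

    Translates the child region in three frames, aligns stop-free frame
    segments to the parent, chains collinear blocks, and counts frame
    changes (the annotated reading frame 0 starts the chain) and chain-
    interrupting stop codons before the final 5% of the parent.
    """
    if len(parent_protein) < 50:
        raise ValueError("parent protein must be >= 50 aa")
    blocks: list[_Block] = []
    for frame in range(3):
        for off, pep, preceded in _frame_segments(child_region, frame):
            blk = _align_segment(pep, parent_protein, off, frame, preceded)
            if blk is not None:
                blocks.append(blk)
    chain = _chain_blocks(blocks)
    if not chain:
        logger.warning("unalignable child/parent pair %s/%s",
                       gene_id, parent_gene_id)
        return PseudogeneCall(gene_id, parent_gene_id, 0.0, 0, 0, False)

    covered: set[int] = set()
    for b in chain:
        covered.update(range(*b.parent_span))
    coverage = len(covered) / len(parent_protein)
    stop_cutoff_aa = len(parent_protein) * (1 - PREMATURE_STOP_MARGIN)

    n_frameshifts = 0
    n_stops = 0
    prev_frame = 0  # the annotated reading frame of the child CDS
    prev_child_end = 0
    for b in chain:
        # frame change relative to the running frame, net of the nt offset
        if b.frame != prev_frame:
            n_frameshifts += 1
        if b.preceded_by_stop and b.parent_span[0] < stop_cutoff_aa \
                and b.frame == prev_frame:
            # a stop codon interrupted this frame's reading before the block
            if prev_child_end <= b.child_nt_span[0]:
                n_stops += 1
        prev_frame = b.frame
        prev_child_end = b.child_nt_span[1]

    is_pseudo = coverage >= min_coverage and (n_frameshifts + n_stops) >= 1
    return PseudogeneCall(
        gene_id=gene_id, parent_gene_id=parent_gene_id,
        parent_coverage=coverage, n_frameshifts=n_frameshifts,
        n_premature_stops=n_stops, is_pseudogene=is_pseudo,
        blocks=[{"frame": b.frame, "parent_span": b.parent_span,
                 "child_nt_span": b.child_nt_span} for b in chain])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_captured_tsv(captured: list[CapturedGene], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "gene_id": c.gene_id, "element_id": c.element_id, "offset": c.offset,
    } for c in captured]).to_csv(path, sep="\t", index=False)


def write_pseudogene_tsv(calls: list[PseudogeneCall], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "gene_id": c.gene_id, "parent_gene_id": c.parent_gene_id,
        "parent_coverage": round(c.parent_coverage, 4),
        "n_frameshifts": c.n_frameshifts,
        "n_premature_stops": c.n_premature_stops,
        "is_pseudogene": c.is_pseudogene,
    } for c in calls]).to_csv(path, sep="\t", index=False)
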