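"""Expansion-pair calling and Nei-Gojobori (1986) Ka/Ks estimation.

Full-length elements descended from one template (an "expansion pair")
are recognized by high identity between their LTRs and matching PBS/PPT
motifs; their captured genes are paired by best reciprocal protein
identity. Divergence between paired coding sequences is quantified with
the NG86 counting method:

* the synonymous fraction of each codon position is the share of its
  three single-base changes that preserve the amino acid (changes to stop
  codons count as nonsynonymous), summed to S per sequence and averaged
  over the two sequences; N = 3 x codons - S;
* observed differences between unequal codons are averaged over all
  minimal substitution pathways (equal weights, pathways through stop
  codons excluded; if every pathway hits a stop, the differences count as
  nonsynonymous);
* proportions ps = Sd/S and pn = Nd/N receive the Jukes-Cantor multiple-
  hit correction K = -(3/4) ln(1 - 4p/3), undefined for p >= 3/4.

Ka/Ks < 1 indicates purifying selection, ~1 neutral evolution, > 1
positive selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from .align import global_nt_identity, global_protein_alignment, protein_identity
from .simulate import STOP_CODONS

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}


def _build_table() -> None:
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    table = unambiguous_dna_by_id[1]
    for c1 in "ACGT":
        for c2 in "ACGT":
            for c3 in "ACGT":
                codon = c1 + c2 + c3
                _CODON_TABLE[codon] = ("*" if codon in table.stop_codons
                                       else table.forward_table[codon])


_build_table()


def codon_aa(codon: str) -> str:
    return _CODON_TABLE[codon]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class ElementPair:
    element_a: str
    element_b: str
    ltr5_identity: float
    ltr3_identity: float
    pbs_match: bool
    ppt_match: bool

    @property
    def mean_ltr_identity(self) -> float:
        return (self.ltr5_identity + self.ltr3_identity) / 2


@dataclass
class GenePair:
    gene_a: str
    gene_b: str
    protein_identity: float
    element_pair: tuple[str, str]


@dataclass
class CodonAlignment:
    codons: list[tuple[str, str]]

    @property
    def n_codons(self) -> int:
        return len(self.codons)


@dataclass
class KaKsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float

    @property
    def ps(self) -> float:
        return self.Sd / self.S_sites if self.S_sites > 0 else math.nan

    @property
    def pn(self) -> float:
        return self.Nd / self.N_sites if self.N_sites > 0 else math.nan

    @property
    def Ks(self) -> float:
        return _jukes_cantor(self.ps)

    @property
    def Ka(self) -> float:
        return _jukes_cantor(self.pn)

    @property
    def ratio(self) -> float:
        ka, ks = self.Ka, self.Ks
        if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
            return math.nan
        return ka / ks


def _jukes_cantor(p: float) -> float:
    if math.isnan(p) or p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


def pair_elements(elements, genome: str,
                  min_ltr_identity: float = 0.80,
                  motif_match_identity: float = 0.90) -> list[ElementPair]:
    """All element pairs whose 5' and 3' LTRs both match at >= threshold.

    Pairs are ranked by mean LTR identity; PBS/PPT flags record whether
    the motif sequences match at >= `motif_match_identity`.
    """
    pairs: list[ElementPair] = []
    seqs = {}
    for el in elements:
        seqs[el.id] = {
            "ltr5": genome[el.ltr5_span[0]:el.ltr5_span[1]],
            "ltr3": genome[el.ltr3_span[0]:el.ltr3_span[1]],
            "pbs": (genome[el.features.pbs[0]:el.features.pbs[0]
                           + len(el.features.pbs[1])]
                    if getattr(el, "features", None) and el.features.pbs else ""),
            "ppt": (el.features.ppt[1]
                    if getattr(el, "features", None) and el.features.ppt else ""),
        }
    ids = [el.id for el in elements]
    for a, b in itertools.combinations(ids, 2):
        id5 = global_nt_identity(seqs[a]["ltr5"], seqs[b]["ltr5"])
        if id5 < min_ltr_identity:
            continue
        id3 = global_nt_identity(seqs[a]["ltr3"], seqs[b]["ltr3"])
        if id3 < min_ltr_identity:
            continue
        pbs_match = bool(seqs[a]["pbs"] and seqs[b]["pbs"]
                         and global_nt_identity(seqs[a]["pbs"], seqs[b]["pbs"])
                         >= motif_match_identity)
        ppt_match = bool(seqs[a]["ppt"] and seqs[b]["ppt"]
                         and global_nt_identity(seqs[a]["ppt"], seqs[b]["ppt"])
                         >= motif_match_identity)
        pairs.append(ElementPair(a, b, id5, id3, pbs_match, ppt_match))
    pairs.sort(key=lambda p: -p.mean_ltr_identity)
    return pairs


def pair_genes(captured, element_pairs: list[ElementPair], gene_models,
               min_protein_identity: float = 0.50) -> list[GenePair]:
    """Best reciprocal captured-gene pairs within each element pair."""
    by_element: dict[str, list[str]] = {}
    for cg in captured:
        by_element.setdefault(cg.element_id, []).append(cg.gene_id)
    proteins = {g.gene_id: g.protein for g in gene_models}
    out: list[GenePair] = []
    for ep in element_pairs:
        genes_a = [g for g in by_element.get(ep.element_a, []) if proteins.get(g)]
        genes_b = [g for g in by_element.get(ep.element_b, []) if proteins.get(g)]
        if not genes_a or not genes_b:
            continue
        scores = {(ga, gb): protein_identity(proteins[ga], proteins[gb])
                  for ga in genes_a for gb in genes_b}
        for ga in genes_a:
            gb = max(genes_b, key=lambda g: scores[(ga, g)])
            if max(genes_a, key=lambda g: scores[(g, gb)]) != ga:
                continue  # not reciprocal
            ident = scores[(ga, gb)]
            if ident >= min_protein_identity:
                out.append(GenePair(ga, gb, ident, (ep.element_a, ep.element_b)))
    return out


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------


class CodonAlignmentError(ValueError):
    pass


def codon_align(cds_a: str, cds_b: str,
                protein_alignment=None) -> CodonAlignment:
    """Back-translate a protein alignment onto its coding sequences.

    Each aligned residue pair maps to its codon pair; alignment columns
    with a gap, and codons containing N, are dropped. The translations of
    the CDSs must equal the aligned protein sequences (trailing stop
    codons on the CDSs are tolerated) and internal stops are rejected.
    """
    from .simulate import translate

    for name, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) % 3 != 0:
            raise CodonAlignmentError(f"cds_{name} length not divisible by 3")
    prot_a = translate(cds_a)
    prot_b = translate(cds_b)
    if prot_a.endswith("*"):
        prot_a = prot_a[:-1]
    if prot_b.endswith("*"):
        prot_b = prot_b[:-1]
    for name, prot in (("a", prot_a), ("b", prot_b)):
        if "*" in prot:
            raise CodonAlignmentError(
                f"cds_{name} contains an internal stop codon at aa position "
                f"{prot.index('*')}")
    if protein_alignment is None:
        protein_alignment = global_protein_alignment(prot_a, prot_b)
    else:
        seq_a, seq_b = protein_alignment.sequences
        if str(seq_a) != prot_a or str(seq_b) != prot_b:
            mism = next((i for i, (x, y) in enumerate(
                zip(str(seq_a), prot_a)) if x != y), len(prot_a))
            raise CodonAlignmentError(
                f"protein alignment does not match translation "
                f"(first mismatch near aa {mism})")
    codons = []
    a_blocks, b_blocks = protein_alignment.aligned
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        for off in range(a1 - a0):
            ca = cds_a[3 * (a0 + off):3 * (a0 + off) + 3]
            cb = cds_b[3 * (b0 + off):3 * (b0 + off) + 3]
            if "N" in ca or "N" in cb:
                continue
            codons.append((ca, cb))
    return CodonAlignment(codons=codons)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Expected synonymous sites of one codon (sum of per-position fractions)."""
    aa = codon_aa(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if codon_aa(alt) == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over pathways.

    All orders of the differing positions are enumerated; pathways whose
    intermediate codons are stops are excluded. When no stop-free pathway
    exists the differences are counted as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_acc = 0.0
    non_acc = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = ca
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if codon_aa(nxt) == "*" and nxt != cb:
                ok = False
                break
            if codon_aa(nxt) == codon_aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_acc += syn
            non_acc += non
            n_paths += 1
    if n_paths == 0:
        return 0.0, float(len(diff_pos))
    return syn_acc / n_paths, non_acc / n_paths


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """NG86 site and difference counts for one codon alignment."""
    if alignment.n_codons < 10:
        raise ValueError("need >= 10 aligned codons")
    S = 0.0
    Sd = Nd = 0.0
    for ca, cb in alignment.codons:
        S += (_syn_sites(ca) + _syn_sites(cb)) / 2
        s, n = _pathway_counts(ca, cb)
        Sd += s
        Nd += n
    N = 3 * alignment.n_codons - S
    return KaKsResult(S_sites=S, N_sites=N, Sd=Sd, Nd=Nd)


def kaks_for_pair(cds_a: str, cds_b: str) -> KaKsResult:
    """Convenience: protein-align, back-translate, and run NG86."""
    return ng86(codon_align(cds_a, cds_b))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize(results: list[KaKsResult],
              ratio_bins: list[float] | None = None) -> dict:
    """Distribution table and means over defined values.

    Undefined ratios (Ks = 0 or out of the correction domain) are
    excluded from the means and reported separately; bin frequencies sum
    to 1 over the defined ratios.
    """
    if not results:
        return {"n": 0}
    if ratio_bins is None:
        ratio_bins = [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, float("inf")]
    kas = [r.Ka for r in results if not math.isnan(r.Ka)]
    kss = [r.Ks for r in results if not math.isnan(r.Ks)]
    ratios = [r.ratio for r in results if not math.isnan(r.ratio)]
    hist = [0] * (len(ratio_bins) - 1)
    for x in ratios:
        for i in range(len(ratio_bins) - 1):
            if ratio_bins[i] <= x < ratio_bins[i + 1]:
                hist[i] += 1
                break
    total = len(ratios)
    return {
        "n": len(results),
        "n_defined": total,
        "n_undefined": len(results) - total,
        "mean_ka": sum(kas) / len(kas) if kas else math.nan,
        "mean_ks": sum(kss) / len(kss) if kss else math.nan,
        "mean_ratio": sum(ratios) / total if total else math.nan,
        "bins": list(zip(ratio_bins[:-1], ratio_bins[1:])),
        "frequencies": [h / total if total else 0.0 for h in hist],
    }


def write_kaks_tsv(rows: list[tuple[str, str, KaKsResult]],
                   path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "gene_a": a, "gene_b": b, "n_codons": round((r.S_sites + r.N_sites) / 3),
        "S_sites": round(r.S_sites, 4), "N_sites": round(r.N_sites, 4),
        "Sd": round(r.Sd, 4), "Nd": round(r.Nd, 4),
        "Ka": round(r.Ka, 6) if not math.isnan(r.Ka) else "NA",
        "Ks": round(r.Ks, 6) if not math.isnan(r.Ks) else "NA",
        "ratio": round(r.ratio, 6) if not math.isnan(r.ratio) else "NA",
        "estimator": "NG86+JC",
    } for a, b, r in rows]).to_csv(path, sep="\t", index=False)
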