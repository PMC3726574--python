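"""Chromosomal density, term enrichment, expression and smRNA evidence.

This module covers the downstream characterization of detected elements
and their captured genes:

* per-chromosome density profiles (fraction of all elements per window)
  and a permutation test for enrichment near the centromere;
* term over-representation: hypergeometric tests with Benjamini-Hochberg
  FDR for GO-style term sets (significant at p < 0.05 and FDR < 0.25),
  and 2x2 chi-square tests for protein-domain frequencies (significant at
  p < 0.01, with Fisher's exact test substituted when any expected cell
  is below 5);
* expression calls from cDNA/EST alignment evidence (>= 95% identity over
  >= 90% of length), MPSS tag abundance (>= 5 in both the 17-bp and 20-bp
  signature sets), and precomputed microarray / RNA-seq flags -- a gene
  is expressed if any source fires;
* expression divergence between paralogous gene pairs (status discordance
  or a >= 2-fold abundance difference on a shared source);
* small-RNA mapping: exact full-length matches inside gene sequences,
  retained only when the smRNA has a single occurrence in the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .align import revcomp


@dataclass
class DensityProfile:
    chrom: str
    window_bp: int
    fractions: list[float]
    counts: list[int]
    centromere: int | None = None


@dataclass
class EnrichmentResult:
    term: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    p_value: float
    fdr: float = math.nan
    direction: str = "over"
    significant: bool = False


@dataclass
class ExpressionEvidence:
    gene_id: str
    est_hits: list[tuple[float, float]] = field(default_factory=list)
    mpss_17: float | None = None
    mpss_20: float | None = None
    array_expressed: bool = False
    rnaseq_expressed: bool = False


@dataclass
class SmRNAHit:
    smrna_id: str
    gene_id: str
    position: int
    genome_hit_count: int


# ---------------------------------------------------------------------------
# density and centromere enrichment
# ---------------------------------------------------------------------------


def density_profile(elements, chrom_lengths: dict[str, int],
                    window_bp: int = 1_000_000,
                    centromeres: dict[str, int] | None = None
                    ) -> list[DensityProfile]:
    """Per-window element fractions; fractions sum to 1 over the genome.

    Each element is assigned to the window containing its midpoint;
    fractions are normalized by the genome-wide element count, matching
    the convention of plotting the percentage of all elements per window.
    """
    centromeres = centromeres or {}
    total = 0
    counts: dict[str, list[int]] = {}
    for chrom, length in chrom_lengths.items():
        counts[chrom] = [0] * max(1, math.ceil(length / window_bp))
    for el in elements:
        mid = (el.start + el.end) // 2
        if el.chrom not in counts:
            raise ValueError(f"element on unknown chromosome {el.chrom}")
        if mid >= chrom_lengths[el.chrom] + window_bp:
            raise ValueError(
                f"element midpoint {mid} beyond chromosome {el.chrom}")
        idx = min(mid // window_bp, len(counts[el.chrom]) - 1)
        counts[el.chrom][idx] += 1
        total += 1
    profiles = []
    for chrom in chrom_lengths:
        profiles.append(DensityProfile(
            chrom=chrom, window_bp=window_bp,
            fractions=[c / total if total else 0.0 for c in counts[chrom]],
            counts=counts[chrom],
            centromere=centromeres.get(chrom)))
    return profiles


def centromere_enrichment(elements, centromere: int, chrom_length: int,
                          radius_bp: int, n_perm: int = 1000,
                          seed: int = 0) -> tuple[float, float]:
    """Observed fraction of elements within `radius_bp` of the centromere
    and a one-sided permutation p-value under uniform repositioning."""
    if radius_bp >= chrom_length / 2:
        raise ValueError("radius must be below half the chromosome length")
    mids = np.array([(el.start + el.end) // 2 for el in elements])
    if mids.size == 0:
        raise ValueError("no elements to test")
    observed = float(np.mean(np.abs(mids - centromere) <= radius_bp))
    rng = np.random.default_rng(seed)
    null_pos = rng.integers(0, chrom_length, size=(n_perm, mids.size))
    null_frac = np.mean(np.abs(null_pos - centromere) <= radius_bp, axis=1)
    p = (1 + int(np.sum(null_frac >= observed))) / (n_perm + 1)
    return observed, float(p)


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------


def term_enrichment(fg_genes: set[str], bg_genes: set[str],
                    term_table: dict[str, set[str]], mode: str = "go",
                    go_p: float = 0.05, go_fdr: float = 0.25,
                    domain_p: float = 0.01) -> list[EnrichmentResult]:
    """Term over/under-representation of a foreground inside a background.

    GO mode: one-sided hypergeometric over-representation p-value per
    term, BH FDR across terms, significant at p < `go_p` and FDR <
    `go_fdr`. Domain mode: two-sided 2x2 chi-square (foreground vs rest
    of background, with/without the domain), Fisher's exact test when any
    expected count is below 5, significant at p < `domain_p`; direction
    follows the sign of the foreground-vs-background proportion gap.
    Terms absent from the foreground are skipped.
    """
    if not fg_genes <= bg_genes:
        raise ValueError("foreground must be a subset of the background")
    gene_terms = {g: term_table.get(g, set()) for g in bg_genes}
    terms = sorted({t for ts in gene_terms.values() for t in ts})
    M = len(bg_genes)
    n_fg = len(fg_genes)
    results: list[EnrichmentResult] = []
    for term in terms:
        with_term = {g for g in bg_genes if term in gene_terms[g]}
        k = len(with_term & fg_genes)
        K = len(with_term)
        if k == 0:
            continue
        fg_prop = k / n_fg if n_fg else 0.0
        bg_prop = K / M if M else 0.0
        direction = "over" if fg_prop >= bg_prop else "under"
        if mode == "go":
            p = float(stats.hypergeom.sf(k - 1, M, K, n_fg))
            results.append(EnrichmentResult(term, k, n_fg, K, M, p,
                                            direction="over"))
        elif mode == "domain":
            rest_with = K - k
            rest_total = M - n_fg
            table = np.array([[k, n_fg - k],
                              [rest_with, rest_total - rest_with]])
            expected = stats.contingency.expected_freq(table)
            if (expected < 5).any():
                _, p = stats.fisher_exact(table, alternative="two-sided")
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            results.append(EnrichmentResult(term, k, n_fg, K, M, float(p),
                                            direction=direction))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if not results:
        return results
    if mode == "go":
        from statsmodels.stats.multitest import multipletests
        _, fdrs, _, _ = multipletests([r.p_value for r in results],
                                      method="fdr_bh")
        for r, fdr in zip(results, fdrs):
            r.fdr = float(fdr)
            r.significant = r.p_value < go_p and r.fdr < go_fdr
    else:
        for r in results:
            r.significant = r.p_value < domain_p
    return results


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

EST_MIN_IDENTITY = 0.95
EST_MIN_COVERAGE = 0.90
MPSS_MIN_ABUNDANCE = 5.0


def call_expressed(evidence: ExpressionEvidence) -> bool:
    """A gene is expressed if any evidence source fires.

    Sources: an EST/cDNA hit at >= 95% identity covering >= 90% of length;
    MPSS normalized abundance >= 5 in both the 17-bp and 20-bp signature
    sets; a microarray presence flag; an RNA-seq presence flag.
    """
    for identity, coverage in evidence.est_hits:
        if identity >= EST_MIN_IDENTITY and coverage >= EST_MIN_COVERAGE:
            return True
    if (evidence.mpss_17 is not None and evidence.mpss_20 is not None
            and evidence.mpss_17 >= MPSS_MIN_ABUNDANCE
            and evidence.mpss_20 >= MPSS_MIN_ABUNDANCE):
        return True
    return bool(evidence.array_expressed or evidence.rnaseq_expressed)


def expression_divergence(evidence_a: ExpressionEvidence,
                          evidence_b: ExpressionEvidence,
                          fold_threshold: float = 2.0) -> bool:
    """Expression divergence between two paralogous genes.

    Diverged when expression status is discordant, or when both are
    expressed and a shared quantitative source (MPSS 17/20-bp abundance)
    differs by at least `fold_threshold`.
    """
    ea = call_expressed(evidence_a)
    eb = call_expressed(evidence_b)
    if ea != eb:
        return True
    if not (ea and eb):
        return False
    log_thr = math.log2(fold_threshold)
    for attr in ("mpss_17", "mpss_20"):
        va = getattr(evidence_a, attr)
        vb = getattr(evidence_b, attr)
        if va is not None and vb is not None and va > 0 and vb > 0:
            if abs(math.log2(va / vb)) >= log_thr:
                return True
    return False


# ---------------------------------------------------------------------------
# small RNAs
# ---------------------------------------------------------------------------


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def smrna_unique_hits(gene_seqs: dict[str, str], smrnas: dict[str, str],
                      genome: str) -> tuple[list[SmRNAHit], dict[str, int]]:
    """Exact full-length smRNA matches at unique genomic sites.

    Each smRNA is matched exactly (both strands) inside the gene
    sequences; matched smRNAs are then re-searched against the whole
    genome (both strands) and kept only when they occur exactly once.
    Returns the hits and per-gene unique-smRNA counts.
    """
    genome = genome.upper()
    hits: list[SmRNAHit] = []
    per_gene: dict[str, int] = {g: 0 for g in gene_seqs}
    for sid, smrna in smrnas.items():
        smrna = smrna.upper()
        if not 18 <= len(smrna) <= 30:
            continue
        rc = revcomp(smrna)
        gene_matches = []
        for gid, gseq in gene_seqs.items():
            gseq = gseq.upper()
            pos = gseq.find(smrna)
            if pos < 0:
                pos = gseq.find(rc)
            if pos >= 0:
                gene_matches.append((gid, pos))
        if not gene_matches:
            continue
        genome_count = _count_occurrences(genome, smrna)
        if rc != smrna:
            genome_count += _count_occurrences(genome, rc)
        if genome_count != 1:
            continue
        for gid, pos in gene_matches:
            hits.append(SmRNAHit(smrna_id=sid, gene_id=gid, position=pos,
                                 genome_hit_count=genome_count))
            per_gene[gid] += 1
    return hits, per_gene


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_density_bedgraph(profiles: list[DensityProfile],
                           path: str | Path) -> None:
    lines = []
    for p in profiles:
        for i, frac in enumerate(p.fractions):
            lines.append(f"{p.chrom}\t{i * p.window_bp}"
                         f"\t{(i + 1) * p.window_bp}\t{frac:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_enrichment_tsv(results: list[EnrichmentResult],
                         path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "term": r.term, "fg_count": r.fg_count, "fg_total": r.fg_total,
        "bg_count": r.bg_count, "bg_total": r.bg_total,
        "p_value": r.p_value, "fdr": r.fdr, "direction": r.direction,
        "significant": r.significant,
    } for r in results]).to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path: str | Path) -> dict[str, ExpressionEvidence]:
    """Evidence table: gene_id, est_identity, est_coverage, mpss_17,
    mpss_20, array_expressed, rnaseq_expressed (empty fields = absent)."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    out: dict[str, ExpressionEvidence] = {}
    for _, row in df.iterrows():
        ev = out.setdefault(row["gene_id"],
                            ExpressionEvidence(gene_id=row["gene_id"]))
        if not pd.isna(row.get("est_identity")) \
                and not pd.isna(row.get("est_coverage")):
            ev.est_hits.append((float(row["est_identity"]),
                                float(row["est_coverage"])))
        for col, attr in (("mpss_17", "mpss_17"), ("mpss_20", "mpss_20")):
            if col in row and not pd.isna(row[col]):
                setattr(ev, attr, float(row[col]))
        for col in ("array_expressed", "rnaseq_expressed"):
            if col in row and not pd.isna(row[col]):
                setattr(ev, col, bool(row[col]))
    return out
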