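"""Brute-force Nei-Gojobori counting oracle.

Written independently of the package implementation: the genetic code
comes from Biopython's translator, synonymous site fractions are found by
explicitly constructing every single-base neighbor of every codon, and
pathway averaging enumerates substitution orders by recursion. Used to
cross-check the package's NG86 estimator on random codon pairs.
"""

from __future__ import annotations

from Bio.Seq import Seq

BASES = "ACGT"


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def syn_fraction_of_position(codon: str, pos: int) -> float:
    """Fraction of the three changes at `pos` that preserve the amino acid."""
    preserved = 0
    for base in BASES:
        if base == codon[pos]:
            continue
        neighbor = codon[:pos] + base + codon[pos + 1:]
        if aa_of(neighbor) == aa_of(codon):
            preserved += 1
    return preserved / 3.0


def syn_sites_of_codon(codon: str) -> float:
    return sum(syn_fraction_of_position(codon, p) for p in range(3))


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    Recursively explores every order of fixing the differing positions,
    discarding branches that pass through a stop codon. If no stop-free
    pathway exists, all differences are reported as nonsynonymous.
    """
    paths: list[tuple[int, int]] = []

    def walk(cur: str, syn: int, non: int) -> None:
        if cur == codon_b:
            paths.append((syn, non))
            return
        for pos in range(3):
            if cur[pos] == codon_b[pos]:
                continue
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if aa_of(nxt) == "*" and nxt != codon_b:
                continue
            if aa_of(nxt) == aa_of(cur):
                walk(nxt, syn + 1, non)
            else:
                walk(nxt, syn, non + 1)

    walk(codon_a, 0, 0)
    if not paths:
        n_diff = sum(a != b for a, b in zip(codon_a, codon_b))
        return 0.0, float(n_diff)
    # each full-length pathway of k steps was reached once per ordering
    syn_total = sum(p[0] for p in paths)
    non_total = sum(p[1] for p in paths)
    return syn_total / len(paths), non_total / len(paths)


def ng86_counts(pairs: list[tuple[str, str]]) -> tuple[float, float, float, float]:
    """(S_sites, N_sites, Sd, Nd) over a list of aligned codon pairs."""
    S = Sd = Nd = 0.0
    for ca, cb in pairs:
        S += (syn_sites_of_codon(ca) + syn_sites_of_codon(cb)) / 2.0
        s, n = count_differences(ca, cb)
        Sd += s
        Nd += n
    N = 3.0 * len(pairs) - S
    return S, N, Sd, Nd
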