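"""Independent brute-force oracles used to cross-check the NG86 engine.

Deliberately built on Biopython's translation rather than the package's own
codon tables, and on explicit enumeration of mutation orderings.
"""

import itertools

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_sites(codon: str) -> tuple[float, float]:
    s = 0.0
    for pos in range(3):
        alts = [
            codon[:pos] + nt + codon[pos + 1 :]
            for nt in "ACGT"
            if nt != codon[pos]
        ]
        alts = [a for a in alts if a not in STOPS]
        if alts:
            s += sum(_aa(a) == _aa(codon) for a in alts) / len(alts)
    return s, 3.0 - s


def brute_differences(c1: str, c2: str) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    syn_sum = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = c1
        syn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            syn += _aa(cur) == _aa(nxt)
            cur = nxt
        if ok:
            syn_sum += syn
            n_paths += 1
    if n_paths == 0:
        raise ValueError("all pathways blocked")
    sd = syn_sum / n_paths
    return sd, len(positions) - sd


def brute_pair_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for an aligned stop-free pair, codon by codon."""
    S1 = S2 = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        s1, _ = brute_sites(c1)
        s2, _ = brute_sites(c2)
        sd, nd = brute_differences(c1, c2)
        S1 += s1
        S2 += s2
        Sd += sd
        Nd += nd
        n_codons += 1
    S = 0.5 * (S1 + S2)
    return S, 3.0 * n_codons - S, Sd, Nd
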