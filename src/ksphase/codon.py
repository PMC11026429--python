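"""Codon-level bookkeeping for synonymous/nonsynonymous substitution counting.

Implements the Nei–Gojobori (1986) primitives on the standard nuclear genetic
code: per-codon synonymous/nonsynonymous site fractions and pathway-averaged
difference counts between codon pairs.  Changes to stop codons are excluded
both from site denominators and from mutational pathways, following the usual
NG86 convention.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"

_TABLE = unambiguous_dna_by_id[1]  # standard nuclear code
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
AMINO_ACID = dict(_TABLE.forward_table)


def is_sense_codon(codon: str) -> bool:
    """True for a 3-letter unambiguous, non-stop codon."""
    return codon in AMINO_ACID


def translate(codon: str) -> str:
    """One-letter amino acid of a sense codon."""
    return AMINO_ACID[codon]


@lru_cache(maxsize=None)
def single_nt_neighbors(codon: str) -> tuple[str, ...]:
    """All 9 codons one nucleotide change away (stops included)."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return tuple(out)


@lru_cache(maxsize=None)
def synonymous_changes(codon: str) -> tuple[tuple[int, str], ...]:
    """Single-nucleotide changes that preserve the amino acid.

    Returns (position, new_base) pairs; changes creating stop codons are
    never synonymous here because stops are excluded outright.
    """
    aa = AMINO_ACID[codon]
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and AMINO_ACID[alt] == aa:
                out.append((pos, nt))
    return tuple(out)


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts for one codon.

    Each position contributes a synonymous fraction equal to the number of
    amino-acid-preserving single-nucleotide changes divided by the number of
    non-stop changes at that position; the position always counts as one
    full site, so s + n == 3.

    Raises ValueError on stop or ambiguous codons.
    """
    if codon not in AMINO_ACID:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = AMINO_ACID[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if AMINO_ACID[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences NG86-style.

    Averages the per-step classification over every ordering of the single
    nucleotide steps from ``codon1`` to ``codon2``; orderings that pass
    through a stop codon are excluded.  Returns counts summing to the number
    of differing positions.

    Raises ValueError if either codon is not a sense codon, or if every
    pathway is blocked by stop codons (no valid decomposition).
    """
    for c in (codon1, codon2):
        if c not in AMINO_ACID:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = codon1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(AMINO_ACID[cur] == AMINO_ACID[nxt])
            cur = nxt
        if ok:
            syn_total += sum(steps)
            n_paths += 1
    if n_paths == 0:
        raise ValueError(f"no stop-free pathway between {codon1} and {codon2}")
    sd = syn_total / n_paths
    return sd, len(diff_pos) - sd
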