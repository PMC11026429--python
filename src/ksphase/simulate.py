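"""Synthetic allotetraploid data generator.

Emulates the statistical structure the downstream analysis assumes: for each
gene slot an ancestral coding sequence gives rise to one reference-diploid
copy and two homeologous focal copies (one per subgenome), with synonymous
divergences chosen so that every pairwise Ks matches its target level.
Substitution is synonymous-only and event-based: the number of events on a
branch is Poisson with mean ks × S (S = NG86 synonymous site count of the
branch's starting sequence) and each event picks uniformly among the
currently synonymous single-nucleotide changes, so multiple hits occur
naturally and translated proteins never change.

Also provides an error-free uniform-coverage read simulator for k-mer based
genome sizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codon as _codon
from .ks import CodonAlignmentPair

#: Jukes–Cantor domain bound; divergences at or above this saturate NG86.
SATURATION_KS = 0.75

_SENSE = _codon.SENSE_CODONS


def _random_ancestor(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_SENSE), size=n_codons)
    return [_SENSE[i] for i in idx]


def synonymous_site_count(codons: list[str]) -> float:
    """Total NG86 synonymous sites of a stop-free codon sequence."""
    return sum(_codon.count_sites(c)[0] for c in codons)


def evolve_synonymous(
    codons: list[str], ks: float, rng: np.random.Generator
) -> list[str]:
    """Apply Poisson(ks × S) synonymous single-nucleotide events to a copy.

    Events pick uniformly among the amino-acid-preserving, stop-avoiding
    single-nucleotide changes available in the current sequence; the codon
    list is never mutated in place.
    """
    if ks < 0:
        raise ValueError(f"ks must be non-negative, got {ks}")
    out = list(codons)
    n_events = rng.poisson(ks * synonymous_site_count(out))
    if n_events == 0:
        return out
    weights = np.array(
        [len(_codon.synonymous_changes(c)) for c in out], dtype=float
    )
    for _ in range(n_events):
        total = weights.sum()
        if total == 0:  # pathological: no synonymous change anywhere
            break
        i = rng.choice(len(out), p=weights / total)
        choices = _codon.synonymous_changes(out[i])
        pos, nt = choices[rng.integers(0, len(choices))]
        out[i] = out[i][:pos] + nt + out[i][pos + 1 :]
        weights[i] = len(_codon.synonymous_changes(out[i]))
    return out


def simulate_codon_pair(
    ancestor_length_codons: int, ks_true: float, seed: int | np.random.Generator
) -> CodonAlignmentPair:
    """Simulate one duplicate gene pair at a given true synonymous divergence.

    The full divergence is applied to one lineage (pairwise Ks is invariant
    to how it is split between branches); the other copy is the unchanged
    ancestor, so the number of applied events can be recounted exactly.
    """
    if ancestor_length_codons < 1:
        raise ValueError("ancestor length must be at least 1 codon")
    if not 0 <= ks_true < SATURATION_KS:
        raise ValueError(
            f"ks_true must lie in [0, {SATURATION_KS}) to stay below NG86 "
            f"saturation, got {ks_true}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = _random_ancestor(ancestor_length_codons, rng)
    derived = evolve_synonymous(anc, ks_true, rng)
    return CodonAlignmentPair("".join(anc), "".join(derived), "copy1", "copy2")


@dataclass(frozen=True)
class SimScenario:
    """Parameterization of the synthetic allotetraploid.

    The defaults encode the study conditions: 15 focal chromosomes, eight in
    the low-divergence subgenome A (ortholog Ks ≈ 0.05 versus the reference
    diploid), seven in subgenome B (≈ 0.09), and a homeolog (paralog) peak
    at Ks ≈ 0.102.  Membership follows the published chromosome assignment.
    """

    n_chromosomes: int = 15
    subgenome_membership: dict[str, str] = field(
        default_factory=lambda: {
            f"chr{i:02d}": ("A" if i in (1, 3, 5, 7, 8, 10, 13, 14) else "B")
            for i in range(1, 16)
        }
    )
    ks_ortholog_A: float = 0.05
    ks_ortholog_B: float = 0.09
    ks_paralog: float = 0.102
    genes_per_chromosome: int = 50
    codons_per_gene: int = 300
    seed: int = 0

    def __post_init__(self):
        for ks in (self.ks_ortholog_A, self.ks_ortholog_B, self.ks_paralog):
            if not 0 <= ks < SATURATION_KS:
                raise ValueError(f"Ks level {ks} outside [0, {SATURATION_KS})")
        if self.genes_per_chromosome < 1:
            raise ValueError("genes_per_chromosome must be >= 1")
        if self.codons_per_gene < 1:
            raise ValueError("codons_per_gene must be >= 1")
        chroms = self.chromosomes()
        missing = [c for c in chroms if c not in self.subgenome_membership]
        if missing:
            raise ValueError(f"missing subgenome membership for {missing}")
        bad = {
            c: m
            for c, m in self.subgenome_membership.items()
            if m not in ("A", "B")
        }
        if bad:
            raise ValueError(f"memberships must be 'A' or 'B': {bad}")
        # the three pairwise targets must fit on a 3-taxon star tree
        if any(b < 0 for b in self.branch_lengths()):
            raise ValueError(
                "Ks levels violate the triangle inequality: ks_paralog must "
                "lie between |ks_ortholog_A - ks_ortholog_B| and their sum"
            )

    def chromosomes(self) -> list[str]:
        return [f"chr{i:02d}" for i in range(1, self.n_chromosomes + 1)]

    def branch_lengths(self) -> tuple[float, float, float]:
        """(reference, copy A, copy B) branch lengths of the star tree.

        Solving the three pairwise constraints ref–A = ks_A, ref–B = ks_B,
        A–B = ks_paralog under branch additivity.
        """
        r = 0.5 * (self.ks_ortholog_A + self.ks_ortholog_B - self.ks_paralog)
        a = 0.5 * (self.ks_ortholog_A + self.ks_paralog - self.ks_ortholog_B)
        b = 0.5 * (self.ks_ortholog_B + self.ks_paralog - self.ks_ortholog_A)
        return r, a, b

    def to_dict(self) -> dict:
        return {
            "n_chromosomes": self.n_chromosomes,
            "subgenome_membership": dict(self.subgenome_membership),
            "ks_ortholog_A": self.ks_ortholog_A,
            "ks_ortholog_B": self.ks_ortholog_B,
            "ks_paralog": self.ks_paralog,
            "genes_per_chromosome": self.genes_per_chromosome,
            "codons_per_gene": self.codons_per_gene,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        return cls(**d)


@dataclass
class SimOutput:
    """Sequences plus tables emitted by :func:`simulate_dataset`.

    ``sequences`` maps record id ``<orthogroup>|<species>|<chromosome>`` to
    the nucleotide string; ``gene_map`` is a gene/species/chromosome/
    orthogroup table; ``truth`` echoes the scenario.
    """

    sequences: dict[str, str]
    gene_map: pd.DataFrame
    truth: SimScenario

    @property
    def orthogroups(self) -> list[str]:
        return sorted(self.gene_map["orthogroup"].unique())


FOCAL_SPECIES = "focal"
REFERENCE_SPECIES = "reference"


def simulate_dataset(scenario: SimScenario) -> SimOutput:
    """Generate the full synthetic ortholog/homeolog dataset.

    Each orthogroup holds exactly three copies descending from a common
    ancestor along a star tree: one reference-diploid ortholog and the two
    focal homeologs, both placed on homeologous chromosome pairs (gene g on
    chromosome c carries subgenome c's divergence).  Chromosomes are paired
    (A with B) so every homeolog pair spans the two subgenomes, mirroring
    the duplicated-gene layout of an allotetraploid.
    """
    rng = np.random.default_rng(scenario.seed)
    r_len, a_len, b_len = scenario.branch_lengths()
    chroms = scenario.chromosomes()
    a_chroms = [c for c in chroms if scenario.subgenome_membership[c] == "A"]
    b_chroms = [c for c in chroms if scenario.subgenome_membership[c] == "B"]
    # degenerate scenarios with a single subgenome still emit full triples
    if not a_chroms:
        a_chroms = chroms
    if not b_chroms:
        b_chroms = chroms
    # one gene slot per (larger-subgenome chromosome, gene index); homeolog
    # partners rotate through the smaller subgenome so counts stay balanced
    slots = [c for c in a_chroms for _ in range(scenario.genes_per_chromosome)]

    sequences: dict[str, str] = {}
    rows = []
    for og_counter, chrom_a in enumerate(slots, start=1):
        chrom_b = b_chroms[(og_counter - 1) % len(b_chroms)]
        og = f"OG{og_counter:05d}"
        anc = _random_ancestor(scenario.codons_per_gene, rng)
        ref = evolve_synonymous(anc, r_len, rng)
        cop_a = evolve_synonymous(anc, a_len, rng)
        cop_b = evolve_synonymous(anc, b_len, rng)
        # record ids use a species-or-subgenome tag so the two focal copies
        # stay distinct even when they land on the same chromosome
        for species, tag, chrom, seq in (
            (REFERENCE_SPECIES, REFERENCE_SPECIES, "ref_chr", ref),
            (FOCAL_SPECIES, "A", chrom_a, cop_a),
            (FOCAL_SPECIES, "B", chrom_b, cop_b),
        ):
            gene_id = f"{og}|{tag}|{chrom}"
            sequences[gene_id] = "".join(seq)
            rows.append(
                {
                    "gene": gene_id,
                    "species": species,
                    "chromosome": chrom,
                    "orthogroup": og,
                }
            )
    gene_map = pd.DataFrame(rows, columns=["gene", "species", "chromosome", "orthogroup"])
    return SimOutput(sequences=sequences, gene_map=gene_map, truth=scenario)


def simulate_reads(
    genome_length: int,
    coverage: float,
    read_length: int,
    seed: int | np.random.Generator,
) -> tuple[str, list[str]]:
    """Error-free reads uniformly sampled from a random genome.

    Returns (genome, reads); the number of reads is
    round(coverage × genome_length / read_length) so expected per-base depth
    equals the requested coverage.  When read_length == genome_length the
    reads are exact full-length copies.
    """
    if coverage <= 0:
        raise ValueError(f"coverage must be positive, got {coverage}")
    if read_length < 1 or read_length > genome_length:
        raise ValueError(
            f"read_length must be in [1, genome_length], got {read_length}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genome = "".join(bases[rng.integers(0, 4, size=genome_length)])
    n_reads = int(round(coverage * genome_length / read_length))
    starts = rng.integers(0, genome_length - read_length + 1, size=n_reads)
    reads = [genome[s : s + read_length] for s in starts]
    return genome, reads
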