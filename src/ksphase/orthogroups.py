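"""Orthogroup copy-number filtering.

Selects orthogroups that are single-copy in every listed diploid species and
duplicated (by default exactly two copies) in the focal polyploid — the gene
sets on which homeolog Ks distributions are computed — and provides
per-species copy-number summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("gene", "species", "orthogroup")


def validate_orthogroup_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format (gene, species, orthogroup) table invariants."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"orthogroup table missing columns: {missing}")
    if table["gene"].duplicated().any():
        dups = table.loc[table["gene"].duplicated(), "gene"].head().tolist()
        raise ValueError(f"duplicate gene ids in orthogroup table: {dups}")
    if table[list(_REQUIRED_COLUMNS)].isna().any().any():
        raise ValueError("orthogroup table contains missing values")
    return table


def copy_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Wide orthogroup-by-species copy-count matrix (0 where absent)."""
    validate_orthogroup_table(table)
    return (
        table.groupby(["orthogroup", "species"])
        .size()
        .unstack(fill_value=0)
        .rename_axis(columns=None)
    )


@dataclass
class CopyNumberSummary:
    species: str
    n_orthogroups: int
    distribution: dict[int, int]
    fraction_single_copy: float
    fraction_duplicated: float


def copy_number_summary(table: pd.DataFrame, species: str) -> CopyNumberSummary:
    """Copy-count distribution for one species over orthogroups containing it.

    ``fraction_single_copy`` is the share of those orthogroups with exactly
    one copy; ``fraction_duplicated`` the share with two or more.
    """
    counts = copy_counts(table)
    if species not in counts.columns:
        raise ValueError(f"species {species!r} absent from orthogroup table")
    present = counts[species][counts[species] > 0]
    if present.empty:
        raise ValueError(f"species {species!r} has no orthogroups with copies")
    dist = present.value_counts().sort_index()
    n = int(len(present))
    return CopyNumberSummary(
        species=species,
        n_orthogroups=n,
        distribution={int(k): int(v) for k, v in dist.items()},
        fraction_single_copy=float((present == 1).sum() / n),
        fraction_duplicated=float((present >= 2).sum() / n),
    )


@dataclass(frozen=True)
class FilterCriterion:
    """Single-copy-in-diploids / duplicated-in-focal selection rule.

    ``reference_species`` names the diploid whose ortholog is carried along
    with each selected homeolog pair for downstream Ks phasing; it must be
    one of the listed diploids.
    """

    diploid_species: tuple[str, ...]
    focal_species: str
    reference_species: str
    focal_copy_number: int = 2
    diploid_copy_number: int = 1

    def __post_init__(self):
        if not self.diploid_species:
            raise ValueError("diploid species list must be non-empty")
        if self.focal_species in self.diploid_species:
            raise ValueError("focal species cannot appear in the diploid list")
        if self.reference_species not in self.diploid_species:
            raise ValueError("reference species must be one of the diploids")
        if self.focal_copy_number < 2:
            raise ValueError("focal copy number must be >= 2")


@dataclass
class FilterResult:
    passing_orthogroups: list[str]
    triples: pd.DataFrame  # orthogroup, focal_gene_1, focal_gene_2, reference_gene
    n_sequences: int = field(init=False)

    def __post_init__(self):
        # focal pair + reference ortholog per orthogroup
        self.n_sequences = 3 * len(self.passing_orthogroups)


def select_orthogroups(table: pd.DataFrame, criterion: FilterCriterion) -> FilterResult:
    """Apply the selection rule and emit (homeolog pair, reference) triples.

    An orthogroup passes iff every listed diploid has exactly
    ``diploid_copy_number`` copies (absence fails) and the focal species has
    exactly ``focal_copy_number`` copies.  Focal genes within a triple are
    ordered lexicographically.
    """
    validate_orthogroup_table(table)
    counts = copy_counts(table)
    for sp in (*criterion.diploid_species, criterion.focal_species):
        if sp not in counts.columns:
            counts[sp] = 0
    mask = counts[criterion.focal_species] == criterion.focal_copy_number
    for sp in criterion.diploid_species:
        mask &= counts[sp] == criterion.diploid_copy_number
    passing = sorted(counts.index[mask])

    by_og = table.groupby("orthogroup")
    rows = []
    kept = []
    for og in passing:
        sub = by_og.get_group(og)
        focal = sorted(sub.loc[sub["species"] == criterion.focal_species, "gene"])
        ref = sub.loc[sub["species"] == criterion.reference_species, "gene"]
        if ref.empty:
            logger.warning(
                "orthogroup %s passed the filter but lacks a %s ortholog; dropped",
                og,
                criterion.reference_species,
            )
            continue
        kept.append(og)
        rows.append(
            {
                "orthogroup": og,
                "focal_gene_1": focal[0],
                "focal_gene_2": focal[1],
                "reference_gene": ref.iloc[0],
            }
        )
    triples = pd.DataFrame(
        rows, columns=["orthogroup", "focal_gene_1", "focal_gene_2", "reference_gene"]
    )
    return FilterResult(passing_orthogroups=kept, triples=triples)
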