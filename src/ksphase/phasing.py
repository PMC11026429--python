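"""Two-subgenome assignment of chromosomes from ortholog Ks distributions.

In an allotetraploid, chromosomes inherited from the parent closer to the
reference diploid show systematically lower Ks against it than chromosomes
from the other parent.  This module aggregates gene-level Ks per chromosome
and splits the chromosome medians into two clusters with the exact optimal
1-D two-cluster partition (minimum within-cluster sum of squares over
contiguous splits of the sorted medians, which is globally optimal in one
dimension).  The lower-Ks cluster is labeled subgenome A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ChromosomeKsSummary:
    chromosome: str
    n_genes: int
    median_ks: float
    mean_ks: float
    iqr_ks: float


def summarize_by_chromosome(
    ks_table: pd.DataFrame,
    gene_to_chromosome: pd.DataFrame | dict[str, str],
    gene_column: str = "gene2",
    min_genes: int = 10,
) -> tuple[list[ChromosomeKsSummary], list[str]]:
    """Per-chromosome Ks summaries from a gene-level Ks table.

    ``ks_table`` must have a ``Ks`` column, a ``flag`` column (only ``ok``
    records are used) and a gene-id column named by ``gene_column``;
    ``gene_to_chromosome`` maps those gene ids to chromosomes (DataFrame
    with gene/chromosome columns, or a plain dict).

    Returns (summaries for chromosomes with >= min_genes usable records,
    chromosome ids left unassigned for want of data).
    """
    if isinstance(gene_to_chromosome, pd.DataFrame):
        mapping = dict(
            zip(gene_to_chromosome["gene"], gene_to_chromosome["chromosome"])
        )
    else:
        mapping = dict(gene_to_chromosome)
    ok = ks_table[ks_table["flag"] == "ok"].copy()
    ok["chromosome"] = ok[gene_column].map(mapping)
    unmapped = ok["chromosome"].isna()
    if unmapped.any():
        raise ValueError(
            f"{int(unmapped.sum())} gene(s) in the Ks table have no "
            f"chromosome assignment, e.g. {ok.loc[unmapped, gene_column].iloc[0]!r}"
        )
    if ok.empty:
        raise ValueError("no usable (flag == ok) Ks records to summarize")
    summaries: list[ChromosomeKsSummary] = []
    unassigned: list[str] = []
    for chrom, grp in ok.groupby("chromosome", sort=True):
        ks = grp["Ks"].to_numpy(dtype=float)
        if len(ks) < min_genes:
            logger.warning(
                "chromosome %s has only %d usable Ks records (< %d); unassigned",
                chrom, len(ks), min_genes,
            )
            unassigned.append(str(chrom))
            continue
        q1, q3 = np.percentile(ks, [25, 75])
        summaries.append(
            ChromosomeKsSummary(
                chromosome=str(chrom),
                n_genes=int(len(ks)),
                median_ks=float(np.median(ks)),
                mean_ks=float(np.mean(ks)),
                iqr_ks=float(q3 - q1),
            )
        )
    return summaries, unassigned


@dataclass
class SubgenomePartition:
    """Result of the two-cluster chromosome split.

    ``assignments`` maps chromosome → 'A' (lower-Ks cluster) or 'B';
    ``separation`` is the gap between cluster centers divided by the pooled
    within-cluster spread of medians; the partition is flagged ambiguous
    when the gap is below one pooled spread (labels are still reported
    unless the medians are all identical).
    """

    assignments: dict[str, str]
    center_A: float
    center_B: float
    separation: float
    ambiguous: bool
    summaries: list[ChromosomeKsSummary] = field(default_factory=list)

    @property
    def n_A(self) -> int:
        return sum(1 for v in self.assignments.values() if v == "A")

    @property
    def n_B(self) -> int:
        return sum(1 for v in self.assignments.values() if v == "B")


def optimal_split_1d(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact optimal two-cluster partition of 1-D values by SSE.

    Sorts the values and evaluates all n-1 contiguous splits, returning a
    boolean mask (True = upper cluster, on the original order) and the
    minimal total within-cluster sum of squared deviations.  Contiguity is
    sufficient: the 1-D SSE optimum is always a contiguous split of the
    sorted values.  Deterministic; ties resolve to the smallest upper
    cluster.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two values to split")
    order = np.argsort(values, kind="stable")
    x = values[order]
    best_sse = np.inf
    best_cut = 1
    for cut in range(1, n):
        lo, hi = x[:cut], x[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse - 1e-15:
            best_sse = sse
            best_cut = cut
    mask = np.zeros(n, dtype=bool)
    mask[order[best_cut:]] = True
    return mask, float(best_sse)


def partition_two_clusters(
    summaries: list[ChromosomeKsSummary],
    ambiguity_gap_factor: float = 1.0,
) -> SubgenomePartition:
    """Split chromosome median-Ks values into subgenomes A (low) and B (high).

    The separation statistic is the distance between the two cluster
    median-of-medians divided by the pooled within-cluster IQR of medians;
    when the gap is smaller than ``ambiguity_gap_factor`` × pooled spread
    the partition is flagged ambiguous.  All-identical medians yield an
    ambiguous result with labels withheld.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 chromosome summaries to partition")
    medians = np.array([s.median_ks for s in summaries], dtype=float)
    chroms = [s.chromosome for s in summaries]
    if np.allclose(medians, medians[0]):
        return SubgenomePartition(
            assignments={},
            center_A=float(medians[0]),
            center_B=float(medians[0]),
            separation=0.0,
            ambiguous=True,
            summaries=list(summaries),
        )
    upper_mask, _ = optimal_split_1d(medians)
    low = medians[~upper_mask]
    high = medians[upper_mask]
    center_a = float(np.median(low))
    center_b = float(np.median(high))
    gap = center_b - center_a

    def _iqr(v: np.ndarray) -> float:
        if len(v) < 2:
            return 0.0
        q1, q3 = np.percentile(v, [25, 75])
        return float(q3 - q1)

    pooled = (len(low) * _iqr(low) + len(high) * _iqr(high)) / len(medians)
    separation = gap / pooled if pooled > 0 else np.inf
    ambiguous = gap < ambiguity_gap_factor * pooled
    assignments = {
        c: ("B" if up else "A") for c, up in zip(chroms, upper_mask)
    }
    return SubgenomePartition(
        assignments=assignments,
        center_A=center_a,
        center_B=center_b,
        separation=float(separation),
        ambiguous=bool(ambiguous),
        summaries=list(summaries),
    )


def homeolog_consistency(
    partition: SubgenomePartition,
    paralog_pairs: pd.DataFrame,
    gene_to_chromosome: pd.DataFrame | dict[str, str],
) -> tuple[float, pd.DataFrame]:
    """Fraction of homeolog pairs whose copies fall in different subgenomes.

    ``paralog_pairs`` needs ``focal_gene_1``/``focal_gene_2`` columns; pairs
    on unassigned chromosomes are excluded from the denominator.
    """
    if isinstance(gene_to_chromosome, pd.DataFrame):
        mapping = dict(
            zip(gene_to_chromosome["gene"], gene_to_chromosome["chromosome"])
        )
    else:
        mapping = dict(gene_to_chromosome)
    rows = []
    for _, row in paralog_pairs.iterrows():
        c1 = mapping.get(row["focal_gene_1"])
        c2 = mapping.get(row["focal_gene_2"])
        s1 = partition.assignments.get(c1)
        s2 = partition.assignments.get(c2)
        if s1 is None or s2 is None:
            continue
        rows.append(
            {
                "focal_gene_1": row["focal_gene_1"],
                "focal_gene_2": row["focal_gene_2"],
                "subgenome_1": s1,
                "subgenome_2": s2,
                "split_across": s1 != s2,
            }
        )
    detail = pd.DataFrame(
        rows,
        columns=["focal_gene_1", "focal_gene_2", "subgenome_1", "subgenome_2", "split_across"],
    )
    frac = float(detail["split_across"].mean()) if len(detail) else float("nan")
    return frac, detail
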