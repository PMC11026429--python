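"""Chromosome-level Ks aggregation and the exact two-cluster subgenome split."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ksphase.phasing import (
    ChromosomeKsSummary,
    homeolog_consistency,
    optimal_split_1d,
    partition_two_clusters,
    summarize_by_chromosome,
)


def _summaries(medians):
    return [
        ChromosomeKsSummary(f"c{i}", 20, m, m, 0.01)
        for i, m in enumerate(medians)
    ]


def _ks_table(genes_ks):
    return pd.DataFrame(
        [{"gene2": g, "Ks": k, "flag": "ok"} for g, k in genes_ks]
    )


class TestSummarize:
    def test_median_arithmetic(self):
        table = _ks_table([("g1", 0.04), ("g2", 0.05), ("g3", 0.06)])
        mapping = {"g1": "c1", "g2": "c1", "g3": "c1"}
        summaries, unassigned = summarize_by_chromosome(
            table, mapping, min_genes=3
        )
        assert len(summaries) == 1 and not unassigned
        assert summaries[0].median_ks == pytest.approx(0.05)
        assert summaries[0].n_genes == 3

    def test_below_min_genes_unassigned(self):
        table = _ks_table([("g1", 0.04), ("g2", 0.05)])
        summaries, unassigned = summarize_by_chromosome(
            table, {"g1": "c1", "g2": "c1"}, min_genes=10
        )
        assert summaries == [] and unassigned == ["c1"]

    def test_non_ok_records_excluded(self):
        table = pd.DataFrame(
            [
                {"gene2": "g1", "Ks": 0.05, "flag": "ok"},
                {"gene2": "g2", "Ks": float("inf"), "flag": "saturated"},
            ]
        )
        summaries, _ = summarize_by_chromosome(
            table, {"g1": "c1", "g2": "c1"}, min_genes=1
        )
        assert summaries[0].n_genes == 1

    def test_unmapped_gene_errors(self):
        table = _ks_table([("g1", 0.04)])
        with pytest.raises(ValueError, match="no chromosome"):
            summarize_by_chromosome(table, {}, min_genes=1)


class TestOptimalSplit:
    def test_worked_example(self):
        medians = np.array([0.048, 0.052, 0.089, 0.091])
        upper, _ = optimal_split_1d(medians)
        assert list(upper) == [False, False, True, True]

    @pytest.mark.parametrize("n", [2, 3, 5, 8, 11, 15])
    def test_contiguous_split_equals_exhaustive_optimum(self, n):
        """1-D SSE two-clustering: sorted-split optimum == global optimum."""
        rng = np.random.default_rng(n)
        for _ in range(8):
            vals = rng.uniform(0, 0.2, size=n)

            def sse(mask):
                lo, hi = vals[~mask], vals[mask]
                return ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()

            best = min(
                sse(np.array(m))
                for m in itertools.product([False, True], repeat=n)
                if any(m) and not all(m)
            )
            _, got = optimal_split_1d(vals)
            assert got == pytest.approx(best, abs=1e-12)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            optimal_split_1d(np.array([0.1]))


class TestPartition:
    def test_recovers_8_7_structure(self):
        medians = [0.05] * 8 + [0.09] * 7
        rng = np.random.default_rng(0)
        medians = [m + rng.normal(0, 0.003) for m in medians]
        part = partition_two_clusters(_summaries(medians))
        assert part.n_A == 8 and part.n_B == 7
        assert not part.ambiguous
        assert part.center_A < part.center_B

    def test_label_A_is_lower_cluster(self):
        part = partition_two_clusters(_summaries([0.09, 0.05, 0.091, 0.052]))
        assert part.assignments["c1"] == "A" and part.assignments["c3"] == "A"
        assert part.assignments["c0"] == "B" and part.assignments["c2"] == "B"

    def test_order_invariance(self):
        medians = [0.048, 0.09, 0.052, 0.088, 0.051]
        a = partition_two_clusters(_summaries(medians))
        shuffled = _summaries(medians)
        shuffled = [shuffled[i] for i in (3, 1, 4, 0, 2)]
        b = partition_two_clusters(shuffled)
        assert a.assignments == b.assignments

    def test_identical_medians_withhold_labels(self):
        part = partition_two_clusters(_summaries([0.07, 0.07, 0.07]))
        assert part.ambiguous and part.assignments == {}

    def test_needs_two_summaries(self):
        with pytest.raises(ValueError):
            partition_two_clusters(_summaries([0.05]))


class TestHomeologConsistency:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["focal_gene_1", "focal_gene_2"])

    def test_perfect_split(self):
        part = partition_two_clusters(_summaries([0.05, 0.09]))
        pairs = self._pairs([("gA", "gB")])
        frac, detail = homeolog_consistency(
            part, pairs, {"gA": "c0", "gB": "c1"}
        )
        assert frac == 1.0
        assert bool(detail["split_across"].iloc[0]) is True

    def test_same_cluster_pairs_score_zero(self):
        part = partition_two_clusters(_summaries([0.05, 0.09]))
        pairs = self._pairs([("g1", "g2"), ("g3", "g4")])
        mapping = {"g1": "c0", "g2": "c0", "g3": "c1", "g4": "c1"}
        frac, _ = homeolog_consistency(part, pairs, mapping)
        assert frac == 0.0

    def test_random_assignment_matches_binomial_expectation(self):
        """Shuffled chromosome labels put ~half of pairs across subgenomes."""
        rng = np.random.default_rng(42)
        n_chrom = 10
        part = partition_two_clusters(
            _summaries([0.05] * 5 + [0.09] * 5)
        )
        n_pairs = 400
        pairs = self._pairs([(f"x{i}", f"y{i}") for i in range(n_pairs)])
        mapping = {}
        for i in range(n_pairs):
            mapping[f"x{i}"] = f"c{rng.integers(n_chrom)}"
            mapping[f"y{i}"] = f"c{rng.integers(n_chrom)}"
        frac, _ = homeolog_consistency(part, pairs, mapping)
        # expected 0.5; 5 sigma binomial band
        assert abs(frac - 0.5) < 5 * np.sqrt(0.25 / n_pairs)

    def test_unassigned_chromosomes_excluded(self):
        part = partition_two_clusters(_summaries([0.05, 0.09]))
        pairs = self._pairs([("g1", "g2")])
        frac, detail = homeolog_consistency(
            part, pairs, {"g1": "c0", "g2": "unknown_chr"}
        )
        assert np.isnan(frac) and detail.empty


def test_synthetic_dataset_recovers_membership(small_dataset):
    from ksphase.ks import CodonAlignmentPair, batch_ks
    from ksphase.orthogroups import FilterCriterion, select_orthogroups

    sim = small_dataset
    crit = FilterCriterion(("reference",), "focal", "reference")
    triples = select_orthogroups(sim.gene_map, crit).triples
    pairs = [
        CodonAlignmentPair(sim.sequences[row.reference_gene], sim.sequences[g],
                           row.reference_gene, g)
        for row in triples.itertuples(index=False)
        for g in (row.focal_gene_1, row.focal_gene_2)
    ]
    summaries, _ = summarize_by_chromosome(
        batch_ks(pairs), sim.gene_map, min_genes=5
    )
    assert len(summaries) == 15
    part = partition_two_clusters(summaries)
    truth = sim.truth.subgenome_membership
    assert part.assignments == {c: truth[c] for c in part.assignments}
    assert part.n_A == 8 and part.n_B == 7
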