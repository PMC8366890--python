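import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapassort.popgen import (
    Grouping,
    PopgenError,
    allele_counts,
    frequency_table,
    habitat_grouping,
    holm_adjust,
    nei_fst_pair,
    pairwise_analysis,
    permutation_test_pair,
    sample_alleles,
    site_grouping,
)
from hapassort.lineages import LineageAssignment
from hapassort.seqio import Alignment, MetadataTable, make_dataset


def dataset_from_alleles(site_alleles):
    """Build a dataset whose haplotypes are given letters per (site, habitat)."""
    base = "ACGTACGT"
    variant = {"N": base, "S": "TTGTACGA", "X": "ACGTACGA", "Y": "AGGTACGT"}
    ids, seqs, records = [], [], []
    k = 0
    for site, habitat, alleles in site_alleles:
        for a in alleles:
            sid = f"{site}{k:02d}"
            k += 1
            ids.append(sid)
            seqs.append(variant[a])
            records.append(
                {"sample_id": sid, "site": site, "habitat": habitat, "region": "keys"}
            )
    return make_dataset(
        Alignment.from_sequences(ids, seqs), MetadataTable.from_records(records)
    )


class TestNeiFst:
    def test_fixed_difference_four_vs_one(self):
        fst, hs, ht = nei_fst_pair([4, 0], [0, 1])
        assert (fst, hs, ht) == (1.0, 0.0, pytest.approx(0.5))

    def test_identical_polymorphic_groups_slightly_negative(self):
        fst, hs, ht = nei_fst_pair([5, 5], [5, 5])
        assert hs == pytest.approx(0.55556, abs=1e-4)
        assert ht == pytest.approx(0.52778, abs=1e-4)
        assert fst == pytest.approx(-0.0526, abs=1e-3)

    def test_singleton_plug_in_fallback(self):
        # the study's 4-samples-vs-1 site comparison
        fst, hs, ht = nei_fst_pair([3, 1], [1, 0])
        assert fst == pytest.approx(0.324, abs=1e-3)

    def test_both_fixed_same_allele_is_zero(self):
        fst, hs, ht = nei_fst_pair([4, 0], [7, 0])
        assert fst == 0.0 and ht == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(PopgenError):
            nei_fst_pair([0, 0], [1, 1])

    @given(
        c1=st.lists(st.integers(0, 8), min_size=2, max_size=5),
        c2=st.lists(st.integers(0, 8), min_size=2, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_invariants(self, c1, c2):
        n = min(len(c1), len(c2))
        c1, c2 = c1[:n], c2[:n]
        if sum(c1) < 1 or sum(c2) < 1:
            return
        fst, hs, ht = nei_fst_pair(c1, c2)
        assert fst <= 1.0 + 1e-12
        # symmetric in the two groups
        assert nei_fst_pair(c2, c1)[0] == pytest.approx(fst, abs=1e-12)
        # invariant to allele relabeling
        perm = list(reversed(range(n)))
        fst_p = nei_fst_pair([c1[i] for i in perm], [c2[i] for i in perm])[0]
        assert fst_p == pytest.approx(fst, abs=1e-12)
        # fst = 1 exactly when groups hold no within-group diversity but differ
        if fst == pytest.approx(1.0):
            assert hs == pytest.approx(0.0) and ht > 0


class TestPermutationTest:
    def test_exhaustive_four_vs_one(self):
        # NNNN|S: 5 assignments, only the observed isolates the S allele
        p, n_used, exhaustive, degenerate = permutation_test_pair(
            np.array([0, 0, 0, 0, 1]), 4, 1
        )
        assert p == 0.2
        assert n_used == 5 and exhaustive and not degenerate

    def test_monomorphic_pool(self):
        p, _, _, degenerate = permutation_test_pair(np.zeros(6, dtype=int), 3, 3)
        assert p == 1.0 and degenerate

    def test_exhaustive_matches_direct_enumeration(self):
        # independent oracle: enumerate every labelled permutation
        alleles = np.array([0, 0, 1, 1, 2, 0])
        n1 = 3
        p, _, exhaustive, _ = permutation_test_pair(alleles, n1, 3)
        assert exhaustive
        obs = nei_fst_pair(np.bincount(alleles[:n1], minlength=3),
                           np.bincount(alleles[n1:], minlength=3))[0]
        hits = total = 0
        for perm in itertools.permutations(alleles):
            g1 = np.bincount(np.array(perm[:n1]), minlength=3)
            g2 = np.bincount(np.array(perm[n1:]), minlength=3)
            total += 1
            if nei_fst_pair(g1, g2)[0] >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total)

    def test_monte_carlo_converges_to_exhaustive(self):
        alleles = np.array([0, 0, 0, 1, 1, 2])
        exact, _, _, _ = permutation_test_pair(alleles, 3, 3)
        mc, n_used, exhaustive, _ = permutation_test_pair(
            alleles, 3, 3, n_perm=10_000, seed=1, exhaustive_cap=1
        )
        assert not exhaustive and n_used == 10_000
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc - exact) < 3 * se + 2 / 10_000  # add-one offset

    def test_seed_reproducibility(self):
        alleles = np.tile([0, 1, 2, 0], 5)
        a = permutation_test_pair(alleles, 10, 10, n_perm=500, seed=7,
                                  exhaustive_cap=1)
        b = permutation_test_pair(alleles, 10, 10, n_perm=500, seed=7,
                                  exhaustive_cap=1)
        assert a == b

    def test_size_mismatch_rejected(self):
        with pytest.raises(PopgenError):
            permutation_test_pair(np.array([0, 1]), 2, 1)


class TestGroupingsAndCounts:
    def test_habitat_pooling_excludes_other(self):
        ds = dataset_from_alleles(
            [("o1", "offshore_reef", "NNN"), ("g1", "grass_bed", "SS"),
             ("u1", "other", "N")]
        )
        grouping = habitat_grouping(ds)
        assert set(grouping.labels) == {"offshore_reef", "grass_bed"}
        assert grouping.sizes() == {"offshore_reef": 3, "grass_bed": 2}

    def test_overlapping_groups_rejected(self):
        with pytest.raises(PopgenError):
            Grouping({"a": ("x", "y"), "b": ("y",)})

    def test_counts_conserve_group_sizes(self):
        ds = dataset_from_alleles(
            [("o1", "offshore_reef", "NNSX"), ("g1", "grass_bed", "SSY")]
        )
        counts = allele_counts(ds, habitat_grouping(ds))
        assert {g: int(c.sum()) for g, c in counts.items()} == {
            "offshore_reef": 4,
            "grass_bed": 3,
        }

    def test_lineage_mode_two_alleles(self):
        ds = dataset_from_alleles(
            [("o1", "offshore_reef", "NNNN"), ("g1", "grass_bed", "S")]
        )
        labels = {s: ("northern" if ds.alignment.row(s) == "ACGTACGT" else "southern")
                  for s in ds.sample_ids}
        assignment = LineageAssignment(labels, 0.1, "test")
        alleles = sample_alleles(ds, "lineage", assignment)
        assert set(alleles.values()) == {0, 1}

    def test_all_distinct_haplotypes_count_one(self, tiny_alignment):
        meta = MetadataTable.from_records(
            [{"sample_id": s, "site": "x", "habitat": "other", "region": "r"}
             for s in tiny_alignment.sample_ids]
        )
        ds = make_dataset(tiny_alignment, meta)
        counts = allele_counts(ds, Grouping({"all": ds.sample_ids}))
        assert list(counts["all"]) == [1, 1, 1, 1]


class TestPairwiseAnalysis:
    def test_three_habitat_groups_give_three_pairs(self):
        ds = dataset_from_alleles(
            [("o1", "offshore_reef", "NNSS"), ("i1", "inshore_reef", "NSNS"),
             ("g1", "grass_bed", "SSNN")]
        )
        table = pairwise_analysis(ds, habitat_grouping(ds), n_perm=99, seed=0)
        assert len(table) == 3
        assert set(table.columns) >= {"group1", "group2", "fst", "p_value", "exhaustive"}
        assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()

    def test_site_level_four_vs_one_exhaustive(self):
        # reproduces the study's XMuta-vs-KML configuration
        ds = dataset_from_alleles(
            [("xmuta", "offshore_reef", "NNNN"), ("kml", "grass_bed", "S")]
        )
        table = pairwise_analysis(ds, site_grouping(ds), seed=0)
        row = table.iloc[0]
        assert row["exhaustive"]
        assert row["fst"] == 1.0
        assert row["p_value"] == pytest.approx(0.2)

    def test_single_group_rejected(self):
        ds = dataset_from_alleles([("o1", "offshore_reef", "NNSS")])
        with pytest.raises(PopgenError):
            pairwise_analysis(ds, habitat_grouping(ds), n_perm=99)


class TestHolmAndFrequencies:
    def test_holm_small_case(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_frequency_table(self):
        ds = dataset_from_alleles(
            [("o1", "offshore_reef", "NNNN"), ("g1", "grass_bed", "SSN")]
        )
        labels = {
            s: ("northern" if ds.alignment.row(s) == "ACGTACGT" else "southern")
            for s in ds.sample_ids
        }
        assignment = LineageAssignment(labels, 0.1, "test")
        table = frequency_table(ds, assignment, habitat_grouping(ds))
        by_group = table.set_index("group")
        assert by_group.loc["offshore_reef", "n"] == 4
        assert by_group.loc["offshore_reef", "prop_northern"] == 1.0
        assert by_group.loc["grass_bed", "n_northern"] == 1
        sums = table["prop_northern"] + table["prop_southern"]
        assert np.allclose(sums, 1.0)


class TestNullCalibrationShape:
    def test_pvalues_conservative_under_exchangeability(self):
        # alpha = 0: permutation p-values stochastically >= uniform
        from hapassort.simulate import SimConfig, SiteSpec, simulate_dataset

        sites = (
            SiteSpec("a", "offshore_reef", 10),
            SiteSpec("b", "inshore_reef", 10),
        )
        pvals = []
        for seed in range(40):
            sim = simulate_dataset(SimConfig(sites=sites, alpha=0.0, seed=seed))
            t = pairwise_analysis(
                sim.dataset, habitat_grouping(sim.dataset), n_perm=199, seed=seed
            )
            pvals.extend(t["p_value"])
        pvals = np.sort(pvals)
        # one-sided: empirical CDF never exceeds uniform by more than noise
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        assert np.max(ecdf - pvals) < 1.36 / np.sqrt(len(pvals)) + 0.1
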