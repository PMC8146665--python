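"""Hamming distances and dendrogram cutting against brute-force oracles."""

import numpy as np
import pytest

from hapsignal.hapcluster import (
    WILDTYPE_LABEL,
    cluster_population_summary,
    cluster_signature_variants,
    hamming_matrix,
    hierarchical_clusters,
)
from hapsignal.hapio import Region, ValidationError

from conftest import CLUSTER_REGION, make_hapset, make_panel


def naive_hamming(matrix):
    """Double-loop SNP-difference count between all haplotype pairs."""
    n = matrix.shape[1]
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            out[i, j] = int((matrix[:, i] != matrix[:, j]).sum())
    return out


def graph_components(square, cut):
    """Connected components of the graph joining pairs at distance <= cut."""
    n = square.shape[0]
    comp = list(range(n))

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if square[i, j] <= cut:
                comp[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


class TestHammingMatrix:
    def test_identical_haplotypes_distance_zero(self):
        hs = make_hapset(np.ones((4, 4)))
        assert (hamming_matrix(hs).condensed == 0).all()

    def test_hand_count(self):
        hs = make_hapset(np.array([[1, 0], [0, 1], [1, 1]]))
        assert hamming_matrix(hs)[0, 1] == 2  # 101 vs 011

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(50)
        matrix = rng.integers(0, 2, size=(50, 20)).astype(np.uint8)
        hs = make_hapset(matrix)
        dist = hamming_matrix(hs)
        np.testing.assert_array_equal(dist.square(), naive_hamming(matrix))
        assert dist.condensed.max() <= 50

    def test_empty_region_rejected(self):
        hs = make_hapset(np.zeros((3, 4)), positions=[10, 20, 30])
        with pytest.raises(ValidationError):
            hamming_matrix(hs, Region("3R", 500, 600))


class TestHierarchicalClusters:
    def test_pair_plus_outlier(self):
        # d(h1,h2)=0, d(.,h3)=10 -> {h1,h2} together, h3 apart at cut 7
        matrix = np.zeros((10, 4), dtype=np.uint8)
        matrix[:, 2:] = 1  # one diploid sample carries 10 alt alleles
        hs = make_hapset(matrix)
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=7,
                                  min_cluster_freq=0.0)
        assert a.labels[0] == a.labels[1]
        assert a.labels[2] == a.labels[3]
        assert a.labels[0] != a.labels[2]

    def test_single_linkage_chains(self):
        # d(h1,h2)=5, d(h2,h3)=5, d(h1,h3)=10: one cluster at cut 7
        matrix = np.zeros((10, 4), dtype=np.uint8)
        matrix[:5, [1, 3]] = 1   # h2 ~ 5 from h1
        matrix[5:, 3] = 1        # pad: make column 3 a second distinct hap
        matrix = np.array(
            [[0] * 5 + [0] * 5, [1] * 5 + [0] * 5, [1] * 5 + [1] * 5,
             [1] * 5 + [1] * 5]
        ).T.astype(np.uint8)
        hs = make_hapset(matrix)
        d = hamming_matrix(hs)
        assert d[0, 1] == 5 and d[1, 2] == 5 and d[0, 2] == 10
        a = hierarchical_clusters(d, hs, linkage="single", cut_height=7)
        assert len(set(a.labels)) == 1

    def test_cut_zero_groups_identical_haplotypes(self):
        rng = np.random.default_rng(51)
        base = rng.integers(0, 2, size=(12, 3)).astype(np.uint8)
        matrix = base[:, [0, 0, 1, 1, 2, 0]]  # duplicates of three haplotypes
        hs = make_hapset(matrix)
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=0,
                                  min_cluster_freq=0.0)
        keys = [tuple(matrix[:, i]) for i in range(6)]
        for i in range(6):
            for j in range(6):
                assert (a.labels[i] == a.labels[j]) == (keys[i] == keys[j])

    def test_matches_graph_component_oracle(self):
        """Single-linkage flat clusters = components of the <=h graph."""
        rng = np.random.default_rng(52)
        for trial in range(20):
            matrix = rng.integers(0, 2, size=(30, 16)).astype(np.uint8)
            hs = make_hapset(matrix)
            dist = hamming_matrix(hs)
            cut = int(rng.integers(0, 12))
            a = hierarchical_clusters(dist, hs, linkage="single",
                                      cut_height=cut, min_cluster_freq=0.0)
            oracle = graph_components(dist.square(), cut)
            # same partition up to relabelling
            for i in range(16):
                for j in range(16):
                    assert (a.labels[i] == a.labels[j]) == (
                        oracle[i] == oracle[j]
                    ), f"trial {trial} cut {cut}"

    def test_labels_ordered_by_descending_size(self):
        matrix = np.zeros((10, 10), dtype=np.uint8)
        matrix[:, :4] = 0          # 4 identical haplotypes
        matrix[:5, 4:10] = 1       # 6 identical haplotypes, far from first
        hs = make_hapset(matrix)
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=0)
        assert (a.labels[4:] == "C1").all()
        assert (a.labels[:4] == "C2").all()

    def test_small_clusters_fold_into_wildtype(self):
        matrix = np.zeros((10, 10), dtype=np.uint8)
        matrix[:, 9] = 1
        hs = make_hapset(matrix)
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=0,
                                  min_cluster_freq=0.2)
        assert a.labels[9] == WILDTYPE_LABEL
        assert (a.labels[:9] == "C1").all()

    def test_partition_invariant_to_haplotype_order(self):
        rng = np.random.default_rng(53)
        matrix = rng.integers(0, 2, size=(25, 20)).astype(np.uint8)
        hs = make_hapset(matrix)
        perm = rng.permutation(20)
        # permute whole samples to keep the two-per-sample pairing valid
        perm = np.concatenate(
            [[2 * i, 2 * i + 1] for i in rng.permutation(10)]
        )
        hs2 = hs.take_haplotypes(perm)
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=5)
        b = hierarchical_clusters(hamming_matrix(hs2), hs2, cut_height=5)
        for x in range(20):
            for y in range(20):
                assert (a.labels[perm[x]] == a.labels[perm[y]]) == (
                    b.labels[x] == b.labels[y]
                )

    def test_invalid_cut_rejected(self):
        hs = make_hapset(np.zeros((3, 4)))
        with pytest.raises(ValidationError):
            hierarchical_clusters(hamming_matrix(hs), hs, cut_height=-1)


class TestPopulationSummary:
    def test_all_wildtype_row(self):
        hs = make_hapset(np.zeros((2, 4)))
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=7,
                                  min_cluster_freq=1.1)  # force everything wt
        summary = cluster_population_summary(a, make_panel(hs))
        assert summary.loc["pop1", WILDTYPE_LABEL] == 1.0

    def test_hand_tally(self):
        matrix = np.zeros((10, 4), dtype=np.uint8)
        matrix[:, 2:] = 1
        hs = make_hapset(matrix)
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=0,
                                  min_cluster_freq=0.6)  # only one names C1
        summary = cluster_population_summary(a, make_panel(hs))
        assert summary.loc["pop1"].sum() == pytest.approx(1.0)
        assert set(summary.columns) == {"C1", WILDTYPE_LABEL} or \
            set(summary.columns) == {WILDTYPE_LABEL}

    def test_matches_direct_tally(self):
        rng = np.random.default_rng(54)
        matrix = rng.integers(0, 2, size=(20, 12)).astype(np.uint8)
        pops = ["KE", "KE", "AO", "AO", "KE", "AO"]
        hs = make_hapset(matrix, populations=pops)
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=6)
        summary = cluster_population_summary(a, make_panel(hs))
        hap_pops = np.repeat(pops, 2)
        for pop in ("KE", "AO"):
            for label in summary.columns:
                expected = (
                    (a.labels[hap_pops == pop] == label).sum()
                    / (hap_pops == pop).sum()
                )
                assert summary.loc[pop, label] == pytest.approx(expected)


class TestSignatureVariants:
    def test_planted_signature(self):
        matrix = np.zeros((8, 10), dtype=np.uint8)
        matrix[0, :6] = 1      # variant 0 carried by the C1 block
        matrix[1:, :6] = 1     # make the block internally identical, distinct
        hs = make_hapset(matrix)
        a = hierarchical_clusters(hamming_matrix(hs), hs, cut_height=0)
        table = cluster_signature_variants(a, hs, [hs.sites[0]])
        c1 = table[table["cluster"] == "C1"].iloc[0]
        wt_or_c2 = table[table["cluster"] != "C1"].iloc[0]
        assert c1["carrier_proportion"] == 1.0 and bool(c1["signature"])
        assert wt_or_c2["carrier_proportion"] == 0.0 and not bool(
            wt_or_c2["signature"]
        )

    def test_unknown_variant_rejected(self):
        from hapsignal.hapio import VariantSite

        hs = make_hapset(np.zeros((2, 4)))
        a = hierarchical_clusters(hamming_matrix(hs), hs)
        with pytest.raises(ValidationError):
            cluster_signature_variants(a, hs, [VariantSite("3R", 9, "A", "C")])


class TestSweepRecovery:
    def test_swept_haplotypes_form_one_cluster(self, sweep_sim):
        """On a planted sweep the carriers land (mostly) in one cluster.

        The wild type legitimately splits into several haplotype families, so
        the comparison is carrier status vs membership of the cluster holding
        the plurality of carriers: adjusted Rand index > 0.8, with the swept
        cluster both concentrated (most carriers in it) and pure (mostly
        carriers)."""
        from collections import Counter

        from sklearn.metrics import adjusted_rand_score

        hapset, _, truth = sweep_sim
        dist = hamming_matrix(hapset, CLUSTER_REGION)
        a = hierarchical_clusters(dist, hapset)
        carrier_labels = np.asarray(a.labels)[truth.carrier_flags]
        swept_cluster = Counter(carrier_labels).most_common(1)[0][0]
        in_swept = np.asarray(a.labels) == swept_cluster

        ari = adjusted_rand_score(
            truth.carrier_flags.astype(int), in_swept.astype(int)
        )
        assert ari > 0.8
        # concentration: most carriers share that one cluster
        assert (carrier_labels == swept_cluster).mean() > 0.8
        # purity: that cluster is essentially all carriers
        assert truth.carrier_flags[in_swept].mean() > 0.9

    def test_focal_variant_is_cluster_signature(self, sweep_sim):
        hapset, _, truth = sweep_sim
        dist = hamming_matrix(hapset, CLUSTER_REGION)
        a = hierarchical_clusters(dist, hapset)
        focal = hapset.sites[truth.focal_site]
        table = cluster_signature_variants(a, hapset, [focal])
        c1 = table[table["cluster"] == "C1"].iloc[0]
        assert bool(c1["signature"])
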