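"""Nearest-neighbour distances, the clustering rule, and cluster annotation."""

import random
from collections import Counter, defaultdict

import numpy as np
import pytest

from bcrep.clustering import (
    allowed_mismatches,
    annotate_clusters,
    classify_abundance,
    cluster_center,
    cluster_repertoire,
    nn_distances,
    threshold_scan,
)


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def brute_force_nn(seqs):
    """O(n^2) oracle for the nearest-neighbour histogram."""
    hist = Counter()
    for i, a in enumerate(seqs):
        best = None
        for j, b in enumerate(seqs):
            if i != j and len(a) == len(b):
                d = _hamming(a, b)
                best = d if best is None else min(best, d)
        if best is not None:
            hist[best] += 1
    return dict(hist)


def brute_force_partition(samples, k):
    """Union-find oracle for single-linkage clustering under the rule:
    same V, same J, same CDR3 length, Hamming <= floor(L / k)."""
    items = [(s.key, r) for s in samples for r in s.records]
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i][1], items[j][1]
            if (a.v_gene, a.j_gene, len(a.cdr3_aa)) != (b.v_gene, b.j_gene, len(b.cdr3_aa)):
                continue
            if _hamming(a.cdr3_aa, b.cdr3_aa) <= len(a.cdr3_aa) // k:
                parent[find(i)] = find(j)
    groups = defaultdict(set)
    for idx, (key, rec) in enumerate(items):
        groups[find(idx)].add((key, rec.id))
    return {frozenset(g) for g in groups.values()}


def as_partition(cluster_set):
    return {
        frozenset((key, rid) for key, ids in c.members.items() for rid in ids)
        for c in cluster_set.clusters
    }


class TestNNDistances:
    def test_hand_example(self):
        nn = nn_distances(["AAAA", "AAAB", "CCCC"])
        assert nn.histogram == {1: 2, 4: 1}

    def test_identical_sequences_have_zero_distance(self):
        nn = nn_distances(["AAAA"] * 4)
        assert nn.histogram == {0: 4}

    def test_no_comparator_is_excluded(self):
        nn = nn_distances(["AAAA", "AAAB", "CCCCC"])
        assert nn.n_excluded == 1 and nn.total == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nn_distances([])

    def test_matches_brute_force_on_random_set(self):
        rng = random.Random(77)
        seqs = [
            "".join(rng.choice("AB") for _ in range(rng.choice([5, 6])))
            for _ in range(1000)
        ]
        assert nn_distances(seqs).histogram == brute_force_nn(seqs)


class TestAllowedMismatches:
    @pytest.mark.parametrize("length,k,expected", [(12, 12, 1), (24, 12, 2), (11, 12, 0), (15, 8, 1)])
    def test_floor_rule(self, length, k, expected):
        assert allowed_mismatches(length, k) == expected

    def test_min_allowed_floor_raise(self):
        assert allowed_mismatches(11, 12, min_allowed=1) == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            allowed_mismatches(0, 12)


class TestClusterRepertoire:
    def test_hand_example_two_clusters(self, rec, make_sample):
        sample = make_sample([
            rec(0, "CARDYWGQGTLV"), rec(1, "CARDYWGQGTLW"), rec(2, "CTTTTTTTTTTV"),
        ])
        cs = cluster_repertoire(sample, k=12)
        assert as_partition(cs) == {
            frozenset({(sample.key, "seq0"), (sample.key, "seq1")}),
            frozenset({(sample.key, "seq2")}),
        }

    def test_same_cdr3_different_v_gene_stays_split(self, rec, make_sample):
        sample = make_sample([rec(0, v="IGHV1-1"), rec(1, v="IGHV2-1")])
        assert len(cluster_repertoire(sample, k=12)) == 2

    def test_matches_brute_force_partition(self, bimodal_sample):
        import copy

        sub = copy.copy(bimodal_sample)
        sub.records = bimodal_sample.records[:500]
        cs = cluster_repertoire(sub, k=12)
        assert as_partition(cs) == brute_force_partition([sub], k=12)

    def test_partition_covers_every_sequence_exactly_once(self, bimodal_clusters, bimodal_sample):
        assigned = sorted(
            rid for c in bimodal_clusters.clusters
            for ids in c.members.values() for rid in ids
        )
        assert assigned == sorted(r.id for r in bimodal_sample.records)

    def test_invariant_under_record_and_sample_order(self, rec, make_sample):
        records = [rec(i, cdr3) for i, cdr3 in enumerate(
            ["CARDYWGQGTLV", "CARDYWGQGTLW", "CTTTTTTTTTTV", "CARDYWGQGTLV"]
        )]
        s1 = make_sample(records, replicate="a")
        s2 = make_sample([rec(10 + i) for i in range(3)], replicate="b")
        forward = cluster_repertoire([s1, s2], k=12)
        shuffled_s1 = make_sample(records[::-1], replicate="a")
        backward = cluster_repertoire([s2, shuffled_s1], k=12)
        assert as_partition(forward) == as_partition(backward)

    def test_empty_cdr3_skipped_with_warning(self, rec, make_sample):
        good = rec(0)
        bad = rec(1)
        bad.cdr3_aa = ""
        with pytest.warns(UserWarning, match="empty CDR3"):
            cs = cluster_repertoire(make_sample([good, bad]), k=12)
        assert len(cs) == 1


class TestClusterCenter:
    def test_modal_member(self, rec, make_sample):
        sample = make_sample(
            [rec(i, "CARDYWGQGTLV") for i in range(5)]
            + [rec(5 + i, "CARDYWGQGTLW") for i in range(2)]
        )
        (cluster,) = cluster_repertoire(sample, k=12).clusters
        assert cluster_center(cluster) == "CARDYWGQGTLV"

    def test_tie_breaks_lexicographically(self, rec, make_sample):
        sample = make_sample(
            [rec(i, "CARDYWGQGTLV") for i in range(3)]
            + [rec(3 + i, "CARDYWGQGTLA") for i in range(3)]
        )
        (cluster,) = cluster_repertoire(sample, k=12).clusters
        assert cluster_center(cluster) == "CARDYWGQGTLA"

    def test_singleton(self, rec, make_sample):
        (cluster,) = cluster_repertoire(make_sample([rec(0, "CAAAW")]), k=12).clusters
        assert cluster_center(cluster) == "CAAAW"


class TestAbundance:
    def test_boundary_at_ten_sequences(self, rec, make_sample):
        for n, expected in [(10, "abundant"), (9, "rare")]:
            sample = make_sample([rec(i) for i in range(n)])
            (cluster,) = cluster_repertoire(sample, k=12).clusters
            assert classify_abundance(cluster, sample.key) == expected

    def test_threshold_is_0p01_percent_of_full_depth(self):
        assert 10 / 100_000 * 100 == pytest.approx(0.01)


class TestAnnotate:
    def test_mean_mutation_and_subclass_counts(self, rec, make_sample):
        sample = make_sample([rec(0, mut=2), rec(1, mut=4)])
        cs = annotate_clusters(cluster_repertoire(sample, k=12), [sample])
        (cluster,) = cs.clusters
        assert cluster.mean_v_mutations == pytest.approx(3.0)
        assert cluster.subclass_counts == {"IgG1": 2}

    def test_matches_direct_recomputation(self, bimodal_sample, bimodal_clusters):
        annotate_clusters(bimodal_clusters, [bimodal_sample])
        by_id = {r.id: r for r in bimodal_sample.records}
        for cluster in bimodal_clusters.clusters[:50]:
            ids = [rid for ids in cluster.members.values() for rid in ids]
            assert cluster.mean_v_mutations == pytest.approx(
                np.mean([by_id[r].v_mutation_count for r in ids])
            )
            assert sum(cluster.subclass_counts.values()) == cluster.total_size


class TestThresholdScan:
    def test_coarser_threshold_never_increases_cluster_count(self, bimodal_sample):
        table = threshold_scan([bimodal_sample], k_values=[4, 8, 12, 26])
        by_k = table.set_index("k")["n_clusters"]
        assert by_k[8] <= by_k[12] <= by_k[26]
        assert by_k[4] <= by_k[8]

    def test_strict_threshold_leaves_two_aa_pairs_unclustered(self, rec, make_sample):
        sample = make_sample([rec(0, "CARDYWGQGTLV"), rec(1, "CARDYWGQGALW")])
        table = threshold_scan([sample], k_values=[12, 26])
        by_k = table.set_index("k")["n_clusters"]
        assert by_k[26] == 2  # floor(12/26) = 0: the distance-2 pair stays split
        assert by_k[12] == 2  # floor(12/12) = 1: still split
        assert cluster_repertoire(sample, k=6).clusters[0].total_size == 2

    def test_cluster_count_plateaus_between_8_and_12(self, bimodal_sample):
        """With clones >= 3 apart and reads within 2 of their clone, any
        threshold admitting 1-2 mismatches recovers nearly the same
        partition; stricter or looser thresholds change it sharply."""
        table = threshold_scan(
            [bimodal_sample], k_values=[8, 10, 12, 16, 26]
        ).set_index("k")["n_clusters"]
        across_plateau = (table[12] - table[8]) / table[12]
        above_plateau = (table[26] - table[12]) / table[12]
        assert across_plateau < 0.2
        assert above_plateau > 0.5
        # the interval just above the plateau changes faster per unit k
        assert (table[16] - table[12]) / 4 > (table[12] - table[8]) / 4


def test_clustering_collapses_first_nn_peak(bimodal_sample, bimodal_clusters):
    """After clustering, cluster centers are mostly distinct clones, so the
    0-2 substitution peak of the distance histogram shrinks."""
    pre = nn_distances([r.cdr3_aa for r in bimodal_sample.records]).as_series()
    centers = [c.center_cdr3 for c in bimodal_clusters.clusters]
    post = nn_distances(centers, level="cluster_center").as_series()
    assert post[:3].sum() < pre[:3].sum()
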