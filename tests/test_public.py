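"""Sharing spectra, public/private structure, antigen annotation."""

import numpy as np
import pytest

from bcrep.clustering import annotate_clusters, cluster_repertoire
from bcrep.public import (
    AntigenReference,
    annotate_specificity,
    public_private_compare,
    sharing_spectrum,
    specificity_enrichment,
)
from bcrep.simulate import (
    make_germline_db,
    make_public_pool,
    sample_reads,
    simulate_repertoire,
    spawn_seeds,
)


def small_cohort(seed=91, n_participants=10, n_public=5, n_clones=300,
                 n_reads=1500, public_slots="head"):
    db = make_germline_db(25, 5, seed=seed)
    seeds = spawn_seeds(seed, 2 * n_participants + 1)
    pool = make_public_pool(db, n_public, seed=seeds[-1]) if n_public else None
    samples = []
    for i in range(n_participants):
        rep = simulate_repertoire(
            db, n_clones, public_pool=pool, seed=seeds[2 * i],
            participant=f"P{i:02d}", public_slots=public_slots,
        )
        samples.append(sample_reads(rep, 1000, n_reads, seed=seeds[2 * i + 1]).to_sample())
    return pool, samples


class TestSharingSpectrum:
    def test_everything_shared(self, rec, make_sample):
        samples = [
            make_sample([rec(i, "CARDYWGQGTLVW")], participant=f"P{i}")
            for i in range(3)
        ]
        spec = sharing_spectrum(cluster_repertoire(samples, k=12))
        assert spec.counts == {3: 1}
        assert spec.public_fraction == 1.0

    def test_disjoint_repertoires_are_private(self, rec, make_sample):
        samples = [
            make_sample([rec(i, v=f"IGHV{i + 1}-1")], participant=f"P{i}")
            for i in range(3)
        ]
        spec = sharing_spectrum(cluster_repertoire(samples, k=12))
        assert spec.counts == {1: 3}
        assert spec.public_fraction == 0.0
        assert spec.percents[1] == pytest.approx(100.0)

    def test_injected_public_clones_recovered_across_ten_participants(self):
        pool, samples = small_cohort()
        cs = cluster_repertoire(samples, k=12)
        spec = sharing_spectrum(cs)
        fully_shared = [
            c for c in cs.clusters if len(c.participants) == len(samples)
        ]
        assert len(fully_shared) >= len(pool)
        pool_keys = {(c.v_gene, c.j_gene, c.cdr3_aa) for c in pool}
        recovered = {
            (c.v_gene, c.j_gene, c.center_cdr3)
            for c in fully_shared
        }
        assert pool_keys <= recovered
        assert spec.total == len(cs)


class TestPublicPrivateCompare:
    def test_single_participant_rejected(self, rec, make_sample):
        cs = cluster_repertoire(make_sample([rec(0)]), k=12)
        with pytest.raises(ValueError):
            public_private_compare(cs, "size")

    def test_expanded_public_clones_detected_as_larger(self):
        _, samples = small_cohort(seed=93)
        cs = cluster_repertoire(samples, k=12)
        cmp = public_private_compare(cs, "size")
        assert cmp.public_mean > cmp.private_mean
        assert cmp.pvalue < 0.05

    def test_mutation_metric_requires_annotation(self):
        _, samples = small_cohort(seed=95, n_participants=3)
        cs = cluster_repertoire(samples, k=12)
        with pytest.raises(ValueError, match="annotate"):
            public_private_compare(cs, "mutation")
        annotate_clusters(cs, samples)
        cmp = public_private_compare(cs, "mutation")
        assert len(cmp.per_participant) == 3

    def test_null_is_calibrated(self):
        """With public/private metrics drawn from one distribution the
        paired test rejects at roughly its nominal level."""
        from bcrep.public import paired_test_null_calibration

        rate = paired_test_null_calibration(n_sims=200, n_participants=10, seed=97)
        assert rate == pytest.approx(0.05, abs=0.04)


class TestAnnotateSpecificity:
    def _clusters(self, rec, make_sample):
        sample = make_sample([
            rec(0, "CARDYWGQGTLV"), rec(1, "CARDYWGQGTLV"),
            rec(2, "CTTTTTTTTTTTTTTV", v="IGHV3-1"),
        ])
        return cluster_repertoire(sample, k=12)

    def test_exact_match_labels_cluster(self, rec, make_sample):
        cs = self._clusters(rec, make_sample)
        labels = annotate_specificity(cs, [AntigenReference("TT", ["CARDYWGQGTLV"])])
        labeled = {cs.by_id(cid).center_cdr3 for cid in labels}
        assert labeled == {"CARDYWGQGTLV"}

    def test_one_mismatch_within_length_12_allowance(self, rec, make_sample):
        cs = self._clusters(rec, make_sample)
        labels = annotate_specificity(cs, [AntigenReference("TT", ["CARDYWGQGTLA"])])
        assert {cs.by_id(cid).center_cdr3 for cid in labels} == {"CARDYWGQGTLV"}

    def test_v_gene_not_required_to_match(self, rec, make_sample):
        cs = self._clusters(rec, make_sample)
        labels = annotate_specificity(
            cs, [AntigenReference("flu", ["CTTTTTTTTTTTTTTV"])]
        )
        assert {cs.by_id(cid).center_cdr3 for cid in labels} == {"CTTTTTTTTTTTTTTV"}

    def test_length_mismatch_never_labels(self, rec, make_sample):
        cs = self._clusters(rec, make_sample)
        assert annotate_specificity(cs, [AntigenReference("TT", ["CARDYWGQGTL"])]) == {}

    def test_member_matching_is_superset_of_center_matching(self):
        _, samples = small_cohort(seed=99, n_participants=3)
        cs = cluster_repertoire(samples, k=12)
        refs = [AntigenReference("TT", [cs.clusters[0].center_cdr3])]
        by_center = annotate_specificity(cs, refs, match="center")
        by_member = annotate_specificity(cs, refs, match="members")
        assert set(by_center) <= set(by_member)

    def test_empty_references_rejected(self, rec, make_sample):
        cs = self._clusters(rec, make_sample)
        with pytest.raises(ValueError):
            annotate_specificity(cs, [])


class TestSpecificityEnrichment:
    def test_no_labels_gives_zero_percentages(self):
        _, samples = small_cohort(seed=101, n_participants=3)
        cs = cluster_repertoire(samples, k=12)
        result = specificity_enrichment(cs, {})
        assert (result.per_participant["public_mean"] == 0).all()
        assert (result.per_participant["private_mean"] == 0).all()

    def test_planted_public_specificities_enrich_public_repertoire(self):
        pool, samples = small_cohort(seed=103)
        cs = cluster_repertoire(samples, k=12)
        refs = [AntigenReference("TT", [c.cdr3_aa for c in pool[:3]]),
                AntigenReference("flu", [c.cdr3_aa for c in pool[3:]])]
        labels = annotate_specificity(cs, refs)
        result = specificity_enrichment(cs, labels)
        assert result.public_mean > result.private_mean
        pcts = np.concatenate([
            result.per_participant["public_mean"], result.per_participant["private_mean"]
        ])
        assert ((0 <= pcts) & (pcts <= 100)).all()
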