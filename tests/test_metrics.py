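"""VJ usage, correlation, PCA, summary metrics, and cluster persistence."""

from collections import Counter

import numpy as np
import pytest

from bcrep.clustering import cluster_repertoire
from bcrep.metrics import (
    persistence,
    summary_metrics,
    usage_correlation,
    vj_pca,
    vj_usage,
)
from bcrep.simulate import (
    drift_repertoire,
    make_replicates,
    sample_reads,
    simulate_repertoire,
)


class TestVJUsage:
    def test_single_combination(self, rec, make_sample):
        sample = make_sample([rec(i) for i in range(4)])
        assert vj_usage(sample) == {("IGHV1-1", "IGHJ1"): 1.0}

    def test_even_split(self, rec, make_sample):
        sample = make_sample([rec(0, v="IGHV1-1"), rec(1, v="IGHV2-1")])
        assert vj_usage(sample) == {
            ("IGHV1-1", "IGHJ1"): 0.5, ("IGHV2-1", "IGHJ1"): 0.5,
        }

    def test_matches_counting_oracle(self, bimodal_sample):
        usage = vj_usage(bimodal_sample)
        tally = Counter((r.v_gene, r.j_gene) for r in bimodal_sample.records)
        assert usage == {
            vj: n / len(bimodal_sample.records) for vj, n in tally.items()
        }
        assert sum(usage.values()) == pytest.approx(1.0)


class TestUsageCorrelation:
    def test_identical_vectors_correlate_perfectly(self):
        u = {("IGHV1-1", "IGHJ1"): 0.7, ("IGHV2-1", "IGHJ2"): 0.3}
        assert usage_correlation(u, u) == pytest.approx(1.0)

    def test_symmetric_and_key_order_invariant(self):
        u1 = {("V1", "J1"): 0.7, ("V2", "J2"): 0.3}
        u2 = {("V2", "J2"): 0.6, ("V3", "J1"): 0.4}
        assert usage_correlation(u1, u2) == pytest.approx(usage_correlation(u2, u1))

    def test_zero_variance_flagged(self):
        u = {("V1", "J1"): 1.0}
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(usage_correlation(u, u))

    def test_unrelated_usage_decorrelates(self):
        rng = np.random.default_rng(61)
        keys = [(f"V{i}", f"J{j}") for i in range(30) for j in range(6)]
        w1 = rng.dirichlet(np.ones(len(keys)))
        w2 = rng.dirichlet(np.ones(len(keys)))
        r = usage_correlation(dict(zip(keys, w1)), dict(zip(keys, w2)))
        assert abs(r) < 0.25

    def test_within_participant_usage_exceeds_between(self, germline):
        """Participants carry distinct VJ biases; visits of one participant
        drift but stay far more correlated than different participants."""
        from itertools import combinations

        from bcrep.simulate import drift_repertoire, spawn_seeds

        usages = {}
        for p, seed in enumerate(spawn_seeds(59, 4)):
            rep = simulate_repertoire(germline, 500, abundance_shape=1.1, seed=seed)
            us = []
            for day in (0, 7):
                visit = rep if day == 0 else drift_repertoire(rep, 0.5, 0.25, seed + 1, day)
                us.append(vj_usage(sample_reads(visit, 1500, 2500, seed=seed + day).to_sample()))
            usages[p] = us
        within = np.mean([usage_correlation(*us) for us in usages.values()])
        between = np.mean([
            usage_correlation(usages[a][0], usages[b][0])
            for a, b in combinations(usages, 2)
        ])
        assert within > between

    def test_pcr_replicates_correlate_above_0_99(self, germline):
        rep = simulate_repertoire(germline, 300, seed=63)
        r1, r2 = make_replicates(rep, "pcr", seed=64, n_cells=2000, n_reads=4000)
        r = usage_correlation(vj_usage(r1.to_sample()), vj_usage(r2.to_sample()))
        assert r > 0.99


class TestPCA:
    def test_identical_samples_sit_at_origin(self):
        u = {("V1", "J1"): 0.5, ("V2", "J1"): 0.5}
        coords, explained = vj_pca([u, u, u])
        np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-12)
        assert explained.sum() <= 1.0 + 1e-12

    def test_fewer_than_three_samples_rejected(self):
        u = {("V1", "J1"): 1.0}
        with pytest.raises(ValueError):
            vj_pca([u, u])

    def test_sample_order_only_permutes_rows(self):
        rng = np.random.default_rng(65)
        keys = [(f"V{i}", "J1") for i in range(10)]
        usages = [dict(zip(keys, rng.dirichlet(np.ones(10)))) for _ in range(5)]
        labels = [f"s{i}" for i in range(5)]
        coords, _ = vj_pca(usages, labels)
        perm = [3, 1, 4, 0, 2]
        coords_perm, _ = vj_pca([usages[i] for i in perm], [labels[i] for i in perm])
        np.testing.assert_allclose(
            coords_perm.loc[labels].to_numpy(), coords.to_numpy(), atol=1e-9
        )

    def test_participants_separate_on_first_components(self, germline):
        """Repeat samples of one participant (shared VJ bias) fall closer
        together than samples from different participants."""
        samples = []
        for p_idx, seed in enumerate([71, 72, 73]):
            rep = simulate_repertoire(germline, 300, seed=seed, participant=f"P{p_idx}")
            for day, s2 in enumerate([1, 2]):
                rs = sample_reads(rep, 1500, 2500, seed=seed * 10 + s2)
                sample = rs.to_sample()
                sample.day = day
                samples.append(sample)
        coords, _ = vj_pca(
            [vj_usage(s) for s in samples], [s.label for s in samples]
        )
        xy = coords.to_numpy()
        within, between = [], []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                d = np.linalg.norm(xy[i] - xy[j])
                (within if samples[i].participant == samples[j].participant else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestSummaryMetrics:
    def test_hand_fixture(self, rec, make_sample):
        sample = make_sample([
            rec(0, "CAAAW", mut=2, sub="IgG1"),
            rec(1, "CAAAAAW", mut=4, sub="IgG2"),
        ])
        m = summary_metrics(sample)
        assert m.mean_cdr3_length == pytest.approx(6.0)
        assert m.mean_v_mutations == pytest.approx(3.0)
        assert m.subclass_proportions == {"IgG1": 0.5, "IgG2": 0.5}

    def test_single_sequence(self, rec, make_sample):
        m = summary_metrics(make_sample([rec(0, "CARDW", mut=7)]))
        assert m.mean_cdr3_length == 5.0 and m.mean_v_mutations == 7.0

    def test_uniform_subclass(self, rec, make_sample):
        m = summary_metrics(make_sample([rec(i, sub="IgG1") for i in range(3)]))
        assert m.subclass_proportions == {"IgG1": 1.0}

    def test_empty_sample_rejected(self, make_sample):
        with pytest.raises(ValueError):
            summary_metrics(make_sample([]))


class TestPersistence:
    def _temporal_samples(self, germline, seed=81, days=(0, 7, 14, 21, 28)):
        rep = simulate_repertoire(germline, 400, seed=seed)
        out = []
        for day in days:
            visit = rep if day == 0 else drift_repertoire(rep, 0.4, 0.2, seed + day, day)
            rs = sample_reads(visit, 1200, 2000, seed=seed * 7 + day)
            out.append(rs.to_sample())
        return out

    def test_everpresent_cluster_counts_all_days(self, rec, make_sample):
        samples = [
            make_sample([rec(i, "CARDYWGQGTLVW")], day=d) for i, d in enumerate(range(5))
        ]
        cs = cluster_repertoire(samples, k=12)
        table = persistence(cs, samples)
        assert table.summary == {5: 1}

    def test_histogram_partitions_all_clusters(self, germline):
        samples = self._temporal_samples(germline)
        cs = cluster_repertoire(samples, k=12)
        table = persistence(cs, samples)
        assert sum(table.summary.values()) == len(cs)

    def test_abundant_clusters_persist_longer(self, germline):
        from bcrep.clustering import classify_abundance

        samples = self._temporal_samples(germline)
        cs = cluster_repertoire(samples, k=12)
        table = persistence(cs, samples)
        day0 = samples[0].key
        abundant, rare = [], []
        for c in cs.clusters:
            if c.size_in(day0) == 0:
                continue
            target = abundant if classify_abundance(c, day0) == "abundant" else rare
            target.append(table.timepoints_present[c.id])
        assert np.mean(abundant) > np.mean(rare)

    def test_pair_sharing_counts_are_consistent(self, germline):
        samples = self._temporal_samples(germline, days=(0, 7))
        cs = cluster_repertoire(samples, k=12)
        table = persistence(cs, samples)
        row = table.pair_sharing.iloc[0]
        assert row["n_shared"] == row["n_shared_abundant"] + row["n_shared_rare"]
        assert row["n_shared"] == table.summary.get(2, 0)
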