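"""Public vs private repertoire structure and antigen-specificity annotation.

Because all samples are clustered jointly, a cluster's presence in several
participants is directly observable: the public repertoire is the set of
clusters detected in at least two participants, the private repertoire the
clusters unique to one.  Clusters are annotated for suspected antigen
specificity when a published antigen-specific CDR3 would have fallen into
the cluster under the clustering rule itself.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bcrep.clustering import Cluster, ClusterSet, allowed_mismatches


@dataclass(slots=True)
class SharingSpectrum:
    """Distribution of clusters over the number of participants sharing them."""

    counts: dict[int, int]  # n participants -> cluster count
    percents: dict[int, float]  # same, as percent of total clusters
    public_ids: set[int]
    private_ids: set[int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def public_fraction(self) -> float:
        """Fraction of all clusters present in >= 2 participants."""
        return len(self.public_ids) / self.total if self.total else 0.0


def sharing_spectrum(cluster_set: ClusterSet) -> SharingSpectrum:
    """Count, for each cluster, the participants it appears in."""
    n_by_cluster = {c.id: len(c.participants) for c in cluster_set.clusters}
    hist = Counter(n_by_cluster.values())
    total = len(cluster_set.clusters)
    return SharingSpectrum(
        counts=dict(sorted(hist.items())),
        percents={n: cnt / total * 100.0 for n, cnt in sorted(hist.items())},
        public_ids={cid for cid, n in n_by_cluster.items() if n >= 2},
        private_ids={cid for cid, n in n_by_cluster.items() if n == 1},
    )


@dataclass(slots=True)
class PairedComparison:
    metric: str
    per_participant: pd.DataFrame  # columns: participant, public_mean, private_mean
    public_mean: float
    public_sem: float
    private_mean: float
    private_sem: float
    statistic: float
    pvalue: float
    excluded: list[str] = field(default_factory=list)


def _cluster_metric(cluster: Cluster, metric: str, participant: str) -> float:
    if metric == "size":
        return float(
            sum(len(ids) for key, ids in cluster.members.items() if key[0] == participant)
        )
    if metric == "mutation":
        if cluster.mean_v_mutations is None:
            raise ValueError("clusters are not annotated; run annotate_clusters first")
        return float(cluster.mean_v_mutations)
    if metric == "cdr3_length":
        return float(cluster.cdr3_length)
    raise ValueError(f"unknown metric {metric!r}")


def _paired_test(pairs: pd.DataFrame, metric: str, excluded: list[str]) -> PairedComparison:
    pub = pairs["public_mean"].to_numpy()
    priv = pairs["private_mean"].to_numpy()
    if len(pairs) < 2:
        raise ValueError("paired comparison needs at least 2 participants")
    diffs = pub - priv
    if np.allclose(diffs, 0):
        statistic, pvalue = 0.0, 1.0
    else:
        statistic, pvalue = stats.wilcoxon(pub, priv)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return PairedComparison(
        metric=metric, per_participant=pairs,
        public_mean=float(pub.mean()), public_sem=sem(pub),
        private_mean=float(priv.mean()), private_sem=sem(priv),
        statistic=float(statistic), pvalue=float(pvalue), excluded=excluded,
    )


def public_private_compare(
    cluster_set: ClusterSet,
    metric: Literal["size", "mutation", "cdr3_length"] = "size",
    spectrum: SharingSpectrum | None = None,
) -> PairedComparison:
    """Per-participant mean of a cluster metric over public vs private
    clusters, with a paired test across participants.

    The pairing is per participant (each contributes one public and one
    private mean); the paired comparison is the Wilcoxon signed-rank test on
    those pairs.  Participants with no public (or no private) clusters are
    excluded from the pairing with a warning.
    """
    spectrum = spectrum or sharing_spectrum(cluster_set)
    participants = sorted({key[0] for key in cluster_set.sample_keys})
    if len(participants) < 2:
        raise ValueError("paired comparison needs at least 2 participants")
    rows = []
    excluded = []
    for p in participants:
        pub_vals, priv_vals = [], []
        for cl in cluster_set.clusters:
            if p not in cl.participants:
                continue
            val = _cluster_metric(cl, metric, p)
            (pub_vals if cl.id in spectrum.public_ids else priv_vals).append(val)
        if not pub_vals or not priv_vals:
            warnings.warn(f"participant {p} has no {'public' if not pub_vals else 'private'} clusters; excluded")
            excluded.append(p)
            continue
        rows.append(
            {"participant": p, "public_mean": float(np.mean(pub_vals)),
             "private_mean": float(np.mean(priv_vals))}
        )
    return _paired_test(pd.DataFrame(rows), metric, excluded)


def paired_test_null_calibration(
    n_sims: int = 500,
    n_participants: int = 10,
    n_clusters: int = 30,
    public_fraction: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the paired public-vs-private comparison.

    For each simulated null dataset, every participant's public and private
    cluster metrics are drawn from the same lognormal size distribution
    (no public/private structure), per-participant means are formed, and
    the same Wilcoxon signed-rank path used by ``public_private_compare``
    is applied.  Returns the fraction of datasets rejected at ``alpha`` —
    nominally ``alpha`` itself for a calibrated test.
    """
    rng = np.random.default_rng(seed)
    n_pub = max(1, int(round(n_clusters * public_fraction)))
    n_priv = n_clusters - n_pub
    rejections = 0
    for _ in range(n_sims):
        rows = []
        for p in range(n_participants):
            sizes = rng.lognormal(1.0, 1.0, size=n_clusters)
            rows.append(
                {"participant": f"P{p}", "public_mean": float(sizes[:n_pub].mean()),
                 "private_mean": float(sizes[n_pub : n_pub + n_priv].mean())}
            )
        result = _paired_test(pd.DataFrame(rows), "size", [])
        rejections += result.pvalue <= alpha
    return rejections / n_sims


@dataclass(slots=True)
class AntigenReference:
    """Published CDR3s with known specificity for one antigen."""

    antigen: str
    cdr3s: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3s:
            raise ValueError("reference needs at least one CDR3")
        self.cdr3s = [s.upper() for s in self.cdr3s]


def annotate_specificity(
    cluster_set: ClusterSet,
    references: Sequence[AntigenReference],
    k: int = 12,
    match: Literal["center", "members"] = "center",
) -> dict[int, set[str]]:
    """Label clusters whose CDR3 matches a known antigen-specific CDR3.

    A reference CDR3 labels a cluster iff it has the cluster's CDR3 length
    and lies within ``allowed_mismatches(L, k)`` substitutions of the
    cluster center (or, with ``match="members"``, of any member CDR3) —
    i.e. the known sequence would have fallen into the cluster during
    clustering.  V/J annotations are deliberately not required to match:
    comparison is on CDR3 identity only.
    """
    if not references:
        raise ValueError("no references given")
    labels: dict[int, set[str]] = {}
    for cl in cluster_set.clusters:
        targets = [cl.center_cdr3] if match == "center" else list(cl.cdr3_counts)
        allowed = allowed_mismatches(cl.cdr3_length, k)
        hits = set()
        for ref in references:
            for ref_cdr3 in ref.cdr3s:
                if len(ref_cdr3) != cl.cdr3_length:
                    continue
                for target in targets:
                    d = sum(a != b for a, b in zip(ref_cdr3, target))
                    if d <= allowed:
                        hits.add(ref.antigen)
                        break
                if ref.antigen in hits:
                    break
        if hits:
            labels[cl.id] = hits
    return labels


def specificity_enrichment(
    cluster_set: ClusterSet,
    labels: dict[int, set[str]],
    spectrum: SharingSpectrum | None = None,
) -> PairedComparison:
    """Percent of clusters with an antigen label, public vs private, per
    participant, with the same paired test as ``public_private_compare``."""
    spectrum = spectrum or sharing_spectrum(cluster_set)
    participants = sorted({key[0] for key in cluster_set.sample_keys})
    rows = []
    excluded = []
    for p in participants:
        n_pub = n_priv = lab_pub = lab_priv = 0
        for cl in cluster_set.clusters:
            if p not in cl.participants:
                continue
            is_labeled = cl.id in labels
            if cl.id in spectrum.public_ids:
                n_pub += 1
                lab_pub += is_labeled
            else:
                n_priv += 1
                lab_priv += is_labeled
        if n_pub == 0 or n_priv == 0:
            warnings.warn(f"participant {p} has no {'public' if n_pub == 0 else 'private'} clusters; excluded")
            excluded.append(p)
            continue
        rows.append(
            {"participant": p, "public_mean": lab_pub / n_pub * 100.0,
             "private_mean": lab_priv / n_priv * 100.0}
        )
    return _paired_test(pd.DataFrame(rows), "percent_labeled", excluded)
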