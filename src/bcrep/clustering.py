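"""Clonal clustering of CDR3 sequences and cluster-level annotation.

Sequences are grouped into clusters — proxies for shared clonal origin or
antigen specificity — when they have the same V gene, the same J gene, the
same CDR3 amino-acid length, and CDR3 sequences within a proportional
mismatch allowance (one substitution per ``k`` amino acids, default k=12,
i.e. >= 92% similarity).  Within each (V, J, length) partition, clusters are
the single-linkage connected components of the graph joining CDR3 pairs
within the allowance.  All samples are clustered jointly so that cluster
identity is directly comparable across replicates, timepoints and
participants.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from bcrep.records import RepertoireSample, SequenceRecord

SampleKey = tuple[str, int, str, str]


# ---------------------------------------------------------------------------
# nearest-neighbour distances


@dataclass(slots=True)
class NNDistribution:
    """Histogram of distances from each sequence to its nearest neighbour.

    The nearest neighbour of a CDR3 is the closest other same-length CDR3 in
    the same set (Hamming distance, substitutions only).  Sequences with no
    same-length comparator are excluded and counted in ``n_excluded``.
    """

    histogram: dict[int, int]
    level: str = "sequence"
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return sum(self.histogram.values())

    def as_series(self) -> pd.Series:
        if not self.histogram:
            return pd.Series(dtype=int)
        idx = range(0, max(self.histogram) + 1)
        return pd.Series([self.histogram.get(d, 0) for d in idx], index=idx, name="count")


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def _pairwise_hamming(mat: np.ndarray, chunk: int = 512) -> np.ndarray:
    m = len(mat)
    out = np.empty((m, m), dtype=np.int32)
    for start in range(0, m, chunk):
        block = mat[start : start + chunk]
        out[start : start + chunk] = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
    return out


def nn_distances(sequences: Sequence[str], level: str = "sequence") -> NNDistribution:
    """Nearest-neighbour distance distribution of a set of CDR3s."""
    if not sequences:
        raise ValueError("no sequences given")
    by_length: dict[int, list[int]] = defaultdict(list)
    for i, s in enumerate(sequences):
        by_length[len(s)].append(i)
    hist: Counter[int] = Counter()
    excluded = 0
    for length, idxs in by_length.items():
        if len(idxs) < 2:
            excluded += len(idxs)
            continue
        mat = _encode([sequences[i] for i in idxs])
        m = len(mat)
        for start in range(0, m, 512):
            block = mat[start : start + 512]
            d = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
            for row in range(len(block)):
                d[row, start + row] = np.iinfo(np.int32).max
            hist.update(d.min(axis=1).tolist())
    return NNDistribution(histogram=dict(hist), level=level, n_excluded=excluded)


# ---------------------------------------------------------------------------
# clustering


def allowed_mismatches(cdr3_length: int, k: int = 12, min_allowed: int = 0) -> int:
    """Substitutions allowed between same-cluster CDR3s of a given length.

    One mismatch per ``k`` amino acids, floor(L / k): CDR3s shorter than
    ``k`` require exact identity unless ``min_allowed`` raises the floor.
    """
    if cdr3_length < 1 or k < 1:
        raise ValueError("cdr3_length and k must be >= 1")
    return max(min_allowed, cdr3_length // k)


@dataclass(slots=True)
class Cluster:
    id: int
    v_gene: str
    j_gene: str
    cdr3_length: int
    center_cdr3: str
    members: dict[SampleKey, list[str]] = field(default_factory=dict)
    cdr3_counts: dict[str, int] = field(default_factory=dict)
    mean_v_mutations: float | None = None
    subclass_counts: dict[str, int] | None = None

    def size_in(self, sample_key: SampleKey) -> int:
        return len(self.members.get(sample_key, ()))

    @property
    def total_size(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def participants(self) -> set[str]:
        return {key[0] for key, ids in self.members.items() if ids}


@dataclass(slots=True)
class ClusterSet:
    clusters: list[Cluster]
    k: int
    sample_keys: list[SampleKey]
    assignments: dict[tuple[SampleKey, str], int]

    def __len__(self) -> int:
        return len(self.clusters)

    def by_id(self, cluster_id: int) -> Cluster:
        return self.clusters[cluster_id]

    def sizes_for(self, sample_key: SampleKey) -> dict[int, int]:
        """Cluster id -> member count for one sample (zero sizes omitted)."""
        out = {}
        for c in self.clusters:
            n = c.size_in(sample_key)
            if n:
                out[c.id] = n
        return out

    def ids_for(self, sample_key: SampleKey) -> set[int]:
        return {c.id for c in self.clusters if c.size_in(sample_key)}


def _partitions(samples: Iterable[RepertoireSample]):
    """Group records by (V, J, CDR3 length); map CDR3 -> [(sample_key, record)]."""
    parts: dict[tuple[str, str, int], dict[str, list[tuple[SampleKey, SequenceRecord]]]]
    parts = defaultdict(lambda: defaultdict(list))
    for sample in samples:
        for rec in sample.records:
            if not rec.cdr3_aa:
                warnings.warn(f"record {rec.id} has an empty CDR3; skipped")
                continue
            parts[(rec.v_gene, rec.j_gene, len(rec.cdr3_aa))][rec.cdr3_aa].append(
                (sample.key, rec)
            )
    return parts


def _components(unique: list[str], allowed: int) -> np.ndarray:
    """Single-linkage component label per unique CDR3."""
    m = len(unique)
    if m == 1 or allowed == 0:
        return np.arange(m)
    dist = _pairwise_hamming(_encode(unique))
    adj = csr_matrix(dist <= allowed)
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_repertoire(
    samples: Sequence[RepertoireSample] | RepertoireSample,
    k: int = 12,
    min_allowed: int = 0,
) -> ClusterSet:
    """Cluster sequences from all samples jointly.

    Returns a partition: every (sample, sequence) pair is assigned to exactly
    one cluster.  Cluster ids are assigned in a canonical order (by V, J,
    length, then center CDR3) so the result is invariant to input order.
    """
    if isinstance(samples, RepertoireSample):
        samples = [samples]
    parts = _partitions(samples)
    raw: list[Cluster] = []
    for (v, j, length) in sorted(parts):
        cdr3_map = parts[(v, j, length)]
        unique = sorted(cdr3_map)
        labels = _components(unique, allowed_mismatches(length, k, min_allowed))
        by_label: dict[int, list[str]] = defaultdict(list)
        for cdr3, lab in zip(unique, labels):
            by_label[lab].append(cdr3)
        for lab in sorted(by_label, key=lambda l: min(by_label[l])):
            members: dict[SampleKey, list[str]] = defaultdict(list)
            counts: Counter[str] = Counter()
            for cdr3 in by_label[lab]:
                for key, rec in cdr3_map[cdr3]:
                    members[key].append(rec.id)
                    counts[cdr3] += 1
            cl = Cluster(
                id=-1, v_gene=v, j_gene=j, cdr3_length=length,
                center_cdr3="", members=dict(members), cdr3_counts=dict(counts),
            )
            cl.center_cdr3 = cluster_center(cl)
            raw.append(cl)
    raw.sort(key=lambda c: (c.v_gene, c.j_gene, c.cdr3_length, c.center_cdr3))
    assignments: dict[tuple[SampleKey, str], int] = {}
    for cid, cl in enumerate(raw):
        cl.id = cid
        for key, ids in cl.members.items():
            for rid in ids:
                assignments[(key, rid)] = cid
    return ClusterSet(
        clusters=raw, k=k,
        sample_keys=[s.key for s in samples],
        assignments=assignments,
    )


def cluster_center(cluster: Cluster) -> str:
    """The dominant (modal) member CDR3; ties broken lexicographically."""
    if not cluster.cdr3_counts:
        raise ValueError("empty cluster")
    best = max(cluster.cdr3_counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
    return best[0]


def classify_abundance(cluster: Cluster, sample_key: SampleKey, min_count: int = 10) -> str:
    """"abundant" iff the cluster holds >= ``min_count`` sequences in that sample.

    At the standard 100,000-sequence depth, 10 sequences is 0.01% of the
    sequenced repertoire.
    """
    return "abundant" if cluster.size_in(sample_key) >= min_count else "rare"


def annotate_clusters(
    cluster_set: ClusterSet, samples: Sequence[RepertoireSample]
) -> ClusterSet:
    """Fill mean V-gene mutation counts and subclass compositions in place."""
    lookup: dict[tuple[SampleKey, str], SequenceRecord] = {}
    for sample in samples:
        for rec in sample.records:
            lookup[(sample.key, rec.id)] = rec
    for cl in cluster_set.clusters:
        muts: list[int] = []
        subs: Counter[str] = Counter()
        for key, ids in cl.members.items():
            for rid in ids:
                rec = lookup[(key, rid)]
                muts.append(rec.v_mutation_count)
                subs[rec.subclass] += 1
        cl.mean_v_mutations = float(np.mean(muts)) if muts else None
        cl.subclass_counts = dict(subs)
    return cluster_set


def threshold_scan(
    samples: Sequence[RepertoireSample],
    k_values: Iterable[int] = range(4, 27),
) -> pd.DataFrame:
    """Scan the clustering threshold k and summarize the resulting partitions.

    For each k: the number of clusters formed, the largest CDR3 distance
    joined within a cluster, and the smallest distance left split between
    clusters of the same (V, J, length) partition.  Larger k (stricter
    similarity) yields more, tighter clusters; coarser thresholds merge
    unrelated sequences and the cluster count drops sharply.
    """
    k_values = sorted(set(int(k) for k in k_values), reverse=True)
    if len(k_values) < 2:
        raise ValueError("need at least 2 threshold values")
    parts = _partitions(samples)
    cached = []
    for (v, j, length), cdr3_map in parts.items():
        unique = sorted(cdr3_map)
        dist = _pairwise_hamming(_encode(unique)) if len(unique) > 1 else None
        cached.append((length, unique, dist))
    rows = []
    for k in k_values:
        n_clusters = 0
        max_intra = 0
        min_inter: float = np.inf
        for length, unique, dist in cached:
            allowed = allowed_mismatches(length, k)
            if dist is None or allowed == 0:
                labels = np.arange(len(unique))
            else:
                adj = csr_matrix(dist <= allowed)
                _, labels = connected_components(adj, directed=False)
            n_clusters += len(np.unique(labels))
            if dist is not None and len(unique) > 1:
                same = labels[:, None] == labels[None, :]
                off = ~np.eye(len(unique), dtype=bool)
                if (same & off).any():
                    max_intra = max(max_intra, int(dist[same & off].max()))
                if (~same).any():
                    min_inter = min(min_inter, int(dist[~same].min()))
        rows.append(
            {
                "k": k,
                "n_clusters": n_clusters,
                "max_intra_distance": max_intra,
                "min_inter_distance": min_inter if np.isfinite(min_inter) else np.nan,
            }
        )
    return pd.DataFrame(rows)
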