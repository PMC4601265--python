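"""Global repertoire summaries and temporal persistence of clusters."""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bcrep.clustering import ClusterSet, SampleKey, classify_abundance
from bcrep.records import RepertoireSample

VJKey = tuple[str, str]


def vj_usage(sample: RepertoireSample) -> dict[VJKey, float]:
    """Fraction of the repertoire using each (V, J) gene combination.

    Zero-usage combinations are omitted; fractions sum to 1.
    """
    counts: Counter[VJKey] = Counter((r.v_gene, r.j_gene) for r in sample.records)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty sample")
    return {vj: n / total for vj, n in counts.items()}


def _align(vectors: Sequence[Mapping[VJKey, float]]) -> np.ndarray:
    keys = sorted(set().union(*[set(v) for v in vectors]))
    return np.array([[v.get(k, 0.0) for k in keys] for v in vectors])


def usage_correlation(u1: Mapping[VJKey, float], u2: Mapping[VJKey, float]) -> float:
    """Pearson correlation of two usage vectors on the union of VJ keys
    (absent combinations count as zero usage).  Returns NaN with a warning
    when either vector has zero variance."""
    mat = _align([u1, u2])
    if np.ptp(mat[0]) == 0 or np.ptp(mat[1]) == 0:
        warnings.warn("usage correlation undefined: zero variance")
        return float("nan")
    r, _ = stats.pearsonr(mat[0], mat[1])
    return float(r)


def vj_pca(usage: Sequence[Mapping[VJKey, float]] | pd.DataFrame, labels: Sequence[str] | None = None):
    """PCA of VJ usage across samples.

    Columns (VJ combinations) are centered but not scaled — usage fractions
    already share a scale.  Returns ``(coordinates, explained_variance)``:
    per-sample scores on the first two components and the fraction of total
    variance each explains.  Component signs are fixed by making the
    largest-magnitude loading of each component positive, so results are
    reproducible across sample orderings.
    """
    if isinstance(usage, pd.DataFrame):
        mat = usage.to_numpy(dtype=float)
        labels = list(usage.index) if labels is None else list(labels)
    else:
        mat = _align(usage)
        labels = [f"sample{i}" for i in range(len(mat))] if labels is None else list(labels)
    if len(mat) < 3:
        raise ValueError("PCA needs at least 3 samples")
    centered = mat - mat.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float((s**2).sum())
    n_comp = min(2, len(s))
    coords = np.zeros((len(mat), 2))
    explained = np.zeros(2)
    for c in range(n_comp):
        load = vt[c]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
        coords[:, c] = centered @ load
        explained[c] = (s[c] ** 2) / total_var if total_var > 0 else 0.0
    return (
        pd.DataFrame(coords, index=labels, columns=["PC1", "PC2"]),
        explained,
    )


@dataclass(slots=True)
class SummaryMetrics:
    mean_cdr3_length: float
    mean_v_mutations: float
    subclass_proportions: dict[str, float]


def summary_metrics(sample: RepertoireSample) -> SummaryMetrics:
    """Mean CDR3 length, mean V-gene mutation count, and subclass mix,
    computed over all sequences in the sample."""
    if not sample.records:
        raise ValueError("empty sample")
    lengths = [len(r.cdr3_aa) for r in sample.records]
    muts = [r.v_mutation_count for r in sample.records]
    subs: Counter[str] = Counter(r.subclass for r in sample.records)
    total = len(sample.records)
    return SummaryMetrics(
        mean_cdr3_length=float(np.mean(lengths)),
        mean_v_mutations=float(np.mean(muts)),
        subclass_proportions={s: n / total for s, n in sorted(subs.items())},
    )


@dataclass(slots=True)
class PersistenceTable:
    """Cluster presence across timepoints for one participant/isotype."""

    timepoints_present: dict[int, int]  # cluster id -> number of days seen
    summary: dict[int, int]  # t -> number of clusters seen on exactly t days
    pair_sharing: pd.DataFrame  # per day-pair shared clusters by abundance class


def persistence(
    cluster_set: ClusterSet,
    samples: Sequence[RepertoireSample],
    min_abundant: int = 10,
) -> PersistenceTable:
    """How many timepoints each cluster is detected at.

    Presence on a day means >= 1 member sequence in any of that day's
    samples.  ``pair_sharing`` lists, for every pair of days, how many
    shared clusters are abundant vs rare (abundance classified in the
    earlier day's sample) — the tabular replacement for a circular
    cluster-sharing plot.
    """
    days = sorted({s.day for s in samples})
    keys_by_day: dict[int, list[SampleKey]] = defaultdict(list)
    for s in samples:
        keys_by_day[s.day].append(s.key)
    present: dict[int, set[int]] = {}
    for day in days:
        ids: set[int] = set()
        for key in keys_by_day[day]:
            ids |= cluster_set.ids_for(key)
        present[day] = ids
    n_days: dict[int, int] = Counter()
    for day in days:
        for cid in present[day]:
            n_days[cid] += 1
    summary = dict(Counter(n_days.values()))
    rows = []
    for i, d1 in enumerate(days):
        for d2 in days[i + 1 :]:
            shared = present[d1] & present[d2]
            n_abundant = 0
            for cid in shared:
                cl = cluster_set.by_id(cid)
                if any(
                    classify_abundance(cl, key, min_abundant) == "abundant"
                    for key in keys_by_day[d1]
                ):
                    n_abundant += 1
            rows.append(
                {
                    "day1": d1,
                    "day2": d2,
                    "n_shared": len(shared),
                    "n_shared_abundant": n_abundant,
                    "n_shared_rare": len(shared) - n_abundant,
                }
            )
    return PersistenceTable(
        timepoints_present=dict(n_days),
        summary=summary,
        pair_sharing=pd.DataFrame(rows),
    )
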