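"""Repertoire diversity: single indices, clonality, and Hill profiles.

Each cluster is treated as a distinct species with relative abundance p_i.
Shannon entropy weights rare clusters, Simpson's concentration weights
abundant ones, and the Hill diversity family D_alpha spans the continuum
between them; diversity profiles over an alpha grid therefore characterize
a repertoire more completely than any single index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from bcrep.clustering import ClusterSet, SampleKey

DEFAULT_ALPHAS = np.arange(0.0, 10.5, 0.5)


def _validate(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p <= 0).any():
        raise ValueError("frequencies must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def frequencies(cluster_set: ClusterSet, sample_key: SampleKey) -> np.ndarray:
    """Cluster relative abundances p_i for one sample."""
    sizes = np.array(list(cluster_set.sizes_for(sample_key).values()), dtype=float)
    if sizes.size == 0:
        raise ValueError(f"no sequences for sample {sample_key}")
    return sizes / sizes.sum()


def shannon(p) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats)."""
    p = _validate(p)
    return float(-(p * np.log(p)).sum())


def simpson(p) -> float:
    """Simpson's concentration index C = sum p_i^2 (coincidence probability)."""
    p = _validate(p)
    return float((p * p).sum())


def clonality(
    rep1_key: SampleKey, rep2_key: SampleKey, cluster_set: ClusterSet
) -> float:
    """Probability that sequences drawn from two PCR replicates fall in the
    same cluster: sum_c f1(c) f2(c) over the joint cluster set.

    A cross-replicate analogue of Simpson's index; for identical replicates
    it reduces to Simpson's concentration.
    """
    for key in (rep1_key, rep2_key):
        if key not in cluster_set.sample_keys:
            raise ValueError(f"sample {key} was not clustered in this ClusterSet")
    s1 = cluster_set.sizes_for(rep1_key)
    s2 = cluster_set.sizes_for(rep2_key)
    t1 = sum(s1.values())
    t2 = sum(s2.values())
    if t1 == 0 or t2 == 0:
        raise ValueError("empty replicate")
    return float(sum(s1[c] * s2.get(c, 0) for c in s1) / (t1 * t2))


@dataclass(slots=True)
class DiversityProfile:
    alphas: np.ndarray
    values: np.ndarray
    label: str = ""


def hill_diversity(p, alpha: float) -> float:
    """Hill number D_alpha = (sum p_i^alpha)^(1/(1-alpha)); D_1 = exp(H)."""
    p = _validate(p)
    if abs(alpha - 1.0) < 1e-9:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**alpha).sum() ** (1.0 / (1.0 - alpha)))


def hill_profile(p, alphas: Sequence[float] = DEFAULT_ALPHAS, label: str = "") -> DiversityProfile:
    """Diversity profile over an alpha grid (default 0..10 step 0.5).

    D_0 is cluster richness, D_1 the exponential of Shannon entropy, D_2 the
    inverse Simpson concentration; the profile is non-increasing in alpha.
    """
    alphas = np.asarray(list(alphas), dtype=float)
    values = np.array([hill_diversity(p, a) for a in alphas])
    return DiversityProfile(alphas=alphas, values=values, label=label)


def profile_cluster(profiles: Sequence[DiversityProfile]):
    """Compare diversity profiles and cluster the samples.

    Pairwise Euclidean distance over the profile values, then complete-
    linkage agglomeration.  Profiles are ordered by label before linkage so
    distance ties resolve deterministically.  Returns ``(distance_matrix,
    linkage_matrix, labels)``; the distance matrix is a labelled DataFrame
    and the linkage matrix is in scipy ``hclust`` form.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    grid = profiles[0].alphas
    for prof in profiles[1:]:
        if len(prof.alphas) != len(grid) or not np.allclose(prof.alphas, grid):
            raise ValueError("profiles are on different alpha grids")
    ordered = sorted(profiles, key=lambda pr: pr.label)
    labels = [pr.label for pr in ordered]
    mat = np.stack([pr.values for pr in ordered])
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    z = linkage(squareform(dist, checks=False), method="complete")
    return pd.DataFrame(dist, index=labels, columns=labels), z, labels
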