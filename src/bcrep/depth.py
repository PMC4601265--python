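"""Sequencing- and sampling-depth estimation.

Rarefaction treats each cluster as a species and asks how many distinct
clusters are seen at increasing sequencing depth; the Chao estimator
extrapolates the curve to its asymptote from the singleton and doubleton
cluster counts; the Chapman capture-recapture estimator turns the cluster
overlap between two replicate samples into a (lower-bound) estimate of the
effective repertoire size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy.special import gammaln


@dataclass(slots=True)
class RarefactionCurve:
    depths: np.ndarray
    observed_clusters: np.ndarray
    s_obs: int
    f1: int
    f2: int
    chao_estimate: float
    n_total: int
    extrapolated_depths: np.ndarray | None = None
    extrapolated_clusters: np.ndarray | None = None


def _cluster_counts(labels: Sequence) -> np.ndarray:
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    return counts


def chao_richness(s_obs: int, f1: int, f2: int) -> float:
    """Chao's nonparametric richness estimate from singletons/doubletons.

    Classic form s_obs + f1^2 / (2 f2); when there are no doubletons the
    bias-corrected fallback s_obs + f1 (f1 - 1) / 2 avoids division by zero.
    A lower bound for the true number of clusters.
    """
    if f1 < 0 or f2 < 0:
        raise ValueError("f1 and f2 must be >= 0")
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def _exact_expected_richness(counts: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """E[clusters at depth d] under sampling without replacement.

    Hypergeometric closed form: sum_i 1 - C(N - n_i, d) / C(N, d).
    """
    n_total = int(counts.sum())
    out = np.empty(len(depths))
    for k, d in enumerate(depths):
        rest = n_total - counts
        with np.errstate(invalid="ignore"):
            log_miss = (
                gammaln(rest + 1) - gammaln(rest - d + 1)
                - (gammaln(n_total + 1) - gammaln(n_total - d + 1))
            )
        p_miss = np.where(rest >= d, np.exp(log_miss), 0.0)
        out[k] = float((1.0 - p_miss).sum())
    return out


def rarefy(
    labels: Sequence,
    step: int = 1000,
    repeats: int = 10,
    seed: int = 0,
    method: str = "montecarlo",
) -> RarefactionCurve:
    """Rarefaction curve of cluster richness vs sequencing depth.

    ``labels`` holds the cluster label of every sequence in the sample.
    Depths run in ``step`` increments up to the sample size (always
    including the full depth).  ``method="montecarlo"`` averages observed
    richness over ``repeats`` random subsamples without replacement;
    ``method="exact"`` evaluates the hypergeometric expectation instead.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("no labels given")
    if step > n:
        raise ValueError(f"step {step} exceeds sample size {n}")
    counts = _cluster_counts(labels)
    s_obs = len(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    depths = np.arange(step, n + 1, step)
    if depths[-1] != n:
        depths = np.append(depths, n)
    if method == "exact":
        observed = _exact_expected_richness(counts, depths)
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        acc = np.zeros(len(depths))
        for _ in range(repeats):
            perm = rng.permutation(labels)
            for k, d in enumerate(depths):
                acc[k] += len(np.unique(perm[:d]))
        observed = acc / repeats
    else:
        raise ValueError(f"unknown method {method!r}")
    return RarefactionCurve(
        depths=depths, observed_clusters=observed, s_obs=s_obs,
        f1=f1, f2=f2, chao_estimate=chao_richness(s_obs, f1, f2), n_total=n,
    )


def extrapolate(
    curve: RarefactionCurve, target_depth: int = 500_000, step: int = 1000
) -> RarefactionCurve:
    """Extend a rarefaction curve beyond the observed depth.

    Uses the Chao-based extrapolation
    ``S(n + m) = s_obs + f0_hat * (1 - (1 - f1 / (n * f0_hat + f1)) ** m)``
    with ``f0_hat = chao - s_obs``; the extension rises monotonically toward
    the Chao asymptote.  With no singletons the curve is already saturated
    and extends flat at ``s_obs``.  Extrapolations beyond about twice the
    observed depth should be treated as rough values only.
    """
    n = curve.n_total
    if target_depth <= n:
        raise ValueError("target_depth must exceed the observed depth")
    extra = np.arange(n, target_depth + 1, step)
    if extra[-1] != target_depth:
        extra = np.append(extra, target_depth)
    f0 = curve.chao_estimate - curve.s_obs
    if curve.f1 == 0 or f0 <= 0:
        values = np.full(len(extra), float(curve.s_obs))
    else:
        m = extra - n
        values = curve.s_obs + f0 * (1.0 - (1.0 - curve.f1 / (n * f0 + curve.f1)) ** m)
    curve.extrapolated_depths = extra
    curve.extrapolated_clusters = values
    return curve


def depth_for_fraction(curve: RarefactionCurve, fraction: float = 0.9) -> float:
    """Smallest depth at which the extrapolated richness reaches
    ``fraction`` of the Chao estimate; ``inf`` if unreachable on the
    asymptote (e.g. fraction=1 with singletons present)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if curve.extrapolated_depths is None:
        raise ValueError("extrapolate() the curve first")
    if fraction >= 1.0 - 1e-12 and curve.f1 > 0:
        return math.inf  # full richness sits on the asymptote
    target = fraction * curve.chao_estimate
    for d, s in zip(curve.depths, curve.observed_clusters):
        if s >= target:
            return float(d)
    for d, s in zip(curve.extrapolated_depths, curve.extrapolated_clusters):
        if s >= target:
            return float(d)
    return math.inf


def chapman(n1: int, n2: int, m: int) -> float:
    """Chapman's bias-corrected capture-recapture population-size estimate.

    ``n1`` and ``n2`` are the cluster counts in the two replicates and ``m``
    the number shared.  Assumes equal catchability; power-law clone
    abundances violate that assumption and deflate the estimate, so treat it
    as a lower bound on the effective repertoire size.
    """
    if m > min(n1, n2):
        raise ValueError("shared count m cannot exceed min(n1, n2)")
    return (n1 + 1) * (n2 + 1) / (m + 1) - 1


def overlap_min(a: set, b: set) -> float:
    """Percent cluster overlap normalized by the smaller set:
    |A ∩ B| / min(|A|, |B|) × 100."""
    if not a or not b:
        raise ValueError("overlap of an empty set is undefined")
    return len(a & b) / min(len(a), len(b)) * 100.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_sampled(observed: int, estimate: float) -> float:
    """Observed / estimated cluster count × 100, to one decimal (half-up)."""
    if estimate <= 0:
        raise ValueError("estimate must be > 0")
    return round_half_up(observed / estimate * 100.0, 1)
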