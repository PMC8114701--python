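"""Class balancing by k-means clustering and proportional undersampling.

To build a balanced (or ratio-controlled) dataset without distorting the
composition of the majority class, negative samples are clustered on their
1-mer + 2-mer frequency vectors (20 dimensions) with k-means (200 centers
by default), and ``O_i = round(x_i / total * target)`` samples are drawn
uniformly from cluster i of size ``x_i``.  Because each cluster rounds
independently, ``sum(O_i)`` can deviate from ``target`` by at most half the
number of clusters; an optional largest-remainder correction enforces the
exact total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from lncfuse.features import kmer_frequencies
from lncfuse.io import Transcript


def cluster_features(t: "Transcript | str") -> np.ndarray:
    """The 20-dim clustering vector: 4 one-mer + 16 two-mer frequencies."""
    return kmer_frequencies(t, ks=(1, 2))


@dataclass
class ClusterPlan:
    """K-means assignment of negative samples plus cluster sizes."""

    n_clusters: int
    assignments: np.ndarray  #: cluster id per sample
    x: np.ndarray  #: cluster sizes x_i

    @property
    def total(self) -> int:
        return int(self.x.sum())


def cluster_negatives(
    negatives: Sequence[Transcript], n_clusters: int = 200, seed: int = 0
) -> ClusterPlan:
    """Cluster negative samples on k-mer composition.

    ``n_clusters`` scales down automatically to the number of samples for
    small runs.
    """
    if len(negatives) == 0:
        raise ValueError("no negative samples to cluster")
    n_clusters = min(n_clusters, len(negatives))
    feats = np.stack([cluster_features(t) for t in negatives])
    km = KMeans(n_clusters=n_clusters, n_init=5, random_state=seed)
    assignments = km.fit_predict(feats)
    x = np.bincount(assignments, minlength=n_clusters)
    return ClusterPlan(n_clusters=n_clusters, assignments=assignments, x=x)


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(v + 0.5).astype(int)


def undersample_counts(
    x: np.ndarray, total: int, target: int, exact_total: bool = False
) -> np.ndarray:
    """Per-cluster selection counts ``O_i = round(x_i / total * target)``.

    ``round`` is half-up.  With ``exact_total=True`` a largest-remainder
    adjustment forces ``sum(O_i) == target`` (never selecting more than
    ``x_i`` from cluster i).
    """
    x = np.asarray(x)
    if target > total:
        raise ValueError(f"target {target} exceeds total {total}")
    raw = x / total * target
    counts = np.minimum(_round_half_up(raw), x)
    if exact_total:
        diff = target - int(counts.sum())
        remainders = raw - np.floor(raw)
        order = np.argsort(-remainders if diff > 0 else remainders)
        k = 0
        while diff != 0 and k < 10 * len(x):
            i = order[k % len(x)]
            if diff > 0 and counts[i] < x[i]:
                counts[i] += 1
                diff -= 1
            elif diff < 0 and counts[i] > 0:
                counts[i] -= 1
                diff += 1
            k += 1
    return counts


def undersample(
    negatives: Sequence[Transcript],
    plan: ClusterPlan,
    target: int,
    seed: int = 0,
    exact_total: bool = False,
) -> list[Transcript]:
    """Select ~``target`` negatives, preserving cluster proportions."""
    counts = undersample_counts(plan.x, plan.total, target, exact_total=exact_total)
    rng = np.random.default_rng(seed)
    selected: list[Transcript] = []
    for i in range(plan.n_clusters):
        members = np.flatnonzero(plan.assignments == i)
        take = rng.choice(members, size=counts[i], replace=False)
        selected.extend(negatives[j] for j in take)
    return selected


def make_ratio_dataset(
    pos: Sequence[Transcript],
    neg: Sequence[Transcript],
    ratio: int = 1,
    n_clusters: int = 200,
    seed: int = 0,
    exact_total: bool = False,
) -> tuple[list[Transcript], list[Transcript]]:
    """Build a positives : negatives = 1 : ``ratio`` dataset.

    Positives pass through unchanged; negatives are cluster-undersampled
    to ``ratio * len(pos)`` (up to per-cluster rounding slack unless
    ``exact_total``).

    Raises
    ------
    ValueError
        If fewer negatives exist than the requested ratio needs.
    """
    target = ratio * len(pos)
    if target > len(neg):
        raise ValueError(
            f"need {target} negatives for ratio 1:{ratio} but only {len(neg)} available"
        )
    plan = cluster_negatives(neg, n_clusters=n_clusters, seed=seed)
    return list(pos), undersample(neg, plan, target, seed=seed, exact_total=exact_total)
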