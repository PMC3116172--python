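"""Training/testing division by diversity ranking.

Two schemes are provided.  The *diverse subset* scheme greedily ranks the
whole library by max-min Euclidean distance in the normalized descriptor
space, then takes the first 65% (round half up) of the ranking as the
training set.  The *cluster plus diverse subset* scheme first clusters the
compounds on the same descriptors, ranks each cluster separately, splits
each cluster 65/35 with the same rounding, and pools the per-cluster
parts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from cycloqsar.descriptors import DescriptorMatrix


@dataclass
class DiversityRanking:
    order: np.ndarray  # permutation of 0..N-1
    metric: str = "euclidean"
    start: int = 0

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        n = len(self.order)
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("ranking order is not a permutation")


@dataclass
class DatasetSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    scheme: str = "diverse"
    train_fraction: float = 0.65

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        tr, te = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train and test overlap")

    @property
    def n(self) -> int:
        return len(self.train_indices) + len(self.test_indices)

    def to_csv(self, path: str | Path, ids: Sequence[str], clustering: "Clustering | None" = None) -> None:
        part = {}
        for i in self.train_indices:
            part[int(i)] = "train"
        for i in self.test_indices:
            part[int(i)] = "test"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "cluster", "partition"])
            for i, cid in enumerate(ids):
                cl = "" if clustering is None else int(clustering.labels[i])
                w.writerow([cid, cl, part[i]])


@dataclass
class Clustering:
    labels: np.ndarray  # compound index -> contiguous cluster id
    method: str = "kmeans"
    k: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def _as_array(X: DescriptorMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def rank_diverse(X: DescriptorMatrix | np.ndarray, start: int = 0) -> DiversityRanking:
    """Greedy max-min diversity ranking.

    The start entry is ranked first; each subsequent rank goes to the
    unranked entry whose minimum Euclidean distance to all already-ranked
    entries is largest.  Ties break to the lowest original index.
    """
    A = _as_array(X)
    if A.ndim == 1:
        A = A[:, None]
    n = A.shape[0]
    if n < 1:
        raise ValueError("empty matrix")
    if np.isnan(A).any():
        raise ValueError("NaN in descriptor matrix")
    if not 0 <= start < n:
        raise ValueError(f"start index {start} out of range")
    order = [start]
    # squared distances preserve the argmax and avoid n sqrt passes
    mind = np.sum((A - A[start]) ** 2, axis=1)
    mind[start] = -np.inf
    for _ in range(n - 1):
        nxt = int(np.argmax(mind))  # argmax returns the lowest tied index
        order.append(nxt)
        d = np.sum((A - A[nxt]) ** 2, axis=1)
        np.minimum(mind, d, out=mind)
        mind[nxt] = -np.inf
    return DiversityRanking(np.array(order), "euclidean", start)


def _train_size(n: int, frac: float) -> int:
    """Round-half-up train size, capped so both partitions are non-empty."""
    n_train = math.floor(frac * n + 0.5)
    return max(1, min(n - 1, n_train))


def split_by_rank(ranking: DiversityRanking, frac: float = 0.65) -> DatasetSplit:
    """Split a diversity ranking into training (first ``frac``) and testing."""
    if not 0.0 < frac < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    n = len(ranking.order)
    if n < 2:
        raise ValueError("need at least 2 compounds to split")
    k = _train_size(n, frac)
    return DatasetSplit(ranking.order[:k], ranking.order[k:], "diverse", frac)


def cluster_compounds(
    X: DescriptorMatrix | np.ndarray, k: int, seed: int = 0
) -> Clustering:
    """Seeded k-means clustering on the normalized descriptor matrix.

    Labels are relabeled contiguously in order of first occurrence so the
    result is invariant to k-means' internal label permutation.
    """
    A = _as_array(X)
    n = A.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    if k == 1:
        return Clustering(np.zeros(n, dtype=int), "kmeans", 1, seed)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(A)
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return Clustering(labels, "kmeans", k, seed)


def default_k(n: int) -> int:
    """Default cluster count: about one cluster per 20 compounds."""
    return max(2, round(n / 20))


def cluster_diverse_split(
    X: DescriptorMatrix | np.ndarray,
    k: int | None = None,
    frac: float = 0.65,
    seed: int = 0,
    clustering: Optional[Clustering] = None,
) -> tuple[DatasetSplit, Clustering]:
    """Per-cluster diversity ranking and 65/35 split, pooled over clusters.

    Within each cluster the ranking starts from the cluster member that
    comes first in the original record order.  Per-cluster train sizes use
    round-half-up with test >= 1 for clusters of size >= 2; singleton
    clusters go entirely to training.  A precomputed ``clustering`` may be
    supplied; otherwise seeded k-means is run.
    """
    A = _as_array(X)
    n = A.shape[0]
    if clustering is None:
        if k is None:
            k = default_k(n)
        clustering = cluster_compounds(A, k, seed)
    if len(clustering.labels) != n:
        raise ValueError("clustering does not label every compound")
    train: list[int] = []
    test: list[int] = []
    for c in range(clustering.n_clusters):
        members = np.flatnonzero(clustering.labels == c)
        if len(members) == 0:
            continue
        if len(members) == 1:
            train.append(int(members[0]))
            continue
        sub = rank_diverse(A[members], start=0)
        n_tr = _train_size(len(members), frac)
        train.extend(int(members[i]) for i in sub.order[:n_tr])
        test.extend(int(members[i]) for i in sub.order[n_tr:])
    if not test:
        raise ValueError("cluster-diverse split produced an empty test set")
    return (
        DatasetSplit(np.array(sorted(train)), np.array(sorted(test)), "cluster_diverse", frac),
        clustering,
    )
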