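"""Class balancing by chemical-diversity clustering and train/external splits.

Activity datasets are usually inactive-heavy.  Rather than discarding
majority-class compounds at random, the majority class is clustered with
Ward's agglomerative method on Euclidean descriptor distances and then
downsampled with per-cluster quotas proportional to cluster size
(largest-remainder rounding, every non-empty cluster represented when the
target allows).  This keeps the retained inactives spread over the chemical
space covered by the original set.  The balanced 1:1 dataset is then split
75/25 into training and external (hold-out) parts, stratified by class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "LabeledDataset",
    "SplitPair",
    "BalanceResult",
    "cluster_majority_class",
    "stratified_downsample",
    "balance_dataset",
    "split_train_external",
]


@dataclass
class LabeledDataset:
    """Aligned compound ids, selected-descriptor matrix and binary labels."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.ids) == self.X.shape[0] == self.y.shape[0]):
            raise ValueError("ids, X and y are misaligned")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
            cell_line=self.cell_line,
        )


@dataclass
class SplitPair:
    train: LabeledDataset
    external: LabeledDataset
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train.ids) & set(self.external.ids)
        if overlap:
            raise ValueError(f"train/external ids overlap: {sorted(overlap)[:5]}")


def cluster_majority_class(
    X: np.ndarray,
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
) -> np.ndarray:
    """Ward/Euclidean agglomerative clustering; returns 0-based assignments.

    Exactly one of ``n_clusters`` or ``distance_threshold`` must be given —
    the cut height replaces the visual dendrogram inspection this procedure
    descends from, so it is an explicit, reproducible parameter.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 compounds to cluster")
    if (n_clusters is None) == (distance_threshold is None):
        raise ValueError("give exactly one of n_clusters or distance_threshold")
    if n_clusters is not None and n_clusters > X.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds {X.shape[0]} compounds")
    Z = linkage(X, method="ward", metric="euclidean")
    if n_clusters is not None:
        assign = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        assign = fcluster(Z, t=distance_threshold, criterion="distance")
    return assign - 1


def stratified_downsample(
    clusters: np.ndarray, target: int, seed: int
) -> np.ndarray:
    """Pick ``target`` member indices with per-cluster proportional quotas.

    Quotas follow largest-remainder rounding on cluster sizes; when the
    target is at least the number of non-empty clusters, every cluster
    contributes at least one member.  Sampling within a cluster is without
    replacement with a fixed seed.
    """
    clusters = np.asarray(clusters)
    total = clusters.shape[0]
    if target < 0:
        raise ValueError("target must be nonnegative")
    if target > total:
        raise ValueError(f"target {target} exceeds population {total}")
    if target == total:
        return np.arange(total)

    labels, sizes = np.unique(clusters, return_counts=True)
    exact = target * sizes / total
    quotas = np.floor(exact).astype(int)
    # guarantee representation before distributing the remainder
    if target >= len(labels):
        quotas = np.maximum(quotas, 1)
    # reconcile to the exact target: add by largest fractional remainder,
    # remove from the largest quotas (never below the floor of 1)
    frac = exact - np.floor(exact)
    order_add = sorted(
        range(len(labels)), key=lambda i: (-frac[i], -sizes[i], labels[i])
    )
    i = 0
    while quotas.sum() < target:
        j = order_add[i % len(labels)]
        if quotas[j] < sizes[j]:
            quotas[j] += 1
        i += 1
    order_del = sorted(range(len(labels)), key=lambda i: (-quotas[i], labels[i]))
    i = 0
    floor = 1 if target >= len(labels) else 0
    while quotas.sum() > target:
        j = order_del[i % len(labels)]
        if quotas[j] > floor:
            quotas[j] -= 1
        i += 1

    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for lab, q in zip(labels, quotas):
        members = np.flatnonzero(clusters == lab)
        chosen.append(rng.choice(members, size=q, replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)


@dataclass
class BalanceResult:
    dataset: LabeledDataset
    removed_ids: list[str]  # majority-class compounds dropped by downsampling
    clusters: np.ndarray  # cluster assignment of the majority class


def balance_dataset(
    dataset: LabeledDataset,
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
    seed: int = 0,
) -> BalanceResult:
    """Downsample the majority class to an exact 1:1 class ratio.

    The majority class is Ward-clustered and sampled per cluster; the
    minority class is kept whole.  Removed majority compounds are returned
    — they later serve as presumed inactives in the screening set.
    """
    y = dataset.y
    n_active = int(y.sum())
    n_inactive = int((1 - y).sum())
    if n_active == 0 or n_inactive == 0:
        raise ValueError("both classes must be nonempty")

    if n_active == n_inactive:
        return BalanceResult(
            dataset=dataset,
            removed_ids=[],
            clusters=np.zeros(max(n_active, n_inactive), dtype=int),
        )

    majority = 0 if n_inactive > n_active else 1
    target = min(n_active, n_inactive)
    maj_idx = np.flatnonzero(y == majority)
    min_idx = np.flatnonzero(y != majority)

    if n_clusters is None and distance_threshold is None:
        n_clusters = 1
    n_clusters = min(n_clusters, len(maj_idx)) if n_clusters is not None else None
    clusters = cluster_majority_class(
        dataset.X[maj_idx], n_clusters=n_clusters, distance_threshold=distance_threshold
    )
    picked = stratified_downsample(clusters, target, seed)
    keep = np.sort(np.concatenate([min_idx, maj_idx[picked]]))
    removed = sorted(set(maj_idx) - set(maj_idx[picked]))
    return BalanceResult(
        dataset=dataset.subset(keep),
        removed_ids=[dataset.ids[i] for i in removed],
        clusters=clusters,
    )


def split_train_external(
    dataset: LabeledDataset, train_fraction: float = 0.75, seed: int = 0
) -> SplitPair:
    """Class-stratified random split into training and external sets.

    The total training size is round(train_fraction * n); per-class counts
    are floors topped up by largest fractional remainder so the total is
    preserved exactly.
    """
    n = len(dataset)
    if n < 4:
        raise ValueError("need at least 4 compounds to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(dataset.y, return_counts=True)
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small} has fewer than 2 members")

    total_train = int(round(train_fraction * n))
    exact = train_fraction * counts
    quota = np.floor(exact).astype(int)
    frac = exact - quota
    order = sorted(
        range(len(classes)), key=lambda i: (-frac[i], -counts[i], classes[i])
    )
    i = 0
    while quota.sum() < total_train:
        j = order[i % len(classes)]
        if quota[j] < counts[j] - 1:  # keep >=1 per class in external
            quota[j] += 1
        i += 1
    while quota.sum() > total_train:
        j = order[i % len(classes)]
        if quota[j] > 1:
            quota[j] -= 1
        i += 1

    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    for cls, q in zip(classes, quota):
        members = np.flatnonzero(dataset.y == cls)
        train_idx.append(rng.choice(members, size=q, replace=False))
    train_mask = np.zeros(n, dtype=bool)
    train_mask[np.concatenate(train_idx)] = True
    return SplitPair(
        train=dataset.subset(np.flatnonzero(train_mask)),
        external=dataset.subset(np.flatnonzero(~train_mask)),
        seed=seed,
    )
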