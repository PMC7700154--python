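"""Descriptor filtering and mRMR feature ranking with the MIQ score.

Fragment count matrices are first pruned of rare columns (present in fewer
than 1% of compounds by default), then ranked by minimal-redundancy
maximal-relevance greedy selection.  Relevance and redundancy are plug-in
mutual informations on presence/absence indicators; the Mutual Information
Quotient (MIQ) variant scores a candidate f against the selected set S as

    MIQ(f) = I(f; y) / mean_{s in S} I(f; s)

and the first pick maximises plain relevance I(f; y).  MI is computed in
nats; the unit cancels in the quotient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragments import DescriptorTable

__all__ = [
    "FeatureRanking",
    "frequency_filter",
    "mutual_info_binary",
    "mrmr_miq_select",
]

_ZERO_REDUNDANCY_EPS = 1e-12
_QUOTIENT_CAP = 1e12


def frequency_filter(
    table: DescriptorTable, min_fraction: float = 0.01
) -> DescriptorTable:
    """Drop columns present in less than ``min_fraction`` of compounds.

    A column survives iff its presence fraction is >= min_fraction (strict
    "less than" removal).
    """
    if len(table.ids) == 0:
        raise ValueError("empty descriptor table")
    frac = table.presence_fraction()
    kept = [lab for lab, f in zip(table.labels, frac) if f >= min_fraction]
    return table.select_columns(kept)


def _mi_nats(n11, n10, n01, n00) -> np.ndarray:
    """Plug-in MI of 2x2 contingency counts, vectorised; 0·log 0 := 0."""
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    n = n11 + n10 + n01 + n00
    mi = np.zeros_like(n11)
    px1 = (n11 + n10) / n
    py1 = (n11 + n01) / n
    for nxy, px, py in (
        (n11, px1, py1),
        (n10, px1, 1 - py1),
        (n01, 1 - px1, py1),
        (n00, 1 - px1, 1 - py1),
    ):
        p = nxy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * np.log(p / (px * py))
        mi += np.where(p > 0, term, 0.0)
    return np.maximum(mi, 0.0)  # clamp away -0.0 / rounding noise


def mutual_info_binary(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information in nats between two binary vectors."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size == 0:
        raise ValueError("empty vectors")
    n11 = int(np.sum(x & y))
    n10 = int(np.sum(x & ~y))
    n01 = int(np.sum(~x & y))
    n00 = int(np.sum(~x & ~y))
    return float(_mi_nats(n11, n10, n01, n00))


def _mi_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI of each column of binary matrix X with binary vector y, in nats."""
    n = X.shape[0]
    col1 = X.sum(axis=0)
    n11 = y @ X
    n10 = col1 - n11
    n01 = y.sum() - n11
    n00 = n - col1 - n01
    return _mi_nats(n11, n10, n01, n00)


@dataclass(frozen=True)
class FeatureRanking:
    """Ordered mRMR selection with per-step relevance and mean redundancy."""

    labels: tuple[str, ...]
    relevance: np.ndarray
    redundancy: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate features in ranking")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.labels) + 1),
                "label": self.labels,
                "relevance": self.relevance,
                "redundancy": self.redundancy,
            }
        )


def mrmr_miq_select(
    table: DescriptorTable, labels: np.ndarray, k: int = 500
) -> FeatureRanking:
    """Greedy mRMR ranking by the MIQ criterion, keeping at most ``k``.

    Fragment counts are binarised to presence/absence.  Step 1 picks the
    most label-relevant feature; later steps maximise relevance divided by
    mean MI redundancy against the already-selected set.  A (near-)zero
    mean redundancy is replaced by a tiny epsilon with the quotient capped,
    and ties break by higher relevance, then lexicographic feature label,
    so the ordering is fully deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    y = np.asarray(labels).astype(bool).astype(np.float64)
    if y.shape[0] != len(table.ids):
        raise ValueError("labels do not align with descriptor table rows")
    X = (table.matrix > 0).toarray().astype(np.float64)
    p = X.shape[1]
    names = np.array(table.labels)

    relevance = _mi_vector(X, y)
    selected: list[int] = []
    sel_relevance: list[float] = []
    sel_redundancy: list[float] = []
    red_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)

    n_steps = min(k, p)
    for step in range(n_steps):
        if step == 0:
            score = relevance.copy()
        else:
            mean_red = red_sum / len(selected)
            degenerate = mean_red < _ZERO_REDUNDANCY_EPS
            denom = np.where(degenerate, _ZERO_REDUNDANCY_EPS, mean_red)
            score = np.minimum(relevance / denom, _QUOTIENT_CAP)
        # deterministic argmax: score desc, relevance desc, label asc
        cand = np.flatnonzero(available)
        order = sorted(
            cand, key=lambda j: (-score[j], -relevance[j], names[j])
        )
        best = order[0]
        selected.append(best)
        sel_relevance.append(float(relevance[best]))
        sel_redundancy.append(
            float(red_sum[best] / max(len(selected) - 1, 1)) if step else 0.0
        )
        available[best] = False
        red_sum += _mi_vector(X, X[:, best])

    return FeatureRanking(
        labels=tuple(names[j] for j in selected),
        relevance=np.array(sel_relevance),
        redundancy=np.array(sel_redundancy),
        k=n_steps,
    )
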