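"""Multi-objective desirability ensembles over per-cell-line classifiers.

A compound attractive against several cell lines should score well on all
of them at once.  Each cell line's desirability d(y_k) is the geometric
mean of the active-class scores of that cell line's member models, and the
global desirability is the geometric mean across the k cell lines:

    D1 = (d(y_1) d(y_2) ... d(y_k))^(1/k)

D1 lives in (0, 1], is monotone in every member score, and is bounded by
the smallest and largest member desirability — one poor cell line drags
the whole compound down, which is precisely the multi-objective intent.

Because several qualified models may exist per cell line, the ensemble is
chosen by exhaustive search over the Cartesian product of nonempty model
subsets of each cell line (∏_k (2^{m_k} − 1) candidates), each evaluated on
a labeled screening set by early-recognition metrics: BEDROC first, then
enrichment factor, then AUC as tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

from .fragments import DescriptorTable
from .models import BaseModel, score_compounds
from .vsmetrics import RankedList, auc, bedroc, enrichment_factor, rank_by_score

__all__ = [
    "EnsembleModel",
    "ScreeningResult",
    "cell_line_desirability",
    "global_desirability",
    "enumerate_model_combinations",
    "select_best_combination",
    "screen_library",
]


def cell_line_desirability(scores: np.ndarray) -> np.ndarray:
    """Geometric mean of member-model scores; accepts (n,) or (n, m)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] == 0:
        raise ValueError("no model scores for this cell line")
    if np.any(scores <= 0) or np.any(scores > 1):
        raise ValueError("scores must lie in (0, 1]")
    return np.exp(np.log(scores).mean(axis=1))


def global_desirability(d: np.ndarray) -> np.ndarray:
    """Geometric mean across cell-line desirabilities; accepts (k,) or (n, k)."""
    d = np.asarray(d, dtype=float)
    one_dim = d.ndim == 1
    d = np.atleast_2d(d)
    if d.shape[1] == 0:
        raise ValueError("need at least one cell line")
    if np.any(d <= 0):
        raise ValueError("desirabilities must be positive")
    out = np.exp(np.log(d).mean(axis=1))
    return float(out[0]) if one_dim else out


@dataclass
class EnsembleModel:
    """Qualified base models grouped by cell line, plus selection metrics."""

    members: dict[str, list[BaseModel]]
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one cell line")
        for cl, models in self.members.items():
            if not models:
                raise ValueError(f"cell line {cl} has no member models")
            for m in models:
                if not m.qualified:
                    raise ValueError(f"model {m.name} is not qualified (AC <= 0.8)")

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.members)

    @property
    def model_names(self) -> list[str]:
        return [m.name for cl in self.cell_lines for m in self.members[cl]]

    def manifest(self) -> dict:
        return {
            "cell_lines": self.cell_lines,
            "members": {cl: [m.name for m in self.members[cl]] for cl in self.cell_lines},
            "selection": self.selection,
        }


@dataclass
class ScreeningResult:
    """Compounds ordered by global desirability, with full score breakdown."""

    table: pd.DataFrame  # columns: rank, compound_id, D1, d:<cl>, s:<model>

    @property
    def ids(self) -> list[str]:
        return self.table["compound_id"].tolist()

    def ranked_list(self, active_ids: set[str]) -> RankedList:
        flags = np.array([cid in active_ids for cid in self.ids])
        return RankedList(ids=tuple(self.ids), active=flags)


def screen_library(ensemble: EnsembleModel, library: DescriptorTable) -> ScreeningResult:
    """Score a library and order it by D1 descending, ties by compound id."""
    if len(library.ids) == 0:
        raise ValueError("empty screening library")
    d_cols: dict[str, np.ndarray] = {}
    s_cols: dict[str, np.ndarray] = {}
    for cl in ensemble.cell_lines:
        member_scores = np.column_stack(
            [score_compounds(m, library) for m in ensemble.members[cl]]
        )
        for m, col in zip(ensemble.members[cl], member_scores.T):
            s_cols[f"s:{m.name}"] = col
        d_cols[f"d:{cl}"] = cell_line_desirability(member_scores)
    d_matrix = np.column_stack([d_cols[f"d:{cl}"] for cl in ensemble.cell_lines])
    d1 = global_desirability(d_matrix)

    order = sorted(range(len(library.ids)), key=lambda i: (-d1[i], library.ids[i]))
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "compound_id": [library.ids[i] for i in order],
            "D1": d1[order],
            **{k: v[order] for k, v in d_cols.items()},
            **{k: v[order] for k, v in s_cols.items()},
        }
    )
    return ScreeningResult(table=frame)


def enumerate_model_combinations(
    qualified: dict[str, list[BaseModel]],
) -> list[EnsembleModel]:
    """All ensembles formed by a nonempty subset of each cell line's models.

    Every cell line must be represented (the global desirability is over
    all k cell lines); the count is ∏_k (2^{m_k} − 1).
    """
    if not qualified:
        raise ValueError("no cell lines supplied")
    for cl, models in qualified.items():
        if not models:
            raise ValueError(f"cell line {cl} has no qualified models")
    cell_lines = sorted(qualified)
    per_line_subsets = [
        [
            list(sub)
            for r in range(1, len(qualified[cl]) + 1)
            for sub in combinations(qualified[cl], r)
        ]
        for cl in cell_lines
    ]
    out = []
    for choice in product(*per_line_subsets):
        out.append(EnsembleModel(members=dict(zip(cell_lines, choice))))
    return out


def select_best_combination(
    combinations_list: list[EnsembleModel],
    vs_library: DescriptorTable,
    active_ids: set[str],
    alpha: float,
    chi: float = 0.01,
) -> tuple[EnsembleModel, pd.DataFrame]:
    """Rank a labeled screening set with every candidate ensemble.

    The winner maximises BEDROC(alpha), with EF(chi) then AUC breaking
    ties; the audit table records every candidate's metrics.  Per-model
    scores are computed once and reused across combinations.
    """
    if not combinations_list:
        raise ValueError("no candidate combinations")
    if not active_ids:
        raise ValueError("screening set has no annotated actives")

    # cache per-model score vectors: combinations reuse the same models
    score_cache: dict[str, np.ndarray] = {}

    def model_scores(m: BaseModel) -> np.ndarray:
        if m.name not in score_cache:
            score_cache[m.name] = score_compounds(m, vs_library)
        return score_cache[m.name]

    flags = np.array([cid in active_ids for cid in vs_library.ids])
    rows = []
    best_idx, best_key = 0, None
    for i, ens in enumerate(combinations_list):
        d_matrix = np.column_stack(
            [
                cell_line_desirability(
                    np.column_stack([model_scores(m) for m in ens.members[cl]])
                )
                for cl in ens.cell_lines
            ]
        )
        d1 = global_desirability(d_matrix)
        ranked = rank_by_score(vs_library.ids, d1, flags)
        b = bedroc(ranked, alpha)
        e = enrichment_factor(ranked, chi)
        a = auc(ranked)
        rows.append(
            {
                "combination": "+".join(ens.model_names),
                "n_models": len(ens.model_names),
                "bedroc": b,
                "ef": e,
                "auc": a,
            }
        )
        key = (b, e, a, -i)  # deterministic: earlier candidate wins exact ties
        if best_key is None or key > best_key:
            best_key, best_idx = key, i

    audit = pd.DataFrame(rows)
    winner = combinations_list[best_idx]
    winner.selection = {
        "alpha": alpha,
        "chi": chi,
        "bedroc": float(audit.loc[best_idx, "bedroc"]),
        "ef": float(audit.loc[best_idx, "ef"]),
        "auc": float(audit.loc[best_idx, "auc"]),
    }
    return winner, audit
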