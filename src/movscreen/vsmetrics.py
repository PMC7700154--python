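"""Early-recognition metrics for ranked virtual-screening lists.

A virtual-screening run orders a compound library so that presumed actives
concentrate at the top.  This module evaluates such orderings with the three
standard early-recognition quantities:

* ``auc`` — one minus the mean relative rank of the actives (the area under
  the accumulation curve for large N);
* ``enrichment_factor`` — how many times more actives sit in the top
  fraction of the list than a uniform scattering would place there;
* ``bedroc`` — the Boltzmann-enhanced discrimination of ROC, an
  exponentially weighted, [0, 1]-normalised variant of the enrichment idea
  whose weight decay is set by the ``alpha`` parameter.

``solve_alpha`` inverts the calibration relation linking ``alpha`` to the
fraction of the list ``z`` where early recognition matters and the expected
share ``theta`` of the total weight carried by that fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, exp

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RankedList",
    "EarlyRecognitionReport",
    "rank_by_score",
    "auc",
    "enrichment_factor",
    "bedroc",
    "solve_alpha",
    "accumulation_curve",
    "evaluate_ranking",
]


@dataclass(frozen=True)
class RankedList:
    """An ordered screening list with binary active annotations.

    ``ids`` are ordered best-first (rank 1 first).  ``active`` is a boolean
    vector aligned with ``ids``.  Ranks are 1-based; the relative rank of an
    active at rank r is r/N.
    """

    ids: tuple[str, ...]
    active: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        act = np.asarray(self.active, dtype=bool)
        if len(self.ids) != act.shape[0]:
            raise ValueError("ids and active flags differ in length")
        if len(self.ids) == 0:
            raise ValueError("ranked list is empty")
        object.__setattr__(self, "active", act)

    @property
    def total(self) -> int:
        return len(self.ids)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def active_ranks(self) -> np.ndarray:
        """1-based ranks of the active compounds, strictly increasing."""
        return np.flatnonzero(self.active) + 1

    @property
    def relative_ranks(self) -> np.ndarray:
        return self.active_ranks / self.total


def rank_by_score(
    ids: list[str] | tuple[str, ...],
    scores: np.ndarray,
    active: np.ndarray,
) -> RankedList:
    """Order compounds by descending score; ties broken by compound id.

    The deterministic tie-break makes the downstream metrics well defined:
    they require a strict ordering.
    """
    ids = list(ids)
    scores = np.asarray(scores, dtype=float)
    active = np.asarray(active, dtype=bool)
    if not (len(ids) == scores.shape[0] == active.shape[0]):
        raise ValueError("ids, scores and active flags differ in length")
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return RankedList(
        ids=tuple(ids[i] for i in order),
        active=active[np.array(order)],
    )


def auc(ranked: RankedList) -> float:
    """Area under the accumulation curve: 1 − mean relative rank of actives."""
    if ranked.n_active == 0:
        raise ValueError("AUC undefined: no active compounds in the list")
    return 1.0 - float(ranked.relative_ranks.mean())


def enrichment_factor(ranked: RankedList, chi: float) -> float:
    """Enrichment factor at the top fraction ``chi`` of the list.

    The cutoff is k = ceil(chi * N) positions; with a actives among them,
    EF = (a / n) / (k / N).  The ceiling convention makes the top-1% slice
    of a 772-compound list exactly 8 entries.
    """
    if not 0.0 < chi <= 1.0:
        raise ValueError(f"chi must be in (0, 1], got {chi}")
    if ranked.n_active == 0:
        raise ValueError("EF undefined: no active compounds in the list")
    N = ranked.total
    n = ranked.n_active
    k = ceil(chi * N)
    a = int(ranked.active[:k].sum())
    return (a / n) / (k / N)


def _rie(ranked: RankedList, alpha: float) -> tuple[float, float, float]:
    """Robust initial enhancement and its attainable extremes.

    RIE = (1/n) Σ exp(−α x_i) / [ (1/N) (1 − e^−α) / (e^{α/N} − 1) ],
    RIE_max = (1 − e^{−α Ra}) / (Ra (1 − e^{−α})),
    RIE_min = (1 − e^{α Ra}) / (Ra (1 − e^{α})),
    with Ra = n/N and x_i the relative ranks of the actives.
    """
    N = ranked.total
    n = ranked.n_active
    ra = n / N
    x = ranked.relative_ranks
    denom = (1.0 / N) * (1.0 - exp(-alpha)) / (exp(alpha / N) - 1.0)
    rie = float(np.exp(-alpha * x).mean()) / denom
    rie_max = (1.0 - exp(-alpha * ra)) / (ra * (1.0 - exp(-alpha)))
    rie_min = (1.0 - exp(alpha * ra)) / (ra * (1.0 - exp(alpha)))
    return rie, rie_min, rie_max


def bedroc(ranked: RankedList, alpha: float) -> float:
    """BEDROC at decay parameter ``alpha``: (RIE − RIE_min)/(RIE_max − RIE_min).

    Equals 1 when all actives occupy the first n ranks and 0 when they
    occupy the last n; undefined for all-active or all-inactive lists.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    n, N = ranked.n_active, ranked.total
    if n == 0 or n == N:
        raise ValueError("BEDROC undefined: list must contain both classes")
    rie, rie_min, rie_max = _rie(ranked, alpha)
    # best/worst orderings can overshoot the analytic extremes by ~1e-16
    return float(np.clip((rie - rie_min) / (rie_max - rie_min), 0.0, 1.0))


def solve_alpha(theta: float = 0.80, z: float = 0.01) -> float:
    """Solve the alpha calibration equation θ(1−e^−α) − 1 + e^{−αz} = 0.

    ``z`` is the fraction of the ranked list where enrichment matters and
    ``theta`` the expected contribution of that fraction to the overall
    enrichment.  The positive root is located by bracketed root-finding;
    θ=0.80, z=0.01 gives α ≈ 160.9.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    if not 0.0 < z < 1.0:
        raise ValueError(f"z must be in (0, 1), got {z}")

    def f(a: float) -> float:
        return theta * (1.0 - exp(-a)) - 1.0 + exp(-a * z)

    lo, hi = 1e-9, 1e6
    if f(lo) * f(hi) > 0:
        raise ValueError("no sign change in bracket; alpha has no positive root")
    alpha = float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))
    if abs(f(alpha)) >= 1e-10:
        raise RuntimeError(f"alpha solver residual too large: {f(alpha):.3e}")
    return alpha


def accumulation_curve(ranked: RankedList) -> np.ndarray:
    """Step curve of (fraction screened, fraction of actives retrieved).

    Returns an array of shape (N+1, 2) from (0, 0) to (1, 1), monotone
    nondecreasing in both coordinates.
    """
    if ranked.n_active == 0:
        raise ValueError("accumulation curve undefined: no actives")
    N = ranked.total
    frac_screened = np.arange(N + 1) / N
    retrieved = np.concatenate(([0], np.cumsum(ranked.active))) / ranked.n_active
    return np.column_stack([frac_screened, retrieved])


@dataclass(frozen=True)
class EarlyRecognitionReport:
    auc: float
    ef: float
    chi: float
    bedroc: float
    alpha: float
    theta: float | None
    z: float | None
    ra: float
    rie: float
    rie_min: float
    rie_max: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ef": self.ef,
            "chi": self.chi,
            "bedroc": self.bedroc,
            "alpha": self.alpha,
            "theta": self.theta,
            "z": self.z,
            "ra": self.ra,
            "rie": self.rie,
            "rie_min": self.rie_min,
            "rie_max": self.rie_max,
        }


def evaluate_ranking(
    ranked: RankedList,
    chi: float = 0.01,
    alpha: float | None = None,
    theta: float = 0.80,
    z: float = 0.01,
) -> EarlyRecognitionReport:
    """Full early-recognition report; alpha solved from (theta, z) if absent."""
    if alpha is None:
        alpha = solve_alpha(theta, z)
        th, zz = theta, z
    else:
        th, zz = None, None
    rie, rie_min, rie_max = _rie(ranked, alpha)
    return EarlyRecognitionReport(
        auc=auc(ranked),
        ef=enrichment_factor(ranked, chi),
        chi=chi,
        bedroc=bedroc(ranked, alpha),
        alpha=alpha,
        theta=th,
        z=zz,
        ra=ranked.n_active / ranked.total,
        rie=rie,
        rie_min=rie_min,
        rie_max=rie_max,
    )
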