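"""Base classifiers with GA-wrapped feature selection and BCR fitness.

Per cell line, six learner families are supported: RBF-kernel SVM, random
forest, a multilayer perceptron, a decision tree, k-nearest neighbours and
gradient-boosted trees (XGBoost).  Feature subsets over the candidate
descriptors are chosen by a bit-string genetic algorithm whose fitness is
the mean balanced classification rate (BCR) over stratified bootstrap
resamples of the training set, scored on the out-of-bag compounds:

    BCR = (SN + SP)/2 · (1 − |SN − SP|)

which rewards accuracy only when sensitivity and specificity agree.  A
fitted model qualifies for ensemble membership when its accuracy on the
untouched external split strictly exceeds 0.8.

Model scores for screening are always mapped to (0, 1]: probability-capable
learners use their active-class probability; margin learners (SVM) pass
their decision value through a logistic map.  Scores are clipped to
[1e-6, 1] so downstream geometric means stay defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import LabeledDataset, SplitPair
from .fragments import DescriptorTable

__all__ = [
    "PerformanceMetrics",
    "GAConfig",
    "BaseModel",
    "LEARNER_IDS",
    "compute_metrics",
    "make_learner",
    "bootstrap_bcr_fitness",
    "ga_select_features",
    "train_base_model",
    "score_compounds",
]

SCORE_FLOOR = 1e-6
QUALIFICATION_AC = 0.8

LEARNER_IDS = ("SVM", "RF", "NN", "DTREE", "KNN", "XGBoost")

#: fixed, untuned hyperparameters per learner family
LEARNER_DEFAULTS: dict[str, dict] = {
    "SVM": {"C": 1.0, "gamma": "scale"},
    "RF": {"n_estimators": 100, "max_depth": None},
    "NN": {"hidden_layer_sizes": (32,), "max_iter": 400, "alpha": 1e-3},
    "DTREE": {"max_depth": None, "min_samples_leaf": 1},
    "KNN": {"n_neighbors": 5},
    "XGBoost": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.3},
}


@dataclass(frozen=True)
class PerformanceMetrics:
    ac: float
    sn: float
    sp: float
    bcr: float

    def as_dict(self) -> dict:
        return {"ac": self.ac, "sn": self.sn, "sp": self.sp, "bcr": self.bcr}


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> PerformanceMetrics:
    """Accuracy, sensitivity, specificity and balanced classification rate.

    SN is the fraction of actives (label 1) correctly recovered, SP the
    same for inactives.  Both classes must be present in ``y_true``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    for cls, name in ((1, "active"), (0, "inactive")):
        if not np.any(y_true == cls):
            raise ValueError(f"no {name} compounds: SN/SP undefined")
    ac = float((y_true == y_pred).mean())
    sn = float((y_pred[y_true == 1] == 1).mean())
    sp = float((y_pred[y_true == 0] == 0).mean())
    bcr = (sn + sp) / 2.0 * (1.0 - abs(sn - sp))
    return PerformanceMetrics(ac=ac, sn=sn, sp=sp, bcr=bcr)


def make_learner(learner_id: str, seed: int = 0, params: dict | None = None):
    """Instantiate an unfitted classifier with the fixed default settings."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    if learner_id not in LEARNER_IDS:
        raise ValueError(f"unknown learner {learner_id!r}; choose from {LEARNER_IDS}")
    kwargs = {**LEARNER_DEFAULTS[learner_id], **(params or {})}
    if learner_id == "SVM":
        return SVC(kernel="rbf", random_state=seed, **kwargs)
    if learner_id == "RF":
        return RandomForestClassifier(random_state=seed, **kwargs)
    if learner_id == "NN":
        return MLPClassifier(random_state=seed, **kwargs)
    if learner_id == "DTREE":
        return DecisionTreeClassifier(random_state=seed, **kwargs)
    if learner_id == "KNN":
        return KNeighborsClassifier(**kwargs)
    return XGBClassifier(
        random_state=seed, verbosity=0, use_label_encoder=False,
        eval_metric="logloss", **kwargs,
    )


def _fit(clf, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny resamples
        clf.fit(X, y)
    return clf


def _active_scores(clf, X: np.ndarray) -> np.ndarray:
    """Probability-like active-class score in [SCORE_FLOOR, 1]."""
    if hasattr(clf, "predict_proba"):
        classes = list(clf.classes_)
        scores = clf.predict_proba(X)[:, classes.index(1)]
    else:
        margin = clf.decision_function(X)
        scores = 1.0 / (1.0 + np.exp(-margin))
    return np.clip(scores, SCORE_FLOOR, 1.0)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for wrapper feature selection."""

    population: int = 50
    generations: int = 30
    bootstrap_splits: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # None -> 1/L per bit
    elitism: int = 1
    tournament_size: int = 3
    init_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.bootstrap_splits < 1:
            raise ValueError("bootstrap_splits must be >= 1")


def bootstrap_bcr_fitness(
    mask: np.ndarray,
    dataset: LabeledDataset,
    learner_id: str,
    n_splits: int = 100,
    seed: int = 0,
    learner_params: dict | None = None,
) -> float:
    """Mean out-of-bag BCR over stratified bootstrap resamples.

    Each split draws a bootstrap sample (with replacement, stratified by
    class so training always sees both classes), fits the learner on the
    masked features, and scores BCR on the out-of-bag compounds.  A split
    whose out-of-bag part lacks a class is redrawn (bounded retries).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    X = dataset.X[:, mask]
    y = dataset.y
    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(y == c) for c in (0, 1)}
    if any(v.size == 0 for v in idx_by_class.values()):
        raise ValueError("dataset must contain both classes")

    bcrs = []
    for _ in range(n_splits):
        for _retry in range(10):
            boot = np.concatenate(
                [rng.choice(v, size=v.size, replace=True) for v in idx_by_class.values()]
            )
            oob = np.setdiff1d(np.arange(y.size), boot)
            if oob.size and len(np.unique(y[oob])) == 2:
                break
        else:
            continue  # give up on this split; extremely rare
        clf = _fit(make_learner(learner_id, seed=seed, params=learner_params), X[boot], y[boot])
        bcrs.append(compute_metrics(y[oob], clf.predict(X[oob])).bcr)
    if not bcrs:
        raise RuntimeError("all bootstrap splits were degenerate")
    return float(np.mean(bcrs))


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def ga_select_features(
    dataset: LabeledDataset,
    learner_id: str,
    config: GAConfig | None = None,
    learner_params: dict | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Bit-string GA over feature masks; returns (best mask, fitness trace).

    Tournament selection, uniform crossover, per-bit mutation, elitism.
    The trace records the best-so-far fitness per generation and is
    nondecreasing by construction.  Fitness evaluations are cached per
    mask, and the bootstrap splits are derived from the GA seed alone so a
    mask always maps to one fitness value.
    """
    config = config or GAConfig()
    L = dataset.X.shape[1]
    if L < 2:
        raise ValueError("need at least 2 candidate features")
    rng = np.random.default_rng(config.seed)
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / L
    fitness_seed = int(np.random.default_rng(config.seed + 1).integers(2**31 - 1))

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = bootstrap_bcr_fitness(
                mask, dataset, learner_id,
                n_splits=config.bootstrap_splits,
                seed=fitness_seed,
                learner_params=learner_params,
            )
        return cache[key]

    pop = [
        _repair(rng.random(L) < config.init_prob, rng)
        for _ in range(config.population)
    ]
    best_mask: np.ndarray | None = None
    best_fit = -np.inf
    trace: list[float] = []

    for gen in range(config.generations):
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
        trace.append(best_fit)
        if gen == config.generations - 1:
            break

        order = np.argsort(-fits, kind="stable")
        next_pop = [pop[i].copy() for i in order[: config.elitism]]

        def tournament() -> np.ndarray:
            contenders = rng.integers(0, len(pop), size=config.tournament_size)
            return pop[contenders[np.argmax(fits[contenders])]]

        while len(next_pop) < config.population:
            p1, p2 = tournament().copy(), tournament().copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(L) < 0.5
                p1[swap], p2[swap] = p2[swap], p1[swap].copy()
            for child in (p1, p2):
                flip = rng.random(L) < mut
                child ^= flip
                next_pop.append(_repair(child, rng))
                if len(next_pop) == config.population:
                    break
        pop = next_pop

    assert best_mask is not None
    return best_mask, trace


@dataclass
class BaseModel:
    """A fitted per-cell-line classifier with its feature mask and metrics."""

    cell_line: str
    learner_id: str
    mask: np.ndarray
    candidate_labels: tuple[str, ...]
    classifier: object
    metrics: PerformanceMetrics
    qualified: bool
    seed: int = 0
    learner_params: dict = field(default_factory=dict)

    @property
    def feature_labels(self) -> tuple[str, ...]:
        return tuple(
            lab for lab, keep in zip(self.candidate_labels, self.mask) if keep
        )

    @property
    def name(self) -> str:
        return f"{self.cell_line}-{self.learner_id}"

    def manifest(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "learner": self.learner_id,
            "n_features": int(self.mask.sum()),
            "features": list(self.feature_labels),
            "metrics": self.metrics.as_dict(),
            "qualified": self.qualified,
            "seed": self.seed,
            "learner_params": self.learner_params,
        }


def train_base_model(
    split: SplitPair,
    learner_id: str,
    mask: np.ndarray,
    candidate_labels: list[str] | tuple[str, ...],
    seed: int = 0,
    learner_params: dict | None = None,
) -> BaseModel:
    """Fit on the training split, evaluate on the external split.

    Qualification requires external accuracy strictly above 0.8 — a model
    at exactly 0.8 is not admitted to the ensemble pool.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    if mask.size != len(candidate_labels):
        raise ValueError("mask length does not match candidate labels")
    clf = _fit(
        make_learner(learner_id, seed=seed, params=learner_params),
        split.train.X[:, mask],
        split.train.y,
    )
    metrics = compute_metrics(split.external.y, clf.predict(split.external.X[:, mask]))
    return BaseModel(
        cell_line=split.train.cell_line,
        learner_id=learner_id,
        mask=mask,
        candidate_labels=tuple(candidate_labels),
        classifier=clf,
        metrics=metrics,
        qualified=metrics.ac > QUALIFICATION_AC,
        seed=seed,
        learner_params=dict(learner_params or {}),
    )


def score_compounds(model: BaseModel, table: DescriptorTable) -> np.ndarray:
    """Active-class scores in [1e-6, 1] for every compound in ``table``.

    Fragments absent from the screening table are imputed as zero counts —
    a molecule simply lacking a substructure is in-domain.
    """
    X = table.dense_for(list(model.feature_labels))
    return _active_scores(model.classifier, X)
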