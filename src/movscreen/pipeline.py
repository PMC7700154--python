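"""End-to-end orchestration: curate → describe → select → balance → train
→ assemble → screen → evaluate.

The pipeline is configuration-driven and fully seeded: every random choice
(molecule generation, downsampling, splits, GA, bootstrap) derives from the
single config seed through a spawned seed tree, so identical config and
inputs reproduce identical outputs.  Stage outputs are written as plain
TSV/JSON under the output directory together with a run manifest recording
the config hash and per-file digests.  The slow stage — GA-wrapped model
training — caches its fitted models keyed by the config hash, so re-runs
and downstream stages resume without retraining.

The screening (VS) set is assembled from three disjoint sources, none of
which touch model training: the withheld reference actives, their
property-matched decoys, and the majority-class compounds removed during
balancing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from pydantic import BaseModel as PydanticModel, Field

from . import chemio, synthdata
from .datasets import BalanceResult, LabeledDataset, SplitPair, balance_dataset, split_train_external
from .ensemble import (
    EnsembleModel,
    ScreeningResult,
    enumerate_model_combinations,
    screen_library,
    select_best_combination,
)
from .features import frequency_filter, mrmr_miq_select
from .fragments import DescriptorTable, FragmentConfig, build_descriptor_table
from .models import BaseModel as QSARModel, GAConfig, ga_select_features, train_base_model
from .vsmetrics import accumulation_curve, evaluate_ranking, solve_alpha

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "curate",
    "describe",
    "select-features",
    "balance",
    "train",
    "assemble",
    "screen",
    "evaluate",
)


# ---------------------------------------------------------------------------
# configuration schema


class SynthSection(PydanticModel):
    n_compounds: int = 300
    cell_lines: list[str] = Field(default_factory=lambda: ["CL1", "CL2", "CL3"])
    noise_rate: float = 0.05
    n_screen_actives: int = 8
    decoys_per_active: int = 50


class DataSection(PydanticModel):
    source: str = "synthetic"  # "synthetic" or "files"
    activity_tables: list[str] = Field(default_factory=list)
    screen_smiles: str | None = None
    screen_active_ids: str | None = None
    blocklist: str | None = None


class FragmentSection(PydanticModel):
    sequences: bool = True
    atom_centered: bool = True
    atom_centered_fixed: bool = False
    triplets: bool = True
    min_len: int = 2
    max_len: int = 8
    fixed_length: int = 3

    def to_config(self) -> FragmentConfig:
        return FragmentConfig(**self.model_dump())


class FeatureSection(PydanticModel):
    min_fraction: float = 0.01
    k: int = 500


class BalanceSection(PydanticModel):
    n_clusters: int = 4
    distance_threshold: float | None = None
    train_fraction: float = 0.75


class GASection(PydanticModel):
    population: int = 20
    generations: int = 10
    bootstrap_splits: int = 25
    crossover_rate: float = 0.8
    mutation_rate: float | None = None
    elitism: int = 1
    tournament_size: int = 3
    init_prob: float = 0.1


class EnsembleSection(PydanticModel):
    chi: float = 0.01
    theta: float = 0.80
    z: float = 0.01
    alpha: float | None = None  # solved from (theta, z) when absent


class PipelineConfig(PydanticModel):
    seed: int = 0
    out_dir: str = "run"
    learners: list[str] = Field(default_factory=lambda: ["SVM", "DTREE", "KNN"])
    data: DataSection = Field(default_factory=DataSection)
    synth: SynthSection = Field(default_factory=SynthSection)
    fragments: FragmentSection = Field(default_factory=FragmentSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    balance: BalanceSection = Field(default_factory=BalanceSection)
    ga: GASection = Field(default_factory=GASection)
    ensemble: EnsembleSection = Field(default_factory=EnsembleSection)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunResult:
    """Objects produced by the pipeline plus the reproducibility manifest."""

    config: PipelineConfig
    manifest: dict
    compounds: list = dc_field(default_factory=list)
    datasets: dict = dc_field(default_factory=dict)  # cell line -> LabeledDataset
    splits: dict = dc_field(default_factory=dict)  # cell line -> SplitPair
    models: list = dc_field(default_factory=list)  # all BaseModels
    qualified: dict = dc_field(default_factory=dict)  # cell line -> [BaseModel]
    best_ensemble: EnsembleModel | None = None
    audit: pd.DataFrame | None = None
    screening: ScreeningResult | None = None
    report: dict | None = None
    n_combinations: int = 0
    vs_active_ids: set = dc_field(default_factory=set)
    removed_inactive_ids: dict = dc_field(default_factory=dict)


def _seed_tree(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def run_pipeline(config: PipelineConfig, until: str = "evaluate") -> RunResult:
    """Execute the pipeline stages in order up to ``until``.

    All outputs land under ``config.out_dir``; the returned RunResult also
    carries the in-memory objects for programmatic use.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; stages: {STAGES}")
    stop = STAGES.index(until)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _seed_tree(config.seed)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    result = RunResult(config=config, manifest=manifest)

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            str(f.relative_to(out)): _file_digest(f) for f in files if f.exists()
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # -- simulate / load -----------------------------------------------------
    synth_seed = _sub_seed(rng)
    balance_seed = _sub_seed(rng)
    split_seed = _sub_seed(rng)
    train_seed_rng = np.random.default_rng(_sub_seed(rng))

    if config.data.source == "synthetic":
        study = synthdata.generate_study(
            n_compounds=config.synth.n_compounds,
            cell_lines=config.synth.cell_lines,
            noise_rate=config.synth.noise_rate,
            seed=synth_seed,
            n_screen_actives=config.synth.n_screen_actives,
            decoys_per_active=config.synth.decoys_per_active,
        )
        records = [r for table in study.activity_tables.values() for r in table]
        screen_pairs = list(study.screen_library)
        screen_active_ids = set(study.screen_active_ids)
        blocklist: set[str] = set()
        files = []
        for cl, table in study.activity_tables.items():
            p = out / f"activity_{cl}.csv"
            pd.DataFrame([r.__dict__ for r in table]).to_csv(p, index=False)
            files.append(p)
        p = out / "screen.smi"
        p.write_text("".join(f"{smi}\t{cid}\n" for cid, smi in screen_pairs))
        files.append(p)
        p = out / "screen_actives.txt"
        p.write_text("".join(f"{cid}\n" for cid in sorted(screen_active_ids)))
        files.append(p)
        record("simulate", files)
    elif config.data.source == "files":
        records = []
        for path in config.data.activity_tables:
            recs, _ = chemio.parse_activity_table(path)
            records.extend(recs)
        if not config.data.screen_smiles:
            raise ValueError("config.data.screen_smiles is required with source=files")
        screen_pairs = chemio.read_smiles_file(config.data.screen_smiles)
        screen_active_ids = set()
        if config.data.screen_active_ids:
            screen_active_ids = set(
                Path(config.data.screen_active_ids).read_text().split()
            )
        blocklist = set()
        if config.data.blocklist:
            blocklist = set(Path(config.data.blocklist).read_text().split())
        record("simulate", [])
    else:
        raise ValueError(f"unknown data source {config.data.source!r}")
    if stop <= STAGES.index("simulate"):
        return result

    # -- curate ---------------------------------------------------------------
    curation = chemio.curate(records, blocklist=blocklist)
    result.compounds = curation.compounds
    chemio.write_curated_table(curation.compounds, out / "curated.tsv")
    chemio.write_rejections(curation.rejections, out / "rejections.tsv")
    record("curate", [out / "curated.tsv", out / "rejections.tsv"])
    cell_lines = sorted({cl for c in curation.compounds for cl in c.labels})
    if stop <= STAGES.index("curate"):
        return result

    # -- describe -------------------------------------------------------------
    frag_config = config.fragments.to_config()
    tables: dict[str, DescriptorTable] = {}
    labels_by_line: dict[str, np.ndarray] = {}
    files = []
    for cl in cell_lines:
        members = [c for c in curation.compounds if cl in c.labels]
        tables[cl] = build_descriptor_table(members, frag_config)
        labels_by_line[cl] = np.array([c.labels[cl] for c in members])
        tables[cl].save(out / f"descriptors_{cl}")
        files += [out / f"descriptors_{cl}.mtx"]
    # screening library gets the same treatment; standardized structures
    screen_std = [(cid, chemio.standardize_structure(smi)[1]) for cid, smi in screen_pairs]
    vs_table = build_descriptor_table(screen_std, frag_config)
    vs_table.save(out / "descriptors_screen")
    files += [out / "descriptors_screen.mtx"]
    record("describe", files)
    if stop <= STAGES.index("describe"):
        return result

    # -- select-features ------------------------------------------------------
    candidates: dict[str, list[str]] = {}
    files = []
    for cl in cell_lines:
        filtered = frequency_filter(tables[cl], config.features.min_fraction)
        ranking = mrmr_miq_select(filtered, labels_by_line[cl], k=config.features.k)
        candidates[cl] = list(ranking.labels)
        p = out / f"ranking_{cl}.tsv"
        ranking.to_frame().to_csv(p, sep="\t", index=False)
        files.append(p)
    record("select-features", files)
    if stop <= STAGES.index("select-features"):
        return result

    # -- balance + split ------------------------------------------------------
    files = []
    for cl in cell_lines:
        sub = tables[cl].select_columns(candidates[cl])
        ds = LabeledDataset(
            ids=list(sub.ids),
            X=sub.matrix.toarray(),
            y=labels_by_line[cl],
            cell_line=cl,
        )
        balanced: BalanceResult = balance_dataset(
            ds,
            n_clusters=config.balance.n_clusters,
            distance_threshold=config.balance.distance_threshold,
            seed=balance_seed,
        )
        result.datasets[cl] = balanced.dataset
        result.removed_inactive_ids[cl] = balanced.removed_ids
        result.splits[cl] = split_train_external(
            balanced.dataset, config.balance.train_fraction, seed=split_seed
        )
        rows = []
        for cid in ds.ids:
            split = (
                "train"
                if cid in set(result.splits[cl].train.ids)
                else "external"
                if cid in set(result.splits[cl].external.ids)
                else "removed"
            )
            rows.append({"compound_id": cid, "cell_line": cl, "split": split})
        p = out / f"dataset_{cl}.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        files.append(p)
    record("balance", files)
    if stop <= STAGES.index("balance"):
        return result

    # -- train ----------------------------------------------------------------
    cache_file = out / f"models_{config.config_hash()}.joblib"
    if cache_file.exists():
        result.models = joblib.load(cache_file)
        logger.info("loaded %d cached models from %s", len(result.models), cache_file)
    else:
        for cl in cell_lines:
            for learner in config.learners:
                ga = GAConfig(
                    population=config.ga.population,
                    generations=config.ga.generations,
                    bootstrap_splits=config.ga.bootstrap_splits,
                    crossover_rate=config.ga.crossover_rate,
                    mutation_rate=config.ga.mutation_rate,
                    elitism=config.ga.elitism,
                    tournament_size=config.ga.tournament_size,
                    init_prob=config.ga.init_prob,
                    seed=_sub_seed(train_seed_rng),
                )
                # GA runs on the training split only; external stays untouched
                mask, trace = ga_select_features(result.splits[cl].train, learner, ga)
                model = train_base_model(
                    result.splits[cl],
                    learner,
                    mask,
                    candidates[cl],
                    seed=ga.seed,
                )
                model.ga_trace = trace  # kept for the audit trail
                result.models.append(model)
                logger.info(
                    "%s: AC=%.3f BCR=%.3f qualified=%s",
                    model.name, model.metrics.ac, model.metrics.bcr, model.qualified,
                )
        joblib.dump(result.models, cache_file)
    metrics_rows = [
        {"model": m.name, **m.metrics.as_dict(), "n_features": int(m.mask.sum()),
         "qualified": m.qualified}
        for m in result.models
    ]
    p = out / "model_metrics.tsv"
    pd.DataFrame(metrics_rows).to_csv(p, sep="\t", index=False)
    record("train", [p, cache_file])
    result.qualified = {
        cl: [m for m in result.models if m.cell_line == cl and m.qualified]
        for cl in cell_lines
    }
    if stop <= STAGES.index("train"):
        return result

    # -- assemble -------------------------------------------------------------
    empty = [cl for cl, ms in result.qualified.items() if not ms]
    if empty:
        raise RuntimeError(f"no qualified model (external AC > 0.8) for: {empty}")

    # VS set: withheld/screen actives + decoys + balance-removed inactives
    removed_ids = sorted({i for ids in result.removed_inactive_ids.values() for i in ids})
    id_to_smiles = {c.compound_id: c.standardized_smiles for c in curation.compounds}
    vs_pairs = list(screen_std) + [(i, id_to_smiles[i]) for i in removed_ids]
    # training compounds must never appear in the evaluation set
    train_ids = {cid for cl in cell_lines for cid in result.splits[cl].train.ids}
    vs_pairs = [(i, s) for i, s in vs_pairs if i not in train_ids]
    seen: set[str] = set()
    vs_pairs = [(i, s) for i, s in vs_pairs if not (i in seen or seen.add(i))]
    full_vs_table = build_descriptor_table(vs_pairs, frag_config)
    result.vs_active_ids = screen_active_ids

    alpha = config.ensemble.alpha
    if alpha is None:
        alpha = solve_alpha(config.ensemble.theta, config.ensemble.z)
    combos = enumerate_model_combinations(result.qualified)
    result.n_combinations = len(combos)
    best, audit = select_best_combination(
        combos, full_vs_table, screen_active_ids, alpha=alpha, chi=config.ensemble.chi
    )
    result.best_ensemble = best
    result.audit = audit
    audit.to_csv(out / "combination_audit.tsv", sep="\t", index=False)
    (out / "ensemble.json").write_text(json.dumps(best.manifest(), indent=2))
    record("assemble", [out / "combination_audit.tsv", out / "ensemble.json"])
    if stop <= STAGES.index("assemble"):
        return result

    # -- screen ---------------------------------------------------------------
    result.screening = screen_library(best, full_vs_table)
    p = out / "ranked.tsv"
    result.screening.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
    record("screen", [p])
    if stop <= STAGES.index("screen"):
        return result

    # -- evaluate -------------------------------------------------------------
    ranked = result.screening.ranked_list(screen_active_ids)
    report = evaluate_ranking(
        ranked,
        chi=config.ensemble.chi,
        alpha=config.ensemble.alpha,
        theta=config.ensemble.theta,
        z=config.ensemble.z,
    )
    result.report = report.as_dict()
    (out / "metrics.json").write_text(json.dumps(result.report, indent=2))
    curve = accumulation_curve(ranked)
    pd.DataFrame(curve, columns=["fraction_screened", "fraction_actives"]).to_csv(
        out / "accumulation_curve.tsv", sep="\t", index=False
    )
    record("evaluate", [out / "metrics.json", out / "accumulation_curve.tsv"])
    return result
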