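# movscreen

Multi-objective, desirability-based ensemble QSAR for ligand-based virtual
screening and drug repurposing.

## What problem this solves

Given compounds assayed against several cancer cell lines (e.g. the
osteosarcoma lines HOS, MG63, SAOS2, U2OS), a repurposing candidate should
look active against *all* of them at once.  `movscreen` builds a binary
activity classifier per cell line and learner family, then fuses them into
one ranking score, the global desirability

    D1 = ( d(y_1) · d(y_2) · … · d(y_k) )^(1/k)

where each d(y_k) is the geometric mean of that cell line's member-model
active-class scores (all in (0, 1]).  Because D1 is a geometric mean, one
poor cell line drags a compound down — the multi-objective intent.  The
best ensemble is found by exhaustively evaluating every combination of
nonempty qualified-model subsets per cell line (∏_k (2^{m_k} − 1)
candidates) on a labeled screening set, judged by early-recognition
metrics: BEDROC(α), enrichment factor EF(χ), and AUC.

Along the way the package provides, as reusable pieces:

* **chemio** — activity-table parsing, RDKit-based structure
  standardization (salt stripping, nitro normalization, aromatization,
  idempotent canonical SMILES), 10 µM strict-threshold class assignment
  with a >75% majority vote across repeated assays, structure-level
  deduplication *before* voting;
* **fragments** — substructural fragment counts (atom/bond sequences of
  2–8 atoms, atom-centered bundles, distance triplets) in a sparse table;
* **features** — 1% frequency filter and deterministic mRMR ranking with
  the mutual-information quotient, keeping the top 500;
* **datasets** — Ward/Euclidean clustering of the majority class with
  quota downsampling to an exact 1:1 ratio, stratified 75/25 splits;
* **models** — six learner families (RBF SVM, RF, MLP, decision tree,
  kNN, XGBoost) with genetic-algorithm feature selection driven by
  out-of-bag balanced-classification-rate (BCR) fitness over bootstrap
  resamples; external accuracy > 0.8 qualifies a model;
* **ensemble / vsmetrics** — desirability assembly, exhaustive
  combination search, and AUC / EF / BEDROC with the α-calibration solver;
* **synthdata** — download-free synthetic studies: grammar-generated
  molecules, planted pharmacophore signals, property-matched decoys.

See `docs/methods.md` for the science and every numerical convention.

## Worked example

Run the default synthetic study — three pseudo-cell-lines, 300 compounds
each, 5% label noise, reduced GA (population 20, 10 generations, 25
bootstrap splits), learners SVM/DTREE/KNN — end to end (about a minute on
one CPU):

```
movscreen run --seed 7 --out run7
```

With seed 7 this prints (and writes to `run7/metrics.json`):

```json
{
  "auc": 0.9779411764705882,
  "ef": 25.5,
  "bedroc": 1.0,
  "alpha": 160.94379124341006,
  ...
}
```

What happened, stage by stage (all artifacts land in `run7/`): 8 qualified
base models emerged (`model_metrics.tsv`; e.g. all three CL1 learners
passed external AC > 0.8), the exhaustive search scored (2³−1)(2²−1)(2³−1)
= 147 combinations (`combination_audit.tsv`), and the winning ensemble
{CL1-DTREE, CL2-KNN, CL3-DTREE} ranked the 204-compound held-out screen
(`ranked.tsv`) with all 8 planted pan-active molecules in the top ranks —
hence BEDROC = 1.0 at α = 160.9 (α solved from θ = 0.8, z = 0.01) and an
enrichment factor of 25.5 at 1% of the list, against ~1 expected for a
random ordering.  The top of `ranked.tsv`:

```
 rank compound_id  D1  d:CL1  d:CL2  d:CL3
    1    ACT00001 1.0    1.0    1.0    1.0
    2    ACT00002 1.0    1.0    1.0    1.0
    ...
```

Standalone metric evaluation of any ranked list (TSV with `compound_id`
and `is_active` columns, best first, or with a `score` column):

```
movscreen evaluate --ranked ranked.tsv --chi 0.01 --theta 0.8 --z 0.01
```

Other subcommands (`simulate`, `curate`, `describe`, `select-features`,
`balance`, `train`, `assemble`, `screen`) run the pipeline up to that
stage; `--config FILE` supplies a YAML configuration (schema:
`movscreen.pipeline.PipelineConfig`), `--seed` and `--out` override it.
Real data enters through `data.source: files` with activity CSVs and a
screening SMILES file.

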