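# Methods

## Problem and overall design

`movscreen` builds ligand-based virtual-screening models for compounds
assayed against several cancer cell lines and combines them into one
multi-objective ranking.  The premise: a drug-repurposing candidate should
look active against *every* cell line of interest simultaneously, so the
final score is a desirability aggregate of per-cell-line classifier
outputs, and the quantity that matters is *early recognition* — how many
true actives land in the top ~1% of the ranked library — rather than plain
classification accuracy.

The pipeline stages are: activity-table curation → fragment descriptors →
frequency filter + mRMR feature ranking → diversity-aware class balancing
→ 75/25 train/external split → GA-wrapped classifier training per cell
line and learner → desirability-ensemble assembly by exhaustive
combination search → screening and early-recognition evaluation.

## Curation

Assay records carry a compound id, SMILES, cell line, assay type (IC50,
GI50 or EC50) and a standard value in µM.  Structures are standardized
with RDKit: chemotype normalization (e.g. both nitro spellings collapse to
the charge-separated form), retention of the largest organic covalent
fragment (ties broken by heavy-atom count, then lexicographic canonical
SMILES), explicit-hydrogen removal and aromaticity perception.  The
operation is idempotent; unparsable inputs are logged rejections, never
silent drops.  Full tautomer canonicalization is deliberately not applied:
the rules are tool-specific and poorly standardized, so the normalization
is restricted to the chemotypes listed above.

Activity classes use a 10 µM potency threshold with strict inequalities:
below 10 µM → active, above → inactive.  A value of exactly 10 µM supports
neither claim and is excluded from voting rather than assigned a class.
When one structure (after deduplication, which merges assay records
*before* classification) has several assays, the majority class is adopted
only if its share strictly exceeds 75%; otherwise the compound is rejected
as contradictory.  Reference drugs destined for the screening set are
removed by an id/SMILES blocklist after deduplication.

## Fragment descriptors

Descriptors are counts of 2D substructural fragments over the molecular
graph:

* **Sequences**: all simple paths of 2–8 atoms.  Labels alternate atom and
  bond symbols (`-`, `=`, `#`, `~` aromatic; aromatic atoms suffixed `a`);
  each path is rendered forward and reversed and the lexicographically
  smaller string kept, so each undirected path counts once.
* **Atom-centered fragments**: per atom, the sorted bundle of all rooted
  simple paths up to the maximum length; a fixed-length variant restricts
  to one path length.  Both variants sit behind config flags because their
  definitions in the fragment-descriptor literature differ between tools;
  the variable-length variant is on by default.
* **Triplets**: unordered atom triples in one connected component, encoded
  by sorted element symbols plus sorted pairwise shortest-path distances.

Rings contribute through their constituent simple paths; atoms never
repeat within a path.  Counting semantics, not any specific tool's label
syntax, is the contract — the test suite pins the counts to an independent
permutation-based exhaustive enumeration on small molecules and to the
closed form (a linear chain of n atoms has n−k+1 paths of k atoms).

## Feature selection

Columns present in fewer than 1% of compounds are removed.  The remaining
counts are binarized to presence/absence (fragment counts are sparse and
heavy-tailed; presence carries nearly all the signal at this data scale)
and ranked by greedy mRMR with the mutual-information quotient: step one
maximizes I(f; y); later steps maximize I(f; y) / mean_{s∈S} I(f; s).  MI
is the plug-in estimate on the 2×2 table in nats (the unit cancels in the
quotient).  A near-zero mean redundancy (< 1e−12) is replaced by that
epsilon with the quotient capped at 1e12; ties break by higher relevance,
then lexicographic label, making the ranking fully deterministic.  The top
500 features (or all survivors, if fewer) become the GA's candidate pool.

## Balancing and splitting

The majority class is clustered by Ward's method on Euclidean distances
over the selected descriptors (no scaling — counts share a common unit).
The cluster count (or a linkage-distance threshold) is an explicit config
parameter: the procedure it reproduces chose cut-offs from dendrograms by
eye, and an explicit parameter is the reproducible equivalent.  Quotas
proportional to cluster size (largest-remainder rounding, floor of one per
cluster when the target allows) are sampled without replacement, giving an
exactly 1:1 dataset that still covers the majority class's chemical space.
Removed majority compounds are set aside as presumed inactives for the
screening set.  The balanced set is split 75/25 into train/external,
stratified by class (per-class counts by largest remainder preserving the
total); the external set is never touched until final model evaluation.

## Base models and GA feature selection

Six learner families are supported: RBF-kernel SVM, random forest, an MLP,
a decision tree, kNN and XGBoost, each with fixed, untuned hyperparameters
(see `models.LEARNER_DEFAULTS`); hyperparameter optimization is explicitly
out of scope.  Feature subsets are chosen by a bit-string GA (tournament
size 3, uniform crossover at 0.8, per-bit mutation 1/L, elitism 1, initial
bit probability 0.1 so masks start sparse; population 50 × 30 generations
at full scale).  Fitness is the mean BCR over stratified bootstrap
resamples of the *training* split (100 at full scale), evaluated on the
out-of-bag compounds — stratified resampling keeps both classes in every
training draw, and out-of-bag scoring is the reproducible reading of
"bootstrap splits".  BCR = ((SN+SP)/2)·(1−|SN−SP|) zeroes out degenerate
one-class predictors that plain accuracy would reward at 0.5.

The fitted model's external accuracy must strictly exceed 0.8 to qualify
for ensemble membership.  Scores for screening are active-class
probabilities where available; SVM margins pass through a logistic map
(monotone, bounded, no refit); all scores are clipped to [1e−6, 1] so the
geometric means downstream stay finite.

## Desirability ensemble

Per cell line, the desirability d(y_k) of a compound is the geometric mean
of its member-model scores; the global score is

    D1 = (d(y_1) · d(y_2) · … · d(y_k))^(1/k),

the geometric mean across cell lines.  Every cell line must be represented
(k is the cell-line count); allowing variable k is config-gated off.  All
∏_k (2^{m_k} − 1) combinations of nonempty qualified-model subsets are
evaluated on a labeled screening set; the winner maximizes BEDROC(α), with
EF(χ = 0.01) and then AUC breaking ties, and an audit table records every
candidate.  Ranking ties in D1 break by compound id, so the ordering is a
deterministic function of the inputs.

## Early-recognition metrics

For a ranked list of N compounds with n actives at relative ranks x_i:

* AUC = 1 − mean(x_i);
* EF(χ) = (a/n)/(k/N) with k = ⌈χN⌉ top positions containing a actives.
  The ceiling convention is deliberate: it is the unique reading that
  makes the worked 772-compound examples (top 1% = 8 positions; EF of
  27.57/20.68/13.8 for 4/3/2 actives) come out exactly;
* BEDROC(α) = (RIE − RIE_min)/(RIE_max − RIE_min), where RIE is the
  exponentially weighted mean e^{−αx_i} normalized by its uniform
  expectation.  BEDROC is exactly 1/0 for front-/back-loaded actives; the
  implementation clips ~1e−16 overshoot at the extremes.
* α is calibrated by solving θ(1−e^{−α}) − 1 + e^{−αz} = 0 (Brent's
  method, residual < 1e−10): θ is the share of total weight expected from
  the top fraction z.  θ = 0.80, z = 0.01 gives α ≈ 160.9.  θ defaults to
  0.80, the conventional calibration.

Metrics require a strict ordering; tie-breaking is the ranker's job.

## Synthetic studies

The generator builds valence-valid molecules from a grammar (C2–C6
backbones decorated with rings and common functional groups) and plants a
per-cell-line activity signal: molecules containing that line's
pharmacophore substructure (defaults: pyridine, carboxylic acid, nitro)
draw potencies log-uniform in 0.05–9 µM, others in 11–500 µM, with
membership flipped at the noise rate before the draw — so labels are never
on the 10 µM boundary and the flip fraction is binomial at the configured
rate.  Pharmacophore-bearing grammar tokens are upweighted so each planted
class covers roughly a fifth to a third of the library.

The screening set mimics benchmark decoy construction: a handful of
"pan-active" molecules carrying *all* pharmacophores at once (the
multi-target compounds the ensemble should surface) plus ~50 decoys per
active chosen nearest in a z-scaled space of heavy-atom count, ring count
and heteroatom fraction, excluding exact structure matches, union
deduplicated.  Because the pan-actives are property-similar to one
another, their nearest-decoy sets overlap and the deduplicated union is
smaller than actives × 50; the per-active selection still sees 50
candidates each.  The default study is 3 pseudo-cell-lines × 300
compounds at 5% noise.

What passing tests on this substrate do **not** show: real assay noise is
not independent label flipping, real SAR is not a single substructure, and
real decoys are presumed — not guaranteed — inactive.  The synthetic
results validate the machinery end to end, not chemical generalization.

## Pipeline, determinism and problem sizes

Every random choice derives from one config seed through a spawned seed
tree; re-running a config byte-reproduces the ranked output.  The default
demonstration configuration uses the reduced GA (population 20, 10
generations, 25 bootstrap splits) and the three cheapest learner families
(SVM, decision tree, kNN), which completes the full study — curation
through exhaustive combination search over a few hundred ensembles — in
about a minute on one CPU while exercising every stage; the full-scale
GA (50×30×100) and six-learner roster are plain config changes.  Fitted
models are cached on disk keyed by the config hash, so downstream stages
resume without retraining; other stages are cheap and recompute.

## Known limitations

* No applicability-domain analysis: screening scores are produced for any
  molecule, however far from the training chemistry.
* The fragment labels follow this package's canonical syntax; they are not
  interchangeable with any external fragmentation tool's label files.
* mRMR uses presence/absence; count-magnitude information is discarded.
* The exhaustive combination search is exponential in the per-cell-line
  qualified-model count; with six learners and four cell lines it is
  trivially small, but large model pools would need pruning.
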