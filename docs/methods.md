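# Methods

## Problem setting

Given a protein with a bound allosteric modulator, FPocket detects a set of
candidate pockets and emits 19 physicochemical descriptors per pocket
(score, druggability score, alpha-sphere counts and radii, SASA terms,
volume, hydrophobicity/polarity/charge scores, flexibility, ...). One
pocket per protein is the allosteric site. The task is to order each
protein's pockets so the allosteric one ranks first — a grouped ranking
problem, not pooled binary classification: scores are only ever compared
within a protein, so the model needs to learn relative differences among a
protein's pockets rather than a universal cross-protein rule.

## Curation pipeline

Stages run in a fixed order; every dropped entry is logged with a reason
and the report checks that drops + retained equal the input count.

1. **Resolution** — keep entries with recorded resolution strictly below
   `resolution_max` (default 3.0 Å). Entries with no recorded resolution
   (NMR structures) fail the filter: only demonstrably high-resolution
   structures pass.
2. **Modulator multiplicity** — exactly one modulator residue instance is
   required; zero or several make the positive/negative ratio of the group
   ill-defined, so the entry is dropped.
3. **Distance labeling** — centers of mass (standard atomic masses over
   heavy atoms; a geometric mode exists because the weighting convention is
   not universal) of every pocket and of the modulator; the closest pocket
   becomes the unique positive. If even the closest pocket is farther than
   `distance_max` (default 10 Å) the detection is considered unreliable and
   the entry is dropped. Exact distance ties break toward the lower pocket
   index, making labels deterministic.
4. **Redundancy removal** — global Needleman–Wunsch identity (match +1,
   mismatch 0, linear gap −1; identity = identical pairs / alignment length
   including gaps) over the ATOM-derived sequence of the longest chain.
   A greedy pass in input order: a candidate exceeding `identity_max`
   (default 0.30) against retained entries survives only if its
   modulator–pocket distance is shorter than every conflicting survivor's
   (finer labeling wins). The pass is idempotent and the output contains no
   pair above the threshold. The argument pair is canonicalized before
   aligning so identity is exactly symmetric despite co-optimal alignments.
5. **Split** — protein-level random split into `round(n·f)` train and the
   rest test, driven by an explicit, logged seed.

All thresholds are strict inequalities ("smaller than", "greater than"),
so boundary values (resolution exactly 3.0 Å is dropped; distance exactly
10 Å is kept) behave predictably.

## Ranking engine

LambdaMART: gradient-boosted regression trees driven by lambdarank
gradients computed per protein group.

* **Gains** are binary, so `2^G − 1 ∈ {0, 1}` and IDCG of any group with a
  positive is 1. All-zero-relevance groups (possible at prediction time,
  impossible in curated training data) score NDCG 1.0 and produce zero
  gradients instead of crashing.
* **|ΔNDCG|** is evaluated against the current predicted order with ties
  broken by row index, so gradients are deterministic.
* **Trees** grow best-first to `max_leaves` (default 31). Split gain is the
  Newton gain `0.5·(G_L²/(H_L+r) + G_R²/(H_R+r) − G²/(H+r))` with ridge
  `r = 1e−3`; leaf values are Newton steps `−G/(H+r)`. The ridge keeps
  leaf values finite when curvatures vanish (e.g. single-item groups).
  A split must strictly increase gain and leave `min_samples_leaf`
  (default 5) rows on both sides; thresholds are midpoints between
  adjacent distinct feature values.
* **Defaults**: σ = 1.0, learning rate 0.1, 500 trees, NDCG truncation K =
  full group size (any truncation is a modelling choice; full depth is the
  least arbitrary default and K is configurable). Training is
  single-threaded and bit-reproducible from the seed; the seed only drives
  the optional per-tree feature subsampling.
* **Serialization** is a versioned JSON document (trees as flat arrays,
  params, feature order, per-feature gains). Python's float repr
  round-trips exactly, so a saved/loaded model predicts bit-identically.
* **Feature importance** is total realized split gain per feature — the
  native explanation for tree ensembles here; per-sample Shapley-value
  attribution is intentionally out of scope and can be layered on
  externally.

## Evaluation

The top-ranked pocket of each protein is the single positive prediction.
Consequences asserted by the tests: FP = FN for any input, so precision,
recall and F1 coincide (F1 is computed from counts as `2TP/(2TP+FP+FN)` so
the collapse is exact in floating point); Top-1 · n_proteins = TP. MCC and
specificity follow the usual confusion-matrix formulas; zero denominators
yield 0 with a warning. Reports carry the split seed and a dataset
fingerprint (row count + content hash) for provenance.

## Synthetic data

The generator emulates the *statistical shape* of curated pocket data, not
protein physics: per protein, a pocket count drawn as `2 + Poisson(mean−2)`
(mean 21 — the observed average pocket count per protein; the shift
respects the ≥ 2 minimum, and ties dispersion to the mean), 19 iid normal
descriptors, and one uniformly placed positive whose descriptors are
shifted by `effect_size · noise_sd`. Default effects follow the direction
structure reported for real allosteric pockets: +1.5 SD on score,
volume_score and charge_score, −1.0 SD on flexibility and total_sasa.
Feature baselines are unit normals: realism is not the goal, testability
is. Real descriptors are correlated, heavy-tailed and on wildly different
scales, so passing tests demonstrate the machinery (labeling, grouping,
optimization, evaluation) rather than real-data accuracy.

Under these defaults the best achievable ranking is bounded: the
Bayes-optimal ranker is the projection on the known effect direction
(Mahalanobis separation √8.75 ≈ 2.96 SD), which Monte Carlo places at
Top-1 ≈ 0.84 and Top-3 ≈ 0.96 for ~21-pocket groups. The trained ranker
reaches Top-1 ≈ 0.80 and Top-3 ≈ 0.94 — close to that ceiling. These
numbers measure the synthetic conditions, not any real benchmark.

Structure fixtures are geometrically exact toy complexes: each pocket is a
symmetric 4-carbon cluster (center of mass = nominal center exactly),
pockets sit 40 Å apart, and a single-atom modulator is placed at a chosen
distance from a chosen pocket, so parsing + labeling must reproduce a known
label vector. Residue names are controllable to steer pairwise sequence
identity in redundancy tests.

## Numerical and design choices

* Pocket centers come from the pocket atom files (`pocketN_atm.pdb`), not
  alpha-sphere centers; both conventions exist, and pocket atoms are what
  FPocket reliably emits.
* PDB parsing is by fixed column positions; ATOM-derived sequences (not
  SEQRES) so only resolved residues count; nonstandard residues map to X;
  altLoc B+ atoms are skipped.
* Logistic terms are clipped at ±500 before exponentiation.
* Ranking ties break toward the lower pocket index everywhere (labels,
  predictions, baseline), so every ordering is deterministic.
* The FPocket-score baseline ranks by the score descriptor with the same
  tie-break, giving a model-free reference ranker.

## Problem sizes

The default test-and-acceptance workload trains on 200 synthetic proteins
(~4200 pockets) with 500 trees, about half a minute per model on one core;
the held-out evaluation uses 100 proteins. Unit and property tests use
10–60 proteins and reduced tree counts, which is sufficient to exercise
every code path deterministically.

## Known limitations

* The ranker is exact-split, single-threaded: appropriate for thousands of
  pockets, not millions of rows.
* Sequence identity uses one global alignment parameterization; no
  CD-HIT-style clustering, no chain pairing beyond the longest chain.
* mmCIF input, NMR model selection, and running FPocket itself are out of
  scope; the package consumes FPocket's text output.
* Real-data headline numbers require the external structure databases and
  FPocket runs; nothing here claims to reproduce them.
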