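# pocketrank

Rank protein pockets by their relevance to allosteric sites with a
learning-to-rank model.

Allosteric drug discovery needs to know *which* pocket of a target protein
is the allosteric site. Binary classifiers trained on pooled pockets from
many proteins must learn an absolute rule that transfers across families —
a hard and often unnecessary problem, because in practice all pockets of
one protein are compared against each other. `pocketrank` instead treats
each protein as a query group and its FPocket-detected pockets as the items
to be ordered, training a LambdaMART ranker (gradient-boosted regression
trees driven by lambdarank gradients) on the 19 FPocket physicochemical
descriptors of each pocket.

The package is aimed at structural bioinformaticians who have
protein–modulator complexes (PDB files) and FPocket output, and want a
reproducible path from raw structures to a trained, serializable pocket
ranker.

## The model

Each protein contributes one group of pockets with binary relevance
(exactly one annotated allosteric pocket). Ranking quality is measured by
the normalized discounted cumulative gain,

    DCG@K  = Σ_{i=1..K} (2^{G_i} − 1) / log2(i + 1)
    NDCG@K = DCG@K / IDCG@K,

with gains G_i ∈ {0, 1}. Training uses the lambdarank construction: for
each pair (i, j) with G_i > G_j,

    λ_ij = −σ · |ΔNDCG@K(i↔j)| / (1 + exp(σ(s_i − s_j))),

where |ΔNDCG| is the NDCG change from swapping the pair in the current
predicted order. Per-item sums of λ (and the corresponding second
derivatives) are the gradients/curvatures that each boosting round's
regression tree fits with Newton-step leaves, grown best-first to a leaf
budget.

The companion pipeline reproduces standard dataset curation for this task:
resolution filter (< 3 Å), single-modulator check, distance labeling (the
pocket whose center of mass is closest to the modulator is the positive;
entries whose closest pocket is > 10 Å away are dropped), global-alignment
sequence-redundancy removal at 30 % identity (the entry with the shorter
modulator–pocket distance survives), and a protein-level 80/20 split.

Evaluation follows the one-positive-prediction-per-protein scheme: the
top-ranked pocket is the single positive prediction, which forces FP = FN
and hence precision = recall = F1; Top-1/2/3 rates count proteins whose
true allosteric pocket is ranked within the top k.

## Worked example

```python
import pocketrank as pr

# synthetic study conditions: ~21 pockets/protein, one positive each,
# positive shifted along the directions reported for real allosteric sites
train = pr.generate_feature_table(pr.SyntheticSpec(n_proteins=200, seed=11))
test  = pr.generate_table(pr.SyntheticSpec(n_proteins=100, seed=12))

model = pr.train(train, pr.LambdaRankParams(seed=11))
report = pr.evaluate_model(model, test)
print(report.to_text())
print(pr.feature_importance(model).head(3))
```

prints

```
Precision    0.800
Accuracy     0.981
Recall       0.800
Specificity  0.990
F1 score     0.800
MCC          0.790
Top 1        80.0%
Top 2        92.0%
Top 3        94.0%
charge_score    2728.601743
score           2166.655449
volume_score    1578.745291
Name: gain, dtype: float64
```

Precision, recall and F1 coincide because each protein gets exactly one
positive prediction; Top-k is the fraction of the 100 held-out proteins
whose true pocket is ranked within the top k. The importance ranking
recovers the descriptors the generator actually shifted.

The same flow is available from the shell:

```
pocketrank simulate --n-proteins 200 --seed 11 --out train.csv
pocketrank train    --table train.csv --seed 11 --out model.json
pocketrank rank     --model model.json --fpocket 1ABC_out/
pocketrank evaluate --model model.json --table test.csv
pocketrank curate   --structures pdbs/ --fpocket fpocket/ \
                    --manifest manifest.csv --seed 1 --out train.csv
```

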