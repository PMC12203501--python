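# subloc3d

Multi-label classification of **protein subcellular localization** from
3-D fluorescence microscopy images of single cells, with optional
**knowledge enhancement** from Gene Ontology (GO) annotation graphs.

Spatial proteomics screens tag a protein, image live cells in 3-D
(protein channel plus a nuclear reference stain), and annotate each
protein with the compartments it occupies — often several, each with a
confidence grade.  Training a per-cell classifier on such data faces
three structural problems: classes are heavily imbalanced; protein-level
labels are *weak* at the cell level (an annotated pattern may be absent
from an individual cell); and image evidence alone cannot separate
compartments that look alike.  `subloc3d` addresses all three:

* a **dual-branch residual encoder** — a 3-D stack on the volume and a
  2-D stack on its maximum-intensity z-projection — fused by an adaptive
  elementwise gate into one image feature;
* an **asymmetric, confidence-weighted classification loss**

  L_slc = (1/C) Σ_j α_j [ −y_j ln p_j − (1−y_j)(p_j−m)₊^r ln(1−(p_j−m)₊) ]

  with focusing exponent r = 4, probability margin m = 0.05, and per-class
  weights α from annotation grades (1.0 / 0.5 / 0.1 for grades 3/2/1);
* **joint knowledge-graph embedding**: protein–GO triples (h, r, t) are
  scored by TransE, RotatE, PairRE or ComplEx; during training the head
  entity of a cell's triples is the cell's own adapted image feature,
  optimized with the contrastive margin loss
  −ln σ(γ−d(h,r,t)) − (1/n) Σ ln σ(d(h,r,t′)−γ) over same-category
  corrupted tails; at prediction time a protein's *knowledge feature* is
  recovered from its triples alone by inverting the scoring function for
  the head and average-pooling — so it works for proteins never seen in
  training;
* a **protein-ID aggregation loss** (softmax over training proteins,
  asymmetric, restricted to nine low-variability compartments) that makes
  cells of one protein embed coherently.

The three losses combine as `1.0·L_slc + 0.1·L_ke + 0.1·L_id`.  Because
no public 3-D screen ships with this package, a first-class **synthetic
generator** renders single cells (nucleus + nine compartment patterns)
with configurable imbalance, mixing weights, confidence grades,
weak-annotation dropout and a matching GO-style graph — every claim the
package makes is testable offline on one CPU.

## Worked example

```python
from subloc3d import (SimConfig, simulate_dataset, simulate_kg,
                      stratified_protein_split, LocalizationClassifier,
                      evaluate)

cfg = SimConfig(seed=11)                      # 30 proteins x 20 cells, 6 classes
table, truth = simulate_dataset(cfg)          # volumes (2, 12, 32, 32)
graph = simulate_kg(table, cfg)               # protein-GO + GO-GO triples
stratified_protein_split(table, seed=11)      # 70/15/15 at the protein level

model = LocalizationClassifier(kge_method="pairre", epochs=10, seed=11)
model.fit(table, graph)

test = table.subset("test")
report = evaluate(model.predict_proba(test), table.label_matrix(test),
                  model.classes_)
print({k: round(v, 3) for k, v in report.macro.items()})
```

Output from this exact script:

```
{'mMCC': 0.93, 'mF1': 0.955, 'mJS': 0.917, 'mAP': 0.999}
```

meaning the model recovers the localization classes of cells from
*held-out proteins* with macro-MCC 0.93: per class, predictions and
ground truth are strongly correlated well beyond chance (MCC 0 = chance,
1 = perfect), and ranking quality (mAP) is near-ceiling.  With
`kge_method=None` the same script trains the image-only ablation.

The same pipeline is available from the shell:

```bash
subloc3d simulate --out data --seed 11
subloc3d build-kg --annotations data/annotations.csv --out kg --seed 11
subloc3d train    --annotations data/annotations.csv \
                  --triples kg/triples.tsv --categories kg/entity_categories.tsv \
                  --go-texts kg/go_texts.tsv --out model --seed 11
subloc3d predict  --checkpoint model/checkpoint.npz \
                  --annotations data/annotations.csv \
                  --triples kg/triples.tsv --categories kg/entity_categories.tsv \
                  --go-texts kg/go_texts.tsv --out preds
subloc3d evaluate --predictions preds/probabilities.csv \
                  --annotations data/annotations.csv --out eval --split test
```

`docs/methods.md` documents the model, the generator's assumptions, the
designed experiments and every numerical choice.

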