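# goensembles

Heterogeneous ensembles for Gene Ontology (GO) term prediction from
protein sequences.

Automated protein function prediction must cope with the fact that no
single classifier is best for every functional term: community
assessments keep finding that different algorithms win on different GO
terms and proteins. `goensembles` is a library + CLI for the ensemble
answer to that problem. It treats each GO term as an independent binary
classification task over normalized amino-acid 3-mer frequencies and
builds three families of *heterogeneous ensembles* on top of a roster of
twelve diverse base classifiers:

* **mean aggregation** of the base classifiers' scores,
* **stacking** — a meta-classifier (8 algorithm slots) trained on
  held-out base predictions,
* **CES** — greedy forward ensemble selection with replacement
  (Caruana-style): repeatedly add the base model whose addition most
  improves the selection metric of the multiset-mean score.

Class imbalance is handled by under-sampled bagging (every bag keeps all
positives plus an equal-size random negative sample; predictions are
bag-averaged), and the whole procedure runs inside a **nested
cross-validation**: base classifiers train on inner folds, ensembles
train on the held-out inner-fold predictions, and everything is
evaluated on outer test folds that nothing was trained on. Performance
is measured by **F_max** — the maximum F-measure
F = 2PR/(P + R) over all score thresholds — and ensembles are compared
with the best base classifier per term via **ΔF_max**, per-stratum
Wilcoxon signed-rank tests, and Friedman + Nemenyi average-rank
comparisons with critical-difference output.

It ships a synthetic-fixtures module that generates complete toy studies
(OBO ontology, FASTA sequences with planted 3-mer motifs, GAF-like
annotation tables with evidence codes and label noise), so the entire
pipeline is exercisable end-to-end without downloading anything.

## Worked example

Generate a toy study (300 proteins, two annotated terms with planted
motif signal, 5% label noise), run the full pipeline, and compare
methods:

```bash
goensembles simulate --out demo --seed 1 --n-proteins 300 \
    --positives 60,40 --planting-rate 0.9 --label-noise 0.05
goensembles run --fasta demo/fixture.fasta --obo demo/fixture.obo \
    --annotations demo/annotations.tsv --outdir demo_run \
    --min-pos 30 --n-bags 3 --k-outer 3 --k-inner 3 --seed 1
goensembles compare --results demo_run/results.tsv \
    --out demo_run/comparison.json
```

`run` writes one scores file per term plus `demo_run/results.tsv` with a
row per (term, method):

```
term_id     method  fmax          threshold     delta_fmax  size_category  level
GO:0000008  NB      0.3333333333  0.6666666667              NA             3
GO:0000008  LR      0.4680851064  0.5000431546              NA             3
...
```

`fmax` is each method's maximum F-measure on the pooled outer-test
scores and `threshold` the smallest score achieving it; `delta_fmax`
(ensembles only) is the gap to the best of the twelve base classifiers
for that term; `level` is the term's depth in the ontology (shortest
path from the root). On this seed the strongest methods on GO:0000008
are stacking with random forest (F_max 0.634) and the PART-slot base
classifier (0.633) — with only ~58 positives the task is hard and base
and ensemble methods are close. `compare` prints

```
Friedman chi2=38.2314 p=0.0121 CD=23.331 -> demo_run/comparison.json
```

i.e. the 22 methods' average ranks over the two terms differ
significantly by the tie-corrected Friedman test (p ≈ 0.012), and the
JSON records the ranks, the Nemenyi critical difference and the groups
of statistically equivalent methods (with only N = 2 terms the CD is
huge — real studies use hundreds of terms).

The same machinery is available as a library (`featurize`,
`label_term`, `make_bags`, `run_term_pipeline`, `fmax`,
`friedman_nemenyi`, ...); see `docs/methods.md` for the scientific
conventions and `tests/` for executable examples.

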