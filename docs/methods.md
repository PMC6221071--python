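# Methods

`goensembles` treats protein function prediction as one binary
classification problem per Gene Ontology (GO) term and asks whether
*heterogeneous ensembles* — combinations of many different base
classifiers — predict better than the best individual classifier for
that term. This note records the model, the defaults and why they are
what they are, what the synthetic data does and does not emulate, and
the numerical conventions frozen into the implementation.

## Sequence representation

Each protein sequence is represented by its normalized k-mer frequency
vector: counts of every length-k window over the 20-letter standard
amino-acid alphabet, divided by the full sequence length L. With the
default k = 3 the feature space is exactly 20³ = 8000 columns, in frozen
lexicographic order; all downstream matrices reference features by name.
The denominator is L rather than the window count L − k + 1 (the two
differ by a per-protein constant factor that is irrelevant to ranking
but matters for reproducibility; L is the convention here, and
`normalize_by_full_length=False` switches to window counts).

Nonstandard residues (B, J, O, U, X, Z and `*`) are handled by the
`drop-kmer` policy by default: windows containing any such letter
contribute no count, which keeps the feature space exactly |alphabet|^k.
Sequences shorter than k produce an all-zero row with a logged warning
rather than an error, so batch featurization never aborts mid-run.

## Labels from the ontology

Annotations are first filtered by evidence code: curated (ISS, ISO, ISA,
ISM, IGC, IBA, IBD, IKR, IRD, RCA, TAS, NAS, IC) and experimental (EXP,
IDA, IPI, IMP, IGI, IEP) codes are kept, electronic annotations (IEA)
are dropped, and duplicate (protein, term) pairs are collapsed. For a
target term T:

* **positives** — proteins directly annotated to T;
* **excluded** — proteins annotated only to ancestors or descendants of
  T (their membership is genuinely uncertain: a descendant annotation
  implies T under the true-path rule, an ancestor annotation may later
  be refined to T);
* **negatives** — everything else in the featurized universe.

Positives are *direct* annotations only (no true-path propagation); a
propagation switch exists but is off, because the exclusion of
descendant-annotated proteins from the negatives only makes sense if
they are not already counted as positives. Terms enter a study when
they have strictly more than `min_pos` positives (default 200), and are
reported in three disjoint size categories using half-open intervals:
small (200, 500], medium (500, 1000], large (1000, ∞).

Ancestor/descendant/level queries traverse `is_a` and `part_of` edges
(the GO convention for annotation propagation; configurable), per
namespace only. A term's *level* is the shortest-path edge count from
its namespace root — deeper terms are more specific functions.

## Class imbalance: under-sampled bagging

Positives are typically rare, so each training split is re-sampled into
`n_bags` balanced bags (default 10): every bag keeps **all** positives
and draws an equal-sized without-replacement sample of negatives. Bag i
is a deterministic function of (seed, i), so any bag can be regenerated
independently. Each base classifier is fitted once per bag and its
predictions averaged over bags, which both addresses imbalance and
injects diversity among same-type models.

## The classifier rosters

Twelve base slots (NB, LR, SGD, VP, AB, DT, LB, RT, RF, RIPPER, PART,
KNN) and eight stacking meta slots (NB, AB, DT, LB, KNN, LR, SGD, RF)
map to scikit-learn estimators:

| slot | estimator | notes |
|------|-----------|-------|
| NB | `GaussianNB` | dense input |
| LR | `LogisticRegression(max_iter=1000)` | 100 iterations does not converge at 8000 columns |
| SGD | `SGDClassifier` | hinge loss; margins min–max squashed |
| VP | `Perceptron` | margins min–max squashed |
| AB | `AdaBoostClassifier` | |
| DT | `DecisionTreeClassifier` | |
| LB | `GradientBoostingClassifier` | `max_features='sqrt'` when >1000 columns (exhaustive split scans at 8000 columns are ~10× slower for no ranking benefit) |
| RT | `DecisionTreeClassifier(splitter='random')` | |
| RF | `RandomForestClassifier` | |
| RIPPER | `DecisionTreeClassifier(entropy, max_depth=5, min_samples_leaf=5)` | rule-learner surrogate |
| PART | `DecisionTreeClassifier(entropy, min_samples_leaf=10)` | rule-learner surrogate |
| KNN | `KNeighborsClassifier` | |

The contract, not the vendor, is normative: every slot consumes a
feature matrix plus binary labels and emits scores in [0, 1] read as
positive-class confidence. Probabilistic estimators report
`predict_proba`; margin-only estimators (SGD, VP) are min–max squashed
using the margin range observed on their own training data and clipped
to [0, 1] (a constant margin scores 0.5), because downstream F_max
thresholding needs a common scale. Rule induction (RIPPER, PART) has no
scikit-learn implementation, so those slots are served by decision-tree
surrogates with rule-learner-like capacity controls. All remaining
hyperparameters are scikit-learn defaults.

k-mer matrices are ~1–3% dense, so learners accept scipy sparse input
and the pipeline slices one shared CSR matrix per term; the dense-only
slot (NB) densifies internally. This changes speed, not results.

## Nested cross-validation

Supervised ensembles involve two training rounds (bases, then the
combiner), so a single CV loop would let the meta-layer train on
predictions made for proteins its bases saw. The nested scheme:

1. Split the term's dataset into `k_outer` stratified outer folds.
2. Within each outer-train set, split again into `k_inner` inner folds.
   Base classifiers are fitted on balanced bags of each inner-train set
   and predict the corresponding inner test; these held-out,
   bag-averaged predictions, collected across inner folds, form the
   **meta matrix** (one row per outer-train protein, one column per
   base classifier).
3. Ensembles are fitted on the meta matrix. Base classifiers are refit
   on full outer-train bags so that the "best base classifier"
   comparison uses the same training budget, and everything is scored
   on the untouched outer test.
4. Outer-test scores are pooled across folds into one score vector per
   method (a single precision–recall curve per term per method, matching
   CAFA-style evaluation and avoiding fold-level threshold instability),
   and F_max is computed on the pooled vector.

Every unit of work (classifier × bag × inner fold; ensemble × outer
fold) is a pure function of its declared inputs with its own derived
seed, so units can run in any order or in parallel (joblib threads)
with bit-identical results. An optional `fit_recorder` hook receives
every (context, training-row-indices) pair, which the tests use to
audit that no outer-test index is ever seen during that fold's
training; the hook is reliable in serial and threaded execution (shared
memory), which is how the audit runs.

Defaults are k_outer = 5, k_inner = 5 (not stated by the source
methodology, which defers to its predecessor; five-fold keeps ≥40
positives per inner fold at the 200-positive selection floor).
Stratification is by class label only.

## Ensemble layers

All three families consume the prediction matrix (columns in fixed
roster order):

* **Mean** — unsupervised row-wise average.
* **Stacking** — a meta-classifier (any of the 8 meta slots) trained on
  the meta matrix; denoted e.g. `LR.S` for stacking with logistic
  regression.
* **CES** — Caruana-style greedy forward ensemble selection *with
  replacement*: start empty; each iteration, evaluate every base
  (duplicates allowed — multiplicity acts as a weight in the multiset
  mean) and add the one that maximizes the selection metric (default:
  F_max on the meta matrix; AUC available); stop when no candidate
  strictly improves the metric, with a max_iter = 100 safety cap. Ties
  break to the lowest roster index. No internal validation split is
  used inside CES: the meta matrix is already held out from base
  training by the nested CV. The trace of accepted steps is recorded
  and is non-decreasing by construction.

## Evaluation

**F_max** is the maximum F-measure over all binarization thresholds.
Conventions frozen here: the threshold set is the observed unique score
values (exact maximum, no grid); predictions at exactly τ count as
positive (≥); F = 0 where P + R = 0; ties in the maximum resolve to the
smallest achieving threshold. Two useful facts the tests rely on: F_max
is invariant under strictly monotone transforms of the scores, and
F_max ≥ 2π/(1+π) always, with equality in expectation for uninformative
scores (π is the positive prevalence; the bound is the F of the
all-positive prediction).

**ΔF_max** for an ensemble is its F_max minus the best of the twelve
base classifiers' F_max on the same pooled outer-test scores. Note the
best base is selected on the test scores themselves, so ΔF_max > 0 is a
conservative bar: the benchmark enjoys a max-of-twelve selection
advantage.

**Statistics.** Per-stratum paired comparisons use the two-sided
Wilcoxon signed-rank test (exact null for n ≤ 25 without ties, normal
approximation with tie correction above; zeros dropped). Comparison of
m methods over N terms uses average ranks (1 = best, ties averaged,
each term's ranks summing to m(m+1)/2), the tie-corrected Friedman
chi-square test, and the Nemenyi critical difference
CD = q_α · sqrt(m(m+1)/(6N)) with q_α from the studentized range at
α = 0.05 (the conventional level). Methods are grouped into maximal
rank-contiguous cliques whose average ranks all lie within CD. The
comparison is emitted as structured JSON (ranks, statistic, p, CD,
groups); a rendered CD bar figure is optional and untested.

## Synthetic fixtures

The generator emulates the *structure* of a GO study — a rooted is_a
toy DAG (b-ary tree plus diamond edges) with one namespace, random
amino-acid sequences, annotation tables with realistic evidence codes,
term sizes spanning the three categories and levels 1..depth — with a
fully controlled signal: each annotated term owns planted 3-mer motifs
written into its positives with probability ρ, and a fraction ε of
per-term memberships is flipped as label noise. Annotated terms are
chosen mutually unrelated (no ancestor/descendant pairs), deepest
levels first, so labeling is unambiguous. All randomness flows from one
seed through named substreams (sequences, assignment, planting, noise),
making every artifact byte-reproducible.

Motif planting is the signal mechanism because 3-mers are exactly what
the pipeline's representation sees, which makes end-to-end checks
sharp. What the generator does **not** emulate: homology and shared
ancestry between sequences (no train/test redundancy), realistic
residue composition or length distributions, inter-species structure,
and correlated annotations across related terms. Passing tests
therefore demonstrate the *machinery* (no leakage, correct statistics,
the ensemble mechanism) rather than expected performance on real
proteomes.

### The complementary-signal study

The `complementary_signal_fixture` builds the study used to check the
direction of the ensemble-vs-best-base comparison: ~600 proteins, one
term with 250 positives split into two equal subgroups, planting rate
0.9, label noise 0.05. The two subgroups carry signals of different
*families*, chosen so that no single base classifier can cover the
whole positive class:

* subgroup 0 — sparse motifs: each member carries one motif from a
  four-motif pool. Split-selecting learners (trees, boosting, forests)
  isolate these cleanly, but a regularized linear model cannot recover
  a one-occurrence indicator among 8000 features at this sample size.
* subgroup 1 — composition tilt: sequences drawn with W/Y/H/C enriched
  3×. This is a dense direction over thousands of k-mer features that
  linear models estimate well, while offering no high-purity single
  split for trees.

Each base family is therefore recall-limited to roughly half the
positives (F_max ≈ 0.6–0.75 against a noise ceiling near 0.86), and
only aggregation across heterogeneous classifiers recovers the union —
the regime in which stacking with logistic regression consistently
yields ΔF_max > 0. Earlier all-motif designs were rejected after an
oracle analysis (a stacking model fit directly on the test-side
prediction matrix *with labels*) showed that no combination of the base
columns could beat the selected best base there: single-family signals
make base errors nested rather than complementary.

### Problem sizes used in tests and the acceptance script

The library defaults remain k_outer = 5, k_inner = 5, n_bags = 10. The
shipped studies (test suite and `scripts/acceptance.py`) run the
complementary-signal pipeline at k_outer = 3, k_inner = 3, n_bags = 3
and sequences of 80–140 residues — the package's desk-scale
configuration, which preserves every structural property being tested
(leak-freedom, pooling, bag averaging, both ensemble layers) at about a
tenth of the full-default compute. The no-signal baseline check accepts
F_max within [2π/(1+π), 2π/(1+π) + 0.12]; the upper allowance is the
a-priori optimism of maximizing F over thresholds at ~200 test points.

## Known limitations

* Rule-induction slots are tree surrogates; exact Weka behavior is out
  of scope by design.
* Margin squashing is per-model min–max, so margin-slot scores are not
  comparable across folds in absolute value (rank-based evaluation is
  unaffected; pooled-curve thresholds for those two slots are noisier).
* The leak-audit recorder assumes shared memory (serial or threaded
  execution).
* GO jargon: cross-namespace reasoning, annotation propagation inside
  predictors, and protein-centric (CAFA-style multi-term) F_max are all
  out of scope; evaluation is term-centric binary classification.
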