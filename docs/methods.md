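# Methods

## Scope and data model

`drugresc` scores drug *instances* — single replicates of a treatment
condition (compound, dose, cell line, duration) — against labeled single
cells. Inputs are (a) a log2-scale gene-by-cell expression matrix, (b) a
binary phenotype per cell (1 = disease-associated; produced upstream by any
phenotype-association method and consumed here as given), and (c) per-
instance differential-expression vectors or prebuilt up/down gene sets.
Cells and genes are matched by exact identifier; a cell present in the
expression matrix but not the label file (or vice versa) is an error rather
than a silent intersection, because silently dropped cells are the most
common way label misalignment goes unnoticed.

## Signature construction

From an instance's log-fold-change vector `c` and p-value vector `p`, the
up-signature is `{g : c_g > 0, p_g < 0.01}` and the down-signature
`{g : c_g < 0, p_g < 0.01}`. Both inequalities are strict, so `c_g = 0` and
`p_g = 0.01` are excluded; no multiple-testing correction is applied to the
per-gene p-values. Instance filtering retains a single dose (10 µM by
convention, the most common assay concentration in public perturbation
compendia). Instances whose signatures are empty on both sides are excluded
from scoring with a log message, not scored as zero — an all-zero feature
column would distort the importance null.

## Reversal scoring (drug-by-cell matrix)

Each cell's genes are ranked by absolute expression; rank `N` goes to the
largest |value|, rank 1 to the smallest. Ties in |expression| are broken by
lexicographic gene symbol: the enrichment walk needs a total order, and a
deterministic tie rule makes runs bit-reproducible (average-rank schemes
would put non-integer weights inside the walk for no benefit — only the
order matters downstream). The walk statistic uses hit weights `|r_j|^α`
with `α = 0.25` and uniform miss increments `1/(N − NG)`; the enrichment
score is the signed value of `P_hit − P_miss` at the position of maximal
absolute deviation. When a positive and a negative extreme tie exactly —
which genuinely happens, since the extremes bracketing the hit run are
rational numbers — the earliest position wins; a 1e-9 tolerance absorbs
float-summation noise so that independent evaluation orders agree. Two
implementations are kept deliberately: an optimized cumulative-sum version
used everywhere, and a plain position-by-position reference walk
(`enrichment_score_reference`); the test suite and the acceptance script
hold them to 1e-12 agreement on random instances.

`D2C = ES_up − ES_down`; a side that is empty after intersecting with the
matrix's genes contributes 0 with a warning, and an instance with no
overlapping genes at all is dropped. A signature side covering *every*
ranked gene leaves `P_miss` undefined (division by `N − NG`) and is treated
as unusable rather than patched. The matrix builder streams cell by cell —
per cell it materializes one ranking and one cumulative-sum buffer per
signature — so memory does not scale with the number of cells.

## Drug importance

The default scorer fits a bagged ensemble of `ntree = 100` classification
trees (Gini impurity, unlimited depth, minimum leaf size 1 — the standard
random-forest defaults) on the D2C matrix with cells as observations.
Bootstrap draws (n cells with replacement) and their out-of-bag (OOB)
complements are recorded per tree; `mtry`, the number of candidate features
per split, is chosen from the grid {⌊√D/2⌋, ⌊√D⌋, ⌊2√D⌋, ⌊D/3⌋} ∪ {1}
(clipped to [1, D]) by minimum OOB error, smallest value on ties. The
importance of instance `d` is the mean over trees of the *count* drop in
correct OOB votes after permuting `X_d` within the OOB set — one fresh
permutation per (instance, tree), streamed from a single seeded generator
so the whole run is bit-reproducible. The count form follows the method's
printed definition; the conventional mean-decrease-in-accuracy (dividing by
each tree's OOB size) is available via `normalize="rate"`, and
`n_permutations > 1` averages several permutations per tree for variance
reduction. Permuting a constant column is a no-op by construction, so such
instances score exactly zero. Raw scores are min–max standardized to [0, 1];
an all-equal vector maps to 0.5 with a warning.

Alternative backends score instances marginally or jointly:

* **Wilcoxon** — two-sided rank-sum p-value between phenotype groups,
  importance −log10 p; the exact null distribution is used for tie-free
  groups up to size 25, the normal approximation otherwise; an all-tied
  column scores 0.
* **ANOVA / Welch** — Bartlett's test at level 0.05 gates between the
  one-way F statistic and Welch's heteroskedastic F (computed for two
  groups via the t² = F identity).
* **L1 logistic regression** — |coefficient| on standardized columns, the
  penalty strength selected by stratified 5-fold cross-validation ("CV-
  optimal" is the reading adopted for the ambiguous "minimum regularization
  strength"; the smallest-λ reading would simply return the least-penalized
  model).
* **SVM-RBF sensitivity** and **gradient-boosting gain** — thin adapters
  over external learners, provided for comparability and only smoke-tested.
* **Majority vote** — an instance is a candidate if at least k = 3 of the
  backends place it in the top half of their rankings.

## Evaluation protocol

Positives are known-indication instances; because curated non-indications
do not exist, negatives are drawn uniformly without replacement from a
tissue-matched candidate pool, an equal number per replicate, with 10
independently seeded draws (seeds master+1 … master+10). Per replicate:
AUROC (Mann–Whitney pair convention, tied pairs 0.5), AUPR (precision
summed over recall increments, tied scores grouped), and F1/accuracy after
predicting positive for the top-m ranked instances with m = |positives|
(ties broken by instance id) — for balanced lists this is a median split,
making a threshold parameter unnecessary. F1 is the standard
2TP/(2TP+FP+FN). Aggregates are the mean and sample standard deviation over
replicates; a single replicate reports sd = 0 with a flag.

## Synthetic data

The generator emulates the statistical shape the scorer assumes, directly
on the log2 scale (a count layer would add nothing: only rank order enters
the walk). Gene means are drawn from Uniform(1, 8) log2 units — a plausible
abundance range — with Normal noise (sd 1.0) and clipping at 0. A disease
program of 100 genes (defaults: 2000 genes, 300 cells, 10% disease cells)
is split into an up-half (+effect_size in disease cells) and a down-half
(−effect_size). Positive drugs *reverse* the program — down-signature over
the up-half, up-signature over the down-half, covering a
`reversal_strength` fraction of each (default 1.0, the idealized full
reversal) — while negative drugs carry size-matched signatures over random
non-program genes. Signature genes receive p-values strictly below the 0.01
cutoff and |logfc| ~ |Normal(max(effect, 1), 0.2)|, so signature recovery
from the DE tables is exact and the planted structure is known to the
tests. All draws flow from one seed; identical configurations reproduce
identical fixtures byte for byte.

What the generator does **not** emulate: dropout/zero inflation, library-
size variation, landmark-gene panels and inference tiers of real
perturbation assays, correlated gene modules beyond the single program, or
dose–response structure. Passing tests therefore demonstrate correctness of
the algorithms and recoverability under clean planted signal, not
performance on real single-cell data.

## Numerical and degenerate-case choices

* Enrichment tie rule and 1e-9 extreme-tie tolerance: above.
* `N < 2` genes, single-class labels, fewer than 2 cells per class, empty
  candidate pools, and all-zero library cells raise errors; they indicate
  upstream problems no default could repair.
* Bootstrap draws that happen to miss both classes or have an empty OOB set
  are redrawn (probability ≈ 0.37^n of an empty OOB set vanishes for
  realistic cell counts).
* Duplicate gene symbols are collapsed by arithmetic mean per cell before
  any scoring; the operation is idempotent.
* Normalization is total-count scaling to 1e6 followed by log2(x + 1); the
  pseudocount is exposed in `RunConfig`. Gene-length-corrected TPM is out
  of scope — matrices normalized upstream can be supplied directly.

## Known limitations

* **Count-based permutation importance is biased for duplicated or highly
  correlated feature columns under class imbalance.** When several
  instances share (nearly) identical D2C columns, trees select that column
  family in many splits; permuting it scrambles OOB predictions, and with a
  90/10 phenotype split those predictions were mostly correct majority
  votes, so the vote-count drop is systematically positive even when labels
  carry no signal. The package's own benchmark shows this: with five
  positive drugs that all fully reverse the same program, the drug-level
  AUROC at zero planted effect is ≈ 1.0 instead of 0.5, while a single
  planted instance among independent decoys calibrates correctly (AUROC
  ≈ 0.5). Marginal backends (Wilcoxon, ANOVA) do not share the bias; with
  balanced cell classes it disappears. Interpret forest importances of
  highly correlated instance families accordingly.
* Directionality is not resolved: a large importance says an instance's
  reversal scores separate the phenotypes, not which phenotype the drug
  would push cells toward; inspect the sign of the group-mean D2C gap.
* One permutation per (instance, tree) keeps the estimator faithful to its
  definition but noisy; use `n_permutations` for stabler scores.
* The problem sizes exercised by the test suite and `scripts/acceptance.py`
  (2000 genes × 300 cells, 20 instances, 10 seeds per condition) were
  chosen to make the full planted-recovery, null-calibration and benchmark
  experiments reproducible in minutes on a laptop core; the code paths are
  identical at larger scale, and the matrix builder's per-cell streaming
  keeps memory flat in the number of cells.
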