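# Methods

## Problem and model

A cysteine's reactivity toward electrophilic probes can change when the
protein is phosphorylated; the change is site-specific and falls into
three classes: decreased, unchanged or increased. `cysreact` treats this
as hierarchical classification from sequence context: a binary
*occurrence* model distinguishes changed from unchanged sites, and a
binary *direction* model, consulted only for sites predicted changed,
distinguishes increased from decreased. The composition yields the
tri-class label; a site whose occurrence probability is below the cutoff
is unchanged regardless of the direction model. The hierarchical design
lets each stage carry its own feature selection and rebalancing, which a
direct three-way classifier (retained as a comparator,
`models.train_direct_tri`) cannot.

Both stages are gradient-boosted tree ensembles (XGBoost) trained at
library defaults except three knobs: `n_estimators` chosen by
cross-validation and `max_depth` / `min_child_weight` by grid search
(`HyperparameterProtocol.default()`: trees {50…800}, depth {3…10}, child
weight {1, 3, 5}, 10 folds). `HyperparameterProtocol.fast()` pins
200 trees / depth 4 / child weight 1 with 3 folds; the test suite and the
desk-scale experiments use it because on simulated benchmarks of a few
thousand sites the tuned and pinned configurations are indistinguishable
while the search multiplies cost ~50-fold.

## Features

Windows are 21-mers centered on the cysteine (1-based, fully closed
coordinates), 'X'-padded at protein boundaries. Window length trades
context against dilution; 21 is the default and is configurable
(`EncoderConfig.window_length`, any odd length ≥ 3).

Block order is fixed — [PSSM | CKSAAP | Atchley | EBGW | BLOSUM62 |
P-dis | IUPRED] — and feature names are stable strings (e.g.
`CKSAAP_k0_SS`, `B62_p-3_L`, `Pdis_S`), so selected-feature lists are
portable across runs. Defaults and dimensions:

| block | default | dim | notes |
|---|---|---|---|
| PSSM | BLOSUM62-row fallback | 420 | per-position 20 scores; a supplied (L×20) profile from a profile-search tool may be used instead |
| CKSAAP | k ∈ {0,1}, alphabet 20+X | 882 | counts of ordered k-spaced pairs / (L−k−1); including 'X' makes boundary composition visible |
| Atchley | five published factors | 105 | per position |
| EBGW | J = 5 | 15 | three binary patterns (hydrophobic∪polar, ∪acidic, ∪basic); weight_j = 1-fraction of first ⌊jL/J⌋ characters |
| BLOSUM62 | — | 420 | per-position substitution rows |
| P-dis | whole-protein distances | 3 | 1/min distance to nearest phospho-S, -T, -S/T; 0 if none |
| IUPRED | passthrough | 1 | supplied per-residue disorder score of the site |

Total 1846. The pad character 'X' encodes as zeros in every positional
block: it is an information-free boundary marker with no published
substitution row or factor values. A missing IUPRED score is an error by
default (`impute_iupred` opts into a fallback value) because the disorder
score is among the most informative single features and silent imputation
would mask annotation gaps.

## Dataset assembly

Redundant proteins are removed greedily, longest first, dropping any
sequence whose global-alignment identity (matches / alignment length;
match 1, mismatch 0, gap open −1, extend −0.5) with a retained sequence
exceeds the threshold (default 0.30). This is an exact-alignment stand-in
for word-heuristic clustering tools and is deterministic given the
length/id ordering; the retained set is an antichain under the threshold.

The benchmark is balanced by undersampling: all changed sites are kept
and an equal number of unchanged sites is drawn uniformly without
replacement (seeded). The stratified validation split takes
⌊fraction·n⌋ per class (default 20%), which reproduces the canonical
benchmark arithmetic exactly: (80, 290, 370) → validation (16, 58, 74),
train (64, 232, 296).

## Rebalancing

SMOTE generates synthetic minority points x + λ(x_nn − x) with λ ~
U(0, 1), x a uniformly drawn minority sample and x_nn one of its k = 5
nearest minority neighbours (k is the technique's canonical default and
shrinks with a warning when the minority is smaller). Tomek links are
mutually-nearest opposite-class pairs; only the majority member is
removed. `smote_tomek` oversamples the minority to parity and then cleans
links, and is applied to the direction task's *training* split only —
validation data never enters any resampling path (guarded by tests).
A config flag allows applying it to the occurrence task for ablations.

## Feature selection

An elastic net (combined L1/L2, coordinate-descent path, 10-fold CV over
l1-ratio {0.1…0.99} and an automatic 50-point strength path) is fit per
task on standardized features with 0/1-coded labels; constant features
standardize to zero and get zero coefficients. A sweep over 50 log-spaced
coefficient-magnitude thresholds spanning (0, max|coef|] scores each
surviving subset by 10-fold CV of a logistic model (accuracy by default,
AUC selectable); the best threshold — smallest on ties, which keeps more
features and lowers variance — defines the selection. An empty subset
scores at chance (majority-class accuracy or AUC 0.5). Selection is run
independently for the occurrence and the direction task, by default on
the resampled training data; the selected counts are data-dependent.

## Metrics

Sn = TP/(TP+FN), Sp = TN/(FP+TN), ACC, and MCC with the convention
MCC = 0 when any denominator factor vanishes. AUC is the Mann–Whitney
pairwise statistic (ties ½), identical to the trapezoidal area under the
emitted ROC curve on tie-free scores; AUPR uses stepwise interpolation
(Σ ΔR·P), the conservative rule. Tri-class evaluation reports accuracy
and per-class precision/recall/F1 with F1 = 0 when precision+recall = 0.
Positional enrichment compares two window sets per (flank position,
residue) by frequency difference and a two-proportion z-test, reporting
raw and Bonferroni-adjusted p-values across all tested cells (the
multiplicity rule is a package choice; degenerate cells where both
proportions are 0 or 1 get p = 1).

## Synthetic data

The generator emits one protein per site (length uniform on [41, 81],
i.i.d. uniform residues over the 20 standard amino acids, cysteine at the
center) and plants three class signals:

* **ps_enrichment** — each flank position (±10) of a *decreased* site is
  replaced by P or S (50/50) with this probability; default 0.5, which
  makes the planted serine excess directly detectable by the enrichment
  statistics (differences > 0.2).
* **pdis_shift** — mixing weight toward class-specific phospho placement:
  changed sites get a phospho-S/T at distance 1 + Poisson(2); unchanged
  sites get none (p = 0.5) or a distant one (uniform 12–20). The
  background (weight 1 − shift) is class-independent.
* **disorder_shift** — mixing weight toward class-specific disorder
  scores: decreased ~ Beta(5, 2), increased ~ Beta(2, 5), unchanged ~
  Beta(2, 2), ordered to mirror the observed decreased > unchanged >
  increased disorder tendency; background Beta(2, 2).

Because every effect is a mixing weight, 0 is exactly the null model (all
classes identically distributed) and planted signal is monotone in each
weight — the basis of the null-calibration and monotonicity tests.
Default class counts are the benchmark's 80:290:6357. The generator does
*not* emulate realistic residue composition (a uniform background is
used), protein-level correlation between sites, multiple cysteines per
protein, or genuine disorder propensity from sequence — so passing
recovery tests demonstrate that the pipeline extracts planted signal
faithfully, not that real proteomes carry this much signal.

## Problem sizes in tests

Parameter-recovery tests simulate 2000 sites (200/700/1100), train with
the fast protocol and require held-out occurrence and direction AUC ≥ 0.9
under strong effects and ∈ [0.4, 0.6] under the null. Monotonicity is
checked at effect grid {0, 0.5, 1.0}, one effect at a time with the
others nulled, averaging three seeds at 400 sites each. These sizes give
stable statistics at interactive runtimes.

## Replication on real data

The real benchmark (the published supplementary site table and IUPRED
scores computed for those proteins) cannot be redistributed with the
package; `scripts/replicate_benchmark.py` runs the identical protocol on
user-supplied copies and prints occurrence AUC, direction AUC and
tri-class accuracy next to the published reference figures (≈0.82, ≈0.92,
≈0.76). Run-to-run spread from the undersampling and split seeds is
expected.

## Known limitations

* The PSSM block's default is a substitution-matrix proxy; true
  position-specific profiles require an external profile search.
* Tyrosine phosphorylation is not considered (S/T only).
* The redundancy filter's exact global alignment is O(n²) in the number
  of proteins and is intended for benchmark-scale inputs, not whole
  proteomes.
* Decision cutoffs default to 0.5 for both stages; operating points for
  specific Sn/Sp trade-offs must be chosen by the user.
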