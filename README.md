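# cysreact

Predicting phosphorylation-dependent changes in cysteine reactivity from
protein sequence.

Cysteine thiol reactivity, measured by chemoproteomic probes, is a strong
indicator of functional importance, and phosphorylation events on the same
protein can raise or lower it site-specifically. Experimental measurement
of this cross-talk is slow and limited in scale; `cysreact` is a
sequence-based machine-learning predictor that assigns each cysteine one
of three labels — **decreased** (−1), **unchanged** (0) or **increased**
(+1) reactivity upon phosphorylation — for chemoproteomics and PTM
cross-talk researchers who want proteome-wide candidate sites.

## Method

Each cysteine is represented by a 21-mer sequence window centered on the
site ('X'-padded at protein boundaries) plus two annotations:

* **Sequence blocks** — five encodings concatenated per window:
  position-specific scores (PSSM; BLOSUM62-row fallback by default),
  composition of k-spaced amino-acid pairs (CKSAAP, k ∈ {0, 1}, 21-letter
  alphabet), the five Atchley physicochemical factors per position,
  encoding based on grouped weight (EBGW, three physicochemical
  binarizations × J = 5 nested prefixes) and per-position BLOSUM62 rows.
* **P-dis** — reciprocal of the distance from the cysteine to its nearest
  phosphorylated S, T and S-or-T residue on the whole protein (0 when no
  such site exists; maximum 1 for an adjacent site).
* **IUPRED** — the supplied intrinsic-disorder score of the cysteine.

The default configuration yields 1846 named features. An elastic net with
a cross-validated coefficient-magnitude threshold selects features
separately for each task; the minority class of the direction task is
rebalanced with SMOTE-Tomek (synthetic minority interpolation followed by
Tomek-link cleaning). Classification is hierarchical: a binary XGBoost
*occurrence* stage (changed vs unchanged, trained on a benchmark balanced
by undersampling the unchanged pool) gates a binary XGBoost *direction*
stage (increased vs decreased); sites below the occurrence cutoff are
labelled unchanged. Evaluation uses Sn/Sp/ACC/MCC, ROC-AUC and AUPR for
the binary stages and accuracy with per-class precision/recall/F1 for the
tri-classifier, plus two-sample positional residue-enrichment statistics
for comparing window sets.

A synthetic-proteome generator plants the benchmark's observed class
structure (P/S-enriched flanks for decreased sites, class-shifted disorder
scores, phospho sites near changed and far from unchanged cysteines) so
the entire pipeline is testable end-to-end without external data.

## Worked example

`examples/simulate_train_evaluate.py` simulates 440 labelled sites with
moderate planted effects, runs the full pipeline and prints:

```
occurrence (changed vs unchanged):
  AUC 0.8589  Sn 0.7097  Sp 0.7500  MCC 0.4601
direction (increased vs decreased, changed sites only):
  AUC 0.8261  Sn 0.5000  Sp 0.9565
hierarchical tri-class accuracy: 0.6984
  decreased precision 0.667 recall 0.783 F1 0.720
  unchanged precision 0.727 recall 0.750 F1 0.738
  increased precision 0.667 recall 0.250 F1 0.364
```

The occurrence AUC is the probability that a randomly chosen changed site
outranks a randomly chosen unchanged one; the low increased-class recall
reflects that class's small sample size, the benchmark's hardest aspect.
Other examples: `examples/encode_site.py` (window, P-dis and feature
blocks for one site), `examples/enrichment_analysis.py` (positional
residue enrichment between site groups), `examples/scan_proteins.py`
(proteome scanning with a trained model).

There is also a thin CLI mirroring the library stages:

```bash
cysreact simulate --n-increased 40 --n-decreased 120 --n-unchanged 300 --out sim/
cysreact encode --fasta sim/proteins.fasta --phospho sim/phospho.tsv \
    --iupred sim/iupred.tsv --labels sim/labels.tsv --out X.tsv
cysreact pipeline --out run/        # full dataset->train->evaluate run
cysreact predict --model run/model --fasta sim/proteins.fasta \
    --phospho sim/phospho.tsv --iupred sim/iupred.tsv --out preds.tsv
```

## Input formats

FASTA for sequences (ids up to first whitespace); tab-separated
annotation tables with headers `protein_id position residue` (phospho
sites, 1-based, S/T), `protein_id position score` (disorder scores in
[0, 1]) and `protein_id position label` (labels `increased` /
`decreased` / `unchanged`). All coordinates are 1-based and fully closed.
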