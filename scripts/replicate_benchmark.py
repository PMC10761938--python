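"""Replicate the published benchmark evaluation on real data.

This pipeline was developed against the published benchmark of
phosphorylation-affected cysteines (80 increased / 290 decreased / 6357
unchanged sites in 307 proteins). That table and the per-residue IUPRED
disorder scores are not redistributable here, so this replication runs
only when you supply them:

  * --fasta    the benchmark proteins (UniProt sequences, multi-FASTA)
  * --phospho  TSV `protein_id  position  residue` of S/T phospho sites
  * --iupred   TSV `protein_id  position  score` of disorder scores
  * --labels   TSV `protein_id  position  label` with label one of
               increased / decreased / unchanged (the benchmark site table)

With those inputs it assembles the balanced benchmark (370 changed + 370
unchanged), makes the stratified 20% validation split, selects features
per task with the elastic net, rebalances the direction training set with
SMOTE-Tomek, trains the two gated XGBoost stages, and prints the
independent-validation occurrence AUC, direction AUC and hierarchical
tri-class accuracy. Published reference values for this protocol are an
occurrence AUC near 0.82, a direction AUC near 0.92 and a tri-class
accuracy near 0.76; expect run-to-run spread from the undersampling and
split seeds.

Example:
    python scripts/replicate_benchmark.py \
        --fasta data/benchmark.fasta --phospho data/phospho.tsv \
        --iupred data/iupred.tsv --labels data/labels.tsv \
        --seed 42 --out scratch/replication
"""

import argparse
import json
from pathlib import Path

from cysreact.pipeline import merge_config, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    ap.add_argument("--fasta", required=True)
    ap.add_argument("--phospho", required=True)
    ap.add_argument("--iupred", required=True)
    ap.add_argument("--labels", required=True)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--protocol", choices=["fast", "default"], default="default",
                    help="hyperparameter tuning protocol")
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()

    for path in (args.fasta, args.phospho, args.iupred, args.labels):
        if not Path(path).exists():
            raise SystemExit(f"input not found: {path}")

    cfg = merge_config(
        {
            "data": {
                "source": "files",
                "fasta": args.fasta,
                "phospho": args.phospho,
                "iupred": args.iupred,
                "labels": args.labels,
            },
            "train": {"protocol": args.protocol},
            "seed": args.seed,
        }
    )
    report = run_pipeline(cfg, args.out)
    print(
        "occurrence AUC {:.4f} | direction AUC {:.4f} | tri accuracy {:.4f}".format(
            report["occurrence"]["AUC"],
            report["direction"]["AUC"],
            report["hierarchical_tri"]["Accuracy"],
        )
    )
    print(f"full report: {args.out}/report.json")


if __name__ == "__main__":
    main()
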