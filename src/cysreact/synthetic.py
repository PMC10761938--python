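"""Synthetic proteomes with planted class structure.

The generator emulates the benchmark's observed signal so every pipeline
stage is testable without external data: flanks of decreased-reactivity
cysteines are enriched for proline/serine, disorder scores shift by class
(decreased high, increased low, unchanged intermediate), and phosphorylated
S/T residues sit close to changed sites but far from (or absent near)
unchanged sites.

Each effect size is a mixing weight in [0, 1]: with that probability the
class-specific distribution is used, otherwise a shared background — so 0
is exactly the null model and signal strength is monotone in the weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import (
    STANDARD_AA,
    CysteineSite,
    ProteinRecord,
    write_fasta,
    write_labels_tsv,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated benchmark.

    ``class_counts`` is (increased, decreased, unchanged); the default
    matches the benchmark's post-filter site counts. Effect sizes:
    ``ps_enrichment`` is the per-position probability that a decreased
    site's flank residue is replaced by P or S; ``disorder_shift`` and
    ``pdis_shift`` are the mixing weights toward the class-specific
    disorder-score and phospho-distance distributions.
    """

    class_counts: tuple[int, int, int] = (80, 290, 6357)
    length_min: int = 41
    length_max: int = 81
    ps_enrichment: float = 0.5
    disorder_shift: float = 1.0
    pdis_shift: float = 1.0
    flank: int = 10
    seed: int = 42
    #: Beta(a, b) disorder-score parameters by class
    disorder_betas: dict = field(
        default_factory=lambda: {-1: (5, 2), 1: (2, 5), 0: (2, 2)}
    )
    background_beta: tuple[float, float] = (2, 2)

    def validate(self) -> None:
        if any(c < 0 for c in self.class_counts) or sum(self.class_counts) == 0:
            raise ValueError("infeasible class counts")
        for e in (self.ps_enrichment, self.disorder_shift, self.pdis_shift):
            if not 0.0 <= e <= 1.0:
                raise ValueError("effect sizes must lie in [0, 1]")
        if self.length_min < 4 * self.flank + 1:
            raise ValueError("proteins too short for the flank size")


def _phospho_distance(label: int, cfg: SimulationConfig, rng) -> int | None:
    """Distance of the (single) phospho site from the cysteine, or None.

    Class-specific: changed sites get a nearby site (1 + Poisson(2)),
    unchanged sites get none half the time, otherwise a distant one.
    Background (weight 1 - pdis_shift): none half the time, else uniform.
    """
    far_lo, far_hi = 12, 2 * cfg.flank
    if rng.uniform() < cfg.pdis_shift:
        if label in (-1, 1):
            return 1 + int(rng.poisson(2))
        return None if rng.uniform() < 0.5 else int(rng.integers(far_lo, far_hi + 1))
    return None if rng.uniform() < 0.5 else int(rng.integers(1, far_hi + 1))


def simulate_proteome(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[dict[str, ProteinRecord], list[CysteineSite]]:
    """One protein per site, cysteine at the center, fully reproducible
    under ``config.seed``. Returns (records, labelled sites)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(STANDARD_AA))
    records: dict[str, ProteinRecord] = {}
    sites: list[CysteineSite] = []
    labels = np.concatenate(
        [
            np.full(config.class_counts[0], 1),
            np.full(config.class_counts[1], -1),
            np.full(config.class_counts[2], 0),
        ]
    )
    for i, label in enumerate(labels):
        pid = f"SYN{i:05d}"
        n = int(rng.integers(config.length_min, config.length_max + 1))
        seq = rng.choice(aa, size=n)
        center = n // 2 + 1  # 1-based
        seq[center - 1] = "C"

        # P/S flank enrichment for decreased-reactivity sites
        if label == -1 and config.ps_enrichment > 0:
            for off in range(-config.flank, config.flank + 1):
                if off == 0:
                    continue
                if rng.uniform() < config.ps_enrichment:
                    seq[center - 1 + off] = "P" if rng.uniform() < 0.5 else "S"

        # single phospho site at a class-dependent distance
        phospho: list[tuple[int, str]] = []
        d = _phospho_distance(int(label), config, rng)
        if d is not None:
            side = -1 if rng.uniform() < 0.5 else 1
            pos = center + side * d
            if not 1 <= pos <= n:
                pos = center - side * d
            res = "S" if rng.uniform() < 0.5 else "T"
            seq[pos - 1] = res
            phospho.append((pos, res))

        # per-residue disorder scores; site score drawn from the class Beta
        a0, b0 = config.background_beta
        iupred = {p: float(s) for p, s in enumerate(rng.beta(a0, b0, size=n), 1)}
        if rng.uniform() < config.disorder_shift:
            a, b = config.disorder_betas[int(label)]
        else:
            a, b = a0, b0
        iupred[center] = float(rng.beta(a, b))

        rec = ProteinRecord(pid, "".join(seq), phospho, iupred)
        records[pid] = rec
        sites.append(CysteineSite(pid, center, int(label)))
    return records, sites


def simulate_to_files(config: SimulationConfig, outdir) -> None:
    """Write the simulation in the same FASTA/TSV formats the ingestion
    layer reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, sites = simulate_proteome(config)
    write_fasta({pid: r.sequence for pid, r in records.items()}, outdir / "proteins.fasta")
    ph_rows, iu_rows = [], []
    for pid, rec in records.items():
        for pos, res in rec.phospho_sites:
            ph_rows.append({"protein_id": pid, "position": pos, "residue": res})
        for pos, score in rec.iupred.items():
            iu_rows.append({"protein_id": pid, "position": pos, "score": round(score, 4)})
    pd.DataFrame(ph_rows, columns=["protein_id", "position", "residue"]).to_csv(
        outdir / "phospho.tsv", sep="\t", index=False
    )
    pd.DataFrame(iu_rows, columns=["protein_id", "position", "score"]).to_csv(
        outdir / "iupred.tsv", sep="\t", index=False
    )
    write_labels_tsv(sites, outdir / "labels.tsv")


def make_golden_fixtures() -> tuple[dict[str, ProteinRecord], list[CysteineSite]]:
    """A small fixed dataset with hand-verifiable windows and P-dis values.

    Includes: a short protein whose window is mostly padding; a 41-mer with
    a pad-free window; a site with nearest phospho-S at distance 5 and
    phospho-T at distance 2 (P-dis = (0.2, 0.5, 0.5)); an unphosphorylated
    protein; plus a deterministic simulated batch to reach 20 proteins.
    """
    hand: list[ProteinRecord] = []
    hand.append(ProteinRecord("G01", "MCDEF", [], {2: 0.73}))
    seq2 = "A" * 20 + "C" + "A" * 20
    hand.append(ProteinRecord("G02", seq2, [], {21: 0.5}))
    # C at 10, phospho-S at 15, phospho-T at 12
    seq3 = list("A" * 20)
    seq3[9], seq3[14], seq3[11] = "C", "S", "T"
    hand.append(ProteinRecord("G03", "".join(seq3), [(15, "S"), (12, "T")], {10: 0.4}))
    seq4 = "GAVLICQNST" * 3
    hand.append(ProteinRecord("G04", seq4, [], {5: 0.1, 15: 0.2, 25: 0.3}))
    hand_sites = [
        CysteineSite("G01", 2, 0),
        CysteineSite("G02", 21, 1),
        CysteineSite("G03", 10, -1),
        CysteineSite("G04", 5, 0),
    ]
    sim_cfg = SimulationConfig(class_counts=(4, 6, 6), seed=7)
    sim_records, sim_sites = simulate_proteome(sim_cfg)
    records = {r.id: r for r in hand}
    records.update(sim_records)
    return records, hand_sites + sim_sites
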