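"""Sequence ingestion, cysteine-centered windows, redundancy filtering and
benchmark assembly.

All coordinates are 1-based and fully closed, following UniProt convention.
The unit of input is a :class:`ProteinRecord` — a sequence together with its
phosphorylation-site annotations and per-residue disorder (IUPRED) scores.
Classified instances are :class:`CysteineSite` objects keyed by
``(protein_id, position)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

#: the twenty standard amino acids, alphabetical one-letter order
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: pseudo amino acid used to pad windows that run off a sequence boundary
PAD = "X"

LABEL_NAMES = {-1: "decreased", 0: "unchanged", 1: "increased"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class ProteinRecord:
    """A protein sequence with phospho-site and disorder annotations.

    Parameters
    ----------
    id : str
        Accession (e.g. a UniProt id).
    sequence : str
        Amino-acid sequence; the 20 standard letters plus possibly
        nonstandard letters (U, B, Z, O, J ...).
    phospho_sites : list of (int, str)
        1-based positions of phosphorylated residues with their residue
        type, 'S' or 'T'.
    iupred : dict[int, float]
        1-based position -> disorder score in [0, 1]. May be sparse (only
        positions of interest).
    """

    id: str
    sequence: str
    phospho_sites: list[tuple[int, str]] = field(default_factory=list)
    iupred: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.sequence)
        for pos, res in self.phospho_sites:
            if not 1 <= pos <= n:
                raise ValueError(
                    f"{self.id}: phospho position {pos} outside 1..{n}"
                )
            if res not in ("S", "T"):
                raise ValueError(f"{self.id}: phospho residue {res!r} not S/T")
            if self.sequence[pos - 1] != res:
                raise ValueError(
                    f"{self.id}: sequence has {self.sequence[pos - 1]!r} at "
                    f"{pos}, annotation says {res!r}"
                )
        for pos, score in self.iupred.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{self.id}: IUPRED score {score} at {pos} outside [0,1]"
                )


@dataclass(frozen=True)
class CysteineSite:
    """A cysteine instance; ``label`` is -1 decreased / 0 unchanged / +1
    increased, or ``None`` for unlabeled sites (e.g. proteome scanning)."""

    protein_id: str
    position: int
    label: int | None = None

    @property
    def key(self) -> str:
        return f"{self.protein_id}:{self.position}"


@dataclass(frozen=True)
class Window:
    """A fixed-length peptide centered on a site, 'X'-padded at sequence
    boundaries."""

    peptide: str
    pad_char: str = PAD

    @property
    def length(self) -> int:
        return len(self.peptide)

    @property
    def center_offset(self) -> int:
        return (len(self.peptide) - 1) // 2

    @property
    def center(self) -> str:
        return self.peptide[self.center_offset]


def extract_window(record: ProteinRecord | str, position: int, length: int = 21) -> Window:
    """Extract the ``length``-mer centered at ``position`` (1-based).

    Positions falling outside the sequence are filled with the pad
    character 'X'. ``length`` must be odd so the site is exactly central.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if length < 3 or length % 2 == 0:
        raise ValueError(f"window length must be odd and >= 3, got {length}")
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside 1..{len(seq)}")
    flank = (length - 1) // 2
    lo, hi = position - flank, position + flank  # 1-based closed
    left_pad = max(0, 1 - lo)
    right_pad = max(0, hi - len(seq))
    core = seq[max(lo, 1) - 1 : min(hi, len(seq))]
    return Window(PAD * left_pad + core + PAD * right_pad)


@dataclass
class WindowScan:
    """Result of enumerating cysteine windows over one protein."""

    windows: list[tuple[int, Window]]
    n_dropped: int


def enumerate_cysteine_windows(
    record: ProteinRecord,
    length: int = 21,
    allowed_alphabet: frozenset[str] | set[str] = frozenset(STANDARD_AA),
) -> WindowScan:
    """One window per 'C' in the sequence; windows containing any residue
    outside ``allowed_alphabet`` ∪ {'X'} are dropped and counted.

    The drop rule mirrors proteome scanning, where peptides containing
    unusual amino acids (selenocysteine etc.) are discarded.
    """
    ok = set(allowed_alphabet) | {PAD}
    kept: list[tuple[int, Window]] = []
    dropped = 0
    for i, aa in enumerate(record.sequence, start=1):
        if aa != "C":
            continue
        w = extract_window(record, i, length)
        if set(w.peptide) <= ok:
            kept.append((i, w))
        else:
            dropped += 1
    return WindowScan(kept, dropped)


_aligner = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-0.5,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    if not a or not b:
        return 0.0
    aln = _aligner.align(a, b)[0]
    return aln.counts().identities / aln.length


def redundancy_filter(
    records: list[ProteinRecord], identity_threshold: float = 0.30
) -> list[ProteinRecord]:
    """Greedy longest-first redundancy removal.

    Records are visited longest first (ties broken by id); a record is
    dropped if its pairwise identity with any already-retained record
    exceeds ``identity_threshold``. This mirrors cd-hit's greedy ordering
    with an exact global alignment in place of its word heuristic.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    retained: list[ProteinRecord] = []
    for rec in order:
        if all(
            pairwise_identity(rec.sequence, kept.sequence) <= identity_threshold
            for kept in retained
        ):
            retained.append(rec)
    return retained


def assemble_benchmark(
    sites: list[CysteineSite], seed: int = 42
) -> list[CysteineSite]:
    """Balance changed vs unchanged by undersampling the unchanged pool.

    All changed sites (label +1 or -1) are kept; exactly as many unchanged
    sites are sampled uniformly without replacement. If the unchanged pool
    is smaller than the changed set, all unchanged sites are kept and a
    warning is issued.
    """
    changed = [s for s in sites if s.label in (-1, 1)]
    unchanged = [s for s in sites if s.label == 0]
    if not changed:
        raise ValueError("no changed (increased/decreased) sites in input")
    rng = np.random.default_rng(seed)
    if len(unchanged) < len(changed):
        warnings.warn(
            f"unchanged pool ({len(unchanged)}) smaller than changed set "
            f"({len(changed)}); keeping all unchanged sites"
        )
        sampled = list(unchanged)
    else:
        idx = rng.choice(len(unchanged), size=len(changed), replace=False)
        sampled = [unchanged[i] for i in sorted(idx)]
    return changed + sampled


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Multi-FASTA -> {id: sequence}; ids taken up to first whitespace."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_phospho_tsv(path) -> dict[str, list[tuple[int, str]]]:
    """TSV with header ``protein_id  position  residue``."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: dict[str, list[tuple[int, str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, []).append((int(row.position), row.residue))
    return out


def read_iupred_tsv(path) -> dict[str, dict[int, float]]:
    """TSV with header ``protein_id  position  score``."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: dict[str, dict[int, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, {})[int(row.position)] = float(row.score)
    return out


def read_labels_tsv(path) -> list[CysteineSite]:
    """TSV with header ``protein_id  position  label``; label is one of
    increased / decreased / unchanged."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    sites = []
    for row in df.itertuples(index=False):
        lab = str(row.label).strip().lower()
        if lab not in LABEL_CODES:
            raise ValueError(f"unknown label {row.label!r}")
        sites.append(CysteineSite(row.protein_id, int(row.position), LABEL_CODES[lab]))
    return sites


def write_labels_tsv(sites: list[CysteineSite], path) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in sites],
            "position": [s.position for s in sites],
            "label": [LABEL_NAMES[s.label] for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_records(fasta_path, phospho_path=None, iupred_path=None) -> dict[str, ProteinRecord]:
    """Assemble validated ProteinRecords from the three input files."""
    seqs = read_fasta(fasta_path)
    phospho = read_phospho_tsv(phospho_path) if phospho_path else {}
    iupred = read_iupred_tsv(iupred_path) if iupred_path else {}
    records = {}
    for pid, seq in seqs.items():
        rec = ProteinRecord(pid, seq, phospho.get(pid, []), iupred.get(pid, {}))
        rec.validate()
        records[pid] = rec
    return records


def export_benchmark_tsv(
    sites: list[CysteineSite],
    records: dict[str, ProteinRecord],
    path,
    length: int = 21,
) -> None:
    """One row per site: window peptide, annotations and label."""
    rows = []
    for s in sites:
        rec = records[s.protein_id]
        w = extract_window(rec, s.position, length)
        rows.append(
            {
                "protein_id": s.protein_id,
                "position": s.position,
                "peptide": w.peptide,
                "iupred": rec.iupred.get(s.position, np.nan),
                "label": LABEL_NAMES.get(s.label, "unlabeled"),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
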