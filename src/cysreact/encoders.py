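"""Feature encoders: turn a cysteine window plus its annotations into a
fixed-length named feature vector.

Six blocks are concatenated in a fixed order:

    [PSSM | CKSAAP | Atchley | EBGW | BLOSUM62 | P-dis | IUPRED]

Positional blocks (PSSM, Atchley, BLOSUM62) emit one sub-vector per window
position; the pad character 'X' encodes as zeros everywhere — it is an
information-free boundary marker, not a residue. CKSAAP counts k-spaced
ordered residue pairs; EBGW computes cumulative 1-fractions of the window
under three physicochemical binarizations. P-dis is the reciprocal distance
from the cysteine to its nearest phosphorylated S, T and S-or-T residue on
the whole protein (0 when none exists), and IUPRED is the supplied disorder
score of the cysteine itself, passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .seqdata import PAD, STANDARD_AA, CysteineSite, ProteinRecord, Window, extract_window

# Atchley et al. five-factor solution of amino-acid physicochemical variation
# (factor I polarity/hydrophobicity, II secondary structure, III size,
# IV codon composition, V charge).
ATCHLEY_FACTORS: dict[str, tuple[float, ...]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

# EBGW physicochemical classes: hydrophobic, polar, acidic, basic.
_HYDROPHOBIC = set("GAVLIMPFW")
_POLAR = set("QNSTYC")
_ACIDIC = set("DE")
_BASIC = set("HKR")
#: the three pairwise-union binary patterns
EBGW_GROUPS: tuple[frozenset[str], ...] = (
    frozenset(_HYDROPHOBIC | _POLAR),
    frozenset(_HYDROPHOBIC | _ACIDIC),
    frozenset(_HYDROPHOBIC | _BASIC),
)


@lru_cache(maxsize=1)
def _blosum62_rows() -> dict[str, np.ndarray]:
    """Per-residue BLOSUM62 row restricted to the 20 standard columns;
    'X' maps to a zero row."""
    m = substitution_matrices.load("BLOSUM62")
    rows = {
        aa: np.array([float(m[aa, b]) for b in STANDARD_AA]) for aa in STANDARD_AA
    }
    rows[PAD] = np.zeros(len(STANDARD_AA))
    return rows


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("values and names length mismatch")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


@dataclass(frozen=True)
class EncoderConfig:
    """Block hyperparameters; every dimension is derivable from here.

    Defaults: 21-mer windows, CKSAAP over gaps {0, 1} on the 21-letter
    alphabet (20 standard + the pad 'X', so boundary composition is visible
    to the model), EBGW with J = 5 nested prefixes, and PSSM in
    BLOSUM62-row fallback mode (a documented proxy; a supplied per-position
    profile may be used instead). Total default dimension:
    420 + 882 + 105 + 15 + 420 + 3 + 1 = 1846.
    """

    window_length: int = 21
    cksaap_gaps: tuple[int, ...] = (0, 1)
    cksaap_alphabet: str = STANDARD_AA + PAD
    ebgw_j: int = 5
    pssm_mode: str = "blosum-fallback"  # or "supplied-file"

    @property
    def offsets(self) -> list[int]:
        f = (self.window_length - 1) // 2
        return list(range(-f, f + 1))

    @property
    def block_dims(self) -> dict[str, int]:
        L = self.window_length
        return {
            "PSSM": L * 20,
            "CKSAAP": len(self.cksaap_gaps) * len(self.cksaap_alphabet) ** 2,
            "Atchley": L * 5,
            "EBGW": 3 * self.ebgw_j,
            "BLOSUM62": L * 20,
            "Pdis": 3,
            "IUPRED": 1,
        }

    @property
    def total_dim(self) -> int:
        return sum(self.block_dims.values())

    def feature_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for off in self.offsets:
            for aa in STANDARD_AA:
                names.append(f"PSSM_p{off:+d}_{aa}")
        for k in self.cksaap_gaps:
            for a in self.cksaap_alphabet:
                for b in self.cksaap_alphabet:
                    names.append(f"CKSAAP_k{k}_{a}{b}")
        for off in self.offsets:
            for j in range(1, 6):
                names.append(f"Atchley_p{off:+d}_f{j}")
        for h in range(1, 4):
            for j in range(1, self.ebgw_j + 1):
                names.append(f"EBGW_H{h}_j{j}")
        for off in self.offsets:
            for aa in STANDARD_AA:
                names.append(f"B62_p{off:+d}_{aa}")
        names += ["Pdis_S", "Pdis_T", "Pdis_ST", "IUPRED"]
        return tuple(names)


def _check_residues(window: Window) -> None:
    bad = set(window.peptide) - set(STANDARD_AA) - {PAD}
    if bad:
        raise ValueError(f"nonstandard residue(s) {sorted(bad)} in window")


def encode_blosum62(window: Window) -> np.ndarray:
    """Per position the residue's 20 BLOSUM62 substitution scores;
    'X' gives a zero row. Shape (L*20,)."""
    _check_residues(window)
    rows = _blosum62_rows()
    return np.concatenate([rows[aa] for aa in window.peptide])


def encode_atchley(window: Window) -> np.ndarray:
    """Per position the five Atchley factors; 'X' gives zeros. Shape (L*5,)."""
    _check_residues(window)
    zero = (0.0,) * 5
    return np.array(
        [v for aa in window.peptide for v in ATCHLEY_FACTORS.get(aa, zero)]
    )


def encode_cksaap(
    window: Window,
    gaps: tuple[int, ...] = (0, 1),
    alphabet: str = STANDARD_AA + PAD,
) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs.

    For each gap k and ordered pair (a, b): the count of positions i with
    window[i] == a and window[i+k+1] == b, divided by L-k-1 (the number of
    k-spaced pairs in the window). Pairs involving residues outside the
    alphabet contribute nothing.
    """
    L = window.length
    pep = window.peptide
    idx = {aa: i for i, aa in enumerate(alphabet)}
    A = len(alphabet)
    out = np.zeros(len(gaps) * A * A)
    for g, k in enumerate(gaps):
        n_pairs = L - k - 1
        if n_pairs <= 0:
            raise ValueError(f"window too short for gap {k}")
        base = g * A * A
        for i in range(n_pairs):
            a, b = pep[i], pep[i + k + 1]
            if a in idx and b in idx:
                out[base + idx[a] * A + idx[b]] += 1.0
        out[base : base + A * A] /= n_pairs
    return out


def encode_ebgw(window: Window, j_max: int = 5) -> np.ndarray:
    """Encoding based on grouped weight.

    Each of the three binary patterns maps the window to 0/1 (1 if the
    residue belongs to the pattern's group union, 'X' always 0); for
    j = 1..J the weight is the 1-fraction of the first floor(j*L/J)
    characters. Shape (3*J,).
    """
    L = window.length
    out = np.zeros(3 * j_max)
    for h, group in enumerate(EBGW_GROUPS):
        bits = np.array([1.0 if aa in group else 0.0 for aa in window.peptide])
        for j in range(1, j_max + 1):
            n = (j * L) // j_max
            out[h * j_max + j - 1] = bits[:n].sum() / n
    return out


def encode_pssm(
    window: Window,
    profile: np.ndarray | None = None,
    mode: str = "blosum-fallback",
) -> np.ndarray:
    """Position-specific scores for the window.

    ``supplied-file`` mode emits the given (L, 20) profile rows verbatim
    (rows aligned to window positions, 'X'-padded positions must be zero
    rows supplied by the caller or are zeroed here when the profile marks
    them NaN). ``blosum-fallback`` mode emits each residue's BLOSUM62 row —
    a substitution-matrix proxy usable without any sequence database.
    """
    if mode == "blosum-fallback":
        return encode_blosum62(window)
    if mode != "supplied-file":
        raise ValueError(f"unknown pssm mode {mode!r}")
    if profile is None:
        raise ValueError("pssm_mode='supplied-file' requires a profile")
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (window.length, 20):
        raise ValueError(
            f"profile shape {profile.shape} != ({window.length}, 20)"
        )
    profile = np.where(np.isnan(profile), 0.0, profile)
    return profile.reshape(-1)


def p_dis(site: CysteineSite, record: ProteinRecord) -> np.ndarray:
    """Reciprocal distance to the nearest phosphorylated S, T, and S-or-T.

    Distances are sequence-position differences on the whole protein; a
    missing site type gives 0 for that component. Components lie in [0, 1]
    with maximum 1 attained by an immediately adjacent phospho-residue.
    """
    dists = {"S": None, "T": None}
    for pos, res in record.phospho_sites:
        d = abs(site.position - pos)
        if d == 0:
            continue  # a phospho annotation on the cysteine position itself
        if dists[res] is None or d < dists[res]:
            dists[res] = d
    s = 1.0 / dists["S"] if dists["S"] else 0.0
    t = 1.0 / dists["T"] if dists["T"] else 0.0
    return np.array([s, t, max(s, t)])


def encode_site(
    site: CysteineSite,
    record: ProteinRecord,
    config: EncoderConfig = EncoderConfig(),
    pssm_profile: np.ndarray | None = None,
    impute_iupred: float | None = None,
) -> FeatureVector:
    """Full feature vector for one cysteine site.

    The IUPRED score of the site must be present in ``record.iupred``
    unless ``impute_iupred`` supplies a fallback value; the score is a
    top-ranked feature, so silent imputation is opt-in.
    """
    w = extract_window(record, site.position, config.window_length)
    iup = record.iupred.get(site.position, impute_iupred)
    if iup is None:
        raise ValueError(
            f"no IUPRED score for {site.key}; pass impute_iupred to allow"
        )
    blocks = [
        encode_pssm(w, pssm_profile, config.pssm_mode),
        encode_cksaap(w, config.cksaap_gaps, config.cksaap_alphabet),
        encode_atchley(w),
        encode_ebgw(w, config.ebgw_j),
        encode_blosum62(w),
        p_dis(site, record),
        np.array([iup]),
    ]
    values = np.concatenate(blocks)
    names = config.feature_names()
    if len(values) != len(names):
        raise AssertionError("block dimensions inconsistent with config")
    return FeatureVector(values, names)


def encode_dataset(
    sites: list[CysteineSite],
    records: dict[str, ProteinRecord],
    config: EncoderConfig = EncoderConfig(),
    impute_iupred: float | None = None,
) -> pd.DataFrame:
    """Feature matrix with one row per site, indexed by ``protein_id:position``."""
    names = config.feature_names()
    mat = np.empty((len(sites), len(names)))
    for i, s in enumerate(sites):
        mat[i] = encode_site(
            s, records[s.protein_id], config, impute_iupred=impute_iupred
        ).values
    return pd.DataFrame(mat, index=[s.key for s in sites], columns=list(names))


def labels_series(sites: list[CysteineSite]) -> pd.Series:
    return pd.Series([s.label for s in sites], index=[s.key for s in sites])


def write_feature_tsv(X: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index_label="site")


def read_feature_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")
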