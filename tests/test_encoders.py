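"""Feature encoders: published-table lookups, pair counting, grouped
weights, phospho proximity and the concatenated site vector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cysreact.encoders import (
    ATCHLEY_FACTORS,
    EncoderConfig,
    encode_atchley,
    encode_blosum62,
    encode_cksaap,
    encode_ebgw,
    encode_pssm,
    encode_site,
    p_dis,
    read_feature_tsv,
    write_feature_tsv,
    encode_dataset,
)
from cysreact.seqdata import STANDARD_AA, CysteineSite, ProteinRecord, Window

windows = st.text(alphabet=STANDARD_AA + "X", min_size=5, max_size=21).filter(
    lambda s: len(s) % 2 == 1
)


class TestBlosum62:
    def test_cysteine_self_score(self):
        v = encode_blosum62(Window("C" * 5))
        c_col = STANDARD_AA.index("C")
        assert v[0 * 20 + c_col] == 9  # published BLOSUM62 C-C entry

    def test_pad_is_zero_row(self):
        v = encode_blosum62(Window("XAX"))
        assert np.all(v[:20] == 0) and np.all(v[40:] == 0)
        assert np.any(v[20:40] != 0)

    def test_all_pad_window(self):
        assert np.all(encode_blosum62(Window("X" * 21)) == 0)
        assert encode_blosum62(Window("X" * 21)).shape == (420,)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            encode_blosum62(Window("AUC"))


class TestAtchley:
    def test_published_factor_values(self):
        v = encode_atchley(Window("A"))
        assert v[0] == pytest.approx(-0.591)
        assert tuple(v) == ATCHLEY_FACTORS["A"]

    def test_pad_is_zeros(self):
        assert np.all(encode_atchley(Window("X")) == 0)

    def test_dimension(self):
        assert encode_atchley(Window("A" * 21)).shape == (105,)


def cksaap_oracle(pep, gaps, alphabet):
    """Exhaustive enumeration of k-spaced pairs."""
    out = []
    for k in gaps:
        counts = {(a, b): 0 for a in alphabet for b in alphabet}
        n_pairs = len(pep) - k - 1
        for i in range(n_pairs):
            pair = (pep[i], pep[i + k + 1])
            if pair in counts:
                counts[pair] += 1
        out.extend(counts[(a, b)] / n_pairs for a in alphabet for b in alphabet)
    return np.array(out)


class TestCksaap:
    def test_adjacent_pairs_around_center(self):
        w = Window("A" * 10 + "C" + "A" * 10)
        v = encode_cksaap(w, gaps=(0,), alphabet=STANDARD_AA)
        A = len(STANDARD_AA)
        ai, ci = STANDARD_AA.index("A"), STANDARD_AA.index("C")
        assert v[ai * A + ai] == pytest.approx(18 / 20)
        assert v[ai * A + ci] == pytest.approx(1 / 20)
        assert v[ci * A + ai] == pytest.approx(1 / 20)
        assert v.sum() == pytest.approx(1.0)

    def test_gap_one_matches_oracle(self):
        w = Window("A" * 10 + "C" + "A" * 10)
        v = encode_cksaap(w, gaps=(1,), alphabet=STANDARD_AA)
        assert np.allclose(v, cksaap_oracle(w.peptide, (1,), STANDARD_AA))
        A = len(STANDARD_AA)
        ai = STANDARD_AA.index("A")
        assert v[ai * A + ai] == pytest.approx(17 / 19)

    def test_all_pad_window_alphabet_dependence(self):
        w = Window("X" * 21)
        with_x = encode_cksaap(w, gaps=(0,), alphabet=STANDARD_AA + "X")
        without_x = encode_cksaap(w, gaps=(0,), alphabet=STANDARD_AA)
        xi = (STANDARD_AA + "X").index("X")
        assert with_x[xi * 21 + xi] == pytest.approx(1.0)
        assert np.all(without_x == 0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(windows)
    def test_matches_exhaustive_enumeration(self, pep):
        w = Window(pep)
        v = encode_cksaap(w, gaps=(0, 1), alphabet=STANDARD_AA + "X")
        assert np.allclose(v, cksaap_oracle(pep, (0, 1), STANDARD_AA + "X"))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(windows)
    def test_block_sums_to_one_per_gap(self, pep):
        """With every character in the alphabet, counts/(L-k-1) sum to 1."""
        v = encode_cksaap(Window(pep), gaps=(0, 1), alphabet=STANDARD_AA + "X")
        A2 = 21 * 21
        assert v[:A2].sum() == pytest.approx(1.0)
        assert v[A2:].sum() == pytest.approx(1.0)


class TestEbgw:
    def test_hydrophobic_residue_all_ones(self):
        assert np.all(encode_ebgw(Window("G" * 21), 5) == 1.0)

    def test_all_pad_all_zero(self):
        assert np.all(encode_ebgw(Window("X" * 21), 5) == 0.0)

    def test_acidic_residue_pattern(self):
        v = encode_ebgw(Window("D" * 21), 5).reshape(3, 5)
        assert np.all(v[0] == 0) and np.all(v[1] == 1) and np.all(v[2] == 0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(windows)
    def test_weights_bounded_and_final_equals_global(self, pep):
        v = encode_ebgw(Window(pep), 5).reshape(3, 5)
        assert np.all((v >= 0) & (v <= 1))
        from cysreact.encoders import EBGW_GROUPS

        for h, group in enumerate(EBGW_GROUPS):
            frac = sum(c in group for c in pep) / len(pep)
            assert v[h, -1] == pytest.approx(frac)


class TestPssm:
    def test_fallback_equals_blosum(self):
        w = Window("ACDEF")
        assert np.array_equal(encode_pssm(w), encode_blosum62(w))

    def test_supplied_zero_profile(self):
        w = Window("ACDEF")
        assert np.all(encode_pssm(w, np.zeros((5, 20)), "supplied-file") == 0)

    def test_supplied_profile_passthrough(self):
        w = Window("ACDEF")
        prof = np.zeros((5, 20))
        prof[2] = np.arange(1, 21)
        v = encode_pssm(w, prof, "supplied-file")
        assert np.array_equal(v[40:60], np.arange(1, 21))

    def test_missing_profile_rejected(self):
        with pytest.raises(ValueError):
            encode_pssm(Window("ACDEF"), None, "supplied-file")


class TestPdis:
    def test_adjacent_site_reaches_maximum(self):
        rec = ProteinRecord("p", "CS", [(2, "S")])
        assert p_dis(CysteineSite("p", 1), rec)[0] == 1.0

    def test_no_phospho_sites_is_zero(self):
        rec = ProteinRecord("p", "ACDEF")
        assert np.all(p_dis(CysteineSite("p", 1), rec) == 0)

    def test_nearest_distances(self):
        seq = list("A" * 20)
        seq[9], seq[14], seq[11] = "C", "S", "T"
        rec = ProteinRecord("p", "".join(seq), [(15, "S"), (12, "T")])
        assert np.allclose(p_dis(CysteineSite("p", 10), rec), [0.2, 0.5, 0.5])

    def test_matches_brute_force_scan(self, rng):
        """S-or-T component = max of the components; all in [0,1]."""
        for _ in range(50):
            n = 40
            phospho = []
            seq = list("A" * n)
            cys = int(rng.integers(1, n + 1))
            seq[cys - 1] = "C"
            for _ in range(int(rng.integers(0, 5))):
                pos = int(rng.integers(1, n + 1))
                if pos == cys:
                    continue
                res = "S" if rng.uniform() < 0.5 else "T"
                seq[pos - 1] = res
                phospho.append((pos, res))
            # keep only the last annotation per position
            dedup = {}
            for pos, res in phospho:
                dedup[pos] = res
            phospho = [(p, r) for p, r in dedup.items()]
            rec = ProteinRecord("p", "".join(seq), phospho)
            v = p_dis(CysteineSite("p", cys), rec)
            by_type = {"S": [], "T": []}
            for pos, res in phospho:
                by_type[res].append(abs(pos - cys))
            exp_s = 1 / min(by_type["S"]) if by_type["S"] else 0.0
            exp_t = 1 / min(by_type["T"]) if by_type["T"] else 0.0
            assert np.allclose(v, [exp_s, exp_t, max(exp_s, exp_t)])
            assert np.all((v >= 0) & (v <= 1))
            assert v[2] >= v[0] and v[2] >= v[1]


class TestEncodeSite:
    def test_default_dimension(self, config):
        assert config.total_dim == 1846
        assert len(config.feature_names()) == 1846

    def test_iupred_passthrough_and_pdis_zero(self, golden, config):
        records, _ = golden
        fv = encode_site(CysteineSite("G01", 2, 0), records["G01"], config)
        s = fv.to_series()
        assert s["IUPRED"] == 0.73
        assert s["Pdis_S"] == 0 and s["Pdis_T"] == 0 and s["Pdis_ST"] == 0

    def test_missing_iupred_errors_unless_imputed(self):
        rec = ProteinRecord("p", "ACDEF")
        with pytest.raises(ValueError, match="IUPRED"):
            encode_site(CysteineSite("p", 2, 0), rec)
        fv = encode_site(CysteineSite("p", 2, 0), rec, impute_iupred=0.5)
        assert fv.to_series()["IUPRED"] == 0.5

    def test_deterministic(self, golden, config):
        records, _ = golden
        site = CysteineSite("G03", 10, -1)
        a = encode_site(site, records["G03"], config).values
        b = encode_site(site, records["G03"], config).values
        assert np.array_equal(a, b)

    def test_feature_names_round_trip_tsv(self, golden, config, tmp_path):
        records, sites = golden
        X = encode_dataset(sites[:4], records, config)
        write_feature_tsv(X, tmp_path / "X.tsv")
        X2 = read_feature_tsv(tmp_path / "X.tsv")
        assert list(X2.columns) == list(X.columns)
        assert np.allclose(X2.to_numpy(), X.to_numpy())
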