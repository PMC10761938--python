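"""Encode one cysteine site: window extraction, phospho proximity and the
full 1846-dimensional feature vector.

The protein below has its cysteine at position 10, a phosphorylated serine
at 15 (distance 5) and a phosphorylated threonine at 12 (distance 2), so
the P-dis triple is (1/5, 1/2, 1/2) — larger means a closer phospho site.
"""

from cysreact import CysteineSite, EncoderConfig, ProteinRecord, encode_site, extract_window, p_dis

seq = list("A" * 20)
seq[9], seq[14], seq[11] = "C", "S", "T"
record = ProteinRecord(
    "DEMO1", "".join(seq), phospho_sites=[(15, "S"), (12, "T")], iupred={10: 0.73}
)
site = CysteineSite("DEMO1", 10)

window = extract_window(record, site.position, 21)
print("21-mer window (X = boundary pad):", window.peptide)
print("P-dis (S, T, S-or-T):", p_dis(site, record))

config = EncoderConfig()
fv = encode_site(site, record, config)
print("total feature dimension:", len(fv.values))
print("block dimensions:", config.block_dims)
s = fv.to_series()
print("IUPRED passthrough:", s["IUPRED"], "| Pdis_T:", s["Pdis_T"])
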