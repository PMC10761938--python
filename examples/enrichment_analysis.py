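"""Positional residue enrichment between two groups of cysteine windows.

Simulates decreased- and unchanged-reactivity sites with proline/serine
enrichment planted in the decreased flanks, then tests, per flank position
and residue, whether the two groups differ (two-proportion z-test). Rows
with a positive difference are residues over-represented near
decreased-reactivity cysteines.
"""

from cysreact import positional_enrichment, extract_window, simulate_proteome
from cysreact.synthetic import SimulationConfig

records, sites = simulate_proteome(
    SimulationConfig(class_counts=(0, 200, 200), ps_enrichment=0.5, seed=3)
)
windows = {
    lab: [extract_window(records[s.protein_id], s.position, 21).peptide
          for s in sites if s.label == lab]
    for lab in (-1, 0)
}

df = positional_enrichment(windows[-1], windows[0])
top = df.sort_values("diff", ascending=False).head(8)
print("top enriched (position, residue, f_decreased - f_unchanged, p):")
for row in top.itertuples(index=False):
    print(f"  {row.position:+3d}  {row.residue}  {row.diff:+.3f}  p={row.p_value:.2e}")
n_sig = (df["p_bonferroni"] < 0.01).sum()
print(f"{n_sig} (position, residue) cells significant after Bonferroni")
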