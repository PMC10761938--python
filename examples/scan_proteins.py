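"""Proteome scanning: predict every cysteine of unseen proteins.

Trains a hierarchical model on a small simulated benchmark, then scans a
second, independently simulated protein set. Each cysteine window is
encoded and assigned P(changed), P(increased) and a tri-class label;
windows containing nonstandard residues would be dropped and counted.
"""

from cysreact import HierarchicalModel, HyperparameterProtocol, scan_proteome
from cysreact.encoders import encode_dataset, labels_series
from cysreact.models import train_binary
from cysreact.synthetic import SimulationConfig, simulate_proteome

records, sites = simulate_proteome(SimulationConfig(class_counts=(30, 70, 100), seed=1))
X = encode_dataset(sites, records)
y = labels_series(sites)
fast = HyperparameterProtocol.fast()
occ, _ = train_binary(X, (y != 0).astype(int), fast, seed=1)
mask = (y != 0).to_numpy()
dire, _ = train_binary(X[mask], (y[mask] == 1).astype(int), fast, seed=1)
model = HierarchicalModel(occ, dire, list(X.columns), list(X.columns))

new_records, _ = simulate_proteome(SimulationConfig(class_counts=(5, 10, 25), seed=99))
predictions, summary = scan_proteome(new_records, model)
print(predictions.head(5).to_string(index=False))
print("summary:", summary)
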