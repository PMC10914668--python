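"""Build a pKi affinity matrix from long-format Ki records.

Generates a small synthetic study, applies the inclusion filters (human
tissue only, median aggregation of replicate measurements, >=5 drugs per
receptor and >=5 receptors per drug, constant receptors dropped) and prints
the resulting drug x receptor pKi fingerprint matrix.
"""

import numpy as np

from aptaxa import build_affinity_matrix, filter_human
from aptaxa.synthetic import SyntheticConfig, generate

data = generate(SyntheticConfig(
    n_drugs=8, n_receptors=10, n_clusters=2, missing_rate=0.1,
    records_per_cell=3, seed=0,
))
print(f"{len(data.records)} Ki measurements "
      f"({data.config.records_per_cell} replicates per observed cell)")

human = filter_human(data.records)
affinity = build_affinity_matrix(human)
print(f"affinity matrix after filters: {affinity.shape[0]} drugs x "
      f"{affinity.shape[1]} receptors")
print(f"observed cells: {affinity.observed.sum()} "
      f"({affinity.observed.mean():.0%})")

# pKi = 9 - log10(Ki nM): higher pKi = tighter binding
obs = affinity.values[affinity.observed]
print(f"pKi range: {np.min(obs):.2f} .. {np.max(obs):.2f} "
      "(a pKi of 9 corresponds to Ki = 1 nM)")
print(affinity.to_frame().round(2).iloc[:5, :6])
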