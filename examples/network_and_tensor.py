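"""Build co-splicing networks from inclusion profiles and stack them.

Edge weights are Pearson correlations between exon inclusion-rate
profiles (negatives clamped to zero); the networks are then aligned on a
shared exon universe and stacked into a third-order tensor.
"""

import numpy as np
import pandas as pd

from cosplice import InclusionMatrix, assemble_tensor, correlation_network

rng = np.random.default_rng(0)
samples = [f"s{j}" for j in range(8)]

networks = []
for dataset in ("tissueA", "tissueB"):
    # exons e1..e3 share a splicing program (correlated rates); e4 is free
    driver = rng.uniform(0.2, 0.8, size=8)
    rows = {
        "e1": np.clip(driver + rng.normal(0, 0.03, 8), 0, 1),
        "e2": np.clip(driver + rng.normal(0, 0.03, 8), 0, 1),
        "e3": np.clip(driver + rng.normal(0, 0.05, 8), 0, 1),
        "e4": rng.uniform(0, 1, 8),
    }
    values = pd.DataFrame(rows, index=samples).T
    profiles = InclusionMatrix(values, pd.Series("G", index=values.index, dtype=object))
    networks.append(correlation_network(profiles, dataset_id=dataset))

tensor = assemble_tensor(networks)
print(f"tensor: {tensor.n_nodes} exons x {tensor.n_nodes} x {tensor.n_networks} networks")
for k, net_id in enumerate(tensor.network_ids):
    print(f"\n{net_id} edge weights:")
    print(pd.DataFrame(tensor.weights[k], index=tensor.node_ids,
                       columns=tensor.node_ids).round(2).to_string())

print(
    "\nThe e1-e2-e3 block is heavy (correlations near 1) in both datasets -"
    " the signature a frequent co-splicing cluster leaves in the tensor -"
    " while e4's edges stay near zero."
)
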