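"""Generate the synthetic tick/vole study dataset.

Draws the default study design — 228/73 ticks and 177/92 voles in
forest/ecotone, 126 bacterial genera organised in co-circulating packets —
and writes reads.tsv, tree.nwk and ground_truth.json under results/data/.
"""

import sys

from micronet.synthetic_data import SimConfig, simulate_read_matrix, write_outputs

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1

cfg = SimConfig(seed=seed)
sim = simulate_read_matrix(cfg)
write_outputs(sim, "results/data")

m = sim.read_matrix
richness = (m.counts > 0).sum(axis=1)
print(f"samples: {len(m.sample_ids)}  genera: {len(m.taxa)}")
for carrier in ("tick", "vole"):
    idx = m.meta["carrier"] == carrier
    print(f"mean genera per {carrier}: {richness[idx].mean():.2f} "
          f"(min {richness[idx].min()}, max {richness[idx].max()})")
print("wrote results/data/{reads.tsv, tree.nwk, ground_truth.json}")
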