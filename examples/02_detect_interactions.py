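"""Detect directed species interactions in a simulated survey.

Converts reads to eDNA copies via the spike-in, standardizes the merged
series, and scans every ordered species pair for conditional transfer
entropy, printing the statistically clear edges next to the simulator's
true interaction matrix.
"""
import numpy as np

from edmnet import (
    all_pairs,
    reads_to_copies,
    select_top_species,
    simulate_dataset,
    standardize_merge,
)

from edmnet.simulate import make_params

params = make_params(6, connectance=0.2, seed=11,
                     interaction_range=(0.25, 0.4))
df, truth = simulate_dataset(n_species=6, n_sites=3, n_steps=48,
                             params=params, seed=11)
quant = reads_to_copies(df, spike_species="sp00",
                        min_spike_copies="auto", min_spike_reads="auto")
species = select_top_species(quant, 6)
panel = standardize_merge(quant, species)

iset = all_pairs(panel, species, n_boot=200, seed=1)
frame = iset.to_frame()
clear = frame[frame["clear"]].sort_values("te", ascending=False)
print(clear[["cause", "effect", "tp", "E", "te", "p_value"]].to_string(index=False))

a = truth["params"].interaction
names = truth["species_names"]
true_edges = {(names[j], names[i]) for i in range(len(names))
              for j in range(len(names)) if i != j and a[i, j] != 0}
found = {(r.cause, r.effect) for r in iset.clear_edges()}
print(f"\ntrue directed links: {sorted(true_edges)}")
print(f"recovered: {len(found & true_edges)}/{len(true_edges)} true, "
      f"{len(found - true_edges)} extra")
print("te is the information flow (nats/point) from cause to effect at the "
      "retained causal lag tp; p is rotation-null clarity.")
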