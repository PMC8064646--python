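"""Choosing the number of latent states.

Two routes are compared on data with a known k = 4: the individual-HMM
within/between pattern-similarity criterion and the group-HMM BIC curve.
(Smaller than the defaults to keep the demo quick.)
"""

import statesync as ss

ds, truth = ss.simulate_state_dataset(n_subjects=10, T=400, V=50, k=4, seed=9)

sel_i = ss.select_k_individual(ds, k_range=(2, 6), seed=0)
print("individual-HMM criterion (within - between pattern similarity):")
print(sel_i.table.round(3).to_string(index=False))
print(f"selected k = {sel_i.k_best} (true k = {truth.k_true})")

sel_g = ss.select_k_group(ds, k_range=(2, 6), seed=0)
print("\ngroup-HMM BIC curve:")
print(sel_g.table.round(1).to_string(index=False))
print(f"selected k = {sel_g.k_best} at the BIC minimum")
print("  -> both criteria peak where the generating process has its true")
print("     number of states.")
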