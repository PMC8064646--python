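"""Group-HMM state segmentation, cross-subject alignment and concordance.

Fits one hidden Markov model to all subjects (stacked PCA space, subjects as
independent sequences), decodes each subject's state path, aligns decoded
states to the generating truth with the Hungarian algorithm, and computes
the concordance series — the proportion of subjects in each state at each TR.
"""

import numpy as np

import statesync as ss

ds, truth = ss.simulate_state_dataset(
    n_subjects=20, T=500, V=60, k=4, event_windows=[(200, 240, 3)], seed=2,
)

rts = ss.pca_reduce(ds, var_threshold=0.90, scope="stacked")
print(f"stacked PCA kept f={rts.f} components ({rts.var_explained:.1%} variance)")

model = ss.fit_hmm_em(rts, k=4, seed=0, n_init=2)
paths = ss.decode_sequences(model, rts)

# align decoded states to the ground-truth emissions (voxel space)
patterns = ss.backproject_state_patterns(model, rts)
zs = [ss.zscore_within_subject(s) for s in ds.subjects]
truth_z = np.stack([
    np.vstack([z.data[truth.state_paths_true[i] == s + 1] for i, z in enumerate(zs)]).mean(0)
    for s in range(4)
])
align = ss.align_states([patterns], reference_patterns=truth_z)
mapping = align.mappings[0]
acc = np.mean([
    (ss.relabel_path(p, mapping).labels == truth.state_paths_true[i]).mean()
    for i, p in enumerate(paths)
])
print(f"Viterbi label accuracy after Hungarian alignment: {acc:.1%}")
print(f"mean matched emission-pattern correlation: {align.mean_within:.3f}")

conc = ss.concordance([ss.relabel_path(p, mapping) for p in paths], k=4)
forced = conc.c[2, 200:240].mean()  # state 3, inside the forced window
baseline = np.r_[conc.c[2, :200], conc.c[2, 240:]].mean()
print(f"concordance of state 3: {forced:.2f} inside the event window, "
      f"{baseline:.2f} elsewhere")
print("  -> subjects land in the same state exactly when the event occurs;")
print("     otherwise states are shared but expressed on private schedules.")
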