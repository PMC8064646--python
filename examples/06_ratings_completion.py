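"""Completing sparsely sampled emotion ratings by collaborative filtering.

Subjects rate their feelings only at a dozen random pauses across a ~45-min
stimulus.  Boxcar dilation spreads each rating over a 60-s window (averaging
overlaps), and nonnegative matrix factorization trained by SGD on the
observed cells predicts every unobserved second.
"""

import numpy as np

import statesync as ss

ratings, truth = ss.simulate_sparse_ratings(
    n_subjects=50, duration_s=2702, rank=2, seed=6,
)
sparse = ratings[0]
print(f"observed fraction before dilation: {sparse.mask.mean():.1%}")

dilated = ss.boxcar_dilate(sparse, width_s=60)
print(f"observed fraction after 60-s dilation: {dilated.mask.mean():.1%}")

model = ss.fit_nmf_sgd(dilated, n_factors=2, n_iter=100, seed=0)
completed = ss.predict_complete(model)

holdout = ~dilated.mask  # cells never observed, even after dilation
res = ss.holdout_eval(model, truth[0], holdout)
print(f"held-out cells: {res.n_cells}, RMSE = {res.rmse:.3f}, "
      f"correlation = {res.correlation:.3f}")
print("  -> two nonnegative factors reconstruct each subject's full rating")
print("     time course from ~12 sparse self-reports.")
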