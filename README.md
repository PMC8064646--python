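# statesync

Tools for finding shared structure in multi-subject neural time series whose
raw signals look entirely idiosyncratic.  In transmodal cortex (e.g.
ventromedial prefrontal cortex) different people watching the same
naturalistic stimulus show almost no intersubject correlation in either
their regional time courses or their instantaneous voxel patterns — yet
they may still visit a *common repertoire of latent states*, each on their
own schedule, converging only at emotionally salient events.  `statesync`
implements the full analysis chain for testing that hypothesis, exercisable
end to end on synthetic data with known ground truth.

## What it computes

**Intersubject correlation (ISC).**  All pairwise Pearson correlations
between subjects are Fisher-averaged:

    ISC = R( 2/(N²−N) · Σᵢ Σ_{j<i} Z(corr(Sᵢ, Sⱼ)) ),   Z(r) = atanh(r)

in three flavors — temporal (mean regional time courses), spatial
(multivoxel patterns at each TR, giving an instantaneous synchrony series),
and spatiotemporal (vectorized lower triangles of each subject's T × T
pattern-recurrence matrix).  Inference: subject-wise bootstrap (resample
subjects with replacement, drop same-subject pairings) and a paired
sign permutation test with Benjamini–Hochberg FDR across parcels.

**Recurrence and time scales.**  Per-subject recurrence matrices, cell-wise
group t-tests with FDR, per-voxel and pattern autocorrelation functions
summarized by a robust three-parameter exponential fit
`α·exp(−βx) + c`, and the analytic lag at which the fitted curve crosses a
threshold (0.1 by default) — the region's intrinsic time scale.

**Hidden Markov state segmentation.**  Diagonal-covariance Gaussian HMMs on
PCA-reduced series (components retaining 90% variance), fitted per subject
or once for the whole group with subjects as independent sequences; Viterbi
decoding; Hungarian matching of state patterns across subjects; model
selection by cross-subject within/between pattern similarity (individual)
or the BIC curve, `BIC = ln(n)(k² + 2kf − 1) − 2·loglik` (group);
state-concordance time series; circle-shift permutation tests; voxel-wise
state-occupancy contrasts with FDR.

**Shared response modelling (SRM).**  Deterministic alternating
minimization of `Σᵢ ‖Xᵢ − Wᵢ S‖²` with orthonormal per-dataset transforms,
strict fit/transform separation for functional alignment, and a
cross-experiment variant linking state concordances, facial action units
and emotion ratings in one latent space.

**Collaborative filtering of sparse ratings.**  Emotion ratings collected at
~12 random pauses over a 45-minute stimulus are completed by dilating each
rating over a 60-s boxcar window (overlaps average) and factorizing the
observed cells with nonnegative matrix factorization trained by stochastic
gradient descent.

## Worked example

```python
import numpy as np
import statesync as ss

# subjects share 4 latent states but express them on private schedules,
# except inside a forced "event" window (TRs 200-240, state 3)
ds, truth = ss.simulate_state_dataset(
    n_subjects=20, T=500, V=60, k=4, event_windows=[(200, 240, 3)], seed=2)

print(f"temporal ISC = {ss.temporal_isc(ds).isc:.3f}")

rts = ss.pca_reduce(ds, var_threshold=0.90, scope="stacked")
model = ss.fit_hmm_em(rts, k=4, seed=0, n_init=2)
paths = ss.decode_sequences(model, rts)
conc = ss.concordance(paths, k=4)
```

Running `examples/03_hmm_state_segmentation.py` (this script, with the
alignment steps included) prints:

```
stacked PCA kept f=45 components (90.2% variance)
Viterbi label accuracy after Hungarian alignment: 100.0%
mean matched emission-pattern correlation: 1.000
concordance of state 3: 1.00 inside the event window, 0.27 elsewhere
```

Temporal ISC is near zero — subjects' mean time courses do not line up —
yet the group HMM recovers every subject's latent state sequence, and the
concordance series spikes to 1.0 exactly where the event forces a common
state, mirroring how affectively salient scenes momentarily synchronize
otherwise idiosyncratic state dynamics.  The other scripts in `examples/`
walk through ISC flavors, autocorrelation time scales, model selection,
SRM alignment, rating completion, and the cross-experiment latent space.

A thin CLI orchestrates the same functions
(`statesync run --config examples/demo_pipeline.yaml --out out/`);
identical config and seed give byte-identical outputs.

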