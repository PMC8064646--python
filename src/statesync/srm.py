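"""Deterministic shared response modelling (SRM) for functional alignment.

The SRM factorizes a set of feature-by-time matrices ``X_i`` (one per
subject, or one per study) as ``X_i ~ W_i S`` with per-dataset orthonormal
transforms ``W_i`` and a single shared response ``S``.  Fitting alternates
exact updates:

* ``W_i``: orthogonal Procrustes, ``W_i = U V^T`` from the SVD of
  ``X_i S^T``;
* ``S``: the average of the back-rotated data, ``mean_i(W_i^T X_i)``,

which never increases the summed squared reconstruction error.  Transforms
fitted on one dataset (e.g. one viewing episode) can be applied to held-out
data from another, keeping alignment estimation strictly independent of any
downstream statistic.

The same machinery links heterogeneous experiments: concordance, facial
action-unit and emotion-rating time series are resampled to a common grid,
z-scored per feature, and jointly factorized into a small shared latent
space whose per-study backprojections make each component interpretable in
each study's native feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SRMModel",
    "CrossExperimentLatent",
    "fit_srm",
    "srm_transform",
    "resample_series",
    "cross_experiment_latent",
]


@dataclass
class SRMModel:
    d: int
    transforms: list[np.ndarray]  # per-dataset (V_i, d), orthonormal columns
    shared: np.ndarray  # (d, T)
    train_error: float
    n_iter: int
    error_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _objective(datasets, transforms, shared) -> float:
    return float(sum(np.sum((x - w @ shared) ** 2) for x, w in zip(datasets, transforms)))


def fit_srm(
    datasets: list[np.ndarray],
    d: int,
    n_iter: int = 30,
    seed: int = 0,
    tol: float = 1e-8,
) -> SRMModel:
    """Alternating-minimization fit of the deterministic SRM.

    ``datasets`` are feature-by-time matrices sharing the time axis.  The
    shared response is initialized from the first dataset's top-``d``
    principal scores (deterministic up to sign, which the iterations absorb).
    The objective ``sum_i ||X_i - W_i S||^2`` is non-increasing across
    iterations; fitting stops early when the decrease falls below ``tol``.
    """
    datasets = [np.asarray(x, dtype=np.float64) for x in datasets]
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    T = datasets[0].shape[1]
    for i, x in enumerate(datasets):
        if x.ndim != 2 or x.shape[1] != T:
            raise ValueError(f"dataset {i} has shape {x.shape}; expected (*, {T})")
        if d > x.shape[0]:
            raise ValueError(
                f"d={d} exceeds the {x.shape[0]} features of dataset {i}"
            )
    if d > T:
        raise ValueError(f"d={d} exceeds the number of time points T={T}")

    # init: top-d left singular vectors of the first dataset -> S = U_d^T X_0
    u, _, _ = np.linalg.svd(datasets[0], full_matrices=False)
    shared = u[:, :d].T @ datasets[0]

    transforms = [np.zeros((x.shape[0], d)) for x in datasets]
    trace = []
    prev = np.inf
    it = 0
    for it in range(1, n_iter + 1):
        for i, x in enumerate(datasets):
            u, _, vt = np.linalg.svd(x @ shared.T, full_matrices=False)
            transforms[i] = u @ vt
        shared = np.mean([w.T @ x for w, x in zip(transforms, datasets)], axis=0)
        err = _objective(datasets, transforms, shared)
        trace.append(err)
        if prev - err < tol:
            break
        prev = err
    return SRMModel(
        d=d,
        transforms=transforms,
        shared=shared,
        train_error=trace[-1],
        n_iter=it,
        error_trace=np.asarray(trace),
    )


def srm_transform(X_new: np.ndarray, transform: np.ndarray) -> np.ndarray:
    """Project new feature-by-time data into the shared space: ``W^T X``.

    Strict fit/transform separation: transforms learned on one dataset or
    episode apply unchanged to any other with the same feature set.
    """
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.shape[0] != transform.shape[0]:
        raise ValueError(
            f"data has {X_new.shape[0]} features but transform expects "
            f"{transform.shape[0]}"
        )
    return transform.T @ X_new


def resample_series(series: np.ndarray, new_T: int) -> np.ndarray:
    """Linearly interpolate a feature-by-time matrix onto ``new_T`` samples."""
    series = np.asarray(series, dtype=np.float64)
    old_T = series.shape[1]
    old_x = np.linspace(0.0, 1.0, old_T)
    new_x = np.linspace(0.0, 1.0, new_T)
    return np.stack([np.interp(new_x, old_x, row) for row in series])


@dataclass
class CrossExperimentLatent:
    latent: np.ndarray  # (d, T)
    transforms: list[np.ndarray]
    backprojections: list[np.ndarray]  # per study: (features, d) loadings
    component_isc: np.ndarray  # (d,) cross-study temporal ISC per component
    model: SRMModel


def cross_experiment_latent(
    series: list[np.ndarray],
    d: int,
    common_T: int | None = None,
    zscore: bool = True,
    seed: int = 0,
    n_iter: int = 100,
) -> CrossExperimentLatent:
    """Shared latent space across heterogeneous experiments.

    Each entry of ``series`` is a feature-by-time matrix from one study
    (e.g. state concordances, action-unit intensities, completed emotion
    ratings).  Series are linearly resampled to a common length (the
    shortest by default), z-scored per feature, and jointly factorized with
    :func:`fit_srm`.  The per-study transform columns are the loadings of
    each latent component in that study's native feature space, and
    ``component_isc`` reports the Fisher-averaged cross-study temporal ISC
    of each component's projected time course.
    """
    from .isc import fisher_z, inverse_fisher_z

    if len(series) < 2:
        raise ValueError("cross-experiment alignment needs at least 2 series")
    series = [np.asarray(x, dtype=np.float64) for x in series]
    if common_T is None:
        common_T = min(x.shape[1] for x in series)
    resampled = [resample_series(x, common_T) for x in series]
    if zscore:
        normed = []
        for x in resampled:
            sd = x.std(axis=1, keepdims=True)
            normed.append((x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd))
        resampled = normed
    model = fit_srm(resampled, d=d, n_iter=n_iter, seed=seed)
    projections = np.stack(
        [srm_transform(x, w) for x, w in zip(resampled, model.transforms)]
    )  # (n_studies, d, T)
    n_studies = projections.shape[0]
    comp_isc = np.empty(d)
    iu = np.tril_indices(n_studies, k=-1)
    for c in range(d):
        comps = projections[:, c, :]
        sd = comps.std(axis=1)
        if np.any(sd == 0):
            comp_isc[c] = np.nan
            continue
        r = np.corrcoef(comps)[iu]
        comp_isc[c] = inverse_fisher_z(
            np.mean(fisher_z(np.clip(r, -1, 1), clip=True))
        )
    return CrossExperimentLatent(
        latent=model.shared,
        transforms=model.transforms,
        backprojections=model.transforms,
        component_isc=comp_isc,
        model=model,
    )
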