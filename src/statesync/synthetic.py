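"""Ground-truth-known generators for every downstream analysis stage.

Each generator is a pure function of its seed.  The flagship generator,
:func:`simulate_state_dataset`, emulates the latent-state structure the state
segmentation machinery assumes: every subject follows an independent
first-order Markov chain over ``k`` hidden states; a state emits its mean
voxel pattern plus temporally autocorrelated (AR(1)) Gaussian noise; optional
event windows force all subjects into a common state, mimicking moments of a
naturalistic stimulus that momentarily synchronize otherwise idiosyncratic
state sequences.

Defaults mirror the regime the analyses are designed for: long-dwelling
states (sticky transitions), state mean patterns drawn i.i.d. N(0, 1) per
voxel — mutually near-orthogonal and near-equidistant in voxel space — and
noise of the same marginal scale as the patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import Dataset, SubjectTimeSeries

__all__ = [
    "GroundTruth",
    "default_transition_matrix",
    "simulate_state_dataset",
    "simulate_ar1_dataset",
    "simulate_srm_dataset",
    "simulate_sparse_ratings",
]


@dataclass
class GroundTruth:
    """The generating parameters and latent draws behind a synthetic dataset.

    State labels are 1-based, matching how decoded paths are reported.
    """

    k_true: int
    trans_true: np.ndarray  # (k, k) row-stochastic
    start_true: np.ndarray  # (k,) simplex
    emissions_true: np.ndarray  # (k, V) state mean patterns
    state_paths_true: np.ndarray  # (N, T) ints in 1..k
    event_windows: list[tuple[int, int, int]]
    noise_sd: float
    ar1_rho: float
    seed: int

    def __post_init__(self) -> None:
        k = self.k_true
        if self.trans_true.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if np.max(np.abs(self.trans_true.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition rows must sum to 1")
        if abs(self.start_true.sum() - 1.0) > 1e-12:
            raise ValueError("start distribution must sum to 1")
        if self.emissions_true.shape[0] != k:
            raise ValueError(
                f"emissions has {self.emissions_true.shape[0]} rows but k={k}"
            )
        if self.state_paths_true.size and (
            self.state_paths_true.min() < 1 or self.state_paths_true.max() > k
        ):
            raise ValueError("state labels must lie in 1..k")
        T = self.state_paths_true.shape[1]
        for start, end, forced in self.event_windows:
            if not (0 <= start < end <= T):
                raise ValueError(f"event window [{start}, {end}) outside [0, {T})")
            if not (1 <= forced <= k):
                raise ValueError(f"forced state {forced} outside 1..{k}")


def default_transition_matrix(k: int, stay: float = 0.9) -> np.ndarray:
    """Sticky row-stochastic matrix: P(stay) = ``stay``, rest uniform."""
    if k == 1:
        return np.ones((1, 1))
    off = (1.0 - stay) / (k - 1)
    trans = np.full((k, k), off)
    np.fill_diagonal(trans, stay)
    return trans


def _ar1_noise(rng: np.random.Generator, T: int, V: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise per voxel with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros((T, V))
    white = rng.standard_normal((T, V))
    out = np.empty((T, V))
    out[0] = white[0]  # stationary start: marginal variance 1
    innov_sd = np.sqrt(1.0 - rho**2)
    for t in range(1, T):
        out[t] = rho * out[t - 1] + innov_sd * white[t]
    return sd * out


def _sample_chain(
    rng: np.random.Generator, T: int, start: np.ndarray, trans: np.ndarray
) -> np.ndarray:
    """One Markov path (0-based labels) via the inverse-CDF method."""
    k = len(start)
    cdf_start = np.cumsum(start)
    cdf_trans = np.cumsum(trans, axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=np.int64)
    path[0] = np.searchsorted(cdf_start, u[0])
    for t in range(1, T):
        path[t] = np.searchsorted(cdf_trans[path[t - 1]], u[t])
    return np.minimum(path, k - 1)


def simulate_state_dataset(
    n_subjects: int = 20,
    T: int = 500,
    V: int = 60,
    k: int = 4,
    trans: np.ndarray | None = None,
    start: np.ndarray | None = None,
    emissions: np.ndarray | None = None,
    emission_scale: float = 1.0,
    noise_sd: float = 1.0,
    ar1_rho: float = 0.3,
    event_windows: list[tuple[int, int, int]] | None = None,
    seed: int = 0,
    tr_seconds: float = 2.0,
    study_label: str = "synthetic_states",
) -> tuple[Dataset, GroundTruth]:
    """Shared-emission Markov state process with subject-specific sequences.

    Each subject draws an independent state path from ``(start, trans)``;
    inside each ``(start_tr, end_tr, forced_state)`` event window every
    subject is forced into ``forced_state`` (1-based), after which the chain
    resumes from that state.  The observation at TR ``t`` is the emission
    pattern of the current state plus AR(1)-filtered Gaussian noise with
    marginal SD ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    if trans is None:
        trans = default_transition_matrix(k)
    trans = np.asarray(trans, dtype=np.float64)
    if start is None:
        start = np.full(k, 1.0 / k)
    start = np.asarray(start, dtype=np.float64)
    if emissions is None:
        emissions = emission_scale * rng.standard_normal((k, V))
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.shape != (k, V):
        raise ValueError(f"emissions shape {emissions.shape} does not match (k={k}, V={V})")
    event_windows = sorted(tuple(int(x) for x in w) for w in (event_windows or []))

    paths = np.empty((n_subjects, T), dtype=np.int64)
    subjects = []
    for i in range(n_subjects):
        path = _sample_chain(rng, T, start, trans)
        for w_start, w_end, forced in event_windows:
            path[w_start:w_end] = forced - 1
            # re-draw the post-window continuation so the chain resumes from
            # the forced state rather than the overwritten pre-window draw
            if w_end < T:
                path[w_end:] = _sample_chain(
                    rng, T - w_end + 1, np.eye(k)[forced - 1], trans
                )[1:]
        paths[i] = path + 1
        noise = _ar1_noise(rng, T, V, ar1_rho, noise_sd)
        data = emissions[path] + noise
        subjects.append(
            SubjectTimeSeries(
                subject_id=f"sub-{i:03d}", data=data, tr_seconds=tr_seconds,
                roi_name="synthetic_roi",
            )
        )
    truth = GroundTruth(
        k_true=k, trans_true=trans, start_true=start, emissions_true=emissions,
        state_paths_true=paths, event_windows=list(event_windows),
        noise_sd=noise_sd, ar1_rho=ar1_rho, seed=seed,
    )
    return Dataset(subjects=subjects, study_label=study_label), truth


def simulate_ar1_dataset(
    n_subjects: int = 1,
    T: int = 2000,
    V: int = 50,
    rho: float = 0.8,
    seed: int = 0,
    tr_seconds: float = 2.0,
) -> Dataset:
    """Stationary AR(1) voxel series with unit marginal variance."""
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    subjects = [
        SubjectTimeSeries(
            subject_id=f"sub-{i:03d}",
            data=_ar1_noise(rng, T, V, rho, 1.0),
            tr_seconds=tr_seconds,
            roi_name="ar1_roi",
        )
        for i in range(n_subjects)
    ]
    return Dataset(subjects=subjects, study_label="synthetic_ar1")


def simulate_srm_dataset(
    n_subjects: int = 10,
    T: int = 200,
    V: int = 50,
    d: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    tr_seconds: float = 2.0,
) -> tuple[Dataset, np.ndarray, list[np.ndarray]]:
    """Data generated by the shared response model: ``X_i = W_i S + noise``.

    Returns the dataset (each subject stored as a ``T x V`` matrix, i.e. the
    transpose of ``X_i``), the shared response ``S`` (``d x T``) and the true
    per-subject orthonormal transforms ``W_i`` (``V x d``).
    """
    if d > V:
        raise ValueError(f"latent dimension d={d} exceeds voxel count V={V}")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((d, T))
    transforms = []
    subjects = []
    for i in range(n_subjects):
        w, _ = np.linalg.qr(rng.standard_normal((V, d)))
        transforms.append(w)
        x = w @ shared
        if noise_sd > 0:
            x = x + noise_sd * rng.standard_normal((V, T))
        subjects.append(
            SubjectTimeSeries(
                subject_id=f"sub-{i:03d}", data=x.T, tr_seconds=tr_seconds,
                roi_name="srm_roi",
            )
        )
    return Dataset(subjects=subjects, study_label="synthetic_srm"), shared, transforms


def pause_schedule(
    rng: np.random.Generator,
    duration_s: float,
    first_window: tuple[float, float] = (30.0, 270.0),
    gap_window: tuple[float, float] = (200.0, 280.0),
) -> np.ndarray:
    """Random rating-pause times: an initial uninterrupted period drawn
    uniformly from ``first_window`` seconds, then inter-pause gaps uniform on
    ``gap_window`` seconds, truncated at ``duration_s``."""
    times = []
    t = rng.uniform(*first_window)
    while t < duration_s:
        times.append(t)
        t += rng.uniform(*gap_window)
    return np.asarray(times)


def _smooth_nonneg_basis(rng: np.random.Generator, rank: int, T: int) -> np.ndarray:
    """Rank smooth nonnegative temporal components in [0, 1], shape (rank, T)."""
    t = np.linspace(0, 1, T)
    basis = np.empty((rank, T))
    for r in range(rank):
        curve = np.zeros(T)
        for _ in range(3):  # few slow sinusoids => smooth on the minute scale
            freq = rng.uniform(0.5, 4.0)
            phase = rng.uniform(0, 2 * np.pi)
            curve += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * freq * t + phase)
        curve -= curve.min()
        peak = curve.max()
        basis[r] = curve / peak if peak > 0 else curve
    return basis


def simulate_sparse_ratings(
    n_subjects: int = 50,
    duration_s: int = 2702,
    n_dims: int = 1,
    rank: int = 2,
    observed_schedule="random_pauses",
    seed: int = 0,
    scale_max: float = 5.0,
):
    """Sparse nonnegative subject-by-time rating matrices on a 1-Hz grid.

    The dense truth for each dimension is a smooth nonnegative rank-``rank``
    matrix ``U @ B`` (subject loadings times slow temporal basis), scaled to
    ``[0, scale_max]``.  Each subject rates all dimensions at their own pause
    times — either an explicit list of times (seconds) or the default scheme:
    first pause uniform on [30, 270] s, later gaps uniform on [200, 280] s.

    Returns ``(ratings, truth)`` where ``ratings`` is a list of
    :class:`~statesync.ratings.SparseRatingMatrix` (one per dimension, all
    sharing the pause schedule) and ``truth`` is an
    ``(n_dims, n_subjects, duration_s)`` array.
    """
    from .ratings import SparseRatingMatrix

    rng = np.random.default_rng(seed)
    T = int(duration_s)
    truth = np.empty((n_dims, n_subjects, T))
    for dim in range(n_dims):
        basis = _smooth_nonneg_basis(rng, rank, T)
        loadings = rng.uniform(0.2, 1.0, size=(n_subjects, rank))
        dense = loadings @ basis
        peak = dense.max()
        truth[dim] = scale_max * dense / peak if peak > 0 else dense

    masks = np.zeros((n_subjects, T), dtype=bool)
    for i in range(n_subjects):
        if isinstance(observed_schedule, str) and observed_schedule == "random_pauses":
            times = pause_schedule(rng, duration_s)
        else:
            times = np.asarray(observed_schedule, dtype=float)
        bins = np.floor(times).astype(int)
        bins = bins[(bins >= 0) & (bins < T)]
        masks[i, bins] = True

    ratings = []
    for dim in range(n_dims):
        values = np.where(masks, truth[dim], 0.0)
        ratings.append(
            SparseRatingMatrix(
                values=values,
                mask=masks.copy(),
                dimension_label=f"dim-{dim:02d}",
                time_step_seconds=1.0,
                subject_ids=[f"sub-{i:03d}" for i in range(n_subjects)],
                scale_max=scale_max,
            )
        )
    return ratings, truth
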