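"""Intersubject correlation (ISC) and the resampling tests built on it.

ISC summarizes how similar a signal is across subjects: all pairwise Pearson
correlations are Fisher z-transformed, the strict lower triangle of the
pairwise matrix is averaged, and the mean is mapped back through the inverse
Fisher transform,

    ISC = R( 2 / (N^2 - N) * sum_{i} sum_{j<i} Z(corr(S_i, S_j)) ),

with Z(r) = atanh(r) and R its inverse.  Three flavors are provided:

* temporal  — each subject's mean (or user-supplied) time course;
* spatial   — the subjects' multivoxel patterns at a single TR, giving an
              instantaneous synchronization series over TRs;
* spatiotemporal — the vectorized strict lower triangle of each subject's
              T x T pattern-recurrence matrix, a signature of the subject's
              full spatiotemporal trajectory.

Inference uses a subject-wise bootstrap (resample subjects with replacement,
drop cells that pair a subject with itself) and, for paired comparisons
across conditions, a sign permutation test with Benjamini-Hochberg FDR
correction across parcels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .dataio import Dataset

__all__ = [
    "PairwiseSimilarity",
    "ISCResult",
    "SpatialISCResult",
    "fisher_z",
    "inverse_fisher_z",
    "pairwise_similarity",
    "isc_from_pairwise",
    "temporal_isc",
    "spatial_isc_per_tr",
    "spatiotemporal_isc",
    "subjectwise_bootstrap",
    "paired_sign_permutation",
    "fdr_bh",
]

#: correlations at or beyond 1 - CLIP_EPS are clipped when clip_r is enabled
CLIP_EPS = 1e-7


def fisher_z(r, clip: bool = False):
    """Fisher z-transform, ``z = [ln(1+r) - ln(1-r)] / 2``.

    With ``clip=True``, correlations with ``|r| >= 1 - 1e-7`` are clipped to
    that bound instead of raising; the policy only alters values already
    within 1e-7 of a perfect correlation.
    """
    r = np.asarray(r, dtype=np.float64)
    if clip:
        r = np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS)
    elif np.any(np.abs(r) >= 1 - CLIP_EPS):
        bad = np.atleast_1d(np.abs(r) >= 1 - CLIP_EPS).nonzero()[0]
        raise ValueError(
            f"(near-)perfect correlation at index {bad[:1].tolist()} has a "
            "divergent Fisher z; enable clipping to handle perfectly "
            "correlated pairs"
        )
    return np.arctanh(r)


def inverse_fisher_z(z):
    """Inverse Fisher transform, ``r = (e^{2z} - 1) / (e^{2z} + 1)``."""
    return np.tanh(np.asarray(z, dtype=np.float64))


@dataclass
class PairwiseSimilarity:
    """Symmetric N x N matrix of pairwise Pearson correlations."""

    r: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if len(self.labels) != n:
            raise ValueError("labels length mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.r.shape[0]

    def lower_triangle(self) -> np.ndarray:
        return self.r[np.tril_indices(self.n, k=-1)]


@dataclass
class ISCResult:
    isc: float
    pairwise: PairwiseSimilarity
    boot_distribution: np.ndarray | None = None
    p_value: float | None = None
    n_boot: int = 0
    seed: int | None = None
    #: arithmetic mean of the pairwise r values (descriptive companion to
    #: the Fisher-averaged isc; the two are reported side by side)
    mean_pairwise_r: float = field(default=np.nan)


@dataclass
class SpatialISCResult:
    """Instantaneous spatial ISC at each TR, with summary moments."""

    values: np.ndarray  # (T,), NaN where a constant pattern made a TR undefined
    mean: float
    sd: float
    missing_trs: np.ndarray


def _pearson_rows(x: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between rows of ``x``."""
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"row {bad} is constant; correlation undefined")
    return np.corrcoef(x)


def pairwise_similarity(features: np.ndarray, labels: list[str]) -> PairwiseSimilarity:
    """Pairwise Pearson correlations between per-subject feature vectors."""
    features = np.asarray(features, dtype=np.float64)
    sd = features.std(axis=1)
    if np.any(sd == 0):
        bad = labels[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"subject {bad!r} has a constant feature vector")
    r = np.corrcoef(features)
    np.fill_diagonal(r, 1.0)
    return PairwiseSimilarity(r=np.clip(r, -1.0, 1.0), labels=list(labels))


def isc_from_pairwise(ps: PairwiseSimilarity, clip_r: bool = False) -> float:
    """Fisher-averaged mean of the strict lower triangle."""
    tri = ps.lower_triangle()
    return float(inverse_fisher_z(np.mean(fisher_z(tri, clip=clip_r))))


def _build_result(
    features: np.ndarray, labels, clip_r: bool, n_boot: int, seed: int
) -> ISCResult:
    ps = pairwise_similarity(features, labels)
    isc = isc_from_pairwise(ps, clip_r=clip_r)
    result = ISCResult(
        isc=isc, pairwise=ps, mean_pairwise_r=float(np.mean(ps.lower_triangle()))
    )
    if n_boot:
        dist, p = subjectwise_bootstrap(ps, n_boot=n_boot, seed=seed, clip_r=clip_r)
        result.boot_distribution, result.p_value = dist, p
        result.n_boot, result.seed = n_boot, seed
    return result


def temporal_isc(
    ds: Dataset,
    reduce: str = "mean",
    vectors: np.ndarray | None = None,
    clip_r: bool = False,
    n_boot: int = 0,
    seed: int = 0,
) -> ISCResult:
    """ISC of each subject's mean-over-voxels time course.

    ``reduce='given'`` uses ``vectors`` (N x T) as the per-subject series
    instead, e.g. for single components or behavioral channels.
    """
    if ds.n_subjects < 2:
        raise ValueError("temporal ISC needs at least 2 subjects")
    if reduce == "mean":
        series = np.stack([s.data.mean(axis=1) for s in ds.subjects])
    elif reduce == "given":
        if vectors is None:
            raise ValueError("reduce='given' requires vectors")
        series = np.asarray(vectors, dtype=np.float64)
        if series.shape != (ds.n_subjects, ds.n_trs):
            raise ValueError(
                f"vectors shape {series.shape} does not match (N={ds.n_subjects}, "
                f"T={ds.n_trs})"
            )
    else:
        raise ValueError(f"unknown reduce mode {reduce!r}")
    sd = series.std(axis=1)
    if np.any(sd == 0):
        bad = ds.subject_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"subject {bad!r} has a constant time series")
    return _build_result(series, ds.subject_ids, clip_r, n_boot, seed)


def spatial_isc_per_tr(ds: Dataset, clip_r: bool = True) -> SpatialISCResult:
    """Instantaneous spatial ISC: Fisher-averaged pairwise pattern similarity
    across subjects at every TR.

    TRs where any subject's pattern is constant are set to NaN and reported
    in ``missing_trs`` (skipped, never imputed).
    """
    if ds.n_voxels < 3:
        raise ValueError("spatial ISC needs at least 3 voxels")
    if ds.n_subjects < 2:
        raise ValueError("spatial ISC needs at least 2 subjects")
    X = np.stack([s.data for s in ds.subjects])  # (N, T, V)
    N, T, V = X.shape
    mean = X.mean(axis=2, keepdims=True)
    sd = X.std(axis=2)
    ok = np.all(sd > 0, axis=0)  # (T,)
    Z = (X - mean) / np.where(sd[..., None] == 0, 1.0, sd[..., None])
    values = np.full(T, np.nan)
    iu = np.tril_indices(N, k=-1)
    # per-TR pairwise correlation = Z_t Z_t^T / V over subjects
    corr = np.einsum("itv,jtv->tij", Z, Z) / V
    for t in np.flatnonzero(ok):
        tri = np.clip(corr[t][iu], -1.0, 1.0)
        values[t] = inverse_fisher_z(np.mean(fisher_z(tri, clip=clip_r)))
    valid = values[~np.isnan(values)]
    return SpatialISCResult(
        values=values,
        mean=float(valid.mean()) if valid.size else np.nan,
        sd=float(valid.std()) if valid.size else np.nan,
        missing_trs=np.flatnonzero(~ok),
    )


def spatiotemporal_isc(
    ds: Dataset, clip_r: bool = False, n_boot: int = 0, seed: int = 0
) -> ISCResult:
    """ISC of each subject's vectorized recurrence-matrix lower triangle.

    The recurrence lower triangle captures when a subject revisits similar
    spatial patterns, so two subjects can score high while expressing the
    same trajectory structure at different absolute times only if the times
    coincide; it is a strict spatiotemporal signature.
    """
    from .dynamics import recurrence_matrix

    if ds.n_subjects < 2:
        raise ValueError("spatiotemporal ISC needs at least 2 subjects")
    T = ds.n_trs
    iu = np.tril_indices(T, k=-1)
    feats = np.stack([recurrence_matrix(s).m[iu] for s in ds.subjects])
    if np.any(np.isnan(feats)):
        raise ValueError("recurrence matrices contain missing cells (constant patterns)")
    return _build_result(feats, ds.subject_ids, clip_r, n_boot, seed)


def subjectwise_bootstrap(
    ps: PairwiseSimilarity, n_boot: int = 5000, seed: int = 0, clip_r: bool = False
) -> tuple[np.ndarray, float]:
    """Subject-wise bootstrap for the ISC of a pairwise similarity matrix.

    Each replicate resamples subject indices with replacement, rebuilds the
    similarity matrix, drops every cell that pairs a subject with itself
    (including duplicates created by the resampling), and Fisher-averages the
    remaining strict-lower-triangle cells.  The two-sided p-value shifts the
    bootstrap distribution to a null centered at zero (percentile method)
    with the +1/(n_boot+1) small-sample correction.
    """
    n = ps.n
    if n < 3:
        raise ValueError("subject-wise bootstrap needs at least 3 subjects")
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    tri = ps.lower_triangle()
    if np.allclose(tri, tri[0]):
        warnings.warn("all pairwise correlations identical; bootstrap is degenerate")
    observed = isc_from_pairwise(ps, clip_r=clip_r)
    iu, il = np.tril_indices(n, k=-1)
    dist = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            keep = idx[iu] != idx[il]  # drop same-participant pairings
            if keep.any():  # redraw the rare replicate with no valid pair
                break
        cells = ps.r[idx[iu][keep], idx[il][keep]]
        dist[b] = inverse_fisher_z(np.mean(fisher_z(cells, clip=clip_r)))
    shifted = dist - dist.mean()
    p = float((np.sum(np.abs(shifted) >= abs(observed)) + 1) / (n_boot + 1))
    return dist, p


def paired_sign_permutation(
    values_a: np.ndarray, values_b: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> float:
    """Two-sided paired-sample sign permutation test on ``mean(a - b)``.

    The null flips the sign of each pair's difference at random; the p-value
    carries the +1/(n_perm+1) correction.  Zero-variance, zero-mean
    differences return p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired test needs two equal-length vectors of length >= 2")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p-value uninformative")
        return 1.0
    stat = d.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = (signs * d).mean(axis=1)
    return float((np.sum(np.abs(null) >= abs(stat)) + 1) / (n_perm + 1))


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg FDR: returns (reject mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=np.float64)
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape), p_adj.reshape(p.shape)
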