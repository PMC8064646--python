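"""Temporal recurrence of spatial patterns and autocorrelation time scales.

A subject's recurrence matrix correlates the multivoxel pattern at every TR
with the pattern at every other TR; block-diagonal structure in it signals
slow, state-like dynamics.  Autocorrelation functions (per voxel, or of whole
patterns) are summarized by fitting a three-parameter exponential decay

    acf(x) ~ alpha * exp(-beta * x) + c

with a robust (soft-L1) least-squares estimator, and the intrinsic time scale
is read off as the lag at which the fitted curve crosses a correlation
threshold (0.1 by default), solved analytically from the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .dataio import SubjectTimeSeries
from .isc import fdr_bh, fisher_z

__all__ = [
    "RecurrenceMatrix",
    "AutocorrFit",
    "recurrence_matrix",
    "voxel_autocorrelation",
    "pattern_autocorrelation",
    "fit_exponential",
    "lag_to_threshold",
    "recurrence_group_ttest",
]

NEVER = np.inf
"""Sentinel returned by :func:`lag_to_threshold` when the fitted curve never
decays below the threshold (e.g. the floor ``c`` sits above it)."""


@dataclass
class RecurrenceMatrix:
    """T x T Pearson similarity of a subject's spatial patterns over time."""

    m: np.ndarray
    subject_id: str
    missing_trs: np.ndarray

    @property
    def n_trs(self) -> int:
        return self.m.shape[0]


@dataclass
class AutocorrFit:
    lags: np.ndarray
    acf: np.ndarray
    alpha: float
    beta: float
    c: float
    sse: float
    converged: bool
    threshold: float = 0.1

    def curve(self, x) -> np.ndarray:
        return self.alpha * np.exp(-self.beta * np.asarray(x, dtype=float)) + self.c

    @property
    def lag_to_threshold(self) -> float:
        return lag_to_threshold(self, self.threshold)


def recurrence_matrix(sts: SubjectTimeSeries) -> RecurrenceMatrix:
    """Correlate the spatial pattern at each TR with every other TR.

    TRs with a constant pattern get NaN rows/columns and are listed in
    ``missing_trs``; the diagonal is exactly 1 for valid TRs.
    """
    if sts.n_voxels < 2:
        raise ValueError("recurrence needs at least 2 voxels")
    X = sts.data
    sd = X.std(axis=1)
    ok = sd > 0
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(ok, sd, 1.0)[:, None]
    m = (Z @ Z.T) / sts.n_voxels
    np.clip(m, -1.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    missing = np.flatnonzero(~ok)
    m[missing, :] = np.nan
    m[:, missing] = np.nan
    return RecurrenceMatrix(m=m, subject_id=sts.subject_id, missing_trs=missing)


def voxel_autocorrelation(
    sts: SubjectTimeSeries, max_lag: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel autocorrelation up to ``max_lag`` TRs and its median curve.

    ``acf[v, L-1]`` is the Pearson correlation of voxel ``v``'s series with
    itself shifted by ``L`` TRs, computed on the overlapping ``T - L``
    samples (no padding).  Constant voxels are excluded (NaN rows) and the
    median is taken over the remaining voxels.

    Returns ``(acf_matrix, median_curve, lags)``.
    """
    T, V = sts.data.shape
    if T <= max_lag + 2:
        raise ValueError(f"need T > max_lag + 2; got T={T}, max_lag={max_lag}")
    lags = np.arange(1, max_lag + 1)
    acf = np.full((V, max_lag), np.nan)
    X = sts.data
    constant = X.std(axis=0) == 0
    for L in lags:
        a, b = X[:-L], X[L:]
        am = a - a.mean(axis=0)
        bm = b - b.mean(axis=0)
        denom = np.sqrt((am**2).sum(axis=0) * (bm**2).sum(axis=0))
        ok = (denom > 0) & ~constant
        acf[ok, L - 1] = (am * bm).sum(axis=0)[ok] / denom[ok]
    median = np.nanmedian(acf, axis=0)
    return acf, median, lags


def pattern_autocorrelation(
    sts: SubjectTimeSeries, max_lag: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Mean similarity of the pattern at ``t`` with the pattern at ``t + L``.

    Exactly the mean of the L-th superdiagonal of the recurrence matrix.
    Returns ``(acf, lags)``.
    """
    if sts.n_trs <= max_lag + 2:
        raise ValueError(f"need T > max_lag + 2; got T={sts.n_trs}, max_lag={max_lag}")
    rm = recurrence_matrix(sts).m
    lags = np.arange(1, max_lag + 1)
    acf = np.array([np.nanmean(np.diagonal(rm, offset=int(L))) for L in lags])
    return acf, lags


def fit_exponential(
    acf: np.ndarray, lags: np.ndarray, threshold: float = 0.1
) -> AutocorrFit:
    """Robust fit of ``alpha * exp(-beta * x) + c`` to an autocorrelation curve.

    Soft-L1 loss within nonlinear least squares; bounds alpha in [0, 2],
    beta in [0, 10], c in [-1, 1]; start at (1, 0.5, 0).
    """
    acf = np.asarray(acf, dtype=np.float64)
    lags = np.asarray(lags, dtype=np.float64)
    ok = np.isfinite(acf)
    if ok.sum() < 4:
        raise ValueError("need at least 4 finite lag points to fit")
    x, y = lags[ok], acf[ok]

    def residuals(p):
        alpha, beta, c = p
        return alpha * np.exp(-beta * x) + c - y

    res = optimize.least_squares(
        residuals,
        x0=(1.0, 0.5, 0.0),
        bounds=([0.0, 0.0, -1.0], [2.0, 10.0, 1.0]),
        loss="soft_l1",
    )
    alpha, beta, c = res.x
    return AutocorrFit(
        lags=lags, acf=acf, alpha=float(alpha), beta=float(beta), c=float(c),
        sse=float(np.sum(res.fun**2)), converged=bool(res.success),
        threshold=threshold,
    )


def lag_to_threshold(fit: AutocorrFit, threshold: float = 0.1) -> float:
    """Lag at which the fitted decay crosses ``threshold``.

    Solved analytically: ``x = ln(alpha / (threshold - c)) / beta``, clamped
    to ``[0, max_lag]``.  Returns :data:`NEVER` (inf) when the floor ``c``
    sits at or above the threshold or the curve cannot reach it.
    """
    max_lag = float(fit.lags[-1])
    if fit.c >= threshold:
        return NEVER
    gap = threshold - fit.c
    if fit.alpha <= gap:  # already below threshold at lag 0
        return 0.0
    if fit.beta <= 0:
        return NEVER
    x = np.log(fit.alpha / gap) / fit.beta
    return float(np.clip(x, 0.0, max_lag))


def recurrence_group_ttest(
    recurrences: list[RecurrenceMatrix], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell-wise one-sample t-test of Fisher-z recurrence across subjects.

    Every strict-lower-triangle cell present in all subjects is tested
    against 0 and Benjamini-Hochberg corrected at ``q``; cells missing in any
    subject are excluded.  Returns symmetric ``(t_map, p_map, significant)``
    arrays with NaN/False on excluded cells and the diagonal.
    """
    if len(recurrences) < 3:
        raise ValueError("group t-test needs at least 3 subjects")
    T = recurrences[0].n_trs
    if any(r.n_trs != T for r in recurrences):
        raise ValueError("all recurrence matrices must share T")
    stack = np.stack([r.m for r in recurrences])  # (N, T, T)
    il = np.tril_indices(T, k=-1)
    cells = stack[:, il[0], il[1]]  # (N, n_cells)
    valid = np.all(np.isfinite(cells), axis=0)
    z = fisher_z(np.clip(cells[:, valid], -1.0, 1.0), clip=True)
    t_stat, p_val = stats.ttest_1samp(z, 0.0, axis=0)

    t_map = np.full((T, T), np.nan)
    p_map = np.full((T, T), np.nan)
    sig = np.zeros((T, T), dtype=bool)
    rows, cols = il[0][valid], il[1][valid]
    t_map[rows, cols] = t_stat
    p_map[rows, cols] = p_val
    if valid.any():
        reject, _ = fdr_bh(p_val, q=q)
        sig[rows, cols] = reject
    # mirror to the upper triangle; the map is symmetric by construction
    t_map = np.where(np.isnan(t_map), t_map.T, t_map)
    p_map = np.where(np.isnan(p_map), p_map.T, p_map)
    sig = sig | sig.T
    return t_map, p_map, sig
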