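"""Hidden-Markov brain-state segmentation and cross-subject state alignment.

Two complementary fitting regimes are supported:

* **individual** — one HMM per subject on that subject's PCA-reduced series;
  states are then matched across subjects with the Hungarian algorithm on
  the spatial correlation of back-projected emission patterns, and the
  number of states is chosen to maximize the average within-state minus
  between-state pattern similarity across subjects.
* **group** — a single HMM over all subjects, fitted on a shared stacked-PCA
  space with each subject entering as an independent sequence; the number of
  states is chosen at the largest drop of the Bayesian information
  criterion,

      BIC(k) = ln(n) * (k^2 + 2 k f - 1) - 2 * loglik,

  where ``n`` counts observations, ``f`` PCA features, and the parameter
  count collects (k - 1) start, k(k - 1) transition, and 2 k f emission
  parameters.

Emissions are diagonal-covariance Gaussians over principal-component scores
(EM via hmmlearn, best of several restarts); decoded Viterbi paths feed the
concordance series — the proportion of subjects occupying each state at each
TR — and voxel-wise state-occupancy contrasts.  State labels are 1-based
everywhere in reported objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn import hmm as _hmm
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .dataio import Dataset, SubjectTimeSeries, zscore_within_subject
from .isc import fdr_bh

__all__ = [
    "ReducedTimeSeries",
    "GaussianHMM",
    "StatePath",
    "StateAlignment",
    "ConcordanceSeries",
    "KSelectionResult",
    "pca_reduce",
    "fit_hmm_em",
    "viterbi_decode",
    "decode_sequences",
    "backproject_state_patterns",
    "align_states",
    "relabel_path",
    "select_k_individual",
    "bic",
    "select_k_group",
    "concordance",
    "circleshift_corr_test",
    "state_contrast",
]

VARIANCE_FLOOR = 1e-5


@dataclass
class ReducedTimeSeries:
    """PCA scores retaining a target fraction of variance.

    ``scores`` stacks all sequences row-wise; ``seq_lengths`` partitions the
    rows back into subjects (a single entry for per-subject scope).
    """

    scores: np.ndarray  # (total_T, f)
    loadings: np.ndarray  # (V, f), orthonormal columns
    var_explained: float
    f: int
    fit_scope: str  # "per-subject" | "stacked"
    seq_lengths: list[int]
    subject_ids: list[str] = field(default_factory=list)
    mean_: np.ndarray | None = None  # (V,) column means removed before PCA

    def per_sequence(self) -> list[np.ndarray]:
        out, offset = [], 0
        for length in self.seq_lengths:
            out.append(self.scores[offset : offset + length])
            offset += length
        return out


@dataclass
class GaussianHMM:
    """A fitted diagonal-covariance Gaussian HMM."""

    k: int
    f: int
    start: np.ndarray  # (k,)
    trans: np.ndarray  # (k, k)
    means: np.ndarray  # (k, f)
    variances: np.ndarray  # (k, f)
    loglik: float
    n_obs: int
    seed: int
    converged: bool = True
    em_history: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_hmmlearn(self) -> _hmm.GaussianHMM:
        m = _hmm.GaussianHMM(
            n_components=self.k, covariance_type="diag", init_params="", params=""
        )
        m.n_features = self.f
        m.startprob_ = self.start.copy()
        m.transmat_ = self.trans.copy()
        m.means_ = self.means.copy()
        m.covars_ = self.variances.copy()
        return m


@dataclass
class StatePath:
    """Viterbi state labels, 1-based, for one subject."""

    labels: np.ndarray  # (T,), ints in 1..k
    subject_id: str
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValueError(f"labels must lie in 1..{self.k}")


@dataclass
class StateAlignment:
    """Hungarian matching of every subject's states onto a reference.

    ``mappings[i][j]`` is the reference state (1-based) matched to subject
    ``i``'s state ``j + 1``.
    """

    mappings: list[np.ndarray]
    reference_id: str
    similarity: list[np.ndarray]  # per-subject k x k pattern correlations
    mean_within: float
    mean_between: float


@dataclass
class ConcordanceSeries:
    """``c[s, t]``: proportion of subjects in state ``s + 1`` at TR ``t``."""

    c: np.ndarray  # (k, T)
    n_subjects: int

    def __post_init__(self) -> None:
        col_sums = self.c.sum(axis=0)
        if np.max(np.abs(col_sums - 1.0)) > 1e-12:
            raise ValueError("concordance columns must sum to 1")


@dataclass
class KSelectionResult:
    k_best: int
    table: pd.DataFrame
    flat: bool = False
    dropped_k: list[int] = field(default_factory=list)


def pca_reduce(
    data, var_threshold: float = 0.90, scope: str = "per-subject"
) -> ReducedTimeSeries:
    """Keep the smallest number of components explaining ``var_threshold``.

    ``scope='per-subject'`` accepts a single matrix or
    :class:`SubjectTimeSeries`; ``scope='stacked'`` accepts a
    :class:`Dataset`, z-scores every subject within themselves, row-stacks
    them and fits one shared loading matrix.
    """
    if not (0 < var_threshold <= 1):
        raise ValueError(f"var_threshold must lie in (0, 1], got {var_threshold}")
    if scope == "per-subject":
        if isinstance(data, SubjectTimeSeries):
            sid, X = data.subject_id, data.data
        else:
            sid, X = "subject", np.asarray(data, dtype=np.float64)
        lengths = [X.shape[0]]
        ids = [sid]
    elif scope == "stacked":
        if not isinstance(data, Dataset):
            raise TypeError("scope='stacked' requires a Dataset")
        zs = [s if s.zscored else zscore_within_subject(s) for s in data.subjects]
        X = np.vstack([s.data for s in zs])
        lengths = [s.n_trs for s in zs]
        ids = data.subject_ids
    else:
        raise ValueError(f"unknown scope {scope!r}")

    n_max = min(X.shape)
    pca = PCA(n_components=n_max, svd_solver="full")
    scores_full = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    f = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    f = min(f, n_max)
    return ReducedTimeSeries(
        scores=scores_full[:, :f],
        loadings=pca.components_[:f].T,
        var_explained=float(cum[f - 1]),
        f=f,
        fit_scope=scope,
        seq_lengths=lengths,
        subject_ids=ids,
        mean_=pca.mean_.copy(),
    )


def _init_probe_model(
    rng: np.random.Generator, X: np.ndarray, k: int, n_iter: int, tol: float
) -> _hmm.GaussianHMM:
    """A diagonal-Gaussian HMM seeded with k distinct random observations as
    means, uniform start/transition probabilities, and per-feature data
    variances."""
    model = _hmm.GaussianHMM(
        n_components=k,
        covariance_type="diag",
        min_covar=VARIANCE_FLOOR,
        n_iter=n_iter,
        tol=tol,
        init_params="",
        implementation="scaling",
    )
    model.startprob_ = np.full(k, 1.0 / k)
    model.transmat_ = np.full((k, k), 1.0 / k)
    idx = rng.choice(X.shape[0], size=k, replace=False)
    model.means_ = X[idx].copy()
    model.covars_ = np.tile(np.maximum(X.var(axis=0), VARIANCE_FLOOR), (k, 1))
    return model


def fit_hmm_em(
    rts: ReducedTimeSeries,
    k: int,
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 500,
    tol: float = 1e-4,
    probe_iter: int = 25,
) -> GaussianHMM:
    """EM fit of a diagonal-covariance Gaussian HMM.

    Restarts use a probe-and-polish schedule: ``n_init`` short EM runs
    (``probe_iter`` iterations each) from diverse random-observation
    initializations, after which only the best probe by log-likelihood is
    polished to convergence (``max_iter``/``tol``).  This explores basins at
    a fraction of the cost of full restarts.  Sequences listed in
    ``rts.seq_lengths`` enter as independent chains (shared parameters,
    separate forward passes).  The per-iteration log-likelihood history of
    the polish run is retained for monotonicity checks; variances are
    floored at ``1e-5``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X, lengths = rts.scores, rts.seq_lengths
    n_obs = X.shape[0]
    n_params = k * k + 2 * k * rts.f - 1
    if n_obs < 2 * n_params:
        warnings.warn(
            f"only {n_obs} observations for {n_params} parameters (k={k}, f={rts.f})"
        )
    rng = np.random.default_rng(seed)
    best = None
    # hmmlearn logs sub-float-precision "not converging" deltas at the
    # optimum; they are numerical wobble, not fit failures
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(max(1, n_init)):
            probe = _init_probe_model(rng, X, k, n_iter=probe_iter, tol=0.0)
            try:
                probe.fit(X, lengths)
                score = probe.score(X, lengths)
            except ValueError:
                continue  # rare degenerate init; other probes cover it
            if best is None or score > best[0]:
                best = (score, probe)
        if best is None:
            raise RuntimeError(f"all {n_init} EM initializations failed for k={k}")
        model = best[1]
        model.n_iter = max_iter
        model.tol = tol
        model.init_params = ""
        model.fit(X, lengths)
        score = model.score(X, lengths)
    variances = np.maximum(model.covars_.reshape(k, rts.f, rts.f).diagonal(axis1=1, axis2=2)
                           if model.covars_.ndim == 3 else model.covars_, VARIANCE_FLOOR)
    return GaussianHMM(
        k=k,
        f=rts.f,
        start=model.startprob_.copy(),
        trans=model.transmat_.copy(),
        means=model.means_.copy(),
        variances=np.asarray(variances, dtype=np.float64).reshape(k, rts.f),
        loglik=float(score),
        n_obs=n_obs,
        seed=seed,
        converged=bool(model.monitor_.converged),
        em_history=np.asarray(model.monitor_.history, dtype=np.float64),
    )


def viterbi_decode(model: GaussianHMM, scores: np.ndarray, subject_id: str = "") -> StatePath:
    """Most probable state sequence (max-product dynamic program), 1-based."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] != model.f:
        raise ValueError(
            f"scores shape {scores.shape} incompatible with model f={model.f}"
        )
    labels = model.to_hmmlearn().predict(scores)
    return StatePath(labels=labels + 1, subject_id=subject_id, k=model.k)


def decode_sequences(model: GaussianHMM, rts: ReducedTimeSeries) -> list[StatePath]:
    """Viterbi-decode every sequence in a (possibly stacked) reduction."""
    ids = rts.subject_ids or [f"seq-{i}" for i in range(len(rts.seq_lengths))]
    return [
        viterbi_decode(model, seq, subject_id=sid)
        for seq, sid in zip(rts.per_sequence(), ids)
    ]


def backproject_state_patterns(model: GaussianHMM, rts: ReducedTimeSeries) -> np.ndarray:
    """Reconstruct each state's mean voxel pattern (k x V).

    The full state mean is restored — component-space emission means rotated
    through the loadings plus the column means removed before PCA — so the
    patterns live in the data's own units.  (Comparing mean-removed
    deviations instead makes k = 2 degenerate: the two centered patterns are
    exact mirrors and anticorrelate perfectly regardless of structure.)
    """
    patterns = model.means @ rts.loadings.T
    if rts.mean_ is not None:
        patterns = patterns + rts.mean_
    return patterns


def _pattern_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation of each row of ``a`` with each row of ``b``."""
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.maximum(np.linalg.norm(az, axis=1, keepdims=True), 1e-30)
    bz /= np.maximum(np.linalg.norm(bz, axis=1, keepdims=True), 1e-30)
    return az @ bz.T


def align_states(
    patterns_by_subject: list[np.ndarray],
    reference_index: int = 0,
    reference_patterns: np.ndarray | None = None,
    reference_id: str = "reference",
) -> StateAlignment:
    """Match states across subjects by maximizing summed pattern correlation.

    For each subject the assignment problem between that subject's ``k``
    patterns and the reference's is solved exactly (Hungarian algorithm,
    cost = 1 - Pearson correlation; ties resolve to the lowest-index
    assignment).  ``mean_within`` averages the matched correlations over all
    subjects, ``mean_between`` the unmatched cells.
    """
    if reference_patterns is None:
        reference_patterns = patterns_by_subject[reference_index]
        reference_id = f"subject_{reference_index}"
    k = reference_patterns.shape[0]
    mappings, sims = [], []
    within, between = [], []
    for patterns in patterns_by_subject:
        if patterns.shape != reference_patterns.shape:
            raise ValueError("all subjects must share (k, V) pattern shape")
        corr = _pattern_corr(patterns, reference_patterns)
        rows, cols = linear_sum_assignment(1.0 - corr)
        mapping = np.empty(k, dtype=np.int64)
        mapping[rows] = cols + 1  # 1-based reference labels
        mappings.append(mapping)
        sims.append(corr)
        matched = corr[rows, cols]
        within.append(matched.mean())
        mask = np.ones_like(corr, dtype=bool)
        mask[rows, cols] = False
        between.append(corr[mask].mean() if mask.any() else np.nan)
    return StateAlignment(
        mappings=mappings,
        reference_id=reference_id,
        similarity=sims,
        mean_within=float(np.mean(within)),
        mean_between=float(np.nanmean(between)),
    )


def relabel_path(path: StatePath, mapping: np.ndarray) -> StatePath:
    """Rewrite a path's labels through an alignment mapping (1-based)."""
    return StatePath(
        labels=np.asarray(mapping)[path.labels - 1], subject_id=path.subject_id, k=path.k
    )


def select_k_individual(
    ds: Dataset,
    k_range=(2, 25),
    seed: int = 0,
    var_threshold: float = 0.90,
    n_init: int = 5,
    max_iter: int = 200,
    tol: float = 1e-3,
    reference_index: int = 0,
    criterion: str = "difference",
) -> KSelectionResult:
    """Choose k maximizing cross-subject within- vs between-state similarity.

    For each k an HMM is fitted per subject, emission means are back-projected
    to voxel space and Hungarian-aligned to a reference subject (lowest index
    by default, for reproducibility); the score is the mean over subjects of
    within-state minus between-state pattern correlation (``criterion='ratio'``
    divides instead).  A k failing for more than 20% of subjects is dropped.
    """
    ks = _expand_k_range(k_range)
    reductions = [pca_reduce(s, var_threshold, scope="per-subject") for s in ds.subjects]
    rows, dropped = [], []
    for k in ks:
        patterns, failures = [], 0
        for i, rts in enumerate(reductions):
            try:
                model = fit_hmm_em(
                    rts, k, seed=seed + 1000 * k + i, n_init=n_init,
                    max_iter=max_iter, tol=tol,
                )
                patterns.append(backproject_state_patterns(model, rts))
            except RuntimeError:
                failures += 1
        if failures > 0.2 * ds.n_subjects or len(patterns) < 2:
            dropped.append(k)
            continue
        alignment = align_states(patterns, reference_index=reference_index)
        within, between = alignment.mean_within, alignment.mean_between
        score = within / between if criterion == "ratio" else within - between
        rows.append({"k": k, "within": within, "between": between, "score": score})
    if not rows:
        raise RuntimeError("individual-HMM selection failed for every k")
    table = pd.DataFrame(rows)
    scores = table["score"].to_numpy()
    k_best = int(table["k"].iloc[int(np.argmax(scores))])
    flat = bool(scores.max() - scores.min() < 0.01)
    return KSelectionResult(k_best=k_best, table=table, flat=flat, dropped_k=dropped)


def bic(model: GaussianHMM) -> float:
    """``ln(n) * (k^2 + 2 k f - 1) - 2 * loglik``."""
    if model.n_obs <= 0:
        raise ValueError("model has no observations")
    n_params = model.k**2 + 2 * model.k * model.f - 1
    return float(np.log(model.n_obs) * n_params - 2.0 * model.loglik)


def select_k_group(
    ds: Dataset,
    k_range=(2, 25),
    seed: int = 0,
    var_threshold: float = 0.90,
    n_init: int = 5,
    max_iter: int = 200,
    tol: float = 1e-3,
    selection_rule: str = "min_bic",
) -> KSelectionResult:
    """Choose the number of group-HMM states from the BIC curve.

    A single stacked-PCA reduction is shared across all k; each k fits one
    group HMM with subjects as independent sequences.  Two selection rules:

    * ``'min_bic'`` (default) — the k minimizing BIC, the standard use of
      the criterion; on data with genuinely separated states the BIC curve
      has an interior minimum at the true k.
    * ``'largest_drop'`` — the k whose discrete first difference
      ``BIC(k) - BIC(k_prev)`` is most negative, an elbow heuristic suited
      to monotonically decreasing BIC curves.  Note that because the
      marginal log-likelihood gain of an extra state never increases with k
      at the optimum, this rule cannot strictly prefer the true k over
      ``k_true - 1`` on cleanly separated data; it is provided for
      comparability, not recommended for recovery.

    Ties break toward smaller k (parsimony).
    """
    ks = _expand_k_range(k_range)
    rts = pca_reduce(ds, var_threshold, scope="stacked")
    rows, dropped = [], []
    for k in ks:
        try:
            model = fit_hmm_em(
                rts, k, seed=seed + 1000 * k, n_init=n_init, max_iter=max_iter, tol=tol
            )
        except RuntimeError:
            dropped.append(k)
            continue
        rows.append({"k": k, "loglik": model.loglik, "bic": bic(model)})
    if len(rows) < 2:
        raise RuntimeError("group-HMM selection needs BIC at two or more k values")
    table = pd.DataFrame(rows)
    dbic = np.diff(table["bic"].to_numpy())
    table["dbic"] = np.concatenate([[np.nan], dbic])
    if selection_rule == "min_bic":
        best_pos = int(np.argmin(table["bic"].to_numpy()))
    elif selection_rule == "largest_drop":
        best_pos = int(np.argmin(dbic)) + 1  # argmin takes the first (smaller k)
    else:
        raise ValueError(f"unknown selection_rule {selection_rule!r}")
    return KSelectionResult(
        k_best=int(table["k"].iloc[best_pos]), table=table, dropped_k=dropped
    )


def concordance(paths: list[StatePath], k: int) -> ConcordanceSeries:
    """Per-state proportion of subjects occupying it at each TR."""
    if not paths:
        raise ValueError("need at least one path")
    T = paths[0].labels.size
    counts = np.zeros((k, T))
    for path in paths:
        if path.labels.size != T:
            raise ValueError("all paths must share T")
        if path.labels.min() < 1 or path.labels.max() > k:
            raise ValueError(f"path {path.subject_id!r} has labels outside 1..{k}")
        for s in range(k):
            counts[s] += path.labels == s + 1
    return ConcordanceSeries(c=counts / len(paths), n_subjects=len(paths))


def circleshift_corr_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Pearson correlation with a circular-shift permutation null.

    The null rotates ``y`` by uniform random nonzero offsets, preserving its
    autocorrelation; the two-sided p-value carries the +1 correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 10:
        raise ValueError("need equal-length 1-D series of length >= 10")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant series; correlation undefined")
    T = x.size
    xz = (x - x.mean()) / (x.std() * np.sqrt(T))
    yz = (y - y.mean()) / (y.std() * np.sqrt(T))
    r = float(np.dot(xz, yz))
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, T, size=n_perm)
    null = np.array([np.dot(xz, np.roll(yz, int(s))) for s in shifts])
    p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_perm + 1))
    return r, p


def state_contrast(
    ds_voxels: Dataset,
    paths: list[StatePath],
    state_s: int,
    q: float = 0.05,
    min_trs: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Voxel-wise occupancy contrast: state ``state_s`` vs all other states.

    Per subject and voxel the difference of mean activity inside vs outside
    the state is computed; a one-sample t-test across subjects per voxel is
    Benjamini-Hochberg corrected at ``q``.  Subjects with fewer than
    ``min_trs`` TRs on either side are dropped (and reported); an error is
    raised if no subject remains or the complement is empty (contrasting a
    state against itself is undefined).

    Returns ``(t_map, p_map, significant, dropped_subject_ids)``.
    """
    if len(paths) != ds_voxels.n_subjects:
        raise ValueError("one path per subject required")
    k = paths[0].k
    if k < 2:
        raise ValueError("state contrast undefined with a single state")
    if not (1 <= state_s <= k):
        raise ValueError(f"state {state_s} outside 1..{k}")
    diffs, dropped = [], []
    for sts, path in zip(ds_voxels.subjects, paths):
        in_s = path.labels == state_s
        out_s = ~in_s
        if in_s.sum() < min_trs or out_s.sum() < min_trs:
            dropped.append(sts.subject_id)
            continue
        diffs.append(sts.data[in_s].mean(axis=0) - sts.data[out_s].mean(axis=0))
    if len(diffs) < 3:
        raise ValueError(
            f"only {len(diffs)} subjects usable for state {state_s} contrast"
        )
    D = np.stack(diffs)
    t_map, p_map = stats.ttest_1samp(D, 0.0, axis=0)
    reject, _ = fdr_bh(p_map, q=q)
    return t_map, p_map, reject, dropped


def _expand_k_range(k_range) -> list[int]:
    if isinstance(k_range, (tuple, list)) and len(k_range) == 2:
        lo, hi = int(k_range[0]), int(k_range[1])
        return list(range(lo, hi + 1))
    return [int(k) for k in k_range]
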