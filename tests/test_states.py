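import numpy as np
import pytest

import statesync as ss
from statesync.dataio import Dataset, SubjectTimeSeries
from statesync.states import (
    GaussianHMM,
    ReducedTimeSeries,
    StatePath,
    _pattern_corr,
)


def brute_force_viterbi(model: GaussianHMM, scores: np.ndarray) -> np.ndarray:
    """Independent oracle: maximize the joint log-probability over every
    possible state sequence by exhaustive enumeration."""
    from itertools import product

    from scipy.stats import norm

    T = scores.shape[0]
    logp_obs = np.stack(
        [
            norm.logpdf(scores, model.means[s], np.sqrt(model.variances[s])).sum(axis=1)
            for s in range(model.k)
        ]
    )  # (k, T)
    log_start = np.log(np.maximum(model.start, 1e-300))
    log_trans = np.log(np.maximum(model.trans, 1e-300))
    best, best_lp = None, -np.inf
    for seq in product(range(model.k), repeat=T):
        lp = log_start[seq[0]] + logp_obs[seq[0], 0]
        for t in range(1, T):
            lp += log_trans[seq[t - 1], seq[t]] + logp_obs[seq[t], t]
        if lp > best_lp:
            best_lp, best = lp, seq
    return np.asarray(best) + 1


def _rts_from_scores(scores, loadings=None, mean=None):
    scores = np.asarray(scores, float)
    f = scores.shape[1]
    if loadings is None:
        loadings = np.eye(f)
    return ReducedTimeSeries(
        scores=scores, loadings=loadings, var_explained=1.0, f=f,
        fit_scope="per-subject", seq_lengths=[scores.shape[0]],
        mean_=mean,
    )


class TestPCAReduce:
    def test_exact_low_rank_recovered(self, rng):
        basis = rng.standard_normal((3, 30))
        weights = rng.standard_normal((100, 3))
        rts = ss.pca_reduce(weights @ basis, var_threshold=0.90)
        assert rts.f == 3
        recon = rts.scores @ rts.loadings.T + rts.mean_
        np.testing.assert_allclose(recon, weights @ basis, atol=1e-8)

    def test_white_noise_needs_nearly_all_components(self, rng):
        rts = ss.pca_reduce(rng.standard_normal((500, 10)), var_threshold=0.90)
        assert rts.f >= 9

    def test_scores_orthogonal(self, rng):
        rts = ss.pca_reduce(rng.standard_normal((80, 12)), var_threshold=0.95)
        gram = rts.scores.T @ rts.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_stacked_scope_shares_loadings(self, state_dataset):
        ds, _ = state_dataset
        rts = ss.pca_reduce(ds, scope="stacked")
        assert rts.scores.shape[0] == ds.n_subjects * ds.n_trs
        assert len(rts.seq_lengths) == ds.n_subjects
        np.testing.assert_allclose(
            rts.loadings.T @ rts.loadings, np.eye(rts.f), atol=1e-8
        )

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ValueError, match="var_threshold"):
            ss.pca_reduce(rng.standard_normal((20, 4)), var_threshold=1.5)


class TestFitHMM:
    def test_single_state_closed_form(self, rng):
        scores = rng.standard_normal((200, 3)) * [1.0, 2.0, 0.5] + [0.0, 1.0, -2.0]
        model = ss.fit_hmm_em(_rts_from_scores(scores), k=1, n_init=1)
        np.testing.assert_allclose(model.means[0], scores.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(
            model.variances[0], scores.var(axis=0), rtol=0.05
        )
        np.testing.assert_allclose(model.trans, [[1.0]], atol=1e-10)

    def test_em_loglik_nondecreasing(self, state_dataset):
        ds, _ = state_dataset
        rts = ss.pca_reduce(ds, scope="stacked")
        model = ss.fit_hmm_em(rts, k=3, seed=1, n_init=1, max_iter=50)
        hist = model.em_history
        assert np.all(np.diff(hist) >= -1e-6)

    def test_true_k_beats_smaller_k_in_likelihood(self, state_dataset):
        ds, _ = state_dataset
        rts = ss.pca_reduce(ds, scope="stacked")
        ll4 = ss.fit_hmm_em(rts, k=4, seed=0, n_init=2, max_iter=100).loglik
        ll2 = ss.fit_hmm_em(rts, k=2, seed=0, n_init=2, max_iter=100).loglik
        assert ll4 > ll2

    def test_parameter_recovery_well_separated(self):
        ds, truth = ss.simulate_state_dataset(
            n_subjects=10, T=300, V=40, k=4, noise_sd=0.5, seed=17
        )
        rts = ss.pca_reduce(ds, scope="stacked")
        model = ss.fit_hmm_em(rts, k=4, seed=0, n_init=2, max_iter=200)
        patterns = ss.backproject_state_patterns(model, rts)
        # reference: state-conditional means of the analyzed (z-scored) data
        zs = [ss.zscore_within_subject(s).data for s in ds.subjects]
        ref = np.stack([
            np.vstack([z[truth.state_paths_true[i] == s + 1] for i, z in enumerate(zs)]).mean(0)
            for s in range(4)
        ])
        align = ss.align_states([patterns], reference_patterns=ref)
        assert align.mean_within > 0.95


class TestViterbi:
    def test_single_state_path(self, rng):
        scores = rng.standard_normal((20, 2))
        model = ss.fit_hmm_em(_rts_from_scores(scores), k=1, n_init=1)
        path = ss.viterbi_decode(model, scores)
        np.testing.assert_array_equal(path.labels, np.ones(20, dtype=int))

    def test_near_noiseless_decoding_exact(self):
        ds, truth = ss.simulate_state_dataset(
            n_subjects=4, T=200, V=20, k=3, noise_sd=0.05, seed=5
        )
        rts = ss.pca_reduce(ds, scope="stacked")
        model = ss.fit_hmm_em(rts, k=3, seed=0, n_init=2)
        paths = ss.decode_sequences(model, rts)
        patterns = ss.backproject_state_patterns(model, rts)
        zs = [ss.zscore_within_subject(s).data for s in ds.subjects]
        ref = np.stack([
            np.vstack([z[truth.state_paths_true[i] == s + 1] for i, z in enumerate(zs)]).mean(0)
            for s in range(3)
        ])
        align = ss.align_states([patterns], reference_patterns=ref)
        acc = np.mean([
            (ss.relabel_path(p, align.mappings[0]).labels == truth.state_paths_true[i]).mean()
            for i, p in enumerate(paths)
        ])
        assert acc >= 0.99

    def test_matches_exhaustive_search_on_small_models(self, rng):
        for trial in range(8):
            k = int(rng.integers(2, 4))
            T = int(rng.integers(4, 9))
            f = 2
            trans = rng.dirichlet(np.ones(k), size=k)
            start = rng.dirichlet(np.ones(k))
            model = GaussianHMM(
                k=k, f=f, start=start, trans=trans,
                means=rng.standard_normal((k, f)) * 2,
                variances=rng.uniform(0.5, 1.5, size=(k, f)),
                loglik=0.0, n_obs=T, seed=0,
            )
            scores = rng.standard_normal((T, f))
            ours = ss.viterbi_decode(model, scores).labels
            oracle = brute_force_viterbi(model, scores)
            np.testing.assert_array_equal(ours, oracle)


class TestBackprojection:
    def test_identity_loadings_return_means(self, rng):
        scores = rng.standard_normal((50, 3))
        model = ss.fit_hmm_em(_rts_from_scores(scores), k=1, n_init=1)
        patterns = ss.backproject_state_patterns(model, _rts_from_scores(scores))
        np.testing.assert_allclose(patterns, model.means, atol=1e-12)

    def test_orthonormal_map_preserves_inner_products(self, rng):
        w, _ = np.linalg.qr(rng.standard_normal((30, 5)))
        means = rng.standard_normal((4, 5))
        patterns = means @ w.T
        np.testing.assert_allclose(patterns @ patterns.T, means @ means.T, atol=1e-10)


class TestAlignment:
    def test_permutation_recovered_exactly(self, rng):
        ref = rng.standard_normal((3, 25))
        # subject states are the reference permuted: 1->3, 2->1, 3->2
        subject = ref[[1, 2, 0]]
        align = ss.align_states([subject], reference_patterns=ref)
        np.testing.assert_array_equal(align.mappings[0], [2, 3, 1])

    def test_matches_brute_force_assignment(self, rng):
        from itertools import permutations

        for _ in range(10):
            k = int(rng.integers(2, 5))
            subj = rng.standard_normal((k, 15))
            ref = rng.standard_normal((k, 15))
            align = ss.align_states([subj], reference_patterns=ref)
            corr = _pattern_corr(subj, ref)
            best = max(
                permutations(range(k)),
                key=lambda perm: sum(corr[i, perm[i]] for i in range(k)),
            )
            ours = align.mappings[0] - 1
            total_ours = sum(corr[i, ours[i]] for i in range(k))
            total_best = sum(corr[i, best[i]] for i in range(k))
            assert abs(total_ours - total_best) < 1e-12

    def test_self_alignment_is_identity(self, rng):
        ref = rng.standard_normal((4, 20))
        align = ss.align_states([ref], reference_patterns=ref)
        np.testing.assert_array_equal(align.mappings[0], [1, 2, 3, 4])
        assert abs(align.mean_within - 1.0) < 1e-10


class TestBIC:
    def test_direct_evaluation(self):
        m = GaussianHMM(
            k=2, f=3, start=np.array([0.5, 0.5]), trans=np.eye(2),
            means=np.zeros((2, 3)), variances=np.ones((2, 3)),
            loglik=-500.0, n_obs=100, seed=0,
        )
        assert abs(ss.bic(m) - 1069.0776) < 1e-3

    def test_single_state_evaluation(self):
        m = GaussianHMM(
            k=1, f=1, start=np.ones(1), trans=np.ones((1, 1)),
            means=np.zeros((1, 1)), variances=np.ones((1, 1)),
            loglik=0.0, n_obs=10, seed=0,
        )
        assert abs(ss.bic(m) - 4.6052) < 1e-3

    def test_penalty_monotone_in_k(self):
        def make(k):
            return GaussianHMM(
                k=k, f=3, start=np.ones(k) / k, trans=np.ones((k, k)) / k,
                means=np.zeros((k, 3)), variances=np.ones((k, 3)),
                loglik=-100.0, n_obs=50, seed=0,
            )

        bics = [ss.bic(make(k)) for k in range(1, 6)]
        assert np.all(np.diff(bics) > 0)


class TestConcordance:
    def test_counting_example(self):
        paths = [
            StatePath(labels=np.array([lab]), subject_id=f"s{i}", k=2)
            for i, lab in enumerate([2, 2, 2, 1])
        ]
        conc = ss.concordance(paths, k=2)
        assert conc.c[1, 0] == 0.75
        assert conc.c[0, 0] == 0.25

    def test_identical_paths_one_hot(self, rng):
        labels = rng.integers(1, 4, size=30)
        paths = [StatePath(labels=labels.copy(), subject_id=f"s{i}", k=3) for i in range(5)]
        conc = ss.concordance(paths, k=3)
        assert np.all(np.max(conc.c, axis=0) == 1.0)
        np.testing.assert_allclose(conc.c.sum(axis=0), 1.0, atol=1e-12)

    def test_out_of_range_label_rejected(self):
        path = StatePath(labels=np.array([1, 2, 3]), subject_id="a", k=3)
        with pytest.raises(ValueError, match="outside"):
            ss.concordance([path], k=2)


class TestCircleShift:
    def test_identical_autocorrelated_series_significant(self):
        x = np.cumsum(np.random.default_rng(3).standard_normal(200))
        r, p = ss.circleshift_corr_test(x, x.copy(), n_perm=200, seed=0)
        assert r > 0.999
        assert p <= 2 / 201

    def test_statistic_is_plain_pearson(self, rng):
        x, y = rng.standard_normal((2, 50))
        r, _ = ss.circleshift_corr_test(x, y, n_perm=100, seed=1)
        assert abs(r - np.corrcoef(x, y)[0, 1]) < 1e-12

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ss.circleshift_corr_test(np.ones(20), np.arange(20.0), n_perm=100, seed=0)


class TestStateContrast:
    def test_planted_voxels_recovered(self):
        rng = np.random.default_rng(8)
        N, T, V = 20, 300, 60
        emissions = rng.standard_normal((4, V)) * 0.0
        emissions[1, :10] = 1.0  # state 2 activates voxels 0..9 only
        ds, truth = ss.simulate_state_dataset(
            n_subjects=N, T=T, V=V, k=4, emissions=emissions, noise_sd=0.5, seed=8
        )
        paths = [
            StatePath(labels=truth.state_paths_true[i], subject_id=f"s{i}", k=4)
            for i in range(N)
        ]
        t_map, p_map, sig, dropped = ss.state_contrast(ds, paths, state_s=2, q=0.05)
        assert not dropped
        assert sig[:10].all()
        assert sig[10:].sum() <= 0.1 * V

    def test_single_state_contrast_undefined(self, rng):
        ds = Dataset([SubjectTimeSeries(f"s{i}", rng.standard_normal((20, 5))) for i in range(4)])
        paths = [StatePath(labels=np.ones(20, dtype=int), subject_id=f"s{i}", k=1) for i in range(4)]
        with pytest.raises(ValueError, match="single state"):
            ss.state_contrast(ds, paths, state_s=1)

    def test_subjects_without_occupancy_dropped(self, rng):
        ds = Dataset([SubjectTimeSeries(f"s{i}", rng.standard_normal((30, 5))) for i in range(5)])
        labels = [np.r_[np.ones(15), 2 * np.ones(15)].astype(int) for _ in range(4)]
        labels.append(np.ones(30, dtype=int))  # never enters state 2
        paths = [StatePath(labels=l, subject_id=f"s{i}", k=2) for i, l in enumerate(labels)]
        *_, dropped = ss.state_contrast(ds, paths, state_s=2)
        assert dropped == ["s4"]


class TestSelectK:
    def test_degenerate_single_state_data_flagged(self):
        ds, _ = ss.simulate_state_dataset(
            n_subjects=4, T=120, V=20, k=1, noise_sd=1.0, seed=30
        )
        res = ss.select_k_individual(
            ds, k_range=(2, 4), seed=0, n_init=1, max_iter=50, tol=1e-2
        )
        assert set(res.table["k"]) <= {2, 3, 4}
        assert isinstance(res.flat, bool)

    def test_group_bic_curve_complete_and_deterministic(self, state_dataset):
        ds, _ = state_dataset
        r1 = ss.select_k_group(ds, k_range=(2, 5), seed=3, n_init=1, max_iter=50, tol=1e-2)
        r2 = ss.select_k_group(ds, k_range=(2, 5), seed=3, n_init=1, max_iter=50, tol=1e-2)
        assert len(r1.table) == 4
        assert np.all(np.isfinite(r1.table["bic"]))
        assert r1.k_best == r2.k_best
        np.testing.assert_allclose(r1.table["bic"], r2.table["bic"], atol=1e-9)
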