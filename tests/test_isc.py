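import numpy as np
import pytest

import statesync as ss
from statesync.dataio import Dataset, SubjectTimeSeries
from statesync.isc import (
    fdr_bh,
    isc_from_pairwise,
    pairwise_similarity,
)


def _dataset_from_series(series, V=1):
    """Each subject's mean time course equals the given series."""
    return Dataset(
        subjects=[
            SubjectTimeSeries(f"s{i}", np.tile(np.asarray(x, float)[:, None], (1, V)))
            for i, x in enumerate(series)
        ]
    )


def brute_force_isc(r_matrix):
    """Independent oracle: the Fisher-averaged pairwise mean, as an explicit
    double loop over all unordered pairs."""
    n = r_matrix.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i):
            total += np.arctanh(r_matrix[i, j])
    return np.tanh(2.0 * total / (n * n - n))


class TestFisherTransform:
    def test_zero_maps_to_zero(self):
        assert ss.fisher_z(0.0) == 0.0

    def test_half_is_half_log_three(self):
        assert abs(ss.fisher_z(0.5) - np.log(3) / 2) < 1e-12
        assert abs(ss.fisher_z(0.5) - 0.5493) < 1e-4

    def test_round_trip_exact(self):
        for r in np.linspace(-0.999, 0.999, 201):
            assert abs(ss.inverse_fisher_z(ss.fisher_z(r)) - r) < 1e-12

    def test_unit_correlation_rejected_without_clipping(self):
        with pytest.raises(ValueError, match="Fisher"):
            ss.fisher_z(1.0)

    def test_clipping_policy_only_touches_near_perfect(self):
        assert ss.fisher_z(0.9, clip=True) == ss.fisher_z(0.9)
        assert np.isfinite(ss.fisher_z(1.0, clip=True))


class TestTemporalISC:
    def test_hand_computed_three_subjects(self):
        res = ss.temporal_isc(
            _dataset_from_series([[0, 1, 2, 3], [0, 1, 2, 4], [3, 1, 2, 0]])
        )
        tri = np.sort(res.pairwise.lower_triangle())
        np.testing.assert_allclose(
            tri, [-0.8315218, -0.8, 0.9827076], atol=1e-6
        )
        assert abs(res.isc - 0.026433) < 5e-3

    def test_identical_subjects_need_clipping(self):
        series = [np.sin(np.arange(20.0))] * 3
        with pytest.raises(ValueError):
            ss.temporal_isc(_dataset_from_series(series))
        res = ss.temporal_isc(_dataset_from_series(series), clip_r=True)
        assert res.isc > 0.999

    def test_null_white_noise_is_small(self):
        rng = np.random.default_rng(0)
        ds = _dataset_from_series(rng.standard_normal((20, 1000)))
        assert abs(ss.temporal_isc(ds).isc) < 0.02

    def test_constant_subject_named_in_error(self):
        with pytest.raises(ValueError, match="s1"):
            ss.temporal_isc(_dataset_from_series([[0, 1, 2], [5, 5, 5], [2, 1, 0]]))

    def test_affine_invariance_per_subject(self, rng):
        base = rng.standard_normal((5, 80))
        ds1 = _dataset_from_series(base)
        scaled = [3.0 * x + i for i, x in enumerate(base)]
        ds2 = _dataset_from_series(scaled)
        assert abs(ss.temporal_isc(ds1).isc - ss.temporal_isc(ds2).isc) < 1e-12


class TestSpatialISC:
    def test_shared_pattern_with_jitter_near_one(self, rng):
        pattern = rng.standard_normal(50)
        subs = [
            SubjectTimeSeries(f"s{i}", np.vstack([pattern + 1e-6 * rng.standard_normal(50),
                                                  rng.standard_normal(50)]))
            for i in range(5)
        ]
        res = ss.spatial_isc_per_tr(Dataset(subs))
        assert res.values[0] > 0.999

    def test_independent_patterns_average_near_zero(self, rng):
        subs = [
            SubjectTimeSeries(f"s{i}", rng.standard_normal((40, 100)))
            for i in range(10)
        ]
        res = ss.spatial_isc_per_tr(Dataset(subs))
        assert abs(res.mean) < 0.02

    def test_forced_event_window_raises_instantaneous_isc(self):
        ds, truth = ss.simulate_state_dataset(
            n_subjects=10, T=200, V=40, k=4, event_windows=[(80, 120, 1)], seed=3
        )
        res = ss.spatial_isc_per_tr(ds)
        inside = np.nanmean(res.values[80:120])
        outside = np.nanmean(np.r_[res.values[:80], res.values[120:]])
        assert inside > outside

    def test_constant_pattern_tr_reported_missing(self, rng):
        data = rng.standard_normal((5, 10))
        data[2] = 7.0  # constant pattern at TR 2
        subs = [SubjectTimeSeries("a", data), SubjectTimeSeries("b", rng.standard_normal((5, 10)))]
        res = ss.spatial_isc_per_tr(Dataset(subs))
        assert 2 in res.missing_trs
        assert np.isnan(res.values[2])


class TestSpatiotemporalISC:
    def test_identical_subjects_unit_correlation(self, rng):
        data = rng.standard_normal((30, 20))
        ds = Dataset([SubjectTimeSeries("a", data), SubjectTimeSeries("b", data.copy())])
        res = ss.spatiotemporal_isc(ds, clip_r=True)
        assert res.pairwise.r[1, 0] > 0.999

    def test_shared_state_sequence_beats_independent(self):
        emissions = np.random.default_rng(5).standard_normal((4, 30))
        shared, truth = ss.simulate_state_dataset(
            n_subjects=6, T=120, V=30, k=4, emissions=emissions,
            noise_sd=0.3, seed=21,
        )
        # same emissions, but force every subject onto the same path
        path = truth.state_paths_true[0]
        common = Dataset([
            SubjectTimeSeries(
                f"c{i}",
                emissions[path - 1]
                + 0.3 * np.random.default_rng(100 + i).standard_normal((120, 30)),
            )
            for i in range(6)
        ])
        isc_shared = ss.spatiotemporal_isc(common).isc
        isc_idio = ss.spatiotemporal_isc(shared).isc
        assert isc_shared > isc_idio

    def test_independent_noise_near_zero(self, rng):
        subs = [
            SubjectTimeSeries(f"s{i}", rng.standard_normal((100, 50)))
            for i in range(10)
        ]
        assert abs(ss.spatiotemporal_isc(Dataset(subs)).isc) < 0.03


class TestSubjectwiseBootstrap:
    def test_identical_signals_give_smallest_p(self, rng):
        base = rng.standard_normal(60)
        feats = np.stack([base + 1e-4 * rng.standard_normal(60) for _ in range(8)])
        ps = pairwise_similarity(feats, [f"s{i}" for i in range(8)])
        _, p = ss.subjectwise_bootstrap(ps, n_boot=200, seed=0, clip_r=True)
        assert p <= 2 / 201

    def test_deterministic_given_seed(self, rng):
        feats = rng.standard_normal((6, 40))
        ps = pairwise_similarity(feats, [f"s{i}" for i in range(6)])
        d1, p1 = ss.subjectwise_bootstrap(ps, n_boot=150, seed=3)
        d2, p2 = ss.subjectwise_bootstrap(ps, n_boot=150, seed=3)
        np.testing.assert_array_equal(d1, d2)
        assert p1 == p2

    def test_degenerate_similarity_warns(self):
        r = np.full((4, 4), 0.5)
        np.fill_diagonal(r, 1.0)
        ps = ss.PairwiseSimilarity(r=r, labels=list("abcd"))
        with pytest.warns(UserWarning, match="degenerate"):
            ss.subjectwise_bootstrap(ps, n_boot=100, seed=0)


class TestPairedSignPermutation:
    def test_equal_vectors_give_p_one(self):
        a = np.arange(10.0)
        assert ss.paired_sign_permutation(a, a.copy(), n_perm=200, seed=0) == 1.0

    def test_saturated_effect_smallest_p(self, rng):
        b = rng.standard_normal(20)
        a = b + 10 + 0.01 * rng.standard_normal(20)
        p = ss.paired_sign_permutation(a, b, n_perm=200, seed=1)
        assert p <= 2 / 201

    def test_fdr_companion_rejects_none_under_null(self, rng):
        pvals = rng.uniform(0.2, 1.0, size=50)
        reject, adj = fdr_bh(pvals, q=0.05)
        assert not reject.any()
        assert adj.shape == pvals.shape


class TestEq4Oracle:
    def test_matches_brute_force_loop_on_random_instances(self, rng):
        for _ in range(20):
            n = rng.integers(3, 9)
            feats = rng.standard_normal((n, 30))
            ps = pairwise_similarity(feats, [f"s{i}" for i in range(n)])
            assert abs(isc_from_pairwise(ps) - brute_force_isc(ps.r)) < 1e-12
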