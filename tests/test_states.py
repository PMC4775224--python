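"""Opening-event clustering, thresholds, Gaussian-sum fits, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.mixture import GaussianMixture

import forcefret as ff


class TestKmeansCluster:
    def test_three_singletons_zero_inertia(self):
        model = ff.kmeans_cluster([5.0, 15.0, 25.0], [0.4, 0.6, 0.8], k=3)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        assert model.centroids[:, 0] == pytest.approx([5.0, 15.0, 25.0])
        assert model.centroids[:, 1] == pytest.approx([0.4, 0.6, 0.8])

    def test_centroid_recovery_within_three_se(self):
        f, e, _ = ff.simulate_opening_events(80, seed=0)
        model = ff.kmeans_cluster(f, e, k=3, seed=0)
        for i, (mu_f, mu_e, sd_f, sd_e) in enumerate(
            [(7.0, 0.46, 1.5, 0.04), (16.0, 0.68, 1.5, 0.04), (26.0, 0.80, 1.5, 0.04)]
        ):
            se_f, se_e = sd_f / np.sqrt(80), sd_e / np.sqrt(80)
            assert abs(model.centroids[i, 0] - mu_f) < 3 * se_f
            assert abs(model.centroids[i, 1] - mu_e) < 3 * se_e

    def test_same_seed_identical_assignments(self):
        f, e, _ = ff.simulate_opening_events(50, seed=1)
        a = ff.kmeans_cluster(f, e, k=3, seed=5)
        b = ff.kmeans_cluster(f, e, k=3, seed=5)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.centroids == pytest.approx(b.centroids)

    def test_degenerate_and_undersized_inputs_rejected(self):
        with pytest.raises(ValueError):
            ff.kmeans_cluster([1.0, 1.0, 1.0], [0.5, 0.5, 0.5], k=3)
        with pytest.raises(ValueError):
            ff.kmeans_cluster([1.0, 2.0], [0.1, 0.2], k=3)
        with pytest.raises(ValueError):
            ff.kmeans_cluster([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], k=1)


class TestDeriveThresholds:
    def test_midpoint_convention(self):
        model = ff.kmeans_cluster([7.0, 16.0, 26.0], [0.40, 0.70, 0.90], k=3)
        model = ff.derive_thresholds(model)
        assert model.fret_thresholds[0] == pytest.approx(0.55)
        assert model.force_thresholds == pytest.approx((11.5, 21.0))

    def test_invariant_under_event_order_permutation(self):
        f, e, _ = ff.simulate_opening_events(40, seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(f))
        a = ff.derive_thresholds(ff.kmeans_cluster(f, e, k=3, seed=0))
        b = ff.derive_thresholds(ff.kmeans_cluster(f[perm], e[perm], k=3, seed=0))
        assert a.fret_thresholds == pytest.approx(b.fret_thresholds, abs=1e-9)
        assert a.force_thresholds == pytest.approx(b.force_thresholds, abs=1e-9)

    def test_requires_k_three(self):
        model = ff.kmeans_cluster([1.0, 2.0, 9.0, 10.0], [0.1, 0.2, 0.8, 0.9], k=2)
        with pytest.raises(ValueError):
            ff.derive_thresholds(model)


class TestGaussianSumFit:
    def test_single_population_leaves_surplus_components_empty(self):
        rng = np.random.default_rng(3)
        fit = ff.fit_gaussian_sum(rng.normal(0.5, 0.05, 5000))
        order = np.argsort(fit.amplitudes)[::-1]
        assert fit.means[order[0]] == pytest.approx(0.5, abs=0.01)
        assert np.all(fit.amplitudes[order[1:]] < 0.05 * fit.amplitudes[order[0]])

    def test_four_separated_populations_recovered(self):
        rng = np.random.default_rng(4)
        values = np.concatenate(
            [rng.normal(m, 0.04, 2000) for m in (0.10, 0.35, 0.60, 0.85)]
        )
        fit = ff.fit_gaussian_sum(values)
        assert fit.means == pytest.approx([0.10, 0.35, 0.60, 0.85], abs=0.01)
        assert np.all(np.diff(fit.means) > 0)  # sorted ascending
        assert np.all(fit.sds > 0)

    def test_binned_fit_agrees_with_unbinned_oracle(self):
        """Empty edge bins must not shift means: compare against an unbinned
        Gaussian-mixture fit of the same data."""
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(0.3, 0.05, 3000), rng.normal(0.8, 0.05, 3000)]
        )
        fit = ff.fit_gaussian_sum(values, n_components=2)
        gm = GaussianMixture(2, random_state=0).fit(values.reshape(-1, 1))
        oracle = np.sort(gm.means_.ravel())
        assert fit.means == pytest.approx(oracle, abs=0.01)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ff.fit_gaussian_sum(np.random.default_rng(0).normal(0.5, 0.1, 50))


class TestSegmentTrajectory:
    def test_constant_mid_band_is_weakly_bound(self):
        seg = ff.segment_trajectory(np.full(60, 0.65), (0.57, 0.74))
        assert set(seg.labels) == {"WB"}

    def test_two_frame_excursion_reassigned(self):
        e = np.full(60, 0.65)
        e[30:32] = 0.80
        seg = ff.segment_trajectory(e, (0.57, 0.74), excursion_tolerance=2)
        assert set(seg.labels) == {"WB"}

    def test_constant_low_is_apo(self):
        seg = ff.segment_trajectory(np.full(60, 0.40), (0.57, 0.74))
        assert set(seg.labels) == {"APO"}

    def test_sustained_level_shift_changes_state(self):
        rng = np.random.default_rng(6)
        e = np.concatenate([rng.normal(0.45, 0.05, 150), rng.normal(0.80, 0.05, 150)])
        seg = ff.segment_trajectory(e)
        assert np.mean(seg.labels[:150] == "APO") > 0.9
        assert np.mean(seg.labels[150:] == "SB") > 0.9

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        e = np.concatenate([rng.normal(0.46, 0.06, 200), rng.normal(0.73, 0.1, 200)])
        first = ff.segment_trajectory(e).labels
        second = ff.segment_trajectory(e).labels
        assert np.array_equal(first, second)

    def test_invalid_frames_are_hard_boundaries(self):
        e = np.concatenate([np.full(30, 0.65), [np.nan] * 3, np.full(30, 0.40)])
        seg = ff.segment_trajectory(e)
        assert np.all(seg.labels[30:33] == "INVALID")
        assert set(seg.labels[:30]) == {"WB"}
        assert set(seg.labels[33:]) == {"APO"}

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ff.segment_trajectory(np.array([]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_labels_deterministic_and_complete(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(0.65, 0.12, 120)
        seg = ff.segment_trajectory(e)
        assert len(seg.labels) == len(e)
        assert set(seg.labels) <= {"APO", "WB", "SB"}


class TestPoolStateStatistics:
    def test_single_constant_trace(self):
        seg = ff.segment_trajectory(np.full(40, 0.73), (0.57, 0.74))
        stats = ff.pool_state_statistics([seg])
        assert stats["WB"]["mean"] == pytest.approx(0.73)
        assert stats["WB"]["variance"] == pytest.approx(0.0)
        assert stats["WB"]["n"] == 40
        assert "APO" not in stats  # absent, not zero

    def test_pooled_mean_is_weighted_mean_of_traces(self):
        rng = np.random.default_rng(8)
        segs = [
            ff.segment_trajectory(rng.normal(0.65, 0.02, n), (0.57, 0.74))
            for n in (50, 200)
        ]
        stats = ff.pool_state_statistics(segs)
        ns = [np.sum(s.labels == "WB") for s in segs]
        mus = [s.efficiency[s.labels == "WB"].mean() for s in segs]
        weighted = np.average(mus, weights=ns)
        assert stats["WB"]["mean"] == pytest.approx(weighted, rel=1e-12)
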