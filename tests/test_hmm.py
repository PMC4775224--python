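"""Sequential HMM fitting, decoding and dwell-time rate extraction."""

import numpy as np
import pytest

import forcefret as ff
from forcefret.hmm import HMMModel


def _toy_model(means, sds=None, p_stay=0.9, frame_period=0.05):
    n = len(means)
    t = np.zeros((n, n))
    for i in range(n):
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
        t[i, i] = p_stay
        for j in nbrs:
            t[i, j] = (1 - p_stay) / len(nbrs)
    return HMMModel(
        n_states=n,
        means=np.asarray(means, dtype=float),
        sds=np.asarray(sds if sds is not None else [0.05] * n, dtype=float),
        transmat=t,
        startprob=np.full(n, 1.0 / n),
        frame_period=frame_period,
        log_likelihood=0.0,
        ll_history=np.array([0.0]),
        converged=True,
        state_names=tuple(f"S{i}" for i in range(n)) if n != 4 else ("UF", "A", "B", "C"),
    )


def brute_force_viterbi(model, series):
    """Exhaustive maximum-likelihood path over all n_states**T paths."""
    k, t = model.n_states, len(series)
    paths = np.indices((k,) * t).reshape(t, -1).T  # (k^T, T)
    log_a = np.where(model.transmat > 0, np.log(np.where(model.transmat > 0, model.transmat, 1)), -np.inf)
    log_pi = np.log(model.startprob)
    log_b = (
        -0.5 * ((series[None, :] - model.means[:, None]) / model.sds[:, None]) ** 2
        - np.log(model.sds)[:, None]
    )  # (k, T)
    score = log_pi[paths[:, 0]] + log_b[paths[:, 0], 0]
    for i in range(1, t):
        score = score + log_a[paths[:, i - 1], paths[:, i]] + log_b[paths[:, i], i]
    return paths[np.argmax(score)]


class TestConcatenateRefolds:
    def test_lengths_and_boundaries(self, mech, cf):
        cfg = ff.condition_sim_config("TPP", refold_duration=5.0, ramp_enabled=False)
        traces = [ff.simulate_trace(cfg, mech, seed=s) for s in range(2)]
        series, lengths = ff.concatenate_refolds(traces, cf)
        assert list(lengths) == [100, 100]
        assert len(series) == 200

    def test_traces_without_refold_skipped_with_warning(self, mech, cf):
        cfg = ff.condition_sim_config("TPP", refold_duration=5.0, ramp_enabled=False)
        good = ff.simulate_trace(cfg, mech, seed=0)
        bad = ff.simulate_trace(
            ff.condition_sim_config("TPP", refold_duration=0.05), mech, seed=1
        )
        with pytest.warns(UserWarning, match="refold"):
            series, lengths = ff.concatenate_refolds([good, bad], cf)
        assert len(lengths) == 1

    def test_order_permutation_leaves_emissions_unchanged(self, mech, cf):
        cfg = ff.condition_sim_config("TPP", refold_duration=15.0, ramp_enabled=False)
        traces = [ff.simulate_trace(cfg, mech, seed=s) for s in range(8)]
        s1, l1 = ff.concatenate_refolds(traces, cf)
        s2, l2 = ff.concatenate_refolds(traces[::-1], cf)
        m1 = ff.fit_hmm(s1, l1, n_states=4, seed=0, n_restarts=1)
        m2 = ff.fit_hmm(s2, l2, n_states=4, seed=0, n_restarts=1)
        assert m1.means == pytest.approx(m2.means, abs=0.02)


class TestFitHmm:
    def test_two_state_emission_recovery(self):
        """Synthetic two-level series: emission means recovered to 0.01."""
        rng = np.random.default_rng(0)
        chunks, state = [], 0
        for _ in range(200):
            n = rng.integers(5, 40)
            chunks.append(rng.normal((0.3, 0.8)[state], 0.05, n))
            state = 1 - state
        series = np.concatenate(chunks)
        model = ff.fit_hmm(series, [len(series)], n_states=2, seed=0)
        assert model.means == pytest.approx([0.3, 0.8], abs=0.01)

    def test_banded_topology_forbids_state_skips(self, mech, cf):
        cfg = ff.condition_sim_config("TPP", refold_duration=20.0, ramp_enabled=False)
        traces = [ff.simulate_trace(cfg, mech, seed=s) for s in range(10)]
        series, lengths = ff.concatenate_refolds(traces, cf)
        model = ff.fit_hmm(series, lengths, n_states=4, seed=0, n_restarts=1)
        # P(A -> C in one frame) and all other off-band entries exactly zero
        band = np.abs(np.subtract.outer(range(4), range(4))) <= 1
        assert np.all(model.transmat[~band] == 0.0)
        assert model.transmat[1, 3] == 0.0

    def test_log_likelihood_monotone_over_em(self, mech, cf):
        cfg = ff.condition_sim_config("TPP", refold_duration=20.0, ramp_enabled=False)
        traces = [ff.simulate_trace(cfg, mech, seed=s) for s in range(5)]
        series, lengths = ff.concatenate_refolds(traces, cf)
        model = ff.fit_hmm(series, lengths, n_states=4, seed=0, n_restarts=1)
        assert np.all(np.diff(model.ll_history) >= -1e-6)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            ff.fit_hmm(np.full(100, 0.5), [100], n_states=2)


class TestViterbiPath:
    def test_noiseless_series_decodes_generating_path(self):
        model = _toy_model([0.2, 0.5, 0.8], sds=[0.05, 0.05, 0.05], p_stay=0.8)
        truth = np.array([0, 0, 1, 1, 1, 2, 2, 1, 0, 0])
        series = model.means[truth]
        assert np.array_equal(ff.viterbi_path(model, series, [10]), truth)

    def test_path_never_skips_a_state(self):
        model = _toy_model([0.1, 0.4, 0.6, 0.9], p_stay=0.95)
        rng = np.random.default_rng(1)
        series = rng.uniform(0, 1, 500)
        path = ff.viterbi_path(model, series, [250, 250])
        # jumps within each segment stay on the chain
        assert np.all(np.abs(np.diff(path[:250])) <= 1)
        assert np.all(np.abs(np.diff(path[250:])) <= 1)

    def test_agrees_with_exhaustive_enumeration(self):
        """Oracle: argmax over all 4^10 paths of the joint log-probability."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            means = np.sort(rng.uniform(0.1, 0.9, 4))
            model = _toy_model(means, sds=rng.uniform(0.03, 0.15, 4),
                               p_stay=rng.uniform(0.6, 0.95))
            series = rng.uniform(0, 1, 10)
            expected = brute_force_viterbi(model, series)
            assert np.array_equal(ff.viterbi_path(model, series, [10]), expected)


class TestTransitionRates:
    def test_reciprocal_of_directional_transition_time(self):
        """Dwells of 0.4 s and 0.6 s in B, each exiting to C: the B->C
        transition time is 0.5 s and the rate 2.0 /s."""
        fp = 0.05
        b, c, a = 2, 3, 1
        path = (
            [a] * 5 + [b] * 8 + [c] * 10 + [b] * 12 + [c] * 5
        )  # dwells: 8 and 12 frames = 0.4 s, 0.6 s
        table = ff.transition_rates(np.array(path), [len(path)], fp)
        assert table.transition_times["B->C"] == pytest.approx(0.5)
        assert table.rates["B->C"] == pytest.approx(2.0)
        assert table.counts["B->C"] == 2

    def test_boundary_dwells_censored(self):
        fp = 0.05
        path = np.array([2] * 10 + [3] * 10)
        # single segment: both dwells touch a boundary -> no complete dwells
        table = ff.transition_rates(path, [20], fp)
        assert "B->C" in table.absent
        assert table.censored["B"] == 1

    def test_boundary_crossing_contributes_no_transition(self):
        fp = 0.05
        seg = [1] * 10 + [2] * 10 + [1] * 10
        path = np.array(seg + seg)
        split = ff.transition_rates(path, [30, 30], fp)
        fused = ff.transition_rates(path, [60], fp)
        # fused counts one extra A-dwell completed across the junction
        assert fused.counts["A->B"] == split.counts["A->B"] + 1

    def test_ctmc_rate_recovery_within_ten_percent(self):
        """500+ complete dwells in B at k(B->C) = 1.0 /s, k(B->A) = 0.5 /s."""
        rng = np.random.default_rng(3)
        fp = 0.02
        path = []
        state = 1
        for _ in range(4000):
            if state == 1:
                path += [1] * max(1, rng.geometric(0.8))
                state = 2
            else:
                dwell = rng.exponential(1.0 / 1.5)  # total exit rate 1.5 /s
                path += [2] * max(1, int(round(dwell / fp)))
                state = 3 if rng.uniform() < (1.0 / 1.5) else 1
                path += [state] * max(1, rng.geometric(0.8))
                state = 1
        table = ff.transition_rates(np.array(path), [len(path)], fp)
        assert table.counts["B->C"] > 500
        assert table.rates["B->C"] == pytest.approx(1.0, rel=0.1)
        assert table.rates["B->A"] == pytest.approx(0.5, rel=0.1)

    def test_fast_rates_flagged_as_lower_bounds(self):
        fp = 0.05
        path = np.array([1] + [2, 3] * 30 + [1])
        table = ff.transition_rates(path, [len(path)], fp)
        assert table.lower_bound["B->C"]  # ~20 /s at a 20 frames/s camera
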