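"""Simulator ground truth: hidden-state kinetics, photon statistics,
quasi-static mechanics and reproducibility."""

import numpy as np
import pytest
from scipy import stats as sps

import forcefret as ff
from forcefret.simulate import rate_matrix

from conftest import ZERO_KINETICS


class TestHiddenStateKinetics:
    def test_frozen_chain_stays_in_initial_state(self, mech):
        cfg = ff.condition_sim_config(
            "TPP",
            kinetics=dict(ZERO_KINETICS),
            initial_tertiary="A",
            refold_duration=5.0,
            ramp_enabled=False,
        )
        trace = ff.simulate_trace(cfg, mech, seed=0)
        assert np.all(trace.truth_tertiary == "APO")

    def test_stationary_closed_form_matches_generator(self):
        """Detailed-balance closed form vs the eigenvector of the generator."""
        kin = {"UF->A": 2.0, "A->UF": 0.3, "A->B": 1.0, "B->A": 0.1, "B->C": 0.5, "C->B": 0.05}
        q = rate_matrix(kin)
        w, v = np.linalg.eig(q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi /= pi.sum()
        assert ff.ctmc_stationary(kin) == pytest.approx(pi, abs=1e-12)
        sub = ff.ctmc_stationary(kin, ("A", "B", "C"))
        assert sub == pytest.approx(pi[1:] / pi[1:].sum(), abs=1e-12)

    def test_refold_occupancy_matches_subchain_stationary(self, mech):
        """Fraction of refold time in A/B/C over replicate traces matches the
        closed-form stationary occupancy of the folded subchain within 3 SE."""
        kin = {"UF->A": 2.0, "A->UF": 0.3, "A->B": 1.0, "B->A": 0.1, "B->C": 0.5, "C->B": 0.05}
        cfg = ff.condition_sim_config(
            "TPP",
            kinetics=kin,
            refold_duration=30.0,
            ramp_enabled=False,
            initial_tertiary="stationary",
        )
        fracs = []
        for seed in range(1000):
            t = ff.simulate_trace(cfg, mech, seed=seed)
            counts = [np.sum(t.truth_tertiary == s) for s in ("APO", "WB", "SB")]
            tot = sum(counts)
            if tot:
                fracs.append(np.asarray(counts) / tot)
        fracs = np.asarray(fracs)
        target = ff.ctmc_stationary(kin, ("A", "B", "C"))
        se = fracs.std(axis=0, ddof=1) / np.sqrt(len(fracs))
        assert np.all(np.abs(fracs.mean(axis=0) - target) < 3 * se)

    def test_dwell_times_are_exponential(self):
        """KS test of sampled dwell durations against Exp(total exit rate)."""
        kin = {"UF->A": 1.0, "A->UF": 0.8, "A->B": 1.2, "B->A": 0.7, "B->C": 0.9, "C->B": 1.1}
        q = rate_matrix(kin)
        rng = np.random.default_rng(12)
        dwells = {s: [] for s in ("UF", "A", "B", "C")}
        while min(len(v) for v in dwells.values()) < 500:
            states, times = ff.sample_ctmc(kin, 2000.0, "stationary", rng)
            bounds = np.append(times, 2000.0)
            for s, t0, t1 in zip(states[:-1], bounds[:-2], bounds[1:-1]):
                dwells[s].append(t1 - t0)  # last visit censored, excluded
        for i, s in enumerate(("UF", "A", "B", "C")):
            rate = -q[i, i]
            _, p = sps.kstest(dwells[s][:2000], "expon", args=(0, 1.0 / rate))
            assert p > 0.01, f"dwells in {s} not Exp({rate})"


class TestPhotonChannels:
    def test_zero_fret_without_crosstalk_gives_zero_acceptor(self, mech):
        cfg = ff.condition_sim_config("TPP", beta=0.0, bg_donor=0.0, bg_acceptor=0.0)
        rng = np.random.default_rng(0)
        _, i_a = ff.simulate_photon_frame(0.0, cfg, rng)
        assert i_a == 0

    def test_balanced_split_at_half_transfer(self):
        """E = 0.5, gamma = 1, 1000 photons/frame -> (500, 500) +/- 3 SE."""
        cfg = ff.condition_sim_config(
            "TPP", beta=0.0, gamma=1.0, bg_donor=0.0, bg_acceptor=0.0,
            donor_rate=20000.0,
        )
        rng = np.random.default_rng(1)
        d, a = ff.simulate_photon_frames(np.full(100_000, 0.5), cfg, rng)
        se = np.sqrt(500.0 / 100_000)
        assert abs(d.mean() - 500.0) < 3 * se
        assert abs(a.mean() - 500.0) < 3 * se

    def test_default_crosstalk_ratio(self):
        """Donor-only frames show the default 0.13 acceptor/donor ratio."""
        cfg = ff.condition_sim_config(
            "TPP", bg_donor=0.0, bg_acceptor=0.0, donor_rate=16000.0
        )
        rng = np.random.default_rng(2)
        d, a = ff.simulate_photon_frames(np.zeros(100_000), cfg, rng)
        assert a.mean() / d.mean() == pytest.approx(0.13, abs=0.002)

    def test_rejects_invalid_efficiency(self):
        cfg = ff.condition_sim_config("TPP")
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            ff.simulate_photon_frame(1.2, cfg, rng)
        with pytest.raises(ValueError):
            ff.simulate_photon_frames(np.array([0.3, -0.1]), cfg, rng)


class TestQuasiStaticMechanics:
    def test_short_separation_gives_negligible_force(self, mech):
        f, _ = ff.simulate_fec_point(10.0, "F", mech, 0.3)
        assert f == pytest.approx(0.0, abs=0.01)
        f0, x0 = ff.simulate_fec_point(0.0, "F", mech, 0.3)
        assert f0 == 0.0 and x0 == 0.0

    def test_force_nondecreasing_in_separation(self, mech):
        seps = np.linspace(850, 1100, 30)
        forces = [ff.simulate_fec_point(s, "F", mech, 0.3)[0] for s in seps]
        assert np.all(np.diff(forces) >= 0)

    def test_unfolding_at_fixed_separation(self, mech):
        """Releasing the RNA at fixed separation: extension up, force down."""
        f_fold, x_fold = ff.simulate_fec_point(1050.0, "Fpp", mech, 0.3)
        f_uf, x_uf = ff.simulate_fec_point(1050.0, "UF", mech, 0.3)
        assert x_uf > x_fold
        assert f_uf < f_fold

    def test_rupture_force_draws_match_configured_mean(self, mech):
        """Per-class drawn critical forces of the first rip within 3 SE."""
        for cls, init in (("F", "A"), ("Fp", "B"), ("Fpp", "C")):
            cfg = ff.condition_sim_config(
                "TPP", refold_duration=0.5, initial_tertiary=init,
                kinetics=dict(ZERO_KINETICS),
            )
            first = [
                ff.simulate_trace(cfg, mech, seed=s).meta["rupture_forces_drawn"][0]
                for s in range(150)
            ]
            mu, sd = cfg.rupture_forces[cls][0]
            se = np.std(first, ddof=1) / np.sqrt(len(first))
            assert abs(np.mean(first) - mu) < 3 * se


class TestTraceRecord:
    def test_identical_seeds_bitwise_identical(self, mech):
        cfg = ff.condition_sim_config("TPP", refold_duration=5.0)
        a = ff.simulate_trace(cfg, mech, seed=42)
        b = ff.simulate_trace(cfg, mech, seed=42)
        for f in ("time", "trap_separation", "force", "extension", "i_donor", "i_acceptor"):
            assert np.array_equal(getattr(a, f), getattr(b, f)), f
        assert np.array_equal(a.truth_tertiary, b.truth_tertiary)

    def test_truth_labels_cover_every_frame(self, mech):
        t = ff.simulate_trace(ff.condition_sim_config("TPP"), mech, seed=3)
        assert len(t.truth_tertiary) == len(t) == len(t.truth_conformation)
        assert t.time[1] - t.time[0] == pytest.approx(0.05)
        assert np.all(np.diff(t.time) > 0)
        assert np.all(t.i_donor >= 0) and np.all(t.i_acceptor >= 0)

    def test_frame_budget_too_small_rejected(self, mech):
        cfg = ff.condition_sim_config("TPP", refold_duration=30.0, n_frames_max=100)
        with pytest.raises(ValueError, match="n_frames_max"):
            ff.simulate_trace(cfg, mech, seed=0)

    def test_invalid_config_parameters_rejected(self):
        with pytest.raises(ValueError):
            ff.condition_sim_config("TPP", frame_period=0.0)
        with pytest.raises(ValueError):
            ff.condition_sim_config("TPP", beta=1.0)
        with pytest.raises(ValueError):
            ff.condition_sim_config(
                "TPP",
                fret_states={
                    "UNFOLDED": (0.44, 0.08),
                    "APO": (0.8, 0.06),  # breaks APO < WB < SB ordering
                    "WB": (0.73, 0.1),
                    "SB": (0.80, 0.04),
                },
            )

    def test_bleaching_silences_channels(self, mech):
        cfg = ff.condition_sim_config(
            "none", refold_duration=20.0, ramp_enabled=False,
            bleach_rate_donor=0.5, bg_donor=5.0, bg_acceptor=5.0,
        )
        t = ff.simulate_trace(cfg, mech, seed=8)
        tail = slice(len(t) - 40, len(t))  # donor bleaches well before 20 s
        assert t.i_donor[tail].mean() < 30  # backgrounds only
        assert t.i_acceptor[tail].mean() < 30
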