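"""Synthetic dumbbell force-FRET experiment generator.

One simulated cycle mirrors the assay: the traps are brought close so the
aptamer refolds under low load (< 5 pN) while its tertiary state evolves as
a continuous-time Markov chain UF <-> A <-> B <-> C; the trap separation is
then ramped linearly, and the secondary-structure conformation held at ramp
start (F, F'.TPP or F''.TPP, set by the tertiary state reached during
refolding) ruptures in its characteristic sequence of rips, each a
Gaussian-distributed critical force releasing a known contour gain.

Mechanics are quasi-static: at every frame the force balances the trap
displacement against the series worm-like chain (handles + released RNA).
Photon channels are Poisson counts around the expected donor/acceptor
signal for the frame's true FRET efficiency, including donor->acceptor
leakage (beta), detection imbalance (gamma), backgrounds, and optional
bleaching/blinking.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .config import (
    CONFORMATIONS,
    KINETIC_TRANSITIONS,
    TERTIARY_LABELS,
    TERTIARY_STATES,
    MechanicalModel,
    SimConfig,
)
from .trace import TraceRecord
from .wlc import wlc_extension

__all__ = [
    "simulate_trace",
    "simulate_photon_frame",
    "simulate_photon_frames",
    "simulate_fec_point",
    "simulate_opening_events",
    "sample_ctmc",
    "ctmc_stationary",
    "rate_matrix",
]

_STATE_INDEX = {s: i for i, s in enumerate(TERTIARY_STATES)}
_TERTIARY_OF_CONF = {"F": "A", "Fp": "B", "Fpp": "C"}
_CONF_OF_STATE = {"UF": "UF", "A": "F", "B": "Fp", "C": "Fpp"}


# ---------------------------------------------------------------------------
# hidden-state kinetics

def rate_matrix(kinetics: dict) -> np.ndarray:
    """4x4 CTMC generator for the sequential chain UF <-> A <-> B <-> C."""
    if set(kinetics) != set(KINETIC_TRANSITIONS):
        raise ValueError(f"kinetics must define exactly {KINETIC_TRANSITIONS}")
    q = np.zeros((4, 4))
    for key, rate in kinetics.items():
        a, b = key.split("->")
        q[_STATE_INDEX[a], _STATE_INDEX[b]] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def ctmc_stationary(kinetics: dict, states=TERTIARY_STATES) -> np.ndarray:
    """Stationary occupancy of the (sub)chain restricted to ``states``.

    The chain is birth-death, so detailed balance gives the closed form
    pi_{i+1}/pi_i = k(i -> i+1)/k(i+1 -> i) along the requested span.
    Transitions with zero reverse rate make the upstream states transient
    (weight 0).
    """
    idx = [TERTIARY_STATES.index(s) for s in states]
    if sorted(idx) != list(range(min(idx), max(idx) + 1)):
        raise ValueError("states must be a contiguous span of the chain")
    order = sorted(idx)
    fwd = {0: "UF->A", 1: "A->B", 2: "B->C"}
    rev = {0: "A->UF", 1: "B->A", 2: "C->B"}
    w = [1.0]
    for i in order[:-1]:
        kf, kr = kinetics[fwd[i]], kinetics[rev[i]]
        if kr == 0.0:
            if kf == 0.0:
                w.append(0.0)  # unreachable upward
                continue
            # absorbing upward: all stationary mass moves past i
            w = [0.0] * len(w)
            w.append(1.0)
            continue
        w.append(w[-1] * kf / kr)
    w = np.asarray(w, dtype=float)
    out = w / w.sum()
    # return in the order the caller asked for
    return out[[order.index(i) for i in idx]]


def sample_ctmc(
    kinetics: dict,
    duration: float,
    initial: str,
    rng: np.random.Generator,
):
    """Sample one CTMC path.

    Returns (states, times): visited state labels and entry times, with
    ``times[0] == 0``; the final visit is censored at ``duration``.
    ``initial`` may be a state label or ``"stationary"``.
    """
    q = rate_matrix(kinetics)
    if initial == "stationary":
        pi = ctmc_stationary(kinetics)
        state = int(rng.choice(4, p=pi))
    else:
        state = _STATE_INDEX[initial]
    states, times = [TERTIARY_STATES[state]], [0.0]
    t = 0.0
    while True:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        p = q[state].clip(min=0.0)
        state = int(rng.choice(4, p=p / p.sum()))
        states.append(TERTIARY_STATES[state])
        times.append(t)
    return states, np.asarray(times)


def _states_at(times_grid: np.ndarray, states: list, entry_times: np.ndarray):
    """State label at each requested time (piecewise-constant path)."""
    idx = np.searchsorted(entry_times, times_grid, side="right") - 1
    return np.asarray(states, dtype=object)[idx]


# ---------------------------------------------------------------------------
# photon channels

def _expected_counts(e_true, config: SimConfig):
    e = np.asarray(e_true, dtype=float)
    budget = config.donor_rate * config.frame_period
    donor_signal = budget * (1.0 - e)
    acceptor_signal = budget * e * config.gamma
    mu_d = donor_signal + config.bg_donor
    mu_a = acceptor_signal + config.beta * donor_signal + config.bg_acceptor
    return mu_d, mu_a


def simulate_photon_frame(e_true: float, config: SimConfig, rng: np.random.Generator):
    """Poisson donor/acceptor counts for one frame at true efficiency E."""
    if not 0.0 <= e_true <= 1.0:
        raise ValueError("E_true must be in [0, 1]")
    mu_d, mu_a = _expected_counts(e_true, config)
    return int(rng.poisson(mu_d)), int(rng.poisson(mu_a))


def simulate_photon_frames(e_true, config: SimConfig, rng: np.random.Generator):
    """Vectorized Poisson counts for an array of per-frame efficiencies."""
    e = np.asarray(e_true, dtype=float)
    if np.any(e < 0) or np.any(e > 1):
        raise ValueError("E_true must be in [0, 1]")
    mu_d, mu_a = _expected_counts(e, config)
    return rng.poisson(mu_d), rng.poisson(mu_a)


# ---------------------------------------------------------------------------
# quasi-static mechanics

def _molecular_extension(force: float, mech: MechanicalModel, released_nm: float) -> float:
    x = wlc_extension(force, mech.handle1) + wlc_extension(force, mech.handle2)
    if released_nm > 1e-9:
        x += wlc_extension(force, mech.released_params(released_nm))
    return x


def _resolve_released(conformation, mech: MechanicalModel) -> float:
    if isinstance(conformation, str):
        if conformation == "UF":
            return max(mech.total_gain(c) for c in mech.contour_gain)
        if conformation in CONFORMATIONS:
            return 0.0
        raise ValueError(f"unknown conformation {conformation!r}")
    released = float(conformation)
    if released < 0:
        raise ValueError("released contour must be >= 0")
    return released


def simulate_fec_point(
    trap_separation: float,
    conformation,
    mech: MechanicalModel,
    stiffness: float,
    f_hint: float | None = None,
):
    """Quasi-static (force, extension) at one trap separation.

    ``conformation`` is a class label ("F"/"Fp"/"Fpp" = folded, "UF" =
    fully unfolded) or a float giving the released ssRNA contour in nm.
    Solves trap_force = WLC tension by bracketed root finding; the slack
    regime (separation shorter than needed for any tension) returns zero
    force.
    """
    if trap_separation < 0:
        raise ValueError("trap separation must be >= 0")
    if stiffness <= 0:
        raise ValueError("stiffness must be > 0")
    released = _resolve_released(conformation, mech)

    def resid(f: float) -> float:
        return f / stiffness + _molecular_extension(f, mech, released) - trap_separation

    if resid(0.0) >= 0.0:
        return 0.0, trap_separation  # slack tether
    lo, hi = 0.0, 10.0
    if f_hint is not None and f_hint > 0:
        lo = max(0.0, f_hint - 2.0)
        hi = f_hint + 4.0
        if resid(lo) > 0:
            lo = 0.0
    while resid(hi) < 0.0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("force-balance root find failed to bracket")
    force = brentq(resid, lo, hi, rtol=1e-10, maxiter=200)
    extension = trap_separation - force / stiffness
    return force, extension


# ---------------------------------------------------------------------------
# full cycle

def _draw_rip_forces(
    conformation: str, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Critical forces for the conformation's rip schedule, kept strictly
    increasing (and above the refold load) so successive rips land in
    distinct frames of the quasi-static ramp."""
    crits = []
    floor = config.refold_force + 1.5
    for mu, sd in config.rupture_forces[conformation]:
        f = max(rng.normal(mu, sd), floor)
        crits.append(f)
        floor = f + config.min_rip_force_gap
    return np.asarray(crits)


def simulate_trace(
    config: SimConfig,
    mech: MechanicalModel | None = None,
    seed: int | None = None,
) -> TraceRecord:
    """Simulate one refold + ramp cycle with ground-truth labels.

    Identical (config, mech, seed) triples give bitwise-identical records.
    """
    mech = mech or MechanicalModel()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    for c in config.rupture_forces:
        if len(config.rupture_forces[c]) != len(mech.contour_gain[c]):
            raise ValueError(f"rip schedule mismatch for {c!r} between config and mechanics")

    n_refold = int(round(config.refold_duration / config.frame_period))
    if n_refold > config.n_frames_max:
        raise ValueError("n_frames_max too small to cover refold_duration")

    # --- refolding period: CTMC on the tertiary state at constant low load
    path_states, path_times = sample_ctmc(
        config.kinetics, config.refold_duration, config.initial_tertiary, rng
    )
    frame_mid = (np.arange(n_refold) + 0.5) * config.frame_period
    tert = list(_states_at(frame_mid, path_states, path_times))

    total_unfolded = max(mech.total_gain(c) for c in mech.contour_gain)
    k = config.trap_stiffness
    f0 = config.refold_force
    x_folded = _molecular_extension(f0, mech, 0.0)
    sep_refold = x_folded + f0 / k
    # at fixed separation the force relaxes when the RNA contour is released
    def _force_at_fixed_sep(released: float, hint: float) -> tuple:
        return simulate_fec_point(sep_refold, released, mech, k, f_hint=hint)

    f_uf, x_uf = _force_at_fixed_sep(total_unfolded, f0)

    force = [f0 if s != "UF" else f_uf for s in tert]
    ext = [x_folded if s != "UF" else x_uf for s in tert]
    sep = [sep_refold] * n_refold

    # --- force ramp on the conformation held at ramp start
    ramp_conf = _CONF_OF_STATE[tert[-1]] if n_refold else _CONF_OF_STATE[config.initial_tertiary]
    rip_frames: list[int] = []  # first post-rip frame, absolute index
    rip_crits = np.empty(0)
    released_per_frame: list[float] = []
    if config.ramp_enabled:
        if ramp_conf == "UF":
            released = total_unfolded
            gains = np.empty(0)
            rip_crits = np.empty(0)
        else:
            released = 0.0
            gains = np.asarray(mech.contour_gain[ramp_conf], dtype=float)
            rip_crits = _draw_rip_forces(ramp_conf, config, rng)
        s = sep_refold if ramp_conf == "UF" else x_folded + f0 / k
        # re-balance the starting separation for an unfolded molecule
        if ramp_conf == "UF":
            s = _molecular_extension(f0, mech, released) + f0 / k
        f_prev = f0
        next_rip = 0
        frame = n_refold
        while frame < config.n_frames_max:
            s += config.ramp_speed * config.frame_period
            f, x = simulate_fec_point(s, released, mech, k, f_hint=f_prev)
            while next_rip < len(rip_crits) and f >= rip_crits[next_rip]:
                released += gains[next_rip]
                rip_frames.append(frame)
                next_rip += 1
                f, x = simulate_fec_point(s, released, mech, k, f_hint=f_prev)
            force.append(f)
            ext.append(x)
            sep.append(s)
            tert.append(tert[-1] if n_refold else config.initial_tertiary)
            released_per_frame.append(released)
            f_prev = f
            frame += 1
            if f >= config.ramp_max_force and next_rip >= len(rip_crits):
                break

    n = len(force)
    time = np.arange(n) * config.frame_period
    force = np.asarray(force)
    ext = np.asarray(ext)
    sep = np.asarray(sep)
    tert = np.asarray(tert, dtype=object)

    # tertiary truth on the ramp: held state until the first rip, then unfolded
    first_rip = rip_frames[0] if rip_frames else None
    truth_tert = np.array([TERTIARY_LABELS[s] for s in tert], dtype=object)
    truth_conf = np.array([_CONF_OF_STATE[s] for s in tert], dtype=object)
    if config.ramp_enabled and n > n_refold:
        ramp_idx = np.arange(n_refold, n)
        truth_conf[ramp_idx] = ramp_conf
        truth_tert[ramp_idx] = (
            TERTIARY_LABELS[_TERTIARY_OF_CONF[ramp_conf]] if ramp_conf != "UF" else "UNFOLDED"
        )
        if first_rip is not None:
            truth_conf[first_rip:] = "UF"
            truth_tert[first_rip:] = "UNFOLDED"

    # --- true per-frame FRET efficiency
    e_true = np.empty(n)
    for i in range(n):
        if truth_tert[i] == "UNFOLDED" and i >= n_refold:
            mu, sd = config.stretched_fret
        else:
            mu, sd = config.fret_states[truth_tert[i]]
        e_true[i] = mu + sd * rng.standard_normal()
    np.clip(e_true, 0.0, 1.0, out=e_true)

    # --- photophysics: bleaching and (optional) acceptor blinking
    donor_alive = np.ones(n, dtype=bool)
    acceptor_on = np.ones(n, dtype=bool)
    if config.bleach_rate_donor > 0:
        t_bleach = rng.exponential(1.0 / config.bleach_rate_donor)
        donor_alive = time < t_bleach
    if config.bleach_rate_acceptor > 0:
        t_bleach = rng.exponential(1.0 / config.bleach_rate_acceptor)
        acceptor_on &= time < t_bleach
    if config.blink_rate_off > 0:
        on = True
        t = 0.0
        while t < time[-1] + config.frame_period:
            rate = config.blink_rate_off if on else config.blink_rate_on
            t_next = t + rng.exponential(1.0 / rate)
            if not on:
                acceptor_on &= ~((time >= t) & (time < t_next))
            on = not on
            t = t_next
    e_emit = np.where(acceptor_on, e_true, 0.0)
    budget = config.donor_rate * config.frame_period
    donor_signal = np.where(donor_alive, budget * (1.0 - e_emit), 0.0)
    acceptor_signal = np.where(donor_alive, budget * e_emit * config.gamma, 0.0)
    i_donor = rng.poisson(donor_signal + config.bg_donor)
    i_acceptor = rng.poisson(
        acceptor_signal + config.beta * donor_signal + config.bg_acceptor
    )

    force_meas = force + config.force_noise * rng.standard_normal(n)
    ext_meas = ext + config.extension_noise * rng.standard_normal(n)

    meta = {
        "seed": int(config.seed if seed is None else seed),
        "ligand_condition": config.ligand_condition,
        "ramp_conformation": ramp_conf,
        "rip_frames": [int(i) for i in rip_frames],
        "rupture_forces_drawn": [float(f) for f in rip_crits[: len(rip_frames)]],
        "opening_forces_frame": [float(force[i - 1]) for i in rip_frames],
        "e_true_mean_by_state": {
            s: float(v[0]) for s, v in config.fret_states.items()
        },
    }
    return TraceRecord(
        time=time,
        trap_separation=sep,
        force=np.clip(force_meas, 0.0, None),
        extension=ext_meas,
        i_donor=i_donor,
        i_acceptor=i_acceptor,
        refold_end_index=n_refold,
        truth_conformation=truth_conf,
        truth_tertiary=truth_tert,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# opening-event scatter (cluster-analysis input)

DEFAULT_EVENT_CLUSTERS = {
    # conformation class -> (mean force pN, mean FRET, SD force, SD FRET)
    "F": (7.0, 0.46, 1.5, 0.04),
    "Fp": (16.0, 0.68, 1.5, 0.04),
    "Fpp": (26.0, 0.80, 1.5, 0.04),
}


def simulate_opening_events(
    n_per_class: int = 50,
    clusters: dict | None = None,
    seed: int = 0,
):
    """Draw (opening force, opening FRET) pairs from per-class bivariate
    Gaussians, emulating the scatter of FEC opening transitions.

    Returns (forces, frets, labels) as arrays of length 3 * n_per_class.
    The default cluster centres place the force midpoints at 11.5 / 21.0 pN
    and the FRET midpoints at 0.57 / 0.74.
    """
    clusters = clusters or DEFAULT_EVENT_CLUSTERS
    rng = np.random.default_rng(seed)
    forces, frets, labels = [], [], []
    for cls, (mu_f, mu_e, sd_f, sd_e) in clusters.items():
        forces.append(rng.normal(mu_f, sd_f, n_per_class))
        frets.append(rng.normal(mu_e, sd_e, n_per_class))
        labels += [cls] * n_per_class
    return (
        np.concatenate(forces),
        np.concatenate(frets),
        np.asarray(labels, dtype=object),
    )
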