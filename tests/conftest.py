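"""Shared fixtures: simulated trace sets are session-scoped because the
acceptance-style checks reuse the same study conditions."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import forcefret as ff

ZERO_KINETICS = {k: 0.0 for k in ("UF->A", "A->UF", "A->B", "B->A", "B->C", "C->B")}


@pytest.fixture(scope="session")
def mech():
    return ff.MechanicalModel()


@pytest.fixture(scope="session")
def cf():
    return ff.CorrectionFactors(beta=0.13, gamma=1.0, bg_donor=10.0, bg_acceptor=10.0)


def simulate_condition(condition, n_traces, base_seed, mech, **overrides):
    cfg = ff.condition_sim_config(condition, **overrides)
    seeds = np.random.SeedSequence(base_seed).generate_state(n_traces) % (2**31 - 1)
    return cfg, [ff.simulate_trace(cfg, mech, seed=int(s)) for s in seeds]


def pipeline_stats(traces, mech, cf, thresholds=(0.57, 0.74)):
    """Rips -> segmentation -> pooled per-state statistics, as the pipeline
    applies them (refold frames plus pre-first-rip ramp frames below 10 pN)."""
    rips_per_trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in traces:
            try:
                rips_per_trace.append(ff.detect_rips(t, mech, cf))
            except ValueError:
                rips_per_trace.append([])
    segmented = ff.segment_traces(traces, rips_per_trace, cf, thresholds=thresholds)
    return ff.pool_state_statistics(segmented), segmented, rips_per_trace


@pytest.fixture(scope="session")
def condition_stats(mech, cf):
    """Pooled per-state statistics for all four ligand conditions, 50
    30-s refold traces each (the Fig-5-style study conditions)."""
    out = {}
    for i, cond in enumerate(["none", "TPP", "T", "TMP"]):
        _, traces = simulate_condition(cond, 50, 100 + i, mech, refold_duration=30.0)
        stats, segmented, _ = pipeline_stats(traces, mech, cf)
        out[cond] = {"stats": stats, "segmented": segmented, "traces": traces}
    return out
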