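"""End-to-end analysis pipeline.

``run_pipeline`` composes the stages in experiment order: simulate (or
load) traces -> correct photon channels -> detect rips -> cluster opening
events and derive thresholds -> segment FRET trajectories -> pooled
per-state statistics and global Gaussian-sum histogram -> HMM kinetics on
the concatenated refolds.  Only refolding frames and pre-first-rip ramp
frames below the force cap are segmented; everything after the first rip
(or the whole ramp when no rip was found) is masked as UNFOLDED.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .config import MechanicalModel, RunConfig
from .fec import detect_rips
from .fret import CorrectionFactors, correct_intensities, fret_efficiency
from .hmm import concatenate_refolds, fit_hmm, transition_rates, viterbi_path
from .simulate import simulate_trace
from .states import (
    derive_thresholds,
    fit_gaussian_sum,
    kmeans_cluster,
    pool_state_statistics,
    segment_trajectory,
)
from .trace import TraceRecord

__all__ = ["ResultBundle", "run_pipeline", "segment_traces", "correction_factors"]


@dataclass
class ResultBundle:
    """Everything one pipeline run produces, plus provenance."""

    traces: list = field(default_factory=list)
    rip_events: list = field(default_factory=list)  # (trace_id, RipEvent)
    cluster_model: object | None = None
    segmented: list = field(default_factory=list)
    state_stats: dict = field(default_factory=dict)
    gaussian_fit: object | None = None
    hmm_model: object | None = None
    dwell_table: object | None = None
    provenance: dict = field(default_factory=dict)


def correction_factors(config: RunConfig) -> CorrectionFactors:
    gamma = config.analysis.gamma
    return CorrectionFactors(
        beta=config.analysis.beta,
        gamma=1.0 if gamma == "auto" else float(gamma),
        bg_donor=config.analysis.bg_donor,
        bg_acceptor=config.analysis.bg_acceptor,
    )


def segment_traces(
    traces: list[TraceRecord],
    rips_per_trace: list[list],
    cf: CorrectionFactors,
    thresholds=(0.57, 0.74),
    excursion_tolerance: int = 2,
    force_cap: float = 10.0,
):
    """Segment each trace's refold + pre-first-rip frames against the FRET
    thresholds; frames after the first rip, ramp frames above ``force_cap``
    and whole ramps without any detected rip stay UNFOLDED."""
    segmented = []
    for trace, rips in zip(traces, rips_per_trace):
        i_d, i_a = correct_intensities(trace.i_donor, trace.i_acceptor, cf)
        e = np.asarray(fret_efficiency(i_d, i_a), dtype=float)
        n = len(trace)
        mask = np.zeros(n, dtype=bool)
        mask[trace.refold_slice] = True
        if rips:
            first_rip = min(r.frame_index for r in rips)
            ramp = np.arange(trace.refold_end_index, first_rip)
            ramp = ramp[trace.force[ramp] <= force_cap]
            mask[ramp] = True
        seg = segment_trajectory(
            np.where(mask, e, np.nan), thresholds, excursion_tolerance
        )
        seg.labels[~mask] = "UNFOLDED"
        seg.state_stats = {}
        seg.__post_init__()  # refresh stats after masking
        segmented.append(seg)
    return segmented


def run_pipeline(config: RunConfig, traces: list[TraceRecord] | None = None) -> ResultBundle:
    """Run the full analysis; simulates traces unless given some.

    Deterministic for a fixed config: every sub-seed derives from
    ``config.io.seed``.
    """
    bundle = ResultBundle()
    mech = config.mechanics or MechanicalModel()
    ana = config.analysis
    cf = correction_factors(config)

    stage = "simulate"
    try:
        if traces is None:
            ss = np.random.SeedSequence(config.io.seed)
            seeds = ss.generate_state(config.io.n_traces) % (2**31 - 1)
            traces = [
                simulate_trace(config.simulator, mech, seed=int(s)) for s in seeds
            ]
        bundle.traces = traces

        stage = "detect_rips"
        rips_per_trace = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in traces:
                try:
                    rips = detect_rips(
                        t,
                        mech,
                        cf,
                        min_jump=ana.min_jump,
                        smooth_window=ana.smooth_window,
                        class_thresholds=ana.force_thresholds,
                    )
                except ValueError:
                    rips = []
                rips_per_trace.append(rips)
        bundle.rip_events = [
            (i, r) for i, rips in enumerate(rips_per_trace) for r in rips
        ]

        stage = "cluster"
        opening = [
            (rips[0].opening_force, rips[0].opening_fret)
            for rips in rips_per_trace
            if rips and np.isfinite(rips[0].opening_fret)
        ]
        thresholds = ana.fret_thresholds
        if len(opening) >= 3 * ana.k:
            f, e = np.array(opening).T
            try:
                model = derive_thresholds(
                    kmeans_cluster(f, e, k=ana.k, n_restarts=ana.n_restarts, seed=config.io.seed)
                )
                bundle.cluster_model = model
                if thresholds is None:
                    thresholds = model.fret_thresholds
            except ValueError:
                pass
        if thresholds is None:
            thresholds = (0.57, 0.74)

        stage = "segment"
        bundle.segmented = segment_traces(
            traces,
            rips_per_trace,
            cf,
            thresholds=thresholds,
            excursion_tolerance=ana.excursion_tolerance,
            force_cap=ana.segment_force_cap,
        )
        bundle.state_stats = pool_state_statistics(bundle.segmented)

        stage = "gaussian_fit"
        pooled = np.concatenate(
            [
                seg.efficiency[np.isin(seg.labels, ("APO", "WB", "SB"))]
                for seg in bundle.segmented
            ]
        )
        if pooled.size >= 200:
            try:
                bundle.gaussian_fit = fit_gaussian_sum(pooled, bin_width=ana.bin_width)
            except RuntimeError:
                pass

        stage = "hmm"
        series, lengths = concatenate_refolds(traces, cf)
        keep = np.isfinite(series)
        if keep.all() and series.size >= 500:
            model = fit_hmm(
                series,
                lengths,
                n_states=ana.hmm_states,
                seed=config.io.seed,
                frame_period=config.simulator.frame_period,
                n_restarts=ana.hmm_restarts,
                max_iter=ana.hmm_max_iter,
            )
            bundle.hmm_model = model
            path = viterbi_path(model, series, lengths)
            bundle.dwell_table = transition_rates(
                path, lengths, config.simulator.frame_period, model.state_names
            )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    cfg_repr = json.dumps(config.simulator.to_dict(), sort_keys=True)
    bundle.provenance = {
        "version": __version__,
        "seed": config.io.seed,
        "n_traces": len(bundle.traces),
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "fret_thresholds": list(thresholds),
        "force_thresholds": list(ana.force_thresholds),
    }
    return bundle
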