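"""Sequential hidden-Markov kinetics of refolding FRET trajectories.

Refolding-period FRET series from many cycles are concatenated (with
segment boundaries recorded, so no transition is ever counted across a
boundary) and fitted with a sequential N-state HMM: Gaussian emissions on
E and a tridiagonal-banded transition matrix, so only neighbouring states
on the chain UF - A - B - C can interconvert within a frame.  Baum-Welch
expectation-maximization preserves the off-band zeros.  The most-likely
state path per segment (Viterbi) yields directional dwell statistics;
the rate for X -> Y is the number of decoded X -> Y transitions divided by
the total time spent in complete (uncensored) dwells of X, and the
directional transition time is its reciprocal.  Dwells truncated by a
segment boundary are censored and excluded.  UF and A share low-FRET
emissions and are distinguished only dynamically; their initial means are
split symmetrically about the low-FRET level to break the symmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .fret import CorrectionFactors, correct_intensities, fret_efficiency

__all__ = [
    "HMMModel",
    "DwellTable",
    "concatenate_refolds",
    "fit_hmm",
    "viterbi_path",
    "transition_rates",
]

STATE_NAMES_4 = ("UF", "A", "B", "C")


@dataclass
class HMMModel:
    """Fitted sequential HMM: emissions, banded transitions, frame period."""

    n_states: int
    means: np.ndarray  # per-state emission mean E, along the chain
    sds: np.ndarray  # per-state emission SD, > 0
    transmat: np.ndarray  # per-frame probabilities, tridiagonal-banded
    startprob: np.ndarray
    frame_period: float  # s
    log_likelihood: float
    ll_history: np.ndarray  # EM log-likelihood per iteration (non-decreasing)
    converged: bool
    state_names: tuple = STATE_NAMES_4

    def __post_init__(self) -> None:
        if np.any(self.sds <= 0):
            raise ValueError("emission SDs must be > 0")
        band = np.abs(np.subtract.outer(range(self.n_states), range(self.n_states))) <= 1
        if np.any(self.transmat[~band] != 0.0):
            raise ValueError("transition matrix must be tridiagonal-banded")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")

    def matrix_rates(self) -> dict:
        """Diagnostic rates from the transition matrix, k = p / dt for the
        off-diagonal band (valid when p << 1)."""
        out = {}
        for i in range(self.n_states):
            for j in (i - 1, i + 1):
                if 0 <= j < self.n_states:
                    key = f"{self.state_names[i]}->{self.state_names[j]}"
                    out[key] = float(self.transmat[i, j] / self.frame_period)
        return out


@dataclass
class DwellTable:
    """Directional dwell statistics from a decoded state path.

    ``rates[pair]`` is transitions-per-second in the origin state;
    ``transition_times[pair]`` its reciprocal.  Pairs with zero observed
    transitions appear in ``absent`` with a lower-bound note instead of a
    rate.  Rates at or above ~half the frame rate are flagged as lower
    bounds (faster kinetics cannot be resolved at the camera frame time).
    """

    rates: dict = field(default_factory=dict)  # pair -> 1/s
    transition_times: dict = field(default_factory=dict)  # pair -> s
    counts: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    censored: dict = field(default_factory=dict)  # state -> censored dwell count
    lower_bound: dict = field(default_factory=dict)  # pair -> bool
    absent: dict = field(default_factory=dict)  # pair -> note


def concatenate_refolds(traces, cf: CorrectionFactors | None = None):
    """Corrected refolding-period E series of many cycles, concatenated.

    Returns (series, lengths): one 1-D array and per-segment lengths, the
    form consumed by the fitting and decoding routines so that transitions
    are never counted across a trace boundary.  Traces without a refold
    segment are skipped with a warning.
    """
    cf = cf or CorrectionFactors()
    chunks, lengths = [], []
    for t in traces:
        if t.refold_end_index < 2:
            warnings.warn("skipping trace without refold segment", stacklevel=2)
            continue
        i_d, i_a = correct_intensities(
            t.i_donor[t.refold_slice], t.i_acceptor[t.refold_slice], cf
        )
        e = fret_efficiency(i_d, i_a)
        chunks.append(np.asarray(e, dtype=float))
        lengths.append(len(chunks[-1]))
    if not chunks:
        raise ValueError("no traces with refold segments")
    return np.concatenate(chunks), np.asarray(lengths, dtype=int)


def _banded_transmat(n: int, p_stay: float = 0.95) -> np.ndarray:
    t = np.zeros((n, n))
    for i in range(n):
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
        t[i, i] = p_stay
        for j in nbrs:
            t[i, j] = (1.0 - p_stay) / len(nbrs)
    return t


def default_init_means(series: np.ndarray, n_states: int) -> np.ndarray:
    """Initial emission means: data quantiles, with the two lowest states
    split +/- 0.02 about the low-FRET level when n_states = 4 (UF and A
    share emissions and differ only dynamically)."""
    if n_states == 4:
        low = np.quantile(series, 0.10)
        mid = np.quantile(series, 0.60)
        high = np.quantile(series, 0.90)
        return np.array([low - 0.02, low + 0.02, mid, high])
    qs = np.linspace(0.1, 0.9, n_states)
    return np.quantile(series, qs)


def fit_hmm(
    series,
    lengths,
    n_states: int = 4,
    seed: int = 0,
    frame_period: float = 0.05,
    n_restarts: int = 3,
    max_iter: int = 200,
    tol: float = 1e-3,
    init_means=None,
) -> HMMModel:
    """Fit the sequential banded Gaussian HMM by expectation-maximization.

    Multistart: ``n_restarts`` EM runs from jittered initial means (seeded
    from ``seed``), keeping the best final log-likelihood.  Off-band
    transition entries start at exactly zero and remain zero under the EM
    update.  Non-convergence is reported on the returned model (with its
    log-likelihood history) rather than raised.
    """
    series = np.asarray(series, dtype=float)
    finite = np.isfinite(series)
    if not finite.all():
        raise ValueError("series contains non-finite values; mask before fitting")
    if series.size < 500:
        raise ValueError("need at least 500 frames to fit the HMM")
    lengths = np.asarray(lengths, dtype=int)
    if lengths.sum() != series.size:
        raise ValueError("segment lengths must sum to the series length")
    base_means = (
        np.asarray(init_means, dtype=float)
        if init_means is not None
        else default_init_means(series, n_states)
    )
    var0 = max(series.var() / n_states, 1e-4)

    rng = np.random.default_rng(seed)
    best = None
    x = series.reshape(-1, 1)
    for r in range(n_restarts):
        jitter = 0.0 if r == 0 else rng.normal(0.0, 0.01, n_states)
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            init_params="",
            params="stmc",
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.startprob_ = np.full(n_states, 1.0 / n_states)
        model.transmat_ = _banded_transmat(n_states)
        model.means_ = (base_means + jitter).reshape(-1, 1)
        model.covars_ = np.full((n_states, 1), var0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, lengths=lengths)
        score = model.monitor_.history[-1]
        if best is None or score > best[0]:
            best = (score, model)
    score, model = best
    names = STATE_NAMES_4 if n_states == 4 else tuple(f"S{i}" for i in range(n_states))
    return HMMModel(
        n_states=n_states,
        means=model.means_.ravel().copy(),
        sds=np.sqrt(model.covars_.ravel()).copy(),
        transmat=model.transmat_.copy(),
        startprob=model.startprob_.copy(),
        frame_period=frame_period,
        log_likelihood=float(score),
        ll_history=np.asarray(model.monitor_.history, dtype=float),
        converged=bool(model.monitor_.converged),
        state_names=names,
    )


def _as_hmmlearn(model: HMMModel) -> GaussianHMM:
    m = GaussianHMM(n_components=model.n_states, covariance_type="diag", init_params="")
    m.startprob_ = model.startprob
    m.transmat_ = model.transmat
    m.means_ = model.means.reshape(-1, 1)
    m.covars_ = (model.sds**2).reshape(-1, 1)
    return m


def viterbi_path(model: HMMModel, series, lengths) -> np.ndarray:
    """Most-likely state index path, decoded independently per segment."""
    series = np.asarray(series, dtype=float).reshape(-1, 1)
    lengths = np.asarray(lengths, dtype=int)
    m = _as_hmmlearn(model)
    return m.predict(series, lengths=lengths)


def transition_rates(
    path,
    lengths,
    frame_period: float,
    state_names=STATE_NAMES_4,
) -> DwellTable:
    """Directional rates from a decoded path.

    A dwell is a maximal run in one state; dwells touching a segment
    boundary are censored and excluded.  For adjacent states X, Y:
    rate(X->Y) = (# complete dwells in X exiting to Y) / (total time in
    complete dwells of X); the directional transition time is 1/rate.
    SE is rate/sqrt(count).  Rates >= half the frame rate are flagged as
    lower bounds; pairs with no observed exit are reported absent.
    """
    path = np.asarray(path, dtype=int)
    lengths = np.asarray(lengths, dtype=int)
    if lengths.sum() != path.size:
        raise ValueError("segment lengths must sum to the path length")
    n_states = len(state_names)
    dwell_time = np.zeros(n_states)  # complete dwells only
    exit_counts = np.zeros((n_states, n_states), dtype=int)
    censored = np.zeros(n_states, dtype=int)

    start = 0
    for seg_len in lengths:
        seg = path[start : start + seg_len]
        start += seg_len
        i = 0
        while i < seg_len:
            j = i
            while j < seg_len and seg[j] == seg[i]:
                j += 1
            s = seg[i]
            if i == 0 or j == seg_len:  # touches a boundary: censored
                censored[s] += 1
            else:
                dwell_time[s] += (j - i) * frame_period
                exit_counts[s, seg[j]] += 1
            i = j

    table = DwellTable()
    for i in range(n_states):
        for j in (i - 1, i + 1):
            if not 0 <= j < n_states:
                continue
            pair = f"{state_names[i]}->{state_names[j]}"
            n_ij = int(exit_counts[i, j])
            table.counts[pair] = n_ij
            table.censored[state_names[i]] = int(censored[i])
            if n_ij == 0 or dwell_time[i] == 0:
                table.absent[pair] = (
                    "no complete dwells observed for this transition; any rate "
                    "estimate would only be a lower bound on the dwell time"
                )
                continue
            rate = n_ij / dwell_time[i]
            table.rates[pair] = float(rate)
            table.transition_times[pair] = float(1.0 / rate)
            table.ses[pair] = float(rate / np.sqrt(n_ij))
            table.lower_bound[pair] = bool(rate >= 0.5 / frame_period)
    return table
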