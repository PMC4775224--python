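"""State assignment from opening events and FRET trajectories.

Opening events (opening force vs opening FRET) are clustered by k-means
(k = 3) after per-axis z-scoring; midpoints between adjacent sorted
centroid coordinates give the force thresholds separating the F / F'.TPP /
F''.TPP conformations and the FRET thresholds separating the APO / WB / SB
helix-arm states.  Full FRET trajectories are then segmented against the
FRET thresholds with a short-excursion rule: brief departures (at most
``excursion_tolerance`` consecutive frames) from a state's band are
reassigned to the surrounding state, so label changes require a sustained
level shift.  A global FRET histogram (bin width 0.025) is fitted to a sum
of four Gaussians by nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "GaussianSumFit",
    "SegmentedTrajectory",
    "kmeans_cluster",
    "derive_thresholds",
    "fit_gaussian_sum",
    "segment_trajectory",
    "pool_state_statistics",
]

STATE_OF_BAND = {0: "APO", 1: "WB", 2: "SB"}


@dataclass
class ClusterModel:
    """k-means clustering of opening events with derived axis thresholds."""

    k: int
    centroids: np.ndarray  # (k, 2): (opening force pN, opening FRET), sorted by force
    assignments: np.ndarray  # event -> cluster index (into sorted centroids)
    inertia: float
    fret_thresholds: tuple | None = None  # (t_low, t_high)
    force_thresholds: tuple | None = None  # (f_low, f_high)


@dataclass
class GaussianSumFit:
    """Least-squares fit of a binned FRET histogram to a sum of Gaussians."""

    amplitudes: np.ndarray  # counts at peak, >= 0, sorted by mean
    means: np.ndarray  # ascending
    sds: np.ndarray  # > 0
    residual_norm: float
    bin_width: float = 0.025
    bin_centers: np.ndarray | None = None
    counts: np.ndarray | None = None

    def predict(self, x):
        x = np.asarray(x, dtype=float)[..., None]
        comps = self.amplitudes * np.exp(-0.5 * ((x - self.means) / self.sds) ** 2)
        return comps.sum(axis=-1)


@dataclass
class SegmentedTrajectory:
    """Per-frame APO/WB/SB/UNFOLDED/INVALID labels with the E series."""

    labels: np.ndarray  # dtype object, one label per frame
    efficiency: np.ndarray
    excursion_tolerance: int = 2
    state_stats: dict = field(default_factory=dict)  # state -> (mean, var, n)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.efficiency):
            raise ValueError("labels and efficiency must have equal length")
        if not self.state_stats:
            self.state_stats = {
                s: stats
                for s, stats in _per_state_stats(self.labels, self.efficiency).items()
            }


def _per_state_stats(labels, efficiency) -> dict:
    out = {}
    for s in ("APO", "WB", "SB"):
        sel = labels == s
        n = int(sel.sum())
        if n:
            e = efficiency[sel]
            out[s] = (float(e.mean()), float(e.var()), n)
    return out


# ---------------------------------------------------------------------------
# clustering

def kmeans_cluster(
    opening_forces,
    opening_frets,
    k: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterModel:
    """k-means on (opening force, opening FRET) events.

    Axes are z-scored before clustering (pN and FRET units differ by an
    order of magnitude); centroids are reported back in original units and
    sorted by opening force.  Best of ``n_restarts`` initializations by
    within-cluster sum of squares; deterministic for a given seed.
    """
    f = np.asarray(opening_forces, dtype=float)
    e = np.asarray(opening_frets, dtype=float)
    if f.shape != e.shape or f.ndim != 1:
        raise ValueError("opening_forces and opening_frets must be equal-length 1-D")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(f) < k:
        raise ValueError(f"need at least k={k} events")
    x = np.column_stack([f, e])
    scale = x.std(axis=0, ddof=0)
    if np.any(scale == 0):
        raise ValueError("degenerate events: an axis has zero variance")
    z = (x - x.mean(axis=0)) / scale
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(z)
    centroids = km.cluster_centers_ * scale + x.mean(axis=0)
    order = np.argsort(centroids[:, 0])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterModel(
        k=k,
        centroids=centroids[order],
        assignments=relabel[km.labels_],
        inertia=float(km.inertia_),
    )


def derive_thresholds(model: ClusterModel) -> ClusterModel:
    """Midpoint thresholds between adjacent sorted centroid coordinates.

    Requires k = 3 (two thresholds per axis).  Thresholds are set
    independently per axis: force thresholds between force-sorted force
    coordinates, FRET thresholds between FRET-sorted FRET coordinates, so
    the result is invariant under cluster relabeling.
    """
    if model.k != 3:
        raise ValueError("threshold derivation requires k = 3")
    forces = np.sort(model.centroids[:, 0])
    frets = np.sort(model.centroids[:, 1])
    model.force_thresholds = (
        float((forces[0] + forces[1]) / 2),
        float((forces[1] + forces[2]) / 2),
    )
    model.fret_thresholds = (
        float((frets[0] + frets[1]) / 2),
        float((frets[1] + frets[2]) / 2),
    )
    return model


# ---------------------------------------------------------------------------
# Gaussian-sum histogram fit

def _gauss_sum(x, *params):
    x = np.asarray(x, dtype=float)[..., None]
    p = np.asarray(params).reshape(-1, 3)  # (amp, mean, sd)
    return (p[:, 0] * np.exp(-0.5 * ((x - p[:, 1]) / p[:, 2]) ** 2)).sum(axis=-1)


def fit_gaussian_sum(
    fret_values,
    n_components: int = 4,
    bin_width: float = 0.025,
    min_values: int = 200,
) -> GaussianSumFit:
    """Fit the binned FRET histogram to a sum of Gaussians.

    Components are added greedily: the first is initialized at the
    histogram mode, each subsequent one at the largest positive residual
    of the current fit, then all are re-fitted jointly.  Data drawn from
    fewer populations than ``n_components`` therefore leave the surplus
    components at near-zero amplitude instead of splitting a peak.
    Component means are returned sorted ascending.
    """
    e = np.asarray(fret_values, dtype=float)
    e = e[np.isfinite(e)]
    if len(e) < min_values:
        raise ValueError(f"need at least {min_values} FRET values, got {len(e)}")
    lo = np.floor(e.min() / bin_width) * bin_width
    hi = np.ceil(e.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(e, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2

    sigma0 = max(2 * bin_width, e.std() / 4)
    params: list[float] = []
    best = None
    for _ in range(n_components):
        resid = counts - (_gauss_sum(centers, *params) if params else 0.0)
        i0 = int(np.argmax(resid))
        amp0 = max(float(resid[i0]), 1.0)
        params = list(params) + [amp0, float(centers[i0]), sigma0]
        lower = [0.0, lo - bin_width, bin_width / 4] * (len(params) // 3)
        upper = [np.inf, hi + bin_width, hi - lo + bin_width] * (len(params) // 3)
        try:
            popt, _ = curve_fit(
                _gauss_sum,
                centers,
                counts,
                p0=params,
                bounds=(lower, upper),
                maxfev=20000,
            )
            params = list(popt)
            best = popt
        except RuntimeError:
            # keep the previous parameters; report the residual achieved
            break
    if best is None:
        raise RuntimeError("Gaussian-sum fit failed to converge for any component count")
    p = np.asarray(params).reshape(-1, 3)
    if len(p) < n_components:  # pad non-converged components at zero amplitude
        pad = np.zeros((n_components - len(p), 3))
        pad[:, 2] = sigma0
        p = np.vstack([p, pad])
    order = np.argsort(p[:, 1])
    p = p[order]
    resid = counts - _gauss_sum(centers, *p.ravel())
    return GaussianSumFit(
        amplitudes=p[:, 0],
        means=p[:, 1],
        sds=p[:, 2],
        residual_norm=float(np.linalg.norm(resid)),
        bin_width=bin_width,
        bin_centers=centers,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# trajectory segmentation

def _runs(labels: np.ndarray):
    """(start, stop, label) for each maximal constant run."""
    n = len(labels)
    out = []
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((i, j, labels[i]))
        i = j
    return out


def _persistence_smooth(base: np.ndarray, tol: int) -> np.ndarray:
    """Smooth frame-wise band labels: the state changes only where a
    different band persists for more than ``tol`` consecutive frames."""
    labels = base.copy()
    current = None
    pending_start = None  # short runs seen before any sustained run
    for i, j, lab in _runs(base):
        if lab == "INVALID":
            current = None
            pending_start = None
            continue
        if j - i > tol:
            if current is None and pending_start is not None:
                labels[pending_start:i] = lab  # leading excursions join the anchor
            current = lab
        elif current is not None:
            labels[i:j] = current
        elif pending_start is None:
            pending_start = i
        # stretches with no sustained run at all keep their frame-wise labels
    return labels


def _robust_sigma(e: np.ndarray) -> float:
    """Per-frame noise scale from the median absolute successive difference
    (insensitive to the sparse level shifts between states)."""
    d = np.abs(np.diff(e))
    d = d[np.isfinite(d)]
    return float(np.median(d) / (1.4826 * np.sqrt(2))) if d.size else 0.0


def _binary_segment(e: np.ndarray, lo: int, hi: int, sigma: float,
                    split_z: float, min_seg: int, out: list) -> None:
    """Recursive change-point search: split [lo, hi) at the most significant
    mean shift while the standardized shift exceeds ``split_z``."""
    n = hi - lo
    if n < 2 * min_seg:
        out.append((lo, hi))
        return
    x = e[lo:hi]
    c = np.cumsum(x)
    total = c[-1]
    k = np.arange(min_seg, n - min_seg + 1)  # left part has k frames
    mean_l = c[k - 1] / k
    mean_r = (total - c[k - 1]) / (n - k)
    z = np.abs(mean_l - mean_r) / (sigma * np.sqrt(1.0 / k + 1.0 / (n - k)))
    best = int(np.argmax(z))
    if z[best] <= split_z:
        out.append((lo, hi))
        return
    split = lo + int(k[best])
    _binary_segment(e, lo, split, sigma, split_z, min_seg, out)
    _binary_segment(e, split, hi, sigma, split_z, min_seg, out)


def _viterbi_refine(x: np.ndarray, labels: np.ndarray, p_switch: float,
                    sigma_floor: float = 0.02) -> np.ndarray:
    """Refine block labels by a level-aware smoothing decode.

    Gaussian levels for the classes present are estimated from the current
    labels; the most likely label path under a symmetric switching prior
    (probability ``p_switch`` of changing state per frame) is then decoded.
    Dwell boundaries land where the likelihood favours them instead of
    where frame noise happens to cross a threshold, and a dwell too short
    to overcome the switching penalty is absorbed whole rather than carved
    by value.
    """
    classes = [c for c in ("APO", "WB", "SB") if np.sum(labels == c) >= 3]
    if len(classes) < 2:
        return labels
    mus = np.array([x[labels == c].mean() for c in classes])
    sds = np.array([max(x[labels == c].std(), sigma_floor) for c in classes])
    k = len(classes)
    log_a = np.full((k, k), np.log(p_switch / (k - 1)))
    np.fill_diagonal(log_a, np.log1p(-p_switch))
    log_b = -0.5 * ((x[:, None] - mus) / sds) ** 2 - np.log(sds)
    n = len(x)
    psi = np.zeros((n, k), dtype=np.int8)
    delta = log_b[0].copy()
    for t in range(1, n):
        cand = delta[:, None] + log_a
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(k)] + log_b[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return np.asarray([classes[i] for i in path], dtype=object)


def segment_trajectory(
    efficiency,
    thresholds=(0.57, 0.74),
    excursion_tolerance: int = 2,
    split_z: float = 4.0,
    p_switch: float = 0.02,
) -> SegmentedTrajectory:
    """Assign APO/WB/SB labels to a FRET series by banded thresholds.

    Assignment is segment-wise: quasi-stable stretches of the trajectory
    are classified by their level, so brief excursions (at most
    ``excursion_tolerance`` consecutive frames) beyond a threshold never
    change the assigned state, and a state whose noise distribution
    straddles a threshold is not fragmented frame by frame.

    Segments come from recursive binary change-point detection on E
    (a boundary is placed only where the standardized mean shift exceeds
    ``split_z``, with the frame noise estimated robustly from successive
    differences and segments no shorter than ``excursion_tolerance + 1``
    frames), classified by segment mean against the thresholds: below
    ``thresholds[0]`` APO, above ``thresholds[1]`` SB, in between WB.
    A level-aware smoothing decode (see :func:`_viterbi_refine`) then
    re-estimates the dwell boundaries from the class levels actually
    present, and the decoded segments are re-classified by their means.
    For an effectively noise-free series the frame-wise band labels with
    short-excursion smoothing are used directly.

    The operation is deterministic and idempotent in the labels it
    assigns.  Non-finite E values are labeled INVALID and act as hard
    boundaries (no segment crosses them).
    """
    e = np.asarray(efficiency, dtype=float)
    if len(e) == 0:
        raise ValueError("empty FRET series")
    t_low, t_high = thresholds
    if t_low >= t_high:
        raise ValueError("thresholds must satisfy t_low < t_high")
    base = np.where(e < t_low, "APO", np.where(e > t_high, "SB", "WB")).astype(object)
    base[~np.isfinite(e)] = "INVALID"

    labels = base.copy()
    valid = np.where(base == "INVALID", "INVALID", "VALID").astype(object)
    for b0, b1, lab in _runs(valid):
        if lab == "INVALID":
            continue
        block = e[b0:b1]
        sigma = _robust_sigma(block)
        if sigma < 1e-9:
            labels[b0:b1] = _persistence_smooth(base[b0:b1], excursion_tolerance)
            continue
        segs: list = []
        _binary_segment(e, b0, b1, sigma, split_z, excursion_tolerance + 1, segs)
        for i, j in segs:
            mu = e[i:j].mean()
            labels[i:j] = "APO" if mu < t_low else ("SB" if mu > t_high else "WB")
        labels[b0:b1] = _viterbi_refine(block, labels[b0:b1], p_switch)
        for i, j, _ in _runs(labels[b0:b1]):
            mu = block[i:j].mean()
            labels[b0 + i : b0 + j] = (
                "APO" if mu < t_low else ("SB" if mu > t_high else "WB")
            )
    return SegmentedTrajectory(
        labels=labels, efficiency=e, excursion_tolerance=excursion_tolerance
    )


def pool_state_statistics(segmented) -> dict:
    """Pool per-state FRET statistics over a list of segmented trajectories.

    Returns {state: {"mean", "variance", "n"}} for each state with at least
    one labeled frame; states never visited are absent from the result
    (not reported as zero).
    """
    values: dict[str, list] = {}
    for seg in segmented:
        for s in ("APO", "WB", "SB"):
            sel = seg.labels == s
            if sel.any():
                values.setdefault(s, []).append(seg.efficiency[sel])
    out = {}
    for s, chunks in values.items():
        e = np.concatenate(chunks)
        out[s] = {
            "mean": float(e.mean()),
            "variance": float(e.var()),
            "n": int(len(e)),
        }
    return out
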