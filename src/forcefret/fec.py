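"""Force-extension-curve analysis: rip detection and classification.

An opening transition ("rip") is an abrupt extension gain during the force
ramp, marking rupture of a structural element.  Each rip is characterized
by its opening force F_1/2 (force at the last pre-rip frame), its length
gain delta_x (difference of the double-WLC branches fitted before and
after the rip, evaluated at F_1/2), and the corrected FRET efficiency just
before the rip.  Conformation classes are assigned from the opening force
of the first rip: below the low threshold the aptamer unfolded without
bound ligand (F), between the thresholds from the weakly bound state
(F'.TPP), above the high threshold from the tightly bound state (F''.TPP).

Because the ramp itself advances the extension every frame (the molecule
and traps are compliant), rips are detected on baseline-subtracted
frame-to-frame steps of the median-filtered extension: the local median
step is removed before comparing against ``min_jump``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .config import MechanicalModel
from .fret import CorrectionFactors, correct_intensities, fret_efficiency
from .trace import TraceRecord
from .wlc import double_wlc_extension, wlc_extension

__all__ = ["RipEvent", "detect_rips", "classify_by_force", "estimate_released_contour"]


@dataclass
class RipEvent:
    """One detected opening transition."""

    frame_index: int  # first post-rip frame (absolute index in the trace)
    opening_force: float  # F_1/2, pN: force at the last pre-rip frame
    delta_x: float  # nm: contour-gain step evaluated at F_1/2
    opening_fret: float  # corrected E at the last pre-rip frame
    conformation_class: str = "ambiguous"

    def __post_init__(self) -> None:
        if self.opening_force <= 0:
            raise ValueError("opening_force must be > 0")


def classify_by_force(opening_force: float, thresholds=(11.5, 21.0)) -> str:
    """Assign a conformation class from the opening force.

    Below ``thresholds[0]``: F (no bound ligand); between the thresholds:
    Fp (weakly bound); above ``thresholds[1]``: Fpp (tightly bound).
    """
    low, high = thresholds
    if low >= high:
        raise ValueError("thresholds must satisfy low < high")
    if opening_force < 0:
        raise ValueError("opening_force must be >= 0")
    if opening_force < low:
        return "F"
    if opening_force <= high:
        return "Fp"
    return "Fpp"


def estimate_released_contour(
    forces,
    extensions,
    mech: MechanicalModel,
) -> float:
    """Released ssRNA contour length (nm) explaining a FEC segment.

    For each frame the handle extension at the measured force is subtracted
    and the residual is divided by the relative extension of the unfolded
    RNA at that force; the per-frame estimates are averaged.  Frames below
    1 pN are skipped (the WLC inversion is ill-conditioned near zero load).
    """
    forces = np.asarray(forces, dtype=float)
    extensions = np.asarray(extensions, dtype=float)
    est = []
    unit = mech.released_params(1.0)  # z(F) = extension of 1 nm of ssRNA
    for f, x in zip(forces, extensions):
        if f < 1.0:
            continue
        x_handles = wlc_extension(f, mech.handle1) + wlc_extension(f, mech.handle2)
        z = wlc_extension(f, unit)
        est.append((x - x_handles) / z)
    if not est:
        raise ValueError("no usable frames (need force >= 1 pN)")
    return max(float(np.mean(est)), 0.0)


def detect_rips(
    trace: TraceRecord,
    mech: MechanicalModel,
    cf: CorrectionFactors | None = None,
    min_jump: float = 5.0,
    smooth_window: int = 3,
    baseline_window: int = 15,
    min_force_drop: float = 0.6,
    class_thresholds=(11.5, 21.0),
    fit_residual_tol: float = 5.0,
) -> list[RipEvent]:
    """Detect opening transitions on the ramp segment of a trace.

    The extension is median-filtered over ``smooth_window`` frames; rips are
    frames whose baseline-subtracted step exceeds ``min_jump`` nm.  Because
    rupture at fixed trap separation also relaxes the tension, a frame whose
    extension step exceeds half of ``min_jump`` *and* whose force falls more
    than ``min_force_drop`` pN below the local loading trend is accepted as
    well; this two-channel rule keeps borderline rips (extension gain partly
    absorbed by the compliant handles and traps) without admitting noise.
    For each rip, F_1/2 is the force at the last pre-rip frame, delta_x is
    the difference of double-WLC branches (released contour fitted to the
    segments flanking the rip) evaluated at F_1/2, and the opening FRET is
    the corrected efficiency at the last pre-rip frame.  Events are returned
    in frame order, classified by opening force.
    """
    cf = cf or CorrectionFactors()
    ramp = trace.ramp_slice
    n_ramp = ramp.stop - ramp.start
    if n_ramp < 3:
        raise ValueError("trace has no usable ramp segment")
    ext = median_filter(trace.extension[ramp], size=smooth_window, mode="nearest")
    force = trace.force[ramp]
    steps = np.diff(ext)
    baseline = median_filter(steps, size=baseline_window, mode="nearest")
    jumps = steps - baseline
    fsteps = np.diff(force)
    fbase = median_filter(fsteps, size=baseline_window, mode="nearest")
    fdrop = fbase - fsteps  # positive = force fell below the loading trend
    strong = jumps > min_jump
    weak = (jumps > 0.3 * min_jump) & (fdrop > min_force_drop)
    # the frames right after a rip sit on a new, softer WLC branch, which
    # biases both local baselines; weak-rule hits there are echoes, and a
    # genuine next rip needs >= 3 frames of reloading at these ramp rates
    rip_local: list[int] = []
    last = -10
    for i in np.flatnonzero(strong | weak):
        if strong[i] or i - last > 2:
            rip_local.append(int(i) + 1)  # first post-rip frame, ramp coords
            last = i
    rip_local = np.asarray(rip_local, dtype=int)

    i_d, i_a = correct_intensities(trace.i_donor, trace.i_acceptor, cf)
    e_corr = fret_efficiency(i_d, i_a)

    # fit the released contour on each inter-rip segment
    bounds = [0] + [int(i) for i in rip_local] + [n_ramp]
    seg_contour: list[float] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        seg_f = force[lo:hi]
        seg_x = ext[lo:hi]
        usable = seg_f >= 1.0
        if usable.sum() == 0:
            seg_contour.append(0.0 if k == 0 else seg_contour[-1])
            continue
        seg_contour.append(
            estimate_released_contour(seg_f[usable], seg_x[usable], mech)
        )

    events: list[RipEvent] = []
    for k, i in enumerate(rip_local):
        pre = int(i) - 1
        f_half = float(force[pre])
        l_before, l_after = seg_contour[k], seg_contour[k + 1]
        released_before = mech.released_params(l_before) if l_before > 1e-6 else None
        released_after = mech.released_params(l_after) if l_after > 1e-6 else None
        # handle2 extension cancels in the branch difference
        dx = double_wlc_extension(f_half, mech.handle1, released_after) - (
            double_wlc_extension(f_half, mech.handle1, released_before)
        )
        # residual of the post-rip branch fit against the measured FEC
        lo, hi = bounds[k + 1], bounds[k + 2]
        usable = force[lo:hi] >= 1.0
        if usable.any():
            model = np.array(
                [
                    wlc_extension(f, mech.handle1)
                    + wlc_extension(f, mech.handle2)
                    + (wlc_extension(f, released_after) if released_after else 0.0)
                    for f in force[lo:hi][usable]
                ]
            )
            resid = float(np.mean(np.abs(model - ext[lo:hi][usable])))
            if resid > fit_residual_tol:
                warnings.warn(
                    f"rip at frame {ramp.start + int(i)}: post-rip WLC branch fit "
                    f"residual {resid:.1f} nm exceeds {fit_residual_tol:.1f} nm",
                    stacklevel=2,
                )
        events.append(
            RipEvent(
                frame_index=ramp.start + int(i),
                opening_force=f_half,
                delta_x=max(dx, 0.0),
                opening_fret=float(e_corr[ramp.start + pre]),
                conformation_class=classify_by_force(f_half, class_thresholds),
            )
        )
    return events
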