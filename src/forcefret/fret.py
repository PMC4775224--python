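"""FRET efficiency corrections and photophysics helpers.

Raw donor/acceptor camera counts are contaminated by background, by leakage
of donor emission into the acceptor channel (beta), and by unequal detection
efficiency / quantum yield between the two channels (gamma).  The corrected
efficiency is

    E = I_A / (I_A + I_D)

with I_A the background- and leakage-corrected acceptor counts and I_D the
gamma-scaled, background-corrected donor counts.  Applying gamma to the
donor channel is algebraically identical to the common convention
E = I_A / (I_A + gamma * I_D).

Also provided: the Foerster distance-efficiency relation and the
absorbance-based Trolox-quinone concentration estimate used to verify the
triplet-quencher buffer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrectionFactors",
    "correct_intensities",
    "fret_efficiency",
    "estimate_beta",
    "estimate_gamma",
    "forster_efficiency",
    "trolox_quinone_conc",
]


@dataclass(frozen=True)
class CorrectionFactors:
    """Channel correction factors for a dye pair / detection path.

    beta: donor -> acceptor spectral leakage fraction, in [0, 1).
    gamma: relative detection-efficiency x quantum-yield factor (> 0).
    bg_donor, bg_acceptor: mean background counts per frame (>= 0).
    """

    beta: float = 0.13
    gamma: float = 1.0
    bg_donor: float = 0.0
    bg_acceptor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.bg_donor < 0 or self.bg_acceptor < 0:
            raise ValueError("backgrounds must be >= 0")


def correct_intensities(i_donor_raw, i_acceptor_raw, cf: CorrectionFactors):
    """Apply background, leakage and gamma corrections to raw counts.

    Returns (I_D, I_A):

        I_D = gamma * (donor_raw - bg_donor)
        I_A = (acceptor_raw - bg_acceptor) - beta * (donor_raw - bg_donor)

    Negative corrected values are retained (not clipped) so that downstream
    statistics keep the full noise structure; callers may flag them.
    """
    d = np.asarray(i_donor_raw, dtype=float) - cf.bg_donor
    a = np.asarray(i_acceptor_raw, dtype=float) - cf.bg_acceptor
    i_a = a - cf.beta * d
    i_d = cf.gamma * d
    return i_d, i_a


def fret_efficiency(i_d, i_a):
    """E = I_A / (I_A + I_D) on corrected counts; no clamping to [0, 1].

    Frames with zero total corrected counts are returned as NaN (invalid).
    """
    i_d = np.asarray(i_d, dtype=float)
    i_a = np.asarray(i_a, dtype=float)
    total = i_a + i_d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total != 0, i_a / total, np.nan)
    if e.ndim == 0:
        return float(e)
    return e


def estimate_beta(
    i_donor_raw,
    i_acceptor_raw,
    bg_donor: float = 0.0,
    bg_acceptor: float = 0.0,
    min_frames: int = 100,
):
    """Estimate the donor->acceptor leakage fraction from donor-only frames.

    On frames with no true acceptor signal (E = 0), the background-subtracted
    acceptor counts are pure leakage, so beta is the ratio of the acceptor to
    donor channel means.  Returns (beta_hat, se) with the standard error
    propagated from the per-channel sample variances (ratio delta method).
    """
    d = np.asarray(i_donor_raw, dtype=float) - bg_donor
    a = np.asarray(i_acceptor_raw, dtype=float) - bg_acceptor
    n = d.size
    if n < min_frames:
        raise ValueError(f"need at least {min_frames} donor-only frames, got {n}")
    md, ma = d.mean(), a.mean()
    if md <= 0:
        raise ValueError("mean donor signal must be positive")
    beta_hat = ma / md
    # delta method for a ratio of independent means
    var = (a.var(ddof=1) / n) / md**2 + (ma**2 / md**4) * (d.var(ddof=1) / n)
    return beta_hat, float(np.sqrt(var))


def estimate_gamma(
    i_donor_raw,
    i_acceptor_raw,
    transition_frame: int,
    cf: CorrectionFactors,
    window: int = 50,
    min_frames: int = 10,
):
    """Estimate gamma from the anticorrelated step at a FRET transition.

    Across an abrupt change in E (e.g. an opening transition), the acceptor
    loses and the donor gains signal from the same photon budget, so

        gamma = |delta I_A| / |delta I_D|

    where deltas are (mean after - mean before) of background- and
    leakage-corrected counts in windows flanking ``transition_frame``.

    Raises ValueError when the donor step is indistinguishable from zero
    (gamma then unidentifiable).
    """
    d = np.asarray(i_donor_raw, dtype=float) - cf.bg_donor
    a = np.asarray(i_acceptor_raw, dtype=float) - cf.bg_acceptor
    a = a - cf.beta * d  # leakage-corrected, but *not* gamma-scaled
    t = int(transition_frame)
    lo = max(0, t - window)
    hi = min(len(d), t + window)
    before = slice(lo, t)
    after = slice(t, hi)
    if t - lo < min_frames or hi - t < min_frames:
        raise ValueError(
            f"need >= {min_frames} frames on each side of the transition"
        )
    dd = d[after].mean() - d[before].mean()
    da = a[after].mean() - a[before].mean()
    se_dd = np.sqrt(d[after].var(ddof=1) / (hi - t) + d[before].var(ddof=1) / (t - lo))
    if abs(dd) < 3.0 * se_dd:
        raise ValueError("no resolvable donor step: gamma unidentifiable")
    return abs(da) / abs(dd)


def forster_efficiency(r, r0):
    """Dipole-dipole coupling efficiency E = 1 / [1 + (R/R0)^6].

    Strictly decreasing in R; E(R0) = 0.5, E(0) = 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    if r0 <= 0:
        raise ValueError("Foerster radius must be > 0")
    e = 1.0 / (1.0 + (r / r0) ** 6)
    return float(e) if e.ndim == 0 else e


def trolox_quinone_conc(
    absorbance: float,
    path_cm: float = 1.0,
    tx_total: float = 3e-3,
    eps_tx: float = 400.0,
    eps_tq: float = 11600.0,
):
    """Trolox-quinone concentration from 255-nm absorbance.

    [TQ] = (A/d - eps_TX * [TX]0) / (eps_TQ - eps_TX)

    with extinction coefficients in l/(mol*cm), path length d in cm and the
    total Trolox concentration [TX]0 in mol/l.  Returns ([TQ] in mol/l,
    percent TQ of total).  A negative concentration indicates inconsistent
    inputs and raises ValueError.
    """
    if path_cm <= 0:
        raise ValueError("path length must be > 0")
    if eps_tq == eps_tx:
        raise ValueError("extinction coefficients must differ")
    tq = (absorbance / path_cm - eps_tx * tx_total) / (eps_tq - eps_tx)
    if tq < -1e-15:
        raise ValueError("negative [TQ]: inconsistent absorbance / concentration")
    tq = max(tq, 0.0)
    return tq, 100.0 * tq / tx_total
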