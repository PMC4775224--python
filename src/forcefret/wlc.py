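"""Worm-like-chain polymer elasticity.

Entropic elasticity of DNA handles and unfolded RNA is described by the
Marko-Siggia interpolation formula, which maps relative extension x/L to
force given a persistence length P and contour length L:

    F(x) = (kBT/P) * [ 1/4 (1 - x/L)^-2 - 1/4 + x/L ]

The inverse (extension at a given force) has no convenient closed form and
is obtained by bracketed root finding on x/L in [0, 1).  A "double" WLC is
two (or more) chains in series at equal tension: DNA handles plus, once the
aptamer has unfolded, the released single-stranded RNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

KBT_PN_NM = 4.11  # thermal energy at ~298 K, pN*nm

__all__ = [
    "WLCParams",
    "wlc_force",
    "wlc_extension",
    "double_wlc_extension",
    "KBT_PN_NM",
]


@dataclass(frozen=True)
class WLCParams:
    """Parameters of a single worm-like chain.

    Attributes
    ----------
    persistence_length : float
        Persistence length P in nm; sets the force scale kBT/P.
    contour_length : float
        Contour length L in nm; extension asymptote.
    kBT : float
        Thermal energy in pN*nm.
    """

    persistence_length: float
    contour_length: float
    kBT: float = KBT_PN_NM

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.contour_length <= 0:
            raise ValueError("contour_length must be > 0")
        if self.kBT <= 0:
            raise ValueError("kBT must be > 0")


def wlc_force(rel_extension, params: WLCParams):
    """Marko-Siggia interpolation force at relative extension x/L.

    Parameters
    ----------
    rel_extension : float or ndarray
        x/L in [0, 1).
    params : WLCParams

    Returns
    -------
    float or ndarray
        Force in pN; strictly increasing in x/L, diverging as x/L -> 1.
    """
    z = np.asarray(rel_extension, dtype=float)
    if np.any(z < 0) or np.any(z >= 1):
        raise ValueError("relative extension must satisfy 0 <= x/L < 1")
    scale = params.kBT / params.persistence_length
    f = scale * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return float(f) if np.isscalar(rel_extension) else f


def wlc_extension(force: float, params: WLCParams, rtol: float = 1e-12) -> float:
    """Extension (nm) of a single WLC at the given tension.

    Numeric inverse of :func:`wlc_force` by bracketed root finding on
    x/L in [0, 1).  Exact inverse to solver tolerance.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    if force == 0.0:
        return 0.0
    scale = params.kBT / params.persistence_length

    def resid(z: float) -> float:
        return scale * (0.25 / (1.0 - z) ** 2 - 0.25 + z) - force

    # upper bracket: 1/4(1-z)^-2 term dominates; z_hi < 1 strictly
    z_hi = 1.0 - 0.5 / np.sqrt(force / scale + 1.0)
    while resid(z_hi) < 0:  # pragma: no cover - defensive; bound is analytic
        z_hi = 0.5 * (1.0 + z_hi)
    z = brentq(resid, 0.0, z_hi, rtol=rtol, maxiter=200)
    return z * params.contour_length


def double_wlc_extension(
    force: float, handles: WLCParams, released: WLCParams | None = None
) -> float:
    """Series extension of handles plus an optional released polymer.

    Chains in series carry equal tension, so extensions add.  With
    ``released=None`` this is just the handle extension (folded branch);
    with the unfolded RNA present it is the fully/partially unfolded branch.
    """
    x = wlc_extension(force, handles)
    if released is not None:
        x += wlc_extension(force, released)
    return x
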