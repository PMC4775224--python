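"""Per-frame record of one refold + force-ramp cycle."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TraceRecord"]


@dataclass
class TraceRecord:
    """Observables of one dumbbell cycle, sampled at the camera frame rate.

    Mechanics channels (time, trap separation, force, molecular extension)
    and photon channels (integer donor/acceptor counts per frame), plus
    optional ground-truth labels when the record comes from the simulator.
    ``refold_end_index`` is the first frame of the force ramp; frames before
    it belong to the low-load refolding period.
    """

    time: np.ndarray  # s
    trap_separation: np.ndarray  # nm
    force: np.ndarray  # pN
    extension: np.ndarray  # nm
    i_donor: np.ndarray  # counts/frame
    i_acceptor: np.ndarray  # counts/frame
    refold_end_index: int
    truth_conformation: np.ndarray | None = None  # UF/F/Fp/Fpp per frame
    truth_tertiary: np.ndarray | None = None  # UNFOLDED/APO/WB/SB per frame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("trap_separation", "force", "extension", "i_donor", "i_acceptor"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != time length")
        for name in ("truth_conformation", "truth_tertiary"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length != time length")
        if np.any(self.i_donor < 0) or np.any(self.i_acceptor < 0):
            raise ValueError("photon counts must be non-negative")
        if np.any(self.force < -1e-9):
            raise ValueError("force must be non-negative")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time must advance in constant frame steps")
        if not 0 <= self.refold_end_index <= n:
            raise ValueError("refold_end_index out of range")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def frame_period(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self) > 1 else float("nan")

    @property
    def refold_slice(self) -> slice:
        return slice(0, self.refold_end_index)

    @property
    def ramp_slice(self) -> slice:
        return slice(self.refold_end_index, len(self))
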