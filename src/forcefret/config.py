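"""Experiment and run configuration.

`SimConfig` + `MechanicalModel` describe one synthetic dumbbell experiment:
an RNA aptamer held between two optically trapped beads through DNA handles,
carrying a donor/acceptor dye pair whose FRET efficiency reports the
tertiary (helix-arm) state while the force channel reports secondary
structure.  `condition_sim_config` returns the package defaults for the
four ligand conditions studied (no ligand, TPP, TMP, thiamine).

`RunConfig` is the TOML-backed configuration consumed by the pipeline and
the command-line interface.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .wlc import KBT_PN_NM, WLCParams

__all__ = [
    "SimConfig",
    "MechanicalModel",
    "AnalysisConfig",
    "IOConfig",
    "RunConfig",
    "condition_sim_config",
    "default_mechanical_model",
    "load_run_config",
    "KINETIC_TRANSITIONS",
    "TERTIARY_STATES",
    "CONFORMATIONS",
]

# hidden tertiary chain: unfolded <-> apart <-> weakly bound <-> strongly bound
TERTIARY_STATES = ("UF", "A", "B", "C")
TERTIARY_LABELS = {"UF": "UNFOLDED", "A": "APO", "B": "WB", "C": "SB"}

# secondary-structure conformation classes seen in force-extension curves
CONFORMATIONS = ("F", "Fp", "Fpp")

KINETIC_TRANSITIONS = ("UF->A", "A->UF", "A->B", "B->A", "B->C", "C->B")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic refold + force-ramp cycle.

    Units: nm, pN, s, photons/frame.  ``fret_states`` maps tertiary-state
    labels (UNFOLDED/APO/WB/SB) to (mean E, SD of E) of the per-frame
    efficiency; ``stretched_fret`` is the post-rupture (dyes pulled apart)
    level on the ramp.  ``rupture_forces`` maps a conformation class to the
    ordered per-rip (mean, SD) critical forces of its opening transitions.
    """

    ramp_speed: float = 200.0  # trap-separation rate, nm/s
    trap_stiffness: float = 0.3  # effective trap stiffness, pN/nm
    refold_duration: float = 10.0  # low-load refolding period, s
    refold_force: float = 2.0  # held load during refolding, pN
    refold_force_cap: float = 5.0  # refolding loads must stay below this
    frame_period: float = 0.05  # camera exposure, s
    n_frames_max: int = 2000
    ramp_enabled: bool = True
    ramp_max_force: float = 30.0  # pN; ramp stops here
    seed: int = 0
    ligand_condition: str = "TPP"  # none | TPP | TMP | T

    donor_rate: float = 16000.0  # expected donor photons/s at E=0
    beta: float = 0.13  # donor->acceptor leakage fraction
    gamma: float = 1.0  # detection/quantum-yield imbalance
    bg_donor: float = 10.0  # background photons/frame
    bg_acceptor: float = 10.0
    bleach_rate_donor: float = 0.0  # 1/s; 0 = photostable record
    bleach_rate_acceptor: float = 0.0
    blink_rate_off: float = 0.0  # acceptor dark-state entry rate, 1/s
    blink_rate_on: float = 10.0  # dark -> bright recovery rate, 1/s

    # per-frame measurement noise on the mechanics channels
    extension_noise: float = 0.5  # nm
    force_noise: float = 0.1  # pN

    fret_states: dict = field(
        default_factory=lambda: {
            "UNFOLDED": (0.44, 0.08),
            "APO": (0.46, 0.0632),
            "WB": (0.73, 0.1000),
            "SB": (0.80, 0.0447),
        }
    )
    stretched_fret: tuple = (0.03, 0.02)

    rupture_forces: dict = field(
        default_factory=lambda: {
            "F": ((7.0, 1.0), (10.5, 0.8), (14.0, 0.8)),
            "Fp": ((16.0, 1.5), (17.5, 0.3)),
            "Fpp": ((26.0, 1.5),),
        }
    )
    min_rip_force_gap: float = 2.5  # pN between successive rips of one FEC

    kinetics: dict = field(
        default_factory=lambda: {
            "UF->A": 2.0,
            "A->UF": 0.3,
            "A->B": 1.0,
            "B->A": 0.1,
            "B->C": 0.5,
            "C->B": 0.05,
        }
    )
    initial_tertiary: str = "UF"  # UF/A/B/C or "stationary"

    def __post_init__(self) -> None:
        for name in (
            "ramp_speed",
            "trap_stiffness",
            "refold_duration",
            "frame_period",
            "donor_rate",
            "gamma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        for name in (
            "bg_donor",
            "bg_acceptor",
            "bleach_rate_donor",
            "bleach_rate_acceptor",
            "blink_rate_off",
            "extension_noise",
            "force_noise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.refold_force >= self.refold_force_cap:
            raise ValueError("refold_force must stay below refold_force_cap")
        if set(self.kinetics) != set(KINETIC_TRANSITIONS):
            raise ValueError(f"kinetics must define exactly {KINETIC_TRANSITIONS}")
        if any(v < 0 for v in self.kinetics.values()):
            raise ValueError("kinetic rates must be >= 0")
        for state, (_, sd) in self.fret_states.items():
            if sd <= 0:
                raise ValueError(f"fret_states[{state}] SD must be > 0")
        means = [self.fret_states[s][0] for s in ("APO", "WB", "SB")]
        if not (means[0] < means[1] < means[2]):
            raise ValueError("fret_states means must be strictly increasing APO < WB < SB")
        first = [self.rupture_forces[c][0][0] for c in CONFORMATIONS]
        if not (first[0] < first[1] < first[2]):
            raise ValueError("opening-force means must be strictly increasing F < Fp < Fpp")
        for c, rips in self.rupture_forces.items():
            if any(sd <= 0 or mu <= 0 for mu, sd in rips):
                raise ValueError(f"rupture_forces[{c}] means and SDs must be > 0")
        if self.initial_tertiary not in TERTIARY_STATES + ("stationary",):
            raise ValueError(f"unknown initial_tertiary {self.initial_tertiary!r}")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rupture_forces"] = {
            c: [list(r) for r in rips] for c, rips in d["rupture_forces"].items()
        }
        d["fret_states"] = {s: list(v) for s, v in d["fret_states"].items()}
        d["stretched_fret"] = list(d["stretched_fret"])
        return d


@dataclass(frozen=True)
class MechanicalModel:
    """WLC mechanics of the dumbbell: two DNA handles in series with the
    RNA, whose unfolded portion contributes single-stranded contour.

    ``contour_gain`` maps each conformation class to the per-rip contour
    gains (nm of ssRNA released), matching ``SimConfig.rupture_forces``.
    """

    handle1: WLCParams = field(
        default_factory=lambda: WLCParams(persistence_length=40.0, contour_length=340.0)
    )
    handle2: WLCParams = field(
        default_factory=lambda: WLCParams(persistence_length=40.0, contour_length=680.0)
    )
    unfolded_rna: WLCParams = field(
        default_factory=lambda: WLCParams(persistence_length=1.0, contour_length=78.0)
    )
    contour_gain: dict = field(
        default_factory=lambda: {
            "F": (30.0, 26.0, 22.0),
            "Fp": (75.0, 3.0),
            "Fpp": (78.0,),
        }
    )

    def __post_init__(self) -> None:
        for c, gains in self.contour_gain.items():
            if any(g <= 0 for g in gains):
                raise ValueError(f"contour gains for {c} must be > 0")

    def total_gain(self, conformation: str) -> float:
        return float(sum(self.contour_gain[conformation]))

    def released_params(self, released_nm: float) -> WLCParams:
        """WLC parameters of `released_nm` of unfolded ssRNA."""
        return WLCParams(
            persistence_length=self.unfolded_rna.persistence_length,
            contour_length=released_nm,
            kBT=self.unfolded_rna.kBT,
        )


def default_mechanical_model() -> MechanicalModel:
    return MechanicalModel()


# state FRET (mean, SD) per ligand condition; SDs are the square roots of
# the per-state efficiency variances of the segmented-data summary tables
_CONDITION_FRET = {
    "none": {"APO": (0.46, 0.0632), "WB": (0.73, 0.1000), "SB": (0.80, 0.0447)},
    "TPP": {"APO": (0.46, 0.0632), "WB": (0.73, 0.1000), "SB": (0.80, 0.0447)},
    "T": {"APO": (0.46, 0.0632), "WB": (0.64, 0.0707), "SB": (0.80, 0.0447)},
    "TMP": {"APO": (0.46, 0.0632), "WB": (0.69, 0.0548), "SB": (0.80, 0.0447)},
}

_CONDITION_KINETICS = {
    # no ligand: the aptamer folds but the arms never dock
    "none": {"UF->A": 2.0, "A->UF": 0.3, "A->B": 0.0, "B->A": 0.0, "B->C": 0.0, "C->B": 0.0},
    "TPP": {"UF->A": 2.0, "A->UF": 0.3, "A->B": 1.0, "B->A": 0.1, "B->C": 0.5, "C->B": 0.05},
    # analogs bind (arms approach) but cannot dock: no B -> C step
    "T": {"UF->A": 2.0, "A->UF": 0.3, "A->B": 1.0, "B->A": 0.1, "B->C": 0.0, "C->B": 0.0},
    "TMP": {"UF->A": 2.0, "A->UF": 0.3, "A->B": 1.0, "B->A": 0.1, "B->C": 0.0, "C->B": 0.0},
}


def condition_sim_config(ligand: str = "TPP", **overrides) -> SimConfig:
    """Default simulation settings for a ligand condition.

    ``ligand`` is one of none/TPP/TMP/T.  Emission means follow the
    segmented-data summary values for each condition (no ligand 0.46,
    TPP weakly bound 0.73, thiamine 0.64, TMP 0.69); kinetics differ in
    whether the docking (B -> C) step is available.
    """
    if ligand not in _CONDITION_FRET:
        raise ValueError(f"unknown ligand condition {ligand!r}")
    fret = {"UNFOLDED": (0.44, 0.08)}
    fret.update(_CONDITION_FRET[ligand])
    kw = dict(
        ligand_condition=ligand,
        fret_states=fret,
        kinetics=dict(_CONDITION_KINETICS[ligand]),
    )
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the analysis half of the pipeline."""

    beta: float = 0.13
    gamma: float | str = 1.0  # numeric, or "auto" to estimate per trace
    bg_donor: float = 10.0
    bg_acceptor: float = 10.0
    min_jump: float = 5.0  # nm; rip detection threshold
    smooth_window: int = 3  # frames; median filter for rip detection
    k: int = 3  # k-means cluster count
    n_restarts: int = 20
    fret_thresholds: tuple | None = None  # override (t_low, t_high)
    force_thresholds: tuple = (11.5, 21.0)
    excursion_tolerance: int = 2  # frames
    segment_force_cap: float = 10.0  # pN; ramp frames above are not segmented
    bin_width: float = 0.025
    hmm_states: int = 4
    hmm_restarts: int = 3
    hmm_max_iter: int = 200


@dataclass(frozen=True)
class IOConfig:
    out_dir: str = "forcefret_out"
    n_traces: int = 50
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    simulator: SimConfig = field(default_factory=SimConfig)
    mechanics: MechanicalModel = field(default_factory=MechanicalModel)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    io: IOConfig = field(default_factory=IOConfig)


def _build(cls, section: dict, what: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return section


def load_run_config(path: str | Path) -> RunConfig:
    """Read a TOML run configuration.

    Recognized tables: [simulator], [mechanics], [analysis], [io].  Unknown
    keys are rejected so typos cannot silently fall back to defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - {"simulator", "mechanics", "analysis", "io"}
    if unknown:
        raise ValueError(f"unknown config tables: {sorted(unknown)}")

    sim_raw = dict(raw.get("simulator", {}))
    ligand = sim_raw.pop("ligand_condition", "TPP")
    for key in ("fret_states",):
        if key in sim_raw:
            sim_raw[key] = {s: tuple(v) for s, v in sim_raw[key].items()}
    if "rupture_forces" in sim_raw:
        sim_raw["rupture_forces"] = {
            c: tuple(tuple(r) for r in rips)
            for c, rips in sim_raw["rupture_forces"].items()
        }
    if "stretched_fret" in sim_raw:
        sim_raw["stretched_fret"] = tuple(sim_raw["stretched_fret"])
    _build(SimConfig, sim_raw, "simulator")
    sim = condition_sim_config(ligand, **sim_raw)

    mech_raw = dict(raw.get("mechanics", {}))
    for key in ("handle1", "handle2", "unfolded_rna"):
        if key in mech_raw:
            mech_raw[key] = WLCParams(**mech_raw[key])
    if "contour_gain" in mech_raw:
        mech_raw["contour_gain"] = {
            c: tuple(g) for c, g in mech_raw["contour_gain"].items()
        }
    mech = MechanicalModel(**_build(MechanicalModel, mech_raw, "mechanics"))

    ana_raw = dict(raw.get("analysis", {}))
    for key in ("fret_thresholds", "force_thresholds"):
        if key in ana_raw and ana_raw[key] is not None:
            ana_raw[key] = tuple(ana_raw[key])
    ana = AnalysisConfig(**_build(AnalysisConfig, ana_raw, "analysis"))

    io = IOConfig(**_build(IOConfig, dict(raw.get("io", {})), "io"))
    return RunConfig(simulator=sim, mechanics=mech, analysis=ana, io=io)
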