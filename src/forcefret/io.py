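"""Trace and result file formats.

Traces are TSV with the header
``time_s  trap_sep_nm  force_pN  ext_nm  i_donor  i_acceptor  truth_conf  truth_tert``
(truth columns optional) plus a JSON sidecar (same stem, ``.json``) holding
``refold_end_index``, the generating configuration and any ground-truth
metadata.  Result tables are plain CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import TraceRecord

__all__ = ["write_trace", "read_trace", "read_traces", "write_rip_table", "write_json"]

_COLUMNS = [
    "time_s",
    "trap_sep_nm",
    "force_pN",
    "ext_nm",
    "i_donor",
    "i_acceptor",
    "truth_conf",
    "truth_tert",
]


def write_trace(trace: TraceRecord, path: str | Path) -> Path:
    """Write a trace as TSV + JSON sidecar; returns the TSV path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "trap_sep_nm": trace.trap_separation,
            "force_pN": trace.force,
            "ext_nm": trace.extension,
            "i_donor": trace.i_donor.astype(int),
            "i_acceptor": trace.i_acceptor.astype(int),
        }
    )
    if trace.truth_conformation is not None:
        df["truth_conf"] = trace.truth_conformation
    if trace.truth_tertiary is not None:
        df["truth_tert"] = trace.truth_tertiary
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"refold_end_index": int(trace.refold_end_index), "meta": trace.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trace(path: str | Path) -> TraceRecord:
    """Read one trace TSV (+ optional sidecar).

    Malformed headers, ragged rows, negative counts or non-monotone time
    raise ValueError naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from None
    required = _COLUMNS[:6]
    if list(df.columns[:6]) != required:
        raise ValueError(
            f"{path}: header must start with {required}, got {list(df.columns[:6])}"
        )
    for col in ("i_donor", "i_acceptor"):
        bad = np.flatnonzero(df[col].to_numpy() < 0)
        if bad.size:
            raise ValueError(f"{path}: negative counts in row {bad[0] + 1}")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(f"{path}: non-monotone time at row {bad[0] + 2}")

    refold_end = 0
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        refold_end = int(info.get("refold_end_index", 0))
        meta = info.get("meta", {})
    return TraceRecord(
        time=t,
        trap_separation=df["trap_sep_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        extension=df["ext_nm"].to_numpy(),
        i_donor=df["i_donor"].to_numpy(),
        i_acceptor=df["i_acceptor"].to_numpy(),
        refold_end_index=refold_end,
        truth_conformation=(
            df["truth_conf"].to_numpy(dtype=object) if "truth_conf" in df else None
        ),
        truth_tertiary=(
            df["truth_tert"].to_numpy(dtype=object) if "truth_tert" in df else None
        ),
        meta=meta,
    )


def read_traces(directory: str | Path) -> list[TraceRecord]:
    """Read every ``*.tsv`` trace in a directory (sorted by name)."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise ValueError(f"no trace TSV files in {directory}")
    return [read_trace(p) for p in paths]


def write_rip_table(rows: list[dict], path: str | Path) -> Path:
    """Rip events as CSV: trace_id, frame, F_half_pN, dx_nm, opening_fret, class."""
    path = Path(path)
    pd.DataFrame(
        rows, columns=["trace_id", "frame", "F_half_pN", "dx_nm", "opening_fret", "class"]
    ).to_csv(path, index=False, float_format="%.5f")
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder))
    return path
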