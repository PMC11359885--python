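"""CSV/JSON formats shared across the pipeline.

All time columns are seconds from recording start; units are embedded in
column names (``_s``, ``_uS``, ``_mV``, ``_pct``). Numeric round trips are
lossless to >= 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import NoiseEvent, StimulusProtocol
from .synthetic import ComponentTraces, RawSignal

__all__ = [
    "read_traces",
    "write_traces",
    "read_raw",
    "write_raw",
    "read_protocol",
    "write_protocol",
    "read_features",
    "write_features",
]

_FLOAT_FMT = "%.12g"

TRACE_COLUMNS = ("time_s", "sc_uS", "ss_uS", "sp_mV")
RAW_COLUMNS = ("time_s", "v_mV")
PROTOCOL_COLUMNS = ("onset_s", "duration_s", "level_db", "label")


class IOError_(ValueError):
    """Malformed artifact file."""


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise IOError_(f"{path}: empty input file") from None
    for col in required:
        if col not in df.columns:
            raise IOError_(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise IOError_(f"{path}: no data rows")
    return df


def _check_monotonic_time(path, t: np.ndarray) -> None:
    if np.any(np.diff(t) <= 0):
        raise IOError_(f"{path}: time_s must be strictly increasing")


def read_traces(path) -> ComponentTraces:
    df = _read_csv(path, TRACE_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    _check_monotonic_time(path, t)
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return ComponentTraces(
        sample_rate_hz=fs,
        time_s=t,
        sc_uS=df["sc_uS"].to_numpy(dtype=float),
        ss_uS=df["ss_uS"].to_numpy(dtype=float),
        sp_mV=df["sp_mV"].to_numpy(dtype=float),
    )


def write_traces(path, traces: ComponentTraces) -> None:
    pd.DataFrame(
        {
            "time_s": traces.time_s,
            "sc_uS": traces.sc_uS,
            "ss_uS": traces.ss_uS,
            "sp_mV": traces.sp_mV,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_raw(path) -> RawSignal:
    df = _read_csv(path, RAW_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    _check_monotonic_time(path, t)
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return RawSignal(
        sample_rate_hz=fs, time_s=t, v_mV=df["v_mV"].to_numpy(dtype=float)
    )


def write_raw(path, raw: RawSignal) -> None:
    pd.DataFrame({"time_s": raw.time_s, "v_mV": raw.v_mV}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_protocol(path) -> StimulusProtocol:
    """Read an event log; rest/baseline structure is inferred from spacing."""
    df = _read_csv(path, PROTOCOL_COLUMNS[:3])
    events = tuple(
        NoiseEvent(
            onset_s=float(r["onset_s"]),
            duration_s=float(r["duration_s"]),
            level_db=float(r["level_db"]),
            label=str(r.get("label", "")) if "label" in df.columns else "",
        )
        for _, r in df.sort_values("onset_s").iterrows()
    )
    pre = events[0].onset_s
    rest = (
        events[1].onset_s - events[0].offset_s if len(events) > 1 else 0.0
    )
    total = events[-1].offset_s + rest
    return StimulusProtocol(
        events=events, pre_baseline_s=pre, post_event_rest_s=rest, total_s=total
    )


def write_protocol(path, protocol: StimulusProtocol) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "duration_s": e.duration_s,
                "level_db": e.level_db,
                "label": e.label,
            }
            for e in protocol.events
        ]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features(path) -> pd.DataFrame:
    return _read_csv(path, ("subject_id", "level_db"))


def write_features(path, features: pd.DataFrame) -> None:
    features.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
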