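"""Stimulus-locked response detection and the five electrodermal features.

For each noise event and channel the detector finds a response onset (first
significant slope inside a post-stimulus latency window) and the following
peak, from which the features are computed:

* ``scr_amp_uS`` / ``ssr_amp_uS`` / ``spr_amp_mV`` — onset-to-peak value
  difference (signed); for biphasic skin-potential responses, the
  difference from the first peak to the second, opposite-direction peak.
* ``scr_tris_s`` — SCR rise time, peak time minus onset time.
* ``spret_pct`` — skin potential relative early turn:
  100 * (SPR peak time - SCR peak time) / SCR rise time.

Skin conductance responses are positive-going by physiology; potential and
susceptance responses may take either polarity and the detector follows
whichever direction crosses its slope threshold first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .protocol import NoiseEvent, StimulusProtocol
from .synthetic import ComponentTraces, FEATURES

__all__ = [
    "DetectionConfig",
    "ChannelTrace",
    "Response",
    "detect_response",
    "amplitude",
    "scr_tris",
    "spret",
    "build_feature_table",
]


class ExtractionError(ValueError):
    """Invalid extraction input."""


@dataclass(frozen=True)
class DetectionConfig:
    """Detector tuning.

    latency_window_s : (min, max) onset search window after stimulus onset.
    min_scr_amp_uS / min_spr_amp_mV / min_ssr_amp_uS : smallest accepted
        response amplitude per channel (conventional 0.02 uS SCR criterion,
        scaled to the other channels).
    smooth_halfwidth_s : moving-average halfwidth applied before slope
        estimation.
    min_slope_frac : onset threshold as a fraction of the window's maximum
        absolute slope (adaptive, so large and small responses are timed
        consistently).
    biphasic_second_lobe_frac : minimum second-lobe deflection relative to
        the first lobe for a skin-potential response to count as biphasic.
    """

    latency_window_s: tuple[float, float] = (0.5, 6.0)
    min_scr_amp_uS: float = 0.02
    min_spr_amp_mV: float = 0.05
    min_ssr_amp_uS: float = 0.01
    smooth_halfwidth_s: float = 0.1
    min_slope_frac: float = 0.2
    biphasic_second_lobe_frac: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.latency_window_s
        if not 0 <= lo < hi:
            raise ExtractionError("latency window must satisfy 0 <= min < max")
        for v in (self.min_scr_amp_uS, self.min_spr_amp_mV, self.min_ssr_amp_uS):
            if v < 0:
                raise ExtractionError("amplitude thresholds must be >= 0")
        if not 0 < self.biphasic_second_lobe_frac <= 1:
            raise ExtractionError("biphasic_second_lobe_frac must lie in (0, 1]")

    def min_amp(self, channel: str) -> float:
        return {
            "SC": self.min_scr_amp_uS,
            "SP": self.min_spr_amp_mV,
            "SS": self.min_ssr_amp_uS,
        }[channel]


@dataclass(frozen=True)
class ChannelTrace:
    """One channel of a recording: sample times plus values."""

    time_s: np.ndarray
    values: np.ndarray
    channel: str  # "SC" | "SP" | "SS"

    def __post_init__(self) -> None:
        if self.channel not in ("SC", "SP", "SS"):
            raise ExtractionError(f"unknown channel {self.channel!r}")
        if len(self.time_s) != len(self.values):
            raise ExtractionError("time and value arrays must match in length")


@dataclass(frozen=True)
class Response:
    """Detected onset/peak structure for one event on one channel."""

    channel: str
    event_index: int
    onset_t_s: float
    onset_value: float
    peak_t_s: float
    peak_value: float
    shape: str  # monophasic_pos | monophasic_neg | biphasic
    second_peak_t_s: Optional[float] = None
    second_peak_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.onset_t_s >= self.peak_t_s:
            raise ExtractionError("onset must precede peak")
        if self.shape == "biphasic" and self.second_peak_t_s is None:
            raise ExtractionError("biphasic response requires a second peak")


def amplitude(resp: Response) -> float:
    """Signed response amplitude.

    Monophasic: peak value minus onset value. Biphasic (SP only): second
    peak value minus first peak value.
    """
    if resp.shape == "biphasic":
        return float(resp.second_peak_value - resp.peak_value)
    return float(resp.peak_value - resp.onset_value)


def scr_tris(resp: Response) -> float:
    """SCR rise time: onset-to-peak interval in seconds."""
    if resp.channel != "SC":
        raise ExtractionError("rise time is defined for the SC channel")
    return float(resp.peak_t_s - resp.onset_t_s)


def spret(scr: Response, spr: Response) -> float:
    """Skin potential relative early turn, in percent.

    100 * (SPR peak time - SCR peak time) / SCR rise time. For biphasic
    skin-potential responses the terminal (second) peak anchors the SPR
    peak time, consistent with the peak-to-peak amplitude rule.
    """
    spr_peak_t = (
        spr.second_peak_t_s if spr.shape == "biphasic" else spr.peak_t_s
    )
    return float(100.0 * (spr_peak_t - scr.peak_t_s) / (scr.peak_t_s - scr.onset_t_s))


# ---------------------------------------------------------------------------
# Detection


def _local_extremum(y: np.ndarray, start: int, stop: int, direction: int) -> int | None:
    """Index of the first interior local extremum of direction*y in [start, stop)."""
    z = direction * y
    for i in range(max(start, 1), min(stop, len(y) - 1)):
        if z[i] >= z[i - 1] and z[i] > z[i + 1]:
            return i
    return None


def detect_response(
    trace: ChannelTrace,
    event: NoiseEvent,
    cfg: DetectionConfig = DetectionConfig(),
    window_end_s: float | None = None,
) -> Optional[Response]:
    """Detect the stimulus-locked response to one event, if any.

    The onset is the first sample inside the latency window whose smoothed
    slope exceeds an adaptive threshold (a fraction of the window's maximum
    slope, with an absolute floor); the peak is the first subsequent local
    extremum. Skin-potential responses qualify as biphasic when an
    opposite-direction extremum after the first peak deflects by at least
    ``biphasic_second_lobe_frac`` of the first lobe. Returns ``None`` when
    no deflection reaches the channel's amplitude threshold.

    ``window_end_s`` bounds the peak search (typically the next event's
    onset); it defaults to the end of the trace.
    """
    t, y = trace.time_s, np.asarray(trace.values, dtype=float)
    if len(t) < 5:
        return None
    fs = 1.0 / float(np.median(np.diff(t)))
    lo, hi = cfg.latency_window_s
    i0 = int(np.searchsorted(t, event.onset_s + lo))
    i1 = int(np.searchsorted(t, event.onset_s + hi))
    if i0 >= len(t):
        warnings.warn(
            f"latency window for event at {event.onset_s:.1f}s lies past the "
            "trace end; no detection attempted",
            stacklevel=2,
        )
        return None
    if i1 > len(t):
        warnings.warn(
            f"latency window for event at {event.onset_s:.1f}s truncated at "
            "the trace end",
            stacklevel=2,
        )
        i1 = len(t)
    iend = len(t) if window_end_s is None else int(np.searchsorted(t, window_end_s))
    iend = min(max(iend, i1), len(t))
    if iend - i0 < 3:
        return None

    half = max(1, int(round(cfg.smooth_halfwidth_s * fs)))
    sm = uniform_filter1d(y, size=2 * half + 1, mode="nearest")
    grad = np.gradient(sm, t)

    directions = (1,) if trace.channel == "SC" else (1, -1)
    floor = cfg.min_amp(trace.channel)  # per-second absolute slope floor

    best: tuple[int, int] | None = None  # (onset_idx, direction)
    for d in directions:
        g = d * grad
        gmax = float(np.max(g[i0:iend]))
        thr = max(cfg.min_slope_frac * gmax, floor)
        idx = np.nonzero(g[i0:i1] >= thr)[0]
        if idx.size:
            cand = i0 + int(idx[0])
            if best is None or cand < best[0]:
                best = (cand, d)
    if best is None:
        return None
    onset_idx, d = best

    # The smoothing window smears the rise backwards by up to its halfwidth;
    # re-find the threshold crossing on the raw gradient near the candidate.
    graw = np.gradient(y, t)
    g = d * graw
    lo2 = max(i0, onset_idx - 2 * half)
    hi2 = min(i1 + 2 * half, iend)
    if hi2 > lo2:
        gmax_raw = float(np.max(g[lo2:iend]))
        thr2 = max(cfg.min_slope_frac * gmax_raw, floor)
        idx = np.nonzero(g[lo2:hi2] >= thr2)[0]
        if idx.size:
            onset_idx = lo2 + int(idx[0])

    peak_idx = _local_extremum(sm, onset_idx + 1, iend, d)
    if peak_idx is None:
        peak_idx = onset_idx + int(np.argmax(d * y[onset_idx:iend]))
        if peak_idx == onset_idx:
            return None
    else:
        j0, j1 = max(onset_idx + 1, peak_idx - half), min(iend, peak_idx + half + 1)
        peak_idx = j0 + int(np.argmax(d * y[j0:j1]))

    onset_v, peak_v = float(y[onset_idx]), float(y[peak_idx])
    shape = "monophasic_pos" if d > 0 else "monophasic_neg"
    second_t = second_v = None

    if trace.channel == "SP":
        k = _local_extremum(sm, peak_idx + 1, iend, -d)
        if k is not None:
            j0, j1 = max(peak_idx + 1, k - half), min(iend, k + half + 1)
            k = j0 + int(np.argmax(-d * y[j0:j1]))
            first_defl = peak_v - onset_v
            second_defl = float(y[k]) - onset_v
            if (
                np.sign(second_defl) == -np.sign(first_defl)
                and abs(second_defl) >= cfg.biphasic_second_lobe_frac * abs(first_defl)
            ):
                shape = "biphasic"
                second_t, second_v = float(t[k]), float(y[k])

    resp = Response(
        channel=trace.channel,
        event_index=-1,
        onset_t_s=float(t[onset_idx]),
        onset_value=onset_v,
        peak_t_s=float(t[peak_idx]),
        peak_value=peak_v,
        shape=shape,
        second_peak_t_s=second_t,
        second_peak_value=second_v,
    )
    if abs(amplitude(resp)) < cfg.min_amp(trace.channel):
        return None
    return resp


def build_feature_table(
    traces: ComponentTraces,
    protocol: StimulusProtocol,
    cfg: DetectionConfig = DetectionConfig(),
    subject_id: int | str = 0,
) -> pd.DataFrame:
    """Extract all five features for every protocol event.

    Returns one row per event with the feature columns of the generator's
    table plus detected onset/peak times (``scr_onset_t_s``,
    ``scr_peak_t_s``, ``spr_peak_t_s``). Events without a qualifying
    response carry NaN in the affected features — absence is never
    zero-filled. Deterministic given its inputs.
    """
    for ch in ("sc_uS", "ss_uS", "sp_mV"):
        if getattr(traces, ch, None) is None:
            raise ExtractionError(f"traces are missing channel {ch}")
    if len(protocol) and traces.time_s[-1] < protocol.events[-1].onset_s:
        warnings.warn("traces end before the last protocol event", stacklevel=2)

    chans = {
        "SC": ChannelTrace(traces.time_s, traces.sc_uS, "SC"),
        "SP": ChannelTrace(traces.time_s, traces.sp_mV, "SP"),
        "SS": ChannelTrace(traces.time_s, traces.ss_uS, "SS"),
    }
    rows = []
    events = protocol.events
    for i, ev in enumerate(events):
        w_end = events[i + 1].onset_s if i + 1 < len(events) else None
        r = {name: detect_response(chans[name], ev, cfg, w_end) for name in chans}
        scr, spr, ssr = r["SC"], r["SP"], r["SS"]
        row = {
            "subject_id": subject_id,
            "event_index": i,
            "level_db": ev.level_db,
            "scr_amp_uS": amplitude(scr) if scr else np.nan,
            "spr_amp_mV": amplitude(spr) if spr else np.nan,
            "ssr_amp_uS": amplitude(ssr) if ssr else np.nan,
            "scr_tris_s": scr_tris(scr) if scr else np.nan,
            "spret_pct": spret(scr, spr) if (scr and spr) else np.nan,
            "spr_shape": spr.shape if spr else None,
            "scr_onset_t_s": scr.onset_t_s if scr else np.nan,
            "scr_peak_t_s": scr.peak_t_s if scr else np.nan,
            "spr_peak_t_s": (
                (spr.second_peak_t_s if spr.shape == "biphasic" else spr.peak_t_s)
                if spr
                else np.nan
            ),
        }
        rows.append(row)
    cols = [
        "subject_id", "event_index", "level_db", *FEATURES, "spr_shape",
        "scr_onset_t_s", "scr_peak_t_s", "spr_peak_t_s",
    ]
    return pd.DataFrame(rows, columns=cols)
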