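"""Noise-elicited EDA correction.

Treats measured electrodermal activity as the sum of intrinsic activity and
a noise-elicited component. With a log of ambient noise events (onset,
dB level) and a fitted amplitude-vs-level model, responses are attributed
to events by latency, and the model-estimated noise-elicited amplitude is
subtracted from the per-bin skin conductance response score:

    corrected = sum(SCR amplitudes) - sum(estimated noise-elicited amps)

within each time bin (default 5 min). Corrected scores are deliberately not
clipped at zero: a negative bin signals model overcorrection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocol import NoiseEvent
from .synthetic import BASE_LEVEL_DB

__all__ = [
    "AmplitudeLevelModel",
    "CorrectionResult",
    "fit_amplitude_vs_level",
    "attribute_responses",
    "correct_bins",
]


class CorrectionError(ValueError):
    """Invalid correction input."""


@dataclass(frozen=True)
class AmplitudeLevelModel:
    """Mean response amplitude as a function of noise level.

    ``x`` counts 5 dB steps above 70 dB. ``linear``: a + b*x;
    ``exponential``: a * exp(b*x) (requires a > 0). ``status`` is "ok" or
    "fallback_linear" when an exponential fit was requested but the data
    could not support one (non-positive mean amplitudes).
    """

    form: str
    a: float
    b: float
    fit_rss: float
    n_points: int
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.form not in ("linear", "exponential"):
            raise CorrectionError(f"unknown model form {self.form!r}")
        if self.form == "exponential" and self.a <= 0:
            raise CorrectionError("exponential model requires a > 0")
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise CorrectionError("model parameters must be finite")

    def predict(self, level_db) -> np.ndarray:
        x = (np.asarray(level_db, dtype=float) - BASE_LEVEL_DB) / 5.0
        if self.form == "linear":
            return self.a + self.b * x
        return self.a * np.exp(self.b * x)


@dataclass
class CorrectionResult:
    """Per-bin raw, noise-elicited and corrected SCR amplitude scores (uS)."""

    bin_edges_s: np.ndarray
    raw_score: np.ndarray
    noise_elicited_score: np.ndarray
    corrected_score: np.ndarray
    n_responses: np.ndarray
    n_attributed: np.ndarray


def fit_amplitude_vs_level(
    features: pd.DataFrame,
    form: str = "exponential",
    dv: str = "scr_amp_uS",
) -> AmplitudeLevelModel:
    """Fit mean response amplitude against the noise level.

    Level means are computed from all non-missing rows; the linear form is
    an ordinary least-squares line in x, the exponential is nonlinear least
    squares initialized from the log-linear fit. If an exponential is
    requested but some level mean is non-positive, the fit falls back to
    linear with ``status="fallback_linear"`` and a warning.
    """
    if dv not in features.columns:
        raise CorrectionError(f"feature {dv!r} not in table")
    d = features[["level_db", dv]].dropna()
    means = d.groupby("level_db")[dv].mean()
    if len(means) < 3:
        raise CorrectionError(
            f"need >= 3 distinct levels with data, got {len(means)}"
        )
    x = (means.index.to_numpy(dtype=float) - BASE_LEVEL_DB) / 5.0
    y = means.to_numpy(dtype=float)

    status = "ok"
    if form == "exponential" and np.any(y <= 0):
        warnings.warn(
            "non-positive mean amplitudes: exponential model undefined, "
            "falling back to linear",
            stacklevel=2,
        )
        form, status = "linear", "fallback_linear"

    if form == "linear":
        b, a = np.polyfit(x, y, 1)
        rss = float(np.sum((y - (a + b * x)) ** 2))
        return AmplitudeLevelModel("linear", float(a), float(b), rss, len(y), status)

    # exponential, y > 0 everywhere
    b0, loga0 = np.polyfit(x, np.log(y), 1)
    p, _ = curve_fit(
        lambda xx, a, b: a * np.exp(b * xx), x, y,
        p0=[float(np.exp(loga0)), float(b0)], maxfev=10000,
    )
    a, b = float(p[0]), float(p[1])
    rss = float(np.sum((y - a * np.exp(b * x)) ** 2))
    return AmplitudeLevelModel("exponential", a, b, rss, len(y), "ok")


def attribute_responses(
    responses: pd.DataFrame,
    events: Sequence[NoiseEvent],
    window: tuple[float, float] = (0.5, 6.0),
) -> pd.DataFrame:
    """Attribute responses to noise events by onset latency.

    A response is noise-attributed iff its onset lies within
    ``(window[0], window[1])`` seconds after some event onset; among
    qualifying events the nearest preceding one wins (ties to the earlier
    event). ``responses`` needs an ``onset_t_s`` column (as produced by the
    extractor's ``scr_onset_t_s``, renamed or passed via ``onset_col``
    semantics below — the column ``onset_t_s`` or ``scr_onset_t_s`` is
    accepted). Returns the table with ``event_id`` (index into ``events``,
    -1 when unattributed) and ``event_level_db`` columns added.
    """
    col = "onset_t_s" if "onset_t_s" in responses.columns else "scr_onset_t_s"
    if col not in responses.columns:
        raise CorrectionError("responses need an onset_t_s/scr_onset_t_s column")
    lo, hi = window
    onsets = np.asarray([e.onset_s for e in events], dtype=float)
    order = np.argsort(onsets, kind="stable")
    onsets = onsets[order]

    out = responses.copy()
    ev_id = np.full(len(out), -1, dtype=int)
    ev_level = np.full(len(out), np.nan)
    t = out[col].to_numpy(dtype=float)
    for i, ti in enumerate(t):
        if not np.isfinite(ti) or onsets.size == 0:
            continue
        # nearest preceding event whose window contains the onset
        j = int(np.searchsorted(onsets, ti - lo, side="right")) - 1
        while j >= 0:
            lat = ti - onsets[j]
            if lat > hi:
                break
            if lat >= lo:
                while j > 0 and onsets[j - 1] == onsets[j]:
                    j -= 1  # tie: earlier event wins
                ev_id[i] = int(order[j])
                ev_level[i] = events[int(order[j])].level_db
                break
            j -= 1
    out["event_id"] = ev_id
    out["event_level_db"] = ev_level
    return out


def correct_bins(
    responses: pd.DataFrame,
    events: Sequence[NoiseEvent],
    model: AmplitudeLevelModel,
    bin_s: float = 300.0,
    window: tuple[float, float] = (0.5, 6.0),
    total_s: float | None = None,
    amp_col: str = "scr_amp_uS",
) -> CorrectionResult:
    """Per-bin noise-elicited correction of the SCR amplitude score.

    raw_score sums response amplitudes whose onset falls in the bin;
    noise_elicited_score sums the model prediction at each attributed
    event's level; corrected = raw - noise_elicited (unclipped). Event
    levels outside the model's fitted range are extrapolated with a
    warning.
    """
    if bin_s <= 0:
        raise CorrectionError("bin_s must be > 0")
    att = attribute_responses(responses, events, window)
    col = "onset_t_s" if "onset_t_s" in att.columns else "scr_onset_t_s"
    att = att[np.isfinite(att[col]) & np.isfinite(att[amp_col])]

    t_max = float(total_s) if total_s is not None else (
        float(att[col].max()) + 1.0 if len(att) else bin_s
    )
    n_bins = max(1, int(np.ceil(t_max / bin_s)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_s

    attributed = att[att["event_id"] >= 0]
    if len(attributed):
        fitted = np.array([e.level_db for e in events])
        lo, hi = (fitted.min(), fitted.max()) if fitted.size else (np.nan, np.nan)
        lv = attributed["event_level_db"].to_numpy()
        # levels the model was fitted on are the feature-table levels; warn
        # when attributed events fall outside the observed span
        if lv.size and (lv.min() < lo or lv.max() > hi):
            warnings.warn("event level outside fitted range: extrapolating",
                          stacklevel=2)

    raw = np.zeros(n_bins)
    noise = np.zeros(n_bins)
    n_resp = np.zeros(n_bins, dtype=int)
    n_att = np.zeros(n_bins, dtype=int)
    bins = np.clip((att[col].to_numpy() // bin_s).astype(int), 0, n_bins - 1)
    amps = att[amp_col].to_numpy(dtype=float)
    evl = att["event_level_db"].to_numpy(dtype=float)
    attmask = att["event_id"].to_numpy() >= 0
    for b, amp, lvl, is_att in zip(bins, amps, evl, attmask):
        raw[b] += amp
        n_resp[b] += 1
        if is_att:
            noise[b] += float(model.predict(lvl))
            n_att[b] += 1
    return CorrectionResult(
        bin_edges_s=edges,
        raw_score=raw,
        noise_elicited_score=noise,
        corrected_score=raw - noise,
        n_responses=n_resp,
        n_attributed=n_att,
    )
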