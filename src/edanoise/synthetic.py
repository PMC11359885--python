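"""Synthetic electrodermal cohorts with known ground truth.

The generator produces, for each simulated subject, the five per-stimulus
response features (SCR amplitude, SPR amplitude, SSR amplitude, SCR rise
time, SPRET) from a linear mixed model in the noise level, then optionally
renders them into continuous skin-conductance / susceptance / potential
traces and a raw AC-carrier voltage, so that every downstream stage
(demodulation, detection, statistics, correction) can be tested against a
known truth.

Generating model, per feature f, subject i, level step x = (dB - 70)/5:

    y_ifx = (beta0_f + b0_if) + (beta1_f + b1_if) * x + eps_ifx

with (b0, b1) a zero-mean bivariate normal (per-feature SDs, shared
intercept-slope correlation) and eps iid normal. The ``paper2024`` preset
pins the fixed slopes to the published per-5 dB dose-response estimates:
SCR_Amp +1.2 uS, SPR_Amp -0.7 mV, SSR_Amp -0.2 uS, SCR_Tris +0.4 s,
SPRET +7.3%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .protocol import NoiseEvent, StimulusProtocol, build_protocol

__all__ = [
    "FEATURES",
    "GeneratorConfig",
    "CarrierConfig",
    "ComponentTraces",
    "RawSignal",
    "paper2024_config",
    "scr_kernel",
    "bateman_peak_time",
    "generate_feature_table",
    "synthesize_traces",
    "synthesize_raw_carrier",
]

#: Canonical feature column names (units embedded).
FEATURES = ("scr_amp_uS", "spr_amp_mV", "ssr_amp_uS", "scr_tris_s", "spret_pct")

#: dB level anchoring the x = 0 step.
BASE_LEVEL_DB = 70.0

# Physical floors applied to drawn features (normal tails are clipped here;
# with the default preset the clipping probability is ~1e-4 per draw).
_MIN_SCR_AMP_US = 0.05
_MIN_TRIS_S = 0.3
_MIN_SPRET_PCT = -80.0


class GeneratorError(ValueError):
    """Invalid generator configuration or inputs."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Per-feature mappings are keyed by the names in :data:`FEATURES`.
    """

    n_subjects: int = 40
    levels_db: tuple[float, ...] = (70.0, 75.0, 80.0, 85.0, 90.0)
    fixed_intercepts: Mapping[str, float] = field(
        default_factory=lambda: {
            "scr_amp_uS": 2.0,
            "spr_amp_mV": -1.5,
            "ssr_amp_uS": -0.15,
            "scr_tris_s": 2.5,
            "spret_pct": 15.0,
        }
    )
    fixed_slopes_per5db: Mapping[str, float] = field(
        default_factory=lambda: {
            "scr_amp_uS": 1.2,
            "spr_amp_mV": -0.7,
            "ssr_amp_uS": -0.2,
            "scr_tris_s": 0.4,
            "spret_pct": 7.3,
        }
    )
    random_sd_intercept: Mapping[str, float] = field(
        default_factory=lambda: {
            "scr_amp_uS": 0.5,
            "spr_amp_mV": 0.4,
            "ssr_amp_uS": 0.08,
            "scr_tris_s": 0.4,
            "spret_pct": 8.0,
        }
    )
    random_sd_slope: Mapping[str, float] = field(
        default_factory=lambda: {
            "scr_amp_uS": 0.25,
            "spr_amp_mV": 0.15,
            "ssr_amp_uS": 0.05,
            "scr_tris_s": 0.12,
            "spret_pct": 2.5,
        }
    )
    random_corr: float = 0.3
    residual_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "scr_amp_uS": 0.3,
            "spr_amp_mV": 0.25,
            "ssr_amp_uS": 0.06,
            "scr_tris_s": 0.25,
            "spret_pct": 6.0,
        }
    )
    tonic_sc_uS: float = 5.0
    tonic_ss_uS: float = 2.0
    tonic_sp_mV: float = -15.0
    drift_sd: float = 0.0
    spr_biphasic_prob: float = 0.3
    kernel_tau_rise_s: float = 0.75
    kernel_tau_decay_s: float = 3.0
    onset_smooth_s: float = 0.05
    response_latency_s: float = 1.5
    latency_jitter_s: float = 0.3
    sample_rate_hz: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise GeneratorError("n_subjects must be >= 1")
        lv = np.asarray(self.levels_db, dtype=float)
        if lv.size == 0 or np.any(np.diff(lv) <= 0):
            raise GeneratorError("levels_db must be nonempty and strictly increasing")
        for name, m in (
            ("random_sd_intercept", self.random_sd_intercept),
            ("random_sd_slope", self.random_sd_slope),
            ("residual_sd", self.residual_sd),
        ):
            for f in FEATURES:
                if m[f] < 0:
                    raise GeneratorError(f"{name}[{f}] must be >= 0")
        if not -1.0 <= self.random_corr <= 1.0:
            raise GeneratorError("random_corr must lie in [-1, 1]")
        if not 0.0 <= self.spr_biphasic_prob <= 1.0:
            raise GeneratorError("spr_biphasic_prob must lie in [0, 1]")
        if not 0 < self.kernel_tau_rise_s < self.kernel_tau_decay_s:
            raise GeneratorError("require 0 < tau_rise < tau_decay")
        if self.sample_rate_hz <= 0:
            raise GeneratorError("sample_rate_hz must be > 0")
        if self.drift_sd < 0:
            raise GeneratorError("drift_sd must be >= 0")


def paper2024_config(**overrides) -> GeneratorConfig:
    """The calibrated preset: 40 subjects, 70-90 dB, published fixed slopes."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


@dataclass(frozen=True)
class CarrierConfig:
    """AC excitation used for admittance measurement.

    A ~20 uA, 20 Hz current is driven through the skin; the measured voltage
    amplitude and phase encode conductance and susceptance. ``excitation_mV``
    is the source-side voltage before current conversion (informational).
    """

    freq_hz: float = 20.0
    current_uA: float = 20.0
    excitation_mV: float = 200.0
    phase_ref_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.freq_hz <= 0:
            raise GeneratorError("freq_hz must be > 0")
        if self.current_uA <= 0:
            raise GeneratorError("current_uA must be > 0")


@dataclass
class ComponentTraces:
    """Sampled skin conductance (uS), susceptance (uS) and potential (mV)."""

    sample_rate_hz: float
    time_s: np.ndarray
    sc_uS: np.ndarray
    ss_uS: np.ndarray
    sp_mV: np.ndarray
    truncated_events: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.sc_uS) == len(self.ss_uS) == len(self.sp_mV) == n):
            raise GeneratorError("channel arrays must have equal length")
        for name in ("time_s", "sc_uS", "ss_uS", "sp_mV"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise GeneratorError(f"{name} contains non-finite values")


@dataclass
class RawSignal:
    """Single-channel measured voltage: DC skin potential plus AC carrier."""

    sample_rate_hz: float
    time_s: np.ndarray
    v_mV: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.v_mV)):
            raise GeneratorError("v_mV contains non-finite values")


# ---------------------------------------------------------------------------
# Response kernel


def bateman_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Peak time of the difference-of-exponentials kernel."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def scr_kernel(t_rel, amp: float, tau_rise: float, tau_decay: float):
    """Bateman (biexponential) response kernel, normalized to peak at ``amp``.

    k(t) = amp * (exp(-t/tau_decay) - exp(-t/tau_rise)) / c, with c chosen so
    the maximum equals 1; the peak occurs at
    t_p = tau_r*tau_d/(tau_d - tau_r) * ln(tau_d/tau_r). Zero for t < 0.
    """
    if not 0 < tau_rise < tau_decay:
        raise GeneratorError(
            f"require 0 < tau_rise < tau_decay, got {tau_rise}, {tau_decay}"
        )
    t = np.asarray(t_rel, dtype=float)
    tp = bateman_peak_time(tau_rise, tau_decay)
    c = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    out = np.where(
        t >= 0.0,
        amp * (np.exp(-np.maximum(t, 0.0) / tau_decay)
               - np.exp(-np.maximum(t, 0.0) / tau_rise)) / c,
        0.0,
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Feature-level generation


def generate_feature_table(
    config: GeneratorConfig,
    protocol: StimulusProtocol | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort's per-stimulus features and the matching ground truth.

    Returns ``(features, truth)``. ``features`` has one row per
    subject x event with columns ``subject_id, event_index, level_db,
    level_step`` plus the five features and ``spr_shape``. ``truth`` mirrors
    it and adds true channel onset/peak times consistent with the drawn
    rise times and SPRET (SPR peak = SCR peak + SPRET * Tris / 100), used by
    :func:`synthesize_traces` and by round-trip tests.

    Identical configs (including seed) give identical tables.
    """
    if protocol is None:
        protocol = build_protocol(config.levels_db)
    if len(protocol) != len(config.levels_db):
        raise GeneratorError("protocol event count must match levels_db")

    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    k = len(config.levels_db)
    x = (np.asarray(config.levels_db, dtype=float) - BASE_LEVEL_DB) / 5.0

    rows: dict[str, np.ndarray] = {}
    sub = np.repeat(np.arange(n), k)
    rows["subject_id"] = sub
    rows["event_index"] = np.tile(np.arange(k), n)
    rows["level_db"] = np.tile(np.asarray(config.levels_db, dtype=float), n)
    rows["level_step"] = np.tile(x, n)

    rho = config.random_corr
    for f in FEATURES:
        s0 = config.random_sd_intercept[f]
        s1 = config.random_sd_slope[f]
        cov = np.array(
            [[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]], dtype=float
        )
        b = rng.multivariate_normal(np.zeros(2), cov, size=n)  # svd handles SD=0
        eps = rng.normal(0.0, config.residual_sd[f], size=(n, k))
        y = (
            (config.fixed_intercepts[f] + b[:, [0]])
            + (config.fixed_slopes_per5db[f] + b[:, [1]]) * x[None, :]
            + eps
        )
        rows[f] = y.reshape(-1)

    # physical floors (rare with the default preset)
    rows["scr_amp_uS"] = np.maximum(rows["scr_amp_uS"], _MIN_SCR_AMP_US)
    rows["scr_tris_s"] = np.maximum(rows["scr_tris_s"], _MIN_TRIS_S)
    rows["spret_pct"] = np.maximum(rows["spret_pct"], _MIN_SPRET_PCT)

    biphasic = rng.random(size=n * k) < config.spr_biphasic_prob
    shape = np.where(
        biphasic,
        "biphasic",
        np.where(rows["spr_amp_mV"] < 0, "monophasic_neg", "monophasic_pos"),
    )
    rows["spr_shape"] = shape

    features = pd.DataFrame(rows)

    # timing truth
    jit = rng.uniform(
        -config.latency_jitter_s, config.latency_jitter_s, size=n * k
    )
    onsets = np.array([e.onset_s for e in protocol.events])
    ev_onset = np.tile(onsets, n)
    scr_onset = ev_onset + config.response_latency_s + jit
    scr_peak = scr_onset + features["scr_tris_s"].to_numpy()
    spr_onset = scr_onset.copy()
    spr_peak = scr_peak + features["spret_pct"].to_numpy() * features[
        "scr_tris_s"
    ].to_numpy() / 100.0
    # first (minor) lobe peak of biphasic SPRs sits at 45% of onset->terminal-peak
    spr_first_peak = np.where(
        biphasic, spr_onset + 0.45 * (spr_peak - spr_onset), np.nan
    )

    truth = features.copy()
    truth["scr_onset_t_s"] = scr_onset
    truth["scr_peak_t_s"] = scr_peak
    truth["spr_onset_t_s"] = spr_onset
    truth["spr_first_peak_t_s"] = spr_first_peak
    truth["spr_peak_t_s"] = spr_peak
    truth["ssr_onset_t_s"] = scr_onset
    truth["ssr_peak_t_s"] = scr_peak
    return features, truth


# ---------------------------------------------------------------------------
# Trace rendering


def _raised_cosine_biphasic(t, t1, t2, p1, p2, decay):
    """C1 biphasic waveform: 0 -> p1 at t1 -> p2 at t2 -> 0 over ``decay``.

    Extrema sit exactly at t1 and t2 with values p1 and p2, which keeps the
    rendered peak times and the peak-to-peak amplitude identical to the
    drawn ground truth (summing two Bateman lobes would shift both).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m1 = (t >= 0) & (t < t1)
    out[m1] = p1 * 0.5 * (1 - np.cos(np.pi * t[m1] / t1))
    m2 = (t >= t1) & (t < t2)
    out[m2] = p1 + (p2 - p1) * 0.5 * (1 - np.cos(np.pi * (t[m2] - t1) / (t2 - t1)))
    m3 = (t >= t2) & (t < t2 + decay)
    out[m3] = p2 * 0.5 * (1 + np.cos(np.pi * (t[m3] - t2) / decay))
    return out


def synthesize_traces(
    protocol: StimulusProtocol,
    truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> ComponentTraces:
    """Render one subject's ground-truth rows into continuous channel traces.

    SC gets a Bateman kernel per event, time-scaled so onset-to-peak equals
    the true rise time and peak-minus-onset equals the true amplitude; SS a
    kernel with the true (typically negative) amplitude on the same timing;
    SP a signed monophasic kernel peaking at the SPRET-implied time, or a
    raised-cosine biphasic pair whose terminal-minus-first peak difference
    equals the true SPR amplitude. Responses whose kernels run past the end
    of the trace are truncated and flagged in ``truncated_events``.

    ``truth`` must contain exactly one row per protocol event (one subject).
    ``rng`` is only used when ``config.drift_sd > 0``.
    """
    if len(truth) != len(protocol):
        raise GeneratorError("truth must contain one row per protocol event")
    for _, r in truth.iterrows():
        if not (r["scr_amp_uS"] > 0 and r["scr_tris_s"] > 0):
            raise GeneratorError("true SCR_Amp and SCR_Tris must be > 0")

    fs = config.sample_rate_hz
    n = int(round(protocol.total_s * fs))
    t = np.arange(n) / fs
    tp0 = bateman_peak_time(config.kernel_tau_rise_s, config.kernel_tau_decay_s)

    sc = np.zeros(n)
    ss = np.zeros(n)
    sp = np.zeros(n)
    truncated: list[int] = []

    for _, r in truth.iterrows():
        ev = int(r["event_index"])
        tris = float(r["scr_tris_s"])
        scale = tris / tp0
        tr = config.kernel_tau_rise_s * scale
        td = config.kernel_tau_decay_s * scale

        # SC and SS share onset/peak timing
        t_on = float(r["scr_onset_t_s"])
        sc += scr_kernel(t - t_on, float(r["scr_amp_uS"]), tr, td)
        ss += scr_kernel(t - t_on, float(r["ssr_amp_uS"]), tr, td)

        # SP
        sp_on = float(r["spr_onset_t_s"])
        rise = float(r["spr_peak_t_s"]) - sp_on
        amp = float(r["spr_amp_mV"])
        if rise <= 0:
            truncated.append(ev)
            continue
        if r["spr_shape"] == "biphasic":
            t1 = float(r["spr_first_peak_t_s"]) - sp_on
            # curvature-matched return-to-baseline: keeps the terminal
            # extremum symmetric, so smoothing does not displace it
            decay = max((rise - t1) * np.sqrt(0.6), 0.5)
            sp += _raised_cosine_biphasic(
                t - sp_on, t1, rise, -0.4 * amp, 0.6 * amp, decay
            )
            tail = rise + decay
        else:
            sp_scale = rise / tp0
            sp += scr_kernel(
                t - sp_on,
                amp,
                config.kernel_tau_rise_s * sp_scale,
                config.kernel_tau_decay_s * sp_scale,
            )
            tail = rise + 3.0 * config.kernel_tau_decay_s * sp_scale
        if max(t_on + tris, sp_on + tail) > protocol.total_s:
            truncated.append(ev)

    # Physiological responses rise smoothly; a short Gaussian convolution
    # rounds the kernels' onset feet (the raw Bateman kernel has a slope
    # discontinuity there, whose spectrum would otherwise reach the AC
    # carrier band and fold into the demodulated skin-potential channel).
    if config.onset_smooth_s > 0:
        from scipy.ndimage import gaussian_filter1d

        sig = config.onset_smooth_s * fs
        sc = gaussian_filter1d(sc, sig, mode="nearest")
        ss = gaussian_filter1d(ss, sig, mode="nearest")
        sp = gaussian_filter1d(sp, sig, mode="nearest")

    sc += config.tonic_sc_uS
    ss += config.tonic_ss_uS
    sp += config.tonic_sp_mV

    if config.drift_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        step = config.drift_sd / np.sqrt(fs)
        for arr in (sc, ss, sp):
            arr += np.cumsum(rng.normal(0.0, step, size=n))

    if np.any(sc <= 0):
        raise GeneratorError("rendered skin conductance is non-positive somewhere")
    return ComponentTraces(
        sample_rate_hz=fs,
        time_s=t,
        sc_uS=sc,
        ss_uS=ss,
        sp_mV=sp,
        truncated_events=tuple(sorted(set(truncated))),
    )


def synthesize_raw_carrier(
    traces: ComponentTraces, carrier: CarrierConfig
) -> RawSignal:
    """Render component traces into the measured single-channel voltage.

    v(t) = sp(t) + 1000 * |I / Y(t)| * sin(2*pi*f*t + phase_ref - arg Y(t))

    with Y = G + jB in uS, I in uA, so the carrier amplitude is in mV
    (20 uA across 20 uS gives a 1 V = 1000 mV tone). Requires the trace
    sampling rate to exceed twice the carrier frequency (>= 20x recommended).
    """
    fs = traces.sample_rate_hz
    if fs <= 2.0 * carrier.freq_hz:
        raise GeneratorError(
            f"sample rate {fs} Hz must exceed 2 x carrier frequency "
            f"({carrier.freq_hz} Hz)"
        )
    y = traces.sc_uS + 1j * traces.ss_uS
    mag = np.abs(y)
    if np.any(mag == 0):
        raise GeneratorError("admittance magnitude is zero somewhere (non-physical)")
    amp_mV = 1000.0 * carrier.current_uA / mag
    phase = (
        2.0 * np.pi * carrier.freq_hz * traces.time_s
        + carrier.phase_ref_rad
        - np.angle(y)
    )
    v = traces.sp_mV + amp_mV * np.sin(phase)
    return RawSignal(sample_rate_hz=fs, time_s=traces.time_s.copy(), v_mV=v)
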