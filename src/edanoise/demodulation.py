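"""Digital lock-in separation of the raw skin voltage.

The measurement drives a small AC current (default 20 uA at 20 Hz) through
the skin while recording the voltage, which is the sum of the DC skin
potential and a carrier tone whose amplitude and phase encode the complex
skin admittance Y = G + jB. Phase-sensitive detection multiplies the raw
signal by reference sin/cos at the carrier frequency, low-passes the
products (zero-phase Butterworth), and converts the resulting voltage
phasor back to conductance and susceptance by complex division.

Conventions: with reference phase r and v(t) = A sin(2*pi*f*t + r - phi),
the demodulated pair is v_inphase = A cos(phi), v_quad = -A sin(phi), so
the voltage phasor v_inphase + j*v_quad = A exp(-j*phi) and

    Y_uS = 1000 * I_uA / (v_inphase + j*v_quad)   [voltages in mV].

Capacitive susceptance is positive in this convention, so sudomotor
susceptance responses appear as negative deflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .synthetic import CarrierConfig, ComponentTraces, RawSignal

__all__ = [
    "DemodConfig",
    "DemodResult",
    "lockin_demodulate",
    "phasor_to_admittance",
    "demodulate_to_traces",
    "estimate_phase_ref",
]


class DemodError(ValueError):
    """Invalid demodulation configuration or input."""


@dataclass(frozen=True)
class DemodConfig:
    """Lock-in post-detection filtering and output rate.

    lp_cutoff_hz : -3 dB low-pass cutoff for the demodulated products (must
        sit well below the carrier; sudomotor dynamics live below ~0.5 Hz).
    filter_type : ``gaussian`` (zero-phase Gaussian FIR; monotone step
        response, so sharp response onsets do not pre-ring into the
        baseline) or ``butter`` (forward-backward Butterworth of
        ``filter_order``; flatter passband but rings around step-like
        inputs).
    settle_s : initial transient discarded from the outputs.
    out_rate_hz : decimated output rate.
    """

    lp_cutoff_hz: float = 1.0
    filter_type: str = "gaussian"
    filter_order: int = 4
    settle_s: float = 2.0
    out_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.lp_cutoff_hz <= 0:
            raise DemodError("lp_cutoff_hz must be > 0")
        if self.filter_type not in ("gaussian", "butter"):
            raise DemodError(f"unknown filter_type {self.filter_type!r}")
        if self.settle_s < 0:
            raise DemodError("settle_s must be >= 0")
        if self.filter_order < 1:
            raise DemodError("filter_order must be >= 1")
        if self.out_rate_hz <= 0:
            raise DemodError("out_rate_hz must be > 0")


@dataclass
class DemodResult:
    """Decimated DC and in-phase/quadrature channels, settle period removed."""

    sample_rate_hz: float
    time_s: np.ndarray
    dc_mV: np.ndarray
    v_inphase_mV: np.ndarray
    v_quad_mV: np.ndarray


def _lowpass(x: np.ndarray, fs: float, cfg: DemodConfig) -> np.ndarray:
    if cfg.filter_type == "butter":
        sos = sps.butter(
            cfg.filter_order, cfg.lp_cutoff_hz, btype="low", fs=fs, output="sos"
        )
        return sps.sosfiltfilt(sos, x)
    # Gaussian with its -3 dB point at the cutoff: sigma = sqrt(ln2)/(2 pi fc)
    sigma_s = np.sqrt(np.log(2.0)) / (2.0 * np.pi * cfg.lp_cutoff_hz)
    return gaussian_filter1d(x, sigma=sigma_s * fs, mode="nearest", truncate=6.0)


def lockin_demodulate(
    raw: RawSignal, carrier: CarrierConfig, cfg: DemodConfig = DemodConfig()
) -> DemodResult:
    """Split a raw voltage into DC and in-phase/quadrature carrier channels.

    Returns low-passed, decimated traces with the first ``settle_s`` seconds
    dropped. Raises if the cutoff does not separate the bands.
    """
    fs = raw.sample_rate_hz
    if cfg.lp_cutoff_hz >= carrier.freq_hz:
        raise DemodError(
            f"lp_cutoff_hz ({cfg.lp_cutoff_hz}) must be < carrier frequency "
            f"({carrier.freq_hz}): DC and AC components are inseparable"
        )
    if fs <= 2.0 * carrier.freq_hz:
        raise DemodError("raw sample rate must exceed 2 x carrier frequency")

    w = 2.0 * np.pi * carrier.freq_hz * raw.time_s + carrier.phase_ref_rad
    sin_w, cos_w = np.sin(w), np.cos(w)
    vi = _lowpass(2.0 * raw.v_mV * sin_w, fs, cfg)
    vq = _lowpass(2.0 * raw.v_mV * cos_w, fs, cfg)
    # Carrier subtraction before DC extraction: a time-varying envelope has
    # sidebands at the carrier rate that fold into the DC band and would
    # contaminate the skin-potential channel. The AC part is reconstructed
    # from a one-carrier-cycle moving-average envelope (zero lag beyond half
    # a cycle, exact cancellation of the 2f products) and removed before the
    # output low-pass.
    ncyc = max(1, int(round(fs / carrier.freq_hz)))
    vi_fast = uniform_filter1d(2.0 * raw.v_mV * sin_w, ncyc, mode="nearest")
    vq_fast = uniform_filter1d(2.0 * raw.v_mV * cos_w, ncyc, mode="nearest")
    dc = _lowpass(raw.v_mV - (vi_fast * sin_w + vq_fast * cos_w), fs, cfg)

    step = max(1, int(round(fs / cfg.out_rate_hz)))
    start = int(np.ceil(cfg.settle_s * fs))
    stop = len(raw.v_mV) - start if start > 0 else None  # edge transient at both ends
    sl = slice(start, stop, step)
    return DemodResult(
        sample_rate_hz=fs / step,
        time_s=raw.time_s[sl].copy(),
        dc_mV=dc[sl],
        v_inphase_mV=vi[sl],
        v_quad_mV=vq[sl],
    )


def phasor_to_admittance(
    v_inphase_mV, v_quad_mV, carrier: CarrierConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Convert the demodulated voltage phasor to conductance and susceptance.

    Complex division of the (real, at the reference phase) current phasor by
    the voltage phasor: Y = 1000 * I_uA / (v_i + j v_q), returned as
    ``(g_uS, b_uS)``.
    """
    vi = np.asarray(v_inphase_mV, dtype=float)
    vq = np.asarray(v_quad_mV, dtype=float)
    if np.any(vi**2 + vq**2 == 0):
        raise DemodError("zero voltage phasor: admittance undefined")
    y = 1000.0 * carrier.current_uA / (vi + 1j * vq)
    return y.real, y.imag


def demodulate_to_traces(
    raw: RawSignal, carrier: CarrierConfig, cfg: DemodConfig = DemodConfig()
) -> ComponentTraces:
    """Full chain: raw voltage -> (SP, SC, SS) component traces."""
    d = lockin_demodulate(raw, carrier, cfg)
    g, b = phasor_to_admittance(d.v_inphase_mV, d.v_quad_mV, carrier)
    return ComponentTraces(
        sample_rate_hz=d.sample_rate_hz,
        time_s=d.time_s,
        sc_uS=g,
        ss_uS=b,
        sp_mV=d.dc_mV,
    )


def estimate_phase_ref(
    raw: RawSignal,
    carrier: CarrierConfig,
    cfg: DemodConfig = DemodConfig(),
    segment_s: tuple[float, float] | None = None,
) -> float:
    """Estimate the reference phase from a stationary calibration segment.

    Demodulates with phase 0 and returns the phase that rotates the mean
    phasor onto the in-phase axis (maximizing in-phase power). Useful when
    source and digitizer do not share a clock; the simulator does share one,
    so the default reference phase is exact there.
    """
    d = lockin_demodulate(
        raw, CarrierConfig(carrier.freq_hz, carrier.current_uA,
                           carrier.excitation_mV, 0.0), cfg
    )
    if segment_s is not None:
        m = (d.time_s >= segment_s[0]) & (d.time_s <= segment_s[1])
        vi, vq = d.v_inphase_mV[m], d.v_quad_mV[m]
    else:
        vi, vq = d.v_inphase_mV, d.v_quad_mV
    if vi.size == 0:
        raise DemodError("calibration segment contains no samples")
    return float(np.arctan2(np.mean(vq), np.mean(vi)))
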