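# Methods

## Scope and model overview

The package treats electrodermal activity (EDA) as three simultaneously
measured channels at one skin site: skin conductance (SC, μS) and skin
susceptance (SS, μS) — the real and imaginary parts of skin admittance
probed by a weak AC current — and skin potential (SP, mV), the DC voltage
between measuring and reference electrodes. Brief environmental noises act
as startle-type sympathetic stimuli; each stimulus elicits phasic
responses (SCR/SSR/SPR) whose size grows with sound pressure level. The
pipeline simulates such recordings, demodulates them, extracts
per-stimulus response features, estimates the dose–response effect of
noise level, and subtracts the estimated noise-elicited component from
summary scores.

## Stimulus protocol

The default protocol places five 5 s stimuli at 70, 75, 80, 85 and 90 dB
SPL, each followed by a 60 s relaxation, after a 60 s pre-stimulus
baseline — a 385 s timeline with onsets at 60, 125, 190, 255 and 320 s.
The total duration constrains but does not uniquely determine the split
between baseline and rests; the 60 s pre-baseline is the one reading
consistent with equal event spacing, and the builder exposes all three
durations for other designs. Each level is tied to a distinct noise type
(fan, industrial, footsteps, ICU, siren); type and level are confounded by
design, so the generator parameterizes level only.

## Synthetic cohorts

### Feature-level generating model

For each feature f, subject i and level step x = (dB − 70)/5 ∈ {0..4}:

    y = (β₀f + b₀ᵢf) + (β₁f + b₁ᵢf)·x + ε,
    (b₀, b₁) ~ N(0, Σf),  ε ~ N(0, σf²),

with a shared intercept–slope correlation (default 0.3). The calibrated
preset (`paper2024_config`) pins the fixed slopes to the published
per-5 dB dose–response estimates: SCR_Amp +1.2 μS, SPR_Amp −0.7 mV,
SSR_Amp −0.2 μS, SCR_Tris +0.4 s, SPRET +7.3 %. Intercepts and variance
components are not published; the defaults (e.g. SCR_Amp: β₀ = 2 μS,
SD(b₀) = 0.5, SD(b₁) = 0.25, σ = 0.3 μS) were chosen once as values a
practitioner would call realistic for strong startle-type responses while
keeping amplitudes and rise times physically positive under normal tails
(violation probability ~10⁻⁴ per draw; draws are clipped at 0.05 μS,
0.3 s and −80 % as floors). A consequence is that the simulated cohorts'
confidence intervals are somewhat narrower than the published ones —
positivity was prioritized over matching CI width, which is not an
evaluation target. SPRET is drawn jointly-consistently: the implied SPR
peak offset is SPRET·Tris/100 after the SCR peak, and the truth table
records all onset/peak times. SPRs are biphasic with probability 0.3
(default), otherwise monophasic with the drawn sign.

### Trace rendering

SC, SS and monophasic SP responses use the Bateman (difference of
exponentials) kernel, normalized to unit peak and time-scaled so
onset-to-peak equals the drawn rise time; peak-minus-onset then equals the
drawn amplitude exactly. Default shape τ_rise = 0.75 s, τ_decay = 3 s
before scaling — the standard sudomotor response model. Biphasic SPs use
raised-cosine segments with extrema placed exactly at the drawn first and
terminal peak times (lobes −0.4·A then +0.6·A, so terminal-minus-first
equals the drawn amplitude A); summed Bateman lobes would displace both
extrema and break the ground-truth annotations. The return-to-baseline
segment is curvature-matched at the terminal extremum so smoothing does
not displace it.

All phasic activity is convolved with a short Gaussian (σ = 50 ms). This
models the smooth rise of real sudomotor responses and is numerically
load-bearing: an un-smoothed kernel has a slope discontinuity at onset
whose spectrum reaches the 20 Hz carrier band, and any admittance-envelope
content at exactly the carrier frequency folds into the demodulated DC
(skin potential) channel, where no linear filter can remove it. With the
50 ms smoothing that leakage is suppressed by ~10⁻⁶.

Responses whose kernels run past the end of the trace are truncated and
flagged rather than rejected. Baselines default to 5 μS (SC), 2 μS (SS)
and −15 mV (SP); slow drift is off by default (`drift_sd = 0`) and, when
enabled, is a Gaussian random walk added to all channels.

### Carrier synthesis

The raw measured voltage is v(t) = SP(t) + 1000·|I/Y(t)|·sin(2πft + r −
arg Y(t)) mV, with Y = G + jB in μS and I = 20 μA at f = 20 Hz from an
ideal current source (20 μA across 20 μS gives a 1 V tone). Component
traces intended for carrier rendering are sampled at 400 Hz (20× the
carrier); feature-level and trace-level work uses 20 Hz.

## Lock-in demodulation

Reference sin/cos at the carrier frequency multiply the raw signal; the
products are low-passed, decimated (default 20 Hz output) and converted to
admittance by complex division Y = 1000·I/(v_i + j·v_q). With reference
phase r and v = A sin(2πft + r − φ), the convention v_i = A cos φ,
v_q = −A sin φ makes capacitive susceptance positive, so sudomotor
susceptance responses appear as negative deflections.

Numerical choices:

* **Output filter**: zero-phase Gaussian FIR with −3 dB at 1 Hz (default).
  A forward–backward Butterworth (also available) has a flatter passband
  but pre-rings at response onsets; the ring is symmetric about each onset
  and large enough (~0.3 mV for typical SPRs) to masquerade as the first
  lobe of a biphasic response. The Gaussian's monotone step response
  avoids this at the cost of ~2 % droop on the fastest response rises.
* **Carrier subtraction**: before DC extraction, the AC part reconstructed
  from a one-carrier-cycle moving-average envelope is removed; the
  envelope's low-frequency sidebands otherwise leak into the skin
  potential channel.
* **Settling**: the first and last `settle_s` (default 2 s) are dropped —
  FIR edge effects are largest there.
* **Reference phase**: source and digitizer share a clock in simulation,
  so the phase is known; `estimate_phase_ref` recovers it from a
  stationary (resistive) calibration segment otherwise.

Stationary admittance and potential are recovered well within 1 % / 0.1 mV
after settling; during fast response rises a few percent of transient
filter droop is expected and tolerated by the feature round-trip budget.

## Response detection and features

For each stimulus the detector searches a latency window (default 0.5–6 s
post onset) on each channel. The onset is the first sample whose smoothed
slope (moving average, halfwidth 0.1 s) exceeds an adaptive threshold —
20 % of the window's maximum slope, with an absolute floor equal to the
channel's amplitude criterion per second — then refined against the raw
gradient so the smoothing window does not pull onsets early. The peak is
the first subsequent interior local extremum (value taken from the raw
trace). SC responses are positive-going by physiology; SP and SS may take
either polarity, and the detector follows whichever direction crosses
threshold first — for biphasic SPs this correctly orders the lobes,
whereas a strict largest-deflection rule would lock onto the dominant
terminal lobe and mistime the response. An SP response is biphasic when a
later opposite-direction extremum deflects (from the onset value) by at
least half the first lobe.

Features follow the standard definitions: amplitudes are peak-minus-onset
(signed), except biphasic SPR amplitude which is terminal-peak minus
first-peak; Tris is SCR peak time minus onset time; SPRET anchors on the
SPR's terminal peak for biphasic shapes, consistent with the peak-to-peak
amplitude rule. Responses below channel thresholds (0.02 μS SCR — the
conventional criterion — 0.05 mV SPR, 0.01 μS SSR) are recorded as
missing, never zero-filled, and missingness propagates through the
statistics (complete cases for the ANOVA, all available observations for
the mixed model).

On noise-free rendered cohorts the detector matches ground-truth onset and
peak times within one sample period for ≥ 99 % of events and amplitudes
within 5 %.

## Statistics

* **Repeated-measures ANOVA**: one-way within-subject decomposition
  computed directly from sums of squares; F = MS_level / MS_error on
  (k−1, (n−1)(k−1)) df. No sphericity correction is applied — the
  uncorrected within-subject F is reported. Exact additivity is reported
  as F = +inf, p = 0.
* **Sidak post hocs**: all k(k−1)/2 paired t tests;
  p_adj = 1 − (1 − p)^m with m = 10 for five levels (the number of
  pairwise comparisons; Sidak ≤ Bonferroni everywhere).
* **Mixed model**: REML via statsmodels MixedLM with a free 2×2 random
  covariance; Wald 95 % CIs. Level coding is per 5 dB step above 70 dB,
  so β₁ is directly the per-5 dB effect; recoding in raw dB rescales it by
  exactly 1/5. Non-convergence raises with diagnostics rather than
  falling back silently. At 40 subjects the Wald CI covers the generating
  slope at ≈ 95 % (empirically 95/100 replicates).

## Noise-elicited correction

The measured SCR score is modeled as intrinsic plus noise-elicited
activity. Mean amplitude vs level is fitted either linearly (a + b·x) or
exponentially (a·e^{b·x}, nonlinear least squares initialized from the
log-linear fit; falls back to linear with a warning when level means are
non-positive). A response is attributed to a noise event when its onset
falls 0.5–6 s after the event onset (nearest preceding event wins, ties to
the earlier). Within each bin (default 300 s) the corrected score is the
raw amplitude sum minus the model-predicted amplitudes of attributed
responses. Corrected scores are deliberately not clipped at zero —
negative bins flag overcorrection. The model is fitted population-level by
default; per-subject refits are possible by passing a subject's own
feature rows. In the perfect-model limit (no intrinsic activity, model
equal to the generating law) the corrected scores fall below 5 % of raw.

## Problem sizes

Slope-recovery checks average 20 independent cohorts of 40 subjects at
feature fidelity, and 8 cohorts of 10 subjects through the full
render → carrier → demodulate → extract chain; CI coverage uses 100
replicates. These sizes give Monte-Carlo standard errors comfortably
below the tolerances they are tested against.

## What the generator does and does not emulate

Emulated: the graded-noise protocol, mixed-model dose–response structure
with subject heterogeneity, response-shape geometry (onset/peak timing,
mono/biphasic SPs), the AC+DC measurement physics including
envelope-to-DC crosstalk, and feature-level residual noise. Not emulated:
electrode polarization, motion artifacts, habituation across repeated
stimuli, overlapping/spontaneous (non-stimulus) responses, tonic-level
dynamics beyond optional slow drift, and measurement noise in the raw
voltage. Passing round-trip tests therefore demonstrate correctness of
the pipeline's algebra and detection logic under clean conditions, not
robustness to every artifact of field recordings.

## Known limitations

* Noise type and level are confounded by design; only level effects are
  modeled or recoverable.
* The detector is a single-pass slope-threshold method; it does not
  deconvolve overlapping responses and will merge responses closer than
  the kernel decay.
* The exponential correction model is fitted to level means; with few
  levels it can be nearly collinear with the linear form, and model choice
  should rest on the residual sums of squares it reports.
* Simulated non-responses arise only from the amplitude floor, so
  missingness rates are lower than in field data.
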