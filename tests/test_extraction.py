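import numpy as np
import pandas as pd
import pytest

from edanoise import (
    ChannelTrace,
    DetectionConfig,
    Response,
    amplitude,
    build_feature_table,
    build_protocol,
    detect_response,
    generate_feature_table,
    paper2024_config,
    scr_tris,
    spret,
    synthesize_traces,
)
from edanoise.protocol import NoiseEvent
from edanoise.synthetic import ComponentTraces


def _resp(channel="SC", onset_t=1.0, onset_v=2.0, peak_t=4.0, peak_v=3.5,
          shape="monophasic_pos", second_t=None, second_v=None):
    return Response(channel=channel, event_index=0, onset_t_s=onset_t,
                    onset_value=onset_v, peak_t_s=peak_t, peak_value=peak_v,
                    shape=shape, second_peak_t_s=second_t,
                    second_peak_value=second_v)


class TestAmplitude:
    def test_monophasic_sc(self):
        assert amplitude(_resp()) == pytest.approx(1.5)

    def test_monophasic_negative_sp(self):
        r = _resp(channel="SP", onset_v=-20.0, peak_v=-21.4,
                  shape="monophasic_neg")
        assert amplitude(r) == pytest.approx(-1.4)

    def test_biphasic_peak_to_peak_rule(self):
        # lobes +0.5 then -1.0 relative to onset at 0 -> amplitude -1.5 mV
        r = _resp(channel="SP", onset_v=0.0, peak_v=0.5, shape="biphasic",
                  second_t=6.0, second_v=-1.0)
        assert amplitude(r) == pytest.approx(-1.5)


class TestScrTris:
    def test_interval(self):
        assert scr_tris(_resp(onset_t=61.5, peak_t=64.5)) == pytest.approx(3.0)

    def test_equal_onset_and_peak_not_representable(self):
        with pytest.raises(Exception):
            _resp(onset_t=2.0, peak_t=2.0)

    def test_non_sc_channel_rejected(self):
        with pytest.raises(Exception):
            scr_tris(_resp(channel="SP", shape="monophasic_neg"))


class TestSpret:
    @pytest.mark.parametrize("scr_onset,scr_peak,spr_peak,expect", [
        (1.0, 4.0, 5.0, pytest.approx(100 / 3)),
        (1.0, 4.0, 4.0, 0.0),
        (2.0, 6.0, 5.0, -25.0),
    ])
    def test_formula(self, scr_onset, scr_peak, spr_peak, expect):
        scr = _resp(onset_t=scr_onset, peak_t=scr_peak)
        spr = _resp(channel="SP", onset_t=scr_onset, peak_t=spr_peak,
                    onset_v=0.0, peak_v=-1.0, shape="monophasic_neg")
        assert spret(scr, spr) == expect

    def test_biphasic_uses_terminal_peak(self):
        scr = _resp(onset_t=1.0, peak_t=4.0)
        spr = _resp(channel="SP", onset_t=1.0, peak_t=3.0, onset_v=0.0,
                    peak_v=0.5, shape="biphasic", second_t=5.0, second_v=-1.0)
        assert spret(scr, spr) == pytest.approx(100 / 3)

    def test_common_time_shift_invariance(self):
        scr1 = _resp(onset_t=1.0, peak_t=4.0)
        spr1 = _resp(channel="SP", onset_t=1.0, peak_t=5.0, onset_v=0, peak_v=-1,
                     shape="monophasic_neg")
        scr2 = _resp(onset_t=11.0, peak_t=14.0)
        spr2 = _resp(channel="SP", onset_t=11.0, peak_t=15.0, onset_v=0,
                     peak_v=-1, shape="monophasic_neg")
        assert spret(scr1, spr1) == spret(scr2, spr2)


class TestDetectResponse:
    def test_flat_trace_yields_none(self):
        t = np.arange(0, 100, 0.05)
        tr = ChannelTrace(t, np.full_like(t, 5.0), "SC")
        assert detect_response(tr, NoiseEvent(30, 5, 80)) is None

    def test_window_past_trace_end_warns(self):
        t = np.arange(0, 10, 0.05)
        tr = ChannelTrace(t, np.full_like(t, 5.0), "SC")
        with pytest.warns(UserWarning):
            assert detect_response(tr, NoiseEvent(30, 5, 80)) is None

    def test_synthesized_event_onset_and_peak_located(
        self, five_level_protocol, rendered_subject
    ):
        traces, rows = rendered_subject
        tr = ChannelTrace(traces.time_s, traces.sc_uS, "SC")
        r0 = rows.iloc[0]
        resp = detect_response(tr, five_level_protocol.events[0],
                               window_end_s=five_level_protocol.events[1].onset_s)
        dt = 1.0 / traces.sample_rate_hz
        assert resp is not None
        assert abs(resp.onset_t_s - r0["scr_onset_t_s"]) <= dt + 1e-9
        assert abs(resp.peak_t_s - r0["scr_peak_t_s"]) <= dt + 1e-9

    def test_biphasic_spr_shape_detected(self, five_level_protocol):
        cfg = paper2024_config(seed=2, n_subjects=1, spr_biphasic_prob=1.0)
        _, truth = generate_feature_table(cfg, five_level_protocol)
        rows = truth[truth.subject_id == 0]
        traces = synthesize_traces(five_level_protocol, rows, cfg)
        tr = ChannelTrace(traces.time_s, traces.sp_mV, "SP")
        for i, ev in enumerate(five_level_protocol.events):
            nxt = (five_level_protocol.events[i + 1].onset_s
                   if i + 1 < len(five_level_protocol.events) else None)
            resp = detect_response(tr, ev, window_end_s=nxt)
            assert resp is not None and resp.shape == "biphasic"
            assert resp.second_peak_t_s is not None


class TestProperties:
    def test_time_shift_invariance(self, small_cohort):
        """Shifting traces and protocol together leaves features unchanged."""
        cfg, _, truth = small_cohort
        rows = truth[truth.subject_id == 2]
        shift = 13.0
        p1 = build_protocol(cfg.levels_db)
        p2 = build_protocol(cfg.levels_db, pre_baseline_s=60.0 + shift)
        tr1 = synthesize_traces(p1, rows, cfg)
        rows2 = rows.copy()
        for c in ("scr_onset_t_s", "scr_peak_t_s", "spr_onset_t_s",
                  "spr_first_peak_t_s", "spr_peak_t_s", "ssr_onset_t_s",
                  "ssr_peak_t_s"):
            rows2[c] = rows2[c] + shift
        tr2 = synthesize_traces(p2, rows2, cfg)
        f1 = build_feature_table(tr1, p1, subject_id=2)
        f2 = build_feature_table(tr2, p2, subject_id=2)
        for c in ("scr_amp_uS", "spr_amp_mV", "ssr_amp_uS", "scr_tris_s",
                  "spret_pct"):
            assert np.allclose(f1[c], f2[c], atol=1e-6, equal_nan=True)

    def test_amplitude_equivariance(self, five_level_protocol, small_cohort):
        """Scaling the phasic SC part scales SCR amplitude, not Tris/SPRET."""
        cfg, _, truth = small_cohort
        rows = truth[truth.subject_id == 1]
        tr = synthesize_traces(five_level_protocol, rows, cfg)
        f1 = build_feature_table(tr, five_level_protocol, subject_id=1)
        scaled = ComponentTraces(
            tr.sample_rate_hz, tr.time_s,
            cfg.tonic_sc_uS + 3.0 * (tr.sc_uS - cfg.tonic_sc_uS),
            tr.ss_uS, tr.sp_mV,
        )
        f2 = build_feature_table(scaled, five_level_protocol, subject_id=1)
        assert np.allclose(f2["scr_amp_uS"], 3.0 * f1["scr_amp_uS"], rtol=1e-6)
        assert np.allclose(f2["scr_tris_s"], f1["scr_tris_s"], atol=1e-9)
        assert np.allclose(f2["spret_pct"], f1["spret_pct"], rtol=1e-6)

    def test_detector_matches_ground_truth_on_noise_free_traces(self):
        """>= 99% of events located within one sample period per channel."""
        ok = tot = 0
        for seed in (3, 7, 11, 21, 33):
            cfg = paper2024_config(seed=seed, n_subjects=4)
            proto = build_protocol(cfg.levels_db)
            _, truth = generate_feature_table(cfg, proto)
            dt = 1.0 / cfg.sample_rate_hz + 1e-9
            for sid, rows in truth.groupby("subject_id"):
                traces = synthesize_traces(proto, rows, cfg)
                tab = build_feature_table(traces, proto, subject_id=sid)
                m = tab.merge(rows, on=["subject_id", "event_index"],
                              suffixes=("_d", "_t"))
                for _, r in m.iterrows():
                    if abs(r["ssr_amp_uS_t"]) < 0.02:
                        continue  # below detector acceptance threshold
                    tot += 1
                    ok += (
                        abs(r["scr_onset_t_s_d"] - r["scr_onset_t_s_t"]) <= dt
                        and abs(r["scr_peak_t_s_d"] - r["scr_peak_t_s_t"]) <= dt
                        and abs(r["spr_peak_t_s_d"] - r["spr_peak_t_s_t"]) <= dt
                    )
        assert tot > 80
        assert ok / tot >= 0.99


class TestBuildFeatureTable:
    def test_flat_traces_give_all_missing_but_five_records(
        self, five_level_protocol
    ):
        fs = 20.0
        n = int(385 * fs)
        t = np.arange(n) / fs
        tr = ComponentTraces(fs, t, np.full(n, 5.0), np.full(n, 2.0),
                             np.full(n, -15.0))
        tab = build_feature_table(tr, five_level_protocol)
        assert len(tab) == 5
        assert tab["scr_amp_uS"].isna().all()
        assert tab["spret_pct"].isna().all()

    def test_empty_protocol_gives_empty_table(self):
        fs = 20.0
        t = np.arange(100) / fs
        tr = ComponentTraces(fs, t, np.full(100, 5.0), np.full(100, 2.0),
                             np.full(100, -15.0))
        proto = build_protocol((70,), stim_s=1, rest_s=1, pre_baseline_s=1)
        proto = proto.__class__(events=(), pre_baseline_s=0,
                                post_event_rest_s=0, total_s=5.0)
        tab = build_feature_table(tr, proto)
        assert len(tab) == 0

    def test_round_trip_amplitudes_within_5pct(
        self, five_level_protocol, small_cohort
    ):
        cfg, _, truth = small_cohort
        for sid, rows in truth.groupby("subject_id"):
            traces = synthesize_traces(five_level_protocol, rows, cfg)
            tab = build_feature_table(traces, five_level_protocol, subject_id=sid)
            m = tab.merge(rows, on=["subject_id", "event_index"],
                          suffixes=("_d", "_t"))
            det = m.dropna(subset=["scr_amp_uS_d"])
            assert np.allclose(det["scr_amp_uS_d"], det["scr_amp_uS_t"],
                               rtol=0.05)
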