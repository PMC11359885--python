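import numpy as np
import pandas as pd
import pytest

from edanoise import (
    CarrierConfig,
    FEATURES,
    build_protocol,
    generate_feature_table,
    paper2024_config,
    scr_kernel,
    synthesize_raw_carrier,
    synthesize_traces,
)
from edanoise.synthetic import GeneratorError, bateman_peak_time


class TestScrKernel:
    def test_zero_at_onset(self):
        assert scr_kernel(0.0, amp=2.0, tau_rise=0.75, tau_decay=3.0) == 0.0

    def test_peak_value_equals_amp(self):
        tp = bateman_peak_time(0.75, 3.0)
        assert scr_kernel(tp, amp=1.7, tau_rise=0.75, tau_decay=3.0) == pytest.approx(1.7)

    def test_value_matches_grid_search_normalizer(self):
        """Normalizing constant checked against brute-force maximization."""
        tr, td = 0.75, 3.0
        t_grid = np.linspace(0, 30, 300001)
        unnorm = np.exp(-t_grid / td) - np.exp(-t_grid / tr)
        c = unnorm.max()
        expected = (np.exp(-1.0 / td) - np.exp(-1.0 / tr)) / c
        assert scr_kernel(1.0, 1.0, tr, td) == pytest.approx(expected, rel=1e-8)

    def test_negative_times_are_zero(self):
        out = scr_kernel(np.array([-1.0, -0.1, 0.5]), 1.0, 0.75, 3.0)
        assert out[0] == 0.0 and out[1] == 0.0 and out[2] > 0.0

    def test_invalid_taus_rejected(self):
        with pytest.raises(GeneratorError):
            scr_kernel(1.0, 1.0, tau_rise=3.0, tau_decay=0.75)


class TestGenerateFeatureTable:
    def test_degenerate_sds_give_exact_linear_means(self):
        zero = {f: 0.0 for f in FEATURES}
        cfg = paper2024_config(
            n_subjects=3, random_sd_intercept=zero, random_sd_slope=zero,
            residual_sd=zero,
        )
        feat, _ = generate_feature_table(cfg)
        for f in FEATURES:
            expect = cfg.fixed_intercepts[f] + cfg.fixed_slopes_per5db[f] * feat[
                "level_step"
            ]
            assert np.allclose(feat[f], expect)

    def test_seed_determinism(self):
        cfg = paper2024_config(seed=11, n_subjects=5)
        f1, t1 = generate_feature_table(cfg)
        f2, t2 = generate_feature_table(cfg)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        f1, _ = generate_feature_table(paper2024_config(seed=1, n_subjects=5))
        f2, _ = generate_feature_table(paper2024_config(seed=2, n_subjects=5))
        assert not np.allclose(f1["scr_amp_uS"], f2["scr_amp_uS"])

    def test_large_cohort_slope_matches_generating_equation(self):
        """Law of large numbers: mean per-step gain approaches beta1."""
        cfg = paper2024_config(seed=4, n_subjects=200)
        feat, _ = generate_feature_table(cfg)
        w = feat.pivot_table(index="subject_id", columns="level_step",
                             values="scr_amp_uS")
        slope = ((w[4.0] - w[0.0]) / 4.0).mean()
        assert slope == pytest.approx(1.2, abs=0.1)

    def test_truth_times_consistent_with_spret(self):
        _, truth = generate_feature_table(paper2024_config(seed=6, n_subjects=3))
        implied = 100.0 * (truth["spr_peak_t_s"] - truth["scr_peak_t_s"]) / truth[
            "scr_tris_s"
        ]
        assert np.allclose(implied, truth["spret_pct"])

    def test_physical_floors(self):
        feat, _ = generate_feature_table(paper2024_config(seed=8, n_subjects=50))
        assert (feat["scr_amp_uS"] > 0).all()
        assert (feat["scr_tris_s"] > 0).all()


class TestSynthesizeTraces:
    def test_zero_amplitude_truth_gives_flat_baselines(self, five_level_protocol):
        cfg = paper2024_config(n_subjects=1)
        _, truth = generate_feature_table(cfg, five_level_protocol)
        t0 = truth[truth.subject_id == 0].copy()
        for col in ("scr_amp_uS", "spr_amp_mV", "ssr_amp_uS"):
            t0[col] = 1e-12 if col == "scr_amp_uS" else 0.0
        tr = synthesize_traces(five_level_protocol, t0, cfg)
        assert np.allclose(tr.sc_uS, cfg.tonic_sc_uS, atol=1e-10)
        assert np.allclose(tr.ss_uS, cfg.tonic_ss_uS, atol=1e-10)
        assert np.allclose(tr.sp_mV, cfg.tonic_sp_mV, atol=1e-10)

    def test_single_event_peak_minus_onset_equals_true_amp(self):
        proto = build_protocol((80,), stim_s=5, rest_s=60, pre_baseline_s=30)
        cfg = paper2024_config(n_subjects=1, levels_db=(80.0,))
        _, truth = generate_feature_table(cfg, proto)
        row = truth[truth.subject_id == 0]
        tr = synthesize_traces(proto, row, cfg)
        amp = tr.sc_uS.max() - cfg.tonic_sc_uS
        assert amp == pytest.approx(float(row["scr_amp_uS"].iloc[0]), rel=0.02)

    def test_rendering_linearity(self, five_level_protocol):
        """Scaling all true amplitudes scales the phasic part pointwise."""
        cfg = paper2024_config(seed=9, n_subjects=1)
        _, truth = generate_feature_table(cfg, five_level_protocol)
        rows = truth[truth.subject_id == 0]
        scaled = rows.copy()
        for col in ("scr_amp_uS", "spr_amp_mV", "ssr_amp_uS"):
            scaled[col] = rows[col] * 2.0
        tr1 = synthesize_traces(five_level_protocol, rows, cfg)
        tr2 = synthesize_traces(five_level_protocol, scaled, cfg)
        assert np.allclose(
            tr2.sc_uS - cfg.tonic_sc_uS, 2.0 * (tr1.sc_uS - cfg.tonic_sc_uS),
            atol=1e-9,
        )
        assert np.allclose(
            tr2.sp_mV - cfg.tonic_sp_mV, 2.0 * (tr1.sp_mV - cfg.tonic_sp_mV),
            atol=1e-9,
        )

    def test_biphasic_peak_to_peak_matches_amplitude(self, five_level_protocol):
        cfg = paper2024_config(n_subjects=1, spr_biphasic_prob=1.0, seed=2)
        _, truth = generate_feature_table(cfg, five_level_protocol)
        rows = truth[truth.subject_id == 0]
        tr = synthesize_traces(five_level_protocol, rows, cfg)
        r = rows.iloc[0]
        fs = cfg.sample_rate_hz
        i1 = int(r["spr_first_peak_t_s"] * fs)
        i2 = int(r["spr_peak_t_s"] * fs)
        p1 = tr.sp_mV[i1 - 3 : i1 + 4]
        p2 = tr.sp_mV[i2 - 3 : i2 + 4]
        amp = float(r["spr_amp_mV"])
        peak1 = p1.max() if amp < 0 else p1.min()
        peak2 = p2.min() if amp < 0 else p2.max()
        assert peak2 - peak1 == pytest.approx(amp, rel=0.03)

    def test_kernel_truncation_flagged(self):
        proto = build_protocol((90,), stim_s=5, rest_s=0.5, pre_baseline_s=1)
        cfg = paper2024_config(n_subjects=1, levels_db=(90.0,))
        _, truth = generate_feature_table(cfg, proto)
        tr = synthesize_traces(proto, truth[truth.subject_id == 0], cfg)
        assert 0 in tr.truncated_events


class TestSynthesizeRawCarrier:
    def _const_traces(self, g, b, sp, fs=400.0, dur=1.0):
        from edanoise.synthetic import ComponentTraces

        n = int(dur * fs)
        t = np.arange(n) / fs
        return ComponentTraces(fs, t, np.full(n, g), np.full(n, b), np.full(n, sp))

    def test_pure_conductance_gives_exact_volt_tone(self, carrier):
        tr = self._const_traces(20.0, 0.0, 0.0)
        raw = synthesize_raw_carrier(tr, carrier)
        expect = 1000.0 * np.sin(2 * np.pi * 20.0 * tr.time_s)
        assert np.allclose(raw.v_mV, expect, atol=1e-9)

    def test_zero_admittance_rejected(self, carrier):
        tr = self._const_traces(1.0, 0.0, 0.0)
        tr.sc_uS[:] = 0.0
        with pytest.raises(GeneratorError):
            synthesize_raw_carrier(tr, carrier)

    def test_equal_g_and_b_gives_45_degree_lag(self, carrier):
        tr = self._const_traces(20.0, 20.0, 0.0)
        raw = synthesize_raw_carrier(tr, carrier)
        amp = 1000.0 / np.sqrt(2.0)
        expect = amp * np.sin(2 * np.pi * 20.0 * tr.time_s - np.pi / 4)
        assert np.allclose(raw.v_mV, expect, atol=1e-9)

    def test_undersampled_traces_rejected(self, carrier):
        tr = self._const_traces(20.0, 0.0, 0.0, fs=30.0)
        with pytest.raises(GeneratorError):
            synthesize_raw_carrier(tr, carrier)
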