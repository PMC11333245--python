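"""Tests of the synthetic sleep-RR / ECG generator."""

import numpy as np
import pytest

import sleephrv as sh
from sleephrv.series import BeatSeries, build_rr, merged_beat_rr
from sleephrv.synthetic import (
    STAGE_REM,
    STAGE_WAKE,
    GeneratorConfig,
    binomial_cascade,
    config_for_group,
    generate_ecg,
    generate_hypnogram,
    generate_rr,
)


class TestConfig:
    def test_presets_cover_groups(self):
        for g in ("non", "early", "middle"):
            cfg = config_for_group(g)
            assert cfg.group == g and cfg.baseline_rr > 0

    @pytest.mark.parametrize(
        "bad",
        [
            dict(baseline_rr=-0.1),
            dict(resp_period=12.0),
            dict(duration_h=4.0),
            dict(cascade_asymmetry=0.4),
            dict(cascade_asymmetry=1.0),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            GeneratorConfig(**bad)


class TestHypnogram:
    def test_epoch_count_and_boundaries(self):
        hyp = generate_hypnogram(config_for_group("non", duration_h=8.0, seed=1))
        assert hyp.n_epochs == 960
        assert np.all(hyp.starts % 30 == 0) and np.all(hyp.ends % 30 == 0)
        np.testing.assert_allclose(hyp.ends - hyp.starts, 30.0)

    def test_deterministic_given_seed(self):
        cfg = config_for_group("early", seed=5)
        h1, h2 = generate_hypnogram(cfg), generate_hypnogram(cfg)
        np.testing.assert_array_equal(h1.stages, h2.stages)

    def test_short_recording_rejected_with_rule_message(self):
        with pytest.raises(ValueError, match="5 h"):
            GeneratorConfig(duration_h=4.5)

    def test_rem_fraction_increases_across_night(self):
        fracs = []
        for seed in range(6):
            hyp = generate_hypnogram(config_for_group("non", seed=seed))
            half = hyp.duration_s / 2
            fracs.append(
                hyp.rem_fraction(half, hyp.duration_s) - hyp.rem_fraction(0, half)
            )
        assert np.mean(fracs) > 0.05

    def test_stage_lookup_half_open(self):
        hyp = generate_hypnogram(config_for_group("non", seed=1))
        assert hyp.stage_at(0.0) == hyp.stages[0]
        assert hyp.stage_at(29.999) == hyp.stages[0]
        assert hyp.stage_at(30.0) == hyp.stages[1]


class TestGenerateRR:
    def test_deterministic(self):
        cfg = config_for_group("non", seed=3)
        hyp = generate_hypnogram(cfg)
        b1, b2 = generate_rr(cfg, hyp), generate_rr(cfg, hyp)
        np.testing.assert_array_equal(b1.r_times, b2.r_times)

    def test_all_components_off_gives_constant_rr(self):
        cfg = config_for_group(
            "non", seed=1, overnight_drift=0.0, lf_amplitude=0.0,
            rsa_amplitude_nrem=0.0, rsa_amplitude_rem=0.0, fractal_amplitude=0.0,
        )
        beats = generate_rr(cfg)
        rr = np.diff(beats.r_times)
        np.testing.assert_allclose(rr, 0.90, atol=1e-9)

    def test_beat_times_strictly_increasing_and_bounded(self, non_recording):
        _, _, beats = non_recording
        rr = np.diff(beats.r_times)
        assert np.all(rr > 0.3) and np.all(rr < 2.0)

    def test_non_preset_q1_mean_rr(self):
        """First-quarter mean RR of the non-pregnancy preset is ~0.90 s."""
        means = []
        for seed in (1, 2, 3):
            cfg = config_for_group("non", seed=seed)
            hyp = generate_hypnogram(cfg)
            beats = generate_rr(cfg, hyp)
            rr = np.diff(beats.r_times)
            q1 = rr[: rr.size // 4]
            means.append(q1.mean())
        assert abs(np.mean(means) - 0.90) < 0.05

    def test_fractal_only_white_target_gives_alpha_half(self):
        """With only the fractal component at target H=0.5, the DFA
        exponent of the interpolated series recovers 0.5."""
        alphas = []
        for seed in (1, 2, 3):
            cfg = config_for_group(
                "non", seed=seed, overnight_drift=0.0, lf_amplitude=0.0,
                rsa_amplitude_nrem=0.0, rsa_amplitude_rem=0.0,
                fractal_target_H=0.5,
            )
            beats = generate_rr(cfg)
            rr = build_rr(beats)
            alphas.append(
                sh.dfa_alpha(rr.rr, sh.scales_seconds(rr.rr.size))
            )
        assert abs(np.mean(alphas) - 0.5) < 0.05

    def test_negative_rr_parameters_rejected(self):
        cfg = config_for_group("non", seed=1, baseline_rr=0.02, resp_period=4.0,
                               rsa_amplitude_nrem=0.5)
        with pytest.raises(ValueError, match="non-positive RR"):
            generate_rr(cfg)

    def test_group_mean_rr_ordering(self):
        means = {}
        for g in ("non", "early", "middle"):
            vals = []
            for seed in (1, 2, 3):
                beats = generate_rr(config_for_group(g, seed=seed))
                vals.append(np.diff(beats.r_times).mean())
            means[g] = np.mean(vals)
        assert means["non"] > means["early"] > means["middle"]


class TestBinomialCascade:
    def test_two_level_split_values(self):
        c = binomial_cascade(0.6, 2)
        np.testing.assert_allclose(c.values, [0.36, 0.24, 0.24, 0.16])

    @pytest.mark.parametrize("a,depth", [(0.6, 4), (0.75, 8), (0.9, 10)])
    def test_mass_conserved_at_every_level(self, a, depth):
        fine = binomial_cascade(a, depth).values
        for level in range(depth - 1, 0, -1):
            fine = fine.reshape(-1, 2).sum(axis=1)
            np.testing.assert_allclose(
                fine, binomial_cascade(a, level).values, atol=1e-12
            )
        assert binomial_cascade(a, depth).values.sum() == pytest.approx(1.0)

    def test_randomised_variant_conserves_mass(self):
        c = binomial_cascade(0.7, 10, rng=np.random.default_rng(0))
        assert c.values.sum() == pytest.approx(1.0)
        assert np.all(c.values > 0)

    @pytest.mark.parametrize("a", [0.5, 0.4, 1.0, 1.2])
    def test_invalid_multiplier_rejected(self, a):
        with pytest.raises(ValueError):
            binomial_cascade(a, 8)


class TestGenerateECG:
    def test_round_trip_regular_beats(self):
        """Template ECG at 1.0 s beat spacing survives R-peak detection."""
        beats = BeatSeries(np.arange(0.0, 120.0, 1.0))
        cfg = config_for_group("non", seed=2)
        ecg = generate_ecg(beats, cfg, fs=200)
        det = sh.detect_rpeaks(ecg.signal, ecg.fs)
        inner = det.r_times[(det.r_times > 2) & (det.r_times < 118)]
        gt = beats.r_times[(beats.r_times > 2) & (beats.r_times < 118)]
        d = np.abs(inner[:, None] - gt[None, :]).min(axis=1)
        assert d.max() <= 1.0 / 200 + 1e-9  # each peak within one sample
        np.testing.assert_allclose(np.diff(inner), 1.0, atol=2.0 / 200)

    def test_zero_artifact_rate_gives_no_labels(self):
        beats = BeatSeries(np.arange(0.0, 60.0, 1.0))
        ecg = generate_ecg(beats, config_for_group("non", seed=1), fs=128)
        assert ecg.artifacts == []

    def test_flat_windows_have_zero_variance(self):
        beats = BeatSeries(np.arange(0.0, 1200.0, 1.0))
        cfg = config_for_group("non", seed=9, artifact_rate=30.0)
        ecg = generate_ecg(beats, cfg, fs=100)
        flats = [(s, e) for s, e, k in ecg.artifacts if k == "flat"]
        assert flats, "expected at least one flat window at this rate"
        for s, e in flats:
            lo, hi = int(s * 100) + 1, int(e * 100) - 1
            assert ecg.signal[lo:hi].var() == 0.0

    def test_sampling_rate_range_enforced(self):
        beats = BeatSeries(np.arange(0.0, 10.0, 1.0))
        with pytest.raises(ValueError):
            generate_ecg(beats, config_for_group("non"), fs=50)


class TestEndToEnd:
    def test_artifact_free_ecg_reproduces_generator_rr(self):
        """ECG -> Pan-Tompkins -> RR matches the generator's beat series."""
        cfg = config_for_group("non", seed=4)
        hyp = generate_hypnogram(cfg)
        beats = generate_rr(cfg, hyp)
        keep = beats.r_times < 600.0
        sub = BeatSeries(beats.r_times[keep])
        ecg = generate_ecg(sub, cfg, fs=200)
        det = sh.detect_rpeaks(ecg.signal, ecg.fs)
        gt = sub.r_times[(sub.r_times > 2) & (sub.r_times < 598)]
        d = np.abs(det.r_times[:, None] - gt[None, :]).min(axis=0)
        assert (d <= 0.010).mean() >= 0.99
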