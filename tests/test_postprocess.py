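"""Post-processing chain: normalization, spike detection, time rescaling,
clinical high-pass, background noise and polarity doubling."""

import numpy as np
import pytest
from scipy import signal

from dynamotypes.postprocess import (
    BackgroundNoiseConfig,
    add_background_noise,
    detect_spikes,
    highpass,
    normalize01,
    polarity_double,
    postprocess,
    rescale_time,
)


class TestNormalize:
    def test_affine_map(self):
        out = normalize01(np.array([-2.0, 0.0, 6.0]))
        assert np.allclose(out, [0.0, 0.25, 1.0])

    def test_idempotent(self):
        x = np.array([0.0, 0.3, 1.0])
        assert np.allclose(normalize01(x), x)

    def test_exact_bounds(self, rng):
        out = normalize01(rng.normal(size=500))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            normalize01(np.ones(10))


class TestDetectSpikes:
    def test_recovers_gaussian_bump_times(self):
        fs = 100.0
        t = np.arange(0, 30, 1 / fs)
        centers = [3.0, 9.0, 15.0, 21.0, 27.0]
        x = sum(np.exp(-0.5 * ((t - c) / 0.1) ** 2) for c in centers)
        found = detect_spikes(x, fs)
        assert len(found) == len(centers)
        for c, i in zip(centers, found):
            assert abs(i / fs - c) <= 1.5 / fs

    def test_flat_trace_empty(self):
        assert len(detect_spikes(np.zeros(100), 10.0)) == 0

    def test_scale_invariant(self, rng):
        fs = 50.0
        t = np.arange(0, 60, 1 / fs)
        x = signal.sawtooth(2 * np.pi * 0.5 * t, width=0.05) + 0.02 * rng.normal(
            size=len(t)
        )
        a = detect_spikes(x, fs)
        b = detect_spikes(2.0 * x, fs)
        assert np.array_equal(a, b)


class TestRescaleTime:
    def test_median_rate_hits_target(self, sn_sh_record):
        rec = sn_sh_record
        seiz = rec.trace[rec.onset_sample : rec.offset_sample]
        spikes = detect_spikes(seiz, rec.fs)
        rate = 1.0 / np.median(np.diff(spikes) / rec.fs)
        assert rate == pytest.approx(10.0, rel=0.05)

    def test_rate_always_in_clinical_band(self, record_cache):
        for onset, offset in [("SN", "SH"), ("SNIC", "SH"), ("SupH", "SH")]:
            rec = record_cache(onset, offset)
            seiz = rec.trace[rec.onset_sample : rec.offset_sample]
            spikes = detect_spikes(seiz, rec.fs)
            rate = 1.0 / np.median(np.diff(spikes) / rec.fs)
            assert 1.0 <= rate <= 30.0

    def test_rescaling_is_idempotent(self, curves):
        from dynamotypes.integrate import IntegratorConfig, integrate
        from dynamotypes.registry import get_recipe

        path = get_recipe("SN", "SH", "hysteresis").build(curves)
        res = integrate(path, config=IntegratorConfig(tstep=0.05, duration=8000))
        a = rescale_time(res)
        b = rescale_time(res)
        assert a.fs == b.fs

    def test_too_few_spikes_rejected(self, curves):
        from dynamotypes.integrate import IntegratorConfig, integrate
        from dynamotypes.registry import get_recipe

        path = get_recipe("SN", "SH", "hysteresis").build(curves)
        res = integrate(path, config=IntegratorConfig(tstep=0.05, duration=8000))
        # truncate the labelled window to fewer than 3 spikes
        from dataclasses import replace as _  # noqa: F401

        res.offset_index = res.onset_index + 10
        with pytest.raises(ValueError):
            rescale_time(res)


class TestHighpass:
    def test_constant_input_decays_to_zero(self):
        out = highpass(np.ones(20_000), fs=200.0, cutoff=0.5)
        assert abs(out[-1]) < 1e-3
        assert np.all(np.abs(out[-2000:]) < 1e-2)

    def test_passband_sinusoid_within_two_percent(self):
        fs = 200.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        out = highpass(x, fs, cutoff=0.5)
        tail = out[len(out) // 2 :]
        assert tail.max() == pytest.approx(1.0, abs=0.02)
        # analytic magnitude response of the designed filter at 10 Hz
        sos = signal.butter(2, 0.5, btype="highpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[10.0], fs=fs)
        assert abs(h[0]) == pytest.approx(tail.max(), abs=0.02)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(np.zeros(100), fs=10.0, cutoff=6.0)

    def test_preserves_length(self, rng):
        x = rng.normal(size=5000)
        assert len(highpass(x, 100.0)) == len(x)


class TestBackgroundNoise:
    def test_alpha_zero_is_identity(self, rng):
        x = rng.normal(size=1000)
        out = add_background_noise(x, BackgroundNoiseConfig(0.0), seed=1)
        assert np.array_equal(out, x)

    def test_scaling_is_exactly_alpha_times_max(self, rng):
        from dynamotypes.integrate import generate_pink_noise

        x = np.abs(rng.normal(size=4096)) + 0.5
        out = add_background_noise(x, BackgroundNoiseConfig(0.4), seed=9)
        pink = generate_pink_noise(len(x), 9).samples
        assert np.allclose(out - x, pink * 0.4 * x.max(), atol=1e-12)

    def test_deterministic_per_seed(self, rng):
        x = rng.normal(size=512)
        a = add_background_noise(x, BackgroundNoiseConfig(0.2), seed=3)
        b = add_background_noise(x, BackgroundNoiseConfig(0.2), seed=3)
        assert np.array_equal(a, b)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            BackgroundNoiseConfig(-0.1)


class TestPolarityDoubling:
    def test_doubles_count_and_preserves_labels(self, sn_sh_record):
        out = polarity_double([sn_sh_record] * 5)
        assert len(out) == 10
        for rec in out:
            assert rec.labels == sn_sh_record.labels
            assert rec.onset_sample == sn_sh_record.onset_sample

    def test_flip_is_involution(self, sn_sh_record):
        once = polarity_double([sn_sh_record])[1]
        twice = polarity_double([once])[1]
        assert np.allclose(twice.trace, sn_sh_record.trace, atol=1e-12)
        assert twice.polarity == sn_sh_record.polarity

    def test_spike_times_identical_under_flip(self, sn_sh_record):
        flip = polarity_double([sn_sh_record])[1]
        a = detect_spikes(sn_sh_record.trace, sn_sh_record.fs)
        b = detect_spikes(-flip.trace, flip.fs)
        assert np.array_equal(a, b)


class TestPipeline:
    def test_labels_invariant_under_postprocessing(self, curves):
        from dynamotypes.integrate import IntegratorConfig, integrate
        from dynamotypes.registry import get_recipe

        path = get_recipe("SN", "SH", "hysteresis").build(curves)
        res = integrate(path, config=IntegratorConfig(tstep=0.05, duration=8000))
        recs = [
            postprocess(res, alpha=a, cutoff=c, seed=s)
            for a, c, s in [(0.0, None, 0), (0.4, 0.5, 1), (0.2, 0.1, 7)]
        ]
        assert len({r.onset_sample for r in recs}) == 1
        assert len({r.offset_sample for r in recs}) == 1
        assert recs[0].onset_sample == res.onset_index

    def test_stage_parameters_recorded_in_provenance(self, curves):
        from dynamotypes.integrate import IntegratorConfig, integrate
        from dynamotypes.registry import get_recipe

        path = get_recipe("SN", "SH", "hysteresis").build(curves)
        res = integrate(path, config=IntegratorConfig(tstep=0.05, duration=8000))
        rec = postprocess(res, alpha=0.2, cutoff=0.3, seed=11)
        assert rec.provenance["highpass"]["cutoff_hz"] == 0.3
        assert rec.provenance["background_noise"]["alpha"] == 0.2
        assert "rescale" in rec.provenance
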