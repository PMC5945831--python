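import numpy as np
import pytest

from muforce.metrics import power_spectrum
from muforce.simulate import (
    SyntheticGroundTruth,
    benchmark_scene,
    make_force_profile,
    make_spike_trains,
    make_templates,
    mean_overlap,
    render_semg,
)


class TestTemplates:
    def test_single_template_zero_mean(self):
        (tpl,) = make_templates(1, seed=0)
        assert abs(tpl.waveform.mean()) < 1e-12
        assert tpl.waveform.size <= 100

    def test_seven_templates_distinguishable(self):
        tpls = make_templates(7, seed=0)
        for i in range(7):
            for j in range(i + 1, 7):
                a, b = tpls[i].waveform, tpls[j].waveform
                c = np.correlate(a, b, mode="full")
                corr = np.abs(c).max() / (np.linalg.norm(a) * np.linalg.norm(b))
                assert corr < 0.9

    def test_deterministic(self):
        a = make_templates(5, seed=3)
        b = make_templates(5, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.waveform, y.waveform)

    def test_spectral_centroid_in_muap_band(self):
        for tpl in make_templates(7, seed=1):
            padded = np.tile(np.pad(tpl.waveform, (0, 160)), 8)
            _, _, centroid = power_spectrum(padded, 16000.0, nperseg=2048)
            assert 100.0 <= centroid <= 400.0


class TestSpikeTrains:
    def test_zero_force_no_spikes(self):
        t = np.arange(0, 5, 0.001)
        trains = make_spike_trains(t, np.zeros_like(t), G=5, seed=0)
        assert all(tr.firing_times.size == 0 for tr in trains)

    def test_full_drive_interval_range(self):
        t = np.arange(0, 10, 0.001)
        trains = make_spike_trains(t, np.ones_like(t), G=5, seed=0)
        for tr in trains:
            ipi = np.diff(tr.firing_times) * 1000.0
            assert 45.0 <= ipi.mean() <= 105.0

    def test_recruitment_monotone_in_force(self):
        t = np.arange(0, 5, 0.001)
        counts = []
        for level in (0.1, 0.4, 0.7, 1.0):
            trains = make_spike_trains(t, np.full_like(t, level), G=7, seed=1)
            counts.append(sum(tr.firing_times.size > 0 for tr in trains))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_refractory_floor_and_ordering(self):
        t = np.arange(0, 10, 0.001)
        trains = make_spike_trains(t, np.ones_like(t), G=3, seed=2)
        for tr in trains:
            d = np.diff(tr.firing_times)
            assert np.all(d > 0)
            assert np.all(d >= 0.020 - 1e-12)


class TestRender:
    def _truth(self, trains_times, noise=0.0, seed=0):
        tpls = make_templates(len(trains_times), seed=seed)
        from muforce.simulate import SpikeTrain

        trains = [
            SpikeTrain(mu_id=i, firing_times=np.asarray(ts), recruitment_threshold=0.0)
            for i, ts in enumerate(trains_times)
        ]
        t = np.arange(0, 1.0, 0.001)
        return SyntheticGroundTruth(
            templates=tpls,
            trains=trains,
            mixing_gains=np.ones(len(trains)),
            noise_sigma=noise,
            force_times=t,
            force_profile=np.zeros_like(t),
            seed=seed,
        )

    def test_no_spikes_no_noise_silent(self):
        rec = render_semg(self._truth([[]]), duration_s=1.0)
        np.testing.assert_array_equal(rec.samples, 0)

    def test_single_spike_exact_placement(self):
        truth = self._truth([[0.5]])
        rec = render_semg(truth, duration_s=1.0)
        w = truth.templates[0].waveform
        i0 = int(round(0.5 * 16000))
        np.testing.assert_array_equal(rec.samples[i0 : i0 + w.size], w)
        assert np.all(rec.samples[: i0] == 0)

    def test_superposition_is_additive(self):
        truth_both = self._truth([[0.5, 0.5025]])
        rec_both = render_semg(truth_both, duration_s=1.0)
        a = render_semg(self._truth([[0.5]]), duration_s=1.0)
        b = render_semg(self._truth([[0.5025]]), duration_s=1.0)
        np.testing.assert_allclose(rec_both.samples, a.samples + b.samples, atol=1e-12)


class TestBenchmarkScene:
    def test_deterministic(self):
        a, fa, _ = benchmark_scene("trapezoid", seed=5)
        b, fb, _ = benchmark_scene("trapezoid", seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(fa.values, fb.values)

    def test_trapezoid_profile_shape(self):
        times, profile = make_force_profile("trapezoid")
        # first cycle: rises from rest, holds at the cycle amplitude, falls
        first = profile[(times >= 0) & (times < 2.0)]
        hold = profile[(times >= 0.3) & (times < 0.8)]
        assert profile[0] == 0.0
        assert np.allclose(hold, hold[0])
        assert first.max() == hold[0]
        assert np.all(profile[(times >= 1.0) & (times < 2.0)] == 0.0)

    def test_recruitment_peaks_at_hold(self):
        _, _, truth = benchmark_scene("trapezoid", seed=0, G=7)
        t_hold = 0.5
        active_hold = sum(
            np.any(np.abs(tr.firing_times - t_hold) < 0.2) for tr in truth.trains
        )
        t_rest = 1.5
        active_rest = sum(
            np.any(np.abs(tr.firing_times - t_rest) < 0.2) for tr in truth.trains
        )
        assert active_hold > active_rest

    def test_superposition_ordering(self):
        _, _, low = benchmark_scene("low_force", seed=0, G=7)
        _, _, high = benchmark_scene("high_superposition", seed=0, G=7)
        assert mean_overlap(high) > mean_overlap(low)

    def test_snr_contract(self):
        rec, _, truth = benchmark_scene("trapezoid", seed=3, G=7, snr_db=10.0)
        truth_clean = SyntheticGroundTruth(
            templates=truth.templates,
            trains=truth.trains,
            mixing_gains=truth.mixing_gains,
            noise_sigma=0.0,
            force_times=truth.force_times,
            force_profile=truth.force_profile,
            seed=truth.seed,
        )
        clean = render_semg(truth_clean)
        noise = rec.samples - clean.samples
        snr = 10 * np.log10(np.mean(clean.samples**2) / np.mean(noise**2))
        assert abs(snr - 10.0) < 1.0

    def test_ramp_preset_sweeps_up_then_down(self):
        _, force, truth = benchmark_scene("ramp", seed=1, G=3)
        apex = np.argmax(truth.force_profile)
        assert np.all(np.diff(truth.force_profile[:apex]) >= 0)
        assert np.all(np.diff(truth.force_profile[apex:]) <= 0)
        assert force.values.max() <= 100.0

    def test_force_trace_grid(self):
        _, force, _ = benchmark_scene("trapezoid", seed=0)
        assert force.rate_hz == 10.0
        assert np.allclose(np.diff(force.times), 0.1)
        assert force.values.max() <= 100.0


class TestPhysiologicalIntervals:
    def test_ipi_mode_at_full_recruitment(self):
        """With every unit recruited, interval histograms peak in 50-100 ms
        (firing rates 10-20 Hz)."""
        from muforce.metrics import ipi_mode_ms

        t = np.arange(0, 30, 0.001)
        trains = make_spike_trains(t, np.full_like(t, 0.9), G=7, seed=0)
        modes = [ipi_mode_ms(tr.firing_times * 1000.0) for tr in trains]
        assert all(50.0 <= m <= 100.0 for m in modes)
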