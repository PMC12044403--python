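"""Filtering, line-noise removal, referencing, bad channels, spherical
splines, segmentation."""

import numpy as np
import pytest

from neurowalk.core import Recording
from neurowalk.io import standard_positions
from neurowalk.preprocess import (average_reference, bandpass_filter,
                                  detect_bad_channels, interpolate_channels,
                                  remove_line_noise, segment_epochs)
from neurowalk.synthetic import (CouplingEdge, CouplingSpec,
                                 generate_coupled_recording)


def _tone(freq, sfreq, duration, amp=1.0, phase=0.0):
    t = np.arange(int(duration * sfreq)) / sfreq
    return amp * np.sin(2 * np.pi * freq * t + phase)


def _amp_at(x, freq, sfreq):
    """Single-bin amplitude via the DFT projection."""
    t = np.arange(x.size) / sfreq
    c = np.exp(-2j * np.pi * freq * t)
    return 2 * np.abs((x * c).mean())


class TestBandpass:
    SFREQ = 1000.0

    def test_passband_tone_preserved(self):
        x = _tone(10.0, self.SFREQ, 10.0)
        rec = Recording(["A"], self.SFREQ, x[None, :])
        out = bandpass_filter(rec).data[0]
        core = slice(2000, -2000)
        amp_in = _amp_at(x[core], 10.0, self.SFREQ)
        amp_out = _amp_at(out[core], 10.0, self.SFREQ)
        assert abs(amp_out / amp_in - 1) < 0.02
        # zero-phase: cross-correlation peaks at zero shift
        xc = np.correlate(out[core], x[core], mode="full")
        assert np.argmax(xc) == len(x[core]) - 1

    def test_stopband_tone_attenuated(self):
        x = _tone(80.0, self.SFREQ, 10.0)
        rec = Recording(["A"], self.SFREQ, x[None, :])
        out = bandpass_filter(rec).data[0]
        core = slice(2000, -2000)
        assert _amp_at(out[core], 80.0, self.SFREQ) <= 0.01

    def test_dc_removed(self):
        rec = Recording(["A"], self.SFREQ, np.full((1, 10_000), 7.5))
        out = bandpass_filter(rec).data[0]
        assert abs(out[2000:-2000].mean()) < 0.05

    def test_linearity(self, rng):
        x = rng.normal(0, 1, (2, 12000))
        y = rng.normal(0, 1, (2, 12000))
        fx = bandpass_filter(Recording(["A", "B"], self.SFREQ, x)).data
        fy = bandpass_filter(Recording(["A", "B"], self.SFREQ, y)).data
        fxy = bandpass_filter(
            Recording(["A", "B"], self.SFREQ, 2 * x - 3 * y)).data
        assert np.allclose(fxy, 2 * fx - 3 * fy, atol=1e-9)

    def test_too_short_signal_rejected(self):
        rec = Recording(["A"], self.SFREQ, np.zeros((1, 100)))
        with pytest.raises(ValueError, match="short"):
            bandpass_filter(rec)

    def test_invalid_band_rejected(self):
        rec = Recording(["A"], self.SFREQ, np.zeros((1, 10_000)))
        with pytest.raises(ValueError, match="band"):
            bandpass_filter(rec, low=40.0, high=0.5)


class TestLineNoise:
    SFREQ = 500.0

    def test_line_tone_removed_collateral_preserved(self):
        x = _tone(50.0, self.SFREQ, 20.0, amp=5.0) + _tone(10.0, self.SFREQ,
                                                           20.0, amp=2.0)
        rec = Recording(["A"], self.SFREQ, x[None, :])
        out = remove_line_noise(rec).data[0]
        core = slice(1000, -1000)
        a50_in = _amp_at(x[core], 50.0, self.SFREQ)
        a50_out = _amp_at(out[core], 50.0, self.SFREQ)
        assert 20 * np.log10(a50_in / max(a50_out, 1e-12)) >= 20
        a10_out = _amp_at(out[core], 10.0, self.SFREQ)
        assert abs(a10_out / 2.0 - 1) <= 0.05

    def test_no_line_content_near_identity(self, rng):
        x = rng.normal(0, 1, (1, 8000))
        rec = Recording(["A"], self.SFREQ, x)
        # broadband noise has some mass near 50 Hz; RMS change stays small
        out = remove_line_noise(rec).data
        assert np.sqrt(((out - x) ** 2).mean()) <= 0.1 * np.sqrt((x ** 2).mean())

    def test_pure_line_mostly_removed(self):
        x = _tone(50.0, self.SFREQ, 20.0, amp=3.0)
        rec = Recording(["A"], self.SFREQ, x[None, :])
        out = remove_line_noise(rec).data[0]
        assert np.sqrt((out ** 2).mean()) <= 0.1 * np.sqrt((x ** 2).mean())


class TestAverageReference:
    def test_column_sums_zero(self, rng):
        rec = Recording(list("ABCD"), 100.0, rng.normal(0, 5, (4, 500)))
        out = average_reference(rec)
        assert np.allclose(out.data.sum(axis=0), 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        rec = Recording(list("ABC"), 100.0, rng.normal(0, 5, (3, 100)))
        once = average_reference(rec)
        twice = average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_antisymmetric_pair_unchanged(self, rng):
        v = rng.normal(0, 1, 200)
        rec = Recording(["A", "B"], 100.0, np.vstack([v, -v]))
        out = average_reference(rec)
        assert np.allclose(out.data, rec.data, atol=1e-12)


class TestBadChannels:
    def test_flatline_flagged(self, rng):
        data = rng.normal(0, 5, (3, 2500))
        data[1, 500:2100] = 0.0  # 6.4 s flat in a 10-s recording at 250 Hz
        rec = Recording(["A", "B", "C"], 250.0, data)
        report = detect_bad_channels(rec)
        assert report.flatline_channels == {"B"}

    def test_short_flat_run_not_flagged(self, rng):
        data = rng.normal(0, 5, (2, 2500))
        data[0, 100:600] = 0.0  # 2 s < 5 s criterion
        rec = Recording(["A", "B"], 250.0, data)
        assert detect_bad_channels(rec).flatline_channels == set()

    # conduction-like fixture: near-zero-lag pair couplings so each good
    # channel has a neighbor correlated above the 0.8 criterion, the way
    # volume conduction correlates neighboring sites on a real scalp
    STRONG = CouplingSpec(
        (CouplingEdge("A", "B", 10.0, 0.05, 1.0),
         CouplingEdge("C", "E", 12.0, 0.05, 1.0)),
        noise_sd=0.5, amplitude=5.0)

    def test_uncorrelated_channel_flagged(self):
        flagged = 0
        for seed in range(10):
            rec = generate_coupled_recording(self.STRONG,
                                             ["A", "B", "C", "D", "E"],
                                             250.0, 10.0, seed=seed)
            report = detect_bad_channels(rec)
            if report.low_correlation_channels == {"D"}:
                flagged += 1
        assert flagged == 10

    def test_noiseless_coupled_channels_clean(self):
        spec = CouplingSpec((CouplingEdge("A", "B", 10.0, 0.0, 1.0),),
                            noise_sd=0.0)
        rec = generate_coupled_recording(spec, ["A", "B"], 250.0, 10.0, seed=0)
        report = detect_bad_channels(rec)
        assert report.low_correlation_channels == set()
        assert report.flatline_channels == set()

    def test_clean_generator_output_yields_empty_report(self):
        """Channels with conduction-level coupling and no artifacts pass
        both criteria across 20 seeds."""
        for seed in range(20):
            rec = generate_coupled_recording(self.STRONG,
                                             ["A", "B", "C", "E"],
                                             250.0, 10.0, seed=400 + seed)
            report = detect_bad_channels(rec)
            assert report.all_bad == set(), f"seed {seed}: {report.all_bad}"


class TestSphericalSpline:
    def _smooth_field_recording(self, labels, sfreq=250.0, n=250):
        """Potentials from a smooth low-order field on the sphere."""
        pos = standard_positions(labels)
        t = np.arange(n) / sfreq
        drivers = np.vstack([np.sin(2 * np.pi * 5 * t),
                             np.cos(2 * np.pi * 7 * t),
                             np.sin(2 * np.pi * 9 * t)])
        data = np.array([np.asarray(pos[l]) @ drivers for l in labels])
        rec = Recording(list(labels), sfreq, data)
        rec.positions = pos
        return rec

    def test_no_bad_channels_is_identity(self, rng):
        rec = Recording(["Cz", "Pz"], 100.0, rng.normal(0, 1, (2, 50)))
        out = interpolate_channels(rec, set())
        assert np.array_equal(out.data, rec.data)

    def test_good_channels_untouched(self):
        from neurowalk.core import default_region_map

        rm = default_region_map()
        labels = [e for r in rm.regions for e in rm.electrodes(r)]
        rec = self._smooth_field_recording(labels)
        out = interpolate_channels(rec, {"Cz"})
        for i, l in enumerate(labels):
            if l != "Cz":
                assert np.array_equal(out.data[i], rec.data[i])

    def test_leave_one_out_reconstruction(self):
        from neurowalk.core import default_region_map

        rm = default_region_map()
        labels = [e for r in rm.regions for e in rm.electrodes(r)]
        rec = self._smooth_field_recording(labels)
        for held_out in ("Cz", "Pz", "C3"):
            out = interpolate_channels(rec, {held_out})
            i = rec.index(held_out)
            err = np.sqrt(((out.data[i] - rec.data[i]) ** 2).mean())
            scale = np.sqrt((rec.data[i] ** 2).mean())
            assert err / scale <= 0.10, held_out

    def test_missing_positions_rejected(self, rng):
        rec = Recording(["Cz", "Pz", "Oz", "Fz", "C3"], 100.0,
                        rng.normal(0, 1, (5, 50)))
        with pytest.raises(ValueError, match="montage"):
            interpolate_channels(rec, {"Cz"})


class TestSegmentEpochs:
    def _rec(self, duration=200.0, sfreq=100.0):
        n = int(duration * sfreq)
        return Recording(["A", "B"], sfreq,
                         np.arange(2 * n, dtype=float).reshape(2, n))

    def test_three_segments_exact_length(self):
        rec = self._rec()
        epochs = segment_epochs(rec, [(0.0, "elevator", "neutral"),
                                      (60.0, "plank_start", "neutral"),
                                      (120.0, "plank_end", "neutral")])
        assert len(epochs) == 3
        for e in epochs:
            assert e.recording.n_samples == 6000
        assert [e.task for e in epochs] == ["elevator", "plank", "plank"]

    def test_overlapping_segments_allowed(self):
        rec = self._rec()
        epochs = segment_epochs(rec, [(0.0, "elevator", "neutral"),
                                      (30.0, "plank_end", "neutral")])
        assert all(e.recording.n_samples == 6000 for e in epochs)

    def test_out_of_bounds_segment_named(self):
        rec = self._rec()
        with pytest.raises(ValueError, match="plank_end"):
            segment_epochs(rec, [(150.0, "plank_end", "negative")])

    def test_slice_content_matches_source(self):
        rec = self._rec()
        (epoch,) = segment_epochs(rec, [(10.0, "elevator", "negative")])
        assert np.array_equal(epoch.recording.data,
                              rec.data[:, 1000:7000])
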