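"""Accelerometer summaries, Welch coherence (mean and median averaging),
the method x resolution grid, SNR and peak metrics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

import ckc
from ckc import coherence as coh
from ckc.containers import AccelTrace, CoherenceSpectrum
from conftest import quick_config


def coupled_pair(n, fs, snr=1.0, seed=0, f=2.0):
    """Two noisy observations of a shared 2 Hz line, for coherence tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    s = np.sin(2 * np.pi * f * t)
    amp = np.sqrt(2.0 * snr)  # sine power amp^2/2 = snr * unit noise power
    x = amp * s + rng.normal(size=n)
    y = amp * np.cos(2 * np.pi * f * t) + rng.normal(size=n)
    return x, y


class TestPrepareAccel:
    def test_clock_offset_and_drift_inverted_exactly(self):
        cfg = quick_config(duration_s=10.0, clock_offset_s=0.25, clock_drift=1e-4)
        _, trace, _ = ckc.simulate_movement(cfg)
        eeg_events = np.array([1.0, cfg.duration_s - 1.0])
        to_eeg = coh.sync_clock_map(trace.sync_events, eeg_events)
        true_times = np.arange(trace.n_samples) / cfg.accel_fs_hz
        assert np.max(np.abs(to_eeg(trace.timestamps) - true_times)) < 1e-9

    def test_residual_misalignment_below_1_ms(self):
        """After TTL sync the resampled acceleration is aligned with the
        ground-truth acceleration to within 1 ms (best cross-correlation lag
        at zero +/- 2 samples), despite clock offset and drift."""
        cfg = quick_config(duration_s=20.0, seed=5, bitflip_prob=0.0,
                           clock_offset_s=0.4, clock_drift=5e-5)
        rec = ckc.simulate_recording(cfg)
        acc = coh.prepare_accel(rec.accel, rec.events, rec.n_samples, method="pca")
        # ground-truth acceleration on the EEG grid (true clock)
        fs_a = cfg.accel_fs_hz
        t_true = np.arange(rec.truth.displacement.size) / fs_a
        a_true = np.gradient(np.gradient(rec.truth.displacement, 1 / fs_a), 1 / fs_a)
        grid = np.arange(rec.n_samples) / rec.fs_hz
        ref = np.interp(grid, t_true, a_true)
        sig = acc.signal_1d - acc.signal_1d.mean()
        ref = ref - ref.mean()
        mid = slice(2000, -2000)
        lags = np.arange(-10, 11)  # 0.5 ms steps at 2000 Hz
        corrs = [
            abs(np.dot(np.roll(sig, lag)[mid], ref[mid])) for lag in lags
        ]
        assert abs(lags[int(np.argmax(corrs))]) <= 2

    def test_gravity_only_magnitude_is_near_zero(self):
        n = 20000
        samples = np.zeros((3, n), dtype=np.int32)
        samples[2] = 8192  # 1 g on the z axis
        trace = AccelTrace(
            samples=samples,
            timestamps=np.arange(n) / 1094.0,
            sync_events=np.array([1.0, 17.0]),
        )
        acc = coh.prepare_accel(trace, np.array([1.0, 17.0]), 30000)
        assert np.max(np.abs(acc.signal_1d)) < 1e-6

    def test_single_axis_motion_pca_recovers_axis(self):
        n = 20000
        t = np.arange(n) / 1094.0
        motion = 3000 * np.sin(2 * np.pi * 2.0 * t)
        samples = np.zeros((3, n), dtype=np.int32)
        samples[1] = np.rint(motion).astype(np.int32)
        trace = AccelTrace(
            samples=samples, timestamps=t, sync_events=np.array([1.0, 17.0])
        )
        acc = coh.prepare_accel(trace, np.array([1.0, 17.0]), 30000, method="pca")
        ref = np.interp(np.arange(30000) / 2000.0, t, motion)
        r = np.corrcoef(acc.signal_1d, ref)[0, 1]
        assert abs(r) > 0.999

    def test_insufficient_sync_events_rejected(self):
        trace = AccelTrace(
            samples=np.zeros((3, 100), dtype=np.int32),
            timestamps=np.arange(100) / 1094.0,
            sync_events=np.array([0.01]),
        )
        with pytest.raises(ValueError):
            coh.prepare_accel(trace, np.array([0.01]), 200)

    def test_excessive_sync_residual_rejected(self):
        with pytest.raises(ValueError):
            coh.sync_clock_map(
                np.array([0.0, 5.0, 10.0]), np.array([0.0, 5.01, 10.0])
            )


class TestWelchCoherence:
    @pytest.mark.parametrize("averaging", ["mean", "median"])
    def test_identical_signals_give_unit_coherence(self, averaging):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8000)
        _, c = coh.welch_coherence(x, x, 1000.0, 1.0, averaging=averaging)
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    @pytest.mark.parametrize("averaging", ["mean", "median"])
    def test_symmetric_in_arguments(self, averaging):
        x, y = coupled_pair(8000, 1000.0, seed=1)
        _, cxy = coh.welch_coherence(x, y, 1000.0, 2.0, averaging=averaging)
        _, cyx = coh.welch_coherence(y, x, 1000.0, 2.0, averaging=averaging)
        np.testing.assert_allclose(cxy, cyx, atol=1e-14)

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(-50, 50).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-50, 50).filter(lambda v: abs(v) > 1e-3),
    )
    def test_scale_invariant(self, a, b):
        x, y = coupled_pair(4000, 500.0, seed=2)
        _, c0 = coh.welch_coherence(x, y, 500.0, 2.0, averaging="median")
        _, c1 = coh.welch_coherence(a * x, b * y, 500.0, 2.0, averaging="median")
        np.testing.assert_allclose(c0, c1, rtol=1e-9, atol=1e-12)

    def test_mean_mode_matches_scipy_exactly(self):
        """Mean averaging reproduces scipy.signal.coherence bit-for-bit."""
        rng = np.random.default_rng(3)
        for fs, seg in ((1000.0, 1.0), (2000.0, 2.0)):
            n = int(20 * fs)
            x, y = coupled_pair(n, fs, seed=rng.integers(1 << 30))
            nperseg = int(seg * fs)
            noverlap = int(round(0.8 * nperseg))
            f_ref, c_ref = signal.coherence(
                x, y, fs=fs, window="hann", nperseg=nperseg,
                noverlap=noverlap, detrend="constant",
            )
            f_got, c_got = coh.welch_coherence(x, y, fs, seg, overlap=0.8)
            np.testing.assert_allclose(f_got, f_ref, atol=1e-12)
            np.testing.assert_allclose(c_got, c_ref, rtol=1e-10, atol=1e-12)

    def test_independent_noise_bias_is_one_over_k(self):
        """With K disjoint segments the expected coherence of independent
        white noise is 1/K (known estimator bias)."""
        fs, seg, k = 500.0, 1.0, 10
        n = int(k * seg * fs)
        vals = []
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            _, c = coh.welch_coherence(x, y, fs, seg, overlap=0.0)
            vals.append(c[5:-5].mean())  # interior bins
        assert abs(np.mean(vals) - 1.0 / k) < 0.15 / k

    def test_median_beats_mean_under_transient(self):
        """A large transient in one segment degrades the median-averaged F0
        coherence strictly less than the mean-averaged one."""
        fs, seg = 500.0, 2.0
        worse = 0
        for seed in range(10):
            x, y = coupled_pair(int(40 * fs), fs, snr=4.0, seed=seed)
            f, c_clean = coh.welch_coherence(x, y, fs, seg, averaging="median")
            i0 = np.argmin(np.abs(f - 2.0))
            xc = x.copy()
            xc[3000:4000] += 40.0 * np.random.default_rng(seed).normal(size=1000)
            _, c_mean = coh.welch_coherence(xc, y, fs, seg, averaging="mean")
            _, c_med = coh.welch_coherence(xc, y, fs, seg, averaging="median")
            if abs(c_med[i0] - c_clean[i0]) < abs(c_mean[i0] - c_clean[i0]):
                worse += 1
        assert worse >= 9

    def test_median_robust_up_to_half_corrupted(self):
        """With k < K/2 corrupted segments the median stays closer to the
        clean value than the mean (formal robustness property)."""
        fs, seg = 500.0, 2.0
        n = int(40 * fs)
        nperseg = int(seg * fs)
        rng = np.random.default_rng(11)
        x, y = coupled_pair(n, fs, snr=4.0, seed=99)
        f, c_clean = coh.welch_coherence(x, y, fs, seg, averaging="median")
        i0 = np.argmin(np.abs(f - 2.0))
        for k_bad in (2, 5, 8):  # of K = 20 disjoint positions
            xc = x.copy()
            starts = rng.choice(20, size=k_bad, replace=False) * nperseg
            for s in starts:
                xc[s : s + nperseg] += 30.0 * rng.normal(size=nperseg)
            _, c_mean = coh.welch_coherence(xc, y, fs, seg, averaging="mean")
            _, c_med = coh.welch_coherence(xc, y, fs, seg, averaging="median")
            assert abs(c_med[i0] - c_clean[i0]) < abs(c_mean[i0] - c_clean[i0])

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            coh.welch_coherence(np.ones(500), np.ones(500), 500.0, 2.0)

    def test_zero_power_bins_flagged_as_zero(self):
        x = np.zeros(4000)
        with pytest.warns(UserWarning, match="zero-power"):
            _, c = coh.welch_coherence(x, x, 500.0, 2.0)
        assert np.all(c == 0.0)

    def test_detects_coupling_at_every_resolution(self):
        """A long stationary, moderately coupled pair yields > 6 dB SNR at
        2 Hz for all four epoch lengths (1 .. 0.125 Hz resolutions).

        The coupling is kept moderate: at 1 Hz resolution the 3 Hz baseline
        bin is adjacent to the 2 Hz line and sits inside the Hann main lobe,
        so an arbitrarily strong line would leak into its own baseline.
        """
        fs = 500.0
        x, y = coupled_pair(int(160 * fs), fs, snr=0.01, seed=8)
        for seg in (1.0, 2.0, 4.0, 8.0):
            for averaging in ("mean", "median"):
                f, c = coh.welch_coherence(x, y, fs, seg, averaging=averaging)
                c2 = c[np.argmin(np.abs(f - 2.0))]
                c3 = c[np.argmin(np.abs(f - 3.0))]
                snr = 20 * np.log10(c2 / c3)
                assert snr > 6.0, (seg, averaging, snr)


class TestGrid:
    @pytest.fixture(scope="class")
    def grid(self):
        cfg = quick_config(duration_s=30.0, seed=21)
        rec = ckc.simulate_recording(cfg)
        from conftest import run_pipeline

        _, rec5, _ = run_pipeline(rec, segment_s=2.0)
        trace, _ = ckc.kinematics.correct_bit_flips(rec.accel)
        return rec, rec5, coh.ckc_grid(rec5, trace, fmax=10.0)

    def test_grid_has_16_cells(self, grid):
        _, _, spectra = grid
        assert len(spectra) == 16
        combos = {
            (s.accel_method, s.averaging, s.segment_s) for s in spectra
        }
        assert len(combos) == 16

    def test_all_spectra_satisfy_invariants(self, grid):
        _, _, spectra = grid
        for s in spectra:
            assert np.all((s.values >= 0) & (s.values <= 1))
            np.testing.assert_allclose(np.diff(s.freqs_hz), s.resolution_hz)
            assert s.segment_s * s.resolution_hz == pytest.approx(1.0)
            # 2, 3 and 4 Hz are exact bins at every resolution
            for f in (2.0, 3.0, 4.0):
                s.bin_index(f)

    def test_f0_peak_channel_near_source(self, grid):
        """The argmax channel at 2 Hz falls within one electrode spacing of
        the simulated source in at least 14 of the 16 grid cells."""
        rec, rec5, spectra = grid
        src = rec5.montage.position("C3")
        # one electrode spacing: distance to the nearest montage neighbor
        d = np.linalg.norm(rec5.montage.positions - src, axis=1)
        neighbor = np.sort(d)[1]
        subset = rec5.montage.subsets["analysis"]
        idx = [spectra[0].channels.index(l) for l in subset]
        hits = 0
        for s in spectra:
            best = subset[int(np.argmax(s.at(2.0)[idx]))]
            if np.linalg.norm(rec5.montage.position(best) - src) <= 1.5 * neighbor:
                hits += 1
        assert hits >= 14


class TestSnrAndMetrics:
    def fabricate_spectrum(self, values, freqs=None):
        freqs = np.arange(23) * 0.5 if freqs is None else freqs
        montage = ckc.default_montage(61)
        return CoherenceSpectrum(
            values=values,
            freqs_hz=freqs,
            channels=montage.labels,
            resolution_hz=0.5,
            segment_s=2.0,
            overlap=0.8,
            averaging="median",
            accel_method="magnitude",
        ), montage

    def test_snr_of_equal_coherence_is_zero_db(self):
        spec, _ = self.fabricate_spectrum(np.full((61, 23), 0.25))
        np.testing.assert_allclose(coh.snr_db(spec, 2.0), 0.0, atol=1e-12)

    def test_tenfold_coherence_is_plus_20_db(self):
        vals = np.full((61, 23), 0.05)
        spec, _ = self.fabricate_spectrum(vals)
        i2 = spec.bin_index(2.0)
        vals2 = vals.copy()
        vals2[:, i2] = 0.5
        spec2, _ = self.fabricate_spectrum(vals2)
        np.testing.assert_allclose(coh.snr_db(spec2, 2.0), 20.0, atol=1e-9)

    def test_snr_increases_with_source_power(self):
        snrs = []
        for source_snr in (0.05, 0.4):
            cfg = quick_config(duration_s=20.0, seed=31, source_snr=source_snr)
            rec = ckc.simulate_recording(cfg)
            acc = coh.prepare_accel(rec.accel, rec.events, rec.n_samples)
            spec = coh.channel_coherence(rec, acc, 2.0, averaging="median", fmax=6.0)
            idx = [spec.channels.index(l) for l in rec.montage.subsets["analysis"]]
            snrs.append(np.median(coh.snr_db(spec, 2.0)[idx]))
        assert snrs[1] > snrs[0]

    def test_single_hot_channel_is_argmax(self):
        vals = np.zeros((61, 23))
        montage = ckc.default_montage(61)
        i = montage.labels.index("FC3")
        vals[i, :] = 0.9
        spec, montage = self.fabricate_spectrum(vals)
        m = coh.peak_metrics(spec, montage, hand="right")
        assert m.peak_channel_f0 == "FC3"
        assert m.peak_channel_f1 == "FC3"

    def test_left_hand_contra_is_right_set(self):
        rng = np.random.default_rng(5)
        vals = np.clip(rng.uniform(0, 0.5, size=(61, 23)), 0, 1)
        spec, montage = self.fabricate_spectrum(vals)
        m = coh.peak_metrics(spec, montage, hand="left")
        assert m.contra_f0 == m.mean_right_f0
        assert m.ipsi_f0 == m.mean_left_f0
        m2 = coh.peak_metrics(spec, montage, hand="right")
        assert m2.contra_f0 == m2.mean_left_f0

    def test_missing_subset_channels_rejected(self):
        vals = np.zeros((59, 23))
        montage = ckc.default_montage(61).drop(["C3", "C4"])
        spec = CoherenceSpectrum(
            values=vals,
            freqs_hz=np.arange(23) * 0.5,
            channels=montage.labels,
            resolution_hz=0.5,
            segment_s=2.0,
            overlap=0.8,
            averaging="mean",
            accel_method="pca",
        )
        full = ckc.default_montage(61)
        with pytest.raises(KeyError):
            coh.peak_metrics(spec, full, hand="left")

    def test_contralateral_dominance_across_replicates(self):
        """Right-sided source + left-hand condition: contra > ipsi at F1 in
        (nearly) all replicates."""
        hits = 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = quick_config(
                duration_s=20.0, seed=500 + seed, source_channel="C4",
                moved_hand="left",
            )
            rec = ckc.simulate_recording(cfg)
            acc = coh.prepare_accel(rec.accel, rec.events, rec.n_samples)
            spec = coh.channel_coherence(rec, acc, 2.0, averaging="median", fmax=6.0)
            m = coh.peak_metrics(spec, rec.montage, hand="left")
            if m.contra_f1 > m.ipsi_f1:
                hits += 1
        assert hits >= n_rep - 1
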