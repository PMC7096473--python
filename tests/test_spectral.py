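import numpy as np
import pytest

from gammatune.spectral import (
    BandDefinition,
    PowerSpectrum,
    band_power_change,
    baseline_spectrum,
    change_spectrum,
    line_exclusions,
    multitaper_psd,
    psd_in_window,
    spectrogram,
    tf_difference,
    time_frequency_map,
)

FS = 2000.0


def brute_force_band_power_change(stim, base, band):
    """Independent oracle: explicit loops over conditions and frequencies."""
    keys = list(stim.keys())
    st, bl = {}, {}
    for k in keys:
        s_sum = 0.0
        b_sum = 0.0
        for j, f in enumerate(stim[k].f):
            included = band.lo_hz <= f <= band.hi_hz
            for center, half in band.exclusions:
                if abs(f - center) <= half:
                    included = False
            if included:
                s_sum += stim[k].P[j]
                b_sum += base[k].P[j]
        st[k] = np.log10(s_sum)
        bl[k] = np.log10(b_sum)
    bl_ave = sum(bl.values()) / len(keys)
    return {k: 10.0 * (st[k] - bl_ave) for k in keys}


class TestMultitaperPsd:
    def test_white_noise_parseval(self, rng):
        segs = rng.standard_normal((200, 1000))
        segs -= segs.mean(axis=1, keepdims=True)
        psd = multitaper_psd(segs, FS)
        total = np.sum(psd.P) * psd.df
        var = segs.var(axis=1).mean()
        assert abs(total - var) / var < 0.05

    def test_pure_tone_peak_within_rayleigh(self):
        t = np.arange(1000) / FS
        seg = np.sin(2 * np.pi * 52.0 * t)
        psd = multitaper_psd([seg], FS)
        rayleigh = FS / 1000
        assert abs(psd.f[np.argmax(psd.P)] - 52.0) <= rayleigh

    def test_zero_signal_gives_zero_power(self):
        psd = multitaper_psd(np.zeros((3, 500)), FS)
        assert np.all(psd.P == 0)

    def test_unequal_segments_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            multitaper_psd([np.zeros(100), np.zeros(101)], FS)

    def test_frequency_grid_spans_zero_to_nyquist(self, rng):
        psd = multitaper_psd(rng.standard_normal((2, 800)), FS)
        assert psd.f[0] == 0.0 and psd.f[-1] == FS / 2


class TestSpectrogram:
    def test_stationary_signal_is_flat_in_time(self, rng):
        trials = rng.standard_normal((200, 1600))
        t_ax = np.arange(1600) / FS
        t, w, E = spectrogram(trials, FS, t_ax)
        band = (w >= 100) & (w <= 300)
        series = E[:, band].mean(axis=1)
        assert series.max() / series.min() < 1.5

    def test_gated_tone_raises_band_energy(self, rng, t_axis):
        tone = np.sin(2 * np.pi * 60.0 * t_axis) * (t_axis >= 0)
        trials = 0.1 * rng.standard_normal((20, t_axis.size)) + tone
        t, w, E = spectrogram(trials, FS, t_axis)
        fi = np.argmin(np.abs(w - 60.0))
        pre = E[t < -0.2, fi].mean()
        post = E[(t > 0.2) & (t < 0.6), fi].mean()
        assert post > 10 * pre

    def test_first_window_center_geometry(self, rng, t_axis):
        t, _, _ = spectrogram(rng.standard_normal((2, t_axis.size)), FS, t_axis)
        assert t[0] >= -0.375 - 1e-12
        assert np.allclose(np.diff(t), 0.025)

    def test_window_longer_than_trial_rejected(self, rng):
        with pytest.raises(ValueError, match="window longer"):
            spectrogram(rng.standard_normal((2, 100)), FS, np.arange(100) / FS)


class TestBaselineSpectrum:
    def test_pooled_equals_across_trial_mean(self, rng, t_axis):
        """One condition with doubled variance: pooling is the arithmetic
        mean of per-trial spectra in the power domain (direct oracle)."""
        n = t_axis.size
        cond_a = rng.standard_normal((10, n))
        cond_b = np.sqrt(2.0) * rng.standard_normal((10, n))
        traces = np.vstack([cond_a, cond_b])
        pooled = baseline_spectrum(traces, t_axis, FS, window=(-0.5, 0.0))
        per_trial = [
            psd_in_window(tr[None, :], t_axis, (-0.5, 0.0), FS).P
            for tr in traces
        ]
        np.testing.assert_allclose(pooled.P, np.mean(per_trial, axis=0),
                                   rtol=1e-10)

    def test_empty_trial_set_rejected(self, t_axis):
        with pytest.raises(ValueError, match="empty"):
            baseline_spectrum(np.empty((0, t_axis.size)), t_axis, FS)


class TestTfDifference:
    def test_identity_is_zero_db(self):
        E = np.ones((4, 10))
        assert np.all(tf_difference(E, np.ones(10)) == 0.0)

    def test_doubling_is_3_db(self):
        B = np.linspace(1, 2, 10)
        D = tf_difference(2 * B[None, :], B)
        np.testing.assert_allclose(D, 10 * np.log10(2), atol=1e-10)

    def test_tenfold_is_10_db(self):
        B = np.full(8, 0.5)
        np.testing.assert_allclose(tf_difference(10 * B[None, :], B), 10.0,
                                   atol=1e-12)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tf_difference(np.zeros((1, 3)), np.ones(3))


def _random_psd_fixture(rng, n_cond=5, n_f=201):
    f = np.linspace(0, FS / 2, n_f)
    stim = {}
    base = {}
    for i in range(n_cond):
        stim[i] = PowerSpectrum(f=f, P=rng.uniform(0.1, 5.0, n_f), n_trials=10)
        base[i] = PowerSpectrum(f=f, P=rng.uniform(0.1, 5.0, n_f), n_trials=10)
    return stim, base


class TestBandPowerChange:
    def test_equal_power_gives_zero_change(self):
        f = np.linspace(0, 1000, 501)
        P = np.ones_like(f)
        psd = {0: PowerSpectrum(f=f, P=P, n_trials=1),
               1: PowerSpectrum(f=f, P=P, n_trials=1)}
        res = band_power_change(psd, psd, BandDefinition(30, 65))
        assert all(abs(r.delta_db) < 1e-12 for r in res)

    def test_tenfold_band_power_gives_10_db(self):
        f = np.linspace(0, 1000, 501)
        base = {0: PowerSpectrum(f=f, P=np.ones_like(f), n_trials=1)}
        stim = {0: PowerSpectrum(f=f, P=10 * np.ones_like(f), n_trials=1)}
        res = band_power_change(stim, base, BandDefinition(30, 65))
        assert res[0].delta_db == pytest.approx(10.0, abs=1e-12)

    def test_line_spike_is_masked_out(self, rng):
        """A spectrum with an added spike at exactly 50 Hz yields the same
        change as the spike-free spectrum when 50 +/- 2 Hz is excluded."""
        f = np.linspace(0, 1000, 501)  # 2 Hz grid
        band = BandDefinition(30, 65, exclusions=((50.0, 2.0),))
        P = rng.uniform(0.5, 1.5, f.size)
        spiked = P.copy()
        spiked[np.abs(f - 50.0) < 1e-9] += 100.0
        base = {0: PowerSpectrum(f=f, P=np.ones_like(f), n_trials=1)}
        clean = band_power_change(
            {0: PowerSpectrum(f=f, P=P, n_trials=1)}, base, band)
        dirty = band_power_change(
            {0: PowerSpectrum(f=f, P=spiked, n_trials=1)}, base, band)
        assert dirty[0].delta_db == pytest.approx(clean[0].delta_db, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        band = BandDefinition(
            30, 65, exclusions=line_exclusions(50.0, 65.0))
        for _ in range(5):
            stim, base = _random_psd_fixture(rng)
            expected = brute_force_band_power_change(stim, base, band)
            got = {r.condition_id: r.delta_db
                   for r in band_power_change(stim, base, band)}
            for k in expected:
                assert got[k] == pytest.approx(expected[k], rel=1e-10)

    def test_fully_excluded_band_rejected(self, rng):
        stim, base = _random_psd_fixture(rng)
        band = BandDefinition(48, 52, exclusions=((50.0, 3.0),))
        with pytest.raises(ValueError, match="no included bins"):
            band_power_change(stim, base, band)

    def test_scale_invariance(self, rng, t_axis):
        """Multiplying all traces by a constant leaves delta power unchanged."""
        traces = rng.standard_normal((12, t_axis.size))
        band = BandDefinition(30, 65)

        def delta(tr):
            stim = {0: psd_in_window(tr[:6], t_axis, (0.25, 0.75), FS),
                    1: psd_in_window(tr[6:], t_axis, (0.25, 0.75), FS)}
            base = {0: psd_in_window(tr[:6], t_axis, (-0.5, 0.0), FS),
                    1: psd_in_window(tr[6:], t_axis, (-0.5, 0.0), FS)}
            return [r.delta_db for r in band_power_change(stim, base, band)]

        np.testing.assert_allclose(delta(traces), delta(37.2 * traces),
                                   rtol=1e-9)


class TestChangeSpectrum:
    def test_identical_spectra_flat_zero(self, rng):
        f = np.linspace(0, 1000, 100)
        P = rng.uniform(1, 2, 100)
        a = PowerSpectrum(f=f, P=P, n_trials=1)
        assert np.all(change_spectrum(a, a) == 0)

    def test_bump_peaks_at_bump_frequency(self):
        f = np.linspace(0, 200, 401)
        B = np.ones_like(f)
        P = 1 + 3 * np.exp(-((f - 52) ** 2) / 8)
        db = change_spectrum(PowerSpectrum(f=f, P=P, n_trials=1),
                             PowerSpectrum(f=f, P=B, n_trials=1))
        assert f[np.argmax(db)] == pytest.approx(52.0, abs=0.5)

    def test_site_average_on_db_scale(self):
        assert np.mean([6.0, 0.0]) == 3.0  # averaging is on dB values
        f = np.linspace(0, 100, 11)
        B = PowerSpectrum(f=f, P=np.ones(11), n_trials=1)
        s1 = PowerSpectrum(f=f, P=10 ** 0.6 * np.ones(11), n_trials=1)
        s2 = PowerSpectrum(f=f, P=np.ones(11), n_trials=1)
        avg = np.mean([change_spectrum(s1, B), change_spectrum(s2, B)], axis=0)
        np.testing.assert_allclose(avg, 3.0, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = PowerSpectrum(f=np.linspace(0, 100, 11), P=np.ones(11), n_trials=1)
        b = PowerSpectrum(f=np.linspace(0, 200, 11), P=np.ones(11), n_trials=1)
        with pytest.raises(ValueError, match="grid"):
            change_spectrum(a, b)


class TestTimeFrequencyMap:
    def test_map_satisfies_db_identity(self, rng, t_axis):
        trials = rng.standard_normal((10, t_axis.size))
        m = time_frequency_map(trials, FS, t_axis, baseline_window=(-0.5, 0.0))
        np.testing.assert_allclose(
            m.D, 10 * (np.log10(m.E) - np.log10(m.B)[None, :]), atol=1e-12
        )


class TestLineExclusions:
    def test_harmonics_up_to_fmax(self):
        assert line_exclusions(50.0, 250.0) == (
            (50.0, 2.0), (100.0, 2.0), (150.0, 2.0), (200.0, 2.0), (250.0, 2.0)
        )
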