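import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammatune.spectral import BandDefinition
from gammatune.tuning import (
    average_tuning_curves,
    axial_distance_deg,
    bootstrap_median_se,
    compare_tuning,
    gamma_peak,
    orientation_selectivity,
    preferred_orientation,
    salient_peaks,
    tuning_over_parameter,
)

GRID8 = [22.5 * k for k in range(8)]


def direct_circular_sums(R, theta_deg):
    """Independent oracle: literal evaluation of the doubled-angle sums."""
    s = sum(r * math.sin(2 * math.radians(th)) for r, th in zip(R, theta_deg))
    c = sum(r * math.cos(2 * math.radians(th)) for r, th in zip(R, theta_deg))
    pref = math.degrees(0.5 * math.atan2(s, c)) % 180.0
    sel = math.hypot(s, c) / sum(R)
    return pref, sel


class TestPreferredOrientation:
    def test_single_active_orientation(self):
        R = [1.0] + [0.0] * 7
        assert preferred_orientation(R, GRID8) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_profile_peaked_at_90(self):
        # symmetric about 90 deg on the 8-point grid
        R = [0.1, 0.2, 0.5, 1.0, 2.0, 1.0, 0.5, 0.2]
        assert preferred_orientation(R, GRID8) == pytest.approx(90.0, abs=1e-9)

    def test_von_mises_profile_matches_direct_sums(self):
        kappa, center = 2.0, 60.0
        R = [math.exp(kappa * math.cos(2 * math.radians(th - center)))
             for th in GRID8]
        pref = preferred_orientation(R, GRID8)
        pref_oracle, _ = direct_circular_sums(R, GRID8)
        assert pref == pytest.approx(pref_oracle, abs=1e-12)
        # small residual offset is grid discretization (60 deg is not an
        # 8-point grid node), not estimator error
        assert axial_distance_deg(pref, center) < 0.01

    def test_uniform_profile_is_undefined(self):
        assert math.isnan(preferred_orientation([1.0] * 8, GRID8))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            preferred_orientation([0.0] * 8, GRID8)


class TestOrientationSelectivity:
    def test_single_component_gives_one(self):
        R = [0.0, 0.0, 3.7, 0.0, 0.0, 0.0, 0.0, 0.0]
        assert orientation_selectivity(R, GRID8) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_profile_gives_zero(self):
        assert orientation_selectivity([2.0] * 8, GRID8) == pytest.approx(
            0.0, abs=1e-10)

    def test_matches_direct_complex_sum(self):
        R = [2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        _, sel_oracle = direct_circular_sums(R, GRID8)
        assert orientation_selectivity(R, GRID8) == pytest.approx(
            sel_oracle, abs=1e-14)
        # closed form: |sum| = 1 extra unit vector at 0 deg over total 9
        assert sel_oracle == pytest.approx(1.0 / 9.0, abs=1e-14)

    def test_zero_total_power_rejected(self):
        with pytest.raises(ValueError, match="selectivity"):
            orientation_selectivity([0.0] * 8, GRID8)

    def test_selectivity_increases_with_kappa(self):
        sels = []
        for kappa in (0.5, 1.0, 2.0, 4.0, 8.0):
            R = [math.exp(kappa * math.cos(2 * math.radians(th - 90.0)))
                 for th in GRID8]
            sels.append(orientation_selectivity(R, GRID8))
        assert all(b > a for a, b in zip(sels, sels[1:]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    phi=st.floats(0.0, 180.0, allow_nan=False),
    scale=st.floats(0.01, 100.0, allow_nan=False),
    kappa=st.floats(0.2, 5.0, allow_nan=False),
    center=st.floats(0.0, 180.0, exclude_max=True, allow_nan=False),
)
def test_rotation_equivariance_and_scale_invariance(phi, scale, kappa, center):
    """Rotating all orientations by phi rotates the preferred orientation by
    phi (mod 180) and leaves selectivity unchanged; rescaling R changes
    neither."""
    R = [math.exp(kappa * math.cos(2 * math.radians(th - center)))
         for th in GRID8]
    pref0 = preferred_orientation(R, GRID8)
    sel0 = orientation_selectivity(R, GRID8)
    rotated = [(th + phi) % 180.0 for th in GRID8]
    pref1 = preferred_orientation(R, rotated)
    sel1 = orientation_selectivity(R, rotated)
    assert axial_distance_deg(pref1, (pref0 + phi) % 180.0) < 1e-7
    assert sel1 == pytest.approx(sel0, abs=1e-10)
    R2 = [scale * r for r in R]
    assert axial_distance_deg(preferred_orientation(R2, GRID8), pref0) < 1e-7
    assert orientation_selectivity(R2, GRID8) == pytest.approx(sel0, rel=1e-9)


class TestGammaPeak:
    def test_gaussian_bump_located(self):
        f = np.arange(0, 200, 2.0)
        change = np.exp(-((f - 52.0) ** 2) / 30.0)
        pk = gamma_peak(f, change, BandDefinition(20, 75))
        assert pk.peak_hz == 52.0 and not pk.on_edge

    def test_monotone_decrease_flags_low_edge(self):
        f = np.arange(0, 200, 2.0)
        pk = gamma_peak(f, -f, BandDefinition(20, 75))
        assert pk.peak_hz == 20.0 and pk.on_edge

    def test_tie_breaks_to_lower_frequency(self):
        f = np.arange(0, 100, 2.0)
        change = np.zeros_like(f)
        change[(f == 40) | (f == 60)] = 5.0
        assert gamma_peak(f, change, BandDefinition(30, 70)).peak_hz == 40.0

    def test_empty_band_rejected(self):
        f = np.arange(0, 100, 2.0)
        with pytest.raises(ValueError):
            gamma_peak(f, np.ones_like(f), BandDefinition(40, 41,
                                                          exclusions=((40.5, 2),)))


class TestSalientPeaks:
    def test_flat_conditions_dropped_peaked_kept(self):
        f = np.arange(0, 200, 2.0)
        band = BandDefinition(20, 75)
        bump = 5 * np.exp(-((f - 48.0) ** 2) / 30.0)
        flat = 0.1 * np.ones_like(f)
        peaks = salient_peaks(f, {100.0: bump, 3.125: flat}, band)
        assert set(peaks) == {100.0}
        assert peaks[100.0].peak_hz == 48.0

    def test_peak_frequency_rises_with_contrast(self):
        """Simulated contrast sweep: recovered peak frequency nondecreasing
        in contrast (known frequency map in the generator)."""
        from gammatune.conditions import FULLSCREEN, StimulusCondition
        from gammatune.simulate import default_params, simulate_trial
        from gammatune.spectral import change_spectrum, psd_in_window

        p = default_params("LFP", line_amp=0.0)
        t_ax = -0.5 + np.arange(2600) / 2000.0
        band = BandDefinition(20, 75)
        change = {}
        for c in (25.0, 50.0, 100.0):
            stim = StimulusCondition(FULLSCREEN, 90.0, 4.0, c)
            traces = np.array(
                [simulate_trial(stim, p, 500 + s)[0] for s in range(30)])
            ps = psd_in_window(traces, t_ax, (0.25, 0.75), 2000.0)
            pb = psd_in_window(traces, t_ax, (-0.5, 0.0), 2000.0)
            change[c] = change_spectrum(ps, pb)
            f = ps.f
        peaks = salient_peaks(f, change, band)
        assert set(peaks) == {25.0, 50.0, 100.0}
        freqs = [peaks[c].peak_hz for c in (25.0, 50.0, 100.0)]
        assert freqs == sorted(freqs)


class TestCompareTuning:
    def test_affine_relation_gives_unit_correlation(self):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        r, p = compare_tuning(a, 2 * a + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_negation_gives_minus_one(self):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        assert compare_tuning(a, -a)[0] == pytest.approx(-1.0)

    def test_matches_hand_computed_r(self):
        a = np.arange(1.0, 7.0)
        b = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 5.0])
        # direct formula: cov / (sd_a sd_b)
        r_direct = (np.mean(a * b) - a.mean() * b.mean()) / (
            a.std() * b.std())
        r, _ = compare_tuning(a, b)
        assert r == pytest.approx(r_direct, rel=1e-12)

    def test_zero_variance_flagged_nan(self):
        r, p = compare_tuning([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)


class TestBootstrapMedianSe:
    def test_constant_values_give_zero(self):
        assert bootstrap_median_se([3.0] * 10, n_boot=200, seed=1) == 0.0

    def test_deterministic_for_fixed_seed(self):
        v = [1.0, 5.0, 2.0, 8.0, 3.0]
        assert bootstrap_median_se(v, seed=7) == bootstrap_median_se(v, seed=7)

    def test_matches_independent_resampler(self):
        """Second implementation with its own resampling scheme agrees to 2%."""
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        se = bootstrap_median_se(v, n_boot=10_000, seed=3)
        rng = np.random.default_rng(1234)
        meds = [np.median(rng.choice(v, size=v.size, replace=True))
                for _ in range(10_000)]
        se_oracle = np.std(meds, ddof=1)
        assert se == pytest.approx(se_oracle, rel=0.02)


class TestTuningCurves:
    def test_missing_condition_rejected(self):
        band = BandDefinition(30, 65)
        with pytest.raises(ValueError, match="missing"):
            tuning_over_parameter({0.3: 1.0, 0.6: 2.0}, "radius_deg", band,
                                  expected_values=[0.3, 0.6, 1.2])

    def test_single_site_average_is_identity_with_zero_sem(self):
        band = BandDefinition(30, 65)
        c = tuning_over_parameter({0.3: 1.0, 0.6: 2.0, 1.2: 3.0},
                                  "radius_deg", band)
        x, mean, sem = average_tuning_curves([c])
        np.testing.assert_array_equal(mean, c.y)
        assert np.all(sem == 0)

    def test_cross_site_mean_and_sem(self):
        band = BandDefinition(30, 65)
        c1 = tuning_over_parameter({1.0: 0.0, 2.0: 2.0}, "sf_cpd", band)
        c2 = tuning_over_parameter({1.0: 2.0, 2.0: 4.0}, "sf_cpd", band)
        x, mean, sem = average_tuning_curves([c1, c2])
        np.testing.assert_allclose(mean, [1.0, 3.0])
        np.testing.assert_allclose(sem, np.sqrt(2.0) / np.sqrt(2.0))
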