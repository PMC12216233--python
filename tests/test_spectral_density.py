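import numpy as np
import pytest

from gapspec import units
from gapspec.spectral_density import (
    Acf,
    SpectralDensity,
    acf_to_sd,
    average_acfs,
    find_peaks,
    reorganization_energy,
    window_acf,
)
from gapspec.synthetic import la_like_spec, target_acf
from gapspec.vertical_gradient import NormalModeSet, vg_sd


def brute_force_acf(series: np.ndarray) -> np.ndarray:
    """Hand-expanded unbiased estimator: C(j) = 1/(N-j) sum_k dE(k+j) dE(k)."""
    x = series - series.mean()
    n = x.size
    out = np.empty(n)
    for j in range(n):
        s = 0.0
        for k in range(n - j):
            s += x[k + j] * x[k]
        out[j] = s / (n - j)
    return out


def brute_force_transform(acf: Acf, grid: np.ndarray) -> np.ndarray:
    """Direct O(N*M) trapezoid of (beta w / pi) C(t) cos(wt), in cm^-1."""
    beta = units.beta_ev(acf.temperature)
    out = np.empty(grid.size)
    for i, nu in enumerate(grid):
        w = units.ANGFREQ_PER_CM * nu
        integrand = acf.values * np.cos(w * acf.lags)
        out[i] = beta * w / np.pi * np.trapezoid(integrand, acf.lags) \
            * units.CM_PER_EV
    return out


class TestWindowAcf:
    def test_constant_series_gives_zero(self):
        acf = window_acf(np.full(100, 4.5), dt=5.0, window_length=250.0)
        np.testing.assert_allclose(acf.values, 0.0, atol=1e-25)

    def test_five_point_series_matches_hand_expansion(self):
        series = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        acf = window_acf(series, dt=1.0, window_length=5.0)
        np.testing.assert_allclose(acf.values, brute_force_acf(series),
                                   rtol=0, atol=1e-12)

    @pytest.mark.parametrize("n", [64, 1000, 4096])
    def test_fft_path_equals_direct_sum(self, n):
        rng = np.random.default_rng(n)
        series = 4.5 + 0.1 * rng.standard_normal(n)
        acf = window_acf(series, dt=1.0, window_length=float(n))
        oracle = brute_force_acf(series)
        scale = np.abs(oracle).max()
        np.testing.assert_allclose(acf.values, oracle, atol=1e-10 * scale)

    def test_pure_tone_recovers_half_squared_amplitude(self):
        n, dt, amp = 4000, 1.0, 0.2
        w0 = 2 * np.pi * 20 / n  # 20 full periods in the window
        t = np.arange(n) * dt
        acf = window_acf(4.5 + amp * np.cos(w0 * t), dt=dt,
                         window_length=n * dt, max_lag=n * dt / 2)
        expected = amp**2 / 2 * np.cos(w0 * acf.lags)
        assert np.abs(acf.values - expected).max() < 0.05 * amp**2 / 2

    def test_window_counts_and_errors(self):
        series = np.zeros(4000) + 4.5
        acf = window_acf(series, dt=5.0, window_length=4000.0)
        assert acf.n_windows == 5  # a 20-ps replica at 4-ps windows
        with pytest.raises(ValueError, match="longer than series"):
            window_acf(series[:100], dt=5.0, window_length=4000.0)
        with pytest.raises(ValueError, match="at least 2 frames"):
            window_acf(series, dt=5.0, window_length=5.0)

    def test_mean_shift_invariance(self):
        rng = np.random.default_rng(2)
        series = 4.5 + 0.05 * rng.standard_normal(800)
        a1 = window_acf(series, 5.0, 1000.0)
        a2 = window_acf(series + 3.21, 5.0, 1000.0)
        np.testing.assert_allclose(a1.values, a2.values, atol=1e-14)

    def test_overlap_increases_window_count(self):
        series = np.cos(np.arange(1000) * 0.1) + 5.0
        a0 = window_acf(series, 1.0, 200.0, overlap=0.0)
        a5 = window_acf(series, 1.0, 200.0, overlap=0.5)
        assert a5.n_windows == 2 * a0.n_windows - 1


class TestAcfToSd:
    def test_zero_acf_gives_zero_sd(self):
        acf = Acf(lags=np.arange(0, 100.0), values=np.zeros(100),
                  n_windows=1, window_length=100.0)
        sd = acf_to_sd(acf)
        np.testing.assert_array_equal(sd.values, 0.0)

    def test_debye_closed_form(self):
        """C0 e^{-t/tau} transforms to (beta w/pi) C0 tau/(1+w^2 tau^2)."""
        tau, c0, T = 100.0, 1e-3, 300.0
        t = np.arange(0.0, 1201.0)  # dt = tau/100, t_max = 12 tau
        acf = Acf(lags=t, values=c0 * np.exp(-t / tau), n_windows=1,
                  window_length=t[-1], temperature=T)
        grid = np.arange(0.0, 1061.0)  # w*tau <= 20
        sd = acf_to_sd(acf, freq_grid=grid)
        w = units.ANGFREQ_PER_CM * grid
        exact = units.beta_ev(T) * w / np.pi * c0 * tau / (1 + (w * tau)**2) \
            * units.CM_PER_EV
        rel = np.abs(sd.values[1:] - exact[1:]) / exact[1:]
        assert rel.max() < 0.005

    def test_matches_direct_double_sum(self):
        rng = np.random.default_rng(7)
        acf = Acf(lags=np.arange(0, 500.0, 5.0),
                  values=1e-3 * rng.standard_normal(100),
                  n_windows=1, window_length=495.0)
        # C(0) must be a variance
        acf.values[0] = abs(acf.values[0])
        grid = np.arange(0.0, 2001.0, 10.0)
        sd = acf_to_sd(acf, freq_grid=grid)
        oracle = brute_force_transform(acf, grid)
        scale = np.abs(oracle).max()
        np.testing.assert_allclose(sd.values, oracle, atol=1e-10 * scale)

    def test_j_zero_is_exactly_zero(self):
        acf = target_acf(la_like_spec(), np.arange(0, 2000.0, 5.0))
        sd = acf_to_sd(acf)
        assert sd.values[0] == 0.0
        assert np.isrealobj(sd.values)

    def test_temperature_must_be_positive(self):
        acf = Acf(lags=np.arange(0, 10.0), values=np.ones(10),
                  n_windows=1, window_length=9.0)
        with pytest.raises(ValueError, match="temperature"):
            acf_to_sd(acf, temperature=-5.0)


class TestSumRule:
    """Integral J(w)/w dw = beta C(0) / 2 for band-limited baths."""

    def test_exact_lorentzian_bath_acf(self):
        spec = la_like_spec(seed=0)
        acf = target_acf(spec, np.arange(0.0, 6000.0, 2.0))
        sd = acf_to_sd(acf)
        lam = reorganization_energy(sd)
        expected = units.beta_ev(spec.temperature) * acf.c0 / 2 \
            * units.CM_PER_EV
        assert abs(lam / expected - 1) < 0.01

    def test_windowed_estimator_on_generated_series(self):
        from gapspec.synthetic import generate_gap_trajectory

        spec = la_like_spec(seed=4)
        traj = generate_gap_trajectory(spec)
        acf = window_acf(traj.energies[:, 0], traj.dt, 4000.0,
                         temperature=spec.temperature)
        sd = acf_to_sd(acf)
        lam = reorganization_energy(sd)
        expected = units.beta_ev(spec.temperature) * acf.c0 / 2 \
            * units.CM_PER_EV
        assert abs(lam / expected - 1) < 0.01

    def test_debye_reorganization_integral(self):
        """Integral J/w dw = beta C0 / 2 for the exponential ACF."""
        tau, c0, T = 100.0, 1e-3, 300.0
        t = np.arange(0.0, 1401.0, 0.5)
        acf = Acf(lags=t, values=c0 * np.exp(-t / tau), n_windows=1,
                  window_length=t[-1], temperature=T)
        sd = acf_to_sd(acf, freq_grid=np.arange(0.0, 6000.0, 2.0))
        lam = reorganization_energy(sd)
        expected = units.beta_ev(T) * c0 / 2 * units.CM_PER_EV
        assert abs(lam / expected - 1) < 0.01

    def test_zero_sd_gives_zero_lambda(self):
        sd = SpectralDensity(frequencies=np.arange(0.0, 100.0),
                             values=np.zeros(100), temperature=300.0)
        assert reorganization_energy(sd) == 0.0


class TestFindPeaks:
    def test_single_lorentzian_center(self):
        modes = NormalModeSet(frequencies=np.array([1400.0]),
                              lambdas=np.array([100.0]))
        sd = vg_sd(modes, hwhm=20.0)
        table = find_peaks(sd)
        assert len(table) == 1
        assert abs(table.center_cm1.iloc[0] - 1400.0) <= 2.0

    def test_flat_sd_gives_empty_table(self):
        sd = SpectralDensity(frequencies=np.arange(0.0, 100.0),
                             values=np.zeros(100), temperature=300.0)
        assert len(find_peaks(sd)) == 0

    def test_constructed_two_to_one_area_ratio(self):
        modes = NormalModeSet(frequencies=np.array([1400.0, 1700.0]),
                              lambdas=np.array([200.0, 100.0]))
        sd = vg_sd(modes, hwhm=15.0)
        table = find_peaks(sd)
        assert len(table) == 2
        ratio = table.lambda_cm1.iloc[0] / table.lambda_cm1.iloc[1]
        assert abs(ratio - 2.0) < 0.05 * 2.0

    def test_pure_tone_sd_peaks_at_tone_frequency(self):
        nu0 = 800.0
        w0 = units.ANGFREQ_PER_CM * nu0
        t = np.arange(0.0, 4000.0, 2.0)
        series = 4.5 + 0.1 * np.cos(w0 * t)
        acf = window_acf(series, 2.0, 4000.0)
        sd = acf_to_sd(acf)
        peak = find_peaks(sd, min_prominence=0.5)
        assert abs(peak.center_cm1.iloc[0] - nu0) <= 1.0


class TestAverageAcfs:
    def test_pooling_weights_by_window_count(self):
        lags = np.arange(0, 50.0, 5.0)
        a = Acf(lags=lags, values=np.ones(10), n_windows=1, window_length=45.0)
        b = Acf(lags=lags, values=np.zeros(10), n_windows=3,
                window_length=45.0)
        pooled = average_acfs([a, b])
        np.testing.assert_allclose(pooled.values, 0.25)
        assert pooled.n_windows == 4

    def test_mismatched_grids_rejected(self):
        a = Acf(lags=np.arange(0, 50.0, 5.0), values=np.ones(10),
                n_windows=1, window_length=45.0)
        b = Acf(lags=np.arange(0, 25.0, 5.0), values=np.ones(5),
                n_windows=1, window_length=20.0)
        with pytest.raises(ValueError, match="lag grid"):
            average_acfs([a, b])
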