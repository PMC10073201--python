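"""Detrending, Morlet CWT, ridge extraction and PD recovery."""

import numpy as np
import pytest

import phasekit as pk
from phasekit.wavelet import ridge_from_phases


@pytest.fixture(scope="module")
def t150():
    return np.arange(0.0, 150.0, 1.0)


class TestSincDetrend:
    def test_constant_series_maps_to_zero(self, t150):
        out = pk.sinc_detrend(np.full(len(t150), 7.3))
        assert np.abs(out).max() < 1e-9

    def test_oscillation_preserved_slope_removed(self, t150):
        osc = np.cos(2 * np.pi * t150 / 24.0)
        out = pk.sinc_detrend(osc + 0.01 * t150)
        interior = (t150 > 48) & (t150 < 102)
        resid = out[interior] - osc[interior]
        # slope removed, oscillation kept within 5% away from edges
        assert np.abs(resid).max() < 0.05
        amp = np.ptp(out[interior]) / 2
        assert amp == pytest.approx(1.0, abs=0.05)

    def test_pure_linear_trend_removed(self, t150):
        out = pk.sinc_detrend(5.0 + 0.02 * t150)
        assert np.abs(out).max() < 1e-9

    def test_zero_mean_output_on_white_noise(self, rng, t150):
        noise = rng.normal(0, 1, len(t150))
        out = pk.sinc_detrend(noise)
        assert abs(out.mean()) < 0.1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            pk.sinc_detrend(np.zeros(50))


class TestCwtSpectrum:
    def test_calibration_24h_cosine(self, t150):
        spec = pk.cwt_spectrum(np.cos(2 * np.pi * t150 / 24.0), t=t150)
        mid = len(t150) // 2
        k = np.argmax(spec.power[:, mid])
        dp = spec.periods[1] - spec.periods[0]
        assert spec.periods[k] == pytest.approx(24.0, abs=dp)
        # unit-amplitude normalisation: ridge power ≈ 1
        assert spec.power[k, mid] == pytest.approx(1.0, abs=0.05)

    def test_two_components_give_two_local_maxima(self, t150):
        x = np.cos(2 * np.pi * t150 / 24.0) + np.cos(2 * np.pi * t150 / 12.0)
        spec = pk.cwt_spectrum(x, t=t150)
        mid = len(t150) // 2
        prof = spec.power[:, mid]
        # FFT oracle: the two strongest spectral lines sit at 12 h and 24 h
        # (to the resolution of the 150 h record, one bin = 1/150 h⁻¹)
        freqs = np.fft.rfftfreq(len(t150), 1.0)
        amp = np.abs(np.fft.rfft(x))
        top = sorted(freqs[np.argsort(amp)[-2:]])
        for f_top, target in zip(top, (1 / 24.0, 1 / 12.0)):
            assert abs(f_top - target) <= 1.0 / len(t150)
        for target in (12.0, 24.0):
            k = np.argmin(np.abs(spec.periods - target))
            window = prof[max(0, k - 4): k + 5]
            assert prof[k] == pytest.approx(window.max(), rel=0.01)
            assert prof[k] > 0.5

    def test_zero_series_zero_power(self, t150):
        spec = pk.cwt_spectrum(np.zeros(len(t150)), t=t150)
        assert spec.power.max() == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            pk.cwt_spectrum(np.zeros(40), dt=1.0)


class TestExtractRidge:
    def test_chirp_ridge_period_monotone(self):
        # instantaneous period sliding 26 h -> 22 h over 150 h
        t = np.arange(0.0, 150.0, 1.0)
        inst_period = 26.0 - 4.0 * t / 150.0
        phase = np.cumsum(2 * np.pi / inst_period) - 2 * np.pi / inst_period[0]
        ridge = pk.extract_ridge(pk.cwt_spectrum(np.cos(phase), t=t))
        interior = ~ridge.in_coi
        p = ridge.period[interior]
        # decreasing trend, and tracking the generating instantaneous
        # period to within the envelope-induced smoothing (the Morlet
        # envelope spans ~one period, blurring a 4 h/150 h sweep by
        # sweep rate × envelope width ≈ 0.7 h)
        assert p[0] > p[-1] + 1.0
        assert np.abs(p - inst_period[interior]).max() < 1.0

    def test_pure_cosine_phase_advances_2pi_per_period(self, t150):
        ridge = pk.extract_ridge(
            pk.cwt_spectrum(np.cos(2 * np.pi * t150 / 24.0), t=t150))
        interior = ~ridge.in_coi
        slope = np.polyfit(t150[interior], ridge.phase[interior], 1)[0]
        assert slope == pytest.approx(2 * np.pi / 24.0, rel=0.01)

    def test_period_bounded_by_grid(self, rng, t150):
        ridge = pk.extract_ridge(
            pk.cwt_spectrum(rng.normal(0, 1, len(t150)), t=t150))
        assert ridge.period.min() >= 10.0
        assert ridge.period.max() <= 48.0


class TestPdFromRidges:
    def _ridge_pair(self, lead_h, t=None):
        if t is None:
            t = np.arange(0.0, 150.0, 1.0)
        make = lambda shift: pk.extract_ridge(pk.cwt_spectrum(
            np.cos(2 * np.pi * (t + shift) / 24.0), t=t))
        return make(lead_h), make(0.0), t

    def test_identical_ridges_give_zero(self):
        r, _, t = self._ridge_pair(0.0)
        pd_series = pk.pd_from_ridges(r, r)
        assert np.abs(pd_series.pd).max() < 1e-12

    @pytest.mark.parametrize("lead, expected", [(2.0, 2.0), (13.0, -11.0)])
    def test_lead_sign_and_wrap(self, lead, expected):
        ri, rj, t = self._ridge_pair(lead)
        pd_series = pk.pd_from_ridges(ri, rj)
        interior = (t > 48) & (t < 102)
        assert np.median(pd_series.pd[interior]) == pytest.approx(
            expected, abs=0.1)

    def test_delaying_second_trace_makes_pd_more_positive(self):
        ri, rj, t = self._ridge_pair(1.0)
        rj_delayed = self._ridge_pair(-1.0)[0]   # j peaking 1 h later
        base = np.median(pk.pd_from_ridges(ri, rj).pd[40:110])
        delayed = np.median(pk.pd_from_ridges(ri, rj_delayed).pd[40:110])
        assert delayed > base + 0.5

    def test_mismatched_grids_rejected(self):
        ri, rj, _ = self._ridge_pair(0.0)
        short = pk.WaveletRidge(t=ri.t[:-1], period=ri.period[:-1],
                                phase=ri.phase[:-1], power=ri.power[:-1])
        with pytest.raises(ValueError):
            pk.pd_from_ridges(ri, short)


class TestTimeAveragedPeriod:
    def test_constant_period_recovered(self, t150):
        ridge = pk.extract_ridge(
            pk.cwt_spectrum(np.cos(2 * np.pi * t150 / 25.7), t=t150))
        assert pk.time_averaged_period(ridge) == pytest.approx(25.7, rel=0.01)

    def test_linear_ramp_averages_to_midpoint(self):
        t = np.arange(0.0, 100.0, 1.0)
        ridge = pk.WaveletRidge(t=t, period=np.linspace(22, 26, len(t)),
                                phase=np.zeros(len(t)), power=np.ones(len(t)))
        assert pk.time_averaged_period(ridge) == pytest.approx(24.0)

    def test_uncoupled_nts_recording_within_1pct(self):
        p = pk.OscillatorParams(tau_a=25.7, tau_n=22.5, tau_v=23.4, K_an=0,
                                K_na=0, K_av=0, K_va=0, gamma=0.77)
        traj = pk.simulate(p, t_span=(0, 150))
        series = pk.make_bioluminescence(traj, pk.RecordingConfig(noise_sd=0))
        ridge = pk.extract_ridge(pk.cwt_spectrum(
            pk.sinc_detrend(series["NTS"]), t=series["t"]))
        assert pk.time_averaged_period(ridge) == pytest.approx(22.5, rel=0.01)

    def test_empty_window_rejected(self, t150):
        ridge = ridge_from_phases(t150, 2 * np.pi * t150 / 24.0)
        with pytest.raises(ValueError):
            pk.time_averaged_period(ridge, window=(500.0, 600.0))


class TestRoundTrip:
    def test_locked_simulation_periods_and_pds_recovered(self, fitted,
                                                         stable_fp):
        """simulate -> render (noise-free) -> detrend -> CWT -> ridge
        recovers instantaneous period within 1% and PDs within 0.25 h,
        one maximum analysed period excluded from each edge."""
        init = (0.0, -stable_fp.theta_an, -stable_fp.theta_av)
        traj = pk.simulate(fitted, initial_phases=init, t_span=(0, 150))
        truth = pk.phases_to_pd(traj)
        series = pk.make_bioluminescence(traj, pk.RecordingConfig(noise_sd=0))
        ridges = {}
        for region in ("AP", "NTS", "4Vep"):
            det = pk.sinc_detrend(series[region])
            ridges[region] = pk.extract_ridge(
                pk.cwt_spectrum(det, t=series["t"]))
        mask = (series["t"] >= 48.0) & (series["t"] <= 150.0 - 48.0)
        # all three oscillators locked at the collective period
        collective = 2 * np.pi / np.gradient(traj.theta_a, traj.t)
        for region in ("AP", "NTS", "4Vep"):
            rel = np.abs(ridges[region].period[mask] / collective[mask] - 1)
            assert rel.max() < 0.01
        pd_an = pk.pd_from_ridges(ridges["AP"], ridges["NTS"])
        pd_av = pk.pd_from_ridges(ridges["AP"], ridges["4Vep"])
        assert np.abs(pd_an.pd - truth.theta_an)[mask].max() < 0.25
        assert np.abs(pd_av.pd - truth.theta_av)[mask].max() < 0.25
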