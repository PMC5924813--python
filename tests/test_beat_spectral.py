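"""Spectral proxy computation: AR decomposition, bands, nu, baroreflex gain."""

import numpy as np
import pytest
from scipy.signal import periodogram

from ansmap.beat_spectral import (
    BeatSeries,
    SpectralComponent,
    alpha_index,
    band_powers,
    classify_band,
    compute_proxies,
    fit_ar_spectrum,
    normalized_units,
)
from ansmap.errors import DegenerateInputError, SeriesTooShortError
from ansmap.synthetic_cohort import SeriesConfig, generate_beat_series


class TestFitArSpectrum:
    def test_constant_series_is_degenerate(self):
        s = BeatSeries(np.full(300, 1000.0), kind="RR")
        with pytest.raises(DegenerateInputError):
            fit_ar_spectrum(s)

    def test_short_series_rejected(self):
        s = BeatSeries(np.linspace(900, 1100, 40), kind="RR")
        with pytest.raises(SeriesTooShortError):
            fit_ar_spectrum(s)

    def test_single_sinusoid_recovered(self, single_sine_tachogram):
        """Planted 0.10 cycles/beat oscillation at mean RR 1 s -> 0.10 Hz peak.

        The dominant component must sit at the periodogram peak and carry
        close to the analytic sinusoid power amp^2 / 2 = 450 ms^2.
        """
        dec = fit_ar_spectrum(single_sine_tachogram, order=12)
        dom = max(dec.components, key=lambda c: c.power)
        assert abs(dom.center_freq - 0.10) < 0.01
        assert abs(dom.power - 450.0) / 450.0 < 0.15
        # independent oracle: periodogram peak location
        x = single_sine_tachogram.values
        f, pxx = periodogram(x - x.mean(), fs=1.0 / dec.mean_interval_s)
        assert abs(f[np.argmax(pxx)] - dom.center_freq) < 0.01

    def test_two_sinusoids_classified_lf_hf(self, two_sine_tachogram):
        dec = fit_ar_spectrum(two_sine_tachogram, order=12)
        banded = {c.band: c for c in dec.components if c.band in ("LF", "HF")}
        assert set(banded) == {"LF", "HF"}
        assert abs(banded["LF"].center_freq - 0.10) < 0.01
        assert abs(banded["HF"].center_freq - 0.25) < 0.01
        # analytic sinusoid powers amp^2/2
        assert abs(banded["LF"].power - 450.0) / 450.0 < 0.15
        assert abs(banded["HF"].power - 312.5) / 312.5 < 0.15

    @pytest.mark.parametrize("order", [8, 10, 12, 16])
    def test_power_conservation(self, two_sine_tachogram, order):
        dec = fit_ar_spectrum(two_sine_tachogram, order=order)
        total = sum(c.power for c in dec.components)
        assert total == pytest.approx(dec.total_power, rel=0.01)

    def test_total_power_tracks_variance(self, two_sine_tachogram):
        dec = fit_ar_spectrum(two_sine_tachogram, order=12)
        var = two_sine_tachogram.values.var()
        assert abs(dec.total_power - var) / var < 0.05

    @pytest.mark.parametrize("f0", [0.05, 0.10, 0.25, 0.30])
    def test_planted_frequency_recovery(self, rng, f0):
        n = np.arange(300)
        x = 1000 + 30 * np.sin(2 * np.pi * f0 * n) + rng.normal(0, 5, 300)
        dec = fit_ar_spectrum(BeatSeries(x, kind="RR"), order=12)
        dom = max(dec.components, key=lambda c: c.power)
        assert abs(dom.center_freq - f0) < 0.01  # mean RR 1 s: cycles/beat == Hz

    def test_auto_order_selection(self, single_sine_tachogram):
        dec = fit_ar_spectrum(single_sine_tachogram, order="auto")
        assert 8 <= dec.ar_order <= 20
        dom = max(dec.components, key=lambda c: c.power)
        assert abs(dom.center_freq - 0.10) < 0.01

    def test_sap_series_requires_mean_interval(self, rng):
        sap = BeatSeries(120 + rng.normal(0, 2, 300), kind="SAP")
        with pytest.raises(ValueError, match="mean_interval_s"):
            fit_ar_spectrum(sap)


class TestClassifyBand:
    def _decomp(self, comps):
        from ansmap.beat_spectral import SpectrumDecomposition

        return SpectrumDecomposition(components=tuple(comps), total_power=1.0,
                                     ar_order=12, mean_interval_s=1.0)

    @pytest.mark.parametrize("freq,frac,expected", [
        (0.10, 0.4, "LF"),
        (0.25, 0.3, "HF"),
        (0.25, 0.04, "noise"),
        (0.01, 0.2, "VLF"),
        (0.45, 0.2, "unclassified"),
        (0.14, 0.10, "LF"),   # band edges inclusive
        (0.15, 0.10, "HF"),
    ])
    def test_band_rules(self, freq, frac, expected):
        c = SpectralComponent(center_freq=freq, power=frac, power_fraction=frac)
        dec = self._decomp([c])
        assert classify_band(c, dec).band == expected

    def test_total_function(self, two_sine_tachogram):
        dec = fit_ar_spectrum(two_sine_tachogram)
        assert all(c.band in ("VLF", "LF", "HF", "noise", "unclassified")
                   for c in dec.components)


class TestBandPowers:
    def _decomp(self, comps):
        from ansmap.beat_spectral import SpectrumDecomposition

        total = sum(c.power for c in comps)
        return SpectrumDecomposition(components=tuple(comps), total_power=total,
                                     ar_order=12, mean_interval_s=1.0)

    def test_weighted_center_frequency(self):
        comps = [
            SpectralComponent(0.09, 100.0, 100 / 150, band="LF"),
            SpectralComponent(0.12, 50.0, 50 / 150, band="LF"),
        ]
        bp = band_powers(self._decomp(comps))
        assert bp["LFa"] == pytest.approx(150.0)
        assert bp["LFHz"] == pytest.approx(0.10)

    def test_empty_band_flagged(self):
        comps = [SpectralComponent(0.10, 100.0, 1.0, band="LF")]
        bp = band_powers(self._decomp(comps))
        assert bp["HFa"] == 0.0
        assert np.isnan(bp["HFHz"])


class TestNormalizedUnits:
    def test_symmetric_case(self):
        nu = normalized_units({"TP": 100.0, "LFa": 40.0, "HFa": 40.0, "VLFa": 20.0})
        assert nu["LFnu"] == pytest.approx(50.0)
        assert nu["HFnu"] == pytest.approx(50.0)

    def test_zero_lf(self):
        nu = normalized_units({"TP": 100.0, "LFa": 0.0, "HFa": 40.0, "VLFa": 20.0})
        assert nu["LFnu"] == 0.0

    def test_noise_stays_in_denominator(self):
        """LF 450 + HF 450 + noise 100, no VLF: nu sum to 90 < 100."""
        nu = normalized_units({"TP": 1000.0, "LFa": 450.0, "HFa": 450.0, "VLFa": 0.0})
        assert nu["LFnu"] == pytest.approx(45.0)
        assert nu["HFnu"] == pytest.approx(45.0)

    def test_degenerate_denominator(self):
        with pytest.raises(DegenerateInputError):
            normalized_units({"TP": 10.0, "LFa": 1.0, "HFa": 1.0, "VLFa": 10.0})


class TestAlphaIndex:
    def test_arithmetic(self):
        from ansmap.beat_spectral import SpectrumDecomposition

        def dec(lf, hf):
            comps = (
                SpectralComponent(0.10, lf, 0.5, band="LF"),
                SpectralComponent(0.25, hf, 0.5, band="HF"),
            )
            return SpectrumDecomposition(comps, lf + hf, 12, 1.0)

        assert alpha_index(dec(100, 25), dec(4, 1)) == pytest.approx(5.0)
        assert alpha_index(dec(7, 7), dec(7, 7)) == pytest.approx(1.0)

    def test_planted_gain_recovery(self):
        cfg = SeriesConfig(baroreflex_gain=10.0, rr_noise_sd=3.0, seed=11)
        rr, sap = generate_beat_series(cfg)
        rr_dec = fit_ar_spectrum(rr, order=12)
        sap_dec = fit_ar_spectrum(sap, order=12, mean_interval_s=1.0)
        a = alpha_index(rr_dec, sap_dec)
        assert abs(a - 10.0) / 10.0 < 0.10

    def test_scale_equivariance(self):
        """Scaling the RR oscillation amplitudes by c scales alpha by c."""
        base = SeriesConfig(baroreflex_gain=8.0, rr_noise_sd=1.0, seed=5)
        scaled = SeriesConfig(baroreflex_gain=16.0, rr_noise_sd=2.0, seed=5)
        alphas = []
        for cfg in (base, scaled):
            rr, sap = generate_beat_series(cfg)
            alphas.append(alpha_index(
                fit_ar_spectrum(rr, order=12),
                fit_ar_spectrum(sap, order=12, mean_interval_s=1.0),
            ))
        assert alphas[1] / alphas[0] == pytest.approx(2.0, rel=0.05)

    def test_zero_sap_band_power_raises(self, rng, single_sine_tachogram):
        rr_dec = fit_ar_spectrum(single_sine_tachogram)  # has no HF component
        with pytest.raises(DegenerateInputError):
            alpha_index(rr_dec, rr_dec)


class TestComputeProxies:
    @pytest.fixture
    def subject(self):
        rest = generate_beat_series(SeriesConfig(seed=21))
        stand_cfg = SeriesConfig(mean_rr_ms=850, sap_lf_amp=4.5, sap_hf_amp=1.5, seed=22)
        rr_stand, _ = generate_beat_series(stand_cfg)
        return rest[0], rest[1], rr_stand

    def test_record_invariants(self, subject):
        rr, sap, stand = subject
        rec = compute_proxies(rr, sap, stand, cuff_sap=120, cuff_dap=80,
                              age=40, gender="M", group="Normal")
        assert rec.HR == pytest.approx(60000.0 / rec.RR_Mean, rel=1e-3)
        assert 0 <= rec.RR_LFnu <= 100 and 0 <= rec.RR_HFnu <= 100
        assert rec.RR_LF_HF == pytest.approx(rec.RR_LFa / rec.RR_HFa, rel=1e-3)
        for p in ("RR_TP", "RR_LFa", "RR_HFa", "SAP_LFa"):
            assert getattr(rec, p) >= 0
        assert np.isfinite(rec.dRRLFnu)
        assert rec.SAP == 120 and rec.DAP == 80

    def test_missing_stand_flags_delta(self, subject):
        rr, sap, _ = subject
        rec = compute_proxies(rr, sap, None, cuff_sap=120, cuff_dap=80)
        assert np.isnan(rec.dRRLFnu)

    def test_hr_from_rr_mean(self, subject):
        rr, sap, _ = subject
        rec = compute_proxies(rr, sap, None, cuff_sap=120, cuff_dap=80)
        assert rec.RR_Mean == pytest.approx(np.mean(rr.values))


class TestBeatSeriesValidation:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            BeatSeries(np.array([1000.0, -5.0, 900.0]), kind="RR")

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            BeatSeries(np.array([1000.0, np.nan]), kind="RR")
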