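"""Synthetic-data generator: quantization, ground truth, parameter recovery."""

import numpy as np
import pytest
from scipy import signal as sps

from ratqeeg import connectivity as conn
from ratqeeg import spectral as spec
from ratqeeg import synthetic_data as syn


class TestQuantize:
    def test_step_matches_hardware_resolution(self):
        # +/-500 uV at 16 bit -> 7.63 nV per count
        step_nv = syn.quantization_step(500.0, 16) * 1000.0
        assert step_nv == pytest.approx(7.63, abs=0.005)

    def test_zero_signal_gives_zero_counts(self):
        assert np.all(syn.quantize(np.zeros(100), 500.0, 16) == 0)

    def test_ramp_reconstruction_error_bounded_by_half_step(self):
        ramp = np.linspace(-499.9, 499.9, 10_001)
        step = syn.quantization_step(500.0, 16)
        back = syn.dequantize(syn.quantize(ramp, 500.0, 16), 500.0, 16)
        assert np.abs(back - ramp).max() <= step / 2 + 1e-12

    def test_clipping_at_half_range(self):
        out = syn.dequantize(syn.quantize(np.array([1000.0, -1000.0]), 500.0, 16))
        assert np.abs(out).max() <= 500.0 + 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.quantize(np.zeros(4), -1.0, 16)
        with pytest.raises(ValueError):
            syn.quantize(np.zeros(4), 500.0, 1)


class TestConfigValidation:
    def test_duration_shorter_than_schedule_rejected(self):
        cfg = syn.default_config(seed=0, duration=100.0)
        with pytest.raises(ValueError, match="epoch schedule"):
            cfg.validate()

    def test_lag_longer_than_band_period_rejected(self):
        cfg = syn.default_config(seed=0)
        cfg.coupling_spec = [syn.Coupling("F3", "T3", "alpha", 0.5, 100.0)]
        with pytest.raises(ValueError, match="ill-posed"):
            cfg.validate()

    def test_zero_lag_with_nonzero_weight_rejected(self):
        cfg = syn.default_config(seed=0)
        cfg.coupling_spec = [syn.Coupling("F3", "T3", "alpha", 0.5, 0.0)]
        with pytest.raises(ValueError, match="positive lag"):
            cfg.validate()

    def test_coupling_chains_rejected(self):
        cfg = syn.default_config(seed=0)
        cfg.coupling_spec = [
            syn.Coupling("F3", "F4", "alpha", 0.5, 8.0),
            syn.Coupling("F4", "C3", "alpha", 0.5, 8.0),
        ]
        with pytest.raises(ValueError, match="chain"):
            cfg.validate()


def _short_cfg(seed, **kw):
    base = dict(
        epoch_schedule={"baseline": (0.0, 120.0)},
        duration=120.0,
        admin_time=60.0,
    )
    base.update(kw)
    return syn.default_config(seed=seed, **base)


class TestGroundTruth:
    def test_coherences_in_unit_interval_and_powers_nonnegative(self):
        _, truth = syn.generate_recording(_short_cfg(0))
        lc = truth.lagged_coherence.coherence
        assert ((lc >= 0) & (lc <= 1)).all()
        assert (truth.band_power.power >= 0).all()

    def test_zero_coupling_means_zero_ground_truth_coherence(self):
        cfg = _short_cfg(1)
        cfg.coupling_spec = []
        cfg.global_coupling = {}
        _, truth = syn.generate_recording(cfg)
        assert (truth.lagged_coherence.coherence == 0).all()

    def test_unit_power_gain_keeps_power_constant_across_epochs(self):
        cfg = syn.default_config(
            seed=2, epoch_schedule=syn.compressed_schedule(30.0),
            duration=120.0, admin_time=30.0,
            drug_effect={"E1": syn.EpochEffect(power_gain=1.0)},
        )
        _, truth = syn.generate_recording(cfg)
        piv = truth.band_power.pivot_table(index=["channel", "band"],
                                           columns="epoch", values="power")
        assert np.allclose(piv["baseline"], piv["E1"])
        assert np.allclose(piv["baseline"], piv["E3"])

    def test_power_gain_scales_true_power(self):
        cfg = syn.default_config(
            seed=2, epoch_schedule=syn.compressed_schedule(30.0),
            duration=120.0, admin_time=30.0,
            drug_effect={"E1": syn.EpochEffect(power_gain=0.6)},
        )
        _, truth = syn.generate_recording(cfg)
        b = truth.power_of("baseline", "F3", "alpha")
        e1 = truth.power_of("E1", "F3", "alpha")
        # pink/white background does not scale, so the ratio is slightly above 0.6
        assert 0.6 < e1 / b < 0.75

    def test_same_seed_is_bit_identical(self):
        r1, _ = syn.generate_recording(_short_cfg(3))
        r2, _ = syn.generate_recording(_short_cfg(3))
        assert np.array_equal(r1.data, r2.data)


class TestParameterRecovery:
    def test_empirical_band_power_matches_truth_within_10pct(self):
        # channel-averaged band power per seed against the analytic truth
        for seed in range(20):
            rec, truth = syn.generate_recording(_short_cfg(100 + seed))
            bins = spec.power_spectrum(rec.data, rec.sfreq)
            bp = spec.band_power(bins).mean(axis=0)
            for i, band in enumerate(spec.default_bands().names):
                gt = truth.power_of("baseline", "F3", band)
                assert abs(bp[i] - gt) / gt < 0.10, (seed, band)

    def test_doubling_amplitude_quadruples_power(self):
        def cfg_with_alpha(amp):
            c = _short_cfg(7)
            c.band_amplitudes = {"alpha": amp}
            c.pink_noise_amplitude = 0.0
            c.white_noise_amplitude = 0.0
            return c

        rec1, t1 = syn.generate_recording(cfg_with_alpha(15.0))
        rec2, t2 = syn.generate_recording(cfg_with_alpha(30.0))
        g1 = t1.power_of("baseline", "F3", "alpha")
        g2 = t2.power_of("baseline", "F3", "alpha")
        assert g2 / g1 == pytest.approx(4.0, rel=1e-9)
        ai = spec.default_bands().names.index("alpha")
        e1 = spec.band_power(spec.power_spectrum(rec1.data, rec1.sfreq)).mean(0)[ai]
        e2 = spec.band_power(spec.power_spectrum(rec2.data, rec2.sfreq)).mean(0)[ai]
        assert e2 / e1 == pytest.approx(4.0, rel=0.10)
        assert e1 == pytest.approx(g1, rel=0.10)

    def test_zero_lag_shared_source_invisible_to_lagged_coherence(self):
        # instantaneous mixture built outside the generator's lag machinery
        fs, n = 250.0, int(120 * 250)
        rng = np.random.default_rng(11)
        sos = sps.butter(4, [8.0, 12.0], btype="bandpass", output="sos", fs=fs)
        shared = sps.sosfilt(sos, rng.standard_normal(n))
        a = shared + 0.5 * rng.standard_normal(n)
        b = 0.8 * shared + 0.5 * rng.standard_normal(n)
        lc = conn.lagged_coherence_matrix(np.vstack([a, b]), fs)
        assert lc[0, 1].max() <= 0.05

    def test_delayed_shared_source_matches_independent_oracle(self):
        """Estimator and GroundTruth both match a test-local closed form.

        The oracle below rebuilds the cross-spectrum of the delayed
        shared-source model from the Butterworth transfer functions,
        independently of the generator's own ground-truth code.
        """
        fs = 250.0
        w, lag_ms, band = 0.8, 12.0, "alpha"
        cfg = _short_cfg(13)
        cfg.coupling_spec = [syn.Coupling("F3", "T3", band, w, lag_ms)]
        cfg.global_coupling = {}
        rec, truth = syn.generate_recording(cfg)

        freqs = np.linspace(0.0, fs / 2, 8192)
        scheme = spec.default_bands()
        psd = {}
        for name, lo, hi in scheme.bands:
            sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos", fs=fs)
            _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
            shape = np.abs(h) ** 2
            amp = cfg.band_amplitudes[name]
            psd[name] = amp**2 * shape / np.mean(shape) * (2.0 / fs)
        fpink = np.maximum(freqs, 1.0)
        pshape = 1.0 / fpink
        pshape[freqs == 0] = 0.0
        psd_pink = cfg.pink_noise_amplitude**2 * pshape / np.mean(pshape) * (2 / fs)
        total = sum(psd.values()) + psd_pink + cfg.white_noise_amplitude**2 * 2 / fs
        tau = round(lag_ms / 1000 * fs) / fs
        sxy = w * psd[band] * np.exp(-2j * np.pi * freqs * tau)
        # integrate per 1-Hz analysis bin exactly as the estimator does
        lcs, wts = [], []
        for f0 in scheme.bins_of(band):
            sel = (freqs >= f0 - 0.25) & (freqs < f0 + 0.75)
            sx = total[sel].sum()
            sxyi = sxy[sel].sum()
            lcs.append(sxyi.imag**2 / (sx * sx - sxyi.real**2))
            wts.append(sx)
        oracle = float(np.average(lcs, weights=wts))

        est = conn.lagged_coherence_matrix(rec.data, fs)[0, 8,
                                                         scheme.names.index(band)]
        gt = truth.coherence_of("baseline", ("F3", "T3"), band)
        assert abs(gt - oracle) < 0.01
        assert abs(est - oracle) < 0.05
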