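"""FIR filtering, epoch extraction, reliability, and segment selection."""

import numpy as np
import pytest

from ratqeeg import preprocess as pre
from ratqeeg import synthetic_data as syn
from ratqeeg.signal_io import Marker, Recording, StudyManifest


def _recording(layout, data, markers=(), admin=None):
    return Recording(data=data, sfreq=250.0, layout=layout,
                     markers=list(markers), admin_time=admin)


class TestBandpassFir:
    def test_passband_tone_amplitude_preserved(self, layout):
        t = np.arange(250 * 10) / 250.0
        tone = np.sin(2 * np.pi * 10.0 * t)
        rec = _recording(layout, np.tile(tone, (12, 1)))
        out = pre.bandpass_fir(rec)
        mid = out.data[0, 500:-500]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_attenuated_as_designed(self, layout):
        # oracle: the designed filter's own frequency response at 60 Hz
        _, h60 = pre.fir_response(freqs=[60.0])
        t = np.arange(250 * 10) / 250.0
        tone = np.sin(2 * np.pi * 60.0 * t)
        rec = _recording(layout, np.tile(tone, (12, 1)))
        out = pre.bandpass_fir(rec)
        mid = np.abs(out.data[0, 500:-500]).max()
        assert mid <= float(h60[0]) * 1.05

    def test_dc_offset_suppressed(self, layout):
        rec = _recording(layout, np.full((12, 2500), 100.0))
        out = pre.bandpass_fir(rec)
        assert abs(out.data[0, 500:-500].mean()) < 1.0

    def test_even_tap_count_rejected(self, layout):
        rec = _recording(layout, np.zeros((12, 2500)))
        with pytest.raises(ValueError, match="odd"):
            pre.bandpass_fir(rec, n_taps=110)

    def test_zero_net_shift(self, layout):
        # a bandpassed impulse stays centred on its original sample
        x = np.zeros((12, 2501))
        x[:, 1250] = 1.0
        rec = _recording(layout, x)
        out = pre.bandpass_fir(rec)
        assert np.argmax(np.abs(out.data[0])) == 1250


class TestExtractEpochs:
    def test_post_windows_measured_from_administration(self, layout):
        man = StudyManifest()
        rec = _recording(layout, np.zeros((12, 250 * 5400)), admin=600.0)
        eps = pre.extract_epochs(rec, man)
        assert eps["E1"].duration == 600.0
        # E1 spans [1800, 2400] absolute: markers re-referenced to slice start
        rec2 = _recording(layout, np.zeros((12, 250 * 5400)),
                          markers=[Marker(1800.0, 1810.0, "active")], admin=600.0)
        eps2 = pre.extract_epochs(rec2, man)
        m = eps2["E1"].markers[0]
        assert (m.start, m.end) == (0.0, 10.0)

    def test_all_four_epochs_present_on_full_recording(self, layout):
        man = StudyManifest()
        rec = _recording(layout, np.zeros((12, 250 * 6000)), admin=600.0)
        eps = pre.extract_epochs(rec, man)
        assert all(eps[n] is not None for n in ("baseline", "E1", "E2", "E3"))

    def test_short_recording_flags_late_epochs_missing(self, layout):
        man = StudyManifest()
        rec = _recording(layout, np.zeros((12, 250 * 3600)), admin=600.0)
        eps = pre.extract_epochs(rec, man)
        assert eps["E1"] is not None
        assert eps["E2"] is None and eps["E3"] is None

    def test_missing_admin_time_is_an_error(self, layout):
        rec = _recording(layout, np.zeros((12, 250 * 100)))
        with pytest.raises(ValueError, match="administration"):
            pre.extract_epochs(rec, StudyManifest())


class TestReliability:
    def test_identical_halves_give_unity(self):
        block = np.random.default_rng(0).normal(size=(4, 250))
        blocks = np.vstack([block, block])
        sh, tr = pre.reliability(blocks)
        assert tr == pytest.approx(1.0)

    def test_tenfold_amplitude_jump_fails_test_retest(self, rng):
        first = rng.normal(size=(30, 250))
        second = 10.0 * rng.normal(size=(30, 250))
        sh, tr = pre.reliability(np.vstack([first, second]))
        # closed form: 1 - |1 - 100| / (1 + 100)
        assert tr == pytest.approx(1.0 - 99.0 / 101.0, abs=0.02)
        assert tr < 0.9

    def test_stationary_noise_passes_both_criteria(self, rng):
        failures = 0
        for _ in range(200):
            sh, tr = pre.reliability(rng.normal(size=(120, 50)))
            failures += (sh < 0.9) or (tr < 0.9)
        assert failures / 200 < 0.01

    def test_all_zero_signal_is_degenerate_unity(self):
        sh, tr = pre.reliability(np.zeros((10, 250)))
        assert sh == 1.0 and tr == 1.0

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError, match="4"):
            pre.reliability(np.zeros((3, 250)))


def _clean_epoch(seed, duration=600.0):
    cfg = syn.default_config(
        seed=seed, epoch_schedule={"baseline": (0.0, duration)},
        duration=duration, admin_time=duration / 2,
    )
    rec, _ = syn.generate_recording(cfg)
    return rec


class TestSelectSegments:
    def test_clean_ten_minute_epoch_yields_two_minutes(self):
        segs = pre.select_segments(_clean_epoch(1), pre.SelectionCriteria())
        assert segs.accepted
        assert segs.total_s == 120.0

    def test_artifact_laden_epoch_rejected_below_30s(self):
        rec = _clean_epoch(2, duration=120.0)
        rms = rec.data.std()
        for s in range(20, 120):  # only the first 20 s stay clean
            rec.data[:, s * 250:(s + 1) * 250] += 10.0 * rms
        segs = pre.select_segments(rec, pre.SelectionCriteria())
        assert not segs.accepted
        assert segs.total_s < 30.0
        assert "30" in segs.reason

    def test_no_inactivity_is_rejected_with_reason(self):
        rec = _clean_epoch(3, duration=60.0)
        rec.markers = [Marker(0.0, 60.0, "active")]
        segs = pre.select_segments(rec, pre.SelectionCriteria())
        assert not segs.accepted
        assert "inactivity" in segs.reason

    def test_selection_never_intersects_excluded_intervals(self):
        rec = _clean_epoch(4, duration=300.0)
        rec.markers = [Marker(50.0, 70.0, "active"), Marker(150.0, 160.0, "handling"),
                       Marker(200.0, 210.0, "sleep_suspect")]
        segs = pre.select_segments(rec, pre.SelectionCriteria())
        assert segs.accepted
        for a, b in segs.segments:
            for m in rec.markers:
                assert b <= m.start or a >= m.end

    def test_selection_is_deterministic(self):
        s1 = pre.select_segments(_clean_epoch(5), pre.SelectionCriteria())
        s2 = pre.select_segments(_clean_epoch(5), pre.SelectionCriteria())
        assert s1.segments == s2.segments

    @pytest.mark.parametrize("seed", range(5))
    def test_accepted_set_monotone_in_amplitude_factor(self, seed):
        rec = _clean_epoch(50 + seed, duration=200.0)

        def accepted_seconds(factor):
            crit = pre.SelectionCriteria(amplitude_factor=factor,
                                         target_total_s=1e9)
            segs = pre.select_segments(rec, crit)
            out = set()
            for a, b in segs.segments:
                out.update(range(int(a), int(b)))
            return out

        loose = accepted_seconds(1.25)
        strict = accepted_seconds(1.10)
        assert strict <= loose
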