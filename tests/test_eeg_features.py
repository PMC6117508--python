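import numpy as np
import pytest

import neurofuse as nf
from neurofuse import eeg_features as ef
from neurofuse.errors import ContractError


def make_eeg(signals, srate=100.0, labels=None, events=(), bad_blocks=()):
    signals = np.atleast_2d(signals)
    labels = labels or [f"ch{i}" for i in range(signals.shape[0])]
    return nf.EEGRecording(signals, srate, labels,
                           events=nf.EventTable(list(events)),
                           bad_blocks=list(bad_blocks))


class TestRereference:
    def test_average_reference_zero_mean(self, rng):
        eeg = make_eeg(rng.standard_normal((5, 500)))
        out = ef.rereference(eeg, "average")
        assert np.abs(out.signals.mean(axis=0)).max() < 1e-10
        assert out.reference == "average"

    def test_single_channel_reference_zeroes_it(self, rng):
        eeg = make_eeg(rng.standard_normal((4, 200)),
                       labels=["Fp1", "Cz", "O1", "O2"])
        out = ef.rereference(eeg, "channels", ["Cz"])
        assert np.abs(out.signals[1]).max() < 1e-12

    def test_linked_mastoids_mean_zero(self, rng):
        eeg = make_eeg(rng.standard_normal((4, 200)),
                       labels=["M1", "M2", "C3", "C4"])
        out = ef.rereference(eeg, "channels", ["M1", "M2"])
        assert np.abs((out.signals[0] + out.signals[1]) / 2).max() < 1e-12

    def test_idempotent_and_offset_invariant(self, rng):
        eeg = make_eeg(rng.standard_normal((4, 300)))
        once = ef.rereference(eeg, "average")
        twice = ef.rereference(once, "average")
        assert np.allclose(once.signals, twice.signals, atol=1e-12)
        shifted = make_eeg(eeg.signals + 42.0)
        assert np.allclose(ef.rereference(shifted, "average").signals,
                           once.signals, atol=1e-10)

    def test_unknown_channel_lists_labels(self, rng):
        eeg = make_eeg(rng.standard_normal((2, 100)), labels=["a", "b"])
        with pytest.raises(ContractError, match="'a'"):
            ef.rereference(eeg, "channels", ["zz"])


class TestFilterEEG:
    srate = 250.0

    def _tone(self, freq, duration=16.0):
        t = np.arange(int(duration * self.srate)) / self.srate
        return np.sin(2 * np.pi * freq * t)

    def test_passband_tone_preserved(self):
        x = self._tone(10.0)
        eeg = make_eeg(x, srate=self.srate)
        mid = slice(500, -500)  # away from filtfilt edge transients
        fir = ef.filter_eeg(eeg, 1.0, 30.0, "fir").signals[0]
        assert abs(np.abs(fir[mid]).max() / np.abs(x[mid]).max() - 1) < 0.01
        fft = ef.filter_eeg(eeg, 1.0, 30.0, "fft").signals[0]
        assert np.abs(fft - x).max() < 1e-6  # exact-bin tone is untouched

    def test_stopband_tone_attenuated(self):
        eeg = make_eeg(self._tone(50.0), srate=self.srate)
        mid = slice(500, -500)
        fir = ef.filter_eeg(eeg, 1.0, 30.0, "fir").signals[0]
        assert np.abs(fir[mid]).max() < 10 ** (-40 / 20)  # > 40 dB down
        fft = ef.filter_eeg(eeg, 1.0, 30.0, "fft").signals[0]
        assert np.abs(fft).max() < 1e-6

    def test_methods_agree_on_broadband_noise(self, rng):
        eeg = make_eeg(rng.standard_normal(5000), srate=self.srate)
        fir = ef.filter_eeg(eeg, 1.0, 30.0, "fir").signals[0]
        fft = ef.filter_eeg(eeg, 1.0, 30.0, "fft").signals[0]
        mid = slice(500, -500)
        assert np.corrcoef(fir[mid], fft[mid])[0, 1] > 0.99

    def test_filter_commutes_with_channel_selection(self, rng):
        eeg = make_eeg(rng.standard_normal((4, 3000)), srate=self.srate)
        full = ef.filter_eeg(eeg, 1.0, 30.0, "fft").signals[2]
        single = make_eeg(eeg.signals[2], srate=self.srate)
        alone = ef.filter_eeg(single, 1.0, 30.0, "fft").signals[0]
        assert np.allclose(full, alone, atol=1e-10)

    def test_band_outside_nyquist_rejected(self, rng):
        eeg = make_eeg(rng.standard_normal(1000), srate=self.srate)
        with pytest.raises(ContractError):
            ef.filter_eeg(eeg, 1.0, 200.0)

    def test_events_untouched(self, rng):
        eeg = make_eeg(rng.standard_normal(2000), srate=self.srate,
                       events=[(1.5, 0, "GSWD")])
        out = ef.filter_eeg(eeg, 1.0, 30.0, "fft")
        assert out.events == eeg.events


class TestEditEvents:
    def test_add_then_delete_restores(self, rng):
        eeg = make_eeg(rng.standard_normal(2000), srate=100,
                       events=[(1.0, 0, "A")])
        added = ef.edit_events(eeg, add=[(12.5, 0, "1001")])
        assert (12.5, 0.0, "1001") in added.events.rows()
        back = ef.edit_events(added, delete=[1])
        assert back.events == eeg.events

    def test_out_of_order_adds_stored_sorted(self, rng):
        eeg = make_eeg(rng.standard_normal(2000), srate=100)
        out = ef.edit_events(eeg, add=[(9.0, 0, "b"), (3.0, 0, "a")])
        assert list(out.events.onsets) == [3.0, 9.0]

    def test_bad_delete_index(self, rng):
        eeg = make_eeg(rng.standard_normal(100), srate=100)
        with pytest.raises(ContractError):
            ef.edit_events(eeg, delete=[0])


class TestExtractOnsets:
    def test_bad_block_exclusion(self, rng):
        eeg = make_eeg(rng.standard_normal(4000), srate=100,
                       events=[(10, 0, "GSWD"), (20, 0, "GSWD"),
                               (30, 0, "GSWD")],
                       bad_blocks=[(15.0, 25.0)])
        feat = ef.extract_onsets(eeg, ["GSWD"])
        assert list(feat.times_s) == [10.0, 30.0]
        assert np.all(feat.values == 1.0)
        kept = ef.extract_onsets(eeg, ["GSWD"], exclude_bad=False)
        assert list(kept.times_s) == [10.0, 20.0, 30.0]

    def test_no_match_gives_empty(self, rng):
        eeg = make_eeg(rng.standard_normal(100), srate=100,
                       events=[(0.5, 0, "other")])
        assert len(ef.extract_onsets(eeg, ["GSWD"])) == 0

    def test_matches_bruteforce_interval_scan(self, rng):
        onsets = np.sort(rng.uniform(0, 60, 40))
        blocks = [(5.0, 9.0), (20.0, 21.5), (50.0, 59.0)]
        eeg = make_eeg(rng.standard_normal(6000), srate=100,
                       events=[(float(t), 0, "E") for t in onsets],
                       bad_blocks=blocks)
        feat = ef.extract_onsets(eeg, ["E"])
        expected = sorted(
            t for t in onsets
            if not any(lo <= t < hi for lo, hi in blocks)
        )
        assert np.allclose(feat.times_s, expected)


class TestBandPower:
    def test_sinusoid_closed_form(self):
        srate, L = 200.0, 400
        A = 12.0
        t = np.arange(4 * L) / srate
        eeg = make_eeg(A * np.sin(2 * np.pi * 10.0 * t), srate=srate)
        feat = ef.extract_band_power(eeg, (8, 12), window_s=L / srate)
        assert np.allclose(feat.values, A**2 * L / 2, rtol=1e-6)

    def test_zero_signal_zero_power(self):
        eeg = make_eeg(np.zeros(1000), srate=100)
        feat = ef.extract_band_power(eeg, (8, 12), window_s=1.0)
        assert np.all(feat.values == 0)

    def test_tr_locked_count_matches_volumes(self, rng):
        tr, n_vols = 2.0, 30
        eeg = make_eeg(rng.standard_normal(int(100 * tr * n_vols)),
                       srate=100)
        feat = ef.extract_band_power(eeg, (8, 12), window_s=tr, step_s=tr)
        assert len(feat) == n_vols
        assert feat.tr_locked

    def test_band_partition_sums_to_total_power(self, rng):
        srate = 128.0
        eeg = make_eeg(rng.standard_normal(1024), srate=srate)
        window = 512 / srate
        bands = [(0.125, 16.0), (16.0, 32.0), (32.0, 64.0)]
        parts = []
        for lo, hi in bands:
            f = ef.extract_band_power(eeg, (lo, hi), window_s=window,
                                      step_s=window)
            parts.append(f.values)
        # sum over the partition = total one-sided power above DC
        seg0 = eeg.signals[0, :512]
        seg1 = eeg.signals[0, 512:]
        for i, seg in enumerate((seg0, seg1)):
            freqs, p = ef.band_power_spectrum(seg, srate)
            # shared edges are counted once per band with inclusive bounds,
            # so subtract the doubly counted edge bins
            total = sum(parts[j][i] for j in range(3))
            edge_bins = p[np.isin(freqs, [16.0, 32.0])].sum()
            assert total - edge_bins == pytest.approx(p[1:].sum(), rel=1e-8)

    def test_bad_block_window_flagged_missing(self, rng):
        eeg = make_eeg(rng.standard_normal(1000), srate=100,
                       bad_blocks=[(3.0, 4.0)])
        feat = ef.extract_band_power(eeg, (8, 12), window_s=1.0, step_s=1.0)
        assert np.isnan(feat.values[3])
        assert np.isfinite(feat.values[0])

    def test_empty_band_reports_resolution(self, rng):
        eeg = make_eeg(rng.standard_normal(1000), srate=100)
        with pytest.raises(ContractError, match="resolution"):
            ef.extract_band_power(eeg, (10.01, 10.02), window_s=1.0)

    def test_power_nonnegative(self, rng):
        eeg = make_eeg(rng.standard_normal((3, 2000)), srate=100)
        feat = ef.extract_band_power(eeg, (1, 40), window_s=2.0)
        assert np.all(feat.values >= 0)


class TestERPAmplitudes:
    srate = 500.0

    def _eeg_with_peaks(self, n_events=5, amp=10.0, noise=0.0, rng=None):
        S = int(self.srate * 30)
        sig = (rng.standard_normal(S) * noise if rng is not None and noise
               else np.zeros(S))
        events = []
        for k in range(n_events):
            onset = 3.0 + 4.0 * k
            i = int((onset + 0.3) * self.srate)  # peak at +300 ms
            sig[i] += amp
            events.append((onset, 0.0, "P300"))
        return make_eeg(sig, srate=self.srate, events=events)

    def test_planted_peak_recovered(self, rng):
        eeg = self._eeg_with_peaks(amp=10.0)
        feat = ef.extract_erp_amplitudes(
            eeg, "P300", epoch_window_s=(-0.2, 0.8),
            measure_window_s=(0.25, 0.35), channel="ch0", mode="peak")
        assert np.allclose(feat.values, 10.0, atol=1e-9)

    def test_constant_channel_mean_mode_zero(self):
        eeg = make_eeg(np.full(5000, 3.3), srate=self.srate,
                       events=[(2.0, 0, "P300"), (5.0, 0, "P300")])
        feat = ef.extract_erp_amplitudes(eeg, "P300", channel="ch0",
                                         mode="mean")
        assert np.allclose(feat.values, 0.0, atol=1e-12)

    def test_event_accounting_with_drops(self, rng):
        eeg = self._eeg_with_peaks(n_events=5)
        eeg = ef.edit_events(eeg, add=[(29.9, 0, "P300")])  # epoch runs off
        eeg.bad_blocks.append((6.8, 7.2))  # swallows the 7 s event
        with pytest.warns(UserWarning, match="dropped"):
            feat = ef.extract_erp_amplitudes(eeg, "P300", channel="ch0",
                                             mode="peak")
        assert len(feat) == 6 - 1 - 1

    def test_component_series_as_virtual_channel(self, rng):
        eeg = self._eeg_with_peaks(amp=5.0)
        component = eeg.signals[0] * 2.0  # e.g. an ICA component
        feat = ef.extract_erp_amplitudes(eeg, "P300", channel=component,
                                         mode="peak")
        assert np.allclose(feat.values, 10.0, atol=1e-9)
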