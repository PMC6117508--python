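"""EEG conditioning and fusion-feature extraction.

Conditioning covers offline re-referencing (average or a chosen channel
set), zero-phase band filtering (windowed-sinc FIR with an FFT brick-wall
alternative) and programmatic event editing.  Features destined for
EEG-informed fMRI analysis are event onsets, windowed spectral band power
and event-related potential (ERP) amplitudes; each can be locked to the
fMRI TR grid, and features falling inside marked bad blocks are excluded
without shifting absolute time.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ContractError
from .io import EEGRecording, EventTable

__all__ = [
    "FeatureSeries",
    "rereference",
    "filter_eeg",
    "edit_events",
    "extract_onsets",
    "band_power_spectrum",
    "extract_band_power",
    "extract_erp_amplitudes",
]


@dataclass
class FeatureSeries:
    """A time-stamped EEG feature series on the recording's clock.

    ``kind`` is one of onsets / power / amplitude.  Onsets carry unit
    values.  ``values`` may contain NaN where a window or epoch was
    invalidated by a bad block (the flag, not a measurement of zero).
    """

    kind: str
    times_s: np.ndarray
    values: np.ndarray
    tr_locked: bool = False
    band_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in ("onsets", "power", "amplitude"):
            raise ContractError(f"unknown feature kind {self.kind!r}")
        if self.times_s.shape != self.values.shape:
            raise ContractError("times and values must align")
        if np.any(np.diff(self.times_s) < 0):
            raise ContractError("feature times must be sorted")
        if self.kind == "onsets" and not np.all(self.values == 1.0):
            raise ContractError("onset features carry unit values")

    def __len__(self) -> int:
        return self.times_s.size


def _in_bad_block(t: float, bad_blocks) -> bool:
    return any(start <= t < end for start, end in bad_blocks)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------


def rereference(eeg: EEGRecording, mode="average",
                channels: list[str] | None = None) -> EEGRecording:
    """Re-express all channels against a new reference.

    ``mode='average'`` subtracts the per-sample mean over all channels;
    ``mode='channels'`` subtracts the mean of the listed channels (a single
    channel being the usual case, e.g. Cz).
    """
    if mode == "average":
        ref = eeg.signals.mean(axis=0)
        tag = "average"
    elif mode == "channels":
        if not channels:
            raise ContractError("mode='channels' needs a non-empty channel list")
        idx = [eeg.channel_index(c) for c in channels]
        ref = eeg.signals[idx].mean(axis=0)
        tag = "channels:" + ",".join(channels)
    else:
        raise ContractError(f"unknown re-reference mode {mode!r}")
    return dataclasses.replace(eeg, signals=eeg.signals - ref, reference=tag)


def _fir_taps(low_hz: float, high_hz: float, srate: float) -> np.ndarray:
    nyq = srate / 2.0
    lowcut = low_hz > 0
    highcut = high_hz < nyq
    edge = low_hz if lowcut else high_hz
    numtaps = int(round(3.0 * srate / edge))
    numtaps += 1 - numtaps % 2  # zero-phase filtering needs odd length
    numtaps = max(numtaps, 11)
    if lowcut and highcut:
        return sps.firwin(numtaps, [low_hz, high_hz], fs=srate, pass_zero=False)
    if lowcut:
        return sps.firwin(numtaps, low_hz, fs=srate, pass_zero=False)
    return sps.firwin(numtaps, high_hz, fs=srate, pass_zero=True)


def filter_eeg(eeg: EEGRecording, low_hz: float, high_hz: float,
               method: str = "fir") -> EEGRecording:
    """Zero-phase band filtering of every channel.

    ``low_hz = 0`` gives a low-pass, ``high_hz = Nyquist`` a high-pass.
    ``method='fir'`` applies a windowed-sinc filter forward and backward;
    ``method='fft'`` zeroes Fourier coefficients outside the band (an ideal
    response, at the price of edge ringing).  Events and bad blocks are
    untouched.
    """
    nyq = eeg.srate_hz / 2.0
    if not 0 <= low_hz < high_hz <= nyq + 1e-9:
        raise ContractError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyq} Hz"
        )
    if low_hz == 0 and high_hz >= nyq:
        return dataclasses.replace(eeg, signals=eeg.signals.copy())
    if method == "fir":
        taps = _fir_taps(low_hz, high_hz, eeg.srate_hz)
        if eeg.n_samples <= 3 * len(taps):
            raise ContractError(
                f"recording too short for FIR of length {len(taps)}; "
                "use method='fft'"
            )
        out = sps.filtfilt(taps, [1.0], eeg.signals, axis=1)
    elif method == "fft":
        freqs = np.fft.rfftfreq(eeg.n_samples, d=1.0 / eeg.srate_hz)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        coef = np.fft.rfft(eeg.signals, axis=1)
        coef *= keep[None, :]
        out = np.fft.irfft(coef, n=eeg.n_samples, axis=1)
    else:
        raise ContractError(f"unknown filter method {method!r}")
    return dataclasses.replace(eeg, signals=out)


def edit_events(eeg: EEGRecording, add=None, delete=None) -> EEGRecording:
    """Add rows to / delete rows from the event table (kept onset-sorted)."""
    rows = eeg.events.rows()
    if delete:
        n = len(rows)
        for i in delete:
            if not 0 <= i < n:
                raise ContractError(f"delete index {i} out of range 0..{n - 1}")
        keep = set(range(n)) - set(delete)
        rows = [rows[i] for i in sorted(keep)]
    if add:
        rows.extend(tuple(r) for r in add)
    return dataclasses.replace(eeg, events=EventTable(rows))


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def extract_onsets(eeg: EEGRecording, event_types,
                   exclude_bad: bool = True) -> FeatureSeries:
    """Onset times of matching events, optionally dropping bad-block hits."""
    selected = eeg.events.select(event_types)
    onsets = [
        t for t in selected.onsets
        if not (exclude_bad and _in_bad_block(t, eeg.bad_blocks))
    ]
    onsets = np.asarray(sorted(onsets), dtype=float)
    return FeatureSeries("onsets", onsets, np.ones_like(onsets))


def band_power_spectrum(segment: np.ndarray, srate: float):
    """One-sided DFT power of a segment: p_k = 2|Y_k|^2 / L.

    The DC bin is |Y_0|^2 / L and, for even L, the Nyquist bin is also
    undoubled, so the bins sum to the segment's total power sum(x^2).
    """
    x = np.asarray(segment, dtype=np.float64)
    L = x.size
    Y = np.fft.rfft(x)
    p = 2.0 * np.abs(Y) ** 2 / L
    p[0] /= 2.0
    if L % 2 == 0:
        p[-1] /= 2.0
    freqs = np.fft.rfftfreq(L, d=1.0 / srate)
    return freqs, p


def extract_band_power(eeg: EEGRecording, band_hz, channels=None,
                       window_s: float = 2.0,
                       step_s: float | None = None) -> FeatureSeries:
    """Windowed spectral power within a frequency band.

    Each window of L samples contributes the sum of one-sided DFT bin
    powers ``2|Y_k|^2/L`` whose frequency lies in ``band_hz``, averaged
    over the selected channels.  Windows overlapping a bad block are
    returned as NaN (flagged missing, not zero).  ``window_s = step_s = TR``
    produces a TR-locked series ready for regressor building.
    """
    low, high = float(band_hz[0]), float(band_hz[1])
    nyq = eeg.srate_hz / 2.0
    if not 0 <= low < high <= nyq + 1e-9:
        raise ContractError(f"band [{low}, {high}] Hz outside (0, {nyq}] Hz")
    if step_s is None:
        step_s = window_s
    L = int(round(window_s * eeg.srate_hz))
    step = int(round(step_s * eeg.srate_hz))
    if L < 2 or L > eeg.n_samples:
        raise ContractError(f"window of {L} samples does not fit the recording")
    freqs = np.fft.rfftfreq(L, d=1.0 / eeg.srate_hz)
    in_band = (freqs >= low - 1e-9) & (freqs <= high + 1e-9)
    if not in_band.any():
        raise ContractError(
            f"band [{low}, {high}] Hz contains no DFT bin at resolution "
            f"{eeg.srate_hz / L:.6g} Hz; widen the band or the window"
        )
    if channels is None:
        idx = list(range(eeg.n_channels))
    else:
        idx = [eeg.channel_index(c) for c in channels]
    times, values = [], []
    for start in range(0, eeg.n_samples - L + 1, step):
        t0 = start / eeg.srate_hz
        t1 = (start + L) / eeg.srate_hz
        times.append(t0)
        if any(t0 < end and start_b < t1 for start_b, end in eeg.bad_blocks):
            values.append(np.nan)
            continue
        seg = eeg.signals[idx, start:start + L]
        Y = np.fft.rfft(seg, axis=1)
        p = 2.0 * np.abs(Y) ** 2 / L
        p[:, 0] /= 2.0
        if L % 2 == 0:
            p[:, -1] /= 2.0
        values.append(p[:, in_band].sum(axis=1).mean())
    return FeatureSeries("power", np.asarray(times), np.asarray(values),
                         tr_locked=(step_s == window_s), band_hz=(low, high))


def extract_erp_amplitudes(eeg: EEGRecording, event_type: str,
                           epoch_window_s=(-0.2, 0.8),
                           measure_window_s=(0.25, 0.35),
                           channel: str | np.ndarray = None,
                           mode: str = "mean",
                           baseline_s=(-0.2, 0.0),
                           exclude_bad: bool = True) -> FeatureSeries:
    """Per-event ERP amplitude on one channel (or a supplied component).

    Each epoch is baseline-corrected by the mean over ``baseline_s`` and
    summarized within ``measure_window_s`` as the mean or the signed
    extremum (``mode='peak'``).  ``channel`` may be a label or a
    precomputed 1-D component series (e.g. an ICA component) acting as a
    virtual channel.  Epochs extending outside the recording are dropped
    with a warning; events inside bad blocks are dropped when requested.
    """
    if mode not in ("mean", "peak"):
        raise ContractError(f"mode must be 'mean' or 'peak', got {mode!r}")
    e0, e1 = map(float, epoch_window_s)
    m0, m1 = map(float, measure_window_s)
    b0, b1 = map(float, baseline_s)
    if not (e0 <= m0 < m1 <= e1 and e0 <= b0 < b1 <= e1):
        raise ContractError("measure and baseline windows must lie in the epoch")
    if isinstance(channel, str):
        series = eeg.signals[eeg.channel_index(channel)]
    elif channel is None:
        series = eeg.signals[0]
    else:
        series = np.asarray(channel, dtype=np.float64)
        if series.ndim != 1 or series.size != eeg.n_samples:
            raise ContractError("component series must match the recording length")
    sr = eeg.srate_hz
    times, values = [], []
    n_dropped = 0
    for onset in eeg.events.select([event_type]).onsets:
        if exclude_bad and _in_bad_block(onset, eeg.bad_blocks):
            continue
        i0 = int(round((onset + e0) * sr))
        i1 = int(round((onset + e1) * sr))
        if i0 < 0 or i1 > series.size:
            n_dropped += 1
            continue
        epoch = series[i0:i1]
        rel = lambda t: int(round((t - e0) * sr))  # noqa: E731
        baseline = epoch[rel(b0):rel(b1)].mean()
        seg = epoch[rel(m0):rel(m1)] - baseline
        if mode == "mean":
            amp = seg.mean()
        else:
            amp = seg[np.argmax(np.abs(seg))]  # signed extremum
        times.append(float(onset))
        values.append(float(amp))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} events dropped: epoch extends outside the recording",
            stacklevel=2,
        )
    return FeatureSeries("amplitude", np.asarray(times), np.asarray(values))
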