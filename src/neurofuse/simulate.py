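"""Seeded synthetic-data generators with ground truth.

Every pipeline input has a generator here: 4-D BOLD volumes with AR(1)
temporal noise, spatially clustered "hub" voxels sharing a latent series at
a target correlation, and event-locked activations built as onset impulses
convolved with a single-gamma HRF of known peak latency; smooth rigid-body
motion series; and multichannel EEG with background noise, band-limited
oscillations and biphasic spike-like events whose true onsets ride along
in the event table.  All randomness flows through ``numpy.random.default_rng``
(PCG64) so a seed pins the outputs bit-for-bit.

These generators emulate the statistical structure the measures respond to
— correlation, local smoothness, hemodynamic delay — not biophysics: there
is no neural-mass model, no draining-vein geometry and no MR artifact
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .io import BrainMask, EEGRecording, EventTable, MotionParams, Volume4D
from .regressors import hrf_kernel

__all__ = ["SimTruth", "simulate_bold", "simulate_motion", "simulate_eeg",
           "default_spike_template"]

GRAND_MEAN_OFFSET = 1000.0  # keeps auto-masking and grand-mean scaling realistic
DEFAULT_AR1 = 0.3


@dataclass
class SimTruth:
    """Ground truth of a simulated BOLD run."""

    seed: int
    hub_voxels: list[np.ndarray] = field(default_factory=list)
    hub_target_r: list[float] = field(default_factory=list)
    activation_voxels: np.ndarray | None = None
    true_peak_s: float | None = None
    true_beta: float = 0.0
    event_onsets_s: np.ndarray | None = None
    ar1_coef: float = DEFAULT_AR1
    noise_sigma: float = 1.0


def _ar1_noise(rng: np.random.Generator, shape, T: int, coef: float,
               sigma: float) -> np.ndarray:
    white = rng.standard_normal(shape + (T,))
    out = np.empty_like(white)
    out[..., 0] = white[..., 0]
    for t in range(1, T):
        out[..., t] = coef * out[..., t - 1] + white[..., t]
    # stationary marginal variance of AR(1) is sigma^2/(1-coef^2); rescale
    return out * (sigma * np.sqrt(1.0 - coef**2))


def simulate_bold(shape=(8, 8, 8), T: int = 120, tr: float = 2.0,
                  seed: int = 0, hub_voxels=None, hub_target_r: float = 0.6,
                  activation_voxels=None, true_peak_s: float = 5.0,
                  true_beta: float = 0.0, event_onsets_s=None,
                  ar1_coef: float = DEFAULT_AR1, noise_sigma: float = 1.0,
                  ) -> tuple[Volume4D, BrainMask, SimTruth]:
    """Simulate a BOLD run with optional hubs and event-locked activation.

    ``hub_voxels`` is a list of voxel-index arrays; each hub shares one
    latent series mixed so member pairs correlate near ``hub_target_r``
    (mixing weight = target r, since corr(sqrt(w) z + sqrt(1-w) e_i,
    sqrt(w) z + sqrt(1-w) e_j) = w for unit-variance parts).
    ``activation_voxels`` gain ``true_beta`` times the impulse train at
    ``event_onsets_s`` convolved with a single-gamma HRF peaking at
    ``true_peak_s``.  A grand-mean offset of 1000 is added.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 3:
        raise ContractError("each spatial dimension must be >= 3")
    if not 0 <= hub_target_r <= 0.99:
        raise ContractError(f"infeasible hub correlation target {hub_target_r}")
    rng = np.random.default_rng(seed)
    data = _ar1_noise(rng, shape, T, ar1_coef, noise_sigma)

    truth = SimTruth(seed=seed, ar1_coef=ar1_coef, noise_sigma=noise_sigma)
    if hub_voxels:
        for hub in hub_voxels:
            hub = np.atleast_2d(np.asarray(hub, dtype=int))
            latent = rng.standard_normal(T)
            latent = (latent - latent.mean()) / latent.std()
            w = hub_target_r
            for vx in hub:
                eps = data[tuple(vx)]
                eps = (eps - eps.mean()) / eps.std()
                data[tuple(vx)] = (np.sqrt(w) * latent
                                   + np.sqrt(1.0 - w) * eps) * noise_sigma
            truth.hub_voxels.append(hub)
            truth.hub_target_r.append(hub_target_r)

    if activation_voxels is not None and event_onsets_s is not None:
        onsets = np.asarray(event_onsets_s, dtype=float)
        kern = hrf_kernel("single_gamma", dt=tr / 16, peak_s=true_peak_s)
        grid = np.zeros(T * 16)
        for t in onsets:
            grid[min(int(round(t / (tr / 16))), grid.size - 1)] += 1.0
        resp = np.convolve(grid, kern.samples)[:grid.size][::16]
        act = np.atleast_2d(np.asarray(activation_voxels, dtype=int))
        for vx in act:
            data[tuple(vx)] += true_beta * resp
        truth.activation_voxels = act
        truth.true_peak_s = float(true_peak_s)
        truth.true_beta = float(true_beta)
        truth.event_onsets_s = onsets

    data += GRAND_MEAN_OFFSET
    vol = Volume4D(data=data, tr_seconds=tr, voxel_size_mm=(3.0, 3.0, 3.0),
                   affine=np.diag([3.0, 3.0, 3.0, 1.0]))
    mask = BrainMask(np.ones(shape, dtype=bool))
    return vol, mask, truth


def simulate_motion(T: int, amplitude: float = 0.5,
                    seed: int = 0) -> MotionParams:
    """Smooth random-walk realignment series, peak magnitude ``amplitude``."""
    if T < 3:
        raise ContractError("need T >= 3 time points of motion")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.standard_normal((T, 6)), axis=0)
    # moving-average smoothing, window 5
    kernel = np.ones(5) / 5.0
    smooth = np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="same") for j in range(6)]
    )
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth = smooth * (amplitude / peak)
    return MotionParams(smooth)


def default_spike_template(srate_hz: float) -> np.ndarray:
    """Biphasic 250 ms spike-wave template, unit peak amplitude."""
    n = int(round(0.25 * srate_hz))
    t = np.linspace(0, 1, n, endpoint=False)
    wave = np.sin(2 * np.pi * 2 * t) * np.exp(-3 * t)  # sharp then slow wave
    peak = np.abs(wave).max()
    return wave / peak if peak > 0 else wave


def simulate_eeg(channels: int = 4, duration_s: float = 60.0,
                 srate_hz: float = 250.0, spike_times_s=(),
                 spike_amplitude_uv: float = 100.0,
                 spike_template: np.ndarray | None = None,
                 bands=((10.0, 5.0),), noise_uv: float = 10.0,
                 seed: int = 0) -> EEGRecording:
    """Simulate multichannel EEG with planted spikes and oscillations.

    Background is 1/f-shaped noise (RMS ``noise_uv``); each ``(freq_hz,
    amplitude_uv)`` pair in ``bands`` adds a random-phase sinusoid per
    channel; scaled ``spike_template`` copies are added at
    ``spike_times_s`` on every channel and recorded as events of type
    "GSWD".  Overlapping spikes superpose.
    """
    rng = np.random.default_rng(seed)
    S = int(round(duration_s * srate_hz))
    C = int(channels)
    freqs = np.fft.rfftfreq(S, d=1.0 / srate_hz)
    shaping = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, 1e-6)), 0.0)
    white = rng.standard_normal((C, S))
    pink = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping[None, :], n=S,
                        axis=1)
    pink *= noise_uv / pink.std(axis=1, keepdims=True)
    signals = pink
    t = np.arange(S) / srate_hz
    for freq, amp in bands:
        phases = rng.uniform(0, 2 * np.pi, size=C)
        signals = signals + amp * np.sin(
            2 * np.pi * freq * t[None, :] + phases[:, None])
    if spike_template is None:
        spike_template = default_spike_template(srate_hz)
    rows = []
    for onset in spike_times_s:
        if not 0 <= onset < duration_s:
            raise ContractError(f"spike time {onset} outside recording")
        i0 = int(round(onset * srate_hz))
        i1 = min(i0 + spike_template.size, S)
        signals[:, i0:i1] += spike_amplitude_uv * spike_template[: i1 - i0]
        rows.append((float(onset), 0.0, "GSWD"))
    return EEGRecording(
        signals=signals,
        srate_hz=float(srate_hz),
        channel_labels=[f"EEG{i + 1:03d}" for i in range(C)],
        events=EventTable(rows),
    )
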