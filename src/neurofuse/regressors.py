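"""Hemodynamic response kernels and EEG-feature-to-BOLD regressor building.

Three HRF families are provided: a single gamma density whose only free
parameter is the peak latency (the basis for multi-peak GLM analyses), the
canonical double-gamma (response peak 6 s, undershoot 16 s, ratio 1/6) and
the Glover two-gamma parameterization.  Feature series are painted onto a
microtime grid (16 bins per TR by default), convolved with the kernel and
resampled at each volume's start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .denoise import NuisanceDesign
from .eeg_features import FeatureSeries
from .errors import ContractError

__all__ = ["HRFKernel", "DesignMatrix", "hrf_kernel", "build_regressor",
           "assemble_design"]

DEFAULT_MICROTIME_BINS = 16
DEFAULT_DURATION_S = 32.0

# Glover (auditory) two-gamma constants: t^a exp(-t/b) lobes with a1=6,
# a2=12, b=0.9 s and undershoot fraction c=0.35, peaks at a*b.
_GLOVER = dict(a1=6.0, a2=12.0, b1=0.9, b2=0.9, c=0.35)
# canonical double-gamma: delays 6/16 s, dispersions 1, undershoot ratio 1/6
_CANONICAL = dict(delay=6.0, undershoot_delay=16.0, dispersion=1.0,
                  u_dispersion=1.0, ratio=1.0 / 6.0)


@dataclass
class HRFKernel:
    """An HRF sampled at microtime resolution ``dt``, peak-normalized to 1."""

    samples: np.ndarray
    dt: float
    model_tag: str
    peak_s: float
    duration_s: float = DEFAULT_DURATION_S

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.isfinite(self.samples).all():
            raise ContractError("HRF samples must be finite")

    @property
    def argmax_s(self) -> float:
        return float(np.argmax(self.samples) * self.dt)

    def resample(self, dt: float) -> "HRFKernel":
        if abs(dt - self.dt) < 1e-12:
            return self
        t = np.arange(0.0, self.duration_s + dt / 2, dt)
        new = np.interp(t, np.arange(self.samples.size) * self.dt, self.samples)
        peak = np.abs(new).max()
        return HRFKernel(new / peak if peak > 0 else new, dt, self.model_tag,
                         self.peak_s, self.duration_s)


def hrf_kernel(model_tag: str, dt: float, peak_s: float | None = None,
               duration_s: float = DEFAULT_DURATION_S) -> HRFKernel:
    """Sample an HRF model on [0, duration] at resolution ``dt``.

    ``single_gamma`` is a gamma density with unit scale and shape
    ``peak_s + 1`` so its mode sits at ``peak_s`` — the peak latency is the
    one free parameter.  ``spm_canonical`` and ``glover`` use the published
    double-gamma constants.  All kernels are scaled to maximum magnitude 1,
    which makes downstream regressors scale-free in ``dt``.
    """
    if not dt > 0:
        raise ContractError(f"dt must be > 0, got {dt}")
    t = np.arange(0.0, duration_s + dt / 2, dt)
    if model_tag == "single_gamma":
        if peak_s is None or peak_s <= 0:
            raise ContractError("single_gamma needs peak_s > 0")
        h = stats.gamma.pdf(t, a=peak_s + 1.0, scale=1.0)
    elif model_tag == "spm_canonical":
        p = _CANONICAL
        h = stats.gamma.pdf(t, a=p["delay"] / p["dispersion"],
                            scale=p["dispersion"])
        h -= p["ratio"] * stats.gamma.pdf(
            t, a=p["undershoot_delay"] / p["u_dispersion"],
            scale=p["u_dispersion"])
        peak_s = p["delay"] - p["dispersion"]  # mode of the main lobe
    elif model_tag == "glover":
        g = _GLOVER
        with np.errstate(divide="ignore", invalid="ignore"):
            l1 = (t / (g["a1"] * g["b1"])) ** g["a1"] * np.exp(
                -(t - g["a1"] * g["b1"]) / g["b1"])
            l2 = (t / (g["a2"] * g["b2"])) ** g["a2"] * np.exp(
                -(t - g["a2"] * g["b2"]) / g["b2"])
        h = np.nan_to_num(l1 - g["c"] * l2)
        peak_s = g["a1"] * g["b1"]
    else:
        raise ContractError(
            f"unknown HRF model {model_tag!r} "
            "(single_gamma, spm_canonical, glover)"
        )
    peak = np.abs(h).max()
    if peak == 0:
        raise ContractError("degenerate HRF (all zero)")
    return HRFKernel(h / peak, dt, model_tag, float(peak_s), duration_s)


def build_regressor(feature: FeatureSeries, hrf: HRFKernel, tr: float,
                    n_vols: int,
                    microtime_bins: int = DEFAULT_MICROTIME_BINS) -> np.ndarray:
    """Convolve a feature series with an HRF on the TR grid.

    Onset features become unit impulses (scaled by their values) on a
    microtime grid of ``tr / microtime_bins``; TR-locked series become
    per-TR boxcars with missing (NaN) values linearly interpolated.  The
    convolution is sampled at each volume's first microtime bin.
    """
    if n_vols < 1 or tr <= 0:
        raise ContractError("need n_vols >= 1 and tr > 0")
    if len(feature) == 0:
        warnings.warn("empty feature series; regressor is all zero",
                      stacklevel=2)
        return np.zeros(n_vols)
    if feature.times_s.max() >= n_vols * tr:
        raise ContractError(
            f"feature at {feature.times_s.max():.3f} s lies beyond the run "
            f"({n_vols} volumes x {tr} s)"
        )
    dt = tr / microtime_bins
    n_bins = n_vols * microtime_bins
    neural = np.zeros(n_bins)
    if feature.kind == "onsets" or not feature.tr_locked:
        for t, v in zip(feature.times_s, feature.values):
            if np.isnan(v):
                continue
            neural[min(int(round(t / dt)), n_bins - 1)] += v
    else:
        values = feature.values.copy()
        nan = np.isnan(values)
        if nan.all():
            raise ContractError("TR-locked feature has no valid values")
        if nan.any():
            idx = np.arange(values.size)
            values[nan] = np.interp(idx[nan], idx[~nan], values[~nan])
        per_tr = np.zeros(n_vols)
        vol_idx = np.clip(np.round(feature.times_s / tr).astype(int), 0,
                          n_vols - 1)
        per_tr[vol_idx] = values
        neural = np.repeat(per_tr, microtime_bins)
    kernel = hrf.resample(dt)
    conv = np.convolve(neural, kernel.samples)[:n_bins]
    return conv[::microtime_bins].copy()


@dataclass
class DesignMatrix:
    """T x P design with a column partition and default contrasts."""

    matrix: np.ndarray
    labels: list[str]
    partition: dict[str, list[int]]
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.shape[1] != len(self.labels):
            raise ContractError("design labels do not match columns")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ContractError(f"duplicate design labels: {dupes}")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def interest_columns(self) -> list[int]:
        return self.partition.get("interest", [])

    def contrast_vector(self, label: str) -> np.ndarray:
        if label not in self.contrasts:
            raise ContractError(
                f"no contrast {label!r}; available: {sorted(self.contrasts)}"
            )
        return self.contrasts[label]


def assemble_design(columns_of_interest, interest_labels=None,
                    nuisance: NuisanceDesign | None = None,
                    drift: NuisanceDesign | None = None,
                    add_intercept: bool = True) -> DesignMatrix:
    """Stack [interest | nuisance | drift | intercept] with contrasts.

    One t-contrast is registered per interest column plus an F-contrast
    spanning all of them.
    """
    interest = np.atleast_2d(np.asarray(columns_of_interest, dtype=np.float64))
    if interest.shape[0] == 1 and interest.shape[1] > 1:
        interest = interest.T
    T = interest.shape[0]
    if interest_labels is None:
        interest_labels = [f"interest_{i}" for i in range(interest.shape[1])]
    blocks = [interest]
    labels = list(interest_labels)
    partition = {"interest": list(range(interest.shape[1]))}
    cursor = interest.shape[1]
    for name, block in (("nuisance", nuisance), ("drift", drift)):
        if block is not None and block.n_columns:
            if block.n_timepoints != T:
                raise ContractError(f"{name} block row count != {T}")
            blocks.append(block.matrix)
            labels += block.labels
            partition[name] = list(range(cursor, cursor + block.n_columns))
            cursor += block.n_columns
    if add_intercept:
        blocks.append(np.ones((T, 1)))
        labels.append("intercept")
        partition["intercept"] = [cursor]
        cursor += 1
    matrix = np.hstack(blocks)
    P = matrix.shape[1]
    contrasts: dict[str, np.ndarray] = {}
    for j, lab in zip(partition["interest"], interest_labels):
        c = np.zeros(P)
        c[j] = 1.0
        contrasts[lab] = c
    F = np.zeros((len(partition["interest"]), P))
    for row, j in enumerate(partition["interest"]):
        F[row, j] = 1.0
    contrasts["interest_F"] = F
    return DesignMatrix(matrix, labels, partition, contrasts)
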