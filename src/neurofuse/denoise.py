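"""Nuisance construction and removal for resting-state BOLD series.

The standard confound model removed here is head motion (in one of the
6/12/24/36-parameter expansions), linear trend, tissue (white matter / CSF)
mean signals and, optionally, the global signal, via voxelwise least
squares; very-low and high frequency physiological noise is attenuated by
an ideal (frequency-domain) bandpass, 0.01-0.08 Hz by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .io import BrainMask, MotionParams, Volume4D

__all__ = [
    "NuisanceDesign",
    "build_motion_regressors",
    "extract_tissue_means",
    "regress_nuisance",
    "ideal_bandpass",
    "bandpass_volume",
    "dct_drift_basis",
    "linear_trend_column",
    "global_mean_normalize",
]

MOTION_SCHEMES = (6, 12, 24, 36)
DEFAULT_BAND_HZ = (0.01, 0.08)


@dataclass
class NuisanceDesign:
    """T x P confound matrix with column labels."""

    matrix: np.ndarray
    labels: list[str]
    scheme_tag: str = "custom"

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.shape[1] != len(self.labels):
            raise ContractError(
                f"{self.matrix.shape[1]} columns but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ContractError("duplicate nuisance column labels")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def hstack(self, other: "NuisanceDesign") -> "NuisanceDesign":
        if other.n_timepoints != self.n_timepoints:
            raise ContractError("cannot stack designs of different lengths")
        return NuisanceDesign(
            np.hstack([self.matrix, other.matrix]),
            self.labels + other.labels,
            "custom",
        )


def _lag(x: np.ndarray, k: int) -> np.ndarray:
    """Shift rows down by k, zero-padding the first k rows."""
    out = np.zeros_like(x)
    if k == 0:
        return x.copy()
    out[k:] = x[:-k]
    return out


def build_motion_regressors(motion: MotionParams, scheme: int = 24) -> NuisanceDesign:
    """Expand the 6 rigid-body parameters R into a motion confound block.

    * 6:  [R]
    * 12: [R, dR]            (backward difference, first row 0)
    * 24: [R, R^2, R_{t-1}, R^2_{t-1}]
    * 36: 24-block plus [R_{t-2}, R^2_{t-2}]

    Lagged columns are zero-padded at the start.
    """
    if scheme not in MOTION_SCHEMES:
        raise ContractError(f"scheme must be one of {MOTION_SCHEMES}, got {scheme}")
    R = motion.series
    T = R.shape[0]
    if scheme == 36 and T < 3:
        raise ContractError("scheme 36 needs at least 3 time points (lag 2)")
    names = ["tx", "ty", "tz", "pitch", "yaw", "roll"]

    def block(mat: np.ndarray, prefix: str) -> tuple[np.ndarray, list[str]]:
        return mat, [f"{prefix}_{n}" for n in names]

    blocks = [block(R, "mot")]
    if scheme == 12:
        dR = np.zeros_like(R)
        dR[1:] = np.diff(R, axis=0)
        blocks.append(block(dR, "dmot"))
    elif scheme >= 24:
        blocks.append(block(R**2, "mot_sq"))
        blocks.append(block(_lag(R, 1), "mot_lag1"))
        blocks.append(block(_lag(R, 1) ** 2, "mot_sq_lag1"))
        if scheme == 36:
            blocks.append(block(_lag(R, 2), "mot_lag2"))
            blocks.append(block(_lag(R, 2) ** 2, "mot_sq_lag2"))
    matrix = np.hstack([b[0] for b in blocks])
    labels = [lab for b in blocks for lab in b[1]]
    assert matrix.shape[1] == scheme
    return NuisanceDesign(matrix, labels, scheme_tag=str(scheme))


def extract_tissue_means(vol: Volume4D, masks: list[BrainMask],
                         labels: list[str] | None = None) -> NuisanceDesign:
    """Per-mask spatial mean series (e.g. white-matter and CSF signals)."""
    cols = []
    for i, m in enumerate(masks):
        m.check_compatible(vol)
        cols.append(vol.data[m.flags].mean(axis=0))
    if labels is None:
        labels = [f"tissue_{i}" for i in range(len(masks))]
    return NuisanceDesign(np.column_stack(cols), list(labels))


def linear_trend_column(T: int) -> NuisanceDesign:
    """Centered linear trend, orthogonal to the intercept."""
    t = np.arange(T, dtype=float)
    return NuisanceDesign((t - t.mean())[:, None], ["trend"])


def regress_nuisance(vol: Volume4D, design: NuisanceDesign,
                     mask: BrainMask) -> Volume4D:
    """Remove confounds voxelwise by OLS; the voxel temporal mean is re-added.

    An intercept is appended if the design does not already span one.
    Out-of-mask voxels pass through untouched.  Rank-deficient designs are
    fit with the pseudoinverse (a warning names the dependent columns).
    """
    vol.require_timeseries("regress_nuisance")
    mask.check_compatible(vol)
    T = vol.n_vols
    if design.n_timepoints != T:
        raise ContractError(
            f"design has {design.n_timepoints} rows for {T} volumes"
        )
    X = np.column_stack([design.matrix, np.ones(T)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal does not lower rank
        dependent = [
            design.labels[j]
            for j in range(design.n_columns)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        warnings.warn(
            "rank-deficient nuisance design; fitting by pseudoinverse "
            f"(dependent columns: {dependent})",
            stacklevel=2,
        )
    Y = vol.data[mask.flags].T  # T x V
    beta = np.linalg.pinv(X) @ Y
    resid = Y - X @ beta
    resid += Y.mean(axis=0, keepdims=True)
    out = vol.data.copy()
    out[mask.flags] = resid.T
    return vol.with_data(out)


def _bandpass_mask(n: int, tr: float, low_hz: float, high_hz: float) -> np.ndarray:
    nyquist = 1.0 / (2.0 * tr)
    if not 0 <= low_hz < high_hz:
        raise ContractError(f"need 0 <= low < high, got [{low_hz}, {high_hz}]")
    if high_hz > nyquist + 1e-12:
        raise ContractError(
            f"high edge {high_hz} Hz exceeds Nyquist {nyquist} Hz at TR {tr} s"
        )
    freqs = np.fft.rfftfreq(n, d=tr)
    # half-open (low, high]: edge bins belong to the band below, so disjoint
    # bands covering (0, Nyquist] reconstruct the demeaned signal exactly
    keep = (freqs > low_hz + 1e-12) & (freqs <= high_hz + 1e-12)
    keep[0] = low_hz == 0  # DC retained only for an explicit low edge of 0
    return keep


def ideal_bandpass(series: np.ndarray, low_hz: float, high_hz: float,
                   tr: float, axis: int = -1) -> np.ndarray:
    """Ideal (brick-wall) bandpass via the discrete Fourier transform.

    Fourier coefficients with frequency in (low, high] are retained and all
    others zeroed; DC is removed unless ``low_hz == 0``.  The filter is
    idempotent by construction.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[axis]
    keep = _bandpass_mask(n, tr, low_hz, high_hz)
    coef = np.fft.rfft(series, axis=axis)
    shape = [1] * series.ndim
    shape[axis] = keep.size
    coef *= keep.reshape(shape)
    return np.fft.irfft(coef, n=n, axis=axis)


def bandpass_volume(vol: Volume4D, low_hz: float = DEFAULT_BAND_HZ[0],
                    high_hz: float = DEFAULT_BAND_HZ[1],
                    mask: BrainMask | None = None,
                    keep_mean: bool = True) -> Volume4D:
    """Apply the ideal bandpass along time; voxel means re-added by default.

    Re-adding the temporal mean keeps subsequent grand-mean normalization
    meaningful even though the filter itself excludes DC.
    """
    vol.require_timeseries("bandpass_volume")
    data = vol.data
    if mask is not None:
        mask.check_compatible(vol)
        sub = data[mask.flags]
        filt = ideal_bandpass(sub, low_hz, high_hz, vol.tr_seconds, axis=1)
        if keep_mean:
            filt += sub.mean(axis=1, keepdims=True)
        out = data.copy()
        out[mask.flags] = filt
        return vol.with_data(out)
    filt = ideal_bandpass(data, low_hz, high_hz, vol.tr_seconds, axis=3)
    if keep_mean:
        filt += data.mean(axis=3, keepdims=True)
    return vol.with_data(filt)


def dct_drift_basis(T: int, tr: float, cutoff_s: float = 128.0) -> NuisanceDesign:
    """Discrete-cosine drift columns for periods above ``cutoff_s``.

    K = floor(2 * T * tr / cutoff_s) - 1 unit-normalized, mutually
    orthogonal columns (the constant term is excluded); an empty basis is
    returned for runs shorter than the cutoff.
    """
    K = int(np.floor(2.0 * T * tr / cutoff_s)) - 1
    K = max(K, 0)
    t = np.arange(T)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * T)) for k in range(1, K + 1)]
    if not cols:
        return NuisanceDesign(np.empty((T, 0)), [], "drift")
    matrix = np.column_stack([c / np.linalg.norm(c) for c in cols])
    return NuisanceDesign(matrix, [f"dct_{k}" for k in range(1, K + 1)], "drift")


def global_mean_normalize(vol: Volume4D, mask: BrainMask) -> Volume4D:
    """Scale the volume so the in-mask grand mean equals 100.

    This is the conventional ``data = 100 * data / global mean`` step run
    before GLM fitting; it makes effect sizes percent-of-global-mean.
    """
    mask.check_compatible(vol)
    grand = vol.data[mask.flags].mean()
    if grand == 0 or not np.isfinite(grand):
        raise ContractError(f"global mean is {grand}; cannot normalize")
    return vol.with_data(vol.data * (100.0 / grand))
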