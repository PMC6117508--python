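"""Local multimodal serial analysis (LMSA).

LMSA fuses EEG and fMRI serially at each voxel.  Step one runs canonical
correlation analysis between a lagged matrix of the EEG feature series
(columns = the series delayed by 0..L TRs, spanning plausible hemodynamic
delays) and the BOLD time series of the voxel's 27-voxel neighborhood;
when the first canonical pair is significant, the EEG-side variate is an
estimate of the locally expressed, hemodynamically delayed EEG activity,
and its lag weights are a data-driven HRF estimate.  Step two regresses
the center voxel's own series on that variate (plus confounds) and maps
the variate coefficient's t-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .denoise import NuisanceDesign
from .eeg_features import FeatureSeries
from .errors import ContractError
from .io import BrainMask, Volume4D

__all__ = [
    "LaggedFeatureMatrix",
    "LMSAVoxelResult",
    "LMSAResult",
    "feature_to_tr_grid",
    "build_lagged_matrix",
    "cca_first",
    "lmsa_map",
    "estimated_hrf",
]


@dataclass
class LaggedFeatureMatrix:
    """T x (L+1) matrix; column l is the series delayed by l TRs."""

    matrix: np.ndarray
    lags_trs: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.lags_trs = np.asarray(self.lags_trs, dtype=int)
        if self.matrix.shape[1] != self.lags_trs.size:
            raise ContractError("lag labels do not match columns")


@dataclass
class LMSAVoxelResult:
    canonical_corr: float
    eeg_weights: np.ndarray  # the estimated HRF over lags
    fmri_weights: np.ndarray
    variate: np.ndarray
    t_value: float
    p_cca: float
    significant: bool
    lags_trs: np.ndarray = field(default=None)  # type: ignore[assignment]
    tr: float = float("nan")


@dataclass
class LMSAResult:
    t_map: np.ndarray
    significance: np.ndarray
    canonical_corr_map: np.ndarray
    voxel_results: dict[tuple[int, int, int], LMSAVoxelResult]
    flagged: np.ndarray
    alpha: float


def feature_to_tr_grid(feature: FeatureSeries, tr: float,
                       n_vols: int) -> np.ndarray:
    """Lock a feature series to the TR grid.

    Onsets become per-TR event counts; TR-locked series are placed at
    their volume index (missing values linearly interpolated); other
    series are binned by TR (summed).
    """
    out = np.zeros(n_vols)
    if len(feature) == 0:
        return out
    if feature.times_s.max() >= n_vols * tr:
        raise ContractError("feature extends beyond the run")
    if feature.kind != "onsets" and feature.tr_locked:
        values = feature.values.copy()
        nan = np.isnan(values)
        if nan.any() and not nan.all():
            idx = np.arange(values.size)
            values[nan] = np.interp(idx[nan], idx[~nan], values[~nan])
        vol_idx = np.clip(np.round(feature.times_s / tr).astype(int), 0,
                          n_vols - 1)
        out[vol_idx] = values
        return out
    for t, v in zip(feature.times_s, feature.values):
        if np.isnan(v):
            continue
        out[min(int(t / tr), n_vols - 1)] += v
    return out


def build_lagged_matrix(feature: FeatureSeries, tr: float, n_vols: int,
                        max_lag_trs: int = 6) -> LaggedFeatureMatrix:
    """Delay-embed a TR-locked feature: column l = shift down by l rows."""
    if max_lag_trs >= n_vols:
        raise ContractError(
            f"max lag {max_lag_trs} must be below the run length {n_vols}"
        )
    base = feature_to_tr_grid(feature, tr, n_vols)
    cols = []
    for lag in range(max_lag_trs + 1):
        col = np.zeros(n_vols)
        col[lag:] = base[:n_vols - lag]
        cols.append(col)
    return LaggedFeatureMatrix(np.column_stack(cols),
                               np.arange(max_lag_trs + 1), tr)


def _drop_dependent(M: np.ndarray, tol: float = 1e-10):
    """Independent-column subset via rank-revealing QR; returns (cols, kept)."""
    if M.shape[1] == 0:
        return M, np.arange(0)
    _, R, piv = linalg.qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag[0], 1e-300)).sum()) if diag.size else 0
    kept = np.sort(piv[:rank])
    return M[:, kept], kept


def cca_first(X: np.ndarray, Y: np.ndarray):
    """First canonical correlation of two column-demeaned sets.

    Returns ``(rho, a, b, p_value)`` with the weights scaled so each
    variate has unit variance, and a p-value from Bartlett's chi-square
    approximation (the likelihood-ratio test that all canonical roots
    vanish, df = p*q).  Rank-deficient sides are reduced by dropping
    dependent columns (their weights are returned as 0).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    T = X.shape[0]
    if Y.shape[0] != T:
        raise ContractError("X and Y must share the time axis")
    p_full, q_full = X.shape[1], Y.shape[1]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Xr, kept_x = _drop_dependent(Xc)
    Yr, kept_y = _drop_dependent(Yc)
    p, q = Xr.shape[1], Yr.shape[1]
    if p == 0 or q == 0:
        raise ContractError("a side of the CCA has no varying columns")
    if T <= p + q:
        raise ContractError(
            f"need T > p + q for CCA (T={T}, p={p}, q={q}); reduce lags or "
            "the neighborhood"
        )
    # whiten each side through its QR factor, then SVD the cross product
    Qx, Rx = np.linalg.qr(Xr)
    Qy, Ry = np.linalg.qr(Yr)
    U, svals, Vt = np.linalg.svd(Qx.T @ Qy)
    rhos = np.clip(svals, 0.0, 1.0)
    rho = float(rhos[0])
    a_r = linalg.solve_triangular(Rx, U[:, 0])
    b_r = linalg.solve_triangular(Ry, Vt[0])
    a = np.zeros(p_full)
    b = np.zeros(q_full)
    a[kept_x] = a_r
    b[kept_y] = b_r
    # unit-variance variates (sample variance with 1/(T-1))
    u = Xc @ a
    v = Yc @ b
    su = u.std(ddof=1)
    sv = v.std(ddof=1)
    if su > 0:
        a /= su
    if sv > 0:
        b /= sv
    # Bartlett: -(T - 1 - (p+q+1)/2) * sum log(1 - rho_i^2) ~ chi2(p*q)
    m = min(p, q)
    with np.errstate(divide="ignore"):
        log_terms = np.log1p(-(rhos[:m] ** 2))
    statistic = -(T - 1 - (p + q + 1) / 2.0) * log_terms.sum()
    p_value = float(stats.chi2.sf(statistic, p * q))
    return rho, a, b, p_value


def _neighborhood(coord, flags, radius: int = 1):
    lo = np.maximum(np.asarray(coord) - radius, 0)
    hi = np.minimum(np.asarray(coord) + radius + 1, flags.shape)
    block = [
        (x, y, z)
        for x in range(lo[0], hi[0])
        for y in range(lo[1], hi[1])
        for z in range(lo[2], hi[2])
        if flags[x, y, z]
    ]
    return np.asarray(block, dtype=int)


def lmsa_map(vol: Volume4D, feature: FeatureSeries, tr: float | None = None,
             mask: BrainMask | None = None, max_lag_trs: int = 6,
             alpha: float = 0.05, nuisance: NuisanceDesign | None = None,
             min_members: int = 9, neighborhood_radius: int = 1,
             variate_side: str = "eeg") -> LMSAResult:
    """Per-voxel CCA fusion map.

    At each in-mask voxel the lagged EEG matrix is canonically correlated
    with the neighborhood BOLD set; where Bartlett's test passes at
    ``alpha`` the voxel's own series is regressed on the canonical variate
    (EEG side by default, sign fixed so the lag weights sum >= 0) plus
    confounds, and the variate coefficient's t is mapped.  Non-significant
    voxels carry t = 0 and are flagged.
    """
    vol.require_timeseries("lmsa_map")
    tr = float(tr if tr is not None else vol.tr_seconds)
    if mask is None:
        mask = BrainMask(np.ones(vol.shape3d, dtype=bool))
    mask.check_compatible(vol)
    if variate_side not in ("eeg", "fmri"):
        raise ContractError("variate_side must be 'eeg' or 'fmri'")
    T = vol.n_vols
    lagged = build_lagged_matrix(feature, tr, T, max_lag_trs)
    X = lagged.matrix
    flags = mask.flags
    shape = vol.shape3d
    t_map = np.full(shape, np.nan)
    rho_map = np.full(shape, np.nan)
    sig = np.zeros(shape, dtype=bool)
    flagged = np.zeros(shape, dtype=bool)
    results: dict[tuple[int, int, int], LMSAVoxelResult] = {}
    conf_cols = []
    if nuisance is not None and nuisance.n_columns:
        if nuisance.n_timepoints != T:
            raise ContractError("nuisance rows != volumes")
        conf_cols.append(nuisance.matrix)
    for coord in map(tuple, np.argwhere(flags)):
        nb = _neighborhood(coord, flags, neighborhood_radius)
        if nb.shape[0] < min_members:
            flagged[coord] = True
            continue
        Ylocal = vol.data[nb[:, 0], nb[:, 1], nb[:, 2]].T  # T x q
        try:
            rho, a, b, p_cca = cca_first(X, Ylocal)
        except ContractError:
            flagged[coord] = True
            continue
        rho_map[coord] = rho
        if a.sum() < 0:  # sign convention keeps HRF estimates comparable
            a, b = -a, -b
        significant = p_cca < alpha
        if not significant:
            t_map[coord] = 0.0
            flagged[coord] = True
            results[coord] = LMSAVoxelResult(rho, a, b,
                                             (X - X.mean(axis=0)) @ a,
                                             0.0, p_cca, False,
                                             lagged.lags_trs, tr)
            continue
        if variate_side == "eeg":
            v = (X - X.mean(axis=0)) @ a
        else:
            v = (Ylocal - Ylocal.mean(axis=0)) @ b
        design = np.column_stack([v] + conf_cols + [np.ones(T)])
        y = vol.data[coord[0], coord[1], coord[2], :]
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        dof = T - np.linalg.matrix_rank(design)
        sigma2 = (resid**2).sum() / dof
        xtx_inv = np.linalg.pinv(design.T @ design)
        se = np.sqrt(sigma2 * xtx_inv[0, 0])
        t_val = float(beta[0] / se) if se > 0 else 0.0
        t_map[coord] = t_val
        sig[coord] = True
        results[coord] = LMSAVoxelResult(rho, a, b, v, t_val, p_cca, True,
                                         lagged.lags_trs, tr)
    return LMSAResult(t_map=t_map, significance=sig,
                      canonical_corr_map=rho_map, voxel_results=results,
                      flagged=flagged, alpha=alpha)


def estimated_hrf(voxel_result: LMSAVoxelResult):
    """Peak-normalized EEG-side lag weights as an HRF estimate.

    Returns ``(times_s, weights)`` with times = lag * TR.  Only defined
    for voxels whose CCA passed the significance gate.
    """
    if not voxel_result.significant:
        raise ContractError("voxel not significant; no HRF estimate")
    w = voxel_result.eeg_weights
    peak = np.abs(w).max()
    weights = w / peak if peak > 0 else w.copy()
    times = voxel_result.lags_trs * voxel_result.tr
    return times, weights
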