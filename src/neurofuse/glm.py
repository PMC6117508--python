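"""Voxelwise general linear models for EEG-informed fMRI mapping.

Two analyses are provided.  The conventional voxelwise GLM fits one design
and reports t-maps for single contrasts and extra-sum-of-squares F-maps
for column sets.  The multi-HRF variant targets epileptiform-discharge
mapping, where the hemodynamic response latency is uncertain: the data are
fitted once per single-gamma HRF peak (3, 5, 7 and 9 s by default), the
maximal T is retained per voxel together with the winning peak, and a
joint F-test over all peak regressors is emitted alongside.

High-frequency drift is handled by including discrete-cosine confound
columns (128 s cutoff) rather than pre-filtering, which keeps the degrees
of freedom exact; grand-mean scaling to 100 is applied upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .denoise import NuisanceDesign
from .eeg_features import FeatureSeries
from .errors import ContractError
from .io import BrainMask, Volume4D
from .regressors import DesignMatrix, assemble_design, build_regressor, hrf_kernel

__all__ = ["StatMap", "GLM2Result", "fit_glm", "fit_glm2", "DEFAULT_PEAKS"]

DEFAULT_PEAKS = (3.0, 5.0, 7.0, 9.0)


@dataclass
class StatMap:
    """A voxelwise statistic map with its fit by-products.

    Out-of-mask voxels hold NaN (a missing-value marker — 0 is a valid
    statistic value and is never used as one).
    """

    stat: np.ndarray
    kind: str
    dof: tuple[float, float]
    beta: np.ndarray | None = None
    resid_var: np.ndarray | None = None

    def p_values(self) -> np.ndarray:
        if self.kind == "t":
            return 2.0 * stats.t.sf(np.abs(self.stat), self.dof[1])
        return stats.f.sf(self.stat, self.dof[0], self.dof[1])


@dataclass
class GLM2Result:
    peaks: tuple[float, ...]
    t_maps: dict[float, StatMap]
    max_t: np.ndarray
    best_peak: np.ndarray
    joint_f: StatMap
    designs: dict[float, DesignMatrix] = field(default_factory=dict)


def _ols(X: np.ndarray, Y: np.ndarray):
    """OLS of every column of Y (T x V) on X; pinv handles rank deficiency."""
    T = X.shape[0]
    rank = np.linalg.matrix_rank(X)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    dof = T - rank
    if dof <= 0:
        raise ContractError(
            f"no residual degrees of freedom: T={T}, design rank={rank}"
        )
    return beta, resid, rss, rank, dof, pinv


def fit_glm(vol: Volume4D, design: DesignMatrix, mask: BrainMask,
            contrast) -> StatMap:
    """Voxelwise OLS with a t- or F-contrast.

    ``contrast`` may be a contrast label registered on the design, a 1-D
    vector (t) or a 2-D matrix (extra-sum-of-squares F between the full
    model and the model with the spanned columns removed).
    """
    vol.require_timeseries("fit_glm")
    mask.check_compatible(vol)
    X = design.matrix
    if X.shape[0] != vol.n_vols:
        raise ContractError(
            f"design rows {X.shape[0]} != volumes {vol.n_vols}"
        )
    if isinstance(contrast, str):
        contrast = design.contrast_vector(contrast)
    contrast = np.asarray(contrast, dtype=np.float64)
    is_f = contrast.ndim == 2  # a matrix contrast requests an F test
    c = np.atleast_2d(contrast)
    if c.shape[1] != X.shape[1]:
        raise ContractError(
            f"contrast length {c.shape[1]} != design columns {X.shape[1]}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient design; using pseudoinverse",
                      stacklevel=2)
    Y = vol.data[mask.flags].T  # T x V
    beta, resid, rss, rank, dof, pinv = _ols(X, Y)
    sigma2 = rss / dof
    shape = vol.shape3d

    def to_map(values: np.ndarray) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[mask.flags] = values
        return out

    beta_maps = np.full(shape + (X.shape[1],), np.nan)
    beta_maps[mask.flags] = beta.T

    if not is_f:
        cvec = c[0]
        var_c = cvec @ pinv @ pinv.T @ cvec  # c (X'X)^+ c'
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = (cvec @ beta) / np.sqrt(sigma2 * var_c)
        return StatMap(to_map(tvals), "t", (1.0, float(dof)),
                       beta=beta_maps, resid_var=to_map(sigma2))

    # F via extra sum of squares: drop the columns the contrast spans
    dropped = np.where(np.any(c != 0, axis=0))[0]
    X_red = np.delete(X, dropped, axis=1)
    if X_red.shape[1]:
        _, _, rss_red, rank_red, _, _ = _ols(X_red, Y)
    else:
        rss_red, rank_red = (Y**2).sum(axis=0), 0
    df_num = rank - rank_red
    if df_num <= 0:
        raise ContractError("contrast spans no additional model dimensions")
    with np.errstate(divide="ignore", invalid="ignore"):
        fvals = ((rss_red - rss) / df_num) / sigma2
    fvals = np.where(np.isfinite(fvals), np.maximum(fvals, 0.0), np.nan)
    return StatMap(to_map(fvals), "F", (float(df_num), float(dof)),
                   beta=beta_maps, resid_var=to_map(sigma2))


def fit_glm2(vol: Volume4D, feature: FeatureSeries,
             peaks=DEFAULT_PEAKS, tr: float | None = None,
             mask: BrainMask | None = None,
             nuisance: NuisanceDesign | None = None,
             drift: NuisanceDesign | None = None,
             microtime_bins: int = 16) -> GLM2Result:
    """Multi-HRF GLM: fit once per single-gamma peak latency, keep max T.

    Each peak's design shares the nuisance and drift blocks; per-peak
    interest t-maps are recorded, ``max_t``/``best_peak`` summarize them
    voxelwise, and a joint model containing all peak regressors yields an
    F-map against the confound-only reduced model.
    """
    peaks = tuple(float(p) for p in peaks)
    if not peaks:
        raise ContractError("need at least one HRF peak")
    vol.require_timeseries("fit_glm2")
    tr = float(tr if tr is not None else vol.tr_seconds)
    if mask is None:
        mask = BrainMask(np.ones(vol.shape3d, dtype=bool))
    dt = tr / microtime_bins
    regs = {}
    for p in peaks:
        kern = hrf_kernel("single_gamma", dt=dt, peak_s=p)
        regs[p] = build_regressor(feature, kern, tr, vol.n_vols,
                                  microtime_bins=microtime_bins)
    t_maps, designs = {}, {}
    for p in peaks:
        design = assemble_design(regs[p][:, None], [f"hrf_peak_{p:g}"],
                                 nuisance=nuisance, drift=drift)
        t_maps[p] = fit_glm(vol, design, mask, f"hrf_peak_{p:g}")
        designs[p] = design
    stack = np.stack([t_maps[p].stat for p in peaks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        max_t = np.nanmax(stack, axis=0)
        best_idx = np.nanargmax(
            np.where(np.isnan(stack), -np.inf, stack), axis=0)
    best_peak = np.asarray(peaks, dtype=float)[best_idx]
    best_peak[~mask.flags] = np.nan
    max_t[~mask.flags] = np.nan

    joint_cols = np.column_stack([regs[p] for p in peaks])
    cond = np.linalg.cond(joint_cols - joint_cols.mean(axis=0))
    if cond > 1e8:
        warnings.warn(
            f"peak regressors nearly collinear (condition {cond:.3g}); "
            "joint F computed via pseudoinverse",
            stacklevel=2,
        )
    joint_design = assemble_design(
        joint_cols, [f"hrf_peak_{p:g}" for p in peaks],
        nuisance=nuisance, drift=drift)
    joint_f = fit_glm(vol, joint_design, mask, "interest_F")
    return GLM2Result(peaks=peaks, t_maps=t_maps, max_t=max_t,
                      best_peak=best_peak, joint_f=joint_f, designs=designs)
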