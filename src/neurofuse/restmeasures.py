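"""Voxelwise resting-state measures: FCD mapping, FOCA, dynamic indices.

Functional connectivity density (FCD) counts suprathreshold Pearson
correlations from each voxel: locally, within the contiguous cluster grown
around the voxel (lFCD); globally, to every in-mask voxel (gFCD); and
long-range as their difference (lrFCD = gFCD - lFCD).  FOCA summarizes the
spatio-temporal consistency of a 27-voxel neighborhood in [0, 1].  Each map
is also emitted normalized by its in-mask mean, the conventional step that
reduces between-subject scaling variability.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .io import BrainMask, Volume4D

__all__ = [
    "FCDParams",
    "FCDMaps",
    "FOCAMap",
    "neighbor_offsets",
    "compute_fcd",
    "compute_dynamic_fcd",
    "compute_foca",
    "dynamic_series_stats",
]

DEFAULT_THRESHOLDS = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


def neighbor_offsets(connectivity: int) -> np.ndarray:
    """Offsets of the 6 / 18 / 26 neighbors of a voxel (self excluded)."""
    if connectivity not in (6, 18, 26):
        raise ContractError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=int)


@dataclass
class FCDParams:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    connectivity: int = 26
    window_trs: int | None = None
    step_trs: int | None = None

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        if not thr:
            raise ContractError("need at least one threshold")
        if any(not 0 < t < 1 for t in thr):
            raise ContractError(f"thresholds must lie in (0, 1): {thr}")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ContractError(f"thresholds must be strictly increasing: {thr}")
        self.thresholds = thr
        neighbor_offsets(self.connectivity)  # validates


@dataclass
class FCDMaps:
    """Per-threshold lFCD/gFCD/lrFCD count maps and normalized variants.

    Maps are NaN outside the mask.  ``normalized[...]`` divides by the
    in-mask mean (zero-variance voxels excluded from the denominator).
    """

    thresholds: tuple[float, ...]
    lfcd: dict[float, np.ndarray]
    gfcd: dict[float, np.ndarray]
    lrfcd: dict[float, np.ndarray]
    normalized: dict[tuple[str, float], np.ndarray]
    mask: BrainMask
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]


def _valid_series(vol: Volume4D, mask: BrainMask):
    """In-mask series matrix, standardized; zero-variance voxels flagged."""
    Y = vol.data[mask.flags]  # V x T
    sd = Y.std(axis=1)
    ok = sd > 0
    Z = np.zeros_like(Y)
    Z[ok] = (Y[ok] - Y[ok].mean(axis=1, keepdims=True)) / (
        sd[ok, None] * np.sqrt(Y.shape[1])
    )
    return Z, ok


def _normalize_map(raw: np.ndarray, inside: np.ndarray) -> np.ndarray:
    mean = raw[inside].mean()
    out = np.full_like(raw, np.nan)
    if mean != 0:
        out[inside] = raw[inside] / mean
    return out


def compute_fcd(vol: Volume4D, mask: BrainMask,
                params: FCDParams | None = None) -> FCDMaps:
    """Static FCD maps at every requested correlation threshold.

    gFCD(i) counts in-mask voxels j != i with r(i, j) > threshold (strict).
    lFCD(i) is the size, minus the seed, of the cluster grown from i by
    repeatedly adding voxels that are spatially adjacent (6/18/26
    connectivity) to a cluster member *and* correlate with the seed above
    the threshold.  Correlations are always taken against the seed voxel.
    """
    params = params or FCDParams()
    vol.require_timeseries("compute_fcd")
    mask.check_compatible(vol)
    flags = mask.flags
    coords = np.argwhere(flags)
    V = coords.shape[0]
    Z, ok = _valid_series(vol, mask)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} in-mask voxels have zero temporal variance; "
            "their FCD is 0",
            stacklevel=2,
        )
    index_of = -np.ones(flags.shape, dtype=np.int64)
    index_of[flags] = np.arange(V)
    offsets = neighbor_offsets(params.connectivity)
    shape = flags.shape

    # precompute in-mask neighbor lists once; reused for every threshold
    neighbor_lists: list[np.ndarray] = []
    for c in coords:
        nb = c[None, :] + offsets
        valid = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
        nb = nb[valid]
        idx = index_of[nb[:, 0], nb[:, 1], nb[:, 2]]
        neighbor_lists.append(idx[idx >= 0])

    lfcd_maps, gfcd_maps, lrfcd_maps = {}, {}, {}
    normalized: dict[tuple[float, str], np.ndarray] = {}
    # correlation rows computed in chunks to bound memory on larger grids
    chunk = max(1, int(2**22 // max(V, 1)))
    gcounts = {th: np.zeros(V) for th in params.thresholds}
    supra_rows: dict[float, list] = {th: [] for th in params.thresholds}
    for start in range(0, V, chunk):
        rows = Z[start:start + chunk] @ Z.T  # r(i, .) for the chunk
        for th in params.thresholds:
            supra = rows > th
            supra[np.arange(rows.shape[0]), start + np.arange(rows.shape[0])] = False
            supra[:, ~ok] = False
            supra[~ok[start:start + chunk]] = False
            gcounts[th][start:start + chunk] = supra.sum(axis=1)
            supra_rows[th].append(supra)

    inside = flags
    for th in params.thresholds:
        supra = np.vstack(supra_rows[th])  # V x V boolean, seed-anchored
        lcounts = np.zeros(V)
        for i in range(V):
            if not ok[i]:
                continue
            row = supra[i]
            in_cluster = np.zeros(V, dtype=bool)
            in_cluster[i] = True
            queue = deque([i])
            size = 1
            while queue:
                j = queue.popleft()
                for k in neighbor_lists[j]:
                    if not in_cluster[k] and row[k]:
                        in_cluster[k] = True
                        size += 1
                        queue.append(k)
            lcounts[i] = size - 1
        for name, counts in (("lfcd", lcounts), ("gfcd", gcounts[th]),
                             ("lrfcd", gcounts[th] - lcounts)):
            m = np.full(shape, np.nan)
            m[inside] = counts
            {"lfcd": lfcd_maps, "gfcd": gfcd_maps, "lrfcd": lrfcd_maps}[name][th] = m
            norm_inside = inside.copy()
            norm_inside[inside] = ok  # zero-variance voxels excluded from mean
            normalized[(name, th)] = _normalize_map(m, norm_inside)

    zero_var = np.zeros(shape, dtype=bool)
    zero_var[inside] = ~ok
    return FCDMaps(
        thresholds=params.thresholds,
        lfcd=lfcd_maps,
        gfcd=gfcd_maps,
        lrfcd=lrfcd_maps,
        normalized=normalized,
        mask=mask,
        zero_variance=zero_var,
    )


def compute_dynamic_fcd(vol: Volume4D, mask: BrainMask,
                        params: FCDParams) -> list[FCDMaps]:
    """Sliding-window FCD: static FCD on each windowed sub-series.

    Windows start at 0, step, 2*step, ...; their count is
    floor((T - window) / step) + 1.
    """
    vol.require_timeseries("compute_dynamic_fcd")
    if params.window_trs is None:
        raise ContractError("dynamic FCD needs window_trs")
    window = int(params.window_trs)
    step = int(params.step_trs or 1)
    T = vol.n_vols
    if window > T:
        raise ContractError(f"window {window} exceeds run length {T}")
    if window < 10:
        raise ContractError("sliding window must span at least 10 TRs")
    starts = range(0, T - window + 1, step)
    out = []
    for s in starts:
        sub = vol.with_data(vol.data[..., s:s + window])
        out.append(compute_fcd(sub, mask, FCDParams(
            thresholds=params.thresholds, connectivity=params.connectivity)))
    return out


@dataclass
class FOCAMap:
    raw: np.ndarray
    normalized: np.ndarray
    flagged: np.ndarray
    neighborhood_size: int = 27
    combiner_tag: str = "rectified_product"


def _rectified_product(t: np.ndarray, s: np.ndarray) -> np.ndarray:
    return np.maximum(t, 0.0) * np.maximum(s, 0.0)


def compute_foca(vol: Volume4D, mask: BrainMask, combiner=None,
                 min_members: int = 9) -> FOCAMap:
    """Spatio-temporal consistency of each voxel's 27-voxel neighborhood.

    Per voxel: temporal consistency t_i = mean pairwise correlation among
    the neighborhood's time series; spatial consistency s_i = mean
    correlation between the neighborhood's spatial patterns at consecutive
    time points; FOCA = max(0, t_i) * max(0, s_i), which stays in [0, 1].
    Neighborhoods with fewer than ``min_members`` in-mask voxels or any
    zero-variance pattern score 0 and are flagged.
    """
    vol.require_timeseries("compute_foca")
    if vol.n_vols < 10:
        raise ContractError("FOCA needs at least 10 time points")
    mask.check_compatible(vol)
    if combiner is None:
        combiner = _rectified_product
        tag = "rectified_product"
    else:
        tag = getattr(combiner, "__name__", "custom")
    flags = mask.flags
    shape = flags.shape
    data = vol.data
    T = vol.n_vols
    offsets = np.array([(dx, dy, dz) for dx in (-1, 0, 1)
                        for dy in (-1, 0, 1) for dz in (-1, 0, 1)])
    raw = np.full(shape, np.nan)
    flagged = np.zeros(shape, dtype=bool)
    for c in np.argwhere(flags):
        nb = c[None, :] + offsets
        valid = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
        nb = nb[valid]
        inmask = flags[nb[:, 0], nb[:, 1], nb[:, 2]]
        nb = nb[inmask]
        n = nb.shape[0]
        if n < min_members:
            raw[tuple(c)] = 0.0
            flagged[tuple(c)] = True
            continue
        series = data[nb[:, 0], nb[:, 1], nb[:, 2]]  # n x T
        sd_t = series.std(axis=1)
        sd_s = series.std(axis=0)  # spatial pattern spread per time point
        if (sd_t == 0).any() or (sd_s == 0).any():
            raw[tuple(c)] = 0.0
            flagged[tuple(c)] = True
            continue
        Zt = (series - series.mean(axis=1, keepdims=True)) / (sd_t[:, None])
        R = (Zt @ Zt.T) / T
        t_i = (R.sum() - n) / (n * (n - 1))
        Zs = (series - series.mean(axis=0, keepdims=True)) / sd_s[None, :]
        s_corr = (Zs[:, :-1] * Zs[:, 1:]).sum(axis=0) / n
        s_i = s_corr.mean()
        raw[tuple(c)] = combiner(np.float64(t_i), np.float64(s_i))
    inside = flags & ~flagged
    if not inside.any():
        inside = flags
    normalized = _normalize_map(raw, inside)
    return FOCAMap(raw=raw, normalized=normalized, flagged=flagged,
                   combiner_tag=tag)


def dynamic_series_stats(series) -> dict:
    """Temporal-variability indices of a series of values or maps.

    Returns mean, sample SD, coefficient of variation (SD/mean), the mean
    point-by-point change |1 - v_t / v_{t-1}| and the mean relative ratio
    v_t / v_{t-1}.  Works elementwise when the series elements are arrays.
    Ratio-based indices are NaN-flagged wherever a preceding value is 0.
    """
    arr = np.asarray(series, dtype=np.float64)
    if arr.shape[0] < 2:
        raise ContractError("variability indices need a series of length >= 2")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sd / mean
        prev, cur = arr[:-1], arr[1:]
        ratio = np.where(prev != 0, cur / np.where(prev != 0, prev, 1.0), np.nan)
        point_change = np.abs(1.0 - ratio)
    return {
        "mean": mean,
        "sd": sd,
        "cov": cov,
        "mean_point_change": np.mean(point_change, axis=0),
        "mean_relative_ratio": np.mean(ratio, axis=0),
    }
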