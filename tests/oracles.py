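"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from the definitions, using a
different route than the library (scipy.ndimage flood fill instead of BFS,
eigendecomposition of the CCA normal equations instead of whitened SVD,
closed-form OLS instead of the vectorized fitter).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, ndimage


def fcd_bruteforce(data4d: np.ndarray, mask: np.ndarray, threshold: float,
                   connectivity: int):
    """gFCD/lFCD by full correlation matrix + scipy flood fill.

    lFCD(i) = size - 1 of the connected component containing i within the
    voxel set {i} + {j in mask : r(i, j) > threshold}.
    """
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }[connectivity]
    coords = np.argwhere(mask)
    series = data4d[mask]
    sd = series.std(axis=1)
    ok = sd > 0
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(series)
    R = np.nan_to_num(R)
    gfcd = np.zeros(len(coords))
    lfcd = np.zeros(len(coords))
    for i in range(len(coords)):
        if not ok[i]:
            continue
        supra = (R[i] > threshold) & ok
        supra[i] = False
        gfcd[i] = supra.sum()
        grid = np.zeros(mask.shape, dtype=bool)
        members = coords[supra]
        grid[members[:, 0], members[:, 1], members[:, 2]] = True
        grid[tuple(coords[i])] = True
        labels, _ = ndimage.label(grid, structure=structure)
        lab = labels[tuple(coords[i])]
        lfcd[i] = (labels == lab).sum() - 1
    gmap = np.full(mask.shape, np.nan)
    lmap = np.full(mask.shape, np.nan)
    gmap[mask] = gfcd
    lmap[mask] = lfcd
    return lmap, gmap


def cca_normal_equations(X: np.ndarray, Y: np.ndarray):
    """First canonical correlation from the standard normal equations."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc
    Syy = Yc.T @ Yc
    Sxy = Xc.T @ Yc
    M = linalg.solve(Sxx, Sxy) @ linalg.solve(Syy, Sxy.T)
    eigvals, eigvecs = linalg.eig(M)
    order = np.argsort(-np.real(eigvals))
    rho = float(np.sqrt(np.clip(np.real(eigvals[order[0]]), 0, 1)))
    a = np.real(eigvecs[:, order[0]])
    b = linalg.solve(Syy, Sxy.T @ a)
    return rho, a, b


def ols_t_closed_form(y: np.ndarray, X: np.ndarray, c: np.ndarray):
    """Scalar t-statistic from the textbook formulas."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * c @ XtX_inv @ c)
    return (c @ beta) / se, beta, dof


def direct_convolution_regressor(neural_dt: np.ndarray, hrf_dt: np.ndarray,
                                 bins_per_tr: int) -> np.ndarray:
    """Full-resolution discrete convolution sampled at volume starts."""
    conv = np.convolve(neural_dt, hrf_dt)[: neural_dt.size]
    return conv[::bins_per_tr]
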