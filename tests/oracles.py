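"""Independent oracles used to cross-check the implementation.

Each oracle reaches the target quantity by a different route than the
library (dense brute force, closed form, grid search with a linear
subproblem, or generic numeric optimization), so agreement is evidence and
not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def dense_argmax(bands, lo: float, hi: float, step: float = 0.01) -> float:
    """Brute-force argmax of a Gaussian mixture on a dense wavelength grid."""
    grid = np.arange(lo, hi + step / 2, step)
    total = np.zeros_like(grid)
    for center, width, amp in bands:
        total += amp * np.exp(-((grid - center) ** 2) / (2 * width**2))
    return float(grid[np.argmax(total)])


def gaussian_mixture_intensity(bands, wavelength: float) -> float:
    """Closed-form intensity of a Gaussian mixture at one wavelength."""
    return float(
        sum(a * np.exp(-((wavelength - c) ** 2) / (2 * w**2)) for c, w, a in bands)
    )


def mm_grid_search(concs, values, n_km: int = 4001):
    """Grid-search fit of y = vmax*c/(km+c) + a.

    For fixed km the model is linear in (vmax, a), so each grid point solves
    a 2-parameter linear least-squares problem exactly; km is scanned on a
    fine log grid.  Returns (vmax, km, a, rss).
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(values, dtype=float)
    cpos = c[c > 0]
    best = None
    for km in np.geomspace(cpos.min() / 100.0, cpos.max() * 100.0, n_km):
        u = c / (km + c)
        design = np.column_stack([u, np.ones_like(u)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((design @ coef - y) ** 2))
        if best is None or rss < best[3]:
            best = (float(coef[0]), float(km), float(coef[1]), rss)
    return best


def numeric_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over all rigid transforms, found by generic numeric
    optimization over a rotation vector and translation (no Kabsch)."""
    from scipy.spatial.transform import Rotation

    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)

    def cost(p):
        rot = Rotation.from_rotvec(p[:3])
        moved = rot.apply(mob) + p[3:]
        return np.mean(np.sum((moved - ref) ** 2, axis=1))

    best = None
    for k, rv in enumerate([
        np.zeros(3), np.array([np.pi, 0, 0]), np.array([0, np.pi, 0]),
        np.array([0, 0, np.pi]), np.array([1.0, 1.0, 1.0]),
    ]):
        p0 = np.concatenate([rv, ref.mean(axis=0) - mob.mean(axis=0)])
        res = minimize(cost, p0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        if best is None or res.fun < best:
            best = res.fun
    return float(np.sqrt(best))
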