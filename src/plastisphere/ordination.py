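"""Non-metric multidimensional scaling (Kruskal).

The configuration is updated by Guttman (SMACOF) transforms against
disparities obtained by monotone (pool-adjacent-violators) regression of
configuration distances on the rank order of the observed dissimilarities;
ties get the primary treatment (tied observations are free to take
different disparities).  An update is only accepted if it lowers stress-1,
so the recorded stress trajectory is non-increasing.  Starts are seeded
from classical (metric) MDS, with jitter added for every start after the
first, and the lowest-stress configuration wins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist

from .containers import Ordination

_EPS = 1e-12


def _as_matrix(dm) -> tuple[np.ndarray, list]:
    if hasattr(dm, "ids"):
        return np.asarray(dm.data, dtype=float), list(dm.ids)
    arr = np.asarray(dm, dtype=float)
    return arr, list(range(arr.shape[0]))


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centred matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _disparities(dhat: np.ndarray, order: np.ndarray) -> np.ndarray:
    fitted = isotonic_regression(dhat[order]).x
    out = np.empty_like(dhat)
    out[order] = fitted
    return out


def stress1(dhat: np.ndarray, disp: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(sum (dhat - d*)^2 / sum dhat^2)."""
    denom = float((dhat**2).sum())
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((dhat - disp) ** 2).sum() / denom))


def _guttman(x: np.ndarray, dhat: np.ndarray, disp: np.ndarray,
             iu: tuple) -> np.ndarray:
    n = x.shape[0]
    ratio = np.zeros((n, n))
    ratio[iu] = disp / np.maximum(dhat, _EPS)
    ratio = ratio + ratio.T
    b = -ratio
    np.fill_diagonal(b, ratio.sum(axis=1))
    return (b @ x) / n


def nmds(dm, k: int = 2, n_starts: int = 8, max_iter: int = 300,
         tol: float = 1e-9, seed: int | None = None) -> Ordination:
    """Best-of-``n_starts`` non-metric MDS of a dissimilarity matrix.

    Returns an :class:`Ordination` with coordinates centred at the origin,
    the final stress-1, and the stress history of the winning start.
    """
    d, ids = _as_matrix(dm)
    n = d.shape[0]
    if k < 1 or n_starts < 1:
        raise ValueError("k and n_starts must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")

    iu = np.triu_indices(n, k=1)
    dvec = d[iu]
    rng = np.random.default_rng(seed)
    init0 = _classical_mds(d, k)
    scale = max(np.abs(init0).max(), 1e-6)

    best = None
    for start in range(n_starts):
        x = init0.copy()
        if start > 0:
            x = x + rng.normal(0.0, 0.1 * scale, size=x.shape)
        dhat = pdist(x)
        disp = _disparities(dhat, _refine_order(dvec, dhat))
        stress = stress1(dhat, disp)
        history = [stress]
        converged = False
        for _ in range(max_iter):
            x_new = _guttman(x, dhat, disp, iu)
            dhat_new = pdist(x_new)
            disp_new = _disparities(dhat_new, _refine_order(dvec, dhat_new))
            stress_new = stress1(dhat_new, disp_new)
            if stress_new > stress - 1e-15:  # no improvement: keep previous
                converged = stress - stress_new < tol
                break
            x, dhat, disp = x_new, dhat_new, disp_new
            history.append(stress_new)
            if stress - stress_new < tol:
                converged = True
                stress = stress_new
                break
            stress = stress_new
        if best is None or stress < best[0]:
            best = (stress, x, converged, history)

    stress, x, converged, history = best
    x = x - x.mean(axis=0)
    coords = pd.DataFrame(x, index=ids, columns=[f"axis{i+1}" for i in range(k)])
    return Ordination(coords, stress, n_starts, converged, history)


def _refine_order(dvec: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    """Within blocks of tied dissimilarities, order by the current dhat."""
    return np.lexsort((dhat, dvec))
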