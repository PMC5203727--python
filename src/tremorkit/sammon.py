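"""Sammon nonlinear mapping to two dimensions.

Sammon's mapping places n points in the plane so that their pairwise
Euclidean distances d_ij reproduce the high-dimensional distances d*_ij
as closely as possible under the stress

    E = (1 / sum_{i<j} d*_ij) * sum_{i<j} (d*_ij - d_ij)^2 / d*_ij,

a weighted relative error that emphasises short distances and hence
local structure. Minimisation follows Sammon's original diagonal
pseudo-Newton iteration with a step "magic factor", safeguarded by step
halving so the recorded stress trace never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

_EPS = 1e-12


def _pairwise(coords: np.ndarray) -> np.ndarray:
    return squareform(pdist(coords))


def sammon_stress(d_high: np.ndarray, coords: np.ndarray) -> float:
    """Sammon stress of a 2-D configuration against target distances.

    ``d_high`` is a symmetric zero-diagonal distance matrix; pairs with
    zero target distance are excluded from the sum (they carry no
    weight and would divide by zero). An all-zero matrix is degenerate.
    """
    d_high = np.asarray(d_high, dtype=float)
    coords = np.asarray(coords, dtype=float)
    iu = np.triu_indices(d_high.shape[0], k=1)
    dstar = d_high[iu]
    keep = dstar > 0
    if not np.any(keep):
        raise ValueError("degenerate input: all pairwise distances are zero")
    dstar = dstar[keep]
    d_low = _pairwise(coords)[iu][keep]
    c = dstar.sum()
    return float(np.sum((dstar - d_low) ** 2 / dstar) / c)


@dataclass
class Projection2D:
    """Result of one Sammon run: planar coordinates and stress trace."""

    coords: np.ndarray
    stress: float
    stress_trace: list[float] = field(default_factory=list)
    seed: int | None = None
    converged: bool = False
    n_iter: int = 0


def _init_coords(
    X: np.ndarray, init: str, seed: int | None
) -> np.ndarray:
    if init == "pca":
        Xc = X - X.mean(axis=0)
        # deterministic principal components via SVD with sign convention
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
        U = U * signs
        k = min(2, U.shape[1])
        coords = np.zeros((X.shape[0], 2))
        coords[:, :k] = U[:, :k] * S[:k]
        return coords
    if init == "random":
        rng = np.random.default_rng(seed)
        return rng.standard_normal((X.shape[0], 2))
    raise ValueError(f"unknown init {init!r}")


def sammon_map(
    X: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-9,
    step_factor: float = 0.35,
    init: str = "pca",
    seed: int | None = 0,
) -> Projection2D:
    """Project rows of ``X`` to the plane by Sammon stress minimisation.

    Initialisation is the first two principal components (deterministic)
    or seeded random. Duplicate rows are jittered by 1e-9 x column SD so
    no target distance is exactly zero. Iteration stops at ``max_iter``
    or when the relative stress decrease falls below ``tol``; step
    halving on a stress increase keeps the trace monotone.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D array with at least 3 observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in projection input")

    D = _pairwise(X)
    iu = np.triu_indices(X.shape[0], k=1)
    if np.any(D[iu] == 0):
        rng = np.random.default_rng(seed if seed is not None else 0)
        col_sd = X.std(axis=0)
        scale = 1e-9 * np.where(col_sd > 0, col_sd, 1.0)
        X = X + rng.standard_normal(X.shape) * scale
        D = _pairwise(X)

    coords = _init_coords(X, init, seed)
    # guard a fully degenerate start (e.g. identical PCA scores)
    if np.allclose(coords, coords[0]):
        rng = np.random.default_rng(seed if seed is not None else 0)
        coords = coords + 1e-6 * rng.standard_normal(coords.shape)

    c = D[iu].sum()
    stress = sammon_stress(D, coords)
    trace = [stress]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = _pairwise(coords)
        np.fill_diagonal(d, 1.0)
        Dsafe = np.where(D > 0, D, 1.0)
        dsafe = np.where(d > _EPS, d, _EPS)

        delta = coords[:, None, :] - coords[None, :, :]  # (n, n, 2)
        dif = D - d
        w = np.where(D > 0, 1.0 / (Dsafe * dsafe), 0.0)
        np.fill_diagonal(w, 0.0)

        # gradient and diagonal Hessian of E wrt each coordinate
        g = -(2.0 / c) * np.einsum("ij,ij,ijk->ik", w, dif, delta)
        ratio = delta**2 / dsafe[:, :, None]
        h = -(2.0 / c) * np.einsum(
            "ij,ijk->ik",
            w,
            dif[:, :, None] - ratio * (1.0 + dif[:, :, None] / dsafe[:, :, None]),
        )
        step = np.where(np.abs(h) > _EPS, g / np.abs(h), 0.0)

        alpha = step_factor
        accepted = False
        for _ in range(20):
            cand = coords - alpha * step
            cand_stress = sammon_stress(D, cand)
            if cand_stress <= stress:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            converged = True
            break
        rel = (stress - cand_stress) / stress if stress > 0 else 0.0
        coords, stress = cand, cand_stress
        trace.append(stress)
        if rel < tol:
            converged = True
            break

    return Projection2D(
        coords=coords,
        stress=stress,
        stress_trace=trace,
        seed=seed,
        converged=converged,
        n_iter=it,
    )


def embed_new_points(
    projection: Projection2D,
    X_train: np.ndarray,
    X_new: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """Place new observations by inverse-distance interpolation.

    Sammon mapping has no native out-of-sample transform; in strict
    mode each new point is placed at the inverse-distance-weighted mean
    of the planar images of its ``k`` nearest training neighbours.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    out = np.empty((X_new.shape[0], 2))
    for i, xn in enumerate(X_new):
        dist = np.sqrt(((X_train - xn) ** 2).sum(axis=1))
        nearest = np.argsort(dist, kind="stable")[:k]
        wts = 1.0 / np.maximum(dist[nearest], _EPS)
        wts /= wts.sum()
        out[i] = wts @ projection.coords[nearest]
    return out
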