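"""Multivariate non-normal simulation (Vale–Maurelli construction).

Each feature's marginal is a Fleishman polynomial of a standard normal.
To hit a target correlation ``rho_Y`` between two transformed features,
the latent normal pair needs the *intermediate* correlation ``rho_Z``
solving the cubic

    rho_Y = rho_Z (b_i b_j + 3 b_i d_j + 3 d_i b_j + 9 d_i d_j)
            + 2 rho_Z**2 c_i c_j + 6 rho_Z**3 d_i d_j.

The pairwise intermediate matrix need not be positive semidefinite; it is
repaired by projection to the nearest correlation matrix before drawing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from .fleishman import FleishmanCoefficients, solve_fleishman

__all__ = [
    "CorrelationUnattainableError",
    "intermediate_correlation",
    "nearest_correlation",
    "simulate_features",
    "rescale_to_range",
]

#: eigenvalue floor applied when repairing a non-PSD intermediate matrix
EIGEN_FLOOR = 1e-8

#: tolerance on the polynomial root of the Vale–Maurelli cubic
ROOT_TOL = 1e-10


class CorrelationUnattainableError(ValueError):
    """Target correlation not attainable for the given pair of marginals."""


#: memo of prepared latent factors keyed by (marginals, target matrix)
_FACTOR_CACHE: dict = {}


def intermediate_correlation(
    rho_target: float,
    coef_i: FleishmanCoefficients,
    coef_j: FleishmanCoefficients,
) -> float:
    """Latent-normal correlation producing ``rho_target`` after transforming.

    Returns the real root of the Vale–Maurelli cubic in [-1, 1] nearest the
    target; raises :class:`CorrelationUnattainableError` when no such root
    exists.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError(f"target correlation {rho_target} outside [-1, 1]")
    bi, ci, di = coef_i.b, coef_i.c, coef_i.d
    bj, cj, dj = coef_j.b, coef_j.c, coef_j.d
    lin = bi * bj + 3 * bi * dj + 3 * di * bj + 9 * di * dj
    quad = 2 * ci * cj
    cub = 6 * di * dj
    coeffs = np.array([cub, quad, lin, -rho_target])
    # strip (numerically) zero leading coefficients before root-finding
    nz = np.flatnonzero(np.abs(coeffs) > ROOT_TOL)
    if nz.size == 0:
        return 0.0
    coeffs = coeffs[nz[0]:]
    if coeffs.size == 1:
        raise CorrelationUnattainableError(
            f"degenerate marginals cannot attain correlation {rho_target}"
        )
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    real = real[(real >= -1.0 - 1e-9) & (real <= 1.0 + 1e-9)]
    if real.size == 0:
        raise CorrelationUnattainableError(
            f"correlation {rho_target} unattainable for the given marginals"
        )
    best = real[np.argmin(np.abs(real - rho_target))]
    return float(np.clip(best, -1.0, 1.0))


def nearest_correlation(matrix: np.ndarray, eigen_floor: float = EIGEN_FLOOR) -> np.ndarray:
    """Nearest (Frobenius) correlation matrix with min eigenvalue >= floor.

    PSD inputs are returned unchanged (as a copy). Non-symmetric input is
    an error.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.min(np.linalg.eigvalsh(m)) >= eigen_floor:
        return m.copy()
    # bounded alternating projections, then a clip/renormalize polish to
    # guarantee the eigenvalue floor (corr_nearest alone converges to the
    # floor only asymptotically)
    n_fact = max(1.0, 400.0 / m.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        repaired = np.asarray(corr_nearest(m, threshold=eigen_floor, n_fact=n_fact), dtype=float)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    for _ in range(50):
        w, v = np.linalg.eigh(repaired)
        if w[0] >= eigen_floor * (1 - 1e-6):
            break
        w = np.clip(w, eigen_floor, None)
        repaired = (v * w) @ v.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        repaired = (repaired + repaired.T) / 2.0
        np.fill_diagonal(repaired, 1.0)
    return repaired


def _intermediate_matrix(
    coefs: list[FleishmanCoefficients], target: np.ndarray, feature_ids: list[str]
) -> np.ndarray:
    p = len(coefs)
    inter = np.eye(p)
    cache: dict[tuple, float] = {}
    for i in range(p):
        for j in range(i + 1, p):
            rho = float(target[i, j])
            key = (coefs[i], coefs[j], rho)
            if key not in cache:
                try:
                    cache[key] = intermediate_correlation(rho, coefs[i], coefs[j])
                except CorrelationUnattainableError as exc:
                    raise CorrelationUnattainableError(
                        f"pair ({feature_ids[i]}, {feature_ids[j]}): {exc}"
                    ) from exc
            inter[i, j] = inter[j, i] = cache[key]
    return inter


def simulate_features(specs, corr, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` samples of correlated non-normal features.

    Parameters
    ----------
    specs : list of MomentSpec
        Per-feature targets (skewness, excess kurtosis); order defines the
        column order.
    corr : CorrelationTarget or DataFrame or ndarray
        Target correlation on the transformed (outcome) scale.
    n : int
        Number of samples.
    seed : int
        Seed of the dedicated random stream; same seed, same matrix.

    Returns samples on the standardized scale (zero mean, unit variance per
    feature in population); use :func:`rescale_to_range` to map to feature
    ranges.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = [s.feature_id for s in specs]
    matrix = getattr(corr, "matrix", corr)
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.loc[ids, ids].to_numpy(dtype=float)
    else:
        matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(ids), len(ids)):
        raise ValueError("correlation matrix does not match the feature specs")

    solved: dict[tuple[float, float], FleishmanCoefficients] = {}
    coefs = []
    for s in specs:
        key = (float(s.skewness), float(s.excess_kurtosis))
        if key not in solved:
            try:
                solved[key] = solve_fleishman(*key)
            except Exception as exc:
                raise type(exc)(f"feature {s.feature_id}: {exc}") from exc
        coefs.append(solved[key])

    # the prepared factor depends only on (marginals, target matrix): cache
    # it so repeated scenario builds skip the pairwise root-finding
    cache_key = (tuple(coefs), matrix.tobytes())
    factor = _FACTOR_CACHE.get(cache_key)
    if factor is None:
        inter = _intermediate_matrix(coefs, matrix, ids)
        inter = nearest_correlation(inter)
        # eigendecomposition factor: robust to the floored smallest eigenvalues
        w, v = np.linalg.eigh(inter)
        w = np.clip(w, 0.0, None)
        factor = v * np.sqrt(w)
        if len(_FACTOR_CACHE) > 8:
            _FACTOR_CACHE.clear()
        _FACTOR_CACHE[cache_key] = factor

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(ids))) @ factor.T
    out = np.empty_like(z)
    for k, coef in enumerate(coefs):
        out[:, k] = coef(z[:, k])
    return pd.DataFrame(out, columns=ids)


def rescale_to_range(values, range_min: float, range_max: float) -> np.ndarray:
    """Affine min-max map of ``values`` onto [range_min, range_max]."""
    if not range_min < range_max:
        raise ValueError("range_min must be < range_max")
    v = np.asarray(values, dtype=float)
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        raise ValueError("cannot rescale a constant vector (undefined scale)")
    return range_min + (v - lo) * (range_max - range_min) / (hi - lo)
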