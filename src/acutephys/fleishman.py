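"""Fleishman power-method margins and Vale-Maurelli intermediate correlations.

A Fleishman transform maps a standard normal Z to

    Y = a + b*Z + c*Z**2 + d*Z**3,   with a = -c,

choosing (b, c, d) so that Y has mean 0, variance 1 and prescribed skewness
and excess kurtosis.  Coupling several such margins through a multivariate
normal with an *intermediate* correlation matrix (Vale-Maurelli) yields a
non-normal random vector with the target marginal moments and target
product-moment correlations.  This parameterization is fully determined by
(mean, covariance, skewness, kurtosis) -- exactly the subgroup summaries the
longitudinal simulator is asked to match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


class InfeasibleMomentsError(ValueError):
    """Skewness/kurtosis pair outside the attainable region."""


@dataclass(frozen=True)
class FleishmanCoeffs:
    """Coefficients of Y = a + b Z + c Z^2 + d Z^3 with a = -c."""

    a: float
    b: float
    c: float
    d: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        return self.a + z * (self.b + z * (self.c + z * self.d))


def _moment_residuals(bcd: np.ndarray, skew: float, exkurt: float) -> np.ndarray:
    b, c, d = bcd
    var = b * b + 6.0 * b * d + 2.0 * c * c + 15.0 * d * d
    g1 = 2.0 * c * (b * b + 24.0 * b * d + 105.0 * d * d + 2.0)
    g2 = 24.0 * (
        b * d
        + c * c * (1.0 + b * b + 28.0 * b * d)
        + d * d * (12.0 + 48.0 * b * d + 141.0 * c * c + 225.0 * d * d)
    )
    return np.array([var - 1.0, g1 - skew, g2 - exkurt])


#: Fixed starting points tried in order; first converged root with b >= 0 wins,
#: keeping the solver deterministic.
_STARTS = (
    (1.0, 0.0, 0.0),
    (0.9, 0.15, 0.03),
    (0.75, 0.3, 0.08),
    (0.6, 0.4, 0.12),
    (1.05, 0.1, -0.05),
)


def fleishman_solve(skew: float, exkurt: float, tol: float = 1e-10) -> FleishmanCoeffs:
    """Solve the Fleishman moment equations for (skew, excess kurtosis).

    Raises :class:`InfeasibleMomentsError` when the pair violates the
    general attainability bound ``exkurt >= skew**2 - 2`` or lies outside
    the region the cubic transform can reach.
    """
    skew = float(skew)
    exkurt = float(exkurt)
    if exkurt < skew**2 - 2.0:
        raise InfeasibleMomentsError(
            f"(skew={skew}, exkurt={exkurt}) violates the attainability bound "
            "exkurt >= skew**2 - 2"
        )
    if skew == 0.0 and exkurt == 0.0:
        return FleishmanCoeffs(0.0, 1.0, 0.0, 0.0)
    sign = 1.0 if skew >= 0 else -1.0
    target = abs(skew)
    for start in _STARTS:
        sol = optimize.root(
            _moment_residuals, np.array(start), args=(target, exkurt), method="hybr"
        )
        if not sol.success:
            continue
        b, c, d = sol.x
        if b < 0:  # reflect to the increasing-branch solution
            b, c, d = -b, -c, -d
            if np.max(np.abs(_moment_residuals(np.array([b, c, d]), target, exkurt))) > tol:
                continue
        res = np.max(np.abs(_moment_residuals(sol.x, target, exkurt)))
        if res < tol:
            return FleishmanCoeffs(-sign * c, b, sign * c, d)
    raise InfeasibleMomentsError(
        f"no Fleishman solution for (skew={skew}, exkurt={exkurt}); the pair "
        "lies outside the cubic transform's attainable region (general bound: "
        "exkurt >= skew**2 - 2, the cubic region is slightly smaller)"
    )


def _rho_y(rho_z: float, ci: FleishmanCoeffs, cj: FleishmanCoeffs) -> float:
    """Correlation of two Fleishman margins as a cubic in the normal correlation."""
    lin = (
        ci.b * cj.b + 3.0 * ci.b * cj.d + 3.0 * ci.d * cj.b + 9.0 * ci.d * cj.d
    )
    return rho_z * lin + 2.0 * rho_z**2 * ci.c * cj.c + 6.0 * rho_z**3 * ci.d * cj.d


def intermediate_correlation(
    coeffs_i: FleishmanCoeffs,
    coeffs_j: FleishmanCoeffs,
    target_rho: float,
    tol: float = 1e-10,
) -> float:
    """Normal-scale correlation whose transformed margins correlate at target.

    Solves the Vale-Maurelli cubic ``rho_Y(rho_Z) = target`` by bracketing on
    [-1, 1]; raises :class:`InfeasibleMomentsError` with the attainable range
    when the target cannot be reached.
    """
    if not -1.0 <= target_rho <= 1.0:
        raise ValueError("target correlation must lie in [-1, 1]")
    if target_rho == 0.0:
        return 0.0
    lo, hi = _rho_y(-1.0, coeffs_i, coeffs_j), _rho_y(1.0, coeffs_i, coeffs_j)
    if not (min(lo, hi) - 1e-12 <= target_rho <= max(lo, hi) + 1e-12):
        raise InfeasibleMomentsError(
            f"target correlation {target_rho} outside the attainable range "
            f"[{min(lo, hi):.6f}, {max(lo, hi):.6f}] for these margins"
        )
    f = lambda r: _rho_y(r, coeffs_i, coeffs_j) - target_rho
    return float(optimize.brentq(f, -1.0, 1.0, xtol=tol))


def intermediate_corr_matrix(
    coeffs: "list[FleishmanCoeffs]", target: np.ndarray
) -> np.ndarray:
    """Pairwise intermediate correlation matrix, repaired to PSD if needed.

    The pairwise Vale-Maurelli solution is not guaranteed jointly positive
    semidefinite; negative eigenvalues are clipped at 1e-10 and the matrix
    rescaled to unit diagonal (the adjustment is logged-free since it is a
    deterministic numerical repair of at most O(1e-8) for the presets used).
    """
    T = len(coeffs)
    R = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            R[i, j] = R[j, i] = intermediate_correlation(
                coeffs[i], coeffs[j], float(target[i, j])
            )
    w, V = np.linalg.eigh(R)
    if w.min() < 0:
        w = np.clip(w, 1e-10, None)
        R = V @ np.diag(w) @ V.T
        s = np.sqrt(np.diag(R))
        R = R / np.outer(s, s)
    return R
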