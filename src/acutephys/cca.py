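"""Permutation-tuned sparse canonical correlation analysis.

Implements the penalized matrix decomposition (PMD) formulation of sparse
CCA: rank-1 pairs (u, v) maximizing u' X' Z v subject to ||u||2 <= 1,
||v||2 <= 1 and L1 budgets ||u||1 <= c_x, ||v||1 <= c_z, fitted by
alternating soft-thresholded power iterations with the thresholds chosen
by bisection.  Regularization is tuned by comparing the Fisher-z of the
achieved canonical correlation on the real pairing against its
distribution over row-permuted data; successive variates are extracted by
deflating the cross-product matrix.

Intended use: baseline (pre-exercise) metabolite profiles in one domain
and exercise phenotypes (CPET / strength / anthropometrics) in the other.
Missing trait values are mean-imputed with a flag; traits are standardized
globally (not per sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("acutephys")


def standardize(X: "pd.DataFrame | np.ndarray", impute_mean: bool = True):
    """Column-standardize to mean 0, SD 1; optionally mean-impute missing."""
    A = np.asarray(X, dtype=float)
    if impute_mean and np.isnan(A).any():
        col_mean = np.nanmean(A, axis=0)
        idx = np.where(np.isnan(A))
        A = A.copy()
        A[idx] = np.take(col_mean, idx[1])
        logger.info("standardize: mean-imputed %d missing entries", len(idx[0]))
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant column(s); drop before CCA")
    return (A - mu) / sd


def _soft(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _l1_project(a: np.ndarray, c: float) -> np.ndarray:
    """Soft-threshold + L2-normalize so that ||out||2 = 1 and ||out||1 <= c."""
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("all-zero vector in PMD update")
    out = a / norm
    if np.sum(np.abs(out)) <= c:
        return out
    # bisect the soft threshold until the L1 budget is met
    lo, hi = 0.0, np.abs(a).max()
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s = _soft(a, mid)
        ns = np.linalg.norm(s)
        if ns == 0:
            hi = mid
            continue
        l1 = np.abs(s).sum() / ns
        if l1 > c:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * (1 + np.abs(a).max()):
            break
    s = _soft(a, hi)
    ns = np.linalg.norm(s)
    if ns == 0:
        # budget c = 1 vertex: keep the single largest coordinate
        s = np.zeros_like(a)
        j = int(np.argmax(np.abs(a)))
        s[j] = np.sign(a[j])
        return s
    return s / ns


def pmd_rank1(
    X: np.ndarray,
    Z: np.ndarray,
    c_x: float,
    c_z: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple:
    """Rank-1 sparse CCA factor: returns (u, v, r).

    Columns of X and Z must be standardized; penalties lie in [1, sqrt(p)].
    With c_x = sqrt(p), c_z = sqrt(q) (no active L1 constraint) the result
    is the leading singular pair of X'Z.
    """
    p, q = X.shape[1], Z.shape[1]
    for c, dim, name in ((c_x, p, "c_x"), (c_z, q, "c_z")):
        if not 1.0 <= c <= np.sqrt(dim) + 1e-9:
            raise ValueError(f"{name}={c} outside [1, sqrt({dim})]")
    C = X.T @ Z
    if not np.any(C):
        raise ValueError("all-zero cross-product matrix")
    # deterministic start: leading right singular vector direction
    v = C.sum(axis=0)
    if not np.any(v):
        v = np.ones(q)
    v = v / np.linalg.norm(v)
    u = np.zeros(p)
    for _ in range(max_iter):
        u_new = _l1_project(C @ v, c_x)
        v_new = _l1_project(C.T @ u_new, c_z)
        if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
            u, v = u_new, v_new
            break
        u, v = u_new, v_new
    xu, zv = X @ u, Z @ v
    denom = np.linalg.norm(xu) * np.linalg.norm(zv)
    r = float(xu @ zv / denom) if denom > 0 else 0.0
    # sign convention: the largest-|weight| trait coordinate is positive
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        u, v, = -u, -v
    return u, v, r


def _fisher_z(r: float) -> float:
    r = np.clip(r, -0.999999, 0.999999)
    return float(np.arctanh(r))


def permutation_tune(
    X: np.ndarray,
    Z: np.ndarray,
    penalty_grid,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple:
    """Select (c_x, c_z) by the permutation z-statistic of the first factor.

    For each grid point the Fisher-z of the real canonical correlation is
    standardized against its null distribution over row-permutations of X;
    the grid point with the largest standardized gap wins.  Returns
    (best (c_x, c_z), DataFrame of z per grid point).
    """
    if n_perm < 50:
        raise ValueError("need at least 50 permutations for a stable null")
    grid = list(penalty_grid)
    if not grid:
        raise ValueError("empty penalty grid")
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(X.shape[0]) for _ in range(n_perm)]
    rows = []
    for c_x, c_z in grid:
        _, _, r = pmd_rank1(X, Z, c_x, c_z)
        z_real = _fisher_z(r)
        z_null = np.empty(n_perm)
        for b, perm in enumerate(perms):
            _, _, rb = pmd_rank1(X[perm], Z, c_x, c_z)
            z_null[b] = _fisher_z(rb)
        sd = z_null.std(ddof=1)
        if sd == 0:
            logger.info("grid point (%s, %s) skipped: zero permutation SD", c_x, c_z)
            continue
        rows.append(
            {"c_x": c_x, "c_z": c_z, "r": r,
             "z_stat": (z_real - z_null.mean()) / sd}
        )
    report = pd.DataFrame(rows)
    if report.empty:
        raise ValueError("no usable grid points")
    best = report.loc[report["z_stat"].idxmax()]
    return (float(best["c_x"]), float(best["c_z"])), report


@dataclass
class CcaModel:
    """Sparse CCA result: K variates with weights and correlations."""

    u: pd.DataFrame  # features x K (metabolite-domain weights)
    v: pd.DataFrame  # traits x K (trait-domain weights)
    correlations: np.ndarray  # (K,)
    penalties: tuple
    permutation_z: "pd.DataFrame | None" = None

    @property
    def n_variates(self) -> int:
        return self.u.shape[1]

    def loadings_table(self) -> pd.DataFrame:
        """Long-format (domain, variable, variate, weight) table for reporting."""
        rows = []
        for k in range(self.n_variates):
            col = self.u.columns[k]
            for name, w in self.u[col].items():
                if w != 0:
                    rows.append({"domain": "metabolite", "variable": name,
                                 "variate": k + 1, "weight": float(w)})
            for name, w in self.v[col].items():
                if w != 0:
                    rows.append({"domain": "trait", "variable": name,
                                 "variate": k + 1, "weight": float(w)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Sparse CCA: {self.n_variates} variate(s), penalties {self.penalties}"]
        for k in range(self.n_variates):
            col = self.u.columns[k]
            nu = int((self.u[col] != 0).sum())
            nv = int((self.v[col] != 0).sum())
            lines.append(
                f"  variate {k+1}: r = {self.correlations[k]:.3f}, "
                f"{nu} metabolite / {nv} trait weights"
            )
        return "\n".join(lines)


def extract_variates(
    X, Z, penalties: tuple, K: int = 3,
    x_names=None, z_names=None,
) -> CcaModel:
    """Successive rank-1 sparse CCA factors on the deflated cross-product.

    After each factor the cross-product is deflated by the PMD projection
    C <- C - (u'Cv) u v'; if the deflated matrix is numerically zero,
    fewer than K variates are returned with a log message.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    c_x, c_z = penalties
    if K > min(X.shape[1], Z.shape[1]):
        raise ValueError("K exceeds the smaller domain dimension")
    C = X.T @ Z
    us, vs, rs = [], [], []
    scale = np.abs(C).max()
    for k in range(K):
        if np.abs(C).max() <= 1e-12 * max(scale, 1.0):
            logger.info("extract_variates: deflated matrix ~0 after %d variates", k)
            break
        u, v, _ = _pmd_rank1_on_cross(C, X, Z, c_x, c_z)
        d = float(u @ C @ v)
        xu, zv = X @ u, Z @ v
        denom = np.linalg.norm(xu) * np.linalg.norm(zv)
        r = float(xu @ zv / denom) if denom > 0 else 0.0
        us.append(u)
        vs.append(v)
        rs.append(r)
        C = C - d * np.outer(u, v)
    cols = [f"variate{k+1}" for k in range(len(us))]
    x_names = list(x_names) if x_names is not None else [f"x{i}" for i in range(X.shape[1])]
    z_names = list(z_names) if z_names is not None else [f"z{i}" for i in range(Z.shape[1])]
    return CcaModel(
        u=pd.DataFrame(np.array(us).T, index=x_names, columns=cols),
        v=pd.DataFrame(np.array(vs).T, index=z_names, columns=cols),
        correlations=np.array(rs),
        penalties=penalties,
    )


def _pmd_rank1_on_cross(C, X, Z, c_x, c_z, tol=1e-8, max_iter=1000):
    """PMD alternating updates on a (possibly deflated) cross-product."""
    p, q = C.shape
    v = C.sum(axis=0)
    if not np.any(v):
        v = np.ones(q)
    v = v / np.linalg.norm(v)
    u = np.zeros(p)
    for _ in range(max_iter):
        u_new = _l1_project(C @ v, c_x)
        v_new = _l1_project(C.T @ u_new, c_z)
        if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
            u, v = u_new, v_new
            break
        u, v = u_new, v_new
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        u, v = -u, -v
    return u, v, float(u @ C @ v)


def sparse_cca(
    metabolites: pd.DataFrame,
    traits: pd.DataFrame,
    K: int = 3,
    penalty_grid=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> CcaModel:
    """End-to-end: standardize, permutation-tune penalties, extract variates.

    ``metabolites`` and ``traits`` are samples x variables DataFrames on
    matching row order (e.g. baseline plasma metabolites vs CPET/strength/
    anthropometric phenotypes).
    """
    X = standardize(metabolites)
    Z = standardize(traits)
    p, q = X.shape[1], Z.shape[1]
    if penalty_grid is None:
        cx_grid = np.linspace(1.0, np.sqrt(p), 5)
        cz_grid = np.linspace(1.0, np.sqrt(q), 5)
        penalty_grid = [(a, b) for a in cx_grid for b in cz_grid]
    best, report = permutation_tune(X, Z, penalty_grid, n_perm=n_perm, seed=seed)
    model = extract_variates(
        X, Z, best, K=K,
        x_names=metabolites.columns, z_names=traits.columns,
    )
    model.permutation_z = report
    return model
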