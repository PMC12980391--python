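"""Model-selection benchmark: type-I error and power of six analytic strategies.

Each simulated replicate is one molecular feature measured on the full
repeated-measures design (participants x timepoints, with temporal-profile
missingness).  Every strategy reduces a replicate to a p-value for the same
difference-in-changes hypothesis:

* ``paired_t``            two-sample t-test on per-participant change scores
                          (exercise vs control),
* ``ols``                 cell-means regression ignoring within-participant
                          correlation,
* ``lmm_ri``              random-intercept LMM, Satterthwaite t-test,
* ``lmm_ri_weighted``     the same engine with voom-style precision weights
                          (weights apply only to count-mode data; on
                          continuous scenarios it coincides with lmm_ri),
* ``mmrm_unstructured``   multivariate-normal ML with an unstructured
                          timepoint covariance (EM over missing patterns),
                          Wald t with a cluster-level df,
* ``gee_ar1``             GEE with AR(1) working correlation and robust
                          sandwich covariance, Wald z (deliberately without
                          a small-sample correction, which is what produces
                          the inflation the benchmark is designed to expose).

All engines are vectorized across replicates sharing one realized design,
mirroring how the simulated design was matched to the observed study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from . import core
from .simulate import LongitudinalSimulator, SimScenario, preset_scenario, simulate_design

STRATEGIES = (
    "paired_t",
    "ols",
    "lmm_ri_weighted",
    "lmm_ri",
    "mmrm_unstructured",
    "gee_ar1",
)

_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-6, 6, 61)])


def analytic_power_two_sample_t(
    effect_size: float, n_per_group: int, alpha: float = 0.05
) -> float:
    """Exact noncentral-t power of a two-sided two-sample t-test."""
    return float(
        TTestIndPower().power(
            effect_size=effect_size, nobs1=n_per_group, alpha=alpha, ratio=1.0
        )
    )


class BenchDesign:
    """One realized study design shared by all replicates of a scenario."""

    def __init__(self, scenario: SimScenario, rng: np.random.Generator):
        self.scenario = scenario
        self.meta = simulate_design(scenario, rng)
        X, col_map = core.build_cell_means_design(self.meta, covariates=("sex",))
        self.X = X.to_numpy()
        self.columns = list(X.columns)
        self.cells = col_map["cells"]
        spec = core.delta_delta_contrast(
            self.cells, scenario.effect_group, scenario.effect_timepoint
        )
        self.contrast = spec
        self.L = spec.vector(self.columns)
        parts, self.cluster_idx = np.unique(
            self.meta["participant_id"], return_inverse=True
        )
        self.n_clusters = len(parts)
        self.tp_idx = self.meta["tp_index"].to_numpy()
        self.n_obs, self.p = self.X.shape
        # per-cluster row indices and missingness patterns
        self.cluster_rows = [
            np.where(self.cluster_idx == c)[0] for c in range(self.n_clusters)
        ]
        self.patterns: dict = {}
        for c, rows in enumerate(self.cluster_rows):
            key = tuple(self.tp_idx[rows])
            self.patterns.setdefault(key, []).append(c)
        # subgroup slot bookkeeping for fast value mapping
        sub = self.meta.drop_duplicates("participant_id")
        slot_of: dict = {}
        counters: dict = {}
        for _, row in sub.iterrows():
            key = (row["sex"], row["group"])
            counters[key] = counters.get(key, -1) + 1
            slot_of[row["participant_id"]] = (key, counters[key])
        self._row_map: dict = {}
        for j, (_, row) in enumerate(self.meta.iterrows()):
            key, slot = slot_of[row["participant_id"]]
            self._row_map.setdefault(key, ([], [], []))
            self._row_map[key][0].append(j)
            self._row_map[key][1].append(slot)
            self._row_map[key][2].append(row["tp_index"])

    def realize(self, sim: LongitudinalSimulator, n_features: int,
                rng: np.random.Generator) -> np.ndarray:
        """Draw an (n_obs, n_features) response matrix on this design."""
        wide = sim.draw_wide(n_features, rng)
        Y = np.empty((self.n_obs, n_features))
        for key, (rows, slots, tps) in self._row_map.items():
            Y[np.array(rows)] = wide[key][np.array(slots), np.array(tps), :]
        return Y


# ---------------------------------------------------------------------------
# vectorized strategy engines: each maps Y (n_obs, F) -> (p, estimate, n_fail)
# ---------------------------------------------------------------------------


def _paired_rows(design: BenchDesign, group: str):
    tp = design.scenario.timepoints.index(design.scenario.effect_timepoint)
    meta = design.meta
    pre_rows, tp_rows = [], []
    for rows in design.cluster_rows:
        if meta.iloc[rows[0]]["group"] != group:
            continue
        tps = design.tp_idx[rows]
        has_pre = np.where(tps == 0)[0]
        has_tp = np.where(tps == tp)[0]
        if len(has_pre) and len(has_tp):
            pre_rows.append(rows[has_pre[0]])
            tp_rows.append(rows[has_tp[0]])
    return np.array(pre_rows), np.array(tp_rows)


def paired_t_engine(Y: np.ndarray, design: BenchDesign):
    """Pooled two-sample t on (tp - pre) change scores, exercise vs control."""
    g_ex = design.scenario.effect_group
    g_con = "CON"
    pre_e, tp_e = _paired_rows(design, g_ex)
    pre_c, tp_c = _paired_rows(design, g_con)
    d_e = Y[tp_e] - Y[pre_e]
    d_c = Y[tp_c] - Y[pre_c]
    n1, n2 = d_e.shape[0], d_c.shape[0]
    est = d_e.mean(axis=0) - d_c.mean(axis=0)
    s2 = (
        d_e.var(axis=0, ddof=1) * (n1 - 1) + d_c.var(axis=0, ddof=1) * (n2 - 1)
    ) / (n1 + n2 - 2)
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), n1 + n2 - 2)
    return p, est, 0


def ols_engine(Y: np.ndarray, design: BenchDesign):
    """Cell-means OLS treating all observations as independent."""
    X, L = design.X, design.L
    n, p = X.shape
    G = np.linalg.inv(X.T @ X)
    beta = G @ (X.T @ Y)
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / (n - p)
    est = L @ beta
    se = np.sqrt(s2 * float(L @ G @ L))
    t = est / se
    pv = 2.0 * stats.t.sf(np.abs(t), n - p)
    return pv, est, 0


def _spectral_design(design: BenchDesign):
    Z = np.zeros((design.n_obs, design.n_clusters))
    Z[np.arange(design.n_obs), design.cluster_idx] = 1.0
    d, U = np.linalg.eigh(Z @ Z.T)
    return np.clip(d, 0.0, None), U


def _batched_contrast_var(su2, se2, d, Xt, L):
    """c(theta) = Var(L'beta) per feature; su2, se2 are (F,) arrays."""
    v = se2[None, :] + su2[None, :] * d[:, None]  # (n, F)
    W = 1.0 / v
    M = np.einsum("nf,np,nq->fpq", W, Xt, Xt, optimize=True)
    sol = np.linalg.solve(M, np.broadcast_to(L, (M.shape[0], len(L)))[:, :, None])[:, :, 0]
    return sol @ L


def _batched_crit(su2, se2, d, Xt, Yt, L=None):
    """-2 REML log-likelihood per feature at absolute variances."""
    su2 = np.maximum(su2, 0.0)
    v = se2[None, :] + su2[None, :] * d[:, None]
    W = 1.0 / v
    M = np.einsum("nf,np,nq->fpq", W, Xt, Xt, optimize=True)
    sign, logdetM = np.linalg.slogdet(M)
    WY = W * Yt
    b = np.einsum("nf,np->fp", WY, Xt, optimize=True)
    beta = np.linalg.solve(M, b[:, :, None])[:, :, 0]
    q = (WY * Yt).sum(axis=0) - (b * beta).sum(axis=1)
    crit = np.log(v).sum(axis=0) + logdetM + q
    crit[(sign <= 0) | (q <= 0)] = np.inf
    return crit


def lmm_engine(Y: np.ndarray, design: BenchDesign, weights=None):
    """Batched random-intercept REML + Satterthwaite contrast test.

    Shares a single eigendecomposition of the cluster structure across all
    features; profiles the REML criterion on a log-spaced variance-ratio
    grid with parabolic refinement.  Agrees with
    :func:`acutephys.lmm.fit_feature_lmm` (checked in the test suite).
    """
    X, L = design.X, design.L
    n, p = X.shape
    F = Y.shape[1]
    if weights is not None:
        sw = np.sqrt(weights)
        Y = Y * sw[:, None] if weights.ndim == 1 else Y * np.sqrt(weights)
        X = X * (sw[:, None] if weights.ndim == 1 else 1.0)
    d, U = _spectral_design(design)
    Xt, Yt = U.T @ X, U.T @ Y

    grid = _LAMBDA_GRID
    crits = np.empty((len(grid), F))
    for gi, lam in enumerate(grid):
        v = 1.0 + lam * d
        W = 1.0 / v
        M = Xt.T @ (Xt * W[:, None])
        sign, logdetM = np.linalg.slogdet(M)
        WY = W[:, None] * Yt
        b = Xt.T @ WY
        beta = np.linalg.solve(M, b)
        q = (WY * Yt).sum(axis=0) - (b * beta).sum(axis=0)
        crits[gi] = np.log(v).sum() + logdetM + (n - p) * np.log(q)
    best = np.argmin(crits, axis=0)
    lam_hat = grid[best]
    # parabolic refinement in log-lambda for interior grid optima
    interior = (best > 1) & (best < len(grid) - 1)
    if interior.any():
        bi = best[interior]
        x0, x1, x2 = np.log(grid[bi - 1]), np.log(grid[bi]), np.log(grid[bi + 1])
        f0 = crits[bi - 1, np.where(interior)[0]]
        f1 = crits[bi, np.where(interior)[0]]
        f2 = crits[bi + 1, np.where(interior)[0]]
        denom = (f0 - 2 * f1 + f2)
        shift = np.where(
            np.abs(denom) > 1e-12, 0.5 * (f0 - f2) / np.where(denom == 0, 1, denom), 0.0
        )
        shift = np.clip(shift, -1.0, 1.0)
        lam_hat[interior] = np.exp(x1 + shift * (x2 - x1) / 2 + shift * (x1 - x0) / 2)

    # final per-feature quantities at lam_hat
    v = 1.0 + lam_hat[None, :] * d[:, None]
    W = 1.0 / v
    M = np.einsum("nf,np,nq->fpq", W, Xt, Xt, optimize=True)
    WY = W * Yt
    b = np.einsum("nf,np->fp", WY, Xt, optimize=True)
    beta = np.linalg.solve(M, b[:, :, None])[:, :, 0]
    q = (WY * Yt).sum(axis=0) - (b * beta).sum(axis=1)
    se2 = q / (n - p)
    su2 = lam_hat * se2
    est = beta @ L
    sol = np.linalg.solve(M, np.broadcast_to(L, (F, p))[:, :, None])[:, :, 0]
    c = (sol @ L) * se2

    # Satterthwaite df, batched finite differences in (sigma_u^2, sigma_e^2)
    h_u = np.maximum(su2, se2) * 1e-4
    h_e = se2 * 1e-4
    cvar = lambda a, b_: _batched_contrast_var(a, b_, d, Xt, L)
    g_u = (cvar(su2 + h_u, se2) - cvar(np.maximum(su2 - h_u, 0.0), se2)) / (
        su2 + h_u - np.maximum(su2 - h_u, 0.0)
    )
    g_e = (cvar(su2, se2 + h_e) - cvar(su2, se2 - h_e)) / (2 * h_e)
    crit = lambda a, b_: _batched_crit(a, b_, d, Xt, Yt)
    f0 = crit(su2, se2)
    fuu = (crit(su2 + h_u, se2) - 2 * f0 + crit(su2 - h_u, se2)) / h_u**2
    fee = (crit(su2, se2 + h_e) - 2 * f0 + crit(su2, se2 - h_e)) / h_e**2
    fue = (
        crit(su2 + h_u, se2 + h_e)
        - crit(su2 + h_u, se2 - h_e)
        - crit(su2 - h_u, se2 + h_e)
        + crit(su2 - h_u, se2 - h_e)
    ) / (4 * h_u * h_e)
    det = fuu * fee - fue**2
    # Var(theta) = 2 * inv(H of -2loglik); quadratic form g' A g
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = 2.0 * (g_u**2 * fee - 2 * g_u * g_e * fue + g_e**2 * fuu) / det
    df = 2.0 * c**2 / quad
    bad = ~np.isfinite(df) | (df <= 0)
    df[bad] = n - p
    df = np.clip(df, 1.0, n - p)

    tstat = est / np.sqrt(c)
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    n_fail = int(np.sum(~np.isfinite(pv)))
    return pv, est, n_fail


def _estimate_rho(resid: np.ndarray, design: BenchDesign, dof: int):
    """Moment estimator of the AR(1) parameter from lag-1 residual products."""
    num = np.zeros(resid.shape[1])
    n_pairs = 0
    for rows in design.cluster_rows:
        tps = design.tp_idx[rows]
        order = np.argsort(tps)
        rows, tps = rows[order], tps[order]
        adj = np.where(np.diff(tps) == 1)[0]
        for a in adj:
            num += resid[rows[a]] * resid[rows[a + 1]]
            n_pairs += 1
    s2 = (resid**2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = num / (n_pairs * s2)
    return np.clip(np.nan_to_num(rho), -0.95, 0.95)


def gee_ar1_engine(
    Y: np.ndarray,
    design: BenchDesign,
    n_iter: int = 3,
    rho_override=None,
    bias_corrected: bool = False,
):
    """GEE with AR(1) working correlation and robust sandwich covariance.

    By default the Wald test uses the standard-normal reference without
    small-sample correction, reproducing the liberal behaviour of default
    GEE software when the number of independent clusters is small.
    ``bias_corrected=True`` applies the Mancl-DeRouen adjustment (cluster
    residuals inflated by (I - H_c)^-1 in the sandwich meat), which tempers
    that inflation; it is off by default because the uncorrected behaviour
    is what the benchmark studies.  ``rho_override`` fixes the working
    correlation (used for cross-checks; rho = 0 is the independence working
    model).
    """
    X, L = design.X, design.L
    n, p = X.shape
    F = Y.shape[1]
    beta = np.linalg.pinv(X) @ Y  # (p, F)
    resid = Y - X @ beta
    if rho_override is not None:
        rho = np.full(F, float(rho_override))
        n_iter = 1
    else:
        rho = _estimate_rho(resid, design, n - p)

    pattern_items = [
        (np.abs(np.subtract.outer(np.array(key), np.array(key))), cl)
        for key, cl in design.patterns.items()
    ]
    for _ in range(n_iter):
        B = np.zeros((F, p, p))
        u = np.zeros((F, p))
        for D, clusters in pattern_items:
            R = rho[:, None, None] ** D[None, :, :]
            Rinv = np.linalg.inv(R)
            for cidx in clusters:
                rows = design.cluster_rows[cidx]
                order = np.argsort(design.tp_idx[rows])
                rows = rows[order]
                Xc = X[rows]
                yc = Y[rows]  # (t, F)
                B += np.einsum("fij,ip,jq->fpq", Rinv, Xc, Xc, optimize=True)
                u += np.einsum("fij,jf,ip->fp", Rinv, yc, Xc, optimize=True)
        beta = np.linalg.solve(B, u[:, :, None])[:, :, 0].T  # (p, F)
        resid = Y - X @ beta
        if rho_override is None:
            rho = _estimate_rho(resid, design, n - p)

    # final B, then the sandwich meat with the last working correlation
    B = np.zeros((F, p, p))
    rinv_cache = []
    for D, clusters in pattern_items:
        R = rho[:, None, None] ** D[None, :, :]
        Rinv = np.linalg.inv(R)
        rinv_cache.append(Rinv)
        for cidx in clusters:
            rows = design.cluster_rows[cidx]
            order = np.argsort(design.tp_idx[rows])
            rows = rows[order]
            Xc = X[rows]
            B += np.einsum("fij,ip,jq->fpq", Rinv, Xc, Xc, optimize=True)
    Binv = np.linalg.inv(B)
    Mmeat = np.zeros((F, p, p))
    for (D, clusters), Rinv in zip(pattern_items, rinv_cache):
        for cidx in clusters:
            rows = design.cluster_rows[cidx]
            order = np.argsort(design.tp_idx[rows])
            rows = rows[order]
            Xc = X[rows]
            rc = resid[rows].T  # (F, t)
            if bias_corrected:
                # Mancl-DeRouen: inflate cluster residuals by (I - H_c)^-1
                H = np.einsum("ip,fpq,jq->fij", Xc, Binv, Xc, optimize=True) @ Rinv
                A = np.eye(len(rows))[None, :, :] - H
                rc = np.linalg.solve(A, rc[:, :, None])[:, :, 0]
            s = np.einsum("fij,fj,ip->fp", Rinv, rc, Xc, optimize=True)
            Mmeat += s[:, :, None] * s[:, None, :]
    V = Binv @ Mmeat @ Binv
    est = beta.T @ L
    var = np.einsum("p,fpq,q->f", L, V, L)
    bad = ~(var > 0)
    z = est / np.sqrt(np.where(bad, 1.0, var))
    pv = 2.0 * stats.norm.sf(np.abs(z))
    pv[bad] = np.nan
    return pv, est, int(bad.sum())


def mmrm_engine(
    Y: np.ndarray, design: BenchDesign, max_iter: int = 100, tol: float = 1e-5
):
    """MMRM: multivariate normal fit with unstructured timepoint covariance.

    EM over missingness patterns, with the REML-type correction in the
    M-step (each cluster contributes X_c Cov(beta-hat) X_c' on its observed
    block, the analogue of the n-p denominator in OLS) so the covariance is
    not biased downward by the estimated cell means.  The Wald contrast
    test uses the model-based GLS covariance with a cluster-level df
    (participants minus number of groups), a conservative reference given
    the many covariance parameters estimated from few clusters.
    """
    X, L = design.X, design.L
    n, p = X.shape
    F = Y.shape[1]
    T = len(design.scenario.timepoints)
    nc = design.n_clusters

    beta = np.linalg.pinv(X) @ Y
    resid = Y - X @ beta
    # initial diagonal covariance from per-timepoint residual variance
    Sigma = np.zeros((F, T, T))
    for t in range(T):
        rows = np.where(design.tp_idx == t)[0]
        Sigma[:, t, t] = np.maximum(resid[rows].var(axis=0), 1e-8)

    pattern_items = [(np.array(key), cl) for key, cl in design.patterns.items()]
    converged = np.zeros(F, dtype=bool)
    for _ in range(max_iter):
        B = np.zeros((F, p, p))
        u = np.zeros((F, p))
        inv_cache = []
        for obs, clusters in pattern_items:
            Soo = Sigma[np.ix_(np.arange(F), obs, obs)]
            Sooinv = np.linalg.inv(Soo)
            inv_cache.append(Sooinv)
            for cidx in clusters:
                rows = design.cluster_rows[cidx]
                order = np.argsort(design.tp_idx[rows])
                rows = rows[order]
                Xc = X[rows]
                yc = Y[rows]
                B += np.einsum("fij,ip,jq->fpq", Sooinv, Xc, Xc, optimize=True)
                u += np.einsum("fij,jf,ip->fp", Sooinv, yc, Xc, optimize=True)
        beta = np.linalg.solve(B, u[:, :, None])[:, :, 0].T
        resid = Y - X @ beta
        Binv_iter = np.linalg.inv(B)

        S = np.zeros((F, T, T))
        for (obs, clusters), Sooinv in zip(pattern_items, inv_cache):
            mis = np.setdiff1d(np.arange(T), obs)
            if len(mis):
                Smo = Sigma[np.ix_(np.arange(F), mis, obs)]
                G = np.einsum("fmo,foq->fmq", Smo, Sooinv, optimize=True)
                Smm = Sigma[np.ix_(np.arange(F), mis, mis)]
                Cmm = Smm - np.einsum("fmq,fnq->fmn", G, Smo, optimize=True)
            for cidx in clusters:
                rows = design.cluster_rows[cidx]
                order = np.argsort(design.tp_idx[rows])
                rows = rows[order]
                Xc = X[rows]
                ro = resid[rows].T  # (F, t)
                S[np.ix_(np.arange(F), obs, obs)] += (
                    ro[:, :, None] * ro[:, None, :]
                ) + np.einsum("ip,fpq,jq->fij", Xc, Binv_iter, Xc, optimize=True)
                if len(mis):
                    mhat = np.einsum("fmq,fq->fm", G, ro, optimize=True)
                    S[np.ix_(np.arange(F), obs, mis)] += (
                        ro[:, :, None] * mhat[:, None, :]
                    )
                    S[np.ix_(np.arange(F), mis, obs)] += (
                        mhat[:, :, None] * ro[:, None, :]
                    )
                    S[np.ix_(np.arange(F), mis, mis)] += (
                        mhat[:, :, None] * mhat[:, None, :] + Cmm
                    )
        Sigma_new = S / nc
        Sigma_new = 0.5 * (Sigma_new + np.transpose(Sigma_new, (0, 2, 1)))
        # ridge any non-PD update
        eig = np.linalg.eigvalsh(Sigma_new)
        bad = eig[:, 0] < 1e-10
        if bad.any():
            tr = np.trace(Sigma_new[bad], axis1=1, axis2=2) / T
            Sigma_new[bad] += (1e-6 * tr)[:, None, None] * np.eye(T)
        delta = np.abs(Sigma_new - Sigma).max(axis=(1, 2)) / (
            np.abs(Sigma).max(axis=(1, 2)) + 1e-12
        )
        Sigma = Sigma_new
        converged |= delta < tol
        if converged.all():
            break

    est = beta.T @ L
    Binv = np.linalg.inv(B)
    var = np.einsum("p,fpq,q->f", L, Binv, L)
    df = max(nc - len(design.scenario.groups), 1)
    bad = ~(var > 0)
    t = est / np.sqrt(np.where(bad, 1.0, var))
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    pv[bad] = np.nan
    n_fail = int((~converged).sum() + bad.sum())
    return pv, est, n_fail


_ENGINES = {
    "paired_t": paired_t_engine,
    "ols": ols_engine,
    "lmm_ri": lmm_engine,
    "lmm_ri_weighted": lmm_engine,  # weights only differ for count data
    "mmrm_unstructured": mmrm_engine,
    "gee_ar1": gee_ar1_engine,
}


def apply_strategy(strategy: str, y: np.ndarray, design: BenchDesign):
    """Run one strategy on a single feature dataset -> (p, estimate)."""
    if strategy not in _ENGINES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    Y = np.asarray(y, dtype=float).reshape(-1, 1)
    pv, est, _ = _ENGINES[strategy](Y, design)
    return float(pv[0]), float(est[0])


@dataclass
class BenchmarkReport:
    """Per (strategy, scenario) empirical rejection rates with MC SEs."""

    frame: pd.DataFrame
    alpha: float
    seed: int

    def rate(self, strategy: str, scenario: str) -> float:
        sel = self.frame[
            (self.frame["strategy"] == strategy) & (self.frame["scenario"] == scenario)
        ]
        return float(sel["rate"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Benchmark at alpha={self.alpha:g}, seed={self.seed}",
            f"{'scenario':<14}{'strategy':<20}{'rate %':>8}{'MC SE %':>9}"
            f"{'bias':>9}{'fails':>7}{'reps':>8}",
        ]
        for _, r in self.frame.iterrows():
            lines.append(
                f"{r['scenario']:<14}{r['strategy']:<20}{100*r['rate']:>8.2f}"
                f"{100*r['mc_se']:>9.3f}{r['bias']:>9.4f}{r['n_fail']:>7d}"
                f"{r['n_reps']:>8d}"
            )
        return "\n".join(lines)


def run_benchmark(
    scenarios: dict,
    strategies=STRATEGIES,
    n_reps: int = 20000,
    seed: int = 0,
    alpha: float = 0.05,
    chunk_size: int = 2000,
) -> BenchmarkReport:
    """Monte-Carlo rejection rates of each strategy on each scenario.

    ``scenarios`` maps a name to either a preset name string or a
    (SimScenario, moments) pair.  Replicates are processed in chunks so
    memory stays bounded; everything is reproducible from ``seed``
    (chunk size is part of the configuration).
    """
    if n_reps < 1000:
        raise ValueError("rate estimates need n_reps >= 1000")
    rows = []
    for name, spec in scenarios.items():
        if isinstance(spec, str):
            scenario, moments = preset_scenario(spec)
        else:
            scenario, moments = spec
        rng = np.random.default_rng(seed)
        design = BenchDesign(scenario, rng)
        sim = LongitudinalSimulator(scenario, moments)
        tp = scenario.timepoints.index(scenario.effect_timepoint)
        sd_tp = np.sqrt(
            moments[(scenario.sexes[0], scenario.effect_group)].cov[tp, tp]
        )
        truth = scenario.effect_size * sd_tp

        rej = {s: 0 for s in strategies}
        est_sum = {s: 0.0 for s in strategies}
        fails = {s: 0 for s in strategies}
        done = 0
        while done < n_reps:
            m = min(chunk_size, n_reps - done)
            Y = design.realize(sim, m, rng)
            for s in strategies:
                pv, est, nf = _ENGINES[s](Y, design)
                rej[s] += int(np.nansum(pv < alpha))
                est_sum[s] += float(np.nansum(est))
                fails[s] += nf + int(np.isnan(pv).sum())
            done += m
        for s in strategies:
            rate = rej[s] / n_reps
            rows.append(
                {
                    "scenario": name,
                    "strategy": s,
                    "rate": rate,
                    "mc_se": np.sqrt(rate * (1 - rate) / n_reps),
                    "bias": est_sum[s] / n_reps - truth,
                    "n_fail": fails[s],
                    "n_reps": n_reps,
                }
            )
    return BenchmarkReport(frame=pd.DataFrame(rows), alpha=alpha, seed=seed)
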