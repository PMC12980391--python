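"""Fuzzy c-means clustering of standardized temporal trajectories.

Feature trajectories (group-wise per-timepoint means of normalized
abundances) are z-scored along time, clustered with Bezdek's fuzzy c-means
updates, and the cluster number is chosen by the elbow of the
minimum-centroid-distance curve.  Per-cluster molecule-class enrichment
reuses the competitive (CAMERA-PR) machinery with cluster membership as the
ranking statistic.

The fuzzifier m defaults to the Schwaemmle-Jensen estimate from the
feature count and trajectory dimension (the convention of the Mfuzz
ecosystem), falling back to m = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import pandas as pd

from .core import bh_adjust
from .enrichment import camera_pr

logger = logging.getLogger("acutephys")


def standardize_trajectories(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature's trajectory along time.

    ``profiles`` is features x timepoints (e.g. per-timepoint means within
    one exercise mode).  Rows with zero temporal variance are dropped with
    a log message.  The output is invariant to per-feature affine
    transformations of the input.
    """
    v = profiles.to_numpy(dtype=float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    if (~keep).any():
        logger.info(
            "standardize_trajectories: dropped %d constant profiles", int((~keep).sum())
        )
    z = (v[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=profiles.index[keep], columns=profiles.columns)


def group_mean_trajectories(
    table, meta: pd.DataFrame, group: str, timepoints=None
) -> pd.DataFrame:
    """Per-feature mean trajectory over timepoints within one group."""
    v = table.values if hasattr(table, "values") and not isinstance(table, pd.DataFrame) else table
    meta = meta.set_index("sample_id").loc[v.columns]
    sel = meta["group"] == group
    cols = {}
    tps = timepoints or [t for t in meta.loc[sel, "timepoint"].unique()]
    for tp in tps:
        ids = meta.index[sel & (meta["timepoint"] == tp)]
        if len(ids):
            cols[tp] = v[ids].mean(axis=1)
    return pd.DataFrame(cols)


def schwammle_jensen_m(n_features: int, dim: int) -> float:
    """Data-size-based fuzzifier estimate; falls back to 2.0."""
    if n_features < 3 or dim < 1:
        return 2.0
    m = 1.0 + (1418.0 / n_features + 22.05) * dim**-2.0 + (
        12.33 / n_features + 0.243
    ) * dim ** (-0.0406 * np.log(n_features) - 0.1134)
    return float(np.clip(m, 1.05, 4.0))


@dataclass
class FcmModel:
    """Fitted fuzzy c-means model."""

    centroids: np.ndarray  # (c, T)
    membership: pd.DataFrame  # features x c, rows sum to 1
    fuzzifier: float
    objective: float
    objective_path: np.ndarray
    n_iter: int

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def hard_labels(self) -> pd.Series:
        return self.membership.idxmax(axis=1)


def _kmeanspp_init(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(
            ((X[:, None, :] - np.array(centroids)[None, :, :]) ** 2).sum(-1), axis=1
        )
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centroids.append(X[rng.choice(n, p=probs)])
    return np.array(centroids)


def fcm_fit(
    profiles: pd.DataFrame,
    c: int,
    m: float | None = None,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> FcmModel:
    """Bezdek fuzzy c-means with k-means++-style initialization.

    Alternates the membership update
    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)) and the centroid update
    v_k = sum_i u_ik^m x_i / sum_i u_ik^m until the objective changes by
    less than ``tol``.  The objective is non-increasing across iterations
    (asserted).  A feature coinciding with a centroid receives crisp
    membership 1 in that cluster.
    """
    if c < 2:
        raise ValueError("need c >= 2 clusters")
    X = profiles.to_numpy(dtype=float)
    n, T = X.shape
    if c > n:
        raise ValueError("more clusters than features")
    if m is None:
        m = schwammle_jensen_m(n, T)
    if m <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    V = _kmeanspp_init(X, c, rng)
    obj_path = []
    prev = np.inf
    for it in range(max_iter):
        d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(-1)  # (n, c)
        coincident = d2 <= 1e-300
        # u_ik proportional to d_ik^(-2/(m-1)) = (d2)^(-1/(m-1)); rows normalize
        with np.errstate(divide="ignore"):
            U = d2 ** (-1.0 / (m - 1.0))
        row_coin = coincident.any(axis=1)
        U[row_coin] = 0.0
        U[coincident] = 1.0
        U = U / U.sum(axis=1, keepdims=True)
        Um = U**m
        obj = float((Um * d2).sum())
        obj_path.append(obj)
        assert obj <= prev + 1e-9 * max(1.0, abs(prev)), "FCM objective increased"
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        if prev - obj < tol * max(1.0, abs(prev)):
            prev = obj
            break
        prev = obj
    membership = pd.DataFrame(
        U, index=profiles.index, columns=[f"cluster{k+1}" for k in range(c)]
    )
    return FcmModel(
        centroids=V,
        membership=membership,
        fuzzifier=m,
        objective=prev,
        objective_path=np.array(obj_path),
        n_iter=len(obj_path),
    )


def min_centroid_distance(model: FcmModel) -> float:
    V = model.centroids
    dist = np.sqrt(((V[:, None, :] - V[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(V), k=1)
    return float(dist[iu].min())


def choose_c(
    profiles: pd.DataFrame,
    c_range=range(2, 9),
    m: float | None = None,
    seed: int = 0,
    override: int | None = None,
) -> tuple:
    """Elbow selection of the cluster number.

    Computes the minimum pairwise centroid distance for each candidate c
    and picks the c maximizing the second difference (discrete curvature)
    of the curve; ``override`` mirrors the manual-inspection step and wins
    when given.  Returns (chosen c, DataFrame with the full curve).
    """
    cs = [c for c in c_range]
    if min(cs) < 2 or max(cs) > 12:
        raise ValueError("c_range must lie within [2, 12]")
    dists = []
    for c in cs:
        model = fcm_fit(profiles, c, m=m, seed=seed)
        dists.append(min_centroid_distance(model))
    curve = pd.DataFrame({"c": cs, "min_centroid_distance": dists})
    if len(cs) >= 3:
        # the curve kinks (max positive curvature) at the first over-split
        # solution; the elbow is the c just before it
        second_diff = np.diff(dists, 2)
        chosen = cs[int(np.argmax(second_diff))]
    else:
        chosen = cs[0]
    if override is not None:
        chosen = override
    return chosen, curve


def cluster_class_enrichment(
    model: FcmModel,
    feature_classes: pd.Series,
    alpha_core: float = 0.7,
    min_class_size: int = 3,
    rho: float = 0.01,
) -> pd.DataFrame:
    """Molecule-class enrichment within each cluster.

    Each class is tested per cluster with the competitive correlation-
    adjusted test using that cluster's membership values as the ranking
    statistic; BH adjustment within cluster.  Cluster cores (features with
    argmax membership in the cluster and membership >= ``alpha_core``) are
    reported for reference; empty cores are skipped with a log message.
    """
    classes = pd.Series(feature_classes).reindex(model.membership.index)
    rows = []
    hard = model.hard_labels()
    for k, col in enumerate(model.membership.columns):
        u = model.membership[col]
        core = model.membership.index[(hard == col) & (u >= alpha_core)]
        if len(core) == 0:
            logger.info("cluster %s: empty core at alpha_core=%.2f", col, alpha_core)
        for cls in classes.dropna().unique():
            members = classes.index[classes == cls]
            if len(members) < min_class_size:
                continue
            try:
                t, direction, p = camera_pr(u, members, rho=rho)
            except ValueError:
                continue
            rows.append(
                {"cluster": col, "class": cls, "n_core": int(len(set(core) & set(members))),
                 "z_enrich": t, "direction": direction, "p": p}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy(), out["cluster"].to_numpy())
    return out
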