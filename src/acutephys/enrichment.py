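"""Set enrichment: z-score matrices, set filtering, the correlation-adjusted
competitive test (CAMERA-PR), hypergeometric over-representation, and
per-collection BH adjustment.

The competitive test compares the mean z-score of genes inside a set to the
mean outside it with a two-sample t-statistic whose in-set variance is
inflated by VIF = 1 + (m - 1) * rho to account for inter-gene correlation
(rho defaults to 0.01, the established default of the method); the
reference distribution is t with G - 2 degrees of freedom, G the universe
size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import bh_adjust

logger = logging.getLogger("acutephys")


def read_gmt(path) -> dict:
    """Parse a GMT file: set name -> list of member ids (description dropped)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def zscores_from_results(
    estimate: np.ndarray, se: np.ndarray = None, p: np.ndarray = None
) -> np.ndarray:
    """Signed z-scores from differential results.

    Uses estimate/se when the SE is available (avoiding p-value underflow);
    otherwise the signed normal quantile of the two-sided p, with p clipped
    at 1e-300.
    """
    if se is not None:
        return np.asarray(estimate) / np.asarray(se)
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0)
    z = stats.norm.isf(p / 2.0)
    return np.sign(np.asarray(estimate)) * z


def zscore_matrix(
    da: pd.DataFrame, feature_to_gene: "pd.Series | dict", use_se: bool = True
) -> pd.DataFrame:
    """Genes x contrasts matrix of most-extreme z-scores.

    ``da`` needs columns feature_id, contrast, estimate and se (or p).  Each
    feature is mapped to a gene; when several features map to one gene the
    z of maximal |z| is kept (ties broken by feature-id order); unmapped
    features are dropped with a logged count.
    """
    da = da.copy()
    gene_map = pd.Series(feature_to_gene)
    da["gene"] = da["feature_id"].map(gene_map)
    n_unmapped = int(da["gene"].isna().sum())
    if n_unmapped:
        logger.info("zscore_matrix: dropped %d unmapped feature results", n_unmapped)
    da = da.dropna(subset=["gene"])
    if use_se and "se" in da.columns:
        da["z"] = zscores_from_results(da["estimate"].to_numpy(), da["se"].to_numpy())
    else:
        da["z"] = zscores_from_results(da["estimate"].to_numpy(), p=da["p"].to_numpy())
    da = da.sort_values("feature_id", kind="mergesort")
    da["absz"] = da["z"].abs()
    idx = da.groupby(["gene", "contrast"], sort=False)["absz"].idxmax()
    best = da.loc[idx]
    return best.pivot(index="gene", columns="contrast", values="z")


def filter_sets(collection: dict, universe, min_size: int = 5, min_frac: float = 0.70) -> dict:
    """Intersect sets with the measured universe and apply size filters.

    A set is kept iff its intersection with the universe has at least
    ``min_size`` members AND retains at least ``min_frac`` of its original
    members (boundary inclusive) -- so the surviving members still describe
    what the set label claims.
    """
    uni = set(universe)
    out = {}
    for name, members in collection.items():
        members = list(dict.fromkeys(members))
        inter = [g for g in members if g in uni]
        if len(inter) >= min_size and len(inter) / len(members) >= min_frac:
            out[name] = inter
    return out


def camera_pr(
    z: "pd.Series | np.ndarray", members, rho: float = 0.01
) -> tuple:
    """Correlation-adjusted competitive test of one set on pre-ranked z-scores.

    Returns (z_enrich, direction, p): the VIF-adjusted two-sample statistic,
    'Up'/'Down' by the sign of (mean in-set - mean out-set), and the
    two-sided p from a t distribution with G - 2 df.  With rho = 0 this is
    the ordinary two-sample t-test.
    """
    z = pd.Series(z).dropna()
    G = len(z)
    in_mask = z.index.isin(set(members))
    m = int(in_mask.sum())
    if m < 1:
        raise ValueError("set has no members in the universe")
    if m >= G:
        raise ValueError("set covers the whole universe; no outside genes")
    zin, zout = z[in_mask], z[~in_mask]
    delta = zin.mean() - zout.mean()
    df = G - 2
    s2 = ((zin - zin.mean()) ** 2).sum() + ((zout - zout.mean()) ** 2).sum()
    s2 /= df
    vif = 1.0 + (m - 1) * rho
    var_delta = s2 * (vif / m + 1.0 / (G - m))
    if var_delta <= 0:
        return 0.0, "Up", 1.0
    t = delta / np.sqrt(var_delta)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), ("Up" if delta >= 0 else "Down"), float(p)


def camera_pr_matrix(
    zmat: pd.DataFrame, collection: dict, rho: float = 0.01
) -> pd.DataFrame:
    """camera_pr for every (set, contrast) pair of a z-score matrix."""
    rows = []
    for contrast in zmat.columns:
        z = zmat[contrast].dropna()
        for name, members in collection.items():
            try:
                t, direction, p = camera_pr(z, members, rho=rho)
            except ValueError:
                continue
            rows.append(
                {"set": name, "contrast": contrast, "n_genes": len(set(members) & set(z.index)),
                 "z_enrich": t, "direction": direction, "p": p}
            )
    return pd.DataFrame(rows)


def ora(hits, universe, members) -> tuple:
    """Hypergeometric over-representation: (overlap, fold enrichment, p).

    Upper-tail P(X >= k) drawing |hits| from a universe containing
    |set & universe| successes.  Empty hit lists return p = 1.
    """
    uni = set(universe)
    hits = set(hits) & uni
    members = set(members) & uni
    k = len(hits & members)
    M, n, N = len(uni), len(members), len(hits)
    if N == 0:
        logger.info("ora: empty hit list; p = 1 by convention")
        return 0, np.nan, 1.0
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    expected = N * n / M
    fold = k / expected if expected > 0 else np.nan
    return k, fold, p


def ora_collection(hits, universe, collection: dict) -> pd.DataFrame:
    rows = []
    for name, members in collection.items():
        k, fold, p = ora(hits, universe, members)
        rows.append({"set": name, "overlap": k, "fold": fold, "p": p})
    return pd.DataFrame(rows)


def adjust_collections(
    results: pd.DataFrame,
    by=("tissue", "ome", "contrast", "collection"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """BH adjustment within each (tissue, ome, contrast, collection) stratum."""
    out = results.copy()
    keys = [c for c in by if c in out.columns]
    if keys:
        strata = out[keys].astype(str).agg("|".join, axis=1).to_numpy()
    else:
        strata = np.zeros(len(out), dtype=int)
    out["p_adj"] = bh_adjust(out["p"].to_numpy(), strata)
    out["significant"] = out["p_adj"] < alpha
    return out
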