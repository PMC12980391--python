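"""Metabolomics / lipidomics cleaning chain.

Ordered, logged transforms applied per assay-platform table:

1. average rows sharing a metabolite id,
2. convert non-positive intensities to missing,
3. drop features with > 20% missing values (strictly greater),
4. impute: feature-profile KNN for panels with > 12 features, half-minimum
   for small panels,
5. log2(x + 1),
6. median-MAD normalize (untargeted data only), gated on Kruskal-Wallis
   tests of sample medians / upper quartiles against sex and sex-stratified
   group (skip if any p < 0.01 -- normalization must not erase a real
   biological location shift),

followed by principal-component outlier flagging (box-plot whiskers at a
configurable IQR multiple) and cross-platform redundancy resolution by
internal-standard CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import FeatureTable

#: (IQR multiplier, number of PCs) presets for sample-outlier flagging.
OUTLIER_PRESETS = {"metabolomics": (5.0, 5), "proteomics": (3.0, 3)}


@dataclass
class PrepLog:
    """Ordered record of preprocessing steps and their feature accounting."""

    records: list = field(default_factory=list)

    def add(self, step: str, n_in: int, n_out: int, flagged=None, **params):
        if n_out > n_in:
            raise ValueError(f"step {step!r} increased the feature count")
        self.records.append(
            {
                "step": step,
                "features_in": n_in,
                "features_out": n_out,
                "samples_flagged": list(flagged) if flagged is not None else [],
                "params": params,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def average_duplicates(table: FeatureTable, log: PrepLog | None = None) -> FeatureTable:
    """Entrywise mean of rows sharing a feature id (NaN-ignoring)."""
    v = table.values
    out = v.groupby(level=0, sort=False).mean()
    if log is not None:
        log.add("average_duplicates", len(v), len(out))
    fm = None
    if table.feature_meta is not None:
        fm = table.feature_meta.groupby(level=0, sort=False).first()
    return FeatureTable(out, table.ome, fm)


def mask_nonpositive(table: FeatureTable, log: PrepLog | None = None) -> FeatureTable:
    """Intensities <= 0 become missing (pre-log cleaning)."""
    v = table.values.where(table.values > 0)
    if log is not None:
        log.add("mask_nonpositive", len(v), len(v))
    return FeatureTable(v, table.ome, table.feature_meta)


def filter_missing(
    table: FeatureTable, threshold: float = 0.20, log: PrepLog | None = None
) -> FeatureTable:
    """Keep features whose missing fraction is <= threshold (strict > removal)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    frac = table.values.isna().mean(axis=1)
    keep = frac <= threshold
    out = table.values.loc[keep]
    if log is not None:
        log.add("filter_missing", len(table.values), len(out), threshold=threshold)
    fm = table.feature_meta.loc[keep] if table.feature_meta is not None else None
    return FeatureTable(out, table.ome, fm)


def impute(
    table: FeatureTable,
    knn_min_features: int = 13,
    k: int = 10,
    log: PrepLog | None = None,
) -> FeatureTable:
    """Missing-value imputation: feature-profile KNN or half-minimum.

    Panels with more than 12 features use KNN over feature profiles
    (nan-Euclidean distance on shared observed samples, distance-weighted
    mean of the k nearest features); panels with 12 or fewer use
    half-minimum (each missing entry set to half the feature's minimum
    observed value), the conservative small-panel branch.  Observed entries
    are never altered.
    """
    v = table.values
    if v.isna().all(axis=1).any():
        bad = v.index[v.isna().all(axis=1)].tolist()
        raise ValueError(f"features with no observed values (filter first): {bad[:5]}")
    n_feat = len(v)
    if not v.isna().any().any():
        out = v.copy()
        method = "none"
    elif n_feat >= knn_min_features:
        out = pd.DataFrame(
            _knn_impute_features(v.to_numpy(), k=min(k, n_feat - 1)),
            index=v.index,
            columns=v.columns,
        )
        method = "knn"
    else:
        half_min = v.min(axis=1) / 2.0
        out = v.apply(lambda row: row.fillna(half_min[row.name]), axis=1)
        method = "half_minimum"
    if log is not None:
        log.add("impute", n_feat, n_feat, method=method, k=k)
    return FeatureTable(out, table.ome, table.feature_meta)


def _knn_impute_features(
    X: np.ndarray, k: int = 10, min_overlap: int = 3
) -> np.ndarray:
    """Distance-weighted KNN over feature profiles.

    Distances are Euclidean on the samples both features observe, rescaled
    by sqrt(n_samples / n_shared) (so partial overlap is comparable to full
    overlap); neighbor pairs must share at least ``min_overlap`` observed
    samples.  A missing entry is the 1/distance-weighted mean of the k
    nearest features observed at that sample; an exact-duplicate donor
    (distance zero) is copied verbatim.  Falls back to the feature mean
    when no eligible donor exists.
    """
    n_feat, n_samp = X.shape
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    shared = obs.astype(float) @ obs.T.astype(float)
    # sum over shared coords of (x_i - x_j)^2
    sq = (X0**2) @ obs.T.astype(float)
    cross = X0 @ X0.T
    d2 = sq + sq.T - 2.0 * cross
    # exact duplicates must come out at distance 0 despite the cancellation
    # in the vectorized expansion above
    d2[d2 < 1e-12 * (sq + sq.T)] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (n_samp / shared)
    d2[shared < min_overlap] = np.inf
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)

    out = X.copy()
    for i, j in zip(*np.where(~obs)):
        eligible = obs[:, j] & np.isfinite(d2[i])
        cand = np.where(eligible)[0]
        if cand.size == 0:
            out[i, j] = np.nanmean(X[i])
            continue
        order = cand[np.argsort(d2[i, cand], kind="stable")][:k]
        d = np.sqrt(d2[i, order])
        if d[0] == 0.0:
            exact = order[d == 0.0]
            out[i, j] = X[exact, j].mean()
            continue
        w = 1.0 / d
        out[i, j] = float(np.sum(w * X[order, j]) / np.sum(w))
    return out


def log2_plus1(table: FeatureTable, log: PrepLog | None = None) -> FeatureTable:
    """x -> log2(x + 1); adding 1 keeps (0, 1) intensities non-negative."""
    v = table.values
    if (v < 0).any().any():
        raise ValueError("negative values present; clean before log transform")
    out = np.log2(v + 1.0)
    if log is not None:
        log.add("log2_plus1", len(v), len(v))
    return FeatureTable(out, table.ome, table.feature_meta)


def _kw_pvalue(values: np.ndarray, labels: pd.Series) -> float:
    groups = [values[labels.to_numpy() == g] for g in pd.unique(labels)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def median_mad_normalize(
    table: FeatureTable,
    meta: pd.DataFrame,
    gate_p: float = 0.01,
    log: PrepLog | None = None,
) -> tuple:
    """Per-sample median-MAD normalization behind a Kruskal-Wallis gate.

    Gate: per-sample medians and upper quartiles are each tested against
    sex and against sex-stratified group; if any of the four tests has
    p < ``gate_p``, the location statistics carry real signal and
    normalization is skipped.  Otherwise each sample is centered at its
    median and scaled by its MAD (x 1.4826 for normal consistency).

    Returns (table, gate report dict).
    """
    v = table.values
    meta = meta.set_index("sample_id").loc[v.columns]
    med = v.median(axis=0, skipna=True)
    uq = v.quantile(0.75, axis=0)
    sex = meta["sex"].astype(str)
    sexgroup = sex + ":" + meta["group"].astype(str)
    tests = {
        "median~sex": _kw_pvalue(med.to_numpy(), sex),
        "median~sex_group": _kw_pvalue(med.to_numpy(), sexgroup),
        "upper_quartile~sex": _kw_pvalue(uq.to_numpy(), sex),
        "upper_quartile~sex_group": _kw_pvalue(uq.to_numpy(), sexgroup),
    }
    gated = any(p < gate_p for p in tests.values())
    report = {"applied": not gated, "gate_p": gate_p, "tests": tests}
    if gated:
        if log is not None:
            log.add("median_mad_normalize", len(v), len(v), applied=False, **tests)
        return table, report
    mad = (v - med).abs().median(axis=0, skipna=True) * 1.4826
    zero = mad.index[mad <= 0]
    if len(zero):
        raise ValueError(f"MAD is zero for sample(s): {list(zero[:5])}")
    out = (v - med) / mad
    if log is not None:
        log.add("median_mad_normalize", len(v), len(v), applied=True, **tests)
    return FeatureTable(out, table.ome, table.feature_meta), report


def pc_outlier_flags(
    table: FeatureTable,
    multiplier: float | None = None,
    n_pcs: int | None = None,
    preset: str = "metabolomics",
) -> list:
    """Samples whose leading principal-component scores are box-plot outliers.

    PCA on the centered feature matrix (samples as observations); a sample
    is flagged iff any of the first ``n_pcs`` scores falls outside
    [Q1 - m*IQR, Q3 + m*IQR].  Presets: metabolomics (m=5, 5 PCs),
    proteomics (m=3, 3 PCs).
    """
    m, k = OUTLIER_PRESETS[preset]
    multiplier = m if multiplier is None else multiplier
    n_pcs = k if n_pcs is None else n_pcs
    v = table.values
    if v.isna().any().any():
        raise ValueError("complete (post-imputation) table required")
    Xs = v.to_numpy().T  # samples x features
    rank = min(Xs.shape[0] - 1, Xs.shape[1])
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds the data rank {rank}")
    scores = PCA(n_components=n_pcs).fit_transform(Xs - Xs.mean(axis=0))
    q1, q3 = np.percentile(scores, [25, 75], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    out = (scores < lo) | (scores > hi)
    flagged = v.columns[out.any(axis=1)]
    return list(flagged)


def platform_cv(table: FeatureTable) -> float:
    """Mean internal-standard CV (sd/mean on the raw intensity scale)."""
    if table.feature_meta is None or "is_internal_standard" not in table.feature_meta:
        raise ValueError("platform table lacks internal-standard annotation")
    std_rows = table.feature_meta["is_internal_standard"].fillna(False).astype(bool)
    if not std_rows.any():
        raise ValueError("platform has no internal standards")
    v = table.values.loc[std_rows.to_numpy()]
    cvs = v.std(axis=1, ddof=1) / v.mean(axis=1)
    return float(cvs.mean())


def resolve_redundancy(tables: "list[FeatureTable]", log: PrepLog | None = None) -> tuple:
    """Pick one platform per RefMet id by lowest internal-standard CV.

    For every RefMet id measured on two or more platforms, the measurement
    from the platform whose reference standards have the lowest mean CV is
    kept; the others are dropped.  Ids unique to one platform are kept
    regardless of CV.  Returns (merged FeatureTable, provenance DataFrame
    listing the chosen and losing platforms per shared id).
    """
    if len(tables) < 2:
        raise ValueError("redundancy resolution needs >= 2 platform tables")
    cvs = {}
    for t in tables:
        plats = t.feature_meta["platform"].dropna().unique()
        if len(plats) != 1:
            raise ValueError("each table must carry exactly one platform label")
        cvs[plats[0]] = platform_cv(t)

    frames, metas, prov = [], [], []
    claimed: dict = {}
    for t in sorted(tables, key=lambda t: cvs[t.feature_meta["platform"].dropna().unique()[0]]):
        plat = t.feature_meta["platform"].dropna().unique()[0]
        fm = t.feature_meta
        keep = []
        for fid, ref in fm["refmet_id"].items():
            if fm.loc[fid, "is_internal_standard"]:
                continue
            if ref is None or (isinstance(ref, float) and np.isnan(ref)):
                keep.append(fid)
                continue
            if ref in claimed:
                prov.append(
                    {"refmet_id": ref, "chosen_platform": claimed[ref],
                     "losing_platform": plat, "losing_cv": cvs[plat]}
                )
                continue
            claimed[ref] = plat
            keep.append(fid)
        frames.append(t.values.loc[keep])
        metas.append(fm.loc[keep])
    merged = FeatureTable(pd.concat(frames), tables[0].ome, pd.concat(metas))
    if log is not None:
        log.add("resolve_redundancy", sum(len(t.values) for t in tables),
                len(merged.values), platform_cvs=cvs)
    return merged, pd.DataFrame(prov)


def preprocess(
    table: FeatureTable,
    meta: pd.DataFrame,
    untargeted: bool = True,
    missing_threshold: float = 0.20,
    outlier_preset: str = "metabolomics",
) -> tuple:
    """Full single-platform chain in the fixed order; returns
    (table, flagged samples, PrepLog, gate report)."""
    log = PrepLog()
    t = average_duplicates(table, log)
    t = mask_nonpositive(t, log)
    t = filter_missing(t, missing_threshold, log)
    t = impute(t, log=log)
    t = log2_plus1(t, log)
    report = {"applied": False, "tests": {}}
    if untargeted:
        t, report = median_mad_normalize(t, meta, log=log)
    flagged = pc_outlier_flags(t, preset=outlier_preset)
    log.add("pc_outlier_flags", len(t.values), len(t.values), flagged=flagged)
    return t, flagged, log, report
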