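"""Bulk RNA-seq preprocessing: RIN exclusion, low-expression filtering,
TMM normalization, log-CPM, and design-protected batch-effect regression.

TMM (trimmed mean of M-values) follows the standard construction: the
reference is the sample whose 75th-percentile CPM is closest to the mean
75th percentile; each sample's factor is the weighted mean of gene-wise
log-ratios (M-values) after trimming 30% on M and 5% on A, with inverse
asymptotic binomial variance weights, and factors are rescaled to have
geometric mean one.

The low-expression sentence in the source protocol ("0.5 or fewer counts
per million in at least 10% of samples" defines *removed* genes) read
literally removes nearly everything; the intended edgeR-style rule -- keep
genes with CPM > 0.5 in at least 10% of samples -- is the default
(``mode="keep_expressed"``), with ``mode="literal"`` available.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core import FeatureTable

logger = logging.getLogger("acutephys")


def rin_filter(meta: pd.DataFrame, threshold: float = 5.0, rin_column: str = "rin"):
    """Samples passing the RNA-integrity criterion (RIN >= threshold).

    Samples with RIN strictly below the threshold are excluded; samples
    with no RIN value are excluded with a warning.
    """
    if rin_column not in meta.columns:
        warnings.warn(f"no {rin_column!r} column; all samples excluded", stacklevel=2)
        return []
    rin = pd.to_numeric(meta[rin_column], errors="coerce")
    missing = meta.loc[rin.isna(), "sample_id"]
    if len(missing):
        warnings.warn(
            f"{len(missing)} sample(s) without RIN excluded: "
            f"{missing.tolist()[:5]}",
            stacklevel=2,
        )
    return meta.loc[rin >= threshold, "sample_id"].tolist()


def _cpm(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    return counts / lib[None, :] * 1e6


def filter_low_expression(
    counts: FeatureTable,
    cpm_cut: float = 0.5,
    frac: float = 0.10,
    mode: str = "keep_expressed",
) -> FeatureTable:
    """Remove lowly expressed genes.

    ``keep_expressed`` (default): keep genes with CPM > cpm_cut in at least
    ``frac`` of samples.  ``literal``: remove genes with CPM <= cpm_cut in
    at least ``frac`` of samples (the source wording read literally).
    """
    C = counts.values.to_numpy()
    lib = C.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    cpm = _cpm(C, lib)
    n = C.shape[1]
    if mode == "keep_expressed":
        keep = (cpm > cpm_cut).sum(axis=1) >= frac * n
    elif mode == "literal":
        keep = (cpm <= cpm_cut).sum(axis=1) < frac * n
    else:
        raise ValueError(f"unknown mode {mode!r}")
    logger.info(
        "filter_low_expression(mode=%s): kept %d / %d genes", mode, keep.sum(), len(keep)
    )
    fm = counts.feature_meta.loc[keep] if counts.feature_meta is not None else None
    return FeatureTable(counts.values.loc[keep], counts.ome, fm)


def tmm_factors(
    counts: FeatureTable,
    ref: "int | str | None" = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM normalization factors (geometric mean 1)."""
    C = counts.values.to_numpy(dtype=float)
    lib = C.sum(axis=0)
    if C.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (lib <= 0).any():
        raise ValueError("zero library size")
    uq = np.array([np.quantile(_cpm(C, lib)[:, j], 0.75) for j in range(C.shape[1])])
    if ref is None:
        r = int(np.argmin(np.abs(uq - uq.mean())))
    elif isinstance(ref, str):
        r = list(counts.values.columns).index(ref)
    else:
        r = int(ref)

    factors = np.ones(C.shape[1])
    for j in range(C.shape[1]):
        if j == r:
            continue
        pos = (C[:, j] > 0) & (C[:, r] > 0)
        if not pos.any():
            warnings.warn(
                f"sample {counts.values.columns[j]!r} shares no expressed genes "
                "with the reference; factor set to 1",
                stacklevel=2,
            )
            continue
        yj, yr = C[pos, j], C[pos, r]
        pj, pr = yj / lib[j], yr / lib[r]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        # asymptotic binomial variance of M
        w = 1.0 / ((lib[j] - yj) / (lib[j] * yj) + (lib[r] - yr) / (lib[r] * yr))
        finite = np.isfinite(M) & np.isfinite(A)
        M, A, w = M[finite], A[finite], w[finite]
        if len(M) == 0:
            continue
        m_lo, m_hi = np.quantile(M, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.values.columns, name="tmm_factor")


def log_cpm(
    counts: FeatureTable, factors: "pd.Series | None" = None, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts per million on TMM-effective library sizes.

    log2((count + prior) / (factor * libsize + 2 * prior) * 1e6); returned
    as a plain genes x samples DataFrame of normalized values.
    """
    C = counts.values.to_numpy(dtype=float)
    lib = C.sum(axis=0)
    f = (
        factors.loc[counts.values.columns].to_numpy()
        if factors is not None
        else np.ones(C.shape[1])
    )
    out = np.log2((C + prior) / (f * lib + 2 * prior)[None, :] * 1e6)
    return pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns)


def remove_batch_effects(
    logtable: pd.DataFrame,
    meta: pd.DataFrame,
    batch_covariates: "list[str]",
    protected: "pd.DataFrame | None" = None,
) -> pd.DataFrame:
    """Regress technical batch effects out of a log-scale table.

    Per feature, the protected biological design (age, sex, group x
    timepoint cell means by default) and the batch columns are fitted
    *jointly* and only the fitted batch component is subtracted, so no
    variance attributable to the protected design is removed.  Refuses to
    proceed when a batch covariate is confounded with the protected design
    (e.g. processing batch perfectly collinear with exercise modality, in
    which case group effects would be indistinguishable from batch
    effects).
    """
    from .core import build_cell_means_design

    v = logtable
    meta = meta.set_index("sample_id").loc[list(v.columns)]
    meta.index.name = "sample_id"
    meta = meta.reset_index()
    if protected is None:
        covs = [c for c in ("age", "sex") if c in meta.columns]
        protected, _ = build_cell_means_design(meta, covariates=covs)
    P = protected.loc[v.columns].to_numpy()

    Bcols = []
    names = []
    for b in batch_covariates:
        col = meta.set_index("sample_id").loc[v.columns, b]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            Bcols.append((col - col.mean()).to_numpy()[:, None])
            names.append(b)
        else:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                Bcols.append((col.astype(str) == lev).to_numpy(float)[:, None])
                names.append(f"{b}[{lev}]")
    if not Bcols:
        return logtable
    B = np.hstack(Bcols)

    full = np.hstack([P, B])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            f"batch covariates {names} are confounded with the protected design; "
            "batch effects cannot be separated from biology and are left in "
            "(documented experimental limitation)"
        )
    Y = v.to_numpy().T  # samples x features
    coef, *_ = np.linalg.lstsq(full, Y, rcond=None)
    batch_part = B @ coef[P.shape[1]:, :]
    out = (Y - batch_part).T
    return pd.DataFrame(out, index=v.index, columns=v.columns)
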