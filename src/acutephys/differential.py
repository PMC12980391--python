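"""Per-feature differential abundance via the difference-in-changes LMM.

Exposes a statsmodels-style pair: :class:`DifferentialAbundanceModel`
(constructed from a feature table + sample metadata) whose ``fit()`` returns
:class:`DAResults` carrying estimates, standard errors, Satterthwaite df,
p-values and within-stratum BH-adjusted p-values, plus a failure sidecar.

Includes the minimum-pairing eligibility filter (every group in a contrast
needs at least 3 participants observed at both pre and the contrast
timepoint) and voom-style precision weights for count data, where the
per-observation residual variance is predicted from a lowess fit of
sqrt(residual SD) against average log-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import core
from .core import ContrastSpec, DesignError, FeatureTable, bh_adjust, stratum_id
from .lmm import fit_feature_lmm, test_contrast


def min_pairing_filter(
    meta: pd.DataFrame,
    table: FeatureTable,
    contrasts: "list[ContrastSpec]",
    min_n: int = 3,
) -> pd.DataFrame:
    """Eligibility of each (feature, contrast) under the pairing rule.

    A contrast is eligible for a feature iff every group it involves has at
    least ``min_n`` participants with observed (non-missing) values at both
    pre-exercise and the contrast timepoint.  Returns a boolean DataFrame
    (features x contrast names).
    """
    observed = ~table.values.isna()
    meta = meta.set_index("sample_id").loc[table.values.columns]

    def pair_counts(group: str, tp: str) -> np.ndarray:
        """Per-feature count of participants observed at both pre and tp."""
        counts = np.zeros(len(table.values), dtype=int)
        sub = meta[meta["group"] == group]
        for _, part_samples in sub.groupby("participant_id"):
            tps = part_samples["timepoint"]
            pre_ids = part_samples.index[tps == "pre"]
            tp_ids = part_samples.index[tps == tp]
            if len(pre_ids) == 0 or len(tp_ids) == 0:
                continue
            both = (
                observed[pre_ids[0]].to_numpy() & observed[tp_ids[0]].to_numpy()
            )
            counts += both
        return counts

    cache: dict = {}
    out = {}
    for spec in contrasts:
        groups = [spec.group_a] + ([spec.group_b] if spec.group_b else [])
        elig = np.ones(len(table.values), dtype=bool)
        for g in groups:
            key = (g, spec.timepoint)
            if key not in cache:
                cache[key] = pair_counts(*key)
            elig &= cache[key] >= min_n
        out[spec.name] = elig
    return pd.DataFrame(out, index=table.values.index)


def precision_weights(
    counts: FeatureTable, design: pd.DataFrame, span: float = 0.5, prior: float = 0.5
) -> pd.DataFrame:
    """Voom-style observation weights for transcript counts.

    Fits per-gene OLS on log2-CPM, regresses sqrt(residual SD) on average
    log2-count via lowess, and converts the predicted sqrt-SD at each
    observation's fitted log-count into an inverse-variance weight
    (predicted sqrt-SD to the power -4).  Requires >= 10 genes for the
    trend to be identifiable.
    """
    if counts.ome != "transcript_counts":
        raise ValueError("precision weights apply to transcript counts only")
    C = counts.values.to_numpy()
    n_genes, n_samples = C.shape
    if n_genes < 10:
        raise ValueError("need at least 10 genes to estimate the mean-variance trend")
    X = design.loc[counts.values.columns].to_numpy()
    lib = C.sum(axis=0)
    y = np.log2((C + prior) / (lib + 2 * prior)[None, :] * 1e6)
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    fitted = beta @ X.T
    resid = y - fitted
    dof = n_samples - np.linalg.matrix_rank(X)
    sd = np.sqrt((resid**2).sum(axis=1) / dof)
    if np.all(sd < 1e-12):
        raise ValueError("all residual SDs are degenerate (constant counts?)")
    sqrt_sd = np.sqrt(sd)
    # average log2 count: mean log-cpm shifted back to the count scale
    mean_logcount = y.mean(axis=1) + np.log2(np.exp(np.mean(np.log(lib + 1)))) - np.log2(1e6)
    trend = lowess(sqrt_sd, mean_logcount, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    # fitted log-count per observation
    fitted_count = fitted + np.log2(lib + 2 * prior)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_count, tx, ty)
    w = pred**-4.0
    return pd.DataFrame(w, index=counts.values.index, columns=counts.values.columns)


def default_contrasts(
    cells: "list[str]",
    meta: pd.DataFrame,
    kinds: "tuple[str, ...]" = ("difference_in_changes", "group_specific"),
    mode_vs_mode_as_delta: bool = True,
) -> "list[ContrastSpec]":
    """Enumerate contrasts realizable in the observed design.

    Difference-in-changes contrasts pair each exercise arm with CON at
    every shared during/post timepoint; group-specific contrasts compare
    each group's during/post timepoints to its own pre; mode-vs-mode
    contrasts compare RE to EE as changes from pre (or directly, with
    ``mode_vs_mode_as_delta=False``, realized as a difference of
    group-specific cells).
    """
    cellset = set(cells)
    tps = [t for t in core.TIMEPOINTS if t != "pre"]
    specs: list[ContrastSpec] = []
    for kind in kinds:
        for tp in tps:
            if kind == "difference_in_changes":
                for g in ("EE", "RE"):
                    try:
                        specs.append(core.delta_delta_contrast(cellset, g, tp))
                    except DesignError:
                        continue
            elif kind == "group_specific":
                for g in core.GROUPS:
                    try:
                        specs.append(core.group_specific_contrast(cellset, g, tp))
                    except DesignError:
                        continue
            elif kind == "mode_vs_mode":
                try:
                    if mode_vs_mode_as_delta:
                        specs.append(core.mode_vs_mode_contrast(cellset, "RE", "EE", tp))
                    else:
                        a, b = core.cell_label("RE", tp), core.cell_label("EE", tp)
                        if a in cellset and b in cellset:
                            specs.append(
                                ContrastSpec(
                                    "mode_vs_mode", "RE", "EE", tp, {a: 1.0, b: -1.0}
                                )
                            )
                except DesignError:
                    continue
            else:
                raise ValueError(f"unknown contrast kind {kind!r}")
    return specs


@dataclass
class DAResults:
    """Differential-abundance results: one row per feature x contrast."""

    frame: pd.DataFrame
    failures: pd.DataFrame
    fdr: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["p_adj"] < self.fdr]

    def summary(self) -> str:
        lines = [
            "Differential abundance (difference-in-changes LMM)",
            f"  features x contrasts tested: {len(self.frame)}",
            f"  strata (BH within each):     {self.frame['stratum_id'].nunique()}",
            f"  significant at FDR {self.fdr:g}:     {len(self.significant())}",
            f"  model failures:              {len(self.failures)}",
        ]
        by = (
            self.significant()
            .groupby("contrast")
            .size()
            .sort_values(ascending=False)
        )
        for name, n in by.items():
            lines.append(f"    {name}: {n}")
        return "\n".join(lines)


class DifferentialAbundanceModel:
    """Cell-means LMM differential abundance for one feature table.

    Parameters
    ----------
    table : FeatureTable
        Preprocessed abundances (log scale for intensities, raw counts for
        transcripts -- counts trigger voom-style precision weights).
    meta : DataFrame
        Sample metadata (validated against the core schema).
    covariates : sequence of str
        Fixed-effect adjustment columns (e.g. sex, age, bmi, site).
    contrasts : list of ContrastSpec or "auto"
    tissue : str
        Tissue label used only to form BH strata identifiers.
    """

    def __init__(
        self,
        table: FeatureTable,
        meta: pd.DataFrame,
        covariates=(),
        contrasts="auto",
        tissue: str = "blood",
        min_pair_n: int = 3,
        fdr: float = 0.05,
        df_method: str = "satterthwaite",
    ):
        core.validate_sample_meta(meta)
        table.check_samples(meta)
        self.table = table
        self.meta = meta[meta["sample_id"].isin(table.values.columns)].reset_index(
            drop=True
        )
        self.covariates = tuple(covariates)
        self.tissue = tissue
        self.min_pair_n = min_pair_n
        self.fdr = fdr
        self.df_method = df_method
        self.design, self.col_map = core.build_cell_means_design(
            self.meta, self.covariates
        )
        if contrasts == "auto":
            self.contrasts = default_contrasts(self.col_map["cells"], self.meta)
        else:
            self.contrasts = list(contrasts)
        self.weights = (
            precision_weights(table, self.design)
            if table.ome == "transcript_counts"
            else None
        )

    def fit(self) -> DAResults:
        meta = self.meta.set_index("sample_id").loc[self.design.index]
        groups = meta["participant_id"].to_numpy()
        X = self.design.to_numpy()
        columns = list(self.design.columns)
        elig = min_pairing_filter(meta.reset_index(), self.table, self.contrasts,
                                  self.min_pair_n)
        vals = self.table.values.loc[:, self.design.index]

        rows, fails = [], []
        for fid, y in vals.iterrows():
            yv = y.to_numpy(dtype=float)
            w = (
                self.weights.loc[fid, self.design.index].to_numpy()
                if self.weights is not None
                else None
            )
            try:
                fit = fit_feature_lmm(yv, X, groups, weights=w, columns=columns)
            except (ValueError, FloatingPointError, np.linalg.LinAlgError) as err:
                fails.append((fid, "fit", str(err)))
                continue
            for spec in self.contrasts:
                if not elig.loc[fid, spec.name]:
                    continue
                if not fit.converged:
                    rows.append(
                        (fid, spec.name, spec.timepoint, spec.group_a,
                         np.nan, np.nan, np.nan, np.nan)
                    )
                    fails.append((fid, spec.name, "non-convergent REML"))
                    continue
                try:
                    est, se, df, p = test_contrast(fit, spec, self.df_method)
                except (ValueError, DesignError) as err:
                    fails.append((fid, spec.name, str(err)))
                    continue
                rows.append(
                    (fid, spec.name, spec.timepoint, spec.group_a, est, se, df, p)
                )

        frame = pd.DataFrame(
            rows,
            columns=[
                "feature_id", "contrast", "timepoint", "group",
                "estimate", "se", "df", "p",
            ],
        )
        if len(frame):
            kind_of = {s.name: s.kind for s in self.contrasts}
            frame["stratum_id"] = [
                stratum_id(kind_of[c], g, self.tissue, self.table.ome, tp)
                for c, g, tp in zip(frame["contrast"], frame["group"], frame["timepoint"])
            ]
            frame["p_adj"] = bh_adjust(
                frame["p"].to_numpy(), frame["stratum_id"].to_numpy()
            )
            frame = frame.sort_values(["contrast", "p"], kind="mergesort").reset_index(
                drop=True
            )
        else:
            frame["stratum_id"] = []
            frame["p_adj"] = []
        failures = pd.DataFrame(fails, columns=["feature_id", "stage", "message"])
        return DAResults(frame=frame, failures=failures, fdr=self.fdr)


def run_da(
    table: FeatureTable,
    meta: pd.DataFrame,
    covariates=(),
    contrasts="auto",
    tissue: str = "blood",
    fdr: float = 0.05,
) -> DAResults:
    """One-call wrapper: build the model and fit it."""
    model = DifferentialAbundanceModel(
        table, meta, covariates=covariates, contrasts=contrasts, tissue=tissue, fdr=fdr
    )
    return model.fit()
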