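"""Shared data model: sample metadata, feature tables, cell-means designs,
contrast algebra and stratified Benjamini-Hochberg adjustment.

The study design is a randomized three-arm trial (EE = endurance exercise,
RE = resistance exercise, CON = non-exercise control) with blood sampling at
up to seven timepoints: pre-exercise, 20/40 min during exercise (EE and CON
only; blood cannot safely be drawn during resistance exercise), and 10 min,
30 min, 3.5 h and 24 h post-exercise.  Participants are randomized to a
temporal profile (early / middle / late / all) that determines which of the
later post-exercise timepoints they contribute, a planned-missingness device
that spreads sampling burden while retaining coverage of the full recovery
period.

All hypothesis tests are linear contrasts of group x timepoint cell means,
so the design matrix is parameterized without an intercept: one indicator
per observed cell plus (centered / one-hot) covariate columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("acutephys")

GROUPS = ("EE", "RE", "CON")

#: Timepoints in temporal order.  dur20/dur40 exist only for EE and CON.
TIMEPOINTS = ("pre", "dur20", "dur40", "post10", "post30", "post3.5h", "post24h")

DUR_TIMEPOINTS = ("dur20", "dur40")
POST_TIMEPOINTS = ("post10", "post30", "post3.5h", "post24h")
TEMPORAL_PROFILES = ("early", "middle", "late", "all")

#: Later post-exercise timepoint contributed by each temporal profile,
#: in addition to pre/during/post10 which every participant contributes.
PROFILE_TIMEPOINTS = {
    "early": ("post30",),
    "middle": ("post3.5h",),
    "late": ("post24h",),
    "all": ("post30", "post3.5h", "post24h"),
}

OMES = ("transcript_counts", "protein_log", "metabolite_intensity")

_META_REQUIRED = ("sample_id", "participant_id", "group", "timepoint")


class DesignError(ValueError):
    """Raised when a design matrix or contrast cannot be constructed."""


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it (unchanged).

    Checks the required columns, the uniqueness of
    (participant_id, timepoint), that during-exercise timepoints occur only
    in the EE and CON arms, and that every participant has a pre-exercise
    record (participants without one are flagged with a warning, mirroring
    the pairing requirement of the differential analysis).
    """
    missing = [c for c in _META_REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks required columns: {missing}")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups: {sorted(bad_group)}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    dup = meta.duplicated(subset=["participant_id", "timepoint"])
    if dup.any():
        raise ValueError(
            "(participant_id, timepoint) not unique for: "
            f"{meta.loc[dup, 'participant_id'].unique()[:5].tolist()}"
        )
    dur = meta["timepoint"].isin(DUR_TIMEPOINTS)
    if (dur & (meta["group"] == "RE")).any():
        raise ValueError("during-exercise samples present for the RE arm")
    has_pre = set(meta.loc[meta["timepoint"] == "pre", "participant_id"])
    unpaired = sorted(set(meta["participant_id"]) - has_pre)
    if unpaired:
        warnings.warn(
            f"{len(unpaired)} participant(s) without a pre-exercise sample: "
            f"{unpaired[:5]}",
            stacklevel=2,
        )
    return meta


@dataclass
class FeatureTable:
    """A features x samples abundance matrix with an ome tag.

    ``values`` is indexed by feature_id with sample_id columns; missing
    entries are NaN.  ``feature_meta`` (indexed by feature_id) may carry
    gene_symbol, refmet_id, platform and is_internal_standard annotations.
    Transcript counts must be complete non-negative integers.
    """

    values: pd.DataFrame
    ome: str
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ome not in OMES:
            raise ValueError(f"unknown ome {self.ome!r}; expected one of {OMES}")
        if self.ome == "transcript_counts":
            v = self.values.to_numpy()
            if np.isnan(v).any():
                raise ValueError("transcript counts may not contain missing entries")
            if (v < 0).any() or not np.allclose(v, np.round(v)):
                raise ValueError("transcript counts must be non-negative integers")
        if self.feature_meta is not None:
            if not self.feature_meta.index.equals(self.values.index):
                self.feature_meta = self.feature_meta.reindex(self.values.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def check_samples(self, meta: pd.DataFrame) -> None:
        extra = set(self.values.columns) - set(meta["sample_id"])
        if extra:
            raise ValueError(f"samples absent from metadata: {sorted(extra)[:5]}")


def cell_label(group: str, timepoint: str) -> str:
    return f"{group}:{timepoint}"


@dataclass
class ContrastSpec:
    """A named linear contrast over (group, timepoint) cell means.

    ``coefficients`` maps cell labels (``"EE:post10"``) to weights.  Weights
    always sum to zero; a difference-in-changes contrast has exactly the
    four weights {+1, -1, -1, +1} on (exercise, tp), (exercise, pre),
    (control, tp), (control, pre).
    """

    kind: str
    group_a: str
    group_b: str | None
    timepoint: str
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("difference_in_changes", "group_specific", "mode_vs_mode"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        total = sum(self.coefficients.values())
        if abs(total) > 1e-12:
            raise ValueError(f"contrast weights sum to {total}, not 0")
        if self.kind == "difference_in_changes":
            nz = sorted(v for v in self.coefficients.values() if v != 0)
            if nz != [-1.0, -1.0, 1.0, 1.0]:
                raise ValueError(
                    "difference_in_changes requires weights {+1, -1, -1, +1}"
                )

    @property
    def name(self) -> str:
        if self.kind == "difference_in_changes":
            return f"dd:{self.group_a}-vs-{self.group_b}:{self.timepoint}"
        if self.kind == "group_specific":
            return f"gs:{self.group_a}:{self.timepoint}"
        return f"mode:{self.group_a}-vs-{self.group_b}:{self.timepoint}"

    def vector(self, columns: "pd.Index | list[str]") -> np.ndarray:
        """Expand to a dense weight vector over design-matrix columns."""
        cols = list(columns)
        L = np.zeros(len(cols))
        for cell, w in self.coefficients.items():
            if w == 0:
                continue
            if cell not in cols:
                raise DesignError(f"contrast cell {cell!r} not in design")
            L[cols.index(cell)] = w
        return L


def delta_delta_contrast(
    design_cells: "set[str] | list[str]",
    exercise_group: str,
    timepoint: str,
    control: str = "CON",
) -> ContrastSpec:
    """Difference-in-changes contrast: (tp - pre in exercise) - (tp - pre in CON).

    Isolates the exercise response from circadian, fasting and procedural
    drift shared with the non-exercise control arm.
    """
    cells = set(design_cells)
    need = [
        cell_label(exercise_group, timepoint),
        cell_label(exercise_group, "pre"),
        cell_label(control, timepoint),
        cell_label(control, "pre"),
    ]
    for cell in need:
        if cell not in cells:
            raise DesignError(f"cell {cell!r} missing from design; contrast skipped")
    coef = {need[0]: 1.0, need[1]: -1.0, need[2]: -1.0, need[3]: 1.0}
    return ContrastSpec(
        "difference_in_changes", exercise_group, control, timepoint, coef
    )


def group_specific_contrast(
    design_cells: "set[str] | list[str]", group: str, timepoint: str
) -> ContrastSpec:
    """Within-group change contrast: timepoint minus pre in one arm."""
    cells = set(design_cells)
    need = [cell_label(group, timepoint), cell_label(group, "pre")]
    for cell in need:
        if cell not in cells:
            raise DesignError(f"cell {cell!r} missing from design; contrast skipped")
    return ContrastSpec(
        "group_specific", group, None, timepoint, {need[0]: 1.0, need[1]: -1.0}
    )


def mode_vs_mode_contrast(
    design_cells: "set[str] | list[str]",
    group_a: str = "RE",
    group_b: str = "EE",
    timepoint: str = "post10",
) -> ContrastSpec:
    """Resistance vs endurance as a difference of within-group changes.

    (tp - pre in RE) - (tp - pre in EE); a config switch in run_da selects
    the direct timepoint comparison instead.
    """
    cells = set(design_cells)
    need = [
        cell_label(group_a, timepoint),
        cell_label(group_a, "pre"),
        cell_label(group_b, timepoint),
        cell_label(group_b, "pre"),
    ]
    for cell in need:
        if cell not in cells:
            raise DesignError(f"cell {cell!r} missing from design; contrast skipped")
    coef = {need[0]: 1.0, need[1]: -1.0, need[2]: -1.0, need[3]: 1.0}
    return ContrastSpec("mode_vs_mode", group_a, group_b, timepoint, coef)


def build_cell_means_design(
    meta: pd.DataFrame, covariates: "list[str] | tuple[str, ...]" = ()
) -> tuple[pd.DataFrame, dict]:
    """Build the no-intercept cell-means design matrix.

    One indicator column per observed (group, timepoint) cell, named
    ``group:timepoint``, plus covariate columns: continuous covariates are
    mean-centered (so cell-mean estimates keep their interpretation);
    categorical covariates are one-hot encoded dropping the first level.
    Cells that are legal in the design but unobserved are omitted with a
    warning.  Raises :class:`DesignError` on rank deficiency, naming the
    aliased columns.

    Returns (design DataFrame indexed by sample_id, column map with keys
    ``cells`` and ``covariates``).
    """
    meta = meta.reset_index(drop=True)
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} not in metadata")
        if meta[cov].isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")

    possible = [
        cell_label(g, t)
        for g in GROUPS
        for t in TIMEPOINTS
        if not (g == "RE" and t in DUR_TIMEPOINTS)
    ]
    observed = {
        cell_label(g, t) for g, t in zip(meta["group"], meta["timepoint"])
    }
    cells = [c for c in possible if c in observed]
    dropped = sorted(set(possible) - observed)
    if dropped:
        logger.warning("empty design cells dropped: %s", dropped)

    X = pd.DataFrame(0.0, index=meta["sample_id"], columns=cells)
    labels = [cell_label(g, t) for g, t in zip(meta["group"], meta["timepoint"])]
    for row, lab in zip(X.index, labels):
        X.loc[row, lab] = 1.0

    cov_cols: list[str] = []
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            X[cov] = (col - col.mean()).to_numpy()
            cov_cols.append(cov)
        else:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                name = f"{cov}[{lev}]"
                X[name] = (col.astype(str) == lev).astype(float).to_numpy()
                cov_cols.append(name)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _find_aliased(X.to_numpy(), list(X.columns))
        raise DesignError(
            f"design matrix rank deficient ({rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}"
        )
    col_map = {"cells": cells, "covariates": cov_cols, "dropped_cells": dropped}
    return X, col_map


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    aliased = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            aliased.append(names[j])
        else:
            keep.append(j)
    return aliased


def bh_adjust(pvalues, strata=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within strata.

    ``strata`` assigns each p-value to exactly one stratum (any hashable
    labels); adjustment never pools across strata.  NaN p-values propagate
    NaN and are excluded from their stratum's test count m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if strata is None:
        strata = np.zeros(len(p), dtype=int)
    strata = np.asarray(strata)
    if strata.shape != p.shape:
        raise ValueError("strata must align with pvalues")
    for s in pd.unique(strata):
        idx = np.where((strata == s) & ok)[0]
        if idx.size == 0:
            continue
        ps = p[idx]
        m = ps.size
        order = np.argsort(ps, kind="mergesort")
        ranked = ps[order] * m / np.arange(1, m + 1)
        # enforce step-up monotonicity from the largest p downwards
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.clip(adj, 0.0, 1.0)
        out[idx[order]] = adj
    return out


def stratum_id(contrast: str, group: str, tissue: str, ome: str, timepoint: str) -> str:
    """Canonical stratum identifier for per-stratum FDR control."""
    return f"{contrast}|{group}|{tissue}|{ome}|{timepoint}"
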