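"""Differential-abundance engine: pairing filter, voom-style weights,
planted-effect recovery, null behaviour and invariances."""

import numpy as np
import pandas as pd
import pytest

from acutephys.core import FeatureTable, build_cell_means_design, delta_delta_contrast
from acutephys.differential import (
    DifferentialAbundanceModel,
    default_contrasts,
    min_pairing_filter,
    precision_weights,
    run_da,
)
from acutephys.simulate import (
    SimScenario,
    default_moments,
    preset_scenario,
    simulate_counts,
    simulate_longitudinal,
)


def _mask(table, meta, group, tp, participants, rng=None):
    """Blank out the (participant, timepoint) cells named."""
    meta_idx = meta.set_index("sample_id")
    v = table.values.copy()
    for part in participants:
        ids = meta_idx.index[
            (meta_idx.participant_id == part) & (meta_idx.timepoint == tp)
        ]
        v.loc[:, ids] = np.nan
    return FeatureTable(v, table.ome)


class TestMinPairingFilter:
    @pytest.fixture(scope="class")
    def dataset(self):
        scen, mom = preset_scenario("adipose")  # n=4 per sex x group subgroup
        table, meta = simulate_longitudinal(mom, scen, n_features=3, seed=5)
        return table, meta

    def test_boundary_three_pairs_eligible(self, dataset):
        table, meta = dataset
        specs = [delta_delta_contrast(
            {"EE:pre", "EE:post10", "CON:pre", "CON:post10"}, "EE", "post10")]
        # EE has 8 participants at post10; drop 5 -> exactly 3 complete pairs
        ee_parts = meta.loc[meta.group == "EE", "participant_id"].unique()
        t2 = _mask(table, meta, "EE", "post10", ee_parts[:5])
        elig = min_pairing_filter(meta, t2, specs)
        assert elig.all().all()

    def test_two_pairs_in_con_blocks_contrast(self, dataset):
        table, meta = dataset
        specs = [delta_delta_contrast(
            {"EE:pre", "EE:post10", "CON:pre", "CON:post10"}, "EE", "post10")]
        con_parts = meta.loc[meta.group == "CON", "participant_id"].unique()
        t2 = _mask(table, meta, "CON", "post10", con_parts[: len(con_parts) - 2])
        elig = min_pairing_filter(meta, t2, specs)
        assert not elig.any().any()

    def test_matches_bruteforce_pair_counting(self, dataset, rng):
        """Oracle: direct per-feature counting on a random missingness mask."""
        table, meta = dataset
        v = table.values.copy()
        drop = rng.random(v.shape) < 0.3
        v = v.mask(pd.DataFrame(drop, index=v.index, columns=v.columns))
        t2 = FeatureTable(v, table.ome)
        specs = default_contrasts(
            ["EE:pre", "EE:post10", "CON:pre", "CON:post10"], meta,
            kinds=("difference_in_changes",),
        )
        elig = min_pairing_filter(meta, t2, specs, min_n=3)
        midx = meta.set_index("sample_id")
        for fid in v.index:
            for spec in specs:
                ok = True
                for g in (spec.group_a, spec.group_b):
                    count = 0
                    for part, sub in midx[midx.group == g].groupby("participant_id"):
                        pre = sub.index[sub.timepoint == "pre"]
                        tp = sub.index[sub.timepoint == spec.timepoint]
                        if len(pre) and len(tp) and \
                           not np.isnan(v.loc[fid, pre[0]]) and \
                           not np.isnan(v.loc[fid, tp[0]]):
                            count += 1
                    ok &= count >= 3
                assert elig.loc[fid, spec.name] == ok


class TestPrecisionWeights:
    def test_flat_trend_gives_constant_weights(self, blood_design, rng):
        """Homoscedastic pseudo-counts: weights nearly constant."""
        _, meta = blood_design
        n = len(meta)
        # equal-library, equal-mean counts -> flat mean-variance trend
        C = rng.poisson(1000.0, size=(60, n)).astype(float)
        base = np.round(np.exp(rng.uniform(4, 9, size=60)))
        C = rng.poisson(np.outer(base, np.ones(n))) + 1.0
        table = FeatureTable(
            pd.DataFrame(C, index=[f"g{i}" for i in range(60)],
                         columns=meta.sample_id), "transcript_counts")
        X, _ = build_cell_means_design(meta)
        w = precision_weights(table, X)
        # Poisson log-CPM has a residual trend only at small means; at these
        # depths per-observation weights should vary mildly within a gene
        within = (w.max(axis=1) / w.min(axis=1)).median()
        assert within < 1.5

    def test_trend_weights_increase_with_count(self, blood_design):
        """NB counts with a strong trend: low-count observations downweighted."""
        _, meta = blood_design
        counts = simulate_counts(400, meta, dispersion_slope=20.0, seed=8)
        X, _ = build_cell_means_design(meta)
        w = precision_weights(counts, X)
        mean_count = counts.values.mean(axis=1)
        lo = mean_count < np.quantile(mean_count, 0.2)
        hi = mean_count > np.quantile(mean_count, 0.8)
        assert w.loc[lo].mean().mean() < w.loc[hi].mean().mean()

    def test_too_few_genes_refused(self, blood_design):
        _, meta = blood_design
        counts = simulate_counts(5, meta, seed=1)
        X, _ = build_cell_means_design(meta)
        with pytest.raises(ValueError, match="10 genes"):
            precision_weights(counts, X)

    def test_constant_counts_degenerate(self, blood_design):
        _, meta = blood_design
        C = np.full((20, len(meta)), 100.0)
        table = FeatureTable(
            pd.DataFrame(C, index=[f"g{i}" for i in range(20)],
                         columns=meta.sample_id), "transcript_counts")
        X, _ = build_cell_means_design(meta)
        with pytest.raises(ValueError, match="degenerate"):
            precision_weights(table, X)


class TestRunDa:
    @pytest.fixture(scope="class")
    def planted(self):
        """200 features, 50 with a planted delta=1 effect at post10 in EE."""
        scen_a = SimScenario(n_per_subgroup=10, effect_size=1.0)
        scen_0 = SimScenario(n_per_subgroup=10)
        mom_a = default_moments(scen_a)
        mom_0 = default_moments(scen_0)
        t_alt, meta = simulate_longitudinal(mom_a, scen_a, n_features=50, seed=21)
        t_null, _ = simulate_longitudinal(mom_0, scen_0, n_features=150, seed=22)
        t_null.values.index = [f"null{i:04d}" for i in range(150)]
        values = pd.concat([t_alt.values, t_null.values])
        table = FeatureTable(values, "metabolite_intensity")
        spec = delta_delta_contrast(
            {"EE:pre", "EE:post10", "CON:pre", "CON:post10"}, "EE", "post10")
        res = run_da(table, meta, covariates=("sex",), contrasts=[spec])
        return res, t_alt.values.index

    def test_planted_effects_enriched(self, planted):
        res, true_ids = planted
        sig = set(res.frame.loc[res.frame.p_adj < 0.05, "feature_id"])
        power = len(sig & set(true_ids)) / len(true_ids)
        assert power > 0.5  # delta=1 at n=10/subgroup is comfortably detectable
        # false discoveries controlled
        false = len(sig - set(true_ids))
        assert false <= max(3, 0.1 * max(len(sig), 1))

    def test_estimates_near_truth(self, planted):
        res, true_ids = planted
        est = res.frame.set_index("feature_id").loc[list(true_ids), "estimate"]
        assert est.mean() == pytest.approx(1.0, abs=0.15)

    def test_control_drift_invisible_to_delta_delta(self):
        """A time trend shared by all groups is significant group-specifically
        but null in the difference-in-changes readout."""
        scen = SimScenario(n_per_subgroup=12)
        mom = default_moments(scen)
        table, meta = simulate_longitudinal(mom, scen, n_features=40, seed=33)
        drift = meta.timepoint.eq("post10").to_numpy() * 1.5
        v = table.values + drift[None, :]
        table = FeatureTable(pd.DataFrame(v, index=table.values.index,
                                          columns=table.values.columns),
                             "metabolite_intensity")
        res = run_da(table, meta, covariates=("sex",))
        frame = res.frame
        gs = frame[(frame.contrast == "gs:CON:post10")]
        dd = frame[(frame.contrast == "dd:EE-vs-CON:post10")]
        assert (gs.p_adj < 0.05).mean() > 0.8  # drift detected within CON
        assert (dd.p_adj < 0.05).mean() <= 0.1  # but cancels in delta-delta

    def test_row_permutation_invariance(self):
        scen, mom = preset_scenario("muscle")
        table, meta = simulate_longitudinal(mom, scen, n_features=4, seed=44)
        res1 = run_da(table, meta, covariates=("sex",))
        perm = np.random.default_rng(0).permutation(len(meta))
        meta2 = meta.iloc[perm].reset_index(drop=True)
        table2 = FeatureTable(table.values[meta2.sample_id], table.ome)
        res2 = run_da(table2, meta2, covariates=("sex",))
        a = res1.frame.set_index(["feature_id", "contrast"]).sort_index()
        b = res2.frame.set_index(["feature_id", "contrast"]).sort_index()
        assert np.allclose(a["p"], b["p"], atol=1e-8, equal_nan=True)

    def test_covariates_do_not_bias_delta_delta(self):
        """Randomization property: planted covariate effects leave the
        difference-in-changes estimate unbiased."""
        scen = SimScenario(n_per_subgroup=20)
        mom = default_moments(scen)
        table, meta = simulate_longitudinal(mom, scen, n_features=30, seed=55)
        rng = np.random.default_rng(9)
        meta = meta.copy()
        ages = {p: a for p, a in zip(meta.participant_id.unique(),
                                     rng.uniform(25, 65, meta.participant_id.nunique()))}
        meta["age"] = meta.participant_id.map(ages)
        v = table.values + 0.05 * (meta["age"].to_numpy() - 45)[None, :]
        table = FeatureTable(pd.DataFrame(v, index=table.values.index,
                                          columns=table.values.columns),
                             "metabolite_intensity")
        spec = delta_delta_contrast(
            {"EE:pre", "EE:post10", "CON:pre", "CON:post10"}, "EE", "post10")
        res = run_da(table, meta, covariates=("sex", "age"), contrasts=[spec])
        assert res.frame["estimate"].mean() == pytest.approx(0.0, abs=0.12)

    def test_summary_mentions_strata(self, planted):
        res, _ = planted
        text = res.summary()
        assert "strata" in text
        assert "significant" in text
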