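"""Metabolomics cleaning chain: boundary semantics, imputation oracles,
normalization gate, outlier flags and redundancy resolution."""

import numpy as np
import pandas as pd
import pytest

from acutephys.core import FeatureTable
from acutephys.metabolomics import (
    PrepLog,
    average_duplicates,
    filter_missing,
    impute,
    log2_plus1,
    mask_nonpositive,
    median_mad_normalize,
    pc_outlier_flags,
    platform_cv,
    preprocess,
    resolve_redundancy,
)
from acutephys.simulate import (
    SimScenario,
    simulate_design,
    simulate_metabolite_platforms,
)
from conftest import make_table


def tbl(arr, **kw):
    return make_table(np.asarray(arr, dtype=float), **kw)


class TestAverageDuplicates:
    def test_entrywise_mean(self):
        t = tbl([[1, 3], [3, 1]], features=["m1", "m1"])
        out = average_duplicates(t)
        assert out.values.loc["m1"].tolist() == [2.0, 2.0]

    def test_all_missing_stays_missing(self):
        t = tbl([[1, np.nan], [3, np.nan]], features=["m1", "m1"])
        out = average_duplicates(t)
        assert out.values.loc["m1", "s0"] == 2.0
        assert np.isnan(out.values.loc["m1", "s1"])

    def test_no_duplicates_identity(self):
        t = tbl([[1, 2], [3, 4]])
        pd.testing.assert_frame_equal(average_duplicates(t).values, t.values)


class TestMaskNonpositive:
    @pytest.mark.parametrize("x,missing", [(-1.0, True), (0.0, True), (0.5, False)])
    def test_boundary(self, x, missing):
        out = mask_nonpositive(tbl([[x]]))
        assert np.isnan(out.values.iloc[0, 0]) == missing


class TestFilterMissing:
    def test_exactly_twenty_percent_kept(self):
        row = [1.0] * 8 + [np.nan] * 2  # 20% missing: "> 20%" is strict
        out = filter_missing(tbl([row]))
        assert len(out.values) == 1

    def test_above_twenty_percent_removed(self):
        row = [1.0] * 7 + [np.nan] * 3
        out = filter_missing(tbl([row]))
        assert len(out.values) == 0

    def test_complete_table_identity(self, rng):
        t = tbl(rng.uniform(1, 5, size=(4, 6)))
        assert len(filter_missing(t).values) == 4

    def test_idempotent(self, rng):
        v = rng.uniform(1, 5, size=(10, 10))
        v[0, :3] = np.nan
        t = filter_missing(tbl(v))
        t2 = filter_missing(t)
        pd.testing.assert_frame_equal(t.values, t2.values)


class TestImpute:
    def test_half_minimum_small_panel(self):
        v = np.array([[4.0, 8.0, np.nan], [2.0, 2.0, 2.0]])
        out = impute(tbl(v))
        assert out.values.iloc[0, 2] == 2.0  # half of the row minimum 4.0

    def test_complete_identity(self, rng):
        t = tbl(rng.uniform(1, 5, size=(20, 8)))
        pd.testing.assert_frame_equal(impute(t).values, t.values)

    def test_knn_perfect_neighbor(self, rng):
        """A feature duplicated exactly: the masked entry is filled from its twin."""
        base = rng.uniform(1, 5, size=(50, 12))
        base[1] = base[0]
        masked = base.copy()
        masked[0, 4] = np.nan
        out = impute(tbl(masked))
        assert out.values.iloc[0, 4] == pytest.approx(base[1, 4], abs=1e-9)

    def test_observed_entries_never_altered(self, rng):
        v = rng.uniform(1, 5, size=(30, 10))
        v[2, 3] = np.nan
        t = tbl(v)
        out = impute(t)
        mask = ~np.isnan(v)
        assert np.array_equal(out.values.to_numpy()[mask], v[mask])

    def test_idempotent(self, rng):
        v = rng.uniform(1, 5, size=(30, 10))
        v[2, 3] = np.nan
        once = impute(tbl(v))
        twice = impute(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_missing_feature_rejected(self):
        v = np.full((3, 4), np.nan)
        v[1:] = 1.0
        with pytest.raises(ValueError, match="no observed"):
            impute(tbl(v))


class TestLog2Plus1:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_values(self, x, expected):
        assert log2_plus1(tbl([[x]])).values.iloc[0, 0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_plus1(tbl([[-0.5]]))


@pytest.fixture(scope="module")
def balanced_meta():
    scen = SimScenario(n_per_subgroup=12)
    return simulate_design(scen, np.random.default_rng(2))


class TestMedianMad:
    def test_normalized_samples_centered(self, balanced_meta, rng):
        v = rng.lognormal(2, 0.5, size=(40, len(balanced_meta)))
        t = tbl(np.log2(v + 1), samples=list(balanced_meta.sample_id))
        out, report = median_mad_normalize(t, balanced_meta)
        assert report["applied"]
        med = out.values.median(axis=0)
        assert np.allclose(med, 0.0, atol=1e-12)

    def test_sex_shift_trips_gate(self, balanced_meta, rng):
        v = rng.lognormal(2, 0.3, size=(40, len(balanced_meta)))
        t = np.log2(v + 1)
        sex = balanced_meta.set_index("sample_id")["sex"]
        t = t + 5.0 * (sex == "F").to_numpy()[None, :]  # strong sample-median shift
        table = tbl(t, samples=list(balanced_meta.sample_id))
        out, report = median_mad_normalize(table, balanced_meta)
        assert not report["applied"]
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_zero_mad_named(self, balanced_meta):
        v = np.ones((10, len(balanced_meta)))
        t = tbl(v, samples=list(balanced_meta.sample_id))
        with pytest.raises(ValueError, match="MAD is zero"):
            median_mad_normalize(t, balanced_meta)

    def test_location_scale_equivariance(self, balanced_meta, rng):
        """Output invariant to per-sample affine rescaling of the input."""
        v = rng.normal(10, 2, size=(60, len(balanced_meta)))
        t1 = tbl(v, samples=list(balanced_meta.sample_id))
        scale = rng.uniform(0.5, 2, size=v.shape[1])
        shift = rng.uniform(-3, 3, size=v.shape[1])
        t2 = tbl(v * scale + shift, samples=list(balanced_meta.sample_id))
        o1, r1 = median_mad_normalize(t1, balanced_meta)
        o2, r2 = median_mad_normalize(t2, balanced_meta)
        if r1["applied"] and r2["applied"]:
            assert np.allclose(o1.values, o2.values, atol=1e-10)


class TestPcOutliers:
    def test_planted_outlier_flagged(self, rng):
        v = rng.normal(size=(30, 100))
        v[:, 0] += 0.0
        # plant one sample far out along the dominant direction
        v[:, 7] = v[:, 7] + 20.0
        t = tbl(v)
        flags = pc_outlier_flags(t, multiplier=5, n_pcs=5)
        assert flags == ["s7"]

    def test_huge_multiplier_flags_nothing(self, rng):
        t = tbl(rng.normal(size=(30, 50)))
        assert pc_outlier_flags(t, multiplier=1e6, n_pcs=3) == []

    def test_proteomics_preset_four_planted(self, rng):
        v = rng.normal(size=(50, 300))
        for j in (3, 77, 150, 299):
            v[:, j] += 15.0
        flags = pc_outlier_flags(tbl(v), preset="proteomics")
        assert set(flags) == {"s3", "s77", "s150", "s299"}

    def test_npcs_exceeding_rank(self, rng):
        t = tbl(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="rank"):
            pc_outlier_flags(t, multiplier=3, n_pcs=3)


class TestRedundancy:
    def test_lowest_cv_platform_wins(self, balanced_meta):
        tables, truth = simulate_metabolite_platforms(
            20, 10, {"A": 0.05, "B": 0.20}, 0.0, balanced_meta, seed=6
        )
        merged, prov = resolve_redundancy(tables)
        for ref, plat in truth["best_platform"].items():
            rows = merged.feature_meta[merged.feature_meta.refmet_id == ref]
            assert list(rows.platform.unique()) == [plat]
        assert set(prov.refmet_id) == set(truth["best_platform"])

    def test_unique_id_kept_regardless(self, balanced_meta):
        tables, _ = simulate_metabolite_platforms(
            20, 10, {"A": 0.05, "B": 0.20}, 0.0, balanced_meta, seed=6
        )
        merged, _ = resolve_redundancy(tables)
        own_b = merged.feature_meta[
            merged.feature_meta.refmet_id.astype(str).str.startswith("REFMET_B")
        ]
        assert len(own_b) == 10  # B's platform-unique features all survive

    def test_missing_standards_rejected(self, balanced_meta):
        tables, _ = simulate_metabolite_platforms(
            6, 3, {"A": 0.05, "B": 0.20}, 0.0, balanced_meta, seed=6
        )
        bad = FeatureTable(
            tables[0].values,
            tables[0].ome,
            tables[0].feature_meta.assign(is_internal_standard=False),
        )
        with pytest.raises(ValueError, match="internal standards"):
            resolve_redundancy([bad, tables[1]])


class TestPipeline:
    def test_fixed_order_and_preplog(self, balanced_meta):
        tables, _ = simulate_metabolite_platforms(
            30, 10, {"A": 0.05, "B": 0.20}, 0.10, balanced_meta, seed=9
        )
        out, flagged, log, gate = preprocess(tables[0], balanced_meta)
        steps = [r["step"] for r in log.records]
        assert steps == [
            "average_duplicates", "mask_nonpositive", "filter_missing",
            "impute", "log2_plus1", "median_mad_normalize", "pc_outlier_flags",
        ]
        counts = [(r["features_in"], r["features_out"]) for r in log.records]
        for n_in, n_out in counts:
            assert n_out <= n_in
        assert not out.values.isna().any().any()

    def test_preplog_rejects_feature_gain(self):
        log = PrepLog()
        with pytest.raises(ValueError):
            log.add("bogus", 5, 6)
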