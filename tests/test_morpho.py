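"""Morphological profiling: aggregation, rMAD, GED, activity, interference."""

import numpy as np
import pandas as pd
import pytest

from dompaint.morpho import (
    WellSchema,
    activity_partition,
    aggregate_wells,
    default_schema,
    global_euclidean_distance,
    interference_assessment,
    median_profiles,
    rmad_normalize,
)

from conftest import make_wells


def cells_table(rows):
    return pd.DataFrame(
        rows, columns=["plate", "well", "treatment", "is_control",
                       "nuclear_area", "nuclear_diameter", "cell_area"]
    )


class TestAggregateWells:
    def test_mean_and_unbiased_variance(self, small_schema):
        cells = cells_table([
            ("P1", "W1", "T1", False, 1.0, 1.0, 10.0),
            ("P1", "W1", "T1", False, 3.0, 2.0, 12.0),
        ])
        wells = aggregate_wells(cells, small_schema)
        assert wells.values.loc[0, "nuclear_area__mean"] == pytest.approx(2.0)
        assert wells.values.loc[0, "nuclear_area__var"] == pytest.approx(2.0)

    def test_identical_cells_zero_variance(self, small_schema):
        cells = cells_table([
            ("P1", "W1", "T1", False, 5.0, 2.0, 10.0),
            ("P1", "W1", "T1", False, 5.0, 2.0, 10.0),
            ("P1", "W1", "T1", False, 5.0, 2.0, 10.0),
        ])
        wells = aggregate_wells(cells, small_schema)
        assert wells.values.loc[0, "nuclear_area__mean"] == pytest.approx(5.0)
        assert wells.values.loc[0, "nuclear_area__var"] == pytest.approx(0.0)

    def test_collinear_features_correlation_one(self, small_schema):
        cells = cells_table([
            ("P1", "W1", "T1", False, 1.0, 2.0, 10.0),
            ("P1", "W1", "T1", False, 2.0, 4.0, 11.0),
            ("P1", "W1", "T1", False, 3.0, 6.0, 9.0),
        ])
        wells = aggregate_wells(cells, small_schema)
        assert wells.values.loc[0, "corr__nuclear_area__nuclear_diameter"] == pytest.approx(1.0)

    def test_single_cell_well_flagged_missing(self, small_schema):
        cells = cells_table([("P1", "W1", "T1", False, 5.0, 2.0, 10.0)])
        wells = aggregate_wells(cells, small_schema)
        assert wells.values.loc[0, "nuclear_area__var"] == 0.0
        assert np.isnan(wells.values.loc[0, "corr__nuclear_area__cell_area"])

    def test_nonfinite_rejected(self, small_schema):
        cells = cells_table([("P1", "W1", "T1", False, np.inf, 2.0, 10.0)])
        with pytest.raises(ValueError):
            aggregate_wells(cells, small_schema)


class TestRmadNormalize:
    def test_hand_worked_z_score(self):
        # controls {10,12,14,16,18}: median 14, raw MAD 2; treatment 20 -> 3
        labels = pd.DataFrame({
            "plate": ["P1"] * 6, "well": [f"W{i}" for i in range(6)],
            "treatment": ["DMSO"] * 5 + ["T1"],
            "is_control": [True] * 5 + [False],
        })
        values = pd.DataFrame({"f": [10.0, 12, 14, 16, 18, 20]})
        from dompaint.morpho import WellProfileMatrix
        out = rmad_normalize(WellProfileMatrix(values=values, labels=labels))
        assert out.values.loc[5, "f"] == pytest.approx(3.0)
        assert out.values.loc[2, "f"] == pytest.approx(0.0)  # control at median

    def test_control_median_zero_mad_one(self):
        wells = make_wells(plates=2, seed=3)
        out = rmad_normalize(wells)
        for plate, idx in out.labels.groupby("plate").groups.items():
            ctrl = out.values.loc[[i for i in idx if out.labels.loc[i, "is_control"]]]
            med = ctrl.median(axis=0).to_numpy()
            mad = (ctrl - ctrl.median(axis=0)).abs().median(axis=0).to_numpy()
            assert np.allclose(med, 0.0, atol=1e-9)
            assert np.allclose(mad, 1.0, atol=1e-9)

    def test_constant_control_feature_dropped(self):
        wells = make_wells(seed=4)
        wells.values.loc[wells.labels["is_control"], "f0"] = 7.0
        out = rmad_normalize(wells)
        assert "f0" in out.dropped_features
        assert "f0" not in out.values.columns

    def test_no_controls_rejected(self):
        wells = make_wells(n_controls=0)
        with pytest.raises(ValueError, match="control"):
            rmad_normalize(wells)

    def test_consistency_constant_scaling(self):
        wells = make_wells(seed=5)
        raw = rmad_normalize(wells)
        scaled = rmad_normalize(wells, consistency_constant=True)
        ratio = raw.values.to_numpy() / scaled.values.to_numpy()
        assert np.allclose(ratio[np.isfinite(ratio)], 1.4826, atol=1e-9)

    def test_commutes_with_well_reordering(self):
        wells = make_wells(seed=6)
        out1 = rmad_normalize(wells)
        perm = np.random.default_rng(0).permutation(len(wells.values))
        from dompaint.morpho import WellProfileMatrix
        shuffled = WellProfileMatrix(
            values=wells.values.iloc[perm].reset_index(drop=True),
            labels=wells.labels.iloc[perm].reset_index(drop=True),
        )
        out2 = rmad_normalize(shuffled)
        a = pd.concat([out1.labels["well"], out1.values], axis=1).sort_values("well").set_index("well")
        b = pd.concat([out2.labels["well"], out2.values], axis=1).sort_values("well").set_index("well")
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestMedianProfilesAndGed:
    def test_six_replicate_median(self):
        wells = make_wells(n_treatments=1, replicates=6)
        wells.values["f0"] = [1.0, 2, 3, 4, 5, 6] + list(wells.values["f0"][6:])
        med = median_profiles(wells)
        assert med.loc["T0", "f0"] == pytest.approx(3.5)

    def test_single_replicate_is_itself(self):
        wells = make_wells(n_treatments=2, replicates=1)
        med = median_profiles(wells)
        assert np.allclose(
            med.loc["T1"].to_numpy(),
            wells.values[wells.labels["treatment"] == "T1"].to_numpy()[0],
        )

    def test_against_sort_based_oracle(self):
        rng = np.random.default_rng(7)
        for reps in (3, 4, 5, 6):
            wells = make_wells(n_treatments=1, replicates=reps, seed=reps)
            med = median_profiles(wells)
            x = wells.values[wells.labels["treatment"] == "T0"].to_numpy()
            for j in range(x.shape[1]):
                s = np.sort(x[:, j])
                expected = s[reps // 2] if reps % 2 else (s[reps // 2 - 1] + s[reps // 2]) / 2
                assert med.loc["T0"].iloc[j] == pytest.approx(expected)

    def test_ged_basics(self):
        assert global_euclidean_distance(np.zeros(5)) == 0.0
        assert global_euclidean_distance(np.array([3.0, 4.0])) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            global_euclidean_distance(np.array([]))

    def test_ged_invariances(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=12)
        assert global_euclidean_distance(v) == pytest.approx(
            global_euclidean_distance(rng.permutation(v))
        )
        q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        assert global_euclidean_distance(q @ v) == pytest.approx(
            global_euclidean_distance(v)
        )
        # appending a feature never decreases the distance
        assert global_euclidean_distance(np.append(v, 2.0)) >= global_euclidean_distance(v)


class TestActivityPartition:
    def test_clear_split(self):
        s = pd.Series([0.1, 0.2, 5.0, 6.0], index=list("abcd"))
        lab = activity_partition(s)
        assert list(lab) == ["low", "low", "high", "high"]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 0.3, 5), rng.normal(4, 0.3, 4)])
        s = pd.Series(x)
        lab = activity_partition(s)
        # exhaustive search over all 2-group splits of the sorted values
        xs = np.sort(x)
        best, best_cut = -np.inf, None
        for cut in range(1, len(xs)):
            lo, hi = xs[:cut], xs[cut:]
            b = len(lo) * (lo.mean() - xs.mean()) ** 2 + len(hi) * (hi.mean() - xs.mean()) ** 2
            if b > best:
                best, best_cut = b, cut
        expected = np.where(x >= xs[best_cut], "high", "low")
        assert list(lab) == list(expected)

    def test_identical_scores_all_low(self):
        with pytest.warns(UserWarning):
            lab = activity_partition(pd.Series([1.0, 1.0, 1.0]))
        assert set(lab) == {"low"}

    def test_two_samples(self):
        lab = activity_partition(pd.Series([0.0, 10.0], index=["a", "b"]))
        assert lab["a"] == "low" and lab["b"] == "high"


class TestInterference:
    def table(self):
        return pd.DataFrame(
            [
                ("PBS", "none", "ch1", 100, 100.0),
                ("HA1", "none", "ch1", 100, 150.0),
                ("HA2", "none", "ch1", 100, 100.0),
                ("none", "hoechst", "ch1", 100, 100.0),
                ("HA1", "hoechst", "ch1", 100, 80.0),
            ],
            columns=["sample", "dye", "channel", "concentration_ppm", "readout"],
        )

    def test_autofluorescence_delta(self):
        out = interference_assessment(self.table())
        auto = out[(out["sample"] == "HA1") & (out["kind"] == "autofluorescence")]
        assert auto["delta"].iloc[0] == pytest.approx(50.0)

    def test_quenching_negative_delta(self):
        out = interference_assessment(self.table())
        q = out[(out["sample"] == "HA1") & (out["dye"] == "hoechst")]
        assert q["kind"].iloc[0] == "quenching"
        assert q["delta"].iloc[0] == pytest.approx(-20.0)

    def test_sample_equal_blank_zero(self):
        out = interference_assessment(self.table())
        auto = out[(out["sample"] == "HA2") & (out["kind"] == "autofluorescence")]
        assert auto["delta"].iloc[0] == pytest.approx(0.0)

    def test_missing_blank_rejected(self):
        t = self.table()
        t = t[t["sample"] != "PBS"]
        with pytest.raises(ValueError, match="blank"):
            interference_assessment(t)


def test_default_schema_has_272_features():
    schema = default_schema()
    assert schema.n_features == 272
    assert len(schema.columns) == 272
    assert len(set(schema.columns)) == 272
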