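"""Profile processing: aggregation, annotation, normalization, selection."""

import numpy as np
import pandas as pd
import pytest

import morphosig as m
from morphosig.profiles import feature_columns


def _cells(records):
    return pd.DataFrame.from_records(records)


class TestAggregateWells:
    def test_singleton_well_passes_through(self):
        cells = _cells(
            [{"Metadata_plate_id": "P1", "Metadata_well_id": "A01", "f": 3.5}]
        )
        out = m.aggregate_wells(cells)
        assert out["f"].tolist() == [3.5]
        assert out["Metadata_cell_count"].tolist() == [1]

    def test_even_count_median_is_midpoint(self):
        cells = _cells(
            [
                {"Metadata_plate_id": "P1", "Metadata_well_id": "A01", "f": 0.0},
                {"Metadata_plate_id": "P1", "Metadata_well_id": "A01", "f": 2.0},
            ]
        )
        assert m.aggregate_wells(cells)["f"].tolist() == [1.0]

    def test_matches_sort_and_pick_middle_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for w in range(10):
            for _ in range(5):
                rows.append(
                    {
                        "Metadata_plate_id": "P1",
                        "Metadata_well_id": f"A{w:02d}",
                        "f1": rng.normal(),
                        "f2": rng.normal(),
                    }
                )
        cells = _cells(rows)
        out = m.aggregate_wells(cells).set_index("Metadata_well_id")
        for w, sub in cells.groupby("Metadata_well_id"):
            for f in ("f1", "f2"):
                expected = sorted(sub[f])[2]  # middle of 5
                assert out.loc[w, f] == expected

    def test_cell_row_order_is_irrelevant(self, dataset):
        _, cells, _ = dataset
        shuffled = cells.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = m.aggregate_wells(cells)
        b = m.aggregate_wells(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_conflicting_well_metadata_rejected(self):
        cells = _cells(
            [
                {"Metadata_plate_id": "P1", "Metadata_well_id": "A01",
                 "Metadata_clone_id": "WT01", "f": 0.0},
                {"Metadata_plate_id": "P1", "Metadata_well_id": "A01",
                 "Metadata_clone_id": "WT02", "f": 1.0},
            ]
        )
        with pytest.raises(ValueError, match="not constant"):
            m.aggregate_wells(cells)


class TestAnnotate:
    platemap = pd.DataFrame(
        {
            "plate_id": ["P1", "P1"],
            "well_id": ["A01", "A02"],
            "clone_id": ["WT01", "RES01"],
            "resistance_status": ["sensitive", "resistant"],
            "treatment": ["DMSO 0.1%"] * 2,
            "incubation_time_h": [4, 13],
            "batch": ["B1", "B1"],
        }
    )

    def wells(self, well_ids):
        return pd.DataFrame(
            {
                "Metadata_plate_id": ["P1"] * len(well_ids),
                "Metadata_well_id": well_ids,
                "f": np.arange(len(well_ids), dtype=float),
            }
        )

    def test_complete_platemap_joins_bijectively(self):
        out = m.annotate(self.wells(["A01", "A02"]), self.platemap)
        assert len(out) == 2
        assert out["Metadata_clone_id"].tolist() == ["WT01", "RES01"]

    def test_unknown_well_is_named_in_error(self):
        with pytest.raises(ValueError, match="A03"):
            m.annotate(self.wells(["A01", "A03"]), self.platemap)

    def test_duplicate_platemap_entry_rejected(self):
        dup = pd.concat([self.platemap, self.platemap.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            m.annotate(self.wells(["A01"]), dup)


class TestNormalize:
    def wells(self, values, plates=None):
        values = np.asarray(values, dtype=float)
        plates = plates or ["P1"] * len(values)
        return pd.DataFrame(
            {
                "Metadata_plate_id": plates,
                "Metadata_well_id": [f"A{i:02d}" for i in range(len(values))],
                "f": values,
            }
        )

    def test_symmetric_pair_is_fixed_point(self):
        out = m.normalize(self.wells([-1.0, 1.0]))
        assert out["f"].tolist() == [-1.0, 1.0]

    def test_zero_mean_unit_sd_per_plate(self, dataset):
        platemap, cells, _ = dataset
        wells = m.annotate(m.aggregate_wells(cells), platemap)
        out = m.normalize(wells)
        feats = feature_columns(out)
        for _, sub in out.groupby("Metadata_plate_id"):
            X = sub[feats].to_numpy()
            assert np.abs(np.nanmean(X, axis=0)).max() < 1e-8
            assert np.abs(np.nanstd(X, axis=0) - 1).max() < 1e-8

    def test_plate_scale_and_shift_are_removed(self):
        base = np.array([0.1, -1.2, 2.0, 0.4, -0.6])
        wells = self.wells(
            np.concatenate([base, 100 + 7 * base]),
            plates=["P1"] * 5 + ["P2"] * 5,
        )
        out = m.normalize(wells)
        np.testing.assert_allclose(
            out["f"].to_numpy()[:5], out["f"].to_numpy()[5:], atol=1e-12
        )

    def test_single_well_plate_is_an_error(self):
        with pytest.raises(ValueError, match="single well"):
            m.normalize(self.wells([1.0]))

    def test_constant_feature_becomes_missing(self):
        out = m.normalize(self.wells([2.0, 2.0, 2.0]))
        assert out["f"].isna().all()


class TestSelectFeatures:
    def base_wells(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "Metadata_plate_id": ["P1"] * n,
                "Metadata_well_id": [f"A{i:02d}" for i in range(n)],
            }
        )
        for name in ("f1", "f2", "f3"):
            df[name] = rng.normal(size=n)
        return df

    def test_duplicated_feature_drops_exactly_one(self):
        wells = self.base_wells()
        wells["f1_copy"] = wells["f1"]
        out, report = m.select_features(wells)
        dropped = set(report["feature"])
        assert len(dropped & {"f1", "f1_copy"}) == 1
        assert (report["rule"] == "correlation").all()

    def test_missing_value_attributed_to_missing_rule(self):
        wells = self.base_wells()
        wells.loc[3, "f2"] = np.nan
        out, report = m.select_features(wells)
        row = report.set_index("feature").loc["f2"]
        assert row["rule"] == "missing"
        assert "f2" not in out.columns

    def test_blocklist_pattern_applied_first(self):
        wells = self.base_wells()
        wells["Nuclei_Correlation_Costes"] = np.nan  # would also hit missing
        cfg = m.FeatureSelectionConfig(blocklist=("Nuclei_Correlation_*",))
        _, report = m.select_features(wells, cfg)
        row = report.set_index("feature").loc["Nuclei_Correlation_Costes"]
        assert row["rule"] == "blocklist"

    def test_near_constant_feature_hits_low_variance(self):
        wells = self.base_wells()
        wells["f_const"] = 1.0
        wells.loc[0, "f_const"] = 2.0
        _, report = m.select_features(wells)
        assert report.set_index("feature").loc["f_const", "rule"] == "low_variance"

    def test_all_features_removed_is_an_error(self):
        wells = self.base_wells()[["Metadata_plate_id", "Metadata_well_id"]].copy()
        wells["f"] = 1.0
        with pytest.raises(ValueError):
            m.select_features(wells)

    def test_planted_outlier_feature_dropped_by_outlier_rule(self):
        # a 384-well plate with 300 wells: a single corrupted well can
        # exceed 15 SD after z-scoring (the ceiling is ~sqrt(n_wells))
        cfg = m.SyntheticConfig(
            replicates_per_clone=30,
            n_batches=1,
            plate_rows=16,
            plate_cols=24,
            outlier_rate=0.0008,
            seed=5,
        )
        platemap, cells, truth = m.simulate_dataset(cfg)
        wells = m.annotate(m.aggregate_wells(cells), platemap)
        _, report = m.select_features(m.normalize(wells))
        singly_corrupted = truth.loc[truth["n_outlier_wells"] == 1, "feature"]
        assert len(singly_corrupted) > 0  # the seed plants at least one
        by_rule = report.set_index("feature")["rule"]
        for f in singly_corrupted:
            assert by_rule.get(f) == "outlier", f

    def test_missing_injection_dropped_by_missing_rule(self):
        cfg = m.SyntheticConfig(missing_rate=0.002, seed=6)
        platemap, cells, truth = m.simulate_dataset(cfg)
        wells = m.annotate(m.aggregate_wells(cells), platemap)
        _, report = m.select_features(m.normalize(wells))
        corrupted = truth.loc[truth["n_missing_wells"] > 0, "feature"]
        assert len(corrupted) > 0
        by_rule = report.set_index("feature")["rule"]
        for f in corrupted:
            assert by_rule.get(f) == "missing", f

    def test_selection_is_idempotent(self, selected_wells):
        selected, _ = selected_wells
        again, report = m.select_features(selected)
        assert report.empty
        pd.testing.assert_frame_equal(again, selected)

    def test_no_surviving_pair_exceeds_threshold(self, selected_wells):
        selected, _ = selected_wells
        feats = feature_columns(selected)
        corr = selected[feats].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9

    def test_planted_signature_features_survive_default_pipeline(
        self, selected_wells, dataset
    ):
        selected, _ = selected_wells
        _, _, truth = dataset
        planted = truth.loc[truth["direction"] != 0, "feature"]
        assert set(planted) <= set(feature_columns(selected))
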