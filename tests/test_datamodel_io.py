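"""Data model and I/O: table contracts, readers, standardization."""

import logging

import numpy as np
import pandas as pd
import pytest

from healthycore.datamodel import (
    DataError,
    ConfigurationError,
    FeatureDescriptor,
    FeatureTable,
    SubjectRecord,
    concat_tables,
    default_desikan_features,
)
from healthycore.io import (
    read_aparc_tables,
    read_feature_table,
    split_by,
    standardize,
    write_feature_table,
)

from conftest import make_table, small_features


class TestFeatureDescriptor:
    def test_units_follow_measure(self):
        assert FeatureDescriptor("bankssts", "left", "area").units == "mm2"
        assert FeatureDescriptor("bankssts", "left", "thickness").units == "mm"
        assert FeatureDescriptor("bankssts", "left", "volume").units == "mm3"

    def test_invalid_fields_rejected(self):
        with pytest.raises(ConfigurationError):
            FeatureDescriptor("bankssts", "middle", "area")
        with pytest.raises(ConfigurationError):
            FeatureDescriptor("bankssts", "left", "curvature")

    def test_full_atlas_has_204_features(self):
        feats = default_desikan_features()
        assert len(feats) == 204
        assert len({(f.region_name, f.hemisphere, f.measure) for f in feats}) == 204


class TestFeatureTable:
    def test_duplicate_subject_rejected(self):
        subs = [
            SubjectRecord("S1", "DS1", "HC"),
            SubjectRecord("S1", "DS1", "HC"),
        ]
        with pytest.raises(DataError, match="duplicate subject_id"):
            FeatureTable(subs, small_features(2), np.zeros((2, 2)))

    def test_missing_value_rejected_with_location(self):
        subs = [SubjectRecord("S1", "DS1", "HC")]
        vals = np.array([[1.0, np.nan]])
        with pytest.raises(DataError, match="S1"):
            FeatureTable(subs, small_features(2), vals)

    def test_shape_mismatch_rejected(self):
        subs = [SubjectRecord("S1", "DS1", "HC")]
        with pytest.raises(DataError, match="shape"):
            FeatureTable(subs, small_features(3), np.zeros((1, 2)))

    def test_age_and_group_validation(self):
        with pytest.raises(DataError):
            SubjectRecord("S1", "DS1", "sick")
        with pytest.raises(DataError):
            SubjectRecord("S1", "DS1", "HC", age=-3.0)


class TestReadFeatureTable:
    def test_full_atlas_round_trip(self, tmp_path, rng):
        table = make_table(rng.standard_normal((5, 204)), features=default_desikan_features())
        path = tmp_path / "t.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        assert back.n_features == 204
        assert np.allclose(back.values, table.values, atol=1e-12)
        assert back.subject_ids == table.subject_ids
        assert back.features == table.features
        assert [s.sex for s in back.subjects] == [s.sex for s in table.subjects]

    def test_duplicate_id_in_file(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "subject_id,site,group,age,sex,lh_bankssts_area\n"
            "S1,DS1,HC,30,F,1.0\nS1,DS1,HC,31,M,2.0\n"
        )
        with pytest.raises(DataError, match="S1"):
            read_feature_table(path)

    def test_missing_cell_named(self, tmp_path):
        path = tmp_path / "na.csv"
        path.write_text(
            "subject_id,site,group,age,sex,lh_bankssts_area,rh_bankssts_area\n"
            "S1,DS1,HC,30,F,1.0,NA\nS2,DS1,HC,31,M,2.0,3.0\n"
        )
        with pytest.raises(DataError, match="rh_bankssts_area"):
            read_feature_table(path)
        # imputation fills with the feature median instead
        table = read_feature_table(path, impute=True)
        j = table.feature_names.index("rh_bankssts_area")
        assert table.values[0, j] == 3.0

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,site,group,age,sex,lh_bankssts_area\n"
            "S1,DS1,HC,30,F,oops\n"
        )
        with pytest.raises(DataError, match="lh_bankssts_area"):
            read_feature_table(path)

    def test_missing_metadata_column_is_config_error(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text("subject_id,group,age,sex,lh_bankssts_area\nS1,HC,30,F,1.0\n")
        with pytest.raises(ConfigurationError, match="site"):
            read_feature_table(path)


def _write_aparc(tmp_path, measure, frame):
    path = tmp_path / f"{measure}.tsv"
    frame.to_csv(path, sep="\t", index=False)
    return path


class TestReadAparcTables:
    @pytest.fixture
    def aparc_fixture(self, tmp_path, rng):
        from healthycore.datamodel import DESIKAN_KILLIANY_REGIONS

        ids = ["sub-01", "sub-02", "sub-03"]
        paths = {}
        for measure in ("area", "thickness", "volume"):
            cols = {"lh.aparc." + measure: ids}
            for hemi in ("lh", "rh"):
                for region in DESIKAN_KILLIANY_REGIONS:
                    cols[f"{hemi}_{region}_{measure}"] = rng.random(3) * 100
            # FreeSurfer aggregate columns that must be dropped
            cols["eTIV"] = [1.5e6] * 3
            if measure == "thickness":
                cols["lh_MeanThickness_thickness"] = [2.5] * 3
            if measure == "area":
                cols["lh_WhiteSurfArea_area"] = [9e4] * 3
            paths[measure] = _write_aparc(tmp_path, measure, pd.DataFrame(cols))
        meta = [SubjectRecord(i, "DS1", "HC", age=30.0, sex="F") for i in ids]
        return paths, meta

    def test_merges_to_204_features(self, aparc_fixture):
        paths, meta = aparc_fixture
        table = read_aparc_tables(paths["area"], paths["thickness"], paths["volume"], meta)
        assert table.n_features == 204
        assert table.n_subjects == 3
        units = {f.measure: f.units for f in table.features}
        assert units == {"area": "mm2", "thickness": "mm", "volume": "mm3"}

    def test_row_permutation_invariance(self, aparc_fixture, tmp_path):
        paths, meta = aparc_fixture
        ref = read_aparc_tables(paths["area"], paths["thickness"], paths["volume"], meta)
        shuffled = pd.read_csv(paths["thickness"], sep="\t").iloc[[2, 0, 1]]
        alt = _write_aparc(tmp_path / "..", "thickness_shuffled", shuffled)
        out = read_aparc_tables(paths["area"], alt, paths["volume"], meta)
        assert out.subject_ids == ref.subject_ids
        assert np.allclose(out.values, ref.values)

    def test_missing_subject_listed(self, aparc_fixture, tmp_path):
        paths, meta = aparc_fixture
        truncated = pd.read_csv(paths["thickness"], sep="\t").iloc[:2]
        alt = _write_aparc(tmp_path / "..", "thickness_short", truncated)
        with pytest.raises(DataError, match="sub-03"):
            read_aparc_tables(paths["area"], alt, paths["volume"], meta)


class TestSplitBy:
    def test_group_split_sizes(self, rng):
        hc = make_table(rng.standard_normal((96, 4)), group="HC", prefix="hc")
        cm = make_table(rng.standard_normal((41, 4)), group="CM", prefix="cm")
        pooled = concat_tables([hc, cm])
        parts = split_by(pooled, "group")
        assert parts["HC"].n_subjects == 96
        assert parts["CM"].n_subjects == 41

    def test_partition_is_row_permutation(self, rng):
        a = make_table(rng.standard_normal((5, 3)), site="DS1", prefix="a")
        b = make_table(rng.standard_normal((4, 3)), site="DS2", prefix="b")
        pooled = concat_tables([a, b])
        parts = split_by(pooled, "site")
        rebuilt = concat_tables(list(parts.values()))
        assert sorted(rebuilt.subject_ids) == sorted(pooled.subject_ids)
        order = [pooled.subject_ids.index(s) for s in rebuilt.subject_ids]
        assert np.allclose(rebuilt.values, pooled.values[order])

    def test_single_site_gives_one_entry(self, rng):
        t = make_table(rng.standard_normal((4, 3)))
        assert list(split_by(t, "site")) == ["DS1"]


class TestStandardize:
    def test_self_standardization_moments(self, rng):
        t = make_table(rng.standard_normal((40, 6)) * 5 + 3)
        out, _ = standardize(t)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.values.std(axis=0), 1.0, atol=1e-12)

    def test_round_trip_inversion(self, rng):
        t = make_table(rng.standard_normal((20, 6)) * 7 - 2)
        out, record = standardize(t)
        back = record.invert(out)
        assert np.allclose(back.values, t.values, atol=1e-10)
        assert [f.units for f in back.features] == [f.units for f in t.features]

    def test_reference_statistics_used(self, rng):
        ref = make_table(rng.standard_normal((50, 4)) + 10)
        t = make_table(rng.standard_normal((10, 4)))
        out, rec = standardize(t, reference=ref)
        assert np.allclose(rec.mean, ref.values.mean(axis=0))

    def test_constant_column_dropped_with_log(self, rng, caplog):
        vals = rng.standard_normal((10, 4))
        vals[:, 2] = 7.0
        t = make_table(vals)
        with pytest.raises(DataError):
            standardize(t)
        with caplog.at_level(logging.WARNING, logger="healthycore.io"):
            out, rec = standardize(t, on_zero_variance="drop")
        assert out.n_features == 3
        assert len(rec.dropped) == 1
        assert any("zero-variance" in r.message for r in caplog.records)
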