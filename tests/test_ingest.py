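"""Input-table validation, applicability-domain flagging, study-count filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podqsar import (
    FeatureTable,
    InvalidInputError,
    SchemaError,
    filter_by_study_count,
    flag_out_of_domain,
)
from podqsar.ingest import (
    EffectCategory,
    read_exposure_table,
    read_feature_table,
    read_pod_table,
    write_exposure_table,
    write_feature_table,
)

from conftest import make_pods


class TestFlagOutOfDomain:
    @pytest.mark.parametrize(
        "value,inside_global,local_index,expect_missing",
        [
            (5.2, False, 0.3, True),   # both criteria met -> missing
            (5.2, False, 0.5, False),  # only outside-global -> kept
            (5.2, True, 0.0, False),   # inside global domain always kept
            (5.2, False, 0.39, True),  # just below the 0.4 threshold
            (5.2, False, 0.4, False),  # at the threshold -> kept
        ],
    )
    def test_two_criterion_rule(self, value, inside_global, local_index,
                                expect_missing):
        out = flag_out_of_domain(value, inside_global, local_index)
        assert math.isnan(out) if expect_missing else out == value

    @pytest.mark.parametrize("bad_index", [-0.1, 1.5])
    def test_local_index_out_of_range(self, bad_index):
        with pytest.raises(InvalidInputError):
            flag_out_of_domain(1.0, True, bad_index)

    @given(
        value=st.floats(-1e6, 1e6),
        inside=st.booleans(),
        idx=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, value, inside, idx):
        once = flag_out_of_domain(value, inside, idx)
        twice = flag_out_of_domain(once, inside, idx)
        assert (math.isnan(once) and math.isnan(twice)) or once == twice

    def test_table_level_flagging_idempotent(self, labeled_data):
        table, _ = labeled_data
        once = table.apply_domain_flags()
        assert once.values.isna().to_numpy().any()
        assert once.apply_domain_flags().equals(once)


class TestStudyCountFilter:
    def test_boundary(self):
        ds = make_pods(["A", "B", "C"], [1.0, 2.0, 3.0],
                       study_count=[3, 4, 10])
        kept = filter_by_study_count(ds)
        assert kept.chemical_ids == ["B", "C"]  # 3 studies excluded, 4 kept

    def test_empty_dataset(self):
        ds = make_pods([], [])
        assert len(filter_by_study_count(ds)) == 0

    def test_min_zero_is_identity(self):
        ds = make_pods(["A", "B"], [1.0, 2.0], study_count=[0, 7])
        out = filter_by_study_count(ds, 0)
        pd.testing.assert_frame_equal(out.data, ds.data)

    def test_order_preserved(self):
        ids = list("FEDCBA")
        ds = make_pods(ids, range(6), study_count=[9, 1, 9, 1, 9, 9])
        assert filter_by_study_count(ds).chemical_ids == ["F", "D", "B", "A"]


class TestFeatureTableValidation:
    def test_duplicate_ids_rejected(self):
        values = pd.DataFrame({"WS": [1.0, 2.0]}, index=["A", "A"])
        with pytest.raises(SchemaError, match="duplicate chemical"):
            FeatureTable(values=values)

    def test_binary_values_checked(self):
        values = pd.DataFrame({"B": [0.0, 2.0]}, index=["A", "B"])
        with pytest.raises(InvalidInputError, match="binary"):
            FeatureTable(values=values, feature_kind={"B": "binary"})

    def test_local_index_range_checked(self):
        values = pd.DataFrame({"WS": [1.0]}, index=["A"])
        bad = pd.DataFrame({"WS": [1.2]}, index=["A"])
        with pytest.raises(InvalidInputError):
            FeatureTable(values=values, domain_local_index=bad)

    def test_kind_inference(self, small_table):
        assert small_table.feature_kind == {
            "WS": "continuous", "LogP": "continuous", "Biodeg": "binary"
        }


class TestFeatureCSV:
    def test_read_simple(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("DTXSID,WS\nA,1.5\nB,2.5\nC,\n")
        t = read_feature_table(p)
        assert t.n_chemicals == 3 and t.feature_names == ["WS"]
        assert math.isnan(t.values.loc["C", "WS"])  # empty cell -> missing
        assert t.domain_global.all().all()  # absent domain cols -> inside

    def test_domain_flagging_on_read(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text(
            "DTXSID,WS,WS_AD,WS_ADindex\n"
            "A,1.5,0,0.39\n"   # outside global + low local index -> missing
            "B,2.5,0,0.40\n"   # local index at threshold -> kept
            "C,3.5,1,0.10\n"   # inside global -> kept
        )
        t = read_feature_table(p)
        assert math.isnan(t.values.loc["A", "WS"])
        assert t.values.loc["B", "WS"] == 2.5
        assert t.values.loc["C", "WS"] == 3.5

    def test_na_sentinel_accepted(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("DTXSID,WS\nA,NA\nB,1.0\n")
        assert math.isnan(read_feature_table(p).values.loc["A", "WS"])

    @pytest.mark.parametrize(
        "body,match",
        [
            ("DTXSID,WS\nA,1.0\nA,2.0\n", "duplicate"),
            ("DTXSID,WS\nA,abc\n", "non-numeric"),
            ("DTXSID,WS,X_ADindex\nA,1.0,0.5\n", "no matching feature"),
            ("CASRN,WS\nA,1.0\n", "ID column"),
        ],
    )
    def test_parse_errors(self, tmp_path, body, match):
        p = tmp_path / "f.csv"
        p.write_text(body)
        with pytest.raises(SchemaError, match=match):
            read_feature_table(p)

    def test_roundtrip(self, tmp_path, labeled_data):
        table, _ = labeled_data
        p = tmp_path / "rt.csv"
        write_feature_table(table, p)
        back = read_feature_table(p, flag_domain=False)
        pd.testing.assert_frame_equal(back.values, table.values)
        pd.testing.assert_frame_equal(back.domain_global, table.domain_global)
        pd.testing.assert_frame_equal(
            back.domain_local_index, table.domain_local_index
        )
        assert back.feature_kind == table.feature_kind


class TestPODAndExposureIO:
    def test_pod_roundtrip_by_category(self, tmp_path):
        p = tmp_path / "pods.csv"
        p.write_text(
            "DTXSID,effect_category,log10_pod,study_count\n"
            "A,general_noncancer,1.2,5\n"
            "B,repro_developmental,0.3,8\n"
            "A,repro_developmental,0.9,4\n"
        )
        gen = read_pod_table(p, EffectCategory.GENERAL_NONCANCER)
        rep = read_pod_table(p, "repro_developmental")
        assert gen.chemical_ids == ["A"]
        assert rep.chemical_ids == ["B", "A"]
        assert rep.log10_pod.loc["A"] == 0.9

    def test_pod_nonfinite_rejected(self, tmp_path):
        p = tmp_path / "pods.csv"
        p.write_text("DTXSID,effect_category,log10_pod,study_count\n"
                     "A,general_noncancer,inf,5\n")
        with pytest.raises(InvalidInputError):
            read_pod_table(p, "general_noncancer")

    def test_exposure_roundtrip_and_ordering(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("DTXSID,p95,p5,p50\nA,1e-3,1e-6,1e-4\n")
        t = read_exposure_table(p)
        assert t.percentiles == [5.0, 50.0, 95.0]  # sorted on read
        doses = t.percentile_doses("A")
        assert doses[5.0] < doses[50.0] < doses[95.0]
        out = tmp_path / "e2.csv"
        write_exposure_table(t, out)
        pd.testing.assert_frame_equal(read_exposure_table(out).data, t.data)

    def test_exposure_nonmonotone_rejected(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("DTXSID,p5,p95\nA,1e-3,1e-6\n")
        with pytest.raises(InvalidInputError, match="nondecreasing"):
            read_exposure_table(p)
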