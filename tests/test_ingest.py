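"""Ingestion: readers, dedup, exclusions, labelling, onset derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import tastesig as ts
from tastesig.ingest import pt_code_for
from tastesig.config import jader_dialect

from conftest import make_case_data


class TestFaersReader:
    def test_row_count_equals_line_count(self, faers_dir):
        raw = ts.read_faers_tables(
            faers_dir / "demo.txt", faers_dir / "drug.txt",
            faers_dir / "reac.txt", faers_dir / "ther.txt",
        )
        assert len(raw.demo) == 3  # two versions of case 100, one of 200

    def test_latest_version_survives_dedup(self, faers_dir):
        raw = ts.read_faers_tables(
            faers_dir / "demo.txt", faers_dir / "drug.txt",
            faers_dir / "reac.txt", faers_dir / "ther.txt",
        )
        deduped = ts.dedup_tables(raw)
        c100 = deduped.demo[deduped.demo["case_id"] == "100"]
        assert len(c100) == 1 and c100["version"].iloc[0] == 2
        # detail tables align with the surviving primaryid
        assert set(deduped.drugs["primaryid"]) <= set(deduped.demo["primaryid"])

    def test_age_unit_conversion_months_to_years(self, faers_dir):
        raw = ts.read_faers_tables(
            faers_dir / "demo.txt", faers_dir / "drug.txt",
            faers_dir / "reac.txt", faers_dir / "ther.txt",
        )
        age = raw.demo.loc[raw.demo["case_id"] == "200", "age_years"].iloc[0]
        assert age == pytest.approx(2.0)

    def test_malformed_line_rejected_and_counted(self, faers_dir):
        bad = faers_dir / "demo.txt"
        bad.write_text(bad.read_text() + "300-1$300$1$50\n")  # short line
        raw = ts.read_faers_tables(
            faers_dir / "demo.txt", faers_dir / "drug.txt",
            faers_dir / "reac.txt", faers_dir / "ther.txt",
        )
        assert raw.rejected_lines == 1
        assert len(raw.demo) == 3

    def test_missing_required_column_is_hard_error(self, faers_dir):
        demo = faers_dir / "demo.txt"
        demo.write_text(demo.read_text().replace("caseversion", "casever"))
        with pytest.raises(ValueError, match="caseversion"):
            ts.read_faers_tables(
                faers_dir / "demo.txt", faers_dir / "drug.txt",
                faers_dir / "reac.txt", faers_dir / "ther.txt",
            )


class TestJaderReader:
    def _write(self, tmp_path, demo_rows, drug_rows, reac_rows):
        (tmp_path / "demo.csv").write_text(
            "識別番号,報告回数,性別,年齢,報告者職種\n" + "".join(demo_rows)
        )
        (tmp_path / "drug.csv").write_text(
            "識別番号,医薬品の関与,医薬品（一般名）,投与開始日\n" + "".join(drug_rows)
        )
        (tmp_path / "reac.csv").write_text(
            "識別番号,有害事象,有害事象の発現日\n" + "".join(reac_rows)
        )
        (tmp_path / "hist.csv").write_text("識別番号,原疾患等\n")
        return ts.read_jader_tables(
            tmp_path / "demo.csv", tmp_path / "drug.csv",
            tmp_path / "reac.csv", tmp_path / "hist.csv",
        )

    def test_decade_bucket_maps_to_midpoint(self, tmp_path):
        raw = self._write(
            tmp_path,
            ["J1,1,男性,60歳代,医師\n"],
            ["J1,被疑薬,アムロジピン,2020/05/01\n"],
            ["J1,味覚異常,2020/06/01\n"],
        )
        assert raw.demo["age_years"].iloc[0] == pytest.approx(65.0)

    def test_fullwidth_halfwidth_variants_collapse(self, tmp_path):
        # same drug typed in full-width and half-width katakana/latin
        raw = self._write(
            tmp_path,
            ["J1,1,女性,50歳代,薬剤師\n"],
            ["J1,被疑薬,Ｄｒｕｇｅｘ,2020/05/01\n",
             "J1,被疑薬,Drugex,2020/05/01\n"],
            ["J1,味覚異常,2020/06/01\n"],
        )
        assert len(raw.drugs) == 1
        assert raw.drugs["drug_name"].iloc[0] == "drugex"

    def test_exact_duplicate_rows_removed(self, tmp_path):
        reac = ["J1,味覚異常,2020/06/01\n"] * 3 + [
            f"J1,事象{i},2020/06/01\n" for i in range(17)
        ]
        raw = self._write(
            tmp_path,
            ["J1,1,女性,50歳代,薬剤師\n"],
            ["J1,被疑薬,Drugex,2020/05/01\n"],
            reac,
        )
        assert len(raw.events) == 18  # 20 rows, 3 identical -> 18 distinct

    def test_unknown_marker_becomes_missing(self, tmp_path):
        raw = self._write(
            tmp_path,
            ["J1,1,不明,60歳代,医師\n"],
            ["J1,被疑薬,Drugex,2020/05/01\n"],
            ["J1,味覚異常,2020/06/01\n"],
        )
        assert raw.demo["sex"].iloc[0] == ""


class TestDedup:
    def _frame(self, pairs):
        return pd.DataFrame(
            {"case_id": [p[0] for p in pairs],
             "version": [p[1] for p in pairs],
             "payload": range(len(pairs))}
        )

    def test_max_version_per_case(self):
        out = ts.dedup_latest_version(self._frame([("A", 1), ("A", 3), ("B", 2)]))
        got = {(r.case_id, r.version) for r in out.itertuples()}
        assert got == {("A", 3), ("B", 2)}

    def test_tie_keeps_last_read_row(self):
        out = ts.dedup_latest_version(self._frame([("A", 2), ("A", 2)]))
        assert len(out) == 1 and out["payload"].iloc[0] == 1

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        pairs = [
            (f"c{rng.integers(0, 200)}", int(rng.integers(0, 5)))
            for _ in range(1000)
        ]
        df = self._frame(pairs)
        # independent oracle: single pass keeping max version, later wins ties
        best: dict = {}
        for i, (cid, v) in enumerate(pairs):
            if cid not in best or v >= best[cid][0]:
                best[cid] = (v, i)
        expected = {(cid, v, i) for cid, (v, i) in best.items()}
        got = {
            (r.case_id, r.version, r.payload)
            for r in ts.dedup_latest_version(df).itertuples()
        }
        assert got == expected

    @given(
        st.lists(
            st.tuples(st.sampled_from("abcde"), st.integers(0, 4)),
            max_size=40,
        )
    )
    def test_idempotent(self, pairs):
        df = self._frame(pairs)
        once = ts.dedup_latest_version(df)
        twice = ts.dedup_latest_version(once)
        pd.testing.assert_frame_equal(once, twice)


class TestExclusions:
    def test_planted_defects_recovered(self, cleaned_synth):
        sim, raw, data, attrition = cleaned_synth
        truth = sim.truth
        # ground truth tallies, in the pipeline's first-reason-wins order
        expect = {
            "missing_age": int(truth.missing_age.sum()),
            "anomalous_age": int(truth.anomalous_age.sum()),
            "missing_sex": int(truth.missing_sex.sum()),
        }
        for k, v in expect.items():
            assert attrition[k] == v

    def test_identity_survivors_plus_exclusions(self, cleaned_synth):
        sim, raw, data, attrition = cleaned_synth
        deduped = len(raw.demo) - attrition["duplicate_versions_removed"]
        excluded = sum(attrition[r] for r in ts.ingest.EXCLUSION_REASONS)
        assert attrition["survivors"] + excluded == deduped

    def test_survivors_have_clean_age_and_sex(self, cleaned_synth):
        _, _, data, _ = cleaned_synth
        r = data.reports
        assert r["age_years"].notna().all()
        assert r["age_years"].between(0, 120).all()
        assert r["sex"].isin(["male", "female"]).all()


class TestLabelCases:
    def test_membership_and_count_preserved(self, cleaned_synth):
        sim, _, data, _ = cleaned_synth
        labelled = ts.label_cases(data, ts.PipelineConfig().target_pt_codes)
        assert len(labelled.reports) == len(data.reports)
        # brute-force membership scan over the events table
        targets = set(ts.PipelineConfig().target_pt_codes)
        expect = {
            cid for cid, grp in labelled.events.groupby("case_id")
            if any(code in targets for code in grp["pt_code"])
        }
        got = set(labelled.reports.loc[labelled.reports["is_case"], "case_id"])
        assert got == expect

    def test_empty_target_set_raises(self, cleaned_synth):
        _, _, data, _ = cleaned_synth
        with pytest.raises(ValueError):
            ts.label_cases(data, [])


DYSGEUSIA = 10013911


class TestComputeOnset:
    def _data(self, start, onset):
        return make_case_data(
            [("X", 50.0, "female", True,
              [("drugex", "primary_suspect", start)],
              [(DYSGEUSIA, onset)])]
        )

    def test_same_day_gives_half_day(self):
        rec, tally = ts.compute_onset(
            self._data((2023, 4, 10), (2023, 4, 10)), "drugex", [DYSGEUSIA]
        )
        assert rec["time_to_onset_days"].tolist() == [0.5]
        assert tally["rule4_same_day_half_day"] == 1

    def test_year_month_imputed_to_day_15(self):
        rec, tally = ts.compute_onset(
            self._data((2023, 4, None), (2023, 6, None)), "drugex", [DYSGEUSIA]
        )
        # 2023-04-15 .. 2023-06-15 by calendar subtraction
        assert rec["time_to_onset_days"].tolist() == [61.0]
        assert tally["rule2_day_imputed_15"] == 1

    def test_onset_before_start_excluded(self):
        rec, tally = ts.compute_onset(
            self._data((2023, 5, 1), (2023, 4, 1)), "drugex", [DYSGEUSIA]
        )
        assert rec.empty
        assert tally["rule3_onset_before_start_excluded"] == 1

    def test_year_only_excluded_either_side(self):
        for start, onset in [((2023, None, None), (2023, 6, 1)),
                             ((2023, 4, 1), (2023, None, None))]:
            rec, tally = ts.compute_onset(
                self._data(start, onset), "drugex", [DYSGEUSIA]
            )
            assert rec.empty
            assert tally["rule1_year_only_excluded"] == 1

    def test_never_below_half_day_and_finite(self, cleaned_synth):
        _, _, data, _ = cleaned_synth
        for drug in ("druga", "drugb", "drugc", "drugd"):
            rec, _ = ts.compute_onset(
                data, drug, ts.PipelineConfig().target_pt_codes
            )
            if not rec.empty:
                v = rec["time_to_onset_days"]
                assert (v >= 0.5).all() and np.isfinite(v).all()

    def test_matches_generator_ground_truth(self, cleaned_synth):
        sim, _, data, _ = cleaned_synth
        truth = sim.truth
        cfg = ts.PipelineConfig()
        for drug in ("drugA", "drugB"):
            rec, _ = ts.compute_onset(data, drug, cfg.target_pt_codes)
            got = dict(zip(rec["case_id"], rec["time_to_onset_days"]))
            surviving = set(data.reports["case_id"])
            t = truth[
                (truth.drug == drug) & truth.is_case
                & truth.case_id.isin(surviving)
                & truth.interval_days_expected.notna()
            ]
            expect = dict(zip(t.case_id, t.interval_days_expected))
            assert got == expect


class TestPartialDate:
    @pytest.mark.parametrize(
        "raw,expect",
        [
            ("20230415", (2023, 4, 15)),
            ("202304", (2023, 4, None)),
            ("2023", (2023, None, None)),
            ("2023/04/15", (2023, 4, 15)),
            ("2023/04", (2023, 4, None)),
            ("2023/04/15 12:00", (2023, 4, 15)),
            ("", None),
            ("notadate", None),
            ("20231301", None),  # month 13
        ],
    )
    def test_parse(self, raw, expect):
        p = ts.parse_partial_date(raw)
        if expect is None:
            assert p is None
        else:
            assert (p.year, p.month, p.day) == expect

    def test_invalid_month_rejected(self):
        with pytest.raises(ValueError):
            ts.PartialDate(2023, 13)

    def test_precision_consistency(self):
        assert ts.PartialDate(2023).precision == "year"
        assert ts.PartialDate(2023, 4).precision == "year_month"
        assert ts.PartialDate(2023, 4, 1).precision == "full"

    def test_imputed_ordinal_day15(self):
        import datetime
        assert (ts.PartialDate(2023, 4).imputed_ordinal()
                == datetime.date(2023, 4, 15).toordinal())


def test_pt_code_for_known_and_unknown_terms():
    d = jader_dialect()
    assert pt_code_for("Dysgeusia", d) == DYSGEUSIA
    unknown = pt_code_for("Something else", d)
    assert unknown > 0 and unknown == pt_code_for("Something else", d)
    assert unknown not in set(d.pt_name_to_code.values())


def test_interchange_round_trip(tmp_path, cleaned_synth):
    _, _, data, _ = cleaned_synth
    ts.write_interchange(data, tmp_path)
    back = ts.read_interchange(tmp_path)
    assert back.source == data.source
    assert back.accepted_roles == data.accepted_roles
    assert len(back.reports) == len(data.reports)
    assert ts.build_contingency(back, "drugA") == ts.build_contingency(data, "drugA")
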