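"""Parsing, normalization, deduplication, drug standardization, case selection."""

import numpy as np
import pandas as pd
import pytest

from faerspv import (deduplicate, load_synonym_map, normalize_reports, parse_date,
                     read_table, read_tables, select_target_reports, standardize_drug)
from faerspv.ingest import MANDATORY_COLUMNS


@pytest.mark.parametrize("raw, kind, year, month", [
    ("20230228", "full", 2023, 2),
    ("202302", "partial", 2023, 2),
    ("2023", "partial", 2023, None),
    ("20230230", "missing", None, None),   # impossible calendar date
    ("202313", "missing", None, None),     # impossible month
    ("", "missing", None, None),
    ("N/A", "missing", None, None),
])
def test_parse_date(raw, kind, year, month):
    p = parse_date(raw)
    assert p.kind == kind
    assert p.year == year
    assert p.month == month
    if kind == "full":
        assert p.value == pd.Timestamp(2023, 2, 28)


class TestReadTable:
    def test_toy_demo(self, tmp_path):
        f = tmp_path / "DEMO.txt"
        f.write_text("primaryid$caseid$fda_dt$event_dt$sex$age$age_cod\n"
                     "11$1$20230101$20230101$M$50$YR\n"
                     "21$2$20230201$202301$F$24$MON\n")
        df = read_table(f, "DEMO")
        assert len(df) == 2
        assert list(df.columns[:3]) == ["PRIMARYID", "CASEID", "FDA_DT"]
        rec = normalize_reports(df)
        assert rec.loc[1, "age_years"] == pytest.approx(2.0)  # 24 months
        assert rec.loc[0, "age_years"] == pytest.approx(50.0)
        assert list(rec["sex"]) == ["M", "F"]

    @pytest.mark.parametrize("age, cod, years", [
        ("730.5", "DY", 2.0), ("104.36", "WK", 2.0), ("6", "MON", 0.5),
        ("80", "YR", 80.0), ("200", "YR", None), ("80", "", 80.0),
    ])
    def test_age_conversion(self, age, cod, years):
        demo = pd.DataFrame({"PRIMARYID": ["1"], "CASEID": ["1"],
                             "FDA_DT": ["20230101"], "AGE": [age], "AGE_COD": [cod]})
        got = normalize_reports(demo)["age_years"].iloc[0]
        if years is None:
            assert np.isnan(got)   # implausible age dropped
        else:
            assert got == pytest.approx(years, rel=1e-3)

    def test_missing_mandatory_column(self, tmp_path):
        f = tmp_path / "REAC.txt"
        f.write_text("primaryid$drug_seq\n1$1\n")
        with pytest.raises(ValueError, match="PT"):
            read_table(f, "REAC")

    def test_gndr_cod_alias(self, tmp_path):
        f = tmp_path / "DEMO.txt"
        f.write_text("primaryid$caseid$fda_dt$gndr_cod\n11$1$20230101$F\n")
        assert normalize_reports(read_table(f, "DEMO"))["sex"].iloc[0] == "F"

    def test_synthetic_roundtrip(self, small_db, small_db_dir):
        tables = read_tables({k: small_db_dir / f"{k}.txt" for k in MANDATORY_COLUMNS})
        for kind, df in small_db.tables.items():
            got = tables[kind].astype(str).reset_index(drop=True)
            want = df.astype(str).reset_index(drop=True)
            pd.testing.assert_frame_equal(got, want)


class TestDeduplicate:
    def _demo(self, rows):
        df = pd.DataFrame(rows, columns=["PRIMARYID", "CASEID", "FDA_DT"])
        return normalize_reports(df)

    def test_latest_fda_dt_wins(self):
        demo = self._demo([(1, 111, "20230101"), (2, 111, "20230301")])
        kept, removed = deduplicate(demo)
        assert list(kept["PRIMARYID"]) == [2] and removed == 1

    def test_tie_broken_by_higher_primaryid(self):
        demo = self._demo([(5, 222, "20230301"), (9, 222, "20230301")])
        kept, _ = deduplicate(demo)
        assert list(kept["PRIMARYID"]) == [9]

    def test_missing_date_loses(self):
        demo = self._demo([(7, 333, ""), (3, 333, "20200101")])
        kept, _ = deduplicate(demo)
        assert list(kept["PRIMARYID"]) == [3]

    def test_single_record_unchanged_and_idempotent(self):
        demo = self._demo([(1, 111, "20230101")])
        kept, removed = deduplicate(demo)
        assert removed == 0 and len(kept) == 1
        kept2, removed2 = deduplicate(kept)
        assert removed2 == 0
        pd.testing.assert_frame_equal(kept2, kept)

    def test_planted_duplicates_removed_exactly(self, small_db):
        demo = normalize_reports(small_db.demo)
        kept, removed = deduplicate(demo)
        assert removed == small_db.manifest["n_duplicate_primaryids"]
        assert len(kept) == small_db.manifest["n_reports"]
        kept2, removed2 = deduplicate(kept)
        assert removed2 == 0 and len(kept2) == len(kept)


class TestStandardizeDrug:
    @pytest.fixture()
    def synonym_map(self, tmp_path):
        f = tmp_path / "syn.tsv"
        f.write_text("sodium zirconium cyclosilicate\tLOKELMA\n"
                     "sodium zirconium cyclosilicate\tSodium zirconium cyclosilicate\n"
                     "metformin\tGLUCOPHAGE\n")
        return load_synonym_map(f)

    def test_variants_share_canonical(self, synonym_map):
        drug = pd.DataFrame({"PRIMARYID": [1, 2], "ROLE_COD": ["PS", "PS"],
                             "DRUGNAME": ["LOKELMA", "Sodium zirconium cyclosilicate"]})
        out = standardize_drug(drug, synonym_map)
        assert out["canonical_name"].nunique() == 1

    def test_normalization_rules(self, synonym_map):
        drug = pd.DataFrame({"PRIMARYID": [1], "ROLE_COD": ["PS"],
                             "DRUGNAME": ["  lokelma. "]})
        out = standardize_drug(drug, synonym_map)
        assert out["canonical_name"].iloc[0] == "sodium zirconium cyclosilicate"

    def test_unmatched_retained_with_null(self, synonym_map):
        drug = pd.DataFrame({"PRIMARYID": [1], "ROLE_COD": ["PS"],
                             "DRUGNAME": ["ASPIRIN"]})
        out = standardize_drug(drug, synonym_map)
        assert len(out) == 1 and out["canonical_name"].isna().all()

    def test_conflicting_variant_rejected(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("drug a\tSHARED NAME\ndrug b\tshared  name\n")
        with pytest.raises(ValueError, match="conflict"):
            load_synonym_map(f)


class TestSelectTarget:
    def test_role_filter(self):
        drug = pd.DataFrame({
            "PRIMARYID": [1, 2, 2, 3],
            "ROLE_COD": ["C", "PS", "C", "SS"],
            "DRUGNAME": ["LOKELMA", "LOKELMA", "OTHER", "LOKELMA"],
            "canonical_name": ["szc", "szc", None, "szc"],
        })
        assert select_target_reports(drug, "szc") == {2}
        assert select_target_reports(drug, "szc", roles={"PS", "SS"}) == {2, 3}

    def test_exact_recovery_on_synthetic(self, small_db, small_db_dir):
        demo, _ = deduplicate(normalize_reports(small_db.demo))
        kept = set(demo["PRIMARYID"].astype("int64"))
        syn = load_synonym_map(small_db_dir / "synonyms.tsv")
        drug = standardize_drug(
            small_db.drug[small_db.drug["PRIMARYID"].isin(kept)], syn)
        cases = select_target_reports(drug, small_db.manifest["target_drug"])
        assert len(cases) == small_db.manifest["n_target_reports"]
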