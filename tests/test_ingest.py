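import math

import pytest

from faerspv.ingest import (
    FormatError,
    join_cases,
    normalize_age_years,
    read_quarter,
    read_table,
)
from faerspv.schema import QuarterFileSet


def write(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="latin-1")
    return path


DEMO_HEADER = "primaryid$caseid$i_f_code$event_dt$fda_dt$age$age_cod$sex$occp_cod$reporter_country"


def test_demo_parse_is_lossless(tmp_path):
    """A clean 3-row DEMO file parses into 3 records with fields intact."""
    rows = [
        "100$10$I$20230117$20230201$45$YR$F$CN$US",
        "101$11$F$202301$20230210$6$DEC$M$MD$GB",
        "102$12$I$$20230301$$$F$$FR",
    ]
    path = write(tmp_path / "DEMO23Q1.txt", [DEMO_HEADER] + rows)
    df, log = read_table(path, "DEMO", era="current")
    assert (log.accepted, log.rejected) == (3, 0)
    # round trip: mandatory columns reproduce the input byte-for-byte
    cols = DEMO_HEADER.split("$")
    for raw, (_, rec) in zip(rows, df.iterrows()):
        assert "$".join(rec[c] for c in cols) == raw


def test_row_accounting_covers_every_line(tmp_path):
    """accepted + rejected == line count minus header, per file."""
    lines = [
        DEMO_HEADER,
        "100$10$I$20230117$20230201$45$YR$F$CN$US",
        "bad-row-with$too$few",  # wrong column count
        "$10$I$20230117$20230201$45$YR$F$CN$US",  # blank key
        "xyz$10$I$20230117$20230201$45$YR$F$CN$US",  # non-numeric key
        "101$11$F$20230101$20230210$33$YR$M$MD$GB",
    ]
    path = write(tmp_path / "DEMO23Q1.txt", lines)
    df, log = read_table(path, "DEMO", era="current")
    assert log.n_lines == 5
    assert log.accepted == 2
    assert log.rejected_columns == 1
    assert log.rejected_key == 2
    assert log.accepted + log.rejected == log.n_lines


def test_missing_header_is_format_error(tmp_path):
    path = write(tmp_path / "DEMO23Q1.txt", ["just one field, no delimiter"])
    with pytest.raises(FormatError):
        read_table(path, "DEMO", era="current")


@pytest.mark.parametrize(
    "age, cod, years",
    [
        ("45", "YR", 45.0),
        ("6", "DEC", 60.0),
        ("18", "MON", 1.5),
        ("730.5", "DY", 2.0),
        ("52.1775", "WK", 1.0),
        ("8766", "HR", 1.0),
        ("45", "", 45.0),  # missing unit treated as years
        ("", "YR", float("nan")),
        ("-3", "YR", float("nan")),
        ("45", "??", float("nan")),
    ],
)
def test_age_normalization(age, cod, years):
    got = normalize_age_years(age, cod)
    assert got == pytest.approx(years, rel=1e-9) or (math.isnan(got) and math.isnan(years))


def test_join_cardinality_and_orphans(tmp_path):
    """DEMO+2 DRUG+1 REAC joins; child rows without DEMO are orphans."""
    write(tmp_path / "DEMO23Q1.txt", [DEMO_HEADER, "100$10$I$20230117$20230201$45$YR$F$CN$US"])
    write(
        tmp_path / "DRUG23Q1.txt",
        ["primaryid$drug_seq$role_cod$drugname", "100$1$PS$OZEMPIC", "100$2$C$METFORMIN"],
    )
    write(tmp_path / "REAC23Q1.txt", ["primaryid$pt", "100$Nausea", "999$Headache"])
    qfs = QuarterFileSet(
        quarter="2023q1",
        paths={
            "DEMO": tmp_path / "DEMO23Q1.txt",
            "DRUG": tmp_path / "DRUG23Q1.txt",
            "REAC": tmp_path / "REAC23Q1.txt",
        },
    )
    frames, _ = read_quarter(qfs)
    tables = join_cases(frames)
    assert tables.orphans["REAC"] == 1
    rec = tables.case_report("100")
    assert len(rec["drug"]) == 2
    assert len(rec["reac"]) == 1
    assert not rec["incomplete"]


def test_report_without_drug_flagged_incomplete(tmp_path):
    write(tmp_path / "DEMO23Q1.txt", [DEMO_HEADER, "100$10$I$$20230201$$$F$CN$US"])
    write(tmp_path / "REAC23Q1.txt", ["primaryid$pt", "100$Nausea"])
    qfs = QuarterFileSet(
        quarter="2023q1",
        paths={"DEMO": tmp_path / "DEMO23Q1.txt", "REAC": tmp_path / "REAC23Q1.txt"},
    )
    frames, _ = read_quarter(qfs)
    tables = join_cases(frames)
    assert tables.case_report("100")["incomplete"]


def test_era_independence(tmp_path):
    """The same logical case in legacy (ISR) and current schemas joins identically."""
    legacy = tmp_path / "legacy"
    current = tmp_path / "current"
    legacy.mkdir(), current.mkdir()
    write(
        legacy / "DEMO11Q2.txt",
        [
            "ISR$CASE$I_F_COD$EVENT_DT$FDA_DT$AGE$AGE_COD$GNDR_COD$OCCP_COD$REPORTER_COUNTRY",
            "100$10$I$20110117$20110201$45$YR$F$CN$US",
        ],
    )
    write(legacy / "DRUG11Q2.txt", ["ISR$DRUG_SEQ$ROLE_COD$DRUGNAME", "100$1$PS$BYETTA"])
    write(legacy / "REAC11Q2.txt", ["ISR$PT", "100$Nausea"])
    write(current / "DEMO23Q1.txt", [DEMO_HEADER, "100$10$I$20110117$20110201$45$YR$F$CN$US"])
    write(current / "DRUG23Q1.txt", ["primaryid$drug_seq$role_cod$drugname", "100$1$PS$BYETTA"])
    write(current / "REAC23Q1.txt", ["primaryid$pt", "100$Nausea"])

    def load(base, quarter, yyq):
        qfs = QuarterFileSet(
            quarter=quarter,
            paths={k: base / f"{k}{yyq}.txt" for k in ("DEMO", "DRUG", "REAC")},
        )
        frames, _ = read_quarter(qfs)
        return join_cases(frames).case_report("100")

    rec_legacy = load(legacy, "2011q2", "11Q2")
    rec_current = load(current, "2023q1", "23Q1")
    for rec in (rec_legacy, rec_current):
        rec.pop("quarter", None)
        for child in ("drug", "reac", "indi", "ther", "outc"):
            for row in rec[child]:
                row.pop("quarter", None)
    assert rec_legacy == rec_current
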