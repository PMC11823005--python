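"""FAERS file dialect: table kinds, per-era column registries, partial dates.

FAERS quarterly extracts are "$"-delimited ASCII tables. The FDA changed the
schema at 2012Q4: earlier files key reports on ``ISR`` (and cases on ``CASE``),
later files on ``primaryid``/``caseid``. A declarative registry maps each
era's header names onto one canonical column set so the rest of the package
never sees the era split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "INDI", "THER", "OUTC")

#: canonical (post-mapping) column names per table kind
CANONICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid",
        "caseid",
        "i_f_code",
        "event_dt",
        "fda_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "reporter_country",
    ),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "pt"),
    "INDI": ("primaryid", "indi_drug_seq", "indi_pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt", "end_dt"),
    "OUTC": ("primaryid", "outc_cod"),
}

#: header-name -> canonical-name mapping, per schema era. Matching is
#: case-insensitive; names absent from the mapping pass through unchanged
#: (lowercased) and are treated as opaque extras.
SCHEMA_REGISTRY: dict[str, dict[str, dict[str, str]]] = {
    "current": {
        "DEMO": {"i_f_cod": "i_f_code", "gndr_cod": "sex"},
        "DRUG": {},
        "REAC": {},
        "INDI": {},
        "THER": {},
        "OUTC": {},
    },
    "legacy": {
        "DEMO": {
            "isr": "primaryid",
            "case": "caseid",
            "i_f_cod": "i_f_code",
            "gndr_cod": "sex",
        },
        "DRUG": {"isr": "primaryid"},
        "REAC": {"isr": "primaryid"},
        "INDI": {"isr": "primaryid", "drug_seq": "indi_drug_seq"},
        "THER": {"isr": "primaryid", "drug_seq": "dsg_drug_seq"},
        "OUTC": {"isr": "primaryid"},
    },
}

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: multipliers converting FAERS age units to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


def parse_quarter(label: str) -> tuple[int, int]:
    """Parse a quarter label like ``"2013q1"`` / ``"2013Q1"`` -> (2013, 1)."""
    s = label.strip().lower()
    if len(s) != 6 or s[4] != "q":
        raise ValueError(f"bad quarter label: {label!r} (want 'YYYYqQ')")
    year, q = int(s[:4]), int(s[5])
    if not 1 <= q <= 4:
        raise ValueError(f"bad quarter number in {label!r}")
    return year, q


def schema_era(quarter: str) -> str:
    """Schema era for a quarter: 'legacy' before 2012Q4, else 'current'."""
    year, q = parse_quarter(quarter)
    return "legacy" if (year, q) < (2012, 4) else "current"


@dataclass(frozen=True)
class QuarterFileSet:
    """Paths to the per-table files of one FAERS quarter."""

    quarter: str
    paths: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parse_quarter(self.quarter)  # validates
        unknown = set(self.paths) - set(TABLE_KINDS)
        if unknown:
            raise ValueError(f"unknown table kinds: {sorted(unknown)}")

    @property
    def era(self) -> str:
        return schema_era(self.quarter)

    def sort_key(self) -> tuple[int, int]:
        return parse_quarter(self.quarter)


# --- partial dates -------------------------------------------------------

PRECISION_DAY = "day"
PRECISION_MONTH = "month"
PRECISION_YEAR = "year"
PRECISION_MISSING = "missing"


def parse_partial_date(raw: str | None) -> tuple[str, date | None]:
    """Parse a FAERS date field into (precision, day-level value or None).

    FAERS dates come as 8 (YYYYMMDD), 6 (YYYYMM) or 4 (YYYY) digit strings;
    anything else — including calendar-invalid 8-digit strings — is treated
    as missing. Only day-precision values resolve to a ``datetime.date``.
    """
    if raw is None:
        return PRECISION_MISSING, None
    s = str(raw).strip()
    if not s.isdigit():
        return PRECISION_MISSING, None
    if len(s) == 8:
        try:
            return PRECISION_DAY, date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return PRECISION_MISSING, None
    if len(s) == 6:
        month = int(s[4:6])
        return (PRECISION_MONTH, None) if 1 <= month <= 12 else (PRECISION_MISSING, None)
    if len(s) == 4:
        return PRECISION_YEAR, None
    return PRECISION_MISSING, None


def date_precision(raw: str | None) -> str:
    return parse_partial_date(raw)[0]


def resolve_day(raw: str | None) -> date | None:
    """Day-level date or None (month/year-precision values do NOT resolve)."""
    return parse_partial_date(raw)[1]
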