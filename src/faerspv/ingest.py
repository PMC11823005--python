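"""Reading and joining FAERS-format quarterly ASCII tables.

Files are "$"-delimited with a header row and no quoting (the FAERS
convention; embedded "$" does not occur). Rows whose field count differs
from the header, and rows with an unparseable report key, are rejected and
counted — the load log accounts for every input line. Lines are decoded as
Latin-1 with replacement because real FAERS extracts contain non-UTF-8
bytes.

The column-level parsing is deliberately line-based rather than
``pandas.read_csv``: the dialect requires rejecting under-length rows, which
a CSV reader silently NaN-fills.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    AGE_UNIT_TO_YEARS,
    CANONICAL_COLUMNS,
    SCHEMA_REGISTRY,
    TABLE_KINDS,
    QuarterFileSet,
    resolve_day,
)

logger = logging.getLogger(__name__)

DELIMITER = "$"


@dataclass
class LoadLog:
    """Per-file accounting: every non-header line is accepted or rejected."""

    quarter: str
    kind: str
    path: str
    n_lines: int = 0  # excludes header
    accepted: int = 0
    rejected_columns: int = 0
    rejected_key: int = 0

    @property
    def rejected(self) -> int:
        return self.rejected_columns + self.rejected_key

    def as_dict(self) -> dict:
        return {
            "quarter": self.quarter,
            "kind": self.kind,
            "path": self.path,
            "n_lines": self.n_lines,
            "accepted": self.accepted,
            "rejected_columns": self.rejected_columns,
            "rejected_key": self.rejected_key,
        }


class FormatError(ValueError):
    """Raised when a file violates the FAERS dialect (e.g. missing header)."""


def _map_header(columns: list[str], kind: str, era: str) -> list[str]:
    mapping = SCHEMA_REGISTRY[era][kind]
    return [mapping.get(c.strip().lower(), c.strip().lower()) for c in columns]


def read_table(path: str | Path, kind: str, era: str, quarter: str = "?") -> tuple[pd.DataFrame, LoadLog]:
    """Read one FAERS table file into a string-typed DataFrame.

    Returns the parsed frame (canonical column names; unknown columns kept
    as opaque extras) and a :class:`LoadLog`. Mandatory-key-less and
    wrong-width rows are dropped and counted, never silently repaired.
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    # record only the file name so logs are location-independent
    log = LoadLog(quarter=quarter, kind=kind, path=path.name)
    with open(path, encoding="latin-1", errors="replace") as fh:
        header_line = fh.readline()
        if not header_line.strip() or DELIMITER not in header_line:
            raise FormatError(f"{path}: missing or malformed header line")
        columns = _map_header(header_line.rstrip("\r\n").split(DELIMITER), kind, era)
        required = set(CANONICAL_COLUMNS[kind])
        missing = required - set(columns)
        if missing and "primaryid" in missing:
            raise FormatError(f"{path}: header lacks report key column ({era} era)")
        ncol = len(columns)
        rows: list[list[str]] = []
        for line in fh:
            log.n_lines += 1
            fields = line.rstrip("\r\n").split(DELIMITER)
            if len(fields) != ncol:
                log.rejected_columns += 1
                continue
            rows.append(fields)
    df = pd.DataFrame(rows, columns=columns, dtype=str) if rows else pd.DataFrame(
        {c: pd.Series(dtype=str) for c in columns}
    )
    # reject rows whose report key is empty/non-numeric
    key_ok = df["primaryid"].str.strip().str.isdigit()
    log.rejected_key = int((~key_ok).sum())
    df = df.loc[key_ok].reset_index(drop=True)
    df["primaryid"] = df["primaryid"].str.strip()
    log.accepted = len(df)
    for col in CANONICAL_COLUMNS[kind]:
        if col not in df.columns:
            df[col] = ""
    return df, log


def read_quarter(files: QuarterFileSet) -> tuple[dict[str, pd.DataFrame], list[LoadLog]]:
    """Read every table of one quarter. Returns {kind: frame} and load logs."""
    frames: dict[str, pd.DataFrame] = {}
    logs: list[LoadLog] = []
    for kind, path in files.paths.items():
        df, log = read_table(path, kind, files.era, quarter=files.quarter)
        df["quarter"] = files.quarter
        frames[kind] = df
        logs.append(log)
        logger.info("read %s %s: %d accepted, %d rejected", files.quarter, kind, log.accepted, log.rejected)
    return frames, logs


def normalize_age_years(age: str | float, age_cod: str) -> float:
    """FAERS age + unit code -> age in years (NaN when unparseable).

    A value with a missing unit code is taken as years (the dominant FAERS
    practice for blank AGE_COD).
    """
    try:
        value = float(str(age).strip())
    except (TypeError, ValueError):
        return float("nan")
    if value < 0:
        return float("nan")
    unit = str(age_cod).strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(unit, 1.0 if unit == "" else None)
    if factor is None:
        return float("nan")
    return value * factor


@dataclass
class FaersTables:
    """Joined per-table record sets for a pool of reports.

    All child tables are restricted to primaryids present in ``demo``
    (orphans are excluded at join time and counted). This is the raw,
    pre-deduplication case pool.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    orphans: dict[str, int] = field(default_factory=dict)

    KINDS = {"DEMO": "demo", "DRUG": "drug", "REAC": "reac", "INDI": "indi", "THER": "ther", "OUTC": "outc"}

    def table(self, kind: str) -> pd.DataFrame:
        return getattr(self, self.KINDS[kind])

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def case_report(self, primaryid: str) -> dict:
        """Composite view of one report — demographics plus all child rows."""
        pid = str(primaryid)
        demo_rows = self.demo[self.demo["primaryid"] == pid]
        if demo_rows.empty:
            raise KeyError(f"no DEMO record for primaryid {primaryid}")
        rec = demo_rows.iloc[0].to_dict()
        for kind, attr in self.KINDS.items():
            if kind == "DEMO":
                continue
            child = getattr(self, attr)
            rec[attr] = child[child["primaryid"] == pid].to_dict("records")
        rec["incomplete"] = not rec["drug"] or not rec["reac"]
        return rec

    def restrict(self, primaryids: pd.Index | set) -> "FaersTables":
        """New FaersTables keeping only the given reports."""
        keep = set(primaryids)
        return FaersTables(
            demo=self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True),
            drug=self.drug[self.drug["primaryid"].isin(keep)].reset_index(drop=True),
            reac=self.reac[self.reac["primaryid"].isin(keep)].reset_index(drop=True),
            indi=self.indi[self.indi["primaryid"].isin(keep)].reset_index(drop=True),
            ther=self.ther[self.ther["primaryid"].isin(keep)].reset_index(drop=True),
            outc=self.outc[self.outc["primaryid"].isin(keep)].reset_index(drop=True),
            orphans=dict(self.orphans),
        )


_EMPTY_COLS = {k: list(CANONICAL_COLUMNS[k]) + ["quarter"] for k in TABLE_KINDS}


def _empty(kind: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in _EMPTY_COLS[kind]})


def join_cases(frames: dict[str, pd.DataFrame]) -> FaersTables:
    """Join per-table frames of one or more quarters into a raw case pool.

    Child rows whose primaryid has no DEMO record are orphans: excluded and
    counted. Reports without any DRUG or REAC rows are flagged (column
    ``incomplete`` on demo), not dropped.
    """
    demo = frames.get("DEMO")
    if demo is None or demo.empty:
        raise ValueError("cannot join cases without DEMO records")
    demo = demo.copy()
    known = set(demo["primaryid"])
    out: dict[str, pd.DataFrame] = {}
    orphans: dict[str, int] = {}
    for kind in TABLE_KINDS:
        if kind == "DEMO":
            continue
        df = frames.get(kind)
        if df is None:
            df = _empty(kind)
        mask = df["primaryid"].isin(known)
        orphans[kind] = int((~mask).sum())
        if orphans[kind]:
            logger.warning("%s: excluded %d orphan rows (no DEMO record)", kind, orphans[kind])
        out[kind] = df[mask].reset_index(drop=True)
    has_drug = demo["primaryid"].isin(set(out["DRUG"]["primaryid"]))
    has_reac = demo["primaryid"].isin(set(out["REAC"]["primaryid"]))
    demo["incomplete"] = ~(has_drug & has_reac)
    demo["age_years"] = [
        normalize_age_years(a, c) for a, c in zip(demo["age"], demo["age_cod"])
    ]
    demo["fda_date"] = demo["fda_dt"].map(resolve_day)
    demo["event_date"] = demo["event_dt"].map(resolve_day)
    return FaersTables(
        demo=demo.reset_index(drop=True),
        drug=out["DRUG"],
        reac=out["REAC"],
        indi=out["INDI"],
        ther=out["THER"],
        outc=out["OUTC"],
        orphans=orphans,
    )


def read_quarters(file_sets: list[QuarterFileSet]) -> tuple[FaersTables, list[LoadLog]]:
    """Read and pool several quarters into one raw case pool."""
    all_frames: dict[str, list[pd.DataFrame]] = {k: [] for k in TABLE_KINDS}
    logs: list[LoadLog] = []
    for qfs in sorted(file_sets, key=QuarterFileSet.sort_key):
        frames, qlogs = read_quarter(qfs)
        logs.extend(qlogs)
        for kind, df in frames.items():
            all_frames[kind].append(df)
    pooled = {
        kind: (pd.concat(dfs, ignore_index=True) if dfs else _empty(kind))
        for kind, dfs in all_frames.items()
    }
    return join_cases(pooled), logs


def discover_quarters(directory: str | Path) -> list[QuarterFileSet]:
    """Find FAERS-style files named like DEMO23Q1.txt under a directory."""
    directory = Path(directory)
    found: dict[str, dict[str, Path]] = {}
    for path in sorted(directory.glob("*.txt")):
        name = path.stem.upper()
        for kind in TABLE_KINDS:
            if name.startswith(kind) and len(name) == len(kind) + 4:
                yy, q = name[len(kind):len(kind) + 2], name[-1]
                if not (yy.isdigit() and q.isdigit()):
                    continue
                quarter = f"20{yy}q{q}"
                found.setdefault(quarter, {})[kind] = path
    return [QuarterFileSet(quarter=q, paths=p) for q, p in sorted(found.items())]


def load_log_frame(logs: list[LoadLog]) -> pd.DataFrame:
    return pd.DataFrame([log.as_dict() for log in logs])
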