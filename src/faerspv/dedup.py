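"""Case deduplication: keep the most recent version of every case.

A FAERS case (``caseid``) accumulates versions — an initial report ("I")
followed by follow-ups ("F"), each with its own ``primaryid`` — and the same
case can recur across quarterly files. Deduplication keeps exactly one
survivor per case, chosen by a total order so the result is independent of
input row order:

1. latest FDA receipt date (missing dates sort oldest),
2. follow-up ("F") over initial ("I"),
3. latest event date,
4. largest numeric primaryid (deterministic tie-break).

Receipt date leads because it is the most direct "most recent version"
signal; demographic fields are version context, not match keys — no fuzzy
cross-case linkage is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ingest import FaersTables
from .schema import resolve_day

_EPOCH = pd.Timestamp("1677-09-22")  # sorts before any real FAERS date


def _date_key(raw: pd.Series) -> pd.Series:
    resolved = raw.map(lambda s: resolve_day(s))
    return pd.to_datetime(resolved).fillna(_EPOCH)


@dataclass
class DedupResult:
    tables: FaersTables
    log: pd.DataFrame  # columns: caseid, survivor, removed, reason
    provenance: dict[str, list[str]]  # caseid -> all primaryids collapsed

    @property
    def n_removed(self) -> int:
        return len(self.log)


def deduplicate(tables: FaersTables) -> DedupResult:
    """Collapse report versions to one survivor per caseid.

    Empty input yields empty output. Reports with a blank caseid cannot be
    versioned and survive as their own case (keyed by primaryid).
    ``|input| == |output| + |log|`` always holds.
    """
    demo = tables.demo.copy()
    if demo.empty:
        return DedupResult(tables=tables, log=_empty_log(), provenance={})
    case_key = demo["caseid"].fillna("").str.strip()
    case_key = case_key.where(case_key != "", other="pid:" + demo["primaryid"])
    demo["_case_key"] = case_key
    demo["_k_receipt"] = _date_key(demo["fda_dt"])
    demo["_k_followup"] = (demo["i_f_code"].str.strip().str.upper() == "F").astype(int)
    demo["_k_event"] = _date_key(demo["event_dt"])
    demo["_k_pid"] = pd.to_numeric(demo["primaryid"], errors="coerce").fillna(-1)

    ordered = demo.sort_values(
        ["_case_key", "_k_receipt", "_k_followup", "_k_event", "_k_pid"],
        ascending=[True, False, False, False, False],
        kind="mergesort",
    )
    survivors = ordered.drop_duplicates("_case_key", keep="first")
    removed = ordered[ordered.duplicated("_case_key", keep="first")]

    surv_by_case = survivors.set_index("_case_key")["primaryid"]
    log = pd.DataFrame(
        {
            "caseid": removed["_case_key"].values,
            "survivor": removed["_case_key"].map(surv_by_case).values,
            "removed": removed["primaryid"].values,
            "reason": [
                f"superseded(receipt={r.date()},ifu={'F' if f else 'I'})"
                for r, f in zip(removed["_k_receipt"], removed["_k_followup"])
            ],
        }
    ).sort_values(["caseid", "removed"]).reset_index(drop=True)

    provenance = (
        ordered.groupby("_case_key", sort=True)["primaryid"].agg(list).to_dict()
    )

    keep_ids = survivors["primaryid"]
    out = tables.restrict(keep_ids)
    out.demo = out.demo.drop(
        columns=[c for c in out.demo.columns if c.startswith("_k_") or c == "_case_key"],
        errors="ignore",
    )
    return DedupResult(tables=out, log=log, provenance=provenance)


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in ("caseid", "survivor", "removed", "reason")})
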