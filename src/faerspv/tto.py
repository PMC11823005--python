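"""Time-to-onset (TTO): days from therapy initiation to the adverse event.

TTO for a case is the interval between the earliest fully-dated therapy
start of the exposure drug and the case event date, in whole days. Only
strictly positive, fully dated intervals are analyzable; everything else is
excluded with an explicit reason:

* ``missing_date``     — start or event date absent,
* ``partial_date``     — start or event date only year/month precision
                         (excluded rather than imputed: imputation would
                         fabricate onset times),
* ``non_positive``     — onset of 0 days (dosing and event same day),
* ``start_after_event``— dosing recorded after the event (incorrect dates).

Summaries report the median and interquartile range via linear interpolation
between order statistics (quantile "type 7", the numpy default); the
convention matters because IQR endpoints on day-valued data can shift by a
day between conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import parse_partial_date

#: default day-bin boundaries: (0,30], (30,60], (60,90], (90,180], (180,360], >360
DEFAULT_BINS = (0, 30, 60, 90, 180, 360)

REASONS = ("missing_date", "partial_date", "non_positive", "start_after_event")


def _classify_date(raw: str | None) -> tuple[str | None, object]:
    precision, value = parse_partial_date(raw)
    if precision == "day":
        return None, value
    if precision == "missing":
        return "missing_date", None
    return "partial_date", None  # year or month precision


def compute_tto(
    demo: pd.DataFrame,
    ther: pd.DataFrame,
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Per (case, exposure generic) onset records with exclusion accounting.

    For each exposure assignment, therapy rows are joined on
    (primaryid, drug_seq); the earliest complete start date is the
    initiation. Every (case, generic) pair appears exactly once, either
    included with ``onset_days`` or excluded with a reason.

    Returns columns: caseid, primaryid, generic, onset_days, included,
    exclusion_reason.
    """
    exp = assignments.drop_duplicates(subset=["primaryid", "caseid", "generic"])
    event_by_pid = demo.set_index("primaryid")["event_dt"]

    ther_k = ther.copy()
    ther_k["_key"] = ther_k["primaryid"] + ":" + ther_k["dsg_drug_seq"].astype(str).str.strip()
    starts_by_key: dict[str, list[str]] = (
        ther_k.groupby("_key")["start_dt"].agg(list).to_dict()
    )
    seq_by_pid_gen = (
        assignments.groupby(["primaryid", "generic"])["drug_seq"]
        .agg(lambda s: [str(x).strip() for x in s])
        .to_dict()
    )

    rows = []
    for r in exp.itertuples(index=False):
        start_raws: list[str] = []
        for seq in seq_by_pid_gen.get((r.primaryid, r.generic), []):
            start_raws.extend(starts_by_key.get(f"{r.primaryid}:{seq}", []))
        event_reason, event_date = _classify_date(event_by_pid.get(r.primaryid))

        complete_starts = []
        start_reason = "missing_date" if not start_raws else None
        for raw in start_raws:
            reason, value = _classify_date(raw)
            if value is not None:
                complete_starts.append(value)
            elif reason == "partial_date":
                start_reason = start_reason or "partial_date"
            else:
                start_reason = start_reason or "missing_date"

        onset = None
        reason = None
        if complete_starts and event_reason is None:
            onset = (event_date - min(complete_starts)).days
            if onset == 0:
                reason, onset = "non_positive", None
            elif onset < 0:
                reason, onset = "start_after_event", None
        else:
            # prefer the most specific available reason; partial beats missing
            candidates = [x for x in (event_reason, None if complete_starts else start_reason) if x]
            reason = "partial_date" if "partial_date" in candidates else "missing_date"

        rows.append(
            {
                "caseid": r.caseid,
                "primaryid": r.primaryid,
                "generic": r.generic,
                "onset_days": onset,
                "included": onset is not None,
                "exclusion_reason": reason,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["caseid", "primaryid", "generic", "onset_days", "included", "exclusion_reason"],
    )
    if out.empty:
        out["included"] = out["included"].astype(bool)
    return out


@dataclass
class TTOSummary:
    """Median/IQR, day-bin counts and the cumulative onset curve."""

    n: int
    median_days: float
    iqr_lower_days: float
    iqr_upper_days: float
    bin_counts: dict[str, int] = field(default_factory=dict)
    cumulative: pd.DataFrame | None = None  # columns: day, fraction

    @property
    def empty(self) -> bool:
        return self.n == 0


def _bin_labels(bins: tuple[float, ...]) -> list[str]:
    edges = list(bins)
    labels = [f"({int(lo)},{int(hi)}]" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">{int(edges[-1])}")
    return labels


def summarize_tto(onset_days, bins: tuple[float, ...] = DEFAULT_BINS) -> TTOSummary:
    """Summarize included onset times (a sequence of positive day counts).

    Empty input returns an empty-summary sentinel (n=0, NaN quantiles)
    rather than raising. Bins are left-open/right-closed over positive days
    with a final open ``>last`` bin.
    """
    values = np.asarray(
        onset_days if not isinstance(onset_days, pd.DataFrame) else onset_days["onset_days"],
        dtype=float,
    )
    values = values[~np.isnan(values)]
    labels = _bin_labels(bins)
    if values.size == 0:
        return TTOSummary(
            n=0, median_days=float("nan"), iqr_lower_days=float("nan"),
            iqr_upper_days=float("nan"), bin_counts={lab: 0 for lab in labels},
            cumulative=pd.DataFrame({"day": pd.Series(dtype=float), "fraction": pd.Series(dtype=float)}),
        )
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    edges = list(bins) + [np.inf]
    counts, _ = np.histogram(values, bins=edges)
    # np.histogram is right-open; recount as left-open/right-closed intervals
    bin_counts = {}
    for lab, lo, hi in zip(labels, edges, edges[1:]):
        if np.isinf(hi):
            bin_counts[lab] = int((values > lo).sum())
        else:
            bin_counts[lab] = int(((values > lo) & (values <= hi)).sum())
    days, day_counts = np.unique(values, return_counts=True)
    cumulative = pd.DataFrame(
        {"day": days, "fraction": np.cumsum(day_counts) / values.size}
    )
    return TTOSummary(
        n=int(values.size),
        median_days=float(med),
        iqr_lower_days=float(q1),
        iqr_upper_days=float(q3),
        bin_counts=bin_counts,
        cumulative=cumulative,
    )


def summarize_by(
    records: pd.DataFrame,
    by: str,
    bins: tuple[float, ...] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Per-group TTO summary table (one row per value of ``by``)."""
    rows = []
    for key, grp in records[records["included"]].groupby(by, sort=True):
        s = summarize_tto(grp["onset_days"].astype(float), bins=bins)
        row = {
            by: key, "n": s.n, "median_days": s.median_days,
            "iqr_lower_days": s.iqr_lower_days, "iqr_upper_days": s.iqr_upper_days,
        }
        row.update(s.bin_counts)
        rows.append(row)
    return pd.DataFrame(rows)


def attach_groups(records: pd.DataFrame, reac_with_case: pd.DataFrame, group_pts: dict[str, frozenset[str]]) -> pd.DataFrame:
    """Replicate TTO records per AE group the case's reactions fall in."""
    folded = {
        name: {p.strip().casefold() for p in pts} for name, pts in group_pts.items()
    }
    pt_fold = reac_with_case["pt"].str.strip().str.casefold()
    pieces = []
    for name, pts in folded.items():
        hit = set(reac_with_case.loc[pt_fold.isin(pts), "caseid"])
        sub = records[records["caseid"].isin(hit)].copy()
        sub["ae_group"] = name
        pieces.append(sub)
    if not pieces:
        out = records.iloc[0:0].copy()
        out["ae_group"] = pd.Series(dtype=str)
        return out
    return pd.concat(pieces, ignore_index=True)
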