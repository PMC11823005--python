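"""Reporting odds ratio (ROR) disproportionality analysis.

For a target drug set, a comparator set and an adverse-event PT set, the
2x2 contingency table is

    a  target-drug cases reporting the event      b  target cases without it
    c  comparator cases reporting the event       d  comparator cases without it

counted at case level (a case reporting three matching PTs counts once).
The statistic is ROR = (a/b)/(c/d) with the Wald 95% CI on the log scale,

    CI = exp( ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d) ),    z = 1.96,

with no continuity correction: a zero cell makes the result "not estimable"
rather than silently corrected. A drug-event pair is a *signal* when the
event was reported at least ``n_min`` (default 3) times for the target drug
AND the CI lower bound strictly exceeds 1.

The z value (the exact two-sided 95% normal quantile, conventionally printed
as 1.96) is deliberately not configurable so results stay comparable across
analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)

#: default signal rule: at least this many target-drug event reports
DEFAULT_N_MIN = 3

#: indication-stratum keyword lists (matched case-insensitively as substrings
#: of indication PT text); config-overridable
DM_KEYWORDS = ("DIABETES", "DIABETIC")
WEIGHT_KEYWORDS = ("OBESITY", "WEIGHT", "OVERWEIGHT")


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of one drug-set x event-set x stratum comparison."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_target(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """Target and comparator exchanged."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class SignalResult:
    """ROR point estimate, Wald 95% CI, target event count, signal flag."""

    ror: float
    ci_lower: float
    ci_upper: float
    n: int
    estimable: bool = True
    is_signal: bool | None = None


def compute_ror(t: ContingencyTable) -> SignalResult:
    """ROR and 95% CI for one table; not estimable if any cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return SignalResult(
            ror=float("nan"), ci_lower=float("nan"), ci_upper=float("nan"),
            n=t.a, estimable=False,
        )
    log_ror = math.log(t.a) - math.log(t.b) - math.log(t.c) + math.log(t.d)
    se = math.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)
    return SignalResult(
        ror=math.exp(log_ror),
        ci_lower=math.exp(log_ror - Z_95 * se),
        ci_upper=math.exp(log_ror + Z_95 * se),
        n=t.a,
    )


def flag_signal(r: SignalResult, n_min: int = DEFAULT_N_MIN) -> SignalResult:
    """Apply the signal rule: n >= n_min AND CI lower bound strictly > 1."""
    is_signal = bool(r.estimable and r.n >= n_min and r.ci_lower > 1.0)
    return replace(r, is_signal=is_signal)


def ror_tier(r: SignalResult) -> str:
    """Heatmap tier from the CI lower bound (RORL): 'strong' if RORL > 3,
    'moderate' if 1 < RORL <= 3, 'none' if RORL <= 1, 'na' if not estimable."""
    if not r.estimable or math.isnan(r.ci_lower):
        return "na"
    if r.ci_lower > 3.0:
        return "strong"
    if r.ci_lower > 1.0:
        return "moderate"
    return "none"


# --- case-level masks ----------------------------------------------------


def exposure_mask(
    case_index: pd.Index,
    assignments: pd.DataFrame,
    classes: set[str] | None = None,
    generics: set[str] | None = None,
) -> pd.Series:
    """Boolean Series over caseids: has >=1 assignment in the given classes
    and/or generics (either filter may be None = any)."""
    df = assignments
    if classes is not None:
        df = df[df["drug_class"].isin(classes)]
    if generics is not None:
        df = df[df["generic"].isin(generics)]
    hit = set(df["caseid"])
    return pd.Series(case_index.isin(hit), index=case_index)


def event_mask(case_index: pd.Index, reac_with_case: pd.DataFrame, pts: frozenset[str]) -> pd.Series:
    """Boolean Series over caseids: reported >=1 PT from ``pts``."""
    folded = {p.strip().casefold() for p in pts}
    hit_rows = reac_with_case[
        reac_with_case["pt"].str.strip().str.casefold().isin(folded)
    ]
    hit = set(hit_rows["caseid"])
    return pd.Series(case_index.isin(hit), index=case_index)


def indication_mask(case_index: pd.Index, indi_with_case: pd.DataFrame, keywords: tuple[str, ...]) -> pd.Series:
    """Boolean Series over caseids: any indication PT contains a keyword."""
    upper = indi_with_case["indi_pt"].str.upper()
    mask = pd.Series(False, index=upper.index)
    for kw in keywords:
        mask |= upper.str.contains(kw.upper(), regex=False)
    hit = set(indi_with_case.loc[mask, "caseid"])
    return pd.Series(case_index.isin(hit), index=case_index)


def build_table(
    target: pd.Series,
    comparator: pd.Series,
    event: pd.Series,
    stratum: pd.Series | None = None,
) -> ContingencyTable:
    """Count the 2x2 cells from aligned boolean case masks.

    A case in both target and comparator is assigned to the target only
    (logged). With a stratum mask, counting is restricted to it;
    a+b+c+d then equals the stratum's target+comparator case total.
    """
    overlap = int((target & comparator).sum())
    if overlap:
        logger.warning("%d cases in both target and comparator; kept as target", overlap)
        comparator = comparator & ~target
    if stratum is not None:
        target = target & stratum
        comparator = comparator & stratum
    return ContingencyTable(
        a=int((target & event).sum()),
        b=int((target & ~event).sum()),
        c=int((comparator & event).sum()),
        d=int((comparator & ~event).sum()),
    )


def analyze(
    target: pd.Series,
    comparator: pd.Series,
    event: pd.Series,
    stratum: pd.Series | None = None,
    n_min: int = DEFAULT_N_MIN,
) -> tuple[ContingencyTable, SignalResult]:
    """Build the table, compute the ROR and apply the signal rule."""
    t = build_table(target, comparator, event, stratum)
    return t, flag_signal(compute_ror(t), n_min=n_min)


def scan_pts(
    target: pd.Series,
    comparator: pd.Series,
    reac_with_case: pd.DataFrame,
    pts: frozenset[str],
    stratum: pd.Series | None = None,
    n_min: int = DEFAULT_N_MIN,
) -> pd.DataFrame:
    """PT-level disproportionality scan (heatmap-matrix-ready).

    One row per PT with at least ``n_min`` target-drug cases; columns
    (pt, a, b, c, d, n, ror, ci_lower, ci_upper, is_signal, tier). The scan
    applies no multiple-testing adjustment — raw CIs are reported along
    with the number of comparisons so users can post-adjust.
    """
    case_index = target.index
    rows = []
    for pt in sorted(pts):
        ev = event_mask(case_index, reac_with_case, frozenset({pt}))
        t = build_table(target, comparator, ev, stratum)
        if t.a < n_min:
            continue
        r = flag_signal(compute_ror(t), n_min=n_min)
        rows.append(
            {
                "pt": pt, "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": r.n,
                "ror": r.ror, "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                "is_signal": r.is_signal, "tier": ror_tier(r),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["pt", "a", "b", "c", "d", "n", "ror", "ci_lower", "ci_upper", "is_signal", "tier"],
    )
    out.attrs["n_comparisons"] = len(pts)
    return out
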