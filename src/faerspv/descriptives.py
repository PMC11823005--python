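"""Descriptive tabulation of a deduplicated, exposure-filtered cohort.

Produces characteristics tables (counts and percentages by sex, age group,
reporter type, report year, indication, outcome) and the annual
neuro-vs-other report series. Percentages use the all-cases denominator,
with unknown/absent values collected in an explicit "missing" level, so
every dimension's counts sum to the cohort total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: age group boundaries in years: <18, [18,65), [65,85], >85
DEFAULT_AGE_BOUNDS = (18.0, 65.0, 85.0)

#: worst-outcome severity ranking, most severe first
OUTCOME_RANK = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

DIMENSIONS = ("sex", "age_group", "reporter_type", "report_year", "indication", "outcome")

_HCP_CODES = {"MD", "PH", "OT", "HP", "RN"}  # physician/pharmacist/other HCP
_CONSUMER_CODES = {"CN", "LW"}  # consumer / lawyer (non-HCP)


def age_group(age_years: float, bounds: tuple[float, float, float] = DEFAULT_AGE_BOUNDS) -> str:
    """Age band with boundaries <18, [18,65), [65,85], >85."""
    lo, mid, hi = bounds
    if age_years is None or np.isnan(age_years):
        return "missing"
    if age_years < lo:
        return f"<{int(lo)}"
    if age_years < mid:
        return f"[{int(lo)},{int(mid)})"
    if age_years <= hi:
        return f"[{int(mid)},{int(hi)}]"
    return f">{int(hi)}"


def reporter_type(occp_cod: str) -> str:
    code = str(occp_cod).strip().upper()
    if code in _HCP_CODES:
        return "healthcare professional"
    if code in _CONSUMER_CODES:
        return "consumer/non-HCP"
    return "missing"


def worst_outcome(codes: list[str]) -> str:
    """Most severe outcome code under the DE>LT>HO>DS>CA>RI>OT ranking."""
    present = {str(c).strip().upper() for c in codes}
    for code in OUTCOME_RANK:
        if code in present:
            return code
    return "missing"


def indication_label(
    case_dm: bool,
    case_weight: bool,
) -> str:
    """Single Table-1-style indication label (DM takes precedence when a
    case matches both keyword lists; disproportionality strata, unlike this
    label, keep such cases in both strata)."""
    if case_dm:
        return "DM"
    if case_weight:
        return "weight-loss"
    return "missing"


def cohort_frame(
    demo: pd.DataFrame,
    outc: pd.DataFrame,
    dm_mask: pd.Series,
    weight_mask: pd.Series,
    age_bounds: tuple[float, float, float] = DEFAULT_AGE_BOUNDS,
) -> pd.DataFrame:
    """Assemble the per-case frame all descriptive dimensions read from.

    ``dm_mask``/``weight_mask`` are indication masks indexed by caseid.
    Report year comes from the FDA receipt date (always present in FAERS)
    rather than the often-missing event date.
    """
    df = demo.copy()
    sex = df["sex"].str.strip().str.upper()
    df["sex_level"] = sex.where(sex.isin(["F", "M"]), "missing")
    df["age_group"] = df["age_years"].map(lambda a: age_group(a, age_bounds))
    df["reporter_type"] = df["occp_cod"].map(reporter_type)
    df["report_year"] = df["fda_date"].map(lambda d: str(d.year) if d is not None else "missing")
    outcomes = outc.groupby("primaryid")["outc_cod"].agg(list)
    df["outcome"] = df["primaryid"].map(outcomes).map(
        lambda v: worst_outcome(v) if isinstance(v, list) else "missing"
    )
    df["indication"] = [
        indication_label(bool(dm_mask.get(cid, False)), bool(weight_mask.get(cid, False)))
        for cid in df["caseid"]
    ]
    return df


def tabulate(cohort: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Counts and percent-of-total for one dimension, missing included.

    Returns columns (dimension, level, count, percent); counts sum to the
    cohort size and percents to 100 up to rounding.
    """
    column = {"sex": "sex_level"}.get(dimension, dimension)
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    counts = cohort[column].value_counts(dropna=False).sort_index()
    total = len(cohort)
    return pd.DataFrame(
        {
            "dimension": dimension,
            "level": counts.index.astype(str),
            "count": counts.values,
            "percent": np.round(100.0 * counts.values / total, 1) if total else 0.0,
        }
    ).reset_index(drop=True)


def characteristics_table(cohort: pd.DataFrame, dimensions: tuple[str, ...] = DIMENSIONS) -> pd.DataFrame:
    """Stacked characteristics table over several dimensions (Table-1 shape)."""
    return pd.concat([tabulate(cohort, d) for d in dimensions], ignore_index=True)


def annual_series(cohort: pd.DataFrame, neuro_mask: pd.Series) -> pd.DataFrame:
    """Per-year counts of cases with vs without neuropsychiatric events.

    ``neuro_mask`` is indexed by caseid. Years with no reports get zero
    rows; totals across years equal the cohort size (cases with a missing
    receipt year are reported in a trailing 'missing' row).
    """
    df = cohort.copy()
    df["_neuro"] = df["caseid"].map(neuro_mask).fillna(False).astype(bool)
    years = sorted(y for y in df["report_year"].unique() if y != "missing")
    rows = []
    year_range = (
        [str(y) for y in range(int(min(years)), int(max(years)) + 1)] if years else []
    )
    for year in year_range + (["missing"] if (df["report_year"] == "missing").any() else []):
        sub = df[df["report_year"] == year]
        neuro = int(sub["_neuro"].sum())
        other = len(sub) - neuro
        rows.append(
            {
                "year": year,
                "neuro_count": neuro,
                "other_count": other,
                "proportion_neuro": neuro / len(sub) if len(sub) else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["year", "neuro_count", "other_count", "proportion_neuro"])


def per_drug_shares(
    demo: pd.DataFrame,
    assignments: pd.DataFrame,
    neuro_mask: pd.Series,
) -> pd.DataFrame:
    """Per-generic overall vs neuropsychiatric case counts and shares."""
    rows = []
    for generic, grp in assignments.groupby("generic", sort=True):
        cases = set(grp["caseid"])
        n_total = len(cases)
        n_neuro = int(sum(bool(neuro_mask.get(c, False)) for c in cases))
        rows.append(
            {
                "generic": generic,
                "n_cases": n_total,
                "n_neuro": n_neuro,
                "neuro_share": n_neuro / n_total if n_total else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["generic", "n_cases", "n_neuro", "neuro_share"])
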