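import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faerspv.dispro import (
    ContingencyTable,
    analyze,
    build_table,
    compute_ror,
    event_mask,
    exposure_mask,
    flag_signal,
    indication_mask,
    ror_tier,
    scan_pts,
)

cells = st.integers(min_value=1, max_value=500)


def test_proportional_rows_give_null_ror():
    r = compute_ror(ContingencyTable(10, 90, 100, 900))
    assert r.ror == pytest.approx(1.0)


def test_ror_and_wald_ci_frozen_example():
    """(20,80,50,850): ROR 4.25, 95% CI ~ (2.41, 7.49); digits frozen from an
    independent high-precision (30-digit) evaluation of the log-scale formula."""
    r = compute_ror(ContingencyTable(20, 80, 50, 850))
    assert r.ror == pytest.approx(4.25, abs=1e-12)
    assert r.ci_lower == pytest.approx(2.4108091665301327, rel=1e-12)
    assert r.ci_upper == pytest.approx(7.4922977109786249, rel=1e-12)
    assert r.n == 20


def test_zero_cell_not_estimable():
    r = compute_ror(ContingencyTable(3, 0, 10, 100))
    assert not r.estimable
    assert math.isnan(r.ror)
    assert not flag_signal(r).is_signal


def test_negative_cell_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)


@pytest.mark.parametrize(
    "n, ci_lower, expected",
    [
        (197, 4.30, True),  # strong reported signal shape
        (2, 3.0, False),  # below count threshold
        (50, 1.00, False),  # 'exceeds 1' is strict
        (3, 1.01, True),  # boundary: minimum count, lower just above 1
        (3, 0.99, False),
    ],
)
def test_signal_rule(n, ci_lower, expected):
    assert flag_signal(_result(n, ci_lower)).is_signal is expected


def _result(n, ci_lower):
    from faerspv.dispro import SignalResult

    return SignalResult(ror=ci_lower * 1.2, ci_lower=ci_lower, ci_upper=ci_lower * 2, n=n)


@given(a=cells, b=cells, c=cells, d=cells)
@settings(max_examples=200, deadline=None)
def test_reciprocity(a, b, c, d):
    """Swapping target and comparator inverts the ROR and swaps/inverts the CI."""
    t = ContingencyTable(a, b, c, d)
    r = compute_ror(t)
    s = compute_ror(t.swapped())
    assert s.ror == pytest.approx(1.0 / r.ror, rel=1e-12)
    assert s.ci_lower == pytest.approx(1.0 / r.ci_upper, rel=1e-12)
    assert s.ci_upper == pytest.approx(1.0 / r.ci_lower, rel=1e-12)


@given(a=cells, b=cells, c=cells, d=cells, k=st.integers(min_value=2, max_value=20))
@settings(max_examples=200, deadline=None)
def test_scaling_preserves_ror_and_narrows_ci(a, b, c, d, k):
    t = ContingencyTable(a, b, c, d)
    tk = ContingencyTable(a * k, b * k, c * k, d * k)
    r, rk = compute_ror(t), compute_ror(tk)
    assert rk.ror == pytest.approx(r.ror, rel=1e-12)
    assert rk.ci_lower > r.ci_lower
    assert rk.ci_upper < r.ci_upper


@pytest.mark.parametrize(
    "ci_lower, tier",
    [(3.5, "strong"), (2.0, "moderate"), (1.0, "none"), (0.4, "none")],
)
def test_ror_tier(ci_lower, tier):
    assert ror_tier(_result(10, ci_lower)) == tier


# --- case-level table building ------------------------------------------


def _masks():
    idx = pd.Index([f"c{i}" for i in range(4)])
    target = pd.Series([True, True, False, False], index=idx)
    comp = ~target
    event = pd.Series([True, False, True, False], index=idx)
    return target, comp, event


def test_build_table_minimal():
    target, comp, event = _masks()
    t = build_table(target, comp, event)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_case_level_counting_counts_cases_not_reactions():
    """A case with two PTs in the event set contributes one count to a."""
    idx = pd.Index(["c1", "c2"])
    reac = pd.DataFrame(
        {"caseid": ["c1", "c1", "c2"], "pt": ["Headache", "Migraine", "Nausea"]}
    )
    ev = event_mask(idx, reac, frozenset({"Headache", "Migraine"}))
    assert list(ev) == [True, False]


def test_overlap_assigned_to_target_only(caplog):
    idx = pd.Index(["c1", "c2"])
    target = pd.Series([True, False], index=idx)
    comp = pd.Series([True, True], index=idx)
    event = pd.Series([True, True], index=idx)
    t = build_table(target, comp, event)
    assert (t.a, t.c) == (1, 1)
    assert t.a + t.b + t.c + t.d == 2


def test_cells_match_brute_force_recount():
    """On a 1,000-case planted set the cells equal an independent full
    enumeration over case records."""
    rng = np.random.default_rng(5)
    n = 1000
    idx = pd.Index([f"c{i}" for i in range(n)])
    exposed = rng.random(n) < 0.3
    has_event = rng.random(n) < np.where(exposed, 0.2, 0.1)
    dm = rng.random(n) < 0.5
    target = pd.Series(exposed, index=idx)
    event = pd.Series(has_event, index=idx)
    stratum = pd.Series(dm, index=idx)
    t = build_table(target, ~target, event, stratum=stratum)
    # brute force: loop over every case
    a = b = c = d = 0
    for e, ev, s in zip(exposed, has_event, dm):
        if not s:
            continue
        if e and ev:
            a += 1
        elif e:
            b += 1
        elif ev:
            c += 1
        else:
            d += 1
    assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
    assert t.a + t.b + t.c + t.d == int(dm.sum())


def test_indication_mask_keywords():
    idx = pd.Index(["c1", "c2", "c3"])
    indi = pd.DataFrame(
        {
            "caseid": ["c1", "c2", "c3"],
            "indi_pt": ["Type 2 diabetes mellitus", "Obesity", "Hypertension"],
        }
    )
    dm = indication_mask(idx, indi, ("DIABETES", "DIABETIC"))
    wt = indication_mask(idx, indi, ("OBESITY", "WEIGHT", "OVERWEIGHT"))
    assert list(dm) == [True, False, False]
    assert list(wt) == [False, True, False]


def test_scan_excludes_below_n_min_and_tiers():
    n = 400
    idx = pd.Index([f"c{i}" for i in range(n)])
    target = pd.Series([i < 100 for i in range(n)], index=idx)
    rows = []
    # 'Common PT': 30/100 target, 10/300 comparator -> strong signal
    for i in range(30):
        rows.append((f"c{i}", "Common PT"))
    for i in range(100, 110):
        rows.append((f"c{i}", "Common PT"))
    # 'Rare PT': only 2 target cases -> excluded (n_min)
    rows.append(("c40", "Rare PT"))
    rows.append(("c41", "Rare PT"))
    reac = pd.DataFrame(rows, columns=["caseid", "pt"])
    scan = scan_pts(target, ~target, reac, frozenset({"Common PT", "Rare PT"}))
    assert list(scan["pt"]) == ["Common PT"]
    row = scan.iloc[0]
    assert row["n"] == 30
    assert row["tier"] in {"strong", "moderate"}
    assert scan.attrs["n_comparisons"] == 2
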