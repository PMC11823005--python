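import json

import numpy as np
import pytest

from faerspv.dedup import deduplicate
from faerspv.ingest import read_quarters
from faerspv.simulate import (
    SimConfig,
    SimConfigError,
    SignalSpec,
    signal_event_prob,
    simulate,
    simulate_frames,
)


def test_injected_odds_model_closed_form():
    """true_ror=4, p0=0.05 -> p1 = (4*0.05/0.95)/(1+4*0.05/0.95)."""
    assert signal_event_prob(0.05, 4.0) == pytest.approx(0.17391304347826086, rel=1e-12)
    assert signal_event_prob(0.05, 1.0) == pytest.approx(0.05, rel=1e-12)


def test_saturating_p1_is_config_error():
    cfg = SimConfig(
        n_cases=10,
        signals=(SignalSpec("GLP-1RA", "headache", 1e6),),
    )
    with pytest.raises(SimConfigError, match="saturates"):
        cfg.validate()


def test_mix_validation_reports_all_problems():
    cfg = SimConfig(n_cases=0, duplicate_rate=1.5)
    with pytest.raises(SimConfigError) as exc:
        cfg.validate()
    msg = str(exc.value)
    assert "n_cases" in msg and "duplicate_rate" in msg


def test_identical_config_gives_byte_identical_files(tmp_path):
    cfg = SimConfig(n_cases=300, seed=9)
    r1 = simulate(cfg, out_dir=tmp_path / "a")
    r2 = simulate(SimConfig(n_cases=300, seed=9), out_dir=tmp_path / "b")
    files1 = sorted(p.name for p in (tmp_path / "a").iterdir())
    files2 = sorted(p.name for p in (tmp_path / "b").iterdir())
    assert files1 == files2
    for name in files1:
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_all_emitted_files_parse_with_zero_rejects(sim_snapshot):
    _, result = sim_snapshot
    tables, logs = read_quarters(result.file_sets)
    assert all(log.rejected == 0 for log in logs)
    assert tables.n_reports == result.truth.n_reports
    # every report has >= 1 PS drug and >= 1 reaction
    assert set(tables.demo["primaryid"]) == set(tables.drug["primaryid"])
    assert set(tables.demo["primaryid"]) == set(tables.reac["primaryid"])


def test_duplicate_ledger_bookkeeping(sim_snapshot):
    """Raw report count matches the ledger; dedup recovers unique cases exactly."""
    _, result = sim_snapshot
    ledger = result.truth.duplicate_ledger
    assert sum(ledger.values()) == result.truth.n_reports
    tables, _ = read_quarters(result.file_sets)
    dd = deduplicate(tables)
    assert dd.tables.n_reports == result.truth.n_unique_cases == len(ledger)
    # follow-up versions share caseid, distinct primaryid, later receipt
    demo = result.frames["DEMO"]
    dups = {cid for cid, k in ledger.items() if k > 1}
    sub = demo[demo["caseid"].isin(dups)]
    for cid, grp in sub.groupby("caseid"):
        assert len(grp) == ledger[cid]
        assert grp["primaryid"].nunique() == len(grp)
        final = grp.sort_values("fda_dt").iloc[-1]
        assert final["i_f_code"] == "F"


def test_null_model_has_equal_event_rates():
    """With no injected signals the target and comparator event odds match."""
    cfg = SimConfig(n_cases=20000, seed=2, signals=())
    result = simulate_frames(cfg)
    demo = result.frames["DEMO"]
    drug = result.frames["DRUG"]
    reac = result.frames["REAC"]
    glp1_names = {"DULAGLUTIDE", "TRULICITY", "SEMAGLUTIDE", "OZEMPIC", "RYBELSUS",
                  "WEGOVY", "LIRAGLUTIDE", "VICTOZA", "SAXENDA", "EXENATIDE",
                  "BYETTA", "BYDUREON", "TIRZEPATIDE", "MOUNJARO"}
    ps = drug[drug["role_cod"] == "PS"].copy()
    ps["base"] = ps["drugname"].str.split(" ").str[0]
    target_pids = set(ps[ps["base"].isin(glp1_names)]["primaryid"])
    headache_pids = set(reac[reac["pt"].isin(["Headache", "Head discomfort", "Tension headache"])]["primaryid"])
    pids = demo["primaryid"]
    a = sum(1 for p in pids if p in target_pids and p in headache_pids)
    b = sum(1 for p in pids if p in target_pids and p not in headache_pids)
    c = sum(1 for p in pids if p not in target_pids and p in headache_pids)
    d = sum(1 for p in pids if p not in target_pids and p not in headache_pids)
    or_hat = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert abs(np.log(or_hat)) < 3 * se


def test_expected_cell_consistency_at_scale():
    """Empirical contingency cells converge to SimTruth expectations
    (checked at n = 50,000 within 3 standard errors)."""
    from faerspv import dispro
    from faerspv.meddra import load_ae_groups, resolve_groups, synthetic_hierarchy
    from faerspv.vocab import attach_caseids, classify_drugs, default_dictionary
    import pandas as pd

    cfg = SimConfig(n_cases=50000, seed=13)
    result = simulate_frames(cfg)
    demo = result.frames["DEMO"].drop_duplicates("caseid", keep="last")
    assignments = attach_caseids(
        classify_drugs(result.frames["DRUG"], default_dictionary()), result.frames["DEMO"]
    )
    cases = pd.Index(demo["caseid"])
    reac = attach_caseids(result.frames["REAC"], result.frames["DEMO"])
    groups = resolve_groups(load_ae_groups(), synthetic_hierarchy())
    truth = next(s for s in result.truth.signals if s["ae_group"] == "headache")
    target = dispro.exposure_mask(cases, assignments, classes={"GLP-1RA"})
    event = dispro.event_mask(cases, reac, groups["headache"])
    t = dispro.build_table(target, ~target, event)
    exp = truth["expected_cells"]
    for cell, got in zip("abcd", (t.a, t.b, t.c, t.d)):
        e = exp[cell]
        se = np.sqrt(e)  # binomial count, p small
        assert abs(got - e) < 3 * max(se, 1.0), (cell, got, e)


def test_sim_truth_round_trips_through_json(tmp_path, small_sim_config):
    result = simulate(small_sim_config, out_dir=tmp_path)
    loaded = json.loads((tmp_path / "sim_truth.json").read_text())
    assert loaded["n_unique_cases"] == small_sim_config.n_cases
    assert loaded["missingness"]["duplicate_rate"] == small_sim_config.duplicate_rate
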