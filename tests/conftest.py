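import pandas as pd
import pytest

from faerspv.ingest import FaersTables, join_cases
from faerspv.simulate import SimConfig


def make_tables(demo_rows, drug_rows=(), reac_rows=(), indi_rows=(), ther_rows=(), outc_rows=()):
    """Build a FaersTables from terse tuples (test helper).

    demo: (primaryid, caseid, i_f, event_dt, fda_dt, age, age_cod, sex)
    drug: (primaryid, seq, role, name); reac: (primaryid, pt)
    indi: (primaryid, seq, pt); ther: (primaryid, seq, start, end)
    outc: (primaryid, code)
    """
    demo = pd.DataFrame(
        [
            {
                "primaryid": p, "caseid": c, "i_f_code": f, "event_dt": ev,
                "fda_dt": fda, "age": age, "age_cod": cod, "sex": sex,
                "occp_cod": "CN", "reporter_country": "US", "quarter": "2023q1",
            }
            for (p, c, f, ev, fda, age, cod, sex) in demo_rows
        ],
        dtype=str,
    )
    frames = {
        "DEMO": demo,
        "DRUG": pd.DataFrame(
            [dict(primaryid=p, drug_seq=s, role_cod=r, drugname=n, quarter="2023q1")
             for (p, s, r, n) in drug_rows], dtype=str,
        ),
        "REAC": pd.DataFrame(
            [dict(primaryid=p, pt=t, quarter="2023q1") for (p, t) in reac_rows], dtype=str,
        ),
        "INDI": pd.DataFrame(
            [dict(primaryid=p, indi_drug_seq=s, indi_pt=t, quarter="2023q1")
             for (p, s, t) in indi_rows], dtype=str,
        ),
        "THER": pd.DataFrame(
            [dict(primaryid=p, dsg_drug_seq=s, start_dt=a, end_dt=b, quarter="2023q1")
             for (p, s, a, b) in ther_rows], dtype=str,
        ),
        "OUTC": pd.DataFrame(
            [dict(primaryid=p, outc_cod=o, quarter="2023q1") for (p, o) in outc_rows], dtype=str,
        ),
    }
    frames = {k: v for k, v in frames.items() if not v.empty or k == "DEMO"}
    return join_cases(frames)


@pytest.fixture
def small_sim_config():
    """Desk-scale generator config used across pipeline tests."""
    return SimConfig(n_cases=1500, seed=42)


@pytest.fixture(scope="session")
def sim_snapshot(tmp_path_factory):
    """One simulated FAERS snapshot on disk, shared across a session."""
    from faerspv.simulate import simulate

    out = tmp_path_factory.mktemp("snapshot")
    result = simulate(SimConfig(n_cases=2000, seed=11), out_dir=out)
    return out, result
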