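"""Reporting odds ratio (ROR) disproportionality, from a single 2x2 table
to a full drug-class analysis on synthetic data.

ROR = (a/b)/(c/d) with a Wald 95% CI on the log scale; a drug-event pair
is a signal when n >= 3 AND the CI lower bound strictly exceeds 1.
"""

import pandas as pd

from faerspv import (
    ContingencyTable,
    SimConfig,
    compute_ror,
    deduplicate,
    flag_signal,
    simulate,
)
from faerspv import dispro, meddra
from faerspv.ingest import read_quarters
from faerspv.vocab import attach_caseids, classify_drugs, default_dictionary

# --- one table by hand --------------------------------------------------
t = ContingencyTable(a=20, b=80, c=50, d=850)
r = flag_signal(compute_ror(t))
print(f"table (20,80,50,850): ROR={r.ror:.2f} 95%CI ({r.ci_lower:.2f}, {r.ci_upper:.2f}) "
      f"n={r.n} signal={r.is_signal}")
# -> the odds of the event are ~4x higher among target-drug reports

# --- class-level analysis on a simulated database -----------------------
import tempfile

with tempfile.TemporaryDirectory() as tmp:
    result = simulate(SimConfig(n_cases=8000, seed=3), out_dir=tmp)
    tables, _ = read_quarters(result.file_sets)
data = deduplicate(tables).tables
assignments = attach_caseids(classify_drugs(data.drug, default_dictionary()), data.demo)
cases = pd.Index(data.demo["caseid"])
reac = attach_caseids(data.reac, data.demo)

hierarchy = meddra.synthetic_hierarchy()
groups = meddra.resolve_groups(meddra.load_ae_groups(), hierarchy)
target = dispro.exposure_mask(cases, assignments, classes={"GLP-1RA"})

print(f"\n{int(target.sum())} GLP-1RA primary-suspect cases "
      f"vs {int((~target).sum())} comparator cases")
print(f"{'AE group':32s} {'a':>4s} {'ROR':>6s} {'95% CI':>16s} signal")
for name, pts in groups.items():
    event = dispro.event_mask(cases, reac, pts)
    _, res = dispro.analyze(target, ~target, event)
    ci = f"({res.ci_lower:.2f}, {res.ci_upper:.2f})" if res.estimable else "n/e"
    print(f"{name:32s} {res.n:4d} {res.ror:6.2f} {ci:>16s} {res.is_signal}")
print("\ninjected truths: headache 1.74, migraine 1.28, olfactory 2.44, "
      "sensory 1.69 (others null) — estimates above should bracket these")
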