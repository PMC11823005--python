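"""Generate a synthetic FAERS-format snapshot with planted ground truth.

The generator emits "$"-delimited quarterly files (DEMO/DRUG/REAC/INDI/
THER/OUTC) plus a sim_truth.json sidecar recording what was planted:
injected drug-event odds ratios, per-drug onset medians, the duplicate
ledger and missingness rates.
"""

from pathlib import Path

from faerspv import SimConfig, simulate

out = Path("scratch/example_snapshot")
config = SimConfig(n_cases=2000, seed=7)
result = simulate(config, out_dir=out)

print(f"wrote {len(result.file_sets)} quarters under {out}/")
for fs in result.file_sets:
    print(f"  {fs.quarter}: {sorted(fs.paths)}")
truth = result.truth
print(f"{truth.n_reports} report versions for {truth.n_unique_cases} unique cases")
print(f"(the surplus {truth.n_reports - truth.n_unique_cases} versions are "
      "follow-ups/duplicates that deduplication must remove)")
print("injected signals (drug, AE group, stratum, true ROR):")
for sig in truth.signals:
    print(f"  {sig['drug']:12s} {sig['ae_group']:30s} "
          f"{str(sig['indication']):12s} ROR={sig['true_ror']}")
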