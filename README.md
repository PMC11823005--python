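# faerspv

Pharmacovigilance disproportionality analysis for FAERS-format spontaneous
adverse-event reports — built around the question of neuropsychiatric adverse
events under GLP-1 receptor agonists (semaglutide, dulaglutide, liraglutide,
exenatide, tirzepatide), but usable for any drug-event surveillance on
FAERS-shaped data.

It is a library first (importable modules per pipeline stage, with
`examples/` showing each capability), plus a thin `faerspv` CLI for running
the pipeline from a shell.

## What it does

FDA's Adverse Event Reporting System (FAERS) distributes quarterly
`$`-delimited ASCII tables (DEMO, DRUG, REAC, INDI, THER, OUTC). From those,
the package:

1. **Ingests** each quarter with full per-row accounting, handling both the
   legacy (pre-2012Q4, ISR-keyed) and current (primaryid/caseid) schemas and
   the 8/6/4-digit partial-date dialect.
2. **Deduplicates** multi-version cases, keeping the most recent version per
   case ID (receipt date, then follow-up over initial, then event date, then
   primaryid — a total order, so results are independent of row order).
3. **Classifies exposures** from verbatim drug names via an editable
   generic/brand dictionary, keeping only primary-suspect (PS) roles.
4. **Groups reactions** through a user-supplied MedDRA-style
   PT→HLT→HLGT→SOC table with primary-SOC flags (MedDRA is licensed and does
   not ship; a clearly synthetic toy hierarchy is bundled for testing), and
   assembles eight neuropsychiatric AE groups at HLT/HLGT level.
5. **Computes disproportionality**: for each drug set × AE set × indication
   stratum, the reporting odds ratio

   ROR = (a/b) / (c/d),  95% CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )

   where *a*/*b* are target-drug cases with/without the event and *c*/*d*
   the same for the comparator. A pair is a **signal** when n ≥ 3 and the CI
   lower bound strictly exceeds 1; PT-level scans tier results by the CI
   lower bound (RORL > 3 strong, 1 < RORL ≤ 3 moderate).
6. **Summarizes time-to-onset** (days from therapy initiation to event),
   excluding non-positive, reversed, missing or partial-dated intervals with
   explicit reasons; reports median, IQR, day bins and cumulative curves.
7. **Simulates** whole FAERS-format snapshots with planted ground truth —
   injected odds ratios (signal cases get event odds multiplied by the true
   ROR), per-drug log-normal onset medians, follow-up duplicates and
   partial-date missingness — so every stage is verifiable without any
   download.

## Worked example

```python
from faerspv import ContingencyTable, compute_ror, flag_signal

r = flag_signal(compute_ror(ContingencyTable(a=20, b=80, c=50, d=850)))
print(f"ROR={r.ror:.2f} 95%CI ({r.ci_lower:.2f}, {r.ci_upper:.2f}) "
      f"n={r.n} signal={r.is_signal}")
```

prints

```
ROR=4.25 95%CI (2.41, 7.49) n=20 signal=True
```

— the event's reporting odds are ~4× the comparator's, the CI excludes 1
and there are ≥ 3 target cases, so the pair is flagged.

At database scale (`examples/03_disproportionality.py`, a simulated 8,000-case
snapshot with signals injected at ROR 1.74 for headache and 1.69 for sensory
nerve abnormalities, others null):

```
2445 GLP-1RA primary-suspect cases vs 5555 comparator cases
AE group                            a    ROR           95% CI signal
headache                          131   1.83     (1.45, 2.31) True
...
sensory nerve abnormalities        58   2.19     (1.52, 3.15) True
```

Each estimate's CI brackets its injected truth; null groups stay unflagged.
The other examples cover simulation (`01`), ingest+dedup (`02`),
time-to-onset (`04`) and the full pipeline with its attrition log (`05`).

From the shell:

```
faerspv simulate --out-dir snapshot --n-cases 5000 --seed 7
faerspv run-all --config config.yaml --out-dir results
```

## Project layout

```
src/faerspv/
  schema.py        FAERS dialect, schema-era registry, partial dates
  ingest.py        file reading, row accounting, case joining
  dedup.py         case-version deduplication
  vocab.py         drug name normalization + dictionary classification
  meddra.py        hierarchy handling, AE group resolution
  dispro.py        contingency tables, ROR/CI, signal rule, PT scans
  tto.py           time-to-onset records and summaries
  descriptives.py  characteristics tables, annual series
  simulate.py      synthetic snapshot generator + ground truth
  pipeline.py      end-to-end orchestration, result bundle
  cli.py           thin command-line wrapper
  data/            default drug dictionary, AE groups, synthetic hierarchy
```

See `docs/methods.md` for the statistical model, generator assumptions and
numerical choices.
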