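# Methods

This note documents the statistical model, the conventions the pipeline
commits to where several are defensible, the synthetic-data generator's
assumptions, and the package's known limitations.

## Disproportionality model

For a target drug set T, comparator set C (disjoint from T) and adverse
event PT set E, counting **at case level** (a case reporting several PTs of
E counts once):

|            | event in E | no event in E |
|------------|-----------:|--------------:|
| case in T  | a          | b             |
| case in C  | c          | d             |

The reporting odds ratio is ROR = (a/b)/(c/d), with the Wald interval on
the log scale:

    CI95 = exp( ln ROR ± z · √(1/a + 1/b + 1/c + 1/d) ).

Conventions:

* **z** is the exact two-sided 95% normal quantile, 1.959963984540054
  (conventionally printed 1.96). It is deliberately not configurable, so
  results remain comparable across analyses; using the exact quantile also
  makes the implementation agree with standard 2×2 routines
  (statsmodels `Table2x2`) to full precision, which the test suite checks to
  12 significant digits.
* **No continuity correction.** A zero cell yields a *not estimable* result
  rather than a silently Haldane–Anscombe-corrected one. The n ≥ 3 signal
  rule keeps a > 0 for anything that can be flagged.
* **Signal rule**: `is_signal = (a ≥ n_min) AND (ci_lower > 1)`, strictly,
  with n_min = 3 by default.
* **PT scan tiers** (heatmap semantics): strong if the CI lower bound
  (RORL) > 3, moderate if 1 < RORL ≤ 3, none if RORL ≤ 1 (the boundary
  RORL = 1 is "none"), n/a when not estimable. PTs with a < 3 are omitted
  from the scan.
* **No multiple-testing adjustment.** Scans report raw CIs together with
  the number of comparisons (`DataFrame.attrs["n_comparisons"]`) so users
  can post-adjust.
* **Comparators.** Three constructions: the whole database minus the target;
  non-target antidiabetic dictionary classes; non-target anti-obesity
  classes. For the dictionary-class comparators, *all* cases with any
  target-class PS assignment are excluded from the comparator, so a case
  co-reporting a GLP-1RA never dilutes its own comparison. A case that ends
  up in both target and comparator masks is assigned to the target and the
  overlap is logged.
* **Indication strata.** A case is in the diabetes stratum if any
  indication PT contains a DM keyword ("DIABETES", "DIABETIC") and in the
  weight-loss stratum on the weight keywords ("OBESITY", "WEIGHT",
  "OVERWEIGHT"); keyword lists are config. Strata are analyzed separately
  and are **not exclusive** — a case matching both belongs to both. (The
  Table-1-style descriptive label, in contrast, is single-valued with DM
  taking precedence.)

## Deduplication

FAERS cases accumulate report versions (initial "I" then follow-ups "F"),
and the same case recurs across quarterly files. Deduplication is global
across all loaded quarters and keeps one survivor per case ID under the
total order: latest FDA receipt date → F over I → latest event date →
largest numeric primaryid. Receipt date leads because it most directly
encodes "most recent version"; the numeric tie-break makes the result
deterministic and order-invariant. Missing dates sort before any present
date, so versions with complete data are preferred. Demographic fields are
treated as version context only — no fuzzy cross-case-ID linkage is
attempted. Every removed version is logged with its survivor, so
`|input| = |survivors| + |log|` always holds.

## Exposure classification

Verbatim drug names are uppercased, whitespace-collapsed and stripped of
trailing dose/form tokens ("1 MG", "PEN", "INJECTION", …). The dictionary
maps generic and brand names to (class, generic); the default matching mode
is word-boundary substring, because FAERS verbatim names embed doses and
routes. Collisions (one name, two classes) are load-time configuration
errors listing every offender. Only primary-suspect (PS) rows produce
exposure assignments by default; a report whose only target-class mention
is SS/C/I is not exposed. A case with PS entries for two different
target-class generics counts once in the class-level analysis and once per
generic in per-drug analyses.

The shipped dictionary reconstructs the GLP-1RA generic/brand lists plus
comparator antidiabetic classes (DPP-4 inhibitors, sulfonylureas,
metformin, SGLT2 inhibitors, thiazolidinediones) and anti-obesity drugs
(orlistat, phentermine, naltrexone–bupropion, phentermine–topiramate). It
is a YAML file users should replace for serious use.

## MedDRA-style hierarchy

MedDRA is licensed and cannot ship. The package defines the table format
(PT / HLT / HLGT / SOC / primary-SOC flag, TSV) and validates the key
invariant — exactly one primary SOC per PT — reporting every offender.
Neuropsychiatric PTs are those whose *primary* SOC is "Psychiatric
disorders" or "Nervous system disorders"; multiaxial secondary links do not
count. The eight AE groups (headache, migraine, anxiety, depression,
suicide-related, sleep disorders, olfactory and sensory nerve
abnormalities) are defined as HLT/HLGT selectors in YAML; the bundled
selector terms are reconstructions resolved against the bundled *synthetic*
toy hierarchy, and should be re-pointed at real MedDRA terms by licensed
users. Reaction matching is by PT text, case-insensitive after trimming,
because FAERS REAC stores PT text.

## Time-to-onset

Onset = (case event date) − (earliest complete therapy start date of the
exposure drug), in whole days, computed per (case, generic). Records are
excluded — never imputed — when either date is missing or has only
year/month precision, when onset is 0 (same-day dosing), or when the start
postdates the event; each exclusion carries its reason and every record
appears exactly once. Where a case reports several target AE groups the
record is replicated per group (FAERS carries one event date per report).
Quartiles use linear interpolation between order statistics (quantile
"type 7", the numpy default) — the convention is documented because IQR
endpoints on day-valued data can shift by ±1 day between conventions.
Default day bins: (0,30], (30,60], (60,90], (90,180], (180,360], >360.

## Descriptives

Age groups are <18, [18,65), [65,85], >85 (boundaries configurable; the
two interior boundaries are genuinely ambiguous in prose descriptions and
were fixed once here). Report year comes from the FDA receipt date (always
present) rather than the often-missing event date. The outcome dimension
uses a worst-outcome ranking DE > LT > HO > DS > CA > RI > OT. Percentages
use the all-cases denominator with an explicit "missing" level, so counts
sum to the cohort and percents to 100 up to rounding.

## Synthetic-data generator

The generator emits full FAERS-dialect quarterly files plus a ground-truth
sidecar. Its probability model:

* Each case draws one PS drug from a configurable mix ("OTHER" = the
  non-dictionary background of the database), an indication (DM /
  weight-loss / other / missing) from a per-class mix, demographics, an
  outcome, and reactions.
* **Injected signals.** Each of the eight AE groups fires with baseline
  probability p₀; for cases matching a signal's drug (generic or class) and
  optional stratum, the event *odds* are multiplied by the true ROR:
  p₁ = R·p₀/(1−p₀) / (1 + R·p₀/(1−p₀)), which makes the expected table's
  (a·d)/(b·c) equal R exactly. A p₁ that saturates (> 0.99) is a
  configuration error advising a smaller p₀.
* **Onset times** are round(log-normal), clipped to ≥ 1 day, location set so
  the continuous median equals the configured per-drug median (clipping and
  rounding preserve it); log-scale σ defaults to 2.2, matching the
  right-skew of published onset IQRs (3–66 days around a median of 16), and
  a tail cap at 1,500 days keeps receipt dates within a plausible horizon
  without touching median or IQR. Therapy start dates are uniform within
  the configured years; receipt = event + a 3–90 day reporting lag; files
  are grouped by each version's actual receipt quarter, so follow-up
  versions can land in later quarterly files than their initial reports —
  deliberately exercising cross-quarter deduplication.
* **Duplicates**: a configurable fraction of cases (default 20%) emits an
  earlier "I" version and a later "F" version with distinct primaryids; the
  ledger records every version count, so dedup recovery is exact, not
  statistical.
* **Missingness**: ages, sexes and outcomes are blanked at the configured
  marginal rates; event/start dates are dropped or truncated to 6 or 4
  characters, exercising the partial-date dialect end to end.
* Default marginals (sex 63/32/5, outcome missing 63% with 11.8%
  hospitalization, DM/weight/missing indication split 55/9/36 for the
  target class, dulaglutide the largest GLP-1RA share, per-drug onset
  medians 7/16/27/28 days) follow the published descriptive tables of the
  GLP-1RA cohort this package was built around; they are the generator's
  study conditions, not tuning knobs.

What the generator does **not** emulate: co-prescription structure beyond a
single random concomitant, litigation- or media-driven reporting waves,
secular trends in reporting volume, spelling noise in drug names, and PT
miscoding. Passing recovery tests therefore demonstrates correctness of
the pipeline's accounting and estimators under a clean reporting process —
not robustness to real FAERS data quality, where dictionary coverage and
duplicate heuristics dominate error.

For calibration experiments (CI coverage across hundreds of replicates,
null false-signal rates), `simulate_contingency` draws the 2×2 cells
directly from the same odds model via binomials — distributionally
identical to tabulating a full simulated database with one signal, without
file I/O. The full file-level path is exercised separately by
`round_trip_check`.

## Problem sizes

The test suite runs desk-scale: snapshots of 1,500–4,000 cases for
pipeline behavior, 50,000 for expected-cell convergence (within 3 standard
errors), 33,000 (≈11,000 per drug) for onset-median recovery within 5%,
500 replicates for CI coverage, and the exhaustive 12⁴ grid of 2×2 tables
for oracle equivalence. `scripts/acceptance.py` uses a 60,000-case
database. These sizes were chosen so each check's sampling error is small
against its tolerance.

## Limitations

* Disproportionality measures reporting association, not causal risk; all
  caveats of spontaneous-report data (under/over-reporting, confounding by
  indication, no denominators) apply to any output of this package.
* The bundled dictionary and AE-group terms are reconstructions; analyses
  on real data should supply curated versions (and a licensed MedDRA
  hierarchy).
* Duplicate detection is exact on case ID only; probabilistic linkage of
  re-submitted cases under different IDs is out of scope.
* PRR, EBGM/MGPS and Bayesian IC statistics are not implemented; the
  contingency machinery would support them as extensions.
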