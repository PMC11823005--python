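"""End-to-end pipeline: config -> ingest -> dedup -> exposure -> results.

Runs the whole analysis from a single config and writes every result
surface as CSV (plus a manifest), logging case counts at each filtering
step — disproportionality results are meaningless without auditable
denominators. Outputs are byte-deterministic for a fixed config: no
timestamps, sorted rows, fixed float formatting.

Result files
------------
load_log.csv        per-file parse accounting
dedup_log.csv       removed report versions and their survivors
attrition.csv       case counts after every filter step
characteristics.csv Table-1-style cohort characteristics
annual_series.csv   per-year neuro vs other report counts
per_drug.csv        per-generic overall/neuro counts and shares
pt_scan_<stratum>.csv   PT-level heatmap-matrix-ready scan
signals_forest.csv  AE-group forest-plot-ready signal table
tto_summary.csv     per-drug / per-group / overall TTO summaries
tto_curve.csv       cumulative onset curves
manifest.json       config hash and output inventory
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dispro, meddra
from .dedup import deduplicate
from .descriptives import (
    DEFAULT_AGE_BOUNDS,
    annual_series,
    characteristics_table,
    cohort_frame,
    per_drug_shares,
)
from .ingest import discover_quarters, load_log_frame, read_quarters
from .simulate import SimConfig, simulate
from .tto import DEFAULT_BINS, attach_groups, compute_tto, summarize_by, summarize_tto
from .vocab import DrugDictionary, attach_caseids, classify_drugs, default_dictionary

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"

#: comparator drug-class sets, per the published comparisons
ANTIDIABETIC_CLASSES = (
    "DPP-4 inhibitor", "sulfonylurea", "metformin", "SGLT2 inhibitor", "thiazolidinedione",
)
ANTIOBESITY_CLASSES = ("anti-obesity",)


class ConfigError(ValueError):
    """Pipeline configuration problem; the message lists every issue."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs. ``input_dir`` XOR ``sim``."""

    out_dir: Path
    input_dir: Path | None = None
    sim: SimConfig | None = None
    seed: int = 0
    target_class: str = "GLP-1RA"
    drug_dictionary: Path | None = None  # None = bundled default
    hierarchy: Path | None = None  # None = bundled synthetic toy
    ae_groups: Path | None = None  # None = bundled eight groups
    strata: tuple[str, ...] = ("DM", "weight-loss")
    dm_keywords: tuple[str, ...] = dispro.DM_KEYWORDS
    weight_keywords: tuple[str, ...] = dispro.WEIGHT_KEYWORDS
    tto_bins: tuple[float, ...] = DEFAULT_BINS
    age_bounds: tuple[float, float, float] = DEFAULT_AGE_BOUNDS
    n_min: int = dispro.DEFAULT_N_MIN

    def validate(self) -> None:
        problems = []
        if (self.input_dir is None) == (self.sim is None):
            problems.append("exactly one of input_dir or sim must be set")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            problems.append(f"input_dir does not exist: {self.input_dir}")
        for name in ("drug_dictionary", "hierarchy", "ae_groups"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                problems.append(f"{name} file does not exist: {p}")
        unknown = set(self.strata) - {"all", "DM", "weight-loss"}
        if unknown:
            problems.append(f"unknown strata: {sorted(unknown)}")
        if problems:
            raise ConfigError("invalid PipelineConfig:\n  " + "\n  ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sim = None
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "signals" in sim_raw:
                from .simulate import SignalSpec

                sim_raw["signals"] = tuple(SignalSpec(**s) for s in sim_raw["signals"])
            for key in ("years",):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimConfig(**sim_raw)
        kwargs = {k: v for k, v in raw.items() if k != "sim"}
        for key in ("out_dir", "input_dir", "drug_dictionary", "hierarchy", "ae_groups"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        for key in ("strata", "dm_keywords", "weight_keywords", "tto_bins", "age_bounds"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(sim=sim, **kwargs)

    def canonical_json(self) -> str:
        def default(o):
            if isinstance(o, Path):
                return str(o)
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        # out_dir is where results land, not what they are: exclude it so the
        # hash identifies the analysis, independent of output location
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return json.dumps(payload, default=default, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def run(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and write all result tables."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    attrition: list[tuple[str, int]] = []
    tables_out: dict[str, pd.DataFrame] = {}

    # --- ingest ---------------------------------------------------------
    if config.sim is not None:
        sim_dir = out_dir / "sim_input"
        result = simulate(config.sim, out_dir=sim_dir)
        file_sets = result.file_sets
    else:
        file_sets = discover_quarters(config.input_dir)
        if not file_sets:
            raise ConfigError(f"no FAERS-style files found under {config.input_dir}")
    tables, logs = read_quarters(file_sets)
    tables_out["load_log"] = load_log_frame(logs)
    attrition.append(("raw_reports", tables.n_reports))
    for kind, n in sorted(tables.orphans.items()):
        attrition.append((f"orphan_rows_excluded_{kind}", n))

    # --- dedup ----------------------------------------------------------
    dd = deduplicate(tables)
    tables_out["dedup_log"] = dd.log
    attrition.append(("deduplicated_cases", dd.tables.n_reports))
    data = dd.tables

    # --- exposure -------------------------------------------------------
    dictionary = (
        default_dictionary()
        if config.drug_dictionary is None
        else DrugDictionary.from_yaml(config.drug_dictionary)
    )
    assignments = attach_caseids(classify_drugs(data.drug, dictionary), data.demo)
    cases = pd.Index(data.demo["caseid"])
    reac = attach_caseids(data.reac, data.demo)
    indi = attach_caseids(data.indi, data.demo)

    target = dispro.exposure_mask(cases, assignments, classes={config.target_class})
    attrition.append((f"{config.target_class}_PS_cases", int(target.sum())))

    # --- hierarchy / AE sets -------------------------------------------
    hierarchy = (
        meddra.synthetic_hierarchy()
        if config.hierarchy is None
        else meddra.load_hierarchy(config.hierarchy)
    )
    groups = meddra.resolve_groups(meddra.load_ae_groups(config.ae_groups), hierarchy)
    neuro_pts = frozenset().union(
        *(hierarchy.pts_for_primary_soc(soc) for soc in meddra.TARGET_SOCS)
    )
    neuro = dispro.event_mask(cases, reac, neuro_pts)
    attrition.append(("target_neuro_cases", int((target & neuro).sum())))

    strata_masks: dict[str, pd.Series | None] = {"all": None}
    strata_masks["DM"] = dispro.indication_mask(cases, indi, config.dm_keywords)
    strata_masks["weight-loss"] = dispro.indication_mask(cases, indi, config.weight_keywords)
    for name in config.strata:
        mask = strata_masks[name]
        attrition.append(
            (f"stratum_{name}_target_cases",
             int(target.sum()) if mask is None else int((target & mask).sum()))
        )

    # --- descriptives (target cases with neuropsychiatric events) ------
    demo_idx = data.demo.set_index("caseid")
    cohort_ids = cases[(target & neuro).values]
    cohort_demo = demo_idx.loc[cohort_ids].reset_index()
    cohort = cohort_frame(
        cohort_demo,
        data.outc,
        strata_masks["DM"],
        strata_masks["weight-loss"],
        age_bounds=config.age_bounds,
    )
    tables_out["characteristics"] = characteristics_table(cohort)

    all_target = cohort_frame(
        demo_idx.loc[cases[target.values]].reset_index(),
        data.outc,
        strata_masks["DM"],
        strata_masks["weight-loss"],
        age_bounds=config.age_bounds,
    )
    tables_out["annual_series"] = annual_series(all_target, neuro)
    target_assignments = assignments[assignments["drug_class"] == config.target_class]
    tables_out["per_drug"] = per_drug_shares(data.demo, target_assignments, neuro)

    # --- PT-level scans (heatmap shape) ---------------------------------
    for name in config.strata:
        scan = dispro.scan_pts(
            target, ~target, reac, neuro_pts, stratum=strata_masks[name], n_min=config.n_min
        )
        tables_out[f"pt_scan_{_slug(name)}"] = scan

    # --- AE-group forest tables -----------------------------------------
    glp1_exposed = target  # any case with >=1 PS target-class assignment
    comparators = {
        "rest-of-database": ~target,
        "non-GLP1RA-antidiabetic": (
            dispro.exposure_mask(cases, assignments, classes=set(ANTIDIABETIC_CLASSES))
            & ~glp1_exposed
        ),
        "non-GLP1RA-antiobesity": (
            dispro.exposure_mask(cases, assignments, classes=set(ANTIOBESITY_CLASSES))
            & ~glp1_exposed
        ),
    }
    drug_targets: dict[str, pd.Series] = {config.target_class: target}
    for generic in dictionary.generics(config.target_class):
        drug_targets[generic] = dispro.exposure_mask(cases, assignments, generics={generic})

    rows = []
    for stratum_name in config.strata:
        smask = strata_masks[stratum_name]
        for comp_name, comp_mask in comparators.items():
            for drug_name, drug_mask in drug_targets.items():
                for group_name, pts in groups.items():
                    ev = dispro.event_mask(cases, reac, pts)
                    t, r = dispro.analyze(
                        drug_mask, comp_mask, ev, stratum=smask, n_min=config.n_min
                    )
                    rows.append(
                        {
                            "stratum": stratum_name, "comparator": comp_name,
                            "drug": drug_name, "ae_group_or_pt": group_name,
                            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                            "ror": r.ror, "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                            "n": r.n, "is_signal": r.is_signal, "tier": dispro.ror_tier(r),
                        }
                    )
    tables_out["signals_forest"] = pd.DataFrame(rows)

    # --- TTO ------------------------------------------------------------
    records = compute_tto(data.demo, data.ther, target_assignments)
    neuro_case_ids = set(cohort_ids)
    records_neuro = records[records["caseid"].isin(neuro_case_ids)].reset_index(drop=True)
    per_generic = summarize_by(records_neuro, by="generic", bins=config.tto_bins)
    per_generic.insert(0, "grouping", "generic")
    grouped = attach_groups(records_neuro, reac, groups)
    per_group = summarize_by(grouped, by="ae_group", bins=config.tto_bins)
    per_group.insert(0, "grouping", "ae_group")
    overall = summarize_tto(
        records_neuro.loc[records_neuro["included"], "onset_days"].astype(float),
        bins=config.tto_bins,
    )
    overall_row = pd.DataFrame(
        [{
            "grouping": "overall", "generic": "all", "n": overall.n,
            "median_days": overall.median_days,
            "iqr_lower_days": overall.iqr_lower_days,
            "iqr_upper_days": overall.iqr_upper_days,
            **overall.bin_counts,
        }]
    )
    tables_out["tto_summary"] = pd.concat(
        [overall_row, per_generic, per_group], ignore_index=True
    )
    curves = []
    if overall.cumulative is not None and len(overall.cumulative):
        cur = overall.cumulative.copy()
        cur.insert(0, "group", "overall")
        curves.append(cur)
    for group_name in groups:
        sub = grouped[(grouped["ae_group"] == group_name) & grouped["included"]]
        s = summarize_tto(sub["onset_days"].astype(float), bins=config.tto_bins)
        if s.cumulative is not None and len(s.cumulative):
            cur = s.cumulative.copy()
            cur.insert(0, "group", group_name)
            curves.append(cur)
    tables_out["tto_curve"] = (
        pd.concat(curves, ignore_index=True)
        if curves
        else pd.DataFrame(columns=["group", "day", "fraction"])
    )
    excl = records.groupby("exclusion_reason", dropna=True).size()
    for reason, count in excl.items():
        attrition.append((f"tto_excluded_{reason}", int(count)))
    attrition.append(("tto_included_records", int(records["included"].sum())))

    # --- write ----------------------------------------------------------
    tables_out["attrition"] = pd.DataFrame(attrition, columns=["step", "count"])
    written = {}
    for name, df in sorted(tables_out.items()):
        path = out_dir / f"{name}.csv"
        _write(df, path)
        written[name] = path.name
    manifest = {
        "config_hash": config.config_hash(),
        "outputs": written,
        "n_raw_reports": int(tables.n_reports),
        "n_cases": int(data.n_reports),
        "n_target_cases": int(target.sum()),
        "quarters": [fs.quarter for fs in sorted(file_sets, key=lambda f: f.sort_key())],
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d cases, outputs in %s", data.n_reports, out_dir)
    return PipelineResult(out_dir=out_dir, tables=tables_out, manifest=manifest)


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_").replace("-", "_")
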