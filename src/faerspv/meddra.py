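"""MedDRA-style hierarchy handling and adverse-event group resolution.

MedDRA organizes reaction terms in five levels (LLT - PT - HLT - HLGT -
SOC); FAERS reactions are coded at Preferred Term (PT) level, and the
multiaxial structure links one PT to several System Organ Classes with
exactly one flagged as primary. MedDRA itself is licensed and cannot ship
with the package: the hierarchy is user-supplied as a TSV
(pt / hlt / hlgt / soc / primary_soc), and a synthetic toy hierarchy is
bundled for testing and simulation.

PT matching is by term text, case-insensitively after trimming, because
FAERS REAC rows store PT text rather than numeric codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

TARGET_SOCS = ("Psychiatric disorders", "Nervous system disorders")

GROUP_NAMES = (
    "headache",
    "migraine",
    "anxiety",
    "depression",
    "suicide-related",
    "sleep disorders",
    "olfactory nerve abnormalities",
    "sensory nerve abnormalities",
)


class HierarchyError(ValueError):
    """Hierarchy validation failure; the message lists every offender."""


def _fold(s: pd.Series | str):
    if isinstance(s, str):
        return s.strip().casefold()
    return s.str.strip().str.casefold()


@dataclass
class MeddraHierarchy:
    """Validated PT->HLT->HLGT->SOC table with primary-SOC flags."""

    table: pd.DataFrame  # columns: pt, hlt, hlgt, soc, primary_soc(bool)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        df = self.table
        required = {"pt", "hlt", "hlgt", "soc", "primary_soc"}
        missing = required - set(df.columns)
        if missing:
            raise HierarchyError(f"hierarchy lacks columns: {sorted(missing)}")
        df = df.copy()
        for col in ("pt", "hlt", "hlgt", "soc"):
            df[col] = df[col].astype(str).str.strip()
        if df["primary_soc"].dtype != bool:
            df["primary_soc"] = (
                df["primary_soc"].astype(str).str.strip().str.upper().isin({"Y", "YES", "TRUE", "1"})
            )
        # collapse duplicate (pt, soc) rows
        df = df.drop_duplicates(subset=["pt", "soc"], keep="first").reset_index(drop=True)
        df["_pt_key"] = _fold(df["pt"])
        primaries = df[df["primary_soc"]].groupby("_pt_key").size()
        offenders = []
        for key, grp in df.groupby("_pt_key"):
            n = int(primaries.get(key, 0))
            if n != 1:
                offenders.append(f"{grp['pt'].iloc[0]!r} has {n} primary-SOC rows")
        if offenders:
            raise HierarchyError("invalid primary-SOC flags:\n  " + "\n  ".join(sorted(offenders)))
        self.table = df

    @property
    def pts(self) -> frozenset[str]:
        return frozenset(self.table["pt"])

    def pts_for_primary_soc(self, soc: str) -> frozenset[str]:
        """PTs whose *primary* SOC is ``soc`` (multiaxial links elsewhere
        do not count). Unknown SOC warns and returns the empty set."""
        df = self.table
        if not (_fold(df["soc"]) == _fold(soc)).any():
            warnings.warn(f"SOC {soc!r} not present in hierarchy", stacklevel=2)
            return frozenset()
        mask = df["primary_soc"] & (_fold(df["soc"]) == _fold(soc))
        return frozenset(df.loc[mask, "pt"])

    def pts_for_term(self, level: str, term: str) -> frozenset[str]:
        """All PTs under one HLT/HLGT (any axis), or a PT itself."""
        level = level.upper()
        df = self.table
        if level == "PT":
            hit = df.loc[df["_pt_key"] == _fold(term), "pt"]
            return frozenset(hit)
        if level not in {"HLT", "HLGT"}:
            raise ValueError(f"unknown hierarchy level {level!r}")
        col = level.lower()
        return frozenset(df.loc[_fold(df[col]) == _fold(term), "pt"])


def load_hierarchy(path: str | Path, version: str = "unversioned") -> MeddraHierarchy:
    """Load and validate a hierarchy TSV (pt, hlt, hlgt, soc, primary_soc)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return MeddraHierarchy(table=table, version=version)


def synthetic_hierarchy() -> MeddraHierarchy:
    """The synthetic toy hierarchy bundled with the package.

    A small stand-in shaped like a real MedDRA extract (multiaxial rows,
    primary-SOC flags, the two neuropsychiatric target SOCs plus background
    SOCs); its terms echo real PT names but the table is NOT MedDRA.
    """
    ref = resources.files("faerspv.data") / "synthetic_hierarchy.tsv"
    with resources.as_file(ref) as path:
        return load_hierarchy(path, version="synthetic-toy")


@dataclass(frozen=True)
class AEGroupDefinition:
    """A named adverse-event group: a union of hierarchy selectors.

    Selectors pick terms at PT, HLT or HLGT level; the group's PT set is
    the union of the PTs under every selector.
    """

    name: str
    selectors: tuple[tuple[str, str], ...]  # (level, term)


class GroupConfigError(ValueError):
    pass


def resolve_group(group: AEGroupDefinition, hierarchy: MeddraHierarchy) -> frozenset[str]:
    """PT set of one group. A selector resolving to nothing is a
    configuration error (likely a term/version mismatch)."""
    pts: set[str] = set()
    empty = []
    for level, term in group.selectors:
        hit = hierarchy.pts_for_term(level, term)
        if not hit:
            empty.append(f"({level}, {term!r})")
        pts |= hit
    if empty:
        raise GroupConfigError(
            f"group {group.name!r}: selectors resolve to no PTs: " + ", ".join(empty)
        )
    return frozenset(pts)


def load_ae_groups(path: str | Path | None = None) -> list[AEGroupDefinition]:
    """Load AE group definitions from YAML (defaults to the bundled eight)."""
    if path is None:
        raw = yaml.safe_load(
            (resources.files("faerspv.data") / "ae_groups.yaml").read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    groups = []
    for name, selectors in raw["groups"].items():
        groups.append(
            AEGroupDefinition(
                name=str(name),
                selectors=tuple((str(s["level"]).upper(), str(s["term"])) for s in selectors),
            )
        )
    return groups


def resolve_groups(
    groups: list[AEGroupDefinition], hierarchy: MeddraHierarchy
) -> dict[str, frozenset[str]]:
    return {g.name: resolve_group(g, hierarchy) for g in groups}
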