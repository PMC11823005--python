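"""Drug name normalization, dictionary-based classification, role filtering.

FAERS drug names are free text ("Ozempic 1 mg injection", "SEMAGLUTIDE").
A drug dictionary maps generic and brand names to (class, generic) pairs;
classification applies the dictionary to every drug row of every report and
keeps only the roles of interest — the primary-suspect ("PS") filter used
for exposure definition, by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

#: trailing tokens stripped during name normalization (doses, forms, routes)
DEFAULT_SUFFIX_TOKENS = frozenset(
    {
        "PEN", "INJECTION", "INJ", "TABLET", "TABLETS", "CAPSULE", "CAPSULES",
        "SOLUTION", "SUSPENSION", "ORAL", "SUBCUTANEOUS", "PREFILLED",
        "SYRINGE", "AUTOINJECTOR", "AUTO-INJECTOR", "MG", "MCG", "ML", "G",
        "MG/ML", "HCL", "ER", "XR", "SR", "KIT", "DOSE", "WEEKLY", "DAILY",
    }
)

_NUMERIC_TOKEN = re.compile(r"^[\d.,/%]+$")
_NUM_UNIT_TOKEN = re.compile(
    r"^\d[\d.,]*(MG|MCG|ML|G|IU|UNITS?)(/[\d.,]*(MG|MCG|ML|G|DAY|WEEK))?$"
)


def normalize_name(verbatim: str, suffix_tokens: frozenset[str] = DEFAULT_SUFFIX_TOKENS) -> str:
    """Uppercase, collapse whitespace, strip trailing dose/form tokens.

    >>> normalize_name("Ozempic 1 mg injection")
    'OZEMPIC'
    """
    s = re.sub(r"\s+", " ", str(verbatim).upper().strip())
    tokens = s.split(" ")
    while len(tokens) > 1:
        t = tokens[-1]
        if t in suffix_tokens or _NUMERIC_TOKEN.match(t) or _NUM_UNIT_TOKEN.match(t):
            tokens.pop()
        else:
            break
    return " ".join(tokens)


class DictionaryError(ValueError):
    """Dictionary configuration problem; message lists every collision."""


@dataclass(frozen=True)
class DictionaryEntry:
    drug_class: str
    generic: str
    brands: tuple[str, ...] = ()
    match_mode: str = "word"  # "word" (word-boundary substring) or "exact"

    @property
    def names(self) -> tuple[str, ...]:
        return (self.generic,) + self.brands


@dataclass
class DrugDictionary:
    """Validated name -> (class, generic) lookup.

    No name may map to two classes; collisions are configuration errors at
    load time, reported all at once.
    """

    entries: list[DictionaryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._lookup: dict[str, DictionaryEntry] = {}
        collisions: list[str] = []
        for entry in self.entries:
            for name in entry.names:
                key = name.strip().upper()
                prev = self._lookup.get(key)
                if prev is not None and (prev.drug_class, prev.generic) != (entry.drug_class, entry.generic):
                    collisions.append(
                        f"{key!r}: {prev.drug_class}/{prev.generic} vs {entry.drug_class}/{entry.generic}"
                    )
                else:
                    self._lookup[key] = entry
        if collisions:
            raise DictionaryError("dictionary name collisions:\n  " + "\n  ".join(collisions))
        self._word_patterns = [
            (re.compile(r"(?:^|[^A-Z0-9])" + re.escape(name) + r"(?:$|[^A-Z0-9])"), entry, name)
            for name, entry in sorted(self._lookup.items())
            if entry.match_mode == "word"
        ]

    @property
    def classes(self) -> list[str]:
        return sorted({e.drug_class for e in self.entries})

    def generics(self, drug_class: str) -> list[str]:
        return sorted({e.generic for e in self.entries if e.drug_class == drug_class})

    def match(self, verbatim: str) -> list[tuple[str, str]]:
        """All (class, generic) pairs matching a verbatim drug name."""
        norm = normalize_name(verbatim)
        hits: dict[tuple[str, str], None] = {}
        exact = self._lookup.get(norm)
        if exact is not None:
            hits[(exact.drug_class, exact.generic)] = None
        for pattern, entry, _name in self._word_patterns:
            if pattern.search(norm):
                hits[(entry.drug_class, entry.generic)] = None
        return list(hits)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugDictionary":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "DrugDictionary":
        entries = []
        for drug_class, drugs in raw["classes"].items():
            for generic, spec in drugs.items():
                spec = spec or {}
                entries.append(
                    DictionaryEntry(
                        drug_class=str(drug_class),
                        generic=str(generic).upper(),
                        brands=tuple(str(b).upper() for b in spec.get("brands", [])),
                        match_mode=spec.get("match_mode", "word"),
                    )
                )
        return cls(entries=entries)


def default_dictionary() -> DrugDictionary:
    """The dictionary shipped with the package (user-replaceable YAML)."""
    ref = resources.files("faerspv.data") / "drug_dictionary.yaml"
    return DrugDictionary.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


def classify_drugs(
    drug: pd.DataFrame,
    dictionary: DrugDictionary,
    role_filter: frozenset[str] | set[str] | None = frozenset({"PS"}),
) -> pd.DataFrame:
    """Classify every drug row against the dictionary.

    Returns one row per (report drug row x matched generic) with columns
    ``primaryid, drug_seq, role_cod, drug_class, generic``. With
    ``role_filter={"PS"}`` only primary-suspect rows yield assignments —
    reports whose only target-class entries are SS/C/I contribute none.
    Matching is deterministic and order-independent: unique verbatim names
    are matched once and merged back.
    """
    df = drug.copy()
    df["role_cod"] = df["role_cod"].str.strip().str.upper()
    if role_filter is not None:
        df = df[df["role_cod"].isin(set(role_filter))]
    if df.empty:
        return pd.DataFrame(
            {c: pd.Series(dtype=str) for c in ("primaryid", "drug_seq", "role_cod", "drug_class", "generic")}
        )
    unique_names = pd.unique(df["drugname"])
    matches = {name: dictionary.match(name) for name in unique_names}
    if "drug_seq" not in df.columns:
        df["drug_seq"] = ""
    df = df[["primaryid", "drug_seq", "role_cod", "drugname"]].copy()
    df["_match"] = df["drugname"].map(matches)
    df = df[df["_match"].str.len() > 0].explode("_match", ignore_index=True)
    if df.empty:
        return pd.DataFrame(
            {c: pd.Series(dtype=str) for c in ("primaryid", "drug_seq", "role_cod", "drug_class", "generic")}
        )
    df[["drug_class", "generic"]] = pd.DataFrame(df["_match"].tolist(), index=df.index)
    out = df[["primaryid", "drug_seq", "role_cod", "drug_class", "generic"]]
    return out.sort_values(["primaryid", "drug_seq", "drug_class", "generic"]).reset_index(drop=True)


def attach_caseids(assignments: pd.DataFrame, demo: pd.DataFrame) -> pd.DataFrame:
    """Add the caseid of each report to an assignment table."""
    key = demo.set_index("primaryid")["caseid"]
    out = assignments.copy()
    out["caseid"] = out["primaryid"].map(key)
    return out
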