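"""Event-term selection and drug-name consolidation.

Adverse events arrive coded as preferred terms (PTs); the target
condition is selected through a user-supplied standardized-query term
list (an SMQ-style set, narrow scope recommended).  No licensed
terminology ships with the package: term sets and drug synonym tables
are plain tabular files the user provides.

Matching is exact after normalization (trim + casefold for PTs; trim +
lowercase + punctuation folding for drug names).  No fuzzy matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "TermSet",
    "DrugSynonymTable",
    "flag_target_events",
    "normalize_drugs",
    "normalize_term",
    "normalize_drug_name",
]

DRUG_CLASSES = ("hormonal", "oncological", "ophthalmic", "nervous system", "other")

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s]")


class ConfigurationError(ValueError):
    pass


def normalize_term(term: str) -> str:
    """Trim and casefold a preferred term for exact matching."""
    return _WS.sub(" ", str(term).strip()).casefold()


def normalize_drug_name(name: str) -> str:
    """Lowercase, fold punctuation to spaces, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", str(name).lower())).strip()


@dataclass(frozen=True)
class TermSet:
    """A named set of preferred terms with a scope (narrow or broad)."""

    name: str
    scope: str
    terms: frozenset[str]  # normalized

    @classmethod
    def from_terms(cls, name: str, scope: str, terms: Iterable[str]) -> "TermSet":
        norm = frozenset(normalize_term(t) for t in terms if str(t).strip())
        if not norm:
            raise ConfigurationError(f"term set {name!r} is empty")
        if scope not in ("narrow", "broad"):
            raise ConfigurationError(f"term set scope must be narrow or broad, got {scope!r}")
        return cls(name=name, scope=scope, terms=norm)

    @classmethod
    def from_file(cls, path: str | Path, *, delimiter: str = "\t") -> "TermSet":
        """Read a term set from a tabular file.

        Columns: ``pt`` (required), ``smq`` and ``scope`` (optional;
        defaults: file stem, narrow).  One row per preferred term.
        """
        path = Path(path)
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        if "pt" not in df.columns:
            raise ConfigurationError(f"{path}: term file needs a 'pt' column")
        name = df["smq"].iloc[0] if "smq" in df.columns and len(df) else path.stem
        scope = df["scope"].iloc[0] if "scope" in df.columns and len(df) else "narrow"
        return cls.from_terms(name, scope, df["pt"])

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def flag_target_events(events: pd.DataFrame, terms: TermSet) -> set[str]:
    """Record ids of reports containing at least one target PT.

    Counting is report-level: a report with three matching PTs is
    flagged once.  A broad-scope set is accepted with a warning (narrow
    scope is the high-specificity convention for signal detection).
    """
    if len(terms) == 0:
        raise ConfigurationError("empty term set")
    if terms.scope != "narrow":
        logger.warning("term set %r has scope %r; narrow scope is recommended",
                       terms.name, terms.scope)
    norm = events["pt"].map(normalize_term)
    return set(events.loc[norm.isin(terms.terms), "record_id"])


@dataclass(frozen=True)
class DrugSynonymTable:
    """Many-to-one verbatim-name -> (generic, therapeutic class) mapping."""

    mapping: Mapping[str, str]          # normalized verbatim -> generic
    classes: Mapping[str, str] = field(default_factory=dict)  # generic -> class

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in DRUG_CLASSES}
        if bad:
            raise ConfigurationError(
                f"unknown therapeutic classes {sorted(bad)}; allowed: {DRUG_CLASSES}"
            )

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "DrugSynonymTable":
        """Rows of (verbatim, generic, drug_class)."""
        mapping: dict[str, str] = {}
        classes: dict[str, str] = {}
        for verbatim, generic, drug_class in rows:
            mapping[normalize_drug_name(verbatim)] = generic
            mapping.setdefault(normalize_drug_name(generic), generic)
            if drug_class:
                classes[generic] = drug_class
        if not mapping:
            raise ConfigurationError("drug synonym table is empty")
        return cls(mapping=mapping, classes=classes)

    @classmethod
    def from_file(cls, path: str | Path, *, delimiter: str = "\t") -> "DrugSynonymTable":
        """Read a synonym table: columns ``verbatim``, ``generic``, ``drug_class``."""
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        for col in ("verbatim", "generic"):
            if col not in df.columns:
                raise ConfigurationError(f"{path}: synonym file needs a {col!r} column")
        if "drug_class" not in df.columns:
            df["drug_class"] = ""
        return cls.from_rows(df[["verbatim", "generic", "drug_class"]].itertuples(index=False))

    @classmethod
    def from_vocab(cls, drug_vocab) -> "DrugSynonymTable":
        """Build from a generator drug vocabulary (DrugSpec sequence)."""
        rows = []
        for spec in drug_vocab:
            rows.append((spec.generic, spec.generic, spec.drug_class))
            for brand in spec.brands:
                rows.append((brand, spec.generic, spec.drug_class))
        return cls.from_rows(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (v, g, self.classes.get(g, ""))
                for v, g in sorted(self.mapping.items())
            ],
            columns=["verbatim", "generic", "drug_class"],
        )


def normalize_drugs(
    exposures: pd.DataFrame, synonyms: DrugSynonymTable
) -> tuple[pd.DataFrame, int]:
    """Add ``generic`` and ``drug_class`` columns to a drug-exposure frame.

    Verbatim names are matched case-insensitively after trimming and
    punctuation folding; unmatched names pass through verbatim (trimmed)
    and are tallied in the returned count.  Never increases the number
    of distinct names.
    """
    out = exposures.copy()
    norm = out["verbatim"].map(normalize_drug_name)
    mapped = norm.map(dict(synonyms.mapping))
    unmatched = mapped.isna()
    n_unmapped = int(unmatched.sum())
    if n_unmapped:
        logger.info("%d drug mentions left unmapped by the synonym table", n_unmapped)
    out["generic"] = mapped.where(~unmatched, out["verbatim"].str.strip())
    out["drug_class"] = out["generic"].map(dict(synonyms.classes))
    return out, n_unmapped
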