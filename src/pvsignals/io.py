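"""Reading, writing and cleaning FAERS-dialect quarterly tables.

The dialect is the FDA quarterly ASCII layout: ``$``-delimited text, one
header row, UTF-8, one file per table.  Four tables are used here:

``DEMO``
    one row per report version: record id (PRIMARYID analogue), case id
    (CASEID analogue), receipt date (FDA_DT analogue), event date, age
    with unit code, sex, weight, country, reporter occupation code.
``DRUG``
    one row per drug mention: record id, drug sequence number, verbatim
    drug name, role code (PS/SS/C/I), route, indication.
``REAC``
    one row per reported preferred term.
``THER``
    therapy start date per drug sequence number.

Dates are 8-digit ``YYYYMMDD`` integers; partial dates (``YYYYMM`` or
``YYYY``) occur and are kept, sorted at reduced precision, and usable
for interval arithmetic only at month precision or better (day imputed
as 15).
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FaersTables",
    "FormatError",
    "read_tables",
    "write_tables",
    "harmonize",
    "harmonize_age",
    "harmonize_ages",
    "deduplicate",
    "filter_reporters",
    "date_sort_key",
    "parse_partial_date",
    "REPORTER_CATEGORIES",
]


class FormatError(ValueError):
    """A table file does not conform to the expected dialect."""


DEMO_COLUMNS = [
    "primaryid", "caseid", "fda_dt", "event_dt",
    "age", "age_cod", "sex", "wt", "reporter_country", "occp_cod",
]
DRUG_COLUMNS = ["primaryid", "drug_seq", "drugname", "role_cod", "route", "indi_pt"]
REAC_COLUMNS = ["primaryid", "pt"]
THER_COLUMNS = ["primaryid", "drug_seq", "start_dt"]

_TABLE_COLUMNS = {
    "demo": DEMO_COLUMNS,
    "drug": DRUG_COLUMNS,
    "reac": REAC_COLUMNS,
    "ther": THER_COLUMNS,
}

REPORTER_CATEGORIES = (
    "physician",
    "pharmacist",
    "other-health-professional",
    "consumer",
    "unknown",
)

# FAERS occupation codes -> reporter category
_OCCP_MAP = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other-health-professional",
    "HP": "other-health-professional",
    "CN": "consumer",
    "LW": "consumer",
}

_SEX_MAP = {"F": "female", "M": "male"}

_ROLE_MAP = {
    "PS": "suspect",
    "SS": "suspect",
    "C": "concomitant",
    "I": "interacting",
}

# age unit code -> factor to years
_AGE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (24.0 * 365.25),
}

AGE_MAX_YEARS = 120.0


@dataclass
class FaersTables:
    """The four raw tables of one extract, plus per-file malformed-row tallies."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    malformed: dict[str, int] = field(default_factory=dict)

    def copy(self) -> "FaersTables":
        return FaersTables(
            self.demo.copy(), self.drug.copy(), self.reac.copy(), self.ther.copy(),
            dict(self.malformed),
        )


def _read_one(path: str | Path, name: str, delimiter: str) -> tuple[pd.DataFrame, int]:
    # field counts are validated row by row (a dataframe reader would
    # coerce over/under-wide rows into an index or NaN padding instead
    # of rejecting them, and the malformed tally is part of the contract)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{name} table file not found: {path}")
    expected = _TABLE_COLUMNS[name]
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header row") from None
        cols = [c.strip().lower() for c in header]
        for col in expected:
            if col not in cols:
                raise FormatError(
                    f"{path}: missing mandatory column {col!r} in {name} table"
                )
        idx = [cols.index(c) for c in expected]
        width = len(cols)
        rows: list[list[str]] = []
        bad = 0
        for row in reader:
            if not row:
                continue
            if len(row) != width:
                bad += 1
                continue
            rows.append([row[i] for i in idx])
    df = pd.DataFrame(rows, columns=expected, dtype=object)
    return df, bad


def read_tables(
    demo: str | Path,
    drug: str | Path,
    reac: str | Path,
    ther: str | Path,
    *,
    delimiter: str = "$",
) -> FaersTables:
    """Read one extract; malformed rows are counted and dropped, never silent.

    Raises :class:`FormatError` naming the file and column when a
    mandatory column is absent.
    """
    out = {}
    malformed = {}
    for name, path in (("demo", demo), ("drug", drug), ("reac", reac), ("ther", ther)):
        out[name], malformed[name] = _read_one(path, name, delimiter)
        if malformed[name]:
            logger.warning("%s: %d malformed rows dropped", path, malformed[name])
    return FaersTables(out["demo"], out["drug"], out["reac"], out["ther"], malformed)


def write_tables(tables: FaersTables, directory: str | Path, *, delimiter: str = "$") -> dict[str, Path]:
    """Write the four tables as ``<dir>/{demo,drug,reac,ther}.txt``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("demo", "drug", "reac", "ther"):
        p = directory / f"{name}.txt"
        getattr(tables, name).to_csv(p, sep=delimiter, index=False)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# dates
# ---------------------------------------------------------------------------

_DIGITS = re.compile(r"\D")


def date_sort_key(raw: str | float | None) -> str:
    """Sortable 8-character key for a possibly partial FAERS date.

    Full dates sort naturally; ``YYYYMM`` pads with ``00`` so a partial
    month sorts before every full date in that month; unparseable dates
    map to the empty string and sort first.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ""
    s = _DIGITS.sub("", str(raw).strip())
    if len(s) == 8 or len(s) == 6 or len(s) == 4:
        return s.ljust(8, "0")
    return ""


def parse_partial_date(raw: str | float | None, *, impute_day: int = 15) -> pd.Timestamp | None:
    """Parse a FAERS date at month precision or better; else ``None``.

    ``YYYYMM`` dates get ``impute_day`` as the day; 4-digit year-only
    dates are insufficient for interval arithmetic and return ``None``.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = _DIGITS.sub("", str(raw).strip())
    try:
        if len(s) == 8:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), impute_day)
    except ValueError:
        return None
    return None


# ---------------------------------------------------------------------------
# age harmonization
# ---------------------------------------------------------------------------


def harmonize_age(value: float | str | None, unit: str | None) -> float:
    """Convert an (age, unit-code) pair to years; NaN when unusable.

    Unit codes follow FAERS ``AGE_COD``: YR, DEC, MON, WK, DY, HR.
    Values harmonizing outside [0, 120] years, unknown units and
    unparseable values all become NaN (missing), never an exception.
    """
    try:
        v = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return math.nan
    if not math.isfinite(v):
        return math.nan
    factor = _AGE_FACTORS.get((unit or "").strip().upper())
    if factor is None:
        return math.nan
    years = v * factor
    if years < 0 or years > AGE_MAX_YEARS:
        return math.nan
    return years


def harmonize_ages(values: pd.Series, units: pd.Series) -> tuple[pd.Series, dict[str, int]]:
    """Vector form of :func:`harmonize_age` with reason tallies."""
    counts = {"missing": 0, "unknown_unit": 0, "out_of_range": 0}
    out = []
    for v, u in zip(values, units):
        vs = str(v).strip() if v is not None else ""
        if vs == "" or vs.lower() == "nan":
            counts["missing"] += 1
            out.append(math.nan)
            continue
        factor = _AGE_FACTORS.get(str(u).strip().upper())
        if factor is None:
            counts["unknown_unit"] += 1
            out.append(math.nan)
            continue
        y = harmonize_age(vs, u)
        if math.isnan(y):
            counts["out_of_range"] += 1
        out.append(y)
    return pd.Series(out, index=values.index, dtype=float), counts


# ---------------------------------------------------------------------------
# harmonized record frames
# ---------------------------------------------------------------------------


def harmonize(tables: FaersTables) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Turn raw tables into typed report / drug-exposure / event frames.

    Returns ``(reports, exposures, events)``:

    * ``reports``: record_id, case_id, receipt_date (raw), event_date
      (raw), age (years), sex, weight, country, reporter.
    * ``exposures``: record_id, drug_seq, verbatim, role, route,
      indication, start_date (raw, joined from THER).
    * ``events``: record_id, pt (blank PTs dropped).
    """
    demo = tables.demo
    ages, _ = harmonize_ages(demo["age"], demo["age_cod"])
    reports = pd.DataFrame(
        {
            "record_id": demo["primaryid"].str.strip(),
            "case_id": demo["caseid"].str.strip(),
            "receipt_date": demo["fda_dt"].str.strip(),
            "event_date": demo["event_dt"].str.strip(),
            "age": ages,
            "sex": demo["sex"].str.strip().str.upper().map(_SEX_MAP).fillna("unknown"),
            "weight": pd.to_numeric(demo["wt"], errors="coerce"),
            "country": demo["reporter_country"].str.strip(),
            "reporter": demo["occp_cod"].str.strip().str.upper().map(_OCCP_MAP).fillna("unknown"),
        }
    )

    drug = tables.drug
    exposures = pd.DataFrame(
        {
            "record_id": drug["primaryid"].str.strip(),
            "drug_seq": drug["drug_seq"].str.strip(),
            "verbatim": drug["drugname"].str.strip(),
            "role": drug["role_cod"].str.strip().str.upper().map(_ROLE_MAP).fillna("unknown"),
            "route": drug["route"].str.strip(),
            "indication": drug["indi_pt"].str.strip(),
        }
    )
    ther = tables.ther.copy()
    ther["primaryid"] = ther["primaryid"].str.strip()
    ther["drug_seq"] = ther["drug_seq"].str.strip()
    exposures = exposures.merge(
        ther.rename(columns={"primaryid": "record_id", "start_dt": "start_date"}),
        on=["record_id", "drug_seq"],
        how="left",
    )
    exposures["start_date"] = exposures["start_date"].fillna("")

    pts = tables.reac["pt"].str.strip()
    events = pd.DataFrame(
        {"record_id": tables.reac["primaryid"].str.strip(), "pt": pts}
    ).loc[pts != ""]
    events = events.reset_index(drop=True)
    return reports, exposures, events


# ---------------------------------------------------------------------------
# inclusion rules
# ---------------------------------------------------------------------------


def deduplicate(reports: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per case: most recent receipt date, then highest record id.

    This is the FDA deduplication convention for spontaneous reports
    organized by record id (PRIMARYID), case id (CASEID) and receipt
    date (FDA_DT): among versions sharing a case id, the record with the
    most recent receipt date is retained, ties broken by the numerically
    (fallback: lexicographically) highest record id.  Unparseable dates
    sort first, so they are retained only when alone.  Idempotent.
    """
    if reports.empty:
        return reports.copy()
    df = reports.copy()
    df["_date_key"] = df["receipt_date"].map(date_sort_key)
    num = pd.to_numeric(df["record_id"], errors="coerce")
    df["_num_key"] = num.fillna(-1.0)
    df["_str_key"] = df["record_id"].astype(str)
    df = df.sort_values(
        ["case_id", "_date_key", "_num_key", "_str_key"], kind="mergesort"
    )
    df = df.groupby("case_id", sort=False).tail(1)
    df = df.drop(columns=["_date_key", "_num_key", "_str_key"])
    return df.sort_index()


def filter_reporters(reports: pd.DataFrame, allowed: set[str] | list[str]) -> pd.DataFrame:
    """Keep reports whose reporter category is in ``allowed``.

    Category names are the harmonized ones in :data:`REPORTER_CATEGORIES`.
    """
    allowed = set(allowed)
    unknown = allowed - set(REPORTER_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown reporter categories: {sorted(unknown)}")
    return reports.loc[reports["reporter"].isin(allowed)].copy()
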