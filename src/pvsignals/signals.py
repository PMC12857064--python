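"""Positive-signal criteria, strength classification and result ranking.

A drug-event pair is a *positive signal* when (by default) all four
algorithms agree:

* ROR  >= 3 and its 95% CI lower bound > 1
* PRR  >= 3 and its 95% CI lower bound > 1
* BCPNN: IC025 > 0
* MGPS:  EBGM05 > 2 and a > 0

preceded by a minimum-case filter (a >= 3 by default: pairs reported
fewer than three times are never scored as signals).  Positive signals
are banded by strength on the configured IC field: weak (0, 1.5],
medium (1.5, 3], strong (> 3].

Two points are deliberately configurable because published practice is
inconsistent: (i) some result tables state the ROR/PRR inclusion rule
as a case threshold ("a >= 3 and CI > 1") rather than a point
threshold — both are expressible here via ``min_cases`` and the point
thresholds; (ii) strength may be banded on the IC credibility lower
bound (the stated definition, the default) or on the IC point estimate
(the ``ic_point_compat`` preset, which matches how some published tables
band in practice).
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "SignalCriteria",
    "apply_min_case_filter",
    "evaluate",
    "rank_and_annotate",
    "SIGNALS_COLUMN_ORDER",
]

SIGNALS_COLUMN_ORDER = [
    "drug", "drug_class", "a",
    "ror", "ror_ci_low", "ror_ci_high",
    "prr", "prr_ci_low", "prr_ci_high",
    "chi2", "p_value",
    "ebgm", "ebgm05", "ic", "ic025",
    "positive", "strength",
]


class SignalCriteria(BaseModel):
    """Thresholds and combination rule for the four-algorithm screen."""

    min_cases: int = Field(ge=0, default=3)
    ror_point: float = Field(gt=0.0, default=3.0)
    prr_point: float = Field(gt=0.0, default=3.0)
    ci_low_threshold: float = Field(gt=0.0, default=1.0)
    ic025_threshold: float = 0.0
    ebgm05_threshold: float = Field(gt=0.0, default=2.0)
    combination: Literal["all"] | int = "all"
    strength_field: Literal["ic025", "ic"] = "ic025"
    weak_max: float = Field(gt=0.0, default=1.5)
    medium_max: float = Field(gt=0.0, default=3.0)

    @model_validator(mode="after")
    def _bands_ordered(self) -> "SignalCriteria":
        if not self.weak_max < self.medium_max:
            raise ValueError("strength bands must satisfy weak_max < medium_max")
        if isinstance(self.combination, int) and not 1 <= self.combination <= 4:
            raise ValueError("combination any-k requires 1 <= k <= 4")
        return self

    @classmethod
    def ic_point_compat(cls, **overrides) -> "SignalCriteria":
        """Preset banding strength on the IC point estimate."""
        overrides.setdefault("strength_field", "ic")
        return cls(**overrides)


def apply_min_case_filter(
    tables: pd.DataFrame, min_cases: int = 3
) -> tuple[pd.DataFrame, int]:
    """Drop pairs with fewer than ``min_cases`` co-reports (cell a).

    Returns the surviving frame and the number of pairs removed.
    """
    keep = tables["a"] >= min_cases
    removed = int((~keep).sum())
    if removed:
        logger.info("minimum-case filter removed %d of %d pairs", removed, len(tables))
    return tables.loc[keep].copy(), removed


def evaluate(results: pd.DataFrame, criteria: SignalCriteria | None = None) -> pd.DataFrame:
    """Apply the four positive-signal rules and band signal strength.

    ``results`` must carry the scored-statistic columns (``a``, ``ror``,
    ``ror_ci_low``, ``prr``, ``prr_ci_low``, ``ic025``, ``ebgm05`` and
    the strength field).  Adds per-rule boolean columns, ``positive``
    and ``strength`` (weak/medium/strong for positives, else none).
    NaN statistics fail their rule.
    """
    criteria = criteria or SignalCriteria()
    out = results.copy()
    out["ror_rule"] = (
        (out["ror"] >= criteria.ror_point)
        & (out["ror_ci_low"] > criteria.ci_low_threshold)
    ).fillna(False)
    out["prr_rule"] = (
        (out["prr"] >= criteria.prr_point)
        & (out["prr_ci_low"] > criteria.ci_low_threshold)
    ).fillna(False)
    out["bcpnn_rule"] = (out["ic025"] > criteria.ic025_threshold).fillna(False)
    out["mgps_rule"] = (
        (out["ebgm05"] > criteria.ebgm05_threshold) & (out["a"] > 0)
    ).fillna(False)

    n_rules = (
        out[["ror_rule", "prr_rule", "bcpnn_rule", "mgps_rule"]].sum(axis=1)
    )
    need = 4 if criteria.combination == "all" else int(criteria.combination)
    out["positive"] = n_rules >= need

    s = out[criteria.strength_field]
    strength = np.select(
        [
            out["positive"] & (s > criteria.medium_max),
            out["positive"] & (s > criteria.weak_max),
            out["positive"] & (s > 0),
        ],
        ["strong", "medium", "weak"],
        default="none",
    )
    out["strength"] = strength
    return out


def rank_and_annotate(
    evaluated: pd.DataFrame,
    classes: Mapping[str, str] | pd.Series | None = None,
    *,
    sort_by: str = "ror",
) -> pd.DataFrame:
    """Attach therapeutic classes and sort deterministically.

    Ordering: chosen statistic descending, drug name ascending on ties.
    Drugs absent from the class annotation get class ``other`` with a
    warning.
    """
    out = evaluated.copy()
    if "drug_class" not in out.columns or classes is not None:
        mapping = dict(classes) if classes is not None else {}
        cls = out.index.to_series().map(mapping)
        missing = cls.isna() | (cls == "")
        if missing.any():
            logger.warning(
                "no class annotation for %d drugs (set to 'other'): %s",
                int(missing.sum()), ", ".join(sorted(out.index[missing])[:10]),
            )
        out["drug_class"] = cls.where(~missing, "other")
    else:
        miss = out["drug_class"].isna() | (out["drug_class"] == "")
        if miss.any():
            logger.warning("no class annotation for %d drugs (set to 'other')", int(miss.sum()))
        out["drug_class"] = out["drug_class"].where(~miss, "other")
    out = out.sort_index(kind="mergesort")
    out = out.sort_values(sort_by, ascending=False, kind="mergesort")
    return out
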