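"""Disproportionality statistics for 2x2 drug-event contingency tables.

A spontaneous-report database is summarised, for one drug-event pair, by
the four-cell table

    =============  =============  =================
    .              target event   all other events
    =============  =============  =================
    target drug    a              b
    other drugs    c              d
    =============  =============  =================

with ``N = a + b + c + d`` deduplicated reports.  Four statistics are in
routine pharmacovigilance use and all are computed here:

ROR
    Reporting odds ratio ``(a*d)/(b*c)`` with the Woolf (log-normal) 95%
    confidence interval ``exp(ln ROR ± 1.96*sqrt(1/a + 1/b + 1/c + 1/d))``.
PRR
    Proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with interval
    ``exp(ln PRR ± 1.96*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``, reported
    together with the Pearson chi-square statistic (1 df, no continuity
    correction) and its p-value.
IC (BCPNN)
    Information component ``log2(a*N / ((a+b)*(a+c)))``, the log2
    observed-to-expected ratio.  The lower credibility bound ``IC025`` is
    ``E(IC) - 2*sqrt(V(IC))`` under the Bayesian confidence-propagation
    model with Dirichlet/beta priors ``alpha1 = beta1 = 1``,
    ``alpha = beta = 2``, ``gamma11 = 1``.
EBGM (MGPS point form)
    Relative reporting ratio ``a*N / ((a+b)*(a+c))`` with the one-sided
    95% log-normal lower bound
    ``EBGM05 = exp(ln EBGM - 1.64*sqrt(1/a + 1/b + 1/c + 1/d))``.
    Note ``IC == log2(EBGM)`` identically; no Bayesian shrinkage is
    applied (the full gamma-Poisson mixture is out of scope).

All quantities are evaluated in log space so they remain stable at the
scale of a full spontaneous-report database (N ~ 10^7, d >> a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "ror",
    "prr",
    "bcpnn_ic",
    "ebgm",
    "score_table",
    "build_contingency",
    "contingency_by_drug",
    "reconstruct_table",
    "results_frame",
]

# interval multipliers as conventionally printed (two-sided 95%; one-sided 95%)
Z_TWO_SIDED = 1.96
Z_ONE_SIDED = 1.64

# BCPNN hyperparameters (uniform pairwise prior)
_ALPHA1 = 1.0
_BETA1 = 1.0
_ALPHA = 2.0
_BETA = 2.0
_GAMMA11 = 1.0

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cell counts for one drug-event pair.

    Cells may be floats (continuity-corrected or algebraically
    reconstructed tables are not integral).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = float(getattr(self, name))  # also guards integer overflow downstream
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"cell {name} must be finite and >= 0, got {v!r}")
            object.__setattr__(self, name, v)
        if self.n < 1:
            raise ValueError("table total N must be >= 1")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> float:
        """Reports mentioning the target drug (a+b)."""
        return self.a + self.b

    @property
    def event_total(self) -> float:
        """Reports mentioning the target event (a+c)."""
        return self.a + self.c

    def with_continuity(self, k: float = 0.5) -> "ContingencyTable":
        """Return a copy with ``k`` added to every cell (Haldane-style)."""
        return ContingencyTable(self.a + k, self.b + k, self.c + k, self.d + k)


@dataclass(frozen=True)
class SignalResult:
    """All four disproportionality statistics for one table.

    ``estimable`` is False when any statistic could not be computed from
    the raw cells (zero cells without continuity correction); the
    affected fields are NaN rather than raised.
    """

    a: float
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    prr_ci_low: float
    prr_ci_high: float
    chi2: float
    p_value: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    estimable: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "a": self.a,
            "ror": self.ror,
            "ror_ci_low": self.ror_ci_low,
            "ror_ci_high": self.ror_ci_high,
            "prr": self.prr,
            "prr_ci_low": self.prr_ci_low,
            "prr_ci_high": self.prr_ci_high,
            "chi2": self.chi2,
            "p_value": self.p_value,
            "ic": self.ic,
            "ic025": self.ic025,
            "ebgm": self.ebgm,
            "ebgm05": self.ebgm05,
            "estimable": self.estimable,
        }


_NAN3 = (math.nan, math.nan, math.nan)


def ror(table: ContingencyTable, *, continuity: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI.

    Returns ``(point, ci_low, ci_high)``; NaNs when any cell is zero and
    ``continuity`` is off (the ratio is then not estimable).
    """
    t = table.with_continuity() if continuity else table
    if min(t.a, t.b, t.c, t.d) <= 0:
        return _NAN3
    ln_ror = math.log(t.a) + math.log(t.d) - math.log(t.b) - math.log(t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (
        math.exp(ln_ror),
        math.exp(ln_ror - Z_TWO_SIDED * se),
        math.exp(ln_ror + Z_TWO_SIDED * se),
    )


def prr(
    table: ContingencyTable, *, continuity: bool = False
) -> tuple[float, float, float, float, float]:
    """Proportional reporting ratio with 95% CI, chi-square and p-value.

    Returns ``(point, ci_low, ci_high, chi2, p)``.  The chi-square is the
    Pearson statistic ``N*(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` on 1 df,
    without Yates continuity correction.  The point requires ``a > 0``
    and ``c > 0``; the interval additionally tolerates ``b = 0`` or
    ``d = 0`` (those cells enter only through the margins).
    """
    t = table.with_continuity() if continuity else table
    chi2, p = _pearson_chi2(t)
    if t.a <= 0 or t.c <= 0 or t.drug_total <= 0 or (t.c + t.d) <= 0:
        return math.nan, math.nan, math.nan, chi2, p
    ln_prr = (
        math.log(t.a) - math.log(t.drug_total) - math.log(t.c) + math.log(t.c + t.d)
    )
    var = 1 / t.a - 1 / t.drug_total + 1 / t.c - 1 / (t.c + t.d)
    se = math.sqrt(max(var, 0.0))
    return (
        math.exp(ln_prr),
        math.exp(ln_prr - Z_TWO_SIDED * se),
        math.exp(ln_prr + Z_TWO_SIDED * se),
        chi2,
        p,
    )


def _pearson_chi2(t: ContingencyTable) -> tuple[float, float]:
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if min(margins) <= 0:
        return math.nan, math.nan
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    chi2 = num / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(_st.chi2.sf(chi2, df=1))
    return chi2, p


def bcpnn_ic(
    table: ContingencyTable,
    *,
    method: str = "bate",
    fixed_offset: float = 1.67,
) -> tuple[float, float]:
    """Information component point estimate and lower credibility bound.

    The point estimate is the plain log2 observed/expected ratio
    ``log2(a*N / ((a+b)*(a+c)))``.

    ``method`` selects the lower bound:

    ``"bate"`` (default)
        ``E(IC) - 2*sqrt(V(IC))`` from the closed-form posterior
        expectation and variance of the confidence-propagation model with
        priors ``alpha1 = beta1 = 1``, ``alpha = beta = 2``,
        ``gamma11 = 1``.
    ``"fixed_offset"``
        ``ic - fixed_offset``; a compatibility mode for published result
        tables whose IC intervals are a constant width around the point.

    Returns ``(ic, ic025)``; NaNs when ``a = 0`` or a margin is zero.
    """
    a, n = table.a, table.n
    m_drug, m_event = table.drug_total, table.event_total
    if a <= 0 or m_drug <= 0 or m_event <= 0:
        return math.nan, math.nan
    ic = (math.log(a) + math.log(n) - math.log(m_drug) - math.log(m_event)) / _LN2
    if method == "fixed_offset":
        return ic, ic - fixed_offset
    if method != "bate":
        raise ValueError(f"unknown IC method {method!r}")

    gamma = _GAMMA11 * (n + _ALPHA) * (n + _BETA) / ((m_drug + _ALPHA1) * (m_event + _BETA1))
    e_ic = (
        math.log(a + _GAMMA11)
        + math.log(n + _ALPHA)
        + math.log(n + _BETA)
        - math.log(n + gamma)
        - math.log(m_drug + _ALPHA1)
        - math.log(m_event + _BETA1)
    ) / _LN2
    v_ic = (
        (n - a + gamma - _GAMMA11) / ((a + _GAMMA11) * (1 + n + gamma))
        + (n - m_drug + _ALPHA - _ALPHA1) / ((m_drug + _ALPHA1) * (1 + n + _ALPHA))
        + (n - m_event + _BETA - _BETA1) / ((m_event + _BETA1) * (1 + n + _BETA))
    ) / (_LN2**2)
    return ic, e_ic - 2.0 * math.sqrt(v_ic)


def ebgm(table: ContingencyTable) -> tuple[float, float]:
    """Relative reporting ratio (MGPS point form) and one-sided 95% bound.

    Returns ``(ebgm, ebgm05)``.  The point needs ``a > 0``; the bound
    additionally needs all four cells positive (symmetric four-cell
    variance on the log scale).
    """
    a, n = table.a, table.n
    m_drug, m_event = table.drug_total, table.event_total
    if a <= 0 or m_drug <= 0 or m_event <= 0:
        return math.nan, math.nan
    ln_ebgm = math.log(a) + math.log(n) - math.log(m_drug) - math.log(m_event)
    point = math.exp(ln_ebgm)
    if min(table.b, table.c, table.d) <= 0:
        return point, math.nan
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    return point, math.exp(ln_ebgm - Z_ONE_SIDED * se)


def score_table(
    table: ContingencyTable,
    *,
    ic_method: str = "bate",
    ic_fixed_offset: float = 1.67,
    continuity: bool = False,
) -> SignalResult:
    """Compute every statistic for one table; NaN-fill what is not estimable."""
    t = table.with_continuity() if continuity else table
    r = ror(t)
    p = prr(t)
    ic, ic025 = bcpnn_ic(t, method=ic_method, fixed_offset=ic_fixed_offset)
    e, e05 = ebgm(t)
    vals = (r[0], r[1], r[2], p[0], p[1], p[2], p[3], p[4], ic, ic025, e, e05)
    return SignalResult(
        a=table.a,
        ror=r[0],
        ror_ci_low=r[1],
        ror_ci_high=r[2],
        prr=p[0],
        prr_ci_low=p[1],
        prr_ci_high=p[2],
        chi2=p[3],
        p_value=p[4],
        ic=ic,
        ic025=ic025,
        ebgm=e,
        ebgm05=e05,
        estimable=all(math.isfinite(v) for v in vals),
    )


# ---------------------------------------------------------------------------
# contingency construction (report-level counting)
# ---------------------------------------------------------------------------


def build_contingency(
    exposures: pd.DataFrame,
    flagged: Iterable[str],
    drug: str,
    n_reports: int,
    *,
    drug_column: str = "generic",
) -> ContingencyTable:
    """Build the 2x2 table for one drug against the target-event flag.

    Counting is at report level: a report contributes at most 1 to any
    cell, however many role lines repeat the drug and however many target
    PTs it lists.

    Parameters
    ----------
    exposures
        Drug-mention table with columns ``record_id`` and ``drug_column``
        over the deduplicated report set.
    flagged
        Record ids of reports containing at least one target event.
    drug
        Normalized (generic) drug name of interest.
    n_reports
        Total number of deduplicated reports N (the table universe; it
        can exceed the number of reports with drug rows).
    """
    flagged_set = set(flagged)
    drug_reports = set(
        exposures.loc[exposures[drug_column] == drug, "record_id"].unique()
    )
    a = len(drug_reports & flagged_set)
    b = len(drug_reports) - a
    c = len(flagged_set) - a
    d = n_reports - a - b - c
    if d < 0:
        raise ValueError(
            "n_reports smaller than the union of drug and event reports; "
            "was the input deduplicated?"
        )
    return ContingencyTable(a, b, c, d)


def contingency_by_drug(
    exposures: pd.DataFrame,
    flagged: Iterable[str],
    n_reports: int,
    *,
    drug_column: str = "generic",
) -> pd.DataFrame:
    """Vectorised :func:`build_contingency` over every drug in ``exposures``.

    Returns a frame indexed by drug with columns ``a, b, c, d``.
    """
    pairs = exposures[["record_id", drug_column]].drop_duplicates()
    flagged_set = set(flagged)
    n_event = len(flagged_set)
    is_flagged = pairs["record_id"].isin(flagged_set)
    a = is_flagged.groupby(pairs[drug_column], sort=True).sum()
    total = pairs.groupby(drug_column, sort=True).size()
    out = pd.DataFrame({"a": a.astype(int), "b": (total - a).astype(int)})
    out["c"] = n_event - out["a"]
    out["d"] = n_reports - out["a"] - out["b"] - out["c"]
    out.index.name = "drug"
    if (out["d"] < 0).any():
        raise ValueError("n_reports inconsistent with per-drug report counts")
    return out


def results_frame(
    tables: pd.DataFrame | Mapping[str, ContingencyTable],
    *,
    ic_method: str = "bate",
    ic_fixed_offset: float = 1.67,
    continuity: bool = False,
) -> pd.DataFrame:
    """Score many tables; one row of :class:`SignalResult` fields per drug.

    ``tables`` is either the output of :func:`contingency_by_drug` or a
    mapping of name -> :class:`ContingencyTable`.
    """
    if isinstance(tables, pd.DataFrame):
        items = (
            (idx, ContingencyTable(row.a, row.b, row.c, row.d))
            for idx, row in tables.iterrows()
        )
    else:
        items = tables.items()
    rows = {
        name: score_table(
            t, ic_method=ic_method, ic_fixed_offset=ic_fixed_offset, continuity=continuity
        ).as_dict()
        for name, t in items
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "drug"
    return out


# ---------------------------------------------------------------------------
# algebraic table reconstruction from published report-level totals
# ---------------------------------------------------------------------------


def reconstruct_table(
    a: float,
    n_event: float,
    n_total: float,
    *,
    ror: float | None = None,
    prr: float | None = None,
    ebgm: float | None = None,
) -> ContingencyTable:
    """Recover a full 2x2 table from a published summary row.

    Published disproportionality tables rarely print the cell ``b``
    (reports with the drug but other events), yet it is determined by any
    one printed statistic once ``a`` (pair count), ``n_event = a + c``
    (all target-event reports) and ``n_total = N`` are known.  Exactly
    one of ``ror``, ``prr`` or ``ebgm`` must be given; the corresponding
    monomial equation is solved in closed form:

    * from EBGM: ``a + b = a*N / (n_event * EBGM)``
    * from PRR:  ``a + b = a*N / (PRR*c + a)`` with ``c = n_event - a``
    * from ROR:  ``b = a*(N - n_event) / (ROR*c + a)``

    The returned table has float cells (the solved margin is generally
    non-integral because the printed statistic is rounded).
    """
    anchors = {"ror": ror, "prr": prr, "ebgm": ebgm}
    given = {k: v for k, v in anchors.items() if v is not None}
    if len(given) != 1:
        raise ValueError("exactly one of ror=, prr=, ebgm= must be supplied")
    if a <= 0 or n_event < a or n_total < n_event:
        raise ValueError("need 0 < a <= n_event <= n_total")
    c = n_event - a
    (kind, value), = given.items()
    if value <= 0:
        raise ValueError(f"{kind} must be positive")
    if kind == "ebgm":
        drug_total = a * n_total / (n_event * value)
        b = drug_total - a
    elif kind == "prr":
        drug_total = a * n_total / (value * c + a)
        b = drug_total - a
    else:  # ror
        b = a * (n_total - n_event) / (value * c + a)
    if b < 0:
        raise ValueError("reconstruction gave b < 0; inputs inconsistent")
    d = n_total - n_event - b
    if d < 0:
        raise ValueError("reconstruction gave d < 0; inputs inconsistent")
    return ContingencyTable(float(a), float(b), float(c), float(d))
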