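"""Time-to-onset analysis and the multivariable covariate model.

Time to onset is the number of days from the earliest therapy start of
a report's suspect drug to the report's event date.  Both endpoints
must carry at least month precision (day imputed as 15 for
month-precision dates); negative or incomputable intervals are excluded
and tallied, never silently dropped.

Per-class summaries use linear-interpolation quartiles (the common
default in mainstream statistical software).  Classes are compared by
classical one-way fixed-effects ANOVA.  The covariate model is a
maximum-likelihood logistic regression of the target-event flag on
demographics, report metadata and per-drug indicator terms, with Wald
intervals exponentiated to odds ratios.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

from .io import parse_partial_date

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisError",
    "compute_onsets",
    "summarize_onsets",
    "cumulative_onset_curve",
    "anova_classes",
    "build_covariate_rows",
    "fit_logistic",
]


class AnalysisError(ValueError):
    pass


def compute_onsets(
    exposures: pd.DataFrame,
    reports: pd.DataFrame,
    flagged: Iterable[str],
    *,
    roles: Sequence[str] = ("suspect",),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One onset record per (flagged report, suspect drug) with a computable interval.

    Uses the earliest parseable therapy start among the drug's lines and
    the report's event date.  Returns ``(records, tally)`` where
    ``records`` has columns record_id, generic, drug_class, onset_days
    and ``tally`` counts exclusions by reason (``missing_start``,
    ``missing_event``, ``negative``).

    ``exposures`` must already be normalized (``generic`` and
    ``drug_class`` columns present).
    """
    tally = {"missing_start": 0, "missing_event": 0, "negative": 0}
    flagged = set(flagged)
    ev_date = (
        reports.loc[reports["record_id"].isin(flagged)]
        .set_index("record_id")["event_date"]
        .map(parse_partial_date)
    )

    sub = exposures.loc[
        exposures["record_id"].isin(flagged) & exposures["role"].isin(roles)
    ].copy()
    sub["start"] = sub["start_date"].map(parse_partial_date)
    # earliest start per (report, drug); a drug with no parseable start at all
    # on that report counts once as missing_start
    has_start = sub.dropna(subset=["start"])
    starts = has_start.groupby(["record_id", "generic"], sort=True)["start"].min()
    all_pairs = sub[["record_id", "generic", "drug_class"]].drop_duplicates()
    tally["missing_start"] = len(all_pairs) - len(starts)

    rows = []
    for (rid, generic), start in starts.items():
        event = ev_date.get(rid)
        if event is None or pd.isna(event):
            tally["missing_event"] += 1
            continue
        days = (event - start).days
        if days < 0:
            tally["negative"] += 1
            continue
        rows.append((rid, generic, days))
    records = pd.DataFrame(rows, columns=["record_id", "generic", "onset_days"])
    cls = all_pairs.set_index(["record_id", "generic"])["drug_class"]
    if len(records):
        records["drug_class"] = [
            cls.get((r, g)) for r, g in zip(records["record_id"], records["generic"])
        ]
    else:
        records["drug_class"] = pd.Series(dtype=object)
    records = records[["record_id", "generic", "drug_class", "onset_days"]]
    return records, tally


def summarize_onsets(
    records: pd.DataFrame, *, group: str = "drug_class", low_n: int = 3
) -> pd.DataFrame:
    """Per-group n, mean, sd, and linear-interpolation quartiles.

    Groups with fewer than ``low_n`` records are flagged ``low_n=True``.
    Empty input yields an empty summary.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["n", "mean", "sd", "q1", "median", "q3", "low_n"]
        )

    def _one(v: pd.Series) -> pd.Series:
        x = v.to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
        return pd.Series(
            {
                "n": len(x),
                "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                "q1": q1,
                "median": med,
                "q3": q3,
            }
        )

    out = records.groupby(group, sort=True)["onset_days"].apply(_one).unstack()
    out["n"] = out["n"].astype(int)
    out["low_n"] = out["n"] < low_n
    return out


def cumulative_onset_curve(records: pd.DataFrame, *, group: str = "drug_class") -> pd.DataFrame:
    """(group, day, cumulative report count) pairs for cumulative-onset plots."""
    rows = []
    for g, sub in records.groupby(group, sort=True):
        days = np.sort(sub["onset_days"].to_numpy())
        uniq, counts = np.unique(days, return_counts=True)
        cum = np.cumsum(counts)
        rows.extend((g, int(d), int(c)) for d, c in zip(uniq, cum))
    return pd.DataFrame(rows, columns=[group, "day", "cumulative_reports"])


def anova_classes(records: pd.DataFrame, *, group: str = "drug_class") -> dict[str, float]:
    """Classical one-way fixed-effects ANOVA of onset days across groups.

    Returns ``{"F", "df_between", "df_within", "p"}``.  Requires at
    least two groups with at least two records each.
    """
    groups = [
        sub["onset_days"].to_numpy(dtype=float)
        for _, sub in records.groupby(group, sort=True)
        if len(sub) >= 2
    ]
    if len(groups) < 2:
        raise AnalysisError(
            "one-way ANOVA needs >= 2 groups with >= 2 records each; "
            f"got {len(groups)} usable group(s)"
        )
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    grand = sum(g.sum() for g in groups) / n_total
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        # degenerate: constant within groups; equal means -> no evidence at all
        f = 0.0 if ssb == 0.0 else math.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(_st.f.sf(f, df_b, df_w))
    return {
        "F": float(f),
        "df_between": float(df_b),
        "df_within": float(df_w),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# covariate model
# ---------------------------------------------------------------------------

MISSING_LEVEL = "(missing)"


def build_covariate_rows(
    reports: pd.DataFrame,
    exposures: pd.DataFrame,
    flagged: Iterable[str],
    top_drugs: Sequence[str],
    *,
    categoricals: Sequence[str] = ("sex", "country", "reporter", "route", "indication"),
) -> pd.DataFrame:
    """One covariate row per deduplicated report.

    Columns: ``outcome`` (target-event flag), ``age`` (years; missing
    filled with the cohort median plus an ``age_missing`` indicator),
    the report-level categoricals (missing values as an explicit
    ``(missing)`` level), ``therapy_days`` (earliest suspect therapy
    start to receipt date, same missing treatment) and one 0/1 column
    ``drug_<name>`` per requested drug.

    Route and indication are taken from the report's primary-suspect
    drug line (first suspect line when several).
    """
    flagged = set(flagged)
    df = reports[["record_id", "age", "sex", "country", "reporter", "receipt_date"]].copy()
    df["outcome"] = df["record_id"].isin(flagged).astype(int)

    suspects = exposures.loc[exposures["role"] == "suspect"]
    first_suspect = suspects.drop_duplicates("record_id").set_index("record_id")
    df["route"] = df["record_id"].map(first_suspect["route"])
    df["indication"] = df["record_id"].map(first_suspect["indication"])

    starts = suspects.assign(_s=suspects["start_date"].map(parse_partial_date))
    start_min = starts.dropna(subset=["_s"]).groupby("record_id")["_s"].min()
    receipt = df["receipt_date"].map(parse_partial_date)
    therapy = (
        pd.Series(receipt.values, index=df["record_id"].values)
        - start_min.reindex(df["record_id"].values)
    ).dt.days
    df["therapy_days"] = therapy.values

    for col in categoricals:
        df[col] = df[col].astype(object).where(df[col].notna() & (df[col] != ""), MISSING_LEVEL)

    df["age_missing"] = df["age"].isna().astype(int)
    df["age"] = df["age"].fillna(df["age"].median())
    df["therapy_missing"] = df["therapy_days"].isna().astype(int)
    med = df["therapy_days"].median()
    df["therapy_days"] = df["therapy_days"].fillna(0.0 if pd.isna(med) else med)

    drug_reports = exposures.groupby("generic")["record_id"].agg(set)
    for name in top_drugs:
        rid_set = drug_reports.get(name, set())
        df[f"drug_{name}"] = df["record_id"].isin(rid_set).astype(int)

    return df.drop(columns=["receipt_date"]).set_index("record_id")


def fit_logistic(
    rows: pd.DataFrame,
    *,
    outcome: str = "outcome",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Maximum-likelihood logistic fit; one row per covariate term.

    Categorical covariates are dummy-coded against their most frequent
    level; continuous covariates enter as-is.  Returns a frame with
    ``coef``, ``or_``, ``or_ci_low``, ``or_ci_high``, ``p`` and an
    ``estimable`` flag (False where separation drove a coefficient to
    the boundary: the interval is reported as NaN rather than a
    meaningless number).  Frame ``attrs`` record convergence and the
    reference levels used.
    """
    y = rows[outcome].astype(float)
    if y.nunique() < 2:
        raise AnalysisError("outcome must contain both classes")
    X_parts = []
    references: dict[str, str] = {}
    for col in rows.columns:
        if col == outcome:
            continue
        s = rows[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            ref = s.value_counts().idxmax()
            references[col] = str(ref)
            levels = [lv for lv in s.value_counts().index if lv != ref]
            for lv in levels:
                X_parts.append(pd.Series((s == lv).astype(float), name=f"{col}[{lv}]"))
        else:
            X_parts.append(s.astype(float))
    X = pd.concat(X_parts, axis=1)
    # drop constant and duplicated columns so the design is full rank
    nunique = X.nunique()
    X = X.loc[:, nunique > 1]
    X = X.loc[:, ~X.T.duplicated()]
    X = sm.add_constant(X, has_constant="add")

    model = sm.Logit(y.to_numpy(), X.to_numpy())
    converged = True
    try:
        fit = model.fit(disp=0, maxiter=max_iter, tol=tol, method="newton")
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:  # singular matrix / separation: fall back to bfgs
        fit = model.fit(disp=0, maxiter=max_iter * 5, method="bfgs")
        converged = bool(fit.mle_retvals.get("converged", False))

    params = pd.Series(fit.params, index=X.columns)
    bse = pd.Series(fit.bse, index=X.columns)
    pvals = pd.Series(fit.pvalues, index=X.columns)
    separated = (params.abs() > 15) | ~np.isfinite(bse) | (bse > 1e3)
    if separated.any():
        logger.warning("possible separation for terms: %s",
                       ", ".join(X.columns[separated]))
    out = pd.DataFrame(
        {
            "coef": params,
            "or_": np.exp(params),
            "or_ci_low": np.exp(params - 1.96 * bse),
            "or_ci_high": np.exp(params + 1.96 * bse),
            "p": pvals,
            "estimable": ~separated,
        }
    )
    out.loc[separated, ["or_ci_low", "or_ci_high"]] = np.nan
    out.attrs["converged"] = converged
    out.attrs["references"] = references
    out.attrs["n"] = int(len(rows))
    return out
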