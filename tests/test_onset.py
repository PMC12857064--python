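"""Time-to-onset computation, summaries, ANOVA and the covariate model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as st

from pvsignals.onset import (
    AnalysisError,
    anova_classes,
    build_covariate_rows,
    compute_onsets,
    fit_logistic,
    summarize_onsets,
)
from pvsignals.synthetic import (
    DrugSpec,
    EventSpec,
    OnsetDist,
    SignalPair,
    SyntheticConfig,
    generate,
)
from pvsignals.io import harmonize
from pvsignals.terms import DrugSynonymTable, normalize_drugs


def _exposures(rows):
    return pd.DataFrame(
        rows, columns=["record_id", "generic", "drug_class", "role", "start_date"]
    )


def _reports(rows):
    return pd.DataFrame(rows, columns=["record_id", "event_date"])


class TestComputeOnsets:
    def test_simple_date_arithmetic(self):
        recs, tally = compute_onsets(
            _exposures([("r1", "d", "other", "suspect", "20230101")]),
            _reports([("r1", "20230501")]),
            {"r1"},
        )
        assert recs["onset_days"].tolist() == [120]
        assert sum(tally.values()) == 0

    def test_event_before_start_excluded_and_tallied(self):
        recs, tally = compute_onsets(
            _exposures([("r1", "d", "other", "suspect", "20230601")]),
            _reports([("r1", "20230101")]),
            {"r1"},
        )
        assert recs.empty and tally["negative"] == 1

    def test_month_precision_imputes_day_15(self):
        recs, _ = compute_onsets(
            _exposures([("r1", "d", "other", "suspect", "202303")]),
            _reports([("r1", "20230415")]),
            {"r1"},
        )
        assert recs["onset_days"].tolist() == [31]

    def test_missing_endpoints_tallied(self):
        recs, tally = compute_onsets(
            _exposures(
                [("r1", "d", "other", "suspect", ""),      # no start
                 ("r2", "d", "other", "suspect", "20230101")]  # no event date
            ),
            _reports([("r1", "20230501"), ("r2", "")]),
            {"r1", "r2"},
        )
        assert recs.empty
        assert tally["missing_start"] == 1 and tally["missing_event"] == 1

    def test_earliest_suspect_start_is_used(self):
        recs, _ = compute_onsets(
            _exposures(
                [("r1", "d", "other", "suspect", "20230301"),
                 ("r1", "d", "other", "suspect", "20230101")]
            ),
            _reports([("r1", "20230501")]),
            {"r1"},
        )
        assert recs["onset_days"].tolist() == [120]

    def test_concomitant_lines_ignored(self):
        recs, _ = compute_onsets(
            _exposures([("r1", "d", "other", "concomitant", "20230101")]),
            _reports([("r1", "20230501")]),
            {"r1"},
        )
        assert recs.empty

    def test_recovers_generator_onset_median(self):
        cfg = SyntheticConfig(
            n_cases=5_000,
            drug_vocab=[DrugSpec(generic="drugX", brands=[], drug_class="other")],
            event_vocab=[EventSpec(pt="Lens cloud", smq_narrow=True)],
            background_exposure=0.5,
            background_event=0.2,
            signal_pairs=[SignalPair(drug="drugX", event="Lens cloud", rr=4.0)],
            onset_dist={"other": OnsetDist(mu=math.log(120.0), sigma=0.5)},
            duplicate_rate=0.0,
            partial_date_frac=0.0,
            seed=11,
        )
        data = generate(cfg)
        reports, exposures, events = harmonize(data.tables)
        exposures, _ = normalize_drugs(exposures, DrugSynonymTable.from_vocab(cfg.drug_vocab))
        flagged = set(events["record_id"])
        recs, _ = compute_onsets(exposures, reports, flagged)
        assert len(recs) > 1500
        med = recs["onset_days"].median()
        assert abs(med - 120.0) / 120.0 < 0.10

    def test_recovers_two_class_mean_separation(self):
        cfg = SyntheticConfig(
            n_cases=6_000,
            drug_vocab=[
                DrugSpec(generic="drugEye", brands=[], drug_class="ophthalmic"),
                DrugSpec(generic="drugOther", brands=[], drug_class="other"),
            ],
            event_vocab=[EventSpec(pt="Lens cloud", smq_narrow=True)],
            background_exposure=0.3,
            background_event=0.3,
            signal_pairs=[],
            duplicate_rate=0.0,
            partial_date_frac=0.0,
            seed=4,
        )
        data = generate(cfg)
        reports, exposures, events = harmonize(data.tables)
        exposures, _ = normalize_drugs(exposures, DrugSynonymTable.from_vocab(cfg.drug_vocab))
        recs, _ = compute_onsets(exposures, reports, set(events["record_id"]))
        summary = summarize_onsets(recs)
        for cls in ("ophthalmic", "other"):
            row = summary.loc[cls]
            se = row["sd"] / math.sqrt(row["n"])
            assert abs(row["mean"] - cfg.onset_dist[cls].mean_days) < 3 * se


class TestSummaries:
    def test_interpolated_quartiles_of_1_to_5(self):
        recs = pd.DataFrame(
            {"drug_class": "x", "onset_days": [1, 2, 3, 4, 5], "record_id": list("abcde"), "generic": "d"}
        )
        row = summarize_onsets(recs).loc["x"]
        assert (row["q1"], row["median"], row["q3"]) == (2, 3, 4)

    def test_single_value_group(self):
        recs = pd.DataFrame(
            {"drug_class": ["x"], "onset_days": [7], "record_id": ["a"], "generic": ["d"]}
        )
        row = summarize_onsets(recs).loc["x"]
        assert row["mean"] == row["median"] == row["q1"] == row["q3"] == 7
        assert bool(row["low_n"])

    def test_empty_input_gives_empty_summary(self):
        out = summarize_onsets(pd.DataFrame(columns=["drug_class", "onset_days"]))
        assert out.empty

    def test_quartiles_are_permutation_invariant_order_statistics(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(5, 1, 200)
        a = pd.DataFrame({"drug_class": "x", "onset_days": vals})
        b = pd.DataFrame({"drug_class": "x", "onset_days": rng.permutation(vals)})
        ra, rb = summarize_onsets(a).loc["x"], summarize_onsets(b).loc["x"]
        assert ra["q1"] <= ra["median"] <= ra["q3"]
        pd.testing.assert_series_equal(ra, rb)


class TestAnova:
    def test_two_group_hand_oracle(self):
        # groups {1,2,3} vs {101,102,103}: SSB = 15000 on 1 df, MSW = 1 on 4 df
        recs = pd.DataFrame(
            {"drug_class": ["g1"] * 3 + ["g2"] * 3, "onset_days": [1, 2, 3, 101, 102, 103]}
        )
        out = anova_classes(recs)
        assert out["F"] == pytest.approx(15000.0)
        assert out["df_between"] == 1 and out["df_within"] == 4
        assert out["p"] < 0.001
        f, p = st.f_oneway([1, 2, 3], [101, 102, 103])
        assert out["F"] == pytest.approx(f) and out["p"] == pytest.approx(p)

    def test_identical_groups_give_f_zero_p_one(self):
        recs = pd.DataFrame(
            {"drug_class": ["g1"] * 3 + ["g2"] * 3, "onset_days": [5.0] * 6}
        )
        out = anova_classes(recs)
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_insufficient_groups_raise(self):
        recs = pd.DataFrame({"drug_class": ["g1"] * 5, "onset_days": range(5)})
        with pytest.raises(AnalysisError, match="2 groups"):
            anova_classes(recs)

    def test_f_invariant_under_constant_shift(self):
        rng = np.random.default_rng(1)
        recs = pd.DataFrame(
            {
                "drug_class": np.repeat(["a", "b", "c"], 30),
                "onset_days": rng.lognormal(5, 0.8, 90),
            }
        )
        shifted = recs.assign(onset_days=recs["onset_days"] + 1000.0)
        assert anova_classes(recs)["F"] == pytest.approx(anova_classes(shifted)["F"])


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestLogistic:
    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(2)
        n = 4000
        x = rng.integers(0, 2, n)
        y = rng.random(n) < 0.3
        rows = pd.DataFrame({"outcome": y.astype(int), "x": x.astype(float)})
        out = fit_logistic(rows)
        assert out.loc["x", "or_ci_low"] < 1 < out.loc["x", "or_ci_high"]
        assert out.loc["x", "or_"] == pytest.approx(1.0, abs=0.25)

    def test_matches_bruteforce_likelihood_maximization_on_small_fixture(self):
        rng = np.random.default_rng(5)
        n = 20
        x1 = rng.standard_normal(n)
        x2 = rng.integers(0, 2, n).astype(float)
        p = _sigmoid(0.3 + 0.8 * x1 - 0.5 * x2)
        y = (rng.random(n) < p).astype(int)
        rows = pd.DataFrame({"outcome": y, "x1": x1, "x2": x2})
        out = fit_logistic(rows)

        X = np.column_stack([np.ones(n), x1, x2])

        def nll(beta):
            z = X @ beta
            return -(y * z - np.log1p(np.exp(z))).sum()

        res = optimize.minimize(
            nll, np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
        )
        fitted = out["coef"].reindex(["const", "x1", "x2"]).to_numpy()
        assert np.allclose(fitted, res.x, atol=1e-4)

    def test_log_odds_bias_small_across_seeds(self):
        # parameter recovery: true OR 2.0, 20 replicates at n = 50,000
        biases = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 50_000
            x = rng.integers(0, 2, n).astype(float)
            y = (rng.random(n) < _sigmoid(-2.0 + math.log(2.0) * x)).astype(int)
            out = fit_logistic(pd.DataFrame({"outcome": y, "x": x}))
            biases.append(out.loc["x", "coef"] - math.log(2.0))
        assert abs(float(np.mean(biases))) < 0.05

    def test_separation_is_flagged_not_estimable(self):
        n = 60
        x = np.repeat([0.0, 1.0], n // 2)
        y = x.astype(int)  # perfectly separated
        noise = np.tile([0.0, 1.0], n // 2)
        rows = pd.DataFrame({"outcome": y, "x": x, "z": noise})
        out = fit_logistic(rows)
        assert not bool(out.loc["x", "estimable"])
        assert math.isnan(out.loc["x", "or_ci_low"])

    def test_outcome_must_have_both_classes(self):
        rows = pd.DataFrame({"outcome": [1, 1, 1], "x": [0.0, 1.0, 2.0]})
        with pytest.raises(AnalysisError, match="both classes"):
            fit_logistic(rows)


class TestCovariateRows:
    def test_report_level_rows_with_missing_levels_and_drug_indicators(self):
        reports = pd.DataFrame(
            {
                "record_id": ["r1", "r2", "r3"],
                "age": [60.0, np.nan, 70.0],
                "sex": ["female", "male", ""],
                "country": ["US", "US", "JP"],
                "reporter": ["physician", "pharmacist", "physician"],
                "receipt_date": ["20230601", "20230601", "20230601"],
            }
        )
        exposures = pd.DataFrame(
            {
                "record_id": ["r1", "r2", "r3"],
                "generic": ["dA", "dB", "dA"],
                "role": ["suspect", "suspect", "suspect"],
                "route": ["ORAL", "ORAL", "OPHTHALMIC"],
                "indication": ["x", "y", "x"],
                "start_date": ["20230101", "", "20230301"],
            }
        )
        rows = build_covariate_rows(reports, exposures, {"r1"}, ["dA"])
        assert rows.loc["r1", "outcome"] == 1 and rows.loc["r2", "outcome"] == 0
        assert rows.loc["r3", "sex"] == "(missing)"
        assert rows.loc["r2", "age_missing"] == 1
        assert rows.loc["r1", "drug_dA"] == 1 and rows.loc["r2", "drug_dA"] == 0
        assert rows.loc["r1", "therapy_days"] == 151
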