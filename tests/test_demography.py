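"""Record loading, score tables, laterality, and the year-trend model."""

import numpy as np
import pandas as pd
import pytest

from felhip.demography import (
    HipRecord,
    ScoreTable,
    fit_multinomial_trend,
    laterality_from_marginals,
    laterality_from_records,
    load_records,
    proportional_odds_diagnostic,
    summarize_scores,
)
from felhip.multinomial import fit_multinomial


def _rec(left, right, sex="female", **kw):
    kw.setdefault("id", f"c{left}{right}{sex}{np.random.randint(1e9)}")
    kw.setdefault("age_days", 500)
    kw.setdefault("year", 2010)
    return HipRecord(sex=sex, left=left, right=right, **kw)


def random_records(rng, n=400):
    recs = []
    for i in range(n):
        liab = rng.normal(0, 1.5)
        left = int(np.clip(np.digitize(liab + rng.normal(), [0.5, 1.5, 2.5]), 0, 3))
        right = int(np.clip(np.digitize(liab + rng.normal(), [0.5, 1.5, 2.5]), 0, 3))
        recs.append(HipRecord(
            id=f"r{i}", sex="male" if rng.random() < 0.4 else "female",
            age_days=int(rng.integers(300, 2000)),
            year=int(rng.integers(2000, 2020)), left=left, right=right))
    return recs


class TestLoadRecords:
    def test_max_score_is_computed(self, tmp_path):
        p = tmp_path / "pheno.csv"
        p.write_text("id,sex,age_days,year,left,right\n"
                     "a,female,500,2005,1,2\n"
                     "b,male,400,2006,0,0\n")
        recs = load_records(p)
        assert recs[0].max_score == 2
        assert recs[1].max_score == 0
        assert not recs[1].affected

    def test_invalid_score_names_row(self, tmp_path):
        p = tmp_path / "pheno.csv"
        p.write_text("id,sex,age_days,year,left,right\n"
                     "a,female,500,2005,4,2\n")
        with pytest.raises(ValueError, match="row 2"):
            load_records(p)

    def test_nonpositive_age_rejected(self, tmp_path):
        p = tmp_path / "pheno.csv"
        p.write_text("id,sex,age_days,year,left,right\n"
                     "a,female,0,2005,1,2\n")
        with pytest.raises(ValueError, match="age"):
            load_records(p)

    def test_optional_mass_column(self, tmp_path):
        p = tmp_path / "pheno.csv"
        p.write_text("id,sex,age_days,year,left,right,mass_kg\n"
                     "a,female,500,2005,1,2,4.5\nb,male,600,2006,0,1,\n")
        recs = load_records(p)
        assert recs[0].body_mass_kg == 4.5
        assert recs[1].body_mass_kg is None


class TestSummaries:
    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize_scores([])

    def test_all_zero_scores(self):
        recs = [_rec(0, 0) for _ in range(10)]
        assert summarize_scores(recs).prevalence_percent == 0.0

    def test_matches_direct_tally(self, rng):
        recs = random_records(rng)
        s = summarize_scores(recs)
        direct_prev = 100 * np.mean([r.max_score >= 1 for r in recs])
        assert s.prevalence_percent == pytest.approx(direct_prev)
        for k in range(4):
            assert s.max_share_percent[k] == pytest.approx(
                100 * np.mean([r.max_score == k for r in recs]))
        props = s.table.proportions()
        for sex in props.columns.levels[0]:
            assert props[sex].sum(axis=0).to_numpy() == pytest.approx(
                np.ones(3), abs=1e-12)

    def test_inconsistent_table_rejected(self):
        with pytest.raises(ValueError, match="totals"):
            ScoreTable.from_counts({"female": {
                "left": [5, 0, 0, 0], "right": [4, 0, 0, 0],
                "max": [5, 0, 0, 0]}})


class TestLaterality:
    def test_simple_fractions(self):
        recs = [_rec(1, 0), _rec(2, 2)]
        lat = laterality_from_records(recs)
        assert lat["unilateral_frac"] == 0.5
        assert lat["severity_by_laterality"].loc[2, "bilateral"] == 1

    def test_all_bilateral(self):
        recs = [_rec(1, 2), _rec(3, 3)]
        assert laterality_from_records(recs)["unilateral_frac"] == 0.0

    def test_no_affected_errors(self):
        with pytest.raises(ValueError):
            laterality_from_records([_rec(0, 0)])

    def test_right_all_zero_table_gives_unilateral_100(self):
        t = ScoreTable.from_counts({"female": {
            "left": [5, 3, 1, 1], "right": [10, 0, 0, 0],
            "max": [5, 3, 1, 1]}})
        assert laterality_from_marginals(t)["unilateral_frac"] == 1.0

    def test_negative_implied_count_errors(self):
        t = ScoreTable.from_counts({"female": {
            "left": [9, 1, 0, 0], "right": [9, 1, 0, 0],
            "max": [5, 5, 0, 0]}})
        with pytest.raises(ValueError, match="inconsistent"):
            laterality_from_marginals(t)

    def test_marginals_equal_records_on_simulated_data(self, rng):
        recs = random_records(rng, n=600)
        lat_r = laterality_from_records(recs)
        lat_m = laterality_from_marginals(summarize_scores(recs).table)
        assert lat_m["unilateral_frac"] == pytest.approx(
            lat_r["unilateral_frac"], abs=1e-12)
        assert lat_m["bilateral_frac"] == pytest.approx(
            lat_r["bilateral_frac"], abs=1e-12)


class TestMultinomialTrend:
    def test_probabilities_sum_to_one(self, rng):
        recs = random_records(rng)
        m = fit_multinomial_trend(recs)
        grid = m.predict_proportions(range(2000, 2020), "male")
        assert np.allclose(grid.sum(axis=1), 1.0)

    def test_two_categories_match_logistic_oracle(self, rng):
        n = 500
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = (rng.random(n) < p).astype(int)
        X = np.column_stack([np.ones(n), x])
        fit = fit_multinomial(y, X)
        import statsmodels.api as sm
        oracle = sm.Logit(y, X).fit(disp=False)
        assert np.allclose(fit.coef[0], np.asarray(oracle.params), atol=1e-6)

    def test_intercept_only_equals_frequencies(self, rng):
        y = rng.integers(0, 4, 300)
        fit = fit_multinomial(y, np.ones((300, 1)))
        freqs = np.bincount(y, minlength=4) / 300
        assert np.allclose(fit.predict_proba(np.ones((1, 1)))[0], freqs,
                           atol=1e-8)

    def test_separation_triggers_ridge(self):
        y = np.array([0] * 20 + [1] * 20)
        x = np.concatenate([-np.ones(20), np.ones(20)])
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_multinomial(y, np.column_stack([np.ones(40), x]))
        assert fit.ridge > 0 and fit.separation

    def test_proportional_odds_diagnostic(self, rng):
        recs = random_records(rng, n=500)
        out = proportional_odds_diagnostic(recs)
        assert 0.0 <= out["p_value"] <= 1.0
        assert out["df"] > 0
        # the multinomial nests the cumulative model's mean structure only
        # loosely, but must fit at least as well with more parameters
        assert out["loglik_multinomial"] >= out["loglik_cumulative"] - 1e-6
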