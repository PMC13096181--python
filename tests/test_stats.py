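"""Bias statistics: expectations, quadrants, scaling, ANOVA, GLMs."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from beebias.stats import (
    bh_adjust,
    binomial_share_trend,
    classify_quadrants,
    deviation_table,
    era_share_change,
    expected_from_popularity,
    games_howell,
    hc3_covariance,
    nb_glm,
    richness_effort_scaling,
    welch_anova,
)
from beebias.synth import gen_nb_recovery

# observed/expected pairs for the ten focal genera as printed in the study
FOCAL_TABLE = {
    "Apis": (44431, 28860, 15571, 54),
    "Bombus": (7720, 9970, -2250, -23),
    "Megachile": (1184, 4522, -3338, -74),
    "Osmia": (1001, 4343, -3342, -77),
    "Xylocopa": (1256, 4294, -3038, -71),
    "Melipona": (1190, 2332, -1142, -49),
    "Andrena": (1030, 1560, -530, -34),
    "Lasioglossum": (697, 1331, -634, -48),
    "Tetragonula": (423, 1259, -836, -66),
    "Trigona": (939, 1402, -463, -33),
}


# ---------------------------------------------------------------------------
# popularity expectations
# ---------------------------------------------------------------------------

def test_deviation_table_reproduces_focal_genus_residuals():
    observed = {g: v[0] for g, v in FOCAL_TABLE.items()}
    expected = {g: v[1] for g, v in FOCAL_TABLE.items()}
    table = deviation_table(observed, expected).set_index("genus")
    for genus, (_, _, resid, pct) in FOCAL_TABLE.items():
        assert table.loc[genus, "residual"] == pytest.approx(resid)
        assert table.loc[genus, "pct_deviation"] == pct


def test_expected_from_popularity_conserves_totals_and_proportionality():
    observed = {"a": 30.0, "b": 20.0, "c": 10.0}
    prop = expected_from_popularity(observed, {"a": 3.0, "b": 2.0, "c": 1.0})
    np.testing.assert_allclose(prop["residual"], 0.0, atol=1e-9)
    skew = expected_from_popularity(observed, {"a": 1.0, "b": 1.0, "c": 1.0})
    assert skew["expected"].sum() == pytest.approx(skew["observed"].sum(), abs=1e-9)


def test_popularity_input_validation():
    with pytest.raises(ValueError, match="same genera"):
        expected_from_popularity({"a": 1}, {"b": 1})
    with pytest.raises(ValueError, match="positive"):
        expected_from_popularity({"a": 1, "b": 1}, {"a": 1.0, "b": 0.0})


# ---------------------------------------------------------------------------
# policy-group quadrants
# ---------------------------------------------------------------------------

def test_quadrants_corner_cases():
    effort = {"a": 1, "b": 1, "c": 100, "d": 100}
    centrality = {"a": -1, "b": 1, "c": -1, "d": 1}
    qa = classify_quadrants(effort, centrality, effort_threshold=10, centrality_threshold=0)
    groups = dict(zip(qa.assignments["genus"], qa.assignments["group"]))
    assert groups == {"a": "LELC", "b": "LEHC", "c": "HELC", "d": "HEHC"}
    assert sum(qa.group_sizes.values()) == 4


def test_quadrants_all_below_thresholds():
    qa = classify_quadrants({"a": 0, "b": 0}, {"a": -1, "b": -1},
                            effort_threshold=1, centrality_threshold=0)
    assert qa.group_sizes == {"LELC": 2, "LEHC": 0, "HELC": 0, "HEHC": 0}


def test_quadrants_partition_and_managed_share(rng):
    genera = [f"g{i}" for i in range(40)]
    effort = {g: float(rng.integers(0, 500)) for g in genera}
    centrality = {g: float(rng.normal()) for g in genera}
    managed = {g: bool(rng.random() < 0.3) for g in genera}
    qa = classify_quadrants(effort, centrality, managed=managed)
    assert sum(qa.group_sizes.values()) == len(genera)
    for share in qa.managed_share.values():
        assert np.isnan(share) or 0 <= share <= 1


# ---------------------------------------------------------------------------
# scaling and HC3
# ---------------------------------------------------------------------------

def test_scaling_recovers_constructed_exponent(rng):
    richness = {f"g{i}": float(v) for i, v in enumerate(rng.integers(50, 5000, size=120))}
    # articles + 1 = richness^0.5 exactly, so the log-log slope is 0.5
    articles = {g: r**0.5 - 1 for g, r in richness.items()}
    fit = richness_effort_scaling(articles, richness)
    assert fit.slope == pytest.approx(0.5, abs=0.01)
    assert fit.ci[0] < fit.slope < fit.ci[1]


def test_scaling_flags_extreme_outlier(rng):
    richness = {f"g{i}": float(v) for i, v in enumerate(rng.integers(10, 1000, size=60))}
    articles = {g: r**0.6 * float(rng.lognormal(0, 0.1)) for g, r in richness.items()}
    articles["g0"] = 1e6  # one wildly over-studied genus
    fit = richness_effort_scaling(articles, richness, exclude_genera=("g3", "g7"))
    flagged = set(fit.influence.loc[fit.influence["flagged"], "genus"])
    assert "g0" in flagged
    assert "influence_trimmed" in fit.refits
    assert {"exclude_named", "trim_top_richness", "trim_top_articles"} <= set(fit.refits)


def test_hc3_matches_statsmodels(rng):
    X = np.column_stack([np.ones(20), rng.normal(size=20)])
    y = X @ np.array([1.0, 2.0]) + rng.normal(size=20) * (1 + np.abs(X[:, 1]))
    fit = sm.OLS(y, X).fit()
    ours = hc3_covariance(X, fit.resid)
    theirs = sm.OLS(y, X).fit(cov_type="HC3").cov_params()
    np.testing.assert_allclose(ours, theirs, rtol=1e-8)


def test_hc3_scale_equivariance_and_homoscedastic_agreement(rng):
    X = np.column_stack([np.ones(3000), rng.normal(size=3000)])
    y = X @ np.array([0.5, 1.5]) + rng.normal(size=3000)
    fit = sm.OLS(y, X).fit()
    se_hc3 = np.sqrt(np.diag(hc3_covariance(X, fit.resid)))
    np.testing.assert_allclose(se_hc3, fit.bse, rtol=0.05)
    scaled = np.sqrt(np.diag(hc3_covariance(X, 3.0 * fit.resid)))
    np.testing.assert_allclose(scaled, 3.0 * se_hc3, rtol=1e-12)


def test_duplicating_data_shrinks_hc3_se_by_sqrt2(rng):
    X = np.column_stack([np.ones(200), rng.normal(size=200)])
    y = X @ np.array([1.0, 0.8]) + rng.normal(size=200)
    e = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    se1 = np.sqrt(np.diag(hc3_covariance(X, e)))
    X2, e2 = np.vstack([X, X]), np.concatenate([e, e])
    se2 = np.sqrt(np.diag(hc3_covariance(X2, e2)))
    np.testing.assert_allclose(se2, se1 / np.sqrt(2), rtol=0.03)


# ---------------------------------------------------------------------------
# Welch ANOVA, Games-Howell, BH
# ---------------------------------------------------------------------------

def test_welch_f_equals_squared_welch_t(rng):
    from scipy.stats import ttest_ind

    a = rng.normal(0, 1, size=15)
    b = rng.normal(0.8, 2.5, size=25)
    F, df1, df2, p = welch_anova([a, b])
    t = ttest_ind(a, b, equal_var=False)
    assert F == pytest.approx(t.statistic**2, rel=1e-10)
    assert p == pytest.approx(t.pvalue, rel=1e-9)


def test_welch_identical_groups_give_f_zero(rng):
    g = rng.normal(size=20)
    F, _, _, p = welch_anova([g, g.copy(), g.copy()])
    assert F == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_welch_input_validation(rng):
    with pytest.raises(ValueError):
        welch_anova([rng.normal(size=5)])
    with pytest.raises(ValueError, match="zero-variance"):
        welch_anova([np.ones(5), rng.normal(size=5)])


def test_games_howell_identical_groups_and_row_count(rng):
    g = rng.normal(size=12)
    table = games_howell([g, g.copy(), g.copy(), g.copy()])
    assert len(table) == 4 * 3 // 2
    assert (table["p"] > 0.999).all()


def test_games_howell_shifted_group_has_smallest_p(rng):
    groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(5, 0.1, 20)]
    table = games_howell(groups, labels=["a", "b", "c"])
    worst = table.sort_values("p").iloc[0]
    assert "c" in (worst["group_a"], worst["group_b"])
    assert (table["ci_low"] <= table["difference"]).all()
    assert (table["difference"] <= table["ci_high"]).all()


def test_bh_stepup_hand_example_and_trivials():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
def test_bh_matches_statsmodels_and_is_monotone(pvals):
    ours = bh_adjust(pvals)
    theirs = multipletests(pvals, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, theirs, atol=1e-12)
    assert np.all(ours >= np.asarray(pvals) - 1e-15)
    order = np.argsort(pvals)
    assert np.all(np.diff(ours[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# share trends and era changes
# ---------------------------------------------------------------------------

def test_share_trend_recovers_logistic_slope():
    years = np.arange(1975, 2024)
    true_b = 0.0259
    share = 1 / (1 + np.exp(-(-2.0 + true_b * (years - 2000))))
    total = 1_000_000
    succ = np.round(share * total)
    fit = binomial_share_trend(succ, total - succ, years)
    assert fit.slope_per_year == pytest.approx(true_b, abs=1e-3)
    assert fit.p < 1e-10


def test_share_trend_constant_share_and_separation():
    years = np.arange(2000, 2010)
    fit = binomial_share_trend(np.full(10, 50.0), np.full(10, 50.0), years)
    assert fit.slope_per_year == pytest.approx(0.0, abs=1e-8)
    sep = binomial_share_trend(np.full(10, 100.0), np.zeros(10), years)
    assert sep.flagged and sep.slope_per_year is None


def test_share_trend_matches_irls_oracle(rng):
    # small fixture: literal IRLS for the two-column binomial logit GLM
    years = np.arange(1990, 2000).astype(float)
    succ = rng.integers(10, 90, size=10).astype(float)
    fail = 100 - succ
    fit = binomial_share_trend(succ, fail, years.astype(int))

    X = np.column_stack([np.ones(10), years])
    n = succ + fail
    beta = np.zeros(2)
    for _ in range(50):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = n * mu * (1 - mu)
        z = eta + (succ - n * mu) / W
        beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    assert fit.slope_per_year == pytest.approx(beta[1], abs=1e-8)


def test_one_vs_rest_share_trends_with_bh():
    years = np.arange(2000, 2020)
    up = np.round(10 + 2.0 * (years - 2000))
    down = np.round(100 - 2.0 * (years - 2000))
    flat = np.full(len(years), 50.0)
    totals = up + down + flat
    table = binomial_share_trend(
        totals, np.ones(len(years)), years, levels={"up": up, "down": down, "flat": flat}
    ).set_index("level")
    assert table.loc["up", "slope_per_year"] > 0 > table.loc["down", "slope_per_year"]
    assert (table["p_adj"] >= table["p"] - 1e-15).all()


def test_era_share_change_examples():
    years = list(range(2000, 2010))
    counts = pd.DataFrame(
        [{"year": y, "category": "managed", "count": 10} for y in years]
        + [{"year": y, "category": "wild", "count": 90} for y in years]
    )
    out = era_share_change(counts, (2000, 2004), (2005, 2009)).set_index("category")
    assert out.loc["managed", "change_points"] == pytest.approx(0.0)

    rising = pd.DataFrame(
        [{"year": y, "category": "managed", "count": 10 if y < 2005 else 31} for y in years]
        + [{"year": y, "category": "wild", "count": 90 if y < 2005 else 69} for y in years]
    )
    out = era_share_change(rising, (2000, 2004), (2005, 2009)).set_index("category")
    assert out.loc["managed", "change_points"] == pytest.approx(21.0)
    flipped = era_share_change(rising, (2005, 2009), (2000, 2004)).set_index("category")
    assert flipped.loc["managed", "change_points"] == pytest.approx(-21.0)


# ---------------------------------------------------------------------------
# negative-binomial count model
# ---------------------------------------------------------------------------

def test_nb_offset_contract():
    y, X, off, _ = gen_nb_recovery(seed=12, n=1500)
    fit = nb_glm(y, X, offset=off)
    fit2 = nb_glm(y, X, offset=off + math.log(2))
    assert fit2.params["intercept"] == pytest.approx(fit.params["intercept"] - math.log(2), abs=1e-5)
    assert fit2.params["managed"] == pytest.approx(fit.params["managed"], abs=1e-5)


def test_nb_recovers_managed_premium():
    y, X, off, truth = gen_nb_recovery(seed=3, n=2000)
    fit = nb_glm(y, X, offset=off)
    assert fit.params["managed"] == pytest.approx(truth["beta_managed"], abs=0.15)
    assert fit.theta == pytest.approx(truth["theta"], rel=0.25)
    assert fit.ci_low["managed"] < fit.irr["managed"] < fit.ci_high["managed"]
    assert (fit.irr > 0).all()


def test_nb_poisson_limit_matches_poisson_fit(rng):
    n = 1500
    managed = (np.arange(n) % 2).astype(float)
    mu = 5.0 * np.exp(0.7 * managed)
    y = rng.poisson(mu)
    X = pd.DataFrame({"managed": managed})
    fit = nb_glm(y, X)
    pois = sm.GLM(y, sm.add_constant(managed), family=sm.families.Poisson()).fit()
    assert fit.theta > 20  # little overdispersion detected
    assert abs(fit.params["managed"] - pois.params[1]) < 2 * pois.bse[1]


def test_nb_input_validation(rng):
    with pytest.raises(ValueError, match="non-negative"):
        nb_glm([-1, 2, 3], np.ones((3, 1)))
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
    with pytest.raises(ValueError, match="rank"):
        nb_glm([1, 2, 3, 4], X)
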