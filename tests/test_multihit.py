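"""multihit: exact lineage simulation, summaries and the conditional law."""

import numpy as np
import pytest
from scipy import stats

from carcineff import multihit as mh


def hot_model(**kw):
    """Baseline hazard large enough for transformations in small runs."""
    defaults = dict(v=0.05, r_base=1e-3, effect_shape=2.0, effect_rate=1.0,
                    lifespan=80.0, n_lineages=2000)
    defaults.update(kw)
    return mh.MultiHitModel(**defaults)


# ---------------------------------------------------------------------------
# simulation invariants


def test_model_rejects_bad_parameters():
    with pytest.raises(ValueError):
        mh.MultiHitModel(v=-0.1)
    with pytest.raises(ValueError):
        mh.MultiHitModel(n_lineages=0)


def test_simulation_is_seeded_and_consistent():
    m = hot_model(n_lineages=300)
    a = mh.simulate_lineages(m, seed=5)
    b = mh.simulate_lineages(m, seed=5)
    for oa, ob in zip(a, b):
        assert oa.transformed == ob.transformed
        assert np.array_equal(oa.mutation_times, ob.mutation_times)
    for o in a:
        assert np.all(np.diff(o.mutation_times) >= 0)
        assert np.all(o.effects > 0)
        assert len(o.effects) == len(o.mutation_times)
        if o.transformed:
            assert 0 <= o.t_cancer <= m.lifespan
            # the record stops at the cancer time
            assert np.all(o.mutation_times <= o.t_cancer)
        else:
            assert o.t_cancer is None


def test_degenerate_unit_effect_gives_exponential_cancer_times():
    # effect 1 everywhere: hazard is constant r_base, so cancer ages are
    # exponential(r_base) truncated at the lifespan
    m = hot_model(r_base=0.02, n_lineages=4000)
    out = mh.simulate_lineages(m, seed=9, degenerate_effect=1.0)
    t = np.array([o.t_cancer for o in out if o.transformed])
    assert len(t) > 1000
    cdf = stats.expon(scale=1 / 0.02).cdf
    u = cdf(t) / cdf(m.lifespan)
    assert stats.kstest(u, "uniform").pvalue > 0.01


def test_mutation_counts_match_poisson_mean():
    m = hot_model(r_base=0.0, v=0.05, n_lineages=3000)
    out = mh.simulate_lineages(m, seed=21)
    assert not any(o.transformed for o in out)
    k = np.array([len(o.mutation_times) for o in out], dtype=float)
    want = m.v * m.lifespan
    se = k.std(ddof=1) / np.sqrt(len(k))
    assert abs(k.mean() - want) <= 3 * se


# ---------------------------------------------------------------------------
# summaries on hand-built outcomes


def _hand_outcomes():
    return [
        mh.LineageOutcome(np.array([1.0]), np.array([np.e]), True, 2.0),
        mh.LineageOutcome(np.array([]), np.array([]), True, 7.0),
        mh.LineageOutcome(np.array([4.0]), np.array([2.0]), False, None),
    ]


def test_cancer_summaries_hand_values():
    table, inc = mh.cancer_summaries(_hand_outcomes(), age_step=5.0,
                                     lifespan=10.0)
    assert list(table["t_cancer"]) == [2.0, 7.0]
    assert list(table["n_drivers"]) == [1, 0]
    assert table["mean_log_effect"].iloc[0] == pytest.approx(1.0)
    assert np.isnan(table["mean_log_effect"].iloc[1])
    # bin [0,5): one event; at risk 2 + 5 + 5 = 12 lineage-years
    assert inc["events"].tolist() == [1, 1]
    assert inc["lineage_years"].iloc[0] == pytest.approx(12.0)
    assert inc["incidence"].iloc[0] == pytest.approx(1 / 12)
    # bin [5,10): one event; at risk 0 + 2 + 5 = 7
    assert inc["lineage_years"].iloc[1] == pytest.approx(7.0)
    with pytest.raises(ValueError, match="no transformed"):
        mh.cancer_summaries([_hand_outcomes()[2]])


def test_expected_incidence_hand_values():
    m = mh.MultiHitModel(v=0.05, r_base=1e-3, lifespan=10.0, n_lineages=1)
    o = mh.LineageOutcome(np.array([3.0]), np.array([4.0]), True, 7.0)
    inc = mh.expected_incidence([o], m, age_step=5.0)
    # bin [0,5): hazard r for 3y then 4r for 2y -> (3 + 8) * r over 5 years
    assert inc["expected_events"].iloc[0] == pytest.approx(11 * 1e-3)
    assert inc["lineage_years"].iloc[0] == pytest.approx(5.0)
    # bin [5,10): hazard 4r for 2y until transformation at 7 -> 8r over 2y
    assert inc["expected_events"].iloc[1] == pytest.approx(8 * 1e-3)
    assert inc["lineage_years"].iloc[1] == pytest.approx(2.0)
    assert inc["incidence"].iloc[1] == pytest.approx(4e-3)


def test_expected_incidence_increases_with_age_at_defaults():
    # the defining qualitative prediction: incidence rises with age
    m = mh.MultiHitModel(n_lineages=2000)
    out = mh.simulate_lineages(m, seed=2)
    inc = mh.expected_incidence(out, m)
    rate = inc["incidence"].to_numpy()
    assert rate[-1] > rate[0]
    rho = stats.spearmanr(inc["age"], rate).statistic
    assert rho > 0.9


def test_normal_tissue_summaries_hand_values():
    df = mh.normal_tissue_summaries(_hand_outcomes(), age_grid=[5.0, 10.0])
    # at age 5 two lineages are still at risk: the t=7 cancer (0 drivers so
    # far) and the censored one (1 mutation at t=4) -> mean 0.5
    row = df.iloc[0]
    assert row["n_normal"] == 2
    assert row["mean_drivers_normal"] == pytest.approx(0.5)
    assert row["n_cancer"] == 1 and row["mean_drivers_cancer"] == pytest.approx(1.0)
    # at age 10 only the censored lineage is at risk
    row2 = df.iloc[1]
    assert row2["n_normal"] == 1
    assert row2["mean_drivers_normal"] == pytest.approx(1.0)
    assert row2["n_cancer"] == 1
    assert row2["mean_drivers_cancer"] == pytest.approx(0.0)


def test_prediction_correlations_on_monotone_table():
    import pandas as pd

    table = pd.DataFrame({
        "t_cancer": [10.0, 20.0, 30.0, 40.0],
        "n_drivers": [1, 2, 3, 4],
        "mean_log_effect": [4.0, 3.0, 2.0, 1.0],
    })
    c = mh.prediction_correlations(table)
    assert c["drivers_vs_age"] == pytest.approx(1.0)
    assert c["effect_vs_drivers"] == pytest.approx(-1.0)
    assert c["effect_vs_age"] == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# conditional cancer law (rare-transformation limit)


def test_conditional_table_degenerate_effect_is_uniform_poisson():
    m = mh.MultiHitModel(v=0.05, lifespan=80.0)
    t = mh.conditional_cancer_table(m, n_draw=20000, seed=3,
                                    degenerate_effect=1.0)
    # unit effect: cancer age is uniform on [0, lifespan]
    assert stats.kstest(t["t_cancer"] / 80.0, "uniform").pvalue > 0.01
    # driver counts Poisson(v t); mean over uniform t is v L / 2 = 2
    k = t["n_drivers"].to_numpy(dtype=float)
    se = k.std(ddof=1) / np.sqrt(len(k))
    assert abs(k.mean() - 2.0) <= 3 * se
    # log of a unit effect is zero
    mle = t["mean_log_effect"].dropna()
    assert np.allclose(mle, 0.0)


def test_conditional_table_age_density_and_size_biased_effects():
    m = mh.MultiHitModel(v=0.05, effect_shape=2.0, effect_rate=1.0,
                         lifespan=80.0)
    t = mh.conditional_cancer_table(m, n_draw=40000, seed=11)
    # age density proportional to exp(lam t), lam = v (mu - 1) = 0.05
    lam, L = 0.05, 80.0
    want_mean = (L * np.exp(lam * L) - (np.exp(lam * L) - 1) / lam) / (
        np.exp(lam * L) - 1
    )
    ages = t["t_cancer"].to_numpy()
    se = ages.std(ddof=1) / np.sqrt(len(ages))
    assert abs(ages.mean() - want_mean) <= 3 * se
    # single-driver cancers: effect is size-biased Gamma(3, 1), so the mean
    # log effect is digamma(3)
    from scipy.special import digamma

    one = t.loc[t["n_drivers"] == 1, "mean_log_effect"].to_numpy()
    se1 = one.std(ddof=1) / np.sqrt(len(one))
    assert abs(one.mean() - digamma(3.0)) <= 3 * se1


def test_conditional_table_matches_importance_resampled_simulation():
    m = hot_model(v=0.05, r_base=1e-9, n_lineages=3000)
    out = mh.simulate_lineages(m, seed=7)
    sim = mh.conditional_cancer_table_from_outcomes(out, m, n_draw=20000,
                                                    seed=8)
    exact = mh.conditional_cancer_table(m, n_draw=20000, seed=9)
    # same law: compare age and driver-count means within Monte-Carlo error
    for col in ("t_cancer", "n_drivers"):
        a = sim[col].to_numpy(dtype=float)
        b = exact[col].to_numpy(dtype=float)
        # resampled draws reuse 3000 histories, so inflate the tolerance
        tol = 4 * (a.std() / np.sqrt(3000) + b.std() / np.sqrt(len(b)))
        assert abs(a.mean() - b.mean()) <= tol


def test_conditional_from_outcomes_rejects_zero_weight():
    m = mh.MultiHitModel(v=0.05, r_base=0.0, n_lineages=50)
    out = mh.simulate_lineages(m, seed=1)
    with pytest.raises(ValueError, match="zero total"):
        mh.conditional_cancer_table_from_outcomes(out, m, n_draw=10, seed=2)
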