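import numpy as np
import pandas as pd
import pytest

from hybcoal.inference import (
    FeatureExpander,
    MultinomialLogit,
    ScenarioSpec,
    abc_rejection,
    cross_validate_confusion,
    example1_scenarios,
    example2_scenarios,
    fit_multinomial_stepwise,
    fit_summary_statistics,
    simulate_coalescent_hybrid_pilot,
    simulate_profile_statistics,
    simulate_scenario_set,
)
from hybcoal.stats import CLASSIFIER_STATISTIC_NAMES


def toy_table(rng, n=200, informative=True, k=3):
    """Small labelled feature table with three synthetic statistics."""
    labels = rng.integers(k, size=n)
    X = rng.normal(size=(n, 3))
    if informative:
        X[:, 0] += 2.5 * labels
    df = pd.DataFrame(X, columns=["s1", "s2", "s3"])
    df["label"] = [f"c{int(l)}" for l in labels]
    return df


class TestScenarioSimulation:
    def test_single_replicate_single_row(self, rng):
        spec = ScenarioSpec(label="x", n_taxa=6, n_loci=5, coalescence_rate=10.0)
        df = simulate_scenario_set([spec], 1, rng)
        assert len(df) == 1 and df["label"].iloc[0] == "x"
        assert set(CLASSIFIER_STATISTIC_NAMES) <= set(df.columns)

    def test_example_scenario_grids(self):
        e1 = example1_scenarios()
        assert len(e1) == 4
        assert {s.coalescence_rate for s in e1} == {5.0, 15.0}
        assert {s.min_reticulations for s in e1} == {0, 2}
        e2 = example2_scenarios(n_loci=150)
        assert [s.coalescence_rate for s in e2] == [6.0, 10.0, 30.0, 1000.0]
        assert all(s.success_kind == "linear" and s.success_T == 1.3 for s in e2)
        assert all(s.n_loci == 150 for s in e2)

    def test_enforced_hybrid_count_statistics_exist(self, rng):
        spec = ScenarioSpec(
            label="h2", n_taxa=8, n_loci=10, coalescence_rate=15.0,
            lambda_H=0.2, min_reticulations=2, reduce_to_reticulations=2,
        )
        row = simulate_profile_statistics(spec, rng, include_si2=True)
        assert set(row) == {"TE", "QE", "SI", "SI1", "SI2", "RS", "DC", "UC", "US", "TC", "TCA"}


class TestMultinomialLogit:
    def test_matches_sklearn_on_smooth_problem(self, rng):
        from sklearn.linear_model import LogisticRegression

        df = toy_table(rng, n=400)
        X = df[["s1", "s2", "s3"]].to_numpy()
        y = np.searchsorted(np.array(sorted(df.label.unique())), df.label.to_numpy())
        ours = MultinomialLogit(ridge=1e-8).fit(X, y, 3)
        theirs = LogisticRegression(C=1e8, max_iter=5000, tol=1e-10).fit(X, y)
        p1 = ours.predict_proba(X)
        p2 = theirs.predict_proba(X)
        assert np.max(np.abs(p1 - p2)) < 1e-3
        ll_theirs = float(np.sum(np.log(p2[np.arange(len(y)), y])))
        assert ours.loglik_ >= ll_theirs - 1e-3

    def test_separated_classes_fit_perfectly(self, rng):
        df = toy_table(rng, n=150)
        df["s1"] = [10.0 * int(l[1]) for l in df.label]  # perfectly separating
        model = fit_multinomial_stepwise(df, feature_names=["s1", "s2", "s3"], stepwise=False)
        assert (model.predict(df) == df.label).all()


class TestStepwise:
    def test_null_features_eliminate_interactions(self, rng):
        df = toy_table(rng, n=300, informative=False)
        model = fit_multinomial_stepwise(df, feature_names=["s1", "s2", "s3"])
        assert len(model.terms) == 0  # pure-noise interactions never help AIC
        test = toy_table(rng, n=300, informative=False)
        acc = (model.predict(test) == test.label).mean()
        assert abs(acc - 1 / 3) < 0.15

    def test_stepwise_never_increases_aic(self, rng):
        df = toy_table(rng, n=250)
        full = fit_multinomial_stepwise(df, feature_names=["s1", "s2", "s3"], stepwise=False)
        stepped = fit_multinomial_stepwise(df, feature_names=["s1", "s2", "s3"], stepwise=True)
        assert stepped.aic <= full.aic + 1e-9
        assert len(stepped.terms) <= 3


class TestConfusion:
    def test_row_sums_equal_class_counts(self, rng):
        df = toy_table(rng, n=200)
        model = fit_multinomial_stepwise(df, feature_names=["s1", "s2", "s3"], stepwise=False)
        test = toy_table(rng, n=100)
        conf = cross_validate_confusion(model, test)
        assert (conf.sum(axis=1) == test.label.value_counts().reindex(conf.index)).all()

    def test_perfect_model_diagonal(self, rng):
        df = toy_table(rng, n=200)
        df["s1"] = [5.0 * int(l[1]) for l in df.label]
        model = fit_multinomial_stepwise(df, feature_names=["s1", "s2", "s3"], stepwise=False)
        conf = cross_validate_confusion(model, df)
        assert np.trace(conf.to_numpy()) == len(df)


class TestSummaryFits:
    def test_target_equal_to_feature_recovered(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 3)), columns=["s1", "s2", "s3"])
        df["y"] = df["s1"]
        fit = fit_summary_statistics(df, "y", feature_names=["s1", "s2", "s3"])
        assert fit.residual_sd < 1e-8 or np.allclose(fit.predict(df), df["y"], atol=1e-6)

    def test_design_has_interactions(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        df["y"] = df["a"] * df["b"]
        fit = fit_summary_statistics(df, "y", feature_names=list("abcd"))
        assert np.std(df["y"] - fit.predict(df)) < 0.05


@pytest.fixture(scope="module")
def small_pilot():
    rng = np.random.default_rng(99)
    return simulate_coalescent_hybrid_pilot(300, rng, n_taxa=6, n_loci=12)


class TestABC:
    def test_observed_simulation_is_accepted(self, small_pilot):
        f1 = fit_summary_statistics(small_pilot, "log_coal_rate")
        f2 = fit_summary_statistics(small_pilot, "n_hybrids")
        obs = small_pilot.iloc[7]
        res = abc_rejection(small_pilot, f1, f2, obs, radius=0.1)
        assert res.n_accepted >= 1
        # the observed row itself is at distance zero
        assert (res.accepted.index == 7).any()

    def test_infinite_radius_recovers_prior(self, small_pilot):
        f1 = fit_summary_statistics(small_pilot, "log_coal_rate")
        f2 = fit_summary_statistics(small_pilot, "n_hybrids")
        res = abc_rejection(small_pilot, f1, f2, small_pilot.iloc[0], radius=np.inf)
        assert res.n_accepted == len(small_pilot)

    def test_acceptance_monotone_in_radius(self, small_pilot):
        f1 = fit_summary_statistics(small_pilot, "log_coal_rate")
        f2 = fit_summary_statistics(small_pilot, "n_hybrids")
        obs = small_pilot.iloc[0]
        counts = [
            abc_rejection(small_pilot, f1, f2, obs, radius=r).n_accepted
            for r in (0.1, 0.3, 1.0, 3.0)
        ]
        assert counts == sorted(counts)

    def test_zero_acceptance_warns(self, small_pilot):
        f1 = fit_summary_statistics(small_pilot, "log_coal_rate")
        f2 = fit_summary_statistics(small_pilot, "n_hybrids")
        obs = small_pilot.iloc[0].copy()
        obs["TE"] = obs["TE"] + 1e6  # absurd observation far outside the cloud
        with pytest.warns(UserWarning, match="radius"):
            abc_rejection(small_pilot, f1, f2, obs, radius=1e-6)
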