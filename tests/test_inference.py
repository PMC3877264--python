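"""Factorial models, elimination, variance decomposition, predictions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from devallometry import inference
from devallometry.allofit import sma_fit


def make_table(
    rng,
    n=160,
    n_orders=4,
    b=0.25,
    c=-0.05,
    d=-0.02,
    noise=0.6,
    t_ref=30.0,
    order_sd=0.5,
):
    orders = [f"Order{k}" for k in range(n_orders)]
    order = rng.choice(orders, size=n)
    x = rng.uniform(-5, 7, size=n)
    t = rng.normal(30, 3, size=n)
    offs = {o: rng.normal(0, order_sd) for o in orders}
    y = (
        2.0
        + b * x
        + c * (t - t_ref)
        + d * x * (t - t_ref)
        + np.array([offs[o] for o in order])
        + rng.normal(0, noise, size=n)
    )
    return pd.DataFrame(
        {
            "species": [f"sp{i:03d}" for i in range(n)],
            "order": order,
            "ln_mass": x,
            "ln_tdev": y,
            "t_opt": t,
        }
    )


class TestFitFactorial:
    def test_noiseless_coefficients_recovered(self, rng):
        table = make_table(rng, noise=0.0, order_sd=0.0, d=-0.02)
        ffit = inference.fit_factorial(
            table, terms=["ln_mass", "t_opt", "ln_mass:t_opt"], estimator="OLS"
        )
        fit = ffit.fit
        # model: y = (2 - c*30 + ...) re-expressed on uncentered predictors
        assert fit.coef("ln_mass:t_opt") == pytest.approx(-0.02, abs=1e-6)
        assert fit.coef("t_opt") == pytest.approx(-0.05, abs=1e-6)
        assert fit.coef("ln_mass") == pytest.approx(0.25 + 0.02 * 30, abs=1e-6)

    def test_single_order_drops_order_terms_with_note(self, rng):
        table = make_table(rng, n_orders=1)
        ffit = inference.fit_factorial(table, estimator="OLS")
        assert ffit.terms == ["ln_mass", "t_opt", "ln_mass:t_opt"]
        assert any("order" in note for note in ffit.notes)

    def test_marginality_violation_rejected(self, rng):
        table = make_table(rng)
        with pytest.raises(ValueError, match="marginality"):
            inference.fit_factorial(
                table, terms=["ln_mass", "ln_mass:t_opt"], estimator="OLS"
            )

    def test_matches_statsmodels_coefficients(self, rng):
        table = make_table(rng)
        ffit = inference.fit_factorial(table, estimator="OLS")
        ref = smf.ols(
            "ln_tdev ~ ln_mass + t_opt + C(order) + ln_mass:t_opt "
            "+ ln_mass:C(order) + t_opt:C(order) + ln_mass:t_opt:C(order)",
            data=table,
        ).fit()
        mine = dict(zip(ffit.fit.names, ffit.fit.coefficients))
        for name, value in ref.params.items():
            assert mine[name] == pytest.approx(value, rel=1e-8, abs=1e-10)


class TestSequentialAnova:
    def test_rows_sum_exactly_to_model_r2(self, rng):
        table = make_table(rng)
        ffit = inference.fit_factorial(table, estimator="OLS")
        rows = inference.sequential_partial_r2(ffit)
        assert sum(r.partial_r2 for r in rows) == pytest.approx(ffit.r2, abs=1e-12)
        assert all(r.partial_r2 >= 0 for r in rows)

    def test_matches_statsmodels_type_one_anova(self, rng):
        table = make_table(rng)
        # statsmodels/patsy enters categoricals first; use the same entry
        # order so the sequential (order-dependent) decompositions align
        ffit = inference.fit_factorial(
            table,
            terms=["order", "ln_mass", "t_opt", "ln_mass:t_opt"],
            estimator="OLS",
        )
        rows = inference.sequential_partial_r2(ffit)
        ref = smf.ols(
            "ln_tdev ~ ln_mass + t_opt + C(order) + ln_mass:t_opt", data=table
        ).fit()
        tab = sm.stats.anova_lm(ref, typ=1)
        for row, (term, ref_row) in zip(rows, tab.iloc[:-1].iterrows()):
            assert row.ss == pytest.approx(ref_row["sum_sq"], rel=1e-8)
            assert row.F == pytest.approx(ref_row["F"], rel=1e-8)
            assert row.p == pytest.approx(ref_row["PR(>F)"], abs=1e-10)

    def test_pgls_input_unsupported(self, rng, tmp_path):
        table = make_table(rng, n=24, n_orders=2)
        from devallometry import synthgen

        tree = synthgen.simulate_tree(24, seed=1, labels=list(table["species"]))
        ffit = inference.fit_factorial(
            table,
            terms=["ln_mass", "t_opt"],
            estimator="PGLS",
            tree=tree,
        )
        with pytest.raises(ValueError, match="OLS"):
            inference.sequential_partial_r2(ffit)


class TestBackwardElimination:
    def test_elimination_f_matches_statsmodels_nested_comparison(self, rng):
        table = make_table(rng, d=0.0)
        ffit = inference.fit_factorial(table, estimator="OLS")
        _, log = inference.backward_eliminate(ffit, alpha=0.05)
        first = log[0]
        assert first.term == "ln_mass:t_opt:order"
        full = smf.ols(
            "ln_tdev ~ ln_mass + t_opt + C(order) + ln_mass:t_opt "
            "+ ln_mass:C(order) + t_opt:C(order) + ln_mass:t_opt:C(order)",
            data=table,
        ).fit()
        reduced = smf.ols(
            "ln_tdev ~ ln_mass + t_opt + C(order) + ln_mass:t_opt "
            "+ ln_mass:C(order) + t_opt:C(order)",
            data=table,
        ).fit()
        cmp = sm.stats.anova_lm(reduced, full)
        assert first.F == pytest.approx(cmp["F"].iloc[1], rel=1e-8)
        assert first.p == pytest.approx(cmp["Pr(>F)"].iloc[1], abs=1e-10)

    def test_strong_interactions_survive(self, rng):
        table = make_table(rng, n=400, d=-0.15, noise=0.1)
        ffit = inference.fit_factorial(
            table, terms=["ln_mass", "t_opt", "ln_mass:t_opt"], estimator="OLS"
        )
        final, log = inference.backward_eliminate(ffit, alpha=0.05)
        assert final.terms == ffit.terms
        assert all(not step.dropped for step in log)

    def test_marginality_preserved_through_elimination(self, rng):
        table = make_table(rng, d=0.0)
        ffit = inference.fit_factorial(table, estimator="OLS")
        final, log = inference.backward_eliminate(ffit, alpha=0.05)
        present = set(final.terms)
        for term in final.terms:
            fs = term.split(":")
            for k in range(1, len(fs)):
                assert ":".join(fs[:k]) in present or len(fs) == 1

    def test_negative_interaction_retained_under_high_signal(self, rng):
        kept = 0
        for _ in range(40):
            table = make_table(rng, n=250, d=-0.05, noise=0.2)
            ffit = inference.fit_factorial(table, estimator="OLS")
            final, _ = inference.backward_eliminate(ffit, alpha=0.05)
            if "ln_mass:t_opt" in final.terms:
                kept += final.fit.coef("ln_mass:t_opt") < 0
        assert kept >= 38


class TestPredictions:
    def test_one_mg_zeroes_mass_terms(self, rng):
        table = make_table(rng)
        ffit = inference.fit_factorial(
            table, terms=["ln_mass", "t_opt", "order"], estimator="OLS"
        )
        preds = inference.predict_standardized(ffit, min_n=1, t_opt_values=(30.0,))
        fit = ffit.fit
        ref_order = sorted(table["order"].unique())[0]
        base = fit.coef("Intercept") + 30.0 * fit.coef("t_opt")
        row = preds[(preds["order"] == ref_order)].iloc[0]
        assert row["ln_tdev_pred"] == pytest.approx(base, rel=1e-10)

    def test_matches_hand_linear_combination(self, rng):
        table = make_table(rng)
        ffit = inference.fit_factorial(
            table, terms=["ln_mass", "t_opt", "order", "ln_mass:t_opt"], estimator="OLS"
        )
        preds = inference.predict_standardized(ffit, min_n=1, t_opt_values=(25.0, 35.0))
        fit = ffit.fit
        coef = dict(zip(fit.names, fit.coefficients))
        for _, row in preds.iterrows():
            expect = coef["Intercept"] + row["t_opt"] * coef["t_opt"]
            key = f"C(order)[T.{row['order']}]"
            expect += coef.get(key, 0.0)
            # ln_mass = 0 kills mass and mass:t_opt terms
            assert row["ln_tdev_pred"] == pytest.approx(expect, rel=1e-10)
        # warmer optimum predicts faster development (negative t_opt effect)
        for order in preds["order"].unique():
            sub = preds[preds["order"] == order].sort_values("t_opt")
            assert sub["ln_tdev_pred"].iloc[-1] < sub["ln_tdev_pred"].iloc[0]


class TestBinnedSMA:
    def test_single_bin_equals_global_fit(self, rng):
        table = make_table(rng)
        bins = inference.binned_sma(table, bin_edges=(1000.0,))
        fit = bins["<1000"]
        ref = sma_fit(table["ln_mass"], table["ln_tdev"])
        assert fit.slope == pytest.approx(ref.slope)

    def test_bins_match_manual_subsets(self, rng):
        table = make_table(rng, n=300)
        edges = (28.0, 30.0, 33.0)
        bins = inference.binned_sma(table, bin_edges=edges)
        t = table["t_opt"]
        subsets = {
            "<28": table[t < 28],
            "[28,30)": table[(t >= 28) & (t < 30)],
            "[30,33)": table[(t >= 30) & (t < 33)],
            ">=33": table[t >= 33],
        }
        for label, sub in subsets.items():
            if len(sub) < 3:
                assert bins[label] is None
            else:
                ref = sma_fit(sub["ln_mass"], sub["ln_tdev"])
                assert bins[label].slope == pytest.approx(ref.slope)
                assert bins[label].n == len(sub)


class TestCovariateCheck:
    def test_perfect_dependence_rejected(self, rng):
        table = make_table(rng)
        table["t_opt"] = table["ln_mass"]
        row = inference.covariate_independence_check(table, include_order=False)
        assert row.p < 1e-10

    def test_independent_covariates_rarely_rejected(self, rng):
        rejections = 0
        for _ in range(100):
            table = make_table(rng, n=80)
            row = inference.covariate_independence_check(table)
            rejections += row.p < 0.05
        assert rejections <= 12

    def test_degrees_of_freedom_account_for_order(self, rng):
        table = make_table(rng, n=100, n_orders=5)
        row = inference.covariate_independence_check(table)
        assert row.df1 == 1
        assert row.df2 == 100 - 1 - 1 - 4  # n - intercept - mass - order dummies


class TestSubset:
    def test_counts_match_brute_force(self, rng):
        table = make_table(rng, n=120, n_orders=6)
        sub = inference.subset_min_species(table, min_n=15)
        counts = table["order"].value_counts()
        keep = {o for o, c in counts.items() if c >= 15}
        assert set(sub["order"]) == keep
        assert len(sub) == sum(counts[o] for o in keep)

    def test_min_one_is_identity(self, rng):
        table = make_table(rng)
        sub = inference.subset_min_species(table, min_n=1)
        assert len(sub) == len(table)

    def test_empty_result_rejected(self, rng):
        table = make_table(rng, n=40, n_orders=4)
        with pytest.raises(ValueError):
            inference.subset_min_species(table, min_n=1000)
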