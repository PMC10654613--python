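"""Survival machinery against hand enumeration and lifelines cross-checks."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

import epistrat as es
from epistrat.errors import DataContractError, NumericalError
from epistrat.survival import _efron_loglik, prognostic_residuals

from conftest import SMALL


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = es.km_estimate([3.0, 5.0, 7.0], [0, 0, 0])
        assert km.survival_at(10.0) == 1.0

    def test_all_events_product_limit(self):
        km = es.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_early_censoring_reduces_at_risk_only(self):
        plain = es.km_estimate([2.0, 3.0], [1, 1])
        censored = es.km_estimate([1.0, 2.0, 3.0], [0, 1, 1])
        np.testing.assert_allclose(censored.survival[0], plain.survival[0])
        assert censored.at_risk[0] == 2

    def test_equals_one_minus_ecdf_without_censoring(self, rng):
        t = rng.exponential(10.0, size=50)
        km = es.km_estimate(t, np.ones(50, dtype=int))
        for q in (0.25, 0.5, 0.75):
            x = np.quantile(t, q)
            assert km.survival_at(x) == pytest.approx((t > x).mean())


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        res = es.logrank_test([1, 1, 1, 2, 2, 2], t, e)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_risk_table_enumeration(self):
        """Four samples, group A events at {1,2}, B at {3,4}: oracle sums
        O-E and the hypergeometric variance over the four event times."""
        g = np.array([0, 0, 1, 1])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        o_minus_e = 0.0
        var = 0.0
        for tau in t:
            risk = t >= tau
            n_j = risk.sum()
            n_a = (risk & (g == 0)).sum()
            d_a = 1.0 if (t == tau).any() and g[t == tau][0] == 0 else 0.0
            o_minus_e += d_a - n_a / n_j
            var += (n_a / n_j) * (1 - n_a / n_j)  # d_j=1, (n-d)/(n-1) handled
            # with d_j = 1 the factor d_j (n_j - d_j)/(n_j - 1) is
            # (n_j - 1)/(n_j - 1) = 1 except when n_j = 1 (variance 0)
            if n_j == 1:
                var -= (n_a / n_j) * (1 - n_a / n_j)
        expected = o_minus_e ** 2 / var
        res = es.logrank_test(g, t, e)
        assert res["chi2"] == pytest.approx(expected, abs=1e-9)
        assert res["df"] == 1

    def test_three_groups_have_two_degrees_of_freedom(self, rng):
        t = rng.exponential(10.0, 30)
        res = es.logrank_test(np.repeat([1, 2, 3], 10), t, np.ones(30, int))
        assert res["df"] == 2

    def test_matches_lifelines_on_random_data(self, rng):
        t = rng.exponential(50.0, size=120)
        c = rng.uniform(0, 80, size=120)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        g = rng.integers(0, 3, size=120)
        ours = es.logrank_test(g, obs, ev)
        ref = multivariate_logrank_test(obs, g, ev)
        assert ours["chi2"] == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_invariant_to_relabeling_and_time_shift(self, rng):
        t = rng.exponential(10.0, 40)
        ev = rng.integers(0, 2, 40)
        ev[0] = 1
        g = rng.integers(0, 2, 40)
        base = es.logrank_test(g, t, ev)["chi2"]
        assert es.logrank_test(1 - g, t, ev)["chi2"] == pytest.approx(base)
        assert es.logrank_test(g, t + 7.0, ev)["chi2"] == pytest.approx(base)

    def test_zero_events_flagged(self):
        res = es.logrank_test([1, 2], [1.0, 2.0], [0, 0])
        assert res["p"] == 1.0 and "no_events" in res["flags"]


class TestCox:
    @staticmethod
    def _simulate(rng, n=300, beta=(0.7, -0.3)):
        x = rng.normal(size=(n, len(beta)))
        t = rng.exponential(1.0 / (1e-3 * np.exp(x @ np.array(beta))))
        c = rng.uniform(0, 2500, n)
        return (pd.DataFrame(x, columns=[f"x{i}" for i in range(len(beta))]),
                np.minimum(t, c), (t <= c).astype(int))

    def test_matches_lifelines_estimates(self, rng):
        X, t, e = self._simulate(rng)
        fit = es.cox_fit(X, t, e)
        df = X.copy()
        df["T"], df["E"] = t, e
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.params["coef"], ref.params_, atol=2e-4)
        np.testing.assert_allclose(fit.params["se"], ref.standard_errors_,
                                   atol=1e-4)

    def test_null_covariate_estimates_near_zero(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(500, 1))
            t = rng.exponential(1000.0, 500)
            fit = es.cox_fit(x, t, np.ones(500, int))
            hits += abs(fit.params["coef"].iloc[0]) < 0.15
        assert hits >= 45

    def test_score_test_at_zero_equals_logrank_without_ties(self, rng):
        t = np.sort(rng.exponential(10.0, 60)) + np.arange(60) * 1e-6  # tie-free
        g = rng.integers(0, 2, 60).astype(float)
        e = np.ones(60, int)
        _, grad, hess = _efron_loglik(np.zeros(1), g[:, None] - g.mean(), t, e)
        score_stat = float(grad @ np.linalg.solve(-hess, grad))
        lr = es.logrank_test(g, t, e)["chi2"]
        assert score_stat == pytest.approx(lr, abs=1e-6)

    def test_perfect_separation_flagged(self):
        t = np.arange(1.0, 21.0)
        g = (t > 10).astype(float)  # binary covariate ordering all times
        fit = es.cox_fit(g[:, None], t, np.ones(20, int))
        assert not fit.converged
        assert "monotone_likelihood" in fit.flags

    def test_constant_covariate_rejected(self):
        with pytest.raises(DataContractError):
            es.cox_fit(np.ones((10, 1)), np.arange(1.0, 11.0), np.ones(10, int))


class TestCompareClusters:
    def test_planted_hazard_detected_with_adjustment(self, stratified,
                                                     normalized):
        out = es.compare_clusters(stratified["consensus"].labels,
                                  normalized["clinical"])
        assert out["pfi"]["logrank"]["p"] < 0.05
        assert out["pfi"]["cox"].p("cluster") < 0.05
        assert {"pfi", "dss", "os"} <= set(out)

    def test_collinear_adjustment_flagged_and_dropped(self, stratified,
                                                      normalized):
        clin = normalized["clinical"].copy()
        labels = stratified["consensus"].labels
        clin["shadow"] = (labels == sorted(labels.unique())[1]).astype(float)
        out = es.compare_clusters(labels, clin, adjust_for=("age", "shadow"))
        assert any(f.startswith("collinear") for f in out["pfi"]["flags"])
        assert "shadow" not in out["pfi"]["cox"].params.index


class TestOptimalCutpoint:
    def test_recovers_planted_separation(self, rng):
        n = 120
        group = rng.integers(0, 2, n)
        expr = group + rng.normal(0, 1e-3, n)
        t = rng.exponential(1.0 / (1e-3 * np.exp(1.5 * group)))
        cp = es.optimal_cutpoint(expr, t, np.ones(n, int))
        assert np.array_equal(cp["high"], group == 1)

    def test_minprop_excludes_extremes(self):
        x = np.arange(100, dtype=float)
        t = np.random.default_rng(0).exponential(10.0, 100)
        cp = es.optimal_cutpoint(x, t, np.ones(100, int), minprop=0.1)
        assert 9.0 <= cp["cutpoint"] <= 89.0

    def test_constant_expression_errors(self):
        with pytest.raises(NumericalError):
            es.optimal_cutpoint(np.ones(20), np.arange(1.0, 21.0),
                                np.ones(20, int))


class TestPrognosticScreen:
    def test_excluded_gene_reported_non_variable(self, normalized):
        genes = list(normalized["selection"].genes[:3]) + ["NOT_PRESENT"]
        table = es.prognostic_screen(normalized["norm"],
                                     normalized["clinical"], genes,
                                     excluded=["NOT_PRESENT"])
        row = table.loc["NOT_PRESENT"]
        assert not row["prognostic"] and row["reason"] == "non-variable"
        assert (table["adj_p"].dropna() >= table["p"].dropna() - 1e-12).all()


class TestMetaPcna:
    def test_recovers_planted_module(self, cohort):
        norm = es.normalize_log2(cohort["counts"],
                                 es.size_factors(cohort["counts"]))
        sig, score = es.meta_pcna(norm)
        module = set(cohort["truth"].gene_role.index[
            cohort["truth"].gene_role == "proliferation"]) - {"PCNA"}
        assert len(sig) == int(np.ceil(0.01 * (norm.shape[0] - 1)))
        assert len(set(sig) & module) / len(module) >= 0.8
        assert score.index.equals(norm.columns)

    def test_top_frac_boundary_single_gene(self, rng):
        norm = pd.DataFrame(rng.normal(size=(20, 30)),
                            index=[f"g{i}" for i in range(19)] + ["PCNA"])
        norm.loc["g0"] = norm.loc["PCNA"] * 2 + rng.normal(0, 1e-6, 30)
        sig, _ = es.meta_pcna(norm, top_frac=1e-9)
        assert sig == ["g0"]

    def test_missing_or_constant_anchor_errors(self, rng):
        norm = pd.DataFrame(rng.normal(size=(5, 10)))
        with pytest.raises(DataContractError):
            es.meta_pcna(norm)
        norm2 = pd.DataFrame(np.vstack([np.ones(10), rng.normal(size=(4, 10))]),
                             index=["PCNA", "a", "b", "c", "d"])
        with pytest.raises(NumericalError):
            es.meta_pcna(norm2)

    def test_adjustment_removes_proliferation_only_associations(self):
        """Two-pathway simulation: genes linked to outcome only through a
        shared proliferation factor lose their prognostic flag (BH-adjusted
        within the screened panel) once the meta-PCNA score enters the
        model; directly prognostic genes keep it."""
        removed, kept = 0, 0
        n_rep = 5
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n, n_noise = 250, 1000
            factor = rng.normal(size=n)
            direct = rng.normal(size=n)
            genes = {"PCNA": factor + rng.normal(0, 0.3, n)}
            for i in range(30):  # proliferation-coupled genes
                genes[f"prolif{i}"] = factor + rng.normal(0, 0.3, n)
            genes["direct"] = direct
            for i in range(n_noise):
                genes[f"noise{i}"] = rng.normal(size=n)
            norm = pd.DataFrame(genes).T
            norm.columns = [f"S{i}" for i in range(n)]
            hazard = 1e-3 * np.exp(0.8 * factor + 0.9 * direct)
            t = rng.exponential(1.0 / hazard)
            clin = pd.DataFrame({
                "time_pfi": t, "event_pfi": 1,
                "age": rng.normal(60, 10, n),
                "sex": rng.choice(["F", "M"], n)}, index=norm.columns)
            panel = ([f"prolif{i}" for i in range(30)] + ["direct"]
                     + [f"noise{i}" for i in range(29)])
            plain = es.prognostic_screen(norm, clin, panel)
            _, score = es.meta_pcna(norm)
            clin["meta_pcna_score"] = score
            adj = es.prognostic_screen(norm, clin, panel,
                                       adjust_for=("age", "sex",
                                                   "meta_pcna_score"))
            if (bool(plain.loc["prolif0", "prognostic"])
                    and not bool(adj.loc["prolif0", "prognostic"])):
                removed += 1
            if bool(adj.loc["direct", "prognostic"]):
                kept += 1
        assert removed >= 0.8 * n_rep
        assert kept >= 0.8 * n_rep


class TestPrognosticResiduals:
    @staticmethod
    def _table(direction_by_gene):
        rows = [{"gene": gene, "direction": direction or "",
                 "prognostic": direction is not None}
                for gene, direction in direction_by_gene.items()]
        return pd.DataFrame(rows, columns=["gene", "direction",
                                           "prognostic"]).set_index("gene")

    def test_residual_definition_and_exclusions(self):
        ann = pd.DataFrame({"category": ["histone modification"] * 2},
                           index=["g1", "g2"])
        tables = {
            f"cohort{i}": self._table({"g1": "poor-with-high",
                                       "g2": None})
            for i in range(3)
        }
        tables["cohort3"] = self._table({"g1": "poor-with-low", "g2": None})
        out = prognostic_residuals(tables, ann, groupings=("all",))
        assert out.residuals.loc["g1", "residual"] == 2
        assert out.residuals.loc["g2", "residual"] == 0
        row = out.group_tests.iloc[0]
        assert row["n_positive"] == 1 and row["n_negative"] == 0

    def test_exact_sign_test_value(self):
        ann = pd.DataFrame({"category": ["other"] * 10},
                           index=[f"g{i}" for i in range(10)])
        direction = {f"g{i}": "poor-with-high" for i in range(8)}
        direction.update({f"g{i}": "poor-with-low" for i in range(8, 10)})
        tables = {"c1": self._table(direction), "c2": self._table({})}
        out = prognostic_residuals(tables, ann, groupings=("all",))
        row = out.group_tests.iloc[0]
        assert (row["n_positive"], row["n_negative"]) == (8, 2)
        assert row["p"] == pytest.approx(112 / 1024)

    def test_unknown_grouping_errors(self):
        with pytest.raises(DataContractError):
            prognostic_residuals({"a": self._table({}), "b": self._table({})},
                                 pd.DataFrame(), groupings=("nope",))
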