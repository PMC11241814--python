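import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carlogit.evaluation import (
    comparison_table,
    dic,
    fit_metrics,
    posterior_odds_ratios,
    prevalence_difference,
    select_structure,
)
from carlogit.sampler import PosteriorFit


class TestDIC:
    def test_degenerate_posterior(self):
        out = dic([100.0, 100.0, 100.0], 100.0)
        assert out.p_d == 0.0
        assert out.dic == 100.0

    def test_direct_formula(self):
        out = dic([105.0, 115.0], 100.0)  # mean 110
        assert out.p_d == pytest.approx(10.0)
        assert out.dic == pytest.approx(120.0)

    @given(st.floats(-50, 50))
    def test_affine_shift_identity(self, c):
        d = np.array([90.0, 100.0, 110.0, 104.0])
        base = dic(d, 97.0)
        shifted = dic(d + c, 97.0 + c)
        assert shifted.p_d == pytest.approx(base.p_d)
        assert shifted.dic == pytest.approx(base.dic + c)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            dic([100.0, np.inf], 100.0)
        with pytest.raises(ValueError):
            dic([100.0], 100.0)


class TestSelectStructure:
    def test_all_spatial_tied_prefers_iid(self):
        dics = {"Base": 14023, "IID": 12347, "Besag": 12347, "IID_Besag": 12347}
        assert select_structure(dics) == "IID"

    def test_besag_wins_when_iid_is_worse(self):
        dics = {"Base": 14444, "IID": 14412, "Besag": 14407, "IID_Besag": 14408}
        assert select_structure(dics) == "Besag"

    def test_exact_ties_give_base(self):
        dics = {"Base": 100.0, "IID": 100.0, "Besag": 100.0, "IID_Besag": 100.0}
        assert select_structure(dics) == "Base"

    def test_comparison_table_single_selection(self):
        dics = {"Base": 120.0, "IID": 100.0, "Besag": 100.5, "IID_Besag": 101.9}
        table = comparison_table(dics)
        assert table["selected"].sum() == 1
        sel = table.loc[table["selected"], "structure"].iloc[0]
        assert sel == "IID"
        assert table.loc[table["selected"], "dic"].iloc[0] <= table["dic"].min() + 2

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            select_structure({"Base": np.nan, "IID": 1.0,
                              "Besag": 2.0, "IID_Besag": 3.0})


def _fit_with_beta(draws_by_name, categorical_levels=None):
    names = list(draws_by_name)
    beta = np.column_stack([np.asarray(draws_by_name[n], dtype=float)
                            for n in names])
    return PosteriorFit(
        draws={"beta": beta, "beta0": np.zeros(beta.shape[0])},
        n_chains=1, n_retained_per_chain=beta.shape[0],
        x_names=names, states=(), bin_labels={},
        categorical_levels=categorical_levels or {})


class TestPosteriorOddsRatios:
    def test_zero_draws_give_unit_por(self):
        fit = _fit_with_beta({"x=1": np.zeros(50)})
        por = posterior_odds_ratios(fit)
        row = por.iloc[0]
        assert row["por"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_degenerate_log2_draws(self):
        fit = _fit_with_beta({"x=1": np.full(50, np.log(2.0))})
        row = posterior_odds_ratios(fit).iloc[0]
        assert row["por"] == pytest.approx(2.0)
        assert row["ci_2.5"] == pytest.approx(2.0)
        assert row["ci_97.5"] == pytest.approx(2.0)
        assert row["significant"]

    @pytest.mark.parametrize("lo,hi,expected", [
        (0.9, 1.2, False), (1.05, 1.8, True), (0.4, 0.9, True)])
    def test_significance_flag_rule(self, lo, hi, expected):
        # construct draws whose 2.5/97.5 quantiles exponentiate to (lo, hi)
        q = np.linspace(0.001, 0.999, 2001)
        mu = (np.log(lo) + np.log(hi)) / 2
        sd = (np.log(hi) - np.log(lo)) / (2 * 1.959964)
        from scipy.stats import norm
        draws = norm.ppf(q, loc=mu, scale=sd)
        row = posterior_odds_ratios(_fit_with_beta({"x=1": draws})).iloc[0]
        assert row["ci_2.5"] == pytest.approx(lo, rel=0.02)
        assert row["ci_97.5"] == pytest.approx(hi, rel=0.02)
        assert bool(row["significant"]) is expected

    def test_reference_level_is_unit_without_interval(self):
        fit = _fit_with_beta(
            {"residence=urban": np.full(20, 0.3)},
            categorical_levels={"residence": ("rural", ("urban",))})
        por = posterior_odds_ratios(fit)
        ref = por[por["level"] == "rural (ref)"].iloc[0]
        assert ref["por"] == 1.0
        assert np.isnan(ref["ci_2.5"]) and np.isnan(ref["ci_97.5"])


class TestFitMetrics:
    def test_identity(self):
        m = fit_metrics([10, 20, 30], [10, 20, 30])
        assert (m.r2, m.rmse, m.mae) == (pytest.approx(1.0), 0.0, 0.0)

    def test_hand_computed_example(self):
        m = fit_metrics([10, 20, 30], [12, 18, 33])
        assert m.rmse == pytest.approx(np.sqrt((4 + 4 + 9) / 3), abs=1e-9)
        assert m.mae == pytest.approx((2 + 2 + 3) / 3, abs=1e-9)

    def test_shift_invariance_of_r2(self):
        obs = np.array([5.0, 15.0, 25.0, 40.0])
        m = fit_metrics(obs, obs + 5)
        assert m.r2 == pytest.approx(1.0)
        assert m.mae == pytest.approx(5.0)

    def test_zero_variance_r2_undefined(self):
        m = fit_metrics([10, 10, 10], [9, 11, 10])
        assert np.isnan(m.r2)
        assert m.rmse > 0

    def test_sum_of_squares_variant(self):
        obs = np.array([10.0, 20.0, 30.0])
        m = fit_metrics(obs, obs + 5, r2_method="ss")
        assert m.r2 < 1.0  # penalised for the bias, unlike correlation R2


class TestPrevalenceDifference:
    def _table(self, vals):
        return pd.DataFrame({"state_id": list("abc"),
                             "predicted_pct": vals})

    def test_identical_tables_zero(self):
        t = self._table([10.0, 20.0, 30.0])
        diff = prevalence_difference(t, t)
        assert (diff["difference_pct"] == 0).all()

    def test_sign_convention_increase_positive(self):
        a = self._table([20.0, 10.0, 5.0])
        b = self._table([38.9, 10.0, 5.0])
        diff = prevalence_difference(a, b).set_index("state_id")
        assert diff.loc["a", "difference_pct"] == pytest.approx(18.9)

    def test_antisymmetry(self):
        a = self._table([20.0, 12.0, 7.0])
        b = self._table([25.0, 9.0, 7.5])
        ab = prevalence_difference(a, b)["difference_pct"].to_numpy()
        ba = prevalence_difference(b, a)["difference_pct"].to_numpy()
        np.testing.assert_allclose(ab, -ba)

    def test_mismatched_states_listed(self):
        a = self._table([1.0, 2.0, 3.0])
        b = a.copy()
        b["state_id"] = list("abd")
        with pytest.raises(ValueError, match="'c', 'd'"):
            prevalence_difference(a, b)


def test_observed_vs_predicted_plot_axes():
    from carlogit.plots import observed_vs_predicted

    table = pd.DataFrame({"state_id": [0, 1, 2],
                          "observed_pct": [10.0, 20.0, 30.0],
                          "predicted_pct": [12.0, 18.0, 33.0]})
    ax = observed_vs_predicted(table)
    assert ax.get_xlabel().startswith("observed")
    assert len(ax.collections) == 1  # the scatter layer
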