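"""Predictive checks, SRMR, WAIC and model-comparison machinery."""

import numpy as np
import pandas as pd
import pytest

import gmltmd as g
from gmltmd.evaluation import (
    PredictiveSummary,
    srmr_from_stats,
    _summary_stats,
)
from gmltmd.structures import ComposedItemParameters


def _summary_from(dobs, lower, eap, upper):
    J = len(dobs)
    t = pd.DataFrame({
        "item": [str(j + 1) for j in range(J)],
        "lower": lower, "eap": eap, "upper": upper, "dobs": dobs,
    })
    t["outside"] = (t["dobs"] < t["lower"]) | (t["dobs"] > t["upper"])
    return PredictiveSummary(table=t, n_replicates=100)


class TestWaic:
    def test_two_draw_hand_oracle(self):
        # one cell, two draws: ll = {log 0.5, log 0.25}
        ll = np.log(np.array([[0.5], [0.25]]))[:, :, None]
        w, lppd, p_w = g.waic(ll)
        assert lppd == pytest.approx(np.log(0.375), abs=1e-12)
        expected_var = np.var([np.log(0.5), np.log(0.25)], ddof=1)
        assert p_w == pytest.approx(expected_var, abs=1e-12)
        assert w == pytest.approx(-2 * (np.log(0.375) - expected_var), abs=1e-12)

    def test_duplicated_draw_has_zero_penalty(self):
        base = np.log(np.array([[0.3, 0.8], [0.3, 0.8]]))[:, :, None]
        w, lppd, p_w = g.waic(base)
        assert p_w == 0.0
        assert w == pytest.approx(-2 * np.sum(np.log([0.3, 0.8])), abs=1e-12)

    def test_additivity_over_identical_cells(self):
        ll = np.log(np.array([[0.5], [0.25]]))[:, :, None]
        ll2 = np.concatenate([ll, ll], axis=2)
        w1, lppd1, p1 = g.waic(ll)
        w2, lppd2, p2 = g.waic(ll2)
        assert lppd2 == pytest.approx(2 * lppd1, abs=1e-12)
        assert p2 == pytest.approx(2 * p1, abs=1e-12)

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError, match=">= 2 draws"):
            g.waic(np.zeros((1, 2, 2)))

    def test_nonfinite_cell_named(self):
        ll = np.zeros((2, 1, 2))
        ll[1, 0, 1] = -np.inf
        with pytest.raises(ValueError, match=r"draw 1, cell \(0, 1\)"):
            g.waic(ll)

    def test_all_nan_cells_are_missing(self):
        ll = np.log(np.array([[0.5, np.nan], [0.25, np.nan]]))[:, :, None]
        ll = ll.reshape(2, 1, 2)
        w, lppd, _ = g.waic(ll)
        assert lppd == pytest.approx(np.log(0.375), abs=1e-12)

    def test_matches_arviz_on_random_input(self):
        # independent cross-check; arviz's penalty uses the population
        # variance (ddof=0) where ours is the sample variance (ddof=1)
        import arviz as az

        rng = np.random.default_rng(5)
        S = 80
        ll = np.log(rng.uniform(0.05, 0.95, size=(2, S // 2, 6, 3)))
        idata = az.from_dict(log_likelihood={"y": ll})
        with pytest.warns(UserWarning):
            ref = az.waic(idata, scale="deviance")
        w, lppd, p_w = g.waic(ll.reshape(S, 6, 3))
        ref_p = float(ref.p_waic)
        ref_lppd = -0.5 * float(ref.elpd_waic) + ref_p
        assert lppd == pytest.approx(ref_lppd, rel=1e-10)
        assert p_w * (S - 1) / S == pytest.approx(ref_p, rel=1e-10)
        assert w == pytest.approx(-2 * (lppd - p_w), abs=1e-12)


class TestIntervalMetrics:
    def test_discordance_zero_when_all_inside(self):
        ps = _summary_from([0.5] * 5, [0.4] * 5, [0.5] * 5, [0.6] * 5)
        assert g.discordance_rate(ps) == 0.0
        assert g.interval_bias(ps) == 0.0

    def test_discordance_one_when_all_outside(self):
        ps = _summary_from([0.9] * 5, [0.4] * 5, [0.5] * 5, [0.6] * 5)
        assert g.discordance_rate(ps) == 1.0

    def test_discordance_counts_fraction(self):
        dobs = [0.5] * 23 + [0.9] * 4
        ps = _summary_from(dobs, [0.4] * 27, [0.5] * 27, [0.6] * 27)
        assert g.discordance_rate(ps) == pytest.approx(4 / 27)

    def test_interval_bias_mean_exceedance(self):
        # one of two items outside by 0.04
        ps = _summary_from([0.5, 0.64], [0.4, 0.4], [0.5, 0.5], [0.6, 0.6])
        assert g.interval_bias(ps) == pytest.approx(0.02)

    def test_item_order_invariance(self):
        rng = np.random.default_rng(9)
        dobs = rng.uniform(size=12)
        lower = dobs - rng.uniform(0, 0.1, 12)
        upper = dobs + rng.uniform(0, 0.1, 12)
        upper[3] = dobs[3] - 0.05    # force one outside
        ps = _summary_from(dobs, lower, (lower + upper) / 2, upper)
        perm = rng.permutation(12)
        ps_perm = PredictiveSummary(
            table=ps.table.iloc[perm].reset_index(drop=True), n_replicates=100)
        assert g.discordance_rate(ps) == pytest.approx(g.discordance_rate(ps_perm))
        assert g.interval_bias(ps) == pytest.approx(g.interval_bias(ps_perm))


class TestSrmr:
    def test_identical_stats_give_zero(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, (50, 6))
        props, corr = _summary_stats(y, np.ones_like(y, dtype=bool))
        assert srmr_from_stats(props, corr, props, corr) == 0.0

    def test_closed_form_for_uniform_proportion_shift(self):
        # every proportion off by 0.1, correlations matching:
        # rms over J + J(J-1)/2 pooled residuals
        J = 6
        props = np.full(J, 0.5)
        corr = np.eye(J)
        val = srmr_from_stats(props, corr, props - 0.1, corr)
        expected = 0.1 * np.sqrt(J / (J + J * (J - 1) / 2))
        assert val == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_item_excluded(self, caplog):
        y = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0]])   # item 1 constant
        props, corr = _summary_stats(y, np.ones_like(y, dtype=bool))
        assert np.isnan(corr[0, 1])
        val = srmr_from_stats(props, corr, props, corr)
        assert val == 0.0


class TestPosteriorPredictive:
    def test_point_mass_draws_give_binomial_spread(self, tiny_fit):
        """A fit whose draws are one repeated point must produce intervals
        equal to pure binomial replicate noise."""
        import dataclasses

        fit, y = tiny_fit
        const = {}
        for k, v in fit.draws.items():
            rep = np.broadcast_to(v[:1, :1], v.shape).copy()
            const[k] = rep
        point = dataclasses.replace(fit, draws=const)
        ps = g.posterior_predictive_marginals(point, y, n_replicates=400, seed=4)
        from gmltmd.evaluation import _draw_probabilities

        p = _draw_probabilities(point, 0, 0)
        N = p.shape[0]
        # replicate-proportion variance = mean_i p(1-p) / N per item
        expected_sd = np.sqrt(np.sum(p * (1 - p), axis=0)) / N
        width = ps.table["upper"] - ps.table["lower"]
        np.testing.assert_allclose(width, 2 * 1.96 * expected_sd,
                                   rtol=0.35, atol=0.02)

    def test_reproducible_with_seed(self, tiny_fit):
        fit, y = tiny_fit
        a = g.posterior_predictive_marginals(fit, y, n_replicates=50, seed=3)
        b = g.posterior_predictive_marginals(fit, y, n_replicates=50, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_intervals_widen_with_draw_dispersion(self, tiny_fit):
        import dataclasses

        fit, y = tiny_fit
        ps_base = g.posterior_predictive_marginals(fit, y, n_replicates=300,
                                                   seed=5)
        wide = {k: v.copy() for k, v in fit.draws.items()}
        center = wide["eta"].mean(axis=(0, 1), keepdims=True)
        wide["eta"] = center + 3.0 * (wide["eta"] - center)
        ps_wide = g.posterior_predictive_marginals(
            dataclasses.replace(fit, draws=wide), y, n_replicates=300, seed=5)
        assert (ps_wide.table["upper"] - ps_wide.table["lower"]).mean() > \
            (ps_base.table["upper"] - ps_base.table["lower"]).mean()


class TestPriorPredictive:
    def test_bounds_and_guessing_floor(self, analogy_q, analogy_cs):
        tab = g.prior_predictive_check(g.PriorSpec(), analogy_q, analogy_cs,
                                       "gmltmd", n_sim=150, seed=2,
                                       n_persons=200)
        assert (tab["q2.5"] >= 0).all() and (tab["q97.5"] <= 1).all()
        assert tab["q2.5"].min() > 0    # guessing floor keeps proportions off 0

    def test_point_mass_collapses_to_analytic_marginal(self, analogy_q,
                                                       analogy_cs,
                                                       analogy_truth):
        from scipy.stats import norm
        from gmltmd.simulate import success_probabilities

        tab = g.prior_predictive_check(
            g.PriorSpec(), analogy_q, analogy_cs, "gmltmd", n_sim=150, seed=3,
            n_persons=2000, fixed_params=analogy_truth)
        # analytic marginal by Gauss-Hermite-style quadrature over theta
        nodes = norm.ppf(np.linspace(0.0005, 0.9995, 400))
        wts = np.full(nodes.size, 1.0 / nodes.size)
        pts = np.array(np.meshgrid(nodes[::8], nodes[::8], indexing="ij"))
        pts = pts.reshape(2, -1).T
        p = success_probabilities("gmltmd", analogy_q, analogy_cs,
                                  analogy_truth, pts)
        marginal = p.mean(axis=0)
        np.testing.assert_allclose(tab["mean"], marginal, atol=0.03)

    def test_small_n_sim_rejected(self, analogy_q, analogy_cs):
        with pytest.raises(ValueError, match="n_sim"):
            g.prior_predictive_check(g.PriorSpec(), analogy_q, analogy_cs,
                                     "gmltmd", n_sim=10)


class TestCompareModels:
    def test_single_model_table(self, tiny_fit):
        fit, y = tiny_fit
        tab = g.compare_models([fit], y, n_replicates=60, seed=1)
        assert len(tab.table) == 1
        assert tab.ranking == ["gmltmd"]

    def test_identical_fits_tie_broken_by_name(self, tiny_fit):
        import dataclasses

        fit, y = tiny_fit
        clone = dataclasses.replace(fit, model_kind="aaa_clone")
        tab = g.compare_models([fit, clone], y, n_replicates=60, seed=1)
        assert tab.table["waic"].nunique() == 1
        assert tab.ranking == ["aaa_clone", "gmltmd"]

    def test_shape_mismatch_rejected(self, tiny_fit):
        fit, _ = tiny_fit
        _, _, _, other = g.study_fixture(seed=1, n_persons=11)
        with pytest.raises(ValueError, match="same response matrix"):
            g.compare_models([fit], other)


class TestIccCurve:
    def _composed_item(self):
        return ComposedItemParameters(
            difficulty=np.array([[1.16, 0.08]]),
            active=np.array([[True, True]]),
            discrimination=np.array([[1.66, 1.78]]),
            guessing=np.array([0.08]),
            component_ids=("global", "local"),
        )

    def test_left_asymptote_is_guessing(self):
        tab = g.icc_curve(0, self._composed_item(), np.linspace(-30, 4, 100))
        assert tab["joint"].iloc[0] == pytest.approx(0.08, abs=1e-6)

    def test_component_curve_crosses_half_at_difficulty(self):
        comp = self._composed_item()
        tab = g.icc_curve(0, comp, np.array([1.16, 0.08]))
        assert tab["component_global"].iloc[0] == pytest.approx(0.5)
        assert tab["component_local"].iloc[1] == pytest.approx(0.5)

    def test_steeper_slope_with_larger_alpha(self):
        comp = self._composed_item()
        steep = ComposedItemParameters(
            difficulty=comp.difficulty, active=comp.active,
            discrimination=comp.discrimination * 2,
            guessing=comp.guessing, component_ids=comp.component_ids)
        h = 1e-4
        grid = np.array([1.16 - h, 1.16 + h])
        d1 = np.diff(g.icc_curve(0, comp, grid)["component_global"])[0] / (2 * h)
        d2 = np.diff(g.icc_curve(0, steep, grid)["component_global"])[0] / (2 * h)
        assert d2 > d1 * 1.5

    def test_nonfinite_grid_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            g.icc_curve(0, self._composed_item(), np.array([0.0, np.inf]))
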