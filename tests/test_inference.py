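"""Model construction, posterior structure, diagnostics and summaries."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import kstest, beta, halfnorm

import gmltmd as g
from gmltmd.inference import build_model_structure, make_logpost
from gmltmd.simulate import ResponseMatrix


class TestLogPosteriorGradient:
    @pytest.mark.parametrize("kind", ["lltm", "c2pl", "mltmd", "gmltmd"])
    def test_gradient_matches_finite_differences(self, kind):
        q, cs, params, y = g.study_fixture(seed=3, n_persons=15)
        ms = replace(build_model_structure(q, cs, kind), n_persons=15)
        obs = y.observed.copy()
        obs[0, 0] = False     # one missing cell must drop out cleanly
        f = make_logpost(ms, y.entries, obs, g.PriorSpec())
        rng = np.random.default_rng(0)
        x = 0.3 * rng.standard_normal(ms.dim)
        _, grad = f(x)
        eps = 1e-6
        num = np.empty_like(x)
        for i in range(ms.dim):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num[i] = (f(xp)[0] - f(xm)[0]) / (2 * eps)
        np.testing.assert_allclose(grad, num, rtol=2e-5, atol=2e-5)

    def test_missing_cells_do_not_contribute(self):
        q, cs, params, y = g.study_fixture(seed=4, n_persons=10)
        ms = replace(build_model_structure(q, cs, "gmltmd"), n_persons=10)
        obs_all = np.ones_like(y.observed)
        obs_drop = obs_all.copy()
        obs_drop[2, 5] = False
        f_all = make_logpost(ms, y.entries, obs_all, g.PriorSpec())
        f_drop = make_logpost(ms, y.entries, obs_drop, g.PriorSpec())
        x = 0.2 * np.random.default_rng(1).standard_normal(ms.dim)
        # flipping the masked response changes nothing once it is masked
        y2 = y.entries.copy()
        y2[2, 5] = 1 - y2[2, 5]
        f_drop_flipped = make_logpost(ms, y2, obs_drop, g.PriorSpec())
        assert f_drop(x)[0] == f_drop_flipped(x)[0]
        assert f_all(x)[0] != f_drop(x)[0]


class TestModelStructure:
    def test_parameter_count_contract(self, tiny_fit):
        fit, _ = tiny_fit
        N = fit.structure.n_persons
        assert fit.draws["eta"].shape[-1] == 5
        assert fit.draws["alpha"].shape[-1] == 7
        assert fit.draws["guessing"].shape[-1] == 27
        assert fit.draws["theta"].shape[-2:] == (N, 2)

    def test_lltm_collapses_to_single_component(self, analogy_q, analogy_cs):
        ms = build_model_structure(analogy_q, analogy_cs, "lltm")
        assert ms.n_components == 1
        assert ms.n_eta == 5
        assert not ms.has_alpha and not ms.has_guessing

    def test_c2pl_has_per_item_slopes(self, analogy_q, analogy_cs):
        ms = build_model_structure(analogy_q, analogy_cs, "c2pl")
        assert ms.n_groups == 27
        assert ms.n_components == 1

    def test_unknown_kind_rejected(self, analogy_q, analogy_cs):
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model_structure(analogy_q, analogy_cs, "rasch")


class TestFitModel:
    def test_label_mismatch_rejected(self, analogy_q, analogy_cs):
        _, _, _, y = g.study_fixture(seed=5, n_persons=5)
        bad = ResponseMatrix(entries=y.entries, observed=y.observed,
                             person_ids=y.person_ids,
                             item_ids=tuple(f"x{j}" for j in range(27)))
        with pytest.raises(ValueError, match="labels do not match"):
            g.fit_model(bad, analogy_q, analogy_cs, "lltm")

    def test_seed_determinism(self, analogy_q, analogy_cs):
        _, _, _, y = g.study_fixture(seed=6, n_persons=20)
        cfg = g.SamplerConfig(chains=2, warmup=50, samples=50, seed=123)
        f1 = g.fit_model(y, analogy_q, analogy_cs, "lltm", cfg=cfg)
        f2 = g.fit_model(y, analogy_q, analogy_cs, "lltm", cfg=cfg)
        np.testing.assert_array_equal(f1.draws["eta"], f2.draws["eta"])
        np.testing.assert_array_equal(f1.draws["theta"], f2.draws["theta"])

    def test_likelihood_matches_kernel(self, tiny_fit, analogy_q, analogy_cs,
                                       analogy_partition):
        """exp(pointwise loglik) equals the kernel probability to 1e-10."""
        fit, y = tiny_fit
        ll = fit.pointwise_loglik
        rng = np.random.default_rng(8)
        n_chains, n_draws = fit.draws["theta"].shape[:2]
        for _ in range(50):
            ci = rng.integers(n_chains)
            di = rng.integers(n_draws)
            i = rng.integers(fit.structure.n_persons)
            j = rng.integers(27)
            alpha = {gi: fit.draws["alpha"][ci, di, gi] for gi in range(7)}
            eta = {p: fit.draws["eta"][ci, di, e]
                   for e, p in enumerate(fit.structure.eta_pairs)}
            params = g.ParameterSet(
                theta=fit.draws["theta"][ci, di],
                eta=eta, alpha=alpha,
                guessing=fit.draws["guessing"][ci, di],
            )
            composed = g.expand_composed(analogy_q, analogy_cs, params,
                                         analogy_partition)
            p = g.prob_gmltmd(fit.draws["theta"][ci, di, i], j, composed)
            expected = p if y.entries[i, j] == 1 else 1 - p
            s = ci * n_draws + di
            assert np.exp(ll[s, i, j]) == pytest.approx(expected, abs=1e-10)


class TestPriorReproduction:
    def test_posterior_equals_prior_given_no_data(self, analogy_q, analogy_cs):
        """With every response missing, the sampled posterior must reproduce
        the priors (Kolmogorov–Smirnov at the 1% level on thinned draws)."""
        N, J = 3, 27
        y = ResponseMatrix(entries=np.zeros((N, J), dtype=np.int8),
                           observed=np.zeros((N, J), dtype=bool),
                           person_ids=tuple(f"p{i}" for i in range(N)),
                           item_ids=analogy_q.item_ids)
        fit = g.fit_model(y, analogy_q, analogy_cs, "gmltmd",
                          cfg=g.SamplerConfig(chains=4, warmup=400,
                                              samples=1000, seed=11))
        thin = slice(None, None, 4)
        c = fit.draws["guessing"].reshape(-1, J)[thin].ravel()
        assert kstest(c, beta(3, 20).cdf).pvalue > 0.01
        al = fit.draws["alpha"].reshape(-1, 7)[thin].ravel()
        assert kstest(al, halfnorm(scale=1).cdf).pvalue > 0.01
        th = fit.draws["theta"].reshape(-1, N * 2)[thin].ravel()
        assert kstest(th, "norm").pvalue > 0.01
        et = fit.draws["eta"].reshape(-1, 5)[thin].ravel()
        assert kstest(et, "norm").pvalue > 0.01


class TestDiagnosticsAndSummaries:
    def test_convergence_report_passes_on_good_fit(self, tiny_fit):
        fit, _ = tiny_fit
        report = g.check_convergence(fit, rhat_max=1.2)
        assert report.attrs["passed"]
        assert set(report["block"]) == {"theta", "eta", "alpha", "guessing"}

    def test_single_chain_rejected(self, analogy_q, analogy_cs):
        _, _, _, y = g.study_fixture(seed=6, n_persons=10)
        fit = g.fit_model(y, analogy_q, analogy_cs, "lltm",
                          cfg=g.SamplerConfig(chains=1, warmup=50, samples=50,
                                              seed=2))
        with pytest.raises(ValueError, match=">= 2 chains"):
            g.check_convergence(fit)

    def test_stuck_chain_fails(self, tiny_fit):
        """Two chains with disjoint means must be flagged by split R-hat."""
        fit, _ = tiny_fit
        import dataclasses

        rng = np.random.default_rng(0)
        bad = {k: v.copy() for k, v in fit.draws.items()}
        bad["eta"] = np.stack([
            rng.normal(0.0, 0.05, size=bad["eta"].shape[1:]),
            rng.normal(5.0, 0.05, size=bad["eta"].shape[1:]),
        ])
        broken = dataclasses.replace(fit, draws=bad)
        report = g.check_convergence(broken)
        assert not report.attrs["passed"]
        row = report.set_index("block").loc["eta"]
        assert row["max_rhat"] > 1.01
        assert "eta" in row["failing_parameters"]

    def test_eap_of_constant_draws(self, tiny_fit):
        fit, _ = tiny_fit
        import dataclasses

        const = {k: v.copy() for k, v in fit.draws.items()}
        const["theta"] = np.full_like(const["theta"], 0.7)
        fixed = dataclasses.replace(fit, draws=const)
        tab = g.eap_abilities(fixed)
        assert np.allclose(tab["eap"], 0.7)
        assert np.allclose(tab["q2.5"], 0.7) and np.allclose(tab["q97.5"], 0.7)

    def test_eap_of_symmetric_draws_is_zero(self, tiny_fit):
        fit, _ = tiny_fit
        import dataclasses

        sym = {k: v.copy() for k, v in fit.draws.items()}
        a = np.full(sym["theta"].shape[1:], 1.3)
        sym["theta"] = np.stack([a, -a])
        tab = g.eap_abilities(dataclasses.replace(fit, draws=sym))
        assert np.allclose(tab["eap"], 0.0)
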