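"""Posterior engine: information-criteria oracle, summary properties,
determinism, and small parameter-recovery checks."""

import math

import numpy as np
import pytest

from iccmap.graphs import make_lattice_graph
from iccmap.inference import (
    PosteriorDraws,
    RunConfig,
    cpo_from_loglik,
    dic,
    dic_from_loglik,
    fit,
    hyper_summary,
    posterior_summary,
    waic_from_loglik,
)
from iccmap.model import ModelSpec, PanelData, poisson_loglik_cells
from iccmap.simulate import SimulationConfig, simulate_latent_fields, simulate_panel
from tests_helpers_panel import single_area_panel

AGES = ("15-29", "30-44", "45-59", "60+")

QUICK = RunConfig(n_hyper_draws=16, n_latent_per_hyper=8, seed=0)


def intercept_only_panel(alpha, py, n=3, a=2, t=2, seed=0):
    cfg = SimulationConfig(
        n_rows=n, n_cols=n, n_years=t, age_groups=AGES[:a],
        true_hyperparameters={k: 0.0 for k in
                              ("sigma_b", "sigma_gamma", "sigma_delta", "sigma_theta")}
        | {"phi": 0.5},
        true_beta={},
        baseline_log_rate=alpha,
        py_scale=py,
        area_size_sd=0.0,
        year_growth=0.0,
        age_shares=(1.0 / a,) * a,
        seed=seed,
    )
    g = make_lattice_graph(n, n)
    return simulate_panel(g, simulate_latent_fields(g, cfg), cfg), g


INTERCEPT_SPEC = ModelSpec(
    include_age=False, include_time=False, include_space=False, include_interaction=False
)


class TestInformationCriteriaOracle:
    """Brute-force spreadsheet-style evaluation on 3 cells x 5 draws."""

    y = [1.0, 0.0, 2.0]
    etas = [
        [0.1, -0.3, 0.4],
        [0.0, -0.5, 0.6],
        [0.2, -0.2, 0.5],
        [-0.1, -0.4, 0.7],
        [0.1, -0.1, 0.3],
    ]

    def loglik_matrix(self):
        out = []
        for row in self.etas:
            out.append(
                [
                    y * e - math.exp(e) - math.lgamma(y + 1)
                    for y, e in zip(self.y, row)
                ]
            )
        return np.array(out)

    def test_dic_matches_brute_force(self):
        ll = self.loglik_matrix()
        eta_mean = [sum(col) / 5 for col in zip(*self.etas)]
        plugin = np.array(
            [y * e - math.exp(e) - math.lgamma(y + 1) for y, e in zip(self.y, eta_mean)]
        )
        dbar = -2 * sum(sum(r) for r in ll) / 5
        dhat = -2 * plugin.sum()
        got, p_d = dic_from_loglik(ll, plugin)
        assert p_d == pytest.approx(dbar - dhat, abs=1e-10)
        assert got == pytest.approx(dbar + (dbar - dhat), abs=1e-10)

    def test_waic_matches_brute_force(self):
        ll = self.loglik_matrix()
        lppd = 0.0
        p_w = 0.0
        for j in range(3):
            vals = ll[:, j]
            lppd += math.log(sum(math.exp(v) for v in vals) / 5)
            mean = sum(vals) / 5
            p_w += sum((v - mean) ** 2 for v in vals) / 4  # sample variance
        got, got_p = waic_from_loglik(ll)
        assert got_p == pytest.approx(p_w, abs=1e-10)
        assert got == pytest.approx(-2 * (lppd - p_w), abs=1e-10)

    def test_cpo_matches_brute_force(self):
        ll = self.loglik_matrix()
        score = 0.0
        for j in range(3):
            cpo = 1.0 / (sum(1.0 / math.exp(v) for v in ll[:, j]) / 5)
            score += -math.log(cpo)
        got, n_bad = cpo_from_loglik(ll)
        assert n_bad == 0
        assert got == pytest.approx(score / 3, abs=1e-10)

    def test_single_draw_degenerates(self):
        ll = self.loglik_matrix()[:1]
        d_val, p_d = dic_from_loglik(ll, ll[0])
        assert p_d == pytest.approx(0.0, abs=1e-10)
        assert d_val == pytest.approx(-2 * ll.sum(), abs=1e-10)
        w_val, p_w = waic_from_loglik(ll)
        assert p_w == 0.0

    def test_constant_zero_block_leaves_lppd_unchanged(self):
        # likelihood invariance: identical eta draws => identical WAIC
        ll = self.loglik_matrix()
        assert waic_from_loglik(ll)[0] == pytest.approx(waic_from_loglik(ll.copy())[0])


def constant_draws(c, n_areas=2):
    s = 8
    b = np.full((s, n_areas), math.log(c))
    return PosteriorDraws(
        spec=ModelSpec(include_age=False, include_time=False,
                       include_interaction=False),
        areas=tuple(f"m{i}" for i in range(n_areas)),
        age_groups=("g0",), years=(2004,),
        beta_names=[], alpha=np.zeros(s), beta=np.zeros((s, 0)),
        u=np.zeros((s, n_areas)), v=np.zeros((s, n_areas)), b=b,
        gamma=np.zeros((s, 0)), delta=np.zeros((s, 0)),
        theta=np.zeros((s, 0, 0)), hyper={},
        eta=np.zeros((s, n_areas)), loglik=np.zeros((s, n_areas)),
        eta_mean=np.zeros(n_areas), log_offset=np.zeros(n_areas), seed=0,
    )


class TestPosteriorSummary:
    def test_degenerate_draws(self):
        out = posterior_summary(constant_draws(2.0), "spatial_rr")
        assert (out["median"] == 2.0).all()
        assert (out["lo95"] == 2.0).all() and (out["hi95"] == 2.0).all()
        assert (out["pr_gt_1"] == 1.0).all()
        out_lo = posterior_summary(constant_draws(0.5), "spatial_rr")
        assert (out_lo["pr_gt_1"] == 0.0).all()

    def test_symmetric_draws_give_half_exceedance(self, rng):
        d = constant_draws(1.0)
        d.b = rng.standard_normal((5000, 2))
        out = posterior_summary(d, "spatial_rr")
        assert np.allclose(out["pr_gt_1"], 0.5, atol=0.03)

    def test_exceedance_equals_draw_counting(self, rng):
        d = constant_draws(1.0)
        d.b = rng.standard_normal((200, 2))
        out = posterior_summary(d, "spatial_rr")
        manual = (np.exp(d.b) > 1).mean(axis=0)
        np.testing.assert_array_equal(out["pr_gt_1"].to_numpy(), manual)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary(constant_draws(1.0), "nonsense")

    def test_flagged_run_refused(self):
        d = constant_draws(1.0)
        d.flagged = True
        with pytest.raises(RuntimeError):
            posterior_summary(d, "spatial_rr")
        posterior_summary(d, "spatial_rr", force=True)

    def test_summaries_invariant_to_draw_order(self, rng):
        d = constant_draws(1.0)
        d.b = rng.standard_normal((200, 2))
        out1 = posterior_summary(d, "spatial_rr")
        perm = rng.permutation(200)
        d.b = d.b[perm]
        out2 = posterior_summary(d, "spatial_rr")
        np.testing.assert_allclose(out1["median"], out2["median"])
        np.testing.assert_allclose(out1["pr_gt_1"], out2["pr_gt_1"])


class TestFit:
    def test_intercept_recovery_and_shrinking_cri(self):
        alpha = math.log(2e-3)
        widths = []
        for py in (2e3, 8e4):
            panel, _ = intercept_only_panel(alpha, py)
            draws = fit(INTERCEPT_SPEC, panel, run_config=QUICK)
            lo, hi = np.quantile(draws.alpha, [0.025, 0.975])
            assert lo <= alpha <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_two_runs_same_seed_identical(self):
        panel, g = intercept_only_panel(math.log(1e-3), 5e3)
        spec = ModelSpec(include_age=True, include_time=True,
                         include_space=False, include_interaction=False)
        a = fit(spec, panel, g, run_config=QUICK)
        b = fit(spec, panel, g, run_config=QUICK)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.loglik, b.loglik)
        for nm in a.hyper:
            np.testing.assert_array_equal(a.hyper[nm], b.hyper[nm])
        assert dic(a, panel) == dic(b, panel)

    def test_posterior_beta_matches_poisson_mle_without_random_effects(self):
        # with all random effects off the model is Poisson regression
        # with offset: the posterior for the urban effect should agree
        # with the closed-form aggregate MLE on large data
        cfg = SimulationConfig(
            n_rows=4, n_cols=4, n_years=3, age_groups=AGES[:2],
            true_hyperparameters={"sigma_b": 0.0, "phi": 0.5, "sigma_gamma": 0.0,
                                  "sigma_delta": 0.0, "sigma_theta": 0.0},
            true_beta={"urbanicity": np.array([math.log(1.8)])},
            py_scale=2e4, area_size_sd=0.0, year_growth=0.0,
            age_shares=(0.5, 0.5), p_urban=0.5, seed=5,
        )
        g = make_lattice_graph(4, 4)
        panel = simulate_panel(g, simulate_latent_fields(g, cfg), cfg)
        spec = ModelSpec(include_age=False, include_time=False, include_space=False,
                         include_interaction=False, covariates=("urbanicity",))
        draws = fit(spec, panel, run_config=QUICK)
        urban = panel.covariates["urban"].to_numpy().astype(bool)
        mle = math.log(
            (panel.y[urban].sum() / panel.E[urban].sum())
            / (panel.y[~urban].sum() / panel.E[~urban].sum())
        )
        lo, hi = np.quantile(draws.beta[:, 0], [0.025, 0.975])
        assert lo <= mle <= hi

    def test_strong_mixing_recovered_above_half(self):
        """Space-only data generated at phi = 0.9: the posterior should
        put most of its mass on phi > 0.5."""
        cfg = SimulationConfig(
            n_rows=10, n_cols=10, n_years=2, age_groups=AGES[:2],
            true_hyperparameters={"sigma_b": 1.0, "phi": 0.9, "sigma_gamma": 0.0,
                                  "sigma_delta": 0.0, "sigma_theta": 0.0},
            true_beta={}, py_scale=5e3, baseline_log_rate=math.log(150e-5), seed=31,
        )
        g = make_lattice_graph(10, 10)
        panel = simulate_panel(g, simulate_latent_fields(g, cfg), cfg)
        spec = ModelSpec(include_age=False, include_time=False,
                         include_space=True, include_interaction=False)
        draws = fit(spec, panel, g, run_config=RunConfig(
            n_hyper_draws=32, n_latent_per_hyper=8, seed=2))
        assert (draws.hyper["phi"] > 0.5).mean() > 0.8
        hs = hyper_summary(draws, force=True).set_index("hyper")
        assert hs.loc["sigma_b", "lo95"] < 1.0 < hs.loc["sigma_b", "hi95"] * 1.5

    def test_cell_rate_summary_scale(self):
        panel, _ = intercept_only_panel(math.log(1e-3), 1e4)
        draws = fit(INTERCEPT_SPEC, panel, run_config=QUICK)
        out = posterior_summary(draws, "cell_rate")
        # true rate = 100 per 100,000 person-years
        assert np.median(out["median"]) == pytest.approx(100.0, rel=0.2)
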