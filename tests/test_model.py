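"""The hierarchical model: designs, joint density, sampler and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from rootworm import model as M


def toy_covariates(rows):
    base = {
        "winter_temp": 0.0, "spring_temp": 0.0, "winter_precip": 0.0,
        "maize": 0.0, "year_index": 0, "x": 0.0, "y": 0.0,
    }
    out = []
    for i, row in enumerate(rows):
        d = dict(base)
        d.update(row)
        d.setdefault("trap_id", f"T{i}")
        d.setdefault("year", 2004)
        out.append(d)
    return pd.DataFrame(out)


def empty_model_data(n_ty=0, p_extra=0):
    spec = M.ModelSpec()
    names = ["intercept", *spec.alpha_covariates]
    return M.ModelData(
        y=np.zeros((n_ty, 19)),
        obs=np.zeros((n_ty, 19), dtype=bool),
        z=np.tile(np.linspace(0.1, 1.0, 19), (n_ty, 1)),
        X_alpha=np.ones((n_ty, 1 + len(spec.alpha_covariates))),
        X_gamma=np.ones((n_ty, 1 + len(spec.gamma_covariates))),
        alpha_names=names,
        gamma_names=["intercept", *spec.gamma_covariates],
        index=pd.DataFrame({"trap_id": [], "year": []}),
        z_scale=1.0,
    )


class TestSettings:
    def test_default_protocol_retains_2000_per_chain(self):
        assert M.MCMCSettings().n_retained == 2000

    def test_reduced_protocol(self):
        assert M.MCMCSettings(n_iter=4000, burn_in=2000, thin=2).n_retained == 1000

    @pytest.mark.parametrize(
        "kwargs", [{"burn_in": 30000}, {"thin": 0}, {"n_chains": 0}]
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            M.MCMCSettings(**kwargs)


class TestBuildDesign:
    def test_centred_trap_has_zero_spatial_row(self):
        cov = toy_covariates([{"x": 40.0, "y": -10.0}])
        X, _, names, _ = M.build_design(cov, M.ModelSpec())
        row = dict(zip(names, X[0]))
        assert row["x"] == row["y"] == row["xy"] == row["x2"] == row["y2"] == 0.0
        assert row["intercept"] == 1.0

    def test_derived_terms_arithmetic(self):
        spec = M.ModelSpec(coord_unit_km=1.0)
        cov = toy_covariates([{"x": 1.0, "y": 2.0}, {"x": -1.0, "y": -2.0}])
        X, _, names, _ = M.build_design(cov, spec)
        row = dict(zip(names, X[0]))
        assert (row["x"], row["y"]) == (1.0, 2.0)
        assert (row["xy"], row["x2"], row["y2"]) == (2.0, 1.0, 4.0)

    def test_identical_trap_years_identical_rows(self):
        cov = toy_covariates([{"winter_temp": 1.5}, {"winter_temp": 1.5}])
        X, _, _, _ = M.build_design(cov, M.ModelSpec())
        assert (X[0] == X[1]).all()

    def test_missing_covariate_names_trap_year(self):
        cov = toy_covariates([{"winter_temp": np.nan, "trap_id": "T9", "year": 2007}])
        with pytest.raises(ValueError, match="T9"):
            M.build_design(cov, M.ModelSpec())


def make_state(data, a0=0.5, tau=1.0, latents=None, y_missing=None):
    p_a = data.X_alpha.shape[1]
    p_g = data.X_gamma.shape[1]
    n_ty = data.n_trap_years
    return M.ModelState(
        coef_alpha=np.full(p_a, 0.0) + np.eye(p_a)[0] * a0,
        coef_beta=np.array([0.1]),
        coef_gamma=np.zeros(p_g),
        tau=np.full(3, tau),
        latents=np.tile([0.7, 0.2, 0.1], (n_ty, 1)) if latents is None else latents,
        y_missing=np.zeros(data.n_missing, dtype=int) if y_missing is None else y_missing,
    )


class TestLogJoint:
    def test_empty_dataset_equals_log_prior(self):
        data = empty_model_data()
        spec = M.ModelSpec()
        state = make_state(data, a0=0.5, tau=2.0)
        expected = (
            stats.norm.logpdf(0.5, 0, 10.0)
            + stats.norm.logpdf(0.0, 0, 10.0) * (data.X_alpha.shape[1] - 1)
            + stats.norm.logpdf(0.1, 0, 10.0)
            + stats.norm.logpdf(0.0, 0, 10.0) * data.X_gamma.shape[1]
            + 3 * stats.gamma.logpdf(2.0, 0.01, scale=1 / 0.01)
        )
        assert M.log_joint(state, data, spec) == pytest.approx(expected)

    def test_removing_one_cell_changes_by_its_poisson_logpmf(self):
        data = empty_model_data(n_ty=1)
        data.obs[0, 5] = True
        data.y[0, 5] = 3.0
        spec = M.ModelSpec()
        state = make_state(data)
        with_cell = M.log_joint(state, data, spec, include_imputation=False)
        data2 = empty_model_data(n_ty=1)
        without = M.log_joint(make_state(data2), data2, spec, include_imputation=False)
        log_mu = M._log_mu(state.latents, data.z)[0, 5]
        mu = np.exp(log_mu)
        pmf = 3 * log_mu - mu - gammaln(4.0)
        assert with_cell - without == pytest.approx(pmf)

    def test_missing_cells_touch_only_the_imputation_term(self):
        data = empty_model_data(n_ty=1)  # all 19 cells missing
        spec = M.ModelSpec()
        s1 = make_state(data, y_missing=np.full(19, 2))
        s2 = make_state(data, y_missing=np.full(19, 4))
        assert M.log_joint(s1, data, spec, include_imputation=False) == pytest.approx(
            M.log_joint(s2, data, spec, include_imputation=False)
        )
        assert M.log_joint(s1, data, spec) != pytest.approx(M.log_joint(s2, data, spec))

    def test_nonfinite_state_returns_neg_inf(self):
        data = empty_model_data()
        spec = M.ModelSpec()
        bad = make_state(data)
        bad.coef_alpha = bad.coef_alpha + np.nan
        assert M.log_joint(bad, data, spec) == -np.inf
        neg_tau = make_state(data, tau=-1.0)
        assert M.log_joint(neg_tau, data, spec) == -np.inf


class TestSampler:
    def test_seeding_contract(self, small_dataset):
        from rootworm.synthetic_data import to_model_data

        spec = M.ModelSpec()
        data = to_model_data(small_dataset, spec)
        settings = M.MCMCSettings(n_iter=200, burn_in=100, thin=5, n_chains=1, seed=77)
        a = M.sample(data, spec, settings)
        b = M.sample(data, spec, settings)
        assert (a.coef_alpha == b.coef_alpha).all()
        assert (a.latents == b.latents).all()
        assert (a.y_missing == b.y_missing).all()

    def test_draw_shapes_and_invariants(self, small_fit):
        data, draws = small_fit
        assert draws.n_draws == 200
        assert draws.coef_alpha.shape == (2, 200, data.X_alpha.shape[1])
        assert (draws.tau > 0).all()
        assert (draws.y_missing >= 0).all()
        assert draws.y_missing.dtype.kind == "i"

    def test_gibbs_conditional_matches_quadrature(self):
        """The conjugate intercept update reproduces the normalized slice of
        the joint density (1-D quadrature oracle)."""
        rng = np.random.default_rng(0)
        n = 40
        la = rng.normal(1.3, 0.8, n)
        tau_a = 1.7
        grid = np.linspace(-2, 4, 4001)
        loglik = (
            -0.5 * 0.01 * grid**2
            - 0.5 * tau_a * ((la[None, :] - grid[:, None]) ** 2).sum(axis=1)
        )
        w = np.exp(loglik - loglik.max())
        w /= w.sum()
        q_mean = float((grid * w).sum())
        q_sd = float(np.sqrt(((grid - q_mean) ** 2 * w).sum()))
        draws = np.array(
            [
                M._draw_coef_block(rng, np.ones((n, 1)), la, tau_a, 0.01)[0]
                for _ in range(4000)
            ]
        )
        assert draws.mean() == pytest.approx(q_mean, abs=4 * q_sd / np.sqrt(4000))
        assert draws.std() == pytest.approx(q_sd, rel=0.1)

    def test_empty_dataset_samples_the_prior(self):
        """With no data the coefficient draws recover their N(0, sd 10)
        prior within Monte-Carlo error."""
        data = empty_model_data()
        spec = M.ModelSpec()
        settings = M.MCMCSettings(n_iter=4000, burn_in=1000, thin=1, n_chains=1, seed=2)
        draws = M.sample(data, spec, settings)
        flat = draws.coef_alpha[0, :, 0]
        assert flat.mean() == pytest.approx(0.0, abs=4 * 10 / np.sqrt(len(flat)))
        assert flat.std() == pytest.approx(10.0, rel=0.1)

    def test_save_load_roundtrip(self, small_fit, tmp_path):
        _, draws = small_fit
        M.save_draws(draws, tmp_path)
        back = M.load_draws(tmp_path)
        assert np.allclose(back.coef_alpha, draws.coef_alpha)
        assert np.allclose(back.latents, draws.latents)
        assert (back.y_missing == draws.y_missing).all()
        assert back.settings == draws.settings


def synthetic_scalar_draws(coef_values: np.ndarray) -> M.PosteriorDraws:
    """PosteriorDraws whose every scalar equals the given (C, D) array
    (precisions shifted positive)."""
    C, D = coef_values.shape
    block = coef_values[:, :, None]
    return M.PosteriorDraws(
        coef_alpha=block.copy(),
        coef_beta=block.copy(),
        coef_gamma=block.copy(),
        tau=np.abs(block) + 1.0 + np.zeros((C, D, 3)),
        latents=np.zeros((C, D, 0, 3)),
        y_missing=np.zeros((C, D, 0), dtype=np.int64),
        alpha_names=["intercept"],
        gamma_names=["intercept"],
        index=pd.DataFrame({"trap_id": [], "year": []}),
        z_scale=1.0,
        settings=M.MCMCSettings(n_iter=2 * D, burn_in=D, thin=1, n_chains=C),
        accept_rate=np.zeros((0, 3)),
    )


class TestDiagnose:
    def test_iid_chains_have_unit_rhat(self, rng):
        draws = synthetic_scalar_draws(rng.standard_normal((4, 1000)))
        diag = M.diagnose(draws).set_index("parameter")
        assert diag.loc["alpha:intercept", "rhat"] == pytest.approx(1.0, abs=0.01)
        assert diag.loc["alpha:intercept", "ess_bulk"] > 1000

    def test_stuck_chains_detected(self):
        values = np.vstack([np.zeros(100), np.ones(100)])
        diag = M.diagnose(synthetic_scalar_draws(values)).set_index("parameter")
        rhat = diag.loc["alpha:intercept", "rhat"]
        assert not rhat < 1.1  # huge or nan, never near 1

    def test_single_draw_rejected(self, rng):
        draws = synthetic_scalar_draws(rng.standard_normal((2, 1)))
        with pytest.raises(ValueError, match="retained draws"):
            M.diagnose(draws)
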