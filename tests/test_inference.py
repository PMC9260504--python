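"""Joint density, full conditionals, sampler contracts and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import valgp as vg
from valgp.inference import (
    _FitContext,
    beta_conditional_moments,
    gamma_conditional_moments,
    tau2_conditional,
    v2_conditional,
)


def _toy_params(ctx, **overrides):
    p = vg.ModelParameters(
        u=np.array([0.55, 0.15, 1.0]),
        alpha=np.array([1.1, 0.9, 1.0]),
        gamma_resp=np.zeros(0),
        tau2=0.04,
        v2=0.01,
        gamma0=1.0,
        beta=np.full(5, -0.04),
        sigma2=0.04,
    )
    for k, v in overrides.items():
        setattr(p, k, v)
    return p


# --------------------------------------------------------------------------
# log_joint
# --------------------------------------------------------------------------


def test_likelihood_term_matches_gaussian_density(toy_dataset, default_b):
    """Changing a single response changes log_joint by exactly the Gaussian
    log-density difference of its residual (all other terms cancel)."""
    ctx = _FitContext(toy_dataset, None, default_b)
    params = _toy_params(ctx)
    base = vg.log_joint(params, toy_dataset, None, default_b)

    # shift the first observation so that its residual becomes -0.1 exactly
    mod = toy_dataset.observations.copy()
    k = toy_dataset.state_index.index(mod.loc[0, "state"])
    resid0 = mod.loc[0, "y"] - 1.0 + params.alpha[0] * (1.0 - params.u[k])
    mod.loc[0, "y"] = mod.loc[0, "y"] - resid0 - 0.1
    shifted = vg.ValuationDataset(observations=mod, covariates=toy_dataset.covariates)
    delta = vg.log_joint(params, shifted, None, default_b) - base
    expected = stats.norm.logpdf(-0.1, scale=0.1) - stats.norm.logpdf(resid0, scale=0.1)
    assert delta == pytest.approx(expected, abs=1e-9)

    # a zero-residual datum contributes the normalizing constant only
    mod.loc[0, "y"] = mod.loc[0, "y"] + 0.1
    exact = vg.ValuationDataset(observations=mod, covariates=toy_dataset.covariates)
    delta0 = vg.log_joint(params, exact, None, default_b) - base
    assert delta0 == pytest.approx(
        stats.norm.logpdf(0.0, scale=0.1) - stats.norm.logpdf(resid0, scale=0.1), abs=1e-9
    )


def test_log_joint_raises_on_invalid_parameters(toy_dataset, default_b):
    ctx = _FitContext(toy_dataset, None, default_b)
    with pytest.raises(ValueError):
        vg.log_joint(_toy_params(ctx, tau2=-1.0), toy_dataset, None, default_b)
    with pytest.raises(ValueError):
        vg.log_joint(
            _toy_params(ctx, alpha=np.array([1.0, -0.5, 1.0])), toy_dataset, None, default_b
        )
    with pytest.raises(ValueError):
        # anchor coordinate must stay at 1
        vg.log_joint(
            _toy_params(ctx, u=np.array([0.5, 0.1, 0.9])), toy_dataset, None, default_b
        )


# --------------------------------------------------------------------------
# conditional-consistency: every exact conditional is proportional to the
# joint restricted to its block
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def consistency_setup():
    data = vg.simulate_study("irish", respondents=10, seed=77)
    b = vg.default_roughness_params()
    ctx = _FitContext(data, None, b)
    rng = np.random.default_rng(3)
    params = vg.ModelParameters(
        u=np.clip(rng.normal(0.4, 0.3, ctx.n), -1, 1),
        alpha=np.exp(0.2 * rng.standard_normal(ctx.J)),
        gamma_resp=0.01 * rng.standard_normal(ctx.p),
        tau2=0.05,
        v2=0.02,
        gamma0=1.1,
        beta=np.full(5, -0.05),
        sigma2=0.03,
    )
    params.u[ctx.anchor] = 1.0
    return data, b, ctx, params, rng


def _delta_log_joint(data, b, p1, p2):
    return vg.log_joint(p2, data, None, b) - vg.log_joint(p1, data, None, b)


def test_u_conditional_consistent_with_joint(consistency_setup):
    data, b, ctx, params, rng = consistency_setup
    mean, cov = vg.u_conditional_moments(params, data, None, b)
    f = ctx.free
    dist = stats.multivariate_normal(mean[f], cov[np.ix_(f, f)], allow_singular=True)
    p2 = params.copy()
    p2.u = params.u + 0.0
    p2.u[f] = mean[f] + 0.05 * rng.standard_normal(len(f))
    delta_cond = dist.logpdf(p2.u[f]) - dist.logpdf(params.u[f])
    assert _delta_log_joint(data, b, params, p2) == pytest.approx(delta_cond, abs=1e-6)


def test_gamma_conditional_consistent_with_joint(consistency_setup):
    data, b, ctx, params, rng = consistency_setup
    mean, cov = gamma_conditional_moments(params, ctx)
    dist = stats.multivariate_normal(mean, cov)
    p2 = params.copy()
    p2.gamma_resp = params.gamma_resp + 0.005 * rng.standard_normal(ctx.p)
    delta_cond = dist.logpdf(p2.gamma_resp) - dist.logpdf(params.gamma_resp)
    assert _delta_log_joint(data, b, params, p2) == pytest.approx(delta_cond, abs=1e-6)


@pytest.mark.parametrize("block", ["tau2", "v2"])
def test_variance_conditionals_consistent_with_joint(consistency_setup, block):
    data, b, ctx, params, rng = consistency_setup
    fn = tau2_conditional if block == "tau2" else v2_conditional
    shape, scale = fn(params, ctx)
    dist = stats.invgamma(a=shape, scale=scale)
    p2 = params.copy()
    setattr(p2, block, getattr(params, block) * 1.7)
    delta_cond = dist.logpdf(getattr(p2, block)) - dist.logpdf(getattr(params, block))
    assert _delta_log_joint(data, b, params, p2) == pytest.approx(delta_cond, abs=1e-6)


def test_gp_mean_conditional_consistent_with_joint(consistency_setup):
    data, b, ctx, params, rng = consistency_setup
    mean, cov = beta_conditional_moments(params, ctx)
    dist = stats.multivariate_normal(mean, cov, allow_singular=True)
    p2 = params.copy()
    bump = 0.01 * rng.standard_normal(6)
    p2.gamma0 = params.gamma0 + bump[0]
    p2.beta = params.beta + bump[1:]
    cur = np.concatenate(([params.gamma0], params.beta))
    new = np.concatenate(([p2.gamma0], p2.beta))
    delta_cond = dist.logpdf(new) - dist.logpdf(cur)
    assert _delta_log_joint(data, b, params, p2) == pytest.approx(delta_cond, abs=1e-6)


# --------------------------------------------------------------------------
# conditional_sample_u against an independent GP-regression oracle
# --------------------------------------------------------------------------


def test_u_conditional_matches_gp_regression_oracle(default_b):
    """With all alpha_j = 1 the model is y = u(x) + eps, so the conditional
    mean of u must equal the textbook GP-regression posterior mean computed
    independently in covariance form."""
    codes = ["21111", "33333", "44444", "52345"]
    rng = np.random.default_rng(8)
    rows = []
    for j in range(4):
        for c in codes:
            rows.append((f"r{j}", c, rng.normal(0.5, 0.3)))
    data = vg.ValuationDataset(
        observations=pd.DataFrame(rows, columns=["respondent_id", "state", "y"]),
        covariates=pd.DataFrame(index=pd.Index([f"r{j}" for j in range(4)])),
    )
    params = vg.ModelParameters(
        u=np.zeros(5),
        alpha=np.ones(4),
        gamma_resp=np.zeros(0),
        tau2=0.04,
        v2=0.02,
        gamma0=1.2,
        beta=np.full(5, -0.05),
        sigma2=0.06,
    )
    ctx = _FitContext(data, None, default_b)
    params.u[ctx.anchor] = 1.0
    mean, _ = vg.u_conditional_moments(params, data, None, default_b)

    # oracle: anchored prior moments via public prior API, then the
    # covariance-form GP regression update y = D u + eps
    states = [vg.parse_state(c) for c in data.state_index]
    pm, pc = vg.prior_moments(vg.flat_prior(states), params.gamma0, params.beta,
                              params.sigma2, default_b)
    pm, pc = vg.condition_full_health(pm, pc, ctx.anchor)
    D = np.zeros((ctx.I, ctx.n))
    D[np.arange(ctx.I), ctx.obs_state] = 1.0
    G = D @ pc @ D.T + params.v2 * np.eye(ctx.I)
    gain = pc @ D.T @ np.linalg.inv(G)
    oracle = pm + gain @ (ctx.y - D @ pm)
    np.testing.assert_allclose(mean, oracle, atol=1e-8)


def test_u_conditional_sampler_mean_matches_moments(toy_dataset, default_b):
    ctx = _FitContext(toy_dataset, None, default_b)
    params = _toy_params(ctx)
    mean, cov = vg.u_conditional_moments(params, toy_dataset, None, default_b)
    rng = np.random.default_rng(0)
    draws = np.array(
        [vg.conditional_sample_u(params, ctx, None, default_b, rng) for _ in range(20000)]
    )
    f = ctx.free
    se = np.sqrt(np.diag(cov)[f] / draws.shape[0])
    assert np.all(np.abs(draws[:, f].mean(axis=0) - mean[f]) < 3 * se + 1e-12)
    assert np.allclose(draws[:, ctx.anchor], 1.0)


def test_u_conditional_without_observations_is_the_anchored_prior(default_b):
    """An empty-likelihood conditional must reduce to the anchored GP prior."""
    codes = ["22222", "33333"]
    obs = pd.DataFrame(
        [("r0", "22222", 0.5), ("r1", "33333", 0.2)],
        columns=["respondent_id", "state", "y"],
    )
    data = vg.ValuationDataset(
        observations=obs, covariates=pd.DataFrame(index=pd.Index(["r0", "r1"]))
    )
    ctx = _FitContext(data, None, default_b)
    params = _toy_params(ctx, v2=1e12)  # infinite noise: likelihood carries nothing
    mean, cov = vg.u_conditional_moments(params, data, None, default_b)
    states = [vg.parse_state(c) for c in data.state_index]
    pm, pc = vg.prior_moments(vg.flat_prior(states), params.gamma0, params.beta,
                              params.sigma2, default_b)
    pm, pc = vg.condition_full_health(pm, pc, ctx.anchor)
    np.testing.assert_allclose(mean, pm, atol=1e-6)
    np.testing.assert_allclose(cov, pc, atol=1e-6)


# --------------------------------------------------------------------------
# sampler contracts
# --------------------------------------------------------------------------


def test_same_seed_reproduces_draws_exactly(small_study):
    cfg = vg.MCMCConfig(n_iter=300, n_burnin=100, seed=5)
    a = vg.run_mcmc(small_study, config=cfg)
    b = vg.run_mcmc(small_study, config=cfg)
    np.testing.assert_array_equal(a.u, b.u)
    np.testing.assert_array_equal(a.sigma2, b.sigma2)
    c = vg.run_mcmc(small_study, config=vg.MCMCConfig(n_iter=300, n_burnin=100, seed=6))
    assert not np.array_equal(a.u, c.u)


def test_near_noiseless_data_recovers_truth():
    """With alpha_j = 1 (tau2 -> 0) and tiny residual noise the posterior
    mean of u must sit within 0.02 of the generating utilities."""
    truth = vg.truth_from_published("irish", tau2=0.0, v2=0.0001)
    design = vg.default_design(respondents=30)
    cov = vg.simulate_respondents(30, seed=1)
    data = vg.simulate_valuations(design, truth, cov, seed=2)
    draws = vg.run_mcmc(data, config=vg.MCMCConfig(n_iter=800, n_burnin=300, seed=4))
    tu = np.array([truth.u_of(c) for c in draws.state_index])
    assert np.max(np.abs(draws.u.mean(axis=0) - tu)) < 0.02


def test_sampler_guards_degenerate_inputs(toy_dataset):
    one_resp = vg.ValuationDataset(
        observations=toy_dataset.observations[toy_dataset.observations.respondent_id == "p0"],
        covariates=toy_dataset.covariates,
    )
    with pytest.raises(ValueError, match="fewer than 2"):
        vg.run_mcmc(one_resp)
    with pytest.raises(ValueError, match="free states"):
        vg.run_mcmc(toy_dataset)  # 2 free states, (gamma0, beta) unidentified


def test_posterior_draws_round_trip_through_files(small_fit, tmp_path):
    small_fit.save(tmp_path / "fit")
    back = vg.PosteriorDraws.load(tmp_path / "fit")
    np.testing.assert_allclose(back.u, small_fit.u, atol=1e-10)
    np.testing.assert_allclose(back.tau2, small_fit.tau2, atol=1e-12)
    assert back.state_index == small_fit.state_index


# --------------------------------------------------------------------------
# population-mean correction
# --------------------------------------------------------------------------


def _draws_stub(u, tau2, gamma=None, covs=None):
    S = u.shape[0]
    p = 0 if gamma is None else gamma.shape[1]
    return vg.PosteriorDraws(
        state_index=[f"{i}" * 5 for i in range(1, u.shape[1] + 1)],
        u=u,
        alpha=np.ones((S, 2)),
        gamma_resp=np.zeros((S, p)) if gamma is None else gamma,
        tau2=tau2,
        v2=np.full(S, 0.01),
        gamma0=np.zeros(S),
        beta=np.zeros((S, 5)),
        sigma2=np.full(S, 0.04),
        respondent_ids=["a", "b"],
        covariate_columns=[] if gamma is None else [f"c{k}" for k in range(p)],
        covariates=covs if covs is not None else np.zeros((2, p)),
    )


def test_expected_alpha_closed_forms():
    u = np.full((4, 2), 0.5)
    # no covariates, tau2 = 0: E(alpha) = 1
    np.testing.assert_allclose(vg.expected_alpha(_draws_stub(u, np.zeros(4))), 1.0)
    # no covariates, tau2 = 0.5: exp(0.25)
    np.testing.assert_allclose(
        vg.expected_alpha(_draws_stub(u, np.full(4, 0.5))), np.exp(0.25)
    )
    # all-zero covariate vectors: reduces to exp(tau2/2) whatever gamma is
    gam = np.full((4, 3), 2.0)
    d = _draws_stub(u, np.full(4, 0.5), gamma=gam, covs=np.zeros((2, 3)))
    np.testing.assert_allclose(vg.expected_alpha(d), np.exp(0.25))


def test_expected_alpha_rejects_empty_covariates():
    d = _draws_stub(np.full((4, 2), 0.5), np.zeros(4), gamma=np.zeros((4, 3)))
    with pytest.raises(ValueError):
        vg.expected_alpha(d, covariates=np.zeros((0, 3)))


def test_population_mean_identity_when_ealpha_is_one():
    u = np.array([[0.3, 0.8], [0.5, 0.9]])
    vs = vg.population_mean_utilities(_draws_stub(u, np.zeros(2)))
    np.testing.assert_allclose(vs["population_mean"], u.mean(axis=0))
    np.testing.assert_allclose(vs["posterior_mean"], u.mean(axis=0))


def test_population_mean_single_draw_arithmetic():
    # one draw, u = 0.5, E(alpha) = 1.2  ->  ubar = 1 - 1.2 * 0.5 = 0.4
    tau2 = np.array([2 * np.log(1.2)])
    vs = vg.population_mean_utilities(_draws_stub(np.array([[0.5, 1.0]]), tau2))
    assert vs["population_mean"].iloc[0] == pytest.approx(0.4)
    assert vs["population_mean"].iloc[1] == pytest.approx(1.0)  # u = 1 is invariant


# --------------------------------------------------------------------------
# prediction at unvalued states
# --------------------------------------------------------------------------


def test_prediction_reproduces_fitted_state_summaries(small_fit, default_b):
    target = vg.parse_state(small_fit.state_index[3])
    pred = vg.predict_unvalued_states(small_fit, [target], b=default_b)
    vs = vg.population_mean_utilities(small_fit)
    row = vs[vs.state == target.code].iloc[0]
    assert pred["posterior_mean"].iloc[0] == pytest.approx(row["posterior_mean"], abs=1e-10)
    assert pred["population_sd"].iloc[0] == pytest.approx(row["population_sd"], abs=1e-10)


def test_prediction_matches_hand_conditioning_and_symmetry(default_b):
    """Midpoint target between two symmetric fitted states: the prediction
    must match an independently coded GP conditional and be invariant under
    relabelling the two states."""
    codes = ["21111", "12111"]
    b = default_b
    u_draws = np.array([[0.6, 0.8], [0.8, 0.6]])
    S = 2

    def stub(u):
        return vg.PosteriorDraws(
            state_index=codes,
            u=u,
            alpha=np.ones((S, 1)),
            gamma_resp=np.zeros((S, 0)),
            tau2=np.zeros(S),
            v2=np.full(S, 0.01),
            gamma0=np.full(S, 0.7),
            beta=np.zeros((S, 5)),
            sigma2=np.full(S, 0.05),
            respondent_ids=["r"],
            covariate_columns=[],
            covariates=np.zeros((1, 0)),
        )

    target = vg.parse_state("22111")
    pred = vg.predict_unvalued_states(
        stub(u_draws), [target], b=b, include_gp_noise=False
    )
    # oracle: plain Gaussian conditioning per draw, coded independently
    states = [vg.parse_state(c) for c in codes + ["22111"]]
    A = vg.correlation_matrix(states, b)
    vals = []
    for s in range(S):
        K = 0.05 * A
        m = np.full(3, 0.7)
        mu_t = m[2] + K[2, :2] @ np.linalg.solve(K[:2, :2], u_draws[s] - m[:2])
        vals.append(mu_t)
    assert pred["posterior_mean"].iloc[0] == pytest.approx(np.mean(vals), abs=1e-6)
    # swapping the two symmetric states leaves the prediction unchanged
    swapped = vg.predict_unvalued_states(
        stub(u_draws[:, [1, 0]][[1, 0]]), [target], b=b, include_gp_noise=False
    )
    assert swapped["posterior_mean"].iloc[0] == pytest.approx(
        pred["posterior_mean"].iloc[0], abs=1e-6
    )
    # mirrored draws with prior mean 0.7: the symmetric-kernel weights make
    # the mean prediction at the midpoint exactly the common fitted mean
    assert pred["posterior_mean"].iloc[0] == pytest.approx(0.7, abs=1e-6)


def test_prediction_reverts_to_prior_mean_for_rough_kernel(small_fit):
    rough = vg.RoughnessParams((50.0,) * 5)
    target = vg.parse_state("23232")
    assert target.code not in small_fit.state_index
    pred = vg.predict_unvalued_states(small_fit, [target], b=rough, include_gp_noise=False)
    prior_mean = (
        small_fit.gamma0 + small_fit.beta @ np.asarray(target.levels, float)
    ).mean()
    assert pred["posterior_mean"].iloc[0] == pytest.approx(prior_mean, abs=1e-6)


def test_prediction_requires_extended_informative_prior(small_fit):
    states = [vg.parse_state(c) for c in small_fit.state_index]
    spec = vg.informative_prior_from_draws(small_fit, states)
    with pytest.raises(KeyError, match="extended PriorSpec"):
        vg.predict_unvalued_states(small_fit, [vg.parse_state("23232")], prior=spec)
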