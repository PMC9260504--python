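"""Hierarchical Bayesian model for composite time trade-off (cTTO) valuations.

Response model, for respondent j valuing health state x_ij:

    y_ij = 1 - alpha_j (1 - u(x_ij)) + eps_ij,
    alpha_j ~ LogNormal(t_j' gamma, tau^2),   eps_ij ~ N(0, v^2),

where u(x) is the latent *median* utility surface (GP prior, see
:mod:`valgp.prior`), alpha_j is a positive multiplicative respondent effect
on disutility with covariate-driven location (default covariates: centered
age, its square, and sex), and full health is anchored at u = 1.

Hyperpriors are improper: p(gamma, tau^2, v^2, beta, sigma^2) proportional
to tau^-2 v^-2 sigma^-1.

Posterior sampling is Metropolis-within-Gibbs: exact Gaussian conditionals
for u, the covariate coefficients gamma and the GP mean coefficients
(gamma0, beta); exact inverse-gamma conditionals for tau^2 and v^2;
log-scale random-walk Metropolis for each alpha_j and for sigma^2, with
proposal scales adapted during burn-in toward ~0.4 acceptance.

Value sets report the population *mean* utility

    ubar(x) = 1 - E(alpha) (1 - u(x)),   E(alpha) = E{exp(t'gamma)} exp(tau^2/2),

computed per retained draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from .prior import PriorSpec, flat_prior
from .states import (
    FULL_HEALTH,
    HealthState,
    RoughnessParams,
    correlation_matrix,
    default_roughness_params,
    design_matrix,
    parse_state,
)

DEFAULT_COVARIATE_COLUMNS = ("age_c", "age_c2", "sex")

ALPHA_DIVERGENCE_LIMIT = 1e6
V2_UNDERFLOW_LIMIT = 1e-12


class McmcDivergenceError(RuntimeError):
    """Raised when the sampler wanders into a numerically degenerate region."""


# --------------------------------------------------------------------------
# dataset
# --------------------------------------------------------------------------


def code_covariates(respondents: pd.DataFrame, center_age: bool = True) -> pd.DataFrame:
    """Code raw (age, sex) respondent data into the model covariates.

    Returns a frame indexed like ``respondents`` with columns
    ``age_c`` (age centered at the sample mean, in years), ``age_c2``
    (squared centered age) and ``sex`` (0/1).  Centering stabilizes the
    location of the log-normal respondent effect.
    """
    age = respondents["age"].astype(float)
    age_c = age - age.mean() if center_age else age
    return pd.DataFrame(
        {"age_c": age_c, "age_c2": age_c**2, "sex": respondents["sex"].astype(float)},
        index=respondents.index,
    )


@dataclass
class ValuationDataset:
    """Respondent-level cTTO valuation records plus per-respondent covariates.

    observations: columns ``respondent_id``, ``state`` (5-digit code),
    ``y`` (cTTO value on the dead=0 / full-health=1 scale).
    covariates: one row per respondent (indexed by respondent_id), already
    coded; may have zero columns for a covariate-free model.
    """

    observations: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"respondent_id", "state", "y"}
        if not need.issubset(self.observations.columns):
            raise ValueError(f"observations must have columns {sorted(need)}")
        self.observations = self.observations.reset_index(drop=True).copy()
        self.observations["state"] = self.observations["state"].astype(str)
        for code in self.observations["state"].unique():
            parse_state(code)
        missing = set(self.observations["respondent_id"]) - set(self.covariates.index)
        if missing:
            raise ValueError(f"respondents without covariate rows: {sorted(missing)[:5]}")

    @property
    def respondent_ids(self) -> list:
        return list(dict.fromkeys(self.observations["respondent_id"]))

    @property
    def state_index(self) -> list[str]:
        """Unique state codes in first-appearance order, full health appended."""
        codes = list(dict.fromkeys(self.observations["state"]))
        if FULL_HEALTH not in codes:
            codes.append(FULL_HEALTH)
        return codes

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    def t_matrix(self) -> np.ndarray:
        """(J, p) covariate matrix in respondent order (p may be 0)."""
        resp = self.respondent_ids
        return self.covariates.loc[resp].to_numpy(dtype=float).reshape(len(resp), -1)

    def to_csv(self, path: str | Path) -> None:
        merged = self.observations.merge(
            self.covariates, left_on="respondent_id", right_index=True, how="left"
        )
        merged.to_csv(path, index=False)


def read_valuation_csv(
    path: str | Path,
    covariate_columns: Sequence[str] | None = None,
    center_age: bool = True,
    validate_range: bool = True,
) -> ValuationDataset:
    """Load a valuation study from CSV.

    Expected columns: ``respondent_id``, ``state``, ``y`` and either raw
    ``age``/``sex`` (coded via :func:`code_covariates`) or pre-coded
    ``covariate_columns``.  cTTO values outside [-1, 1] are rejected unless
    ``validate_range`` is off (simulated data with censoring disabled can
    legitimately exceed the feasible range).
    """
    df = pd.read_csv(path, dtype={"state": str})
    if validate_range and ((df["y"] < -1) | (df["y"] > 1)).any():
        bad = df.loc[(df["y"] < -1) | (df["y"] > 1), "y"]
        raise ValueError(
            f"{len(bad)} cTTO values outside [-1, 1] (first: {bad.iloc[0]}); "
            "pass validate_range=False for uncensored simulated data"
        )
    obs = df[["respondent_id", "state", "y"]]
    resp = df.drop_duplicates("respondent_id").set_index("respondent_id")
    if covariate_columns is not None:
        cov = resp[list(covariate_columns)].astype(float)
    elif set(DEFAULT_COVARIATE_COLUMNS).issubset(df.columns):
        cov = resp[list(DEFAULT_COVARIATE_COLUMNS)].astype(float)
    elif {"age", "sex"}.issubset(df.columns):
        cov = code_covariates(resp, center_age=center_age)
    else:
        cov = pd.DataFrame(index=resp.index)
    return ValuationDataset(observations=obs, covariates=cov)


# --------------------------------------------------------------------------
# parameters & configuration
# --------------------------------------------------------------------------


@dataclass
class ModelParameters:
    """One full parameter state theta = (u, alpha, gamma, tau2, v2, gamma0, beta, sigma2)."""

    u: np.ndarray  # per-state median utilities, anchor coordinate = 1
    alpha: np.ndarray  # per-respondent positive effects
    gamma_resp: np.ndarray  # covariate coefficients (p,)
    tau2: float
    v2: float
    gamma0: float  # GP mean intercept
    beta: np.ndarray  # GP mean slopes (5,)
    sigma2: float  # GP scale

    def validate(self, anchor_index: int | None = None) -> None:
        if np.any(self.alpha <= 0):
            raise ValueError("all respondent effects alpha must be positive")
        for name in ("tau2", "v2", "sigma2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if anchor_index is not None and not np.isclose(self.u[anchor_index], 1.0):
            raise ValueError("full-health utility must be anchored at 1")

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            u=self.u.copy(),
            alpha=self.alpha.copy(),
            gamma_resp=self.gamma_resp.copy(),
            tau2=float(self.tau2),
            v2=float(self.v2),
            gamma0=float(self.gamma0),
            beta=self.beta.copy(),
            sigma2=float(self.sigma2),
        )


@dataclass
class MCMCConfig:
    """Sampler settings.  Defaults follow the study analysis: 3,000
    iterations with the first 1,000 discarded as burn-in, no thinning."""

    n_iter: int = 3000
    n_burnin: int = 1000
    thin: int = 1
    seed: int = 0
    prop_scale_alpha: float = 0.25
    prop_scale_sigma2: float = 0.4
    adapt: bool = True
    fix: dict | None = None  # blocks held at their initial values, e.g. {"tau2": 0.04}
    weakly_proper_variances: bool = False  # IG(0.001, 0.001) fallback for tau2/v2

    def __post_init__(self) -> None:
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")
        if not (self.prop_scale_alpha > 0 and self.prop_scale_sigma2 > 0):
            raise ValueError("proposal scales must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC samples plus bookkeeping."""

    state_index: list[str]
    u: np.ndarray  # (S, n_states)
    alpha: np.ndarray  # (S, J)
    gamma_resp: np.ndarray  # (S, p)
    tau2: np.ndarray
    v2: np.ndarray
    gamma0: np.ndarray
    beta: np.ndarray  # (S, 5)
    sigma2: np.ndarray
    acceptance: dict = field(default_factory=dict)
    respondent_ids: list = field(default_factory=list)
    covariate_columns: list[str] = field(default_factory=list)
    covariates: np.ndarray | None = None  # (J, p), for E(alpha)

    @property
    def n_draws(self) -> int:
        return self.u.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"u_{c}": self.u[:, i] for i, c in enumerate(self.state_index)}
        cols.update({f"alpha_{r}": self.alpha[:, j] for j, r in enumerate(self.respondent_ids)})
        cols.update(
            {f"gamma_{c}": self.gamma_resp[:, k] for k, c in enumerate(self.covariate_columns)}
        )
        cols["tau2"] = self.tau2
        cols["v2"] = self.v2
        cols["gamma0"] = self.gamma0
        for d in range(5):
            cols[f"beta_{d + 1}"] = self.beta[:, d]
        cols["sigma2"] = self.sigma2
        return pd.DataFrame(cols)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "draws.csv", index=False)
        manifest = {
            "state_index": self.state_index,
            "respondent_ids": [str(r) for r in self.respondent_ids],
            "covariate_columns": list(self.covariate_columns),
            "acceptance": self.acceptance,
            "n_draws": int(self.n_draws),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if self.covariates is not None and self.covariates.shape[1]:
            pd.DataFrame(self.covariates, columns=self.covariate_columns).to_csv(
                directory / "covariates.csv", index=False
            )

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        df = pd.read_csv(directory / "draws.csv")
        states = manifest["state_index"]
        resp = manifest["respondent_ids"]
        covcols = manifest["covariate_columns"]
        cov = None
        if (directory / "covariates.csv").exists():
            cov = pd.read_csv(directory / "covariates.csv").to_numpy(dtype=float)
        return cls(
            state_index=states,
            u=df[[f"u_{c}" for c in states]].to_numpy(),
            alpha=df[[f"alpha_{r}" for r in resp]].to_numpy(),
            gamma_resp=df[[f"gamma_{c}" for c in covcols]].to_numpy().reshape(len(df), -1),
            tau2=df["tau2"].to_numpy(),
            v2=df["v2"].to_numpy(),
            gamma0=df["gamma0"].to_numpy(),
            beta=df[[f"beta_{d + 1}" for d in range(5)]].to_numpy(),
            sigma2=df["sigma2"].to_numpy(),
            acceptance=manifest.get("acceptance", {}),
            respondent_ids=resp,
            covariate_columns=covcols,
            covariates=cov,
        )


# --------------------------------------------------------------------------
# fit context: precomputed arrays shared by log_joint / conditionals / sampler
# --------------------------------------------------------------------------


class _FitContext:
    """Precomputed quantities for one (data, prior, kernel) triple."""

    def __init__(self, data: ValuationDataset, prior: PriorSpec | None, b: RoughnessParams):
        self.codes = data.state_index
        self.states = [parse_state(c) for c in self.codes]
        self.n = len(self.codes)
        self.anchor = self.codes.index(FULL_HEALTH)
        self.free = np.array([i for i in range(self.n) if i != self.anchor], dtype=int)

        if prior is None or prior.source == "flat":
            prior = flat_prior(self.states)
        else:
            prior = prior.subset(self.states)
        self.prior = prior
        self.u0 = prior.u0_mean
        self.C0 = prior.C0
        self.H = design_matrix(self.states)  # (n, 6)
        self.A = correlation_matrix(self.states, b)

        code_to_idx = {c: i for i, c in enumerate(self.codes)}
        resp_to_idx = {r: j for j, r in enumerate(data.respondent_ids)}
        obs = data.observations
        self.obs_state = obs["state"].map(code_to_idx).to_numpy(dtype=int)
        self.obs_resp = obs["respondent_id"].map(resp_to_idx).to_numpy(dtype=int)
        self.y = obs["y"].to_numpy(dtype=float)
        self.T = data.t_matrix()
        self.J = self.T.shape[0]
        self.p = self.T.shape[1]
        self.I = len(self.y)
        if self.p:
            self.TtT_inv = np.linalg.inv(self.T.T @ self.T)
            self.TtT_inv_chol = cholesky(self.TtT_inv, lower=True)

        self._prior_cache: tuple[float, tuple] | None = None

    # anchored GP prior over the free coordinates, as a function of sigma2
    def anchored_prior(self, sigma2: float):
        """Return (c0, Htil, S_f, cho) with u_free ~ N(c0 + Htil @ beta_full, S_f)."""
        if self._prior_cache is not None and self._prior_cache[0] == sigma2:
            return self._prior_cache[1]
        Sigma = self.C0 + sigma2 * self.A
        a, f = self.anchor, self.free
        var_a = Sigma[a, a]
        k = Sigma[f, a] / var_a
        S_f = Sigma[np.ix_(f, f)] - np.outer(k, Sigma[a, f])
        S_f = (S_f + S_f.T) / 2.0
        c0 = self.u0[f] + k * (1.0 - self.u0[a])
        Htil = self.H[f] - np.outer(k, self.H[a])
        try:
            cho = cho_factor(S_f, lower=True)
        except np.linalg.LinAlgError:
            cho = cho_factor(S_f + 1e-10 * np.eye(len(f)), lower=True)
        out = (c0, Htil, S_f, cho)
        self._prior_cache = (sigma2, out)
        return out

    def gp_logpdf(self, params: ModelParameters) -> float:
        """Log density of the anchored GP prior at params.u (free coords)."""
        c0, Htil, _, cho = self.anchored_prior(params.sigma2)
        beta_full = np.concatenate(([params.gamma0], params.beta))
        resid = params.u[self.free] - c0 - Htil @ beta_full
        solve = cho_solve(cho, resid)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        m = len(self.free)
        return float(-0.5 * (m * np.log(2 * np.pi) + logdet + resid @ solve))

    def residuals(self, params: ModelParameters) -> np.ndarray:
        """y_ij - [1 - alpha_j (1 - u(x_ij))] for every observation."""
        a_obs = params.alpha[self.obs_resp]
        return self.y - 1.0 + a_obs * (1.0 - params.u[self.obs_state])

    def loc_alpha(self, params: ModelParameters) -> np.ndarray:
        """Log-normal locations t_j' gamma (zeros for a covariate-free model)."""
        if self.p:
            return self.T @ params.gamma_resp
        return np.zeros(self.J)


def _as_context(data, prior, b) -> _FitContext:
    return data if isinstance(data, _FitContext) else _FitContext(data, prior, b)


# --------------------------------------------------------------------------
# joint density and full conditionals
# --------------------------------------------------------------------------


def log_joint(
    params: ModelParameters,
    data: ValuationDataset,
    prior: PriorSpec | None = None,
    b: RoughnessParams | None = None,
) -> float:
    """Unnormalized log posterior density of the full parameter state.

    Sum of: Gaussian likelihood of the cTTO residuals (variance v^2), the
    anchored GP prior of u given (gamma0, beta, sigma^2), log-normal
    densities of the respondent effects, and the improper hyperprior
    -log tau^2 - log v^2 - (1/2) log sigma^2.

    Invalid parameters raise (rather than returning -inf) so that support
    violations surface as bugs, not silently rejected states.
    """
    b = b or default_roughness_params()
    ctx = _as_context(data, prior, b)
    params.validate(anchor_index=ctx.anchor)

    resid = ctx.residuals(params)
    lik = -0.5 * ctx.I * np.log(2 * np.pi * params.v2) - resid @ resid / (2 * params.v2)

    gp = ctx.gp_logpdf(params)

    loga = np.log(params.alpha)
    z = loga - ctx.loc_alpha(params)
    lp_alpha = float(
        -np.sum(loga)
        - 0.5 * ctx.J * np.log(2 * np.pi * params.tau2)
        - z @ z / (2 * params.tau2)
    )

    hyper = -np.log(params.tau2) - np.log(params.v2) - 0.5 * np.log(params.sigma2)
    return float(lik + gp + lp_alpha + hyper)


def u_conditional_moments(
    params: ModelParameters,
    data: ValuationDataset,
    prior: PriorSpec | None = None,
    b: RoughnessParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the exact Gaussian full conditional of u.

    Returned over the full state vector: the anchored coordinate has mean 1
    and zero variance.  Conjugate update of the anchored GP prior with the
    Gaussian likelihood, which is linear in u given the alpha_j.
    """
    b = b or default_roughness_params()
    ctx = _as_context(data, prior, b)
    c0, Htil, S_f, cho = ctx.anchored_prior(params.sigma2)
    beta_full = np.concatenate(([params.gamma0], params.beta))
    prior_mean = c0 + Htil @ beta_full

    a_obs = params.alpha[ctx.obs_resp]
    r = ctx.y - 1.0 + a_obs  # y - (1 - alpha_j) = alpha_j u + eps
    d_full = np.bincount(ctx.obs_state, weights=a_obs**2, minlength=ctx.n) / params.v2
    h_full = np.bincount(ctx.obs_state, weights=a_obs * r, minlength=ctx.n) / params.v2

    P0 = cho_solve(cho, np.eye(len(ctx.free)))
    Lam = P0 + np.diag(d_full[ctx.free])
    eta = P0 @ prior_mean + h_full[ctx.free]
    cov_f = np.linalg.inv(Lam)
    cov_f = (cov_f + cov_f.T) / 2.0
    mean_f = cov_f @ eta

    mean = np.empty(ctx.n)
    cov = np.zeros((ctx.n, ctx.n))
    mean[ctx.anchor] = 1.0
    mean[ctx.free] = mean_f
    cov[np.ix_(ctx.free, ctx.free)] = cov_f
    return mean, cov


def conditional_sample_u(
    params: ModelParameters,
    data: ValuationDataset,
    prior: PriorSpec | None,
    b: RoughnessParams | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw from the multivariate-normal full conditional of u."""
    b = b or default_roughness_params()
    ctx = _as_context(data, prior, b)
    mean, cov = u_conditional_moments(params, ctx, None, b)
    f = ctx.free
    L = cholesky(cov[np.ix_(f, f)] + 1e-12 * np.eye(len(f)), lower=True)
    u = mean.copy()
    u[f] = mean[f] + L @ rng.standard_normal(len(f))
    return u


def gamma_conditional_moments(params: ModelParameters, ctx: _FitContext):
    """Gaussian conditional of the covariate coefficients given log alpha."""
    if not ctx.p:
        raise ValueError("model has no covariates")
    mean = ctx.TtT_inv @ (ctx.T.T @ np.log(params.alpha))
    return mean, params.tau2 * ctx.TtT_inv


def tau2_conditional(params: ModelParameters, ctx: _FitContext) -> tuple[float, float]:
    """Inverse-gamma(shape, scale) full conditional of tau^2."""
    z = np.log(params.alpha) - ctx.loc_alpha(params)
    return ctx.J / 2.0, float(z @ z / 2.0)


def v2_conditional(params: ModelParameters, ctx: _FitContext) -> tuple[float, float]:
    """Inverse-gamma(shape, scale) full conditional of v^2."""
    r = ctx.residuals(params)
    return ctx.I / 2.0, float(r @ r / 2.0)


def beta_conditional_moments(params: ModelParameters, ctx: _FitContext):
    """Gaussian conditional of (gamma0, beta) given u and sigma^2."""
    c0, Htil, _, cho = ctx.anchored_prior(params.sigma2)
    W = cho_solve(cho, Htil)  # S_f^{-1} Htil
    P = Htil.T @ W
    rhs = W.T @ (params.u[ctx.free] - c0)
    cov = np.linalg.inv(P)
    cov = (cov + cov.T) / 2.0
    return cov @ rhs, cov


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------


def _initial_parameters(ctx: _FitContext, config: MCMCConfig) -> ModelParameters:
    obs_mean = np.full(ctx.n, 0.5)
    sums = np.bincount(ctx.obs_state, weights=ctx.y, minlength=ctx.n)
    counts = np.bincount(ctx.obs_state, minlength=ctx.n)
    has = counts > 0
    obs_mean[has] = sums[has] / counts[has]
    u = np.clip(obs_mean, -1.0, 1.0)
    u[ctx.anchor] = 1.0

    beta_full, *_ = np.linalg.lstsq(ctx.H[ctx.free], u[ctx.free] - ctx.u0[ctx.free], rcond=None)
    resid0 = ctx.y - u[ctx.obs_state]
    v2 = max(float(np.var(resid0)), 1e-4)
    params = ModelParameters(
        u=u,
        alpha=np.ones(ctx.J),
        gamma_resp=np.zeros(ctx.p),
        tau2=0.04,
        v2=v2,
        gamma0=float(beta_full[0]),
        beta=beta_full[1:].astype(float),
        sigma2=0.05,
    )
    for key, val in (config.fix or {}).items():
        if key in ("tau2", "v2", "sigma2", "gamma0"):
            setattr(params, key, float(val))
        elif key in ("u", "alpha", "gamma_resp", "beta"):
            setattr(params, key, np.asarray(val, dtype=float).copy())
        else:
            raise ValueError(f"unknown fixed block {key!r}")
    params.u[ctx.anchor] = 1.0
    return params


def run_mcmc(
    data: ValuationDataset,
    prior: PriorSpec | None = None,
    b: RoughnessParams | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Metropolis-within-Gibbs sampler for the full hierarchical model.

    Block sweep per iteration: u (exact Gaussian), each alpha_j (log-scale
    random-walk Metropolis, vectorized), gamma (exact Gaussian), tau^2 and
    v^2 (exact inverse-gamma), (gamma0, beta) (exact Gaussian), sigma^2
    (log-scale random-walk Metropolis).  Deterministic given config.seed.

    Blocks named in ``config.fix`` are held at the supplied values.  With
    ``config.weakly_proper_variances`` the tau^2/v^2 conditionals gain an
    inverse-gamma(0.001, 0.001) regularization (a deliberate departure from
    the improper hyperprior, for degenerate toy datasets).
    """
    b = b or default_roughness_params()
    config = config or MCMCConfig()
    ctx = _FitContext(data, prior, b)
    if ctx.J < 2 or ctx.n < 2:
        raise ValueError(
            "refusing to fit with fewer than 2 respondents or 2 states: the "
            "improper hyperpriors give an improper posterior"
        )
    fix = set((config.fix or {}).keys())
    if ctx.p == 0:
        fix.add("gamma_resp")
    if len(ctx.free) < 6 and "beta" not in fix:
        raise ValueError(
            "fewer than 6 free states cannot identify (gamma0, beta) under a "
            "flat prior; fix the GP mean coefficients via config.fix"
        )
    a0 = b0 = 0.001 if config.weakly_proper_variances else 0.0

    rng = np.random.default_rng(config.seed)
    params = _initial_parameters(ctx, config)
    n_keep = config.n_retained
    S = PosteriorDraws(
        state_index=ctx.codes,
        u=np.empty((n_keep, ctx.n)),
        alpha=np.empty((n_keep, ctx.J)),
        gamma_resp=np.empty((n_keep, ctx.p)),
        tau2=np.empty(n_keep),
        v2=np.empty(n_keep),
        gamma0=np.empty(n_keep),
        beta=np.empty((n_keep, 5)),
        sigma2=np.empty(n_keep),
        respondent_ids=data.respondent_ids,
        covariate_columns=list(data.covariates.columns),
        covariates=ctx.T if ctx.p else np.zeros((ctx.J, 0)),
    )

    s_alpha = config.prop_scale_alpha
    s_sigma = config.prop_scale_sigma2
    acc_alpha = acc_sigma = 0.0
    n_alpha = n_sigma = 0
    win_acc_alpha = win_acc_sigma = 0.0
    win_n = 0

    keep = 0
    for it in range(config.n_iter):
        in_burn = it < config.n_burnin

        # --- u: exact Gaussian conditional -------------------------------
        if "u" not in fix:
            params.u = conditional_sample_u(params, ctx, None, b, rng)

        # --- alpha_j: vectorized log-scale random-walk Metropolis ---------
        if "alpha" not in fix:
            delta = 1.0 - params.u[ctx.obs_state]
            Sd2 = np.bincount(ctx.obs_resp, weights=delta**2, minlength=ctx.J)
            Sdy = np.bincount(ctx.obs_resp, weights=delta * (ctx.y - 1.0), minlength=ctx.J)
            mu_a = ctx.loc_alpha(params)

            def alpha_logpost(a, th):
                return (
                    -(a**2 * Sd2 + 2.0 * a * Sdy) / (2 * params.v2)
                    - (th - mu_a) ** 2 / (2 * params.tau2)
                )

            theta = np.log(params.alpha)
            prop = theta + s_alpha * rng.standard_normal(ctx.J)
            logr = alpha_logpost(np.exp(prop), prop) - alpha_logpost(params.alpha, theta)
            accept = np.log(rng.uniform(size=ctx.J)) < logr
            theta = np.where(accept, prop, theta)
            params.alpha = np.exp(theta)
            rate = float(accept.mean())
            win_acc_alpha += rate
            if not in_burn:
                acc_alpha += rate
                n_alpha += 1

        # --- gamma: exact Gaussian ----------------------------------------
        if "gamma_resp" not in fix and ctx.p:
            mean_g, _ = gamma_conditional_moments(params, ctx)
            z = rng.standard_normal(ctx.p)
            params.gamma_resp = mean_g + np.sqrt(params.tau2) * (ctx.TtT_inv_chol @ z)

        # --- tau2, v2: exact inverse-gamma --------------------------------
        if "tau2" not in fix:
            shape, scale = tau2_conditional(params, ctx)
            params.tau2 = float((scale + b0) / rng.gamma(shape + a0))
        if "v2" not in fix:
            shape, scale = v2_conditional(params, ctx)
            params.v2 = float((scale + b0) / rng.gamma(shape + a0))

        # --- (gamma0, beta): exact Gaussian -------------------------------
        if "beta" not in fix:
            mean_b, cov_b = beta_conditional_moments(params, ctx)
            L = cholesky(cov_b + 1e-14 * np.eye(6), lower=True)
            draw = mean_b + L @ rng.standard_normal(6)
            params.gamma0 = float(draw[0])
            params.beta = draw[1:]

        # --- sigma2: log-scale random-walk Metropolis ---------------------
        if "sigma2" not in fix:
            cur = params.sigma2
            cur_lp = ctx.gp_logpdf(params) + 0.5 * np.log(cur)
            prop_s = float(np.exp(np.log(cur) + s_sigma * rng.standard_normal()))
            params.sigma2 = prop_s
            prop_lp = ctx.gp_logpdf(params) + 0.5 * np.log(prop_s)
            if np.log(rng.uniform()) < prop_lp - cur_lp:
                accepted = 1.0
            else:
                params.sigma2 = cur
                ctx.anchored_prior(cur)  # restore cache
                accepted = 0.0
            win_acc_sigma += accepted
            if not in_burn:
                acc_sigma += accepted
                n_sigma += 1

        # --- adaptation during burn-in ------------------------------------
        win_n += 1
        if config.adapt and in_burn and win_n == 50:
            if "alpha" not in fix:
                s_alpha = float(np.clip(s_alpha * np.exp(win_acc_alpha / win_n - 0.4), 1e-3, 10))
            if "sigma2" not in fix:
                s_sigma = float(np.clip(s_sigma * np.exp(win_acc_sigma / win_n - 0.4), 1e-3, 10))
            win_acc_alpha = win_acc_sigma = 0.0
            win_n = 0

        # --- divergence guard ---------------------------------------------
        if np.any(params.alpha > ALPHA_DIVERGENCE_LIMIT) or params.v2 < V2_UNDERFLOW_LIMIT:
            raise McmcDivergenceError(
                f"sampler diverged at iteration {it}: max alpha "
                f"{params.alpha.max():.3g}, v2 {params.v2:.3g}"
            )

        # --- retain --------------------------------------------------------
        if not in_burn and (it - config.n_burnin) % config.thin == 0 and keep < n_keep:
            S.u[keep] = params.u
            S.alpha[keep] = params.alpha
            S.gamma_resp[keep] = params.gamma_resp
            S.tau2[keep] = params.tau2
            S.v2[keep] = params.v2
            S.gamma0[keep] = params.gamma0
            S.beta[keep] = params.beta
            S.sigma2[keep] = params.sigma2
            keep += 1

    S.acceptance = {
        "alpha": acc_alpha / n_alpha if n_alpha else None,
        "sigma2": acc_sigma / n_sigma if n_sigma else None,
        "prop_scale_alpha": s_alpha,
        "prop_scale_sigma2": s_sigma,
    }
    return S


# --------------------------------------------------------------------------
# population-mean correction and prediction
# --------------------------------------------------------------------------


def expected_alpha(
    draws: PosteriorDraws, covariates: np.ndarray | pd.DataFrame | None = None
) -> np.ndarray:
    """Per-draw population expectation of the respondent effect.

    E(alpha) = mean_j exp(t_j' gamma) * exp(tau^2 / 2); without covariates
    the first factor is 1.  Pass ``covariates`` to evaluate over a target
    population different from the fitted sample (default: the fitted one).
    """
    if covariates is None:
        covariates = draws.covariates
    if covariates is None or np.size(covariates) == 0 and draws.gamma_resp.shape[1] == 0:
        return np.exp(draws.tau2 / 2.0)
    tmat = np.asarray(covariates, dtype=float)
    if tmat.ndim != 2 or tmat.shape[0] == 0:
        raise ValueError("covariates must be a non-empty (J, p) array")
    if tmat.shape[1] != draws.gamma_resp.shape[1]:
        raise ValueError("covariate dimension does not match the fitted coefficients")
    mean_exp = np.exp(tmat @ draws.gamma_resp.T).mean(axis=0)  # (S,)
    return mean_exp * np.exp(draws.tau2 / 2.0)


def population_mean_utilities(
    draws: PosteriorDraws, covariates: np.ndarray | pd.DataFrame | None = None
) -> pd.DataFrame:
    """Posterior value set: per-state summaries of u and ubar.

    ubar(x) = 1 - E(alpha)(1 - u(x)) per draw; full health is exactly
    (1, 0) because u(full health) is anchored.
    """
    ea = expected_alpha(draws, covariates)  # (S,)
    ubar = 1.0 - ea[:, None] * (1.0 - draws.u)
    return pd.DataFrame(
        {
            "state": draws.state_index,
            "posterior_mean": draws.u.mean(axis=0),
            "posterior_sd": draws.u.std(axis=0, ddof=1),
            "population_mean": ubar.mean(axis=0),
            "population_sd": ubar.std(axis=0, ddof=1),
        }
    )


def predict_unvalued_states(
    draws: PosteriorDraws,
    targets: Sequence[HealthState],
    b: RoughnessParams | None = None,
    prior: PriorSpec | None = None,
    covariates: np.ndarray | pd.DataFrame | None = None,
    include_gp_noise: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Predict (population-corrected) utilities at states not in the fit.

    Per retained draw, the GP is conditioned at the target states on the
    drawn utility vector at the fitted states: prior mean gamma0 + beta' x
    (plus the informative-prior mean where one was used), covariance
    sigma^2 c(.,.) (plus the informative-prior covariance).  Targets that
    were fitted reproduce their fitted summaries exactly.

    An informative prior must cover the target states; otherwise a KeyError
    asks for an extended PriorSpec.
    """
    b = b or default_roughness_params()
    targets = list(targets)
    fitted_codes = draws.state_index
    fitted_states = [parse_state(c) for c in fitted_codes]
    new = [s for s in targets if s.code not in fitted_codes]
    union = fitted_states + new

    if prior is not None and prior.source != "flat":
        missing = [s.code for s in union if s.code not in prior.codes]
        if missing:
            raise KeyError(
                f"informative prior lacks moments for states {missing}; supply an "
                "extended PriorSpec covering the prediction targets"
            )
        pr = prior.subset(union)
        u0, C0 = pr.u0_mean, pr.C0
    else:
        u0 = np.zeros(len(union))
        C0 = np.zeros((len(union), len(union)))

    nf = len(fitted_states)
    H_all = design_matrix(union)
    A_all = correlation_matrix(union, b)
    rng = np.random.default_rng(seed)
    ea = expected_alpha(draws, covariates)

    S = draws.n_draws
    u_t = np.empty((S, len(targets)))
    # positions of each requested target within the union
    union_codes = [s.code for s in union]
    t_pos = [union_codes.index(s.code) for s in targets]
    new_pos = np.array([i for i in range(nf, len(union))], dtype=int)

    for s_i in range(S):
        beta_full = np.concatenate(([draws.gamma0[s_i]], draws.beta[s_i]))
        m = u0 + H_all @ beta_full
        K = C0 + draws.sigma2[s_i] * A_all
        u_union = np.empty(len(union))
        u_union[:nf] = draws.u[s_i]
        if len(new_pos):
            Kff = K[:nf, :nf]
            Ktf = K[np.ix_(new_pos, np.arange(nf))]
            cho = cho_factor(Kff + 1e-10 * np.eye(nf), lower=True)
            w = cho_solve(cho, u_union[:nf] - m[:nf])
            mu_new = m[new_pos] + Ktf @ w
            if include_gp_noise:
                cov_new = K[np.ix_(new_pos, new_pos)] - Ktf @ cho_solve(cho, Ktf.T)
                cov_new = (cov_new + cov_new.T) / 2.0
                w_e, v_e = np.linalg.eigh(cov_new)
                L = v_e * np.sqrt(np.clip(w_e, 0.0, None))
                mu_new = mu_new + L @ rng.standard_normal(len(new_pos))
            u_union[new_pos] = mu_new
        u_t[s_i] = u_union[t_pos]

    ubar = 1.0 - ea[:, None] * (1.0 - u_t)
    return pd.DataFrame(
        {
            "state": [s.code for s in targets],
            "posterior_mean": u_t.mean(axis=0),
            "posterior_sd": u_t.std(axis=0, ddof=1),
            "population_mean": ubar.mean(axis=0),
            "population_sd": ubar.std(axis=0, ddof=1),
        }
    )
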