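# Methods

## Model

A cTTO response by respondent *j* for health state **x**ᵢⱼ is modelled as

    y_ij = 1 − α_j (1 − u(x_ij)) + ε_ij,
    α_j ~ LogNormal(t_j′γ, τ²),   ε_ij ~ N(0, v²).

The respondent effect α_j scales the *disutility* 1 − u multiplicatively:
values above 1 mark respondents who trade more time away than the median
person for the same state. Because α is log-normal, u(**x**) is the
population **median** utility; value sets report the population **mean**

    ū(x) = 1 − E(α)(1 − u(x)),   E(α) = E{exp(t′γ)} · exp(τ²/2),

evaluated per posterior draw (the covariate expectation averages over the
fitted sample's t_j by default; a different target population can be
supplied). When E(α) = 1 the two surfaces coincide.

The latent surface u over the n fitted states has a Gaussian-process prior

    u | β, σ² ~ N(u₀ + Hβ, C₀ + σ² A)

with H rows (1, x₁, …, x₅) on the raw 1–5 level scale (no centering — the
slopes β are per-level utility decrements), kernel
A_kl = exp{−Σ_d b_d (x_kd − x_ld)²}, and roughness b_d = 2.5/(l_d − 1)² so
that exp(−2.5) ≈ 0.082 is the correlation between the two extreme levels of
one dimension. (u₀, C₀) carry prior information from previously fitted
countries: zero for a single-country analysis, the posterior mean and
covariance of another fit's u draws for a combined analysis, and
elementwise sums of several countries' moments for a multi-country prior.
Covariances estimated from draws are symmetrized and eigenvalue-clipped at
zero.

Full health must satisfy u(11111) = 1 (a respondent valuing full health
trades nothing), imposed by exact Gaussian conditioning of the joint prior
rather than by a pseudo-observation; the anchor coordinate then has zero
prior variance and every other conditional variance can only shrink. The
anchor state is appended to the fitted state list when the data do not
contain it.

Hyperpriors are improper, p(γ, τ², v², β, σ²) ∝ τ⁻² v⁻² σ⁻¹ (flat in γ and
β; the σ term means p(σ²) ∝ (σ²)^(−1/2)). The γ of the GP mean (written
`gamma0`) is a scalar intercept, distinct from the respondent-covariate
vector γ (`gamma_resp`); the two play different roles and are sampled in
different blocks.

## Sampler

Metropolis-within-Gibbs, one sweep per iteration:

| block | update |
|---|---|
| u (free coords) | exact multivariate-normal conditional (conjugate: the likelihood is linear in u given α) |
| α_j, all j | vectorized random-walk Metropolis on log α_j |
| γ (covariates) | exact Gaussian: N((T′T)⁻¹T′ log α, τ²(T′T)⁻¹) |
| τ² | inverse-gamma(J/2, Σ(log α_j − t_j′γ)²/2) |
| v² | inverse-gamma(I/2, Σ residual²/2) |
| (γ₀, β) | exact Gaussian (flat prior, anchored-GP generalized least squares) |
| σ² | random-walk Metropolis on log σ² |

Defaults follow the study analyses: 3,000 iterations, 1,000 burn-in, no
thinning, a single chain. Proposal scales for the two Metropolis blocks
adapt every 50 burn-in iterations toward ~0.4 acceptance and are frozen
afterwards. Responses are modelled unbounded (no censoring at −1), matching
the Gaussian likelihood.

Numerical choices: PSD tolerance 1e−10 with symmetric eigenvalue clipping
before Cholesky factorizations (near-duplicate states, finite-sample prior
covariances); a 1e−10 jitter on conditioning matrices in prediction;
exact conditionals are validated against the joint density by
finite-difference tests. Guards: the sampler refuses < 2 respondents or
< 2 states (the improper hyperpriors then give an improper posterior) and
< 6 free states unless (γ₀, β) is held fixed (a flat prior on six
coefficients cannot be identified from fewer states); it aborts with a
diagnostic if any α exceeds 1e6 or v² underflows 1e−12. An optional
weakly-proper inverse-gamma(0.001, 0.001) regularization of the τ²/v²
conditionals is available behind a config flag (off by default; it
deliberately departs from the improper hyperprior for degenerate toys).

Identifiability: the likelihood only weakly separates the overall scale of
the respondent effects from the overall scale of the disutilities — a joint
move α → cα, (1 − u) → (1 − u)/c changes the fit only through the priors.
This drift cancels exactly in ū, which is why value-set accuracy is always
assessed on the population-mean surface, not on u.

## Prediction at unvalued states

Per retained draw the GP is conditioned at the target states on the drawn
u at the fitted states (prior mean γ₀ + β′x plus the informative-prior mean
where one is used; covariance σ²c plus the informative-prior covariance).
An informative prior must cover the targets — the previous fit's posterior
moments at those states are part of the prior and cannot be invented.
Optionally the conditional GP noise is added per draw (on by default) so
that reported SDs include interpolation uncertainty; targets inside the
fitted set reproduce their fitted summaries exactly either way.

## Synthetic studies

The simulator reproduces the published design: 30 valued states plus full
health, three blocks of 11, the pits state 55555 in every block and state
33252 in two (the published per-block composition is not available; the
bundled blocking is a deterministic reconstruction satisfying exactly those
constraints). Respondents — default 120 per country — are assigned blocks
round-robin, giving the characteristic valuation counts (~120 for the pits,
~80 for the doubled state, ~40 elsewhere). Ages are uniform on 18–75 and
sex Bernoulli(1/2); the real samples' demographics were not published, so
these are configurable placeholders. Responses are drawn from the
generating model above with a true surface taken from either bundled
country's observed means; defaults τ² = 0.04, v² = 0.01. Clamping to the
feasible cTTO range [−1, 1] is available but off by default (the fitted
likelihood has no censoring; when clamping is on, a `censored` flag records
the affected records). The six practice states of the real protocol are
training data and are not simulated. The simulator does not model
interviewer effects, protocol violations, or the cTTO lead-time mechanics,
so passing recovery tests demonstrate correctness of the inference under
the model, not robustness to those real-data features.

## Validation strategy and problem sizes

The raw respondent-level data behind the bundled tables are not public, so
the published posterior columns cannot be regenerated; they are shipped as
data and the published *metrics* (RMSE; Bland–Altman bias, SD and width of
the 95% limits of agreement) are recomputed from the table digits. The
model itself is validated by properties, at sizes chosen to keep the whole
suite around two minutes:

- every exact Gibbs conditional agrees with the joint density
  (finite-difference identity);
- on a 2-state/3-respondent study with fixed hyperparameters the sampler's
  posterior means match a deterministic 41³-point quadrature over the
  respondent effects within 3 Monte-Carlo standard errors (effective sample
  sizes via arviz);
- on the default synthetic study (120 respondents, τ² = 0.04, v² = 0.01,
  3,000 iterations) the 95% credible intervals cover the generating
  utilities for ≥ 26 of 31 states;
- borrowing strength: 20 two-country replicates share a true surface (the
  published Irish surface plus N(0, 0.05) state noise); country A's fit
  supplies the prior for country B, and the combined fit must beat the
  single fit's population-mean RMSE against the true surface in ≥ 80% of
  replicates, with smaller average posterior SDs. These replicates use
  v² = 0.09 (per-observation residual SD 0.3, a realistic cTTO noise
  level): it reproduces the published per-state posterior uncertainty
  (~0.03–0.08) and the regime in which a single small study leaves room
  for a prior to help. At the near-noiseless default v² = 0.01 a single
  120-respondent fit already saturates the data and the two analyses are
  statistically indistinguishable;
- the simulated mean response converges to 1 − exp(τ²/2)(1 − u), closing
  the loop between the generator and the population-mean correction.

## Metric conventions

Differences are observed − predicted. RMSE averages the 30 valued states
by default (whether the published figures average 30 or 31 rows is
ambiguous at the printed precision — both reproduce them to ±0.0015 — so
the full-health flag is exposed). Bland–Altman summaries use all 31 rows,
the sample SD (denominator n − 1) and plain 1.96 limits of agreement
(consistent with the width = 3.92 × SD relation in the published values).
The algebraic identity rmse² = bias² + (n−1)/n · sd² holds when both are
computed over the same rows and is tested.

## Limitations

Single-chain sampling with acceptance rates and trace export as the only
diagnostics (no R-hat across chains, no DIC/WAIC); no censored likelihood
for clamped data; informative priors are summed, never weighted or
discounted; the kernel generalizes to other instruments but only the
EQ-5D-5L design is bundled; prior covariances estimated from short,
autocorrelated chains are noisy — combined analyses benefit from running
the prior country's chain at full length.
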