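# Methods notes

## Model

Each subject carries two latent processes observed only through a cognitive
score. Degradation D(t) is a gamma process: increments over (tᵢ₋₁, tᵢ] are
Gamma(c_ga·logistic(M(tᵢ₋₁))·Δtᵢ, β), guaranteeing monotone paths — the
irreversibility assumption for the underlying pathology. The emotional state
M(t) is a Wiener process whose drift is a tanh-bounded regression on the
interval's cumulative emotional impacts, covariates, the previous
degradation level and an intercept; the tanh link caps the mean change at
±c_μ per unit time. Emotional impacts are two independent compound-Poisson
processes (rates k⁺, k⁻; exponential magnitudes with rates λ⁺, λ⁻);
"positive" impacts raise M and thereby accelerate degradation, "negative"
impacts do the opposite (the sign convention follows the degradation
direction, not colloquial usage). The score is linear-Gaussian in (D, M).

Per interval the update order is: draw impacts, move M using D(tᵢ₋₁), move
D using M(tᵢ₋₁), emit Y from the new pair. Both transitions scale with Δt,
so irregular visit grids are handled natively. Initial latent states are
fixed at D(t₀) = M(t₀) = 0 ("no degradation yet, neutral emotion"); the
score at t₀ is emitted from that state plus noise.

Two modelling conventions worth stating: the interval count of impact
events is Poisson with mean k·Δt (the counting process is a homogeneous
Poisson process); and σ, σ_ε are standard deviations. The impact-coefficient
vector pairs by sign label: ω_δ⁺ multiplies the positive cumulative impact.

## Parameters and defaults

Preset settings 1–5 define the synthetic study conditions (20 sequences ×
21 visits, Δt = 1): shared values ω_δ = (0.1, −0.1), ω_d = 0.05, ω₀ = 0,
c_μ = 3, σ = 0.5, β = 10, h₀ = 30, h_d = −1, h_m = −0.5, σ_ε = 1, λ± = 3.
Setting 1 has c_ga = 10 and impact rates k⁺/k⁻ = 5/4; Setting 2 lowers
c_ga to 5; Settings 3/4 contrast positive- vs negative-dominant impacts
(k⁺/k⁻ = 5/3 vs 3/5, c_ga = 5); Setting 5 switches 3/5 → 5/3 for intervals
ending after t₁₀ (negative-dominant early, positive-dominant late). Score
clamping to [0, 30] exists for display fixtures but is off by default: the
observation model is an unbounded Gaussian and inference relies on that.

## Inference

The model is a nonlinear, non-Gaussian state-space model, so the marginal
likelihood is intractable. We estimate it unbiasedly with a particle filter
and embed the estimate in a particle-marginal Metropolis–Hastings (PMMH)
chain — a pseudo-marginal scheme that targets the exact posterior of the
free parameters with the latent paths marginalized out. We chose
marginalization over explicit path augmentation because it keeps the
sampling space at the handful of free parameters (path augmentation for 10
subjects × 20 intervals would add ~400 tightly coupled dimensions) and
because the filter doubles as the forecasting engine.

Filter design. The degradation increment is proposed blindly from its gamma
transition. The emotional state enters the observation linearly with
Gaussian noise, so given the proposed D and the new observation its
conditional is Gaussian in closed form: we sample M from that conditional
and weight by the M-marginalized one-step predictive (the locally optimal
proposal for the linear sub-state). This cut the log-likelihood estimator's
sd from ≈ 2–4 (plain bootstrap) to ≈ 0.4 at 512 particles on a 10-sequence
Setting-1 dataset — comfortably inside the ≲ 1–1.5 range PMMH needs to mix.
Resampling is systematic, row-wise per subject, triggered at ESS < N/2;
trajectories sharing a visit grid are filtered together as one vectorized
block. Recorded impacts are conditioned on (their Poisson/gamma data terms
enter the likelihood); with `latent_treatment="augmented"` they are instead
sampled inside the filter, for data without impact records and non-zero
impact coefficients.

Sampler. Positive parameters move on the log scale (with the Jacobian in
the prior). Proposals are multivariate Gaussian random walks; during
warm-up the step size adapts toward 25% acceptance (Robbins–Monro) and the
proposal covariance is refreshed every 25 iterations from the trailing 1000
warm-up draws (Haario-style), then frozen. Chains initialize from prior
draws, retrying until the likelihood is finite. Everything is driven by
per-chain child streams of one seed, so fits are bit-reproducible.

Defaults: 3 chains, 1000 warm-up + 1000 sampling iterations, 512 particles.
The shipped recovery study uses 3000 + 3000, which brings every split-chain
R-hat below 1.05 at the 10-sequence problem size; the original protocol of
6000 + 4000 is available through `McmcConfig`.

R-hat is the classic split-chain potential scale reduction factor (each
chain halved; between- vs within-half variance), computed from first
principles and cross-checked against ArviZ's split method in the tests.
Constant chains make the statistic undefined and raise a dedicated error
rather than returning a number.

## Priors

Free parameters and priors are configurable (`PriorSpec`); two profiles
ship. The synthetic profile frees {c_μ, σ, c_ga, β, h₀, h_d, h_m, σ_ε} and
pins the impact rates/coefficients and drift structure at their generating
values. Every prior is deliberately centered ≥ 1 prior sd away from the
Setting-1 generating value, so recovery is demonstrably data-driven.
Tightness is allocated by identifiability: the latent scales of D and M
trade off against (h_d, β) and (h_m, c_μ, σ) — only products such as
h_d·c_ga/β and h_m·c_μ are strongly data-identified — so the loadings
h_d, h_m, the dynamics scales c_μ, σ and the setting-invariant rate β carry
tight scales (2–10%), the standard remedy for scale-degenerate state-space
models and consistent with how such fits are reported with tight
informative priors. Within each product pair the two partners are offset in
opposite directions (e.g. c_μ centered below its value, h_m above in
magnitude; h_d below, β below), so the identified products stay unbiased
while every marginal prior remains off-center — otherwise the mis-centering
of a pinned partner leaks into the free amplitude. The gamma amplitude
c_ga — the quantity the synthetic settings contrast — is left loose
(lognormal sd 0.37, centered near the geometric midpoint of the contrasted
amplitudes) so the data place it: the same profile recovers c_ga ≈ 10 under
Setting 1 and ≈ 5 under Setting 2. With diffuse priors on all eight
parameters joint recovery is not expected; that is a property of the model,
not of the sampler.

The real-cohort-style profile instead frees the drift regression
(ω_d, ω₀, one covariate coefficient such as APOE4) plus the scales and
loadings, pins the impact coefficients at zero (impacts unrecorded in
registry data), and uses tight normal/truncated-normal priors throughout.

## Forecasting

One-step-ahead prediction P{Y(tᵢ₊₁) | Y(t₀..tᵢ)} uses a set of parameter
draws (posterior draws of a fit, or prior draws) each carrying a particle
cloud over the latent state. As each observation arrives, the clouds are
filtered and each draw's cumulative marginal likelihood is updated; draws
are importance-reweighted by that likelihood, which is the sequential
prior-to-posterior parameter update done by reweighting rather than
refitting (a full per-step refit is available via `update="refit"`).
Forecasts propagate the clouds one interval with future impacts drawn from
their compound-Poisson prior, add observation noise, and resample a fixed
number of equally weighted predictive draws — so the reported mean is
exactly the mean of the returned draws, and the 5/95% quantiles come from
the same sample. Forecasts never touch data at or after their target time;
the tests fuzz future observations to enforce this. Default i_min = 1
(first forecast conditions on two visits); the calibration study uses
i_min = 0 to obtain 20 events per 21-visit subject.

Evaluation reports pooled MSE over all prediction events (per-subject MSEs
and their mean are also reported, since pooling convention is a choice),
plus empirical 5–95% coverage.

## What the synthetic generator does and does not emulate

It reproduces the study conditions exactly: group sizes, grid, preset
parameters, the Setting-5 regime switch, and recorded per-interval impacts.
It does not emulate real-cohort features: irregular/missing visits (the
model and filter handle irregular grids, but the fixtures are uniform),
score discreteness and ceiling/floor effects (scores are unbounded
Gaussian draws), covariate-driven heterogeneity (ω_z = 0 in the presets),
or per-subject initial-state variation. Passing tests therefore demonstrate
correctness of the machinery and calibration under the model, not clinical
performance.

## Numerical choices and limitations

- Problem sizes: the shipped recovery/calibration studies use 10 training
  and 10 held-out sequences, 512 filter particles, 3 × (3000 + 3000) MCMC
  iterations, 200 parameter draws × 256 particles for forecasting — sizes
  chosen so the full study runs in minutes on one CPU while leaving the
  Monte-Carlo error well below the quantities being checked.
- Degenerate modes: c_ga = 0 (frozen degradation), σ = 0, σ_ε = 0 and
  k = 0 are accepted by the simulator and forecaster for exactness tests;
  density evaluation and MCMC reject them with a dedicated error.
- Gamma increments with very small shapes underflow to zero mass near 0;
  the filter guards shapes with a floor of 1e-300 only to keep the sampler
  defined.
- The pseudo-marginal chain can stall if the likelihood estimator's
  variance grows (long series, many subjects); raise `n_particles` —
  estimator noise inflates R-hat long before it biases results.
- Split R-hat, not rank-normalized R-hat, is reported (matching the
  convergence criterion used for this model family); heavy-tailed
  posteriors would warrant the rank-normalized variant.
- The latent initial state is shared and fixed at (0, 0). Cohorts enrolled
  mid-disease would need a per-subject initial-degradation parameter; that
  extension is deliberately out of scope here.
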