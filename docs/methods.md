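# Methods

## The model

The central quantity is the species-typical yawn duration, the mean of
the per-yawn durations observed for a species. Across species this
quantity is strictly positive and right-skewed, and it carries
phylogenetic signal: closely related species yawn for similar lengths of
time. The package models the species mean duration $\bar y_i$ (seconds)
as Gamma distributed with a log link,

$$
\bar y_i \sim \mathrm{Gamma}(\mu_i, \alpha), \qquad
\log \mu_i \;=\; \beta_0 + \textstyle\sum_k \beta_k z_{ik} + b_i + u_i,
$$

where the Gamma is parameterized by its mean $\mu$ and shape $\alpha$,
$z_{ik}$ are z-scored predictors (one log-scale brain measure, optionally
plus log body mass), $b \sim \mathrm{MVN}(0,\ \sigma_{\text{phylo}}^2 C)$
is a phylogenetically structured intercept with $C$ the unit-height
phylogenetic correlation matrix of the clade's tree, and
$u_i \sim \mathrm N(0, \sigma_{\text{species}}^2)$ is an i.i.d. species
intercept absorbing heterogeneity not explained by phylogeny. Priors are
regularizing: $\beta \sim \mathrm N(0,1)$ on intercepts and slopes,
$\sigma \sim \mathrm{Exponential}(3)$ on the random-effect SDs, and
$\mathrm{Gamma}(0.01, 0.01)$ on the shape (the conventional diffuse
choice; configurable via `ModelSpec.shape_prior`). Scaling $C$ to unit
height puts $\sigma_{\text{phylo}}$ and $\sigma_{\text{species}}$ on the
same (log-seconds) scale, which is what makes a common Exponential(3)
prior sensible for both.

Posterior summaries follow the robust reporting convention: posterior
median $\beta$, scaled median absolute deviation (MAD $\times$ 1.4826, a
consistent estimator of the posterior SD — this matches the convention
of the Bayesian regression software family this analysis style comes
from), equal-tailed 90% credible interval, $p_+$ = the fraction of draws
strictly greater than zero, and Cohen's $d$ for slopes. No formula for
$d$ is standard in this setting; the package uses the link-scale
standardization $d = \beta / \sqrt{\sigma_{\text{phylo}}^2 +
\sigma_{\text{species}}^2}$ per draw, then summarizes, with $|d| \ge
0.2/0.5/0.8$ labeled small/medium/large.

## Data preparation

Per-yawn events (species, individual, duration) are aggregated to
species means. A species is retained only with at least two yawns from
at least two different individuals. The species mean averages over yawns
by default; averaging over per-individual means first is available
(`mean_over="individuals"`) because the two differ when individuals
contribute unequal yawn counts, and the convention is not dictated by
the aggregation logic itself. An explicit exclusion list removes species
by name (e.g. domesticated species whose brain measures vary strongly by
breed). Endocranial volume converts to brain mass as
$\text{mass} = 1.036 \times \text{ECV}$; a directly measured brain mass
wins over the conversion. Neuronal density is defined as total neurons
per gram of brain ($N/M$), computed before the log transform. All log
transforms are natural logs. Species names are canonicalized (trimmed,
whitespace collapsed to underscores, case-insensitive) before matching
to tree tip labels; species missing from the tree are dropped with a
logged reason, and fewer than four matched species is an error because
the phylogenetic model is not identifiable below that.

## Collinearity gating and size correction

Brain measures scale allometrically with body mass, so a model
"controlling for body mass" by including both predictors risks
multicollinearity bias. The pipeline quantifies that risk with variance
inflation factors (VIF $= 1/(1-R^2)$ from ordinary, non-phylogenetic
regressions on the z-scored log predictors — the standardized metric is
deliberately computed outside the phylogenetic model). When the VIF
exceeds 3, the brain measure is replaced by the residuals of a
phylogenetically controlled (PGLS) regression of the measure on log body
mass, re-standardized and used as the sole predictor; otherwise body
mass enters as a covariate. The size-correction PGLS estimates Pagel's
$\lambda$ by profile maximum likelihood rather than assuming
$\lambda = 1$, for robustness when the signal is imperfect
(`AnalysisPlan.residual_lambda` switches to a fixed value).

## Phylogenetic numerics

$C$ is built by a single tree traversal (entry $(i,j)$ = depth of the
most recent common ancestor). Pagel's $\lambda$ multiplies the
off-diagonal entries; the search space is capped at $[0,1]$ since values
above 1 can break positive semi-definiteness. $\lambda$ is estimated by
profiling the mean and rate of a Brownian model analytically and
optimizing $\lambda$ by bounded scalar search (tolerance $10^{-6}$),
with the endpoints checked explicitly. All GLS solves go through a
Cholesky factorization of $C_\lambda$ (never an explicit inverse), with
a $10^{-10}$ jitter added once on failure. Evolutionary (phylogenetic)
correlations come from the ML bivariate Brownian rate matrix,
equivalently the correlation of phylogenetically independent contrasts
through the origin.

## Posterior computation

No probabilistic-programming backend is assumed; the package carries its
own No-U-Turn Sampler (multinomial trajectory sampling, dual-averaging
step-size adaptation targeting 0.95 acceptance, windowed diagonal
mass-matrix adaptation), with the log posterior and its gradient
compiled by numba. The phylogenetic intercepts are non-centred
($b = \sigma_{\text{phylo}} L \varepsilon$, $L$ the Cholesky factor of
$C$).

With one observation (the species mean) per species,
$\sigma_{\text{species}}$ and the Gamma shape are only weakly separated:
the likelihood mainly constrains the total dispersion
$\sigma_{\text{species}}^2 + 1/\alpha$, and the regularizing priors are
relied on for the split. Sampled naively this produces a curved,
slowly-mixed ridge. The sampler therefore uses internal coordinates
$(s, w)$ with $\sigma_{\text{species}}^2 = e^s w$ and $1/\alpha =
e^s(1-w)$, $w \in (0,1)$ on the logit scale; the Jacobian of this map is
constant, so the posterior is unchanged while the ridge becomes two
nearly independent directions. A diagnostic warning is emitted when the
posterior correlation of $\sigma_{\text{species}}$ and $\alpha$ exceeds
0.9, surfacing the weak separation to the user.

A fit is rejected (a `ConvergenceError`, never a silent pass) unless
max split-$\hat R$ < 1.01 and min bulk ESS > 400 across the reported
parameters ($\beta_0$, $\beta$, $\sigma$'s, $\alpha$). Defaults are 4
chains of 4000 iterations (half warmup); pipeline loops retry a failed
gate with a fresh seed and 60% longer chains, since the binding
constraint is almost always the bulk ESS of the dispersion parameters,
which grows linearly with the number of draws. Fits are bit-reproducible
given (seed, chains, iterations) on a fixed platform.

## Model screening, contrasts and predictions

Random slopes across taxonomic orders are screened with WAIC computed
from pointwise posterior log-likelihoods (log-mean-exp stabilized);
the comparison is paired over species and the more complex model is
adopted only when $\Delta\text{WAIC} = \text{WAIC}_{\text{fixed}} -
\text{WAIC}_{\text{slopes}}$ reaches 2.

Cross-clade contrasts (mammal $-$ bird) pair equal-length,
independently subsampled draw sequences from the two clades' fits; each
fit's subsample is keyed by its own seed, so swapping the argument order
negates the contrast exactly. Below 1000 paired draws the contrast is
refused. The constrained joint model concatenates both clades with a
shared slope, clade-specific intercepts, and a block-diagonal
phylogenetic correlation (one block per clade tree); predictors are
standardized on the pooled sample so "the same brain size" is
well-defined across clades. Expected durations marginalize over the
Gaussian random intercepts in closed form,
$E[y] = \exp(\beta_0 + \beta z + (\sigma_{\text{phylo}}^2 +
\sigma_{\text{species}}^2)/2)$.

The power analysis simulates species means from a template fit's
posterior-median nuisance parameters with a prescribed slope, refits,
and counts a detection when the 90% CI excludes zero (the CI rule is one
of several possible rejection criteria; it is the one adopted here).
Replicates failing the convergence gate are re-run with a new seed up to
three times, then counted as missing.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
a pure-birth (Yule) tree rescaled to unit height (tip branches are
extended by the waiting time to the next unrealized speciation, the
proper Yule snapshot — the raw simulator stops exactly at a birth event,
which would leave duplicate tips and a singular covariance); correlated
log body/brain mass under bivariate Brownian motion; log neuron counts
as an allometric function of log brain mass with i.i.d. noise; and yawn
durations drawn per individual from the species-level Gamma. Because
individual yawns share the species mean, the average of $m$ yawns is
again Gamma with shape $m\alpha$ and the same mean — the species-mean
model fitted downstream is exactly the generative model for aggregated
data. $\lambda$ enters simulation exactly as in estimation (off-diagonal
multiplier of the unit-height correlation matrix), so recovery suites
target the same quantity they estimate.

One consequence worth noting: the *marginal* Pagel's lambda of the
simulated yawn trait is below the simulation lambda even when the latter
is 1, because the i.i.d. species intercept and the Gamma observation
noise add non-phylogenetic variance on top of the lambda-structured
intercept. Lambda recovery is therefore validated on traits simulated as
pure lambda-structured Gaussians, while the end-to-end suite checks
joint recovery of the model's own parameters (intercept, slope, both
random-effect SDs).

Defaults are the recovery-suite reference conditions: 50 species, slope 0.35
per SD, intercept $\log 3.4$ log-seconds, $\sigma_{\text{phylo}} = 0.2$,
$\sigma_{\text{species}} = 0.1$, per-yawn shape 20, $\lambda = 1$, six
individuals per species with two yawns each (near the per-species sampling
typical of comparative yawn datasets), brain-body evolutionary correlation 0.95. What the generator
does **not** emulate: measurement error in brain masses, non-ultrametric
trees, extinction, sex differences, unequal yawn counts across
individuals, and order-level biology beyond optional slope deviations.
Passing recovery tests therefore shows the estimation machinery is
correct and calibrated under the model's own assumptions, not that the
model is right for any particular real dataset.

## Identifiability of order-level random slopes

A caution surfaced by the selection-calibration suite: order-level slope
deviations are identifiable only to the extent the predictor varies
*within* orders. Taxonomic orders are clades, and a phylogenetically
structured predictor (such as log brain mass, evolving by Brownian
motion) is nearly constant within an order — a slope deviation then acts
as an order-level intercept shift, which the phylogenetic intercept
absorbs at lower complexity cost, and WAIC correctly declines the slopes
model even when deviations of SD 0.3 were simulated (only deviations
around SD 1 become detectable). The calibration suite therefore draws
the predictor i.i.d. across species, where SD-0.3 deviations are
detected decisively. On real comparative data this means a negative
random-slope screen for a strongly conserved predictor is weak evidence
against order-varying slopes.

## Numerical and procedural choices

* Equal-tailed CIs, not HPD; quantiles at 5%/95%.
* $p_+$ uses strict inequality; draws exactly at zero count as not
  positive.
* Ties and duplicates: duplicate (species, individual) yawns all count
  toward the species mean.
* Standardization uses the sample SD ($n-1$); z-scoring requires at
  least two distinct values.
* The per-measure analysis warns below 15 species, the small-sample
  regime where detecting small slopes becomes unreliable. Note that
  power computed on synthetic data is an upper bound for real data at
  the same sample size: the generator's aggregated species means are
  cleaner (per-yawn Gamma noise averaged over a balanced design) than
  empirical species means.
* CSV I/O writes floats with `%.17g` and reads with round-trip float
  parsing, so write-then-read is lossless.
* Problem sizes in the validation suites are chosen to keep the full
  suite practical on a single CPU: 20 recovery replicates at 50 species,
  10 selection replicates per scenario at 50 species, 50 power
  replicates at 30 species, and the full-scale acceptance script at
  55 + 46 species with 40 power replicates at 18 species.

## Known limitations

* One observation per species means $\sigma_{\text{species}}$ and
  $\alpha$ are separated only by skewness information and the priors;
  their individual posteriors should be interpreted cautiously (the
  total dispersion is well identified). A concrete consequence seen in
  the recovery suite: the variance components' credible intervals cover
  a fixed generative truth at roughly 70–75% rather than the nominal
  90% (prior-regularized intervals are calibrated on average over the
  prior, not at a fixed point), while the intercept and slope are close
  to nominal.
* The sampler's convergence gate is strict (ESS > 400 on every reported
  parameter); on pathological ridges this costs retries with longer
  chains rather than silently degrading.
* WAIC here is the conditional (species-level) variant; it measures
  within-sample predictive fit given the random effects, not
  leave-one-species-out performance.
* The Gaussian-residual PGLS robustness route models log duration and
  inherits the usual PGLS small-sample caveats.
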