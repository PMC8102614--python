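"""End-to-end analysis orchestration.

For each clade and brain measure the pipeline fits the Gamma GLMM of
species mean yawn duration on the standardized (log) measure.  The
body-size adjustment is gated by collinearity: if the VIF of the measure
and log body mass exceeds the threshold (default 3), the measure is
replaced by the residuals of a phylogenetically controlled regression of
the measure on body mass (re-standardized); otherwise body mass enters as
an additional covariate.  Random slopes across taxonomic orders are
screened by a paired WAIC comparison (adopt slopes only at a difference
of 2 or more).  Cross-clade comparisons contrast posterior draws
(mammal - bird) for intercepts and slopes, and a constrained joint model
with a shared slope, clade intercepts and a block-diagonal phylogenetic
covariance predicts expected yawn duration for clades matched on size.

All log transforms are natural logs.  Expected durations marginalize
over the Gaussian random intercepts in closed form:
E[y] = exp(beta0 + beta z + (sigma_phylo^2 + sigma_species^2) / 2).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from . import bayes_model as bm
from .exceptions import ConvergenceError, DegenerateDataError, InputError
from .io_data import match_tree
from .phylo_core import pgls_fit, phylo_cov, vif
from .synthetic_data import simulate_bm_traits, simulate_tree

logger = logging.getLogger("phyloyawn")

__all__ = [
    "AnalysisPlan",
    "Standardization",
    "standardize",
    "run_measure",
    "run_random_slope_check",
    "contrast_clades",
    "constrained_joint_fit",
    "predict_duration",
    "power_analysis",
    "residual_on_residual_pgls",
    "MEASURE_COLUMNS",
    "fit_with_retry",
]

#: analysis measure -> log-scale column in the species table
MEASURE_COLUMNS = {
    "brain_mass": "log_brain",
    "total_neurons": "log_total_neurons",
    "cortex_pallium_neurons": "log_cortex_neurons",
    "neuron_density": "log_neuron_density",
}

MIN_SPECIES = 4
WARN_SPECIES = 15


@dataclass
class AnalysisPlan:
    """Settings for one clade's analysis."""

    clade: str = "mammal"
    measures: tuple = ("brain_mass",)
    adjust_body: bool = True
    vif_threshold: float = 3.0
    random_slopes_by_order: str = "auto"  # auto | on | off
    residual_lambda: str | float = "ml"   # lambda for the size-correction PGLS
    chains: int = 4
    iterations: int = 4000
    target_accept: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not self.vif_threshold > 1:
            raise InputError("vif_threshold must exceed 1")
        if self.random_slopes_by_order not in ("auto", "on", "off"):
            raise InputError("random_slopes_by_order must be auto, on or off")
        self.measures = tuple(self.measures)
        bad = [m for m in self.measures if m not in MEASURE_COLUMNS]
        if bad:
            raise InputError(f"unknown measures: {bad}")


@dataclass
class Standardization:
    """A z-scoring with its stored mean/SD for back-transformation."""

    mean: float
    sd: float

    def apply(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def invert(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(values):
    """z-scores with sample SD (n-1); returns (z, Standardization)."""
    v = np.asarray(values, dtype=float)
    if np.unique(v[np.isfinite(v)]).size < 2:
        raise DegenerateDataError("need at least 2 distinct values to standardize")
    m = float(np.mean(v))
    s = float(np.std(v, ddof=1))
    if s == 0:
        raise DegenerateDataError("zero variance; cannot standardize")
    st = Standardization(mean=m, sd=s)
    return st.apply(v), st


def fit_with_retry(spec, data, plan: AnalysisPlan, tree=None, corr=None,
                   seed=None, attempts: int = 3):
    """Fit, retrying on a failed convergence gate.

    Each retry reseeds the sampler and lengthens the chains by 60%, since
    the binding constraint is almost always the bulk ESS of the weakly
    identified dispersion parameters, which grows linearly with the
    number of draws.
    """
    base = plan.seed if seed is None else seed
    last = None
    iters = plan.iterations
    for k in range(attempts):
        try:
            return bm.fit_model(
                spec, data, tree=tree, corr=corr, chains=plan.chains,
                iterations=iters, seed=base + 104729 * k,
                target_accept=plan.target_accept,
            )
        except ConvergenceError as e:
            last = e
            logger.warning("convergence gate failed (attempt %d/%d): %s",
                           k + 1, attempts, e)
            iters = int(iters * 1.6)
    raise last


def _subset_for_measure(clade_data: pd.DataFrame, tree, measure: str):
    col = MEASURE_COLUMNS[measure]
    if col not in clade_data.columns:
        raise InputError(f"column {col} missing from the species table")
    sub = clade_data[np.isfinite(clade_data[col].astype(float))].copy()
    if len(sub) < MIN_SPECIES:
        return None, None
    sub_tree, sub = match_tree(sub, tree)
    if len(sub) < WARN_SPECIES:
        warnings.warn(
            f"only {len(sub)} species carry {measure}; estimates will be "
            "imprecise (power is low for small effects at this sample size)",
            stacklevel=2,
        )
    return sub_tree, sub


@dataclass
class MeasureResult:
    """Fits and summaries for one (clade, measure) analysis."""

    measure: str
    n_species: int
    fit_unadjusted: bm.PosteriorDraws
    summary_unadjusted: pd.DataFrame
    vif: float = float("nan")
    branch: str = "none"          # residual | covariate | none
    fit_adjusted: bm.PosteriorDraws = None
    summary_adjusted: pd.DataFrame = None
    skipped_reason: str = ""
    predictor_unadjusted: str = ""
    predictor_adjusted: str = ""


def run_measure(clade_data: pd.DataFrame, tree, measure: str,
                plan: AnalysisPlan) -> MeasureResult | None:
    """Fit the unadjusted model for one measure, plus the body-size
    adjusted model chosen by the VIF rule when ``plan.adjust_body``.

    The unadjusted fit regresses mean yawn duration on the standardized
    log measure alone.  Body-size adjustment either (VIF > threshold)
    feeds re-standardized PGLS residuals of the measure on log body mass
    as the sole predictor, or (VIF below threshold) adds z log body mass
    as a covariate.  Returns ``None`` when too few species carry the
    measure.
    """
    sub_tree, sub = _subset_for_measure(clade_data, tree, measure)
    if sub is None:
        logger.warning("measure %s skipped: fewer than %d species", measure,
                       MIN_SPECIES)
        return None
    col = MEASURE_COLUMNS[measure]
    zm, _ = standardize(sub[col].to_numpy(float))
    zname = f"z_{measure}"
    sub[zname] = zm

    spec_u = bm.ModelSpec(fixed_effects=(zname,))
    fit_u = fit_with_retry(spec_u, sub, plan, tree=sub_tree, seed=plan.seed)
    res = MeasureResult(
        measure=measure, n_species=len(sub), fit_unadjusted=fit_u,
        summary_unadjusted=bm.summarize(fit_u), predictor_unadjusted=zname,
    )
    if not plan.adjust_body:
        return res

    zb, _ = standardize(sub["log_body"].to_numpy(float))
    sub["z_body"] = zb
    vifs = vif(np.column_stack([zm, zb]))
    res.vif = float(vifs.max())
    if res.vif > plan.vif_threshold:
        res.branch = "residual"
        X = pd.DataFrame({"intercept": np.ones(len(sub)),
                          "log_body": sub["log_body"].to_numpy(float)})
        pg = pgls_fit(sub[col].to_numpy(float), X, sub_tree,
                      lambda_mode=plan.residual_lambda)
        zr, _ = standardize(pg.residuals)
        rname = f"z_resid_{measure}"
        sub[rname] = zr
        spec_a = bm.ModelSpec(fixed_effects=(rname,))
        res.predictor_adjusted = rname
    else:
        res.branch = "covariate"
        spec_a = bm.ModelSpec(fixed_effects=(zname, "z_body"))
        res.predictor_adjusted = zname
    logger.info("measure %s: VIF = %.2f -> %s branch", measure, res.vif,
                res.branch)
    res.fit_adjusted = fit_with_retry(spec_a, sub, plan, tree=sub_tree,
                                      seed=plan.seed + 1)
    res.summary_adjusted = bm.summarize(res.fit_adjusted)
    return res


@dataclass
class SlopeCheckResult:
    decision: str                   # "fixed" or "slopes"
    delta: float                    # WAIC_fixed - WAIC_slopes
    se: float
    reason: str = ""
    comparison: bm.WaicComparison = None


def run_random_slope_check(clade_data: pd.DataFrame, tree, measure: str,
                           plan: AnalysisPlan) -> SlopeCheckResult:
    """WAIC screen for order-level random slopes on one measure.

    Fits the fixed-slope and random-slopes variants on identical rows and
    adopts the slopes model only when the paired WAIC difference reaches
    2.  With a single taxonomic order the decision is 'fixed' by
    construction.
    """
    sub_tree, sub = _subset_for_measure(clade_data, tree, measure)
    if sub is None:
        return SlopeCheckResult("fixed", float("nan"), float("nan"),
                                reason="too few species")
    if sub["order"].astype(str).nunique() < 2:
        return SlopeCheckResult("fixed", float("nan"), float("nan"),
                                reason="single taxonomic order")
    col = MEASURE_COLUMNS[measure]
    zm, _ = standardize(sub[col].to_numpy(float))
    zname = f"z_{measure}"
    sub[zname] = zm
    spec_fixed = bm.ModelSpec(fixed_effects=(zname,))
    spec_slopes = bm.ModelSpec(fixed_effects=(zname,), order_slopes=True)
    fit_fixed = fit_with_retry(spec_fixed, sub, plan, tree=sub_tree,
                               seed=plan.seed + 11)
    fit_slopes = fit_with_retry(spec_slopes, sub, plan, tree=sub_tree,
                                seed=plan.seed + 12)
    comp = bm.compare_waic(fit_fixed, fit_slopes)
    logger.info("random-slope check (%s): dWAIC = %.2f [%.2f] -> %s",
                measure, comp.delta, comp.se, comp.decision)
    return SlopeCheckResult(decision=comp.decision, delta=comp.delta,
                            se=comp.se, comparison=comp)


def _paired_subsample(fit_a: bm.PosteriorDraws, fit_b: bm.PosteriorDraws,
                      name_a: str, name_b: str, seed: int):
    xa = fit_a.stacked(name_a)
    xb = fit_b.stacked(name_b)
    m = min(xa.size, xb.size)
    if m < 1000:
        raise InputError(f"need at least 1000 paired draws; have {m}")
    # per-fit subsampling keyed by the fit's own seed, so swapping the
    # argument order negates the contrast exactly
    ia = np.random.default_rng([seed, fit_a.seed]).permutation(xa.size)[:m]
    ib = np.random.default_rng([seed, fit_b.seed]).permutation(xb.size)[:m]
    return xa[ia], xb[ib]


@dataclass
class CladeContrast:
    """Posterior contrasts (first clade minus second) and predictions."""

    delta: dict                 # parameter label -> summary dict
    predicted_duration: dict    # clade label -> summary dict (seconds)
    draws: dict = field(default_factory=dict, repr=False)


def contrast_clades(fit_mammal: bm.PosteriorDraws, fit_bird: bm.PosteriorDraws,
                    seed: int = 0, z_ref: float = 0.0) -> CladeContrast:
    """Contrast two independently fitted clades (mammal - bird).

    Delta draws pair equal-length, independently subsampled posterior
    sequences for the intercept and each shared slope; predicted
    durations are reported per clade at the reference predictor value
    (default the clade average, z = 0).
    """
    slopes_m = fit_mammal.slope_names
    slopes_b = fit_bird.slope_names
    if len(slopes_m) != len(slopes_b):
        raise InputError("fits have different numbers of slopes")
    pairs = [("beta0", "beta0", "delta_beta0")]
    pairs += [(a, b, f"delta_{a}") for a, b in zip(slopes_m, slopes_b)]
    delta = {}
    draws = {}
    for name_a, name_b, label in pairs:
        xa, xb = _paired_subsample(fit_mammal, fit_bird, name_a, name_b, seed)
        d = xa - xb
        delta[label] = bm.summarize_vector(d)
        draws[label] = d
    predicted = {
        "first": predict_duration(fit_mammal, z_ref),
        "second": predict_duration(fit_bird, z_ref),
    }
    return CladeContrast(delta=delta, predicted_duration=predicted, draws=draws)


def predict_duration(draws: bm.PosteriorDraws, z_ref: float,
                     intercept: str = "beta0", slope: str | None = None) -> dict:
    """Posterior expected yawn duration (s) at predictor value ``z_ref``.

    Marginalizes over the Gaussian random intercepts in closed form:
    per draw, E[y] = exp(beta0 + beta * z_ref + (sigma_p^2 + sigma_s^2)/2).
    """
    if slope is None:
        slope = draws.slope_names[0]
    b0 = draws.stacked(intercept)
    b = draws.stacked(slope)
    sp = (draws.stacked("sigma_phylo") if "sigma_phylo" in draws.params
          else np.full_like(b0, float(draws.spec.sigma_phylo_fixed or 0.0)))
    ss = draws.stacked("sigma_species")
    dur = np.exp(b0 + b * z_ref + 0.5 * (sp**2 + ss**2))
    out = bm.summarize_vector(dur)
    out["draws"] = dur
    return out


@dataclass
class JointFitResult:
    """Constrained joint model: shared slope, clade intercepts."""

    fit: bm.PosteriorDraws
    delta_beta0: dict
    predicted_duration: dict    # clade -> summary at the reference z
    z_ref: float
    measure: str
    clades: tuple


def constrained_joint_fit(mammal_data: pd.DataFrame, bird_data: pd.DataFrame,
                          trees: dict, measure: str, plan: AnalysisPlan,
                          reference_clade: str = "bird") -> JointFitResult:
    """One model across both clades with the size slope constrained to
    equivalence.

    Predictors are standardized on the pooled sample so that "the same
    size" is well defined across clades; the phylogenetic random effect
    uses a block-diagonal correlation matrix (one block per clade tree);
    intercepts are clade-specific.  Expected durations are predicted for
    each clade at the reference clade's mean predictor value,
    marginalizing over the random intercepts.
    """
    col = MEASURE_COLUMNS[measure]
    parts = []
    blocks = []
    for label, data in (("mammal", mammal_data), ("bird", bird_data)):
        if label not in trees or trees[label] is None:
            raise InputError(f"missing tree for clade {label!r}")
        sub = data[np.isfinite(data[col].astype(float))].copy()
        sub_tree, sub = match_tree(sub, trees[label])
        sub["clade"] = label
        parts.append(sub)
        blocks.append(phylo_cov(sub_tree, scale_to_unit_height=True).matrix)
    combined = pd.concat(parts, ignore_index=True)
    corr = block_diag(*blocks)

    z, _ = standardize(combined[col].to_numpy(float))
    combined["z_pooled"] = z
    z_ref = float(combined.loc[combined["clade"] == reference_clade,
                               "z_pooled"].mean())

    spec = bm.ModelSpec(fixed_effects=("z_pooled",), intercept_by="clade")
    fit = fit_with_retry(spec, combined, plan, corr=corr, seed=plan.seed + 21,
                         attempts=5)

    d0 = fit.stacked("beta0[mammal]") - fit.stacked("beta0[bird]")
    predicted = {
        lab: predict_duration(fit, z_ref, intercept=f"beta0[{lab}]")
        for lab in ("mammal", "bird")
    }
    return JointFitResult(
        fit=fit, delta_beta0=bm.summarize_vector(d0), predicted_duration=predicted,
        z_ref=z_ref, measure=measure, clades=("mammal", "bird"),
    )


@dataclass
class PowerResult:
    power: float
    se: float
    n_detected: int
    n_completed: int
    n_missing: int
    beta_true: float


def power_analysis(template_fit: bm.PosteriorDraws, beta_true: float,
                   tree=None, n_species: int | None = None, reps: int = 50,
                   seed: int = 0, plan: AnalysisPlan | None = None) -> PowerResult:
    """Simulation-based power for detecting a slope of ``beta_true``.

    Each replicate simulates species mean durations from the template
    fit's posterior-median nuisance parameters (intercept, random-effect
    SDs, Gamma shape) with the prescribed slope on the given tree, refits
    the model, and counts a detection when the 90% credible interval
    excludes zero.  Replicates failing the convergence gate are re-run
    with a fresh seed up to 3 times, then counted as missing.
    """
    if reps < 20:
        raise InputError("power analysis needs at least 20 replicates")
    plan = plan or AnalysisPlan()
    ss = np.random.SeedSequence(seed)
    if tree is None:
        if n_species is None:
            raise InputError("supply a tree or n_species")
        tree = simulate_tree(n_species, 1.0,
                             seed=int(ss.generate_state(1)[0] % (2**31)))
    cov = phylo_cov(tree, scale_to_unit_height=True)
    n = cov.n
    from .phylo_core import chol_with_jitter

    L = chol_with_jitter(cov.matrix + 1e-10 * np.eye(n))

    b0 = float(np.median(template_fit.stacked("beta0")))
    sp = (float(np.median(template_fit.stacked("sigma_phylo")))
          if "sigma_phylo" in template_fit.params else 0.0)
    ssd = float(np.median(template_fit.stacked("sigma_species")))
    alpha = float(np.median(template_fit.stacked("alpha")))

    spec = bm.ModelSpec(fixed_effects=("z_pred",))
    detected = 0
    completed = 0
    missing = 0
    rep_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(reps)]
    for r in range(reps):
        rng = np.random.default_rng(rep_seeds[r])
        x = simulate_bm_traits(tree, (0.0,), np.array([[1.0]]),
                               seed=rep_seeds[r], columns=("x",))["x"].to_numpy()
        z = (x - x.mean()) / x.std(ddof=1)
        eta = (b0 + beta_true * z + sp * (L @ rng.standard_normal(n))
               + ssd * rng.standard_normal(n))
        y = rng.gamma(shape=alpha, scale=np.exp(eta) / alpha)
        data = pd.DataFrame({"species": cov.tip_order,
                             "mean_yawn_duration": y, "z_pred": z})
        try:
            fit = fit_with_retry(spec, data, plan, corr=cov.matrix,
                                 seed=rep_seeds[r] % (2**28))
        except ConvergenceError:
            missing += 1
            continue
        completed += 1
        lo, hi = np.quantile(fit.stacked("beta[z_pred]"), [0.05, 0.95])
        if lo > 0 or hi < 0:
            detected += 1
    power = detected / completed if completed else float("nan")
    se = (math.sqrt(power * (1 - power) / completed) if completed else
          float("nan"))
    return PowerResult(power=power, se=se, n_detected=detected,
                       n_completed=completed, n_missing=missing,
                       beta_true=beta_true)


def residual_on_residual_pgls(clade_data: pd.DataFrame, tree, measure: str):
    """Classical PGLS of residual log yawn duration on the residual brain
    measure, both residualized on log body mass.

    Works on the natural-log scale (the Gaussian-residual simplification)
    and returns the second-stage :class:`~phyloyawn.phylo_core.PglsFit`;
    the slope of interest is the coefficient named by the measure.
    """
    col = MEASURE_COLUMNS[measure]
    sub = clade_data[np.isfinite(clade_data[col].astype(float))].copy()
    sub_tree, sub = match_tree(sub, tree)
    n = len(sub)
    X_body = pd.DataFrame({"intercept": np.ones(n),
                           "log_body": sub["log_body"].to_numpy(float)})
    log_dur = np.log(sub["mean_yawn_duration"].to_numpy(float))
    r_yawn = pgls_fit(log_dur, X_body, sub_tree, lambda_mode="ml").residuals
    r_meas = pgls_fit(sub[col].to_numpy(float), X_body, sub_tree,
                      lambda_mode="ml").residuals
    X2 = pd.DataFrame({"intercept": np.ones(n), measure: r_meas})
    return pgls_fit(r_yawn, X2, sub_tree, lambda_mode="ml")
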