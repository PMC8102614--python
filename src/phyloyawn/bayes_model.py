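"""Bayesian multilevel phylogenetic Gamma regression.

Species mean yawn duration is modeled as Gamma distributed with a log
link:

    y_i ~ Gamma(mean = mu_i, shape = alpha),   log mu_i = eta_i
    eta_i = beta0 + sum_k beta_k z_ik + b_i + u_i

where ``b`` is a phylogenetically structured intercept with covariance
sigma_phylo^2 * C (C the unit-height phylogenetic correlation matrix,
non-centred parameterization) and ``u`` an i.i.d. species intercept with
SD sigma_species.  An optional random-slopes variant lets the slope on
the first predictor vary by taxonomic order.  Priors: Normal(0, 1) on
intercepts and slopes, Exponential(3) on random-effect SDs, Gamma(0.01,
0.01) on the shape (configurable).

Summaries follow the robust-Bayesian reporting convention: posterior
median, scaled median absolute deviation (MAD * 1.4826, a consistent
estimator of the posterior SD), equal-tailed 90% credible interval, the
posterior probability of a positive effect p+, and Cohen's d for slopes,
computed per draw as beta / sqrt(sigma_phylo^2 + sigma_species^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

from ._mcmc import ModelData, pack_start, sample_nuts
from .exceptions import (
    ConvergenceError,
    DomainError,
    InputError,
    InsufficientDataError,
)
from .phylo_core import chol_with_jitter, phylo_cov

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "WaicResult",
    "WaicComparison",
    "gamma_loglik",
    "build_linear_predictor",
    "fit_model",
    "waic",
    "compare_waic",
    "summarize",
    "summarize_vector",
    "MAD_SCALE",
]

#: scale factor making the MAD a consistent estimator of a normal SD
MAD_SCALE = 1.4826022185056018

RHAT_LIMIT = 1.01
ESS_LIMIT = 400.0


@dataclass
class ModelSpec:
    """Declarative definition of one Gamma GLMM.

    ``fixed_effects`` names standardized predictor columns in the data
    (one brain measure, optionally plus z body mass).  ``intercept_by``
    fits one intercept per level of the named column (used by the
    constrained cross-clade model); ``order_slopes`` adds an order-level
    random slope on the first fixed effect.
    """

    response: str = "mean_yawn_duration"
    fixed_effects: tuple = ("z_brain",)
    phylo_intercept: bool = True
    iid_intercept: bool = True
    order_slopes: bool = False
    intercept_by: str | None = None
    sigma_phylo_fixed: float | None = None
    shape_prior: tuple = (0.01, 0.01)
    prior_only: bool = False

    def __post_init__(self):
        self.fixed_effects = tuple(self.fixed_effects)
        if not self.fixed_effects:
            raise InputError("at least one fixed effect is required")


@dataclass
class PosteriorDraws:
    """MCMC output: scalar parameters, per-species effects, pointwise
    log-likelihood, and convergence diagnostics.

    Scalar arrays have shape (chains, draws); per-species arrays
    (chains, draws, n_species)."""

    params: dict
    species: list
    b: np.ndarray
    u: np.ndarray
    pointwise_loglik: np.ndarray
    spec: ModelSpec
    seed: int
    chains: int
    iterations: int
    diagnostics: dict = field(default_factory=dict)
    sampler_stats: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.params.values()))
        return first.shape[0] * first.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    @property
    def slope_names(self) -> list:
        return [k for k in self.params if k.startswith("beta[")]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({k: self.stacked(k) for k in self.params})


def gamma_loglik(duration, mu, shape):
    """Log density of a Gamma with mean ``mu`` and shape ``alpha``:

    alpha*log(alpha/mu) + (alpha-1)*log(y) - alpha*y/mu - logGamma(alpha)
    """
    y = np.asarray(duration, dtype=float)
    m = np.asarray(mu, dtype=float)
    a = np.asarray(shape, dtype=float)
    if np.any(y <= 0) or np.any(m <= 0) or np.any(a <= 0):
        raise DomainError("duration, mu and shape must all be positive")
    out = a * np.log(a / m) + (a - 1.0) * np.log(y) - a * y / m - gammaln(a)
    return float(out) if out.ndim == 0 else out


def build_linear_predictor(spec: ModelSpec, data: pd.DataFrame, params: dict):
    """Per-species linear predictor eta (and mu = exp(eta)).

    ``params`` supplies ``beta0`` (scalar, or mapping level -> value when
    ``intercept_by`` is set), ``beta`` (mapping predictor -> value),
    ``b`` and ``u`` (per-species vectors), and optionally ``slope_dev``
    (mapping order -> slope deviation).  Returns (eta, mu).
    """
    n = len(data)
    if spec.intercept_by is None:
        eta = np.full(n, float(params["beta0"]))
    else:
        levels = data[spec.intercept_by].astype(str)
        try:
            eta = np.array([float(params["beta0"][lv]) for lv in levels])
        except KeyError as e:
            raise InputError(f"missing intercept for level {e}")
    for k, name in enumerate(spec.fixed_effects):
        try:
            bk = float(params["beta"][name])
        except KeyError:
            raise InputError(f"missing slope parameter for {name}")
        z = data[name].to_numpy(dtype=float)
        eta = eta + bk * z
        if k == 0 and "slope_dev" in params and params["slope_dev"]:
            dev = np.array(
                [float(params["slope_dev"].get(o, 0.0)) for o in data["order"]]
            )
            eta = eta + dev * z
    for key in ("b", "u"):
        if key not in params:
            raise InputError(f"missing random-effect vector {key!r}")
        v = np.asarray(params[key], dtype=float)
        if len(v) != n:
            raise InputError(f"random-effect vector {key!r} has wrong length")
        eta = eta + v
    return eta, np.exp(eta)


def _prepare_model_data(spec: ModelSpec, data: pd.DataFrame, tree=None, corr=None):
    n = len(data)
    if n < 4:
        raise InsufficientDataError("at least 4 species required to fit the model")
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(~(y > 0)):
        raise DomainError("response must be strictly positive")

    if corr is None:
        if tree is None:
            raise InputError("either tree or corr must be supplied")
        cov = phylo_cov(tree, scale_to_unit_height=True)
        tip_set = list(data["species"]) if "species" in data else None
        if tip_set is not None and list(cov.tip_order) != list(tip_set):
            raise InputError(
                "data rows are not aligned to the tree tip order; run match_tree first"
            )
        corr = cov.matrix
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (n, n):
        raise InputError("correlation matrix shape does not match the data")
    L = chol_with_jitter(corr + 1e-10 * np.eye(n))

    if spec.intercept_by is None:
        X0 = np.ones((n, 1))
        levels = ["beta0"]
    else:
        lv = data[spec.intercept_by].astype(str)
        uniq = sorted(lv.unique())
        X0 = np.column_stack([(lv == u).to_numpy(float) for u in uniq])
        levels = [f"beta0[{u}]" for u in uniq]

    missing = [c for c in spec.fixed_effects if c not in data.columns]
    if missing:
        raise InputError(f"fixed-effect columns missing from data: {missing}")
    Z = data[list(spec.fixed_effects)].to_numpy(dtype=float)
    if np.any(~np.isfinite(Z)):
        raise InputError("fixed-effect columns contain missing values")

    order_idx = None
    order_levels = []
    if spec.order_slopes:
        if "order" not in data.columns:
            raise InputError("order_slopes requires an 'order' column")
        codes, uniques = pd.factorize(data["order"].astype(str))
        order_idx = codes.astype(np.int64)
        order_levels = [str(u) for u in uniques]

    md = ModelData(
        y=y, X0=X0, Z=Z, L=L, order_idx=order_idx,
        use_slopes=spec.order_slopes, slope_col=0,
        sigma_phylo_fixed=spec.sigma_phylo_fixed, prior_only=spec.prior_only,
        shape_prior=spec.shape_prior,
    )
    return md, levels, order_levels, L


def _unpack_draws(md: ModelData, levels, order_levels, spec, all_draws):
    """all_draws: (chains, ndraws, dim) -> named parameter arrays."""
    chains, nd, _ = all_draws.shape
    idx = md.idx
    params = {}
    for j, name in enumerate(levels):
        params[name] = all_draws[:, :, idx["b0"][0] + j]
    for j, name in enumerate(spec.fixed_effects):
        params[f"beta[{name}]"] = all_draws[:, :, idx["beta"][0] + j]
    if spec.sigma_phylo_fixed is None:
        params["sigma_phylo"] = np.exp(all_draws[:, :, idx["tp"]])
        sp = params["sigma_phylo"]
    else:
        sp = np.full((chains, nd), float(spec.sigma_phylo_fixed))
    # back-transform the (total dispersion, mixing fraction) coordinates
    s_disp = all_draws[:, :, idx["s_disp"]]
    w_mix = 1.0 / (1.0 + np.exp(-all_draws[:, :, idx["t_w"]]))
    params["sigma_species"] = np.exp(0.5 * s_disp) * np.sqrt(w_mix)
    if spec.order_slopes:
        params["sigma_slope"] = np.exp(all_draws[:, :, idx["tsl"]])
    params["alpha"] = np.exp(-s_disp) / (1.0 - w_mix)

    eps_p = all_draws[:, :, idx["eps_p"][0]:idx["eps_p"][1]]
    eps_s = all_draws[:, :, idx["eps_s"][0]:idx["eps_s"][1]]
    b = sp[:, :, None] * (eps_p @ md.L.T)
    u = params["sigma_species"][:, :, None] * eps_s

    eta = (all_draws[:, :, idx["b0"][0]:idx["b0"][1]] @ md.X0.T
           + all_draws[:, :, idx["beta"][0]:idx["beta"][1]] @ md.Z.T + b + u)
    if spec.order_slopes:
        eps_sl = all_draws[:, :, idx["eps_sl"][0]:idx["eps_sl"][1]]
        dev = params["sigma_slope"][:, :, None] * eps_sl[:, :, md.order_idx]
        eta = eta + dev * md.Z[:, md.slope_col][None, None, :]
        for j, name in enumerate(order_levels):
            params[f"slope_dev[{name}]"] = (
                params["sigma_slope"] * eps_sl[:, :, j]
            )
    return params, b, u, eta


def fit_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    tree=None,
    chains: int = 4,
    iterations: int = 4000,
    seed: int = 0,
    corr=None,
    max_depth: int = 10,
    target_accept: float = 0.95,
) -> PosteriorDraws:
    """Sample the posterior with NUTS.

    ``iterations`` is the per-chain total; the first half is warmup
    (adaptation) and discarded.  The run is rejected with
    :class:`ConvergenceError` unless max split-R-hat < 1.01 and min bulk
    ESS > 400 across the reported scalar parameters.  Deterministic given
    (seed, chains, iterations) on a fixed platform.
    """
    md, levels, order_levels, L = _prepare_model_data(spec, data, tree, corr)
    n_warm = iterations // 2
    n_keep = iterations - n_warm

    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(chains)]
    all_draws = np.empty((chains, n_keep, md.dim))
    stats = []
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c] + 7)
        theta0 = pack_start(md, rng)
        draws, st = sample_nuts(md, theta0, n_warm, n_keep, seed=chain_seeds[c],
                                max_depth=max_depth, target_accept=target_accept)
        all_draws[c] = draws
        stats.append(st)

    params, b, u, eta = _unpack_draws(md, levels, order_levels, spec, all_draws)

    alpha = params["alpha"][:, :, None]
    y = md.y[None, None, :]
    pointwise = (
        alpha * (np.log(alpha) - eta)
        + (alpha - 1.0) * md.logy[None, None, :]
        - alpha * y * np.exp(-eta)
        - gammaln(alpha)
    )

    reported = [k for k in params if not k.startswith("slope_dev[")]
    rhat = {}
    ess = {}
    for k in reported:
        arr = params[k]
        rhat[k] = float(az.rhat(arr))
        ess[k] = float(az.ess(arr, method="bulk"))
    diagnostics = {
        "rhat": rhat,
        "ess_bulk": ess,
        "max_rhat": max(rhat.values()),
        "min_ess_bulk": min(ess.values()),
        "warmup": n_warm,
        "kept": n_keep,
    }
    # weak identification warning: sigma_species vs shape
    cor = np.corrcoef(
        params["sigma_species"].reshape(-1), params["alpha"].reshape(-1)
    )[0, 1]
    if abs(cor) > 0.9:
        diagnostics["sigma_species_alpha_corr"] = float(cor)
        warnings.warn(
            "posterior correlation of sigma_species and the Gamma shape exceeds "
            "0.9; these are weakly separated with one observation per species",
            stacklevel=2,
        )

    result = PosteriorDraws(
        params=params, species=list(data.get("species", range(md.n))),
        b=b, u=u, pointwise_loglik=pointwise, spec=spec, seed=seed,
        chains=chains, iterations=iterations, diagnostics=diagnostics,
        sampler_stats=[{k: v for k, v in s.items() if k != "inv_mass"} for s in stats],
    )
    if not spec.prior_only:
        if diagnostics["max_rhat"] >= RHAT_LIMIT or diagnostics["min_ess_bulk"] <= ESS_LIMIT:
            raise ConvergenceError(
                "MCMC failed convergence gate: max R-hat = %.4f (< %.2f required), "
                "min bulk ESS = %.0f (> %.0f required)"
                % (diagnostics["max_rhat"], RHAT_LIMIT,
                   diagnostics["min_ess_bulk"], ESS_LIMIT),
                diagnostics=diagnostics,
            )
    return result


@dataclass
class WaicResult:
    waic: float
    se: float
    p_waic: float
    pointwise: np.ndarray  # per-species -2*(lppd_i - p_i)
    lppd: np.ndarray
    p: np.ndarray


def waic(pointwise_loglik) -> WaicResult:
    """Watanabe-Akaike information criterion from pointwise log-likelihoods.

    ``pointwise_loglik`` has draws on the first axis (chains collapsed)
    and species on the last.  lppd_i is the log of the posterior-mean
    density (computed stably), p_i the posterior variance of the log
    density, WAIC = -2 * sum(lppd_i - p_i).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise InputError("pointwise log-likelihood must be 2-D (draws x species)")
    ndraws, n = ll.shape
    if ndraws < 100:
        raise InputError("at least 100 draws required for WAIC")
    if n < 4:
        raise InputError("at least 4 species required for WAIC")
    if not np.all(np.isfinite(ll)):
        raise InputError("non-finite pointwise log-likelihoods")
    mx = ll.max(axis=0)
    lppd = mx + np.log(np.mean(np.exp(ll - mx), axis=0))
    p = ll.var(axis=0, ddof=1)
    elpd_i = lppd - p
    w = -2.0 * elpd_i
    se = math.sqrt(n * float(np.var(w, ddof=1)))
    return WaicResult(waic=float(w.sum()), se=se, p_waic=float(p.sum()),
                      pointwise=w, lppd=lppd, p=p)


@dataclass
class WaicComparison:
    delta: float       # WAIC_simple - WAIC_slopes; positive favors slopes
    se: float
    decision: str      # "slopes" iff delta >= 2, else "fixed"
    waic_simple: WaicResult
    waic_slopes: WaicResult


def compare_waic(fit_simple: PosteriorDraws, fit_slopes: PosteriorDraws) -> WaicComparison:
    """Paired WAIC comparison of the fixed-slope and random-slopes fits.

    The difference and its SE use per-species pointwise contributions;
    the more complex (slopes) model is adopted only when the difference
    reaches 2.
    """
    if list(fit_simple.species) != list(fit_slopes.species):
        raise InputError("fits are not on identical species rows")
    w1 = waic(fit_simple.pointwise_loglik)
    w2 = waic(fit_slopes.pointwise_loglik)
    d_i = w1.pointwise - w2.pointwise
    n = len(d_i)
    delta = float(d_i.sum())
    se = math.sqrt(n * float(np.var(d_i, ddof=1)))
    decision = "slopes" if delta >= 2.0 else "fixed"
    return WaicComparison(delta=delta, se=se, decision=decision,
                          waic_simple=w1, waic_slopes=w2)


def summarize_vector(x) -> dict:
    """Median, scaled MAD, equal-tailed 90% CI and p+ of a draw vector."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size == 0:
        raise InputError("empty draws")
    med = float(np.median(x))
    mad = MAD_SCALE * float(np.median(np.abs(x - med)))
    lo, hi = np.quantile(x, [0.05, 0.95])
    return {
        "median": med, "mad": mad, "ci5": float(lo), "ci95": float(hi),
        "p_plus": float(np.mean(x > 0)),
    }


def _d_label(d: float) -> str:
    ad = abs(d)
    if ad >= 0.8:
        return "large"
    if ad >= 0.5:
        return "medium"
    if ad >= 0.2:
        return "small"
    return "negligible"


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary table (one row per reported parameter).

    Slopes additionally get Cohen's d, computed per draw as
    beta / sqrt(sigma_phylo^2 + sigma_species^2) and then summarized by
    its posterior median and scaled MAD, with the conventional
    small/medium/large labels at |d| >= 0.2 / 0.5 / 0.8.
    """
    if not draws.params:
        raise InputError("empty draws")
    sp = draws.params.get("sigma_phylo")
    if sp is None:
        sp = np.full_like(draws.params["sigma_species"],
                          float(draws.spec.sigma_phylo_fixed or 0.0))
    ss = draws.params["sigma_species"]
    denom = np.sqrt(sp**2 + ss**2).reshape(-1)

    rows = []
    for name, arr in draws.params.items():
        if name.startswith("slope_dev["):
            continue
        row = {"parameter": name}
        row.update(summarize_vector(arr))
        if name.startswith("beta["):
            d_draws = arr.reshape(-1) / denom
            ds = summarize_vector(d_draws)
            row["d"] = ds["median"]
            row["d_mad"] = ds["mad"]
            row["d_label"] = _d_label(ds["median"])
        row["rhat"] = draws.diagnostics.get("rhat", {}).get(name, np.nan)
        row["ess_bulk"] = draws.diagnostics.get("ess_bulk", {}).get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
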