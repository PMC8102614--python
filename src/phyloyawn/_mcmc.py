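"""Gradient-based MCMC for the phylogenetic Gamma GLMM.

The model, on the unconstrained scale sampled here:

    y_i ~ Gamma(mean = exp(eta_i), shape = alpha)
    eta  = X0 @ b0 + Z @ beta + sigma_p * (L @ eps_p) + sigma_s * eps_s
           [+ sigma_sl * eps_sl[order_i] * z_i  for the random-slopes variant]

with L the Cholesky factor of the unit-height phylogenetic correlation
matrix (non-centred parameterization throughout), priors
b0, beta ~ N(0, 1), sigma ~ Exponential(3) (sampled as log sigma with the
Jacobian included), alpha ~ Gamma(a0, b0) on log alpha, and
eps ~ N(0, 1).

Sampling uses the No-U-Turn Sampler with multinomial trajectory sampling,
dual-averaging step-size adaptation and windowed diagonal mass-matrix
adaptation.  The whole transition kernel is numba-compiled; tree doubling
is implemented iteratively with a binary-counter merge stack, which
performs exactly the sub-tree U-turn checks of the recursive phrasing.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["ModelData", "make_logp_grad", "sample_nuts", "pack_start"]

_LOG3 = math.log(3.0)


@njit(cache=True)
def _digamma(x):
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    f = 1.0 / (x * x)
    return r + math.log(x) - 0.5 / x - f * (
        1.0 / 12.0 - f * (1.0 / 120.0 - f * (1.0 / 252.0 - f * (1.0 / 240.0 - f / 132.0)))
    )


@njit(cache=True)
def _logp_grad(theta, y, logy, X0, Z, L, order_idx, n_orders, use_slopes,
               slope_col, sigma_phylo_fixed, prior_only, a0, b0prior):
    n = y.shape[0]
    k0 = X0.shape[1]
    p = Z.shape[1]
    itp = k0 + p
    its = itp + 1
    if use_slopes:
        itsl = its + 1
        ila = itsl + 1
    else:
        itsl = -1
        ila = its + 1
    iep = ila + 1
    ies = iep + n
    iesl = ies + n

    b0 = theta[:k0]
    beta = theta[k0:itp]
    tp = theta[itp]
    eps_p = theta[iep:ies]
    eps_s = theta[ies:ies + n]

    # the i.i.d. species SD and the Gamma shape jointly set the total
    # species-level dispersion and are weakly separated; sample instead
    # (s, t_w) with sigma_s^2 = e^s * w and 1/alpha = e^s * (1 - w),
    # w = sigmoid(t_w).  The Jacobian |d(log sigma_s, log alpha)/d(s, t_w)|
    # is the constant 1/2, so only the coordinates change, not the
    # posterior.
    s_disp = theta[its]
    t_w = theta[ila]
    w_mix = 1.0 / (1.0 + math.exp(-t_w))
    ts = 0.5 * (s_disp + math.log(w_mix))
    la = -s_disp - math.log(1.0 - w_mix)

    free_p = sigma_phylo_fixed < 0.0
    sp = math.exp(tp) if free_p else sigma_phylo_fixed
    ss = math.exp(ts)
    alpha = math.exp(la)

    Lb = L @ eps_p
    eta = X0 @ b0 + Z @ beta + sp * Lb + ss * eps_s
    if use_slopes:
        ssl = math.exp(theta[itsl])
        eps_sl = theta[iesl:iesl + n_orders]
        w = Z[:, slope_col]
        for i in range(n):
            eta[i] += ssl * eps_sl[order_idx[i]] * w[i]
    else:
        ssl = 0.0
        eps_sl = theta[:0]
        w = theta[:0]

    grad = np.zeros_like(theta)
    lp = 0.0

    if prior_only:
        g_eta = np.zeros(n)
        g_la_lik = 0.0
    else:
        e = np.exp(-eta)
        ye = y * e
        lg = math.lgamma(alpha)
        psi = _digamma(alpha)
        s_eta = 0.0
        s_ye = 0.0
        s_logy = 0.0
        s_dla = 0.0
        for i in range(n):
            s_eta += eta[i]
            s_ye += ye[i]
            s_logy += logy[i]
            s_dla += la + 1.0 - eta[i] + logy[i] - ye[i] - psi
        lp += n * (alpha * la - lg) + (alpha - 1.0) * s_logy - alpha * (s_eta + s_ye)
        g_eta = -alpha + alpha * ye
        g_la_lik = alpha * s_dla

    # priors
    lp += -0.5 * (np.sum(b0 * b0) + np.sum(beta * beta))
    lp += -0.5 * (np.sum(eps_p * eps_p) + np.sum(eps_s * eps_s))
    if free_p:
        lp += _LOG3 - 3.0 * sp + tp
    else:
        lp += -0.5 * tp * tp
    lp += _LOG3 - 3.0 * ss + ts
    lp += a0 * la - b0prior * alpha
    if use_slopes:
        lp += _LOG3 - 3.0 * ssl + theta[itsl]
        lp += -0.5 * np.sum(eps_sl * eps_sl)

    # gradients
    grad[:k0] = X0.T @ g_eta - b0
    grad[k0:itp] = Z.T @ g_eta - beta
    if free_p:
        grad[itp] = sp * np.sum(Lb * g_eta) - 3.0 * sp + 1.0
    else:
        grad[itp] = -tp
    g_ts = ss * np.sum(eps_s * g_eta) - 3.0 * ss + 1.0
    g_la = g_la_lik + a0 - b0prior * alpha
    grad[its] = 0.5 * g_ts - g_la
    grad[ila] = 0.5 * (1.0 - w_mix) * g_ts + w_mix * g_la
    grad[iep:ies] = sp * (L.T @ g_eta) - eps_p
    grad[ies:ies + n] = ss * g_eta - eps_s
    if use_slopes:
        acc = 0.0
        for i in range(n):
            t = w[i] * g_eta[i]
            grad[iesl + order_idx[i]] += ssl * t
            acc += eps_sl[order_idx[i]] * t
        grad[itsl] = ssl * acc - 3.0 * ssl + 1.0
        grad[iesl:iesl + n_orders] -= eps_sl

    return lp, grad


@njit(cache=True)
def _logaddexp(a, b):
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = a if a > b else b
    return m + math.log(math.exp(a - m) + math.exp(b - m))


@njit(cache=True)
def _kinetic(r, inv_mass):
    s = 0.0
    for i in range(r.shape[0]):
        s += inv_mass[i] * r[i] * r[i]
    return 0.5 * s


@njit(cache=True)
def _uturn(d, r_a, r_b, inv_mass):
    """True if either directional derivative along d is negative."""
    sa = 0.0
    sb = 0.0
    for i in range(d.shape[0]):
        sa += d[i] * inv_mass[i] * r_a[i]
        sb += d[i] * inv_mass[i] * r_b[i]
    return sa < 0.0 or sb < 0.0


@njit(cache=True)
def _transition(theta, logp, grad, eps, inv_mass, max_depth, H_div,
                y, logy, X0, Z, L, order_idx, n_orders, use_slopes, slope_col,
                spf, prior_only, a0, b0p):
    """One NUTS transition.  Returns (theta', logp', grad', accept_stat,
    n_leapfrog, depth_reached)."""
    d = theta.shape[0]
    r0 = np.empty(d)
    for i in range(d):
        r0[i] = np.random.standard_normal() / math.sqrt(inv_mass[i])
    H0 = -logp + _kinetic(r0, inv_mass)

    # whole-trajectory state: minus/plus are time-ordered ends
    t_m = theta.copy(); r_m = r0.copy(); g_m = grad.copy()
    t_p = theta.copy(); r_p = r0.copy(); g_p = grad.copy()
    prop = theta.copy()
    prop_logp = logp
    prop_grad = grad.copy()
    log_w = 0.0
    sum_acc = 0.0
    n_leap = 0

    # merge stacks for subtree building
    smax = max_depth + 2
    s_tb = np.empty((smax, d)); s_rb = np.empty((smax, d))
    s_te = np.empty((smax, d)); s_re = np.empty((smax, d))
    s_prop = np.empty((smax, d)); s_plp = np.empty(smax)
    s_pg = np.empty((smax, d))
    s_lw = np.empty(smax); s_size = np.empty(smax, np.int64)

    depth = 0
    while depth < max_depth:
        v = 1.0 if np.random.random() < 0.5 else -1.0
        if v > 0:
            cur_t = t_p.copy(); cur_r = r_p.copy(); cur_g = g_p.copy()
        else:
            cur_t = t_m.copy(); cur_r = r_m.copy(); cur_g = g_m.copy()

        top = 0
        ok = True
        n_steps = 1 << depth
        for leaf in range(n_steps):
            # one leapfrog step in direction v
            h = v * eps
            for i in range(d):
                cur_r[i] += 0.5 * h * cur_g[i]
            for i in range(d):
                cur_t[i] += h * inv_mass[i] * cur_r[i]
            lp1, g1 = _logp_grad(cur_t, y, logy, X0, Z, L, order_idx, n_orders,
                                 use_slopes, slope_col, spf, prior_only, a0, b0p)
            cur_g = g1
            for i in range(d):
                cur_r[i] += 0.5 * h * cur_g[i]
            n_leap += 1
            H = -lp1 + _kinetic(cur_r, inv_mass)
            dH = H0 - H
            if not np.isfinite(dH):
                dH = -np.inf
            lw_leaf = dH
            a = math.exp(dH) if dH < 0.0 else 1.0
            sum_acc += a
            if dH < -H_div:
                ok = False
                break
            # push leaf tree
            s_tb[top] = cur_t; s_rb[top] = cur_r
            s_te[top] = cur_t; s_re[top] = cur_r
            s_prop[top] = cur_t; s_plp[top] = lp1; s_pg[top] = cur_g
            s_lw[top] = lw_leaf; s_size[top] = 1
            top += 1
            # binary-counter merges with internal U-turn checks
            while top >= 2 and s_size[top - 1] == s_size[top - 2]:
                A = top - 2
                B = top - 1
                tot = _logaddexp(s_lw[A], s_lw[B])
                if math.log(np.random.random() + 1e-300) < s_lw[B] - tot:
                    s_prop[A] = s_prop[B]; s_plp[A] = s_plp[B]; s_pg[A] = s_pg[B]
                s_lw[A] = tot
                s_te[A] = s_te[B]; s_re[A] = s_re[B]
                s_size[A] = 2 * s_size[A]
                top -= 1
                diff = v * (s_te[A] - s_tb[A])
                if _uturn(diff, s_re[A], s_rb[A], inv_mass):
                    ok = False
                    break
            if not ok:
                break

        if not ok:
            break

        # biased progressive sampling toward the new subtree
        if math.log(np.random.random() + 1e-300) < s_lw[0] - log_w:
            prop = s_prop[0].copy()
            prop_logp = s_plp[0]
            prop_grad = s_pg[0].copy()
        log_w = _logaddexp(log_w, s_lw[0])

        # extend the trajectory and check the overall U-turn
        if v > 0:
            t_p = s_te[0].copy(); r_p = s_re[0].copy(); g_p = cur_g.copy()
        else:
            t_m = s_te[0].copy(); r_m = s_re[0].copy(); g_m = cur_g.copy()
        diff = t_p - t_m
        depth += 1
        if _uturn(diff, r_p, r_m, inv_mass):
            break

    accept_stat = sum_acc / n_leap if n_leap > 0 else 0.0
    return prop, prop_logp, prop_grad, accept_stat, n_leap, depth


@njit(cache=True)
def _init_eps(theta, logp, grad, inv_mass,
              y, logy, X0, Z, L, order_idx, n_orders, use_slopes, slope_col,
              spf, prior_only, a0, b0p):
    d = theta.shape[0]
    eps = 1.0
    r = np.empty(d)
    for i in range(d):
        r[i] = np.random.standard_normal() / math.sqrt(inv_mass[i])
    H0 = -logp + _kinetic(r, inv_mass)

    def one_step(eps_):
        r1 = r + 0.5 * eps_ * grad
        t1 = theta + eps_ * inv_mass * r1
        lp1, g1 = _logp_grad(t1, y, logy, X0, Z, L, order_idx, n_orders,
                             use_slopes, slope_col, spf, prior_only, a0, b0p)
        r2 = r1 + 0.5 * eps_ * g1
        return -lp1 + _kinetic(r2, inv_mass)

    H1 = one_step(eps)
    dH = H0 - H1
    if not np.isfinite(dH):
        dH = -np.inf
    direction = 1.0 if dH > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        H1 = one_step(eps)
        dH = H0 - H1
        if not np.isfinite(dH):
            dH = -np.inf
        if direction > 0 and dH <= math.log(0.5):
            break
        if direction < 0 and dH >= math.log(0.5):
            break
    return eps


@njit(cache=True)
def _run_chain(theta0, n_warmup, n_draws, seed, max_depth, target_accept,
               y, logy, X0, Z, L, order_idx, n_orders, use_slopes, slope_col,
               spf, prior_only, a0, b0p):
    np.random.seed(seed)
    d = theta0.shape[0]
    theta = theta0.copy()
    logp, grad = _logp_grad(theta, y, logy, X0, Z, L, order_idx, n_orders,
                            use_slopes, slope_col, spf, prior_only, a0, b0p)
    inv_mass = np.ones(d)
    H_div = 1000.0

    eps = _init_eps(theta, logp, grad, inv_mass, y, logy, X0, Z, L, order_idx,
                    n_orders, use_slopes, slope_col, spf, prior_only, a0, b0p)
    mu = math.log(10.0 * eps)
    log_eps_bar = 0.0
    H_bar = 0.0
    gamma = 0.05
    t0 = 10.0
    kappa = 0.75
    m_adapt = 0

    init_len = max(int(0.15 * n_warmup), 10)
    final_len = max(int(0.1 * n_warmup), 10)

    # expanding mass-adaptation windows between init_len and warmup-final_len
    win_bounds = np.empty((20, 2), np.int64)
    n_win = 0
    pos = init_len
    wlen = 25
    while pos + wlen < n_warmup - final_len and n_win < 20:
        win_bounds[n_win, 0] = pos
        win_bounds[n_win, 1] = pos + wlen
        pos += wlen
        wlen *= 2
        n_win += 1
    if n_win > 0:
        win_bounds[n_win - 1, 1] = n_warmup - final_len
    elif n_warmup - final_len > init_len:
        win_bounds[0, 0] = init_len
        win_bounds[0, 1] = n_warmup - final_len
        n_win = 1

    win_i = 0
    wsum = np.zeros(d)
    wsum2 = np.zeros(d)
    wcount = 0
    total_leap = 0

    for it in range(n_warmup):
        theta, logp, grad, astat, nl, _ = _transition(
            theta, logp, grad, eps, inv_mass, max_depth, H_div,
            y, logy, X0, Z, L, order_idx, n_orders, use_slopes, slope_col,
            spf, prior_only, a0, b0p)
        total_leap += nl
        m_adapt += 1
        frac = 1.0 / (m_adapt + t0)
        H_bar = (1.0 - frac) * H_bar + frac * (target_accept - astat)
        log_eps = mu - math.sqrt(m_adapt) / gamma * H_bar
        w = m_adapt ** (-kappa)
        log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
        eps = math.exp(log_eps)

        if win_i < n_win and win_bounds[win_i, 0] <= it < win_bounds[win_i, 1]:
            wsum += theta
            wsum2 += theta * theta
            wcount += 1
        if win_i < n_win and it == win_bounds[win_i, 1] - 1:
            if wcount >= 10:
                for i in range(d):
                    m = wsum[i] / wcount
                    var = (wsum2[i] - wcount * m * m) / (wcount - 1)
                    im = (wcount / (wcount + 5.0)) * var + (5.0 / (wcount + 5.0)) * 1e-3
                    if im < 1e-8:
                        im = 1e-8
                    if im > 1e8:
                        im = 1e8
                    inv_mass[i] = im
            wsum[:] = 0.0
            wsum2[:] = 0.0
            wcount = 0
            win_i += 1
            eps = _init_eps(theta, logp, grad, inv_mass, y, logy, X0, Z, L,
                            order_idx, n_orders, use_slopes, slope_col, spf,
                            prior_only, a0, b0p)
            mu = math.log(10.0 * eps)
            log_eps_bar = 0.0
            H_bar = 0.0
            m_adapt = 0

    if m_adapt > 0:
        eps = math.exp(log_eps_bar)

    draws = np.empty((n_draws, d))
    acc_sum = 0.0
    for it in range(n_draws):
        theta, logp, grad, astat, nl, _ = _transition(
            theta, logp, grad, eps, inv_mass, max_depth, H_div,
            y, logy, X0, Z, L, order_idx, n_orders, use_slopes, slope_col,
            spf, prior_only, a0, b0p)
        total_leap += nl
        acc_sum += astat
        draws[it] = theta

    mean_acc = acc_sum / n_draws if n_draws > 0 else 0.0
    return draws, eps, mean_acc, total_leap, inv_mass


class ModelData:
    """Frozen data/arrays for one model fit, plus the parameter layout."""

    def __init__(self, y, X0, Z, L, order_idx=None, use_slopes=False,
                 slope_col=0, sigma_phylo_fixed=None, prior_only=False,
                 shape_prior=(0.01, 0.01)):
        self.y = np.ascontiguousarray(y, dtype=np.float64)
        self.logy = np.log(self.y)
        self.X0 = np.ascontiguousarray(X0, dtype=np.float64)
        self.Z = np.ascontiguousarray(Z, dtype=np.float64)
        self.L = np.ascontiguousarray(L, dtype=np.float64)
        n = self.y.shape[0]
        self.n = n
        self.k0 = self.X0.shape[1]
        self.p = self.Z.shape[1]
        self.use_slopes = bool(use_slopes)
        self.slope_col = int(slope_col)
        if order_idx is None:
            order_idx = np.zeros(n, dtype=np.int64)
        self.order_idx = np.ascontiguousarray(order_idx, dtype=np.int64)
        self.n_orders = int(self.order_idx.max()) + 1 if self.use_slopes else 0
        self.sigma_phylo_fixed = (
            -1.0 if sigma_phylo_fixed is None else float(sigma_phylo_fixed)
        )
        self.prior_only = bool(prior_only)
        self.shape_prior = (float(shape_prior[0]), float(shape_prior[1]))
        self.dim = (
            self.k0 + self.p + 2 + 1 + 2 * n
            + (1 + self.n_orders if self.use_slopes else 0)
        )
        itp = self.k0 + self.p
        its = itp + 1
        if self.use_slopes:
            itsl = its + 1
            ila = itsl + 1
        else:
            itsl = None
            ila = its + 1
        iep = ila + 1
        ies = iep + n
        iesl = ies + n
        self.idx = {"b0": (0, self.k0), "beta": (self.k0, itp), "tp": itp,
                    "s_disp": its, "tsl": itsl, "t_w": ila, "eps_p": (iep, ies),
                    "eps_s": (ies, ies + n), "eps_sl": (iesl, iesl + self.n_orders)}

    def args(self):
        return (self.y, self.logy, self.X0, self.Z, self.L, self.order_idx,
                self.n_orders, self.use_slopes, self.slope_col,
                self.sigma_phylo_fixed, self.prior_only,
                self.shape_prior[0], self.shape_prior[1])


def make_logp_grad(md: ModelData):
    """Python-callable log posterior + gradient for a model (testing and
    diagnostics; sampling calls the compiled kernel directly)."""
    args = md.args()

    def f(theta):
        return _logp_grad(np.ascontiguousarray(theta, dtype=np.float64), *args)

    return f


def pack_start(md: ModelData, rng) -> np.ndarray:
    """Overdispersed but tame starting point."""
    theta = 0.1 * rng.standard_normal(md.dim)
    if not md.prior_only:
        theta[0] = math.log(float(np.mean(md.y)))
    theta[md.idx["tp"]] = math.log(0.3) + 0.1 * rng.standard_normal()
    # total dispersion sigma_s^2 + 1/alpha ~ 0.3^2 + 1/5, split ~ 0.3
    theta[md.idx["s_disp"]] = math.log(0.29) + 0.1 * rng.standard_normal()
    theta[md.idx["t_w"]] = -0.8 + 0.1 * rng.standard_normal()
    if md.use_slopes:
        theta[md.idx["tsl"]] = math.log(0.3) + 0.1 * rng.standard_normal()
    return theta


def sample_nuts(md: ModelData, theta0, n_warmup, n_draws, seed, max_depth=10,
                target_accept=0.8):
    """One NUTS chain for the model.  Returns (draws, stats)."""
    draws, eps, mean_acc, total_leap, inv_mass = _run_chain(
        np.asarray(theta0, dtype=np.float64), int(n_warmup), int(n_draws),
        int(seed) % (2**31), int(max_depth), float(target_accept), *md.args())
    stats = {"step_size": float(eps), "mean_accept": float(mean_acc),
             "n_leapfrog": int(total_leap), "inv_mass": inv_mass}
    return draws, stats
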