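"""No-U-Turn sampler for the hierarchical Bayesian logistic model.

The target is the posterior of::

    Y ~ Bernoulli(inv_logit(theta1 + W alpha + X2 theta2 + X3 theta3 + X4 theta4))
    theta1..theta4 ~ Normal(0, theta_scale)          # weakly informative
    alpha_m       ~ Normal(0, sigma_a)               # cluster effects
    sigma_a       ~ half-Normal(0, sigma_scale)

on the unconstrained vector ``x = (theta1..theta4, z_1..z_K, u)`` where
``sigma_a = exp(u)`` (log transform with its Jacobian) and, under the
non-centered parameterisation, ``alpha_m = sigma_a * z_m`` with
``z_m ~ Normal(0, 1)``.  Within a cluster every participant shares one
linear predictor, so the likelihood reduces to per-cluster binomial
counts and a gradient evaluation costs O(K).

The sampler is the dynamic-trajectory NUTS with slice sampling across
the doubling tree, dual-averaging step-size adaptation towards a target
acceptance statistic, and Stan-style windowed adaptation of a diagonal
mass matrix (initial fast window, doubling slow windows, terminal fast
window).  Trajectory U-turn checks are performed iteratively with a
checkpoint stack instead of recursion.

Everything here is numba-compiled; a chain over a 20-cluster dataset
takes on the order of 50 ms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["nuts_chain", "logp_grad"]


@njit(cache=True)
def logp_grad(x, s, n, arm, like_scale, theta_scale, sigma_scale,
              non_centered, grad):
    """Log posterior density (unnormalised) and gradient, in place.

    ``s``/``n``/``arm`` are per-cluster success counts, sizes, and
    1-based arm labels.  ``like_scale`` scales the likelihood (0 gives
    prior-only sampling).
    """
    K = s.shape[0]
    u = x[4 + K]
    sigma = np.exp(u)
    lp = 0.0
    tv = theta_scale * theta_scale
    for j in range(4):
        lp -= x[j] * x[j] / (2.0 * tv)
        grad[j] = -x[j] / tv
    sv = sigma_scale * sigma_scale
    # half-Normal prior on sigma plus log-transform Jacobian
    lp += -sigma * sigma / (2.0 * sv) + u
    gu = -sigma * sigma / sv + 1.0
    if non_centered:
        for m in range(K):
            z = x[4 + m]
            lp -= 0.5 * z * z
            grad[4 + m] = -z
    else:
        for m in range(K):
            a = x[4 + m]
            lp -= 0.5 * a * a / (sigma * sigma)
            grad[4 + m] = -a / (sigma * sigma)
            gu += a * a / (sigma * sigma) - 1.0
        lp -= K * u
    if like_scale > 0.0:
        for m in range(K):
            j = arm[m]
            if non_centered:
                eta = x[0] + sigma * x[4 + m]
            else:
                eta = x[0] + x[4 + m]
            if j > 1:
                eta += x[j - 1]
            if eta > 0.0:
                sp = eta + np.log1p(np.exp(-eta))
                pm = 1.0 / (1.0 + np.exp(-eta))
            else:
                e = np.exp(eta)
                sp = np.log1p(e)
                pm = e / (1.0 + e)
            lp += like_scale * (s[m] * eta - n[m] * sp)
            r = like_scale * (s[m] - n[m] * pm)
            grad[0] += r
            if j > 1:
                grad[j - 1] += r
            if non_centered:
                grad[4 + m] += sigma * r
                gu += sigma * x[4 + m] * r
            else:
                grad[4 + m] += r
    grad[4 + K] = gu
    return lp


@njit(cache=True)
def _kinetic(p, inv_mass):
    k = 0.0
    for i in range(p.shape[0]):
        k += inv_mass[i] * p[i] * p[i]
    return 0.5 * k


@njit(cache=True)
def _leapfrog(q, p, g, eps, inv_mass, s, n, arm, like_scale, theta_scale,
              sigma_scale, non_centered):
    d = q.shape[0]
    for i in range(d):
        p[i] += 0.5 * eps * g[i]
    for i in range(d):
        q[i] += eps * inv_mass[i] * p[i]
    lp = logp_grad(q, s, n, arm, like_scale, theta_scale, sigma_scale,
                   non_centered, g)
    for i in range(d):
        p[i] += 0.5 * eps * g[i]
    return lp


@njit(cache=True)
def _checkpoint_slot(a):
    # slot for even leaf index a: popcount of its odd part; distinct for
    # all simultaneously-live left subtree endpoints
    if a == 0:
        return 0
    while a % 2 == 0:
        a //= 2
    c = 0
    while a > 0:
        c += a & 1
        a >>= 1
    return c


@njit(cache=True)
def _nuts_transition(q, lp0, g0, eps, inv_mass, s, n, arm, like_scale,
                     theta_scale, sigma_scale, non_centered, max_depth,
                     Qs, Ps, qm, pm, gm, qp, pp, gp, qc, pc, gc, qext, qprop):
    """One NUTS draw; the accepted position is left in ``qprop``.

    Returns (logp at proposal, mean acceptance statistic, divergent flag,
    tree depth reached).
    """
    d = q.shape[0]
    p0 = np.empty(d)
    for i in range(d):
        p0[i] = np.random.normal() / np.sqrt(inv_mass[i])
    joint0 = lp0 - _kinetic(p0, inv_mass)
    logu = joint0 - np.random.exponential(1.0)
    for i in range(d):
        qm[i] = q[i]; pm[i] = p0[i]; gm[i] = g0[i]
        qp[i] = q[i]; pp[i] = p0[i]; gp[i] = g0[i]
        qprop[i] = q[i]
    nvalid = 1
    depth = 0
    alpha_sum = 0.0
    n_alpha = 0
    divergent = False
    keep_going = True
    lp_prop = lp0
    lp_ext = lp0
    while keep_going and depth < max_depth:
        go_right = np.random.random() < 0.5
        if go_right:
            for i in range(d):
                qc[i] = qp[i]; pc[i] = pp[i]; gc[i] = gp[i]
        else:
            for i in range(d):
                qc[i] = qm[i]; pc[i] = pm[i]; gc[i] = gm[i]
        v = 1.0 if go_right else -1.0
        n_leaves = 1 << depth
        n_ext = 0
        ext_ok = True
        for leaf in range(n_leaves):
            lp = _leapfrog(qc, pc, gc, v * eps, inv_mass, s, n, arm,
                           like_scale, theta_scale, sigma_scale, non_centered)
            joint = lp - _kinetic(pc, inv_mass)
            if not np.isfinite(joint):
                joint = -np.inf
            if logu > joint + 1000.0:
                divergent = True
                ext_ok = False
                break
            if logu <= joint:
                n_ext += 1
                # reservoir-sample the candidate uniformly over valid leaves
                if np.random.random() * n_ext < 1.0:
                    for i in range(d):
                        qext[i] = qc[i]
                    lp_ext = lp
            a = joint - joint0
            if a > 0.0:
                a = 0.0
            alpha_sum += np.exp(a)
            n_alpha += 1
            if leaf % 2 == 0:
                sl = _checkpoint_slot(leaf)
                for i in range(d):
                    Qs[sl, i] = qc[i]
                    Ps[sl, i] = pc[i]
            else:
                # U-turn checks for every power-of-two subtree ending here
                span = 2
                while (leaf + 1) % span == 0:
                    sl = _checkpoint_slot(leaf + 1 - span)
                    sa = 0.0
                    sb = 0.0
                    for i in range(d):
                        dqi = v * (qc[i] - Qs[sl, i])
                        sa += dqi * inv_mass[i] * Ps[sl, i]
                        sb += dqi * inv_mass[i] * pc[i]
                    if sa < 0.0 or sb < 0.0:
                        ext_ok = False
                        break
                    span *= 2
                if not ext_ok:
                    break
        if ext_ok:
            if go_right:
                for i in range(d):
                    qp[i] = qc[i]; pp[i] = pc[i]; gp[i] = gc[i]
            else:
                for i in range(d):
                    qm[i] = qc[i]; pm[i] = pc[i]; gm[i] = gc[i]
            if n_ext > 0 and np.random.random() * nvalid < n_ext:
                for i in range(d):
                    qprop[i] = qext[i]
                lp_prop = lp_ext
            nvalid += n_ext
            sa = 0.0
            sb = 0.0
            for i in range(d):
                dqi = qp[i] - qm[i]
                sa += dqi * inv_mass[i] * pm[i]
                sb += dqi * inv_mass[i] * pp[i]
            if sa < 0.0 or sb < 0.0:
                keep_going = False
        else:
            keep_going = False
        depth += 1
    accept = alpha_sum / n_alpha if n_alpha > 0 else 0.0
    return lp_prop, accept, divergent, depth


@njit(cache=True)
def _find_initial_step(q, lp0, g0, inv_mass, s, n, arm, like_scale,
                       theta_scale, sigma_scale, non_centered):
    """Heuristic initial step size: double/halve until the one-step
    acceptance probability crosses 0.5."""
    d = q.shape[0]
    eps = 1.0
    p = np.empty(d)
    for i in range(d):
        p[i] = np.random.normal() / np.sqrt(inv_mass[i])
    joint0 = lp0 - _kinetic(p, inv_mass)
    qt = q.copy(); pt = p.copy(); gt = g0.copy()
    lp = _leapfrog(qt, pt, gt, eps, inv_mass, s, n, arm, like_scale,
                   theta_scale, sigma_scale, non_centered)
    joint = lp - _kinetic(pt, inv_mass)
    if not np.isfinite(joint):
        joint = -np.inf
    a = 1.0 if (joint - joint0) > np.log(0.5) else -1.0
    for _ in range(100):
        if a * (joint - joint0) <= -a * np.log(2.0):
            break
        eps *= 2.0 ** a
        for i in range(d):
            qt[i] = q[i]; pt[i] = p[i]; gt[i] = g0[i]
        lp = _leapfrog(qt, pt, gt, eps, inv_mass, s, n, arm, like_scale,
                       theta_scale, sigma_scale, non_centered)
        joint = lp - _kinetic(pt, inv_mass)
        if not np.isfinite(joint):
            joint = -np.inf
    return eps


@njit(cache=True)
def nuts_chain(seed, x0, s, n, arm, like_scale, theta_scale, sigma_scale,
               non_centered, n_warmup, n_draws, delta, max_depth):
    """Run one NUTS chain; returns (draws, logp, n_divergent, n_maxdepth).

    Warmup uses dual averaging (gamma 0.05, t0 10, kappa 0.75) towards
    target acceptance ``delta`` and a windowed diagonal mass-matrix
    adaptation (init buffer 75, base window 25 doubling, terminal buffer
    50, regularised sample variances), mirroring standard practice.
    Divergences and saturated tree depths are counted over the retained
    draws only.
    """
    np.random.seed(seed)
    d = x0.shape[0]
    inv_mass = np.ones(d)
    q = x0.copy()
    g = np.empty(d)
    lp = logp_grad(q, s, n, arm, like_scale, theta_scale, sigma_scale,
                   non_centered, g)
    Qs = np.empty((max_depth + 1, d))
    Ps = np.empty((max_depth + 1, d))
    qm = np.empty(d); pm = np.empty(d); gm = np.empty(d)
    qp = np.empty(d); pp = np.empty(d); gp = np.empty(d)
    qc = np.empty(d); pc = np.empty(d); gc = np.empty(d)
    qext = np.empty(d); qprop = np.empty(d)

    eps = _find_initial_step(q, lp, g, inv_mass, s, n, arm, like_scale,
                             theta_scale, sigma_scale, non_centered)
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    hbar = 0.0
    t0 = 10.0
    gamma = 0.05
    kappa = 0.75
    da_count = 0

    init_buffer = 75
    term_buffer = 50
    base_window = 25
    if n_warmup < init_buffer + term_buffer + base_window:
        # tiny warmup: single window over the middle 60%
        init_buffer = max(1, n_warmup // 5)
        term_buffer = max(1, n_warmup // 5)
        base_window = max(1, n_warmup - init_buffer - term_buffer)
    adapt_end = n_warmup - term_buffer
    w_start = init_buffer
    w_size = base_window
    w_end = min(w_start + w_size, adapt_end)
    if w_end + 2 * w_size > adapt_end:
        w_end = adapt_end
    welford_n = 0
    welford_m = np.zeros(d)
    welford_s = np.zeros(d)

    draws = np.empty((n_draws, d))
    lps = np.empty(n_draws)
    n_div = 0
    n_maxdepth = 0

    for it in range(n_warmup + n_draws):
        lp, accept, divergent, depth = _nuts_transition(
            q, lp, g, eps, inv_mass, s, n, arm, like_scale, theta_scale,
            sigma_scale, non_centered, max_depth,
            Qs, Ps, qm, pm, gm, qp, pp, gp, qc, pc, gc, qext, qprop)
        for i in range(d):
            q[i] = qprop[i]
        lp = logp_grad(q, s, n, arm, like_scale, theta_scale, sigma_scale,
                       non_centered, g)
        if it < n_warmup:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            hbar = (1.0 - frac) * hbar + frac * (delta - accept)
            log_eps = mu - np.sqrt(da_count) / gamma * hbar
            eta = da_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if w_start <= it < adapt_end:
                welford_n += 1
                for i in range(d):
                    dlt = q[i] - welford_m[i]
                    welford_m[i] += dlt / welford_n
                    welford_s[i] += dlt * (q[i] - welford_m[i])
                if it == w_end - 1:
                    if welford_n > 1:
                        for i in range(d):
                            var = welford_s[i] / (welford_n - 1)
                            inv_mass[i] = (welford_n / (welford_n + 5.0)) * var \
                                + 1e-3 * (5.0 / (welford_n + 5.0))
                    welford_n = 0
                    for i in range(d):
                        welford_m[i] = 0.0
                        welford_s[i] = 0.0
                    if it < adapt_end - 1:
                        eps = _find_initial_step(
                            q, lp, g, inv_mass, s, n, arm, like_scale,
                            theta_scale, sigma_scale, non_centered)
                        mu = np.log(10.0 * eps)
                        log_eps_bar = 0.0
                        hbar = 0.0
                        da_count = 0
                        w_size *= 2
                        w_end = w_end + w_size
                        if w_end + 2 * w_size > adapt_end:
                            w_end = adapt_end
                    else:
                        # final slow window: restart step-size search so the
                        # terminal buffer re-adapts under the new metric
                        eps = _find_initial_step(
                            q, lp, g, inv_mass, s, n, arm, like_scale,
                            theta_scale, sigma_scale, non_centered)
                        mu = np.log(10.0 * eps)
                        log_eps_bar = 0.0
                        hbar = 0.0
                        da_count = 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            k = it - n_warmup
            for i in range(d):
                draws[k, i] = q[i]
            lps[k] = lp
            if divergent:
                n_div += 1
            if depth >= max_depth:
                n_maxdepth += 1
    return draws, lps, n_div, n_maxdepth
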