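"""Study-level marginal log-likelihoods by adaptive Gauss-Hermite quadrature.

Leave-one-study-out cross-validation needs p(y_i | theta), the likelihood of
one study's counts with its random effects integrated out.  The integrand
(binomial terms times a zero-mean Gaussian) is log-concave in the random
effects, so each integral is computed by mode-centred, Hessian-rescaled
Gauss-Hermite quadrature: Newton iterations find the conditional mode, the
grid is rotated and scaled by the Cholesky factor of the negative Hessian,
and a product rule with K nodes per dimension does the rest.  Everything is
vectorized over (posterior draw, integration unit).

The integration unit is a whole study (dimension 2T) for the within-person
variants, whose random effects are correlated across technologies, and a
single arm (dimension 2) for the NMA variants, whose arms are conditionally
independent; arm contributions are then summed within studies.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit, logsumexp, roots_hermite

from .study_data import StudyTable
from .within_person import complete_design_arrays
from ._posteriors import _binom_const, _softplus


def _default_nodes(d: int) -> int:
    if d <= 2:
        return 9
    if d <= 4:
        return 5
    return 3


def _product_grid(d: int, K: int):
    h, w = roots_hermite(K)
    grids = np.meshgrid(*([h] * d), indexing="ij")
    U = np.stack([g.ravel() for g in grids], axis=-1)  # (K^d, d)
    wgrids = np.meshgrid(*([w] * d), indexing="ij")
    logW = np.sum([np.log(wg.ravel()) for wg in wgrids], axis=0)
    return U, logW + np.sum(U**2, axis=-1)  # weights with e^{|u|^2} factor folded in


def unit_marginal_loglik(tp, nD, tn, nS, off_se, off_sp, cov, K=None, newton_iters=15):
    """Log of the marginal likelihood of each integration unit.

    tp/nD/tn/nS: (U, T) counts; off_se/off_sp: (M, U, T) logit-scale offsets
    (summary means, broadcast per draw); cov: (M, U, 2T, 2T) random-effect
    covariance.  Returns (M, U).
    """
    tp = np.asarray(tp, float)
    U_, T = tp.shape
    d = 2 * T
    K = _default_nodes(d) if K is None else K
    M = off_se.shape[0]
    cov = cov + 1e-10 * np.eye(d)  # tolerate degenerate components
    prec = np.linalg.inv(cov)
    _, logdet_cov = np.linalg.slogdet(cov)
    const = np.sum(_binom_const(tp, nD) + _binom_const(tn, nS), axis=-1)  # (U,)

    def g_terms(nu):
        # nu: (M, U, N, d) at quadrature nodes -> log integrand, (M, U, N)
        eta_se = off_se[:, :, None, :] + nu[..., 0::2]
        eta_sp = off_sp[:, :, None, :] + nu[..., 1::2]
        ll = np.sum(tp[None, :, None, :] * eta_se - nD[None, :, None, :] * _softplus(eta_se), axis=-1)
        ll += np.sum(tn[None, :, None, :] * eta_sp - nS[None, :, None, :] * _softplus(eta_sp), axis=-1)
        quad = np.einsum("muni,muij,munj->mun", nu, prec, nu)
        mvn = -0.5 * (d * np.log(2 * np.pi) + quad) - 0.5 * logdet_cov[:, :, None]
        return ll + const[None, :, None] + mvn

    def g_value(nu):
        eta_se = off_se + nu[..., 0::2]
        eta_sp = off_sp + nu[..., 1::2]
        ll = np.sum(tp * eta_se - nD * _softplus(eta_se), axis=-1)
        ll += np.sum(tn * eta_sp - nS * _softplus(eta_sp), axis=-1)
        return ll - 0.5 * np.einsum("mui,muij,muj->mu", nu, prec, nu)

    # damped Newton ascent to the conditional mode (concave objective; the
    # backtracking guard prevents overshoot where the logistic saturates)
    nu = np.zeros((M, U_, d))
    g_curr = g_value(nu)
    for _ in range(newton_iters):
        p_se = expit(off_se + nu[..., 0::2])
        p_sp = expit(off_sp + nu[..., 1::2])
        grad = np.empty_like(nu)
        grad[..., 0::2] = tp - nD * p_se
        grad[..., 1::2] = tn - nS * p_sp
        grad -= np.einsum("muij,muj->mui", prec, nu)
        curv = np.empty_like(nu)
        curv[..., 0::2] = nD * p_se * (1 - p_se)
        curv[..., 1::2] = nS * p_sp * (1 - p_sp)
        A = prec + curv[..., None] * np.eye(d)
        step = np.linalg.solve(A, grad[..., None])[..., 0]
        scale = np.ones((M, U_, 1))
        for _ in range(12):
            trial = nu + scale * step
            g_trial = g_value(trial)
            worse = g_trial < g_curr - 1e-12
            if not np.any(worse):
                break
            scale[worse[..., None]] *= 0.5
        nu = nu + scale * step
        g_curr = g_value(nu)
        if np.max(np.abs(scale * step)) < 1e-9:
            break

    # negative Hessian at the mode, Cholesky-rotated quadrature grid
    p_se = expit(off_se + nu[..., 0::2])
    p_sp = expit(off_sp + nu[..., 1::2])
    curv = np.empty_like(nu)
    curv[..., 0::2] = nD * p_se * (1 - p_se)
    curv[..., 1::2] = nS * p_sp * (1 - p_sp)
    A = prec + curv[..., None] * np.eye(d)
    Ch = np.linalg.cholesky(A)
    logdet_Ch = np.sum(np.log(np.diagonal(Ch, axis1=-2, axis2=-1)), axis=-1)
    Q = np.linalg.inv(Ch)  # (M, U, d, d)
    Ugrid, logw = _product_grid(d, K)  # (N, d), (N,)
    offsets = np.sqrt(2.0) * np.einsum("nj,muji->muni", Ugrid, Q)
    vals = g_terms(nu[..., None, :] + offsets)  # (M, U, N)
    return (
        logsumexp(vals + logw, axis=-1)
        + 0.5 * d * np.log(2.0)
        - logdet_Ch
    )


def _within_cov_draws(model, params):
    """(M, 2T, 2T) covariance draws from flattened structural parameters."""
    if model == "M1":
        sd = params["sd"]  # (M, d)
        corr = params["corr"]  # (M, d, d)
        return sd[:, :, None] * corr * sd[:, None, :]
    if model == "M2":
        s_se, s_sp, rho = params["s_se"], params["s_sp"], params["rho"]
        M, T = s_se.shape
        d = 2 * T
        cov = np.zeros((M, d, d))
        for t in range(T):
            cov[:, 2 * t, 2 * t] = s_se[:, t] ** 2
            cov[:, 2 * t + 1, 2 * t + 1] = s_sp[:, t] ** 2
            cross = rho[:, t] * s_se[:, t] * s_sp[:, t]
            cov[:, 2 * t, 2 * t + 1] = cov[:, 2 * t + 1, 2 * t] = cross
        return cov
    if model == "M3":
        tau_se, tau_sp = params["tau_se"], params["tau_sp"]
        sig_se, sig_sp = params["sigma_se"], params["sigma_sp"]
        rho_c = params["rho_c"]
        M = tau_se.shape[0]
        T = params["mu_se"].shape[1]
        d = 2 * T
        cov = np.zeros((M, d, d))
        se = np.arange(0, d, 2)
        sp = np.arange(1, d, 2)
        cov[:, se[:, None], se[None, :]] = (tau_se**2)[:, None, None]
        cov[:, sp[:, None], sp[None, :]] = (tau_sp**2)[:, None, None]
        cross = (rho_c * tau_se * tau_sp)[:, None, None]
        cov[:, se[:, None], sp[None, :]] = cross
        cov[:, sp[:, None], se[None, :]] = cross
        cov[:, se, se] += (sig_se**2)[:, None]
        cov[:, sp, sp] += (sig_sp**2)[:, None]
        return cov
    raise ValueError(f"not a within-person model: {model!r}")


def study_pointwise_loglik(model, params, table: StudyTable, technologies, K=None, chunk=200):
    """Marginal log-likelihood per (draw, study).

    ``params`` holds flattened draw arrays (leading dimension M) as produced
    by the fitted posterior.  Returns an (M, S) array in the table's study
    order.
    """
    technologies = tuple(technologies)
    M = np.asarray(params["mu_se"]).shape[0]
    if model == "M2":
        # block-diagonal covariance: the study marginal factorizes over
        # technologies, so the cheap per-arm bivariate path applies
        model = "M1-NMA"
    if model in ("M1", "M3"):
        _, tp, nD, tn, nS = complete_design_arrays(technologies, table)
        S = tp.shape[0]
        cov = _within_cov_draws(model, params)
        out = np.empty((M, S))
        for lo in range(0, M, chunk):
            hi = min(lo + chunk, M)
            m = hi - lo
            off_se = np.broadcast_to(params["mu_se"][lo:hi, None, :], (m, S, tp.shape[1]))
            off_sp = np.broadcast_to(params["mu_sp"][lo:hi, None, :], (m, S, tp.shape[1]))
            cov_b = np.broadcast_to(cov[lo:hi, None, :, :], (m, S, cov.shape[1], cov.shape[2]))
            out[lo:hi] = unit_marginal_loglik(tp, nD, tn, nS, off_se, off_sp, cov_b, K=K)
        return out
    if model in ("M1-NMA", "M2-NMA", "bivariate"):
        tech_index = {t: i for i, t in enumerate(technologies)}
        tidx = np.array([tech_index[a.technology] for a in table.arms])
        study_ids = table.study_ids
        sindex = {s: i for i, s in enumerate(study_ids)}
        sidx = np.array([sindex[a.study_id] for a in table.arms])
        A = len(table.arms)
        tp = np.array([[a.tp] for a in table.arms], float)
        nD = np.array([[a.n_diseased] for a in table.arms], float)
        tn = np.array([[a.tn] for a in table.arms], float)
        nS = np.array([[a.n_sound] for a in table.arms], float)
        s_se, s_sp, rho = params["s_se"], params["s_sp"], params["rho"]
        if s_se.ndim == 2:  # per-technology (M1-NMA / bivariate)
            s_se_a, s_sp_a, rho_a = s_se[:, tidx], s_sp[:, tidx], rho[:, tidx]
        else:
            s_se_a = np.broadcast_to(s_se[:, None], (M, A))
            s_sp_a = np.broadcast_to(s_sp[:, None], (M, A))
            rho_a = np.broadcast_to(rho[:, None], (M, A))
        cov = np.empty((M, A, 2, 2))
        cov[..., 0, 0] = s_se_a**2
        cov[..., 1, 1] = s_sp_a**2
        cov[..., 0, 1] = cov[..., 1, 0] = rho_a * s_se_a * s_sp_a
        out_arm = np.empty((M, A))
        for lo in range(0, M, chunk):
            hi = min(lo + chunk, M)
            off_se = params["mu_se"][lo:hi][:, tidx][..., None]
            off_sp = params["mu_sp"][lo:hi][:, tidx][..., None]
            out_arm[lo:hi] = unit_marginal_loglik(
                tp, nD, tn, nS, off_se, off_sp, cov[lo:hi], K=K
            )
        G = np.zeros((A, len(study_ids)))
        G[np.arange(A), sidx] = 1.0
        return out_arm @ G
    raise ValueError(f"unknown model {model!r}")
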