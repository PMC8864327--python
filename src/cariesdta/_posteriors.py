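"""Unconstrained posterior densities and analytic gradients for the sampler.

Each class maps an unconstrained parameter vector to the model's joint log
posterior (likelihood + priors + change-of-variable terms) with gradients,
vectorized over chains.  Random effects are non-centered: the sampler works
on standard-normal innovations z, scaled by the heterogeneity parameters.

Transforms: heterogeneity SDs are sampled as logs (half-normal prior plus
log-Jacobian), correlations as atanh (2 x 2 LKJ prior plus tanh Jacobian),
and M1's full correlation matrix through canonical partial correlations of a
C-vine with level-dependent Beta exponents -- the exact vine representation
of the LKJ distribution -- so the implied prior on the matrix is LKJ(eta).
Gradients are analytic except for M1's partial-correlation block, which uses
central finite differences (a handful of extra cheap likelihood passes).
"""
from __future__ import annotations

import numpy as np
from scipy.special import betaln, expit, logit

from .errors import ModelSpecError
from .study_data import StudyTable
from .within_person import DEFAULT_PRIORS, complete_design_arrays


def _softplus(x):
    return np.logaddexp(0.0, x)


def _binom_const(k, n):
    return -betaln(1.0 + n - k, 1.0 + k) - np.log(n + 1.0)


def _parse_priors(prior_config):
    cfg = dict(DEFAULT_PRIORS)
    if prior_config:
        cfg.update(prior_config)
    kind, *mu_args = cfg["mu"]
    if kind != "normal":
        raise ModelSpecError("mu prior must be ('normal', mean, sd)")
    kind, sd_scale = cfg["sd"]
    if kind != "half_normal":
        raise ModelSpecError("sd prior must be ('half_normal', scale)")
    kind, eta = cfg["corr"]
    if kind != "lkj":
        raise ModelSpecError("corr prior must be ('lkj', eta)")
    return (mu_args[0], mu_args[1]), sd_scale, eta


class _Posterior:
    """Shared bookkeeping: slice registry over the flat parameter vector."""

    def __init__(self):
        self._slices = {}
        self.dim = 0

    def _add(self, name, size):
        self._slices[name] = slice(self.dim, self.dim + size)
        self.dim += size

    def get(self, X, name):
        return X[..., self._slices[name]]

    # -- prior/transform pieces (vectorized over chains) -------------------
    def _mu_prior(self, mu):
        m0, s0 = self.mu_prior
        lp = np.sum(-0.5 * np.log(2 * np.pi) - np.log(s0) - 0.5 * ((mu - m0) / s0) ** 2, axis=-1)
        grad = -(mu - m0) / s0**2
        return lp, grad

    def _sd_prior(self, log_s):
        """half-Normal(scale) on s = exp(log_s), plus log-Jacobian."""
        s = np.exp(log_s)
        sc = self.sd_scale
        lp = np.sum(
            0.5 * np.log(2 / np.pi) - np.log(sc) - 0.5 * (s / sc) ** 2 + log_s,
            axis=-1,
        )
        grad = 1.0 - (s / sc) ** 2
        return lp, grad

    def _rho_prior(self, y):
        """2x2 LKJ(eta) on rho = tanh(y), plus tanh Jacobian."""
        rho = np.tanh(y)
        with np.errstate(divide="ignore"):
            lp = np.sum(self.lkj_eta * np.log1p(-(rho**2)), axis=-1)
        grad = -2.0 * self.lkj_eta * rho
        return rho, lp, grad

    @staticmethod
    def _z_prior(z):
        axes = tuple(range(1, z.ndim))
        lp = np.sum(-0.5 * z**2 - 0.5 * np.log(2 * np.pi), axis=axes)
        return lp, -z


# ---------------------------------------------------------------------------
# Within-person (complete-design) posteriors
# ---------------------------------------------------------------------------


class _WithinBase(_Posterior):
    def __init__(self, table: StudyTable, technologies, prior_config=None):
        super().__init__()
        self.technologies = tuple(technologies)
        self.mu_prior, self.sd_scale, self.lkj_eta = _parse_priors(prior_config)
        ids, tp, nD, tn, nS = complete_design_arrays(self.technologies, table)
        self.study_ids = ids
        self.tp, self.nD, self.tn, self.nS = tp, nD, tn, nS
        self.S, self.T = tp.shape
        self.const = float(np.sum(_binom_const(tp, nD)) + np.sum(_binom_const(tn, nS)))

    def _binom(self, eta_se, eta_sp):
        """Binomial log-likelihood terms and eta-residuals, summed over (S,T)."""
        ll = np.sum(self.tp * eta_se - self.nD * _softplus(eta_se), axis=(1, 2))
        ll += np.sum(self.tn * eta_sp - self.nS * _softplus(eta_sp), axis=(1, 2))
        r_se = self.tp - self.nD * expit(eta_se)
        r_sp = self.tn - self.nS * expit(eta_sp)
        return ll + self.const, r_se, r_sp

    def _init_mu(self, chains, rng):
        pool_se = np.clip(self.tp.sum(0) / self.nD.sum(0), 0.02, 0.98)
        pool_sp = np.clip(self.tn.sum(0) / self.nS.sum(0), 0.02, 0.98)
        return (
            logit(pool_se) + 0.1 * rng.standard_normal((chains, self.T)),
            logit(pool_sp) + 0.1 * rng.standard_normal((chains, self.T)),
        )


class M3Posterior(_WithinBase):
    """Shared-heterogeneity decomposition nu = u (study) + w (study x tech)."""

    model = "M3"

    def __init__(self, table, technologies, prior_config=None):
        super().__init__(table, technologies, prior_config)
        S, T = self.S, self.T
        self._add("mu_se", T)
        self._add("mu_sp", T)
        self._add("log_tau_se", 1)
        self._add("log_tau_sp", 1)
        self._add("log_sigma_se", 1)
        self._add("log_sigma_sp", 1)
        self._add("y_rho_c", 1)
        self._add("z1", S)
        self._add("z2", S)
        self._add("zw_se", S * T)
        self._add("zw_sp", S * T)

    def logp_grad(self, X):
        C = X.shape[0]
        S, T = self.S, self.T
        mu_se, mu_sp = self.get(X, "mu_se"), self.get(X, "mu_sp")
        lt_se, lt_sp = self.get(X, "log_tau_se"), self.get(X, "log_tau_sp")
        ls_se, ls_sp = self.get(X, "log_sigma_se"), self.get(X, "log_sigma_sp")
        y = self.get(X, "y_rho_c")
        z1, z2 = self.get(X, "z1"), self.get(X, "z2")
        zw_se = self.get(X, "zw_se").reshape(C, S, T)
        zw_sp = self.get(X, "zw_sp").reshape(C, S, T)
        tau_se, tau_sp = np.exp(lt_se), np.exp(lt_sp)
        sig_se, sig_sp = np.exp(ls_se), np.exp(ls_sp)
        rho, lp_rho, g_rho_prior = self._rho_prior(y)
        c = np.sqrt(1.0 - rho**2)

        u_sp_std = rho * z1 + c * z2  # (C, S)
        eta_se = mu_se[:, None, :] + tau_se[:, None] * z1[..., None] + sig_se[:, None] * zw_se
        eta_sp = mu_sp[:, None, :] + tau_sp[:, None] * u_sp_std[..., None] + sig_sp[:, None] * zw_sp

        ll, r_se, r_sp = self._binom(eta_se, eta_sp)
        lp_mu_se, g_mu_se_pri = self._mu_prior(mu_se)
        lp_mu_sp, g_mu_sp_pri = self._mu_prior(mu_sp)
        log_sds = np.concatenate([lt_se, lt_sp, ls_se, ls_sp], axis=-1)
        lp_sd, g_sd = self._sd_prior(log_sds)
        lp_z1, g_z1_pri = self._z_prior(z1)
        lp_z2, g_z2_pri = self._z_prior(z2)
        lp_zwse, g_zwse_pri = self._z_prior(zw_se)
        lp_zwsp, g_zwsp_pri = self._z_prior(zw_sp)

        logp = ll + lp_mu_se + lp_mu_sp + lp_sd + lp_rho + lp_z1 + lp_z2 + lp_zwse + lp_zwsp

        S_se = r_se.sum(axis=2)  # (C, S)
        S_sp = r_sp.sum(axis=2)
        grad = np.empty_like(X)
        grad[..., self._slices["mu_se"]] = r_se.sum(axis=1) + g_mu_se_pri
        grad[..., self._slices["mu_sp"]] = r_sp.sum(axis=1) + g_mu_sp_pri
        grad[..., self._slices["log_tau_se"]] = (
            tau_se * np.sum(S_se * z1, axis=1, keepdims=True) + g_sd[..., 0:1]
        )
        grad[..., self._slices["log_tau_sp"]] = (
            tau_sp * np.sum(S_sp * u_sp_std, axis=1, keepdims=True) + g_sd[..., 1:2]
        )
        grad[..., self._slices["log_sigma_se"]] = (
            sig_se * np.sum(r_se * zw_se, axis=(1, 2))[:, None] + g_sd[..., 2:3]
        )
        grad[..., self._slices["log_sigma_sp"]] = (
            sig_sp * np.sum(r_sp * zw_sp, axis=(1, 2))[:, None] + g_sd[..., 3:4]
        )
        dz2 = np.where(c > 1e-12, rho / np.maximum(c, 1e-12), 0.0)
        grad[..., self._slices["y_rho_c"]] = (
            (1.0 - rho**2)
            * tau_sp
            * np.sum(S_sp * (z1 - dz2 * z2), axis=1, keepdims=True)
            + g_rho_prior
        )
        grad[..., self._slices["z1"]] = tau_se * S_se + tau_sp * rho * S_sp + g_z1_pri
        grad[..., self._slices["z2"]] = tau_sp * c * S_sp + g_z2_pri
        grad[..., self._slices["zw_se"]] = (sig_se[:, None] * r_se + g_zwse_pri).reshape(C, -1)
        grad[..., self._slices["zw_sp"]] = (sig_sp[:, None] * r_sp + g_zwsp_pri).reshape(C, -1)
        return logp, grad

    def initial_positions(self, chains, rng):
        X = 0.01 * rng.standard_normal((chains, self.dim))
        mu_se, mu_sp = self._init_mu(chains, rng)
        X[:, self._slices["mu_se"]] = mu_se
        X[:, self._slices["mu_sp"]] = mu_sp
        for name in ("log_tau_se", "log_tau_sp", "log_sigma_se", "log_sigma_sp"):
            X[:, self._slices[name]] = np.log(0.5) + 0.1 * rng.standard_normal((chains, 1))
        return X

    def param_draws(self, pos):
        out = {
            "mu_se": self.get(pos, "mu_se"),
            "mu_sp": self.get(pos, "mu_sp"),
            "tau_se": np.exp(self.get(pos, "log_tau_se")[..., 0]),
            "tau_sp": np.exp(self.get(pos, "log_tau_sp")[..., 0]),
            "sigma_se": np.exp(self.get(pos, "log_sigma_se")[..., 0]),
            "sigma_sp": np.exp(self.get(pos, "log_sigma_sp")[..., 0]),
            "rho_c": np.tanh(self.get(pos, "y_rho_c")[..., 0]),
        }
        return out


class M2Posterior(_WithinBase):
    """Separate bivariate models per technology (zero between-test correlation)."""

    model = "M2"

    def __init__(self, table, technologies, prior_config=None):
        super().__init__(table, technologies, prior_config)
        S, T = self.S, self.T
        self._add("mu_se", T)
        self._add("mu_sp", T)
        self._add("log_s_se", T)
        self._add("log_s_sp", T)
        self._add("y_rho", T)
        self._add("z1", S * T)
        self._add("z2", S * T)

    def logp_grad(self, X):
        C = X.shape[0]
        S, T = self.S, self.T
        mu_se, mu_sp = self.get(X, "mu_se"), self.get(X, "mu_sp")
        ls_se, ls_sp = self.get(X, "log_s_se"), self.get(X, "log_s_sp")
        y = self.get(X, "y_rho")
        z1 = self.get(X, "z1").reshape(C, S, T)
        z2 = self.get(X, "z2").reshape(C, S, T)
        s_se, s_sp = np.exp(ls_se), np.exp(ls_sp)
        rho, lp_rho, g_rho_prior = self._rho_prior(y)
        c = np.sqrt(1.0 - rho**2)

        mix = rho[:, None, :] * z1 + c[:, None, :] * z2
        eta_se = mu_se[:, None, :] + s_se[:, None, :] * z1
        eta_sp = mu_sp[:, None, :] + s_sp[:, None, :] * mix

        ll, r_se, r_sp = self._binom(eta_se, eta_sp)
        lp_mu_se, g_mu_se_pri = self._mu_prior(mu_se)
        lp_mu_sp, g_mu_sp_pri = self._mu_prior(mu_sp)
        lp_sd, g_sd = self._sd_prior(np.concatenate([ls_se, ls_sp], axis=-1))
        lp_z1, g_z1_pri = self._z_prior(z1)
        lp_z2, g_z2_pri = self._z_prior(z2)
        logp = ll + lp_mu_se + lp_mu_sp + lp_sd + lp_rho + lp_z1 + lp_z2

        grad = np.empty_like(X)
        grad[..., self._slices["mu_se"]] = r_se.sum(axis=1) + g_mu_se_pri
        grad[..., self._slices["mu_sp"]] = r_sp.sum(axis=1) + g_mu_sp_pri
        grad[..., self._slices["log_s_se"]] = s_se * np.sum(r_se * z1, axis=1) + g_sd[..., :T]
        grad[..., self._slices["log_s_sp"]] = s_sp * np.sum(r_sp * mix, axis=1) + g_sd[..., T:]
        dz2 = np.where(c > 1e-12, rho / np.maximum(c, 1e-12), 0.0)
        grad[..., self._slices["y_rho"]] = (
            (1.0 - rho**2) * s_sp * np.sum(r_sp * (z1 - dz2[:, None, :] * z2), axis=1)
            + g_rho_prior
        )
        grad[..., self._slices["z1"]] = (
            s_se[:, None, :] * r_se + s_sp[:, None, :] * rho[:, None, :] * r_sp + g_z1_pri
        ).reshape(C, -1)
        grad[..., self._slices["z2"]] = (
            s_sp[:, None, :] * c[:, None, :] * r_sp + g_z2_pri
        ).reshape(C, -1)
        return logp, grad

    def initial_positions(self, chains, rng):
        X = 0.01 * rng.standard_normal((chains, self.dim))
        mu_se, mu_sp = self._init_mu(chains, rng)
        X[:, self._slices["mu_se"]] = mu_se
        X[:, self._slices["mu_sp"]] = mu_sp
        for name in ("log_s_se", "log_s_sp"):
            X[:, self._slices[name]] = np.log(0.5) + 0.1 * rng.standard_normal((chains, self.T))
        return X

    def param_draws(self, pos):
        return {
            "mu_se": self.get(pos, "mu_se"),
            "mu_sp": self.get(pos, "mu_sp"),
            "s_se": np.exp(self.get(pos, "log_s_se")),
            "s_sp": np.exp(self.get(pos, "log_s_sp")),
            "rho": np.tanh(self.get(pos, "y_rho")),
        }


def chol_from_cpc(p, d):
    """Cholesky factor of a correlation matrix from canonical partial
    correlations (C-vine order: rows i = 1..d-1, columns j < i).  ``p`` has
    shape (..., d(d-1)/2)."""
    lead = p.shape[:-1]
    L = np.zeros(lead + (d, d))
    L[..., 0, 0] = 1.0
    k = 0
    for i in range(1, d):
        rem = np.ones(lead)
        for j in range(i):
            L[..., i, j] = p[..., k] * np.sqrt(rem)
            rem = rem * (1.0 - p[..., k] ** 2)
            k += 1
        L[..., i, i] = np.sqrt(rem)
    return L


def cpc_lkj_exponents(d, eta):
    """Per-CPC Beta exponents alpha such that independent CPCs with density
    proportional to (1 - p^2)^(alpha - 1) imply an LKJ(eta) matrix."""
    alphas = []
    for i in range(1, d):
        for j in range(i):
            alphas.append(eta + 0.5 * (d - 2 - j))
    return np.array(alphas)


class M1Posterior(_WithinBase):
    """Unstructured 2T x 2T between-study covariance."""

    model = "M1"

    def __init__(self, table, technologies, prior_config=None):
        super().__init__(table, technologies, prior_config)
        S, T = self.S, self.T
        d = 2 * T
        self.d = d
        self.P = d * (d - 1) // 2
        self.alphas = cpc_lkj_exponents(d, self.lkj_eta)
        self._add("mu_se", T)
        self._add("mu_sp", T)
        self._add("log_sd", d)
        self._add("y_cpc", self.P)
        self._add("z", S * d)

    def _etas(self, mu_se, mu_sp, sd, L, z):
        nu_std = np.einsum("cij,csj->csi", L, z)
        nu = sd[:, None, :] * nu_std
        eta_se = mu_se[:, None, :] + nu[..., 0::2]
        eta_sp = mu_sp[:, None, :] + nu[..., 1::2]
        return eta_se, eta_sp, nu_std

    def _cpc_part(self, y, mu_se, mu_sp, sd, z):
        """Terms of logp that depend on the partial correlations."""
        p = np.tanh(y)
        L = chol_from_cpc(p, self.d)
        eta_se, eta_sp, _ = self._etas(mu_se, mu_sp, sd, L, z)
        ll, _, _ = self._binom(eta_se, eta_sp)
        # Beta(alpha, alpha) prior on each CPC plus tanh Jacobian
        lp = np.sum(self.alphas * np.log1p(-(p**2)), axis=-1)
        return ll + lp

    def logp_grad(self, X):
        C = X.shape[0]
        S, T, d = self.S, self.T, self.d
        mu_se, mu_sp = self.get(X, "mu_se"), self.get(X, "mu_sp")
        log_sd = self.get(X, "log_sd")
        y = self.get(X, "y_cpc")
        z = self.get(X, "z").reshape(C, S, d)
        sd = np.exp(log_sd)
        p = np.tanh(y)
        L = chol_from_cpc(p, d)

        eta_se, eta_sp, nu_std = self._etas(mu_se, mu_sp, sd, L, z)
        ll, r_se, r_sp = self._binom(eta_se, eta_sp)
        r = np.empty((C, S, d))
        r[..., 0::2] = r_se
        r[..., 1::2] = r_sp

        lp_mu_se, g_mu_se_pri = self._mu_prior(mu_se)
        lp_mu_sp, g_mu_sp_pri = self._mu_prior(mu_sp)
        lp_sd, g_sd = self._sd_prior(log_sd)
        lp_cpc = np.sum(self.alphas * np.log1p(-(p**2)), axis=-1)
        lp_z, g_z_pri = self._z_prior(z)
        logp = ll + lp_mu_se + lp_mu_sp + lp_sd + lp_cpc + lp_z

        grad = np.empty_like(X)
        grad[..., self._slices["mu_se"]] = r_se.sum(axis=1) + g_mu_se_pri
        grad[..., self._slices["mu_sp"]] = r_sp.sum(axis=1) + g_mu_sp_pri
        grad[..., self._slices["log_sd"]] = sd * np.sum(r * nu_std, axis=1) + g_sd
        grad[..., self._slices["z"]] = (
            np.einsum("csi,cij->csj", sd[:, None, :] * r, L) + g_z_pri
        ).reshape(C, -1)
        # finite differences for the partial-correlation block
        h = 1e-5
        g_cpc = np.empty((C, self.P))
        for k in range(self.P):
            yp = y.copy()
            yp[:, k] += h
            fp = self._cpc_part(yp, mu_se, mu_sp, sd, z)
            yp[:, k] -= 2 * h
            fm = self._cpc_part(yp, mu_se, mu_sp, sd, z)
            g_cpc[:, k] = (fp - fm) / (2 * h)
        grad[..., self._slices["y_cpc"]] = g_cpc
        return logp, grad

    def initial_positions(self, chains, rng):
        X = 0.01 * rng.standard_normal((chains, self.dim))
        mu_se, mu_sp = self._init_mu(chains, rng)
        X[:, self._slices["mu_se"]] = mu_se
        X[:, self._slices["mu_sp"]] = mu_sp
        X[:, self._slices["log_sd"]] = np.log(0.5) + 0.1 * rng.standard_normal((chains, self.d))
        return X

    def param_draws(self, pos):
        p = np.tanh(self.get(pos, "y_cpc"))
        L = chol_from_cpc(p, self.d)
        corr = L @ np.swapaxes(L, -1, -2)
        return {
            "mu_se": self.get(pos, "mu_se"),
            "mu_sp": self.get(pos, "mu_sp"),
            "sd": np.exp(self.get(pos, "log_sd")),
            "corr": corr,
        }


# ---------------------------------------------------------------------------
# Network meta-analysis posteriors
# ---------------------------------------------------------------------------


class _NmaBase(_Posterior):
    def __init__(self, table: StudyTable, technologies, prior_config=None):
        super().__init__()
        self.technologies = tuple(technologies)
        self.mu_prior, self.sd_scale, self.lkj_eta = _parse_priors(prior_config)
        tech_index = {t: i for i, t in enumerate(self.technologies)}
        for arm in table.arms:
            if arm.technology not in tech_index:
                raise ModelSpecError(f"unknown technology {arm.technology!r}")
        self.study_ids = table.study_ids
        study_index = {s: i for i, s in enumerate(self.study_ids)}
        self.A = len(table.arms)
        self.T = len(self.technologies)
        self.tidx = np.array([tech_index[a.technology] for a in table.arms])
        self.sidx = np.array([study_index[a.study_id] for a in table.arms])
        self.tp = np.array([a.tp for a in table.arms], float)
        self.nD = np.array([a.n_diseased for a in table.arms], float)
        self.tn = np.array([a.tn for a in table.arms], float)
        self.nS = np.array([a.n_sound for a in table.arms], float)
        self.E = np.zeros((self.A, self.T))
        self.E[np.arange(self.A), self.tidx] = 1.0
        self.const = float(
            np.sum(_binom_const(self.tp, self.nD)) + np.sum(_binom_const(self.tn, self.nS))
        )

    def _binom(self, eta_se, eta_sp):
        ll = np.sum(self.tp * eta_se - self.nD * _softplus(eta_se), axis=-1)
        ll += np.sum(self.tn * eta_sp - self.nS * _softplus(eta_sp), axis=-1)
        r_se = self.tp - self.nD * expit(eta_se)
        r_sp = self.tn - self.nS * expit(eta_sp)
        return ll + self.const, r_se, r_sp

    def _init_mu(self, chains, rng):
        tp_t = self.tp @ self.E
        nD_t = self.nD @ self.E
        tn_t = self.tn @ self.E
        nS_t = self.nS @ self.E
        pool_se = np.clip(tp_t / np.maximum(nD_t, 1.0), 0.02, 0.98)
        pool_sp = np.clip(tn_t / np.maximum(nS_t, 1.0), 0.02, 0.98)
        return (
            logit(pool_se) + 0.1 * rng.standard_normal((chains, self.T)),
            logit(pool_sp) + 0.1 * rng.standard_normal((chains, self.T)),
        )


class M1NmaPosterior(_NmaBase):
    """Separate per-technology variances and correlations."""

    model = "M1-NMA"

    def __init__(self, table, technologies, prior_config=None):
        super().__init__(table, technologies, prior_config)
        self._add("mu_se", self.T)
        self._add("mu_sp", self.T)
        self._add("log_s_se", self.T)
        self._add("log_s_sp", self.T)
        self._add("y_rho", self.T)
        self._add("z1", self.A)
        self._add("z2", self.A)

    def logp_grad(self, X):
        mu_se, mu_sp = self.get(X, "mu_se"), self.get(X, "mu_sp")
        ls_se, ls_sp = self.get(X, "log_s_se"), self.get(X, "log_s_sp")
        y = self.get(X, "y_rho")
        z1, z2 = self.get(X, "z1"), self.get(X, "z2")
        s_se, s_sp = np.exp(ls_se), np.exp(ls_sp)
        rho, lp_rho, g_rho_prior = self._rho_prior(y)
        c = np.sqrt(1.0 - rho**2)
        t = self.tidx

        s_se_a, s_sp_a = s_se[:, t], s_sp[:, t]
        rho_a, c_a = rho[:, t], c[:, t]
        mix = rho_a * z1 + c_a * z2
        eta_se = mu_se[:, t] + s_se_a * z1
        eta_sp = mu_sp[:, t] + s_sp_a * mix

        ll, r_se, r_sp = self._binom(eta_se, eta_sp)
        lp_mu_se, g_mu_se_pri = self._mu_prior(mu_se)
        lp_mu_sp, g_mu_sp_pri = self._mu_prior(mu_sp)
        lp_sd, g_sd = self._sd_prior(np.concatenate([ls_se, ls_sp], axis=-1))
        lp_z1, g_z1_pri = self._z_prior(z1)
        lp_z2, g_z2_pri = self._z_prior(z2)
        logp = ll + lp_mu_se + lp_mu_sp + lp_sd + lp_rho + lp_z1 + lp_z2

        grad = np.empty_like(X)
        grad[..., self._slices["mu_se"]] = r_se @ self.E + g_mu_se_pri
        grad[..., self._slices["mu_sp"]] = r_sp @ self.E + g_mu_sp_pri
        grad[..., self._slices["log_s_se"]] = s_se * ((r_se * z1) @ self.E) + g_sd[..., : self.T]
        grad[..., self._slices["log_s_sp"]] = s_sp * ((r_sp * mix) @ self.E) + g_sd[..., self.T :]
        dz2 = np.where(c_a > 1e-12, rho_a / np.maximum(c_a, 1e-12), 0.0)
        grad[..., self._slices["y_rho"]] = (
            (1.0 - rho**2) * s_sp * ((r_sp * (z1 - dz2 * z2)) @ self.E) + g_rho_prior
        )
        grad[..., self._slices["z1"]] = s_se_a * r_se + s_sp_a * rho_a * r_sp + g_z1_pri
        grad[..., self._slices["z2"]] = s_sp_a * c_a * r_sp + g_z2_pri
        return logp, grad

    def initial_positions(self, chains, rng):
        X = 0.01 * rng.standard_normal((chains, self.dim))
        mu_se, mu_sp = self._init_mu(chains, rng)
        X[:, self._slices["mu_se"]] = mu_se
        X[:, self._slices["mu_sp"]] = mu_sp
        for name in ("log_s_se", "log_s_sp"):
            X[:, self._slices[name]] = np.log(0.5) + 0.1 * rng.standard_normal((chains, self.T))
        return X

    def param_draws(self, pos):
        return {
            "mu_se": self.get(pos, "mu_se"),
            "mu_sp": self.get(pos, "mu_sp"),
            "s_se": np.exp(self.get(pos, "log_s_se")),
            "s_sp": np.exp(self.get(pos, "log_s_sp")),
            "rho": np.tanh(self.get(pos, "y_rho")),
        }


class M2NmaPosterior(_NmaBase):
    """One shared variance pair and correlation across all technologies."""

    model = "M2-NMA"

    def __init__(self, table, technologies, prior_config=None):
        super().__init__(table, technologies, prior_config)
        self._add("mu_se", self.T)
        self._add("mu_sp", self.T)
        self._add("log_s_se", 1)
        self._add("log_s_sp", 1)
        self._add("y_rho", 1)
        self._add("z1", self.A)
        self._add("z2", self.A)

    def logp_grad(self, X):
        mu_se, mu_sp = self.get(X, "mu_se"), self.get(X, "mu_sp")
        ls_se, ls_sp = self.get(X, "log_s_se"), self.get(X, "log_s_sp")
        y = self.get(X, "y_rho")
        z1, z2 = self.get(X, "z1"), self.get(X, "z2")
        s_se, s_sp = np.exp(ls_se), np.exp(ls_sp)
        rho, lp_rho, g_rho_prior = self._rho_prior(y)
        c = np.sqrt(1.0 - rho**2)
        t = self.tidx

        mix = rho * z1 + c * z2
        eta_se = mu_se[:, t] + s_se * z1
        eta_sp = mu_sp[:, t] + s_sp * mix

        ll, r_se, r_sp = self._binom(eta_se, eta_sp)
        lp_mu_se, g_mu_se_pri = self._mu_prior(mu_se)
        lp_mu_sp, g_mu_sp_pri = self._mu_prior(mu_sp)
        lp_sd, g_sd = self._sd_prior(np.concatenate([ls_se, ls_sp], axis=-1))
        lp_z1, g_z1_pri = self._z_prior(z1)
        lp_z2, g_z2_pri = self._z_prior(z2)
        logp = ll + lp_mu_se + lp_mu_sp + lp_sd + lp_rho + lp_z1 + lp_z2

        grad = np.empty_like(X)
        grad[..., self._slices["mu_se"]] = r_se @ self.E + g_mu_se_pri
        grad[..., self._slices["mu_sp"]] = r_sp @ self.E + g_mu_sp_pri
        grad[..., self._slices["log_s_se"]] = (
            s_se * np.sum(r_se * z1, axis=-1, keepdims=True) + g_sd[..., 0:1]
        )
        grad[..., self._slices["log_s_sp"]] = (
            s_sp * np.sum(r_sp * mix, axis=-1, keepdims=True) + g_sd[..., 1:2]
        )
        dz2 = np.where(c > 1e-12, rho / np.maximum(c, 1e-12), 0.0)
        grad[..., self._slices["y_rho"]] = (
            (1.0 - rho**2) * s_sp * np.sum(r_sp * (z1 - dz2 * z2), axis=-1, keepdims=True)
            + g_rho_prior
        )
        grad[..., self._slices["z1"]] = s_se * r_se + s_sp * rho * r_sp + g_z1_pri
        grad[..., self._slices["z2"]] = s_sp * c * r_sp + g_z2_pri
        return logp, grad

    def initial_positions(self, chains, rng):
        X = 0.01 * rng.standard_normal((chains, self.dim))
        mu_se, mu_sp = self._init_mu(chains, rng)
        X[:, self._slices["mu_se"]] = mu_se
        X[:, self._slices["mu_sp"]] = mu_sp
        for name in ("log_s_se", "log_s_sp"):
            X[:, self._slices[name]] = np.log(0.5) + 0.1 * rng.standard_normal((chains, 1))
        return X

    def param_draws(self, pos):
        return {
            "mu_se": self.get(pos, "mu_se"),
            "mu_sp": self.get(pos, "mu_sp"),
            "s_se": np.exp(self.get(pos, "log_s_se")[..., 0]),
            "s_sp": np.exp(self.get(pos, "log_s_sp")[..., 0]),
            "rho": np.tanh(self.get(pos, "y_rho")[..., 0]),
        }


POSTERIORS = {
    "M1": M1Posterior,
    "M2": M2Posterior,
    "M3": M3Posterior,
    "M1-NMA": M1NmaPosterior,
    "M2-NMA": M2NmaPosterior,
    # single-technology bivariate meta-analysis: the one-technology reduction
    # of the NMA model (per-technology and shared structures coincide)
    "bivariate": M1NmaPosterior,
}
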