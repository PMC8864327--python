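"""Fully within-person multi-test accuracy model (variants M1, M2, M3).

Every study evaluates the same T technologies on the same tooth sites.  On
the logit scale, study i / technology t has

    logit Se_it = mu_se[t] + nu_se[i, t]
    logit Sp_it = mu_sp[t] + nu_sp[i, t]

with binomial sampling of TP out of the diseased margin and TN out of the
sound margin, and a 2T-dimensional zero-mean Gaussian for the stacked random
effects nu_i.  The variants differ only in the between-study covariance:

* M1 - unstructured: full 2T x 2T covariance (SDs + correlation matrix),
  estimating correlations between and within technologies.
* M2 - all between-technology correlations zero: block-diagonal per-technology
  2 x 2 covariances, equivalent to separate bivariate models.
* M3 - shared heterogeneity: nu_se[i,t] = u_se[i] + w_se[i,t] (and analogously
  for specificity) with a single study-level (Se, Sp) correlation rho_c and
  one (tau, sigma) variance pair per margin, shared across technologies.

The random-effect vector is stored interleaved per technology:
index 2t -> sensitivity of technology t, index 2t+1 -> its specificity,
so M2's covariance is literally block-diagonal.

Because none of the source studies report fully paired 2 x 4 tables, the
within-study cross-classification between tests is unmodelled: given the
random effects, arms contribute independent binomial margins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, expit

from .errors import ConfigError, EligibilityError, ModelSpecError
from .study_data import StudyTable

VARIANTS = ("M1", "M2", "M3")


def binom_logpmf(k, n, p):
    """log Binomial(k | n, p), vectorized; exact for edge probabilities."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = -betaln(1.0 + n - k, 1.0 + k) - np.log(n + 1.0)
        out = logc + np.where(k > 0, k * np.log(p), 0.0) + np.where(
            n - k > 0, (n - k) * np.log1p(-p), 0.0
        )
    return np.where(
        ((p == 0) & (k > 0)) | ((p == 1) & (k < n)), -np.inf, out
    )


def mvn_logpdf(x, cov):
    """log N(x | 0, cov) with x (..., d)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = x.shape[-1]
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, x.T)  # (d, n)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


@dataclass
class WithinPersonParams:
    """Parameter block for one within-person variant.

    ``nu`` holds the per-study random-effect vectors, shape (S, 2T),
    interleaved [se_1, sp_1, se_2, sp_2, ...].  Which covariance fields are
    required depends on ``variant`` (see module docstring).
    """

    variant: str
    technologies: tuple
    mu_se: np.ndarray
    mu_sp: np.ndarray
    nu: np.ndarray | None = None
    # M1
    sd: np.ndarray | None = None
    corr: np.ndarray | None = None
    # M2
    s_se: np.ndarray | None = None
    s_sp: np.ndarray | None = None
    rho: np.ndarray | None = None
    # M3
    tau_se: float | None = None
    tau_sp: float | None = None
    sigma_se: float | None = None
    sigma_sp: float | None = None
    rho_c: float | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ModelSpecError(f"unknown variant {self.variant!r}")
        self.technologies = tuple(self.technologies)
        self.mu_se = np.asarray(self.mu_se, dtype=float)
        self.mu_sp = np.asarray(self.mu_sp, dtype=float)
        T = len(self.technologies)
        if self.mu_se.shape != (T,) or self.mu_sp.shape != (T,):
            raise ModelSpecError("mu_se / mu_sp must have one entry per technology")
        if self.nu is not None:
            self.nu = np.asarray(self.nu, dtype=float)
            if self.nu.ndim != 2 or self.nu.shape[1] != 2 * T:
                raise ModelSpecError("nu must have shape (n_studies, 2T)")

    @property
    def n_technologies(self) -> int:
        return len(self.technologies)


def build_covariance(variant: str, params: WithinPersonParams) -> np.ndarray:
    """Assemble the 2T x 2T between-study covariance implied by a variant.

    M1: D R D from SDs and the full correlation matrix.
    M2: block-diagonal per-technology 2 x 2 blocks.
    M3: compound symmetry from the u + w decomposition -- diagonals
    tau^2 + sigma^2, within-margin off-diagonals tau^2, and every
    (Se, Sp) cross-entry rho_c * tau_se * tau_sp.
    """
    T = params.n_technologies
    d = 2 * T
    if variant == "M1":
        if params.sd is None or params.corr is None:
            raise ModelSpecError("M1 requires sd (2T,) and corr (2T, 2T)")
        sd = np.asarray(params.sd, dtype=float)
        R = np.asarray(params.corr, dtype=float)
        if sd.shape != (d,) or R.shape != (d, d):
            raise ModelSpecError("M1 dimensions do not match 2T")
        if np.any(sd < 0):
            raise ModelSpecError("SDs must be non-negative")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ModelSpecError("corr must be symmetric with unit diagonal")
        cov = sd[:, None] * R * sd[None, :]
    elif variant == "M2":
        if params.s_se is None or params.s_sp is None or params.rho is None:
            raise ModelSpecError("M2 requires s_se, s_sp, rho per technology")
        s_se = np.asarray(params.s_se, dtype=float)
        s_sp = np.asarray(params.s_sp, dtype=float)
        rho = np.asarray(params.rho, dtype=float)
        if s_se.shape != (T,) or s_sp.shape != (T,) or rho.shape != (T,):
            raise ModelSpecError("M2 parameter shapes must be (T,)")
        if np.any(np.abs(rho) > 1):
            raise ModelSpecError("|rho| must be <= 1")
        cov = np.zeros((d, d))
        for t in range(T):
            block = np.array(
                [
                    [s_se[t] ** 2, rho[t] * s_se[t] * s_sp[t]],
                    [rho[t] * s_se[t] * s_sp[t], s_sp[t] ** 2],
                ]
            )
            cov[2 * t : 2 * t + 2, 2 * t : 2 * t + 2] = block
    elif variant == "M3":
        for name in ("tau_se", "tau_sp", "sigma_se", "sigma_sp", "rho_c"):
            if getattr(params, name) is None:
                raise ModelSpecError(f"M3 requires {name}")
        if abs(params.rho_c) > 1:
            raise ModelSpecError("|rho_c| must be <= 1")
        tau2_se, tau2_sp = params.tau_se**2, params.tau_sp**2
        cross = params.rho_c * params.tau_se * params.tau_sp
        cov = np.zeros((d, d))
        se_idx = np.arange(0, d, 2)
        sp_idx = np.arange(1, d, 2)
        cov[np.ix_(se_idx, se_idx)] = tau2_se
        cov[np.ix_(sp_idx, sp_idx)] = tau2_sp
        cov[np.ix_(se_idx, sp_idx)] = cross
        cov[np.ix_(sp_idx, se_idx)] = cross
        cov[se_idx, se_idx] = tau2_se + params.sigma_se**2
        cov[sp_idx, sp_idx] = tau2_sp + params.sigma_sp**2
    else:
        raise ModelSpecError(f"unknown variant {variant!r}")
    # fail early on a numerically non-PD assembly (boundary cases excepted)
    eigmin = np.min(np.linalg.eigvalsh(cov))
    if eigmin < -1e-10:
        raise ModelSpecError("assembled covariance is not positive semi-definite")
    return cov


def complete_design_arrays(technologies, table: StudyTable):
    """Map a complete-design table onto (study, technology) count grids.

    Returns (study_ids, tp, n_diseased, tn, n_sound), each count array of
    shape (S, T).  Raises :class:`EligibilityError` if any study misses one
    of the technologies.
    """
    techs = tuple(technologies)
    study_ids = table.study_ids
    arms = {}
    for arm in table.arms:
        if arm.technology not in techs:
            raise ModelSpecError(
                f"technology {arm.technology!r} not covered by params {techs}"
            )
        arms[(arm.study_id, arm.technology)] = arm
    for sid in study_ids:
        for t in techs:
            if (sid, t) not in arms:
                raise EligibilityError(
                    f"study {sid!r} is missing technology {t!r}: the within-person "
                    "model needs a complete design; use the network model for "
                    "incomplete networks"
                )
    S, T = len(study_ids), len(techs)
    tp = np.empty((S, T))
    nD = np.empty((S, T))
    tn = np.empty((S, T))
    nS = np.empty((S, T))
    for i, sid in enumerate(study_ids):
        for t, tech in enumerate(techs):
            a = arms[(sid, tech)]
            tp[i, t], nD[i, t] = a.tp, a.n_diseased
            tn[i, t], nS[i, t] = a.tn, a.n_sound
    return study_ids, tp, nD, tn, nS


def log_likelihood_within(params: WithinPersonParams, table: StudyTable) -> float:
    """Joint log-density of counts and random effects under one variant.

    Sum over studies and technologies of the two binomial terms evaluated at
    the study-specific operating points, plus the multivariate-normal density
    of each study's stacked random-effect vector under the variant's
    covariance.  ``params.nu`` must be supplied (one row per study, in the
    table's study order).
    """
    if params.nu is None:
        raise ModelSpecError("params.nu (per-study random effects) is required")
    study_ids, tp, nD, tn, nS = complete_design_arrays(params.technologies, table)
    S, T = tp.shape
    if params.nu.shape[0] != S:
        raise ModelSpecError(
            f"nu has {params.nu.shape[0]} rows but the table has {S} studies"
        )
    nu_se = params.nu[:, 0::2]
    nu_sp = params.nu[:, 1::2]
    p_se = expit(params.mu_se[None, :] + nu_se)
    p_sp = expit(params.mu_sp[None, :] + nu_sp)
    ll = float(np.sum(binom_logpmf(tp, nD, p_se)) + np.sum(binom_logpmf(tn, nS, p_sp)))
    cov = build_covariance(params.variant, params)
    ll += float(np.sum(mvn_logpdf(params.nu, cov)))
    return ll


def m3_icc(tau: float, sigma: float) -> float:
    """Intrastudy correlation: share of logit-scale variance between studies."""
    return tau**2 / (tau**2 + sigma**2)


def m1_params_from_m2(params: WithinPersonParams) -> WithinPersonParams:
    """Re-express an M2 parameter block as an M1 block with zero cross-technology
    correlations (the two variants are equivalent by construction)."""
    if params.variant != "M2":
        raise ModelSpecError("expected an M2 parameter block")
    T = params.n_technologies
    d = 2 * T
    sd = np.empty(d)
    R = np.eye(d)
    for t in range(T):
        sd[2 * t] = params.s_se[t]
        sd[2 * t + 1] = params.s_sp[t]
        R[2 * t, 2 * t + 1] = R[2 * t + 1, 2 * t] = params.rho[t]
    return WithinPersonParams(
        variant="M1",
        technologies=params.technologies,
        mu_se=params.mu_se,
        mu_sp=params.mu_sp,
        nu=params.nu,
        sd=sd,
        corr=R,
    )


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

#: Weakly informative defaults on the probability scale: logit-scale means
#: within roughly (0.05, 0.95) at one prior SD; heterogeneity SDs of order
#: one; correlation matrices mildly shrunk toward identity.
DEFAULT_PRIORS = {
    "mu": ("normal", 0.0, 1.5),
    "sd": ("half_normal", 1.0),
    "corr": ("lkj", 2.0),
}


def _normal_logpdf(x, mean, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _half_normal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = (
        0.5 * np.log(2 / np.pi)
        - np.log(scale)
        - 0.5 * (x / scale) ** 2
    )
    return np.where(x < 0, -np.inf, out)


def _lkj_logdensity(corr: np.ndarray, eta: float) -> float:
    """Unnormalized LKJ density: (eta - 1) * log det(R)."""
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        return -np.inf
    return (eta - 1.0) * logdet


def prior_logdensity(params: WithinPersonParams, prior_config=None) -> float:
    """Sum of prior log-densities over all structural parameters of a variant.

    ``prior_config`` maps the blocks {"mu", "sd", "corr"} to distribution
    tuples ("normal", mean, sd), ("half_normal", scale) or ("lkj", eta).
    The LKJ term is evaluated up to its normalizing constant.  Random effects
    are part of the likelihood (their Gaussian is in
    :func:`log_likelihood_within`), not of the prior.
    """
    cfg = dict(DEFAULT_PRIORS) if prior_config is None else dict(prior_config)
    missing = [k for k in ("mu", "sd", "corr") if k not in cfg]
    if missing:
        raise ConfigError(f"prior configuration missing blocks: {missing}")

    def _eval(kind_spec, value):
        kind = kind_spec[0]
        if kind == "normal":
            return float(np.sum(_normal_logpdf(np.asarray(value, float), *kind_spec[1:])))
        if kind == "half_normal":
            return float(np.sum(_half_normal_logpdf(np.asarray(value, float), kind_spec[1])))
        raise ConfigError(f"unknown prior kind {kind!r}")

    total = _eval(cfg["mu"], params.mu_se) + _eval(cfg["mu"], params.mu_sp)
    corr_spec = cfg["corr"]
    if corr_spec[0] != "lkj":
        raise ConfigError("the corr block must use an ('lkj', eta) prior")
    eta = corr_spec[1]
    if params.variant == "M1":
        total += _eval(cfg["sd"], params.sd)
        total += _lkj_logdensity(np.asarray(params.corr, float), eta)
    elif params.variant == "M2":
        total += _eval(cfg["sd"], params.s_se) + _eval(cfg["sd"], params.s_sp)
        for r in np.atleast_1d(params.rho):
            R2 = np.array([[1.0, r], [r, 1.0]])
            total += _lkj_logdensity(R2, eta)
    elif params.variant == "M3":
        total += _eval(cfg["sd"], [params.tau_se, params.tau_sp,
                                   params.sigma_se, params.sigma_sp])
        R2 = np.array([[1.0, params.rho_c], [params.rho_c, 1.0]])
        total += _lkj_logdensity(R2, eta)
    return float(total)
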