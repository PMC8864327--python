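"""Arm-based network meta-analysis of diagnostic accuracy (M1-NMA, M2-NMA).

Studies evaluate any subset (>= 2) of the technologies; each realized study x
technology arm gets its own bivariate logit-normal random effect:

    (nu_se, nu_sp)_arm ~ N2(0, Sigma_t)

with Sigma_t built from (s_se[t], s_sp[t], rho[t]) per technology (M1-NMA) or
from a single shared (s_se, s_sp, rho) (M2-NMA).  Missing technologies simply
contribute nothing (missing-at-random by design).  The model is arm-based --
absolute summary Se/Sp per technology with prediction intervals fall out
directly -- and deliberately has no study-level intercept shared across
technologies: without fully paired 2 x 4 tables the between-technology
within-study correlation is not identified.  Technologies with few studies
borrow strength only under M2-NMA, through the shared variances.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import EligibilityError, ModelSpecError
from .study_data import StudyTable
from .within_person import binom_logpmf, mvn_logpdf

NMA_VARIANTS = ("M1-NMA", "M2-NMA")


@dataclass
class NmaParams:
    """Parameters of the NMA model.

    ``nu`` has one (nu_se, nu_sp) row per realized arm, in table arm order.
    For M1-NMA the SD/correlation fields are per-technology arrays; for
    M2-NMA they are scalars shared across technologies.
    """

    variant: str
    technologies: tuple
    mu_se: np.ndarray
    mu_sp: np.ndarray
    s_se: np.ndarray | float
    s_sp: np.ndarray | float
    rho: np.ndarray | float
    nu: np.ndarray | None = None

    def __post_init__(self):
        if self.variant not in NMA_VARIANTS:
            raise ModelSpecError(f"unknown NMA variant {self.variant!r}")
        self.technologies = tuple(self.technologies)
        T = len(self.technologies)
        self.mu_se = np.asarray(self.mu_se, dtype=float)
        self.mu_sp = np.asarray(self.mu_sp, dtype=float)
        if self.mu_se.shape != (T,) or self.mu_sp.shape != (T,):
            raise ModelSpecError("mu_se / mu_sp must have one entry per technology")
        if self.variant == "M1-NMA":
            self.s_se = np.asarray(self.s_se, dtype=float)
            self.s_sp = np.asarray(self.s_sp, dtype=float)
            self.rho = np.asarray(self.rho, dtype=float)
            if self.s_se.shape != (T,) or self.s_sp.shape != (T,) or self.rho.shape != (T,):
                raise ModelSpecError("M1-NMA needs per-technology s_se, s_sp, rho")
        else:
            self.s_se = float(self.s_se)
            self.s_sp = float(self.s_sp)
            self.rho = float(self.rho)
        s_se = np.atleast_1d(self.s_se)
        s_sp = np.atleast_1d(self.s_sp)
        rho = np.atleast_1d(self.rho)
        if np.any(s_se < 0) or np.any(s_sp < 0):
            raise ModelSpecError("SDs must be non-negative")
        if np.any(np.abs(rho) > 1):
            raise ModelSpecError("|rho| must be <= 1")

    def tech_cov(self, t: int) -> np.ndarray:
        """2 x 2 between-study covariance block for technology index t."""
        if self.variant == "M1-NMA":
            s1, s2, r = self.s_se[t], self.s_sp[t], self.rho[t]
        else:
            s1, s2, r = self.s_se, self.s_sp, self.rho
        return np.array([[s1**2, r * s1 * s2], [r * s1 * s2, s2**2]])


def check_nma_eligibility(table: StudyTable, technologies=None) -> None:
    """Every study must contribute >= 2 technologies, except in the degenerate
    single-technology table, which reduces the NMA to an ordinary bivariate
    meta-analysis."""
    techs = set(technologies) if technologies is not None else set(table.technologies)
    if len(set(table.technologies)) == 1:
        return
    for sid in table.study_ids:
        n = len(table.technologies_of(sid) & techs)
        if n < 2:
            raise EligibilityError(
                f"study {sid!r} evaluates {n} eligible technology(ies); the "
                "network analysis requires >= 2 directly compared index tests "
                "per study"
            )


def log_likelihood_nma(params: NmaParams, table: StudyTable) -> float:
    """Joint log-density of counts and arm random effects under the NMA model."""
    if params.nu is None:
        raise ModelSpecError("params.nu (per-arm random effects) is required")
    tech_index = {t: i for i, t in enumerate(params.technologies)}
    for arm in table.arms:
        if arm.technology not in tech_index:
            raise ModelSpecError(f"unknown technology {arm.technology!r}")
    check_nma_eligibility(table, params.technologies)
    nu = np.asarray(params.nu, dtype=float)
    if nu.shape != (len(table.arms), 2):
        raise ModelSpecError("nu must have shape (n_arms, 2) in table arm order")
    total = 0.0
    for a, arm in enumerate(table.arms):
        t = tech_index[arm.technology]
        p_se = expit(params.mu_se[t] + nu[a, 0])
        p_sp = expit(params.mu_sp[t] + nu[a, 1])
        total += float(binom_logpmf(arm.tp, arm.n_diseased, p_se))
        total += float(binom_logpmf(arm.tn, arm.n_sound, p_sp))
        total += float(mvn_logpdf(nu[a], params.tech_cov(t))[0])
    return total


def pooled_comparisons(draws, pair):
    """Posterior of (dSe, dSp) for a technology pair, on the probability scale.

    ``draws`` is a fitted :class:`~cariesdta.inference.PosteriorDraws`.  For
    each posterior draw, dSe = expit(mu_se[a]) - expit(mu_se[b]) (and dSp
    analogously), combining direct and indirect evidence through the joint
    posterior.  Returns (dse_draws, dsp_draws) flat arrays.
    """
    a, b = pair
    for tech in (a, b):
        if tech not in draws.technologies:
            raise ModelSpecError(f"technology {tech!r} absent from the model")
    se_a = expit(draws.flat("mu_se", a))
    se_b = expit(draws.flat("mu_se", b))
    sp_a = expit(draws.flat("mu_sp", a))
    sp_b = expit(draws.flat("mu_sp", b))
    return se_a - se_b, sp_a - sp_b
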