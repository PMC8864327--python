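"""Synthetic study networks with the structure the accuracy models assume.

The generator draws study networks from the same data-generating process the
within-person and NMA models posit: logit-normal between-study random
effects, shared reference-standard margins within a study (the within-person
design verifies the same tooth sites once), and binomial sampling of the 2x2
cells.  Latent per-study operating points are returned alongside the counts
so recovery tests never have to re-derive them.

Two factory configurations emulate the two analysis datasets of the source
evidence base: a 19-study complete design over {fluorescence, visual,
imaging} at 66% prevalence (~2,850 sites), and a 64-study incomplete network
over all five technologies at 70% prevalence (~24,600 sites).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError
from .study_data import ArmRecord, StudyTable
from .within_person import WithinPersonParams, build_covariance


@dataclass
class SimulationConfig:
    """Configuration of one simulated study network.

    ``covariance`` is either a full 2T x 2T matrix (interleaved
    [se_1, sp_1, se_2, sp_2, ...] ordering) or the hierarchical components
    dict {tau_se, sigma_se, tau_sp, sigma_sp, rho_c} of the shared-heterogeneity
    decomposition.  ``subset_probs`` (incomplete designs) maps technology
    subsets (size >= 2) to probabilities; alternatively ``subset_size_probs``
    gives a distribution over subset sizes with uniform choice of subsets.
    """

    n_studies: int
    technologies: tuple
    mu_se: dict
    mu_sp: dict
    prevalence: float
    site_count_range: tuple
    seed: int = 0
    design: str = "complete"
    subset_probs: dict | None = None
    subset_size_probs: dict | None = None
    covariance: object = None

    def __post_init__(self):
        self.technologies = tuple(self.technologies)
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError("prevalence must lie strictly inside (0, 1)")
        lo, hi = self.site_count_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ConfigError("site_count_range must be a pair of integers")
        if lo > hi or lo < 2:
            raise ConfigError("site_count_range must satisfy 2 <= low <= high")
        if self.design not in ("complete", "incomplete"):
            raise ConfigError("design must be 'complete' or 'incomplete'")
        missing = [t for t in self.technologies if t not in self.mu_se or t not in self.mu_sp]
        if missing:
            raise ConfigError(f"mu_se/mu_sp missing technologies: {missing}")

    def full_covariance(self) -> np.ndarray:
        """Resolve the configured covariance to an explicit 2T x 2T matrix."""
        T = len(self.technologies)
        if isinstance(self.covariance, dict):
            params = WithinPersonParams(
                variant="M3",
                technologies=self.technologies,
                mu_se=[self.mu_se[t] for t in self.technologies],
                mu_sp=[self.mu_sp[t] for t in self.technologies],
                **self.covariance,
            )
            return build_covariance("M3", params)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2 * T, 2 * T):
            raise ConfigError("covariance matrix must be 2T x 2T")
        if not np.allclose(cov, cov.T):
            raise ConfigError("covariance must be symmetric")
        eigmin = np.min(np.linalg.eigvalsh(cov))
        if eigmin < -1e-10:
            raise ConfigError("covariance must be positive semi-definite")
        return cov


def assign_incomplete_design(config: SimulationConfig, rng=None) -> list:
    """Draw one technology subset per study.

    Deterministic given the seed; marginal subset frequencies follow the
    configured distribution (multinomial sampling).  Every subset must have
    size >= 2 -- a single-technology arm cannot contribute to a comparative
    network.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.subset_probs is not None:
        subsets = [tuple(s) for s in config.subset_probs]
        probs = np.array([config.subset_probs[s] for s in config.subset_probs], float)
    elif config.subset_size_probs is not None:
        from itertools import combinations

        sizes = sorted(config.subset_size_probs)
        subsets, probs = [], []
        for size in sizes:
            combos = list(combinations(config.technologies, size))
            for c in combos:
                subsets.append(c)
                probs.append(config.subset_size_probs[size] / len(combos))
        probs = np.array(probs, float)
    else:
        raise ConfigError("incomplete design needs subset_probs or subset_size_probs")
    for s in subsets:
        if len(s) < 2:
            raise ConfigError(f"subset {s} has size < 2")
        unknown = set(s) - set(config.technologies)
        if unknown:
            raise ConfigError(f"subset {s} uses unknown technologies {unknown}")
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ConfigError("subset probabilities must be non-negative and sum > 0")
    probs = probs / probs.sum()
    idx = rng.choice(len(subsets), size=config.n_studies, p=probs)
    return [subsets[i] for i in idx]


def simulate_study_table(config: SimulationConfig):
    """Simulate a study network; returns (StudyTable, truths DataFrame).

    Per study i: total sites N_i ~ Uniform(site_count_range); diseased margin
    n_D ~ Binomial(N_i, prevalence) with resampling while either margin is
    zero (keeps the margin invariants exact rather than clamping); stacked
    random effects nu_i ~ N(0, Sigma); per assigned technology t,
    Se_it = expit(mu_se[t] + nu_se_it), tp ~ Binomial(n_D, Se_it), and
    analogously for specificity on the sound margin.  The same margins are
    shared by every technology within a study (within-person design).
    """
    rng = np.random.default_rng(config.seed)
    T = len(config.technologies)
    cov = config.full_covariance()
    # allow degenerate (zero-variance) components
    jitter = 1e-12 * np.eye(2 * T)
    chol = np.linalg.cholesky(cov + jitter)
    if config.design == "complete":
        assignments = [config.technologies] * config.n_studies
    else:
        assignments = assign_incomplete_design(config, rng=rng)

    lo, hi = config.site_count_range
    mu_se = np.array([config.mu_se[t] for t in config.technologies])
    mu_sp = np.array([config.mu_sp[t] for t in config.technologies])

    arms, truth_rows = [], []
    for i, assigned in enumerate(assignments):
        sid = f"study_{i + 1:03d}"
        n_total = int(rng.integers(lo, hi + 1))
        while True:
            n_dis = int(rng.binomial(n_total, config.prevalence))
            if 0 < n_dis < n_total:
                break
        n_sound = n_total - n_dis
        nu = chol @ rng.standard_normal(2 * T)
        for t, tech in enumerate(config.technologies):
            if tech not in assigned:
                continue
            se = float(expit(mu_se[t] + nu[2 * t]))
            sp = float(expit(mu_sp[t] + nu[2 * t + 1]))
            tp = int(rng.binomial(n_dis, se))
            tn = int(rng.binomial(n_sound, sp))
            arms.append(
                ArmRecord(
                    study_id=sid,
                    technology=tech,
                    tp=tp,
                    fp=n_sound - tn,
                    fn=n_dis - tp,
                    tn=tn,
                )
            )
            truth_rows.append(
                {
                    "study_id": sid,
                    "technology": tech,
                    "se_true": se,
                    "sp_true": sp,
                    "nu_se": float(nu[2 * t]),
                    "nu_sp": float(nu[2 * t + 1]),
                    "n_diseased": n_dis,
                    "n_sound": n_sound,
                }
            )
    return StudyTable(arms), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Factory configurations emulating the two analysis datasets
# ---------------------------------------------------------------------------

#: Heterogeneity components for the within-person generator.  Total logit-scale
#: SD ~ 1.56 per margin reproduces prediction intervals spanning roughly
#: (0.1, 0.98) around a summary point of 0.7-0.9, and the tau/sigma split
#: gives intrastudy correlations near 0.4 (Se) and 0.48 (Sp).  rho_c is the
#: usual negative Se/Sp trade-off of DTA meta-analysis.
ANALYSIS1_HETEROGENEITY = {
    "tau_se": 1.0,
    "sigma_se": 1.2,
    "tau_sp": 1.05,
    "sigma_sp": 1.1,
    "rho_c": -0.4,
}

#: Analysis-1 summary operating points (logit scale) used as generator truth.
ANALYSIS1_MU = {
    "se": {"fluorescence": float(logit(0.71)), "visual": float(logit(0.82)), "imaging": float(logit(0.48))},
    "sp": {"fluorescence": float(logit(0.88)), "visual": float(logit(0.85)), "imaging": float(logit(0.92))},
}

#: Analysis-2 summary operating points (logit scale) for the 5-technology network.
ANALYSIS2_MU = {
    "se": {
        "visual": float(logit(0.83)),
        "fluorescence": float(logit(0.76)),
        "imaging": float(logit(0.50)),
        "electrical": float(logit(0.83)),
        "transillumination_oct": float(logit(0.76)),
    },
    "sp": {
        "visual": float(logit(0.81)),
        "fluorescence": float(logit(0.83)),
        "imaging": float(logit(0.89)),
        "electrical": float(logit(0.72)),
        "transillumination_oct": float(logit(0.82)),
    },
}

#: Shared NMA heterogeneity (M2-NMA): one SD pair and correlation for all
#: technologies, sized to match the breadth of the published prediction
#: intervals.
ANALYSIS2_HETEROGENEITY = {"s_se": 1.2, "s_sp": 1.2, "rho": -0.4}

#: Subset mix for the 64-study network: the fluorescence/visual/imaging triple
#: dominates (it is the configuration behind the within-person analysis), the
#: remaining mass spreads over pairs, with electrical and transillumination
#: the least-studied technologies.
ANALYSIS2_SUBSET_PROBS = {
    ("fluorescence", "visual", "imaging"): 0.30,
    ("fluorescence", "visual"): 0.16,
    ("fluorescence", "imaging"): 0.12,
    ("visual", "imaging"): 0.12,
    ("visual", "transillumination_oct"): 0.08,
    ("fluorescence", "transillumination_oct"): 0.06,
    ("visual", "electrical"): 0.06,
    ("fluorescence", "electrical"): 0.05,
    ("imaging", "electrical", "transillumination_oct"): 0.05,
}


def analysis1_config(seed: int = 0, n_studies: int = 19) -> SimulationConfig:
    """Within-person emulation: complete 3-technology design, 66% prevalence,
    ~150 sites per study (19 x 150 ~ 2,850 sites)."""
    return SimulationConfig(
        n_studies=n_studies,
        technologies=("fluorescence", "visual", "imaging"),
        mu_se=ANALYSIS1_MU["se"],
        mu_sp=ANALYSIS1_MU["sp"],
        prevalence=0.66,
        site_count_range=(50, 250),
        seed=seed,
        design="complete",
        covariance=dict(ANALYSIS1_HETEROGENEITY),
    )


def analysis2_config(seed: int = 0, n_studies: int = 64) -> SimulationConfig:
    """NMA emulation: incomplete 5-technology network, 70% prevalence,
    ~385 sites per study (64 studies ~ 24,600 sites)."""
    techs = ("visual", "fluorescence", "imaging", "electrical", "transillumination_oct")
    T = len(techs)
    h = ANALYSIS2_HETEROGENEITY
    cov = np.zeros((2 * T, 2 * T))
    for t in range(T):
        cov[2 * t, 2 * t] = h["s_se"] ** 2
        cov[2 * t + 1, 2 * t + 1] = h["s_sp"] ** 2
        cov[2 * t, 2 * t + 1] = cov[2 * t + 1, 2 * t] = h["rho"] * h["s_se"] * h["s_sp"]
    return SimulationConfig(
        n_studies=n_studies,
        technologies=techs,
        mu_se=ANALYSIS2_MU["se"],
        mu_sp=ANALYSIS2_MU["sp"],
        prevalence=0.70,
        site_count_range=(120, 650),
        seed=seed,
        design="incomplete",
        subset_probs=dict(ANALYSIS2_SUBSET_PROBS),
        covariance=cov,
    )
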