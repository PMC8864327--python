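"""Posterior summaries: operating points, intervals, regions, consequences.

Turns fitted draws into the reported quantities: summary sensitivity and
specificity points (posterior medians) with 95% equal-tailed credible
intervals and 95% prediction intervals (the accuracy a future study can be
expected to show, obtained by pushing a fresh random effect through each
posterior draw); pairwise differences on the probability scale; the
intrastudy correlation coefficient of the shared-heterogeneity model;
summary-ROC credible and prediction regions; per-1,000 consequence tables at
a chosen prevalence; and threshold-stratified bivariate fits.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ModelSpecError
from .inference import PosteriorDraws, SamplerSettings, fit
from .study_data import StudyTable


@dataclass
class AccuracySummary:
    technology: str
    se_point: float
    sp_point: float
    se_cri: tuple
    sp_cri: tuple
    se_pri: tuple
    sp_pri: tuple


@dataclass
class PairwiseDifference:
    pair: tuple
    dse_mean: float
    dse_cri: tuple
    dsp_mean: float
    dsp_cri: tuple


@dataclass
class ConsequencesRow:
    technology: str
    prevalence: float
    cohort: int
    tp: int
    fn: int
    tn: int
    fp: int
    tp_ci: tuple | None = None
    fn_ci: tuple | None = None
    tn_ci: tuple | None = None
    fp_ci: tuple | None = None


@dataclass
class RocRegion:
    technology: str
    summary_point: tuple  # (1 - Sp, Se)
    credible_contour: np.ndarray  # (n, 2) closed polygon in (1-Sp, Se)
    prediction_contour: np.ndarray
    study_points: np.ndarray | None = None  # observed (1-Sp, Se) per study
    study_groups: list = field(default_factory=list)  # study ids for linked plots


def _predictive_logits(draws: PosteriorDraws, technology: str, rng) -> np.ndarray:
    """One new-study (logit-Se, logit-Sp) draw per posterior draw."""
    t = draws.tech_idx(technology)
    mu = np.stack(
        [draws.flat("mu_se")[:, t], draws.flat("mu_sp")[:, t]], axis=-1
    )  # (M, 2)
    cov = draws.tech_cov(technology)
    # sample via per-draw Cholesky of the 2x2 (closed form)
    a = np.sqrt(np.maximum(cov[:, 0, 0], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(a > 0, cov[:, 0, 1] / np.where(a > 0, a, 1.0), 0.0)
    c = np.sqrt(np.maximum(cov[:, 1, 1] - b**2, 0.0))
    z = rng.standard_normal(mu.shape)
    out = np.empty_like(mu)
    out[:, 0] = mu[:, 0] + a * z[:, 0]
    out[:, 1] = mu[:, 1] + b * z[:, 0] + c * z[:, 1]
    return out


def summarize(draws: PosteriorDraws, seed: int = 0) -> list:
    """Summary operating points with 95% CrI and 95% PrI per technology.

    Points are posterior medians of expit(mu); credible intervals are the
    2.5/97.5 posterior percentiles; prediction intervals apply the same
    percentiles to predictive new-study draws (one fresh random-effect
    vector per posterior draw, sampled from that draw's between-study
    covariance).
    """
    rng = np.random.default_rng(seed)
    out = []
    for tech in draws.technologies:
        se = expit(draws.flat("mu_se", tech))
        sp = expit(draws.flat("mu_sp", tech))
        pred = expit(_predictive_logits(draws, tech, rng))
        out.append(
            AccuracySummary(
                technology=tech,
                se_point=float(np.median(se)),
                sp_point=float(np.median(sp)),
                se_cri=tuple(np.percentile(se, [2.5, 97.5])),
                sp_cri=tuple(np.percentile(sp, [2.5, 97.5])),
                se_pri=tuple(np.percentile(pred[:, 0], [2.5, 97.5])),
                sp_pri=tuple(np.percentile(pred[:, 1], [2.5, 97.5])),
            )
        )
    return out


def pairwise_differences(draws: PosteriorDraws, pairs=None) -> list:
    """Posterior mean and 95% CrI of (dSe, dSp) for each technology pair."""
    from .network import pooled_comparisons

    if pairs is None:
        techs = draws.technologies
        pairs = [(a, b) for i, a in enumerate(techs) for b in techs[i + 1 :]]
    out = []
    for pair in pairs:
        dse, dsp = pooled_comparisons(draws, pair)
        out.append(
            PairwiseDifference(
                pair=tuple(pair),
                dse_mean=float(np.mean(dse)),
                dse_cri=tuple(np.percentile(dse, [2.5, 97.5])),
                dsp_mean=float(np.mean(dsp)),
                dsp_cri=tuple(np.percentile(dsp, [2.5, 97.5])),
            )
        )
    return out


def intrastudy_icc(draws: PosteriorDraws) -> dict:
    """Posterior of the intrastudy correlation coefficient (M3 only).

    ICC = tau^2 / (tau^2 + sigma^2) per margin: the share of logit-scale
    variability attributable to between-study (rather than study-by-test)
    variation.
    """
    if draws.model != "M3":
        raise ModelSpecError("the intrastudy correlation is defined by the M3 fit")
    out = {}
    for margin in ("se", "sp"):
        tau = draws.flat(f"tau_{margin}")
        sigma = draws.flat(f"sigma_{margin}")
        icc = tau**2 / (tau**2 + sigma**2)
        out[f"icc_{margin}"] = {
            "median": float(np.median(icc)),
            "cri": tuple(np.percentile(icc, [2.5, 97.5])),
            "draws": icc,
        }
    return out


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def consequences_per_1000(
    technology: str,
    se_point: float,
    sp_point: float,
    prevalence: float,
    se_cri=None,
    sp_cri=None,
    cohort: int = 1000,
) -> ConsequencesRow:
    """Absolute consequences per ``cohort`` sites at a given prevalence.

    D = round(N * p) diseased sites; TP = round(D * Se), FN = D - TP;
    S = N - D sound sites; TN = round(S * Sp), FP = S - TN.  Interval
    columns apply the same maps to the credible-interval endpoints
    (order-reversing for FN and FP).
    """
    for name, v in (("se", se_point), ("sp", sp_point), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    D = round_half_away(cohort * prevalence)
    S = cohort - D
    tp = round_half_away(D * se_point)
    tn = round_half_away(S * sp_point)
    row = ConsequencesRow(
        technology=technology,
        prevalence=prevalence,
        cohort=cohort,
        tp=tp,
        fn=D - tp,
        tn=tn,
        fp=S - tn,
    )
    if se_cri is not None:
        lo, hi = (round_half_away(D * v) for v in se_cri)
        row.tp_ci = (lo, hi)
        row.fn_ci = (D - hi, D - lo)
    if sp_cri is not None:
        lo, hi = (round_half_away(S * v) for v in sp_cri)
        row.tn_ci = (lo, hi)
        row.fp_ci = (S - hi, S - lo)
    return row


def _depth_contour(points: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Convex contour of the deepest draws, calibrated to in-sample level.

    Depth is Mahalanobis distance to the point cloud's mean; the contour is
    the convex hull of the retained points -- a kernel-free construction
    that is deterministic given the draws.  Because the hull of a finite
    subset shaves area off the true depth region, the depth cutoff is
    stepped up until the hull actually contains ``level`` of all draws.
    """
    from matplotlib.path import Path
    from scipy.spatial import ConvexHull

    if np.allclose(points.std(axis=0), 0.0):
        return np.repeat(points[:1], 4, axis=0)
    mean = points.mean(axis=0)
    cov = np.atleast_2d(np.cov(points.T)) + 1e-12 * np.eye(2)
    prec = np.linalg.inv(cov)
    delta = points - mean
    maha = np.einsum("ni,ij,nj->n", delta, prec, delta)

    def _hull(q):
        kept = points[maha <= np.quantile(maha, q)]
        if kept.shape[0] < 3 or np.allclose(kept.std(axis=0), 0.0):
            return None
        poly = kept[ConvexHull(kept).vertices]
        return np.vstack([poly, poly[:1]])  # closed

    poly = _hull(level)
    if poly is None:
        return np.repeat(points[:1], 4, axis=0)
    # calibrate: enlarge the cutoff until in-sample containment reaches level
    for q in np.linspace(level, 1.0, 26):
        cand = _hull(q)
        if cand is None:
            continue
        poly = cand
        if Path(poly).contains_points(points).mean() >= level:
            break
    return poly


def contour_contains(contour: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Boolean mask: which points fall inside a closed polygon."""
    from matplotlib.path import Path

    if np.allclose(contour.std(axis=0), 0.0):
        return np.all(np.isclose(points, contour[0]), axis=1)
    return Path(contour).contains_points(points)


def roc_regions(
    draws: PosteriorDraws, table: StudyTable | None = None, seed: int = 0
) -> list:
    """Summary-ROC credible and prediction regions per technology.

    Both regions are built on the logit scale from ranked Mahalanobis depth
    (the central 95% of draws, wrapped in a convex contour) and mapped to
    (1 - Sp, Se) coordinates.  The credible region uses the posterior draws
    of the summary means; the prediction region uses predictive new-study
    draws.  When a table is supplied, observed study points are attached,
    grouped by study for linked within-person plots.
    """
    rng = np.random.default_rng(seed)
    n = draws.n_chains * draws.n_draws
    if n < 500:
        warnings.warn(
            f"only {n} draws available: region contours may be unstable",
            stacklevel=2,
        )
    out = []
    for tech in draws.technologies:
        mu = np.stack(
            [draws.flat("mu_se", tech), draws.flat("mu_sp", tech)], axis=-1
        )
        pred = _predictive_logits(draws, tech, rng)

        def _to_roc(logits):
            return np.stack(
                [1.0 - expit(logits[:, 1]), expit(logits[:, 0])], axis=-1
            )

        cred = _depth_contour(mu)
        predc = _depth_contour(pred)
        point = (
            float(1.0 - expit(np.median(mu[:, 1]))),
            float(expit(np.median(mu[:, 0]))),
        )
        study_points = None
        groups = []
        if table is not None:
            pts = []
            for arm in table.arms:
                if arm.technology != tech:
                    continue
                pts.append(
                    (arm.fp / arm.n_sound, arm.tp / arm.n_diseased, arm.study_id)
                )
            if pts:
                study_points = np.array([(x, y) for x, y, _ in pts])
                groups = [sid for _, _, sid in pts]
        out.append(
            RocRegion(
                technology=tech,
                summary_point=point,
                credible_contour=_to_roc(cred),
                prediction_contour=_to_roc(predc),
                study_points=study_points,
                study_groups=groups,
            )
        )
    return out


@dataclass
class ThresholdBinResult:
    bin_interval: tuple
    n_studies: int
    low_information: bool
    summary: AccuracySummary | None


def threshold_stratified_fit(
    table: StudyTable,
    bin_edges,
    prior_config=None,
    settings: SamplerSettings | None = None,
) -> list:
    """Series of independent bivariate fits, stratified by positivity threshold.

    The table must be restricted to one technology whose arms carry numeric
    thresholds; arms without a parsable threshold are excluded with a
    warning.  Bins are [e_k, e_{k+1}) with the last bin closed.  Bins with
    fewer than 3 studies are flagged low-information; empty bins are flagged
    and not fitted.
    """
    techs = set(table.technologies)
    if len(techs) != 1:
        raise ModelSpecError(
            f"threshold stratification applies to one technology, got {sorted(techs)}"
        )
    edges = np.asarray(bin_edges, float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D sequence")
    usable, excluded = [], []
    for arm in table.arms:
        try:
            thr = float(arm.threshold)
        except (TypeError, ValueError):
            excluded.append(arm.key)
            continue
        usable.append((thr, arm))
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} arm(s) without numeric thresholds: {excluded}",
            stacklevel=2,
        )
    results = []
    settings = settings or SamplerSettings()
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        last = k == len(edges) - 2
        arms = [
            a for thr, a in usable if (lo <= thr < hi) or (last and thr == hi)
        ]
        if not arms:
            results.append(ThresholdBinResult((lo, hi), 0, True, None))
            continue
        sub = StudyTable(arms)
        n_studies = len(sub.study_ids)
        draws = fit("bivariate", sub, prior_config, settings)
        summary = summarize(draws, seed=settings.seed)[0]
        results.append(
            ThresholdBinResult((lo, hi), n_studies, n_studies < 3, summary)
        )
    return results
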