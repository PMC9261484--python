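"""Stable-isotope niche computations.

δ-notation, lipid screening by C/N ratio, baseline-referenced trophic
position, Layman community metrics, standard ellipse areas (with the
small-sample correction and a Bayesian posterior), and the directional
probabilistic overlap of bivariate-normal niche regions.

The bivariate sample (δ13C, δ15N) of a group of fish is summarized two
ways. Geometrically: isotopic ranges (CR, NR), convex-hull total area
(TA), mean distance to the centroid (CD) and nearest-neighbour distance
statistics (MNND, SDNND). Parametrically: the standard ellipse area
SEA = π √(λ1 λ2) of the sample covariance (eigenvalues λ), corrected for
small n as SEAc = SEA (n−1)/(n−2), with a posterior over SEA obtained
from a conjugate Normal–inverse-Wishart model.

Niche-region overlap follows the probabilistic (nicheROVER-style)
definition: for a posterior draw of both groups' normal parameters, the
overlap of A onto B is the probability mass of A's distribution that
falls inside B's α-level elliptical niche region (the χ²(2) contour at
mass α). It is directional: A→B need not equal B→A.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, invwishart

logger = logging.getLogger(__name__)

__all__ = [
    "TrophicPositionParams",
    "NicheSummary",
    "NicheOverlapResult",
    "delta_value",
    "screen_cn",
    "match_baseline",
    "trophic_position",
    "layman_metrics",
    "standard_ellipse",
    "bayesian_sea",
    "niche_region_overlap",
    "niche_summary",
]


@dataclass
class TrophicPositionParams:
    """Trophic-position model constants.

    ``tdf`` is the trophic discrimination factor: the per-trophic-level
    δ15N enrichment, 3.4‰ by convention. ``tp_base`` is the trophic
    level assigned to the baseline resource (1 for primary resources
    such as sediment organic matter).
    """

    tdf: float = 3.4
    tp_base: float = 1.0

    def __post_init__(self) -> None:
        if self.tdf <= 0:
            raise ValueError("tdf must be positive")


@dataclass
class NicheSummary:
    """Layman geometry plus ellipse areas for one group of fish."""

    group_key: tuple
    n: int
    mean13C: float
    mean15N: float
    NR: float
    CR: float
    TA: float
    CD: float
    MNND: float
    SDNND: float
    SEA: float | None = None
    SEAc: float | None = None
    sea_posterior: np.ndarray | None = field(default=None, repr=False)


@dataclass
class NicheOverlapResult:
    """Directional posterior niche-region overlap (percent scale)."""

    from_group: str
    to_group: str
    alpha: float
    posterior_mean: float
    credible_interval: tuple[float, float]
    n_iter: int


def delta_value(r_sample, r_standard) -> float:
    """δ notation: ((R_sample / R_standard) − 1) × 1000, in ‰."""
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_standard <= 0):
        raise ValueError("standard isotope ratio must be positive")
    return (np.asarray(r_sample, dtype=float) / r_standard - 1.0) * 1000.0


def screen_cn(records: pd.DataFrame, threshold: float = 4.0):
    """Split isotope records into (kept, excluded) by C/N ratio.

    Records strictly above the threshold are excluded (high C/N marks
    lipid-rich tissue that biases δ13C); records without a C/N ratio are
    kept with a warning.
    """
    cn = records.get("cn_ratio")
    if cn is None:
        warnings.warn("no cn_ratio column; keeping all records unscreened")
        return records.copy(), records.iloc[0:0].copy()
    missing = cn.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} isotope records lack a C/N ratio; kept unscreened")
    excluded = records[cn.notna() & (cn > threshold)]
    kept = records.drop(index=excluded.index)
    return kept.copy(), excluded.copy()


def match_baseline(
    baselines: pd.DataFrame,
    estuary: str,
    station: str | None = None,
    season: str | None = None,
) -> tuple[float, float, str]:
    """Find the δ15N baseline for a fish's sampling context.

    Precedence: exact (estuary, station, season) match, then the
    (estuary, season) mean, then the estuary mean. Each fallback is
    logged, because it averages baselines over positions the study
    measured separately.

    Returns ``(delta15N_base, tp_base, level)`` where ``level`` names the
    precedence level used.
    """
    if baselines is None or not len(baselines):
        raise LookupError("no baseline table available")
    sub = baselines[baselines["estuary"] == estuary]
    if not len(sub):
        raise LookupError(f"no baseline for estuary {estuary!r}")
    exact = sub[(sub["station"] == station) & (sub["season"] == season)]
    if len(exact):
        row = exact.iloc[0]
        return float(row["delta15N_base"]), float(row.get("tp_base", 1.0)), "estuary-station-season"
    by_season = sub[sub["season"] == season]
    if len(by_season):
        logger.info("baseline fallback to (estuary, season) mean for %s/%s", estuary, season)
        return (
            float(by_season["delta15N_base"].mean()),
            float(by_season.get("tp_base", pd.Series([1.0])).mean()),
            "estuary-season",
        )
    logger.info("baseline fallback to estuary mean for %s", estuary)
    return (
        float(sub["delta15N_base"].mean()),
        float(sub.get("tp_base", pd.Series([1.0])).mean()),
        "estuary",
    )


def trophic_position(
    delta15N,
    baseline: tuple[float, float] | float,
    params: TrophicPositionParams | None = None,
):
    """TP = TP_base + (δ15N − δ15N_base) / TDF.

    ``baseline`` is either a bare δ15N_base (the params' ``tp_base``
    applies) or a ``(delta15N_base, tp_base)`` pair as returned by
    :func:`match_baseline`.
    """
    params = params or TrophicPositionParams()
    if isinstance(baseline, tuple):
        d15n_base, tp_base = baseline[0], baseline[1]
    else:
        d15n_base, tp_base = float(baseline), params.tp_base
    return tp_base + (np.asarray(delta15N, dtype=float) - d15n_base) / params.tdf


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (δ13C, δ15N)")
    return pts


def layman_metrics(points) -> dict[str, float]:
    """Community-wide geometry of a bivariate isotope sample.

    NR/CR are the δ15N and δ13C ranges, TA the convex-hull area (0 for
    collinear points), CD the mean Euclidean distance to the centroid,
    and MNND/SDNND the mean and SD of nearest-neighbour distances.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError("at least two points are required")
    cr = float(np.ptp(pts[:, 0]))
    nr = float(np.ptp(pts[:, 1]))
    centroid = pts.mean(axis=0)
    cd = float(np.linalg.norm(pts - centroid, axis=1).mean())
    dist = squareform(pdist(pts))
    np.fill_diagonal(dist, np.inf)
    nnd = dist.min(axis=1)
    ta = 0.0
    if n >= 3:
        try:
            ta = float(ConvexHull(pts).volume)  # 2-D "volume" is the area
        except QhullError:
            ta = 0.0  # collinear sample: a degenerate flat hull
    return {
        "n": n,
        "mean13C": float(centroid[0]),
        "mean15N": float(centroid[1]),
        "NR": nr,
        "CR": cr,
        "TA": ta,
        "CD": cd,
        "MNND": float(nnd.mean()),
        "SDNND": float(nnd.std(ddof=0)),
    }


def standard_ellipse(points) -> tuple[float, float]:
    """Standard ellipse area SEA = π √(λ1 λ2) and its SEAc correction.

    λ are the eigenvalues of the 2×2 sample covariance (n−1 denominator);
    SEAc = SEA (n−1)/(n−2) counteracts the small-sample downward bias.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 3:
        raise ValueError("at least three points are required for an ellipse")
    cov = np.cov(pts, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0 or not np.isfinite(det):
        raise ValueError("degenerate (singular) sample covariance")
    sea = float(np.pi * np.sqrt(det))
    seac = sea * (n - 1) / (n - 2)
    return sea, seac


# Vague Normal–inverse-Wishart prior for the bivariate isotope model:
# prior df just proper in 2-D, prior scale a small multiple of the
# identity (per mil squared), and a near-zero prior precision on the
# mean so the data dominate.
NIW_PRIOR_DF = 3.0
NIW_PRIOR_SCALE = 0.01
NIW_PRIOR_KAPPA = 1e-3


def _niw_posterior(pts: np.ndarray):
    n = len(pts)
    xbar = pts.mean(axis=0)
    scatter = (pts - xbar).T @ (pts - xbar)
    kappa_n = NIW_PRIOR_KAPPA + n
    nu_n = NIW_PRIOR_DF + n
    # prior mean zero; the kappa terms are negligible by construction
    psi_n = NIW_PRIOR_SCALE * np.eye(2) + scatter + (NIW_PRIOR_KAPPA * n / kappa_n) * np.outer(xbar, xbar)
    mu_n = xbar * n / kappa_n
    return mu_n, kappa_n, nu_n, psi_n


def _posterior_draws(pts: np.ndarray, n_iter: int, rng: np.random.Generator):
    """Draw (mu, Sigma) from the NIW posterior; Sigma as (n_iter, 2, 2)."""
    mu_n, kappa_n, nu_n, psi_n = _niw_posterior(pts)
    sigmas = invwishart.rvs(df=nu_n, scale=psi_n, size=n_iter, random_state=rng)
    sigmas = np.asarray(sigmas).reshape(n_iter, 2, 2)
    chol = np.linalg.cholesky(sigmas / kappa_n)
    z = rng.standard_normal((n_iter, 2))
    mus = mu_n + np.einsum("nij,nj->ni", chol, z)
    return mus, sigmas


def bayesian_sea(points, n_iter: int = 10_000, seed=None) -> np.ndarray:
    """Posterior sample of the standard ellipse area.

    The covariance posterior is the conjugate inverse-Wishart under the
    module's vague Normal–inverse-Wishart prior; each draw Σ maps to the
    ellipse area π √det(Σ). Reproducible under a fixed seed.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise ValueError("at least three points are required")
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    _, sigmas = _posterior_draws(pts, n_iter, rng)
    return np.pi * np.sqrt(np.linalg.det(sigmas))


def _overlap_one_direction(draws_a, draws_b, alpha, n_mc, rng):
    """Per-draw MC mass of A's normal inside B's alpha niche region."""
    mus_a, sigmas_a = draws_a
    mus_b, sigmas_b = draws_b
    n_iter = len(mus_a)
    radius2 = chi2.ppf(alpha, df=2)
    chol_a = np.linalg.cholesky(sigmas_a)
    z = rng.standard_normal((n_iter, n_mc, 2))
    x = mus_a[:, None, :] + np.einsum("nij,nmj->nmi", chol_a, z)
    diff = x - mus_b[:, None, :]
    inv_b = np.linalg.inv(sigmas_b)
    mahal2 = np.einsum("nmi,nij,nmj->nm", diff, inv_b, diff)
    return (mahal2 <= radius2).mean(axis=1)


def niche_region_overlap(
    points_a,
    points_b,
    alpha: float = 0.95,
    n_iter: int = 10_000,
    seed=None,
    n_mc: int = 200,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[NicheOverlapResult, NicheOverlapResult]:
    """Directional probabilistic overlap of two isotopic niche regions.

    For each of ``n_iter`` posterior draws of both groups' bivariate
    normal parameters, the probability mass of one group's distribution
    inside the other's α-level elliptical niche region is estimated by
    Monte Carlo (``n_mc`` points per draw). Returns the pair of results
    (A→B, B→A) on the percent scale with 95% credible intervals.
    """
    pts_a = _as_points(points_a)
    pts_b = _as_points(points_b)
    if len(pts_a) < 4 or len(pts_b) < 4:
        raise ValueError("each group needs at least four points")
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    draws_a = _posterior_draws(pts_a, n_iter, rng)
    draws_b = _posterior_draws(pts_b, n_iter, rng)
    results = []
    for (da, db), (lab_from, lab_to) in (
        ((draws_a, draws_b), labels),
        ((draws_b, draws_a), labels[::-1]),
    ):
        mass = 100.0 * _overlap_one_direction(da, db, alpha, n_mc, rng)
        low, high = np.percentile(mass, [2.5, 97.5])
        results.append(
            NicheOverlapResult(
                from_group=lab_from,
                to_group=lab_to,
                alpha=alpha,
                posterior_mean=float(mass.mean()),
                credible_interval=(float(low), float(high)),
                n_iter=n_iter,
            )
        )
    return results[0], results[1]


def niche_summary(points, group_key: tuple = (), n_iter: int = 0, seed=None) -> NicheSummary:
    """Full niche summary: Layman geometry plus (optionally Bayesian) SEA."""
    pts = _as_points(points)
    geom = layman_metrics(pts)
    sea = seac = None
    posterior = None
    if len(pts) >= 3:
        try:
            sea, seac = standard_ellipse(pts)
        except ValueError:
            sea = seac = None
        if sea is not None and n_iter > 0:
            posterior = bayesian_sea(pts, n_iter=n_iter, seed=seed)
    return NicheSummary(
        group_key=tuple(group_key),
        n=geom["n"],
        mean13C=geom["mean13C"],
        mean15N=geom["mean15N"],
        NR=geom["NR"],
        CR=geom["CR"],
        TA=geom["TA"],
        CD=geom["CD"],
        MNND=geom["MNND"],
        SDNND=geom["SDNND"],
        SEA=sea,
        SEAc=seac,
        sea_posterior=posterior,
    )
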