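"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized instruments (``status`` included or
proxy-substituted) carrying per-variant exposure effects ``beta_exposure``
(``b_x``), outcome effects ``beta_outcome`` (``b_y``) and their standard
errors.  The causal effect ``theta`` is the change in outcome per unit
exposure; for a binary outcome it is a log odds ratio.

Implemented methods and their robustness trade-offs:

* Wald ratio — single-instrument estimate ``b_y / b_x``;
* IVW — inverse-variance-weighted regression of ``b_y`` on ``b_x`` through
  the origin; efficient, but assumes every instrument is valid (no
  pleiotropy).  Default uses multiplicative random effects: the fixed-effect
  SE is inflated by ``sqrt(Q/(J-1))`` when heterogeneity exceeds chance;
* MR-Egger — the same regression with an intercept; the slope is consistent
  under directional pleiotropy if instrument strength is independent of the
  direct effects (InSIDE), and the intercept estimates the average
  pleiotropic effect;
* weighted median — consistent when instruments carrying at least half the
  weight are valid;
* mode-based estimate (MBE) — the mode of a kernel density of the per-SNP
  ratios; consistent when the largest homogeneous group of instruments is
  valid;
* MR-PRESSO — a residual-sum-of-squares global pleiotropy test with a
  simulated null, per-SNP outlier tests, and an outlier-corrected estimate.

Bootstrap and simulation procedures take explicit seeds and are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateWeightsError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .summary_data import HarmonizedInstrument

__all__ = [
    "MREstimate", "PleiotropyResult", "PressoResult",
    "wald_ratio", "ivw", "egger", "weighted_median", "mode_based", "mr_presso",
]


@dataclass
class MREstimate:
    """A causal-effect estimate from one method."""

    method: str
    theta: float
    se: float
    pvalue: float
    df: Union[int, Literal["normal"]]
    n_snps: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "theta": self.theta, "se": self.se,
            "pvalue": self.pvalue, "df": self.df, "n_snps": self.n_snps,
            **({"extras": self.extras} if self.extras else {}),
        }


@dataclass
class PleiotropyResult:
    """Egger intercept test: average directional pleiotropy per instrument."""

    intercept: float
    se: float
    pvalue: float
    df: int


@dataclass
class PressoResult:
    """MR-PRESSO global test, outlier tests, and corrected estimate."""

    global_rss_observed: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]
    outliers: list[str]
    raw_estimate: MREstimate
    corrected_estimate: Optional[MREstimate] = None
    distortion_pvalue: Optional[float] = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _arrays(h: Sequence[HarmonizedInstrument], minimum: int, method: str):
    use = [i for i in h if i.included]
    if len(use) < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {minimum} included instruments, got {len(use)}")
    bx = np.array([i.beta_exposure for i in use], dtype=float)
    sx = np.array([i.se_exposure for i in use], dtype=float)
    by = np.array([i.beta_outcome for i in use], dtype=float)
    sy = np.array([i.se_outcome for i in use], dtype=float)
    rsids = [i.rsid for i in use]
    return rsids, bx, sx, by, sy


def _orient(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip instruments jointly so every exposure effect is non-negative.

    Ratio-based quantities are unchanged; doing this up front makes the
    stochastic estimators bit-invariant under instrument re-orientation.
    """
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def _norm_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate ``b_y / b_x``.

    The default SE is the first-order delta approximation ``se_y / |b_x|``;
    ``second_order`` adds the exposure-uncertainty term
    ``b_y^2 se_x^2 / b_x^4`` under the square root.
    """
    if not inst.included:
        raise InsufficientInstrumentsError(f"{inst.rsid} is not an included instrument")
    bx, by = inst.beta_exposure, inst.beta_outcome
    if bx == 0:
        raise UndefinedRatioError(f"{inst.rsid}: zero exposure effect")
    theta = by / bx
    var = inst.se_outcome**2 / bx**2
    if second_order:
        var += by**2 * inst.se_exposure**2 / bx**4
    se = math.sqrt(var)
    return MREstimate("wald_ratio", theta, se, _norm_p(theta / se), "normal", 1,
                      extras={"rsid": inst.rsid, "second_order": second_order})


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


def ivw(
    h: Sequence[HarmonizedInstrument],
    model: Literal["fixed", "multiplicative_random_effects"] = "multiplicative_random_effects",
) -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression through the origin.

    ``theta = sum(w b_x b_y) / sum(w b_x^2)`` with ``w = 1/se_y^2``.  Under
    the default multiplicative-random-effects model the fixed-effect SE is
    scaled by ``max(1, sqrt(Q/(J-1)))`` so that excess heterogeneity widens,
    and can never narrow, the interval.
    """
    _, bx, _, by, sy = _arrays(h, 2, "ivw")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise DegenerateWeightsError("all weighted exposure effects are zero")
    theta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    j = len(bx)
    mult = max(1.0, math.sqrt(q / (j - 1)))
    se = se_fixed * (mult if model == "multiplicative_random_effects" else 1.0)
    return MREstimate("ivw", theta, se, _norm_p(theta / se), "normal", j,
                      extras={"model": model, "Q": q, "se_fixed": se_fixed,
                              "se_multiplier": mult})


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def egger(h: Sequence[HarmonizedInstrument]) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger regression: weighted fit of ``b_y`` on ``b_x`` with intercept.

    Instruments are first oriented so all exposure effects are positive (the
    intercept is only identified up to this convention).  The residual scale
    ``Q/(J-2)`` is floored at 1 — under-dispersion never shrinks the SEs —
    and p-values use the t distribution with ``J-2`` df.
    """
    _, bx, _, by, sy = _arrays(h, 3, "egger")
    bx, by = _orient(bx, by)
    w = 1.0 / sy**2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (x * w[:, None])
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    resid = by - x @ coef
    j = len(bx)
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (j - 2))
    cov = scale * np.linalg.inv(xtwx)
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_slope = float(2 * stats.t.sf(abs(coef[1] / se_slope), j - 2))
    p_int = float(2 * stats.t.sf(abs(coef[0] / se_int), j - 2))
    slope = MREstimate("egger", float(coef[1]), se_slope, p_slope, j - 2, j,
                       extras={"Q": q, "residual_scale": scale})
    intercept = PleiotropyResult(float(coef[0]), se_int, p_int, j - 2)
    return slope, intercept


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    Sort by theta; the standardized cumulative weight of the j-th order
    statistic is ``(cumsum(w) - w/2) / sum(w)``; the estimate interpolates
    theta linearly at cumulative weight 0.5.
    """
    total = float(np.sum(w))
    if total <= 0:
        raise DegenerateWeightsError("total weight is zero")
    order = np.argsort(theta, kind="stable")
    th, ww = theta[order], w[order]
    s = (np.cumsum(ww) - ww / 2) / total
    return float(np.interp(0.5, s, th))


def weighted_median(
    h: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 1,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratio estimates ``theta_j = b_y/b_x`` are weighted by their inverse
    first-order variance ``(b_x/se_y)^2``.  The SE is the standard deviation
    of the point estimate over ``n_boot`` resamples in which each beta is
    perturbed by its Gaussian standard error (weights held fixed).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    _, bx, sx, by, sy = _arrays(h, 3, "weighted_median")
    bx, by = _orient(bx, by)
    ratios = by / bx
    w = (bx / sy) ** 2
    theta = _weighted_median_point(ratios, w)

    rng = np.random.default_rng(seed)
    j = len(bx)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(j)
        bys = by + sy * rng.standard_normal(j)
        boots[b] = _weighted_median_point(bys / bxs, w)
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    p = _norm_p(theta / se) if se > 0 else 1.0
    return MREstimate("weighted_median", theta, se, p, "normal", j,
                      extras={"n_boot": n_boot, "seed": seed})


# ---------------------------------------------------------------------------
# mode-based estimate
# ---------------------------------------------------------------------------

_MBE_GRID = 512


def _mode_point(ratios: np.ndarray, w: np.ndarray, bandwidth: float) -> float:
    if bandwidth == 0:
        return float(ratios[0])
    lo = ratios.min() - 3 * bandwidth
    hi = ratios.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, _MBE_GRID)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bandwidth) ** 2) @ w
    return float(grid[int(np.argmax(dens))])


def _mbe_bandwidth(ratios: np.ndarray, phi: float) -> float:
    spread = min(float(np.std(ratios, ddof=1)),
                 float(stats.median_abs_deviation(ratios, scale="normal")))
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def mode_based(
    h: Sequence[HarmonizedInstrument],
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 1,
) -> MREstimate:
    """Mode-based estimate: mode of a Gaussian kernel density of the ratios.

    Bandwidth follows the modified Silverman rule
    ``phi * 0.9 * min(sd, mad) * J^(-1/5)`` (mad scaled to the normal).
    ``weighted`` uses inverse-variance weights normalized to one; otherwise
    all ratios count equally ("simple mode").  SE by seeded parametric
    bootstrap; if every ratio is identical the mode is that common value.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    _, bx, sx, by, sy = _arrays(h, 3, "mode_based")
    bx, by = _orient(bx, by)
    ratios = by / bx
    j = len(bx)
    if weighted:
        w = (bx / sy) ** 2
        if np.sum(w) <= 0:
            raise DegenerateWeightsError("total weight is zero")
        w = w / np.sum(w)
    else:
        w = np.full(j, 1.0 / j)
    bandwidth = _mbe_bandwidth(ratios, phi) if np.ptp(ratios) > 0 else 0.0
    theta = _mode_point(ratios, w, bandwidth)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(j)
        bys = by + sy * rng.standard_normal(j)
        r = bys / bxs
        bw = _mbe_bandwidth(r, phi) if np.ptp(r) > 0 else 0.0
        boots[b] = _mode_point(r, w, bw)
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    p = _norm_p(theta / se) if se > 0 else 1.0
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, theta, se, p, "normal", j,
                      extras={"phi": phi, "bandwidth": bandwidth,
                              "grid": _MBE_GRID, "n_boot": n_boot, "seed": seed})


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW estimate leaving each instrument out in turn."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    h: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 1,
    significance: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier detection, corrected estimate.

    The observed statistic is the weighted residual sum of squares
    ``RSS = sum_j w_j (b_yj - theta_(-j) b_xj)^2`` built from leave-one-out
    IVW estimates, so that an outlier cannot mask itself.  Its null
    distribution comes from ``n_sim`` parametric simulations
    ``b_y* ~ Normal(theta_(-j) b_xj, se_yj)``; per-SNP outlier p-values use
    each SNP's simulated residual distribution with Bonferroni adjustment.
    When outliers are found, the raw IVW-type estimate is recomputed without
    them and a distortion test compares the two.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rsids, bx, _, by, sy = _arrays(h, 4, "mr_presso")
    bx, by = _orient(bx, by)
    j = len(bx)
    w = 1.0 / sy**2

    def raw_fit(mask: np.ndarray, label: str) -> MREstimate:
        bxm, bym, wm = bx[mask], by[mask], w[mask]
        jm = len(bxm)
        denom = float(np.sum(wm * bxm**2))
        theta = float(np.sum(wm * bxm * bym)) / denom
        rss = float(np.sum(wm * (bym - theta * bxm) ** 2))
        se = math.sqrt(rss / (jm - 1)) * denom**-0.5
        p = float(2 * stats.t.sf(abs(theta / se), jm - 1))
        return MREstimate(label, theta, se, p, jm - 1, jm)

    raw = raw_fit(np.ones(j, bool), "presso_raw")

    loo = _loo_thetas(bx, by, w)
    obs_contrib = w * (by - loo * bx) ** 2
    rss_obs = float(np.sum(obs_contrib))

    rng = np.random.default_rng(seed)
    by_star = loo * bx + sy * rng.standard_normal((n_sim, j))
    sxy_star = by_star @ (w * bx)
    sxx = np.sum(w * bx**2)
    loo_star = (sxy_star[:, None] - (w * bx) * by_star) / (sxx - w * bx**2)
    contrib_star = w * (by_star - loo_star * bx) ** 2
    rss_star = contrib_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(contrib_star >= obs_contrib, axis=0)) / (n_sim + 1)
    adj = np.minimum(per_snp_p * j, 1.0)
    outlier_pvalues = dict(zip(rsids, adj.astype(float)))
    outlier_mask = adj < significance
    outliers = [r for r, o in zip(rsids, outlier_mask) if o]

    corrected = None
    distortion_p = None
    if outliers and j - len(outliers) >= 2:
        keep = ~outlier_mask
        corrected = raw_fit(keep, "presso_corrected")
        if corrected.theta != 0:
            d_obs = 100.0 * (raw.theta - corrected.theta) / abs(corrected.theta)
            n_out = len(outliers)
            keep_idx = np.flatnonzero(keep)
            d_null = np.empty(n_sim)
            for b in range(n_sim):
                fake = rng.choice(keep_idx, size=n_out, replace=True)
                mask = np.ones(j, bool)
                mask[fake] = False
                if mask.sum() < 2:
                    d_null[b] = 0.0
                    continue
                th_b = raw_fit(mask, "tmp").theta
                d_null[b] = (100.0 * (raw.theta - th_b) / abs(th_b)
                             if th_b != 0 else 0.0)
            distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs)))
                                 / (n_sim + 1))
    return PressoResult(
        global_rss_observed=rss_obs,
        global_pvalue=global_p,
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        raw_estimate=raw,
        corrected_estimate=corrected,
        distortion_pvalue=distortion_p,
    )
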