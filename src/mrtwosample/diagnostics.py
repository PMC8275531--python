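"""Instrument-strength, heterogeneity, influence, and plot-data diagnostics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw, wald_ratio
from .exceptions import DataError, InsufficientInstrumentsError
from .summary_data import HarmonizedInstrument


@dataclass
class HeterogeneityResult:
    """Cochran's Q for the IVW (no-intercept) or Egger (with-intercept) fit.

    Q is the weighted residual sum of squares of the fitted regression,
    referred to a chi-square with J-1 (IVW) or J-2 (Egger) degrees of
    freedom.  Large Q means the per-SNP causal estimates disagree more than
    their sampling error allows, i.e. the model does not describe all
    instruments.
    """

    model: Literal["ivw", "egger"]
    Q: float
    df: int
    pvalue: float


@dataclass
class LeaveOneOutRow:
    dropped_rsid: str
    estimate: MREstimate


@dataclass
class FunnelPoint:
    """One instrument's ratio estimate against its precision 1/se."""

    rsid: str
    ratio_estimate: float
    precision: float


def f_statistic(r2: float, n: int, k: int) -> float:
    """Multi-instrument strength: F = (R^2/(1-R^2)) * (n-k-1)/k.

    ``r2`` is the exposure variance jointly explained by the ``k``
    instruments in a study of ``n`` individuals.  F below ~10 conventionally
    flags a weak instrument.
    """
    if not (0 < r2 < 1):
        raise DataError(f"r2 must be in (0, 1), got {r2}")
    if not n > k + 1 or k < 1:
        raise DataError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    return (r2 / (1 - r2)) * (n - k - 1) / k


def _included_arrays(h: Sequence[HarmonizedInstrument], minimum: int):
    use = [i for i in h if i.included]
    if len(use) < minimum:
        raise InsufficientInstrumentsError(
            f"need >= {minimum} included instruments, got {len(use)}")
    bx = np.array([i.beta_exposure for i in use])
    by = np.array([i.beta_outcome for i in use])
    sx = np.array([i.se_exposure for i in use])
    sy = np.array([i.se_outcome for i in use])
    return use, bx, sx, by, sy


def cochran_q(
    h: Sequence[HarmonizedInstrument],
    model: Literal["ivw", "egger"] = "egger",
) -> HeterogeneityResult:
    """Heterogeneity of per-instrument causal estimates about the fitted model."""
    ddf = 1 if model == "ivw" else 2
    use, bx, _, by, sy = _included_arrays(h, ddf + 1)
    s = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * s, by * s
    w = 1.0 / sy**2
    if model == "ivw":
        theta = np.sum(w * bx * by) / np.sum(w * bx**2)
        resid = by - theta * bx
    else:
        x = np.column_stack([np.ones_like(bx), bx])
        coef = np.linalg.solve(x.T @ (x * w[:, None]), x.T @ (w * by))
        resid = by - x @ coef
    q = float(np.sum(w * resid**2))
    df = len(bx) - ddf
    return HeterogeneityResult(model, q, df, float(stats.chi2.sf(q, df)))


def leave_one_out(h: Sequence[HarmonizedInstrument]) -> list[LeaveOneOutRow]:
    """Default IVW estimate with each included instrument dropped in turn.

    A row whose estimate moves far from the full-set estimate (or crosses
    zero) identifies an instrument that single-handedly drives the result.
    """
    use, *_ = _included_arrays(h, 3)
    rows = []
    for i, inst in enumerate(use):
        subset = use[:i] + use[i + 1:]
        rows.append(LeaveOneOutRow(inst.rsid, ivw(subset)))
    return rows


def single_snp_table(h: Sequence[HarmonizedInstrument]) -> list[MREstimate]:
    """Wald ratio for every included instrument, in input order."""
    return [wald_ratio(i) for i in h if i.included]


def funnel_data(h: Sequence[HarmonizedInstrument]) -> list[FunnelPoint]:
    """Ratio estimate vs precision for a funnel plot.

    Precision is the inverse first-order SE of the ratio, ``|b_x|/se_y``.
    Asymmetry about the combined estimate suggests directional pleiotropy.
    """
    points = []
    for i in h:
        if not i.included:
            continue
        est = wald_ratio(i)
        points.append(FunnelPoint(i.rsid, est.theta, 1.0 / est.se))
    return points


def forest_table(
    h: Sequence[HarmonizedInstrument],
    summary_estimates: Sequence[MREstimate] = (),
) -> pd.DataFrame:
    """Forest-plot table: single-SNP rows first, method summary rows last."""
    rows = []
    for est in single_snp_table(h):
        rows.append({"label": est.extras["rsid"], "kind": "snp",
                     "theta": est.theta, "se": est.se, "pvalue": est.pvalue})
    for est in summary_estimates:
        rows.append({"label": est.method, "kind": "summary",
                     "theta": est.theta, "se": est.se, "pvalue": est.pvalue})
    return pd.DataFrame(rows, columns=["label", "kind", "theta", "se", "pvalue"])


def scatter_data(
    h: Sequence[HarmonizedInstrument],
    fits: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-instrument effect pairs with optional per-method fitted lines.

    ``fits`` maps a method label to (intercept, slope); the lines are
    returned in companion columns so callers can draw them without
    recomputing.  Instruments are oriented to positive exposure effects,
    matching how the with-intercept fits are estimated.
    """
    pts = []
    for i in h:
        if not i.included:
            continue
        s = -1.0 if i.beta_exposure < 0 else 1.0
        pts.append({"rsid": i.rsid,
                    "beta_exposure": s * i.beta_exposure,
                    "beta_outcome": s * i.beta_outcome,
                    "se_exposure": i.se_exposure,
                    "se_outcome": i.se_outcome})
    df = pd.DataFrame(pts, columns=["rsid", "beta_exposure", "beta_outcome",
                                    "se_exposure", "se_outcome"])
    if fits:
        for label, (a, b) in fits.items():
            df[f"fit_{label}"] = a + b * df["beta_exposure"]
    return df
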