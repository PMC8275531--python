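"""Generator of paired two-sample summary statistics with known ground truth.

The generative model is the linear structural model the estimators assume:
each instrument j has a true exposure effect ``gamma_j`` and a direct
(pleiotropic) outcome effect ``alpha_j``, and the true outcome effect is
``theta * gamma_j + alpha_j``.  Observed summary statistics add Gaussian
sampling noise at standard errors realistic for the stated sample sizes:

* exposure SE scales as ``|gamma_j| / z_gw * sqrt(n_ref / n_exposure)``
  where ``z_gw`` is the two-sided z-value at genome-wide significance, so a
  study of ``n_ref`` individuals would put a typical hit exactly at the
  threshold and larger studies clear it comfortably;
* outcome SE uses the standard GWAS approximation
  ``1 / sqrt(2 p (1-p) * N * K(1-K))`` for a binary outcome with case
  fraction K (``1 / sqrt(2 p (1-p) * N)`` for a continuous one), with p the
  effect-allele frequency.

``inside_violation`` correlates ``alpha_j`` with ``gamma_j``, breaking the
InSIDE condition that MR-Egger needs; ``palindromic_fraction`` and
``missing_in_outcome`` inject the harmonization artifacts the pipeline must
handle.  Summary statistics are drawn directly — no individual-level
genotypes — which is sufficient to exercise every analysis stage.

Defaults emulate the bundled forward study: six instruments with
25(OH)D-like effect sizes against a binary outcome of 53,293 individuals at
case fraction 0.358, one palindromic variant in six, no true causal effect
and no pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators as est
from .exceptions import DataError
from .summary_data import (
    GENOME_WIDE_P,
    InstrumentSet,
    VariantAssociation,
    harmonize,
)

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one paired-summary-statistics scenario."""

    n_snps: int = 6
    theta_true: float = 0.0
    gamma_dist: tuple[float, float] = (0.04, 0.03)
    n_exposure: int = 79_366
    n_outcome: int = 53_293
    case_fraction: Optional[float] = 0.358
    pleiotropy: tuple[float, float] = (0.0, 0.0)
    inside_violation: float = 0.0
    palindromic_fraction: float = 1 / 6
    missing_in_outcome: int = 0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    n_ref: int = 20_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise DataError("n_snps must be >= 1")
        if self.gamma_dist[1] < 0 or self.pleiotropy[1] < 0:
            raise DataError("distribution sds must be >= 0")
        if abs(self.inside_violation) > 1:
            raise DataError("inside_violation must be in [-1, 1]")
        if not (0 <= self.palindromic_fraction <= 1):
            raise DataError("palindromic_fraction must be in [0, 1]")
        if self.missing_in_outcome > self.n_snps:
            raise DataError("missing_in_outcome exceeds n_snps")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise DataError("case_fraction must be in (0, 1) or None")


def _pvalue(z: np.ndarray) -> np.ndarray:
    # two-sided, kept strictly inside (0, 1]
    return np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


def simulate_two_sample(
    s: SyntheticScenario,
) -> tuple[InstrumentSet, list[VariantAssociation], dict]:
    """Draw one paired exposure/outcome summary-statistics dataset.

    Returns ``(exposure_set, outcome_associations, truth)`` where ``truth``
    records the causal effect, per-SNP pleiotropic effects, palindromic
    flags and the rsids deleted from the outcome table.
    """
    rng = np.random.default_rng(s.seed)
    j = s.n_snps
    mu_g, sd_g = s.gamma_dist
    gamma = mu_g + sd_g * rng.standard_normal(j)
    eaf = rng.uniform(*s.eaf_range, size=j)

    z_gw = float(stats.norm.isf(GENOME_WIDE_P / 2))
    sigma_x = np.maximum(np.abs(gamma), 1e-6) / z_gw * np.sqrt(s.n_ref / s.n_exposure)
    beta_x = gamma + sigma_x * rng.standard_normal(j)

    mu_a, sd_a = s.pleiotropy
    rho = s.inside_violation
    z_ind = rng.standard_normal(j)
    if sd_g > 0 and rho != 0:
        z_g = (gamma - mu_g) / sd_g
        alpha = mu_a + sd_a * (rho * z_g + np.sqrt(1 - rho**2) * z_ind)
    else:
        alpha = mu_a + sd_a * z_ind

    geno_var = 2 * eaf * (1 - eaf)
    if s.case_fraction is not None:
        k = s.case_fraction
        sigma_y = 1.0 / np.sqrt(geno_var * s.n_outcome * k * (1 - k))
    else:
        sigma_y = 1.0 / np.sqrt(geno_var * s.n_outcome)
    beta_y = s.theta_true * gamma + alpha + sigma_y * rng.standard_normal(j)

    n_pal = int(round(s.palindromic_fraction * j))
    pal_idx = rng.choice(j, size=n_pal, replace=False)
    palindromic = np.zeros(j, bool)
    palindromic[pal_idx] = True
    alleles = []
    for i in range(j):
        pool = _PALINDROMIC_PAIRS if palindromic[i] else _NONPALINDROMIC_PAIRS
        alleles.append(pool[rng.integers(len(pool))])

    rsids = [f"rs9{s.seed % 1000:03d}{i:04d}" for i in range(j)]
    trait_y = "binary" if s.case_fraction is not None else "continuous"
    p_x = _pvalue(beta_x / sigma_x)
    p_y = _pvalue(beta_y / sigma_y)

    exposure_variants = [
        VariantAssociation(
            rsid=rsids[i], effect_allele=alleles[i][0], other_allele=alleles[i][1],
            eaf=float(eaf[i]), beta=float(beta_x[i]), se=float(sigma_x[i]),
            pvalue=float(p_x[i]), trait_type="continuous",
        )
        for i in range(j)
    ]
    missing = set(rng.choice(j, size=s.missing_in_outcome, replace=False).tolist())
    outcome = [
        VariantAssociation(
            rsid=rsids[i], effect_allele=alleles[i][0], other_allele=alleles[i][1],
            eaf=float(eaf[i]), beta=float(beta_y[i]), se=float(sigma_y[i]),
            pvalue=float(p_y[i]), trait_type=trait_y,
        )
        for i in range(j) if i not in missing
    ]
    exposure_set = InstrumentSet(
        exposure_name="synthetic_exposure",
        variants=exposure_variants,
        sample_size=s.n_exposure,
    )
    truth = {
        "theta": s.theta_true,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "palindromic": palindromic.tolist(),
        "missing_rsids": sorted(rsids[i] for i in missing),
        "seed": s.seed,
    }
    return exposure_set, outcome, truth


_ESTIMATOR_MIN = {"ivw": 2, "egger": 3, "weighted_median": 3,
                  "simple_mode": 3, "weighted_mode": 3}


def recovery_experiment(
    s: SyntheticScenario,
    n_reps: int,
    estimators: Sequence[str] = ("ivw", "egger"),
    n_boot: int = 200,
) -> pd.DataFrame:
    """Repeated simulate -> harmonize -> estimate, summarized per estimator.

    Returns one row per estimator with bias, empirical SE of the point
    estimates, mean estimated SE, 95% CI coverage of the true effect, and
    the failure count; when Egger runs, extra rows summarize the intercept
    (bias against the mean pleiotropic effect, rejection rate of the
    zero-pleiotropy test) and the Egger-model Cochran Q rejection rate.
    Replicate seeds derive deterministically from ``s.seed``.
    """
    if n_reps < 2:
        raise DataError("n_reps must be >= 2")
    from .diagnostics import cochran_q  # local import to avoid cycle

    child_seeds = np.random.SeedSequence(s.seed).generate_state(n_reps) % (2**31)
    results: dict[str, list[tuple[float, float]]] = {e: [] for e in estimators}
    failures: dict[str, int] = {e: 0 for e in estimators}
    intercepts: list[tuple[float, float, float]] = []
    q_rejects: list[bool] = []

    for r in range(n_reps):
        rep = replace(s, seed=int(child_seeds[r]))
        exposure, outcome, _ = simulate_two_sample(rep)
        included = [x for x in harmonize(exposure, outcome) if x.included]
        for name in estimators:
            try:
                if name == "ivw":
                    e = est.ivw(included)
                elif name == "egger":
                    e, pleio = est.egger(included)
                    intercepts.append((pleio.intercept, pleio.se, pleio.pvalue))
                    q_rejects.append(cochran_q(included, "egger").pvalue < 0.05)
                elif name == "weighted_median":
                    e = est.weighted_median(included, n_boot=n_boot,
                                            seed=int(child_seeds[r]))
                elif name in ("simple_mode", "weighted_mode"):
                    e = est.mode_based(included, weighted=name == "weighted_mode",
                                       n_boot=n_boot, seed=int(child_seeds[r]))
                else:
                    raise DataError(f"unknown estimator {name!r}")
                results[name].append((e.theta, e.se))
            except est.InsufficientInstrumentsError:
                failures[name] += 1

    rows = []
    for name in estimators:
        vals = np.array(results[name]) if results[name] else np.empty((0, 2))
        if len(vals):
            thetas, ses = vals[:, 0], vals[:, 1]
            cover = np.mean(np.abs(thetas - s.theta_true) <= 1.959963984540054 * ses)
            rows.append({"estimator": name, "n_ok": len(vals),
                         "bias": float(np.mean(thetas) - s.theta_true),
                         "empirical_se": float(np.std(thetas, ddof=1)),
                         "mean_se": float(np.mean(ses)),
                         "coverage": float(cover),
                         "reject_rate": float(np.mean(
                             2 * stats.norm.sf(np.abs(thetas / ses)) < 0.05)),
                         "n_failed": failures[name]})
        else:
            rows.append({"estimator": name, "n_ok": 0, "bias": np.nan,
                         "empirical_se": np.nan, "mean_se": np.nan,
                         "coverage": np.nan, "reject_rate": np.nan,
                         "n_failed": failures[name]})
    if intercepts:
        arr = np.array(intercepts)
        mu_a = s.pleiotropy[0]
        rows.append({"estimator": "egger_intercept", "n_ok": len(arr),
                     "bias": float(np.mean(arr[:, 0]) - mu_a),
                     "empirical_se": float(np.std(arr[:, 0], ddof=1)),
                     "mean_se": float(np.mean(arr[:, 1])),
                     "coverage": float(np.mean(
                         np.abs(arr[:, 0] - mu_a) <= 1.959963984540054 * arr[:, 1])),
                     "reject_rate": float(np.mean(arr[:, 2] < 0.05)),
                     "n_failed": 0})
        rows.append({"estimator": "cochran_q_egger", "n_ok": len(q_rejects),
                     "bias": np.nan, "empirical_se": np.nan, "mean_se": np.nan,
                     "coverage": np.nan,
                     "reject_rate": float(np.mean(q_rejects)), "n_failed": 0})
    return pd.DataFrame(rows).set_index("estimator")
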