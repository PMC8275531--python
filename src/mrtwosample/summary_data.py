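"""Data model for GWAS summary statistics and the steps that turn two studies
into an analysis-ready instrument set.

A two-sample Mendelian randomization analysis starts from per-variant
association records in an exposure study and an outcome study.  Getting from
those to a usable instrument set involves three decisions that this module
makes explicit and testable:

* **selection** — keep genome-wide significant, independent variants
  (conventionally p < 5e-8) as instruments;
* **proxy substitution** — when a lead variant is absent from the other
  study, substitute a variant in strong linkage disequilibrium (here
  r2 >= 0.40), preferring highest r2 and then smallest distance;
* **harmonization** — express both studies' effects on the same effect
  allele, resolving allele swaps and strand flips, and excluding palindromic
  (A/T or C/G) variants whose strand cannot be resolved.

Two transcriptions of published instrument tables (vitamin D -> ADHD and the
reverse direction) ship with the package and back the test suite; see
:func:`load_fixture`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, FixtureNotFoundError

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_PROXY_R2_MIN = 0.40
DEFAULT_PROXY_CRITERIA = ("max_r2", "min_abs_distance")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HarmonizationPolicy = Literal["drop_all_palindromic", "keep_inferable_palindromic"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantAssociation:
    """One variant's association record in one GWAS.

    ``beta`` is always on the analysis scale: for a binary trait reported as
    an odds ratio, the natural log of that odds ratio (``from_odds_ratio``
    records the conversion).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    trait_type: Literal["continuous", "binary"] = "continuous"
    gene: Optional[str] = None
    from_odds_ratio: bool = False
    proxy_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.rsid}: effect and other allele are identical")
        if not (self.se > 0):
            raise DataError(f"{self.rsid}: standard error must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise DataError(f"{self.rsid}: p-value {self.pvalue} outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise DataError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with study-level metadata.

    ``variance_explained`` (R^2) and ``sample_size`` come from the exposure
    study's report; they feed the F-statistic and power analysis, not the
    estimators themselves.
    """

    exposure_name: str
    variants: list[VariantAssociation]
    variance_explained: Optional[float] = None
    sample_size: Optional[int] = None
    p_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        rsids = [v.rsid for v in self.variants]
        if len(rsids) != len(set(rsids)):
            raise DataError(f"duplicate rsids in instrument set {self.exposure_name!r}")
        if self.p_threshold is not None:
            # Proxies inherit their lead's discovery significance, so a
            # proxy row may legitimately exceed the threshold.
            for v in self.variants:
                if v.pvalue >= self.p_threshold and v.proxy_of is None:
                    log.warning(
                        "%s: p=%.3g above selection threshold %.3g",
                        v.rsid, v.pvalue, self.p_threshold,
                    )

    def __len__(self) -> int:
        return len(self.variants)

    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]


@dataclass
class HarmonizedInstrument:
    """Exposure/outcome effect pair expressed on a common effect allele."""

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: Optional[float]
    se_outcome: Optional[float]
    effect_allele: str
    status: Literal[
        "included", "proxy_substituted",
        "excluded_palindromic", "excluded_missing", "excluded_incompatible",
    ]
    proxy_of: Optional[str] = None
    reason: Optional[str] = None

    @property
    def included(self) -> bool:
        """True for instruments the estimators may use (proxies count)."""
        return self.status in ("included", "proxy_substituted")

    def __post_init__(self) -> None:
        if self.status == "proxy_substituted" and self.proxy_of is None:
            raise DataError(f"{self.rsid}: proxy_substituted without proxy_of")
        if self.included:
            vals = (self.beta_exposure, self.se_exposure,
                    self.beta_outcome, self.se_outcome)
            if any(v is None or not math.isfinite(v) for v in vals):
                raise DataError(f"{self.rsid}: included instrument with non-finite fields")
            if self.se_exposure <= 0 or self.se_outcome <= 0:
                raise DataError(f"{self.rsid}: included instrument with non-positive SE")


@dataclass(frozen=True)
class ProxyCandidate:
    """A linkage-disequilibrium proxy for a lead variant."""

    lead_rsid: str
    proxy_rsid: str
    r2: float
    distance: int
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None
    palindromic: bool = False

    def __post_init__(self) -> None:
        if self.r2 < 0:
            raise DataError(f"proxy {self.proxy_rsid}: r2 < 0")
        if self.proxy_rsid == self.lead_rsid:
            raise DataError(f"proxy for {self.lead_rsid} is itself")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def or_to_beta(odds_ratio: float) -> float:
    """Convert an odds ratio to a log-odds effect size (natural log)."""
    if not odds_ratio > 0:
        raise DataError(f"odds ratio must be positive, got {odds_ratio}")
    return math.log(odds_ratio)


def classify_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-complementary (A/T or C/G).

    Palindromic variants read the same on both strands, so allele labels
    alone cannot establish strand alignment between two studies.  Indel
    alleles are not single-nucleotide and return False (strand logic is
    undefined for them).
    """
    a1, a2 = a1.upper(), a2.upper()
    if len(a1) != 1 or len(a2) != 1 or a1 not in _COMPLEMENT or a2 not in _COMPLEMENT:
        log.debug("palindromic check on non-SNP alleles %s/%s -> False", a1, a2)
        return False
    return _COMPLEMENT[a1] == a2


def select_instruments(
    associations: Sequence[VariantAssociation],
    p_threshold: float = GENOME_WIDE_P,
    *,
    exposure_name: str = "exposure",
    variance_explained: Optional[float] = None,
    sample_size: Optional[int] = None,
) -> InstrumentSet:
    """Keep variants significant at ``p_threshold`` as the instrument set."""
    if not (0 < p_threshold <= 1):
        raise DataError(f"p threshold {p_threshold} outside (0, 1]")
    kept = [v for v in associations if v.pvalue < p_threshold]
    if not kept:
        log.warning("no variants pass p < %.3g; estimators will refuse an empty set",
                    p_threshold)
    return InstrumentSet(
        exposure_name=exposure_name,
        variants=kept,
        variance_explained=variance_explained,
        sample_size=sample_size,
        p_threshold=p_threshold,
    )


def select_proxy(
    lead_rsid: str,
    candidates: Iterable[ProxyCandidate],
    criteria: Sequence[str] = DEFAULT_PROXY_CRITERIA,
    r2_min: float = DEFAULT_PROXY_R2_MIN,
) -> Optional[ProxyCandidate]:
    """Pick the best LD proxy for a lead variant, or None.

    Candidates below ``r2_min`` are dropped; the rest are ranked
    lexicographically by ``criteria`` (any of ``max_r2``,
    ``min_abs_distance``, ``non_palindromic``), with the proxy rsid as the
    final deterministic tie-break.
    """
    keyfuncs = {
        "max_r2": lambda c: -c.r2,
        "min_abs_distance": lambda c: abs(c.distance),
        "non_palindromic": lambda c: c.palindromic,
    }
    unknown = [k for k in criteria if k not in keyfuncs]
    if unknown:
        raise DataError(f"unknown proxy criteria {unknown}")
    pool = [c for c in candidates if c.lead_rsid == lead_rsid and c.r2 >= r2_min]
    if not pool:
        return None
    return min(pool, key=lambda c: tuple(kf(c) for kf in
                                         [keyfuncs[k] for k in criteria])
               + (c.proxy_rsid,))


def _complement_alleles(a1: str, a2: str) -> tuple[str, str]:
    try:
        return _COMPLEMENT[a1.upper()], _COMPLEMENT[a2.upper()]
    except KeyError:
        return a1, a2  # indels: no strand flip possible


def harmonize(
    exposure: InstrumentSet,
    outcome: Sequence[VariantAssociation],
    policy: HarmonizationPolicy = "drop_all_palindromic",
    ambiguity_eaf_bound: float = 0.42,
) -> list[HarmonizedInstrument]:
    """Orient outcome effects onto each exposure variant's effect allele.

    For every exposure instrument, in input order:

    * no outcome record -> ``excluded_missing``;
    * palindromic pair -> under ``drop_all_palindromic`` (the default)
      ``excluded_palindromic``; under ``keep_inferable_palindromic`` the
      variant is kept when both studies' effect-allele frequencies are
      clearly away from 0.5 (min(eaf, 1-eaf) < ``ambiguity_eaf_bound``),
      using the frequencies to align strands;
    * matching alleles -> outcome effect used as-is; swapped alleles ->
      outcome beta negated and eaf complemented; opposite strand (with or
      without swap) -> alleles complemented first;
    * irreconcilable alleles -> ``excluded_incompatible`` with a reason.
    """
    by_rsid = {v.rsid: v for v in outcome}
    out: list[HarmonizedInstrument] = []
    for exp in exposure.variants:
        included_status = "proxy_substituted" if exp.proxy_of else "included"
        base = dict(
            rsid=exp.rsid,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            effect_allele=exp.effect_allele.upper(),
            proxy_of=exp.proxy_of,
        )
        outc = by_rsid.get(exp.rsid)
        if outc is None:
            out.append(HarmonizedInstrument(
                beta_outcome=None, se_outcome=None,
                status="excluded_missing",
                reason="absent from outcome study and no proxy available",
                **base))
            continue

        palindromic = classify_palindromic(exp.effect_allele, exp.other_allele)
        if palindromic and policy == "drop_all_palindromic":
            out.append(HarmonizedInstrument(
                beta_outcome=None, se_outcome=None,
                status="excluded_palindromic",
                reason="palindromic and strand-ambiguous",
                **base))
            continue

        ea, oa = exp.effect_allele.upper(), exp.other_allele.upper()
        o_ea, o_oa = outc.effect_allele.upper(), outc.other_allele.upper()
        beta_y, eaf_y = outc.beta, outc.eaf

        def aligned(oea: str, ooa: str) -> Optional[bool]:
            """True = same orientation, False = swapped, None = no match."""
            if (oea, ooa) == (ea, oa):
                return True
            if (oea, ooa) == (oa, ea):
                return False
            return None

        orient = aligned(o_ea, o_oa)
        if orient is None and not palindromic:
            # try the opposite strand
            orient = aligned(*_complement_alleles(o_ea, o_oa))
        if orient is None:
            out.append(HarmonizedInstrument(
                beta_outcome=None, se_outcome=None,
                status="excluded_incompatible",
                reason=f"outcome alleles {o_ea}/{o_oa} irreconcilable with {ea}/{oa}",
                **base))
            continue
        if orient is False:
            beta_y = -beta_y
            eaf_y = None if eaf_y is None else 1 - eaf_y

        if palindromic:
            # keep_inferable policy: frequencies must identify the strand
            if exp.eaf is None or eaf_y is None or \
                    min(exp.eaf, 1 - exp.eaf) >= ambiguity_eaf_bound or \
                    min(eaf_y, 1 - eaf_y) >= ambiguity_eaf_bound:
                out.append(HarmonizedInstrument(
                    beta_outcome=None, se_outcome=None,
                    status="excluded_palindromic",
                    reason="palindromic; frequency too close to 0.5 to infer strand",
                    **base))
                continue
            if (exp.eaf < 0.5) != (eaf_y < 0.5):
                # frequencies disagree: the studies report opposite strands,
                # which for a palindromic pair flips the effect allele
                beta_y = -beta_y
                eaf_y = 1 - eaf_y

        out.append(HarmonizedInstrument(
            beta_outcome=beta_y, se_outcome=outc.se,
            status=included_status, **base))
    return out


def included(harmonized: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The analysis-ready subset of a harmonization result."""
    return [h for h in harmonized if h.included]


def substitute_proxies(
    exposure: InstrumentSet,
    outcome_rsids: set[str],
    candidates: Sequence[ProxyCandidate],
    exposure_lookup: dict[str, VariantAssociation],
    criteria: Sequence[str] = DEFAULT_PROXY_CRITERIA,
    r2_min: float = DEFAULT_PROXY_R2_MIN,
) -> InstrumentSet:
    """Replace instruments missing from the outcome study by their best proxy.

    The proxy's own exposure association (from ``exposure_lookup``, typically
    the full exposure summary statistics) replaces the lead's; leads with no
    usable proxy are kept and will harmonize to ``excluded_missing``.
    """
    new: list[VariantAssociation] = []
    taken = set(exposure.rsids())
    for v in exposure.variants:
        if v.rsid in outcome_rsids:
            new.append(v)
            continue
        usable = [c for c in candidates
                  if c.proxy_rsid in outcome_rsids and c.proxy_rsid in exposure_lookup
                  and c.proxy_rsid not in taken]
        best = select_proxy(v.rsid, usable, criteria=criteria, r2_min=r2_min)
        if best is None:
            log.info("no proxy for %s (r2 >= %.2f); will be excluded_missing",
                     v.rsid, r2_min)
            new.append(v)
        else:
            proxy_assoc = replace(exposure_lookup[best.proxy_rsid], proxy_of=v.rsid)
            log.info("substituting %s for %s (r2=%.4f, distance=%d)",
                     best.proxy_rsid, v.rsid, best.r2, best.distance)
            new.append(proxy_assoc)
            taken.add(best.proxy_rsid)
    return InstrumentSet(
        exposure_name=exposure.exposure_name,
        variants=new,
        variance_explained=exposure.variance_explained,
        sample_size=exposure.sample_size,
        p_threshold=exposure.p_threshold,
    )


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("vitd_to_adhd", "adhd_to_vitd")


def clip_pvalue(p: float) -> float:
    """Floor a parsed p-value at 1e-300: extreme GWAS p-values (printed as
    small as 1e-343) underflow float64 to exactly 0, which the data model
    rejects."""
    return max(float(p), 1e-300)


def _fixture_path(name: str):
    return resources.files("mrtwosample.data").joinpath(f"{name}.tsv")


def load_fixture(name: str) -> tuple[InstrumentSet, list[VariantAssociation], dict]:
    """Load a bundled instrument table.

    ``vitd_to_adhd``: six genome-wide significant 25(OH)D variants and their
    ADHD associations (one an LD proxy).  ``adhd_to_vitd``: twelve ADHD loci
    and their 25(OH)D associations (five proxies, two unmatchable).

    Returns ``(exposure_set, outcome_associations, metadata)``.  The
    exposure set contains the analysis rows (proxies already substituted);
    rows a proxy replaced are available in the raw table but are not
    instruments.  Effects reported as odds ratios are converted to log-odds.
    """
    if name not in FIXTURE_NAMES:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    meta_text = resources.files("mrtwosample.data").joinpath("fixtures_meta.json")
    meta = json.loads(meta_text.read_text())[name]
    df = pd.read_csv(_fixture_path(name), sep="\t", dtype={"chrom": "string"})

    exposure_variants: list[VariantAssociation] = []
    outcome_assocs: list[VariantAssociation] = []
    for _, r in df.iterrows():
        if r["role"] != "instrument":
            continue
        if pd.notna(r.get("exposure_beta")):
            beta, from_or = float(r["exposure_beta"]), False
        else:
            beta, from_or = or_to_beta(float(r["exposure_or"])), True
        exposure_variants.append(VariantAssociation(
            rsid=r["rsid"],
            effect_allele=r["effect_allele"],
            other_allele=r["other_allele"],
            eaf=float(r["eaf"]) if pd.notna(r["eaf"]) else None,
            beta=beta,
            se=float(r["exposure_se"]),
            pvalue=clip_pvalue(r["exposure_p"]),
            chrom=None if pd.isna(r["chrom"]) else str(r["chrom"]),
            pos=None if pd.isna(r["pos"]) else int(r["pos"]),
            trait_type=meta["exposure_trait_type"],
            gene=None if pd.isna(r["gene"]) else r["gene"],
            from_odds_ratio=from_or,
            proxy_of=None if pd.isna(r.get("proxy_of")) else r["proxy_of"],
        ))
        if pd.notna(r.get("outcome_se")):
            if pd.notna(r.get("outcome_beta")):
                beta_y, from_or_y = float(r["outcome_beta"]), False
            else:
                beta_y, from_or_y = or_to_beta(float(r["outcome_or"])), True
            outcome_assocs.append(VariantAssociation(
                rsid=r["rsid"],
                effect_allele=r["outcome_effect_allele"],
                other_allele=r["outcome_other_allele"],
                beta=beta_y,
                se=float(r["outcome_se"]),
                pvalue=clip_pvalue(r["outcome_p"]),
                trait_type=meta["outcome_trait_type"],
                from_odds_ratio=from_or_y,
            ))
    exposure_set = InstrumentSet(
        exposure_name=meta["exposure_name"],
        variants=exposure_variants,
        variance_explained=meta["variance_explained"],
        sample_size=meta["n_exposure"],
        p_threshold=meta["p_threshold"],
    )
    return exposure_set, outcome_assocs, meta


def load_fixture_table(name: str) -> pd.DataFrame:
    """The raw bundled table, including rows replaced by proxies."""
    if name not in FIXTURE_NAMES:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return pd.read_csv(_fixture_path(name), sep="\t", dtype={"chrom": "string"})
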