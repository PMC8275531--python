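"""Readers and writers for delimited summary-statistic and LD-proxy tables."""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .exceptions import ConfigError, DataError
from .summary_data import (
    ProxyCandidate,
    VariantAssociation,
    classify_palindromic,
    clip_pvalue,
    or_to_beta,
)

log = logging.getLogger(__name__)

#: column-map keys understood by :func:`read_summary_stats`
MANDATORY_KEYS = ("rsid", "effect_allele", "other_allele", "se", "pvalue")
OPTIONAL_KEYS = ("eaf", "chrom", "pos")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str],
    trait_type: str = "continuous",
) -> list[VariantAssociation]:
    """Read a delimited GWAS summary-statistics table.

    ``column_map`` maps the keys rsid, effect_allele, other_allele, se,
    pvalue, exactly one of beta/or, and optionally eaf/chrom/pos to the
    file's column names.  An ``or`` column is converted to log-odds.
    Malformed rows are logged and skipped.
    """
    records, skipped = read_summary_stats_counted(path, column_map, trait_type)
    return records


def read_summary_stats_counted(
    path: str | Path,
    column_map: dict[str, str],
    trait_type: str = "continuous",
) -> tuple[list[VariantAssociation], int]:
    """Like :func:`read_summary_stats` but also returns the skipped-row count."""
    path = Path(path)
    has_beta = "beta" in column_map
    has_or = "or" in column_map
    if has_beta == has_or:
        raise ConfigError("column map must name exactly one of 'beta' or 'or'")
    missing = [k for k in MANDATORY_KEYS if k not in column_map]
    if missing:
        raise ConfigError(f"column map missing mandatory keys: {', '.join(missing)}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    absent = [c for c in column_map.values() if c not in df.columns]
    if absent:
        raise ConfigError(f"{path.name}: mapped columns not in file: {', '.join(absent)}")

    records: list[VariantAssociation] = []
    skipped = 0
    for idx, row in df.iterrows():
        try:
            effect_col = column_map["beta"] if has_beta else column_map["or"]
            raw_effect = float(row[effect_col])
            beta = raw_effect if has_beta else or_to_beta(raw_effect)
            eaf = None
            if "eaf" in column_map and pd.notna(row[column_map["eaf"]]):
                eaf = float(row[column_map["eaf"]])
            records.append(VariantAssociation(
                rsid=str(row[column_map["rsid"]]),
                effect_allele=str(row[column_map["effect_allele"]]),
                other_allele=str(row[column_map["other_allele"]]),
                eaf=eaf,
                beta=beta,
                se=float(row[column_map["se"]]),
                pvalue=clip_pvalue(row[column_map["pvalue"]]),
                chrom=(str(row[column_map["chrom"]])
                       if "chrom" in column_map and pd.notna(row[column_map["chrom"]])
                       else None),
                pos=(int(float(row[column_map["pos"]]))
                     if "pos" in column_map and pd.notna(row[column_map["pos"]])
                     else None),
                trait_type=trait_type,
                from_odds_ratio=has_or,
            ))
        except (ValueError, TypeError, DataError) as exc:
            skipped += 1
            log.warning("%s row %d skipped: %s", path.name, idx, exc)
    if skipped:
        log.info("%s: %d rows skipped as malformed", path.name, skipped)
    return records, skipped


def write_summary_stats(variants: Sequence[VariantAssociation],
                        path: str | Path) -> None:
    """Write associations as TSV, round-trippable through the reader."""
    path = Path(path)
    rows = [{
        "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
        "effect_allele": v.effect_allele, "other_allele": v.other_allele,
        "eaf": v.eaf, "beta": repr(v.beta), "se": repr(v.se),
        "pvalue": repr(v.pvalue),
    } for v in variants]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_proxy_table(path: str | Path) -> list[ProxyCandidate]:
    """Read an LD-proxy TSV: lead_rsid, proxy_rsid, r2, distance, a1, a2."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["lead_rsid", "proxy_rsid", "r2", "distance"]
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise ConfigError(f"{path.name}: proxy table missing columns {absent}")
    out = []
    for _, row in df.iterrows():
        a1 = row.get("a1")
        a2 = row.get("a2")
        a1 = None if pd.isna(a1) else str(a1)
        a2 = None if pd.isna(a2) else str(a2)
        out.append(ProxyCandidate(
            lead_rsid=str(row["lead_rsid"]),
            proxy_rsid=str(row["proxy_rsid"]),
            r2=float(row["r2"]),
            distance=int(float(row["distance"])),
            effect_allele=a1,
            other_allele=a2,
            palindromic=classify_palindromic(a1, a2) if a1 and a2 else False,
        ))
    return out
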