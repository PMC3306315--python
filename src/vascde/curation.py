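"""Gene-list curation arithmetic downstream of GO clustering.

The upstream functional-annotation clustering (an external web service) is
not re-implemented; its outputs enter as annotation tables.  This module
covers the bookkeeping applied to them: merging cluster gene lists with
duplicate deletion, rule-based exclusions with an audit trail, counting
boolean annotation flags, and the rounded summary percentages.

Packaged fixtures (TSV, under ``data/fixtures/``) carry the published
gene tables of the etsrp-overexpression study: the top induced genes
(``table1``), the known vascular genes among the upregulated set
(``table2``), and the 50 genes examined by whole-mount in situ
hybridization with their vascular-expression flags (``table3``).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "merge_dedup",
    "apply_exclusions",
    "vascular_summary",
    "coverage_summary",
    "count_flagged",
    "load_fixture",
    "CurationResult",
]

SOURCES = frozenset({"cluster_top1", "cluster_top2", "manual_scan", "examined_50"})


def merge_dedup(*lists: Sequence[str]) -> list[str]:
    """Union of gene lists preserving first-seen order, duplicates dropped.

    Matching is case-sensitive exact id equality.
    """
    seen: dict[str, None] = {}
    for lst in lists:
        for g in lst:
            seen.setdefault(g, None)
    return list(seen)


@dataclass
class CurationResult:
    """Outcome of :func:`apply_exclusions`: kept genes plus an audit log."""

    kept: list[str]
    audit: pd.DataFrame  # columns: gene_id, rule
    warnings: list[str]


def apply_exclusions(
    genes: Sequence[str], exclusion_sets: Mapping[str, Sequence[str]]
) -> CurationResult:
    """Remove genes named in any exclusion set, preserving order.

    Each removal is attributed to the first rule (in mapping order) that
    names the gene, so the audit log partitions the removals.  An exclusion
    id absent from ``genes`` produces a warning entry, not an error.
    """
    universe = set(genes)
    rule_of: dict[str, str] = {}
    warnings: list[str] = []
    for rule, members in exclusion_sets.items():
        for g in members:
            if g not in universe:
                warnings.append(f"exclusion rule {rule!r}: {g!r} not in gene list")
            elif g not in rule_of:
                rule_of[g] = rule
    kept = [g for g in genes if g not in rule_of]
    audit = pd.DataFrame(
        [{"gene_id": g, "rule": r} for g, r in rule_of.items()],
        columns=["gene_id", "rule"],
    )
    return CurationResult(kept=kept, audit=audit, warnings=warnings)


def _round_half_away(value: float, decimals: int) -> float:
    return float(Decimal(repr(value)).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
    ))


def vascular_summary(n_vascular: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of vascular-associated genes, rounded half away from zero.

    E.g. 53 vascular genes of 849 upregulated entries -> 6.2 (percent).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_vascular <= n_total:
        raise ValueError("need 0 <= n_vascular <= n_total")
    return _round_half_away(100.0 * n_vascular / n_total, decimals)


def coverage_summary(n_covered: int, n_database: int) -> int:
    """Integer percentage of database entries covered by mapped reads."""
    if n_database <= 0:
        raise ValueError("n_database must be positive")
    if not 0 <= n_covered <= n_database:
        raise ValueError("need 0 <= n_covered <= n_database")
    return int(_round_half_away(100.0 * n_covered / n_database, 0))


def count_flagged(table: pd.DataFrame, flag: str) -> int:
    """Number of rows whose boolean ``flag`` column is true."""
    if flag not in table.columns:
        raise ValueError(f"unknown flag column {flag!r}")
    col = table[flag]
    if col.dtype != bool and not set(col.unique()) <= {True, False, 0, 1}:
        raise ValueError(f"column {flag!r} is not boolean")
    return int(col.astype(bool).sum())


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged TSV fixture by base name (e.g. ``'table3_examined'``)."""
    ref = resources.files("vascde.data.fixtures").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
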