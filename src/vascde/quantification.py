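"""Per-gene counting of uniquely mapped reads, pooling, and RPKM/CPM.

A gene's count in a sample is the number of reads (read pairs count once)
uniquely assigned to it; ambiguous and unmapped reads contribute nothing.
``mapped_total`` defaults to the number of unique assignments in the sample
— the base the counts themselves live in — with ``total_def='all-mapped'``
available to include ambiguous (mapped but unresolvable) reads instead.

RPKM follows the standard definition: reads per kilobase of transcript per
million mapped reads, i.e. ``1e9 * count / (length_bp * mapped_total)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import ReadAssignment

__all__ = [
    "CountTable",
    "ResolutionTally",
    "count_genes",
    "concat_samples",
    "pool_by_condition",
    "rpkm",
    "cpm",
]

CONDITIONS = ("control", "oe")


@dataclass
class ResolutionTally:
    """How many reads of a sample resolved unique / ambiguous / unmapped."""

    unique: int = 0
    ambiguous: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.unique + self.ambiguous + self.unmapped


@dataclass
class CountTable:
    """Gene x sample matrix of uniquely-mapped read(-pair) counts.

    ``samples`` (indexed by sample id) carries a ``condition`` label and a
    ``lane`` index per column; ``mapped_total`` the per-sample normalization
    base.  Totals may exceed the column sum (reads assigned to genes filtered
    from the table, or all-mapped totals), never fall below it.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    mapped_total: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("samples metadata must match count columns")
        if list(self.counts.columns) != list(self.mapped_total.index):
            raise ValueError("mapped_total must match count columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "condition" not in self.samples.columns or "lane" not in self.samples.columns:
            raise ValueError("samples metadata needs 'condition' and 'lane' columns")
        colsum = self.counts.sum(axis=0)
        if (self.mapped_total < colsum).any():
            bad = self.mapped_total.index[self.mapped_total < colsum].tolist()
            raise ValueError(f"mapped_total below column sum for samples {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))


def count_genes(
    assignments: Iterable[ReadAssignment],
    gene_ids: Sequence[str],
    sample_id: str,
    condition: str = "control",
    lane: int = 1,
    total_def: str = "unique",
) -> tuple[CountTable, ResolutionTally]:
    """Tally unique assignments into a one-sample count column.

    Each unique assignment increments its gene by exactly one (a read pair
    counts once).  A unique assignment to a gene absent from ``gene_ids`` is
    a consistency error.  ``total_def`` picks the mapped-total definition:
    ``'unique'`` (default) or ``'all-mapped'`` (unique + ambiguous).
    """
    if total_def not in ("unique", "all-mapped"):
        raise ValueError(f"unknown total_def {total_def!r}")
    counts = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=np.int64)
    tally = ResolutionTally()
    known = set(gene_ids)
    for a in assignments:
        if a.status == "unique":
            if a.gene_id not in known:
                raise ValueError(
                    f"unique assignment to unknown gene {a.gene_id!r} "
                    f"(read {a.read_id!r})"
                )
            counts[a.gene_id] += 1
            tally.unique += 1
        elif a.status == "ambiguous":
            tally.ambiguous += 1
        else:
            tally.unmapped += 1
    total = tally.unique if total_def == "unique" else tally.unique + tally.ambiguous
    table = CountTable(
        counts=counts.to_frame(sample_id),
        samples=pd.DataFrame(
            {"condition": [condition], "lane": [lane]},
            index=pd.Index([sample_id], name="sample_id"),
        ),
        mapped_total=pd.Series({sample_id: total}),
    )
    return table, tally


def concat_samples(tables: Sequence[CountTable]) -> CountTable:
    """Column-concatenate per-sample tables sharing one gene index."""
    if not tables:
        raise ValueError("need at least one table")
    index = tables[0].counts.index
    for t in tables[1:]:
        if not t.counts.index.equals(index):
            raise ValueError("tables have differing gene sets")
    return CountTable(
        counts=pd.concat([t.counts for t in tables], axis=1),
        samples=pd.concat([t.samples for t in tables], axis=0),
        mapped_total=pd.concat([t.mapped_total for t in tables]),
    )


def pool_by_condition(ct: CountTable) -> CountTable:
    """Sum counts and mapped totals across lanes within each condition.

    The pooled contrast tests one summed column per condition; lanes
    are summed, gene order is preserved, and the pooled sample id is the
    condition label itself.
    """
    conditions = ct.conditions
    if not conditions:
        raise ValueError("count table has no samples")
    cols = {}
    totals = {}
    for cond in conditions:
        members = ct.samples.index[ct.samples["condition"] == cond]
        if len(members) == 0:
            raise ValueError(f"condition {cond!r} has no lanes")
        cols[cond] = ct.counts[members].sum(axis=1)
        totals[cond] = int(ct.mapped_total[members].sum())
    return CountTable(
        counts=pd.DataFrame(cols, index=ct.counts.index),
        samples=pd.DataFrame(
            {"condition": conditions, "lane": [0] * len(conditions)},
            index=pd.Index(conditions, name="sample_id"),
        ),
        mapped_total=pd.Series(totals).reindex(conditions),
    )


def rpkm(ct: CountTable, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm[g, s] = 1e9 * counts[g, s] / (lengths[g] * mapped_total[s])``.
    """
    lengths = lengths.reindex(ct.counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing lengths for genes {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (ct.mapped_total <= 0).any():
        raise ValueError("mapped_total must be positive to compute RPKM")
    denom = np.outer(lengths.to_numpy(float), ct.mapped_total.to_numpy(float))
    return pd.DataFrame(
        1e9 * ct.counts.to_numpy(float) / denom,
        index=ct.counts.index,
        columns=ct.counts.columns,
    )


def cpm(ct: CountTable) -> pd.DataFrame:
    """Counts per million mapped reads (library-size scaling only)."""
    if (ct.mapped_total <= 0).any():
        raise ValueError("mapped_total must be positive to compute CPM")
    return ct.counts / ct.mapped_total.to_numpy(float) * 1e6
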