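"""Per-gene differential expression: Fisher's exact test, BH-FDR, fold calls.

For each gene the pooled raw counts form a 2x2 contingency table

    =============  ==============  =============
    .              gene            all others
    control        a               b = N_c - a
    oe             c               d = N_o - c
    =============  ==============  =============

tested with the two-sided Fisher's exact test (probability-mass rule),
computed in log space so library totals of ~1e7 are safe.  P-values are
adjusted with the Benjamini–Hochberg step-up procedure, fold changes are
ratios of library-size-normalized counts (CPM by default), and a gene is
called ``up``/``down`` when its adjusted p-value is below the FDR threshold
and its fold change is at least ``fc_threshold`` (or at most its inverse).
The defaults — 1.9-fold at 5% FDR — are the thresholds used for the
etsrp-overexpression contrast this package models.

Fisher's test runs on raw pooled counts only: exactness of the
hypergeometric null requires integers, so normalization enters exclusively
through the fold change.
"""

from __future__ import annotations

import numbers
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .quantification import CountTable

__all__ = ["fisher_two_sided", "bh_adjust", "fold_change", "call_de"]

# Multiplicative slack when comparing table probabilities to the observed
# one: a table counts toward the two-sided p-value when
# pmf(x) <= pmf(observed) * (1 + 1e-7).  This is the widely used convention
# for the probability-mass rule and makes exact ties robust to rounding.
TIE_RTOL = 1e-7


def _as_count(x, name: str) -> int:
    if isinstance(x, numbers.Integral) or (
        isinstance(x, float) and float(x).is_integer()
    ):
        v = int(x)
    elif isinstance(x, np.integer):
        v = int(x)
    else:
        raise ValueError(f"{name} must be an integer count, got {x!r}")
    if v < 0:
        raise ValueError(f"{name} must be non-negative, got {v}")
    return v


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the table [[a, b], [c, d]].

    With all margins fixed, sums the hypergeometric probability of every
    table whose probability does not exceed the observed table's
    (probability-mass rule).  Log-space throughout, so cells of ~1e7 are
    handled without under/overflow.  A degenerate table (any zero margin)
    returns 1.0 by convention.
    """
    a, b, c, d = (_as_count(v, n) for v, n in zip((a, b, c, d), "abcd"))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    x = np.arange(lo, hi + 1)
    # log[ C(r1, x) C(r2, c1-x) / C(n, c1) ]
    logpmf = (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
        + gammaln(c1 + 1) + gammaln(c2 + 1) - gammaln(n + 1)
    )
    obs = logpmf[a - lo]
    keep = logpmf <= obs + np.log1p(TIE_RTOL)
    if keep.all():
        return 1.0
    p = float(np.exp(logsumexp(logpmf[keep])))
    return min(1.0, p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Sorting ascending, ``q(i) = min_{j >= i} min(1, m * p(j) / j)``; returned
    in the original order.  Monotone non-decreasing over sorted p-values and
    never below the raw p-value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def fold_change(
    count_a: int | np.ndarray,
    count_b: int | np.ndarray,
    total_a: float,
    total_b: float,
    pseudo: float = 0.5,
) -> float | np.ndarray:
    """Fold change of normalized counts, condition B over condition A.

    ``fc = ((count_b + pseudo*[count_b == 0]) / total_b) /
    ((count_a + pseudo*[count_a == 0]) / total_a)`` — the pseudocount is
    added only to zero cells, so non-zero counts are untouched (keeping
    large observed fold changes finite without shrinking the rest).
    Swapping the conditions maps fc to 1/fc exactly.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    ca = np.asarray(count_a, dtype=float)
    cb = np.asarray(count_b, dtype=float)
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("counts must be non-negative")
    num = np.where(cb == 0, pseudo, cb) / total_b
    den = np.where(ca == 0, pseudo, ca) / total_a
    out = num / den
    return float(out) if out.ndim == 0 else out


def call_de(
    pooled: CountTable,
    fc_threshold: float = 1.9,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
    conditions: tuple[str, str] = ("control", "oe"),
    norm: str = "cpm",
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Test every gene of a two-column pooled count table.

    The multiple-testing family is all genes with a pooled count of at least
    one in either condition; all-zero genes carry no information (p = 1) and
    are dropped before adjustment so they do not dilute the family size.
    Fold changes are ratios of CPM by default (``norm='rpkm'`` with gene
    ``lengths`` gives identical ratios since the length cancels; both are
    exposed for reporting).  Output rows are sorted by descending fold
    change, so called-up genes lead the table.

    Returns a DataFrame with columns: gene_id, count_control, count_oe,
    cpm_control, cpm_oe, fold_change, p, q, call.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    missing = [c for c in conditions if c not in pooled.sample_ids]
    if missing or len(pooled.sample_ids) < 2:
        raise ValueError(
            f"pooled table must contain both condition columns {conditions}"
        )
    if norm not in ("cpm", "rpkm"):
        raise ValueError(f"unknown norm {norm!r}")
    if norm == "rpkm" and lengths is None:
        raise ValueError("norm='rpkm' requires gene lengths")

    cond_a, cond_b = conditions
    ca = pooled.counts[cond_a].to_numpy()
    cb = pooled.counts[cond_b].to_numpy()
    ta = int(pooled.mapped_total[cond_a])
    tb = int(pooled.mapped_total[cond_b])
    if ta <= 0 or tb <= 0:
        raise ValueError("pooled mapped totals must be positive")

    tested = (ca > 0) | (cb > 0)
    genes = np.asarray(pooled.gene_ids)[tested]
    ca, cb = ca[tested], cb[tested]

    p = np.array(
        [fisher_two_sided(a, ta - a, c, tb - c) for a, c in zip(ca, cb)]
    )
    q = bh_adjust(p)
    fc = fold_change(ca, cb, ta, tb, pseudo=pseudocount)

    call = np.full(genes.shape, "unchanged", dtype=object)
    call[(q < fdr) & (fc >= fc_threshold)] = "up"
    call[(q < fdr) & (fc <= 1.0 / fc_threshold)] = "down"

    res = pd.DataFrame(
        {
            "gene_id": genes,
            f"count_{cond_a}": ca,
            f"count_{cond_b}": cb,
            f"cpm_{cond_a}": ca / ta * 1e6,
            f"cpm_{cond_b}": cb / tb * 1e6,
            "fold_change": fc,
            "p": p,
            "q": q,
            "call": call,
        }
    )
    if norm == "rpkm":
        ln = lengths.reindex(genes).to_numpy(float)
        res[f"rpkm_{cond_a}"] = 1e9 * ca / (ln * ta)
        res[f"rpkm_{cond_b}"] = 1e9 * cb / (ln * tb)
    res = res.sort_values("fold_change", ascending=False, kind="stable")
    return res.reset_index(drop=True)
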