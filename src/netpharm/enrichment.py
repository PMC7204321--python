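"""Hypergeometric over-representation analysis with Benjamini-Hochberg control."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .tables_io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    """Overlap statistics of one gene set against the query.

    k: overlap count; K: set size in background; n: query size in
    background; N: background size; p: one-sided hypergeometric tail
    P(X >= k); p_adj: BH-adjusted p; fold: (k/n)/(K/N).
    """

    set_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    fold: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(f"{self.set_id}: k={self.k} outside [0, min(K, n)]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"{self.set_id}: p={self.p} outside (0, 1]")
        if self.p_adj < self.p - 1e-15:
            raise ValueError(f"{self.set_id}: p_adj < p")
        if self.fold < 0:
            raise ValueError(f"{self.set_id}: negative fold")

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Optional[Iterable[str]] = None,
    ease: bool = False,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment of ``query`` in every gene set.

    The background defaults to the union of all collection members (or the
    collection's own background if declared). Query genes and set members
    outside the background are dropped with a warning. ``ease=True``
    substitutes the more conservative k-1 overlap in the tail probability.
    Rows are sorted by p ascending, ties broken by set_id; BH adjustment is
    applied across all tested sets.
    """
    if background is not None:
        bg = frozenset(background)
    elif collection.background is not None:
        bg = collection.background
    else:
        bg = collection.all_members()
    if not bg:
        raise ValueError("background is empty")
    query_set = frozenset(query)
    if not query_set:
        raise ValueError("query is empty")
    dropped = query_set - bg
    if dropped:
        logger.warning("dropping %d query gene(s) outside the background", len(dropped))
    query_set &= bg
    if not query_set:
        raise ValueError("no query genes remain inside the background")

    N, n = len(bg), len(query_set)
    rows: list[EnrichmentRow] = []
    stats: list[tuple[str, str, int, int]] = []
    for set_id, (description, members) in collection.sets.items():
        outside = members - bg
        if outside:
            logger.warning(
                "set %s: dropping %d member(s) outside the background",
                set_id, len(outside),
            )
        members_in = members & bg
        stats.append((set_id, description, len(members_in), len(members_in & query_set)))

    pvals = []
    for _, _, K, k in stats:
        k_eff = max(k - 1, 0) if ease else k
        # exact upper tail P(X >= k_eff); sf(-1) = 1 covers k_eff = 0
        pvals.append(min(float(hypergeom.sf(k_eff - 1, N, K, n)), 1.0))
    p_adj = bh_adjust(pvals)
    for (set_id, description, K, k), p, padj in zip(stats, pvals, p_adj):
        fold = (k / n) / (K / N) if K > 0 else 0.0
        rows.append(
            EnrichmentRow(
                set_id=set_id, description=description, k=k, K=K, n=n, N=N,
                p=p, p_adj=max(padj, p), fold=fold,
            )
        )
    rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


def top_sets(
    rows: Sequence[EnrichmentRow], m: int, by: Literal["p_adj", "p"] = "p_adj"
) -> list[EnrichmentRow]:
    """First ``m`` rows under ascending order of ``by`` (ties by set_id)."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if by not in ("p_adj", "p"):
        raise ValueError(f"unknown ordering key: {by!r}")
    ordered = sorted(rows, key=lambda r: (getattr(r, by), r.set_id))
    return ordered[:m]


def write_enrichment_table(rows: Sequence[EnrichmentRow], path) -> None:
    """TSV with columns set_id, k, K, n, N, p, p_adj, fold, neg_log10_p."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_id\tk\tK\tn\tN\tp\tp_adj\tfold\tneg_log10_p\n")
        for r in rows:
            fh.write(
                f"{r.set_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t"
                f"{r.p_adj:.6g}\t{r.fold:.6g}\t{r.neg_log10_p:.6g}\n"
            )
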