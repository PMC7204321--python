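"""Degree/closeness/betweenness centralities and iterative core-target screening.

A PPI network is reduced to its core nodes by one or more rounds of
inclusive thresholding on the three centralities. By default the
centralities are computed once on the input network and every round is
thresholded against those fixed values ("fixed-centralities"); a
"recompute" mode re-evaluates centralities on each induced subnetwork.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .tables_io import InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CentralityRecord:
    """Degree (raw count), closeness and betweenness (both normalized) of a node."""

    node: str
    dc: int
    cc: float
    bc: float

    def __post_init__(self) -> None:
        if self.dc < 0:
            raise ValueError("dc must be non-negative")
        eps = 1e-12
        if not -eps <= self.cc <= 1 + eps or not -eps <= self.bc <= 1 + eps:
            raise ValueError("cc and bc must lie in [0, 1]")

    def value(self, key: str) -> float:
        return {"dc": self.dc, "cc": self.cc, "bc": self.bc}[key]


@dataclass(frozen=True)
class ScreenCriteria:
    """Inclusive minima on the three centralities."""

    dc_min: int = 0
    cc_min: float = 0.0
    bc_min: float = 0.0

    def __post_init__(self) -> None:
        if self.dc_min < 0:
            raise ValueError("dc_min must be non-negative")
        if not 0.0 <= self.cc_min <= 1.0 or not 0.0 <= self.bc_min <= 1.0:
            raise ValueError("cc_min and bc_min must lie in [0, 1]")

    def accepts(self, rec: CentralityRecord) -> bool:
        return rec.dc >= self.dc_min and rec.cc >= self.cc_min and rec.bc >= self.bc_min

    def __ge__(self, other: "ScreenCriteria") -> bool:
        return (
            self.dc_min >= other.dc_min
            and self.cc_min >= other.cc_min
            and self.bc_min >= other.bc_min
        )


@dataclass(frozen=True)
class ScreenRound:
    """One screening round: thresholds, surviving nodes, induced edge count."""

    criteria: ScreenCriteria
    survivors: frozenset[str]
    induced_edge_count: int


def centralities(net: InteractionNetwork) -> list[CentralityRecord]:
    """Per-node centrality triples, sorted by node id.

    dc is the raw degree. cc is Wasserman-Faust closeness
    ((r-1)/sum_d) * ((r-1)/(N-1)) with r the reachable-component size, 0 for
    isolated nodes, so disconnected inputs stay in [0, 1]. bc is
    shortest-path betweenness with endpoints excluded, pair contributions
    split equally among equally short paths, normalized by (N-1)(N-2)/2.
    """
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        return []
    cc = nx.closeness_centrality(g, wf_improved=True)
    bc = nx.betweenness_centrality(g, normalized=True)
    return [
        CentralityRecord(node=n, dc=g.degree(n), cc=cc[n], bc=bc[n])
        for n in sorted(g.nodes)
    ]


def _induced_edge_count(net: InteractionNetwork, keep: frozenset[str]) -> int:
    return sum(1 for u, v, _ in net.edges() if u in keep and v in keep)


def iterative_screen(
    net: InteractionNetwork,
    rounds: Sequence[ScreenCriteria],
    mode: Literal["fixed-centralities", "recompute"] = "fixed-centralities",
) -> list[ScreenRound]:
    """Apply successive centrality thresholds; survivors are nested across rounds.

    In "fixed-centralities" mode the centralities of the full input network
    are reused for every round (thresholds are expected to tighten
    monotonically; a warning is logged otherwise). In "recompute" mode each
    round recomputes centralities on the subnetwork induced by the previous
    round's survivors. A round with zero survivors terminates the sequence;
    remaining rounds are reported empty.
    """
    if not rounds:
        raise ValueError("at least one screening round is required")
    if mode not in ("fixed-centralities", "recompute"):
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "fixed-centralities":
        for prev, cur in zip(rounds, rounds[1:]):
            if not cur >= prev:
                logger.warning(
                    "screening thresholds are not monotonically tightening: "
                    "%s after %s", cur, prev
                )

    results: list[ScreenRound] = []
    survivors = net.nodes
    fixed = {r.node: r for r in centralities(net)} if mode == "fixed-centralities" else None
    exhausted = False
    for crit in rounds:
        if exhausted:
            results.append(ScreenRound(crit, frozenset(), 0))
            continue
        if fixed is not None:
            recs = [fixed[n] for n in survivors]
        else:
            recs = centralities(net.subgraph(survivors))
        survivors = frozenset(r.node for r in recs if crit.accepts(r))
        results.append(
            ScreenRound(crit, survivors, _induced_edge_count(net, survivors))
        )
        if not survivors:
            exhausted = True
    return results


def rank_nodes(
    records: Sequence[CentralityRecord], key: Literal["dc", "cc", "bc"] = "dc"
) -> list[CentralityRecord]:
    """Stable descending sort by one centrality, ties broken by node id."""
    if key not in ("dc", "cc", "bc"):
        raise ValueError(f"unknown centrality key: {key!r}")
    return sorted(records, key=lambda r: (-r.value(key), r.node))


def quantile_thresholds(records: Sequence[CentralityRecord], q: float) -> ScreenCriteria:
    """The q-quantile of each centrality as inclusive screening thresholds.

    The degree threshold is rounded up to an integer. A convenience for
    users without hand-picked cutoffs; q = 0.5 gives the medians.
    """
    if not records:
        raise ValueError("cannot take quantiles of an empty record list")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    dc_q = float(np.quantile([r.dc for r in records], q))
    cc_q = float(np.quantile([r.cc for r in records], q))
    bc_q = float(np.quantile([r.bc for r in records], q))
    return ScreenCriteria(
        dc_min=int(math.ceil(dc_q)), cc_min=min(cc_q, 1.0), bc_min=min(bc_q, 1.0)
    )
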