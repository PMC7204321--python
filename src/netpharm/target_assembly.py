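"""Herb-compound-target assembly and drug/disease target intersection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .tables_io import CompoundRecord, DiseaseTargetRecord, TargetRecord


@dataclass(frozen=True)
class CompoundTargetMap:
    """User-supplied mapping from compound keys to target gene symbols."""

    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def targets_of(self, compound: str) -> set[str]:
        return {g for c, g in self.pairs if c == compound}

    def compounds_per_target(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, g in self.pairs:
            counts[g] = counts.get(g, 0) + 1
        return counts


@dataclass
class BipartiteNetwork:
    """Two-sided network; edges run between sides only."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        left, right = set(self.left), set(self.right)
        if left & right:
            raise ValueError(f"sides overlap: {sorted(left & right)[:5]}")
        for l, r in self.edges:
            if l not in left or r not in right:
                raise ValueError(f"edge endpoint not in declared node lists: ({l}, {r})")

    @property
    def n_nodes(self) -> int:
        return len(self.left) + len(self.right)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for l, r in self.edges if l == node or r == node)


def _norm(symbol: str) -> str:
    return symbol.strip()


def unique_targets(records: Sequence[TargetRecord]) -> list[str]:
    """Gene symbols with duplicates collapsed, first-occurrence order kept.

    Matching is case-sensitive after whitespace trimming.
    """
    seen: set[str] = set()
    out: list[str] = []
    for r in records:
        sym = _norm(r.gene_symbol)
        if sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


def filter_disease_targets(
    records: Sequence[DiseaseTargetRecord], score_min: float
) -> list[DiseaseTargetRecord]:
    """Keep records with inference_score >= score_min (inclusive).

    Records lacking a score are kept only when ``score_min <= 0``.
    """
    import math

    if not math.isfinite(score_min):
        raise ValueError("score_min must be finite")
    kept = []
    for r in records:
        if r.inference_score is None:
            if score_min <= 0:
                kept.append(r)
        elif r.inference_score >= score_min:
            kept.append(r)
    return kept


def intersect_targets(drug_genes: Iterable[str], disease_genes: Iterable[str]) -> list[str]:
    """Sorted intersection of two gene-symbol sets (trimmed exact match)."""
    drug = {_norm(g) for g in drug_genes}
    disease = {_norm(g) for g in disease_genes}
    return sorted(drug & disease)


def build_bipartite(
    left: Sequence[str],
    right: Sequence[str],
    edges: CompoundTargetMap | Iterable[tuple[str, str]] = (),
) -> BipartiteNetwork:
    """Bipartite network over explicit node lists; node count = |left| + |right|.

    The edge set may be empty — declared nodes are kept either way.
    """
    pairs = edges.pairs if isinstance(edges, CompoundTargetMap) else frozenset(edges)
    return BipartiteNetwork(left=tuple(left), right=tuple(right), edges=frozenset(pairs))


def herb_compound_network(kept: Sequence[CompoundRecord]) -> BipartiteNetwork:
    """Herbs on one side, screened herb-compound entries on the other.

    Each entry contributes exactly one edge to its herb. Entry node ids are
    ``mol_id@herb`` so a molecule shared by several herbs stays distinct.
    """
    herbs: list[str] = []
    entries: list[str] = []
    edges: set[tuple[str, str]] = set()
    for r in kept:
        if r.herb not in herbs:
            herbs.append(r.herb)
        key = f"{r.mol_id}@{r.herb}"
        entries.append(key)
        edges.add((r.herb, key))
    return BipartiteNetwork(left=tuple(herbs), right=tuple(entries), edges=frozenset(edges))
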