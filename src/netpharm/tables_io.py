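"""Readers and writers for every tabular and network format the pipeline touches.

Packaged study fixtures (compound descriptor table, drug-target table,
disease-target list) are exposed through ``load_table1``/``load_table2``/
``load_table3``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: The eight herb abbreviations used throughout the study tables.
HERB_CODES = ("RB", "SR", "RPR", "ATT", "AFI", "RERR", "ZOR", "JF")

# The source tables spell one herb code two ways; canonicalize on input.
_HERB_ALIASES = {"RRER": "RERR"}


class FormatError(ValueError):
    """A delimited-text or network file violated its expected layout."""


def canonicalize_herb(code: str) -> str:
    """Return the canonical herb code, accepting known alias spellings."""
    code = code.strip().upper()
    code = _HERB_ALIASES.get(code, code)
    if code not in HERB_CODES:
        raise FormatError(f"unknown herb code: {code!r}")
    return code


@dataclass(frozen=True)
class CompoundRecord:
    """One herb-compound entry with its six screening descriptors.

    ``ob`` is a percentage and may exceed 100; ``dl`` is unitless in [0, 1].
    """

    mol_id: str
    name: str
    herb: str
    mw: float
    alogp: float
    hdon: int
    hacc: int
    ob: float
    dl: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "herb", canonicalize_herb(self.herb))
        if not self.mw > 0:
            raise ValueError(f"{self.mol_id}: mw must be positive, got {self.mw}")
        if self.hdon < 0 or self.hacc < 0:
            raise ValueError(f"{self.mol_id}: hdon/hacc must be non-negative")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.mol_id}: dl must lie in [0, 1], got {self.dl}")
        if self.ob < 0:
            raise ValueError(f"{self.mol_id}: ob must be non-negative, got {self.ob}")


@dataclass(frozen=True)
class TargetRecord:
    """A protein target with its official gene symbol and herb attribution."""

    uniprot_id: str
    target_name: str
    gene_symbol: str
    herbs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_symbol.strip():
            raise ValueError(f"{self.uniprot_id}: gene_symbol must be non-empty")
        if not self.herbs:
            raise ValueError(f"{self.uniprot_id}: herb attribution must be non-empty")
        object.__setattr__(
            self, "herbs", frozenset(canonicalize_herb(h) for h in self.herbs)
        )


@dataclass(frozen=True)
class DiseaseTargetRecord:
    """A disease-associated gene, optionally carrying an inference score."""

    gene_symbol: str
    inference_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.inference_score is not None and self.inference_score < 0:
            raise ValueError(
                f"{self.gene_symbol}: inference score must be non-negative"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional explicit background universe."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    background: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")
            if self.background is not None and not members <= self.background:
                raise ValueError(
                    f"gene set {set_id!r} has members outside the background"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)


class InteractionNetwork:
    """Simple undirected graph whose edges carry a confidence in [0, 1]."""

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self._g.add_node(str(node))

    def add_edge(self, u: str, v: str, confidence: float) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop not allowed: {u}")
        if not 0.0 <= confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {confidence}")
        if self._g.has_edge(u, v):
            confidence = max(confidence, self._g[u][v]["confidence"])
        self._g.add_edge(u, v, confidence=confidence)

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (u, v, confidence) with u < v, sorted deterministically."""
        out = [
            (min(u, v), max(u, v), d["confidence"])
            for u, v, d in self._g.edges(data=True)
        ]
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def confidence(self, u: str, v: str) -> float:
        return self._g[u][v]["confidence"]

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def subgraph(self, keep: Iterable[str]) -> "InteractionNetwork":
        """Induced subnetwork on ``keep`` (unknown node ids ignored)."""
        keep = set(keep)
        sub = InteractionNetwork()
        for n in self.nodes & keep:
            sub.add_node(n)
        for u, v, c in self.edges():
            if u in keep and v in keep:
                sub.add_edge(u, v, c)
        return sub

    def filter_confidence(self, min_confidence: float) -> "InteractionNetwork":
        """Drop edges below ``min_confidence``; all nodes are retained."""
        out = InteractionNetwork()
        for n in self.nodes:
            out.add_node(n)
        for u, v, c in self.edges():
            if c >= min_confidence:
                out.add_edge(u, v, c)
        return out

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        net = cls()
        for n in g.nodes:
            net.add_node(n)
        for u, v, d in g.edges(data=True):
            net.add_edge(u, v, d.get("confidence", 1.0))
        return net

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"InteractionNetwork(nodes={self.n_nodes}, edges={self.n_edges})"


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

_COMPOUND_COLUMNS = ("mol_id", "name", "herb", "mw", "alogp", "hdon", "hacc", "ob", "dl")
_NUMERIC_COMPOUND_FIELDS = {"mw": float, "alogp": float, "hdon": int,
                            "hacc": int, "ob": float, "dl": float}


def read_compound_table(path: str | Path, delimiter: str = "\t") -> list[CompoundRecord]:
    """Read a compound descriptor table into :class:`CompoundRecord` rows.

    The header must contain every column in ``mol_id, name, herb, mw, alogp,
    hdon, hacc, ob, dl`` (extra columns are ignored). Records are returned in
    file order.
    """
    records: list[CompoundRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return records
        missing = [c for c in _COMPOUND_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        for rownum, row in enumerate(reader, start=2):
            kwargs: dict = {
                "mol_id": row["mol_id"].strip(),
                "name": row["name"].strip(),
                "herb": row["herb"],
            }
            for col, cast in _NUMERIC_COMPOUND_FIELDS.items():
                try:
                    kwargs[col] = cast(row[col])
                except (TypeError, ValueError) as exc:
                    raise FormatError(
                        f"{path}, row {rownum}: cannot parse {col}={row[col]!r}"
                    ) from exc
            records.append(CompoundRecord(**kwargs))
    return records


def write_compound_table(
    records: Sequence[CompoundRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(_COMPOUND_COLUMNS)
        for r in records:
            writer.writerow(
                [r.mol_id, r.name, r.herb, r.mw, r.alogp, r.hdon, r.hacc, r.ob, r.dl]
            )


# ---------------------------------------------------------------------------
# target tables
# ---------------------------------------------------------------------------

_TARGET_COLUMNS = ("uniprot_id", "target_name", "gene_symbol", "herbs")


def read_target_table(path: str | Path, delimiter: str = "\t") -> list[TargetRecord]:
    """Read a drug-target table; herb attributions are '/'-joined codes."""
    records: list[TargetRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return records
        missing = [c for c in _TARGET_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        for row in reader:
            records.append(
                TargetRecord(
                    uniprot_id=row["uniprot_id"].strip(),
                    target_name=row["target_name"].strip(),
                    gene_symbol=row["gene_symbol"].strip(),
                    herbs=frozenset(h for h in row["herbs"].split("/") if h.strip()),
                )
            )
    return records


def write_target_table(
    records: Sequence[TargetRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(_TARGET_COLUMNS)
        for r in records:
            herbs = "/".join(h for h in HERB_CODES if h in r.herbs)
            writer.writerow([r.uniprot_id, r.target_name, r.gene_symbol, herbs])


def read_disease_table(
    path: str | Path, delimiter: str = "\t"
) -> list[DiseaseTargetRecord]:
    """Read a disease gene list with an optional ``inference_score`` column."""
    records: list[DiseaseTargetRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return records
        if "gene_symbol" not in reader.fieldnames:
            raise FormatError(f"{path}: missing required column: gene_symbol")
        has_score = "inference_score" in reader.fieldnames
        for rownum, row in enumerate(reader, start=2):
            score: Optional[float] = None
            if has_score and row["inference_score"].strip():
                try:
                    score = float(row["inference_score"])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}, row {rownum}: cannot parse inference_score="
                        f"{row['inference_score']!r}"
                    ) from exc
            records.append(
                DiseaseTargetRecord(
                    gene_symbol=row["gene_symbol"].strip(), inference_score=score
                )
            )
    return records


def write_disease_table(
    records: Sequence[DiseaseTargetRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["gene_symbol", "inference_score"])
        for r in records:
            writer.writerow(
                [r.gene_symbol, "" if r.inference_score is None else r.inference_score]
            )


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, score_scale: str = "unit") -> InteractionNetwork:
    """Read a 3-column (nodeA, nodeB, score) whitespace-delimited edge list.

    ``score_scale="unit"`` expects scores in [0, 1]; ``"string1000"`` expects
    0-999 integers and divides by 1000. Duplicate A-B/B-A rows collapse
    keeping the maximum confidence; self-loop rows are dropped with a warning.
    """
    if score_scale not in ("unit", "string1000"):
        raise ValueError(f"unknown score_scale: {score_scale!r}")
    net = InteractionNetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                # "#node<TAB>name" lines declare isolated nodes
                parts = line.split()
                if parts[0] == "#node" and len(parts) == 2:
                    net.add_node(parts[1])
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(
                    f"{path}, line {lineno}: expected 3 columns, got {len(parts)}"
                )
            u, v, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{path}, line {lineno}: cannot parse score {raw!r}"
                ) from exc
            if score_scale == "string1000":
                if not 0 <= score <= 999:
                    raise FormatError(
                        f"{path}, line {lineno}: score {score} outside 0-999"
                    )
                score /= 1000.0
            elif not 0.0 <= score <= 1.0:
                raise FormatError(
                    f"{path}, line {lineno}: score {score} outside [0, 1]"
                )
            net.add_node(u)
            net.add_node(v)
            if u == v:
                logger.warning("%s, line %d: dropping self-loop %s-%s", path, lineno, u, v)
                continue
            net.add_edge(u, v, score)
    return net


def write_edge_list(
    net: InteractionNetwork, path: str | Path, score_scale: str = "unit"
) -> None:
    """Write a 3-column edge list plus isolated nodes as comment lines."""
    if score_scale not in ("unit", "string1000"):
        raise ValueError(f"unknown score_scale: {score_scale!r}")
    g = net.to_networkx()
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, c in net.edges():
            score = round(c * 1000) if score_scale == "string1000" else c
            fh.write(f"{u}\t{v}\t{score}\n")
        for n in sorted(net.nodes):
            if g.degree(n) == 0:
                fh.write(f"#node\t{n}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read standard GMT (set_id TAB description TAB member...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}, line {lineno}: expected >= 3 tab-separated fields"
                )
            set_id, description = fields[0], fields[1]
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            sets[set_id] = (description, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(collection.sets):
            description, members = collection.sets[set_id]
            fh.write("\t".join([set_id, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# network export (Cytoscape-compatible)
# ---------------------------------------------------------------------------


def write_network(
    net: InteractionNetwork,
    out_prefix: str | Path,
    node_attrs: Optional[Mapping[str, Mapping[str, object]]] = None,
    formats: Sequence[str] = ("sif", "graphml"),
) -> dict[str, Path]:
    """Export a network as SIF and/or GraphML plus attribute tables.

    SIF uses the relation label ``pp``; isolated nodes are written as
    single-field SIF lines. Returns a map of format name to written path.
    """
    out_prefix = Path(out_prefix)
    if node_attrs:
        unknown = set(node_attrs) - net.nodes
        if unknown:
            raise FormatError(
                f"node attribute rows for unknown node(s): {sorted(unknown)}"
            )
    written: dict[str, Path] = {}
    g = net.to_networkx()
    for fmt in formats:
        if fmt == "sif":
            p = out_prefix.with_suffix(".sif")
            with open(p, "w", encoding="utf-8") as fh:
                for u, v, _ in net.edges():
                    fh.write(f"{u}\tpp\t{v}\n")
                for n in sorted(net.nodes):
                    if g.degree(n) == 0:
                        fh.write(f"{n}\n")
            written["sif"] = p
        elif fmt == "graphml":
            p = out_prefix.with_suffix(".graphml")
            gx = net.to_networkx()
            if node_attrs:
                for n, attrs in node_attrs.items():
                    gx.nodes[n].update(attrs)
            nx.write_graphml(gx, p)
            written["graphml"] = p
        elif fmt == "tables":
            ep = Path(str(out_prefix) + ".edges.tsv")
            with open(ep, "w", encoding="utf-8") as fh:
                fh.write("source\ttarget\tconfidence\n")
                for u, v, c in net.edges():
                    fh.write(f"{u}\t{v}\t{c}\n")
            written["edges"] = ep
            np_ = Path(str(out_prefix) + ".nodes.tsv")
            keys: list[str] = sorted(
                {k for attrs in (node_attrs or {}).values() for k in attrs}
            )
            with open(np_, "w", encoding="utf-8") as fh:
                fh.write("\t".join(["node", *keys]) + "\n")
                for n in sorted(net.nodes):
                    attrs = (node_attrs or {}).get(n, {})
                    fh.write("\t".join([n, *(str(attrs.get(k, "")) for k in keys)]) + "\n")
            written["nodes"] = np_
        else:
            raise ValueError(f"unknown export format: {fmt!r}")
    return written


def read_sif(path: str | Path) -> InteractionNetwork:
    """Read a SIF export back (confidences are not stored in SIF; 1.0 used)."""
    net = InteractionNetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                net.add_node(fields[0])
            elif len(fields) >= 3:
                source, _, targets = fields[0], fields[1], fields[2:]
                net.add_node(source)
                for t in targets:
                    net.add_node(t)
                    net.add_edge(source, t, 1.0)
            else:
                raise FormatError(f"{path}, line {lineno}: malformed SIF line")
    return net


def read_graphml(path: str | Path) -> InteractionNetwork:
    return InteractionNetwork.from_networkx(nx.read_graphml(path))


# ---------------------------------------------------------------------------
# packaged study fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("netpharm").joinpath("data", name)))


def load_table1() -> list[CompoundRecord]:
    """The packaged 77-row herb-compound descriptor table."""
    return read_compound_table(_fixture_path("table1_compounds.tsv"))


def load_table2() -> list[TargetRecord]:
    """The packaged 161-row drug-target table."""
    return read_target_table(_fixture_path("table2_targets.tsv"))


def load_table3() -> list[DiseaseTargetRecord]:
    """The packaged 38-gene disease-target list (no inference scores printed)."""
    return read_disease_table(_fixture_path("table3_disease_targets.tsv"))
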