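"""Seeded generators for every input the pipeline consumes.

Each generator draws from its own RNG stream derived from (seed, generator
name), so adding a generator never perturbs the others' outputs. Defaults
mirror the scale of the study tables: ~77 passing compounds over eight
herbs, 161 drug targets, 200 scored disease targets with a 38-gene
overlap, and a 38-node PPI network with a planted 7-clique core.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tables_io import (
    HERB_CODES,
    CompoundRecord,
    DiseaseTargetRecord,
    GeneSetCollection,
    InteractionNetwork,
    TargetRecord,
    write_compound_table,
    write_disease_table,
    write_edge_list,
    write_gene_list,
    write_gmt,
    write_target_table,
)

#: Inclusive descriptor box within which generated records pass the default screen.
_PASS_BOX = {
    "mw": (180.0, 499.9),
    "alogp": (-2.0, 4.99),
    "hdon": (0, 5),
    "hacc": (0, 10),
    "ob": (30.01, 120.0),
    "dl": (0.181, 0.999),
}
#: Ranges guaranteeing a single-criterion violation (safe against rounding).
_FAIL_RANGES = {
    "mw": (501.0, 800.0),
    "alogp": (5.01, 8.0),
    "hdon": (6, 10),
    "hacc": (11, 15),
    "ob": (0.0, 29.5),
    "dl": (0.0, 0.175),
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs for all synthetic generators."""

    seed: int = 0
    # compound table
    n_compounds: int = 100
    pass_fraction: float = 0.77
    # target lists
    n_targets: int = 161
    n_disease: int = 200
    overlap: int = 38
    disease_score_min: float = 57.56
    # planted-core PPI network
    core_size: int = 7
    n_periphery: int = 31
    periphery_edge_prob: float = 0.05
    core_attach: int = 2
    # annotation collection
    n_sets: int = 20
    planted_set_size: int = 25
    planted_overlap: int = 10
    n_background: int = 500
    query_size: int = 38

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise ValueError("pass_fraction must lie in [0, 1]")
        if not 0.0 <= self.periphery_edge_prob <= 1.0:
            raise ValueError("periphery_edge_prob must lie in [0, 1]")
        if self.overlap > min(self.n_targets, self.n_disease):
            raise ValueError("overlap exceeds a target list size")
        if self.core_size < 2:
            raise ValueError("core_size must be at least 2")
        if self.core_attach < 0 or self.core_attach > self.core_size:
            raise ValueError("core_attach must lie in [0, core_size]")
        if self.planted_overlap > min(self.planted_set_size, self.query_size):
            raise ValueError("planted_overlap exceeds set or query size")
        if self.planted_set_size > self.n_background:
            raise ValueError("planted_set_size exceeds background size")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0xFFFFFFFF, zlib.crc32(stream.encode())])


def gen_compound_table(cfg: SimConfig) -> list[CompoundRecord]:
    """Descriptor table in which exactly round(pass_fraction * n) rows pass
    the default six-criterion screen; failing rows violate one criterion
    chosen uniformly. Herbs are assigned round-robin."""
    rng = _rng(cfg, "compounds")
    n = cfg.n_compounds
    n_pass = round(cfg.pass_fraction * n)
    pass_idx = set(rng.choice(n, size=n_pass, replace=False).tolist())
    records = []
    for i in range(n):
        vals = {
            "mw": round(float(rng.uniform(*_PASS_BOX["mw"])), 2),
            "alogp": round(float(rng.uniform(*_PASS_BOX["alogp"])), 2),
            "hdon": int(rng.integers(_PASS_BOX["hdon"][0], _PASS_BOX["hdon"][1] + 1)),
            "hacc": int(rng.integers(_PASS_BOX["hacc"][0], _PASS_BOX["hacc"][1] + 1)),
            "ob": round(float(rng.uniform(*_PASS_BOX["ob"])), 2),
            "dl": round(float(rng.uniform(*_PASS_BOX["dl"])), 3),
        }
        if i not in pass_idx:
            field = list(_FAIL_RANGES)[int(rng.integers(0, 6))]
            lo, hi = _FAIL_RANGES[field]
            if field in ("hdon", "hacc"):
                vals[field] = int(rng.integers(lo, hi + 1))
            elif field == "dl":
                vals[field] = round(float(rng.uniform(lo, hi)), 3)
            else:
                vals[field] = round(float(rng.uniform(lo, hi)), 2)
        records.append(
            CompoundRecord(
                mol_id=f"MOL{i:06d}",
                name=f"compound-{i}",
                herb=HERB_CODES[i % len(HERB_CODES)],
                **vals,
            )
        )
    return records


def gen_target_sets(
    cfg: SimConfig,
) -> tuple[list[TargetRecord], list[DiseaseTargetRecord], frozenset[str]]:
    """Drug and disease target lists with an exactly planted gene overlap.

    Disease inference scores are drawn at or above ``cfg.disease_score_min``
    so filtering at that threshold retains every record.
    """
    rng = _rng(cfg, "targets")
    shared = [f"CG{i:04d}" for i in range(cfg.overlap)]
    drug_only = [f"DG{i:04d}" for i in range(cfg.n_targets - cfg.overlap)]
    disease_only = [f"SG{i:04d}" for i in range(cfg.n_disease - cfg.overlap)]

    drug_records = []
    for i, sym in enumerate(shared + drug_only):
        n_herbs = int(rng.integers(1, 4))
        herbs = rng.choice(len(HERB_CODES), size=n_herbs, replace=False)
        drug_records.append(
            TargetRecord(
                uniprot_id=f"U{i:05d}",
                target_name=f"protein {sym}",
                gene_symbol=sym,
                herbs=frozenset(HERB_CODES[j] for j in herbs),
            )
        )
    disease_records = [
        DiseaseTargetRecord(
            gene_symbol=sym,
            inference_score=round(float(rng.uniform(cfg.disease_score_min, 150.0)), 2),
        )
        for sym in shared + disease_only
    ]
    return drug_records, disease_records, frozenset(shared)


def gen_planted_core_network(cfg: SimConfig) -> tuple[InteractionNetwork, frozenset[str]]:
    """PPI network with a planted clique core and a sparse periphery.

    Core nodes form a clique of ``core_size``; each periphery node attaches
    to ``core_attach`` uniformly chosen core nodes and to other periphery
    nodes independently with ``periphery_edge_prob``. All confidences are
    drawn in [0.7, 1.0]. With defaults, every core node dominates every
    periphery node on degree, closeness and betweenness with high
    probability.
    """
    rng = _rng(cfg, "ppi")
    core = [f"CORE{i:02d}" for i in range(cfg.core_size)]
    periphery = [f"PER{i:02d}" for i in range(cfg.n_periphery)]
    net = InteractionNetwork()
    for n in core + periphery:
        net.add_node(n)
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            net.add_edge(core[i], core[j], round(float(rng.uniform(0.7, 1.0)), 3))
    for p in periphery:
        for j in rng.choice(cfg.core_size, size=cfg.core_attach, replace=False):
            net.add_edge(p, core[j], round(float(rng.uniform(0.7, 1.0)), 3))
    for i in range(len(periphery)):
        for j in range(i + 1, len(periphery)):
            if rng.random() < cfg.periphery_edge_prob:
                net.add_edge(periphery[i], periphery[j],
                             round(float(rng.uniform(0.7, 1.0)), 3))
    return net, frozenset(core)


def gen_annotation_collection(
    cfg: SimConfig,
) -> tuple[GeneSetCollection, str, list[str]]:
    """Annotation sets with one planted enriched set against a random query.

    The planted set shares ``planted_overlap`` genes with the query; the
    ``n_sets`` decoy sets are uniform draws from the background (null
    overlap). Returns (collection, planted set id, query genes).
    """
    rng = _rng(cfg, "annotations")
    background = [f"G{i:04d}" for i in range(cfg.n_background)]
    query = [background[i] for i in rng.choice(cfg.n_background, size=cfg.query_size,
                                               replace=False)]
    non_query = [g for g in background if g not in set(query)]
    planted_in = [query[i] for i in rng.choice(cfg.query_size, size=cfg.planted_overlap,
                                               replace=False)]
    n_out = cfg.planted_set_size - cfg.planted_overlap
    planted_out = [non_query[i] for i in rng.choice(len(non_query), size=n_out,
                                                    replace=False)]
    planted_id = "SET_PLANTED"
    sets: dict[str, tuple[str, frozenset[str]]] = {
        planted_id: ("planted enriched set", frozenset(planted_in + planted_out))
    }
    for s in range(cfg.n_sets):
        members = [background[i] for i in rng.choice(cfg.n_background,
                                                     size=cfg.planted_set_size,
                                                     replace=False)]
        sets[f"SET{s:03d}"] = (f"decoy set {s}", frozenset(members))
    collection = GeneSetCollection(sets=sets, background=frozenset(background))
    return collection, planted_id, query


def write_scenario(cfg: SimConfig, outdir: str | Path, scenario: str = "all") -> list[Path]:
    """Materialize generator outputs in the text formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    if scenario in ("compounds", "all"):
        write_compound_table(gen_compound_table(cfg), _w(outdir / "compounds.tsv"))
    if scenario in ("targets", "all"):
        drug, disease, _ = gen_target_sets(cfg)
        write_target_table(drug, _w(outdir / "drug_targets.tsv"))
        write_disease_table(disease, _w(outdir / "disease_targets.tsv"))
    if scenario in ("ppi", "all"):
        net, core = gen_planted_core_network(cfg)
        write_edge_list(net, _w(outdir / "ppi_edges.tsv"))
        write_gene_list(sorted(core), _w(outdir / "planted_core.txt"))
    if scenario in ("annotations", "all"):
        collection, planted_id, query = gen_annotation_collection(cfg)
        write_gmt(collection, _w(outdir / "annotations.gmt"))
        write_gene_list(query, _w(outdir / "query_genes.txt"))
        write_gene_list(sorted(collection.background or ()), _w(outdir / "background.txt"))
        (outdir / "planted_set.txt").write_text(planted_id + "\n")
        written.append(outdir / "planted_set.txt")
    if not written:
        raise ValueError(f"unknown scenario: {scenario!r}")
    return written
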