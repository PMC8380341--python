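"""Direction-consistent ceRNA network assembly, integration and export.

Edges connect a differentially expressed miRNA to a differentially
expressed partner (mRNA, lncRNA or circRNA) with the opposite direction,
supported by an intersection-passing target prediction.  Triads join a
sponge edge and an mRNA edge sharing a miRNA; quads join one lncRNA triad
and one circRNA triad sharing both the miRNA and the mRNA.  Hub genes are
mRNA nodes ranked by distinct-miRNA degree.  Networks export as SIF,
GraphML and plain TSVs (Cytoscape-ready).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

SPONGE_CLASSES = ("lncRNA", "circRNA")
INTERACTION_LABEL = {"mRNA": "mir_mrna", "lncRNA": "mir_lnc", "circRNA": "mir_circ"}
CLASS_FROM_LABEL = {v: k for k, v in INTERACTION_LABEL.items()}


@dataclass(frozen=True)
class CeRNAEdge:
    mirna_id: str
    mirna_direction: str
    partner_id: str
    partner_class: str
    partner_direction: str


@dataclass(frozen=True)
class CeRNATriad:
    sponge_id: str
    sponge_class: str
    mirna_id: str
    mrna_id: str
    pattern: str  # up-down-up | down-up-down


@dataclass(frozen=True)
class Quad:
    lncrna_id: str
    circrna_id: str
    mirna_id: str
    mrna_id: str


@dataclass
class CeRNANetwork:
    edges: list[CeRNAEdge] = field(default_factory=list)
    triads: list[CeRNATriad] = field(default_factory=list)
    quads: list[Quad] = field(default_factory=list)
    node_class: dict[str, str] = field(default_factory=dict)
    node_direction: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.node_class)

    def degree(self, node_id: str) -> int:
        return sum(1 for e in self.edges if node_id in (e.mirna_id, e.partner_id))


@dataclass
class HubRanking:
    ranking: list[tuple[str, int]]  # (mrna_id, distinct-miRNA degree), sorted

    def top(self, k: int) -> list[tuple[str, int]]:
        return self.ranking[:k]


def build_edges(
    de_records: pd.DataFrame,
    target_pairs: pd.DataFrame,
    permissive: bool = False,
) -> list[CeRNAEdge]:
    """One edge per intersection-passing pair whose endpoints are DE and
    anticorrelated.

    ``permissive=True`` drops the opposite-direction requirement (both
    endpoints must still be differentially expressed).
    """
    direction = dict(zip(de_records["feature_id"], de_records["direction"]))
    rna_class = dict(zip(de_records["feature_id"], de_records["class"]))
    edges: list[CeRNAEdge] = []
    for row in target_pairs.itertuples(index=False):
        if not row.passes:
            continue
        for fid in (row.mirna_id, row.target_id):
            if fid not in direction:
                raise ValueError(f"target pair references feature absent from DE table: {fid}")
        mdir = direction[row.mirna_id]
        pdir = direction[row.target_id]
        if mdir == "ns" or pdir == "ns":
            continue
        if not permissive and mdir == pdir:
            continue
        edges.append(
            CeRNAEdge(
                mirna_id=row.mirna_id,
                mirna_direction=mdir,
                partner_id=row.target_id,
                partner_class=rna_class[row.target_id],
                partner_direction=pdir,
            )
        )
    edges.sort(key=lambda e: (e.mirna_id, e.partner_class, e.partner_id))
    return edges


def assemble_triads(edges: Iterable[CeRNAEdge]) -> list[CeRNATriad]:
    """All (sponge, miRNA, mRNA) combinations sharing a miRNA with the sponge
    and the mRNA in the same direction (opposite to the miRNA)."""
    by_mirna: dict[str, list[CeRNAEdge]] = {}
    for e in edges:
        by_mirna.setdefault(e.mirna_id, []).append(e)
    triads: list[CeRNATriad] = []
    for mid in sorted(by_mirna):
        group = by_mirna[mid]
        sponges = [e for e in group if e.partner_class in SPONGE_CLASSES]
        mrnas = [e for e in group if e.partner_class == "mRNA"]
        for s in sponges:
            for g in mrnas:
                if s.partner_direction != g.partner_direction:
                    continue
                pattern = (
                    "up-down-up" if s.partner_direction == "up" else "down-up-down"
                )
                triads.append(
                    CeRNATriad(
                        sponge_id=s.partner_id,
                        sponge_class=s.partner_class,
                        mirna_id=mid,
                        mrna_id=g.partner_id,
                        pattern=pattern,
                    )
                )
    triads.sort(key=lambda t: (t.mirna_id, t.sponge_id, t.mrna_id))
    return triads


def integrate_networks(
    triads: Iterable[CeRNATriad],
    edges: Iterable[CeRNAEdge] = (),
    require_shared_mrna: bool = True,
) -> CeRNANetwork:
    """Integrated network: quads join an lncRNA triad and a circRNA triad
    sharing the miRNA (and, by default, also the mRNA)."""
    triads = list(triads)
    lnc = [t for t in triads if t.sponge_class == "lncRNA"]
    circ = [t for t in triads if t.sponge_class == "circRNA"]
    quads: list[Quad] = []
    seen: set[Quad] = set()
    for a in lnc:
        for b in circ:
            if a.mirna_id != b.mirna_id:
                continue
            if require_shared_mrna and a.mrna_id != b.mrna_id:
                continue
            for mrna in {a.mrna_id, b.mrna_id} if not require_shared_mrna else {a.mrna_id}:
                q = Quad(a.sponge_id, b.sponge_id, a.mirna_id, mrna)
                if q not in seen:
                    seen.add(q)
                    quads.append(q)
    quads.sort(key=lambda q: (q.mirna_id, q.lncrna_id, q.circrna_id, q.mrna_id))

    net = CeRNANetwork(triads=triads, quads=quads)
    edge_set: dict[CeRNAEdge, None] = {}
    for e in edges:
        edge_set.setdefault(e)
    net.edges = sorted(
        edge_set, key=lambda e: (e.mirna_id, e.partner_class, e.partner_id)
    )
    for e in net.edges:
        net.node_class[e.mirna_id] = "miRNA"
        net.node_direction[e.mirna_id] = e.mirna_direction
        net.node_class[e.partner_id] = e.partner_class
        net.node_direction[e.partner_id] = e.partner_direction
    return net


def hub_ranking(network: CeRNANetwork, top_k: int = 10) -> HubRanking:
    """mRNA nodes ranked by number of distinct miRNA partners."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    partners: dict[str, set[str]] = {}
    for e in network.edges:
        if e.partner_class == "mRNA":
            partners.setdefault(e.partner_id, set()).add(e.mirna_id)
    ranked = sorted(partners.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return HubRanking(ranking=[(g, len(ms)) for g, ms in ranked])


def to_networkx(network: CeRNANetwork) -> nx.Graph:
    g = nx.Graph()
    for node in network.nodes:
        g.add_node(
            node,
            rna_class=network.node_class[node],
            direction=network.node_direction[node],
            degree=network.degree(node),
        )
    for e in network.edges:
        g.add_edge(
            e.mirna_id, e.partner_id, interaction=INTERACTION_LABEL[e.partner_class]
        )
    return g


def write_sif(network: CeRNANetwork, path: str | Path) -> None:
    lines = [
        f"{e.mirna_id}\t{INTERACTION_LABEL[e.partner_class]}\t{e.partner_id}"
        for e in network.edges
    ]
    Path(path).write_text("\n".join(sorted(set(lines))) + ("\n" if lines else ""))


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    triples = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: malformed SIF line")
        triples.append(tuple(parts))
    return triples


def write_graphml(network: CeRNANetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(network), str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def export_network(network: CeRNANetwork, out_dir: str | Path, fmt: str = "all") -> dict[str, str]:
    """Write SIF / GraphML / TSV representations; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    known = {"SIF", "GraphML", "TSV", "all"}
    if fmt not in known:
        raise ValueError(f"unknown export format: {fmt!r}")
    written: dict[str, str] = {}
    if fmt in ("SIF", "all"):
        p = out / "network.sif"
        write_sif(network, p)
        written["sif"] = str(p)
    if fmt in ("GraphML", "all"):
        p = out / "network.graphml"
        write_graphml(network, p)
        written["graphml"] = str(p)
    if fmt in ("TSV", "all"):
        nodes = pd.DataFrame(
            [
                (
                    n,
                    network.node_class[n],
                    network.node_direction[n],
                    network.degree(n),
                )
                for n in network.nodes
            ],
            columns=["id", "class", "direction", "degree"],
        )
        edges = pd.DataFrame(
            [
                (
                    e.mirna_id,
                    e.mirna_direction,
                    e.partner_id,
                    e.partner_class,
                    e.partner_direction,
                )
                for e in network.edges
            ],
            columns=[
                "mirna_id",
                "mirna_direction",
                "partner_id",
                "partner_class",
                "partner_direction",
            ],
        )
        triads = pd.DataFrame(
            [
                (t.sponge_id, t.sponge_class, t.mirna_id, t.mrna_id, t.pattern)
                for t in network.triads
            ],
            columns=["sponge_id", "sponge_class", "mirna_id", "mrna_id", "pattern"],
        )
        quads = pd.DataFrame(
            [(q.lncrna_id, q.circrna_id, q.mirna_id, q.mrna_id) for q in network.quads],
            columns=["lncrna_id", "circrna_id", "mirna_id", "mrna_id"],
        )
        for name, frame in (
            ("nodes", nodes),
            ("edges", edges),
            ("triads", triads),
            ("quads", quads),
        ):
            p = out / f"{name}.tsv"
            frame.to_csv(p, sep="\t", index=False)
            written[name] = str(p)
    return written
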