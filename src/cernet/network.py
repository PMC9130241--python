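"""Direction-consistent ceRNA triple assembly and trend-network construction.

A ceRNA triple joins a lncRNA-miRNA pair and a miRNA-mRNA pair on the
shared miRNA. A biologically meaningful triple has the sponge (lncRNA)
and the protected target (mRNA) co-directional with the miRNA opposite:
high-low-high (HLH: up/down/up in tumour) or low-high-low (LHL:
down/up/down). Discordant triples are discarded before graph building.

Graphs are ``networkx.Graph`` objects. Node keys are internally
namespaced by molecule type (``"lncRNA:FOO"``) to keep symbol collisions
between classes impossible; exports strip the prefix and carry the type
as a node attribute.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "CeRNATriple",
    "Hub",
    "assemble_triples",
    "split_by_direction",
    "build_graph",
    "find_hubs",
    "extract_subnetwork",
    "export_network",
    "import_network",
    "network_summary",
]

NODE_TYPES = ("lncRNA", "miRNA", "mRNA")
EDGE_TYPES = {"lnc-mir", "mir-mrna"}


@dataclass(frozen=True)
class CeRNATriple:
    lncRNA: str
    miRNA: str
    mRNA: str
    directions: tuple[str, str, str]
    trend: str  # HLH | LHL | discordant

    @staticmethod
    def classify(directions: tuple[str, str, str]) -> str:
        if directions == ("up", "down", "up"):
            return "HLH"
        if directions == ("down", "up", "down"):
            return "LHL"
        return "discordant"


@dataclass(frozen=True)
class Hub:
    node: str
    node_type: str
    degree: int


def _key(node_type: str, name: str) -> str:
    return f"{node_type}:{name}"


def assemble_triples(
    lnc_mir_pairs,
    mir_mrna_pairs,
    directions: dict[str, dict[str, str]],
) -> list[CeRNATriple]:
    """Enumerate every triple where a lncRNA and an mRNA share a miRNA.

    ``directions`` maps RNA class -> {molecule: "up"/"down"}; a molecule
    missing its direction is an error (pairs must be DE-filtered first).
    """
    mir_to_mrna: dict[str, list[str]] = {}
    for m, g in mir_mrna_pairs:
        mir_to_mrna.setdefault(m, []).append(g)

    def direction_of(cls: str, mol: str) -> str:
        try:
            return directions[cls][mol]
        except KeyError:
            raise ValueError(f"{cls} {mol!r} has no direction call") from None

    triples = []
    for lnc, mir in sorted(lnc_mir_pairs):
        for mrna in sorted(mir_to_mrna.get(mir, ())):
            dirs = (
                direction_of("lncRNA", lnc),
                direction_of("miRNA", mir),
                direction_of("mRNA", mrna),
            )
            triples.append(
                CeRNATriple(lnc, mir, mrna, dirs, CeRNATriple.classify(dirs))
            )
    return triples


def split_by_direction(triples) -> dict[str, list[CeRNATriple]]:
    """Partition triples into HLH and LHL lists, discarding discordant ones."""
    out: dict[str, list[CeRNATriple]] = {"HLH": [], "LHL": []}
    n_discard = 0
    for t in triples:
        if t.trend in out:
            out[t.trend].append(t)
        else:
            n_discard += 1
    logger.info(
        "trend split: %d HLH, %d LHL, %d discordant discarded",
        len(out["HLH"]), len(out["LHL"]), n_discard,
    )
    return out


def build_graph(triples, trend: str | None = None) -> nx.Graph:
    """Typed undirected graph of the unique lnc-mir and mir-mRNA edges.

    All triples must share one trend (pass ``trend`` to assert which, or
    let it be inferred); mixing trends raises.
    """
    trends = {t.trend for t in triples}
    if len(trends) > 1:
        raise ValueError(f"mixed-trend triple list: {sorted(trends)}")
    if trend is None:
        trend = trends.pop() if trends else "empty"
    elif trends and trends != {trend}:
        raise ValueError(f"triples have trend {trends.pop()}, expected {trend}")

    g = nx.Graph(trend=trend)
    for t in triples:
        d_l, d_m, d_g = t.directions
        kl, km, kg = _key("lncRNA", t.lncRNA), _key("miRNA", t.miRNA), _key("mRNA", t.mRNA)
        g.add_node(kl, label=t.lncRNA, node_type="lncRNA", direction=d_l)
        g.add_node(km, label=t.miRNA, node_type="miRNA", direction=d_m)
        g.add_node(kg, label=t.mRNA, node_type="mRNA", direction=d_g)
        g.add_edge(kl, km, edge_type="lnc-mir")
        g.add_edge(km, kg, edge_type="mir-mrna")
    logger.info(
        "%s network: %d nodes, %d edges", trend, g.number_of_nodes(), g.number_of_edges()
    )
    return g


def find_hubs(network: nx.Graph, hub_threshold: int = 5) -> list[Hub]:
    """Nodes whose unique-edge degree strictly exceeds hub_threshold.

    Sorted by degree descending, ties broken by node label.
    """
    hubs = [
        Hub(data["label"], data["node_type"], network.degree(n))
        for n, data in network.nodes(data=True)
        if network.degree(n) > hub_threshold
    ]
    return sorted(hubs, key=lambda h: (-h.degree, h.node))


def extract_subnetwork(network: nx.Graph, seed_mrnas) -> nx.Graph:
    """Two-step neighbourhood of the seed mRNAs.

    Keeps the seeds, the miRNAs adjacent to them, and the lncRNAs adjacent
    to those miRNAs, with only the connecting edges; every retained node
    therefore lies on a path to a seed mRNA.
    """
    seeds = list(seed_mrnas)
    if not seeds:
        raise ValueError("empty seed mRNA list")
    keys = []
    for s in seeds:
        k = _key("mRNA", s)
        if k in network:
            keys.append(k)
        else:
            warnings.warn(f"seed mRNA {s!r} not in network; skipped")
    sub = nx.Graph(trend=network.graph.get("trend"))
    for kg in keys:
        sub.add_node(kg, **network.nodes[kg])
        for km in network.neighbors(kg):
            if network.nodes[km]["node_type"] != "miRNA":
                continue
            sub.add_node(km, **network.nodes[km])
            sub.add_edge(km, kg, **network.edges[km, kg])
            for kl in network.neighbors(km):
                if network.nodes[kl]["node_type"] != "lncRNA":
                    continue
                sub.add_node(kl, **network.nodes[kl])
                sub.add_edge(kl, km, **network.edges[kl, km])
    return sub


def network_summary(network: nx.Graph, hub_threshold: int = 5) -> dict:
    """Counts mirroring the usual network accounting: nodes, edges, hubs, per-class nodes."""
    by_type = {t: 0 for t in NODE_TYPES}
    for _, data in network.nodes(data=True):
        by_type[data["node_type"]] += 1
    return {
        "trend": network.graph.get("trend"),
        "nodes": network.number_of_nodes(),
        "edges": network.number_of_edges(),
        "hubs": len(find_hubs(network, hub_threshold)),
        "n_lncRNA": by_type["lncRNA"],
        "n_miRNA": by_type["miRNA"],
        "n_mRNA": by_type["mRNA"],
    }


def export_network(network: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as SIF, GraphML or JSON.

    GraphML and JSON round-trip through :func:`import_network` to an
    identical graph (nodes, edges and attributes). SIF carries topology
    and edge types only.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        # orient each row regulator-first (lncRNA before miRNA, miRNA before mRNA)
        first = {"lnc-mir": "lncRNA", "mir-mrna": "miRNA"}
        rows = []
        for u, v, data in network.edges(data=True):
            if network.nodes[u]["node_type"] != first[data["edge_type"]]:
                u, v = v, u
            rows.append((network.nodes[u]["label"], data["edge_type"], network.nodes[v]["label"]))
        with open(path, "w") as fh:
            for lu, etype, lv in sorted(rows):
                fh.write(f"{lu}\t{etype}\t{lv}\n")
    elif fmt == "graphml":
        g = nx.Graph(trend=str(network.graph.get("trend")))
        for n, data in network.nodes(data=True):
            g.add_node(
                data["label"],
                node_type=data["node_type"],
                direction=data["direction"],
                degree=int(network.degree(n)),
            )
        for u, v, data in network.edges(data=True):
            g.add_edge(
                network.nodes[u]["label"], network.nodes[v]["label"],
                edge_type=data["edge_type"],
            )
        nx.write_graphml(g, path)
    elif fmt == "json":
        payload = {
            "trend": network.graph.get("trend"),
            "nodes": [
                {
                    "id": d["label"],
                    "type": d["node_type"],
                    "direction": d["direction"],
                    "degree": int(network.degree(n)),
                }
                for n, d in sorted(network.nodes(data=True))
            ],
            "edges": [
                {
                    "source": network.nodes[u]["label"],
                    "target": network.nodes[v]["label"],
                    "type": d["edge_type"],
                }
                for u, v, d in sorted(network.edges(data=True))
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown export format {fmt!r} (use sif, graphml or json)")


def import_network(path, fmt: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network` back into the internal form."""
    fmt = fmt.lower()
    path = Path(path)
    g = nx.Graph()
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        g.graph["trend"] = raw.graph.get("trend")
        for n, d in raw.nodes(data=True):
            g.add_node(
                _key(d["node_type"], n),
                label=n, node_type=d["node_type"], direction=d["direction"],
            )
        for u, v, d in raw.edges(data=True):
            ku = _key(raw.nodes[u]["node_type"], u)
            kv = _key(raw.nodes[v]["node_type"], v)
            g.add_edge(ku, kv, edge_type=d["edge_type"])
    elif fmt == "json":
        payload = json.loads(path.read_text())
        g.graph["trend"] = payload["trend"]
        types = {}
        for nd in payload["nodes"]:
            types[nd["id"]] = nd["type"]
            g.add_node(
                _key(nd["type"], nd["id"]),
                label=nd["id"], node_type=nd["type"], direction=nd["direction"],
            )
        for e in payload["edges"]:
            g.add_edge(
                _key(types[e["source"]], e["source"]),
                _key(types[e["target"]], e["target"]),
                edge_type=e["type"],
            )
    elif fmt == "sif":
        # SIF has no node attributes: types are recovered from edge types
        # and edge order (regulator first), directions are unknown.
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                src, etype, tgt = line.rstrip("\n").split("\t")
                if etype == "lnc-mir":
                    tu, tv = "lncRNA", "miRNA"
                elif etype == "mir-mrna":
                    tu, tv = "miRNA", "mRNA"
                else:
                    raise ValueError(f"unknown SIF edge type {etype!r}")
                g.add_node(_key(tu, src), label=src, node_type=tu, direction=None)
                g.add_node(_key(tv, tgt), label=tgt, node_type=tv, direction=None)
                g.add_edge(_key(tu, src), _key(tv, tgt), edge_type=etype)
    else:
        raise ValueError(f"unknown import format {fmt!r}")
    return g


def graphs_equal(a: nx.Graph, b: nx.Graph, attrs: bool = True) -> bool:
    """Structural (and optionally attribute-level) graph equality."""
    if set(a.nodes) != set(b.nodes) or set(map(frozenset, a.edges)) != set(
        map(frozenset, b.edges)
    ):
        return False
    if not attrs:
        return True
    for n in a.nodes:
        da, db = a.nodes[n], b.nodes[n]
        for k in ("label", "node_type", "direction"):
            if da.get(k) != db.get(k):
                return False
    for u, v in a.edges:
        if a.edges[u, v].get("edge_type") != b.edges[u, v].get("edge_type"):
            return False
    return True
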