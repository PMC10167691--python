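"""Prior-knowledge networks: signed directed gene graphs.

A PKN is a directed graph over gene symbols whose edges carry a
regulatory sign: +1 for activation, -1 for inhibition.  Networks are
read from graphml (the exchange format used by pathway databases and
network editors) or from KEGG KGML, and written back to graphml with
optional per-node score annotations.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

ACTIVATION = 1
INHIBITION = -1

#: graphml edge-attribute values understood as activation / inhibition.
_ACTIVATION_TOKENS = {"a", "activation", "+", "1", "+1"}
_INHIBITION_TOKENS = {"i", "inhibition", "-", "-1"}

#: graphml edge attributes probed, in order, for the regulatory sign.
_SIGN_ATTRS = ("signal", "interaction")


class EmptyNetworkError(ValueError):
    """Raised when a parsed network contains no nodes."""


def _normalize_gene(name: str) -> str:
    return str(name).strip().upper()


@dataclass
class SignedNetwork:
    """A signed, directed prior-knowledge network.

    Parameters
    ----------
    name
        Pathway identifier (e.g. a KEGG id or file stem).
    nodes
        Gene symbols.  Normalized to uppercase, whitespace-stripped.
    edges
        Mapping ``(source, target) -> sign`` with sign in {+1, -1}.

    Construction enforces the preparation invariants: self-loops are
    dropped (they would admit degenerate self-sustaining Boolean rules),
    duplicate edges keep the first-seen sign, and every edge endpoint is
    added to the node set.
    """

    name: str
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    #: number of measured genes in the node set; set by :func:`filter_pathways`.
    overlap: int | None = None

    @classmethod
    def from_edges(
        cls,
        name: str,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str, int]],
    ) -> "SignedNetwork":
        norm_nodes = {_normalize_gene(n) for n in nodes}
        norm_edges: dict[tuple[str, str], int] = {}
        for u, v, sign in edges:
            u, v = _normalize_gene(u), _normalize_gene(v)
            if u == v:
                logger.warning("%s: dropping self-loop on %s", name, u)
                continue
            if sign not in (ACTIVATION, INHIBITION):
                raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
            norm_nodes.update((u, v))
            norm_edges.setdefault((u, v), sign)
        return cls(name=name, nodes=norm_nodes, edges=norm_edges)

    def regulators_of(self, node: str) -> list[tuple[str, int]]:
        """In-edges of ``node`` as (source, sign), sorted by source."""
        return sorted(
            ((u, s) for (u, v), s in self.edges.items() if v == node),
            key=lambda t: t[0],
        )

    def targets_of(self, node: str) -> list[str]:
        return sorted(v for (u, v) in self.edges if u == node)

    def in_degree(self, node: str) -> int:
        return sum(1 for (_, v) in self.edges if v == node)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(sorted(self.nodes))
        for (u, v), sign in self.edges.items():
            g.add_edge(u, v, signal="a" if sign == ACTIVATION else "i")
        return g

    def subnetwork(self, nodes: Iterable[str], name: str | None = None) -> "SignedNetwork":
        keep = {_normalize_gene(n) for n in nodes} & self.nodes
        edges = {
            (u, v): s for (u, v), s in self.edges.items() if u in keep and v in keep
        }
        return SignedNetwork(name=name or self.name, nodes=keep, edges=edges)

    def __len__(self) -> int:
        return len(self.nodes)


def _sign_from_token(value: object, context: str) -> int:
    token = str(value).strip().lower()
    if token in _ACTIVATION_TOKENS:
        return ACTIVATION
    if token in _INHIBITION_TOKENS:
        return INHIBITION
    logger.warning("%s: unrecognized edge sign %r, defaulting to activation", context, value)
    return ACTIVATION


def read_graphml(path: str | Path) -> SignedNetwork:
    """Read a signed network from a graphml file.

    Edge signs are taken from a ``signal`` or ``interaction`` edge
    attribute ({"a", "activation", "+"} / {"i", "inhibition", "-"});
    edges lacking a recognizable sign default to activation with a
    logged warning.

    Raises
    ------
    EmptyNetworkError
        If the graph has no nodes.
    """
    path = Path(path)
    graph = nx.read_graphml(path)
    if graph.number_of_nodes() == 0:
        raise EmptyNetworkError(f"{path}: graph has no nodes")
    name = graph.graph.get("name") or path.stem

    def node_label(n: object) -> str:
        data = graph.nodes[n]
        return str(data.get("name", data.get("label", n)))

    edges = []
    for u, v, data in graph.edges(data=True):
        sign_value = next((data[a] for a in _SIGN_ATTRS if a in data), None)
        if sign_value is None:
            logger.warning("%s: edge %s->%s has no sign attribute, assuming activation", path, u, v)
            sign = ACTIVATION
        else:
            sign = _sign_from_token(sign_value, f"{path}:{u}->{v}")
        edges.append((node_label(u), node_label(v), sign))
    return SignedNetwork.from_edges(name, (node_label(n) for n in graph.nodes), edges)


def write_graphml(network: SignedNetwork, path: str | Path) -> None:
    """Write a network to graphml with a ``signal`` edge attribute."""
    nx.write_graphml(network.to_networkx(), Path(path))


def write_annotated_graphml(
    network: SignedNetwork,
    annotations: Mapping[str, Mapping[str, float]],
    path: str | Path,
) -> None:
    """Write graphml with per-node numeric score attributes.

    ``annotations`` maps node -> {score name -> value}.  Every score
    name occurring anywhere is written on every node; nodes without a
    value for a score get 0.

    Raises
    ------
    KeyError
        If an annotated node is not in the network.
    """
    unknown = set(annotations) - network.nodes
    if unknown:
        raise KeyError(f"annotations reference nodes not in network: {sorted(unknown)}")
    score_names = sorted({k for scores in annotations.values() for k in scores})
    g = network.to_networkx()
    for node in g.nodes:
        node_scores = annotations.get(node, {})
        for score in score_names:
            g.nodes[node][score] = float(node_scores.get(score, 0.0))
    nx.write_graphml(g, Path(path))


# ---------------------------------------------------------------------------
# KEGG KGML
# ---------------------------------------------------------------------------

_KGML_ACTIVATING = {"activation", "expression"}
_KGML_INHIBITING = {"inhibition", "repression"}


def _kgml_entry_genes(entry: ET.Element) -> list[str]:
    """Gene symbols for a KGML entry (first token of the graphics name)."""
    graphics = entry.find("graphics")
    label = graphics.get("name", "") if graphics is not None else ""
    if not label:
        label = entry.get("name", "")
    symbols = []
    for part in label.replace("...", "").split(","):
        token = part.strip().rstrip(".")
        if token:
            symbols.append(_normalize_gene(token))
    # a gene entry may list aliases; the first symbol is the display name
    return symbols[:1] if entry.get("type") == "gene" else symbols


def parse_kgml(source: str | Path) -> SignedNetwork:
    """Parse a KEGG KGML pathway document into a signed network.

    ``source`` is a path or an XML string.  Relation subtypes
    activation/expression map to +1, inhibition/repression to -1;
    other or missing subtypes default to +1.  Group entries are
    expanded to their member genes with relations replicated to every
    member.  Compound entries are collapsed: a relation chain
    A -> compound -> B yields a direct edge A -> B whose sign is the
    product of the chain's signs.  Relations referencing unknown entry
    ids are skipped with a warning.
    """
    text = str(source)
    if not text.lstrip().startswith("<"):
        text = Path(source).read_text()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ValueError(f"malformed KGML: {exc}") from exc

    name = root.get("title") or root.get("name") or "kgml"
    entry_genes: dict[str, list[str]] = {}
    entry_type: dict[str, str] = {}
    group_members: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "")
        entry_type[eid] = etype
        if etype == "group":
            group_members[eid] = [c.get("id") for c in entry.findall("component")]
        elif etype == "gene":
            entry_genes[eid] = _kgml_entry_genes(entry)
        elif etype == "compound":
            entry_genes[eid] = []  # placeholder, collapsed below

    def resolve(eid: str) -> list[str]:
        """Entry id -> gene symbols (groups expanded)."""
        if eid in group_members:
            out: list[str] = []
            for member in group_members[eid]:
                out.extend(resolve(member))
            return out
        return entry_genes.get(eid, [])

    # raw edges at the entry level, compounds still present
    raw_edges: list[tuple[str, str, int]] = []
    for relation in root.findall("relation"):
        e1, e2 = relation.get("entry1"), relation.get("entry2")
        if e1 not in entry_type or e2 not in entry_type:
            logger.warning("%s: relation references unknown entry (%s, %s); skipped", name, e1, e2)
            continue
        sign = ACTIVATION
        for subtype in relation.findall("subtype"):
            sname = subtype.get("name", "").lower()
            if sname in _KGML_INHIBITING:
                sign = INHIBITION
                break
            if sname in _KGML_ACTIVATING:
                sign = ACTIVATION
                break
        raw_edges.append((e1, e2, sign))

    # collapse compound-mediated relations into direct gene-gene edges
    compounds = {eid for eid, t in entry_type.items() if t == "compound"}
    changed = True
    while changed:
        changed = False
        for cpd in compounds:
            incoming = [(u, s) for (u, v, s) in raw_edges if v == cpd and u not in compounds]
            outgoing = [(v, s) for (u, v, s) in raw_edges if u == cpd and v not in compounds]
            if incoming and outgoing:
                for u, s1 in incoming:
                    for v, s2 in outgoing:
                        edge = (u, v, s1 * s2)
                        if edge not in raw_edges:
                            raw_edges.append(edge)
                            changed = True
    raw_edges = [
        (u, v, s) for (u, v, s) in raw_edges if u not in compounds and v not in compounds
    ]

    nodes: set[str] = set()
    for eid, etype in entry_type.items():
        if etype in ("gene", "group"):
            nodes.update(resolve(eid))
    edges: list[tuple[str, str, int]] = []
    for e1, e2, sign in raw_edges:
        for u in resolve(e1):
            for v in resolve(e2):
                edges.append((u, v, sign))
    if not nodes:
        raise EmptyNetworkError(f"{name}: KGML contains no gene entries")
    return SignedNetwork.from_edges(name, nodes, edges)


def filter_pathways(
    networks: Iterable[SignedNetwork],
    measured_genes: Iterable[str],
    min_overlap: int = 5,
) -> list[SignedNetwork]:
    """Retain pathways with at least ``min_overlap`` measured genes.

    The default of 5 is the conventional minimum overlap between a
    pathway's node set and the training data for the pathway to be
    analyzable.  Retained networks record their overlap count in
    ``network.overlap``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    measured = {_normalize_gene(g) for g in measured_genes}
    kept = []
    for net in networks:
        count = len(net.nodes & measured)
        if count >= min_overlap:
            net.overlap = count
            kept.append(net)
    return kept
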