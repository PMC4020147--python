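"""Deterministic layout and static export of quasi-median networks.

The layout assigns every condensed character a fixed unit direction (angles
evenly spaced over the half-circle in character order) and every state of
that character an integer offset along it; a node's position is the sum over
characters of ``offset(state) * length(character) * direction``.  Edges of a
parallel class (same character, same state pair) therefore have *identical*
displacement vectors by construction — the parallel-branch property is an
algebraic consequence, not a post-hoc constraint.  Recurrent mutations are
thus immediately visible as bundles of parallel branches.

Exports: standalone SVG 1.1 with accentuation/dimming, Graphviz DOT,
GraphML (via networkx, round-trippable) and a JSON dump of the full graph.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .qmn_core import ACCENT, DIM, QMNEdge, QMNGraph, QMNNode
from .reduce_filter import Character, CondensedCharacter

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class LayoutOptions:
    edge_length: float = 100.0
    #: scale branch length with condensed weight (more merged mutations →
    #: longer branch), as in weighted network drawings
    length_by_weight: bool = True
    #: nudge exactly coincident nodes apart; the nudge moves node centres,
    #: so it is off by default to keep parallel displacements exact
    resolve_overlaps: bool = False


@dataclass(frozen=True)
class LayoutResult:
    coordinates: Mapping[str, Tuple[float, float]]
    directions: Tuple[Tuple[float, float], ...]  # per condensed character
    lengths: Tuple[float, ...]                   # per condensed character


def layout(g: QMNGraph, options: LayoutOptions = LayoutOptions()) -> LayoutResult:
    """Place nodes by the direction-sum construction (deterministic)."""
    k = len(g.characters)
    directions = tuple(
        (math.cos(math.pi * i / max(k, 1)), math.sin(math.pi * i / max(k, 1)))
        for i in range(k))
    lengths = tuple(
        options.edge_length * (c.weight if options.length_by_weight else 1.0)
        for c in g.characters)
    offsets = [
        {state: j for j, state in enumerate(sorted(c.alphabet))}
        for c in g.characters]

    coords: Dict[str, Tuple[float, float]] = {}
    for n in g.nodes:
        x = y = 0.0
        for i, state in enumerate(n.vector):
            off = offsets[i][state]
            x += off * lengths[i] * directions[i][0]
            y += off * lengths[i] * directions[i][1]
        coords[n.node_id] = (x, y)

    if options.resolve_overlaps:
        # deterministic micro-offset for exactly coincident centres, applied
        # in node_id order, perpendicular to the first character direction
        perp = (-directions[0][1], directions[0][0]) if k else (0.0, 1.0)
        seen: Dict[Tuple[float, float], int] = {}
        for n in sorted(g.nodes, key=lambda n: n.node_id):
            key = (round(coords[n.node_id][0], 9), round(coords[n.node_id][1], 9))
            bump = seen.get(key, 0)
            if bump:
                dx = bump * 0.02 * options.edge_length
                x, y = coords[n.node_id]
                coords[n.node_id] = (x + dx * perp[0], y + dx * perp[1])
            seen[key] = bump + 1
    return LayoutResult(coords, directions, lengths)


@dataclass(frozen=True)
class StyleOptions:
    node_min_radius: float = 6.0
    #: node area grows with the number of haplotypes in the node; switchable
    size_by_count: bool = True
    node_radius_scale: float = 4.0
    dim_opacity: float = 0.25
    font_size: float = 10.0
    margin: float = 40.0
    node_fill: str = "#4878a8"
    virtual_fill: str = "#ffffff"
    stroke: str = "#222222"


def _node_radius(n: QMNNode, style: StyleOptions) -> float:
    if not n.sampled or not style.size_by_count:
        return style.node_min_radius
    return style.node_min_radius + style.node_radius_scale * math.sqrt(
        len(n.sample_ids))


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


def export_svg(g: QMNGraph, lay: LayoutResult,
               highlight: Optional[Mapping[str, str]] = None,
               style: StyleOptions = StyleOptions()) -> str:
    """Standalone SVG 1.1 document; byte-identical for identical inputs.

    Element ids equal node/edge ids; accentuated elements render at full
    opacity, dimmed ones at ``style.dim_opacity``.
    """
    coords = lay.coordinates
    radii = {n.node_id: _node_radius(n, style) for n in g.nodes}
    xs = [coords[n.node_id][0] for n in g.nodes]
    ys = [coords[n.node_id][1] for n in g.nodes]
    rmax = max(radii.values()) if radii else 0.0
    m = style.margin + rmax
    min_x, min_y = min(xs) - m, min(ys) - m
    width = (max(xs) - min(xs)) + 2 * m
    height = (max(ys) - min(ys)) + 2 * m

    def opacity(elem_id: str) -> str:
        if highlight is None:
            return "1.0"
        return "1.0" if highlight[elem_id] == ACCENT else f"{style.dim_opacity}"

    out = io.StringIO()
    out.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    out.write(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="{_fmt(min_x)} {_fmt(min_y)} {_fmt(width)} {_fmt(height)}">\n')
    for e in g.edges:
        (x1, y1), (x2, y2) = coords[e.endpoints[0]], coords[e.endpoints[1]]
        out.write(
            f'  <line id="{e.edge_id}" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" stroke="{style.stroke}" '
            f'stroke-width="1.5" opacity="{opacity(e.edge_id)}"/>\n')
    for e in g.edges:
        (x1, y1), (x2, y2) = coords[e.endpoints[0]], coords[e.endpoints[1]]
        mx, my = (x1 + x2) / 2, (y1 + y2) / 2
        out.write(
            f'  <text id="{e.edge_id}-label" x="{_fmt(mx)}" y="{_fmt(my - 3)}" '
            f'font-size="{style.font_size}" font-family="sans-serif" '
            f'text-anchor="middle" opacity="{opacity(e.edge_id)}">'
            f'{_esc(e.label)}</text>\n')
    for n in g.nodes:
        x, y = coords[n.node_id]
        fill = style.node_fill if n.sampled else style.virtual_fill
        out.write(
            f'  <circle id="{n.node_id}" cx="{_fmt(x)}" cy="{_fmt(y)}" '
            f'r="{_fmt(radii[n.node_id])}" fill="{fill}" '
            f'stroke="{style.stroke}" opacity="{opacity(n.node_id)}"/>\n')
        if n.sampled:
            out.write(
                f'  <text id="{n.node_id}-label" x="{_fmt(x)}" '
                f'y="{_fmt(y - radii[n.node_id] - 4)}" '
                f'font-size="{style.font_size}" font-family="sans-serif" '
                f'text-anchor="middle" opacity="{opacity(n.node_id)}">'
                f'{_esc(n.node_id)} ({len(n.sample_ids)})</text>\n')
    out.write('</svg>\n')
    return out.getvalue()


def export_dot(g: QMNGraph, lay: Optional[LayoutResult] = None) -> str:
    """Graphviz DOT text with node/edge attributes."""
    lines = ["graph qmn {"]
    for n in g.nodes:
        attrs = [f'label="{n.node_id}"',
                 f'sampled="{str(n.sampled).lower()}"',
                 f'sample_ids="{",".join(n.sample_ids)}"',
                 f'vector="{"|".join(n.vector)}"']
        if lay is not None:
            x, y = lay.coordinates[n.node_id]
            attrs.append(f'pos="{_fmt(x)},{_fmt(y)}"')
        lines.append(f'  "{n.node_id}" [{", ".join(attrs)}];')
    for e in g.edges:
        lines.append(
            f'  "{e.endpoints[0]}" -- "{e.endpoints[1]}" '
            f'[label="{e.label}", parallel_class="{e.parallel_class_id}", '
            f'edge_id="{e.edge_id}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_networkx(g: QMNGraph) -> nx.MultiGraph:
    """Attribute-complete networkx view (multigraph: parallel classes may
    connect the same node pair through different characters)."""
    G = nx.MultiGraph()
    G.graph["schema_version"] = SCHEMA_VERSION
    for key, value in g.provenance.items():
        G.graph[f"prov_{key}"] = value
    for n in g.nodes:
        G.add_node(n.node_id, sampled=n.sampled,
                   sample_ids=",".join(n.sample_ids),
                   vector="|".join(n.vector))
    for e in g.edges:
        G.add_edge(*e.endpoints, key=e.edge_id, edge_id=e.edge_id,
                   label=e.label, character_index=e.character_index,
                   state_pair="|".join(e.state_pair),
                   parallel_class_id=e.parallel_class_id)
    return G


def export_graphml(g: QMNGraph) -> str:
    """GraphML 1.0 text (networkx writer), round-trippable via
    :func:`graphml_to_graph`."""
    buf = io.BytesIO()
    nx.write_graphml(to_networkx(g), buf)
    return buf.getvalue().decode("utf-8")


def graphml_to_graph(text: str) -> QMNGraph:
    """Rebuild a :class:`QMNGraph` from GraphML written by
    :func:`export_graphml`.

    Nodes, edges, labels, vectors and parallel classes are preserved; the
    condensed character table is not serialized in GraphML (use the JSON
    dump for lossless persistence).
    """
    G = nx.read_graphml(io.BytesIO(text.encode("utf-8")), force_multigraph=True)
    nodes = []
    for nid in G.nodes:
        d = G.nodes[nid]
        samples = tuple(s for s in d.get("sample_ids", "").split(",") if s)
        vector = tuple(v for v in d.get("vector", "").split("|") if v != "") \
            if d.get("vector") else ()
        nodes.append(QMNNode(nid, vector, samples))
    nodes.sort(key=_node_sort_key)
    edges = []
    for u, v, key in sorted(G.edges(keys=True),
                            key=lambda t: int(str(t[2])[1:])):
        d = G.edges[u, v, key]
        edges.append(QMNEdge(
            edge_id=d["edge_id"], endpoints=(u, v),
            character_index=int(d["character_index"]),
            state_pair=tuple(d["state_pair"].split("|")),
            label=d["label"], parallel_class_id=d["parallel_class_id"]))
    prov = {k[5:]: v for k, v in G.graph.items() if k.startswith("prov_")}
    return QMNGraph(tuple(nodes), tuple(edges), (), prov)


def _node_sort_key(n: QMNNode) -> tuple:
    return (n.node_id[0], int(n.node_id[1:]))


def graph_to_json(g: QMNGraph) -> str:
    """Lossless JSON dump of the graph (nodes, edges, provenance)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "provenance": dict(g.provenance),
        "nodes": [
            {"id": n.node_id, "vector": list(n.vector),
             "sample_ids": list(n.sample_ids)} for n in g.nodes],
        "edges": [
            {"id": e.edge_id, "endpoints": list(e.endpoints),
             "character_index": e.character_index,
             "state_pair": list(e.state_pair), "label": e.label,
             "parallel_class_id": e.parallel_class_id} for e in g.edges],
        "characters": [
            {"weight": c.weight,
             "sites": [[m.position, m.insertion_index, m.kind] for m in c.members],
             "alphabet": list(c.alphabet)} for c in g.characters],
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def graph_from_json(text: str) -> QMNGraph:
    """Rebuild nodes/edges/provenance from :func:`graph_to_json` output.

    The condensed character table is restored only as far as labels need it
    (weights/sites/alphabets); member state maps are not round-tripped.
    """
    doc = json.loads(text)
    nodes = tuple(
        QMNNode(d["id"], tuple(d["vector"]), tuple(d["sample_ids"]))
        for d in doc["nodes"])
    edges = tuple(
        QMNEdge(d["id"], tuple(d["endpoints"]), d["character_index"],
                tuple(d["state_pair"]), d["label"], d["parallel_class_id"])
        for d in doc["edges"])
    characters = []
    for d in doc.get("characters", ()):
        alphabet = tuple(d["alphabet"])
        members = tuple(
            Character(pos, idx, kind, alphabet, alphabet[0])
            for pos, idx, kind in d["sites"])
        identity = tuple({s: s for s in alphabet} for _ in members)
        characters.append(CondensedCharacter(members, identity))
    return QMNGraph(nodes, edges, tuple(characters), doc.get("provenance", {}))
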