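"""Quasi-median closure and network (torso) construction.

The quasi-median of three state vectors takes, per character, the majority
state when at least two of the three agree, and all three states when they
pairwise differ (so a fully conflicting character contributes three
candidates, and the quasi-median of a triple is a *set* of vectors — the
Cartesian product over characters).  The quasi-median hull of a data set is
its closure under this triple operation; the quasi-median network connects
hull vectors that differ in exactly one condensed character.

Conflict-free (pairwise compatible) characters yield trees; each pair of
incompatible binary characters yields a 4-cycle, k mutually incompatible
binary characters a k-hypercube.  After filter passage the network is the
"torso": on clean data a single node or a modest star, on problematic data
a reticulated structure whose parallel branch classes name the recurrent
(often phantom) mutations.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .reduce_filter import CondensedCharacter, CondensedMatrix

StateVector = Tuple[str, ...]


class ClosureExplosionError(RuntimeError):
    """Quasi-median closure exceeded the node cap.

    Carries suggestions: the condensed characters with the richest state
    alphabets, the first candidates for a stronger filter.
    """

    def __init__(self, cap: int, size: int, suggestions: Sequence[str]):
        self.cap = cap
        self.size = size
        self.suggestions = list(suggestions)
        hint = "; ".join(self.suggestions) or "n/a"
        super().__init__(
            f"quasi-median closure exceeded the node cap ({size} > {cap}); "
            f"apply a stronger filter — most state-rich characters: {hint}")


def quasi_median_triple(u: StateVector, v: StateVector,
                        w: StateVector) -> Set[StateVector]:
    """Quasi-median of three equal-length state vectors.

    Per character: the majority state when two or three of ``u_i, v_i, w_i``
    coincide, else all three distinct states.  The result is the Cartesian
    product of those per-character sets.
    """
    if not (len(u) == len(v) == len(w)):
        raise ValueError("state vectors must have equal length")
    per_char: List[Tuple[str, ...]] = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            per_char.append((a,))
        elif b == c:
            per_char.append((b,))
        else:
            per_char.append((a, b, c))
    return set(itertools.product(*per_char))


DEFAULT_NODE_CAP = 20_000


def quasi_median_closure(S: Iterable[StateVector],
                         node_cap: int = DEFAULT_NODE_CAP,
                         condensed: Optional[CondensedMatrix] = None
                         ) -> FrozenSet[StateVector]:
    """Smallest superset of ``S`` closed under :func:`quasi_median_triple`.

    Implemented as a worklist over triples containing at least one new
    vector; the closure is a set fixpoint, so the result is independent of
    iteration order.  Raises :class:`ClosureExplosionError` when the hull
    grows past ``node_cap`` (recurrent conflicts need filtering, not more
    nodes); the error names the most state-rich characters when the
    condensed matrix is supplied.
    """
    closed: Set[StateVector] = set(S)
    if not closed:
        raise ValueError("closure of an empty set is undefined")
    if node_cap < len(closed):
        raise ClosureExplosionError(
            node_cap, len(closed),
            _filter_suggestions(condensed) if condensed else ())
    frontier: List[StateVector] = sorted(closed)
    while frontier:
        base = sorted(closed)
        new: Set[StateVector] = set()
        # triples with >= 1 frontier member suffice: any triple of old
        # vectors was already processed in an earlier round
        fr = sorted(set(frontier))
        for i, u in enumerate(fr):
            for v in fr[i:]:
                for w in base:
                    for q in quasi_median_triple(u, v, w):
                        if q not in closed:
                            new.add(q)
            for j, v in enumerate(base):
                for w in base[j:]:
                    for q in quasi_median_triple(u, v, w):
                        if q not in closed:
                            new.add(q)
        closed |= new
        if len(closed) > node_cap:
            raise ClosureExplosionError(
                node_cap, len(closed),
                _filter_suggestions(condensed) if condensed else ())
        frontier = sorted(new)
    return frozenset(closed)


def _filter_suggestions(condensed: CondensedMatrix, top: int = 3) -> List[str]:
    ranked = sorted(
        condensed.characters,
        key=lambda c: (-len(c.alphabet), c.members[0].key))
    out = []
    for c in ranked[:top]:
        site = c.members[0]
        out.append(f"position {site.position} ({len(c.alphabet)} states, "
                   f"weight {c.weight})")
    return out


@dataclass(frozen=True)
class QMNNode:
    """Network vertex: ``h<k>`` when sampled (>=1 haplotype), ``q<k>`` when
    generated only by the closure (virtual)."""

    node_id: str
    vector: StateVector
    sample_ids: Tuple[str, ...] = ()

    @property
    def sampled(self) -> bool:
        return bool(self.sample_ids)


@dataclass(frozen=True)
class QMNEdge:
    """Edge between two vectors differing in exactly one condensed character."""

    edge_id: str
    endpoints: Tuple[str, str]
    character_index: int
    state_pair: Tuple[str, str]
    label: str
    parallel_class_id: str


@dataclass(frozen=True)
class QMNGraph:
    nodes: Tuple[QMNNode, ...]
    edges: Tuple[QMNEdge, ...]
    characters: Tuple[CondensedCharacter, ...]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def node(self, node_id: str) -> QMNNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(f"unknown node id {node_id!r}")

    def edge(self, edge_id: str) -> QMNEdge:
        for e in self.edges:
            if e.edge_id == edge_id:
                return e
        raise KeyError(f"unknown edge id {edge_id!r}")

    @property
    def parallel_classes(self) -> Dict[str, Tuple[QMNEdge, ...]]:
        out: Dict[str, List[QMNEdge]] = {}
        for e in self.edges:
            out.setdefault(e.parallel_class_id, []).append(e)
        return {k: tuple(v) for k, v in out.items()}

    @property
    def n_virtual(self) -> int:
        return sum(1 for n in self.nodes if not n.sampled)


def _input_digest(condensed: CondensedMatrix) -> str:
    h = hashlib.sha256()
    for vec, samples in zip(condensed.row_vectors, condensed.row_samples):
        h.update(("|".join(vec) + "//" + ",".join(samples)).encode())
    return h.hexdigest()[:16]


def build_network(S_closed: Iterable[StateVector],
                  condensed: CondensedMatrix,
                  filter_name: str = "") -> QMNGraph:
    """Assemble the network graph from a closed vector set.

    Sampled nodes get ids ``h1..hn`` in first-appearance order of the
    condensed rows, virtual nodes ``q1..`` in lexicographic vector order.
    Edges connect vectors differing in exactly one condensed character;
    edges with the same character and (unordered) state pair share a
    parallel class, labelled by the mutation(s) of the condensed character.
    """
    closed = set(S_closed)
    sampled: Dict[StateVector, Tuple[str, ...]] = {
        vec: samples for vec, samples in
        zip(condensed.row_vectors, condensed.row_samples)}

    nodes: List[QMNNode] = []
    by_vector: Dict[StateVector, str] = {}
    for k, vec in enumerate(condensed.row_vectors, start=1):
        nodes.append(QMNNode(f"h{k}", vec, sampled[vec]))
        by_vector[vec] = f"h{k}"
    virtuals = sorted(v for v in closed if v not in sampled)
    for k, vec in enumerate(virtuals, start=1):
        nodes.append(QMNNode(f"q{k}", vec))
        by_vector[vec] = f"q{k}"

    # adjacency: group vectors by the vector with character i removed; any
    # two members of a group differ exactly (and only) at i
    edges: List[QMNEdge] = []
    n_chars = len(condensed.characters)
    edge_seq = 0
    for i in range(n_chars):
        buckets: Dict[tuple, List[StateVector]] = {}
        for vec in sorted(closed):
            buckets.setdefault(vec[:i] + vec[i + 1:], []).append(vec)
        for rest in sorted(buckets):
            group = buckets[rest]
            for a, b in itertools.combinations(group, 2):
                s1, s2 = sorted((a[i], b[i]))
                char = condensed.characters[i]
                edge_seq += 1
                edges.append(QMNEdge(
                    edge_id=f"e{edge_seq}",
                    endpoints=(by_vector[a], by_vector[b]),
                    character_index=i,
                    state_pair=(s1, s2),
                    label=char.label(s1, s2),
                    parallel_class_id=f"c{i}|{s1}>{s2}",
                ))

    provenance = {"filter": filter_name, "input_digest": _input_digest(condensed)}
    return QMNGraph(tuple(nodes), tuple(edges), condensed.characters, provenance)


def compute_network(condensed: CondensedMatrix,
                    node_cap: int = DEFAULT_NODE_CAP,
                    filter_name: str = "") -> QMNGraph:
    """Closure + graph assembly in one step."""
    hull = quasi_median_closure(condensed.row_vectors, node_cap=node_cap,
                                condensed=condensed)
    return build_network(hull, condensed, filter_name=filter_name)


TORSO_FILTERED = "filtered"
TORSO_PRUNED = "pruned"


def torso(g: QMNGraph, mode: str = TORSO_FILTERED) -> QMNGraph:
    """The network torso.

    ``filtered`` (default) is the post-filter network unchanged — the usage
    adopted throughout this package.  ``pruned`` additionally strips
    degree-1 *virtual* nodes iteratively (sampled pendants always stay).
    """
    if mode == TORSO_FILTERED:
        return g
    if mode != TORSO_PRUNED:
        raise ValueError(f"unknown torso mode {mode!r}")
    nodes = {n.node_id: n for n in g.nodes}
    edges = list(g.edges)
    while True:
        degree: Dict[str, int] = {nid: 0 for nid in nodes}
        for e in edges:
            degree[e.endpoints[0]] += 1
            degree[e.endpoints[1]] += 1
        prunable = {nid for nid, n in nodes.items()
                    if not n.sampled and degree[nid] <= 1}
        if not prunable:
            break
        nodes = {nid: n for nid, n in nodes.items() if nid not in prunable}
        edges = [e for e in edges
                 if e.endpoints[0] not in prunable
                 and e.endpoints[1] not in prunable]
    return QMNGraph(tuple(nodes.values()), tuple(edges), g.characters,
                    dict(g.provenance, torso=TORSO_PRUNED))


def node_haplotypes(g: QMNGraph, node_id: str) -> List[str]:
    """Sample ids contained in a node (empty for virtual nodes).

    The tabular counterpart of clicking a node in an interactive viewer.
    """
    return list(g.node(node_id).sample_ids)


ACCENT = "accentuated"
DIM = "dimmed"


def select_highlight(g: QMNGraph, selection: str) -> Dict[str, str]:
    """Accent map for a node or parallel-class selection.

    Node selection accentuates the node, its incident edges and their
    opposite endpoints (the induced star); branch selection accentuates
    every edge of the parallel class and all their endpoints.  Everything
    else is dimmed; the map covers every node and edge exactly once.
    """
    node_ids = {n.node_id for n in g.nodes}
    classes = g.parallel_classes
    accent: Set[str] = set()
    if selection in node_ids:
        accent.add(selection)
        for e in g.edges:
            if selection in e.endpoints:
                accent.add(e.edge_id)
                accent.update(e.endpoints)
    elif selection in classes:
        for e in classes[selection]:
            accent.add(e.edge_id)
            accent.update(e.endpoints)
    else:
        raise KeyError(
            f"unknown selection {selection!r}: not a node id or parallel class id")
    out: Dict[str, str] = {}
    for n in g.nodes:
        out[n.node_id] = ACCENT if n.node_id in accent else DIM
    for e in g.edges:
        out[e.edge_id] = ACCENT if e.edge_id in accent else DIM
    return out


def parallel_class_by_label(g: QMNGraph, label: str) -> List[str]:
    """Parallel-class ids whose edges carry the given branch label."""
    return sorted({e.parallel_class_id for e in g.edges if e.label == label})
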