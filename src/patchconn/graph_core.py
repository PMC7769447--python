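"""Dispersal-threshold graphs and their structural descriptors.

A threshold graph links every patch pair whose edge-to-edge distance does not
exceed the dispersal distance d (inclusive: only links *exceeding* d are
eliminated).  From it we get the classic binary connectivity descriptors:
number of links (NL), number of components (NC), component areas, the
area-covering component count, and the all-pairs topological shortest-path
link counts nl_ij that the integral index of connectivity is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import ThresholdExceedsCutoffError
from .io_geometry import EdgeList

__all__ = [
    "ThresholdGraph",
    "ComponentPartition",
    "LinkCountMatrix",
    "build_threshold_graph",
    "components",
    "components_covering",
    "all_pairs_link_counts",
]


@dataclass
class ThresholdGraph:
    """Patches plus the links shorter than one dispersal threshold.

    Nodes are patch ids with areas in m²; links are unordered id pairs whose
    distance is <= ``threshold``.
    """

    threshold: float
    node_ids: list[int]
    node_areas: dict[int, float]
    link_a: np.ndarray
    link_b: np.ndarray

    # internal dense indexing, built once
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {pid: k for k, pid in enumerate(self.node_ids)}
        for arr in (self.link_a, self.link_b):
            for pid in arr.tolist():
                if pid not in self._index:
                    raise ValueError(f"link references unknown node {pid}")
        if np.any(self.link_a == self.link_b):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def nl(self) -> int:
        """Number of links (NL)."""
        return len(self.link_a)

    def links(self) -> set[frozenset[int]]:
        return {frozenset(p) for p in zip(self.link_a.tolist(), self.link_b.tolist())}

    def areas_vector(self) -> np.ndarray:
        """Areas in node order (m²)."""
        return np.array([self.node_areas[i] for i in self.node_ids], float)

    def adjacency(self) -> csr_matrix:
        """Symmetric sparse 0/1 adjacency in node order."""
        n = self.n_nodes
        ia = np.array([self._index[i] for i in self.link_a.tolist()], int)
        ib = np.array([self._index[i] for i in self.link_b.tolist()], int)
        rows = np.concatenate([ia, ib])
        cols = np.concatenate([ib, ia])
        data = np.ones(len(rows), dtype=np.int8)
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    def to_networkx(self):
        """The same graph as a networkx.Graph (areas as node attributes)."""
        import networkx as nx

        g = nx.Graph()
        for pid in self.node_ids:
            g.add_node(pid, area=self.node_areas[pid])
        g.add_edges_from(zip(self.link_a.tolist(), self.link_b.tolist()))
        return g


@dataclass
class ComponentPartition:
    """Connected components of a threshold graph.

    ``members[c]`` lists patch ids of component c; ``areas[c]`` is its total
    area (m², same unit as the node areas); ``labels`` maps id -> component
    index.  Components partition the node set, so areas sum to total habitat.
    """

    members: list[list[int]]
    areas: list[float]
    labels: dict[int, int]

    @property
    def nc(self) -> int:
        """Number of components (NC)."""
        return len(self.members)


def build_threshold_graph(
    node_areas: dict[int, float], edges: EdgeList, d: float
) -> ThresholdGraph:
    """Prune an edge list at dispersal distance ``d`` (inclusive).

    ``node_areas`` maps patch id -> area in m².  Raises if ``d`` exceeds the
    edge list cutoff: pairs between cutoff and d were never enumerated, so the
    graph would silently be missing links.
    """
    if d > edges.cutoff:
        raise ThresholdExceedsCutoffError(
            f"threshold {d} m exceeds edge-list cutoff {edges.cutoff} m"
        )
    keep = edges.distance <= d
    return ThresholdGraph(
        threshold=float(d),
        node_ids=sorted(node_areas),
        node_areas=dict(node_areas),
        link_a=edges.id_a[keep].copy(),
        link_b=edges.id_b[keep].copy(),
    )


def components(g: ThresholdGraph) -> ComponentPartition:
    """Connected components; an isolated patch is its own component."""
    n = g.n_nodes
    if n == 0:
        return ComponentPartition([], [], {})
    _, labels = connected_components(g.adjacency(), directed=False)
    ncomp = int(labels.max()) + 1
    members: list[list[int]] = [[] for _ in range(ncomp)]
    areas = [0.0] * ncomp
    for pid, lab in zip(g.node_ids, labels.tolist()):
        members[lab].append(pid)
        areas[lab] += g.node_areas[pid]
    return ComponentPartition(members, areas, dict(zip(g.node_ids, labels.tolist())))


def components_covering(partition: ComponentPartition, p: float = 0.5) -> int:
    """Smallest number of largest components strictly exceeding ``p`` of total area.

    Components are taken in descending area order (ties broken by lower
    component index); the count k is the first at which the cumulative area
    strictly exceeds p × total.  With p = 0.5 this is the refinement of NC
    that reports how few components hold the majority of the habitat.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if not partition.members:
        return 0
    areas = np.asarray(partition.areas, float)
    order = np.lexsort((np.arange(len(areas)), -areas))
    csum = np.cumsum(areas[order])
    target = p * csum[-1]
    over = np.nonzero(csum > target)[0]
    # with p < 1 the full sum always exceeds the target; p == 1 needs all
    return int(over[0]) + 1 if len(over) else len(areas)


@dataclass
class LinkCountMatrix:
    """All-pairs shortest-path link counts nl_ij, stored per component.

    For patches i, j in the same component, nl_ij is the minimum number of
    links on a path between them (nl_ii = 0); pairs in different components
    are unreachable and reported as ``None`` — never as a large number, so
    downstream code cannot silently misuse them.
    """

    node_ids: list[int]
    labels: dict[int, int]
    block_index: dict[int, int]          # patch id -> position within its block
    blocks: list[np.ndarray]             # per component, dense int matrix

    def nl(self, i: int, j: int) -> int | None:
        ci, cj = self.labels[i], self.labels[j]
        if ci != cj:
            return None
        return int(self.blocks[ci][self.block_index[i], self.block_index[j]])


def all_pairs_link_counts(g: ThresholdGraph) -> LinkCountMatrix:
    """BFS from every node, run per component, on unit link weights."""
    adj = g.adjacency()
    part = components(g)
    ids = np.asarray(g.node_ids)
    labels = np.array([part.labels[i] for i in g.node_ids], int)
    blocks: list[np.ndarray] = []
    block_index: dict[int, int] = {}
    for c, member_ids in enumerate(part.members):
        idx = np.nonzero(labels == c)[0]
        sub = adj[idx][:, idx]
        d = shortest_path(sub, method="D", directed=False, unweighted=True)
        blocks.append(d.astype(np.int32))
        for pos, pid in enumerate(ids[idx].tolist()):
            block_index[pid] = pos
    return LinkCountMatrix(list(g.node_ids), dict(part.labels), block_index, blocks)
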