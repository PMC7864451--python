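"""Contact inference and packing-topology classification.

Which cells genuinely touch is decided by a bounded, radius-weighted 3D
Voronoi construction rather than by distance alone: each cell owns a regular
dodecahedron (fixed canonical orientation) whose inscribed sphere has the
cell's volume-corrected radius, clipped toward every nearby cell by the
plane perpendicular to the centre line at the radius-proportional split
point.  Two cells are in contact when their clipped polyhedra share a face
of positive area on their mutual plane AND their centre distance is below
R_i + R_j.  This prevents spurious next-nearest-neighbour "contacts" under
tight confinement.

A 4-cell arrangement is labelled by graph isomorphism of its contact graph
against the five reference graphs: line (path P4), T-shape (star K1,3),
square (cycle C4), diamond (K4 minus an edge) and tetrahedron (K4).
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from . import _kernels as K
from .mechanics import Cell


class TopologyLabel(str, Enum):
    LINE = "line"
    T_SHAPE = "t_shape"
    SQUARE = "square"
    DIAMOND = "diamond"
    TETRAHEDRON = "tetrahedron"
    OTHER = "other"


_CODE_TO_LABEL = {
    K.LAB_LINE: TopologyLabel.LINE,
    K.LAB_T_SHAPE: TopologyLabel.T_SHAPE,
    K.LAB_SQUARE: TopologyLabel.SQUARE,
    K.LAB_DIAMOND: TopologyLabel.DIAMOND,
    K.LAB_TETRAHEDRON: TopologyLabel.TETRAHEDRON,
    K.LAB_OTHER: TopologyLabel.OTHER,
}
_LABEL_TO_CODE = {v: k for k, v in _CODE_TO_LABEL.items()}


def label_code(label: TopologyLabel | str) -> int:
    """Integer code used by the compiled kernels for a topology label."""
    return _LABEL_TO_CODE[TopologyLabel(label)]


def label_from_code(code: int) -> TopologyLabel:
    return _CODE_TO_LABEL[code]


def reference_graphs() -> dict[TopologyLabel, nx.Graph]:
    """Canonical 4-node reference graphs, one per named topology."""
    refs = {
        TopologyLabel.LINE: [(0, 1), (1, 2), (2, 3)],
        TopologyLabel.T_SHAPE: [(0, 1), (0, 2), (0, 3)],
        TopologyLabel.SQUARE: [(0, 1), (1, 2), (2, 3), (3, 0)],
        TopologyLabel.DIAMOND: [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)],
        TopologyLabel.TETRAHEDRON: [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
    }
    out = {}
    for lab, edges in refs.items():
        g = nx.Graph()
        g.add_nodes_from(range(4))
        g.add_edges_from(edges)
        out[lab] = g
    return out


def classify_topology(graph: nx.Graph) -> TopologyLabel:
    """Label a 4-node contact graph by isomorphism to the reference graphs;
    anything not matching (disconnected graphs, triangle-plus-pendant) is
    ``other``."""
    if graph.number_of_nodes() != 4:
        raise ValueError(
            f"classification requires exactly 4 nodes, got {graph.number_of_nodes()}")
    for label, ref in reference_graphs().items():
        if nx.is_isomorphic(graph, ref):
            return label
    return TopologyLabel.OTHER


def _cells_to_arrays(cells: Sequence[Cell]):
    pos = np.array([c.position for c in cells], dtype=float)
    base = np.array([c.base_radius for c in cells], dtype=float)
    corr = np.array([c.corrected_radius for c in cells], dtype=float)
    return pos, base, corr


def voronoi_contacts(cells: Sequence[Cell]) -> nx.Graph:
    """Contact graph of a set of cells.

    Nodes carry the cell ids; an edge (i, j) means the cells' centre
    distance is below R_i + R_j and their bounded weighted-Voronoi
    polyhedra share a face on the mutual weighted plane.
    """
    cells = list(cells)
    pos, base, corr = _cells_to_arrays(cells)
    n = len(cells)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pos[i] - pos[j]) == 0.0:
                raise ValueError(
                    f"coincident centres for cells {cells[i].id} and {cells[j].id}")
    adj = np.zeros((n, n), dtype=bool)
    K.contact_matrix(pos, base, corr, adj)
    g = nx.Graph()
    g.add_nodes_from(c.id for c in cells)
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                g.add_edge(cells[i].id, cells[j].id)
    return g


def contact_graph_from_arrays(pos: np.ndarray, base_radii: np.ndarray,
                              corrected: np.ndarray | None = None,
                              ids: Iterable[int] | None = None) -> nx.Graph:
    """Array-based variant of :func:`voronoi_contacts` (no Cell objects)."""
    pos = np.asarray(pos, dtype=float)
    base = np.asarray(base_radii, dtype=float)
    n = base.shape[0]
    if corrected is None:
        adj0 = np.zeros((n, n), dtype=bool)
        K.distance_adjacency(pos, base, adj0)
        corrected = np.empty(n)
        K.corrected_radii(pos, base, adj0, corrected)
    else:
        corrected = np.asarray(corrected, dtype=float)
    adj = np.zeros((n, n), dtype=bool)
    K.contact_matrix(pos, base, corrected, adj)
    node_ids = list(ids) if ids is not None else list(range(n))
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                g.add_edge(node_ids[i], node_ids[j])
    return g


def write_edge_list(path, frames: Iterable[tuple[float, nx.Graph]]) -> None:
    """Serialize per-frame contact graphs as whitespace-separated 't i j'
    lines, one line per contact edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for t, g in frames:
            for i, j in sorted(tuple(sorted(e)) for e in g.edges()):
                fh.write(f"{t:.6f} {i} {j}\n")
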