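"""First-order Queen contiguity structures for CAR priors.

Two areal units are Queen neighbors when they share an edge or a corner.
Weights are binary (w_ij in {0,1}); the sampler row-standardizes internally
where the intrinsic CAR conditionals need neighbor means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "AdjacencyStructure",
    "queen_lattice",
    "adjacency_from_zones",
    "read_neighbor_list",
    "write_neighbor_list",
]

_QUEEN_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class AdjacencyStructure:
    """Symmetric binary contiguity among ``n_units`` units (0-based indices)."""

    n_units: int
    neighbors: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.neighbors) != self.n_units:
            raise ValueError("need one neighbor list per unit")
        self.neighbors = [np.asarray(sorted(nb), dtype=int) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            if nb.size and (nb.min() < 0 or nb.max() >= self.n_units):
                raise ValueError(f"unit {i} references an unknown unit")
            if i in nb:
                raise ValueError(f"unit {i} lists itself as a neighbor")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency: {i} lists {j} but not vice versa")

    @property
    def degrees(self) -> np.ndarray:
        """Neighbor counts m_i."""
        return np.array([nb.size for nb in self.neighbors], dtype=int)

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def isolated_units(self) -> np.ndarray:
        return np.nonzero(self.degrees == 0)[0]

    def weights_sparse(self) -> sparse.csr_matrix:
        """Binary weight matrix W as CSR."""
        rows, cols = [], []
        for i, nb in enumerate(self.neighbors):
            rows.extend([i] * nb.size)
            cols.extend(nb.tolist())
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n_units, self.n_units))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W (the ICAR precision kernel)."""
        W = self.weights_sparse().toarray()
        return np.diag(self.degrees.astype(float)) - W

    def connected_components(self) -> np.ndarray:
        """Component label per unit (isolated units are singleton components)."""
        n_comp, labels = sparse.csgraph.connected_components(
            self.weights_sparse(), directed=False
        )
        return labels

    @property
    def n_components(self) -> int:
        return int(self.connected_components().max()) + 1

    def greedy_coloring(self) -> list[np.ndarray]:
        """Partition units into classes with no within-class neighbors.

        Used to vectorize single-site CAR updates: units in one class are
        conditionally independent given the rest of the field.
        """
        order = np.argsort(-self.degrees, kind="stable")
        color = np.full(self.n_units, -1, dtype=int)
        for i in order:
            used = {color[j] for j in self.neighbors[i] if color[j] >= 0}
            c = 0
            while c in used:
                c += 1
            color[i] = c
        return [np.nonzero(color == c)[0] for c in range(color.max() + 1)]


def queen_lattice(nrows: int, ncols: int) -> AdjacencyStructure:
    """Queen contiguity of a full ``nrows x ncols`` lattice.

    Units are cells in row-major order; each cell's neighbors are the <= 8
    touching cells (edges and corners).
    """
    if nrows < 1 or ncols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    neighbors: list[np.ndarray] = []
    for r in range(nrows):
        for c in range(ncols):
            nb = [
                (r + dr) * ncols + (c + dc)
                for dr, dc in _QUEEN_OFFSETS
                if 0 <= r + dr < nrows and 0 <= c + dc < ncols
            ]
            neighbors.append(np.array(nb, dtype=int))
    return AdjacencyStructure(n_units=nrows * ncols, neighbors=neighbors)


def adjacency_from_zones(zones) -> AdjacencyStructure:
    """Queen contiguity between labeled zones of a label raster.

    Units i and j are adjacent iff some cell of i touches (8-connectivity)
    some cell of j. Isolated units trigger a warning but are kept.
    """
    labels = np.asarray(zones.labels if hasattr(zones, "labels") else zones, dtype=int)
    n = int(labels.max())
    pairs: set[tuple[int, int]] = set()
    H, W = labels.shape
    for dr, dc in [(-1, -1), (-1, 0), (-1, 1), (0, 1)]:  # half of the 8 moves
        ar = slice(max(0, -dr), H - max(0, dr))
        ac = slice(max(0, -dc), W - max(0, dc))
        br = slice(max(0, dr), H + min(0, dr))
        bc = slice(max(0, dc), W + min(0, dc))
        a, b = labels[ar, ac], labels[br, bc]
        touching = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[touching].ravel(), b[touching].ravel()):
            pairs.add((min(x, y) - 1, max(x, y) - 1))
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i, j in pairs:
        neighbors[i].add(j)
        neighbors[j].add(i)
    adj = AdjacencyStructure(n_units=n, neighbors=[np.array(sorted(s)) for s in neighbors])
    iso = adj.isolated_units()
    if iso.size:
        warnings.warn(
            f"isolated units (no Queen neighbors): {(iso + 1).tolist()}",
            stacklevel=2,
        )
    return adj


def read_neighbor_list(path) -> AdjacencyStructure:
    """Read a GAL-style neighbor list.

    Format: first line ``n``; then for each unit a line ``id degree`` followed
    by a line of neighbor ids (omitted when degree is 0). Ids are 1-based.
    Symmetry is enforced: an asymmetric file is an error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        tokens_lines = [ln.split() for ln in fh if ln.strip()]
    if not tokens_lines:
        raise ValueError("empty neighbor-list file")
    n = int(tokens_lines[0][0])
    neighbors: dict[int, list[int]] = {}
    i = 1
    while i < len(tokens_lines):
        uid, degree = int(tokens_lines[i][0]), int(tokens_lines[i][1])
        if not (1 <= uid <= n):
            raise ValueError(f"unknown unit id {uid} (n={n})")
        if degree > 0:
            i += 1
            nb = [int(t) for t in tokens_lines[i]]
            if len(nb) != degree:
                raise ValueError(f"unit {uid}: declared degree {degree}, got {len(nb)} ids")
            for j in nb:
                if not (1 <= j <= n):
                    raise ValueError(f"unit {uid} references unknown unit {j}")
            neighbors[uid] = nb
        else:
            neighbors[uid] = []
        i += 1
    missing = set(range(1, n + 1)) - set(neighbors)
    if missing:
        raise ValueError(f"units without an entry: {sorted(missing)}")
    # AdjacencyStructure's validator raises on asymmetry
    return AdjacencyStructure(
        n_units=n,
        neighbors=[np.array([j - 1 for j in neighbors[u]], dtype=int) for u in range(1, n + 1)],
    )


def write_neighbor_list(adj: AdjacencyStructure, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{adj.n_units}\n")
        for i, nb in enumerate(adj.neighbors):
            fh.write(f"{i + 1} {nb.size}\n")
            if nb.size:
                fh.write(" ".join(str(j + 1) for j in nb) + "\n")
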