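"""3D skeletonization and physical network-length measurement.

A binary network mask is thinned to a one-voxel-wide centerline (Lee-type
homotopic thinning), converted to a graph whose nodes are skeleton voxels
and whose edges are all 26-adjacent voxel pairs, and the total network
length is the sum of per-edge Euclidean distances between voxel centers in
physical units:

    len(edge) = sqrt((dz*Dz)^2 + (dy*Dy)^2 + (dx*Dx)^2),   D in {-1, 0, 1}

Anisotropy is handled at measurement time by weighting edges with the voxel
spacing; the volume is never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.morphology import skeletonize

from .stacks import LabelMask, Spacing

# the 13 lexicographically-positive offsets of the 26-neighborhood
_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


@dataclass
class SkeletonGraph:
    """Voxel-centerline graph with physical edge weights.

    ``nodes`` is an (N, 3) array of (z, y, x) skeleton voxel indices;
    ``edges`` an (E, 2) array of indices into ``nodes``, each unordered
    26-neighbor pair appearing exactly once.
    """

    nodes: np.ndarray
    edges: np.ndarray
    spacing: Spacing

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_lengths_um(self) -> np.ndarray:
        if self.n_edges == 0:
            return np.zeros(0)
        delta = self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]]
        return np.sqrt(((delta * np.asarray(self.spacing)) ** 2).sum(axis=1))

    def n_components(self) -> int:
        if self.n_nodes == 0:
            return 0
        data = np.ones(self.n_edges, dtype=np.int8)
        adj = coo_matrix(
            (data, (self.edges[:, 0], self.edges[:, 1])) if self.n_edges else
            (np.zeros(0, dtype=np.int8), (np.zeros(0, int), np.zeros(0, int))),
            shape=(self.n_nodes, self.n_nodes),
        )
        n, _ = connected_components(adj, directed=False)
        return int(n)


@dataclass(frozen=True)
class LengthResult:
    total_length_um: float
    n_skeleton_voxels: int
    n_edges: int
    n_components: int


def skeletonize_3d(mask: LabelMask) -> LabelMask:
    """Thin a binary mask to a one-voxel-wide centerline.

    Homotopy-preserving medial-axis thinning: connected components and loops
    of the input are preserved, and the output is a subset of the input
    foreground.  An empty mask yields an empty skeleton.
    """
    binary = mask.binary
    if not binary.any():
        skel = np.zeros_like(binary, dtype=np.uint8)
    else:
        skel = skeletonize(binary, method="lee").astype(np.uint8)
        skel[skel > 0] = 1
    return LabelMask(voxels=skel, spacing=mask.spacing, class_names={1: "skeleton"})


def build_skeleton_graph(skeleton: LabelMask, spacing: Spacing | None = None) -> SkeletonGraph:
    """Graph over skeleton voxels with one edge per unordered 26-neighbor pair."""
    spacing = spacing if spacing is not None else skeleton.spacing
    binary = skeleton.binary
    nodes = np.argwhere(binary)
    index = np.full(binary.shape, -1, dtype=np.int64)
    index[tuple(nodes.T)] = np.arange(len(nodes))

    edge_parts: list[np.ndarray] = []
    nz, ny, nx = binary.shape
    for dz, dy, dx in _OFFSETS:
        src = index[
            max(0, -dz) : nz - max(0, dz),
            max(0, -dy) : ny - max(0, dy),
            max(0, -dx) : nx - max(0, dx),
        ]
        dst = index[
            max(0, dz) : nz + min(0, dz),
            max(0, dy) : ny + min(0, dy),
            max(0, dx) : nx + min(0, dx),
        ]
        both = (src >= 0) & (dst >= 0)
        if both.any():
            edge_parts.append(np.stack([src[both], dst[both]], axis=1))
    edges = (
        np.concatenate(edge_parts, axis=0)
        if edge_parts
        else np.zeros((0, 2), dtype=np.int64)
    )
    return SkeletonGraph(nodes=nodes, edges=edges, spacing=tuple(spacing))


def measure_length(graph: SkeletonGraph) -> LengthResult:
    """Total network length: sum of per-edge physical Euclidean distances."""
    return LengthResult(
        total_length_um=float(graph.edge_lengths_um().sum()),
        n_skeleton_voxels=graph.n_nodes,
        n_edges=graph.n_edges,
        n_components=graph.n_components(),
    )


def skeleton_length(mask: LabelMask) -> tuple[LengthResult, LabelMask]:
    """Convenience: thin, graph, measure.  Returns (result, skeleton)."""
    skel = skeletonize_3d(mask)
    result = measure_length(build_skeleton_graph(skel))
    return result, skel
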