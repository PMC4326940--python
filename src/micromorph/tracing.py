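"""Traced-cell data model (SWC semantics), SWC I/O, and automated tracing.

Cells are represented as rooted trees of 3-D points in physical micrometres
(``CellTrace``).  Coordinates use 0-based voxel indexing with voxel centres at
``(i + 0.5) * d`` so that anisotropic stacks (e.g. 0.5 μm z-steps over
0.25 μm xy pixels) are unambiguous.

``trace_from_stack`` replaces interactive midline tracing: it binarizes a
stack, thins the foreground to a one-voxel 3-D skeleton, builds a weighted
graph on 26-connected skeleton voxels and returns one spanning tree per
connected component, rooted at the thickest point of the component (the soma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import tifffile
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import NoCellsError, ParameterError, TraceFormatError

ROOT_PARENT = -1

__all__ = [
    "Node",
    "CellTrace",
    "ImageStack",
    "read_swc",
    "write_swc",
    "read_stack",
    "trace_from_stack",
    "fill_volume",
    "ROOT_PARENT",
]


@dataclass(frozen=True)
class Node:
    """One SWC point: id, parent id (-1 for the root), position in μm, radius."""

    id: int
    parent: int
    x: float
    y: float
    z: float
    radius: float = 1.0
    type: int = 0

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class CellTrace:
    """A rooted, acyclic, connected tree of 3-D points describing one cell.

    Node order in ``nodes`` is arbitrary; parents need not precede children.
    """

    nodes: list[Node]
    cell_id: str = ""
    comments: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------ basic
    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def node_index(self) -> dict[int, Node]:
        return {n.id: n for n in self.nodes}

    @property
    def root(self) -> Node:
        roots = [n for n in self.nodes if n.parent == ROOT_PARENT]
        if len(roots) != 1:
            raise TraceFormatError(
                f"trace must have exactly one root, found {len(roots)}"
            )
        return roots[0]

    @property
    def soma_id(self) -> int:
        return self.root.id

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent != ROOT_PARENT:
                ch[n.parent].append(n.id)
        return ch

    def coords(self) -> np.ndarray:
        """(n, 3) array of x, y, z coordinates in μm."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def edges(self) -> list[tuple[Node, Node]]:
        """(parent, child) node pairs."""
        idx = self.node_index
        return [
            (idx[n.parent], n) for n in self.nodes if n.parent != ROOT_PARENT
        ]

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every parent→child edge, μm."""
        if len(self.nodes) < 2:
            return np.zeros(0)
        return np.array(
            [np.linalg.norm(p.xyz - c.xyz) for p, c in self.edges()]
        )

    def depth(self) -> float:
        """Cell depth Z: extent of the trace along the optical axis, μm."""
        zs = [n.z for n in self.nodes]
        return max(zs) - min(zs)

    def translated(self, dx: float, dy: float, dz: float) -> "CellTrace":
        moved = [
            replace(n, x=n.x + dx, y=n.y + dy, z=n.z + dz) for n in self.nodes
        ]
        return CellTrace(moved, cell_id=self.cell_id, comments=list(self.comments))

    def scaled(self, s: float) -> "CellTrace":
        """Uniform spatial scaling about the origin."""
        sc = [replace(n, x=n.x * s, y=n.y * s, z=n.z * s) for n in self.nodes]
        return CellTrace(sc, cell_id=self.cell_id, comments=list(self.comments))

    # -------------------------------------------------------------- validate
    def validate(self) -> None:
        """Raise TraceFormatError unless the trace is a rooted tree.

        Checks: unique ids, exactly one root, parents exist, no cycles,
        connected, finite coordinates.
        """
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise TraceFormatError(f"duplicate node id {dup}")
        idx = set(ids)
        roots = [n for n in self.nodes if n.parent == ROOT_PARENT]
        if len(roots) == 0:
            raise TraceFormatError("no root node (parent -1)")
        if len(roots) > 1:
            raise TraceFormatError(
                "multiple roots: nodes "
                + ", ".join(str(n.id) for n in roots)
            )
        for n in self.nodes:
            if n.parent != ROOT_PARENT and n.parent not in idx:
                raise TraceFormatError(
                    f"node {n.id} references missing parent {n.parent}"
                )
            if not all(np.isfinite([n.x, n.y, n.z])):
                raise TraceFormatError(f"node {n.id} has non-finite coordinates")
        # cycle / connectivity: walk each node up to the root
        parent_of = {n.id: n.parent for n in self.nodes}
        ok: set[int] = {ROOT_PARENT}
        for start in ids:
            path = []
            cur = start
            while cur not in ok:
                if cur in path:
                    raise TraceFormatError(f"cycle through node {cur}")
                path.append(cur)
                cur = parent_of[cur]
            ok.update(path)


@dataclass
class ImageStack:
    """A single-channel 3-D fluorescence stack.

    ``intensities`` is ordered (z, y, x), matching multi-page TIFF layout;
    ``voxel_size`` is (dx, dy, dz) in μm.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 1:
            raise ParameterError("stack must be 3-D with at least one z-plane")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel sizes must be positive")
        if np.any(self.intensities < 0):
            raise ParameterError("intensities must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[0]

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) μm positions of (z, y, x) voxel indices."""
        dx, dy, dz = self.voxel_size
        idx = np.atleast_2d(indices).astype(float)
        out = np.empty_like(idx)
        out[:, 0] = (idx[:, 2] + 0.5) * dx
        out[:, 1] = (idx[:, 1] + 0.5) * dy
        out[:, 2] = (idx[:, 0] + 0.5) * dz
        return out

    def save_tiff(self, path) -> None:
        tifffile.imwrite(path, np.asarray(self.intensities, dtype=np.float32))


def read_stack(path, voxel_size, channel: str = "") -> ImageStack:
    """Read a multi-page TIFF into an ImageStack."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    return ImageStack(data.astype(float), tuple(voxel_size), channel=channel)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> CellTrace:
    """Read an SWC file (id, type, x, y, z, radius, parent; μm).

    Comment lines are preserved in ``CellTrace.comments``.  The result is
    validated; malformed topology raises :class:`TraceFormatError` naming the
    offending node.
    """
    nodes: list[Node] = []
    comments: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            parts = line.split()
            if len(parts) != 7:
                raise TraceFormatError(
                    f"line {lineno}: expected 7 SWC columns, got {len(parts)}"
                )
            nid, ntype, x, y, z, r, parent = parts
            nodes.append(
                Node(
                    id=int(nid),
                    parent=int(parent),
                    x=float(x),
                    y=float(y),
                    z=float(z),
                    radius=float(r),
                    type=int(ntype),
                )
            )
    trace = CellTrace(nodes, comments=comments)
    trace.validate()
    return trace


def write_swc(trace: CellTrace, path) -> None:
    """Write a trace as SWC; coordinates at 1e-6 μm precision (lossless round trip)."""
    with open(path, "w") as fh:
        for c in trace.comments:
            fh.write(c.rstrip("\n") + "\n")
        for n in trace.nodes:
            fh.write(
                f"{n.id} {n.type} {n.x:.6f} {n.y:.6f} {n.z:.6f} "
                f"{n.radius:.6f} {n.parent}\n"
            )


# ---------------------------------------------------------------------------
# Automated tracing from a z-stack
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


def _skeleton_graph(skel: np.ndarray, voxel_size) -> nx.Graph:
    """Weighted graph on 26-connected skeleton voxels; weights in μm."""
    dx, dy, dz = voxel_size
    coords = np.argwhere(skel)
    g = nx.Graph()
    voxset = {tuple(c) for c in coords}
    for c in coords:
        g.add_node(tuple(c))
    step = np.array([dz, dy, dx], dtype=float)
    for c in coords:
        for off in _NEIGHBOR_OFFSETS:
            nb = tuple(c + off)
            if nb in voxset and tuple(c) < nb:
                w = float(np.linalg.norm(off * step))
                g.add_edge(tuple(c), nb, weight=w)
    return g


def _prune_short_spurs(tree: nx.Graph, root, min_voxels: int = 2) -> nx.Graph:
    """Drop terminal paths shorter than ``min_voxels`` edges (thinning artifacts)."""
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for leaf in [n for n in tree.nodes if tree.degree(n) == 1 and n != root]:
            # walk inward until a junction or the root
            path = [leaf]
            cur = leaf
            prev = None
            while True:
                nbrs = [n for n in tree.neighbors(cur) if n != prev]
                if len(nbrs) != 1:
                    break
                prev, cur = cur, nbrs[0]
                if tree.degree(cur) > 2 or cur == root:
                    break
                path.append(cur)
            if len(path) < min_voxels and tree.degree(cur) > 2:
                tree.remove_nodes_from(path)
                changed = True
    return tree


def smooth_chains(trace: CellTrace, passes: int = 2) -> CellTrace:
    """Relax staircase jitter along unbranched runs of a voxel-derived trace.

    Nodes with exactly one child (and a parent) are moved toward the midpoint
    of their neighbours (0.25·parent + 0.5·self + 0.25·child) for ``passes``
    iterations; the root, branch points and tips stay fixed.  This removes
    most of the digital-staircase length inflation of anisotropic skeletons
    without altering topology.
    """
    nodes = {n.id: n for n in trace.nodes}
    children = trace.children_map()
    for _ in range(max(passes, 0)):
        moved = {}
        for nid, n in nodes.items():
            if n.parent == ROOT_PARENT or len(children[nid]) != 1:
                continue
            p = nodes[n.parent].xyz
            c = nodes[children[nid][0]].xyz
            moved[nid] = 0.25 * p + 0.5 * n.xyz + 0.25 * c
        for nid, pos in moved.items():
            n = nodes[nid]
            nodes[nid] = Node(n.id, n.parent, float(pos[0]), float(pos[1]),
                              float(pos[2]), n.radius, n.type)
    return CellTrace(list(nodes.values()), cell_id=trace.cell_id,
                     comments=list(trace.comments))


def trace_from_stack(
    stack: ImageStack,
    intensity_threshold: float,
    soma_seed: tuple[float, float, float] | None = None,
    soma_radius: float = 0.0,
    min_component_voxels: int = 10,
    smooth_passes: int = 2,
) -> list[CellTrace]:
    """Extract one CellTrace per connected foreground component of a stack.

    The stack is binarized at ``intensity_threshold``, thinned to a one-voxel
    3-D skeleton, and each 26-connected skeleton component becomes a spanning
    tree with Euclidean μm edge lengths (anisotropy respected).  Loops — which
    in tree-shaped cells are rasterization artifacts — are broken by removing
    the longest edge of each cycle (minimum spanning tree).  Each component is
    rooted at its thickest point (maximal foreground distance transform), or
    at the skeleton node nearest ``soma_seed`` when given.

    When ``soma_radius`` > 0, skeleton nodes within that distance of the root
    are contracted into the root: thinning a several-μm soma blob produces a
    cluster of junction voxels there that would otherwise read as spurious
    bifurcations.

    Tiny components (< ``min_component_voxels`` skeleton voxels) are noise and
    are dropped.
    """
    img = stack.intensities
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise NoCellsError("stack is constant; no cells to trace")
    if not (lo <= intensity_threshold <= hi):
        raise ParameterError(
            f"threshold {intensity_threshold} outside intensity range [{lo}, {hi}]"
        )
    fg = img >= intensity_threshold
    if not fg.any():
        raise NoCellsError("no foreground voxels above threshold")

    skel = skeletonize(fg)
    if not skel.any():
        raise NoCellsError("skeletonization removed all foreground")

    dx, dy, dz = stack.voxel_size
    # thickness map in μm, anisotropy-aware
    dt = ndimage.distance_transform_edt(fg, sampling=(dz, dy, dx))
    graph = _skeleton_graph(skel, stack.voxel_size)

    traces: list[CellTrace] = []
    components = sorted(nx.connected_components(graph), key=len, reverse=True)
    for ci, comp in enumerate(components):
        if len(comp) < min_component_voxels:
            continue
        sub = graph.subgraph(comp)
        tree = nx.minimum_spanning_tree(sub, weight="weight")

        comp_arr = np.array(sorted(comp))
        centers = stack.voxel_centers_um(comp_arr)
        if soma_seed is not None:
            d = np.linalg.norm(centers - np.asarray(soma_seed, float), axis=1)
            root = tuple(comp_arr[int(np.argmin(d))])
        else:
            thickness = dt[tuple(comp_arr.T)]
            root = tuple(comp_arr[int(np.argmax(thickness))])

        tree = _prune_short_spurs(tree, root)
        if root not in tree:
            continue

        # contract the soma blob into the root
        if soma_radius > 0:
            root_um = stack.voxel_centers_um(np.array([root]))[0]
            near = {
                n
                for n in tree.nodes
                if np.linalg.norm(
                    stack.voxel_centers_um(np.array([n]))[0] - root_um
                )
                < soma_radius
            }
            near.discard(root)
            if near:
                for n in near:
                    nx.contracted_nodes(tree, root, n, self_loops=False, copy=False)

        nodes: list[Node] = []
        order = list(nx.bfs_tree(tree, root).nodes)
        id_of = {vox: i + 1 for i, vox in enumerate(order)}
        parent_of_vox = dict(nx.bfs_predecessors(tree, root))
        for vox in order:
            x, y, z = stack.voxel_centers_um(np.array([vox]))[0]
            parent = id_of[parent_of_vox[vox]] if vox in parent_of_vox else ROOT_PARENT
            nodes.append(
                Node(
                    id=id_of[vox],
                    parent=parent,
                    x=float(x),
                    y=float(y),
                    z=float(z),
                    radius=float(dt[vox]),
                )
            )
        trace = CellTrace(nodes, cell_id=f"traced_{ci:03d}")
        if smooth_passes:
            trace = smooth_chains(trace, smooth_passes)
        trace.validate()
        traces.append(trace)
    if not traces:
        raise NoCellsError("no component met the minimum size")
    return traces


def fill_volume(
    trace: CellTrace, stack: ImageStack, threshold: float
) -> np.ndarray:
    """Flood-fill the supra-threshold voxels 26-connected to the trace.

    Seeded from every trace-node voxel; the fill saturates the connected
    component(s) of ``intensities >= threshold`` that contain a seed.  Returns
    a boolean mask shaped like the stack.  If no seed voxel is above the
    threshold an empty mask is returned with a warning.
    """
    dx, dy, dz = stack.voxel_size
    shape = stack.intensities.shape
    seeds = []
    for n in trace.nodes:
        k = int(n.z / dz)
        j = int(n.y / dy)
        i = int(n.x / dx)
        if 0 <= k < shape[0] and 0 <= j < shape[1] and 0 <= i < shape[2]:
            seeds.append((k, j, i))
        else:
            raise ParameterError(f"trace node {n.id} lies outside the stack")
    mask = stack.intensities >= threshold
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    seed_labels = {labels[s] for s in seeds if mask[s]}
    seed_labels.discard(0)
    if not seed_labels:
        warnings.warn("no trace node above threshold; returning empty mask")
        return np.zeros(shape, dtype=bool)
    return np.isin(labels, sorted(seed_labels))
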