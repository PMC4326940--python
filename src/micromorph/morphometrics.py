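"""Per-cell morphometric parameters for traced microglia.

For one traced cell the quantities of interest are:

* ``n_bifurcations`` — non-soma nodes where a process splits; a node with k
  children contributes k − 1 (the soma is excluded because primary processes
  emanate from it rather than branch).
* ``n_branches`` — maximal paths between consecutive topological nodes (soma,
  branch points, tips); branches of path length ≤ 0.5 μm are not counted,
  but their length still contributes to the total.
* ``total_branch_length`` L — sum of Euclidean edge lengths, μm.
* ``tree_area`` A — area of the convex polygon through the outermost points
  of the z-projected trace, μm².
* ``depth`` Z — z-extent of the trace, μm.
* ``volume`` V = A·Z, μm³.
* ``coverage_volume`` CV = L / V × 1000 — μm of process per (10 μm)³ of
  tissue, a measure of how densely one cell surveys its territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError, ParameterError, UndefinedCoverageError
from .tracing import CellTrace, ROOT_PARENT

MIN_BRANCH_LENGTH = 0.5  # μm; shorter branches are not counted
NORMALIZATION_THICKNESS = 20.0  # μm

__all__ = [
    "Branch",
    "MorphometricRecord",
    "decompose_branches",
    "count_bifurcations",
    "total_branch_length",
    "tree_area",
    "coverage_volume",
    "branch_length_histogram",
    "normalize_to_thickness",
    "measure_trace",
    "records_to_frame",
]


@dataclass(frozen=True)
class Branch:
    """A maximal unbranched path: ordered node ids and its path length in μm."""

    node_ids: tuple[int, ...]
    length: float


@dataclass
class MorphometricRecord:
    cell_id: str
    n_bifurcations: float
    n_branches: float
    total_branch_length: float
    tree_area: float
    depth: float
    volume: float
    coverage_volume: float
    branch_lengths: list[float] = field(default_factory=list)
    normalized: bool = False
    condition: str = ""

    def as_dict(self) -> dict:
        d = {
            "cell_id": self.cell_id,
            "condition": self.condition,
            "n_bifurcations": self.n_bifurcations,
            "n_branches": self.n_branches,
            "total_branch_length": self.total_branch_length,
            "tree_area": self.tree_area,
            "depth": self.depth,
            "volume": self.volume,
            "coverage_volume": self.coverage_volume,
            "normalized": self.normalized,
        }
        return d


def decompose_branches(
    trace: CellTrace, min_length: float = MIN_BRANCH_LENGTH
) -> list[Branch]:
    """Split a trace into maximal branches between topological nodes.

    Topological nodes are the soma, bifurcation points (≥ 2 children) and
    terminal tips.  Every trace edge belongs to exactly one branch.  Branches
    whose path length is ≤ ``min_length`` are dropped from the returned list
    (they are not counted and do not enter the branch-length distribution),
    though their edges still contribute to the total branch length.
    """
    trace.validate()
    if len(trace) < 2:
        return []
    idx = trace.node_index
    children = trace.children_map()
    root = trace.root.id

    def is_topological(nid: int) -> bool:
        return nid == root or len(children[nid]) != 1

    branches: list[Branch] = []
    stack = [(root, c) for c in children[root]]
    while stack:
        start, nxt = stack.pop()
        path = [start]
        length = 0.0
        cur = nxt
        prev = start
        while True:
            path.append(cur)
            length += float(np.linalg.norm(idx[cur].xyz - idx[prev].xyz))
            if is_topological(cur):
                break
            prev, cur = cur, children[cur][0]
        for c in children[cur]:
            stack.append((cur, c))
        if length > min_length:
            branches.append(Branch(tuple(path), length))
    return branches


def count_bifurcations(trace: CellTrace) -> int:
    """Number of bifurcations: Σ max(out-degree − 1, 0) over non-soma nodes."""
    trace.validate()
    children = trace.children_map()
    root = trace.root.id
    return int(
        sum(max(len(c) - 1, 0) for nid, c in children.items() if nid != root)
    )


def total_branch_length(trace: CellTrace) -> float:
    """Sum of all branch segments: Σ Euclidean edge lengths, μm."""
    trace.validate()
    return float(trace.edge_lengths().sum())


def tree_area(trace: CellTrace) -> float:
    """Area constrained by the polygon through the outer points of the
    z-projected trace: the convex hull of (x, y) node positions, μm²."""
    pts = np.unique(trace.coords()[:, :2], axis=0)
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"need ≥ 3 distinct projected points, got {len(pts)}"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError("projected points are collinear") from exc
    return float(hull.volume)  # 2-D hull: 'volume' is the enclosed area


def coverage_volume(
    total_length: float, area: float, depth: float
) -> float:
    """Process length per (10 μm)³ tissue cube: CV = L / (A·Z) × 1000."""
    volume = area * depth
    if volume <= 0:
        raise UndefinedCoverageError("cell volume is zero; coverage undefined")
    return total_length / volume * 1000.0


def measure_trace(
    trace: CellTrace,
    min_length: float = MIN_BRANCH_LENGTH,
    condition: str = "",
) -> MorphometricRecord:
    """Compute the full per-cell morphometric record from a trace."""
    branches = decompose_branches(trace, min_length=min_length)
    L = total_branch_length(trace)
    A = tree_area(trace)
    Z = trace.depth()
    V = A * Z
    cv = coverage_volume(L, A, Z)
    return MorphometricRecord(
        cell_id=trace.cell_id,
        n_bifurcations=count_bifurcations(trace),
        n_branches=len(branches),
        total_branch_length=L,
        tree_area=A,
        depth=Z,
        volume=V,
        coverage_volume=cv,
        branch_lengths=[b.length for b in branches],
        condition=condition,
    )


def branch_length_histogram(
    records: list[MorphometricRecord] | list[float], bin_width: float = 1.0
) -> pd.DataFrame:
    """Distribution of branch lengths pooled over a group of cells.

    Bins are left-closed: [k·w, (k+1)·w).  Returns a DataFrame with columns
    ``bin_left``, ``bin_right``, ``count``; empty input gives an empty frame.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    lengths: list[float] = []
    for r in records:
        if isinstance(r, MorphometricRecord):
            lengths.extend(r.branch_lengths)
        else:
            lengths.append(float(r))
    if not lengths:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    arr = np.asarray(lengths)
    k = np.floor(arr / bin_width).astype(int)
    counts = np.bincount(k)
    edges = np.arange(len(counts)) * bin_width
    return pd.DataFrame(
        {
            "bin_left": edges,
            "bin_right": edges + bin_width,
            "count": counts,
        }
    )


def normalize_to_thickness(
    record: MorphometricRecord, target_thickness: float = NORMALIZATION_THICKNESS
) -> MorphometricRecord:
    """Rescale extensive quantities to a common slice thickness.

    Counts and lengths (bifurcations, branches, L, per-branch lengths) scale
    by ``target_thickness / depth``; the tree area and the coverage volume are
    left unchanged — CV is already volume-normalized.  Cells imaged at exactly
    the target thickness are returned unchanged.
    """
    if record.depth <= 0:
        raise ParameterError("record depth must be positive to normalize")
    f = target_thickness / record.depth
    return replace(
        record,
        n_bifurcations=record.n_bifurcations * f,
        n_branches=record.n_branches * f,
        total_branch_length=record.total_branch_length * f,
        branch_lengths=[bl * f for bl in record.branch_lengths],
        normalized=True,
    )


def records_to_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    """One MorphometricRecord per row, ready for CSV export or group stats."""
    return pd.DataFrame([r.as_dict() for r in records])
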