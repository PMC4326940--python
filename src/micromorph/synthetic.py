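"""Synthetic microglial fields with full ground truth.

Generates traced cells, multi-cell fields (including plaque-centred layered
phenotypes) and rendered noisy multi-channel z-stacks, so every stage of the
morphometry pipeline can be verified against known truth.

The generative cell model is a discrete random tree echoing the three-order
process hierarchy of cortical microglia: 7–9 primary processes leave the
soma; each branch is a short chain of tortuous segments that may bifurcate
into higher-order daughters; fine terminal processes (1–4 μm) sprout along
the backbone.  Aged and plaque-layer phenotypes are reached by reducing the
bifurcation probability and the fine-process rate (and, for amoeboid cells,
shortening segments), mirroring the loss of arborization those cells show.

Closed-form expectations for the model (used as independent oracles):
the expected number of backbone segments is
``n_primary · E[segs/branch] · Σ_{o=1..max_order} (2·bifurcation_prob)^(o−1)``
and each backbone node spawns up to two fine processes of mean length
2.5 μm (Binomial(2, ``fine_process_rate``)), so
``E[L] = E[segments] · (segment_length_mean + 2 · fine_process_rate · 2.5)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError, ParameterError, RenderError
from .tracing import CellTrace, ImageStack, Node, ROOT_PARENT, write_swc

__all__ = [
    "GenParams",
    "SceneTruth",
    "RenderResult",
    "CONDITIONS",
    "condition_params",
    "generate_cell_trace",
    "generate_field",
    "render_stack",
    "expected_total_length",
    "write_scene",
]

# segments per branch, drawn uniformly per order (primaries are long and
# consistent; higher-order side branches are short), and per-order length
# scaling: a cell's territory is set by its primary reach, not by branching
# depth, matching the main/medium/fine process hierarchy
_SEGS_PER_ORDER = ((4, 5), (2, 4), (2, 3))
_ORDER_LENGTH_SCALE = (1.0, 0.35, 0.25)
_FINE_LENGTH_RANGE = (1.0, 4.0)  # μm, terminal fine processes
_Z_FLATTEN = 0.15  # microglia are flat relative to their planar spread

DEFAULT_VOXEL_SIZE = (0.25, 0.25, 0.5)  # μm; z-interval matches confocal stacks
DEFAULT_FIELD_SIZE = (160.0, 160.0, 20.0)  # μm; spans a 32×32 grid of 5 μm squares
PLAQUE_LAYER_RADII = (40.0, 70.0, 140.0)  # μm; L1 / L2 / L3 outer radii

# Reference CD39-like channel-2 intensities (arbitrary units).  The baseline
# population sits near 617 a.u.; plaque-layer L1/L2 cells are CD39-high and
# L3 is an even mix of normal and low expressors.
_MFI_BASE = (617.0, 60.0)
_MFI_HIGH = (950.0, 70.0)
_MFI_LOW = (380.0, 60.0)


@dataclass(frozen=True)
class GenParams:
    """Parameters of the random-tree cell model (lengths in μm)."""

    n_primary: int = 8
    bifurcation_prob: float = 0.5
    segment_length_mean: float = 6.0
    segment_length_sd: float = 1.5
    max_order: int = 3
    fine_process_rate: float = 0.55
    tortuosity: float = 0.3
    condition: str = "young"
    seed: int = 0

    def validate(self) -> None:
        for name in ("bifurcation_prob", "fine_process_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} must be a probability in [0, 1]")
        if self.segment_length_mean <= 0 or self.segment_length_sd < 0:
            raise ParameterError("segment lengths must be positive")
        if self.n_primary < 1:
            raise ParameterError("n_primary must be ≥ 1")
        if self.max_order < 1:
            raise ParameterError("max_order must be ≥ 1")
        if self.tortuosity < 0:
            raise ParameterError("tortuosity must be ≥ 0")


# Condition presets.  n_primary is drawn per cell from the stated range;
# aged and plaque layers reduce bifurcation_prob and fine_process_rate.
CONDITIONS: dict[str, dict] = {
    "young": dict(
        n_primary_range=(7, 9),
        bifurcation_prob=0.6,
        segment_length_mean=6.0,
        segment_length_sd=1.0,
        max_order=3,
        fine_process_rate=0.7,
        tortuosity=0.3,
    ),
    # aged cells keep much of their territory: the loss is dominated by
    # fine/interior processes (with individual surviving processes longer),
    # so the hull shrinks only mildly while coverage drops sharply
    "aged": dict(
        n_primary_range=(7, 9),
        bifurcation_prob=0.4,
        segment_length_mean=6.5,
        segment_length_sd=1.2,
        max_order=3,
        fine_process_rate=0.08,
        tortuosity=0.45,
    ),
    # L1: amoeboid cells hugging the plaque — few, short, unbranched stubs
    "plaque_L1": dict(
        n_primary_range=(3, 5),
        bifurcation_prob=0.05,
        segment_length_mean=2.0,
        segment_length_sd=0.5,
        max_order=1,
        fine_process_rate=0.05,
        tortuosity=0.5,
    ),
    # L2: enlarged cytoplasm, markedly reduced complexity
    "plaque_L2": dict(
        n_primary_range=(5, 7),
        bifurcation_prob=0.2,
        segment_length_mean=4.0,
        segment_length_sd=1.0,
        max_order=2,
        fine_process_rate=0.15,
        tortuosity=0.4,
    ),
    # L3: still ramified but less complex than plaque-free cells
    "plaque_L3": dict(
        n_primary_range=(6, 8),
        bifurcation_prob=0.35,
        segment_length_mean=5.0,
        segment_length_sd=1.2,
        max_order=3,
        fine_process_rate=0.3,
        tortuosity=0.35,
    ),
}


def condition_params(
    condition: str, rng: np.random.Generator, seed: int = 0, **overrides
) -> GenParams:
    """Draw a per-cell GenParams for a named condition (n_primary sampled
    uniformly from the condition's range)."""
    if condition not in CONDITIONS:
        raise ParameterError(
            f"unknown condition {condition!r}; choose from {sorted(CONDITIONS)}"
        )
    cfg = dict(CONDITIONS[condition])
    lo, hi = cfg.pop("n_primary_range")
    params = GenParams(
        n_primary=int(rng.integers(lo, hi + 1)),
        condition=condition,
        seed=seed,
        **cfg,
    )
    if overrides:
        params = replace(params, **overrides)
    params.validate()
    return params


def _order_cfg(order: int) -> tuple[tuple[int, int], float]:
    i = min(order - 1, len(_SEGS_PER_ORDER) - 1)
    return _SEGS_PER_ORDER[i], _ORDER_LENGTH_SCALE[i]


def expected_total_length(params: GenParams) -> float:
    """Closed-form E[total branch length] of the random-tree model, μm."""
    growth = 2.0 * params.bifurcation_prob
    e_fine = (_FINE_LENGTH_RANGE[0] + _FINE_LENGTH_RANGE[1]) / 2.0
    total = 0.0
    for o in range(1, params.max_order + 1):
        n_o = params.n_primary * growth ** (o - 1)
        (s_lo, s_hi), scale = _order_cfg(o)
        e_segs = (s_lo + s_hi) / 2.0
        total += n_o * e_segs * (
            params.segment_length_mean * scale
            + 2.0 * params.fine_process_rate * e_fine
        )
    return total


def _seg_seg_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between 3-D segments p1–p2 and q1–q2."""
    u, v, w0 = p2 - p1, q2 - q1, p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w0, v @ w0
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # one refinement pass after clamping t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm((p1 + s * u) - (q1 + t * v)))


def min_branch_separation(trace: CellTrace, soma_exclude: float = 5.0) -> float:
    """Smallest gap between topologically distant parts of a trace, μm.

    Minimum segment–segment distance over edge pairs that share no node,
    are not parent/child-adjacent, and do not both touch the soma
    neighbourhood (within ``soma_exclude`` of the root, where primary
    processes legitimately converge).  Rendered cells whose separation
    exceeds ~4 tube radii re-trace with exact topology.
    """
    idx = trace.node_index
    root = trace.root.xyz
    edges = []
    for parent, child in trace.edges():
        near_soma = (
            np.linalg.norm(parent.xyz - root) < soma_exclude
            or np.linalg.norm(child.xyz - root) < soma_exclude
        )
        edges.append((parent.id, child.id, parent.xyz, child.xyz, near_soma))
    best = np.inf
    for i in range(len(edges)):
        a0, a1, p1, p2, ns_a = edges[i]
        for j in range(i + 1, len(edges)):
            b0, b1, q1, q2, ns_b = edges[j]
            if {a0, a1} & {b0, b1}:
                continue
            if ns_a and ns_b:
                continue
            # skip grandparent-adjacent pairs (consecutive along one path)
            if idx[a0].parent in (b0, b1) or idx[b0].parent in (a0, a1):
                continue
            best = min(best, _seg_seg_distance(p1, p2, q1, q2))
    return best


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _jitter(direction: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Perturb a unit vector by Gaussian angular noise of scale ``sigma`` rad."""
    d = direction + sigma * rng.normal(size=3) * np.array([1.0, 1.0, _Z_FLATTEN])
    return _unit(d)


def generate_cell_trace(
    params: GenParams,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    bounds: tuple[float, float, float] | None = None,
    cell_id: str = "cell",
    rng: np.random.Generator | None = None,
    slab_thickness: float = 20.0,
) -> CellTrace:
    """Grow one random microglial tree.

    The root (soma) sits at ``origin``; ``params.n_primary`` processes leave
    it at evenly spread azimuths.  Each branch extends a few segments of
    ~N(mean·scale, sd·scale) length — primaries are long (scale 1), higher
    orders short side branches — with per-step angular jitter, then
    bifurcates into two daughters with probability ``bifurcation_prob``
    while below ``max_order``.  Each backbone node spawns a terminal fine process
    (1–4 μm) with probability ``fine_process_rate`` each (two chances per
    node).  Growth along z is confined to a ``slab_thickness`` μm slab
    centred on the soma — microglia are flat and imaged sections are thin.
    When ``bounds`` is given, growth is also reflected at the box walls so
    the trace stays in-field.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    origin = np.asarray(origin, dtype=float)

    nodes: list[Node] = [
        Node(id=1, parent=ROOT_PARENT, x=origin[0], y=origin[1], z=origin[2],
             radius=3.0, type=1)
    ]
    next_id = [2]

    z_lo, z_hi = origin[2] - slab_thickness / 2.0, origin[2] + slab_thickness / 2.0
    if bounds is not None:
        z_lo, z_hi = max(z_lo, 0.0), min(z_hi, bounds[2])

    def clip(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        lims = [(0.0, bounds[0]), (0.0, bounds[1])] if bounds is not None else []
        for ax, (lo, hi) in enumerate(lims):
            if q[ax] < lo:
                q[ax] = 2 * lo - q[ax]
            if q[ax] > hi:
                q[ax] = 2 * hi - q[ax]
            q[ax] = min(max(q[ax], lo), hi)
        # reflect z at the slab faces
        if q[2] < z_lo:
            q[2] = 2 * z_lo - q[2]
        if q[2] > z_hi:
            q[2] = 2 * z_hi - q[2]
        q[2] = min(max(q[2], z_lo), z_hi)
        return q

    def add_node(parent_id: int, pos: np.ndarray, radius: float) -> int:
        nid = next_id[0]
        next_id[0] += 1
        nodes.append(
            Node(id=nid, parent=parent_id, x=float(pos[0]), y=float(pos[1]),
                 z=float(pos[2]), radius=radius, type=0)
        )
        return nid

    def grow_branch(parent_id: int, pos: np.ndarray, direction: np.ndarray,
                    order: int) -> None:
        (s_lo, s_hi), scale = _order_cfg(order)
        n_seg = int(rng.integers(s_lo, s_hi + 1))
        d = direction
        cur_id, cur_pos = parent_id, pos
        radius = max(0.6 - 0.15 * (order - 1), 0.25)
        for _ in range(n_seg):
            length = max(
                0.5,
                rng.normal(params.segment_length_mean * scale,
                           params.segment_length_sd * scale),
            )
            d = _jitter(d, params.tortuosity, rng)
            new_pos = clip(cur_pos + d * length)
            cur_id = add_node(cur_id, new_pos, radius)
            cur_pos = new_pos
            # draw fine-process attributes unconditionally so that a lower
            # fine_process_rate yields a strict sub-tree of the same seed's
            # higher-rate tree (monotone coupling); up to two fines per node
            for _fine in range(2):
                u = rng.random()
                fd = _unit(rng.normal(size=3) * np.array([1.0, 1.0, _Z_FLATTEN]))
                flen = rng.uniform(*_FINE_LENGTH_RANGE)
                if u < params.fine_process_rate:
                    add_node(cur_id, clip(cur_pos + fd * flen), 0.25)
        if order < params.max_order and rng.random() < params.bifurcation_prob:
            axis = _unit(np.cross(d, rng.normal(size=3)))
            split = rng.uniform(0.35, 0.7)  # rad, half-angle between daughters
            for sign in (+1.0, -1.0):
                dd = _unit(d * np.cos(split) + np.cross(axis, d) * np.sin(split) * sign)
                grow_branch(cur_id, cur_pos, dd, order + 1)

    phase = rng.uniform(0, 2 * np.pi)
    for i in range(params.n_primary):
        az = phase + 2 * np.pi * i / params.n_primary
        elev = rng.normal(0, 0.2) * _Z_FLATTEN
        d0 = _unit(np.array([np.cos(az), np.sin(az), elev]))
        grow_branch(1, origin, d0, 1)

    trace = CellTrace(nodes, cell_id=cell_id)
    trace.validate()
    return trace


# ---------------------------------------------------------------------------
# Multi-cell fields
# ---------------------------------------------------------------------------

@dataclass
class SceneTruth:
    """A synthetic field with complete ground truth."""

    traces: list[CellTrace]
    conditions: dict[str, str]          # cell_id -> condition label
    layers: dict[str, str]              # cell_id -> plaque layer or ""
    cell_mfis: dict[str, float]         # cell_id -> channel-2 mean intensity
    field_size: tuple[float, float, float]
    condition: str = "young"            # field-level label
    plaque_center: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise GenerationError("cell ids must be unique")
        X, Y, Z = self.field_size
        for t in self.traces:
            c = t.coords()
            if (c < -1e-9).any() or (c > np.array([X, Y, Z]) + 1e-9).any():
                raise GenerationError(f"trace {t.cell_id} escapes the field")
        if any(m < 0 for m in self.cell_mfis.values()):
            raise GenerationError("MFIs must be non-negative")

    @property
    def somata(self) -> dict[str, np.ndarray]:
        return {t.cell_id: t.root.xyz for t in self.traces}

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.traces:
            s = t.root
            rows.append(
                dict(
                    cell_id=t.cell_id,
                    condition=self.conditions[t.cell_id],
                    layer=self.layers.get(t.cell_id, ""),
                    mfi_ch2=self.cell_mfis[t.cell_id],
                    soma_x=s.x, soma_y=s.y, soma_z=s.z,
                )
            )
        return pd.DataFrame(rows)


def _draw_mfi(condition: str, rng: np.random.Generator) -> float:
    if condition in ("plaque_L1", "plaque_L2"):
        mu, sd = _MFI_HIGH
    elif condition == "plaque_L3":
        mu, sd = _MFI_BASE if rng.random() < 0.5 else _MFI_LOW
    else:
        mu, sd = _MFI_BASE
    return float(max(rng.normal(mu, sd), 0.0))


def generate_field(
    condition: str = "young",
    density: float = 6.0,
    field_size: tuple[float, float, float] = DEFAULT_FIELD_SIZE,
    plaque: tuple[float, float] | None = None,
    layer_radii: tuple[float, float, float] = PLAQUE_LAYER_RADII,
    seed: int = 0,
    n_cells: int | None = None,
    min_separation: float = 18.0,
    params_per_condition: dict[str, dict] | None = None,
) -> SceneTruth:
    """Place cells in a field by a spatial point process and grow each one.

    ``density`` is cells per 100×100 μm²; pass ``n_cells`` for fixed-n mode.
    Somata are placed uniformly with a soft minimum separation (rejection
    sampling).  With a plaque at ``plaque`` (x, y in μm), cells take the layer
    phenotype of the annulus their soma falls in: amoeboid ``plaque_L1``
    within ``layer_radii[0]`` of the centre, ``plaque_L2`` and ``plaque_L3``
    in the next two annuli, and the baseline ``condition`` beyond.  Channel-2
    (CD39-like) intensities are drawn high for L1/L2 and mixed normal/low for
    L3.  Random streams are per cell, derived from (seed, cell index), so
    adding a cell never perturbs existing ones.
    """
    X, Y, Z = field_size
    if density <= 0 and n_cells is None:
        raise GenerationError("density must be positive")
    if plaque is not None:
        px, py = plaque
        if not (0 <= px <= X and 0 <= py <= Y):
            raise GenerationError("plaque center must lie inside the field")
    if n_cells is None:
        n_cells = int(np.random.default_rng([seed, 2**16]).poisson(
            density * X * Y / 1e4
        ))
    if n_cells < 1:
        raise GenerationError("field too small for a single cell at this density")
    overrides = params_per_condition or {}

    margin = 8.0
    if X <= 2 * margin or Y <= 2 * margin:
        raise GenerationError("field too small for one cell")
    positions: list[np.ndarray] = []
    traces: list[CellTrace] = []
    conditions: dict[str, str] = {}
    layers: dict[str, str] = {}
    mfis: dict[str, float] = {}
    for i in range(n_cells):
        rng = np.random.default_rng([seed, i])
        for _ in range(200):
            pos = np.array(
                [
                    rng.uniform(margin, X - margin),
                    rng.uniform(margin, Y - margin),
                    rng.uniform(0.3 * Z, 0.7 * Z),
                ]
            )
            if all(
                np.linalg.norm(pos[:2] - q[:2]) >= min_separation for q in positions
            ):
                break
        positions.append(pos)
        if plaque is not None:
            r = float(np.hypot(pos[0] - plaque[0], pos[1] - plaque[1]))
            if r < layer_radii[0]:
                ccond, layer = "plaque_L1", "L1"
            elif r < layer_radii[1]:
                ccond, layer = "plaque_L2", "L2"
            elif r < layer_radii[2]:
                ccond, layer = "plaque_L3", "L3"
            else:
                ccond, layer = condition, ""
        else:
            ccond, layer = condition, ""
        cid = f"cell_{i:04d}"
        params = condition_params(ccond, rng, seed=seed, **overrides.get(ccond, {}))
        traces.append(
            generate_cell_trace(
                params, origin=tuple(pos), bounds=field_size, cell_id=cid, rng=rng
            )
        )
        conditions[cid] = ccond
        layers[cid] = layer
        mfis[cid] = _draw_mfi(ccond, rng)

    return SceneTruth(
        traces=traces,
        conditions=conditions,
        layers=layers,
        cell_mfis=mfis,
        field_size=field_size,
        condition="plaque" if plaque is not None else condition,
        plaque_center=plaque,
        seed=seed,
    )


def single_cell_scene(
    trace: CellTrace, mfi: float = 600.0, pad: float = 5.0, condition: str = "young"
) -> SceneTruth:
    """Wrap one trace in a tight padded field (for per-cell rendering).

    The trace is translated so its bounding box sits ``pad`` μm from the
    origin and the field hugs the box, keeping per-cell stacks small.
    """
    c = trace.coords()
    lo = c.min(axis=0)
    t = trace.translated(*(pad - lo))
    hi = t.coords().max(axis=0) + pad
    return SceneTruth(
        traces=[t],
        conditions={t.cell_id: condition},
        layers={t.cell_id: ""},
        cell_mfis={t.cell_id: float(mfi)},
        field_size=(float(hi[0]), float(hi[1]), float(hi[2])),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderResult:
    """Rendered channels plus the voxel→cell ground-truth map."""

    channels: dict[str, ImageStack]
    truth_labels: np.ndarray            # int array (z, y, x); 0 = background
    cell_index: dict[int, str]          # label value -> cell_id
    voxel_size: tuple[float, float, float]

    def truth_mask(self, cell_id: str) -> np.ndarray:
        label = next(k for k, v in self.cell_index.items() if v == cell_id)
        return self.truth_labels == label


def _rasterize_trace(
    trace: CellTrace,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Boolean tube mask of a trace: spheres of the node radii swept along edges."""
    dx, dy, dz = voxel_size
    step_um = min(voxel_size) / 2.0
    mask = np.zeros(shape, dtype=bool)
    idx = trace.node_index
    pts: list[np.ndarray] = []
    radii: list[float] = []
    soma = trace.root
    pts.append(soma.xyz)
    radii.append(soma.radius)
    for parent, child in trace.edges():
        p0, p1 = parent.xyz, child.xyz
        seg = p1 - p0
        n = max(int(np.ceil(np.linalg.norm(seg) / step_um)), 1)
        for t in np.linspace(0.0, 1.0, n + 1):
            pts.append(p0 + t * seg)
            radii.append(parent.radius * (1 - t) + child.radius * t)
    # stamp an anisotropic ball per sample point, grouped by radius for speed
    pts_arr = np.asarray(pts)
    radii_arr = np.round(np.asarray(radii), 2)
    for r in np.unique(radii_arr):
        sel = pts_arr[radii_arr == r]
        nz, ny, nx = (
            max(int(np.ceil(r / dz)), 0),
            max(int(np.ceil(r / dy)), 0),
            max(int(np.ceil(r / dx)), 0),
        )
        zz, yy, xx = np.mgrid[-nz : nz + 1, -ny : ny + 1, -nx : nx + 1]
        ball = (zz * dz) ** 2 + (yy * dy) ** 2 + (xx * dx) ** 2 <= r**2 + 1e-9
        offsets = np.argwhere(ball) - np.array([nz, ny, nx])
        centers = np.column_stack(
            [
                np.floor(sel[:, 2] / dz).astype(int),
                np.floor(sel[:, 1] / dy).astype(int),
                np.floor(sel[:, 0] / dx).astype(int),
            ]
        )
        vox = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        good = (
            (vox >= 0).all(axis=1)
            & (vox[:, 0] < shape[0])
            & (vox[:, 1] < shape[1])
            & (vox[:, 2] < shape[2])
        )
        vox = vox[good]
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return mask



def _rasterize_soma(
    trace: CellTrace,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of the soma ball alone."""
    soma = trace.root
    only = CellTrace([Node(1, ROOT_PARENT, soma.x, soma.y, soma.z,
                           soma.radius, 1)], cell_id=trace.cell_id)
    return _rasterize_trace(only, shape, voxel_size)


def render_stack(
    scene: SceneTruth,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    psf_sigma: float = 0.15,
    noise_model: dict | None = None,
    channels: tuple[str, ...] = ("ch1", "ch2"),
    tube_intensity: float = 200.0,
    soma_intensity_factor: float = 2.0,
    seed: int | None = None,
) -> RenderResult:
    """Rasterize a scene into per-channel noisy z-stacks plus a truth map.

    Traces become tubes whose radii come from the node radii (soma ≈ 3 μm,
    backbone ≈ 0.5 μm, fine tips ≈ 0.2 μm), blurred by an isotropic Gaussian
    approximation of the confocal PSF (``psf_sigma`` μm, default matching a
    high-NA lateral FWHM of ~0.35 μm; 0 disables), then corrupted
    by ``noise_model``: ``{"gaussian_sd": σ}`` additive (clipped at 0) or
    ``{"poisson_gain": g}``.  Channel 1 carries the structural label at
    ``tube_intensity`` with somata at ``soma_intensity_factor`` times that
    (their thicker cytoplasm projects brighter); channel 2 carries each
    cell's planted MFI uniformly over its tube.
    The voxel→cell-id map is returned alongside (overlaps keep the earlier
    cell, i.e. first-come).
    """
    dx, dy, dz = voxel_size
    if min(voxel_size) <= 0:
        raise RenderError("voxel sizes must be positive")
    X, Y, Z = scene.field_size
    if dx > X or dy > Y or dz > Z:
        raise RenderError("voxel size exceeds the field extent")
    if noise_model is None:
        noise_model = {"gaussian_sd": 0.05 * tube_intensity}
    shape = (
        max(int(np.ceil(Z / dz)), 1),
        max(int(np.ceil(Y / dy)), 1),
        max(int(np.ceil(X / dx)), 1),
    )
    truth = np.zeros(shape, dtype=np.int32)
    cell_index: dict[int, str] = {}
    ch1 = np.zeros(shape, dtype=float)
    ch2 = np.zeros(shape, dtype=float)
    for li, trace in enumerate(scene.traces, start=1):
        tube = _rasterize_trace(trace, shape, voxel_size)
        soma = _rasterize_soma(trace, shape, voxel_size)
        new = tube & (truth == 0)
        truth[new] = li
        cell_index[li] = trace.cell_id
        ch1[tube] = tube_intensity
        # somata are brighter than processes, as in projected real images
        ch1[soma] = soma_intensity_factor * tube_intensity
        ch2[new] = scene.cell_mfis[trace.cell_id]

    rng = np.random.default_rng(
        scene.seed + 7919 if seed is None else seed
    )
    out: dict[str, ImageStack] = {}
    for name, img in zip(channels, (ch1, ch2)):
        arr = img
        if psf_sigma > 0:
            arr = ndimage.gaussian_filter(
                arr, sigma=(psf_sigma / dz, psf_sigma / dy, psf_sigma / dx)
            )
        if "gaussian_sd" in noise_model and noise_model["gaussian_sd"] > 0:
            arr = arr + rng.normal(0.0, noise_model["gaussian_sd"], size=arr.shape)
        elif "poisson_gain" in noise_model:
            g = noise_model["poisson_gain"]
            arr = rng.poisson(np.clip(arr, 0, None) * g).astype(float) / g
        out[name] = ImageStack(np.clip(arr, 0.0, None), voxel_size, channel=name)
    return RenderResult(
        channels=out, truth_labels=truth, cell_index=cell_index,
        voxel_size=voxel_size,
    )


def write_scene(
    scene: SceneTruth,
    out_dir,
    render: RenderResult | None = None,
) -> None:
    """Write a truth bundle: per-cell SWC, truth CSV, JSON manifest, and —
    when a render is given — one multi-page TIFF per channel."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    swc_dir = out / "swc"
    swc_dir.mkdir(exist_ok=True)
    for t in scene.traces:
        write_swc(t, swc_dir / f"{t.cell_id}.swc")
    scene.truth_table().to_csv(out / "truth.csv", index=False)
    manifest = dict(
        condition=scene.condition,
        field_size=list(scene.field_size),
        plaque_center=list(scene.plaque_center) if scene.plaque_center else None,
        seed=scene.seed,
        n_cells=len(scene.traces),
    )
    if render is not None:
        manifest["voxel_size"] = list(render.voxel_size)
        for name, stack in render.channels.items():
            stack.save_tiff(out / f"{name}.tif")
        np.savetxt(
            out / "truth_labels_zsum.csv",
            (render.truth_labels > 0).sum(axis=0),
            fmt="%d", delimiter=",",
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
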