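# Methods

This note documents the models, conventions and numerical choices behind
`micromorph`, and what its synthetic validation does and does not establish
about real microscopy data.

## Coordinate and unit conventions

All coordinates are physical micrometres. Voxel indexing is 0-based with the
voxel centre at `(i + 0.5)·d` for voxel size `d` per axis; stacks are ordered
`(z, y, x)` to match multi-page TIFF layout. The default voxel geometry is
0.25 × 0.25 × 0.5 μm: a 0.5 μm z-interval is standard for confocal stacks of
this kind, and 0.25 μm/px corresponds to a 1024-px field at high
magnification. Field-level analyses in the acceptance script render at
0.5 × 0.5 × 1 μm to keep arrays small; grid and Sholl statistics are
insensitive to this (they act on the projected skeleton).

## Per-cell morphometrics

A traced cell is a rooted tree of 3-D points with SWC semantics. The
measured parameters:

- **Bifurcations**: Σ max(out-degree − 1, 0) over non-soma nodes. The soma
  is excluded — primary processes emanate from it rather than branch — and a
  multifurcation of degree *k* counts as *k* − 1 bifurcations (observed
  branch points are overwhelmingly binary; this makes the count additive
  under edge subdivision).
- **Branches**: maximal paths between consecutive topological nodes (soma,
  branch points, tips). Branches with path length ≤ 0.5 μm are excluded from
  the count and from the branch-length distribution — sub-half-micron
  "branches" are tracing artifacts at this resolution — but their edges
  still contribute to the total branch length, so the total is invariant to
  the filter.
- **Total branch length** *L*: the sum of Euclidean edge lengths.
- **Tree area** *A*: the convex hull of the node positions projected to the
  xy-plane. The polygon "through the outer points" of an arbor is read as
  the convex hull — the unique convex polygon through the outermost points;
  concave footprints are out of scope. Fewer than 3 distinct projected
  points, or collinear ones, raise a degenerate-geometry error.
- **Depth** *Z*: max z − min z over nodes; **volume** *V* = *A·Z*.
- **Coverage volume** CV = *L*/*V* × 1000: μm of process per (10 μm)³ of
  tissue. The ×1000 factor converts per-μm³ to per-1000 μm³, i.e. a cube of
  side 10 μm — the only reading consistent with that multiplier. CV scales
  as *s*⁻² under uniform spatial scaling by *s* (L × s over V × s³), which
  the tests verify to float tolerance.
- **Thickness normalization**: extensive quantities (counts and lengths) are
  scaled linearly by `20 μm / depth` so cells imaged through different
  section thicknesses are comparable; area and CV are left unchanged (CV is
  already volume-normalized). Linearity is the simplest defensible rule and
  is stated here explicitly because no standard exists.

## Automated tracing from stacks

Manual midline tracing is replaced by: binarize at a user threshold → 3-D
thinning (Lee's method) → graph on 26-connected skeleton voxels with
Euclidean μm edge weights (anisotropy respected) → per-component minimum
spanning tree. Removing the longest edge of every cycle (= MST) is correct
here because microglial backbones are trees; loops in the skeleton are
rasterization artifacts. Roots: the voxel with the maximal foreground
distance-transform value (the soma is the thickest structure), or the node
nearest a user-supplied soma seed.

Three clean-up steps matter in practice:

- **Spur pruning**: terminal skeleton segments shorter than 2 voxels are
  thinning artifacts and are removed before measurement (well below the
  0.5 μm branch filter applied downstream).
- **Soma contraction** (`soma_radius`): thinning a several-μm soma blob
  leaves a cluster of junction voxels that would read as spurious
  bifurcations; nodes within `soma_radius` of the root are contracted into
  it. Manual traces have a single soma point by construction, so this
  restores the intended topology. Default 0 (off); per-cell validation
  passes the known soma radius.
- **Chain smoothing**: voxel chains zig-zag on the anisotropic grid, which
  inflates path length by up to ~10% on oblique runs. Nodes with exactly one
  child are relaxed toward the midpoint of their neighbours
  (0.25·parent + 0.5·self + 0.25·child, 2 passes, junctions and tips fixed),
  after which recovered lengths are typically within 1–2% of truth.

The flood-fill (`fill_volume`) reproduces threshold-bounded volume
reconstruction: it saturates the supra-threshold voxels 26-connected to the
trace, and cannot leak into a spatially disjoint cell.

## Field-level spatial coverage

Maximum z-projection → threshold (Otsu by default; any fixed threshold can
be supplied, and the applied value is always returned/logged — a
reproducible stand-in for a manually chosen background cut) → 2-D thinning.

**Skeleton length** uses chain-code metrics: every unordered pair of
8-adjacent skeleton pixels contributes one step — the pixel size for axial
steps, √2× for diagonal steps — and each pixel is assigned half of each
incident step. This makes length *exactly* additive over any partition of
the image, so the 32×32 grid of 25 μm² squares conserves total length to
float precision (steps crossing a square boundary split half-half). Isolated
pixels count one pixel size. The grid window is the central 160 μm square;
squares with < 1 μm of process are "vacant".

**Modified Sholl profile**: for each radius r (40–140 μm, step 5 μm) the
intersections I(r) are the 8-connected components of skeleton pixels in the
set of pixels the circle passes through (centre distance within half a pixel
diagonal of r — guaranteeing every transversal crossing contains at least
one pixel). The normalized profile Î(r) = I(r)/(2πr) is reported per mm of
perimeter; an N-ray star yields exactly N at every radius and Î decaying as
1/r. When a circle leaves the field, the denominator uses the in-field arc
fraction only (configurable), so clipped circles are not biased low. On
fields of ideal segments the counts match an analytic segment–circle
intersection oracle to ±1 per circle; degenerate inputs (near-tangent
segments, segments closer than ~2 px) can merge or split counts, which is a
property of any pixel-based counter.

## MFI classification

Cells are segmented on the structural channel's max projection (threshold +
8-connected labeling + minimum area). Per-cell MFI is the mean of the second
channel's projection over the cell mask. Classification low/pos/high uses
quantile thresholds of a reference population's MFIs (defaults: 5th/95th
percentile) — a reproducible proxy for thresholds drawn on a reference
scatter plot; the thresholds used are always returned. The classifier is
invariant to any common affine intensity rescaling of test and reference.
Note that with q = 0.05/0.95 a test population identical to the reference
lands ~5% in each tail by construction; recovery of planted outlier
fractions is cleanest with more extreme quantiles (the validation uses
1%/99% for that purpose).

## Group statistics

Tidy tables (group, id, metric, value) feed Student's two-sample t-test
(equal-variance by default, Welch optional) for two groups and one-way ANOVA
with Tukey's HSD for three or more. Observations may be pooled per cell or
per animal — tables carry both ids. Benjamini–Hochberg correction is not
implemented (it applies only to analyses outside this package's scope).

## The synthetic-data model

Cells are discrete random trees designed around the three-order process
hierarchy of cortical microglia:

- `n_primary` (7–9, drawn per cell) primary processes leave the soma at
  evenly spread azimuths.
- A branch of order *o* is a chain of segments — 4–5 long segments for
  primaries, 2–4 and 2–3 shorter ones for orders 2 and 3 (length scales
  1 : 0.35 : 0.25) — with Gaussian angular jitter (`tortuosity`, rad) per
  step. Higher-order processes being *shorter* than the mains they branch
  from means a cell's territory (hull) is set by its primary reach, not by
  its branching depth; this is what lets aged cells lose most of their
  branches while keeping most of their tree area, as observed.
- At the end of a branch below `max_order` (3), the branch bifurcates into
  two daughters with probability `bifurcation_prob`.
- Every backbone node spawns up to two terminal fine processes of 1–4 μm
  with probability `fine_process_rate` each. The random draws for fine
  processes are consumed whether or not the process is attached, so a lower
  rate yields a strict sub-tree of the same seed's higher-rate tree — making
  coverage monotone in the rate, replicate by replicate.
- Growth along z is confined to a 20 μm slab centred on the soma (cells are
  flat; imaged sections are thin), and to the field box when one is given
  (reflection at the walls).

The model has a closed-form expected total length (used as an independent
test oracle): E[L] = Σ_o N_o · E[segs_o] · (scale_o · seg_mean + 2 ·
fine_rate · 2.5), with N_o = n_primary · (2·bifurcation_prob)^(o−1).

**Condition presets.** `young`: bifurcation 0.6, fine rate 0.7,
segments 6 ± 1 μm. `aged`: bifurcation 0.4, fine rate 0.08, segments
6.5 ± 1.2 μm — aging is modelled as a severe loss of fine processes and a
milder loss of branching, with surviving processes slightly longer, which
reproduces the reported phenomenology: total branch length roughly halves,
tree area falls only ~20%, coverage volume falls ~35–45%, and branch/
bifurcation counts collapse. Plaque fields place three concentric layers
(radii 40/70/140 μm, configurable): `plaque_L1` amoeboid stubs,
`plaque_L2` enlarged/low-complexity, `plaque_L3` ramified/reduced, with a
CD39-like channel-2 intensity drawn high for L1/L2 (≈950 ± 70 a.u.) and an
even normal/low mixture (≈617/380 a.u.) for L3 against a ≈617 ± 60 baseline.
Field density defaults to 6 cells per 100×100 μm², a realistic cortical
value; per-cell random streams derive from (master seed, cell index), so
adding cells never perturbs existing ones.

**Rendering.** Traces become tubes with per-node radii (soma ≈ 3 μm,
primaries 0.6 μm down to 0.25 μm fine tips), blurred by an isotropic
Gaussian PSF approximation (default σ = 0.15 μm, matching a high-NA lateral
FWHM of ~0.35 μm), with additive Gaussian noise (default SD = 5% of the tube
intensity) or Poisson noise. Somata render at twice the process intensity —
their thicker cytoplasm projects brighter — which is also what makes
threshold-based per-cell segmentation work on dense fields. Channel 2
carries each cell's planted MFI uniformly over its tube. A voxel→cell-id
truth map is emitted alongside (first-come on overlaps).

**Problem sizes.** The validation suite uses 10–20 cells per rendered
round-trip batch, 170–300 μm fields, 200-replicate Monte-Carlo checks, and
500–1000 permutations for statistical calibration — sizes chosen so the full
study re-runs from scratch in a few minutes on one CPU while keeping
Monte-Carlo standard errors well inside the asserted tolerances.

## What the synthetic validation does and does not show

It shows the *measurement* code is correct: counts are exact, lengths and
hulls match independent oracles, conservation laws hold, classifications
recover planted mixtures, and the whole pipeline preserves
planted group contrasts through rendering, projection and skeletonization.

It does not certify performance on real images. The generator omits uneven
staining, out-of-focus haze, anisotropic PSF tails, cell-body
autofluorescence, vessels and tissue deformation; its fine processes are
thinner than one voxel and are only partially recovered after rendering
(by design — the same is true of real fine processes at this resolution, so
backbone-only cells are used when topology must be recovered exactly).
Absolute field-level numbers (grid means, vacant percentages) depend
strongly on the synthetic density and arbor size and sit below densely
covered real cortex; only their ordering and contrasts across conditions are
meaningful. Thresholds on real data remain a user decision; Otsu is a
default, not a claim.

## Known limitations

- Tracing assumes tree topology; genuinely touching cells merge into one
  component (no watershed separation of contacting arbors).
- Tree area is convex — concave territories are overestimated.
- Sholl is 2-D and field-level, as in the underlying protocol; no per-cell
  3-D Sholl.
- MFI uses the 2-D max projection over the cell mask (a 3-D mean over the
  filled mask is available but not the default).
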