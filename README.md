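# micromorph

Quantitative morphometry and spatial-coverage analysis of microglia from 3-D
fluorescence z-stacks and SWC traces — with a fully ground-truthed synthetic
field generator so every stage of the pipeline can be validated end to end.

Microglia survey the brain parenchyma with ramified processes. Aging and
amyloid pathology erode this arbor: cells lose fine processes and branch
points, and the tissue volume each cell covers shrinks — leaving parts of the
parenchyma unmonitored. `micromorph` implements the measurements used to
quantify that decline, for researchers analysing confocal stacks of
GFP- or IbaI-labelled microglia:

**Per-cell morphometrics** (from an SWC trace of one cell):

- number of bifurcations (non-soma nodes where a process splits; a node with
  *k* daughters counts *k* − 1),
- number of branches — maximal paths between topological nodes; only branches
  longer than 0.5 μm are counted,
- total branch length *L* = Σ Euclidean edge lengths (μm),
- tree area *A* — area of the convex polygon through the outermost points of
  the z-projected arbor (μm²),
- cell depth *Z* (z-extent, μm), volume *V* = *A·Z*,
- **coverage volume** CV = *L* / *V* × 1000 — μm of process per (10 μm)³ of
  tissue, the headline measure of surveillance capacity,
- optional normalization of the extensive parameters to a common 20 μm
  section thickness.

**Field-level spatial coverage** (from a projected, thresholded,
skeletonized field):

- **grid analysis** — a 32×32 grid of 25 μm² squares over the central window;
  process length per square ℓᵢⱼ, its mean and 1 μm-binned histogram, and the
  *vacant-area* percentage (squares with ℓᵢⱼ < 1 μm),
- **modified Sholl analysis** — process crossings of concentric circles
  (radii 40–140 μm, step 5 μm) around a plaque centre or an arbitrary cell,
  normalized to crossings per mm of circle perimeter, Î(r) = I(r)/(2πr),
- density heat maps for visualization.

**Per-cell intensity profiles** — segment IbaI⁺ cells, measure the mean
fluorescence intensity (MFI) of a second channel (e.g. CD39) per cell, and
classify cells low/positive/high against quantile thresholds derived from a
reference (young wild-type) population.

**Group statistics** — mean ± SEM tables, two-group Student/Welch t-tests and
one-way ANOVA with Tukey's HSD, matching standard practice in the field.

**Synthetic data** — a generative random-tree model of microglial fields
(young, aged, and plaque-centred three-layer phenotypes, plus a CD39-like
second channel), rasterized into realistic noisy multi-channel z-stacks with
voxel-level ground truth. See `docs/methods.md` for the model.

## Worked example

```python
import numpy as np
from micromorph import synthetic, tracing, morphometrics, spatial

# grow one cell (backbone only — fine processes are sub-voxel and are not
# fully recoverable from a raster; see docs/methods.md), render, re-trace
rng = np.random.default_rng(0)
params = synthetic.GenParams(n_primary=5, bifurcation_prob=0.6,
                             segment_length_mean=9.0, segment_length_sd=1.0,
                             max_order=2, fine_process_rate=0.0,
                             tortuosity=0.1)
truth = synthetic.generate_cell_trace(params, rng=rng)
scene = synthetic.single_cell_scene(truth)
render = synthetic.render_stack(scene, psf_sigma=0.0,
                                noise_model={"gaussian_sd": 0})
traced = tracing.trace_from_stack(render.channels["ch1"], 100.0,
                                  soma_radius=3.5)[0]

for label, t in (("truth", scene.traces[0]), ("traced", traced)):
    rec = morphometrics.measure_trace(t)
    print(f"{label}: L={rec.total_branch_length:.1f} um, "
          f"bifurcations={rec.n_bifurcations}, CV={rec.coverage_volume:.2f}")
```

prints:

```
truth: L=246.9 um, bifurcations=3, CV=7.15
traced: L=246.6 um, bifurcations=3, CV=7.27
```

i.e. the automated tracer recovers the planted total branch length to ~0.1%
and the branch-point count exactly, and the coverage volume — here ≈ 7 μm of
process per (10 μm)³ tissue cube — agrees to ~2%.

A field-level run from the shell:

```sh
micromorph synth --condition young --n-cells 10 --seed 3 --out demo --render
micromorph grid demo/ch1.tif --pixel-size 0.25
# mean length per square: 4.058 μm; vacant squares (<1 μm): 55.86%
micromorph sholl demo/ch1.tif --pixel-size 0.25 --center 80,80
```

## Layout

- `src/micromorph/synthetic.py` — generative cell/field model and renderer
- `src/micromorph/tracing.py` — SWC data model and I/O, automated 3-D tracing
- `src/micromorph/morphometrics.py` — per-cell parameters
- `src/micromorph/spatial.py` — projection, skeleton, grid, Sholl, heat map
- `src/micromorph/intensity.py` — segmentation, per-cell MFI, classification
- `src/micromorph/stats.py` — group comparison layer
- `src/micromorph/cli.py` — `micromorph` command-line interface
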