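# Methods

This note records the models, conventions and numerical choices behind
`iimdepth`, and what its synthetic tests do and do not demonstrate.

## Imaging model and coordinate conventions

The integral-imaging microscope is modeled only through its projection
geometry. An object point (x, y, z) seen through elemental lens (i, j) of
pitch φ lands on the EIA plane at

    X_EI(i,j) = [f_MLA·f_C·(iφ − x) − f_C·iφ·(z − f_MLA)] / [(g − f_MLA)(z − f_MLA)]

(symmetrically for Y), with f_MLA and f_C the microlens-array and camera-lens
focal lengths and g the MLA-to-camera distance; the inter-lens disparity of a
point at depth z is ΔX = f_MLA·f_C·φ·(i₂−i₁) / [(g−f_MLA)(z−f_MLA)]. These
formulas are taken as printed definitions, not re-derived; configurations
with z = f_MLA or g = f_MLA are rejected as singular. Lens indices are
centered on the optical axis and may be negative. All lengths share one unit
(defaults quoted in mm). The objective and tube-lens focal lengths (f_o, f_t)
are carried in `IIMOpticalParams` for completeness but do not enter the
equations.

Conventions fixed once and used everywhere:

- View-grid origin (0, 0) at top-left; the central view of an n×n grid is
  (n//2, n//2). Pixel coordinates are 0-based, row-major.
- Disparity sign: positive d moves scene content in +x as the view column
  increases (and +y with the view row). Units: px per unit view offset.
- Pixel mapping: intra-EI pixel (a, b) in raster order feeds view (a, b).
- Centered ROI crop with an odd margin keeps the extra view at bottom/right
  (start index `(n − roi)//2`).
- Star arms are the exact center row, center column, main diagonal and
  anti-diagonal of a square, odd-sided grid; each arm is read in increasing
  index order so the central view is the middle element of all four stacks.

## Synthetic data generator

The generator emulates HCI-style benchmark scenes: a grid of angular views
(9×9 by default) whose views are sub-pixel-shifted renderings of textured
depth planes, with disparities chosen in the ±1.5 px working range. Textures
are periodic by construction (band-limited Gaussian noise low-passed in the
Fourier domain at 0.25×Nyquist by default; checkerboard and sinusoid
alternatives), and view (r, c) is the base texture translated by
(d·(r−r₀), d·(c−c₀)) via the FFT phase ramp — exact for integer shifts on any
texture and for any shift on band-limited textures. A margin of
ceil(max |shift|) is rendered and cropped away so wrap-around content never
enters the kept frame. The interpolator choice is recorded in scene metadata
so slope oracles in the tests use the same convention. Generators are pure
functions of (spec, seed).

Multi-plane scenes composite layers whose masks partition the frame
(near-to-far): the farthest layer backfills the whole frame so parallax-opened
gaps are never empty, nearer layers are painted with their mask translated by
the layer's own (rounded) shift, and the ground truth holds each layer's
disparity inside its central-view mask. Optional per-view additive Gaussian
noise is the only sensor model.

What this does **not** emulate: real microscope point-spread functions, lens
aberrations and vignetting beyond a radial gain (handled by the affine
brightness calibration), refractive specimen structure, non-Lambertian
surfaces, and sub-pixel occlusion boundaries. Passing tests therefore show
that the algorithmic chain is self-consistent and recovers known geometry
from idealized captures — not that the trained network transfers to any
particular instrument.

## EPI extraction

Cuboids stack the 9 selected views of one star arm over a spatial patch into
(9, h, w, 3); diagonal "orientations" are carried by which views were
selected — no pixel resampling is performed along the diagonals. Scenes are
tiled with 32×32 patches at stride 13. Since 37·13 + 32 = 513, the final
position on a 512-px axis overruns by one pixel; the source is reflect-padded
by the overrun so exactly ceil((side−patch)/stride)+1 positions exist per
axis (38 for a 512-px side, 1444 records per scene) and no border content is
discarded. Zero-mean normalization subtracts the per-cuboid mean at inference
(idempotent); during training the same per-cuboid rule is applied per batch
element. The `.epib` binary container (documented in `epi.py`: magic,
version, counts, then little-endian float32 records in orientation order 0°,
90°, 45°, 135° followed by the ground-truth patch) is this package's own
format, round-trip bit-exact.

## Network

Architecture as in the README. Choices the architecture description leaves
open, fixed here:

- **Stream fusion.** The two single-channel stream outputs are concatenated
  and passed through a 1×1 convolution (2→1, no activation) initialized to
  weights (0.5, 0.5), bias 0 — differentiable, and exactly the mean at
  initialization.
- **View-axis bookkeeping.** Four VALID 3×3×3 convolutions contract the view
  axis 9→7→5→3→1; a construction-time check rejects configurations whose view
  count does not end at exactly 1, and requires the spatial pre-padding (4 px
  per side) to equal the total spatial shrink. The first 2D layer of each
  stream sees 2×128 = 256 input channels.
- **Optimizer and initialization.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8)
  with the staircase schedule lr·0.9^⌊epoch/100⌋; He-normal weight
  initialization (std √(2/fan_in)), zero biases. Seeds fix initialization and
  batch order; bitwise reproducibility is promised only within this
  implementation, statistical reproducibility across BLAS builds.
- **Loss.** Mean absolute error over ground-truth patches; the subgradient at
  zero error is taken as 0. Loss accounting is done in float64 so the
  training log and the metrics module agree to 1e−9; network arithmetic is
  float32.
- **Implementation.** Convolutions run as strided window views contracted
  with `tensordot`; backward passes are the transpose contractions (27 resp.
  9 shifted accumulations for the input gradient). Gradients are verified
  against central finite differences in the test suite.
- **Seam radius.** On overlapping crops, outputs agree exactly only beyond
  the SAME-padded 2D tail's influence radius — 7 px (seven 3×3 layers), not
  the 4 px of the 3D stage's padding. Whole-frame inference in one pass (the
  default) has no seams.

## Weighted median refinement

The filter implements the direct definition: output(p) is the smallest window
value whose cumulative guide-affinity weight reaches half the window total,
with Gaussian color affinity exp(−‖g(p)−g(q)‖²/2σ²) on the central RGB view
and reflect-padded borders. A constant guide reduces it exactly to the plain
median; every output value exists in its input window; a depth step aligned
with a guide edge survives exactly when σ is far below the guide contrast.
The brute-force per-pixel enumeration is the reference semantics, and the
vectorized implementation is required to match it bit-for-bit. Defaults
radius = 7, σ = 25.5/255 = 0.1 (guides in [0, 1]) are package choices,
config-exposed; the refinement study uses radius 3 on its 48-px scenes so the
window stays small relative to the frame.

## Metrics

RMSE = √(mean y²) on the error map, MAE = mean |y|; RMSE ≥ MAE always
(Jensen), asserted under randomized inputs. Discrete entropy requires
integer-valued input (explicit quantization is the caller's job), treats
0·log 0 as 0, and is bounded by the bit depth. The PSD score is the mean over
all frequency bins of log₁₀|DFT₂(x)|², DC bin included, with ε = 1e−12 inside
the log to guard empty bins; multichannel input collapses to Rec. 601
luminance first. The score is invariant to circular shifts and transposition
and shifts by exactly 2·log₁₀c under scaling by c.

## Scaled-down study sizes

The parameter-recovery study trains a channel-quartered network (3D channels
8, 16, 16, 32; 2D tail 32, 16, 8, 8, 4, 2, 1) on five constant-disparity
planes d ∈ {−1, −0.5, 0, 0.5, 1} rendered at 48×48 px with 9×9 views,
tiled into 8×8 patches at stride 8 (36 per scene, 180 records), for 40 epochs
at lr 2·10⁻³ decayed ×0.9 every 10 epochs, batch 32 — problem sizes chosen so
the whole study is a couple of minutes on one CPU core. Held-out patches come
from fresh-seed textures of the same planes, so recovery must read EPI slope,
not memorized pixels. The full-size configuration (32/64/64/128 channels,
32×32 patches, 2000 epochs at lr 4·10⁻⁴) remains the package default.

## Known limitations

- The network is trained per study; no pretrained weights ship with the
  package.
- Diagonal EPIs are view-selected, not resampled; on non-square pixels this
  conflates the two diagonal baselines.
- The brightness calibration is a per-view affine match to the central view,
  not a full camera calibration.
- `discrete_entropy` and `psd_score` are no-reference proxies; they rank
  contrast/sharpness, they do not validate geometry.
- The multiplane compositor rounds layer-mask shifts to whole pixels, so
  sub-pixel occlusion boundaries are approximate.
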