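# iimdepth

Depth estimation for **integral-imaging microscopy** (IIM, also called
light-field microscopy). An IIM places a microlens array between the
microscope's intermediate image plane and the camera, so one exposure captures
a grid of elemental images (EIA) holding both spatial and angular information
about the specimen. From that single capture, `iimdepth` recovers a per-pixel
**disparity map** — the apparent shift of scene content between adjacent
directional views, proportional to inverse depth — which is the key input for
3D reconstruction of microscopic specimens (watch gears, microchip components,
seedpods, …).

It is aimed at microscopists and image-analysis researchers who have either a
raw elemental-image array plus lens-grid metadata, or an HCI-style grid of
angular view images, and want a dense depth map and a colored point cloud out
the other end.

## Method

The pipeline runs the following stages:

1. **Pixel mapping (EIA → OVI).** Intra-lens pixel (a, b) taken from every
   elemental image forms orthographic (directional) view (a, b): an EIA of
   76×76 lenses with 53×53 px each becomes a 53×53 grid of 76×76-px views.
   The mapping is a pure pixel permutation and inverts exactly.
2. **ROI + brightness calibration.** Views dim toward the grid border, so only
   the centered 39×39-view region of interest is kept (stitching to
   2964×2964 px) and each view's mean/std is matched to the central view.
3. **Star selection.** Nine views at four-view intervals along each of the
   four arms through the grid center — the center row (0°), center column
   (90°), main diagonal (45°) and anti-diagonal (135°).
4. **EPI cuboids.** Each arm's 9 views over a spatial patch are stacked into
   an epipolar-plane-image cuboid of shape 9×h×w×3. In an EPI, a point at
   disparity d traces a line of slope d px/view. Scenes are tiled into 32×32
   patches at stride 13 (a 512-px side yields 38×38 = 1444 records).
5. **Disparity network.** Four branches — one per orientation — each apply
   four 3D convolutions (3×3×3, VALID, ReLU; 32, 64, 64, 128 channels),
   contracting the view axis 9→7→5→3→1. The 0°/90° and 45°/135° branches are
   concatenated pairwise into two streams of seven 2D convolutions (3×3, SAME;
   128, 64, 32, 32, 16, 8, 1 channels, ReLU except the last), and the two
   single-channel maps are fused by a 1×1 convolution initialized to
   averaging. With 4-px spatial pre-padding the network is fully
   convolutional: output shape equals view shape for any H×W. Training
   minimizes the mean absolute error `L = (1/N) Σ |yᵢ − ŷᵢ|` with Adam at
   lr 4·10⁻⁴, decayed ×0.9 every 100 epochs, batch size 32. The convolutions
   and backpropagation are implemented directly in numpy.
6. **Weighted median refinement.** Each pixel of the raw map is replaced by
   the weighted median of its window, with neighbor weights
   `exp(−‖g(p)−g(q)‖²/2σ²)` from the central RGB view g — suppressing interior
   noise while depth edges that coincide with image edges survive exactly.
7. **Metrics & export.** RMSE/MAE against ground truth; no-reference quality
   via discrete entropy (bits) and the mean log-power spectrum; flat colored
   point-cloud export to ASCII PLY.

A synthetic light-field generator (textured planes at known constant or
piecewise-constant disparity in the ±1.5 px working range, sub-pixel-shifted
by FFT phase ramps) provides exact ground truth for every stage's tests.

## Worked example

```
$ iimdepth simulate -d 0.5 --views 9 --size 64 --seed 3 -o demo/scene
wrote scene 'plane' to demo/scene
$ iimdepth extract demo/scene --patch 32 --stride 13 -o demo/scene.epib
wrote 16 cuboid records to demo/scene.epib
$ iimdepth quality --image demo/scene/views/view_04_04.png
{"de": 6.621596603260203, "psd": -0.8029185659005084}
```

The first command renders a 9×9-view light field of a textured plane at a
constant disparity of 0.5 px/view with its ground-truth PFM map; the second
tiles its four orientation EPI cuboids into 4×4 = 16 records of 9×32×32×3
(64-px side, stride 13); the third reports the central view's discrete entropy
(6.62 bits of an 8-bit maximum — a well-contrasted texture) and mean
log-power.

End-to-end parameter recovery, in Python:

```python
import iimdepth as iim
study = iim.parameter_recovery_study(seed=0)
print(study["median_abs_error"])        # 0.0983  (px, held-out patches)
print(study["two_plane_rmse_raw"])      # 0.374   (px)
print(study["two_plane_rmse_refined"])  # 0.357   (px, WMF never hurts here)
```

This trains a channel-quartered network for 40 epochs on five
constant-disparity planes (d ∈ {−1, −0.5, 0, 0.5, 1}) and evaluates on
fresh-texture renderings of the same planes: the median absolute disparity
error is ≈0.1 px, and weighted-median refinement lowers the RMSE on a
two-plane occlusion scene.

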