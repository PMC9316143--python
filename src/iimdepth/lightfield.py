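"""Light-field containers, view/PFM I/O, and the synthetic scene generator.

A light field is stored as a dense rank-5 array of angular views indexed
``(v_row, v_col, y, x, channel)`` with values in [0, 1] — the layout of the
HCI-style benchmarks (typically a 9 × 9 angular grid of 512 × 512 RGB views).
Disparity maps are per-pixel apparent shifts between adjacent views, in units
of pixels per unit view offset; positive disparity means scene content moves
in +x as the view column index increases (and in +y as the view row index
increases).

The synthetic generator renders textured depth planes: view (r, c) is the base
texture translated by ``(d·(r−r0), d·(c−c0))`` about the central view
(r0, c0) = (n_rows//2, n_cols//2). Textures are periodic and shifts are applied
with the FFT phase ramp, which is exact for integer shifts and for bandlimited
textures at any sub-pixel shift; a margin of ceil(max |shift|) is rendered and
cropped away so wrap-around never enters the kept frame. This gives every
downstream module (EPI extraction, the disparity network, the weighted median
filter) scenes with exactly known ground truth.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio

__all__ = [
    "LightField",
    "DisparityMap",
    "SceneBundle",
    "read_lightfield",
    "write_lightfield",
    "read_pfm",
    "write_pfm",
    "make_plane_lightfield",
    "make_multiplane_lightfield",
    "make_texture",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class LightField:
    """Dense grid of angular views, ``views[(v_row, v_col, y, x, channel)]``."""

    views: np.ndarray

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, dtype=np.float32)
        if self.views.ndim != 5:
            raise ValueError(
                f"views must be rank-5 (v_row, v_col, y, x, channel); got rank {self.views.ndim}"
            )
        if not np.all(np.isfinite(self.views)):
            raise ValueError("light-field pixel values must be finite")
        lo, hi = float(self.views.min(initial=0.0)), float(self.views.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"pixel values must lie in [0, 1]; got range [{lo}, {hi}]")

    @property
    def n_rows(self) -> int:
        return self.views.shape[0]

    @property
    def n_cols(self) -> int:
        return self.views.shape[1]

    @property
    def height(self) -> int:
        return self.views.shape[2]

    @property
    def width(self) -> int:
        return self.views.shape[3]

    @property
    def channels(self) -> int:
        return self.views.shape[4]

    @property
    def center_index(self) -> tuple[int, int]:
        return self.n_rows // 2, self.n_cols // 2

    @property
    def center_view(self) -> np.ndarray:
        r0, c0 = self.center_index
        return self.views[r0, c0]


@dataclass
class DisparityMap:
    """Per-pixel disparity in pixels of shift per unit view offset."""

    values: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError(f"disparity map must be rank-2; got rank {self.values.ndim}")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask shape must match values shape")
            if not np.all(np.isfinite(self.values[self.valid_mask])):
                raise ValueError("disparity values must be finite where valid")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError("disparity values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SceneBundle:
    """A light field plus optional ground-truth disparity and provenance metadata."""

    lightfield: LightField
    gt_disparity: DisparityMap | None = None
    name: str = "scene"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gt_disparity is not None:
            lf = self.lightfield
            if self.gt_disparity.shape != (lf.height, lf.width):
                raise ValueError(
                    f"gt_disparity shape {self.gt_disparity.shape} does not match "
                    f"view shape {(lf.height, lf.width)}"
                )


# ---------------------------------------------------------------------------
# view-directory I/O

_VIEW_NAME = "view_{row:02d}_{col:02d}.png"
_VIEW_RE = re.compile(r"view_(\d+)_(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def _to_unit(img: np.ndarray) -> np.ndarray:
    """Scale an integer image to [0, 1] float32 by its dtype's full range."""
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return img.astype(np.float32) / float(info.max)
    return img.astype(np.float32)


def read_lightfield(path: str | Path, n_rows: int | None = None, n_cols: int | None = None) -> LightField:
    """Read a directory of view images named ``view_<row>_<col>.<png|tif>``.

    8-/16-bit images are scaled to [0, 1]. Raises if a grid position is missing
    or if view shapes disagree.
    """
    path = Path(path)
    found: dict[tuple[int, int], Path] = {}
    for f in sorted(path.iterdir()):
        m = _VIEW_RE.match(f.name)
        if m:
            found[(int(m.group(1)), int(m.group(2)))] = f
    if not found:
        raise FileNotFoundError(f"no view images matching view_<row>_<col> in {path}")
    if n_rows is None:
        n_rows = max(k[0] for k in found) + 1
    if n_cols is None:
        n_cols = max(k[1] for k in found) + 1

    views = None
    ref_shape = None
    for r in range(n_rows):
        for c in range(n_cols):
            if (r, c) not in found:
                raise FileNotFoundError(f"missing view image for grid position (row={r}, col={c})")
            img = _to_unit(iio.imread(found[(r, c)]))
            if img.ndim == 2:
                img = img[:, :, None]
            if ref_shape is None:
                ref_shape = img.shape
                views = np.empty((n_rows, n_cols) + ref_shape, dtype=np.float32)
            elif img.shape != ref_shape:
                raise ValueError(
                    f"view {found[(r, c)].name} has shape {img.shape}, expected {ref_shape}"
                )
            views[r, c] = img
    return LightField(views)


def write_lightfield(lf: LightField, path: str | Path) -> None:
    """Write each view as an 8-bit PNG named ``view_<row>_<col>.png``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for r in range(lf.n_rows):
        for c in range(lf.n_cols):
            img = np.clip(np.rint(lf.views[r, c] * 255.0), 0, 255).astype(np.uint8)
            iio.imwrite(path / _VIEW_NAME.format(row=r, col=c), img)


# ---------------------------------------------------------------------------
# PFM disparity interchange
#
# PFM: header line "Pf" (grayscale), then "<width> <height>", then a scale
# whose sign encodes endianness (negative → little-endian); rows are stored
# bottom-to-top as raw float32.


def write_pfm(path: str | Path, dmap: DisparityMap | np.ndarray, scale: float = -1.0) -> None:
    values = dmap.values if isinstance(dmap, DisparityMap) else np.asarray(dmap, dtype=np.float32)
    if values.ndim != 2:
        raise ValueError("PFM writer expects a rank-2 grayscale map")
    if scale == 0:
        raise ValueError("PFM scale must be nonzero")
    data = values.astype("<f4" if scale < 0 else ">f4")
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{values.shape[1]} {values.shape[0]}\n".encode("ascii"))
        fh.write(f"{scale:.6f}\n".encode("ascii"))
        fh.write(data[::-1].tobytes())  # bottom-to-top row order


def read_pfm(path: str | Path) -> DisparityMap:
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header not in (b"Pf", b"PF"):
            raise ValueError(f"malformed PFM header line: {header!r}")
        if header == b"PF":
            raise ValueError("color PFM (PF) not supported; expected grayscale 'Pf'")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"malformed PFM dimension line: {dims!r}")
        width, height = int(dims[0]), int(dims[1])
        scale_line = fh.readline().strip()
        try:
            scale = float(scale_line)
        except ValueError as exc:
            raise ValueError(f"malformed PFM scale line: {scale_line!r}") from exc
        dtype = "<f4" if scale < 0 else ">f4"
        raw = fh.read(width * height * 4)
        if len(raw) != width * height * 4:
            raise ValueError("truncated PFM payload")
        values = np.frombuffer(raw, dtype=dtype).reshape(height, width)[::-1]
    return DisparityMap(np.ascontiguousarray(values, dtype=np.float32))


# ---------------------------------------------------------------------------
# textures


def make_texture(spec: str | dict, height: int, width: int, seed: int = 0) -> np.ndarray:
    """Render a periodic RGB texture in [0, 1].

    ``spec`` is a name or a dict with a ``kind`` key and parameters:

    - ``bandlimited-noise``: Gaussian white noise low-pass filtered in the
      Fourier domain (``cutoff`` as a fraction of Nyquist, default 0.25);
      periodic by construction, so FFT shifts are exact at any sub-pixel offset.
    - ``checker``: square checkerboard (``period`` px per full cycle, default 8;
      must divide the frame for exact periodicity).
    - ``sinusoid``: sum of an x- and a y-cosine at integer frequencies
      (``fx``, ``fy``, default 3 and 5 cycles per frame).
    """
    if isinstance(spec, str):
        spec = {"kind": spec}
    kind = spec["kind"]
    rng = np.random.default_rng(seed)
    if kind == "bandlimited-noise":
        cutoff = float(spec.get("cutoff", 0.25))
        chans = []
        fy = np.fft.fftfreq(height)[:, None]
        fx = np.fft.fftfreq(width)[None, :]
        keep = (np.abs(fy) <= cutoff * 0.5) & (np.abs(fx) <= cutoff * 0.5)
        for _ in range(3):
            white = rng.standard_normal((height, width))
            f = np.fft.fft2(white) * keep
            img = np.fft.ifft2(f).real
            img = (img - img.min()) / (np.ptp(img) + 1e-12)
            chans.append(img)
        return np.stack(chans, axis=-1).astype(np.float32)
    if kind == "checker":
        period = int(spec.get("period", 8))
        yy, xx = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
        board = (((yy // (period // 2)) + (xx // (period // 2))) % 2).astype(np.float32)
        return np.repeat(board[:, :, None], 3, axis=2)
    if kind == "sinusoid":
        fx_c = int(spec.get("fx", 3))
        fy_c = int(spec.get("fy", 5))
        yy, xx = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
        img = 0.5 + 0.25 * np.cos(2 * np.pi * fx_c * xx / width) + 0.25 * np.cos(
            2 * np.pi * fy_c * yy / height
        )
        return np.repeat(img[:, :, None].astype(np.float32), 3, axis=2)
    raise ValueError(f"unknown texture kind: {kind!r}")


def _fft_shift_image(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Translate a periodic image by (dy, dx) pixels via the FFT phase ramp."""
    h, w = img.shape[:2]
    ky = np.fft.fftfreq(h)[:, None]
    kx = np.fft.fftfreq(w)[None, :]
    phase = np.exp(-2j * np.pi * (ky * dy + kx * dx))
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[:, :, ch] = np.fft.ifft2(np.fft.fft2(img[:, :, ch]) * phase).real
    return out


# ---------------------------------------------------------------------------
# synthetic scene generators


def make_plane_lightfield(
    texture_spec: str | dict = "bandlimited-noise",
    disparity_d: float = 0.5,
    n_rows: int = 9,
    n_cols: int = 9,
    height: int = 64,
    width: int = 64,
    seed: int = 0,
    noise_sigma: float = 0.0,
    name: str = "plane",
) -> SceneBundle:
    """Render a single fronto-parallel textured plane at constant disparity.

    View (r, c) is the base texture translated by ``(d·(r−r0), d·(c−c0))``;
    the ground truth is the constant map ``d``. With ``d == 0`` every view
    equals the central view exactly. Optional additive Gaussian noise
    (``noise_sigma``, per-view independent) models sensor noise.
    """
    r0, c0 = n_rows // 2, n_cols // 2
    max_shift = max(abs(disparity_d) * max(r0, n_rows - 1 - r0),
                    abs(disparity_d) * max(c0, n_cols - 1 - c0))
    margin = int(math.ceil(max_shift))
    if 2 * margin >= min(height, width):
        raise ValueError(
            f"disparity {disparity_d} shifts views by up to {max_shift:.1f} px, "
            f"exceeding the {height}x{width} frame after the crop margin"
        )
    big_h, big_w = height + 2 * margin, width + 2 * margin
    base = make_texture(texture_spec, big_h, big_w, seed=seed)
    rng = np.random.default_rng(seed + 1)

    views = np.empty((n_rows, n_cols, height, width, 3), dtype=np.float32)
    for r in range(n_rows):
        for c in range(n_cols):
            dy = disparity_d * (r - r0)
            dx = disparity_d * (c - c0)
            if dy == 0.0 and dx == 0.0:
                shifted = base
            elif float(dy).is_integer() and float(dx).is_integer():
                shifted = np.roll(base, (int(dy), int(dx)), axis=(0, 1))
            else:
                shifted = _fft_shift_image(base, dy, dx)
            img = shifted[margin:margin + height, margin:margin + width]
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma, img.shape)
            views[r, c] = np.clip(img, 0.0, 1.0)

    gt = DisparityMap(np.full((height, width), disparity_d, dtype=np.float32))
    meta = {
        "generator": "plane",
        "texture": texture_spec if isinstance(texture_spec, dict) else {"kind": texture_spec},
        "disparity": disparity_d,
        "seed": seed,
        "interpolation": "fft-phase-ramp",
        "noise_sigma": noise_sigma,
    }
    return SceneBundle(LightField(views), gt, name=name, metadata=meta)


def _layer_mask(mask_spec: str | dict | np.ndarray, height: int, width: int) -> np.ndarray:
    if isinstance(mask_spec, np.ndarray):
        return mask_spec.astype(bool)
    if isinstance(mask_spec, str):
        mask_spec = {"kind": mask_spec}
    kind = mask_spec["kind"]
    yy, xx = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    if kind == "full":
        return np.ones((height, width), dtype=bool)
    if kind == "left-half":
        return xx < width // 2
    if kind == "right-half":
        return xx >= width // 2
    if kind == "top-half":
        return yy < height // 2
    if kind == "bottom-half":
        return yy >= height // 2
    if kind == "center-square":
        side = int(mask_spec.get("side", min(height, width) // 2))
        y0 = (height - side) // 2
        x0 = (width - side) // 2
        return (yy >= y0) & (yy < y0 + side) & (xx >= x0) & (xx < x0 + side)
    raise ValueError(f"unknown mask kind: {kind!r}")


def make_multiplane_lightfield(
    layers: list[tuple[float, str | dict | np.ndarray, str | dict]],
    n_rows: int = 9,
    n_cols: int = 9,
    height: int = 64,
    width: int = 64,
    seed: int = 0,
    name: str = "multiplane",
) -> SceneBundle:
    """Composite several textured planes at different disparities.

    ``layers`` is a near-to-far ordered list of ``(disparity, mask_spec,
    texture_spec)``. In each view every layer is shifted by its own disparity
    and the nearest layer claiming a pixel wins; the ground-truth map holds the
    front-most layer's disparity inside its (central-view) mask. Masks taken
    together must cover the frame; the far-most layer may simply use ``"full"``.
    """
    if not layers:
        raise ValueError("at least one layer required")
    masks: list[np.ndarray] = []
    claimed = np.zeros((height, width), dtype=bool)
    for _, mspec, _ in layers:
        if mspec == "rest":  # complement of all earlier layers
            m = ~claimed
        else:
            m = _layer_mask(mspec, height, width)
        if (m & claimed).any():
            raise ValueError("layer masks overlap; they must partition the frame")
        claimed |= m
        masks.append(m)
    if not claimed.all():
        raise ValueError("layer masks do not cover the frame")
    excl = masks

    r0, c0 = n_rows // 2, n_cols // 2
    views = np.zeros((n_rows, n_cols, height, width, 3), dtype=np.float32)
    gt = np.zeros((height, width), dtype=np.float32)
    # paint far-to-near so near layers overwrite
    for li in reversed(range(len(layers))):
        d, _mspec, tex = layers[li]
        plane = make_plane_lightfield(
            tex, d, n_rows, n_cols, height, width, seed=seed + 31 * li, name=f"layer{li}"
        )
        mask = excl[li]
        for r in range(n_rows):
            for c in range(n_cols):
                if li == len(layers) - 1:
                    # farthest layer backfills the whole frame so occlusion
                    # gaps opened by nearer layers' parallax are never empty
                    views[r, c] = plane.lightfield.views[r, c]
                else:
                    dy = d * (r - r0)
                    dx = d * (c - c0)
                    # layer mask moves with the layer content off-center
                    shifted_mask = _shift_mask(mask, dy, dx)
                    views[r, c][shifted_mask] = plane.lightfield.views[r, c][shifted_mask]
        gt[mask] = d
    meta = {
        "generator": "multiplane",
        "layers": len(layers),
        "seed": seed,
        "interpolation": "fft-phase-ramp",
    }
    return SceneBundle(LightField(np.clip(views, 0, 1)), DisparityMap(gt), name=name, metadata=meta)


def _shift_mask(mask: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Translate a boolean mask by rounded (dy, dx) with edge clamping."""
    iy, ix = int(round(dy)), int(round(dx))
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys = slice(max(iy, 0), min(h + iy, h))
    xs = slice(max(ix, 0), min(w + ix, w))
    ys_src = slice(max(-iy, 0), min(h - iy, h))
    xs_src = slice(max(-ix, 0), min(w - ix, w))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


# ---------------------------------------------------------------------------
# scene manifest


def write_scene(bundle: SceneBundle, path: str | Path) -> None:
    """Write views, optional PFM ground truth, and a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_lightfield(bundle.lightfield, path / "views")
    manifest = {
        "name": bundle.name,
        "views": "views",
        "n_rows": bundle.lightfield.n_rows,
        "n_cols": bundle.lightfield.n_cols,
        "metadata": bundle.metadata,
    }
    if bundle.gt_disparity is not None:
        write_pfm(path / "gt_disparity.pfm", bundle.gt_disparity)
        manifest["gt_disparity"] = "gt_disparity.pfm"
    (path / "scene.json").write_text(json.dumps(manifest, indent=2))


def read_scene(path: str | Path) -> SceneBundle:
    path = Path(path)
    manifest_path = path / "scene.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"scene manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    lf = read_lightfield(path / manifest["views"], manifest["n_rows"], manifest["n_cols"])
    gt = None
    if "gt_disparity" in manifest:
        gt = read_pfm(path / manifest["gt_disparity"])
    return SceneBundle(lf, gt, name=manifest.get("name", path.name),
                       metadata=manifest.get("metadata", {}))
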