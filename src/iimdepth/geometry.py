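"""Integral-imaging microscopy geometry: optics equations, pixel mapping,
ROI cropping, star-pattern view selection, and brightness calibration.

An integral-imaging microscope (IIM) places a microlens array (MLA) between
the microscope's intermediate image plane and the camera lens. Each microlens
forms a small elemental image (EI); the full sensor frame is the elemental
image array (EIA). Orthographic-view images (OVIs, also called directional
views) are assembled by pixel mapping: intra-EI pixel (a, b) taken from every
EI forms directional view (a, b). An EIA of L×L lenses with p×p pixels per
lens therefore yields p×p views of L×L pixels each — e.g. 76×76 EIs of
53×53 px map to 53×53 views of 76×76 px.

The projection model: an object point (x, y, z) seen through elemental lens
(i, j) of pitch φ lands on the EIA plane at

    X_EI(i,j) = [f_MLA f_C (iφ − x) − f_C iφ (z − f_MLA)]
                / [(g − f_MLA)(z − f_MLA)]

(and symmetrically for Y with j, y), where f_MLA and f_C are the MLA and
camera-lens focal lengths and g the MLA-to-camera-lens distance. The
inter-lens disparity of the same point between lenses (i1, j1) and (i2, j2) is

    ΔX = f_MLA f_C φ (i2 − i1) / [(g − f_MLA)(z − f_MLA)]

which is linear in the lens-index difference and antisymmetric under swapping
lenses. Lens indices are centered on the optical axis and may be negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .lightfield import LightField

__all__ = [
    "IIMOpticalParams",
    "ElementalImageArray",
    "ProjectedPoint",
    "project_point",
    "disparity_between_lenses",
    "eia_to_ovi",
    "ovi_to_eia",
    "crop_roi_views",
    "select_star_views",
    "calibrate_brightness",
    "StarStacks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IIMOpticalParams:
    """Optical parameters of the IIM capture system (consistent length units).

    f_o and f_t (objective and tube-lens focal lengths) characterize the
    microscope front end and do not enter the EIA projection equations; they
    are carried for completeness of the capture description.
    """

    f_mla: float
    f_c: float
    pitch_phi: float
    g: float
    f_o: float = 0.0
    f_t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_mla", "f_c", "pitch_phi", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.g == self.f_mla:
            raise ValueError("singular configuration: g == f_mla")


@dataclass
class ElementalImageArray:
    """Single mosaic sensor image plus its lens-grid metadata."""

    image: np.ndarray
    lenses_x: int
    lenses_y: int
    px_per_ei_x: int
    px_per_ei_y: int

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if np.issubdtype(self.image.dtype, np.integer):
            self.image = self.image.astype(np.float32) / float(np.iinfo(self.image.dtype).max)
        if self.image.ndim == 2:
            self.image = self.image[:, :, None]
        h, w = self.image.shape[:2]
        if w != self.lenses_x * self.px_per_ei_x or h != self.lenses_y * self.px_per_ei_y:
            raise ValueError(
                f"EIA image is {h}x{w} px but lens grid implies "
                f"{self.lenses_y * self.px_per_ei_y}x{self.lenses_x * self.px_per_ei_x}"
            )


@dataclass(frozen=True)
class ProjectedPoint:
    x_ei: float
    y_ei: float
    lens_i: int
    lens_j: int


def _check_nonsingular(z: float, params: IIMOpticalParams) -> None:
    if z == params.f_mla:
        raise ValueError("singular configuration: z == f_mla")


def project_point(
    p: tuple[float, float, float], lens: tuple[int, int], params: IIMOpticalParams
) -> ProjectedPoint:
    """Project object point ``p = (x, y, z)`` onto the EIA plane through lens ``(i, j)``."""
    x, y, z = p
    i, j = lens
    _check_nonsingular(z, params)
    denom = (params.g - params.f_mla) * (z - params.f_mla)
    x_ei = (params.f_mla * params.f_c * (i * params.pitch_phi - x)
            - params.f_c * i * params.pitch_phi * (z - params.f_mla)) / denom
    y_ei = (params.f_mla * params.f_c * (j * params.pitch_phi - y)
            - params.f_c * j * params.pitch_phi * (z - params.f_mla)) / denom
    return ProjectedPoint(x_ei, y_ei, i, j)


def disparity_between_lenses(
    lens_a: tuple[int, int], lens_b: tuple[int, int], z: float, params: IIMOpticalParams
) -> tuple[float, float]:
    """EIA-plane shift of a point at depth ``z`` between two elemental lenses."""
    _check_nonsingular(z, params)
    denom = (params.g - params.f_mla) * (z - params.f_mla)
    coef = params.f_mla * params.f_c * params.pitch_phi / denom
    return coef * (lens_b[0] - lens_a[0]), coef * (lens_b[1] - lens_a[1])


# ---------------------------------------------------------------------------
# pixel mapping EIA <-> OVI


def eia_to_ovi(eia: ElementalImageArray) -> LightField:
    """Reassemble the EIA into orthographic (directional) views by pixel mapping.

    View (a, b), pixel (r, c) is EIA pixel (r·p_y + a, c·p_x + b): the same
    intra-EI pixel from every elemental image, in raster order with the
    top-left intra-EI pixel giving the first view. The mapping is a pure
    permutation of sensor pixels.
    """
    py, px = eia.px_per_ei_y, eia.px_per_ei_x
    ly, lx = eia.lenses_y, eia.lenses_x
    img = eia.image
    # (ly, py, lx, px, ch) -> (py, px, ly, lx, ch)
    views = img.reshape(ly, py, lx, px, img.shape[2]).transpose(1, 3, 0, 2, 4)
    return LightField(np.ascontiguousarray(views))


def ovi_to_eia(lf: LightField) -> ElementalImageArray:
    """Exact inverse of :func:`eia_to_ovi`: views back to the mosaic sensor image."""
    py, px = lf.n_rows, lf.n_cols
    ly, lx = lf.height, lf.width
    img = lf.views.transpose(2, 0, 3, 1, 4).reshape(ly * py, lx * px, lf.channels)
    return ElementalImageArray(
        np.ascontiguousarray(img), lenses_x=lx, lenses_y=ly, px_per_ei_x=px, px_per_ei_y=py
    )


# ---------------------------------------------------------------------------
# ROI crop and star selection


def crop_roi_views(lf: LightField, roi_rows: int, roi_cols: int | None = None) -> LightField:
    """Keep the centered ``roi_rows × roi_cols`` sub-grid of views.

    Views themselves are untouched. When the leftover margin is odd the extra
    view goes to the bottom/right.
    """
    if roi_cols is None:
        roi_cols = roi_rows
    if roi_rows > lf.n_rows or roi_cols > lf.n_cols:
        raise ValueError(
            f"ROI {roi_rows}x{roi_cols} exceeds the {lf.n_rows}x{lf.n_cols} view grid"
        )
    r0 = (lf.n_rows - roi_rows) // 2
    c0 = (lf.n_cols - roi_cols) // 2
    return LightField(lf.views[r0:r0 + roi_rows, c0:c0 + roi_cols].copy())


@dataclass
class StarStacks:
    """Four ordered 1-D stacks of views along the star arms through the center.

    Orientations: 0° (center row, left→right), 90° (center column, top→bottom),
    45° (main diagonal, top-left→bottom-right), 135° (anti-diagonal,
    bottom-left→top-right). The central view is the middle element of each.
    """

    horizontal: np.ndarray   # (n, h, w, ch)
    vertical: np.ndarray
    diagonal: np.ndarray     # 45°
    antidiagonal: np.ndarray  # 135°
    center_view: np.ndarray
    indices: list[int]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "0": self.horizontal,
            "90": self.vertical,
            "45": self.diagonal,
            "135": self.antidiagonal,
        }


def select_star_views(lf: LightField, n_views: int = 9, interval: int = 4) -> StarStacks:
    """Sample ``n_views`` views at ``interval`` spacing along each star arm.

    The grid must be square and odd-sided so the diagonals and center are
    exact. With a 39×39 grid, 9 views at interval 4 selects indices
    3, 7, 11, 15, 19, 23, 27, 31, 35 along each arm (centered on view 19).
    """
    if lf.n_rows != lf.n_cols:
        raise ValueError("star selection requires a square view grid")
    side = lf.n_rows
    if side % 2 == 0:
        raise ValueError("star selection requires an odd-sided view grid")
    if n_views % 2 == 0:
        raise ValueError("n_views must be odd so the central view is the middle element")
    span = 1 + (n_views - 1) * interval
    if span > side:
        raise ValueError(
            f"star span {span} exceeds grid side {side}; need side >= {span}"
        )
    center = side // 2
    half = n_views // 2
    idx = [center + (k - half) * interval for k in range(n_views)]

    horizontal = np.stack([lf.views[center, c] for c in idx])
    vertical = np.stack([lf.views[r, center] for r in idx])
    diagonal = np.stack([lf.views[r, r] for r in idx])
    antidiag = np.stack([lf.views[side - 1 - r, r] for r in idx])
    return StarStacks(horizontal, vertical, diagonal, antidiag,
                      center_view=lf.views[center, center].copy(), indices=idx)


# ---------------------------------------------------------------------------
# brightness calibration
#
# OVIs grow dimmer away from the grid center because of the microscope
# illumination and MLA vignetting; a per-view affine gain to the central
# reference view's statistics flattens this before depth estimation.


def calibrate_brightness(
    stacks: StarStacks | np.ndarray, reference: np.ndarray | None = None
) -> StarStacks | np.ndarray:
    """Match each view's mean/std to the central reference view.

    Each view v is mapped to ``(v − mean(v))·(std_ref/std_v) + mean_ref`` and
    clipped to [0, 1]; a zero-variance view gets an offset-only correction.
    """
    if isinstance(stacks, StarStacks):
        ref = stacks.center_view if reference is None else reference
        return StarStacks(
            _calibrate_stack(stacks.horizontal, ref),
            _calibrate_stack(stacks.vertical, ref),
            _calibrate_stack(stacks.diagonal, ref),
            _calibrate_stack(stacks.antidiagonal, ref),
            center_view=stacks.center_view,
            indices=stacks.indices,
        )
    if reference is None:
        raise ValueError("reference view required for a bare stack")
    return _calibrate_stack(stacks, reference)


def _calibrate_stack(stack: np.ndarray, ref: np.ndarray) -> np.ndarray:
    ref_mean = float(ref.mean())
    ref_std = float(ref.std())
    out = np.empty_like(stack)
    for k in range(stack.shape[0]):
        v = stack[k]
        std = float(v.std())
        if std < 1e-6:  # float32 std of a constant view is ~1e-8, not exactly 0
            logger.warning("zero-variance view %d: offset-only brightness correction", k)
            out[k] = np.clip(v - v.mean() + ref_mean, 0.0, 1.0)
        else:
            out[k] = np.clip((v - v.mean()) * (ref_std / std) + ref_mean, 0.0, 1.0)
    return out
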