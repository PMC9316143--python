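"""Weighted median filtering of the disparity map, guided by the central RGB view.

The raw network output carries isolated noise, especially along depth edges.
The weighted median filter replaces each pixel with the weighted median of the
disparity values in its (2r+1)² window, where neighbor q's weight at center p
is the Gaussian color affinity of the guidance image,

    w(p, q) = exp(−‖guide(p) − guide(q)‖² / (2·σ_color²)).

Neighbors on the same side of a guide edge dominate the median, so noise is
suppressed while depth discontinuities that coincide with image edges survive.
The weighted median is the smallest window value whose cumulative weight
reaches half the total — always a value present in the window, never an
invented one. With a constant guide all weights are equal and the filter
reduces to the plain median. Borders are handled by reflect padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .lightfield import DisparityMap

__all__ = ["WmfParams", "weighted_median_filter"]


@dataclass(frozen=True)
class WmfParams:
    """radius: window half-size (px); sigma_color: affinity bandwidth in guide units
    (guides live in [0, 1], so 25.5/255 = 0.1 is a tenth of full scale)."""

    radius: int = 7
    sigma_color: float = 25.5 / 255.0
    weight_kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.sigma_color <= 0:
            raise ValueError("sigma_color must be > 0")
        if self.weight_kernel != "gaussian":
            raise ValueError(f"unknown weight kernel {self.weight_kernel!r}")


def weighted_median_filter(
    depth: DisparityMap | np.ndarray,
    guide: np.ndarray,
    params: WmfParams = WmfParams(),
) -> DisparityMap:
    """Guided weighted median of ``depth`` with the central RGB view as guide."""
    values = depth.values if isinstance(depth, DisparityMap) else np.asarray(depth, dtype=np.float32)
    guide = np.asarray(guide, dtype=np.float64)
    if guide.ndim == 2:
        guide = guide[:, :, None]
    if guide.shape[:2] != values.shape:
        raise ValueError(
            f"guide spatial shape {guide.shape[:2]} does not match depth {values.shape}"
        )
    r = params.radius
    h, w = values.shape
    k = 2 * r + 1

    dpad = np.pad(values, r, mode="reflect")
    gpad = np.pad(guide, ((r, r), (r, r), (0, 0)), mode="reflect")
    dwin = sliding_window_view(dpad, (k, k)).reshape(h, w, k * k)
    gwin = sliding_window_view(gpad, (k, k), axis=(0, 1)).reshape(h, w, guide.shape[2], k * k)

    diff = gwin - guide[:, :, :, None]
    weights = np.exp(-np.sum(diff * diff, axis=2) / (2.0 * params.sigma_color ** 2))

    order = np.argsort(dwin, axis=-1, kind="stable")
    sorted_vals = np.take_along_axis(dwin, order, axis=-1)
    sorted_w = np.take_along_axis(weights, order, axis=-1)
    cum = np.cumsum(sorted_w, axis=-1)
    half = cum[..., -1:] / 2.0
    idx = np.argmax(cum >= half, axis=-1)
    out = np.take_along_axis(sorted_vals, idx[..., None], axis=-1)[..., 0]

    mask = depth.valid_mask if isinstance(depth, DisparityMap) else None
    return DisparityMap(out.astype(np.float32), mask)
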