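"""Multi-orientation EPI cuboids: construction, normalization, padding,
patch tiling, and the ``.epib`` binary cuboid format.

An epipolar-plane image (EPI) is a slice of the light field with one spatial
and one angular axis; a point at disparity d traces a line of slope d px per
view in it. An *EPI cuboid* stacks the 9 views of one star arm over a spatial
patch into a ``(9, h, w, 3)`` block — the network's input unit. Four cuboids
(0°, 90°, 45°, 135°) cover the four star orientations; the diagonal
orientations are carried by *which* views were selected, with no pixel
resampling.

Scenes are tiled into 32×32 patches at stride 13. The stride does not divide
512 − 32 evenly: position 37·13 = 481 overruns a 512-px side by one pixel, so
the source is reflect-padded by the overrun and ceil((side−patch)/stride)+1
positions are kept per axis — 38 for a 512-px side, hence 38 × 38 = 1444
cuboid records per scene, with no border content discarded.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .geometry import StarStacks

__all__ = [
    "EpiCuboid",
    "CuboidRecord",
    "ORIENTATIONS",
    "stacks_to_cuboid",
    "cuboids_from_stacks",
    "tile_scene",
    "tile_positions",
    "normalize_zero_mean",
    "pad_spatial",
    "write_cuboids",
    "read_cuboids",
]

ORIENTATIONS = ("0", "90", "45", "135")


@dataclass
class EpiCuboid:
    """One orientation's stack of views over a spatial patch: ``(view, y, x, ch)``."""

    data: np.ndarray
    orientation: str
    origin: tuple[int, int] = (0, 0)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError(f"cuboid must be rank-4 (view, y, x, ch); got rank {self.data.ndim}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}; got {self.orientation!r}")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]


@dataclass
class CuboidRecord:
    """The four orientation cuboids of one patch plus its ground-truth disparity."""

    cuboids: dict[str, EpiCuboid]
    gt: np.ndarray | None
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if set(self.cuboids) != set(ORIENTATIONS):
            raise ValueError(f"record needs all four orientations {ORIENTATIONS}")
        shapes = {c.data.shape for c in self.cuboids.values()}
        if len(shapes) != 1:
            raise ValueError(f"orientation cuboids disagree in shape: {shapes}")
        if self.gt is not None:
            self.gt = np.asarray(self.gt, dtype=np.float32)
            h, w = next(iter(shapes))[1:3]
            if self.gt.shape != (h, w):
                raise ValueError(f"gt patch {self.gt.shape} does not match cuboid spatial {(h, w)}")

    @property
    def patch_shape(self) -> tuple[int, int]:
        s = self.cuboids["0"].data.shape
        return s[1], s[2]


def stacks_to_cuboid(stack: np.ndarray, orientation: str, n_views: int = 9) -> EpiCuboid:
    """Stack one star arm's views (end-to-end through the center) into a cuboid."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.shape[0] != n_views:
        raise ValueError(f"expected {n_views} views in the stack; got {stack.shape[0]}")
    return EpiCuboid(stack, orientation)


def cuboids_from_stacks(stacks: StarStacks, n_views: int = 9) -> dict[str, EpiCuboid]:
    """Build the four full-frame orientation cuboids from star stacks."""
    d = stacks.as_dict()
    return {o: stacks_to_cuboid(d[o], o, n_views) for o in ORIENTATIONS}


# ---------------------------------------------------------------------------
# tiling


def tile_positions(side: int, patch: int = 32, stride: int = 13) -> list[int]:
    """Patch start positions along one axis: 0, stride, 2·stride, …

    The final start is kept even when its patch overruns the side (the source
    is edge-padded by the overrun), giving ceil((side−patch)/stride)+1
    positions — 38 for side 512, patch 32, stride 13.
    """
    if side < patch:
        raise ValueError(f"scene side {side} smaller than patch {patch}")
    n = int(np.ceil((side - patch) / stride)) + 1
    return [k * stride for k in range(n)]


def tile_scene(
    cuboids: dict[str, EpiCuboid],
    gt: np.ndarray | None = None,
    patch: int = 32,
    stride: int = 13,
) -> list[CuboidRecord]:
    """Tile full-frame orientation cuboids (and gt) into patch records.

    Patches that overrun the frame read from a reflect-padded copy, so every
    start position yields a full ``patch × patch`` record.
    """
    ref = cuboids[ORIENTATIONS[0]].data
    h, w = ref.shape[1:3]
    ys = tile_positions(h, patch, stride)
    xs = tile_positions(w, patch, stride)
    over_y = max(0, ys[-1] + patch - h)
    over_x = max(0, xs[-1] + patch - w)

    padded = {}
    for o in ORIENTATIONS:
        data = cuboids[o].data
        if data.shape != ref.shape:
            raise ValueError("orientation cuboids disagree in shape")
        if over_y or over_x:
            data = np.pad(data, ((0, 0), (0, over_y), (0, over_x), (0, 0)), mode="reflect")
        padded[o] = data
    if gt is not None:
        gt = np.asarray(gt, dtype=np.float32)
        if gt.shape != (h, w):
            raise ValueError(f"gt shape {gt.shape} does not match cuboid spatial {(h, w)}")
        if over_y or over_x:
            gt = np.pad(gt, ((0, over_y), (0, over_x)), mode="reflect")

    records = []
    for y0 in ys:
        for x0 in xs:
            cubs = {
                o: EpiCuboid(
                    padded[o][:, y0:y0 + patch, x0:x0 + patch].copy(),
                    o,
                    origin=(y0, x0),
                )
                for o in ORIENTATIONS
            }
            g = gt[y0:y0 + patch, x0:x0 + patch].copy() if gt is not None else None
            records.append(CuboidRecord(cubs, g, origin=(y0, x0)))
    return records


# ---------------------------------------------------------------------------
# normalization and padding


def normalize_zero_mean(cuboid: EpiCuboid, batch_mean: float | None = None) -> EpiCuboid:
    """Subtract the cuboid's own mean (or a supplied batch mean); scale untouched.

    Idempotent when the per-cuboid mean is used.
    """
    mean = float(cuboid.data.mean()) if batch_mean is None else float(batch_mean)
    return replace(cuboid, data=cuboid.data - mean, normalized=True)


def pad_spatial(cuboid: EpiCuboid, pad: int = 4) -> EpiCuboid:
    """Zero-pad the two spatial axes by ``pad`` on each side.

    With pad 4, a 32×32 patch becomes 40×40, so four VALID 3×3×3 convolutions
    return the spatial size to 32×32.
    """
    if pad == 0:
        return cuboid
    data = np.pad(cuboid.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    return replace(cuboid, data=data)


# ---------------------------------------------------------------------------
# .epib binary cuboid format
#
# Little-endian layout:
#   magic  4 bytes  b"EPIB"
#   version u32     1
#   n_records u32
#   n_views, h, w, ch u32 each
#   has_gt u32      0 or 1
# then per record: origin_y i32, origin_x i32,
#   four cuboids as float32 (orientation order 0, 90, 45, 135),
#   then the gt patch (h*w float32) if has_gt.

_MAGIC = b"EPIB"
_VERSION = 1
_HEADER = struct.Struct("<4s7I")


def write_cuboids(path: str | Path, records: list[CuboidRecord]) -> None:
    if not records:
        raise ValueError("no records to write")
    v, h, w, ch = records[0].cuboids["0"].data.shape
    has_gt = records[0].gt is not None
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, len(records), v, h, w, ch, int(has_gt)))
        for rec in records:
            if rec.cuboids["0"].data.shape != (v, h, w, ch) or (rec.gt is not None) != has_gt:
                raise ValueError("records must share shapes and gt presence")
            fh.write(struct.pack("<2i", *rec.origin))
            for o in ORIENTATIONS:
                fh.write(rec.cuboids[o].data.astype("<f4").tobytes())
            if has_gt:
                fh.write(rec.gt.astype("<f4").tobytes())


def read_cuboids(path: str | Path) -> list[CuboidRecord]:
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) != _HEADER.size:
            raise ValueError("truncated .epib header")
        magic, version, n_records, v, h, w, ch, has_gt = _HEADER.unpack(head)
        if magic != _MAGIC:
            raise ValueError(f"not an .epib file (magic {magic!r})")
        if version != _VERSION:
            raise ValueError(f"unsupported .epib version {version}")
        cuboid_bytes = v * h * w * ch * 4
        records = []
        for _ in range(n_records):
            origin_raw = fh.read(8)
            if len(origin_raw) != 8:
                raise ValueError("truncated .epib record (origin)")
            origin = struct.unpack("<2i", origin_raw)
            cubs = {}
            for o in ORIENTATIONS:
                raw = fh.read(cuboid_bytes)
                if len(raw) != cuboid_bytes:
                    raise ValueError("truncated .epib record (cuboid payload)")
                data = np.frombuffer(raw, dtype="<f4").reshape(v, h, w, ch)
                cubs[o] = EpiCuboid(data.copy(), o, origin=tuple(origin))
            gt = None
            if has_gt:
                raw = fh.read(h * w * 4)
                if len(raw) != h * w * 4:
                    raise ValueError("truncated .epib record (gt payload)")
                gt = np.frombuffer(raw, dtype="<f4").reshape(h, w).copy()
            records.append(CuboidRecord(cubs, gt, origin=tuple(origin)))
        if fh.read(1):
            raise ValueError("trailing bytes after final .epib record")
    return records
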