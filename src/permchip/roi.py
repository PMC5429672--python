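"""Device geometry and the per-data-point ROI triples.

The two-channel device has a central fibrin gel flanked by one or two
endothelialized media channels (lumens). The monolayer sits on the gel-lumen
interface, exposed between the microfluidic posts. One data point is one
ROI triple:

* **lumen region** ("yellow") — a rectangle inside the lumen, giving
  I_lumen;
* **interface line** ("blue") — a one-pixel-wide line on the first gel-side
  pixel row flush against the monolayer, spanning one post gap, giving
  I_y=0 and the monolayer width w_monolayer;
* **gel region** ("red") — a rectangle extending from the interface into the
  gel, giving I_ave,gel and the area A_gel. Its monolayer-side boundary row
  is the interface line itself, so slowly diffusing material accumulating at
  the interface is counted.

Rectangles are half-open ``[row0, row1) x [col0, col1)`` in 0-based pixel
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .image_io import BackgroundModel, ImageStack

__all__ = [
    "Rect",
    "DeviceGeometry",
    "RoiTriple",
    "build_roi_triples",
    "mean_intensity",
    "load_geometry",
    "roi_overlay",
]


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row1 > self.row0 and self.col1 > self.col0):
            raise ValueError(f"empty rectangle {self}")

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def inside(self, shape: tuple[int, int]) -> bool:
        return 0 <= self.row0 and self.row1 <= shape[0] and 0 <= self.col0 and self.col1 <= shape[1]

    def intersects(self, other: "Rect") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )

    def contains(self, other: "Rect") -> bool:
        return (
            self.row0 <= other.row0
            and other.row1 <= self.row1
            and self.col0 <= other.col0
            and other.col1 <= self.col1
        )


@dataclass
class DeviceGeometry:
    """Pixel-space layout of the two-channel device along the diffusion axis.

    Parameters
    ----------
    axis : int
        Image axis along which diffusion proceeds (0 = rows, 1 = columns).
        All positions below are indices along this axis.
    monolayer_positions : sequence of int
        One or two indices of the *first gel pixel line* adjacent to each
        monolayer. Each must border ``gel_span``: either ``gel_span[0]``
        (gel extends toward increasing indices) or ``gel_span[1] - 1``
        (toward decreasing indices).
    gel_span : (int, int)
        Half-open extent of the central gel region.
    lumen_spans : sequence of (int, int)
        Half-open extent of each media channel, one per monolayer, on the
        non-gel side of the corresponding monolayer.
    post_gaps : sequence of (int, int)
        Half-open intervals along the *transverse* axis where the monolayer
        is exposed between posts; shared by both monolayers.
    pixel_size : float
        µm per pixel.
    """

    axis: int
    monolayer_positions: Sequence[int]
    gel_span: tuple[int, int]
    lumen_spans: Sequence[tuple[int, int]]
    post_gaps: Sequence[tuple[int, int]]
    pixel_size: float

    def __post_init__(self) -> None:
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 or 1")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        lo, hi = self.gel_span
        if not hi > lo:
            raise ValueError("gel_span is empty")
        if len(self.monolayer_positions) not in (1, 2):
            raise ValueError("need one or two monolayer positions")
        if len(self.lumen_spans) != len(self.monolayer_positions):
            raise ValueError("one lumen_span per monolayer required")
        for m, (l0, l1) in zip(self.monolayer_positions, self.lumen_spans):
            if m not in (lo, hi - 1):
                raise ValueError(f"monolayer position {m} does not border gel_span {self.gel_span}")
            if not l1 > l0:
                raise ValueError("empty lumen_span")
            if max(l0, lo) < min(l1, hi):
                raise ValueError("lumen_span intersects gel_span")
            if m == lo and not l1 <= lo:
                raise ValueError("lumen must lie on the non-gel side of its monolayer")
            if m == hi - 1 and not l0 >= hi:
                raise ValueError("lumen must lie on the non-gel side of its monolayer")
        if len(set(self.monolayer_positions)) != len(self.monolayer_positions):
            raise ValueError("monolayer positions must be distinct")
        if not self.post_gaps:
            raise ValueError("post_gaps must be non-empty")
        gaps = sorted((int(a), int(b)) for a, b in self.post_gaps)
        for (a0, a1), (b0, b1) in zip(gaps, gaps[1:]):
            if b0 < a1:
                raise ValueError("post gaps overlap")
        for a, b in gaps:
            if not b > a:
                raise ValueError("empty post gap")

    def gel_direction(self, monolayer_position: int) -> int:
        """+1 if the gel extends toward increasing indices from this monolayer."""
        lo, hi = self.gel_span
        if monolayer_position == lo:
            return 1
        if monolayer_position == hi - 1:
            return -1
        raise ValueError(f"{monolayer_position} is not a monolayer position")

    @property
    def gel_width_um(self) -> float:
        lo, hi = self.gel_span
        return (hi - lo) * self.pixel_size


@dataclass
class RoiTriple:
    """One data point's lumen box, interface line and gel box.

    Coordinates are in image (row, col) space regardless of the device
    axis. ``w_monolayer`` (µm) is the physical length of the interface
    line; ``A_gel`` (µm²) the physical area of the gel box.
    """

    lumen_region: Rect
    interface_line: Rect
    gel_region: Rect
    w_monolayer: float
    A_gel: float
    triple_id: str = ""

    def validate(self) -> None:
        if self.lumen_region.intersects(self.gel_region):
            raise ValueError("lumen and gel regions overlap")
        if not self.gel_region.contains(self.interface_line):
            raise ValueError("interface line must lie within the gel region")
        on_row_edge = (
            self.interface_line.row1 - self.interface_line.row0 == 1
            and self.interface_line.row0 in (self.gel_region.row0, self.gel_region.row1 - 1)
        )
        on_col_edge = (
            self.interface_line.col1 - self.interface_line.col0 == 1
            and self.interface_line.col0 in (self.gel_region.col0, self.gel_region.col1 - 1)
        )
        if not (on_row_edge or on_col_edge):
            raise ValueError("interface line must be one pixel wide on a gel-region boundary")
        if not (self.w_monolayer > 0 and self.A_gel > 0):
            raise ValueError("non-positive physical dimensions")


def build_roi_triples(
    geometry: DeviceGeometry,
    gel_depth: float = 600.0,
    lumen_margin: float = 50.0,
) -> list[RoiTriple]:
    """Construct one ROI triple per post gap per monolayer.

    Parameters
    ----------
    geometry : DeviceGeometry
    gel_depth : float
        Extent of the gel (red) box from the interface into the gel, µm,
        measured *including* the interface line. Must not exceed the gel
        extent; with two monolayers the opposite boxes must stay disjoint.
        The default is deep enough to contain the diffusive front over a
        typical early fit window (see the methods note).
    lumen_margin : float
        Extent of the lumen (yellow) box into the channel, µm.
    """
    px = geometry.pixel_size
    depth_px = max(1, int(round(gel_depth / px)))
    margin_px = max(1, int(round(lumen_margin / px)))
    lo, hi = geometry.gel_span
    gel_px = hi - lo
    if depth_px > gel_px:
        raise ValueError(f"gel_depth {gel_depth} µm exceeds gel extent {gel_px * px} µm")
    if len(geometry.monolayer_positions) == 2 and 2 * depth_px > gel_px:
        raise ValueError("gel_depth too large: opposite gel boxes would overlap")

    triples: list[RoiTriple] = []
    for mi, (m, (l0, l1)) in enumerate(zip(geometry.monolayer_positions, geometry.lumen_spans)):
        direction = geometry.gel_direction(m)
        if direction > 0:
            gel_lo, gel_hi = m, m + depth_px
            lum_hi = l1
            lum_lo = max(l0, lum_hi - margin_px)
        else:
            gel_lo, gel_hi = m - depth_px + 1, m + 1
            lum_lo = l0
            lum_hi = min(l1, lum_lo + margin_px)
        for gi, (g0, g1) in enumerate(geometry.post_gaps):
            if geometry.axis == 0:
                gel = Rect(gel_lo, gel_hi, g0, g1)
                line = Rect(m, m + 1, g0, g1)
                lum = Rect(lum_lo, lum_hi, g0, g1)
            else:
                gel = Rect(g0, g1, gel_lo, gel_hi)
                line = Rect(g0, g1, m, m + 1)
                lum = Rect(g0, g1, lum_lo, lum_hi)
            triple = RoiTriple(
                lumen_region=lum,
                interface_line=line,
                gel_region=gel,
                w_monolayer=(g1 - g0) * px,
                A_gel=gel.n_pixels * px**2,
                triple_id=f"m{mi}_gap{gi}",
            )
            triple.validate()
            triples.append(triple)
    return triples


def mean_intensity(
    stack: ImageStack,
    region: Rect,
    frame: int,
    background: Optional[BackgroundModel] = None,
) -> float:
    """Mean background-subtracted intensity of ``region`` in one frame.

    The *mean* is clipped at zero (intensity ∝ concentration ≥ 0).
    Subtraction is not clipped per pixel: doing so would rectify the read
    noise and add a signal-dependent positive bias that distorts the
    early-time slope in low-signal regions.
    """
    if not region.inside(stack.frame_shape):
        raise ValueError(f"region {region} outside frame shape {stack.frame_shape}")
    rs, cs = region.slices
    val = float(stack.frames[frame][rs, cs].astype(float).mean())
    if background is not None:
        if background.mode == "scalar":
            val -= float(background.value)
        else:
            bg = np.asarray(background.value)
            if bg.shape != stack.frame_shape:
                raise ValueError("per-pixel background shape does not match frame shape")
            val -= float(bg[rs, cs].mean())
    return max(val, 0.0)


def load_geometry(path: Union[str, Path]) -> tuple[DeviceGeometry, dict]:
    """Load a device geometry (and any explicit ROIs) from a YAML/JSON config.

    Returns the geometry and the raw config dict (which may carry
    ``gel_depth_um``, ``lumen_margin_um``, ``n_background_frames``,
    ``explicit_rois`` and stack calibration keys).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    geom = DeviceGeometry(
        axis=int(cfg.get("axis", 0)),
        monolayer_positions=[int(m) for m in cfg["monolayer_positions"]],
        gel_span=tuple(int(v) for v in cfg["gel_span"]),
        lumen_spans=[tuple(int(v) for v in s) for s in cfg["lumen_spans"]],
        post_gaps=[tuple(int(v) for v in g) for g in cfg["post_gaps"]],
        pixel_size=float(cfg["pixel_size_um"]),
    )
    return geom, cfg


def triples_from_config(cfg: dict, geometry: DeviceGeometry) -> list[RoiTriple]:
    """Build triples from a geometry config, honouring explicit ROIs if given.

    ``explicit_rois`` entries mirror manual delineation: each has
    ``lumen``, ``line`` and ``gel`` rectangles as [row0, row1, col0, col1].
    """
    explicit = cfg.get("explicit_rois")
    if not explicit:
        return build_roi_triples(
            geometry,
            gel_depth=float(cfg.get("gel_depth_um", 600.0)),
            lumen_margin=float(cfg.get("lumen_margin_um", 50.0)),
        )
    px = geometry.pixel_size
    triples = []
    for i, entry in enumerate(explicit):
        line = Rect(*entry["line"])
        gel = Rect(*entry["gel"])
        n_line = max(line.row1 - line.row0, line.col1 - line.col0)
        triple = RoiTriple(
            lumen_region=Rect(*entry["lumen"]),
            interface_line=line,
            gel_region=gel,
            w_monolayer=n_line * px,
            A_gel=gel.n_pixels * px**2,
            triple_id=entry.get("id", f"roi{i}"),
        )
        triple.validate()
        triples.append(triple)
    return triples


def roi_overlay(shape: tuple[int, int], triples: Sequence[RoiTriple]) -> np.ndarray:
    """Labeled mask for visual audit: 1 = lumen, 2 = gel, 3 = interface line."""
    mask = np.zeros(shape, dtype=np.uint8)
    for t in triples:
        mask[t.lumen_region.slices] = 1
        mask[t.gel_region.slices] = 2
        mask[t.interface_line.slices] = 3
    return mask
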