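"""Calibrated time-lapse stacks and background estimation.

A permeability experiment is a multi-page grayscale TIFF: one frame per time
point, acquired at a fixed interval (typically 30 s), with a handful of
pre-injection frames used to estimate the camera/autofluorescence background.
Physical calibration (µm per pixel, seconds per frame) is carried alongside
the pixel data because every downstream quantity (w_monolayer, A_gel, the
intensity slope) needs it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["ImageStack", "BackgroundModel", "read_stack", "write_stack", "estimate_background"]


@dataclass
class ImageStack:
    """A time-ordered stack of grayscale frames with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative finite intensities, ordered by acquisition time.
    pixel_size : float
        Lateral calibration in µm per pixel (> 0).
    frame_interval : float
        Time between consecutive frames in seconds (> 0).
    label : str
        Free-text description (probe, condition, device id).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (T, H, W), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError("a time-lapse stack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0 µm/px")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0 s")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class BackgroundModel:
    """Background intensity: a scalar or a per-pixel map.

    ``mode`` is ``"scalar"`` (one number subtracted everywhere) or
    ``"per-pixel"`` (a 2-D map matching the frame shape).
    """

    mode: str
    value: Union[float, np.ndarray]

    def __post_init__(self) -> None:
        if self.mode not in ("scalar", "per-pixel"):
            raise ValueError(f"mode must be 'scalar' or 'per-pixel', got {self.mode!r}")
        if self.mode == "scalar":
            self.value = float(self.value)
            if self.value < 0:
                raise ValueError("scalar background must be >= 0")
        else:
            self.value = np.asarray(self.value, dtype=float)
            if self.value.ndim != 2:
                raise ValueError("per-pixel background must be a 2-D map")
            if np.any(self.value < 0):
                raise ValueError("per-pixel background must be >= 0")

    def subtract(self, frame: np.ndarray) -> np.ndarray:
        """Background-subtracted frame, clipped at 0.

        Intensity is proportional to concentration, which is non-negative,
        so negative residuals after subtraction are clipped.
        """
        if self.mode == "per-pixel" and np.shape(self.value) != frame.shape:
            raise ValueError("per-pixel background shape does not match frame shape")
        return np.clip(np.asarray(frame, dtype=float) - self.value, 0.0, None)


def read_stack(
    path: Union[str, Path],
    pixel_size: float,
    frame_interval: float,
    label: str = "",
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Calibration is supplied explicitly (config-driven) rather than parsed
    from TIFF metadata, to avoid dialect dependence; if the file carries a
    resolution tag that disagrees, a warning is logged.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        _check_metadata_consistency(tif, pixel_size)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale multi-page file, got shape {frames.shape}")
    return ImageStack(frames=frames, pixel_size=pixel_size, frame_interval=frame_interval, label=label)


def _check_metadata_consistency(tif: "tifffile.TiffFile", pixel_size: float) -> None:
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is None:
            return
        num, den = xres.value
        if num == 0:
            return
        # TIFF resolution is pixels per unit; RESUNIT 3 = cm
        unit = page.tags.get("ResolutionUnit")
        if unit is not None and getattr(unit.value, "value", unit.value) == 3:
            meta_px_um = 1e4 * den / num
            if not np.isclose(meta_px_um, pixel_size, rtol=0.01):
                logger.warning(
                    "TIFF metadata pixel size %.4g µm/px disagrees with configured %.4g µm/px",
                    meta_px_um,
                    pixel_size,
                )
    except Exception:  # metadata is advisory only
        pass


def write_stack(stack: ImageStack, path: Union[str, Path]) -> None:
    """Write an :class:`ImageStack` to a multi-page TIFF.

    Integer-valued stacks round-trip bit-exactly through :func:`read_stack`.
    """
    tifffile.imwrite(Path(path), stack.frames, photometric="minisblack")


def estimate_background(
    stack: ImageStack,
    n_pre_frames: int,
    mode: str = "scalar",
) -> BackgroundModel:
    """Estimate background from the pre-injection frames.

    Parameters
    ----------
    stack : ImageStack
        The first ``n_pre_frames`` frames must precede tracer injection.
    n_pre_frames : int
        Number of leading frames to use; ``1 <= n_pre_frames < n_frames``.
    mode : {"scalar", "per-pixel"}
        Scalar (default) averages over all pixels of the pre-injection
        frames; per-pixel averages over time only.
    """
    if not 1 <= n_pre_frames < stack.n_frames:
        raise ValueError(
            f"n_pre_frames must be in [1, {stack.n_frames - 1}], got {n_pre_frames}"
        )
    pre = stack.frames[:n_pre_frames].astype(float)
    if mode == "scalar":
        return BackgroundModel(mode="scalar", value=float(pre.mean()))
    if mode == "per-pixel":
        return BackgroundModel(mode="per-pixel", value=pre.mean(axis=0))
    raise ValueError(f"unknown background mode {mode!r}")
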