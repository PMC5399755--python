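"""Ordered grayscale frame stacks and their disk formats.

A :class:`FrameStack` is the in-memory form of a droplet-assay recording:
an ordered set of equally-shaped 2-D grayscale rasters acquired at a fixed
frame rate (10 Hz for the CCD recordings this package models).  Stacks are
written as multi-page TIFF; AVI is accepted on read for real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class FrameReadError(RuntimeError):
    """Raised when a video/stack file cannot be decoded."""


@dataclass
class FrameStack:
    """Ordered grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``; any integer or float
        grayscale dtype.
    frame_rate_hz
        Acquisition rate in frames per second; must be positive.
    pixel_size
        Physical pixel edge length in micrometres per pixel.  Defaults to 1,
        i.e. areas are reported in px².
    """

    frames: np.ndarray
    frame_rate_hz: float = 10.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols) of each frame."""
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame i at i/rate)."""
        return np.arange(len(self)) / self.frame_rate_hz

    def __iter__(self):
        return iter(self.frames)


def write_tiff(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF."""
    import tifffile

    frames = stack.frames
    if frames.dtype not in (np.uint8, np.uint16):
        frames = np.clip(frames, 0, 255).astype(np.uint8)
    tifffile.imwrite(str(path), frames, photometric="minisblack")


def read_stack(path: str | Path, frame_rate_hz: float = 10.0,
               pixel_size: float = 1.0) -> FrameStack:
    """Read a multi-page TIFF or AVI recording into a :class:`FrameStack`.

    Color frames are converted to grayscale by channel averaging.  Raises
    :class:`FrameReadError` naming the file if it cannot be decoded.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            frames = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            frames = iio.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise FrameReadError(f"cannot read frame stack from {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # color -> luminance
        frames = frames.mean(axis=-1)
    if frames.ndim != 3:
        raise FrameReadError(f"{path}: unsupported frame layout {frames.shape}")
    return FrameStack(frames=frames, frame_rate_hz=frame_rate_hz,
                      pixel_size=pixel_size)
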