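"""Reading and writing multi-frame grayscale TIFF stacks.

The instrument software exports one multi-page TIFF per tray measurement,
with the same frame order as its native measurement file.  Frames are kept
as raw unsigned-integer counts end to end; fluorescence ratios are computed
in floating point only at use time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .config_maps import FrameMap, FrameRole, MeasurementID, parse_filename

__all__ = [
    "FluorescenceStack",
    "CalibrationSpec",
    "StackFormatError",
    "read_stack",
    "write_stack",
]


class StackFormatError(ValueError):
    """A TIFF stack does not match the expected instrument export format."""


@dataclass(frozen=True)
class CalibrationSpec:
    """Spatial calibration of the camera: millimetres per pixel."""

    pixel_resolution: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_resolution) or self.pixel_resolution <= 0:
            raise ValueError(
                f"pixel_resolution must be positive and finite, "
                f"got {self.pixel_resolution}"
            )


@dataclass
class FluorescenceStack:
    """Pixel data of one tray measurement bound to its frame map and identity.

    ``frames`` is an array of shape (n_frames, height, width) with unsigned
    8- or 16-bit dtype; frame order follows the frame map.
    """

    id: MeasurementID
    frames: np.ndarray
    frame_map: FrameMap

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise StackFormatError(
                f"frames must be a non-empty (n, h, w) array, got shape "
                f"{self.frames.shape}"
            )
        if self.frames.dtype not in (np.dtype("uint8"), np.dtype("uint16")):
            raise StackFormatError(
                f"frames must be uint8 or uint16, got {self.frames.dtype}"
            )
        if self.frames.shape[0] != len(self.frame_map):
            raise StackFormatError(
                f"stack has {self.frames.shape[0]} frames but frame map "
                f"expects {len(self.frame_map)}"
            )

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def get_frame(
        self, role: FrameRole | str, induction_step: Optional[int] = None
    ) -> np.ndarray:
        """The single raster matching (role, induction step).

        Fo/Fm/absorptivity frames need no step; F'/Fm' frames require one.
        """
        entry = self.frame_map.entry(FrameRole(role), induction_step)
        return self.frames[entry.frame_index - 1]


def read_stack(
    path: str | Path,
    frame_map: FrameMap,
    measurement_id: Optional[MeasurementID] = None,
) -> FluorescenceStack:
    """Read a multi-page grayscale TIFF into a :class:`FluorescenceStack`.

    The measurement identity is parsed from the filename unless given
    explicitly; the page count is checked against the frame map.
    """
    path = Path(path)
    if measurement_id is None:
        measurement_id = parse_filename(path.name)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    if not pages:
        raise StackFormatError(f"{path}: contains no image pages")
    shapes = {p.shape for p in pages}
    if any(p.ndim != 2 for p in pages):
        raise StackFormatError(
            f"{path}: multi-sample (color) pages are not supported; the "
            "instrument exports grayscale frames"
        )
    if len(shapes) != 1:
        raise StackFormatError(f"{path}: pages have ragged dimensions {shapes}")
    dtypes = {p.dtype for p in pages}
    if len(dtypes) != 1:
        raise StackFormatError(f"{path}: pages have mixed dtypes {dtypes}")
    if len(pages) != len(frame_map):
        raise StackFormatError(
            f"{path}: expected {len(frame_map)} frames per the frame map, "
            f"found {len(pages)}"
        )
    return FluorescenceStack(
        id=measurement_id, frames=np.stack(pages), frame_map=frame_map
    )


def write_stack(
    stack: FluorescenceStack, path: str | Path, compression: str | None = "zlib"
) -> Path:
    """Write a stack as a multi-page grayscale TIFF (deflate by default).

    The written file reads back bit-exactly with :func:`read_stack`.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.frames,
        photometric="minisblack",
        compression=compression,
        metadata=None,
    )
    return path
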