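"""Pixelwise photosynthetic parameters and calibrated plant area.

Three parameters are computed from the fluorescence frames, each as a
per-pixel ratio on the plant mask:

* Fv/Fm = (Fm - Fo) / Fm — maximum quantum yield of photosystem II of the
  dark-adapted plant,
* YII   = (Fm' - F') / Fm' — operating PSII quantum yield at an induction
  step in the light,
* NPQ   = (Fm - Fm') / Fm' — non-photochemical quenching, displayed as
  NPQ/4 on a [0, 1] scale by convention.

Per-plant summaries are the mean of the pixelwise ratio (not the ratio of
mean intensities), so the false-colour images and the summary numbers are
mutually consistent.  Denominator pixels below a signal floor are excluded
from both the image and the average; stored values are never clamped —
clamping happens only in the display transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np
from matplotlib import colormaps

from .stack_io import CalibrationSpec

logger = logging.getLogger(__name__)

__all__ = [
    "Parameter",
    "ParameterImage",
    "fvfm",
    "yii",
    "npq",
    "plant_value",
    "calibrate_pixel_resolution",
    "plant_area",
    "render_false_color",
]


class Parameter(str, Enum):
    FvFm = "FvFm"
    YII = "YII"
    NPQ = "NPQ"
    area_mm2 = "area_mm2"


@dataclass
class ParameterImage:
    """A pixelwise parameter raster, NaN outside the defined plant pixels."""

    parameter: Parameter
    induction_step: Optional[int]
    values: np.ndarray  # float raster, NaN where undefined

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def display_values(self) -> np.ndarray:
        """Values on the common [0, 1] display scale (NPQ divided by 4),
        clamped; NaN outside the plant."""
        v = self.values
        if self.parameter is Parameter.NPQ:
            v = v / 4.0
        return np.clip(v, 0.0, 1.0)


SignalFloor = Union[float, str]


def _resolve_floor(denominator: np.ndarray, signal_floor: SignalFloor) -> float:
    """Absolute floor in counts below which the denominator is treated as
    background.  ``"auto"`` = 5% of the frame's maximal signal."""
    if signal_floor == "auto":
        return 0.05 * float(denominator.max())
    floor = float(signal_floor)
    if floor < 0:
        raise ValueError(f"signal floor must be >= 0, got {signal_floor}")
    return floor


def _ratio_image(
    numerator: np.ndarray,
    denominator: np.ndarray,
    mask: np.ndarray,
    parameter: Parameter,
    induction_step: Optional[int],
    signal_floor: SignalFloor,
) -> ParameterImage:
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    if numerator.shape != denominator.shape or numerator.shape != mask.shape:
        raise ValueError("frames and mask must share dimensions")
    floor = _resolve_floor(denominator, signal_floor)
    defined = np.asarray(mask, dtype=bool) & (denominator >= floor) & (denominator > 0)
    values = np.full(numerator.shape, np.nan)
    values[defined] = numerator[defined] / denominator[defined]
    if np.asarray(mask).any() and not defined.any():
        warnings.warn(
            f"{parameter.value}: every mask pixel fell below the signal floor "
            f"({floor:.1f} counts); parameter undefined",
            stacklevel=3,
        )
    return ParameterImage(parameter, induction_step, values)


def fvfm(
    Fo: np.ndarray,
    Fm: np.ndarray,
    mask: np.ndarray,
    signal_floor: SignalFloor = "auto",
) -> ParameterImage:
    """Maximum PSII quantum yield (Fm - Fo) / Fm on the plant mask."""
    img = _ratio_image(np.asarray(Fo, float), Fm, mask, Parameter.FvFm, None, signal_floor)
    img.values = 1.0 - img.values
    return img


def yii(
    Fprime: np.ndarray,
    Fmprime: np.ndarray,
    mask: np.ndarray,
    induction_step: int,
    signal_floor: SignalFloor = "auto",
) -> ParameterImage:
    """Operating PSII quantum yield (Fm' - F') / Fm' at one induction step.

    At step 1 of a dark-adapted protocol (frames 5/6 repeating Fo/Fm) this
    equals Fv/Fm pixel for pixel.
    """
    img = _ratio_image(
        np.asarray(Fprime, float), Fmprime, mask, Parameter.YII, induction_step,
        signal_floor,
    )
    img.values = 1.0 - img.values
    return img


def npq(
    Fm: np.ndarray,
    Fmprime: np.ndarray,
    mask: np.ndarray,
    induction_step: int,
    signal_floor: SignalFloor = "auto",
) -> ParameterImage:
    """Non-photochemical quenching (Fm - Fm') / Fm' at one induction step.

    Zero at step 1 of a dark-adapted protocol (Fm' = Fm); unbounded above.
    """
    img = _ratio_image(
        np.asarray(Fm, float), Fmprime, mask, Parameter.NPQ, induction_step,
        signal_floor,
    )
    img.values = img.values - 1.0
    return img


def plant_value(img: ParameterImage, plant_mask: np.ndarray) -> Optional[float]:
    """Arithmetic mean of defined pixel values inside one plant's mask.

    Returns ``None`` (with a warning) when no defined pixel falls inside
    the mask — an absent plant or one entirely below the signal floor.
    """
    sel = np.asarray(plant_mask, dtype=bool) & img.defined
    if not sel.any():
        logger.warning(
            "%s step=%s: no defined pixels in plant mask; value undefined",
            img.parameter.value,
            img.induction_step,
        )
        return None
    return float(img.values[sel].mean())


def calibrate_pixel_resolution(diameter_mm: float, diameter_px: float) -> CalibrationSpec:
    """mm-per-pixel from an object of known size imaged with the setup
    (e.g. a hole punch): diameter in mm divided by diameter in pixels."""
    if diameter_mm <= 0 or diameter_px <= 0:
        raise ValueError(
            f"diameters must be positive, got {diameter_mm} mm / {diameter_px} px"
        )
    return CalibrationSpec(pixel_resolution=diameter_mm / diameter_px)


def plant_area(pixel_count: int, cal: CalibrationSpec) -> float:
    """Plant surface area in mm^2: pixel count times (mm per pixel)^2."""
    if pixel_count < 0:
        raise ValueError("pixel_count must be >= 0")
    return pixel_count * cal.pixel_resolution**2


def render_false_color(
    img: ParameterImage,
    background: tuple[int, int, int] = (30, 30, 30),
    cmap: str = "viridis",
) -> np.ndarray:
    """False-colour RGB rendering of a parameter image.

    The colormap spans exactly [0, 1] of the display scale (identical
    across all images of an experiment, so colours are comparable);
    undefined pixels take a neutral dark background colour.
    """
    disp = img.display_values()
    cm = colormaps[cmap]
    rgb = (cm(np.nan_to_num(disp, nan=0.0))[..., :3] * 255).astype(np.uint8)
    rgb[~img.defined] = background
    return rgb
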