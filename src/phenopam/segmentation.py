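"""Plant segmentation: entropy threshold, mask cleaning, ROI grid, QC flags.

Plants are separated from the dark background by an automatic threshold
based on Yen's entropic-correlation criterion, the binary mask is cleaned
of small noise, and connected components are attributed to a regular grid
of circular regions of interest (one per pot position).  Two QC flags are
recorded per ROI: *complete* (the plant does not touch the image border,
i.e. was fully imaged) and *independent* (the plant does not merge with a
neighbouring plant's rosette).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .config_maps import FrameRole

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateImageError",
    "yen_threshold",
    "clean_mask",
    "ROILayout",
    "make_roi_grid",
    "QCFlags",
    "PlantSegmentation",
    "assign_plants",
    "SegmentationParams",
    "segment_frame",
    "render_overlay",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


class DegenerateImageError(ValueError):
    """The image has a single gray level; no threshold separates it."""


def _dtype_max(image: np.ndarray) -> int:
    if image.dtype.kind != "u":
        raise TypeError(f"expected an unsigned integer raster, got {image.dtype}")
    return int(np.iinfo(image.dtype).max)


def yen_criterion(counts: np.ndarray) -> np.ndarray:
    """Yen's entropic-correlation criterion over every candidate bin.

    For normalised histogram frequencies p_i the criterion at candidate
    threshold bin t (background = bins <= t) is

        C(t) = 2 ln(P1(t) (1 - P1(t))) - ln(S1(t) S2(t))

    with P1 the cumulative mass, S1 the cumulative squared mass and S2 the
    tail squared mass.  The normalisation constants cancel, so C is
    evaluated from the raw integer ``counts``:

        C(t) = 2 [ln N1 + ln(N - N1)] - [ln sum_bg(c^2) + ln sum_fg(c^2)]

    with N1 the cumulative count.  Integer cumulative sums are exact, so
    histogram plateaus give exactly tied criterion values and the
    smallest-t tie-break is well defined.  Entries with a degenerate split
    (either class empty) are -inf.
    """
    counts = np.asarray(counts, dtype=np.int64)
    N = counts.sum()
    N1 = np.cumsum(counts)
    sq = counts * counts
    S1 = np.cumsum(sq)
    S2 = sq.sum() - S1
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = 2.0 * (np.log(N1.astype(float)) + np.log((N - N1).astype(float))) - (
            np.log(S1.astype(float)) + np.log(S2.astype(float))
        )
    valid = (N1 > 0) & (N1 < N) & (S1 > 0) & (S2 > 0)
    crit[~valid] = -np.inf
    return crit


def yen_threshold(image: np.ndarray, nbins: int = 256) -> int:
    """Automatic threshold maximising Yen's entropic criterion.

    The histogram spans the full dtype range in ``nbins`` equal bins
    (16-bit images are binned, not truncated).  The returned value is a
    gray level: foreground is every pixel **strictly greater** than it.
    Ties in the criterion break toward the smallest threshold.
    """
    image = np.asarray(image)
    dmax = _dtype_max(image)
    flat = image.ravel()
    if flat.min() == flat.max():
        raise DegenerateImageError(
            f"constant image (all pixels = {int(flat[0])}); cannot threshold"
        )
    counts, _ = np.histogram(flat, bins=nbins, range=(0, dmax + 1))
    crit = yen_criterion(counts)
    t = int(np.argmax(crit))  # argmax takes the first maximum: smallest t
    bin_width = (dmax + 1) / nbins
    return int((t + 1) * bin_width) - 1


def clean_mask(
    mask: np.ndarray, min_object_px: int = 100, max_hole_px: int = 100
) -> np.ndarray:
    """Remove small objects and fill small interior holes.

    Connected components (8-connectivity) with fewer than ``min_object_px``
    pixels are removed; interior holes (4-connectivity) with fewer than
    ``max_hole_px`` pixels are filled.  With both parameters 0 the mask is
    returned unchanged.  Idempotent.
    """
    if min_object_px < 0 or max_hole_px < 0:
        raise ValueError("size parameters must be non-negative")
    out = np.asarray(mask).astype(bool)
    # max_size removes sizes <= its value; strict "smaller than" needs -1
    if min_object_px > 1:
        out = morphology.remove_small_objects(
            out, connectivity=2, max_size=min_object_px - 1
        )
    if max_hole_px > 1:
        out = morphology.remove_small_holes(
            out, connectivity=1, max_size=max_hole_px - 1
        )
    return out


@dataclass(frozen=True)
class ROILayout:
    """Regular grid of circular ROIs, numbered row-major from 1."""

    n_rows: int
    n_cols: int
    centers: tuple[tuple[float, float], ...]  # (row, col) pixel coordinates
    radius: float
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols != len(self.centers):
            raise ValueError(
                f"{self.n_rows}x{self.n_cols} grid needs "
                f"{self.n_rows * self.n_cols} centers, got {len(self.centers)}"
            )

    @property
    def n_roi(self) -> int:
        return len(self.centers)

    def circle_mask(self, position: int) -> np.ndarray:
        """Boolean raster of the ROI circle at 1-based ``position``."""
        r0, c0 = self.centers[position - 1]
        rr, cc = np.ogrid[: self.image_shape[0], : self.image_shape[1]]
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2


def make_roi_grid(
    n_rows: int,
    n_cols: int,
    origin: tuple[float, float],
    spacing: float | tuple[float, float],
    radius: float,
    image_shape: tuple[int, int],
) -> ROILayout:
    """Build a row-major grid of disjoint circular ROIs.

    ``origin`` is the (row, col) centre of ROI position 1; ``spacing`` the
    centre-to-centre distance (scalar or per-axis).  Circles must fit
    inside the image and must not overlap.
    """
    dr, dc = (spacing, spacing) if np.isscalar(spacing) else spacing
    if radius <= 0:
        raise ValueError("radius must be positive")
    if radius > min(dr if n_rows > 1 else np.inf, dc if n_cols > 1 else np.inf) / 2:
        raise ValueError(
            f"radius {radius} > half the grid spacing: ROI circles would overlap"
        )
    centers = []
    h, w = image_shape
    for i in range(n_rows):
        for j in range(n_cols):
            r, c = origin[0] + i * dr, origin[1] + j * dc
            if r - radius < 0 or r + radius > h - 1 or c - radius < 0 or c + radius > w - 1:
                raise ValueError(
                    f"ROI at ({r}, {c}) with radius {radius} exceeds image "
                    f"bounds {image_shape}"
                )
            centers.append((float(r), float(c)))
    return ROILayout(
        n_rows=n_rows,
        n_cols=n_cols,
        centers=tuple(centers),
        radius=float(radius),
        image_shape=tuple(image_shape),
    )


@dataclass(frozen=True)
class QCFlags:
    """Per-ROI quality flags: fully imaged, and not merged with a neighbour."""

    complete: bool
    independent: bool


@dataclass
class PlantSegmentation:
    """Foreground mask, per-ROI plant masks and pixel counts, QC flags."""

    foreground: np.ndarray
    roi_masks: list[np.ndarray]
    pixel_counts: list[int]
    flags: list[QCFlags]
    n_unassigned_components: int = 0
    unassigned_px: int = 0
    threshold: Optional[int] = None


def assign_plants(mask: np.ndarray, layout: ROILayout) -> PlantSegmentation:
    """Attribute connected components of a cleaned mask to ROI circles.

    A component belongs to every ROI circle it shares at least one pixel
    with.  A component spanning two or more circles marks all of them
    ``independent=False``; a component touching the image border marks its
    ROI ``complete=False``.  Components intersecting no circle are dropped
    from the per-ROI masks and counted in the diagnostics fields.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != layout.image_shape:
        raise ValueError(
            f"mask shape {mask.shape} != layout image shape {layout.image_shape}"
        )
    labels, n_comp = ndi.label(mask, structure=_EIGHT)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border & mask]).tolist()) - {0}

    roi_labels: list[set[int]] = []
    for pos in range(1, layout.n_roi + 1):
        circle = layout.circle_mask(pos)
        roi_labels.append(set(np.unique(labels[circle & mask]).tolist()) - {0})

    label_to_rois: dict[int, list[int]] = {}
    for pos, labset in enumerate(roi_labels, start=1):
        for lab in labset:
            label_to_rois.setdefault(lab, []).append(pos)

    roi_masks: list[np.ndarray] = []
    counts: list[int] = []
    flags: list[QCFlags] = []
    for labset in roi_labels:
        if labset:
            m = np.isin(labels, sorted(labset))
        else:
            m = np.zeros_like(mask)
        roi_masks.append(m)
        counts.append(int(m.sum()))
        flags.append(
            QCFlags(
                complete=not any(lab in border_labels for lab in labset),
                independent=not any(len(label_to_rois[lab]) > 1 for lab in labset),
            )
        )

    assigned = set(label_to_rois)
    unassigned = [lab for lab in range(1, n_comp + 1) if lab not in assigned]
    unassigned_px = int(np.isin(labels, unassigned).sum()) if unassigned else 0
    if unassigned:
        logger.info(
            "%d foreground component(s) (%d px) intersect no ROI and were discarded",
            len(unassigned),
            unassigned_px,
        )
    return PlantSegmentation(
        foreground=mask,
        roi_masks=roi_masks,
        pixel_counts=counts,
        flags=flags,
        n_unassigned_components=len(unassigned),
        unassigned_px=unassigned_px,
    )


@dataclass
class SegmentationParams:
    """Tunable segmentation knobs; defaults suit 640x480 instrument exports.

    Segmentation runs on the dark-adapted Fm frame by default — maximal
    fluorescence gives the strongest plant/background contrast.
    """

    frame_role: FrameRole = FrameRole.Fm
    nbins: int = 256
    min_object_px: int = 100
    max_hole_px: int = 100


def segment_frame(
    image: np.ndarray, layout: ROILayout, params: Optional[SegmentationParams] = None
) -> PlantSegmentation:
    """Threshold -> clean -> assign, returning the full segmentation."""
    params = params or SegmentationParams()
    t = yen_threshold(image, nbins=params.nbins)
    mask = clean_mask(image > t, params.min_object_px, params.max_hole_px)
    seg = assign_plants(mask, layout)
    seg.threshold = t
    return seg


def render_overlay(
    image: np.ndarray, seg: PlantSegmentation, layout: ROILayout
) -> np.ndarray:
    """Debug rendering: grayscale base, foreground tinted green, ROI rings red.

    Returns an (h, w, 3) uint8 raster suitable for PNG export.
    """
    base = image.astype(float)
    hi = base.max() or 1.0
    gray = (base / hi * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    fg = seg.foreground
    rgb[fg, 1] = np.minimum(255, rgb[fg, 1].astype(int) + 90).astype(np.uint8)
    rr, cc = np.ogrid[: image.shape[0], : image.shape[1]]
    for r0, c0 in layout.centers:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        ring = (d2 <= (layout.radius + 1) ** 2) & (d2 >= (layout.radius - 1) ** 2)
        rgb[ring] = (255, 60, 60)
    return rgb
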