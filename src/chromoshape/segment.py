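"""Detection and screening of round (spheroidal) cells.

Wall-less expanded cells are close to circular in the imaging plane.  The
screening funnel mirrors the acquisition protocol this pipeline models:
detect candidate cells on a wide-field proxy channel, keep the round ones,
and accept only cells showing a single ParB focus in the maximum-intensity
projection (one focus = one chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import InputError, ParameterError
from .stack import ImageStack


@dataclass
class CellROI:
    """One detected cell: mask, centroid, size and screening flags.

    Bounding box is 0-based, half-open ``(y0, y1, x0, x1)``; the mask covers
    the full image frame.  ``roundness = 4*pi*area / perimeter**2`` is 1 for
    an ideal disc and decreases for elongated or ragged shapes.
    """

    id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid_xy_px: tuple[float, float]
    area_px: int
    area_um2: float
    equivalent_diameter_um: float
    roundness: float
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def round_pass(self) -> bool:
        return bool(self.flags.get("round_pass", False))

    @property
    def single_parb_pass(self) -> bool:
        return bool(self.flags.get("single_parb_pass", False))


def max_project(stack: ImageStack, channel: str) -> np.ndarray:
    """Maximum-intensity projection of one channel along z.

    Identity for single-plane stacks.
    """
    return stack.channel(channel).max(axis=0)


def detect_cells(
    stack: ImageStack,
    channel: str = "CELL",
    threshold_method: str = "otsu",
    min_area_um2: float = 1.0,
    smooth_sigma_px: float = 1.0,
    quantile: float = 0.5,
) -> list[CellROI]:
    """Detect cell-sized connected components on one channel.

    The channel's max projection is Gaussian-smoothed (sigma = 1 px by
    default), thresholded (Otsu by default, ``threshold_method='quantile'``
    as an alternative — both are invariant to multiplying the image by a
    positive constant), hole-filled, and split into connected components;
    components smaller than ``min_area_um2`` are dropped.  An empty or
    signal-free image yields an empty list.
    """
    img = max_project(stack, channel).astype(np.float64)
    smoothed = ndimage.gaussian_filter(img, smooth_sigma_px)
    if smoothed.max() <= smoothed.min():
        return []
    if threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
    elif threshold_method == "quantile":
        thr = np.quantile(smoothed, quantile)
    else:
        raise ParameterError(f"unknown threshold_method {threshold_method!r}")
    binary = ndimage.binary_fill_holes(smoothed > thr)
    labels = cc_label(binary, connectivity=2)
    px_um = stack.pixel_size_nm / 1000.0
    min_area_px = min_area_um2 / (px_um**2)
    rois: list[CellROI] = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        mask = labels == prop.label
        y0, x0, y1, x1 = prop.bbox
        perimeter = prop.perimeter_crofton
        roundness = 4.0 * np.pi * prop.area / perimeter**2 if perimeter > 0 else 0.0
        rois.append(
            CellROI(
                id=len(rois),
                mask=mask,
                bbox=(y0, y1, x0, x1),
                centroid_xy_px=(prop.centroid[1], prop.centroid[0]),
                area_px=int(prop.area),
                area_um2=float(prop.area) * px_um**2,
                equivalent_diameter_um=float(prop.equivalent_diameter_area) * px_um,
                roundness=float(min(roundness, 1.0)),
            )
        )
    return rois


def roi_from_mask(mask: np.ndarray, pixel_size_nm: float, roi_id: int = 0) -> CellROI:
    """Build a :class:`CellROI` from an arbitrary binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("mask is empty")
    props = regionprops(mask.astype(np.uint8))
    if len(props) != 1:
        raise InputError("mask must be a single connected component")
    prop = props[0]
    px_um = pixel_size_nm / 1000.0
    y0, x0, y1, x1 = prop.bbox
    perimeter = prop.perimeter_crofton
    roundness = 4.0 * np.pi * prop.area / perimeter**2 if perimeter > 0 else 0.0
    return CellROI(
        id=roi_id,
        mask=mask,
        bbox=(y0, y1, x0, x1),
        centroid_xy_px=(prop.centroid[1], prop.centroid[0]),
        area_px=int(prop.area),
        area_um2=float(prop.area) * px_um**2,
        equivalent_diameter_um=float(prop.equivalent_diameter_area) * px_um,
        roundness=float(min(roundness, 1.0)),
    )


def screen_round(rois: list[CellROI], roundness_min: float = 0.85) -> list[CellROI]:
    """Keep ROIs whose roundness passes the cutoff (order preserved).

    The study this pipeline models screened misdetections out with "a simple
    cell roundness criterion" without quantifying it; 0.85 is this package's
    documented default.
    """
    if not 0.0 < roundness_min <= 1.0:
        raise ParameterError("roundness_min must lie in (0, 1]")
    out = []
    for roi in rois:
        ok = roi.roundness >= roundness_min
        out_roi = replace(roi, flags={**roi.flags, "round_pass": ok})
        if ok:
            out.append(out_roi)
    return out


def select_single_chromosome(
    roi: CellROI,
    parb_projection: np.ndarray,
    psf_sigma_px: float,
    min_prominence: float = 5.0,
    pixel_size_nm: float = 65.35,
) -> bool:
    """True iff exactly one ParB focus is found inside the ROI.

    A single ParB focus in the maximum projection is the proxy for a single
    chromosome per cell; the flag is recorded on the ROI.
    """
    from .foci import detect_foci  # local import to avoid a cycle

    foci = detect_foci(
        parb_projection,
        roi.mask,
        psf_sigma_px=psf_sigma_px,
        min_prominence=min_prominence,
        pixel_size_nm=pixel_size_nm,
        cell_id=roi.id,
        channel="PARB",
    )
    ok = len(foci) == 1
    roi.flags["single_parb_pass"] = ok
    return ok
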