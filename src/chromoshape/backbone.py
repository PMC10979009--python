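"""Annular backbone fitting and ori-anchored contour profiles.

The unconfined chromosome forms an arc that follows the inside of the cell
wall, so its center line ("backbone") is well described in an annular
coordinate system: a circle center, a radius per angular bin, and the set of
angles that actually carry chromosome signal.  Arc length measured from the
angle of the ParB focus (the origin of replication) gives every cell a
common length axis; profiles are flipped so that the chromosome body extends
toward positive length values, and normalized per channel to a mean of 1
("fold-increase").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import ParameterError, ShapeNotArcLikeError
from .foci import Focus
from .segment import CellROI


# ---------------------------------------------------------------------------
# circle fitting


def fit_circle_taubin(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Weighted Taubin algebraic circle fit; returns (cx, cy, r).

    Solves the generalized eigenproblem of the Taubin functional on the
    (weighted) moments of the points; accurate and bias-free enough to serve
    as the starting point of one Gauss-Newton geometric refinement.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    w = w / w.sum()
    xm, ym = (w * x).sum(), (w * y).sum()
    u, v = x - xm, y - ym
    z = u * u + v * v
    Suu = (w * u * u).sum()
    Svv = (w * v * v).sum()
    Suv = (w * u * v).sum()
    Suz = (w * u * z).sum()
    Svz = (w * v * z).sum()
    # solve the 2x2 linear system for the center offset
    A = np.array([[Suu, Suv], [Suv, Svv]])
    b = 0.5 * np.array([Suz, Svz])
    try:
        uc, vc = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise ShapeNotArcLikeError("degenerate point set: circle fit is singular")
    r = math.sqrt(uc * uc + vc * vc + Suu + Svv)
    return xm + uc, ym + vc, r


def refine_circle_gauss_newton(x, y, w, cx, cy, r, n_iter: int = 3):
    """Gauss-Newton refinement of the weighted geometric circle fit."""
    w = np.asarray(w, float)
    w = w / w.sum()
    for _ in range(n_iter):
        dx, dy = x - cx, y - cy
        d = np.hypot(dx, dy)
        d = np.where(d < 1e-12, 1e-12, d)
        resid = d - r
        J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
        Jw = J * w[:, None]
        try:
            step, *_ = np.linalg.lstsq(Jw.T @ J, -(Jw.T @ resid), rcond=None)
        except np.linalg.LinAlgError:
            break
        cx, cy, r = cx + step[0], cy + step[1], r + step[2]
    return cx, cy, abs(r)


# ---------------------------------------------------------------------------


@dataclass
class Backbone:
    """Annular coordinate system for one cell's chromosome arc."""

    center_xy_px: tuple[float, float]
    radius_px: float  # intensity-weighted mean over supported bins
    radius_by_angle_px: np.ndarray  # (n_bins,), NaN where unsupported
    bin_intensity: np.ndarray
    support: np.ndarray  # bool per angular bin
    bin_edges_rad: np.ndarray  # (n_bins + 1,) over [-pi, pi]
    ori_angle_rad: float
    orientation_sign: int = 0  # set by align_and_flip; 0 = undetermined

    @property
    def n_bins(self) -> int:
        return self.support.size

    @property
    def bin_width_rad(self) -> float:
        return 2.0 * math.pi / self.n_bins

    @property
    def angular_coverage_deg(self) -> float:
        return float(self.support.sum()) * math.degrees(self.bin_width_rad)

    def contiguous_coverage_deg(self) -> float:
        return _longest_circular_run(self.support) * math.degrees(self.bin_width_rad)

    def supports_angle(self, angle: float) -> bool:
        idx = int((_wrap(angle) + math.pi) / self.bin_width_rad) % self.n_bins
        return bool(self.support[idx])


def _wrap(angle: float | np.ndarray):
    """Wrap to (-pi, pi]."""
    return -((-angle + math.pi) % (2.0 * math.pi) - math.pi)


def _longest_circular_run(mask: np.ndarray) -> int:
    if mask.all():
        return mask.size
    if not mask.any():
        return 0
    doubled = np.concatenate([mask, mask])
    best = run = 0
    for v in doubled[: 2 * mask.size]:
        run = run + 1 if v else 0
        best = max(best, run)
    return min(best, mask.size)


def fit_backbone(
    dna_image: np.ndarray,
    roi: CellROI,
    parb_focus: Focus,
    n_angular_bins: int = 72,
    support_median_fraction: float = 0.25,
    support_max_fraction: float = 0.10,
    min_radius_px: float = 4.0,
) -> Backbone:
    """Fit the annular backbone of the chromosome arc in one cell.

    Above-Otsu DNA pixels (within the cell mask) are circle-fitted (Taubin
    followed by Gauss-Newton refinement, intensity-weighted); each angular
    bin gets an intensity-weighted mean radius; bins whose integrated
    intensity exceeds ``max(support_median_fraction * median bin intensity,
    support_max_fraction * max bin intensity)`` form the angular support.
    The ori angle is the angle of the ParB focus about the fitted center.

    Raises :class:`ShapeNotArcLikeError` when fewer than 3 angular bins
    carry signal — such cells are excluded from backbone analysis.
    """
    img = np.asarray(dna_image, float)
    mask = roi.mask
    vals = img[mask]
    if vals.size == 0 or vals.max() <= vals.min():
        raise ShapeNotArcLikeError("no DNA signal in ROI")
    bg = float(np.median(vals))
    thr = threshold_otsu(vals)
    sel = mask & (img >= thr)
    ys, xs = np.nonzero(sel)
    if xs.size < 8:
        raise ShapeNotArcLikeError("too few above-threshold DNA pixels")
    w = img[sel] - bg
    cx, cy, r = fit_circle_taubin(xs.astype(float), ys.astype(float), w)
    cx, cy, r = refine_circle_gauss_newton(xs.astype(float), ys.astype(float), w, cx, cy, r)
    if r < min_radius_px:
        # a compact blob fits a degenerate tiny circle; the annular model
        # does not apply
        raise ShapeNotArcLikeError(
            f"fitted annulus radius {r:.2f} px below {min_radius_px} px; "
            "pattern is not arc-like"
        )

    # angular statistics use every masked pixel (background-subtracted), so
    # the dim chromosome tail is not clipped by the Otsu threshold
    ys, xs = np.nonzero(mask)
    w = np.clip(img[ys, xs] - bg, 0.0, None)
    ang = np.arctan2(ys - cy, xs - cx)
    rad = np.hypot(xs - cx, ys - cy)
    edges = np.linspace(-math.pi, math.pi, n_angular_bins + 1)
    idx = np.clip(np.digitize(ang, edges) - 1, 0, n_angular_bins - 1)
    bin_int = np.zeros(n_angular_bins)
    bin_wr = np.zeros(n_angular_bins)
    np.add.at(bin_int, idx, w)
    np.add.at(bin_wr, idx, w * rad)
    with np.errstate(invalid="ignore", divide="ignore"):
        radius_by_angle = np.where(bin_int > 0, bin_wr / np.maximum(bin_int, 1e-300), np.nan)
    t = max(
        support_median_fraction * float(np.median(bin_int)),
        support_max_fraction * float(bin_int.max()),
    )
    support = bin_int > t
    if support.sum() < 3:
        raise ShapeNotArcLikeError(
            f"signal concentrated in {int(support.sum())} angular bin(s); "
            "not arc-like"
        )
    mean_r = float((bin_wr[support].sum()) / bin_int[support].sum())
    ori_angle = math.atan2(parb_focus.y_px - cy, parb_focus.x_px - cx)
    return Backbone(
        center_xy_px=(float(cx), float(cy)),
        radius_px=mean_r,
        radius_by_angle_px=radius_by_angle,
        bin_intensity=bin_int,
        support=support,
        bin_edges_rad=edges,
        ori_angle_rad=float(ori_angle),
    )


# ---------------------------------------------------------------------------


@dataclass
class ContourProfile:
    """Per-channel intensity vs arc length from the origin.

    ``length_axis_um`` holds the left edges of the arc-length bins, starting
    at 0 (the ori).  Before :func:`align_and_flip`, ``positive`` and
    ``negative`` hold the raw per-µm intensities sampled in the two angular
    directions away from ori; afterwards only the chosen direction remains in
    ``positive`` and ``fold_increase`` is populated (mean 1 per channel over
    observed bins).  Unobserved bins (beyond the chromosome) are NaN.
    """

    cell_id: int
    length_axis_um: np.ndarray
    positive: dict[str, np.ndarray]
    negative: dict[str, np.ndarray]
    sampling_bin_um: float
    representative_length_um: float
    oriented: bool = False
    orientation_sign: int = 0
    fold_increase: dict[str, np.ndarray] | None = None

    def observed(self, channel: str) -> np.ndarray:
        return ~np.isnan(self.positive[channel])


def profile_along_backbone(
    images: dict[str, np.ndarray],
    backbone: Backbone,
    roi: CellROI,
    pixel_size_nm: float,
    bin_um: float = 0.13,
    representative_length_um: float = 3.5,
    cell_id: int = 0,
    oversample: int = 6,
) -> ContourProfile:
    """Sample per-channel intensity per unit arc length along the backbone.

    Every masked pixel is assigned an angular offset from the ori angle and
    an arc length ``s = |offset| * R`` (R = mean backbone radius); pixels are
    accumulated into arc-length bins separately for the two angular
    directions, and each bin's integral is divided by the bin arc length
    ("per unit annular section").  A bin counts as observed when its angular
    midpoint lies within the backbone's angular support; unobserved bins are
    NaN out to the fixed representative length.
    """
    if bin_um <= 0:
        raise ParameterError("bin_um must be > 0")
    if representative_length_um <= bin_um:
        raise ParameterError("representative_length_um must exceed bin_um")
    cx, cy = backbone.center_xy_px
    r_um = backbone.radius_px * pixel_size_nm / 1000.0
    n_bins = int(math.ceil(representative_length_um / bin_um))
    axis = np.arange(n_bins) * bin_um
    ys0, xs0 = np.nonzero(roi.mask)
    # wedge integration on a subpixel grid: each pixel's intensity is spread
    # over oversample**2 sample points, so wedge boundaries do not slice
    # whole pixels (keeps a uniform annulus flat to ~1%)
    off = (np.arange(oversample) + 0.5) / oversample - 0.5
    oy, ox = np.meshgrid(off, off, indexing="ij")
    ys = (ys0[:, None] + oy.ravel()[None, :]).ravel()
    xs = (xs0[:, None] + ox.ravel()[None, :]).ravel()
    delta = _wrap(np.arctan2(ys - cy, xs - cx) - backbone.ori_angle_rad)
    s_um = np.abs(delta) * r_um
    k = np.floor(s_um / bin_um).astype(int)
    pos_side = delta >= 0
    in_range = k < n_bins
    dtheta_bin = bin_um / r_um
    observed = {+1: np.zeros(n_bins, bool), -1: np.zeros(n_bins, bool)}
    for sign in (+1, -1):
        for b in range(n_bins):
            mid = backbone.ori_angle_rad + sign * (b + 0.5) * dtheta_bin
            if (b + 1) * dtheta_bin <= math.pi + 1e-9 and backbone.supports_angle(mid):
                observed[sign][b] = True
    positive: dict[str, np.ndarray] = {}
    negative: dict[str, np.ndarray] = {}
    for label, img in images.items():
        img = np.asarray(img, float)
        # robust per-cell background so empty wedge area does not flatten
        # dim parts of the profile
        pix = np.clip(img[ys0, xs0] - np.median(img[ys0, xs0]), 0.0, None)
        vals = np.repeat(pix / oversample**2, oversample**2)
        for sign, store in ((+1, positive), (-1, negative)):
            side = pos_side if sign > 0 else ~pos_side
            tot = np.zeros(n_bins)
            use = side & in_range
            np.add.at(tot, k[use], vals[use])
            arr = tot / bin_um
            arr[~observed[sign]] = np.nan
            store[label] = arr
    return ContourProfile(
        cell_id=cell_id,
        length_axis_um=axis,
        positive=positive,
        negative=negative,
        sampling_bin_um=bin_um,
        representative_length_um=representative_length_um,
    )


def align_and_flip(profile: ContourProfile, dna_channel: str = "DNA") -> ContourProfile:
    """Orient the profile so the chromosome extends toward positive length.

    The direction holding more total DNA intensity is kept as the positive
    axis; cells lying "upside down" (arc curling the other way) thereby
    produce identical profiles.  Idempotent: an already oriented profile is
    returned unchanged.
    """
    if profile.oriented:
        return profile
    pos_tot = np.nansum(profile.positive[dna_channel])
    neg_tot = np.nansum(profile.negative[dna_channel])
    sign = 1 if pos_tot >= neg_tot else -1
    chosen = profile.positive if sign > 0 else profile.negative
    fold = {}
    for label, arr in chosen.items():
        m = np.nanmean(arr)
        fold[label] = arr / m if m and np.isfinite(m) and m > 0 else np.full_like(arr, np.nan)
    return replace(
        profile,
        positive={k: v.copy() for k, v in chosen.items()},
        negative={},
        oriented=True,
        orientation_sign=sign,
        fold_increase=fold,
    )


def estimate_decay_length(
    profile: ContourProfile,
    channel: str = "DNA",
    skip_first: int = 1,
    skip_last: int = 2,
) -> float:
    """Exponential decay length (µm) from a log-linear fit of the profile.

    Interior observed bins are used (the first bin is dominated by the ori
    peak / PSF edge bleed, the last ones by the arc end), and the slope of
    ``log(intensity)`` vs arc length gives ``-1/lambda``.
    """
    if not profile.oriented:
        raise ParameterError("profile must be oriented (align_and_flip) first")
    y = profile.positive[channel]
    obs = np.flatnonzero(~np.isnan(y) & (y > 0))
    if obs.size < skip_first + skip_last + 3:
        raise ParameterError("too few observed bins for a decay fit")
    use = obs[skip_first : obs.size - skip_last]
    slope = np.polyfit(profile.length_axis_um[use], np.log(y[use]), 1)[0]
    if slope >= 0:
        return math.inf
    return -1.0 / slope


def profile_coordinate(
    backbone: Backbone, focus: Focus, pixel_size_nm: float, orientation_sign: int
) -> float:
    """Arc-length coordinate (µm, signed) of a focus projected on the backbone."""
    cx, cy = backbone.center_xy_px
    delta = _wrap(math.atan2(focus.y_px - cy, focus.x_px - cx) - backbone.ori_angle_rad)
    return delta * orientation_sign * backbone.radius_px * pixel_size_nm / 1000.0


def profiles_to_table(profiles: list[ContourProfile]) -> pd.DataFrame:
    """Long-format CSV-ready table (cell_id, channel, s_um, raw, fold)."""
    rows = []
    for p in profiles:
        for ch, arr in p.positive.items():
            fold = p.fold_increase[ch] if p.fold_increase else np.full_like(arr, np.nan)
            for s, raw, fi in zip(p.length_axis_um, arr, fold):
                rows.append(
                    {"cell_id": p.cell_id, "channel": ch, "s_um": s,
                     "raw_per_um": raw, "fold_increase": fi}
                )
    return pd.DataFrame(rows)
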