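"""Ground-truthed synthetic single-cell fluorescence images.

The generator emulates wide-field imaging of wall-less (L-form) *Bacillus
subtilis* cells whose chromosome is free to adopt its unconfined shape:
a spheroidal cell ~2.3 µm across containing a crescent-arc, toroidal, or
compact chromosome pattern, a single PSF-limited ParB focus marking the
replication origin at the crescent tip, and an SMC channel that tracks the
DNA with an adjustable fold-enrichment at the origin.

The image model is

    counts = Poisson( (ideal pattern) * PSF  +  background )  +  N(0, read_noise)

with an isotropic Gaussian PSF.  The chromosome is a one-dimensional density
along an arc, swept into a ribbon of Gaussian transverse width; condensed
regions ("clusters") are added as isotropic Gaussian blobs on the arc.  Every
rendered cell comes with a :class:`SimTruth` record (true origin position,
arc geometry, linear density, cluster table, noiseless channel totals) so
downstream estimators can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.ndimage import gaussian_filter

from .errors import ParameterError, PlacementError
from .stack import CELL, DNA, PARB, SMC, TER, ImageStack

ShapeClass = Literal["crescent", "toroid", "compact", "other"]

_DEFAULT_PHOTONS = {DNA: 2.0e5, SMC: 1.0e5, CELL: 3.0e5, TER: 2.0e4}


class SimParams(BaseModel):
    """All knobs of the single-cell simulator.

    Lengths are explicit about their unit in the field name.  Defaults follow
    the imaging conditions of the study this pipeline models: 65.35 nm/px
    pixels, 200 nm z steps, ~2.3 µm spheroidal cells, crescent arcs spanning
    90-180 degrees, and a 1.6-fold SMC enrichment at the origin.  Photon
    budgets and noise levels are not constrained by published numbers; the
    defaults put the brightest structures at mid-range SNR (peak arc signal
    tens of sigma above the shot-noise floor), see docs/methods.md.
    """

    model_config = ConfigDict(frozen=True)

    pixel_size_nm: float = 65.35
    image_shape: tuple[int, int] = (96, 96)  # (ny, nx)
    n_z: int = 1
    z_step_nm: float = 200.0
    cell_diameter_um: float = 2.3
    shape_class: ShapeClass = "crescent"
    arc_radius_um: float = 0.75
    arc_span_deg: Optional[float] = None  # crescent default: drawn from [90, 180]
    arc_width_sigma_nm: float = 80.0
    density_model: Literal["uniform", "exponential", "piecewise"] = "uniform"
    decay_length_um: float = 1.0
    piecewise_break: float = 0.5  # fraction of arc length where the level drops
    piecewise_ratio: float = 3.0  # density level before / after the break
    primary_cluster_fraction: float = 0.0
    secondary_clusters: tuple[tuple[float, float], ...] = ()  # (fraction, s/L)
    cluster_sigma_nm: float = 150.0
    n_ori_spots: int = 1
    include_ter: bool = False
    n_ter_spots: int = 1
    ter_spot_signal_fraction: float = 0.6  # remainder rendered as diffuse haze
    parb_photons: float = 3.0e4
    photon_budget: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_PHOTONS))
    smc_background_coupling: float = 1.0
    ori_enrichment: float = 1.6
    psf_sigma_nm: float = 120.0
    defocus_scale_nm: float = 400.0  # dz at which the PSF sigma grows by sqrt(2)
    shot_noise: bool = True
    read_noise_sigma: float = 3.0
    background_level: float = 20.0
    ori_angle_deg: Optional[float] = None  # drawn uniformly if None
    curl_sign: Optional[int] = None  # +1 ccw / -1 cw; drawn if None
    n_other_blobs: int = 4
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimParams":
        positive = [
            "pixel_size_nm", "z_step_nm", "cell_diameter_um", "arc_radius_um",
            "arc_width_sigma_nm", "decay_length_um", "cluster_sigma_nm",
            "parb_photons", "psf_sigma_nm", "defocus_scale_nm",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")
        for name in ("read_noise_sigma", "background_level"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for label, photons in self.photon_budget.items():
            if not photons > 0:
                raise ParameterError(f"photon_budget[{label!r}] must be strictly positive")
        if self.n_z < 1:
            raise ParameterError("n_z must be >= 1")
        if not 0.0 <= self.primary_cluster_fraction <= 1.0:
            raise ParameterError("primary_cluster_fraction must lie in [0, 1]")
        total = self.primary_cluster_fraction
        for frac, pos in self.secondary_clusters:
            if not 0.0 <= frac <= 1.0:
                raise ParameterError("secondary_clusters fractions must lie in [0, 1]")
            if not 0.0 <= pos <= 1.0:
                raise ParameterError("secondary_clusters positions are fractions of arc length in [0, 1]")
            total += frac
        if total > 1.0 + 1e-12:
            raise ParameterError("primary + secondary cluster fractions must be <= 1")
        if not 0.0 <= self.ter_spot_signal_fraction <= 1.0:
            raise ParameterError("ter_spot_signal_fraction must lie in [0, 1]")
        if self.arc_span_deg is not None and not 0.0 < self.arc_span_deg <= 360.0:
            raise ParameterError("arc_span_deg must lie in (0, 360]")
        if self.shape_class == "toroid" and self.arc_span_deg not in (None, 360.0):
            raise ParameterError("arc_span_deg: shape_class='toroid' forces arc_span_deg=360")
        if not 0.0 < self.piecewise_break < 1.0:
            raise ParameterError("piecewise_break must lie in (0, 1)")
        if self.curl_sign not in (None, 1, -1):
            raise ParameterError("curl_sign must be +1, -1 or None")
        if self.n_ori_spots < 0 or self.n_ter_spots < 0:
            raise ParameterError("n_ori_spots / n_ter_spots must be >= 0")
        return self


@dataclass
class SimTruth:
    """Ground truth attached to one rendered cell.

    ``s_grid_um`` / ``density`` / ``arc_xy_nm`` describe the linear DNA
    density along the arc (density sums to 1 over the grid); they are ``None``
    for non-arc shapes (compact / other).  The cluster table lists condensed
    blobs as (arc position µm, x nm, y nm, true DNA fraction, primary flag).
    """

    shape_label: ShapeClass
    ori_xy_nm: tuple[float, float]
    annulus_center_nm: tuple[float, float]
    arc_radius_nm: float
    arc_span_deg: float
    ori_angle_rad: float
    curl_sign: int
    cell_center_px: tuple[float, float]
    cell_radius_px: float
    s_grid_um: Optional[np.ndarray]
    density: Optional[np.ndarray]
    arc_xy_nm: Optional[np.ndarray]  # (N, 2)
    clusters: list[dict] = field(default_factory=list)
    channel_totals: dict[str, float] = field(default_factory=dict)
    extra_ori_xy_nm: list[tuple[float, float]] = field(default_factory=list)
    ter_xy_nm: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rendering helpers


def _deposit(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray, masses: np.ndarray) -> None:
    """Bilinear deposit of point masses onto a pixel canvas (in place)."""
    ny, nx = canvas.shape
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    for dy in (0, 1):
        for dx in (0, 1):
            w = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            xi = np.clip(x0 + dx, 0, nx - 1)
            yi = np.clip(y0 + dy, 0, ny - 1)
            np.add.at(canvas, (yi, xi), masses * w)


def _linear_density(params: SimParams, s: np.ndarray, arc_len_um: float) -> np.ndarray:
    """Unnormalized base density model on the arc-length grid (µm)."""
    if params.density_model == "uniform":
        base = np.ones_like(s)
    elif params.density_model == "exponential":
        base = np.exp(-s / params.decay_length_um)
    else:  # piecewise two-level profile
        base = np.where(s < params.piecewise_break * arc_len_um, params.piecewise_ratio, 1.0)
    return base


def _truncated_gaussian(s: np.ndarray, center: float, sigma: float) -> np.ndarray:
    g = np.exp(-0.5 * ((s - center) / sigma) ** 2)
    tot = g.sum()
    return g / tot if tot > 0 else g


def _psf_sigmas_px(params: SimParams) -> list[float]:
    """Per-z-plane effective PSF sigma (px); middle plane is in focus."""
    sig0 = params.psf_sigma_nm / params.pixel_size_nm
    out = []
    for i in range(params.n_z):
        dz = (i - (params.n_z - 1) / 2.0) * params.z_step_nm
        out.append(sig0 * math.sqrt(1.0 + (dz / params.defocus_scale_nm) ** 2))
    return out


def _render_channel(
    pre_canvas: np.ndarray, photons: float, sigmas_px: Sequence[float]
) -> np.ndarray:
    """Normalize a pre-PSF pattern to the photon budget and blur per plane."""
    tot = pre_canvas.sum()
    base = pre_canvas * (photons / tot) if tot > 0 else pre_canvas
    return np.stack([gaussian_filter(base, s, mode="constant", truncate=6.0) for s in sigmas_px])


def simulate_cell(params: SimParams) -> tuple[ImageStack, SimTruth]:
    """Render one synthetic cell; deterministic given ``params.seed``.

    Returns the image stack (channels DNA, PARB, SMC, CELL and optionally
    TER) together with the ground truth.  In the noiseless limit
    (``shot_noise=False``, ``read_noise_sigma=0``, ``background_level=0``)
    each channel integrates to its photon budget up to sub-ppm PSF edge loss.
    """
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_shape
    px = params.pixel_size_nm
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    cell_r_px = params.cell_diameter_um * 1000.0 / 2.0 / px
    psf_px = params.psf_sigma_nm / px
    sigmas = _psf_sigmas_px(params)

    # draw free geometry parameters (before any other rng use, so that the
    # same seed with explicit values matches)
    span = params.arc_span_deg
    if params.shape_class == "toroid":
        span = 360.0
    elif span is None:
        span = float(rng.uniform(90.0, 180.0)) if params.shape_class == "crescent" else 150.0
    ori_angle = (
        math.radians(params.ori_angle_deg)
        if params.ori_angle_deg is not None
        else float(rng.uniform(0.0, 2.0 * math.pi))
    )
    curl = params.curl_sign if params.curl_sign is not None else int(rng.choice([-1, 1]))

    arc_r_px = params.arc_radius_um * 1000.0 / px
    yy, xx = np.mgrid[0:ny, 0:nx]
    cell_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell_r_px**2

    pre = {label: np.zeros((ny, nx)) for label in (DNA, PARB, SMC)}
    pre[CELL] = cell_mask.astype(float)
    if params.include_ter:
        pre[TER] = np.zeros((ny, nx))

    clusters: list[dict] = []
    s_grid = density = arc_xy_nm = None
    ori_xy_px = (cx, cy)
    ter_anchor_px: Optional[tuple[float, float]] = None

    if params.shape_class in ("crescent", "toroid"):
        arc_len_um = arc_r_px * px / 1000.0 * math.radians(span)
        n_grid = max(512, int(arc_len_um * 1000 / 10))  # ~10 nm steps
        s_grid = np.linspace(0.0, arc_len_um, n_grid)
        theta = ori_angle + curl * (s_grid / (arc_r_px * px / 1000.0))
        arc_x = cx + arc_r_px * np.cos(theta)
        arc_y = cy + arc_r_px * np.sin(theta)
        arc_xy_nm = np.column_stack([arc_x, arc_y]) * px

        frac_clusters = params.primary_cluster_fraction + sum(
            f for f, _ in params.secondary_clusters
        )
        base = _linear_density(params, s_grid, arc_len_um)
        base = base / base.sum() * (1.0 - frac_clusters)
        density = base.copy()
        sigma_s_um = params.cluster_sigma_nm / 1000.0
        cluster_specs = []
        if params.primary_cluster_fraction > 0:
            cluster_specs.append((params.primary_cluster_fraction, 0.0, True))
        for frac, pos in params.secondary_clusters:
            cluster_specs.append((frac, pos, False))
        for frac, pos, primary in cluster_specs:
            s_c = pos * arc_len_um
            density += frac * _truncated_gaussian(s_grid, s_c, sigma_s_um)
            i_c = int(np.argmin(np.abs(s_grid - s_c)))
            clusters.append(
                {
                    "s_um": s_c,
                    "x_nm": arc_xy_nm[i_c, 0],
                    "y_nm": arc_xy_nm[i_c, 1],
                    "fraction": frac,
                    "primary": primary,
                }
            )
        # DNA pattern: ribbon (base density) + isotropic cluster blobs.
        ribbon = np.zeros((ny, nx))
        _deposit(ribbon, arc_x, arc_y, base)
        ribbon = gaussian_filter(ribbon, params.arc_width_sigma_nm / px, mode="constant", truncate=6.0)
        blobs = np.zeros((ny, nx))
        for (frac, pos, _), rec in zip(cluster_specs, clusters):
            blobs_i = np.zeros((ny, nx))
            _deposit(
                blobs_i,
                np.array([rec["x_nm"] / px]),
                np.array([rec["y_nm"] / px]),
                np.array([frac]),
            )
            pre_sigma = math.sqrt(max(params.cluster_sigma_nm**2 - params.psf_sigma_nm**2, 1.0)) / px
            blobs += gaussian_filter(blobs_i, pre_sigma, mode="constant", truncate=6.0)
        pre[DNA] = ribbon + blobs
        ori_xy_px = (float(arc_x[0]), float(arc_y[0]))
        ter_anchor_px = (float(arc_x[-1]), float(arc_y[-1]))

        # SMC linear density: follows DNA plus an origin-proximal component.
        # The fold-increase at the origin is a property of the *measured*
        # profile, so the component weight is solved against the
        # PSF-convolved density: blurred fold over the first 130 nm of arc
        # (2 px, a typical profile bin) relative to the blurred mean.
        from scipy.ndimage import gaussian_filter1d

        g0 = params.smc_background_coupling * density
        enrich = _truncated_gaussian(s_grid, 0.0, 0.25)
        ds_um = s_grid[1] - s_grid[0]
        sigma_bins = params.psf_sigma_nm / 1000.0 / ds_um
        blur_g0 = gaussian_filter1d(g0, sigma_bins, mode="constant")
        blur_e = gaussian_filter1d(enrich, sigma_bins, mode="constant")
        head = s_grid <= 0.130
        target = params.ori_enrichment
        a0, b0 = blur_g0[head].mean(), blur_e[head].mean()
        mean_a, mean_b = blur_g0.mean(), blur_e.mean()
        denom = b0 - target * mean_b
        beta = (target * mean_a - a0) / denom if denom > 0 else 0.0
        beta = max(beta, 0.0)
        g = g0 + beta * enrich
        smc = np.zeros((ny, nx))
        _deposit(smc, arc_x, arc_y, g)
        pre[SMC] = gaussian_filter(smc, params.arc_width_sigma_nm / px, mode="constant", truncate=6.0)
    else:
        # compact: one central blob; other: several scattered blobs.
        if params.shape_class == "compact":
            blob_xy = [(cx, cy)]
            fracs = [1.0]
        else:
            # dispersed/undefined pattern: blobs far enough apart that the
            # pattern does not read as a contiguous ribbon
            blob_xy = _scatter_points(
                rng, (cx, cy), 0.8 * cell_r_px, params.n_other_blobs,
                min_sep_px=700.0 / px,
            )
            w = rng.uniform(0.5, 1.5, size=len(blob_xy))
            fracs = list(w / w.sum())
        pat = np.zeros((ny, nx))
        for (bx, by), f in zip(blob_xy, fracs):
            one = np.zeros((ny, nx))
            _deposit(one, np.array([bx]), np.array([by]), np.array([f]))
            pre_sigma = math.sqrt(max(params.cluster_sigma_nm**2 - params.psf_sigma_nm**2, 1.0)) / px
            pat += gaussian_filter(one, pre_sigma, mode="constant", truncate=6.0)
        pre[DNA] = pat
        pre[SMC] = pat.copy()
        order = int(np.argmax(fracs))
        ori_xy_px = blob_xy[order]
        for (bx, by), f in zip(blob_xy, fracs):
            clusters.append(
                {"s_um": math.nan, "x_nm": bx * px, "y_nm": by * px,
                 "fraction": f, "primary": (bx, by) == ori_xy_px}
            )

    # ParB channel: one PSF-limited focus at ori (+ optional extra foci to
    # emulate cells with unresolved replication / multiple origins).
    ori_spots = [ori_xy_px]
    if params.n_ori_spots > 1:
        ori_spots += _scatter_points(
            rng, (cx, cy), 0.8 * cell_r_px, params.n_ori_spots - 1,
            min_sep_px=500.0 / px, avoid=[ori_xy_px],
        )
    if params.n_ori_spots >= 1:
        mass = np.full(len(ori_spots), 1.0 / len(ori_spots))
        _deposit(
            pre[PARB],
            np.array([p[0] for p in ori_spots]),
            np.array([p[1] for p in ori_spots]),
            mass,
        )

    ter_spots: list[tuple[float, float]] = []
    if params.include_ter and params.n_ter_spots >= 1:
        anchor = ter_anchor_px if ter_anchor_px is not None else (cx, cy)
        ter_spots = [anchor]
        if params.n_ter_spots > 1:
            ter_spots += _scatter_points(
                rng, (cx, cy), 0.8 * cell_r_px, params.n_ter_spots - 1,
                min_sep_px=500.0 / px, avoid=[anchor],
            )
        mass = np.full(len(ter_spots), params.ter_spot_signal_fraction / len(ter_spots))
        _deposit(
            pre[TER],
            np.array([p[0] for p in ter_spots]),
            np.array([p[1] for p in ter_spots]),
            mass,
        )
        # diffuse haze over the cell body, emulating the low-SNR ter label
        haze = cell_mask.astype(float)
        haze = haze / haze.sum() * (1.0 - params.ter_spot_signal_fraction)
        pre[TER] += haze

    budgets = dict(_DEFAULT_PHOTONS)
    budgets.update(params.photon_budget)
    budgets[PARB] = params.parb_photons

    labels = [DNA, PARB, SMC, CELL] + ([TER] if params.include_ter else [])
    planes = []
    totals: dict[str, float] = {}
    for label in labels:
        ideal = _render_channel(pre[label], budgets[label], sigmas)
        totals[label] = float(ideal.sum() / params.n_z)
        noisy = ideal + params.background_level
        if params.shot_noise:
            noisy = rng.poisson(noisy).astype(np.float64)
        if params.read_noise_sigma > 0:
            noisy = noisy + rng.normal(0.0, params.read_noise_sigma, size=noisy.shape)
        planes.append(np.clip(noisy, 0.0, None))

    stack = ImageStack(
        np.stack(planes),
        labels,
        pixel_size_nm=px,
        z_step_nm=params.z_step_nm if params.n_z > 1 else None,
    )
    truth = SimTruth(
        shape_label=params.shape_class,
        ori_xy_nm=(ori_xy_px[0] * px, ori_xy_px[1] * px),
        annulus_center_nm=(cx * px, cy * px),
        arc_radius_nm=arc_r_px * px,
        arc_span_deg=span,
        ori_angle_rad=ori_angle,
        curl_sign=curl,
        cell_center_px=(cx, cy),
        cell_radius_px=cell_r_px,
        s_grid_um=s_grid,
        density=density / density.sum() if density is not None else None,
        arc_xy_nm=arc_xy_nm,
        clusters=clusters,
        channel_totals=totals,
        extra_ori_xy_nm=[(x * px, y * px) for x, y in ori_spots[1:]],
        ter_xy_nm=[(x * px, y * px) for x, y in ter_spots],
    )
    return stack, truth


def _scatter_points(rng, center, radius_px, n, min_sep_px, avoid=(), max_tries=2000):
    """Rejection-sample n points in a disc with a minimum mutual separation."""
    pts: list[tuple[float, float]] = []
    existing = list(avoid)
    for _ in range(max_tries):
        if len(pts) == n:
            break
        r = radius_px * math.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * math.pi)
        p = (center[0] + r * math.cos(a), center[1] + r * math.sin(a))
        if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep_px for q in existing + pts):
            pts.append(p)
    if len(pts) < n:
        raise PlacementError(
            f"could not place {n} points with {min_sep_px:.1f} px separation"
        )
    return pts


# ---------------------------------------------------------------------------
# populations


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Reproducible per-cell seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n, dtype=np.uint32)]


def simulate_condition(
    params_grid: Sequence[SimParams] | SimParams,
    n_cells: int,
    seed: int,
) -> tuple[list[tuple[ImageStack, SimTruth]], dict]:
    """Simulate a population of cells plus a manifest.

    Templates from ``params_grid`` are assigned round-robin, so a 2-template
    grid with ``n_cells=100`` yields 50 cells of each.  Per-cell seeds derive
    reproducibly from ``seed``; ``n_cells=1`` reproduces ``simulate_cell``
    for the derived seed exactly.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if isinstance(params_grid, SimParams):
        params_grid = [params_grid]
    seeds = derive_seeds(seed, n_cells)
    cells = []
    records = []
    counts: dict[str, int] = {}
    for i in range(n_cells):
        template = params_grid[i % len(params_grid)]
        p = template.model_copy(update={"seed": seeds[i]})
        cells.append(simulate_cell(p))
        counts[p.shape_class] = counts.get(p.shape_class, 0) + 1
        records.append(
            {"index": i, "seed": seeds[i], "shape_class": p.shape_class,
             "params": p.model_dump(mode="json")}
        )
    manifest = {
        "master_seed": seed,
        "n_cells": n_cells,
        "class_counts": counts,
        "cells": records,
    }
    return cells, manifest


def composite_field(
    cells: Sequence[tuple[ImageStack, SimTruth]],
    fov_shape: tuple[int, int],
    margin_px: int = 2,
) -> tuple[ImageStack, list[SimTruth]]:
    """Tile single-cell stacks onto one field of view without mask overlap.

    Cells are placed on a regular grid; raises :class:`PlacementError` when
    the field cannot hold them all.  Truth coordinates are shifted to the
    field frame.
    """
    if not cells:
        raise PlacementError("no cells to composite")
    tile_y, tile_x = cells[0][0].shape_yx
    labels = cells[0][0].channel_labels
    n_z = cells[0][0].n_z
    px = cells[0][0].pixel_size_nm
    ny, nx = fov_shape
    per_row = (nx - margin_px) // (tile_x + margin_px)
    per_col = (ny - margin_px) // (tile_y + margin_px)
    if per_row * per_col < len(cells):
        raise PlacementError(
            f"field {fov_shape} holds {per_row * per_col} tiles of "
            f"{(tile_y, tile_x)}, but {len(cells)} cells were requested"
        )
    canvas = np.zeros((len(labels), n_z, ny, nx))
    truths = []
    for k, (stack, truth) in enumerate(cells):
        row, col = divmod(k, per_row)
        y0 = margin_px + row * (tile_y + margin_px)
        x0 = margin_px + col * (tile_x + margin_px)
        canvas[:, :, y0 : y0 + tile_y, x0 : x0 + tile_x] += stack.pixels
        dx_nm, dy_nm = x0 * px, y0 * px
        t = SimTruth(**{**truth.__dict__})
        t.ori_xy_nm = (truth.ori_xy_nm[0] + dx_nm, truth.ori_xy_nm[1] + dy_nm)
        t.annulus_center_nm = (
            truth.annulus_center_nm[0] + dx_nm,
            truth.annulus_center_nm[1] + dy_nm,
        )
        t.cell_center_px = (truth.cell_center_px[0] + x0, truth.cell_center_px[1] + y0)
        if truth.arc_xy_nm is not None:
            t.arc_xy_nm = truth.arc_xy_nm + np.array([dx_nm, dy_nm])
        truths.append(t)
    stack = ImageStack(canvas, list(labels), px, cells[0][0].z_step_nm)
    return stack, truths


def simulate_spot_pair(
    separation_nm: float,
    photons: float = 3.0e4,
    psf_sigma_nm: float = 120.0,
    pixel_size_nm: float = 65.35,
    image_shape: tuple[int, int] = (48, 48),
    background_level: float = 20.0,
    read_noise_sigma: float = 3.0,
    shot_noise: bool = True,
    angle_deg: Optional[float] = None,
    seed: int = 0,
) -> tuple[ImageStack, tuple[tuple[float, float], tuple[float, float]]]:
    """Two PSF-limited foci in *separate* channels at a known separation.

    Emulates a two-color colocalization measurement (e.g. a ParB focus and
    the nearest SMC focus): at ~126 nm the pair is far below the one-channel
    two-point resolution, so each channel holds exactly one spot and the
    distance is measured between the per-channel localizations.
    """
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ang = math.radians(angle_deg) if angle_deg is not None else rng.uniform(0, 2 * math.pi)
    jx, jy = rng.uniform(-0.5, 0.5, size=2)
    d_px = separation_nm / pixel_size_nm
    pa = (cx + jx, cy + jy)
    pb = (pa[0] + d_px * math.cos(ang), pa[1] + d_px * math.sin(ang))
    sig = psf_sigma_nm / pixel_size_nm
    planes = []
    for pos in (pa, pb):
        canvas = np.zeros((ny, nx))
        _deposit(canvas, np.array([pos[0]]), np.array([pos[1]]), np.array([1.0]))
        ideal = gaussian_filter(canvas, sig, mode="constant", truncate=6.0) * photons
        noisy = ideal + background_level
        if shot_noise:
            noisy = rng.poisson(noisy).astype(np.float64)
        if read_noise_sigma > 0:
            noisy = noisy + rng.normal(0.0, read_noise_sigma, size=noisy.shape)
        planes.append(np.clip(noisy, 0.0, None)[np.newaxis])
    stack = ImageStack(np.stack(planes), ["A", "B"], pixel_size_nm)
    truth = (
        (pa[0] * pixel_size_nm, pa[1] * pixel_size_nm),
        (pb[0] * pixel_size_nm, pb[1] * pixel_size_nm),
    )
    return stack, truth
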