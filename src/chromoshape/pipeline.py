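"""End-to-end pipeline: images in, per-cell tables and summaries out.

Stage order mirrors the acquisition protocol this package models: cell
selection, roundness screening, single-ParB (single-chromosome) selection,
backbone profiling, cluster decomposition, demograph stacking and shape
classification.  Every excluded cell is recorded with a reason, and the
screening funnel (detected >= round pass >= single ParB >= profiled) lands
in the run manifest.  Given a fixed configuration and seed the run is fully
reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .backbone import (
    align_and_flip,
    fit_backbone,
    profile_along_backbone,
    profiles_to_table,
)
from .clusters import (
    PSF_FWHM_FACTOR,
    clusters_to_table,
    decompose_spots,
    fraction_within_radius,
    group_clusters,
    primary_cluster_stats,
)
from .config import PipelineConfig
from .demograph import build_demograph, demograph_to_frame
from .errors import ChromoshapeError, ShapeNotArcLikeError
from .foci import detect_foci, foci_to_table
from .segment import detect_cells, max_project, screen_round, select_single_chromosome
from .shapeclass import bootstrap_ratio, calls_to_table, classify_shape
from .simgen import SimParams, simulate_condition
from .stack import ImageStack, read_stack

log = logging.getLogger("chromoshape")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    version: str
    seed: int
    funnel: dict[str, int] = field(default_factory=dict)
    cells: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    rois: pd.DataFrame
    foci: pd.DataFrame
    profiles: list
    profile_table: pd.DataFrame
    clusters: pd.DataFrame
    cluster_stats: pd.DataFrame
    demographs: dict
    shape_calls: list
    shape_table: pd.DataFrame
    bootstrap: object | None


def _mix_templates(cfg: PipelineConfig) -> list[SimParams]:
    """Turn a class-mix dict into a round-robin template list (per mille)."""
    sim = cfg.simulate
    base = sim.params.model_copy(
        update={"pixel_size_nm": cfg.pixel_size_nm, "psf_sigma_nm": cfg.psf_sigma_nm}
    )
    mix = sim.class_mix
    total = sum(mix.values())
    templates: list[SimParams] = []
    n = sim.n_cells
    alloc = {k: int(math.floor(v / total * n)) for k, v in mix.items()}
    rem = n - sum(alloc.values())
    for k in sorted(mix, key=mix.get, reverse=True):
        if rem <= 0:
            break
        alloc[k] += 1
        rem -= 1
    # interleave classes so round-robin assignment matches the allocation
    pools = {k: v for k, v in alloc.items() if v > 0}
    while pools:
        for k in list(pools):
            templates.append(base.model_copy(update={"shape_class": k}))
            pools[k] -= 1
            if pools[k] == 0:
                del pools[k]
    return templates


def _load_inputs(cfg: PipelineConfig) -> list[tuple[ImageStack, None]]:
    out = []
    for path in cfg.input_paths:
        out.append((read_stack(path, cfg.channel_map, cfg.pixel_size_nm), None))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; per-cell errors are logged, not fatal."""
    ch = config.channels
    psf_px = config.psf_sigma_nm / config.pixel_size_nm
    if config.input_paths:
        fields = _load_inputs(config)
    elif config.simulate is not None:
        templates = _mix_templates(config)
        cells, _ = simulate_condition(templates, config.simulate.n_cells, config.seed)
        fields = [(stack, truth) for stack, truth in cells]
    else:
        fields = []

    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__, seed=config.seed
    )
    roi_rows, all_foci, profiles, cluster_rows, stat_rows, calls = [], [], [], [], [], []
    n_detected = n_round = n_single = n_profiled = 0
    cell_uid = 0
    link_radius = (
        PSF_FWHM_FACTOR * psf_px if config.clusters.link_radius == "fwhm" else psf_px
    )

    for field_idx, (stack, truth) in enumerate(fields):
        rois = detect_cells(
            stack,
            channel=ch["cell"],
            threshold_method=config.segment.threshold_method,
            min_area_um2=config.segment.min_area_um2,
        )
        n_detected += len(rois)
        kept = screen_round(rois, config.segment.roundness_min)
        n_round += len(kept)
        for roi in kept:
            uid = cell_uid
            cell_uid += 1
            record = {"cell_id": uid, "field": field_idx, "accepted": False, "reason": ""}
            roi_rows.append(
                {
                    "cell_id": uid,
                    "field": field_idx,
                    "centroid_x_px": roi.centroid_xy_px[0],
                    "centroid_y_px": roi.centroid_xy_px[1],
                    "area_um2": roi.area_um2,
                    "roundness": roi.roundness,
                }
            )
            parb_proj = max_project(stack, ch["parb"])
            if not select_single_chromosome(
                roi, parb_proj, psf_px, config.foci.min_prominence, config.pixel_size_nm
            ):
                record["reason"] = "not exactly one ParB focus"
                manifest.cells.append(record)
                log.info("cell %d excluded: %s", uid, record["reason"])
                continue
            n_single += 1
            parb = detect_foci(
                parb_proj, roi.mask, psf_px, config.foci.min_prominence,
                config.pixel_size_nm, uid, ch["parb"], config.foci.refine,
            )[0]
            all_foci.append(parb)
            dna_proj = max_project(stack, ch["dna"])
            try:
                bb = fit_backbone(
                    dna_proj, roi, parb,
                    config.backbone.n_angular_bins,
                    config.backbone.support_median_fraction,
                    config.backbone.support_max_fraction,
                )
            except ShapeNotArcLikeError as exc:
                record["reason"] = f"backbone: {exc}"
                calls.append(classify_shape(dna_proj, roi, config.shapeclass, uid))
                manifest.cells.append(record)
                log.info("cell %d excluded from profiling: %s", uid, exc)
                continue
            images = {"DNA": dna_proj, "SMC": max_project(stack, ch["smc"]),
                      "PARB": parb_proj}
            profile = align_and_flip(
                profile_along_backbone(
                    images, bb, roi, config.pixel_size_nm,
                    config.backbone.bin_um, config.backbone.representative_length_um,
                    cell_id=uid,
                )
            )
            profiles.append(profile)
            n_profiled += 1
            spot_set = decompose_spots(
                dna_proj, roi.mask, psf_px, config.clusters.stop_snr,
                config.clusters.max_spots, config.pixel_size_nm, uid,
            )
            cls = group_clusters(spot_set, link_radius, (parb.x_nm, parb.y_nm))
            cluster_rows.append(clusters_to_table(cls, uid))
            stats = primary_cluster_stats(
                cls, parb, bb, config.pixel_size_nm, profile.orientation_sign
            )
            stats.insert(0, "cell_id", uid)
            stats["fraction_within_500nm"] = fraction_within_radius(
                dna_proj, roi.mask, (parb.x_px, parb.y_px), 500.0, config.pixel_size_nm
            )
            stat_rows.append(stats)
            calls.append(classify_shape(dna_proj, roi, config.shapeclass, uid))
            record.update(accepted=True, reason="")
            manifest.cells.append(record)

    manifest.funnel = {
        "detected": n_detected,
        "round_pass": n_round,
        "single_parb": n_single,
        "profiled": n_profiled,
    }
    demographs = {}
    if profiles:
        for label in ("DNA", "SMC", "PARB"):
            try:
                demographs[label] = build_demograph(
                    profiles, label, config.demograph.order,
                    config.demograph.contrast_method,
                )
            except ChromoshapeError:
                pass
    boot = None
    if calls:
        try:
            boot = bootstrap_ratio(
                calls, config.bootstrap.picks_per_series, config.bootstrap.n_boot,
                seed=config.seed,
            )
        except ChromoshapeError as exc:
            log.warning("bootstrap skipped: %s", exc)

    result = PipelineResult(
        manifest=manifest,
        rois=pd.DataFrame(roi_rows),
        foci=foci_to_table(all_foci),
        profiles=profiles,
        profile_table=profiles_to_table(profiles),
        clusters=pd.concat(cluster_rows, ignore_index=True) if cluster_rows else pd.DataFrame(),
        cluster_stats=pd.concat(stat_rows, ignore_index=True) if stat_rows else pd.DataFrame(),
        demographs=demographs,
        shape_calls=calls,
        shape_table=calls_to_table(calls),
        bootstrap=boot,
    )
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(result.manifest.to_json())
    result.rois.to_csv(out / "rois.csv", index=False)
    result.foci.to_csv(out / "foci.csv", index=False)
    result.profile_table.to_csv(out / "profiles.csv", index=False)
    result.clusters.to_csv(out / "clusters.csv", index=False)
    result.cluster_stats.to_csv(out / "cluster_stats.csv", index=False)
    result.shape_table.to_csv(out / "shape_calls.csv", index=False)
    for label, dg in result.demographs.items():
        demograph_to_frame(dg).to_csv(out / f"demograph_{label}.csv")
        pd.DataFrame(
            {"s_um": dg.length_axis_um, "mean_fold_increase": dg.mean_profile}
        ).to_csv(out / f"mean_profile_{label}.csv", index=False)
    if result.bootstrap is not None:
        b = result.bootstrap
        (out / "bootstrap.json").write_text(
            json.dumps(
                {
                    "condition": b.condition,
                    "n_cells": b.n_cells,
                    "counts": b.counts,
                    "ratio_mean": b.ratio_mean,
                    "ratio_se": b.ratio_se,
                    "n_boot": b.n_boot,
                    "picks_per_series": b.picks_per_series,
                },
                indent=2,
            )
        )
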