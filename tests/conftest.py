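"""Shared fixtures: default geometry and a one-cell analysis helper."""

from __future__ import annotations

import numpy as np
import pytest

import chromoshape as cs
from chromoshape.backbone import align_and_flip, fit_backbone, profile_along_backbone
from chromoshape.foci import detect_foci
from chromoshape.segment import detect_cells, max_project, screen_round

PIXEL_SIZE_NM = 65.35
PSF_SIGMA_NM = 120.0
PSF_PX = PSF_SIGMA_NM / PIXEL_SIZE_NM

NOISELESS = {"shot_noise": False, "read_noise_sigma": 0.0, "background_level": 0.0}


@pytest.fixture
def psf_px() -> float:
    return PSF_PX


@pytest.fixture
def crescent_params() -> cs.SimParams:
    return cs.SimParams(seed=11, shape_class="crescent", arc_span_deg=150,
                        ori_angle_deg=25, curl_sign=1)


def analyze_cell(stack, channels=("DNA",), **profile_kw):
    """Segment -> ParB focus -> backbone -> oriented profile for one cell."""
    rois = screen_round(detect_cells(stack))
    assert len(rois) == 1
    roi = rois[0]
    parb_proj = max_project(stack, "PARB")
    parb = detect_foci(parb_proj, roi.mask, PSF_PX, cell_id=roi.id, channel="PARB")[0]
    dna = max_project(stack, "DNA")
    bb = fit_backbone(dna, roi, parb)
    images = {"DNA": dna}
    for label in channels:
        if label != "DNA":
            images[label] = max_project(stack, label)
    profile = align_and_flip(
        profile_along_backbone(images, bb, roi, PIXEL_SIZE_NM, **profile_kw)
    )
    return roi, parb, bb, profile


def observed(profile, channel="DNA") -> np.ndarray:
    arr = profile.fold_increase[channel]
    return arr[~np.isnan(arr)]
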