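"""Cell detection, roundness screening and single-chromosome selection."""

import numpy as np
import pytest

import chromoshape as cs
from chromoshape.errors import InputError
from chromoshape.segment import (
    detect_cells,
    max_project,
    roi_from_mask,
    screen_round,
    select_single_chromosome,
)

from conftest import NOISELESS, PIXEL_SIZE_NM, PSF_PX


def _stack_from_plane(plane):
    return cs.ImageStack(plane[np.newaxis, np.newaxis], ["CELL"], PIXEL_SIZE_NM)


def test_all_zero_image_yields_no_cells():
    assert detect_cells(_stack_from_plane(np.zeros((64, 64)))) == []


def test_missing_channel_is_an_input_error():
    with pytest.raises(InputError, match="DNA"):
        detect_cells(_stack_from_plane(np.zeros((8, 8))), channel="DNA")


def test_single_spheroid_diameter_recovered_within_10pct():
    p = cs.SimParams(seed=1, **NOISELESS)
    stack, truth = cs.simulate_cell(p)
    rois = detect_cells(stack)
    assert len(rois) == 1
    assert rois[0].equivalent_diameter_um == pytest.approx(2.3, rel=0.10)
    # oracle: pixel count of the true circular mask
    ny, nx = stack.shape_yx
    yy, xx = np.mgrid[0:ny, 0:nx]
    cxp, cyp = truth.cell_center_px
    true_area = ((xx - cxp) ** 2 + (yy - cyp) ** 2 <= truth.cell_radius_px**2).sum()
    assert rois[0].area_px == pytest.approx(true_area, rel=0.10)


def test_two_cells_give_two_disjoint_rois():
    cells, _ = cs.simulate_condition(cs.SimParams(seed=2), 2, seed=2)
    stack, _ = cs.composite_field(cells, (110, 210))
    rois = detect_cells(stack)
    assert len(rois) == 2
    assert not (rois[0].mask & rois[1].mask).any()


def test_segmentation_intensity_scale_invariance():
    p = cs.SimParams(seed=3)
    stack, _ = cs.simulate_cell(p)
    rois = detect_cells(stack)
    scaled = stack.with_pixels(stack.pixels * 7.3)
    rois2 = detect_cells(scaled)
    assert len(rois) == len(rois2) == 1
    assert np.array_equal(rois[0].mask, rois2[0].mask)


def test_disc_retained_rectangle_rejected_by_roundness():
    canvas = np.zeros((64, 64), bool)
    yy, xx = np.mgrid[0:64, 0:64]
    canvas[(xx - 30) ** 2 + (yy - 30) ** 2 <= 20**2] = True
    disc = roi_from_mask(canvas, PIXEL_SIZE_NM)
    assert disc.roundness > 0.95
    assert screen_round([disc], 0.85)

    rect = np.zeros((64, 110), bool)
    rect[20:40, 10:90] = True  # 4:1 aspect
    r = roi_from_mask(rect, PIXEL_SIZE_NM)
    # closed-form roundness of an a x b rectangle: 4*pi*ab / (2a+2b)^2;
    # the Crofton perimeter estimate is good to ~10% at sharp corners
    a, b = 80.0, 20.0
    closed_form = 4 * np.pi * a * b / (2 * a + 2 * b) ** 2
    assert r.roundness == pytest.approx(closed_form, rel=0.15)
    assert screen_round([r], 0.85) == []


def test_screen_round_is_an_idempotent_filter():
    p = cs.SimParams(seed=4)
    stack, _ = cs.simulate_cell(p)
    rois = detect_cells(stack)
    once = screen_round(rois, 0.85)
    twice = screen_round(once, 0.85)
    assert [r.id for r in twice] == [r.id for r in once]
    assert set(r.id for r in once) <= set(r.id for r in rois)
    assert screen_round([], 0.9) == []


def test_max_projection_dominates_every_plane():
    rng = np.random.default_rng(0)
    arr = rng.uniform(size=(1, 3, 8, 8))
    stack = cs.ImageStack(arr, ["DNA"], PIXEL_SIZE_NM, z_step_nm=200.0)
    proj = max_project(stack, "DNA")
    # brute-force per-pixel check against each plane
    for z in range(3):
        assert np.all(proj >= arr[0, z])
    assert np.array_equal(proj, np.max(arr[0], axis=0))
    single = cs.ImageStack(arr[:, :1], ["DNA"], PIXEL_SIZE_NM)
    assert np.array_equal(max_project(single, "DNA"), arr[0, 0])


@pytest.mark.parametrize(
    "n_spots,expected", [(1, True), (2, False), (0, False)]
)
def test_single_parb_selection(n_spots, expected):
    p = cs.SimParams(seed=5, n_ori_spots=max(n_spots, 1))
    stack, _ = cs.simulate_cell(p)
    rois = detect_cells(stack)
    roi = rois[0]
    if n_spots == 0:
        parb = np.zeros(stack.shape_yx)
    else:
        parb = max_project(stack, "PARB")
    got = select_single_chromosome(roi, parb, PSF_PX, pixel_size_nm=PIXEL_SIZE_NM)
    assert got is expected
    assert roi.flags["single_parb_pass"] is expected
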