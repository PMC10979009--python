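"""Sub-pixel focus detection, the 15% signal filter, distances and ratios."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import chromoshape as cs
from chromoshape.errors import ParameterError, UsageError
from chromoshape.foci import (
    Focus,
    count_and_ratio,
    detect_foci,
    filter_foci_by_fraction,
    focus_distance,
)

from conftest import PIXEL_SIZE_NM, PSF_PX


def _render_spots(shape, spots, psf_px=PSF_PX, photons=3e4):
    """Noiseless spot image: delta deposits blurred by the PSF."""
    canvas = np.zeros(shape)
    for x, y, w in spots:
        x0, y0 = int(math.floor(x)), int(math.floor(y))
        fx, fy = x - x0, y - y0
        for dy in (0, 1):
            for dx in (0, 1):
                canvas[y0 + dy, x0 + dx] += (
                    w * (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                )
    return gaussian_filter(canvas, psf_px, mode="constant", truncate=6.0) * photons


def test_single_noiseless_spot_localized_within_0p2_px():
    img = _render_spots((64, 64), [(30.4, 17.6, 1.0)])
    foci = detect_foci(img, np.ones_like(img, bool), PSF_PX)
    assert len(foci) == 1
    assert math.hypot(foci[0].x_px - 30.4, foci[0].y_px - 17.6) <= 0.2


def test_gaussian_fit_refinement_matches_truth():
    img = _render_spots((64, 64), [(30.4, 17.6, 1.0)])
    foci = detect_foci(img, np.ones_like(img, bool), PSF_PX, refine="gauss")
    assert len(foci) == 1
    assert math.hypot(foci[0].x_px - 30.4, foci[0].y_px - 17.6) <= 0.2


def test_blank_region_has_no_foci():
    assert detect_foci(np.zeros((32, 32)), np.ones((32, 32), bool), PSF_PX) == []


def test_psf_sigma_must_be_positive():
    with pytest.raises(ParameterError):
        detect_foci(np.zeros((8, 8)), np.ones((8, 8), bool), 0.0)


def test_two_equal_spots_split_signal_evenly():
    d = 3.0 * PSF_PX
    img = _render_spots((64, 64), [(24.0, 32.0, 1.0), (24.0 + d, 32.0, 1.0)])
    foci = detect_foci(img, np.ones_like(img, bool), PSF_PX)
    assert len(foci) == 2
    for f in foci:
        assert f.fraction_of_cell_signal == pytest.approx(0.5, abs=0.05)


def test_translation_equivariance_whole_pixels():
    img = _render_spots((64, 64), [(24.3, 30.7, 1.0)])
    shifted = np.roll(np.roll(img, 5, axis=1), -3, axis=0)
    f0 = detect_foci(img, np.ones_like(img, bool), PSF_PX)[0]
    f1 = detect_foci(shifted, np.ones_like(img, bool), PSF_PX)[0]
    assert f1.x_px - f0.x_px == pytest.approx(5.0, abs=1e-9)
    assert f1.y_px - f0.y_px == pytest.approx(-3.0, abs=1e-9)


def test_fractions_invariant_to_intensity_rescaling():
    img = _render_spots((64, 64), [(20.0, 20.0, 1.0), (44.0, 40.0, 0.5)])
    a = detect_foci(img, np.ones_like(img, bool), PSF_PX)
    b = detect_foci(img * 123.4, np.ones_like(img, bool), PSF_PX)
    for fa, fb in zip(a, b):
        assert fa.fraction_of_cell_signal == pytest.approx(
            fb.fraction_of_cell_signal, abs=1e-6
        )


def _toy(fraction):
    return Focus(0, "TER", 0, 0, 0, 0, 100.0, fraction)


def test_fraction_filter_threshold_semantics():
    foci = [_toy(0.50), _toy(0.30), _toy(0.10)]
    kept = filter_foci_by_fraction(foci, 0.15)
    assert [f.fraction_of_cell_signal for f in kept] == [0.50, 0.30]
    assert filter_foci_by_fraction([_toy(0.0)] * 3, 0.15) == []
    assert filter_foci_by_fraction(foci, 0.0) == foci
    # idempotent
    assert filter_foci_by_fraction(kept, 0.15) == kept


def test_focus_distance_arithmetic():
    f1 = Focus(1, "A", 0.0, 0.0, 0.0, 0.0, 1.0, 1.0)
    f2 = Focus(1, "B", 3.0, 4.0, 0.0, 0.0, 1.0, 1.0)
    assert focus_distance(f1, f1, PIXEL_SIZE_NM) == 0.0
    assert focus_distance(f1, f2, 65.35) == pytest.approx(326.75)
    f3 = Focus(2, "B", 3.0, 4.0, 0.0, 0.0, 1.0, 1.0)
    with pytest.raises(UsageError):
        focus_distance(f1, f3, PIXEL_SIZE_NM)


def test_spot_pair_distance_recovery_at_paper_scale():
    """Cross-channel pairs at 126 nm separation recover within 30 nm."""
    errs = []
    for seed in range(20):
        stack, _ = cs.simulate_spot_pair(126.0, seed=seed)
        mask = np.ones(stack.shape_yx, bool)
        fa = detect_foci(stack.plane("A"), mask, PSF_PX)[0]
        fb = detect_foci(stack.plane("B"), mask, PSF_PX)[0]
        d = math.hypot(fa.x_nm - fb.x_nm, fa.y_nm - fb.y_nm)
        errs.append(abs(d - 126.0))
    assert np.mean(errs) < 30.0


def _fake_cells(spec):
    """spec: list of (n_ori, [ter fractions])."""
    cells = {}
    for i, (n_ori, ter_fracs) in enumerate(spec):
        cells[i] = {
            "PARB": [Focus(i, "PARB", 0, 0, 0, 0, 1.0, 1.0)] * n_ori,
            "TER": [Focus(i, "TER", 0, 0, 0, 0, 1.0, f) for f in ter_fracs],
        }
    return cells


def test_count_and_ratio_toy_tables():
    summary, ratio = count_and_ratio(_fake_cells([(2, [0.5])] * 5))
    assert ratio == 2.0
    summary, ratio = count_and_ratio(_fake_cells([(1, [0.5])] * 5))
    assert ratio == 1.0  # halted replication: one chromosome
    assert summary.mean["PARB"] == 1.0
    # ter filter removes sub-15% spots before counting
    summary, ratio = count_and_ratio(_fake_cells([(2, [0.5, 0.05])] * 4))
    assert ratio == 2.0
    with pytest.warns(UserWarning, match="undefined"):
        _, ratio = count_and_ratio(_fake_cells([(1, [0.05])] * 3))
    assert ratio is None


def test_count_and_ratio_per_cell_mode():
    cells = _fake_cells([(4, [0.5]), (2, [0.5, 0.4])])
    _, pooled = count_and_ratio(cells)
    _, per_cell = count_and_ratio(cells, mode="per_cell")
    assert pooled == pytest.approx(6 / 3)
    assert per_cell == pytest.approx((4 / 1 + 2 / 2) / 2)
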