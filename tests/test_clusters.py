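"""Spot decomposition, single-linkage clustering and origin-proximal mass."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

import chromoshape as cs
from chromoshape.clusters import (
    PSF_FWHM_FACTOR,
    Spot,
    SpotSet,
    decompose_spots,
    fraction_within_radius,
    group_clusters,
    primary_cluster_stats,
)
from chromoshape.foci import Focus

from conftest import NOISELESS, PIXEL_SIZE_NM, PSF_PX


def _render(shape, spots, photons=2e5):
    canvas = np.zeros(shape)
    for x, y, w in spots:
        canvas[int(round(y)), int(round(x))] += w
    return gaussian_filter(canvas, PSF_PX, mode="constant", truncate=6.0) * photons


def _spotset(positions, amps=None):
    amps = amps or [1.0] * len(positions)
    spots = [Spot(x, y, a) for (x, y), a in zip(positions, amps)]
    total = sum(s.intensity(PSF_PX) for s in spots)
    return SpotSet(0, spots, PSF_PX, PIXEL_SIZE_NM, total, [], "test")


def brute_force_single_linkage(positions, radius):
    """Independent oracle: union-find over the all-pairs distance matrix."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(positions[i], positions[j]) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def test_single_noiseless_spot_fully_recovered():
    img = _render((64, 64), [(30, 20, 1.0)])
    ss = decompose_spots(img, np.ones_like(img, bool), PSF_PX)
    assert len(ss.spots) >= 1
    brightest = max(ss.spots, key=lambda s: s.amplitude)
    assert math.hypot(brightest.x_px - 30, brightest.y_px - 20) <= 0.2
    recovered = sum(s.intensity(PSF_PX) for s in ss.spots) / ss.total_signal
    assert recovered == pytest.approx(1.0, abs=0.02)


def test_two_equal_spots_recover_half_fractions():
    d = 3.0 * PSF_PX
    img = _render((64, 64), [(24, 32, 1.0), (24 + d, 32, 1.0)])
    ss = decompose_spots(img, np.ones_like(img, bool), PSF_PX)
    clusters = group_clusters(ss)  # 3 psf > FWHM linking radius: separate
    assert len(clusters) == 2
    for cl in clusters:
        assert cl.relative_intensity == pytest.approx(0.5, abs=0.05)


def test_blank_image_stops_below_noise():
    rng = np.random.default_rng(0)
    img = rng.normal(10.0, 1.0, size=(32, 32)).clip(0)
    ss = decompose_spots(img, np.ones_like(img, bool), PSF_PX)
    assert ss.spots == []
    assert ss.stopping_reason == "below_noise"


def test_residual_norms_non_increasing():
    img = _render((64, 64), [(20, 20, 1.0), (40, 40, 0.6), (30, 44, 0.4)])
    ss = decompose_spots(img, np.ones_like(img, bool), PSF_PX)
    assert all(b <= a + 1e-9 for a, b in zip(ss.residual_norms, ss.residual_norms[1:]))


def test_chain_linkage_is_transitive():
    radius = PSF_FWHM_FACTOR * PSF_PX
    pos = [(10.0, 10.0), (10.0 + 0.9 * radius, 10.0), (10.0 + 1.8 * radius, 10.0)]
    clusters = group_clusters(_spotset(pos))
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == [0, 1, 2]
    oracle = brute_force_single_linkage(pos, radius)
    assert {frozenset(c.member_ids) for c in clusters} == oracle


def test_gap_beyond_radius_separates_clusters():
    radius = PSF_FWHM_FACTOR * PSF_PX
    pos = [(10.0, 10.0), (10.0 + 1.5 * radius, 10.0)]
    clusters = group_clusters(_spotset(pos))
    assert len(clusters) == 2
    assert sum(c.is_primary for c in clusters) == 1


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_group_clusters_matches_brute_force_oracle(data):
    n = data.draw(st.integers(0, 12))
    coords = data.draw(
        st.lists(
            st.tuples(
                st.floats(0, 50, allow_nan=False), st.floats(0, 50, allow_nan=False)
            ),
            min_size=n,
            max_size=n,
        )
    )
    radius = data.draw(st.floats(0.5, 10.0))
    clusters = group_clusters(_spotset(coords), link_radius_px=radius)
    got = {frozenset(c.member_ids) for c in clusters}
    assert got == brute_force_single_linkage(coords, radius)


def test_growing_linkage_radius_never_adds_clusters():
    rng = np.random.default_rng(1)
    pos = [tuple(p) for p in rng.uniform(0, 40, size=(10, 2))]
    ss = _spotset(pos)
    counts = [len(group_clusters(ss, link_radius_px=r)) for r in (1, 2, 4, 8, 16)]
    assert counts == sorted(counts, reverse=True)


def test_cluster_fractions_sum_with_residual_to_one():
    img = _render((64, 64), [(20, 20, 0.6), (44, 40, 0.4)])
    ss = decompose_spots(img, np.ones_like(img, bool), PSF_PX)
    clusters = group_clusters(ss)
    modeled = sum(c.relative_intensity for c in clusters)
    assert modeled <= 1.0 + 1e-3
    assert modeled == pytest.approx(1.0, abs=0.05)


def test_primary_cluster_stats_table():
    pos = [(10.0, 10.0), (30.0, 30.0)]
    ss = _spotset(pos, amps=[0.4, 0.3])
    clusters = group_clusters(ss)
    parb = Focus(0, "PARB", 10.0, 10.0, 10.0 * PIXEL_SIZE_NM, 10.0 * PIXEL_SIZE_NM, 1, 1)
    table = primary_cluster_stats(clusters, parb, pixel_size_nm=PIXEL_SIZE_NM)
    prim = table[table.is_primary].iloc[0]
    assert prim.distance_to_ori_nm == pytest.approx(0.0, abs=1e-9)
    # 0.4 outranks 0.3
    assert prim.relative_intensity > table[~table.is_primary].iloc[0].relative_intensity
    assert primary_cluster_stats([], parb).empty


def test_fraction_within_radius_limits():
    img = np.zeros((48, 48))
    img[24, 24] = 100.0
    mask = np.ones_like(img, bool)
    assert fraction_within_radius(img, mask, (24, 24), 100.0, PIXEL_SIZE_NM, background=0.0) == 1.0
    # radius covering the whole image
    rng = np.random.default_rng(2)
    img2 = rng.uniform(1, 2, size=(48, 48))
    assert fraction_within_radius(
        img2, mask, (10, 10), 1e6, PIXEL_SIZE_NM, background=0.0
    ) == pytest.approx(1.0)


def test_fraction_within_radius_monotone_in_radius():
    stack, truth = cs.simulate_cell(
        cs.SimParams(seed=3, shape_class="crescent", arc_span_deg=150)
    )
    dna = stack.plane("DNA")
    mask = np.ones_like(dna, bool)
    origin = (truth.ori_xy_nm[0] / PIXEL_SIZE_NM, truth.ori_xy_nm[1] / PIXEL_SIZE_NM)
    fracs = [
        fraction_within_radius(dna, mask, origin, r, PIXEL_SIZE_NM)
        for r in (200, 400, 800, 1600)
    ]
    assert fracs == sorted(fracs)


def test_uniform_arc_fraction_matches_quadrature_oracle():
    """A uniform arc with ori at its tip: the image-integral fraction within
    0.5 µm matches direct quadrature of the truth density."""
    span = math.degrees(2.0 / 0.75)  # 2 µm of arc at radius 0.75 µm
    p = cs.SimParams(
        seed=4, shape_class="crescent", arc_span_deg=span, ori_angle_deg=10,
        curl_sign=1, arc_width_sigma_nm=40.0, **NOISELESS,
    )
    stack, truth = cs.simulate_cell(p)
    # oracle: quadrature over the truth grid
    d = np.hypot(
        truth.arc_xy_nm[:, 0] - truth.ori_xy_nm[0],
        truth.arc_xy_nm[:, 1] - truth.ori_xy_nm[1],
    )
    oracle = truth.density[d <= 500.0].sum()
    # curvature makes the 500 nm chord cover slightly more than 0.5/2.0 arc
    assert oracle == pytest.approx(0.25, abs=0.02)
    dna = stack.plane("DNA")
    mask = np.ones_like(dna, bool)
    origin = (truth.ori_xy_nm[0] / PIXEL_SIZE_NM, truth.ori_xy_nm[1] / PIXEL_SIZE_NM)
    got = fraction_within_radius(dna, mask, origin, 500.0, PIXEL_SIZE_NM, background=0.0)
    # PSF blur spreads ~10% of border mass across the disc edge
    assert got == pytest.approx(oracle, abs=0.05)
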