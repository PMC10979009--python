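"""Generator contracts: photon conservation, truth consistency, determinism."""

import numpy as np
import pytest

import chromoshape as cs
from chromoshape.errors import ParameterError, PlacementError

from conftest import NOISELESS


def test_invalid_params_name_the_field():
    with pytest.raises(ParameterError, match="psf_sigma_nm"):
        cs.SimParams(psf_sigma_nm=-1.0)
    with pytest.raises(ParameterError, match="primary_cluster_fraction"):
        cs.SimParams(primary_cluster_fraction=1.5)
    with pytest.raises(ParameterError, match="cluster fractions"):
        cs.SimParams(primary_cluster_fraction=0.6, secondary_clusters=((0.5, 0.5),))
    with pytest.raises(ParameterError, match="arc_span_deg"):
        cs.SimParams(arc_span_deg=400.0)
    with pytest.raises(ParameterError, match="toroid"):
        cs.SimParams(shape_class="toroid", arc_span_deg=180.0)


def test_noiseless_photon_conservation_per_channel():
    p = cs.SimParams(seed=1, include_ter=True, arc_span_deg=150, **NOISELESS)
    stack, truth = cs.simulate_cell(p)
    budgets = {**p.photon_budget, "PARB": p.parb_photons}
    for label in stack.channel_labels:
        total = stack.channel(label).sum()
        assert total == pytest.approx(budgets[label], rel=1e-6)
        assert truth.channel_totals[label] == pytest.approx(budgets[label], rel=1e-6)


def test_shape_label_passthrough_and_truth_geometry():
    for shape in ("crescent", "toroid", "compact", "other"):
        p = cs.SimParams(seed=2, shape_class=shape)
        _, truth = cs.simulate_cell(p)
        assert truth.shape_label == shape
    p = cs.SimParams(seed=3, shape_class="crescent", arc_span_deg=120)
    _, truth = cs.simulate_cell(p)
    # density normalized, ori on the arc
    assert truth.density.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(truth.density >= 0)
    d0 = np.hypot(
        truth.arc_xy_nm[0, 0] - truth.ori_xy_nm[0],
        truth.arc_xy_nm[0, 1] - truth.ori_xy_nm[1],
    )
    assert d0 <= truth.arc_radius_nm * 0.01 + 65.35  # within one pixel


def test_origin_proximal_mass_matches_quadrature_oracle():
    """With a 0.45 ori blob + uniform remainder, the truth density within
    500 nm of ori must match direct quadrature and be >= 0.45."""
    p = cs.SimParams(
        seed=4, shape_class="crescent", arc_span_deg=150,
        primary_cluster_fraction=0.45, **NOISELESS,
    )
    _, truth = cs.simulate_cell(p)
    # independent quadrature over the truth grid
    d = np.hypot(
        truth.arc_xy_nm[:, 0] - truth.ori_xy_nm[0],
        truth.arc_xy_nm[:, 1] - truth.ori_xy_nm[1],
    )
    oracle = truth.density[d <= 500.0].sum()
    # the uniform remainder contributes ~ (arc length within the disc)/L
    assert oracle >= 0.45
    got = cs.fraction_within_radius_truth(truth, 500.0)
    assert got == pytest.approx(oracle, abs=1e-12)


def test_same_seed_bit_identical():
    p = cs.SimParams(seed=9)
    s1, _ = cs.simulate_cell(p)
    s2, _ = cs.simulate_cell(p)
    assert np.array_equal(s1.pixels, s2.pixels)
    d1, m1 = cs.simulate_condition(p, 10, seed=5)
    d2, m2 = cs.simulate_condition(p, 10, seed=5)
    for (a, _), (b, _) in zip(d1, d2):
        assert np.array_equal(a.pixels, b.pixels)
    assert m1["class_counts"] == m2["class_counts"]


def test_condition_round_robin_counts_and_single_cell_consistency():
    grid = [
        cs.SimParams(shape_class="crescent"),
        cs.SimParams(shape_class="toroid"),
    ]
    cells, manifest = cs.simulate_condition(grid, 100, seed=21)
    assert manifest["class_counts"] == {"crescent": 50, "toroid": 50}
    # n_cells=1 equals simulate_cell for the derived seed
    one, man1 = cs.simulate_condition(grid, 1, seed=21)
    derived = cs.derive_seeds(21, 1)[0]
    direct, _ = cs.simulate_cell(grid[0].model_copy(update={"seed": derived}))
    assert np.array_equal(one[0][0].pixels, direct.pixels)


def test_mirror_symmetric_geometry_reflects_noiseless_render():
    base = dict(
        shape_class="crescent", arc_span_deg=140, seed=6, **NOISELESS,
    )
    # ori at +30 deg curling ccw mirrors (about the vertical axis) to
    # ori at 150 deg curling cw
    a, _ = cs.simulate_cell(cs.SimParams(ori_angle_deg=30, curl_sign=1, **base))
    b, _ = cs.simulate_cell(cs.SimParams(ori_angle_deg=150, curl_sign=-1, **base))
    np.testing.assert_allclose(a.pixels, b.pixels[..., ::-1], atol=1e-9)


def test_photon_budget_monotonicity_on_arc():
    base = dict(shape_class="crescent", arc_span_deg=150, ori_angle_deg=0,
                curl_sign=1, seed=7, **NOISELESS)
    lo, _ = cs.simulate_cell(cs.SimParams(photon_budget={"DNA": 1e5}, **base))
    hi, _ = cs.simulate_cell(cs.SimParams(photon_budget={"DNA": 3e5}, **base))
    on_arc = lo.plane("DNA") > 1.0
    assert np.all(hi.plane("DNA")[on_arc] > lo.plane("DNA")[on_arc])


def test_composite_field_places_or_raises():
    cells, _ = cs.simulate_condition(cs.SimParams(), 4, seed=3)
    stack, truths = cs.composite_field(cells, (220, 220))
    assert stack.shape_yx == (220, 220)
    assert len(truths) == 4
    # noiseless per-cell content is additive, so total is preserved
    with pytest.raises(PlacementError):
        cs.composite_field(cells, (100, 100))


def test_zstack_render_and_max_projection_shape():
    p = cs.SimParams(seed=5, n_z=5, **NOISELESS)
    stack, _ = cs.simulate_cell(p)
    assert stack.n_z == 5
    assert stack.z_step_nm == 200.0
    # middle plane is in focus: sharpest => highest peak
    dna = stack.channel("DNA")
    assert dna[2].max() == dna.max(axis=(1, 2)).max()
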