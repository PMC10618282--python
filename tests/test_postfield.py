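import numpy as np
import pytest

import tmsbem as tb
from tmsbem.operator import BemOperator, build_rhs, FOUR_PI
from tmsbem.postfield import (
    ChargeSolution,
    SurfaceProximityError,
    _point_triangle_distance,
    continuity_residual,
    field_errors,
    interface_fields,
    roi_select,
    save_field_samples,
    secondary_field,
    total_field,
)
from tmsbem.solve import factorize_direct, solve_iterative

from conftest import make_fake_head


@pytest.fixture(scope="module")
def solved_small(small_head, placed_fig8):
    fact = factorize_direct(small_head, method="dense")
    c = fact.solve(build_rhs(small_head, placed_fig8))
    return ChargeSolution(c, small_head, placed_fig8)


# ---------------------------------------------------------------------------
# Point-triangle distance (guard machinery)
# ---------------------------------------------------------------------------


def test_point_triangle_distance_against_sampling(rng):
    tri = rng.normal(size=(5, 3, 3))
    pts = rng.normal(size=(5, 3)) * 2
    got = _point_triangle_distance(tri, pts)
    # brute force: dense barycentric sampling of each triangle
    u = np.linspace(0, 1, 201)
    uu, vv = np.meshgrid(u, u)
    keep = uu + vv <= 1.0
    bary = np.stack([1 - uu[keep] - vv[keep], uu[keep], vv[keep]], axis=1)
    for k in range(5):
        samples = bary @ tri[k]
        brute = np.linalg.norm(samples - pts[k], axis=1).min()
        assert got[k] <= brute + 1e-12
        assert got[k] >= brute - 0.02 * brute - 1e-12


# ---------------------------------------------------------------------------
# Off-surface fields
# ---------------------------------------------------------------------------


def test_zero_charge_total_field_is_primary(small_head, placed_fig8, rng):
    sol = ChargeSolution(np.zeros(small_head.n_facets), small_head, placed_fig8)
    pts = rng.normal(size=(10, 3)) * 0.01  # deep inside
    fs = total_field(sol, pts)
    assert np.array_equal(fs.E_total, fs.E_primary)
    assert np.all(fs.E_secondary == 0.0)


def test_single_facet_far_field_point_charge():
    """Analytic facet field approaches the equivalent point charge in the
    far zone (distance ~40 circumradii: within the analytic near region at
    precision 1e-6 but deep in the multipole limit)."""
    s = 0.02
    tri = np.array([[[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]]])
    tri -= tri.mean(axis=1, keepdims=True)
    head = make_fake_head(tri)
    sol = ChargeSolution(np.array([3.0]), head,
                         tb.build_figure8_coil(0.035, didt=0.0))
    far = np.array([[0.3, 0.15, 0.35]])
    assert np.linalg.norm(far) < 50 * head.circumradii[0]  # analytic path
    E = secondary_field(sol, far, precision=1e-6)
    d = far[0] - head.centroids[0]
    expected = 3.0 * head.areas[0] * d / (FOUR_PI * np.linalg.norm(d) ** 3)
    assert np.linalg.norm(E[0] - expected) / np.linalg.norm(expected) < 1e-3
    assert np.linalg.norm(E[0] - expected) > 0  # genuinely different paths


def test_distance_guard_names_facet(solved_small):
    head = solved_small.head
    # a point a hair off a facet centroid violates the guard
    p = head.centroids[7] + 1e-5 * head.normals[7]
    with pytest.raises(SurfaceProximityError, match="facet"):
        total_field(solved_small, p[None])


def test_fast_path_matches_exact_summation(solved_small, rng):
    pts = rng.normal(size=(100, 3))
    pts = 0.05 * pts / np.linalg.norm(pts, axis=1)[:, None]
    exact = secondary_field(solved_small, pts, backend="exact", precision=1e-6)
    fast = secondary_field(solved_small, pts, backend="treecode", precision=1e-3)
    assert np.linalg.norm(fast - exact) / np.linalg.norm(exact) <= 1e-3


# ---------------------------------------------------------------------------
# Interface fields and the jump identity
# ---------------------------------------------------------------------------


def test_jump_identity_machine_precision(solved_small):
    head = solved_small.head
    E_in, E_out = interface_fields(solved_small)
    jump = np.einsum("fk,fk->f", head.normals, E_out - E_in)
    assert np.abs(jump - solved_small.c).max() < 1e-12 * max(
        1.0, np.abs(solved_small.c).max()
    )


def test_interface_fields_zero_charge(small_head, placed_fig8):
    sol = ChargeSolution(np.zeros(small_head.n_facets), small_head, placed_fig8)
    E_in, E_out = interface_fields(sol)
    Ep = tb.primary_efield(placed_fig8, small_head.centroids)
    assert np.allclose(E_in, Ep, atol=1e-15)
    assert np.allclose(E_out, Ep, atol=1e-15)


def test_interface_subset_matches_full(solved_small):
    idx = np.array([3, 17, 200])
    full_in, full_out = interface_fields(solved_small)
    sub_in, sub_out = interface_fields(solved_small, idx)
    assert np.allclose(sub_in, full_in[idx], atol=1e-13)
    assert np.allclose(sub_out, full_out[idx], atol=1e-13)


def test_outer_surface_blocks_normal_current(single_sphere_head, placed_fig8):
    """With air outside (sigma_out = 0) the interface condition forces
    n.E_in -> 0 on the outer surface at the residual level."""
    op = BemOperator(single_sphere_head, precision=1e-4)
    b = build_rhs(single_sphere_head, placed_fig8)
    c = solve_iterative(op, b, tol=1e-8).solution
    sol = ChargeSolution(c, single_sphere_head, placed_fig8)
    E_in, E_out = interface_fields(sol, precision=1e-4)
    n = single_sphere_head.normals
    nin = np.einsum("fk,fk->f", n, E_in)
    scale = np.sqrt((E_in ** 2).sum(axis=1).mean())
    assert np.sqrt((nin ** 2).mean()) / scale < 1e-3


# ---------------------------------------------------------------------------
# Continuity residual
# ---------------------------------------------------------------------------


def test_continuity_tracks_solver_tolerance(small_head, placed_fig8):
    op = BemOperator(small_head, precision=1e-4)
    b = build_rhs(small_head, placed_fig8)
    rms = {}
    for tol in (1e-4, 1e-8):
        c = solve_iterative(op, b, tol=tol).solution
        sol = ChargeSolution(c, small_head, placed_fig8)
        rms[tol] = continuity_residual(sol, precision=1e-4).rms
    assert rms[1e-4] / rms[1e-8] >= 1e2
    assert rms[1e-8] < 1e-5


def test_continuity_zero_everything(zero_contrast_head, placed_fig8):
    sol = ChargeSolution(np.zeros(zero_contrast_head.n_facets),
                         zero_contrast_head, placed_fig8.with_didt(0.0))
    rep = continuity_residual(sol)
    assert rep.max == 0.0


def test_continuity_flags_unsolved_model(small_head, placed_fig8):
    sol = ChargeSolution(np.zeros(small_head.n_facets), small_head, placed_fig8)
    rep = continuity_residual(sol)
    assert rep.rms > 1e-3  # unsatisfied boundary condition


# ---------------------------------------------------------------------------
# Error metrics and ROI
# ---------------------------------------------------------------------------


def test_field_errors_trivial_cases(rng):
    E = rng.normal(size=(40, 3))
    assert field_errors(E, E) == (0.0, 0.0)
    et, em = field_errors(E, np.zeros_like(E))
    assert (et, em) == (1.0, 1.0)
    et, em = field_errors(E, -E)
    assert et == pytest.approx(2.0) and em == pytest.approx(0.0, abs=1e-15)


def test_field_errors_zero_reference_raises(rng):
    with pytest.raises(ValueError, match="zero"):
        field_errors(np.zeros((5, 3)), rng.normal(size=(5, 3)))


def test_field_errors_trim_and_weights(rng):
    E = rng.normal(size=(100, 3))
    T = E.copy()
    T[0] += 100.0  # one gross outlier
    et_raw, _ = field_errors(E, T)
    et_trim, _ = field_errors(E, T, trim_fraction=0.02)
    assert et_trim < 1e-12 < et_raw
    w = np.ones(100)
    w[0] = 0.0
    et_w, _ = field_errors(E, T, weights=w)
    assert et_w < 1e-12


def test_roi_select_closed_ball():
    pts = np.array([[0, 0, 0], [0.02, 0, 0], [0.021, 0, 0]])
    mask = roi_select(pts, target=(0, 0, 0), radius=0.02)
    assert mask.tolist() == [True, True, False]
    assert roi_select(pts, (0, 0, 0), 1e9).all()
    with pytest.raises(ValueError):
        roi_select(pts, (0, 0, 0), -1.0)


# ---------------------------------------------------------------------------
# Outside limit consistency
# ---------------------------------------------------------------------------


def test_total_field_approaches_interface_outside_limit(solved_small):
    """Off-surface evaluation approaching a facet from outside converges to
    the facet's E_out."""
    head = solved_small.head
    f = 42
    E_out = interface_fields(solved_small, np.array([f]))[1][0]
    diffs = []
    for dist in (2.0, 1.0, 0.5):
        p = head.centroids[f] + dist * head.circumradii[f] * head.normals[f]
        E = total_field(solved_small, p[None], guard=0.1).E_total[0]
        diffs.append(np.linalg.norm(E - E_out))
    assert diffs[2] < diffs[0]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def test_save_field_samples_formats(tmp_path, solved_small, rng):
    pts = rng.normal(size=(7, 3))
    pts = 0.03 * pts / np.linalg.norm(pts, axis=1)[:, None]
    fs = total_field(solved_small, pts)
    csv = tmp_path / "field.csv"
    save_field_samples(fs, csv, fmt="csv")
    data = np.loadtxt(csv, delimiter=",")
    assert data.shape == (7, 7)
    assert np.allclose(data[:, 3:6], fs.E_total, rtol=1e-6)
    assert np.allclose(data[:, 6], np.linalg.norm(fs.E_total, axis=1), rtol=1e-6)
    save_field_samples(fs, tmp_path / "field.vtk", fmt="vtk")
    text = (tmp_path / "field.vtk").read_text()
    assert "POLYDATA" in text and "VECTORS E_total" in text
    save_field_samples(fs, tmp_path / "field.npz", fmt="npz")
    with np.load(tmp_path / "field.npz") as z:
        assert np.array_equal(z["E_total"], fs.E_total)
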