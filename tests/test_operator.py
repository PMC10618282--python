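import dataclasses

import numpy as np
import pytest

import tmsbem as tb
from tmsbem.operator import (
    BemOperator,
    DenseCapExceeded,
    assemble_dense,
    build_rhs,
    facet_quadrature,
    triangle_field_analytic,
    triangle_fields,
)

from conftest import make_fake_head


def quad_oracle_triangle_field(v, p, epsrel=1e-10):
    """Brute-force adaptive quadrature of (1/4pi) int (p-r')/|p-r'|^3 dA'."""
    from scipy.integrate import dblquad

    e1, e2 = v[1] - v[0], v[2] - v[0]
    J = np.linalg.norm(np.cross(e1, e2))
    out = np.zeros(3)
    for k in range(3):
        def f(b, a, k=k):
            rp = v[0] + a * e1 + b * e2
            d = p - rp
            return d[k] / np.linalg.norm(d) ** 3 * J
        out[k], _ = dblquad(f, 0, 1, 0, lambda a: 1 - a,
                            epsabs=1e-13, epsrel=epsrel)
    return out / (4 * np.pi)


# ---------------------------------------------------------------------------
# Analytic triangle integral
# ---------------------------------------------------------------------------


def test_triangle_field_matches_quadrature(rng):
    for _ in range(3):
        v = rng.normal(size=(3, 3))
        p = rng.normal(size=3) * 2.0
        got = triangle_field_analytic(v, p)
        want = quad_oracle_triangle_field(v, p)
        assert np.allclose(got, want, atol=1e-10 * max(1, np.abs(want).max()))


def test_triangle_field_far_point_charge_limit():
    # area 2e-4 m^2 at 1 m: |E| ~ area/(4 pi) = 1.59155e-5 within 0.1%
    s = np.sqrt(2e-4 * 4 / np.sqrt(3))
    v = np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]])
    v -= v.mean(axis=0)
    E = triangle_field_analytic(v, np.array([0.0, 0.0, 1.0]))
    assert abs(np.linalg.norm(E) - 2e-4 / (4 * np.pi)) / (2e-4 / (4 * np.pi)) < 1e-3


def test_triangle_field_centroid_principal_value():
    s = 1.0
    v = np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]])
    E = triangle_field_analytic(v, v.mean(axis=0))
    # normal component is the principal value (zero); in-plane vanishes by
    # the equilateral symmetry
    assert np.allclose(E, 0.0, atol=1e-12)


def test_triangle_field_two_sided_jump(rng):
    v = rng.normal(size=(3, 3))
    n = np.cross(v[1] - v[0], v[2] - v[0])
    n /= np.linalg.norm(n)
    c = v.mean(axis=0)
    eps = 1e-9
    above = triangle_field_analytic(v, c + eps * n)
    below = triangle_field_analytic(v, c - eps * n)
    assert np.allclose(above - below, n, atol=1e-6)  # jump of 1 along n
    pv = triangle_field_analytic(v, c)
    assert abs(np.dot(pv, n)) < 1e-12


def test_triangle_fields_batched_consistency(rng):
    tris = rng.normal(size=(4, 3, 3))
    pts = rng.normal(size=(5, 3)) * 2
    batch = triangle_fields(tris, pts)
    for i in range(5):
        for j in range(4):
            assert np.allclose(
                batch[i, j], triangle_field_analytic(tris[j], pts[i]), atol=1e-13
            )


def test_zero_area_triangle_raises():
    v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    with pytest.raises(ValueError):
        triangle_field_analytic(v, np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# Dense assembly
# ---------------------------------------------------------------------------


def test_zero_contrast_gives_half_identity(zero_contrast_head):
    A = assemble_dense(zero_contrast_head)
    assert np.array_equal(A, 0.5 * np.eye(zero_contrast_head.n_facets))


def test_diagonal_exactly_half(single_sphere_head):
    A = assemble_dense(single_sphere_head)
    assert np.abs(np.diag(A) - 0.5).max() < 1e-14


def test_two_facet_entries_match_double_quadrature(rng):
    """A_mn for a well-separated facet pair against an independent
    double-quadrature oracle (adaptive inner, refined symmetric outer)."""
    tri_m = rng.normal(size=(3, 3)) * 0.04
    tri_n = rng.normal(size=(3, 3)) * 0.04 + np.array([2.0, 0.5, -0.8])
    head = make_fake_head(np.stack([tri_m, tri_n]))
    A = assemble_dense(head, quadrature_order=7)

    # oracle: outer integral by the degree-5 rule on a 1:16 subdivision of
    # t_m (independent arithmetic), inner by adaptive quadrature
    def outer_avg(vm, vn):
        tris = [vm]
        for _ in range(2):
            nxt = []
            for t in tris:
                a, b, c = t
                ab, bc, ca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
                nxt += [np.array(x) for x in
                        ([a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca])]
            tris = nxt
        nrm = np.cross(vm[1] - vm[0], vm[2] - vm[0])
        nrm /= np.linalg.norm(nrm)
        total = 0.0
        for t in tris:
            pts, w = facet_quadrature(t[None], 7)
            for q in range(len(w)):
                total += w[q] * np.dot(nrm, quad_oracle_triangle_field(vn, pts[q, 0]))
        return total / len(tris)

    K = head.contrast[0]
    want_01 = -K * outer_avg(tri_m, tri_n)
    want_10 = -K * outer_avg(tri_n, tri_m)
    assert abs(A[0, 1] - want_01) < 1e-8 * max(abs(want_01), 1e-6)
    assert abs(A[1, 0] - want_10) < 1e-8 * max(abs(want_10), 1e-6)


def test_dense_cap_guard(small_head):
    with pytest.raises(DenseCapExceeded, match="matrix-free"):
        assemble_dense(small_head, cap=100)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


def test_rhs_zero_didt_and_zero_contrast(small_head, zero_contrast_head, placed_fig8):
    assert np.all(build_rhs(small_head, placed_fig8.with_didt(0.0)) == 0.0)
    assert np.all(build_rhs(zero_contrast_head, placed_fig8) == 0.0)


def test_rhs_quadrature_order_converges_h2(placed_fig8):
    """Order-1 vs order-3 facet averages differ by O(h^2): one refinement
    shrinks the difference by about 4x."""
    diffs = []
    for level in (2, 3):
        mesh = tb.icosphere(0.08, level)
        from tmsbem.geometry import Interface, build_head_model

        head = build_head_model([Interface(mesh, 0.3, 0.0, "s")])
        b1 = build_rhs(head, placed_fig8, quadrature_order=1)
        b3 = build_rhs(head, placed_fig8, quadrature_order=3)
        diffs.append(np.linalg.norm(b1 - b3) / np.linalg.norm(b3))
    assert diffs[0] / diffs[1] > 2.5


# ---------------------------------------------------------------------------
# Matrix-free application
# ---------------------------------------------------------------------------


def test_apply_operator_trivial_cases(zero_contrast_head, rng):
    op = BemOperator(zero_contrast_head)
    x = rng.normal(size=zero_contrast_head.n_facets)
    assert np.allclose(op.matvec(x), 0.5 * x, atol=1e-15)
    assert np.all(op.matvec(np.zeros_like(x)) == 0.0)


def test_apply_operator_matches_dense(single_sphere_head, rng):
    A = assemble_dense(single_sphere_head)
    for prec in (1e-4, 1e-6):
        op = BemOperator(single_sphere_head, precision=prec)
        for _ in range(3):
            x = rng.normal(size=single_sphere_head.n_facets)
            err = np.linalg.norm(op.matvec(x) - A @ x) / np.linalg.norm(A @ x)
            assert err <= prec


def test_apply_operator_treecode_backend(small_head, rng):
    op_e = BemOperator(small_head, backend="exact", precision=1e-3)
    op_t = BemOperator(small_head, backend="treecode", precision=1e-3)
    x = rng.normal(size=small_head.n_facets)
    ye, yt = op_e.matvec(x), op_t.matvec(x)
    assert np.linalg.norm(ye - yt) / np.linalg.norm(ye) <= 1e-3


def test_operator_linear_in_contrast(small_head, rng):
    """Scaling K by alpha scales (A - I/2) x and b by alpha."""
    alpha = 0.37
    scaled = dataclasses.replace(small_head, contrast=alpha * small_head.contrast)
    op1 = BemOperator(small_head)
    op2 = BemOperator(scaled)
    x = rng.normal(size=small_head.n_facets)
    y1 = op1.matvec(x) - 0.5 * x
    y2 = op2.matvec(x) - 0.5 * x
    assert np.allclose(y2, alpha * y1, rtol=1e-12, atol=1e-15)


def test_unsupported_precision_rejected(small_head):
    with pytest.raises(ValueError, match="precision"):
        BemOperator(small_head, precision=3e-5)
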