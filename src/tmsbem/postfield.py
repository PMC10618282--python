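"""Field reconstruction, boundary-condition audit, and error metrics.

After the charge solve, the total field at any off-surface point is

    E(r) = E_p(r) + (1/4 pi) sum_n c_n integral_{t_n} (r-r')/|r-r'|^3 dr',

with c_n the scaled surface charge density (rho/eps0, V/m).  On a facet the
field is two-sided: the continuous part (primary field plus principal-value
sum of all facets) carries a jump of -/+ n c/2 on the inner/outer side, so
n . (E_out - E_in) = c holds exactly by construction.

The quasistatic interface condition sigma_in n.E_in = sigma_out n.E_out is
audited by :func:`continuity_residual`; solution-vs-solution comparisons use
the relative vector and magnitude errors of :func:`field_errors`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coil import CoilModel, primary_efield
from .geometry import HeadModel
from .operator import (
    FOUR_PI,
    _triangle_fields_pairwise,
    ndot_secondary_averaged,
    near_eta,
    near_pairs,
)
from .summation import coulomb_field


@dataclass
class ChargeSolution:
    """Per-facet scaled surface charge density c = rho/eps0 (V/m)."""

    c: np.ndarray
    head: HeadModel
    coil: CoilModel

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=np.float64).ravel()
        if len(self.c) != self.head.n_facets:
            raise ValueError("solution length must equal facet count")
        if not np.isfinite(self.c).all():
            raise ValueError("solution contains non-finite entries")


@dataclass
class FieldSamples:
    points: np.ndarray
    E_total: np.ndarray
    E_primary: np.ndarray
    E_secondary: np.ndarray
    tags: dict | None = None


class SurfaceProximityError(ValueError):
    """An observation point violated the surface distance guard."""


# ---------------------------------------------------------------------------
# Point-to-triangle distance (guard)
# ---------------------------------------------------------------------------


def _point_triangle_distance(tri: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Exact distances for matched (triangle, point) pairs, shape (P,)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = pts - a
    d1 = np.einsum("pk,pk->p", ab, ap)
    d2 = np.einsum("pk,pk->p", ac, ap)
    bp = pts - b
    d3 = np.einsum("pk,pk->p", ab, bp)
    d4 = np.einsum("pk,pk->p", ac, bp)
    cp = pts - c
    d5 = np.einsum("pk,pk->p", ab, cp)
    d6 = np.einsum("pk,pk->p", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    closest = np.empty_like(pts)
    done = np.zeros(len(pts), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        closest[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    eps = 1e-300
    assign((d1 <= 0) & (d2 <= 0), a)                                   # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                                  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)                                  # vertex C
    t = d1 / np.maximum(d1 - d3, eps)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t[:, None] * ab)     # edge AB
    t = d2 / np.maximum(d2 - d6, eps)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t[:, None] * ac)     # edge AC
    t = (d4 - d3) / np.maximum((d4 - d3) + (d5 - d6), eps)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + t[:, None] * (c - b))                                   # edge BC
    denom = np.maximum(va + vb + vc, eps)
    v = vb / denom
    w = vc / denom
    assign(np.ones(len(pts), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return np.linalg.norm(pts - closest, axis=1)


# ---------------------------------------------------------------------------
# Secondary / total fields at off-surface points
# ---------------------------------------------------------------------------


def _near_candidates(head: HeadModel, points: np.ndarray, eta: float):
    """Per-point facet indices with centroid distance < eta * rho_n."""
    from scipy.spatial import cKDTree

    tree = cKDTree(head.centroids)
    rmax = float(head.circumradii.max())
    groups = tree.query_ball_point(points, eta * rmax)
    pi, fi = [], []
    for p, grp in enumerate(groups):
        grp = np.asarray(grp, dtype=np.int64)
        if not grp.size:
            continue
        d = np.linalg.norm(head.centroids[grp] - points[p], axis=1)
        keep = grp[d < eta * head.circumradii[grp]]
        pi.append(np.full(keep.size, p, dtype=np.int64))
        fi.append(keep)
    if not pi:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(pi), np.concatenate(fi)


def secondary_field(
    sol: ChargeSolution,
    points: np.ndarray,
    backend: str = "exact",
    precision: float = 1e-6,
    guard: float | None = 0.1,
) -> np.ndarray:
    """Coulomb field of the induced surface charges at off-surface points.

    Far facets contribute as centroid point charges (via the chosen
    backend); facets with centroid distance below eta * rho are replaced by
    their analytic integrals.  With ``guard`` set, a point closer than
    ``guard * circumradius`` to any facet raises
    :class:`SurfaceProximityError` naming the facet (use
    :func:`interface_fields` for on-surface values).
    """
    head = sol.head
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    pi, fi = _near_candidates(head, points, near_eta(precision))

    if guard is not None and pi.size:
        tri = head.face_vertices[fi]
        dist = _point_triangle_distance(tri, points[pi])
        bad = dist < guard * head.circumradii[fi]
        if np.any(bad):
            p, f = int(pi[bad][0]), int(fi[bad][0])
            raise SurfaceProximityError(
                f"point {p} is within {guard} circumradii of facet {f}; "
                "use interface_fields for on-surface evaluation"
            )

    q = sol.c * head.areas
    E = coulomb_field(head.centroids, q, points, backend, precision) / FOUR_PI
    if pi.size:
        tri = head.face_vertices[fi]
        T = _triangle_fields_pairwise(tri, points[pi])
        d = points[pi] - head.centroids[fi]
        r = np.linalg.norm(d, axis=1)
        pc = head.areas[fi, None] * d / (FOUR_PI * r[:, None] ** 3)
        corr = sol.c[fi, None] * (T - pc)
        np.add.at(E, pi, corr)
    return E


def total_field(
    sol: ChargeSolution,
    points: np.ndarray,
    backend: str = "exact",
    precision: float = 1e-6,
    guard: float | None = 0.1,
) -> FieldSamples:
    """Total E-field (primary + secondary) at off-surface points."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    Ep = primary_efield(sol.coil, points)
    Es = secondary_field(sol, points, backend, precision, guard)
    return FieldSamples(points, Ep + Es, Ep, Es)


# ---------------------------------------------------------------------------
# Interface (two-sided) fields and continuity audit
# ---------------------------------------------------------------------------


def interface_fields(
    sol: ChargeSolution,
    facet_indices=None,
    backend: str = "exact",
    precision: float = 1e-6,
):
    """Two-sided limiting fields (E_in, E_out) at facet centroids.

    The continuous part is the primary field plus the principal-value charge
    sum (the self facet contributes only its in-plane component); the sides
    then differ by the local sheet jump: E_in/out = Ec -/+ n c / 2, so
    n . (E_out - E_in) = c exactly.

    Tangential components come from centroid collocation; the normal
    component of the secondary part is the same facet average the boundary
    operator uses, so the interface current condition is satisfied at the
    solver-residual level.
    """
    head = sol.head
    if facet_indices is None:
        facet_indices = np.arange(head.n_facets)
    facet_indices = np.asarray(facet_indices, dtype=np.int64).ravel()
    pts = head.centroids[facet_indices]

    q = sol.c * head.areas
    Ec = coulomb_field(head.centroids, q, pts, backend, precision) / FOUR_PI

    # near corrections, including the self facet's in-plane principal value
    mi, ni = near_pairs(head, near_eta(precision))
    sel = np.isin(mi, facet_indices)
    mi, ni = mi[sel], ni[sel]
    pos = np.full(head.n_facets, -1, dtype=np.int64)
    pos[facet_indices] = np.arange(len(facet_indices))
    rows = pos[mi]
    if mi.size:
        T = _triangle_fields_pairwise(head.face_vertices[ni], head.centroids[mi])
        d = head.centroids[mi] - head.centroids[ni]
        r = np.linalg.norm(d, axis=1)
        pc = head.areas[ni, None] * d / (FOUR_PI * r[:, None] ** 3)
        np.add.at(Ec, rows, sol.c[ni, None] * (T - pc))
    # self principal value (in-plane part; normal component is exactly zero)
    T_self = _triangle_fields_pairwise(
        head.face_vertices[facet_indices], pts
    )
    Ec += sol.c[facet_indices, None] * T_self

    # replace the normal secondary component by the operator-consistent
    # facet average
    nrm = head.normals[facet_indices]
    ndot_avg = ndot_secondary_averaged(
        head, sol.c, backend=backend, precision=precision
    )[facet_indices]
    Ec += nrm * (ndot_avg - np.einsum("fk,fk->f", nrm, Ec))[:, None]

    Ec += primary_efield(sol.coil, pts)
    jump = 0.5 * sol.c[facet_indices, None] * head.normals[facet_indices]
    return Ec - jump, Ec + jump


@dataclass
class ContinuityReport:
    residual: np.ndarray  # per-facet, dimensionless
    rms: float
    max: float
    field_scale: float    # V/m


def continuity_residual(
    sol: ChargeSolution,
    backend: str = "exact",
    precision: float = 1e-6,
) -> ContinuityReport:
    """Relative violation of sigma_in n.E_in = sigma_out n.E_out per facet.

    Normalized by (sigma_in + sigma_out) times the RMS total-field magnitude
    over all facets; reported, never thrown.
    """
    head = sol.head
    E_in, E_out = interface_fields(sol, backend=backend, precision=precision)
    n = head.normals
    jin = head.sigma_in * np.einsum("fk,fk->f", n, E_in)
    jout = head.sigma_out * np.einsum("fk,fk->f", n, E_out)
    scale = float(np.sqrt(np.mean(0.5 * (E_in ** 2 + E_out ** 2).sum(axis=1))))
    if scale == 0.0:
        scale = 1.0
    res = np.abs(jin - jout) / ((head.sigma_in + head.sigma_out) * scale)
    return ContinuityReport(
        residual=res, rms=float(np.sqrt(np.mean(res ** 2))),
        max=float(res.max()), field_scale=scale,
    )


# ---------------------------------------------------------------------------
# Error metrics and ROI selection
# ---------------------------------------------------------------------------


def field_errors(
    E_ref: np.ndarray,
    E_test: np.ndarray,
    weights: np.ndarray | None = None,
    trim_fraction: float = 0.0,
):
    """Relative vector-field and magnitude errors over a point set.

        Error_total = ||E_ref - E_test|| / ||E_ref||
        Error_mag   = || |E_ref| - |E_test| || / || |E_ref| ||

    with the (optionally weighted) 2-norm over all points.  A nonzero
    ``trim_fraction`` removes that fraction of the points with the largest
    local vector error before computing both norms (outlier trimming).
    """
    E_ref = np.atleast_2d(np.asarray(E_ref, dtype=np.float64))
    E_test = np.atleast_2d(np.asarray(E_test, dtype=np.float64))
    if E_ref.shape != E_test.shape:
        raise ValueError("field arrays must have the same shape")
    n = len(E_ref)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=np.float64)
    if trim_fraction > 0.0:
        local = np.linalg.norm(E_ref - E_test, axis=1)
        keep = np.argsort(local)[: max(1, int(np.ceil(n * (1.0 - trim_fraction))))]
        E_ref, E_test, w = E_ref[keep], E_test[keep], w[keep]
    ref_norm = np.sqrt(np.sum(w * (E_ref ** 2).sum(axis=1)))
    if ref_norm == 0.0:
        raise ValueError("reference field is identically zero")
    err_total = np.sqrt(np.sum(w * ((E_ref - E_test) ** 2).sum(axis=1))) / ref_norm
    mag_ref = np.linalg.norm(E_ref, axis=1)
    mag_test = np.linalg.norm(E_test, axis=1)
    mag_norm = np.sqrt(np.sum(w * mag_ref ** 2))
    err_mag = np.sqrt(np.sum(w * (mag_ref - mag_test) ** 2)) / mag_norm
    return float(err_total), float(err_mag)


def roi_select(points: np.ndarray, target, radius: float) -> np.ndarray:
    """Boolean mask of points within the closed ball of ``radius`` around
    ``target`` (the conventional region of interest is a 2 cm sphere about
    the stimulation target)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    target = np.asarray(target, dtype=np.float64)
    return np.linalg.norm(points - target, axis=1) <= radius


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def save_field_samples(samples: FieldSamples, path, fmt: str = "csv") -> None:
    """Write samples as delimited text (x,y,z,Ex,Ey,Ez,|E|), a binary .npz
    container, or ASCII legacy-VTK polydata for visualization."""
    E = samples.E_total
    if fmt == "csv":
        mag = np.linalg.norm(E, axis=1)
        data = np.column_stack([samples.points, E, mag])
        np.savetxt(path, data, delimiter=",", header="x,y,z,Ex,Ey,Ez,|E|")
    elif fmt == "npz":
        np.savez(
            path, points=samples.points, E_total=E,
            E_primary=samples.E_primary, E_secondary=samples.E_secondary,
        )
    elif fmt == "vtk":
        pts = samples.points
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\ntmsbem field samples\n")
            fh.write(f"ASCII\nDATASET POLYDATA\nPOINTS {len(pts)} double\n")
            for p in pts:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            fh.write(f"POINT_DATA {len(pts)}\nVECTORS E_total double\n")
            for e in E:
                fh.write(f"{e[0]:.9g} {e[1]:.9g} {e[2]:.9g}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
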