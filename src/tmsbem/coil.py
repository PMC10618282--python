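"""TMS coil models as collections of elementary current elements.

A coil is a table of straight current elements: a position ``p_j`` (m) and
an oriented length vector ``m_j`` (m, direction x segment length x winding
weight), driven by a common current slew rate dI/dt (A/s).  In the
quasistatic regime the coil's primary (inductive) electric field is

    E_p(r) = -(mu0 / 4 pi) * dI/dt * sum_j m_j / |r - p_j|,

the time derivative of the magnetic vector potential of the elements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: mu0 / 4 pi, exact SI value used throughout.
MU0_OVER_4PI = 1e-7


@dataclass
class CoilModel:
    positions: np.ndarray  # (M, 3) element positions, m
    moments: np.ndarray    # (M, 3) oriented length vectors, m
    didt: float            # A/s
    name: str = ""

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.moments = np.ascontiguousarray(self.moments, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (M, 3)")
        if self.moments.shape != self.positions.shape:
            raise ValueError("moments must match positions shape")
        if len(self.positions) == 0:
            raise ValueError("coil needs at least one element")
        if not (np.isfinite(self.positions).all() and np.isfinite(self.moments).all()):
            raise ValueError("coil arrays must be finite")
        self.didt = float(self.didt)

    @property
    def n_elements(self) -> int:
        return len(self.positions)

    def with_didt(self, didt: float) -> "CoilModel":
        return replace(self, didt=float(didt))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _loop_elements(center, radius, turns, segments, sense):
    """Closed polygonal loop in the z=0 plane; sense +1 = counter-clockwise
    seen from +z.  Elements sit at chord midpoints with chord moments."""
    ang = 2.0 * np.pi * np.arange(segments + 1) / segments
    if sense < 0:
        ang = ang[::-1]
    ring = np.stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang),
         np.full(segments + 1, center[2])], axis=1
    )
    pos = 0.5 * (ring[:-1] + ring[1:])
    mom = ring[1:] - ring[:-1]
    return np.tile(pos, (turns, 1)), np.tile(mom, (turns, 1))


def build_figure8_coil(
    radius: float,
    turns: int = 1,
    segments_per_turn: int = 64,
    wing_separation: float | None = None,
    didt: float = 9.4e7,
    name: str = "figure8",
) -> CoilModel:
    """Parametric figure-8 (butterfly) coil.

    Two coplanar circular wings with opposite winding sense lie in the z=0
    plane with centers on the x axis, ``wing_separation`` apart (default
    ``2*radius``: touching wings).  Coil axis is +z, handle direction +x.
    The opposite senses make the wing B-fields add constructively on the
    axis between the wings.  Element count is ``2*turns*segments_per_turn``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if segments_per_turn < 8:
        raise ValueError("segments_per_turn must be >= 8")
    if turns < 1:
        raise ValueError("turns must be >= 1")
    if wing_separation is None:
        wing_separation = 2.0 * radius
    half = 0.5 * float(wing_separation)
    p1, m1 = _loop_elements(np.array([+half, 0.0, 0.0]), radius, turns,
                            segments_per_turn, +1)
    p2, m2 = _loop_elements(np.array([-half, 0.0, 0.0]), radius, turns,
                            segments_per_turn, -1)
    return CoilModel(np.vstack([p1, p2]), np.vstack([m1, m2]), didt, name)


def build_circular_loop(
    radius: float,
    turns: int = 1,
    segments_per_turn: int = 64,
    didt: float = 9.4e7,
    name: str = "loop",
) -> CoilModel:
    """Single circular loop in the z=0 plane centered at the origin
    (counter-clockwise seen from +z).  Handy for axisymmetric validation."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if segments_per_turn < 8:
        raise ValueError("segments_per_turn must be >= 8")
    p, m = _loop_elements(np.zeros(3), radius, turns, segments_per_turn, +1)
    return CoilModel(p, m, didt, name)


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


def place_coil(
    coil: CoilModel,
    target,
    axis_dir,
    handle_dir,
    standoff: float = 0.0,
) -> CoilModel:
    """Rigidly place a coil relative to a stimulation target.

    ``axis_dir`` is the unit direction from the coil into the head (the coil
    frame's +z axis maps to ``-axis_dir``); ``handle_dir`` is where the coil
    frame's +x axis (the handle) maps.  The coil center lands at
    ``target - standoff * axis_dir``, i.e. ``standoff`` meters back from the
    target along the coil axis.  Moments rotate with the coil; distances are
    preserved exactly.
    """
    target = np.asarray(target, dtype=np.float64)
    a = np.asarray(axis_dir, dtype=np.float64)
    h = np.asarray(handle_dir, dtype=np.float64)
    na, nh = np.linalg.norm(a), np.linalg.norm(h)
    if na == 0 or nh == 0:
        raise ValueError("direction vectors must be nonzero")
    a = a / na
    h = h / nh
    # re-orthogonalize handle against axis if needed
    h = h - np.dot(h, a) * a
    nh = np.linalg.norm(h)
    if nh < 1e-12:
        raise ValueError("handle_dir parallel to axis_dir")
    h = h / nh
    zc = -a                      # coil +z maps here
    xc = h                       # coil +x maps here
    yc = np.cross(zc, xc)
    rot = np.stack([xc, yc, zc], axis=1)  # columns are images of x, y, z
    center = target - standoff * a
    return CoilModel(
        coil.positions @ rot.T + center,
        coil.moments @ rot.T,
        coil.didt,
        coil.name,
    )


# ---------------------------------------------------------------------------
# Primary field
# ---------------------------------------------------------------------------


def primary_efield(
    coil: CoilModel,
    points,
    backend: str = "exact",
    precision: float = 1e-6,
    block: int = 4_000_000,
) -> np.ndarray:
    """Primary (inductive) E-field of the coil at the given points, V/m.

    Exact pairwise summation by default; ``backend="treecode"`` switches to
    the Barnes-Hut backend for large element x point counts.  Points closer
    than 1e-12 m to an element are regularized by that distance; a point
    exactly on an element raises.
    """
    points = np.ascontiguousarray(points, dtype=np.float64)
    squeeze = points.ndim == 1
    if squeeze:
        points = points[None, :]
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    pref = -MU0_OVER_4PI * coil.didt
    if coil.didt == 0.0:
        return np.zeros(3) if squeeze else np.zeros_like(points)

    if backend == "treecode" and coil.n_elements * len(points) > 1_000_000:
        from .summation import treecode_vector_potential

        out = pref * treecode_vector_potential(
            coil.positions, coil.moments, points, precision
        )
    else:
        out = np.zeros_like(points)
        step = max(1, block // max(1, coil.n_elements))
        for s in range(0, len(points), step):
            blk = points[s : s + step]
            d = blk[:, None, :] - coil.positions[None, :, :]  # (P, M, 3)
            r = np.linalg.norm(d, axis=2)
            if np.any(r == 0.0):
                raise ValueError("observation point coincides with a coil element")
            r = np.maximum(r, 1e-12)
            out[s : s + step] = pref * np.einsum("mk,pm->pk", coil.moments, 1.0 / r)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Coil element table I/O (CSV)
# ---------------------------------------------------------------------------


def save_coil(coil: CoilModel, path) -> None:
    """Write a coil element table: ``# didt=<A/s> name=<label>`` header then
    one ``x,y,z,mx,my,mz`` row per element (meters)."""
    data = np.hstack([coil.positions, coil.moments])
    header = f"didt={coil.didt!r} name={coil.name}\nx,y,z,mx,my,mz"
    np.savetxt(path, data, delimiter=",", header=header)


def load_coil(path, didt: float | None = None) -> CoilModel:
    """Read a coil element table written by :func:`save_coil`.  ``didt``
    overrides the value stored in the file."""
    file_didt, name = 0.0, ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if tok.startswith("didt="):
                    file_didt = float(tok[5:])
                elif tok.startswith("name="):
                    name = tok[5:]
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape[1] != 6:
        raise ValueError("coil table must have 6 columns: x,y,z,mx,my,mz")
    return CoilModel(
        data[:, :3], data[:, 3:], file_didt if didt is None else float(didt), name
    )
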