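"""Analytic total E-field inside a spherically symmetric conductor.

For any conductor whose conductivity depends only on radius (a homogeneous
sphere, a four-layer sphere head phantom, ...), the total quasistatic field
induced by an external coil is

    E(r) = E_p(r) - grad phi(r),

where phi is harmonic inside the outer sphere r = R and satisfies the
Neumann condition  d phi / d r = r_hat . E_p  on r = R (no current leaves
the conductor).  The interior field is independent of the radial
conductivity profile and has zero radial component everywhere -- the
classical spherically-symmetric-conductor result, which makes this solution
the ground truth for validating the BEM on multilayer sphere models.

phi is computed by real, fully (4 pi) normalized spherical-harmonic
expansion: the boundary data is projected on a Gauss-Legendre x uniform
azimuth grid, and the regular solid-harmonic series is differentiated term
by term.  Near the polar axis (and at the origin) the spherical-component
synthesis is replaced by central finite differences of phi, which is
pole-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .coil import CoilModel, primary_efield


class ExpansionTailError(RuntimeError):
    """The spherical-harmonic tail exceeds tolerance; increase lmax."""


@dataclass
class SphereModel:
    """Spherically symmetric conductor: outer radius plus (optional) layer
    radii and conductivities.  The layers never enter the analytic field --
    they exist so profile-independence can be asserted against the BEM."""

    outer_radius: float
    layer_radii: tuple = ()
    layer_sigmas: tuple = ()

    def __post_init__(self):
        if self.outer_radius <= 0:
            raise ValueError("outer_radius must be positive")
        radii = (self.outer_radius,) + tuple(self.layer_radii)
        if any(b >= a for a, b in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly decreasing")
        if any(s <= 0 for s in self.layer_sigmas):
            raise ValueError("interior conductivities must be positive")


# ---------------------------------------------------------------------------
# Normalized associated Legendre functions
# ---------------------------------------------------------------------------


def _legendre_norm(lmax: int, x: np.ndarray, s: np.ndarray | None = None) -> np.ndarray:
    """4 pi fully normalized P-bar_lm(x), shape (lmax+1, lmax+1, P).

    Geodesy convention: mean square of P-bar_lm(cos theta) * cos(m lambda)
    over the sphere is 1 (the sqrt(2) azimuth factor for m > 0 is folded
    in).  Standard stable l-recurrence, good far beyond degree 60.  Passing
    sin(theta) explicitly avoids cancellation in 1 - x^2 near the poles.
    """
    x = np.asarray(x, dtype=np.float64)
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None)) if s is None else np.asarray(s)
    P = np.zeros((lmax + 1, lmax + 1) + x.shape)
    P[0, 0] = 1.0
    for m in range(1, lmax + 1):
        f = np.sqrt((2 * m + 1) / (2.0 * m))
        if m == 1:
            f *= np.sqrt(2.0)
        P[m, m] = f * s * P[m - 1, m - 1]
    for m in range(0, lmax):
        P[m + 1, m] = np.sqrt(2 * m + 3) * x * P[m, m]
        for l in range(m + 2, lmax + 1):
            a = np.sqrt((2 * l - 1) * (2 * l + 1) / ((l - m) * (l + m)))
            b = np.sqrt(
                (2 * l + 1) * (l + m - 1) * (l - m - 1)
                / ((l - m) * (l + m) * (2 * l - 3))
            )
            P[l, m] = a * x * P[l - 1, m] - b * P[l - 2, m]
    return P


def _legendre_dtheta(P: np.ndarray, x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """d P-bar_lm / d theta from the same recurrence family.

    Uses sin(theta) dP/dtheta = l x P_lm - c_lm P_(l-1)m; callers must keep
    points off the poles (handled upstream by the finite-difference
    fallback)."""
    lmax = P.shape[0] - 1
    s = np.maximum(s, 1e-300)
    dP = np.zeros_like(P)
    for m in range(0, lmax + 1):
        for l in range(m, lmax + 1):
            c = np.sqrt((l * l - m * m) * (2 * l + 1) / (2 * l - 1)) if l > 0 else 0.0
            prev = P[l - 1, m] if l - 1 >= m else 0.0
            dP[l, m] = (l * x * P[l, m] - c * prev) / s
    return dP


# ---------------------------------------------------------------------------
# Boundary-data expansion
# ---------------------------------------------------------------------------


def _fit_boundary(coil: CoilModel, R: float, lmax: int, oversample: int = 2):
    """Coefficients (g_lm, h_lm) of r_hat . E_p on the sphere r = R."""
    ntheta = oversample * (lmax + 1)
    nlam = oversample * (2 * lmax + 1)
    xg, wg = leggauss(ntheta)
    lam = 2.0 * np.pi * np.arange(nlam) / nlam
    st = np.sqrt(1.0 - xg ** 2)
    pts = np.empty((ntheta, nlam, 3))
    pts[:, :, 0] = R * st[:, None] * np.cos(lam)[None, :]
    pts[:, :, 1] = R * st[:, None] * np.sin(lam)[None, :]
    pts[:, :, 2] = R * xg[:, None]
    Ep = primary_efield(coil, pts.reshape(-1, 3)).reshape(ntheta, nlam, 3)
    g = np.einsum("ijk,ijk->ij", pts, Ep) / R  # r_hat . E_p

    cosm = np.cos(np.outer(np.arange(lmax + 1), lam))  # (m, nlam)
    sinm = np.sin(np.outer(np.arange(lmax + 1), lam))
    C = g @ cosm.T / nlam  # (ntheta, m)
    S = g @ sinm.T / nlam
    P = _legendre_norm(lmax, xg)  # (l, m, ntheta)
    # projection: 4pi-normalized basis, mean square 1; the 1/2 from the
    # Gauss weight normalization, the azimuth mean absorbs cos^2 -> 1/2
    # via the complementary sqrt(2) already folded into P-bar for m > 0.
    glm = 0.5 * np.einsum("lmt,t,tm->lm", P, wg, C)
    hlm = 0.5 * np.einsum("lmt,t,tm->lm", P, wg, S)
    hlm[:, 0] = 0.0
    return glm, hlm


# ---------------------------------------------------------------------------
# Interior synthesis
# ---------------------------------------------------------------------------


def _grad_phi(points, glm, hlm, R, pole_sin=1e-6, fd_step_frac=1e-5):
    """Gradient of the interior harmonic potential at Cartesian points."""
    lmax = glm.shape[0] - 1
    points = np.atleast_2d(points)
    r = np.linalg.norm(points, axis=1)
    s_frac = np.where(r > 0, np.hypot(points[:, 0], points[:, 1]) / np.maximum(r, 1e-300), 0.0)
    regular = (r > 1e-9 * R) & (s_frac > pole_sin)
    out = np.empty_like(points)
    if np.any(regular):
        out[regular] = _grad_phi_spherical(points[regular], glm, hlm, R)
    irregular = ~regular
    if np.any(irregular):
        h = fd_step_frac * R
        pts = points[irregular]
        grad = np.empty_like(pts)
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = h
            grad[:, k] = (
                _phi(pts + dp, glm, hlm, R) - _phi(pts - dp, glm, hlm, R)
            ) / (2 * h)
        out[irregular] = grad
    return out


def _angular(points, lmax):
    r = np.linalg.norm(points, axis=1)
    rr = np.maximum(r, 1e-300)
    x = np.clip(points[:, 2] / rr, -1.0, 1.0)
    s = np.hypot(points[:, 0], points[:, 1]) / rr
    lam = np.arctan2(points[:, 1], points[:, 0])
    P = _legendre_norm(lmax, x, s)
    return r, x, s, lam, P


def _phi(points, glm, hlm, R):
    lmax = glm.shape[0] - 1
    r, x, s, lam, P = _angular(points, lmax)
    mm = np.arange(lmax + 1)
    cosm = np.cos(lam[:, None] * mm[None, :])  # (P, m)
    sinm = np.sin(lam[:, None] * mm[None, :])
    out = np.zeros(len(points))
    for l in range(1, lmax + 1):
        ylm = (
            P[l, : l + 1].T * (glm[l, : l + 1] * cosm[:, : l + 1]
                               + hlm[l, : l + 1] * sinm[:, : l + 1])
        ).sum(axis=1)
        out += (r / R) ** (l - 1) * r / l * ylm
    return out


def _grad_phi_spherical(points, glm, hlm, R):
    lmax = glm.shape[0] - 1
    r, x, s, lam, P = _angular(points, lmax)
    dP = _legendre_dtheta(P, x, s)
    s = np.maximum(s, 1e-300)
    mm = np.arange(lmax + 1)
    cosm = np.cos(lam[:, None] * mm[None, :])
    sinm = np.sin(lam[:, None] * mm[None, :])

    g_r = np.zeros(len(points))
    g_t = np.zeros(len(points))
    g_l = np.zeros(len(points))
    for l in range(1, lmax + 1):
        cg = glm[l, : l + 1] * cosm[:, : l + 1] + hlm[l, : l + 1] * sinm[:, : l + 1]
        dg = (-glm[l, : l + 1] * sinm[:, : l + 1] + hlm[l, : l + 1] * cosm[:, : l + 1])
        rad = (r / R) ** (l - 1)
        g_r += rad * (P[l, : l + 1].T * cg).sum(axis=1)
        g_t += rad / l * (dP[l, : l + 1].T * cg).sum(axis=1)
        g_l += rad / l * (P[l, : l + 1].T * (mm[: l + 1][None, :] * dg)).sum(axis=1) / s
    # unit vectors
    rh = points / np.maximum(r, 1e-300)[:, None]
    lamh = np.stack([-np.sin(lam), np.cos(lam), np.zeros_like(lam)], axis=1)
    thh = np.cross(lamh, rh)
    return g_r[:, None] * rh + g_t[:, None] * thh + g_l[:, None] * lamh


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def analytic_sphere_efield(
    coil: CoilModel,
    points: np.ndarray,
    R: float,
    lmax: int = 60,
    tail_tol: float = 1e-6,
    oversample: int = 2,
) -> np.ndarray:
    """Total induced E-field inside a spherically symmetric conductor.

    All coil elements must lie strictly outside the sphere of radius ``R``
    and all points strictly inside.  The expansion tail is estimated at the
    outermost evaluation radius; :class:`ExpansionTailError` suggests a
    larger ``lmax`` when it exceeds ``tail_tol``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    rc = np.linalg.norm(coil.positions, axis=1)
    if np.any(rc <= R):
        raise ValueError("coil elements must lie strictly outside the sphere")
    rp = np.linalg.norm(points, axis=1)
    if np.any(rp >= R):
        raise ValueError("evaluation points must lie strictly inside the sphere")

    glm, hlm = _fit_boundary(coil, R, lmax, oversample)

    # tail estimate at the outermost evaluation radius
    rmax = float(rp.max()) if len(rp) else 0.0
    deg_amp = np.sqrt((glm ** 2 + hlm ** 2).sum(axis=1))
    with np.errstate(over="ignore"):
        weight = deg_amp * (rmax / R) ** np.maximum(np.arange(lmax + 1) - 1, 0)
    total = weight[1:].sum()
    tail = weight[max(1, lmax - 4):].sum()
    if total > 0 and tail / total > tail_tol:
        raise ExpansionTailError(
            f"expansion tail fraction {tail / total:.2e} exceeds {tail_tol:.1e}; "
            f"increase lmax (currently {lmax}) or move the coil farther out"
        )

    Ep = primary_efield(coil, points)
    return Ep - _grad_phi(points, glm, hlm, R)
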