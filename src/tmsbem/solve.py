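"""Iterative (GMRES) and direct (factorize once, solve many) solution paths.

The BEM system is a discretized second-kind Fredholm equation, hence well
conditioned: unrestarted, unpreconditioned GMRES converges in a few tens of
iterations.  The direct path factors the system matrix once per head model
and reuses the factorization across arbitrarily many right-hand sides (one
per coil placement).  Two factorization methods exist:

* ``dense``: LU with partial pivoting of the assembled matrix;
* ``compressed``: a block-low-rank (BLR) LU over a spatial ordering of the
  facets -- off-diagonal blocks of the factors are truncated to the
  requested precision by SVD, diagonal blocks stay dense.  This matches the
  accuracy contract of hierarchically compressed direct solvers (a
  precision-tunable approximation of A^-1) at small scale; no claim is made
  about asymptotic complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import time

import numpy as np
from scipy.linalg import lu_factor, lu_solve, svd
from scipy.sparse.linalg import gmres

from .geometry import HeadModel
from .operator import BemOperator, DENSE_CAP, DenseCapExceeded, assemble_dense
from .summation import check_precision


@dataclass
class IterativeReport:
    solution: np.ndarray          # per-facet scaled charge density c, V/m
    iterations: int
    residual_history: np.ndarray  # relative 2-norm per iteration
    converged: bool
    final_residual: float


def solve_iterative(
    op,
    b: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> IterativeReport:
    """Unrestarted GMRES on the (matrix-free or dense) BEM operator.

    Returns the scaled charge density and the relative-residual history;
    ``converged`` is False (no exception) if ``max_iter`` is exhausted.
    """
    b = np.asarray(b, dtype=np.float64).ravel()
    if np.any(~np.isfinite(b)):
        raise ValueError("right-hand side contains non-finite entries")
    if not (0.0 < tol < 1.0):
        raise ValueError("tol must be in (0, 1)")
    nrm_b = np.linalg.norm(b)
    if nrm_b == 0.0:
        return IterativeReport(np.zeros_like(b), 0, np.zeros(0), True, 0.0)

    A = op.aslinearoperator() if isinstance(op, BemOperator) else op
    matvec = op.matvec if isinstance(op, BemOperator) else (lambda v: A @ v)

    history = []
    # restart = max_iter with a single outer cycle: full, unrestarted GMRES
    x, info = gmres(
        A, b, rtol=tol, atol=0.0, restart=max_iter, maxiter=1,
        callback=lambda pr: history.append(float(pr)), callback_type="pr_norm",
    )
    final = float(np.linalg.norm(matvec(x) - b) / nrm_b)
    return IterativeReport(
        solution=x,
        iterations=len(history),
        residual_history=np.asarray(history),
        converged=(info == 0 and final <= tol * 1.01),
        final_residual=final,
    )


# ---------------------------------------------------------------------------
# Direct factorization
# ---------------------------------------------------------------------------


@dataclass
class DirectFactorization:
    """Reusable decomposition of the BEM system matrix."""

    method: str                  # "dense" | "compressed"
    n: int
    build_precision: float
    build_seconds: float
    perm: np.ndarray             # spatial facet ordering (identity for dense)
    _dense_lu: tuple | None = None
    _blocks: list = field(default_factory=list)       # block slices (in perm order)
    _diag: list = field(default_factory=list)         # lu_factor of diagonal blocks
    _lower: dict = field(default_factory=dict)        # (i, k) -> (U, V) with L_ik = U @ V
    _upper: dict = field(default_factory=dict)        # (k, j) -> (U, V) with U_kj = U @ V

    def solve(self, B: np.ndarray) -> np.ndarray:
        """Solve A x = b for one RHS vector or a column-stacked RHS matrix.

        Multi-RHS input is processed column by column, so the result is
        bitwise identical to separate single-RHS solves.
        """
        B = np.asarray(B, dtype=np.float64)
        single = B.ndim == 1
        if single:
            B = B[:, None]
        if B.shape[0] != self.n:
            raise ValueError(f"RHS length {B.shape[0]} != system size {self.n}")
        out = np.empty_like(B)
        for j in range(B.shape[1]):
            out[:, j] = self._solve_one(B[:, j])
        return out[:, 0] if single else out

    def _solve_one(self, b: np.ndarray) -> np.ndarray:
        if self.method == "dense":
            return lu_solve(self._dense_lu, b)
        bp = b[self.perm]
        nb = len(self._blocks)
        y = [bp[s].copy() for s in self._blocks]
        for k in range(nb):
            for j in range(k):
                lr = self._lower.get((k, j))
                if lr is not None:
                    U, V = lr
                    y[k] -= U @ (V @ y[j])
        x = [None] * nb
        for k in range(nb - 1, -1, -1):
            acc = y[k].copy()
            for j in range(nb - 1, k, -1):
                ur = self._upper.get((k, j))
                if ur is not None:
                    U, V = ur
                    acc -= U @ (V @ x[j])
            x[k] = lu_solve(self._diag[k], acc)
        xp = np.concatenate(x)
        inv = np.empty_like(self.perm)
        inv[self.perm] = np.arange(self.n)
        return xp[inv]


def _spatial_blocks(points: np.ndarray, max_block: int):
    """Permutation + block slices from recursive coordinate bisection."""
    n = len(points)
    out_perm = np.empty(n, dtype=np.int64)
    blocks = []
    pos = [0]

    def rec(sel):
        if len(sel) <= max_block:
            s = pos[0]
            out_perm[s : s + len(sel)] = sel
            blocks.append(slice(s, s + len(sel)))
            pos[0] += len(sel)
            return
        pts = points[sel]
        ax = int(np.argmax(pts.max(axis=0) - pts.min(axis=0)))
        med = np.median(pts[:, ax])
        left = sel[pts[:, ax] <= med]
        right = sel[pts[:, ax] > med]
        if len(left) == 0 or len(right) == 0:  # degenerate: split by count
            half = len(sel) // 2
            order = np.argsort(pts[:, ax], kind="stable")
            left, right = sel[order[:half]], sel[order[half:]]
        rec(left)
        rec(right)

    rec(np.arange(n))
    return out_perm, blocks


def _compress(M: np.ndarray, eps: float):
    """Adaptive-rank factorization M ~= U @ V with spectral truncation at
    eps relative to the block's largest singular value; returns None (keep
    dense) when low rank saves nothing."""
    if M.shape[0] == 0 or M.shape[1] == 0:
        return None
    u, s, vt = svd(M, full_matrices=False)
    if s[0] == 0.0:
        return np.zeros((M.shape[0], 1)), np.zeros((1, M.shape[1]))
    rank = int(np.sum(s > eps * s[0]))
    rank = max(rank, 1)
    # C-contiguous copies so solves are bitwise reproducible after a
    # serialization round trip (matmul takes the same BLAS path)
    return np.ascontiguousarray(u[:, :rank] * s[:rank]), np.ascontiguousarray(vt[:rank])


def factorize_direct(
    head_or_matrix,
    method: str = "dense",
    precision: float = 1e-6,
    quadrature_order: int = 1,
    cap: int = DENSE_CAP,
    block_size: int = 512,
) -> DirectFactorization:
    """Factor the BEM system matrix for repeated multi-RHS solves.

    Accepts a :class:`HeadModel` (the matrix is assembled internally) or an
    explicit square matrix.  ``precision`` controls the off-diagonal block
    truncation of the compressed method; it is ignored by the dense method.
    """
    t0 = time.perf_counter()
    if isinstance(head_or_matrix, HeadModel):
        head = head_or_matrix
        if head.n_facets > cap:
            raise DenseCapExceeded(
                f"N={head.n_facets} exceeds assembly cap {cap}"
            )
        A = assemble_dense(head, quadrature_order=quadrature_order, cap=cap)
        centroids = head.centroids
    else:
        A = np.array(head_or_matrix, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("matrix must be square")
        centroids = None
    n = A.shape[0]

    if method == "dense":
        fact = DirectFactorization(
            method="dense", n=n, build_precision=0.0, build_seconds=0.0,
            perm=np.arange(n), _dense_lu=lu_factor(A),
        )
    elif method == "compressed":
        precision = check_precision(precision)
        if centroids is None:
            raise ValueError("compressed method needs a HeadModel input")
        perm, blocks = _spatial_blocks(centroids, block_size)
        Ap = A[np.ix_(perm, perm)]
        nb = len(blocks)
        diag, lower, upper = [], {}, {}
        for k in range(nb):
            sk = blocks[k]
            Akk = Ap[sk, sk]
            try:
                dlu = lu_factor(Akk)
            except Exception as exc:  # pragma: no cover - should not occur
                raise RuntimeError(
                    f"singular diagonal block {k} (size {Akk.shape})"
                ) from exc
            diag.append(dlu)
            for i in range(k + 1, nb):
                si = blocks[i]
                lr = _compress(lu_solve(dlu, Ap[si, sk].T, trans=1).T, precision)
                ur = _compress(Ap[sk, si], precision)
                if lr is not None:
                    lower[(i, k)] = lr
                if ur is not None:
                    upper[(k, i)] = ur
            # Schur complement update with the compressed factors, so the
            # factorization is exactly the LU of the BLR approximation
            for i in range(k + 1, nb):
                lr = lower.get((i, k))
                if lr is None:
                    continue
                Lu, Lv = lr
                for j in range(k + 1, nb):
                    ur = upper.get((k, j))
                    if ur is None:
                        continue
                    Uu, Uv = ur
                    Ap[blocks[i], blocks[j]] -= (Lu @ (Lv @ Uu)) @ Uv
        fact = DirectFactorization(
            method="compressed", n=n, build_precision=precision,
            build_seconds=0.0, perm=perm, _blocks=blocks, _diag=diag,
            _lower=lower, _upper=upper,
        )
    else:
        raise ValueError(f"unknown factorization method {method!r}")
    fact.build_seconds = time.perf_counter() - t0
    return fact


def solve_factored(fact: DirectFactorization, B: np.ndarray) -> np.ndarray:
    """x = A^-1 B for one or many right-hand sides (column-stacked)."""
    return fact.solve(B)


# ---------------------------------------------------------------------------
# Factorization cache (versioned binary container)
# ---------------------------------------------------------------------------

_CACHE_VERSION = 1


def save_factorization(fact: DirectFactorization, path) -> None:
    """Serialize a factorization to an .npz container (versioned header)."""
    data = {
        "version": np.int64(_CACHE_VERSION),
        "method": np.array(fact.method),
        "n": np.int64(fact.n),
        "build_precision": np.float64(fact.build_precision),
        "build_seconds": np.float64(fact.build_seconds),
        "perm": fact.perm,
    }
    if fact.method == "dense":
        data["lu"], data["piv"] = fact._dense_lu
    else:
        data["block_starts"] = np.array([s.start for s in fact._blocks])
        data["block_stops"] = np.array([s.stop for s in fact._blocks])
        for k, (lu, piv) in enumerate(fact._diag):
            data[f"diag_lu_{k}"] = lu
            data[f"diag_piv_{k}"] = piv
        for (i, k), (u, v) in fact._lower.items():
            data[f"low_u_{i}_{k}"] = u
            data[f"low_v_{i}_{k}"] = v
        for (k, j), (u, v) in fact._upper.items():
            data[f"up_u_{k}_{j}"] = u
            data[f"up_v_{k}_{j}"] = v
    np.savez(path, **data)


def load_factorization(path) -> DirectFactorization:
    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != _CACHE_VERSION:
            raise ValueError(f"unsupported factorization cache version {z['version']}")
        method = str(z["method"])
        fact = DirectFactorization(
            method=method,
            n=int(z["n"]),
            build_precision=float(z["build_precision"]),
            build_seconds=float(z["build_seconds"]),
            perm=z["perm"],
        )
        if method == "dense":
            # lu_factor returns Fortran-ordered arrays; restore that layout so
            # lu_solve takes the same LAPACK path and results match bitwise
            fact._dense_lu = (np.asfortranarray(z["lu"]), z["piv"])
        else:
            starts, stops = z["block_starts"], z["block_stops"]
            fact._blocks = [slice(int(a), int(b)) for a, b in zip(starts, stops)]
            fact._diag = [
                (np.asfortranarray(z[f"diag_lu_{k}"]), z[f"diag_piv_{k}"])
                for k in range(len(starts))
            ]
            for key in z.files:
                if key.startswith("low_u_"):
                    _, _, i, k = key.split("_")
                    fact._lower[(int(i), int(k))] = (z[key], z[f"low_v_{i}_{k}"])
                elif key.startswith("up_u_"):
                    _, _, k, j = key.split("_")
                    fact._upper[(int(k), int(j))] = (z[key], z[f"up_v_{k}_{j}"])
    return fact
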