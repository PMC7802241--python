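"""Penalized spline design blocks.

Each builder returns a :class:`BasisBlock` holding the design matrix
evaluated at the data, one or more symmetric PSD penalty matrices on the
coefficient space, and an evaluator for new points.  Supported constructions:

* thin plate regression splines (low-rank eigen-approximation of the full
  thin plate problem, 1-D, second-order penalty);
* cubic regression splines in the value-at-knot parameterization;
* cyclic cubic regression splines (value, first and second derivative match
  across the period ends);
* tensor products of two marginal bases with one penalty per margin;
* varying-coefficient (difference smooth) blocks;
* random-intercept (frailty) indicator blocks with identity penalty.

Identifiability: :func:`sum_to_zero` absorbs the constraint "the smooth sums
to zero over the reference grid" into a QR reparameterization, dropping one
coefficient dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "BasisBlock",
    "tprs_basis",
    "cubic_regression_basis",
    "cyclic_cubic_basis",
    "sum_to_zero",
    "varying_coefficient",
    "tensor_product",
    "random_intercept_block",
]


@dataclass
class BasisBlock:
    """A design block with its penalties and evaluator.

    ``evaluate(*args)`` reproduces design rows at new covariate values in
    the *current* (possibly constrained) parameterization.  ``penalties``
    act on the same coefficient space as the design columns.
    """

    design: np.ndarray
    penalties: list[np.ndarray]
    term_kind: str
    labels: list[str]
    evaluate: Callable[..., np.ndarray]
    constraint: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_coef(self) -> int:
        return self.design.shape[1]

    def penalty_quadform(self, beta: np.ndarray) -> list[float]:
        return [float(beta @ S @ beta) for S in self.penalties]


def _check_psd(S: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    S = (S + S.T) / 2.0
    w = np.linalg.eigvalsh(S)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(f"penalty not PSD (min eigenvalue {w.min():.3g})")
    return S


# ---------------------------------------------------------------------------
# thin plate regression splines (1-D, m=2)

def _tps_eta(r: np.ndarray) -> np.ndarray:
    # radial basis for d=1, m=2: eta(r) = r^3 / 12
    return np.abs(r) ** 3 / 12.0


def tprs_basis(t: np.ndarray, k: int, *, max_knots: int = 2000) -> BasisBlock:
    """Low-rank thin plate regression spline basis of rank ``k``.

    The full thin plate spline over the unique values of ``t`` is truncated
    to its ``k - 2`` leading radial eigendirections plus the 2-dimensional
    polynomial null space (constant, linear), which the wiggliness penalty
    ignores.  Columns: [penalized (k-2), intercept, linear].
    """
    t = np.asarray(t, dtype=float)
    if k < 3:
        raise ValueError("thin plate basis needs k >= 3")
    xu = np.unique(t)
    if len(xu) < k:
        raise ValueError(f"k={k} exceeds the {len(xu)} distinct values available")
    if len(xu) > max_knots:
        q = np.linspace(0, 1, max_knots)
        xu = np.unique(np.quantile(xu, q))
    # rescale for conditioning
    shift, scale = xu[0], xu[-1] - xu[0]
    z = (xu - shift) / scale

    E = _tps_eta(z[:, None] - z[None, :])
    w, U = np.linalg.eigh(E)
    order = np.argsort(np.abs(w))[::-1]
    keep = order[:k]
    Uk, Dk = U[:, keep], w[keep]

    T = np.column_stack([np.ones_like(z), z])  # polynomial null space at knots
    # absorb T' Uk delta_k = 0 (orthogonality to the polynomial space)
    A = T.T @ Uk  # rank-2 constraint on the k retained eigen-coefficients
    # null space of A via full SVD
    _, sv, Vt = np.linalg.svd(A, full_matrices=True)
    rank = int(np.sum(sv > sv.max() * 1e-12)) if len(sv) else 0
    Z = Vt[rank:].T  # (k-2) x (k-2-rank)
    n_pen = Z.shape[1]

    S_pen = Z.T @ (Dk[:, None] * Z)
    S = np.zeros((n_pen + 2, n_pen + 2))
    S[:n_pen, :n_pen] = S_pen
    S = _check_psd(S)

    UkZ = Uk @ Z

    def evaluate(x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        zz = (x_new - shift) / scale
        M = _tps_eta(zz[:, None] - z[None, :])
        return np.column_stack([M @ UkZ, np.ones_like(zz), zz])

    design = evaluate(t)
    labels = [f"tprs.{i+1}" for i in range(n_pen)] + ["tprs.const", "tprs.lin"]
    return BasisBlock(
        design=design,
        penalties=[S],
        term_kind="baseline_smooth",
        labels=labels,
        evaluate=evaluate,
        meta={"kind": "tprs", "k": k, "knots": xu, "penalty_rank": n_pen},
    )


# ---------------------------------------------------------------------------
# cubic regression splines (value-at-knot parameterization)

def _cr_FB(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matrices mapping knot values beta to knot second derivatives.

    Natural cubic spline through (knots, beta): second derivatives
    delta = F beta with F = [0; B^{-1} D; 0]; penalty D' B^{-1} D.
    """
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    Binv = np.linalg.inv(B)
    F = np.zeros((k, k))
    F[1:-1] = Binv @ D
    S = D.T @ Binv @ D
    return F, S, h


def _cr_design(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Cardinal cubic spline design rows; linear extrapolation outside."""
    k = len(knots)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    xi = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xi, side="right") - 1, 0, k - 2)
    h = knots[j + 1] - knots[j]
    am = (knots[j + 1] - xi) / h
    ap = (xi - knots[j]) / h
    cm = ((knots[j + 1] - xi) ** 3 / h - h * (knots[j + 1] - xi)) / 6.0
    cp = ((xi - knots[j]) ** 3 / h - h * (xi - knots[j])) / 6.0
    X = np.zeros((len(x), k))
    rows = np.arange(len(x))
    np.add.at(X, (rows, j), am)
    np.add.at(X, (rows, j + 1), ap)
    X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
    # linear extrapolation beyond the knot range (natural spline)
    out_lo = x < knots[0]
    out_hi = x > knots[-1]
    if out_lo.any() or out_hi.any():
        eps = (knots[-1] - knots[0]) * 1e-6
        for mask, x0 in ((out_lo, knots[0]), (out_hi, knots[-1])):
            if mask.any():
                b0 = _cr_design(np.array([x0]), knots, F)[0]
                b1 = _cr_design(np.array([x0 + (eps if x0 == knots[0] else -eps)]), knots, F)[0]
                slope = (b1 - b0) / (eps if x0 == knots[0] else -eps)
                X[mask] = b0 + (x[mask] - x0)[:, None] * slope
    return X


def cubic_regression_basis(x: np.ndarray, k: int, knots: np.ndarray | None = None) -> BasisBlock:
    """Cubic regression spline with ``k`` knots at quantiles of the unique
    values of ``x`` (coefficients are the function values at the knots)."""
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise ValueError("cubic regression basis needs k >= 3")
    if knots is None:
        xu = np.unique(x)
        if len(xu) < k:
            raise ValueError(f"k={k} exceeds the {len(xu)} distinct values available")
        knots = np.unique(np.quantile(xu, np.linspace(0, 1, k)))
    knots = np.asarray(knots, dtype=float)
    F, S, _ = _cr_FB(knots)
    S = _check_psd(S)

    def evaluate(x_new: np.ndarray) -> np.ndarray:
        return _cr_design(x_new, knots, F)

    return BasisBlock(
        design=evaluate(x),
        penalties=[S],
        term_kind="baseline_smooth",
        labels=[f"cr.{i+1}" for i in range(len(knots))],
        evaluate=evaluate,
        meta={"kind": "cr", "k": k, "knots": knots, "penalty_rank": len(knots) - 2},
    )


# ---------------------------------------------------------------------------
# cyclic cubic regression splines

def _cc_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic B, D with f(knot_K) = f(knot_1); K-1 free coefficients."""
    h = np.diff(knots)  # length K-1
    n = len(h)  # number of free coefficients
    B = np.zeros((n, n))
    D = np.zeros((n, n))
    for i in range(n):
        im = (i - 1) % n
        B[i, i] = (h[im] + h[i]) / 3.0
        B[i, (i + 1) % n] += h[i] / 6.0
        B[(i + 1) % n, i] += h[i] / 6.0
        D[i, i] = -(1.0 / h[im] + 1.0 / h[i])
        D[i, im] += 1.0 / h[im]
        D[i, (i + 1) % n] += 1.0 / h[i]
    return B, D


def cyclic_cubic_basis(
    x: np.ndarray,
    k: int,
    period: float = 365.0,
    domain_start: float = 1.0,
) -> BasisBlock:
    """Periodic cubic regression spline over ``[domain_start,
    domain_start + period)`` with ``k`` evenly spaced knots.

    The fitted function, its first and its second derivative match at the
    period ends (day 365 wraps to day 1 for the default calendar domain).
    Coefficients are the function values at the first ``k - 1`` knots.
    """
    x = np.asarray(x, dtype=float)
    if k < 4:
        raise ValueError("cyclic cubic basis needs k >= 4")
    if np.any(x < domain_start) or np.any(x > domain_start + period):
        raise ValueError(f"values outside [{domain_start}, {domain_start + period}]")
    knots = np.linspace(domain_start, domain_start + period, k)
    B, D = _cc_matrices(knots)
    Binv = np.linalg.inv(B)
    F = Binv @ D  # free-coef values -> second derivatives at free knots
    S = _check_psd(D.T @ Binv @ D)
    n = k - 1

    def evaluate(x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        xw = domain_start + np.mod(x_new - domain_start, period)
        j = np.clip(np.searchsorted(knots, xw, side="right") - 1, 0, k - 2)
        h = knots[j + 1] - knots[j]
        am = (knots[j + 1] - xw) / h
        ap = (xw - knots[j]) / h
        cm = ((knots[j + 1] - xw) ** 3 / h - h * (knots[j + 1] - xw)) / 6.0
        cp = ((xw - knots[j]) ** 3 / h - h * (xw - knots[j])) / 6.0
        X = np.zeros((len(x_new), n))
        rows = np.arange(len(x_new))
        np.add.at(X, (rows, j % n), am)
        np.add.at(X, (rows, (j + 1) % n), ap)
        X += cm[:, None] * F[j % n] + cp[:, None] * F[(j + 1) % n]
        return X

    return BasisBlock(
        design=evaluate(x),
        penalties=[S],
        term_kind="baseline_smooth",
        labels=[f"cc.{i+1}" for i in range(n)],
        evaluate=evaluate,
        meta={"kind": "cc", "k": k, "knots": knots, "period": period, "penalty_rank": n - 1},
    )


# ---------------------------------------------------------------------------
# constraint and composition

def sum_to_zero(block: BasisBlock, grid_design: np.ndarray | None = None) -> BasisBlock:
    """Absorb the constraint sum_j f(grid_j) = 0 by QR reparameterization.

    ``grid_design`` is the design evaluated on the reference grid (default:
    the block's own data design).  One coefficient dimension is dropped; the
    penalties are transformed consistently; the evaluator is wrapped so that
    prediction happens in the constrained parameterization.
    """
    if block.constraint is not None:
        raise ValueError("block already constrained")
    G = block.design if grid_design is None else np.asarray(grid_design, dtype=float)
    c = G.sum(axis=0)
    # Z: orthonormal basis of {beta : c' beta = 0}
    Q, _ = np.linalg.qr(c.reshape(-1, 1), mode="complete")
    Z = Q[:, 1:]
    inner = block.evaluate

    def evaluate(*args) -> np.ndarray:
        return inner(*args) @ Z

    return BasisBlock(
        design=block.design @ Z,
        penalties=[_check_psd(Z.T @ S @ Z) for S in block.penalties],
        term_kind=block.term_kind,
        labels=[f"{block.labels[0].split('.')[0]}.c{i+1}" for i in range(Z.shape[1])],
        evaluate=evaluate,
        constraint="sum-to-zero",
        meta={**block.meta, "constraint_Z": Z},
    )


def varying_coefficient(x: np.ndarray, time_block: BasisBlock) -> BasisBlock:
    """Difference-smooth block: design rows of ``time_block`` scaled by the
    0/1 covariate ``x``; represents the smooth deviation f1(t) of group 1's
    log-hazard from the shared time-constant effect."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"varying_coefficient expects a 0/1 covariate, got values {uniq[:5]}")
    if time_block.constraint is None:
        raise ValueError("time_block must be constrained (sum_to_zero) first")
    inner = time_block.evaluate

    def evaluate(x_new: np.ndarray, t_new: np.ndarray) -> np.ndarray:
        return np.asarray(x_new, dtype=float)[:, None] * inner(t_new)

    return BasisBlock(
        design=x[:, None] * time_block.design,
        penalties=[S.copy() for S in time_block.penalties],
        term_kind="varying_coefficient",
        labels=[l.replace("tprs", "vc").replace("cr", "vc") for l in time_block.labels],
        evaluate=evaluate,
        constraint=time_block.constraint,
        meta={**time_block.meta, "vc": True},
    )


def tensor_product(time_block: BasisBlock, season_block: BasisBlock, *, max_dim: int = 400) -> BasisBlock:
    """Tensor-product smooth of age and season.

    Row-wise Kronecker of the (unconstrained) marginal designs; two
    penalties, S_time (x) I and I (x) S_season, one per margin, each
    rescaled by its marginal spectral norm so the two smoothing parameters
    are comparable.  Column order: (time index s, season index m).
    """
    if time_block.constraint is not None or season_block.constraint is not None:
        raise ValueError("tensor margins must be unconstrained; constrain the tensor term")
    St = time_block.penalties[0]
    Sm = season_block.penalties[0]
    S_dim, M_dim = St.shape[0], Sm.shape[0]
    if S_dim * M_dim > max_dim:
        raise ValueError(f"tensor dimension {S_dim}x{M_dim} exceeds cap {max_dim}")
    St = St / np.linalg.norm(St, 2)
    Sm = Sm / np.linalg.norm(Sm, 2)
    P_time = _check_psd(np.kron(St, np.eye(M_dim)))
    P_season = _check_psd(np.kron(np.eye(S_dim), Sm))
    et, em = time_block.evaluate, season_block.evaluate

    def evaluate(t_new: np.ndarray, x_new: np.ndarray) -> np.ndarray:
        A, B = et(t_new), em(x_new)
        return (A[:, :, None] * B[:, None, :]).reshape(len(A), -1)

    design = (time_block.design[:, :, None] * season_block.design[:, None, :]).reshape(
        len(time_block.design), -1
    )
    labels = [f"te.{s+1}.{m+1}" for s in range(S_dim) for m in range(M_dim)]
    return BasisBlock(
        design=design,
        penalties=[P_time, P_season],
        term_kind="tensor",
        labels=labels,
        evaluate=evaluate,
        meta={
            "kind": "tensor",
            "S": S_dim,
            "M": M_dim,
            "period": season_block.meta.get("period"),
            "penalty_rank": None,
        },
    )


def random_intercept_block(subject_ids: np.ndarray) -> BasisBlock:
    """Frailty block: subject indicator design with identity penalty.

    The smoothing parameter attached to the identity penalty is the frailty
    precision 1/sigma^2, so REML selection of it estimates the Gaussian
    frailty variance.
    """
    uniq, inv = np.unique(np.asarray(subject_ids), return_inverse=True)
    n = len(uniq)

    def evaluate(ids_new: np.ndarray) -> np.ndarray:
        ids_new = np.asarray(ids_new)
        X = np.zeros((len(ids_new), n))
        lookup = {s: i for i, s in enumerate(uniq)}
        for r, s in enumerate(ids_new):
            X[r, lookup[s]] = 1.0
        return X

    design = np.zeros((len(inv), n))
    design[np.arange(len(inv)), inv] = 1.0
    return BasisBlock(
        design=design,
        penalties=[np.eye(n)],
        term_kind="random_intercept",
        labels=[f"frailty.{s}" for s in uniq],
        evaluate=evaluate,
        meta={"kind": "frailty", "codes": inv, "subjects": uniq, "penalty_rank": n},
    )
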