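"""Penalized Poisson fitting for piece-wise exponential data.

The working model is Poisson: event indicators with log-exposure offsets,
log link.  At fixed smoothing parameters the penalized likelihood is
maximized by Penalized Iteratively Re-weighted Least Squares (P-IRLS) with
step halving.  Smoothing parameters — including the frailty precision
1/sigma^2 attached to the random-intercept identity penalty — are selected
by Laplace-approximate restricted maximum likelihood (REML) over log
smoothing parameters.

The frailty block is handled by a Schur-complement (arrowhead) solver: the
subject-indicator columns contribute a diagonal block, so solves, log
determinants and the marginal covariance of the dense coefficients cost
O(n_subjects * p^2) instead of O((n_subjects + p)^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse
from scipy.stats import chi2, norm

from .basis import (
    BasisBlock,
    cubic_regression_basis,
    cyclic_cubic_basis,
    sum_to_zero,
    tensor_product,
    tprs_basis,
    varying_coefficient,
)

__all__ = ["ModelSpec", "TensorSpec", "PAMMFit", "fit", "edf", "smooth_test"]

_ETA_CLIP = 30.0


@dataclass(frozen=True)
class TensorSpec:
    """Tensor-product age x season term (replaces the baseline smooth)."""

    season_col: str = "current_doy"
    S: int = 8
    M: int = 8
    period: float = 365.0


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description on a PED table.

    * model 1: ``covariate`` set, ``time_varying=False`` — hazard
      exp(b0 + b1 x + f0(t_j) + z).
    * model 2: ``time_varying=True`` adds the difference smooth x * f1(t_j).
    * model 3: ``tensor`` set (and usually no binary covariate) — hazard
      exp(b0 + g(t_j, season) + z).

    ``frailty`` adds the Gaussian per-subject random intercept.
    """

    covariate: str | None = None
    time_varying: bool = False
    baseline_k: int = 10
    baseline: bool = True
    tensor: TensorSpec | None = None
    frailty: bool = True

    def __post_init__(self) -> None:
        if self.time_varying and self.covariate is None:
            raise ValueError("time_varying requires a covariate")
        if self.tensor is not None and self.baseline:
            object.__setattr__(self, "baseline", False)
        if not self.baseline and self.tensor is None and self.time_varying:
            raise ValueError("time-varying effect needs a time term")


@dataclass
class TermInfo:
    name: str
    sl: slice
    kind: str  # parametric | baseline_smooth | varying_coefficient | tensor
    block: BasisBlock | None = None


@dataclass
class PenaltyInfo:
    term: str
    sl: slice
    S: np.ndarray  # penalty on the term's coefficient slice
    rank: int
    logdet_pos: float  # log pseudo-determinant of S (constant part)
    label: str


@dataclass
class DesignInfo:
    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    terms: dict[str, TermInfo]
    penalties: list[PenaltyInfo]
    tensor_term: str | None
    tensor_rank: int
    frailty_codes: np.ndarray | None
    subjects: np.ndarray | None
    Zs: scipy.sparse.csr_matrix | None
    t_grid: np.ndarray
    interval_widths: np.ndarray
    spec: ModelSpec


def build_design(ped: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Assemble the dense design, penalty list and frailty indexing."""
    if len(ped) == 0 or ped["event"].sum() < 1:
        raise ValueError("PED is degenerate: no rows or no events")
    y = ped["event"].to_numpy(dtype=float)
    offset = ped["offset"].to_numpy(dtype=float)
    t = ped["t_j"].to_numpy(dtype=float)
    t_grid = np.unique(t)
    tau0 = float(ped["tstart"].min())
    interval_widths = np.diff(np.concatenate([[tau0], t_grid]))

    cols: list[np.ndarray] = [np.ones((len(ped), 1))]
    terms: dict[str, TermInfo] = {"intercept": TermInfo("intercept", slice(0, 1), "parametric")}
    penalties: list[PenaltyInfo] = []
    p = 1

    if spec.covariate is not None:
        x = ped[spec.covariate].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"covariate {spec.covariate!r} has missing values")
        cols.append(x[:, None])
        terms[spec.covariate] = TermInfo(spec.covariate, slice(p, p + 1), "parametric")
        p += 1
        ev_by_group = pd.Series(y).groupby(x).sum()
        if (ev_by_group == 0).any():
            warnings.warn(
                f"covariate {spec.covariate!r}: a level has zero events; "
                "estimates/variances may be unstable (separation)",
                RuntimeWarning,
            )

    def _add_block(name: str, block: BasisBlock) -> None:
        nonlocal p
        sl = slice(p, p + block.n_coef)
        terms[name] = TermInfo(name, sl, block.term_kind, block)
        cols.append(block.design)
        for i, S in enumerate(block.penalties):
            S = (S + S.T) / 2
            nrm = np.linalg.norm(S, 2)
            if nrm > 0:
                S = S / nrm  # unit spectral norm so lambdas are comparable
            w = np.linalg.eigvalsh(S)
            pos = w[w > w.max() * 1e-10] if w.max() > 0 else np.array([])
            penalties.append(
                PenaltyInfo(
                    term=name,
                    sl=sl,
                    S=S,
                    rank=len(pos),
                    logdet_pos=float(np.sum(np.log(pos))) if len(pos) else 0.0,
                    label=f"{name}" if len(block.penalties) == 1 else f"{name}.{i+1}",
                )
            )
        p += block.n_coef

    tensor_term = None
    tensor_rank = 0
    if spec.baseline:
        raw = tprs_basis(t, spec.baseline_k)
        f0 = sum_to_zero(raw, grid_design=raw.evaluate(t_grid))
        _add_block("f0", f0)
    if spec.time_varying:
        raw = tprs_basis(t, spec.baseline_k)
        tb = sum_to_zero(raw, grid_design=raw.evaluate(t_grid))
        f1 = varying_coefficient(ped[spec.covariate].to_numpy(dtype=float), tb)
        _add_block("f1", f1)
    if spec.tensor is not None:
        ts = spec.tensor
        if ts.season_col not in ped.columns:
            raise ValueError(f"season column {ts.season_col!r} not in PED")
        doy = ped[ts.season_col].to_numpy(dtype=float)
        tm = cubic_regression_basis(t, ts.S)
        sm = cyclic_cubic_basis(doy, ts.M, period=ts.period)
        te = tensor_product(tm, sm)
        g = sum_to_zero(te)
        _add_block("g", g)
        tensor_term = "g"
        # rank of the summed tensor penalty (constant for positive weights)
        tot = sum(S for S in g.penalties)
        w = np.linalg.eigvalsh((tot + tot.T) / 2)
        tensor_rank = int(np.sum(w > w.max() * 1e-9))

    X = np.hstack(cols)
    frailty_codes = None
    subjects = None
    Zs = None
    if spec.frailty:
        subjects, frailty_codes = np.unique(ped["id"].to_numpy(), return_inverse=True)
        Zs = scipy.sparse.csr_matrix(
            (np.ones(len(ped)), (np.arange(len(ped)), frailty_codes)),
            shape=(len(ped), len(subjects)),
        )
    return DesignInfo(
        X=X,
        y=y,
        offset=offset,
        terms=terms,
        penalties=penalties,
        tensor_term=tensor_term,
        tensor_rank=tensor_rank,
        frailty_codes=frailty_codes,
        subjects=subjects,
        Zs=Zs,
        t_grid=t_grid,
        interval_widths=interval_widths,
        spec=spec,
    )


def _assemble_S(d: DesignInfo, lam: np.ndarray) -> np.ndarray:
    p = d.X.shape[1]
    S = np.zeros((p, p))
    for pen, lk in zip(d.penalties, lam):
        S[pen.sl, pen.sl] += lk * pen.S
    return S


@dataclass
class _PIRLSResult:
    beta: np.ndarray
    b: np.ndarray | None
    eta: np.ndarray
    loglik: float
    penalty: float
    logdet_H: float
    V_dd: np.ndarray
    A_u: np.ndarray  # profiled unpenalized information for the dense block
    dtil: np.ndarray | None
    C: np.ndarray | None
    iters: int
    converged: bool


def _pirls(
    d: DesignInfo,
    lam: np.ndarray,
    lam_frailty: float | None,
    start: tuple[np.ndarray, np.ndarray | None] | None = None,
    tol: float = 1e-11,
    maxit: int = 200,
) -> _PIRLSResult:
    X, y, offset = d.X, d.y, d.offset
    N, p = X.shape
    S_d = _assemble_S(d, lam)
    have_f = d.frailty_codes is not None and lam_frailty is not None
    codes = d.frailty_codes
    Zs = d.Zs

    if start is not None:
        beta = start[0].copy()
        b = start[1].copy() if (have_f and start[1] is not None) else (np.zeros(len(d.subjects)) if have_f else None)
    else:
        beta = np.zeros(p)
        beta[0] = np.log(y.sum() / np.exp(offset).sum())
        b = np.zeros(len(d.subjects)) if have_f else None

    def lin_pred(beta: np.ndarray, b) -> np.ndarray:
        eta_lin = X @ beta
        if have_f:
            eta_lin = eta_lin + b[codes]
        return np.clip(eta_lin, -_ETA_CLIP, _ETA_CLIP)

    def pen_ll(beta, b, eta_lin) -> tuple[float, float]:
        eta = offset + eta_lin
        ll = float(y @ eta - np.exp(eta).sum())
        pen = float(beta @ S_d @ beta)
        if have_f:
            pen += lam_frailty * float(b @ b)
        return ll, pen

    eta_lin = lin_pred(beta, b)
    ll, pen = pen_ll(beta, b, eta_lin)
    obj = ll - 0.5 * pen
    converged = False
    K_cho = None
    dtil = None
    C = None
    A = None
    it = 0
    for it in range(1, maxit + 1):
        mu = np.exp(offset + eta_lin)
        w = mu
        z = eta_lin + (y - mu) / mu
        wz = w * z
        WX = X * w[:, None]
        A = X.T @ WX
        rhs_d = X.T @ wz
        if have_f:
            dvec = np.asarray(Zs.T @ w).ravel()
            C = np.asarray(Zs.T @ WX)  # n_s x p
            rhs_f = np.asarray(Zs.T @ wz).ravel()
            dtil = dvec + lam_frailty
            K = A + S_d - C.T @ (C / dtil[:, None])
            K_cho = scipy.linalg.cho_factor((K + K.T) / 2)
            beta_new = scipy.linalg.cho_solve(K_cho, rhs_d - C.T @ (rhs_f / dtil))
            b_new = (rhs_f - C @ beta_new) / dtil
        else:
            K = A + S_d
            K_cho = scipy.linalg.cho_factor((K + K.T) / 2)
            beta_new = scipy.linalg.cho_solve(K_cho, rhs_d)
            b_new = None
        # step halving on penalized log-likelihood decrease
        step = 1.0
        for _ in range(30):
            beta_try = beta + step * (beta_new - beta)
            b_try = b + step * (b_new - b) if have_f else None
            eta_try = lin_pred(beta_try, b_try)
            ll_t, pen_t = pen_ll(beta_try, b_try, eta_try)
            obj_t = ll_t - 0.5 * pen_t
            if np.isfinite(obj_t) and obj_t >= obj - 1e-12 * (abs(obj) + 1):
                break
            step /= 2.0
        beta, b, eta_lin = beta_try, b_try, eta_try
        ll, pen = ll_t, pen_t
        if abs(obj_t - obj) < tol * (abs(obj_t) + 1.0):
            obj = obj_t
            converged = True
            break
        obj = obj_t

    # final curvature at the solution
    mu = np.exp(offset + eta_lin)
    w = mu
    WX = X * w[:, None]
    A = X.T @ WX
    if have_f:
        dvec = np.asarray(Zs.T @ w).ravel()
        C = np.asarray(Zs.T @ WX)
        dtil = dvec + lam_frailty
        A_u = A - C.T @ (C / dtil[:, None])
        K = A_u + S_d
        K_cho = scipy.linalg.cho_factor((K + K.T) / 2)
        logdet_H = float(np.sum(np.log(dtil)) + 2 * np.sum(np.log(np.diag(K_cho[0]))))
    else:
        A_u = A
        K = A + S_d
        K_cho = scipy.linalg.cho_factor((K + K.T) / 2)
        logdet_H = float(2 * np.sum(np.log(np.diag(K_cho[0]))))
    V_dd = scipy.linalg.cho_solve(K_cho, np.eye(X.shape[1]))
    return _PIRLSResult(
        beta=beta,
        b=b,
        eta=offset + eta_lin,
        loglik=ll,
        penalty=pen,
        logdet_H=logdet_H,
        V_dd=(V_dd + V_dd.T) / 2,
        A_u=A_u,
        dtil=dtil,
        C=C,
        iters=it,
        converged=converged,
    )


def _logdet_S_plus(d: DesignInfo, lam: np.ndarray, lam_frailty: float | None) -> float:
    """log pseudo-determinant of the total penalty over its range space."""
    out = 0.0
    # group penalties by term to handle multi-penalty (tensor) blocks jointly
    by_term: dict[str, list[tuple[PenaltyInfo, float]]] = {}
    for pen, lk in zip(d.penalties, lam):
        by_term.setdefault(pen.term, []).append((pen, lk))
    for term, entries in by_term.items():
        if len(entries) == 1:
            pen, lk = entries[0]
            out += pen.rank * np.log(lk) + pen.logdet_pos
        else:
            tot = sum(lk * pen.S for pen, lk in entries)
            w = np.linalg.eigvalsh((tot + tot.T) / 2)
            rank = d.tensor_rank if term == d.tensor_term else int(np.sum(w > w.max() * 1e-9))
            out += float(np.sum(np.log(np.sort(w)[-rank:])))
    if lam_frailty is not None and d.frailty_codes is not None:
        out += len(d.subjects) * np.log(lam_frailty)
    return out


@dataclass
class PAMMFit:
    """A fitted piece-wise exponential additive mixed model."""

    design: DesignInfo
    beta: np.ndarray
    cov: np.ndarray  # Bayesian posterior covariance of the dense coefficients
    lambdas: dict[str, float]
    sigma_frailty: float | None
    frailty_blups: pd.Series | None
    edf_by_coef: np.ndarray
    edf_by_term: dict[str, float]
    edf_frailty: float | None
    smooth_tests: dict[str, tuple[float, float, float]]  # term -> (stat, rank, p)
    loglik: float
    reml: float
    iterations: int
    converged: bool
    reml_evals: int = 0

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    @property
    def t_grid(self) -> np.ndarray:
        return self.design.t_grid

    def coef_table(self) -> pd.DataFrame:
        labels: list[str] = []
        for name, ti in self.design.terms.items():
            if ti.block is None:
                labels.extend([name] * (ti.sl.stop - ti.sl.start))
            else:
                labels.extend(f"{name}.{l}" for l in ti.block.labels)
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame({"coef": self.beta, "se": se}, index=labels)

    def parametric_estimate(self, term: str) -> tuple[float, float, float]:
        """(estimate, se, two-sided Wald p) for a parametric term."""
        ti = self.design.terms[term]
        if ti.kind != "parametric":
            raise ValueError(f"{term!r} is not parametric")
        i = ti.sl.start
        est = float(self.beta[i])
        se = float(np.sqrt(self.cov[i, i]))
        pval = float(2 * norm.sf(abs(est) / se)) if se > 0 else float("nan")
        return est, se, pval

    def summary(self) -> dict:
        """JSON-exportable fit summary (Table-2-style layout)."""
        out: dict = {
            "terms": {},
            "lambdas": self.lambdas,
            "sigma_frailty": self.sigma_frailty,
            "loglik": self.loglik,
            "reml": self.reml,
            "converged": self.converged,
        }
        for name, ti in self.design.terms.items():
            entry: dict = {"kind": ti.kind, "edf": self.edf_by_term.get(name)}
            if ti.kind == "parametric" and name != "intercept":
                est, se, p = self.parametric_estimate(name)
                entry.update(
                    estimate=est,
                    hr=float(np.exp(est)),
                    hr_ci=[float(np.exp(est - 1.96 * se)), float(np.exp(est + 1.96 * se))],
                    p=p,
                )
            if name in self.smooth_tests:
                stat, rank, p = self.smooth_tests[name]
                entry.update(test_stat=stat, test_rank=rank, test_p=p)
            out["terms"][name] = entry
        if self.edf_frailty is not None:
            out["edf_frailty"] = self.edf_frailty
        return out


def fit(
    ped: pd.DataFrame,
    spec: ModelSpec,
    *,
    lambdas: Sequence[float] | dict[str, float] | None = None,
    sigma_frailty: float | None = None,
    maxit_reml: int = 100,
    reml_tol: float = 1e-7,
    pirls_tol: float = 1e-11,
) -> PAMMFit:
    """Fit the penalized Poisson working model on a PED table.

    Smoothing parameters (and the frailty precision) are chosen by
    Laplace-approximate REML unless fixed via ``lambdas`` (per-penalty, in
    the order of the design's penalty list or keyed by penalty label) and
    ``sigma_frailty``.

    Raises
    ------
    RuntimeError
        If P-IRLS fails to converge at the selected smoothing parameters.
    """
    d = build_design(ped, spec)
    n_pen = len(d.penalties)
    have_f = spec.frailty

    fixed_lam: np.ndarray | None = None
    if lambdas is not None:
        if isinstance(lambdas, dict):
            fixed_lam = np.array([lambdas[p.label] for p in d.penalties], dtype=float)
        else:
            fixed_lam = np.asarray(list(lambdas), dtype=float)
            if len(fixed_lam) != n_pen:
                raise ValueError(f"expected {n_pen} smoothing parameters, got {len(fixed_lam)}")
    fixed_lf = (1.0 / sigma_frailty**2) if (sigma_frailty is not None) else None

    warm: dict = {"start": None}
    evals = {"n": 0}

    # inner solves during the smoothing-parameter search can be looser than
    # the final fit; the REML noise this induces (~1e-5 absolute) is well
    # below the Nelder-Mead function tolerance
    search_tol = max(pirls_tol, 1e-9)

    def neg_reml(rho: np.ndarray) -> float:
        lam = np.exp(rho[:n_pen]) if fixed_lam is None else fixed_lam
        if have_f:
            lf = np.exp(rho[-1]) if fixed_lf is None else fixed_lf
        else:
            lf = None
        res = _pirls(d, lam, lf, start=warm["start"], tol=search_tol)
        warm["start"] = (res.beta, res.b)
        evals["n"] += 1
        reml = (
            res.loglik
            - 0.5 * res.penalty
            + 0.5 * _logdet_S_plus(d, lam, lf)
            - 0.5 * res.logdet_H
        )
        return -reml

    n_free = (n_pen if fixed_lam is None else 0) + (1 if (have_f and fixed_lf is None) else 0)

    def wrapped(rho_free: np.ndarray) -> float:
        if fixed_lam is None:
            rho_full = np.asarray(rho_free, dtype=float)
        else:
            rho_full = np.concatenate([np.log(fixed_lam), np.atleast_1d(rho_free)])
        return neg_reml(rho_full)

    n_evals = 0
    if n_free:
        # coarse coordinate-wise sweep to land in the REML basin, then a
        # derivative-free polish (inner-loop noise makes FD gradients unsafe)
        rho0 = np.zeros(n_free)
        if have_f and fixed_lf is None:
            rho0[-1] = np.log(4.0)  # sigma ~ 0.5
        coarse = np.arange(-9.0, 13.6, 4.5)
        for _ in range(2):
            for k in range(n_free):
                vals = []
                for c in coarse:
                    trial = rho0.copy()
                    trial[k] = c
                    vals.append(wrapped(trial))
                rho0[k] = coarse[int(np.argmin(vals))]
        opt = scipy.optimize.minimize(
            wrapped,
            rho0,
            method="Nelder-Mead",
            options={
                "maxfev": 50 * n_free + 40,
                "xatol": 1e-2,
                "fatol": reml_tol * 1e3,
                "initial_simplex": rho0 + 1.0 * np.vstack([np.zeros(n_free), np.eye(n_free)]),
            },
        )
        rho_free = opt.x
        n_evals = evals["n"]
        lam = np.exp(rho_free[:n_pen]) if fixed_lam is None else fixed_lam
        lf = None
        if have_f:
            lf = np.exp(rho_free[-1]) if fixed_lf is None else fixed_lf
    else:
        lam = fixed_lam if fixed_lam is not None else np.empty(0)
        lf = fixed_lf if have_f else None

    res = _pirls(d, lam, lf, start=warm["start"], tol=pirls_tol, maxit=500)
    if not res.converged:
        raise RuntimeError(
            f"P-IRLS failed to converge after {res.iters} iterations "
            f"(lambdas={lam}, frailty precision={lf})"
        )
    reml_val = (
        res.loglik - 0.5 * res.penalty + 0.5 * _logdet_S_plus(d, lam, lf) - 0.5 * res.logdet_H
    )

    # effective degrees of freedom: F = I - H^{-1} S on the dense block
    S_d = _assemble_S(d, lam)
    F_dd = np.eye(d.X.shape[1]) - res.V_dd @ S_d
    edf_coef = np.diag(F_dd).copy()
    edf_term = {name: float(edf_coef[ti.sl].sum()) for name, ti in d.terms.items()}
    edf_f = None
    if have_f:
        q = np.einsum("ij,jk,ik->i", res.C, res.V_dd, res.C)
        tr_Hinv_ff = float(np.sum(1.0 / res.dtil) + np.sum(q / res.dtil**2))
        edf_f = float(len(d.subjects) - lf * tr_Hinv_ff)

    lambdas_out = {p.label: float(l) for p, l in zip(d.penalties, lam)}
    sigma = float(1.0 / np.sqrt(lf)) if have_f else None
    blups = pd.Series(res.b, index=d.subjects) if have_f else None

    fit_obj = PAMMFit(
        design=d,
        beta=res.beta,
        cov=res.V_dd,
        lambdas=lambdas_out,
        sigma_frailty=sigma,
        frailty_blups=blups,
        edf_by_coef=edf_coef,
        edf_by_term=edf_term,
        edf_frailty=edf_f,
        smooth_tests={},
        loglik=res.loglik,
        reml=float(reml_val),
        iterations=res.iters,
        converged=res.converged,
        reml_evals=n_evals,
    )
    for name, ti in d.terms.items():
        if ti.kind in ("baseline_smooth", "varying_coefficient", "tensor"):
            fit_obj.smooth_tests[name] = smooth_test(fit_obj, name)
    return fit_obj


def edf(fit: PAMMFit, term: str) -> float:
    """Estimated degrees of freedom of a term: the trace of its block of
    the influence matrix F = (X'WX + sum_k lambda_k S_k)^{-1} X'WX."""
    if term == "frailty":
        if fit.edf_frailty is None:
            raise ValueError("model has no frailty term")
        return fit.edf_frailty
    if term not in fit.edf_by_term:
        raise ValueError(f"unknown term {term!r}")
    return fit.edf_by_term[term]


def smooth_test(fit: PAMMFit, term: str) -> tuple[float, float, float]:
    """Wald-type test of "the smooth is zero" (statistic, rank, p-value).

    The fitted curve on the representative-time grid and its Bayesian
    covariance are reduced by an eigen pseudo-inverse whose rank follows the
    term's EDF, and the statistic is referred to a chi-square with that
    rank.
    """
    ti = fit.design.terms.get(term)
    if ti is None or ti.kind == "parametric":
        raise ValueError(f"{term!r} is not a smooth term")
    grid = fit.design.t_grid
    block = ti.block
    if ti.kind == "varying_coefficient":
        Xg = block.evaluate(np.ones(len(grid)), grid)
    elif ti.kind == "tensor":
        # curve over the observed (t, season) data support, subsampled
        d = fit.design
        rows = np.linspace(0, d.X.shape[0] - 1, min(500, d.X.shape[0])).astype(int)
        Xg = d.X[rows, ti.sl]
    else:
        Xg = block.evaluate(grid)
    beta_t = fit.beta[ti.sl]
    V_t = fit.cov[ti.sl, ti.sl]
    fhat = Xg @ beta_t
    Vf = Xg @ V_t @ Xg.T
    w, U = np.linalg.eigh((Vf + Vf.T) / 2)
    ed = fit.edf_by_term[term]
    r = int(np.floor(ed)) + (1 if (ed - np.floor(ed)) >= 0.05 else 0)
    r = max(1, min(r, int(np.sum(w > w.max() * 1e-10))))
    idx = np.argsort(w)[::-1][:r]
    proj = U[:, idx].T @ fhat
    stat = float(np.sum(proj**2 / w[idx]))
    p = float(chi2.sf(stat, df=r))
    return stat, float(r), p
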