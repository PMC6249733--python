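"""Optimizers for nuclear-norm matrix completion with bilinear side information.

The objective (for augmented side matrices X (a x m), Y (b x n)) is

    min_{G,E}  1/2 ||X^T G Y - E||_F^2 + lambda_E ||E||_* + lambda_G ||G||_1
    s.t.       R_Omega(E) = R_Omega(F)

Three solvers are provided:

``fit_stoladmm``
    Stochastic linearized ADMM.  At each iteration the LASSO subproblem for
    G is linearized around the current iterate using only ``s`` sampled rows
    of the implicit Kronecker operator ``A = Y^T kron X^T``, so the full
    ``nm x ab`` operator is never formed.
``fit_ladmm``
    The same iteration with the full (deterministic) gradient, computed in
    matrix form ``X (X^T G Y - B) Y^T``.
``fit_classic_mc``
    Plain nuclear-norm completion without side information (singular value
    thresholding with dual ascent on the observed-entry constraint), used as
    baseline and to initialize E.

Both ADMM variants introduce C = E - X^T G Y and alternate exact/proximal
updates of C, G, E followed by dual ascent on the two multipliers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse.linalg import LinearOperator, lsqr

from .model import BilinearModel, decompose_G
from .operators import (
    ObservedMask,
    SideMatrices,
    kron_row_block,
    operator_norm,
    project_observed,
    soft_threshold,
    svt,
    unvec,
    vec,
)

__all__ = [
    "ProblemData",
    "Hyperparameters",
    "SolverState",
    "IterationWorkspace",
    "FitResult",
    "update_C",
    "stochastic_gradient_g",
    "full_gradient_g",
    "update_G",
    "update_E",
    "update_multipliers",
    "fit_stoladmm",
    "fit_ladmm",
    "fit_classic_mc",
]

logger = logging.getLogger("sidemc")

_EPS = np.finfo(float).eps


def _xtgy(sides: SideMatrices, G: np.ndarray) -> np.ndarray:
    return (sides.X.T @ G) @ sides.Y


def _nuclear_norm(M: np.ndarray) -> float:
    return float(np.linalg.svd(M, compute_uv=False).sum())


@dataclass
class ProblemData:
    """A partially observed matrix F with its mask and (augmented) side features.

    ``F`` may carry NaN at unobserved entries; values on the observed set must
    be finite.  Side matrices are augmented with the all-ones row on
    construction if they are not already.
    """

    F: np.ndarray
    mask: ObservedMask
    sides: SideMatrices

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be two-dimensional")
        if self.F.shape != self.mask.shape:
            raise ValueError(f"F shape {self.F.shape} does not match mask {self.mask.shape}")
        if not self.sides.augmented:
            self.sides = self.sides.augment()
        if self.sides.m != self.F.shape[0] or self.sides.n != self.F.shape[1]:
            raise ValueError(
                f"side matrices describe ({self.sides.m}, {self.sides.n}) entities "
                f"but F is {self.F.shape}"
            )
        if not np.all(np.isfinite(self.F[self.mask.observed])):
            raise ValueError("F must be finite on the observed set")
        self._F_observed: Optional[np.ndarray] = None

    @classmethod
    def from_arrays(cls, F, X, Y, mask: ObservedMask | None = None) -> "ProblemData":
        F = np.asarray(F, dtype=float)
        if mask is None:
            mask = ObservedMask.from_dense(F)
        return cls(F, mask, SideMatrices(X, Y).augment())

    @property
    def m(self) -> int:
        return self.F.shape[0]

    @property
    def n(self) -> int:
        return self.F.shape[1]

    @property
    def F_observed(self) -> np.ndarray:
        """R_Omega(F): observed values with zeros elsewhere."""
        if self._F_observed is None:
            self._F_observed = np.where(self.mask.observed, self.F, 0.0)
        return self._F_observed


@dataclass(frozen=True)
class Hyperparameters:
    """Solver configuration.

    ``s`` defaults to max(1, round(sqrt(a*b / 100))) where ``a*b`` is the
    number of entries of G; ``beta`` defaults to 0.01.  ``tau_policy``
    selects how the proximal parameters are formed: "linearized" uses
    tau_k = tau_safety * sigma_max(A_k)^2 and tau'_k = tau_safety (the
    standard majorization scaling), "paper" uses tau_k just below ||A|| and
    tau'_k just below ||R_Omega(F)||_F with a divergence guard that doubles
    tau whenever a subproblem objective increases.  ``rescale_gradient``
    multiplies the sampled gradient by nm/s so it is unbiased for the full
    gradient; off by default (the plain sum over sampled rows).
    """

    lambda_E: float = 1.0
    lambda_G: float = 1.0
    beta: float = 0.01
    s: Optional[int] = None
    tau_policy: str = "linearized"
    tau_safety: float = 0.99
    rescale_gradient: bool = False
    max_iter: int = 500
    tol: float = 1e-4
    seed: int = 0
    n_jobs: int = 1
    init_mc_iters: int = 10
    g_init: str = "ridge-svt"

    def __post_init__(self):
        if self.lambda_E < 0 or self.lambda_G < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.s is not None and self.s < 1:
            raise ValueError("sampling block size must be a positive integer")
        if self.tau_policy not in ("linearized", "paper"):
            raise ValueError(f"unknown tau_policy {self.tau_policy!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.g_init not in ("ridge-svt", "zero"):
            raise ValueError(f"unknown g_init {self.g_init!r}")

    @staticmethod
    def default_s(a: int, b: int) -> int:
        return max(1, round(math.sqrt(a * b / 100)))


@dataclass
class SolverState:
    """Current iterates: completed matrix E, parameter matrix G, slack C and
    the two multipliers."""

    E: np.ndarray
    G: np.ndarray
    C: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    k: int = 0

    @property
    def g(self) -> np.ndarray:
        return vec(self.G)


@dataclass
class IterationWorkspace:
    """Per-iteration intermediates (see the update operations)."""

    row_indices: Optional[np.ndarray] = None
    Ak: Optional[np.ndarray] = None
    b_full: Optional[np.ndarray] = None
    b_tilde: Optional[np.ndarray] = None
    f1: Optional[np.ndarray] = None
    B2: Optional[np.ndarray] = None
    B3: Optional[np.ndarray] = None
    f2: Optional[np.ndarray] = None
    f3: Optional[np.ndarray] = None


@dataclass
class FitResult:
    """Solver output: parameter matrix G, completed matrix E and diagnostics."""

    G: np.ndarray
    E: np.ndarray
    trace: pd.DataFrame
    converged: bool
    iterations: int
    hyperparameters: Hyperparameters

    @property
    def model(self) -> BilinearModel:
        return decompose_G(self.G)

    @property
    def H(self) -> np.ndarray:
        return self.model.H

    @property
    def u(self) -> np.ndarray:
        return self.model.u

    @property
    def v(self) -> np.ndarray:
        return self.model.v

    @property
    def gamma(self) -> float:
        return self.model.gamma

    def predicted(self, sides: SideMatrices) -> np.ndarray:
        """Model predictions X^T G Y on the training grid (augmented sides)."""
        return _xtgy(sides, self.G)


# ---------------------------------------------------------------------------
# subproblem updates
# ---------------------------------------------------------------------------

def update_C(state: SolverState, data: ProblemData, hp: Hyperparameters) -> np.ndarray:
    """Exact minimizer of the C-subproblem:
    C = beta/(beta+1) (E - X^T G Y + M2/beta)."""
    XtGY = _xtgy(data.sides, state.G)
    return hp.beta / (hp.beta + 1.0) * (state.E - XtGY + state.M2 / hp.beta)


def stochastic_gradient_g(ws: IterationWorkspace, state: SolverState, n_jobs: int = 1) -> np.ndarray:
    """f1 = Ak^T (Ak g - b~) over the sampled constraint rows.

    With ``n_jobs > 1`` the sampled rows are partitioned into shards whose
    contributions are summed, equal to the single-worker value up to
    floating-point reordering.
    """
    g = vec(state.G)
    Ak, b_tilde = ws.Ak, ws.b_tilde
    resid = Ak @ g - b_tilde
    if n_jobs and n_jobs > 1 and Ak.shape[0] >= 2 * n_jobs:
        from joblib import Parallel, delayed

        shards = np.array_split(np.arange(Ak.shape[0]), n_jobs)
        parts = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(lambda ix: Ak[ix].T @ resid[ix])(ix) for ix in shards
        )
        return np.sum(parts, axis=0)
    return Ak.T @ resid


def full_gradient_g(state: SolverState, B: np.ndarray, sides: SideMatrices) -> np.ndarray:
    """Full gradient A^T (A g - b) = vec(X (X^T G Y - B) Y^T) without forming A."""
    R = _xtgy(sides, state.G) - B
    return vec(sides.X @ R @ sides.Y.T)


def update_G(state: SolverState, ws: IterationWorkspace, hp: Hyperparameters, tau: float) -> np.ndarray:
    """Linearized proximal step: soft-threshold g - f1/tau at lambda_G/(tau*beta)."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    z = vec(state.G) - ws.f1 / tau
    g_new = soft_threshold(z, hp.lambda_G / (tau * hp.beta))
    return unvec(g_new, state.G.shape)


def update_E(
    state: SolverState,
    ws: IterationWorkspace,
    hp: Hyperparameters,
    tau_prime: float,
    rank_hint: int | None = None,
    return_values: bool = False,
):
    """SVT step: E <- SVT(E - (f2 + f3)/(2 tau'), lambda_E/(2 beta tau'))."""
    if tau_prime <= 0:
        raise ValueError(f"tau' must be positive, got {tau_prime}")
    point = state.E - (ws.f2 + ws.f3) / (2.0 * tau_prime)
    thr = hp.lambda_E / (2.0 * hp.beta * tau_prime)
    return svt(point, thr, rank_hint=rank_hint, return_values=return_values)


def update_multipliers(
    state: SolverState,
    data: ProblemData,
    hp: Hyperparameters,
    xtgy: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dual ascent: M1 += beta R_Omega(E - F); M2 += beta (E - X^T G Y - C)."""
    if xtgy is None:
        xtgy = _xtgy(data.sides, state.G)
    r1 = project_observed(state.E - data.F_observed, data.mask)
    M1 = state.M1 + hp.beta * r1
    M2 = state.M2 + hp.beta * (state.E - xtgy - state.C)
    return M1, M2


# ---------------------------------------------------------------------------
# classic matrix completion (Eq. without side information)
# ---------------------------------------------------------------------------

def fit_classic_mc(
    F,
    mask: ObservedMask,
    lambda_E: float,
    *,
    max_iter: int = 500,
    tol: float = 1e-5,
    step: float | None = None,
) -> np.ndarray:
    """Nuclear-norm completion by iterative singular value thresholding.

    Solves min lambda_E ||E||_* + 1/2 ||E||_F^2 subject to
    R_Omega(E) = R_Omega(F) by SVT steps with dual ascent on the constraint
    (step size 1.2 * nm/|Omega| unless overridden).  For small lambda_E the
    solution approaches the minimum-nuclear-norm completion.
    """
    if mask.n_observed == 0:
        raise ValueError("mask must contain at least one observed entry")
    F = np.asarray(F, dtype=float)
    Fobs = np.where(mask.observed, F, 0.0)
    if not np.all(np.isfinite(Fobs)):
        raise ValueError("F must be finite on the observed set")
    normF = np.linalg.norm(Fobs)
    if normF == 0:
        return np.zeros_like(Fobs)
    m, n = Fobs.shape
    delta = step if step is not None else 1.2 * m * n / mask.n_observed
    Yk = delta * Fobs
    E = np.zeros_like(Fobs)
    hint = 8
    for _ in range(max_iter):
        E, sv = svt(Yk, lambda_E, rank_hint=hint, return_values=True)
        hint = max(8, sv.size + 2)
        resid = project_observed(Fobs - E, mask)
        if np.linalg.norm(resid) / normF < tol:
            break
        Yk = Yk + delta * resid
    return E


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _masked_ridge_g(data: ProblemData, damp: float = 1e-3, iter_lim: int = 30) -> np.ndarray:
    """Ridge least-squares solution of X^T G Y ~ F on the observed set.

    Solved with LSQR on the implicit Kronecker operator restricted to the
    observed rows; never materializes A.
    """
    sides = data.sides
    a, b = sides.a, sides.b
    m, n = data.m, data.n
    idx = data.mask.linear_indices()
    rhs = data.F_observed.ravel(order="F")[idx]

    def mv(g):
        return _xtgy(sides, unvec(g, (a, b))).ravel(order="F")[idx]

    def rmv(w):
        W = np.zeros(m * n)
        W[idx] = w
        Wm = W.reshape((m, n), order="F")
        return vec(sides.X @ Wm @ sides.Y.T)

    op = LinearOperator((idx.size, a * b), matvec=mv, rmatvec=rmv)
    sol = lsqr(op, rhs, damp=damp, iter_lim=iter_lim)[0]
    return unvec(sol, (a, b))


def _initialize(data: ProblemData, hp: Hyperparameters, rng: np.random.Generator) -> SolverState:
    m, n = data.m, data.n
    a, b = data.sides.a, data.sides.b
    M1 = rng.standard_normal((m, n))
    M2 = rng.standard_normal((m, n))
    if data.mask.n_observed > 0 and np.linalg.norm(data.F_observed) > 0:
        E0 = fit_classic_mc(
            data.F, data.mask, hp.lambda_E, max_iter=hp.init_mc_iters, tol=1e-12
        )
    else:
        E0 = np.zeros((m, n))
    if hp.g_init == "zero" or data.mask.n_observed == 0:
        G0 = np.zeros((a, b))
    else:
        G0 = svt(_masked_ridge_g(data), hp.lambda_G)
    return SolverState(E=E0, G=G0, C=np.zeros((m, n)), M1=M1, M2=M2, k=0)


# ---------------------------------------------------------------------------
# main ADMM loop
# ---------------------------------------------------------------------------

def _g_subobjective(G, ws, sides, hp, full: bool, B=None) -> float:
    if full:
        resid = _xtgy(sides, G) - B
        quad = 0.5 * float(np.sum(resid * resid))
    else:
        r = ws.Ak @ vec(G) - ws.b_tilde
        quad = 0.5 * float(r @ r)
    return hp.lambda_G * float(np.abs(G).sum()) + hp.beta * quad


def _e_subobjective(E, nuc, ws, data, hp) -> float:
    r2 = project_observed(E - ws.B2, data.mask)
    r3 = E - ws.B3
    return (
        hp.lambda_E * nuc
        + 0.5 * hp.beta * float(np.sum(r2 * r2))
        + 0.5 * hp.beta * float(np.sum(r3 * r3))
    )


def _fit(data: ProblemData, hp: Hyperparameters, stochastic: bool) -> FitResult:
    sides = data.sides
    a, b = sides.a, sides.b
    m, n = data.m, data.n
    nm = m * n
    if stochastic:
        s = hp.s if hp.s is not None else Hyperparameters.default_s(a, b)
        s = min(int(s), nm)
    else:
        s = nm
    sampled_path = stochastic  # LADMM always uses the matrix-form gradient
    full_block = s >= nm

    rng = np.random.default_rng(hp.seed)
    state = _initialize(data, hp, rng)
    Fobs = data.F_observed
    mask = data.mask
    normRF = max(np.linalg.norm(Fobs), _EPS)
    opn = operator_norm(sides)

    nuc_E = _nuclear_norm(state.E) if hp.tau_policy == "paper" else 0.0
    rank_hint = None
    rows = []
    converged = False
    guard_limit = 30

    for k in range(hp.max_iter):
        state.k = k
        XtGY = _xtgy(sides, state.G)
        state.C = hp.beta / (hp.beta + 1.0) * (state.E - XtGY + state.M2 / hp.beta)
        B = state.E + state.M2 / hp.beta - state.C

        ws = IterationWorkspace()
        if sampled_path:
            if full_block:
                ws.row_indices = np.arange(nm)
            else:
                ws.row_indices = rng.choice(nm, size=s, replace=False)
            ws.Ak = kron_row_block(sides, ws.row_indices)
            ws.b_tilde = B.ravel(order="F")[ws.row_indices]
            ws.f1 = stochastic_gradient_g(ws, state, n_jobs=hp.n_jobs)
            if hp.rescale_gradient and not full_block:
                ws.f1 = ws.f1 * (nm / s)
            sigma = opn if full_block else float(
                np.linalg.svd(ws.Ak, compute_uv=False)[0]
            )
        else:
            ws.f1 = full_gradient_g(state, B, sides)
            sigma = opn

        if hp.tau_policy == "linearized":
            tau = hp.tau_safety * sigma * sigma
        else:
            tau = hp.tau_safety * sigma
        if sampled_path and not full_block:
            # growing proximal parameter: damps the sampled-gradient noise
            # (without it the G iterate random-walks and the duals diverge)
            tau *= math.sqrt(k + 1.0)
        tau = max(tau, _EPS)

        if hp.tau_policy == "paper":
            base = _g_subobjective(state.G, ws, sides, hp, not sampled_path, B)
            for _ in range(guard_limit):
                G_new = update_G(state, ws, hp, tau)
                if _g_subobjective(G_new, ws, sides, hp, not sampled_path, B) <= base * (
                    1 + 1e-12
                ) + 1e-12:
                    break
                tau *= 2.0
        else:
            G_new = update_G(state, ws, hp, tau)
        state.G = G_new
        XtGY = _xtgy(sides, state.G)

        ws.B2 = project_observed(Fobs - state.M1 / hp.beta, mask)
        ws.B3 = XtGY + state.C - state.M2 / hp.beta
        ws.f2 = project_observed(state.E - Fobs + state.M1 / hp.beta, mask)
        ws.f3 = state.E - ws.B3

        if hp.tau_policy == "linearized":
            tau_p = hp.tau_safety
            E_new, sv = update_E(state, ws, hp, tau_p, rank_hint=rank_hint, return_values=True)
        else:
            tau_p = hp.tau_safety * normRF
            base_e = _e_subobjective(state.E, nuc_E, ws, data, hp)
            for _ in range(guard_limit):
                E_new, sv = update_E(
                    state, ws, hp, tau_p, rank_hint=rank_hint, return_values=True
                )
                if _e_subobjective(E_new, float(sv.sum()), ws, data, hp) <= base_e * (
                    1 + 1e-12
                ) + 1e-12:
                    break
                tau_p *= 2.0
        rank_hint = sv.size + 2
        E_prev, state.E = state.E, E_new
        nuc_E = float(sv.sum())

        state.M1, state.M2 = update_multipliers(state, data, hp, xtgy=XtGY)

        r1 = np.linalg.norm(project_observed(state.E - Fobs, mask)) / normRF
        r2 = np.linalg.norm(state.E - XtGY - state.C) / normRF
        rel_change = np.linalg.norm(state.E - E_prev) / max(np.linalg.norm(E_prev), 1.0)
        diff = XtGY - state.E
        objective = (
            0.5 * float(np.sum(diff * diff))
            + hp.lambda_E * nuc_E
            + hp.lambda_G * float(np.abs(state.G).sum())
        )
        rows.append((k, objective, r1, r2, rel_change))
        if k % 10 == 0:
            logger.info(
                "iter %d: objective=%.6g residual_obs=%.3e residual_couple=%.3e", k, objective, r1, r2
            )
        else:
            logger.debug(
                "iter %d: objective=%.6g residual_obs=%.3e residual_couple=%.3e", k, objective, r1, r2
            )
        if r1 < hp.tol and r2 < hp.tol and rel_change < hp.tol:
            converged = True
            break

    trace = pd.DataFrame(
        rows, columns=["iteration", "objective", "residual_obs", "residual_couple", "rel_change_E"]
    )
    return FitResult(
        G=state.G,
        E=state.E,
        trace=trace,
        converged=converged,
        iterations=len(rows),
        hyperparameters=hp,
    )


def fit_stoladmm(data: ProblemData, hp: Hyperparameters | None = None) -> FitResult:
    """Stochastic linearized ADMM on the side-information completion objective.

    Deterministic given ``hp.seed``.  With ``hp.s >= n*m`` the sampled block
    covers every constraint row and the trajectory coincides with
    :func:`fit_ladmm` (up to floating-point roundoff); the gradient is still
    computed through the explicit sampled-row operator in that case.
    """
    return _fit(data, hp or Hyperparameters(), stochastic=True)


def fit_ladmm(data: ProblemData, hp: Hyperparameters | None = None) -> FitResult:
    """Deterministic linearized ADMM (full gradient in matrix form)."""
    return _fit(data, hp or Hyperparameters(), stochastic=False)
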