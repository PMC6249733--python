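"""Low-level linear operators for bilinear matrix completion.

Conventions
-----------
The target matrix ``F`` is ``m x n`` (row entities by column entities).
Row-side features ``X`` are ``d1 x m`` and column-side features ``Y`` are
``d2 x n``: features live in rows, entities in columns.  Vectorisation is
column-major (``vec`` stacks columns), under which the Kronecker identity

    vec(X^T G Y) = (Y^T kron X^T) vec(G)

holds, and the linear index of entry ``(i, j)`` of an ``m x n`` matrix is
``r = j*m + i``.  All indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "ObservedMask",
    "SideMatrices",
    "project_observed",
    "soft_threshold",
    "svt",
    "augment_features",
    "kron_row_block",
    "operator_norm",
    "vec",
    "unvec",
]

#: matrices whose smaller dimension is at most this use a full LAPACK SVD
#: inside :func:`svt`; larger ones use a rank-growing randomized SVD.
FULL_SVD_MAX = 256


def _as_2d_float(M, name: str = "matrix") -> np.ndarray:
    A = np.asarray(M, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"{name} must be two-dimensional, got shape {A.shape}")
    return A


def vec(G) -> np.ndarray:
    """Column-major vectorisation (stack the columns of ``G``)."""
    return np.asarray(G, dtype=float).ravel(order="F")


def unvec(g, shape) -> np.ndarray:
    """Inverse of :func:`vec` for the given matrix ``shape``."""
    return np.asarray(g, dtype=float).reshape(shape, order="F")


@dataclass(frozen=True)
class ObservedMask:
    """Set of observed entries of an ``m x n`` matrix, stored as a boolean array.

    ``observed[i, j]`` is True when entry ``(i, j)`` was measured.  The
    complement (the missing set) is obtained with :meth:`complement`; the two
    partition the index set exactly.
    """

    observed: np.ndarray

    def __post_init__(self):
        obs = np.asarray(self.observed, dtype=bool)
        if obs.ndim != 2:
            raise ValueError("mask must be two-dimensional")
        object.__setattr__(self, "observed", obs)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], shape: tuple[int, int]) -> "ObservedMask":
        """Build from 0-based (row, col) pairs; rejects duplicates and out-of-range indices."""
        m, n = shape
        obs = np.zeros((m, n), dtype=bool)
        for i, j in pairs:
            if not (0 <= i < m and 0 <= j < n):
                raise ValueError(f"index ({i}, {j}) outside shape ({m}, {n})")
            if obs[i, j]:
                raise ValueError(f"duplicate mask entry ({i}, {j})")
            obs[i, j] = True
        return cls(obs)

    @classmethod
    def from_dense(cls, F) -> "ObservedMask":
        """Observed entries are the finite entries of ``F`` (NaN marks missing)."""
        return cls(np.isfinite(_as_2d_float(F, "F")))

    # -- views -------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.observed.shape

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def pairs(self) -> set[tuple[int, int]]:
        ii, jj = np.nonzero(self.observed)
        return {(int(i), int(j)) for i, j in zip(ii, jj)}

    def complement(self) -> "ObservedMask":
        return ObservedMask(~self.observed)

    def linear_indices(self) -> np.ndarray:
        """Column-major linear indices (r = j*m + i) of the observed entries."""
        return np.flatnonzero(self.observed.ravel(order="F"))


def project_observed(M, mask: ObservedMask) -> np.ndarray:
    """The projection R_Omega: keep entries in the observed set, zero elsewhere."""
    A = _as_2d_float(M, "M")
    if A.shape != mask.shape:
        raise ValueError(f"matrix shape {A.shape} does not match mask shape {mask.shape}")
    return np.where(mask.observed, A, 0.0)


def soft_threshold(v, t: float) -> np.ndarray:
    """Componentwise shrinkage max(|v| - t, 0) * sgn(v), the l1 proximal map."""
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    a = np.asarray(v, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - t, 0.0)


def svt(M, t: float, rank_hint: int | None = None, return_values: bool = False):
    """Singular value thresholding, the proximal operator of ``t * ||.||_*``.

    Small matrices (min dimension <= ``FULL_SVD_MAX``) use a full thin SVD.
    Larger ones use a randomized truncated SVD whose rank is doubled until
    the smallest retained singular value falls below ``t``, so no retained
    component is lost.

    Parameters
    ----------
    rank_hint:
        starting rank for the truncated path (e.g. the rank of the previous
        iterate in an iterative algorithm).
    return_values:
        also return the surviving (already thresholded) singular values.
    """
    A = _as_2d_float(M, "M")
    if not np.all(np.isfinite(A)):
        raise ValueError("svt requires finite entries")
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    mn = min(A.shape)
    if t == 0.0:
        if return_values:
            return A.copy(), np.linalg.svd(A, compute_uv=False)
        return A.copy()
    if mn <= FULL_SVD_MAX:
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
    else:
        # grow the truncation rank until the tail is below the threshold; a
        # full SVD is cheaper once the retained rank is a sizable fraction
        k = max(1, min(int(rank_hint) if rank_hint else 16, mn))
        while True:
            if k > mn // 4:
                U, s, Vt = np.linalg.svd(A, full_matrices=False)
                break
            U, s, Vt = randomized_svd(
                A, n_components=k, n_oversamples=10, n_iter=4, random_state=0
            )
            if s.size and s[-1] < t:
                break
            k = min(mn, 2 * k)
    shrunk = np.maximum(s - t, 0.0)
    keep = shrunk > 0
    Z = (U[:, keep] * shrunk[keep]) @ Vt[keep]
    if return_values:
        return Z, shrunk[keep]
    return Z


def augment_features(X) -> np.ndarray:
    """Append an all-ones row so intercept and linear effects fold into G."""
    A = _as_2d_float(X, "X")
    if A.size == 0:
        raise ValueError("cannot augment an empty feature matrix")
    return np.vstack([A, np.ones((1, A.shape[1]))])


@dataclass(frozen=True)
class SideMatrices:
    """Row-side features ``X`` (d1 x m) and column-side features ``Y`` (d2 x n).

    ``augmented`` records whether the all-ones row has been appended to each;
    callers guard idempotence through this flag (``augment_features`` itself
    always appends).
    """

    X: np.ndarray
    Y: np.ndarray
    augmented: bool = False

    def __post_init__(self):
        object.__setattr__(self, "X", _as_2d_float(self.X, "X"))
        object.__setattr__(self, "Y", _as_2d_float(self.Y, "Y"))

    def augment(self) -> "SideMatrices":
        if self.augmented:
            return self
        return SideMatrices(augment_features(self.X), augment_features(self.Y), True)

    @property
    def a(self) -> int:
        return self.X.shape[0]

    @property
    def b(self) -> int:
        return self.Y.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def n(self) -> int:
        return self.Y.shape[1]


def kron_row_block(sides: SideMatrices, indices: Sequence[int]) -> np.ndarray:
    """Materialize the requested rows of ``A = Y^T kron X^T`` (shape s x a*b).

    Row ``r = j*m + i`` is ``kron(Y[:, j], X[:, i])`` so that, stacking all
    ``n*m`` rows, ``A @ vec(G) == vec(X^T G Y)`` under column-major ``vec``.
    The full operator is never formed: only the ``s`` requested rows are.
    """
    X, Y = sides.X, sides.Y
    m, n = X.shape[1], Y.shape[1]
    idx = np.atleast_1d(np.asarray(indices, dtype=np.int64))
    if idx.size and (idx.min() < 0 or idx.max() >= m * n):
        raise IndexError(f"linear index out of range [0, {m * n})")
    i = idx % m
    j = idx // m
    # rows[r, beta, alpha] = Y[beta, j_r] * X[alpha, i_r]; C-order flatten
    # gives kron index beta*a + alpha, matching column-major vec(G).
    rows = Y[:, j].T[:, :, None] * X[:, i].T[:, None, :]
    return rows.reshape(idx.size, X.shape[0] * Y.shape[0])


def operator_norm(sides: SideMatrices) -> float:
    """Spectral norm of ``Y^T kron X^T`` = sigma_max(X) * sigma_max(Y), without forming it."""
    sx = np.linalg.svd(sides.X, compute_uv=False)
    sy = np.linalg.svd(sides.Y, compute_uv=False)
    return float(sx[0] * sy[0])
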