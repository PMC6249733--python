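"""Synthetic benchmark problems with known ground truth.

Each problem is built as ``F = X^T G Y + N`` from *unaugmented* side
matrices: per-feature rows of X and Y are drawn from a distribution picked
uniformly at random among Gaussian(0,1), Poisson(1) and Gamma(1,1); the
sparse ground-truth interaction matrix G carries N(0, 100) values on a
random support and is redrawn until it is full- or high-rank; the noise N
is i.i.d. N(0,1), so the large interaction signals dominate the noise.
``q`` percent of the entries of F are then removed uniformly at random.

Four standard settings are provided.  Settings II and III append rows to X
and Y that are random linear combinations of the base features, making the
side matrices rank deficient by construction:

=======  ===========  ==========  ==========
setting  F            X           Y
=======  ===========  ==========  ==========
I        200 x 200    15 x 200    20 x 200
II       200 x 200    16 x 200    21 x 200   (1 dependent row each)
III      1000 x 1000  20 x 1000   25 x 1000  (5 dependent rows each)
IV       1000 x 1000  20 x 1000   25 x 1000  (full row rank)
=======  ===========  ==========  ==========

Setting IV reuses setting III's side dimensions but with full-row-rank
features; it is the large-matrix benchmark for timing/accuracy comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .operators import ObservedMask
from .solvers import ProblemData

__all__ = [
    "SETTINGS",
    "SyntheticProblem",
    "generate_side_features",
    "generate_ground_truth_G",
    "generate_problem",
]

SETTINGS = {
    "I": dict(m=200, n=200, d1=15, d2=20, extra_x=0, extra_y=0),
    "II": dict(m=200, n=200, d1=15, d2=20, extra_x=1, extra_y=1),
    "III": dict(m=1000, n=1000, d1=15, d2=20, extra_x=5, extra_y=5),
    "IV": dict(m=1000, n=1000, d1=20, d2=25, extra_x=0, extra_y=0),
}

#: acceptance tolerance for the "full- or high-rank" requirement on G
_RANK_TOL = 1e-8


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SyntheticProblem:
    """A generated problem together with its ground truth."""

    data: ProblemData
    true_F: np.ndarray
    true_G: np.ndarray
    noise: np.ndarray
    setting: str
    q: float
    r: int
    seed: Optional[int]

    @property
    def X(self) -> np.ndarray:
        """Unaugmented row-side features (the solver augments internally)."""
        return self.data.sides.X[:-1]

    @property
    def Y(self) -> np.ndarray:
        return self.data.sides.Y[:-1]

    @property
    def missing(self) -> ObservedMask:
        return self.data.mask.complement()


def generate_side_features(d: int, k: int, rank_deficient_extra: int = 0, seed=None) -> np.ndarray:
    """Draw a (d + extra) x k feature matrix.

    Each of the first ``d`` rows is sampled i.i.d. from one distribution
    chosen uniformly among Gaussian(0,1), Poisson(1) and Gamma(1,1).  The
    remaining ``rank_deficient_extra`` rows are random (standard normal
    coefficient) linear combinations of the first ``d``, so the numerical
    row rank stays ``d``.
    """
    if d < 1 or k < 1 or rank_deficient_extra < 0:
        raise ValueError("invalid feature matrix dimensions")
    rng = _resolve_rng(seed)
    rows = np.empty((d, k))
    families = rng.integers(0, 3, size=d)
    for r, fam in enumerate(families):
        if fam == 0:
            rows[r] = rng.standard_normal(k)
        elif fam == 1:
            rows[r] = rng.poisson(1.0, size=k).astype(float)
        else:
            rows[r] = rng.gamma(1.0, 1.0, size=k)
    if rank_deficient_extra:
        coeff = rng.standard_normal((rank_deficient_extra, d))
        rows = np.vstack([rows, coeff @ rows])
    return rows


def generate_ground_truth_G(
    d1: int,
    d2: int,
    density: float = 0.3,
    seed=None,
    max_retries: int = 50,
) -> np.ndarray:
    """Sparse ground-truth interaction matrix with N(0, 100) nonzeros.

    The support (``round(density * d1 * d2)`` entries) is chosen uniformly at
    random; the draw is repeated until the numerical rank is at least
    ``min(d1, d2) - 1`` ("full- or high-rank").  ``density = 0`` returns the
    zero matrix with the rank condition waived.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = _resolve_rng(seed)
    if density == 0.0:
        return np.zeros((d1, d2))
    n_nonzero = int(round(density * d1 * d2))
    for _ in range(max_retries):
        G = np.zeros(d1 * d2)
        support = rng.choice(d1 * d2, size=n_nonzero, replace=False)
        G[support] = rng.normal(0.0, 10.0, size=n_nonzero)
        G = G.reshape(d1, d2)
        sv = np.linalg.svd(G, compute_uv=False)
        rank = int(np.sum(sv > _RANK_TOL * sv[0])) if sv.size and sv[0] > 0 else 0
        if rank >= min(d1, d2) - 1:
            return G
    raise RuntimeError(
        f"could not draw a high-rank {d1} x {d2} G at density {density} "
        f"in {max_retries} tries"
    )


def generate_problem(
    setting: str,
    q: float,
    seed=None,
    *,
    density: float = 0.3,
    noise_std: float = 1.0,
    dims: dict | None = None,
) -> SyntheticProblem:
    """Assemble a complete synthetic problem for one of the standard settings.

    ``q`` is the percentage of entries removed (exactly ``round(q*m*n/100)``
    of them, uniformly at random).  ``dims`` may override the setting's
    dimensions with a dict of ``m, n, d1, d2, extra_x, extra_y`` — used for
    reduced-size tests; the generation procedure is unchanged.
    """
    if dims is None:
        if setting not in SETTINGS:
            raise ValueError(f"unknown setting {setting!r}; choose from {sorted(SETTINGS)}")
        params = SETTINGS[setting]
    else:
        params = {"extra_x": 0, "extra_y": 0, **dims}
    if not 0.0 <= q <= 100.0:
        raise ValueError("q must be a percentage in [0, 100]")
    rng = _resolve_rng(seed)
    m, n = params["m"], params["n"]
    d1, d2 = params["d1"], params["d2"]
    extra_x, extra_y = params["extra_x"], params["extra_y"]

    X = generate_side_features(d1, m, extra_x, rng)
    Y = generate_side_features(d2, n, extra_y, rng)
    G = generate_ground_truth_G(X.shape[0], Y.shape[0], density, rng)
    noise = rng.normal(0.0, noise_std, size=(m, n)) if noise_std > 0 else np.zeros((m, n))
    true_F = X.T @ G @ Y + noise

    n_missing = int(round(q * m * n / 100.0))
    missing_lin = rng.choice(m * n, size=n_missing, replace=False)
    observed_flat = np.ones(m * n, dtype=bool)
    observed_flat[missing_lin] = False
    mask = ObservedMask(observed_flat.reshape((m, n), order="F"))

    F = true_F.copy()
    F[~mask.observed] = np.nan

    sv = np.linalg.svd(true_F, compute_uv=False)
    r = int(np.sum(sv > 1e-6 * sv[0])) if sv.size and sv[0] > 0 else 0

    data = ProblemData.from_arrays(F, X, Y, mask)
    return SyntheticProblem(
        data=data,
        true_F=true_F,
        true_G=G,
        noise=noise,
        setting=setting if dims is None else f"{setting}*",
        q=float(q),
        r=r,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
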