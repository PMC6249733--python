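"""The fitted bilinear predictor.

A trained completion model is the block matrix

    G = [[H, u],
         [v^T, gamma]]

so that, for augmented feature vectors, ``xbar^T G ybar`` expands to
``x^T H y + x^T u + y^T v + gamma``: an interaction term, two linear terms
and an intercept.  Because the model depends only on side features, it can
score (row entity, column entity) pairs that were absent from training,
e.g. predict the criterion profile of a new subject from genotype alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BilinearModel",
    "decompose_G",
    "reassemble_G",
    "predict_entry",
    "predict_matrix",
    "endorse",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class BilinearModel:
    """Blocks of the parameter matrix G: interaction H (d1 x d2), row effects
    u (d1), column effects v (d2) and intercept gamma."""

    H: np.ndarray
    u: np.ndarray
    v: np.ndarray
    gamma: float

    def __post_init__(self):
        object.__setattr__(self, "H", np.asarray(self.H, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float).ravel())
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float).ravel())
        object.__setattr__(self, "gamma", float(self.gamma))
        if self.H.ndim != 2 or self.H.shape != (self.u.size, self.v.size):
            raise ValueError(
                f"inconsistent blocks: H {self.H.shape}, u {self.u.size}, v {self.v.size}"
            )

    @property
    def d1(self) -> int:
        return self.u.size

    @property
    def d2(self) -> int:
        return self.v.size

    def predict(self, x, y) -> float:
        return predict_entry(self, x, y)


def decompose_G(G) -> BilinearModel:
    """Split the (d1+1) x (d2+1) solver matrix into its model blocks."""
    A = np.asarray(G, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError(f"G must be at least 2 x 2 to carry intercept blocks, got {A.shape}")
    return BilinearModel(
        H=A[:-1, :-1].copy(), u=A[:-1, -1].copy(), v=A[-1, :-1].copy(), gamma=float(A[-1, -1])
    )


def reassemble_G(model: BilinearModel) -> np.ndarray:
    """Inverse of :func:`decompose_G`."""
    a, b = model.d1 + 1, model.d2 + 1
    G = np.empty((a, b))
    G[:-1, :-1] = model.H
    G[:-1, -1] = model.u
    G[-1, :-1] = model.v
    G[-1, -1] = model.gamma
    return G


def predict_entry(model: BilinearModel, x, y) -> float:
    """Score one (row entity, column entity) pair from unaugmented features."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != model.d1 or yv.size != model.d2:
        raise ValueError(
            f"feature lengths ({xv.size}, {yv.size}) do not match model ({model.d1}, {model.d2})"
        )
    return float(xv @ model.H @ yv + xv @ model.u + yv @ model.v + model.gamma)


def predict_matrix(model: BilinearModel, X, Y) -> np.ndarray:
    """All-pairs predictions X^T H Y + linear terms + intercept (X, Y unaugmented)."""
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != model.d1 or Ya.shape[0] != model.d2:
        raise ValueError(
            f"feature counts ({Xa.shape[0]}, {Ya.shape[0]}) do not match model "
            f"({model.d1}, {model.d2})"
        )
    return (
        Xa.T @ model.H @ Ya
        + (Xa.T @ model.u)[:, None]
        + (Ya.T @ model.v)[None, :]
        + model.gamma
    )


def endorse(scores, threshold: float = 0.5) -> np.ndarray:
    """Utility binarisation of raw scores; the pipeline itself evaluates raw values."""
    return np.asarray(scores, dtype=float) >= threshold


def save_model(model: BilinearModel, path, feature_names: tuple[list, list] | None = None) -> None:
    """Serialize as a delimited text dump of G with a small commented header."""
    path = Path(path)
    lines = [
        "# sidemc bilinear model",
        f"# d1 {model.d1}",
        f"# d2 {model.d2}",
    ]
    if feature_names is not None:
        row_names, col_names = feature_names
        lines.append("# row_features " + "\t".join(map(str, row_names)))
        lines.append("# col_features " + "\t".join(map(str, col_names)))
    G = reassemble_G(model)
    body = "\n".join("\t".join(f"{v:.17g}" for v in row) for row in G)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def load_model(path) -> BilinearModel:
    path = Path(path)
    d1 = d2 = None
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) >= 2 and parts[0] == "d1":
                d1 = int(parts[1])
            elif len(parts) >= 2 and parts[0] == "d2":
                d2 = int(parts[1])
            continue
        rows.append([float(tok) for tok in line.split("\t")])
    G = np.asarray(rows, dtype=float)
    if d1 is not None and d2 is not None and G.shape != (d1 + 1, d2 + 1):
        raise ValueError(f"model file header ({d1}, {d2}) inconsistent with body {G.shape}")
    return decompose_G(G)
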