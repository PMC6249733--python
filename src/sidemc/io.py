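"""Delimited-text file formats for matrices, masks and whole problems.

Matrices are plain delimited text (TSV by default, CSV accepted by file
extension or explicit delimiter) with no header; the NaN token marks
missing entries, which is only legal in the target matrix F.  Mask files
are two-column (row, col) index lists, 1-based, with a header line; they
are converted to 0-based internally.  Side matrices are stored features-
in-rows / entities-in-columns, matching the in-memory orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .operators import ObservedMask
from .solvers import Hyperparameters, ProblemData
from .synthetic import SyntheticProblem

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_mask_pairs",
    "write_mask_pairs",
    "read_problem",
    "write_problem",
    "load_problem_dir",
    "RunConfig",
    "load_config",
]

def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else r"\s+"


def read_matrix(path, delimiter: str | None = None) -> np.ndarray:
    """Read a numeric matrix; NA/NaN tokens become NaN entries.

    Parsed with :func:`numpy.loadtxt` so finite values written at full
    precision round-trip exactly.
    """
    import io as _io
    import re

    path = Path(path)
    sep = delimiter if delimiter is not None else ("," if path.suffix.lower() == ".csv" else None)
    text = re.sub(r"(?i)\bnan?\b", "nan", path.read_text())
    try:
        return np.loadtxt(_io.StringIO(text), delimiter=sep, comments="#", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric content ({exc})") from exc


def write_matrix(path, M, delimiter: str = "\t") -> None:
    np.savetxt(path, np.asarray(M, dtype=float), delimiter=delimiter, fmt="%.17g")


def read_mask_pairs(path, delimiter: str | None = None) -> list[tuple[int, int]]:
    """Read a 1-based (row, col) index list with a header row; 0-based output."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), header=0, comment="#", engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mask files need two columns (row, col)")
    rows = df.iloc[:, 0].to_numpy(dtype=int)
    cols = df.iloc[:, 1].to_numpy(dtype=int)
    if (rows < 1).any() or (cols < 1).any():
        raise ValueError(f"{path}: mask indices are 1-based and must be >= 1")
    pairs = list(zip((rows - 1).tolist(), (cols - 1).tolist()))
    if len(set(pairs)) != len(pairs):
        raise ValueError(f"{path}: duplicate mask entries")
    return pairs


def write_mask_pairs(path, pairs, delimiter: str = "\t") -> None:
    lines = ["row" + delimiter + "col"]
    for i, j in sorted(pairs):
        lines.append(f"{i + 1}{delimiter}{j + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_problem(
    f_path,
    x_path,
    y_path,
    mask_path=None,
    delimiter: str | None = None,
) -> ProblemData:
    """Assemble a :class:`ProblemData` from matrix files.

    Missing entries of F are the union of its NaN entries and, if given, the
    (row, col) pairs listed in ``mask_path``.  NaN in X or Y is an error.
    """
    F = read_matrix(f_path, delimiter)
    X = read_matrix(x_path, delimiter)
    Y = read_matrix(y_path, delimiter)
    for name, M, p in (("X", X, x_path), ("Y", Y, y_path)):
        if np.isnan(M).any():
            raise ValueError(f"{p}: missing values are not allowed in side matrix {name}")
    m, n = F.shape
    if X.shape[1] != m:
        raise ValueError(
            f"X has {X.shape[1]} entity columns but F has {m} rows"
        )
    if Y.shape[1] != n:
        raise ValueError(
            f"Y has {Y.shape[1]} entity columns but F has {n} columns"
        )
    observed = np.isfinite(F)
    if mask_path is not None:
        for i, j in read_mask_pairs(mask_path, delimiter):
            if not (0 <= i < m and 0 <= j < n):
                raise ValueError(f"mask entry ({i + 1}, {j + 1}) outside F shape {F.shape}")
            observed[i, j] = False
    return ProblemData.from_arrays(F, X, Y, ObservedMask(observed))


def write_problem(directory, problem: SyntheticProblem, delimiter: str = "\t") -> None:
    """Dump a synthetic problem (with ground truth) as delimited text files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    F = problem.data.F.copy()
    F[~problem.data.mask.observed] = np.nan
    write_matrix(d / "F.tsv", F, delimiter)
    write_matrix(d / "X.tsv", problem.X, delimiter)
    write_matrix(d / "Y.tsv", problem.Y, delimiter)
    write_matrix(d / "true_F.tsv", problem.true_F, delimiter)
    write_matrix(d / "true_G.tsv", problem.true_G, delimiter)
    missing_pairs = zip(*np.nonzero(~problem.data.mask.observed))
    write_mask_pairs(d / "mask.tsv", [(int(i), int(j)) for i, j in missing_pairs], delimiter)
    meta = {
        "setting": problem.setting,
        "q": float(problem.q),
        "rank_true_F": int(problem.r),
        "seed": problem.seed,
        "shape": [int(s) for s in problem.true_F.shape],
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_problem_dir(directory, delimiter: str | None = None):
    """Load a directory written by :func:`write_problem`.

    Returns ``(data, meta, true_F, true_G)`` with the truth entries None when
    absent (real-data directories).
    """
    d = Path(directory)
    data = read_problem(
        d / "F.tsv", d / "X.tsv", d / "Y.tsv",
        mask_path=(d / "mask.tsv") if (d / "mask.tsv").exists() else None,
        delimiter=delimiter,
    )
    meta = yaml.safe_load((d / "meta.yaml").read_text()) if (d / "meta.yaml").exists() else {}
    true_F = read_matrix(d / "true_F.tsv", delimiter) if (d / "true_F.tsv").exists() else None
    true_G = read_matrix(d / "true_G.tsv", delimiter) if (d / "true_G.tsv").exists() else None
    return data, meta, true_F, true_G


@dataclass
class RunConfig:
    """One run of the command-line tool, mirrored by the YAML config format."""

    method: str = "stoladmm"
    f_path: Optional[str] = None
    x_path: Optional[str] = None
    y_path: Optional[str] = None
    mask_path: Optional[str] = None
    out_dir: str = "sidemc_out"
    seed: int = 0
    log_level: str = "INFO"
    hyperparameters: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)

    def build_hyperparameters(self) -> Hyperparameters:
        return Hyperparameters(seed=self.seed, **self.hyperparameters)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)
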