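"""Shared domain types and file I/O.

Two matrix orientations coexist in this package, mirroring the two halves of
the method: dictionary-learning code works on samples-as-columns (``A`` is
``p x N``), while the ELM works on samples-as-rows (``H`` is ``N x m``).
:class:`LabeledDataset` stores the column orientation; the pipeline transposes
exactly once when handing reconstructed signals to the classifier.

Labels are 1-based class indices externally (1..c); predictions are returned
1-based as well.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

_MAGIC = b"FDLM\x01"


# ---------------------------------------------------------------------------
# binary matrix container
# ---------------------------------------------------------------------------

def save_matrix(path: str | Path, matrix: np.ndarray) -> None:
    """Write a 2-D float64 matrix to the flat little-endian container.

    Layout: 5-byte magic, two little-endian int64 (rows, cols), then
    row-major float64 data.  Round trips are bit-exact.
    """
    m = np.ascontiguousarray(np.atleast_2d(np.asarray(matrix, dtype="<f8")))
    if m.ndim != 2:
        raise ValueError("only 2-D matrices are supported")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<qq", m.shape[0], m.shape[1]))
        fh.write(m.tobytes())


def load_matrix(path: str | Path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a matrix container (bad magic)")
        rows, cols = struct.unpack("<qq", fh.read(16))
        data = np.frombuffer(fh.read(rows * cols * 8), dtype="<f8")
    if data.size != rows * cols:
        raise ValueError(f"{path}: truncated container")
    return data.reshape(rows, cols).copy()


def _is_container(path: str | Path) -> bool:
    try:
        with open(path, "rb") as fh:
            return fh.read(len(_MAGIC)) == _MAGIC
    except OSError:
        return False


def load_matrix_any(path: str | Path) -> np.ndarray:
    """Load a matrix from the binary container or delimited text.

    Text files may be comma- or whitespace-delimited, rows = samples.
    """
    if _is_container(path):
        return load_matrix(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    return np.atleast_2d(np.loadtxt(path, delimiter=delimiter, dtype=float))


# ---------------------------------------------------------------------------
# labels / one-hot
# ---------------------------------------------------------------------------

def one_hot(labels: np.ndarray, c: int) -> np.ndarray:
    """N x c 0/1 target matrix; row j has a single 1 at column labels[j]-1."""
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 1 or labels.max() > c):
        raise ValueError(f"labels must lie in 1..{c}")
    out = np.zeros((labels.size, c))
    out[np.arange(labels.size), labels.astype(int) - 1] = 1.0
    return out


def load_labels(path: str | Path) -> np.ndarray:
    raw = np.atleast_1d(np.loadtxt(path, dtype=float).ravel())
    labels = raw.astype(int)
    if not np.array_equal(labels, raw):
        raise ValueError(f"{path}: labels must be integers")
    return labels


# ---------------------------------------------------------------------------
# LabeledDataset
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Column-oriented sample matrix partitioned by class.

    ``A`` is ``p x N`` with samples as columns, grouped contiguously by class
    in ascending label order (the grouping permutation is retained in
    ``permutation``: ``A[:, k]`` came from input column ``permutation[k]``).
    ``Y`` is the ``N x c`` one-hot target matrix for the grouped order.

    By default every sample column is scaled to unit l2 norm at construction
    (standard practice in discriminative dictionary learning); pass
    ``normalize=False`` to keep raw scales.  Zero-norm columns are rejected.
    """

    A: np.ndarray
    labels: np.ndarray
    c: int
    n_per_class: np.ndarray
    class_slices: list[slice]
    Y: np.ndarray
    permutation: np.ndarray
    normalized: bool

    @classmethod
    def from_arrays(
        cls,
        A: np.ndarray,
        labels: Sequence[int] | np.ndarray,
        *,
        normalize: bool = True,
    ) -> "LabeledDataset":
        A = np.asarray(A, dtype=float)
        labels = np.asarray(labels)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D matrix (features x samples)")
        if labels.ndim != 1 or labels.shape[0] != A.shape[1]:
            raise ValueError(
                f"label count {labels.shape} does not match sample count {A.shape[1]}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(int)
            if not np.array_equal(as_int, labels):
                raise ValueError("labels must be integers")
            labels = as_int
        if labels.min() < 1:
            raise ValueError("labels must be >= 1")
        c = int(labels.max())
        counts = np.bincount(labels, minlength=c + 1)[1:]
        if np.any(counts == 0):
            empty = np.flatnonzero(counts == 0) + 1
            raise ValueError(f"empty class(es) after grouping: {empty.tolist()}")
        perm = np.argsort(labels, kind="stable")
        A = A[:, perm].copy()
        labels = labels[perm]
        if normalize:
            norms = np.linalg.norm(A, axis=0)
            if np.any(norms == 0):
                raise ValueError("zero-norm sample column cannot be unit-normalized")
            A /= norms
        starts = np.concatenate([[0], np.cumsum(counts)])
        slices = [slice(int(starts[i]), int(starts[i + 1])) for i in range(c)]
        return cls(
            A=A,
            labels=labels,
            c=c,
            n_per_class=counts,
            class_slices=slices,
            Y=one_hot(labels, c),
            permutation=perm,
            normalized=normalize,
        )

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def N(self) -> int:
        return self.A.shape[1]

    def class_samples(self, i: int) -> np.ndarray:
        """Columns of class ``i`` (1-based), the block ``A_i``."""
        return self.A[:, self.class_slices[i - 1]]

    def subset(self, columns: np.ndarray) -> "LabeledDataset":
        """Dataset restricted to the given (grouped-order) columns.

        Columns are taken as-is (no re-normalization); the parent's
        normalization flag is carried over.
        """
        ds = LabeledDataset.from_arrays(
            self.A[:, columns], self.labels[columns], normalize=False
        )
        ds.normalized = self.normalized
        return ds


def load_dataset(
    features_path: str | Path,
    labels_path: str | Path,
    *,
    normalize: bool = True,
) -> LabeledDataset:
    """Read features (rows = samples, text or binary container) plus labels."""
    feats = load_matrix_any(features_path)
    labels = load_labels(labels_path)
    if feats.shape[0] != labels.shape[0]:
        raise ValueError(
            f"feature rows ({feats.shape[0]}) != label count ({labels.shape[0]})"
        )
    return LabeledDataset.from_arrays(feats.T, labels, normalize=normalize)


def write_dataset(
    dataset: LabeledDataset,
    features_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write grouped samples as rows.  Text gets %.17g (value-exact float64);
    the binary container is used when the path ends in ``.bin``."""
    features_path = Path(features_path)
    if features_path.suffix == ".bin":
        save_matrix(features_path, dataset.A.T)
    else:
        np.savetxt(features_path, dataset.A.T, fmt="%.17g", delimiter=",")
    np.savetxt(labels_path, dataset.labels[:, None], fmt="%d")


# ---------------------------------------------------------------------------
# hyper-parameters / run configuration
# ---------------------------------------------------------------------------

@dataclass
class FDDLHyperparams:
    """Knobs of the dictionary-learning stage.

    lambda1 weights the l1 sparsity of the codes, lambda2 the Fisher
    discrimination penalty on them; eta (default 1) is the coefficient-norm
    weight inside that penalty and keeps the per-class subproblem convex.
    """

    lambda1: float = 0.01
    lambda2: float = 0.01
    eta: float = 1.0
    atoms_per_class: int = 10
    max_outer_iter: int = 30
    tol: float = 1e-4
    seed: int = 0
    init: str = "sample"  # "sample" or "svd"
    fista: bool = False
    coder_ridge: bool = False  # include eta*||x||^2 in test-time coding

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0 or self.eta < 0:
            raise ValueError("lambda1, lambda2, eta must be nonnegative")
        if self.atoms_per_class < 1 or self.max_outer_iter < 1:
            raise ValueError("atoms_per_class and max_outer_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


_DEFAULT_LAMBDA_GRID = (0.001, 0.005, 0.01, 0.05, 0.1)


@dataclass
class RunConfig:
    """Protocol configuration: hyper-parameter grids, CV and repetitions."""

    lambda1_grid: tuple[float, ...] = _DEFAULT_LAMBDA_GRID
    lambda2_grid: tuple[float, ...] = _DEFAULT_LAMBDA_GRID
    m_grid: tuple[int, ...] = tuple(range(100, 1501, 100))
    C_grid: tuple[float, ...] = tuple(float(np.exp(k)) for k in range(-5, 6))
    n_repeats: int = 10
    cv_folds: int = 5
    seed: int = 0
    atoms_per_class: int | None = None
    eta: float = 1.0
    max_outer_iter: int = 30
    frontend: dict | None = None  # band, order, segment, pairs

    @classmethod
    def eeg_defaults(cls, **overrides) -> "RunConfig":
        base = dict(
            m_grid=tuple(range(10, 101, 10)),
            frontend={"band": [8.0, 30.0], "order": 5,
                      "segment": [0.5, 2.5], "pairs": 3},
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lambda1_grid", "lambda2_grid", "m_grid", "C_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=True)


def save_sidecar(path: str | Path, meta: dict) -> None:
    """Deterministic JSON sidecar (sorted keys, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1, default=_jsonable)
        fh.write("\n")


def load_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
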