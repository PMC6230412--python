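"""The full classifier: FDDL encoding stage feeding a regularized ELM.

Training: (1) learn the structured dictionary D and discriminative codes X
on the class-grouped training matrix A; (2) form the reconstructed signals
B = D X; (3) train the ELM on B (samples as rows) against one-hot targets,
with the ridge parameter C picked by closed-form leave-one-out PRESS.
Prediction: unit-normalize the test columns (iff training did), sparse-code
them over the learned dictionary, reconstruct, and classify with the ELM.

Also provides the evaluation protocol used throughout: stratified k-fold
grid search over (lambda1, lambda2, m) and repeated fit/predict runs
reporting mean accuracy +/- sample standard deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import elm as elm_mod
from . import fddl as fddl_mod
from .datasets import (
    FDDLHyperparams,
    LabeledDataset,
    RunConfig,
    load_matrix,
    load_sidecar,
    save_matrix,
    save_sidecar,
)
from .fddl import CodingCoefficients, StructuredDictionary


@dataclass
class FDDLELMModel:
    """Trained encode-then-classify model."""

    dictionary: StructuredDictionary
    elm: elm_mod.ELMModel
    hyper: FDDLHyperparams
    train_summary: dict
    normalize_inputs: bool
    identity_encoding: bool = False  # debug hook: D = I, coding = identity


def _identity_dictionary(p: int, c: int) -> StructuredDictionary:
    """Orthonormal (identity) dictionary used by the reduction debug hook."""
    bounds = np.linspace(0, p, c + 1).astype(int)
    blocks = [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
    return StructuredDictionary(D=np.eye(p), class_blocks=blocks, c=c)


def fddl_elm_fit(
    dataset: LabeledDataset,
    hyper: FDDLHyperparams,
    m: int,
    C_grid: Sequence[float],
    seed: int,
    activation: str = "sigmoid",
    identity_encoding: bool = False,
) -> FDDLELMModel:
    """Fit the two-stage model.  ``seed`` drives both the dictionary
    initialization and the ELM's random hidden layer.

    With ``identity_encoding`` the encoding stage is bypassed (D = I,
    X = A, hence B = A): the pipeline then reduces exactly to a plain ELM
    on the raw features, which is the reference point for testing.
    """
    hyper = dataclasses.replace(hyper, seed=seed)
    if identity_encoding:
        D = _identity_dictionary(dataset.p, dataset.c)
        X = CodingCoefficients(
            X=dataset.A.copy(),
            class_cols=list(dataset.class_slices),
            row_blocks=list(D.class_blocks),
        )
        trace: list[float] = []
    else:
        D, X, trace = fddl_mod.fddl_fit(dataset, hyper)
    B = fddl_mod.reconstruct(D, X)
    model = elm_mod.elm_train(B.T, dataset.Y, m, C_grid, seed, activation)
    return FDDLELMModel(
        dictionary=D,
        elm=model,
        hyper=hyper,
        train_summary={
            "objective_trace": trace,
            "selected_C": model.C,
            "lambda1": hyper.lambda1,
            "lambda2": hyper.lambda2,
            "m": m,
            "atoms_per_class": hyper.atoms_per_class,
            "seed": seed,
        },
        normalize_inputs=dataset.normalized,
        identity_encoding=identity_encoding,
    )


def fddl_elm_predict(
    model: FDDLELMModel, test_samples: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Encode-then-classify new samples (columns).  Returns (scores, labels)."""
    A = np.atleast_2d(np.asarray(test_samples, dtype=float))
    if A.shape[0] != model.dictionary.p:
        raise ValueError(
            f"feature dimension {A.shape[0]} != model dimension {model.dictionary.p}"
        )
    if model.normalize_inputs:
        norms = np.linalg.norm(A, axis=0)
        if np.any(norms == 0):
            raise ValueError("zero-norm test column")
        A = A / norms
    if model.identity_encoding:
        B = A
    else:
        ridge = model.hyper.eta if model.hyper.coder_ridge else 0.0
        X = fddl_mod.code_samples(
            model.dictionary, A, model.hyper.lambda1, ridge_eta=ridge
        )
        B = fddl_mod.reconstruct(model.dictionary, X)
    return elm_mod.elm_predict(model.elm, B.T)


def save_model(model: FDDLELMModel, directory: str | Path) -> None:
    """Serialize a fitted model (binary containers + JSON sidecar); loading
    reproduces predictions bit-for-bit."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_matrix(directory / "dictionary.bin", model.dictionary.D)
    save_matrix(directory / "elm_w_in.bin", model.elm.W_in)
    save_matrix(directory / "elm_bias.bin", model.elm.b[None, :])
    save_matrix(directory / "elm_beta.bin", model.elm.beta)
    if model.elm.input_scale is not None:
        save_matrix(directory / "elm_scale.bin", model.elm.input_scale[None, :])
    save_sidecar(
        directory / "model.json",
        {
            "class_blocks": [[b.start, b.stop] for b in model.dictionary.class_blocks],
            "c": model.dictionary.c,
            "hyper": dataclasses.asdict(model.hyper),
            "elm": {
                "activation": model.elm.activation,
                "C": model.elm.C,
                "m": model.elm.m,
                "seed": model.elm.seed,
            },
            "train_summary": model.train_summary,
            "normalize_inputs": model.normalize_inputs,
            "identity_encoding": model.identity_encoding,
        },
    )


def load_model(directory: str | Path) -> FDDLELMModel:
    directory = Path(directory)
    meta = load_sidecar(directory / "model.json")
    D = load_matrix(directory / "dictionary.bin")
    blocks = [slice(a, b) for a, b in meta["class_blocks"]]
    dictionary = StructuredDictionary(D=D, class_blocks=blocks, c=meta["c"])
    elm_meta = meta["elm"]
    scale_path = directory / "elm_scale.bin"
    elm = elm_mod.ELMModel(
        W_in=load_matrix(directory / "elm_w_in.bin"),
        b=load_matrix(directory / "elm_bias.bin")[0],
        activation=elm_meta["activation"],
        beta=load_matrix(directory / "elm_beta.bin"),
        C=elm_meta["C"],
        m=elm_meta["m"],
        seed=elm_meta["seed"],
        input_scale=load_matrix(scale_path)[0] if scale_path.exists() else None,
    )
    return FDDLELMModel(
        dictionary=dictionary,
        elm=elm,
        hyper=FDDLHyperparams(**meta["hyper"]),
        train_summary=meta["train_summary"],
        normalize_inputs=meta["normalize_inputs"],
        identity_encoding=meta["identity_encoding"],
    )


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(predicted == true))


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment: each class's indices are shuffled
    and dealt round-robin, so per-fold class proportions are within one
    sample of the global proportions."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for pos, j in enumerate(idx):
            folds[pos % k].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def train_test_split(
    dataset: LabeledDataset, test_fraction: float = 0.5, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded shuffled stratified split (default 1:1), mirroring random-
    permutation evaluation protocols."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in range(1, dataset.c + 1):
        idx = np.flatnonzero(dataset.labels == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.extend(idx[:n_test].tolist())
    mask = np.zeros(dataset.N, dtype=bool)
    mask[test_idx] = True
    return dataset.subset(np.flatnonzero(~mask)), dataset.subset(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# model selection and evaluation
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    lambda1: float
    lambda2: float
    m: int
    cv_accuracy: float
    table: list[dict]


def _resolve_atoms(config: RunConfig, n_min: int) -> int:
    if config.atoms_per_class is not None:
        return min(config.atoms_per_class, n_min)
    return min(n_min, 30)


def _make_hyper(config: RunConfig, lambda1: float, lambda2: float, atoms: int) -> FDDLHyperparams:
    return FDDLHyperparams(
        lambda1=lambda1,
        lambda2=lambda2,
        eta=config.eta,
        atoms_per_class=atoms,
        max_outer_iter=config.max_outer_iter,
        seed=config.seed,
    )


def grid_search(dataset: LabeledDataset, config: RunConfig) -> GridSearchResult:
    """Stratified k-fold CV over the (lambda1, lambda2, m) grid.

    Maximizes mean validation accuracy; ties go to smaller m, then smaller
    lambda1, then smaller lambda2 (the scan order makes the first optimum
    win).  C is re-selected by PRESS inside every fit.
    """
    folds = stratified_folds(dataset.labels, config.cv_folds, config.seed)
    splits = []
    for f in range(len(folds)):
        val = folds[f]
        train = np.sort(np.concatenate([folds[g] for g in range(len(folds)) if g != f]))
        train_ds = dataset.subset(train)
        val_ds = dataset.subset(val)
        atoms = _resolve_atoms(config, int(train_ds.n_per_class.min()))
        splits.append((train_ds, val_ds, atoms))

    table: list[dict] = []
    best = None  # (acc, m, lambda1, lambda2)
    for m in sorted(config.m_grid):
        for lam1 in sorted(config.lambda1_grid):
            for lam2 in sorted(config.lambda2_grid):
                accs = []
                for train_ds, val_ds, atoms in splits:
                    hyper = _make_hyper(config, lam1, lam2, atoms)
                    model = fddl_elm_fit(
                        train_ds, hyper, m, config.C_grid, config.seed
                    )
                    _, pred = fddl_elm_predict(model, val_ds.A)
                    accs.append(accuracy(pred, val_ds.labels))
                mean_acc = float(np.mean(accs))
                table.append(
                    {"lambda1": lam1, "lambda2": lam2, "m": m, "cv_accuracy": mean_acc}
                )
                if best is None or mean_acc > best[0]:
                    best = (mean_acc, m, lam1, lam2)
    assert best is not None
    return GridSearchResult(
        lambda1=best[2], lambda2=best[3], m=best[1], cv_accuracy=best[0], table=table
    )


@dataclass
class EvalReport:
    mean_accuracy: float
    sd_accuracy: float
    per_repeat: list[float]
    lambda1: float
    lambda2: float
    m: int
    C_per_repeat: list[float]

    def summary(self) -> str:
        return (
            f"accuracy {100 * self.mean_accuracy:.2f} +/- {100 * self.sd_accuracy:.2f} % "
            f"over {len(self.per_repeat)} repeats "
            f"(lambda1={self.lambda1}, lambda2={self.lambda2}, m={self.m})"
        )


def evaluate(
    dataset_train: LabeledDataset,
    dataset_test: LabeledDataset,
    config: RunConfig,
) -> EvalReport:
    """Repeated fit/predict with seeds seed+0..n_repeats-1.

    If any hyper-parameter grid has more than one cell, a single stratified
    CV grid search on the training set resolves (lambda1, lambda2, m) first;
    C is always re-selected by PRESS within each repeat.  The report gives
    the mean and sample standard deviation (0 when n_repeats = 1) of test
    accuracy.
    """
    if (
        len(config.lambda1_grid) > 1
        or len(config.lambda2_grid) > 1
        or len(config.m_grid) > 1
    ):
        best = grid_search(dataset_train, config)
        lam1, lam2, m = best.lambda1, best.lambda2, best.m
    else:
        lam1 = config.lambda1_grid[0]
        lam2 = config.lambda2_grid[0]
        m = config.m_grid[0]
    atoms = _resolve_atoms(config, int(dataset_train.n_per_class.min()))
    accs: list[float] = []
    Cs: list[float] = []
    for r in range(config.n_repeats):
        seed_r = config.seed + r
        hyper = _make_hyper(config, lam1, lam2, atoms)
        model = fddl_elm_fit(dataset_train, hyper, m, config.C_grid, seed_r)
        _, pred = fddl_elm_predict(model, dataset_test.A)
        accs.append(accuracy(pred, dataset_test.labels))
        Cs.append(model.elm.C)
    mean = float(np.mean(accs))
    sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    return EvalReport(
        mean_accuracy=mean,
        sd_accuracy=sd,
        per_repeat=accs,
        lambda1=lam1,
        lambda2=lam2,
        m=m,
        C_per_repeat=Cs,
    )
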