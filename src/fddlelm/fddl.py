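"""Fisher discrimination dictionary learning (FDDL).

Learns a class-structured dictionary D = [D_1, ..., D_c] (unit-norm atoms)
and coding coefficients X = [X_1, ..., X_c] by minimizing

    J(D, X) = sum_i r(A_i, D, X_i) + lambda1 ||X||_1 + lambda2 f(X)

where the discriminative fidelity of class i is

    r(A_i, D, X_i) = ||A_i - D X_i||_F^2 + ||A_i - D_i X_i^i||_F^2
                     + sum_{j != i} ||D_j X_i^j||_F^2

(X_i^j = rows of X_i belonging to sub-dictionary D_j), and the Fisher
discrimination penalty on the codes is

    f(X) = tr(S_W(X)) - tr(S_B(X)) + eta ||X||_F^2

with the usual within/between-class scatter matrices of the coefficient
columns.  The eta ||X||_F^2 ridge keeps f convex; eta defaults to 1.

Optimization is alternating minimization.  The X step is block proximal
gradient (ISTA with backtracking; the smooth part is quadratic in each
class block, the l1 part is handled by soft thresholding), one class block
at a time.  The D step is atom-wise: for a fixed coefficient row the
unit-norm atom minimizing the stacked least-squares terms has the closed
form d = E z^T / ||E z^T||, so each atom update is an exact constrained
minimization and the objective can never increase.  An atom whose
coefficient row is entirely zero is re-seeded from the worst-reconstructed
sample of its class (its term contributes nothing, so the objective is
unchanged).

Test samples are coded over the full dictionary with the l1-only objective
min_x ||a - D x||^2 + lambda1 ||x||_1 (labels are unknown at test time, so
the class-discriminative terms do not apply); an optional ridge variant
adds eta ||x||^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datasets import FDDLHyperparams, LabeledDataset


@dataclass
class StructuredDictionary:
    """Class-partitioned dictionary D = [D_1, ..., D_c], unit-norm atoms."""

    D: np.ndarray  # p x K
    class_blocks: list[slice]  # column ranges of the D_i
    c: int

    @property
    def p(self) -> int:
        return self.D.shape[0]

    @property
    def K(self) -> int:
        return self.D.shape[1]

    def block(self, i: int) -> np.ndarray:
        """Sub-dictionary of class ``i`` (1-based)."""
        return self.D[:, self.class_blocks[i - 1]]


@dataclass
class CodingCoefficients:
    """Coefficient matrix X (K x N) with class column blocks X_i.

    ``class_cols[i]`` are the columns coding the samples of class i+1;
    ``row_blocks[j]`` are the rows belonging to sub-dictionary D_{j+1}, so
    the sub-block X_i^j is ``X[row_blocks[j], class_cols[i]]``.
    """

    X: np.ndarray
    class_cols: list[slice]
    row_blocks: list[slice]

    @classmethod
    def unpartitioned(cls, X: np.ndarray, row_blocks: list[slice]) -> "CodingCoefficients":
        return cls(X=X, class_cols=[slice(0, X.shape[1])], row_blocks=row_blocks)


@dataclass
class ScatterStats:
    """Within/between-class scatter of the coefficient columns."""

    S_W: np.ndarray
    S_B: np.ndarray
    class_means: np.ndarray  # K x c
    global_mean: np.ndarray  # K


def _coef_array(X) -> np.ndarray:
    return X.X if isinstance(X, CodingCoefficients) else np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# objective pieces
# ---------------------------------------------------------------------------

def fisher_scatter(X, dataset: LabeledDataset) -> ScatterStats:
    """Scatter matrices of the coefficient columns grouped by class.

    S_W = sum_i sum_{x in X_i} (x - m_i)(x - m_i)^T,
    S_B = sum_i n_i (m_i - m)(m_i - m)^T.
    """
    Xa = _coef_array(X)
    if Xa.shape[1] != dataset.N:
        raise ValueError("coefficient columns do not match dataset samples")
    K = Xa.shape[0]
    m = Xa.mean(axis=1)
    S_W = np.zeros((K, K))
    S_B = np.zeros((K, K))
    means = np.empty((K, dataset.c))
    for i, sl in enumerate(dataset.class_slices):
        Xi = Xa[:, sl]
        if Xi.shape[1] == 0:
            raise ValueError(f"empty class {i + 1}")
        mi = Xi.mean(axis=1)
        means[:, i] = mi
        centered = Xi - mi[:, None]
        S_W += centered @ centered.T
        d = mi - m
        S_B += Xi.shape[1] * np.outer(d, d)
    return ScatterStats(S_W=S_W, S_B=S_B, class_means=means, global_mean=m)


def _scatter_traces(Xa: np.ndarray, class_slices: list[slice]) -> tuple[float, float]:
    """tr(S_W), tr(S_B) without forming the K x K matrices."""
    m = Xa.mean(axis=1)
    tr_w = 0.0
    tr_b = 0.0
    for sl in class_slices:
        Xi = Xa[:, sl]
        mi = Xi.mean(axis=1)
        tr_w += float(np.sum((Xi - mi[:, None]) ** 2))
        tr_b += Xi.shape[1] * float(np.sum((mi - m) ** 2))
    return tr_w, tr_b


def discrimination_term(X, dataset: LabeledDataset, eta: float) -> float:
    """f(X) = tr(S_W) - tr(S_B) + eta ||X||_F^2."""
    Xa = _coef_array(X)
    tr_w, tr_b = _scatter_traces(Xa, dataset.class_slices)
    return tr_w - tr_b + eta * float(np.sum(Xa**2))


def fidelity_term(dataset: LabeledDataset, D: StructuredDictionary, X) -> float:
    """Discriminative reconstruction error, summed over classes."""
    Xa = _coef_array(X)
    total = 0.0
    for i in range(dataset.c):
        total += _class_fidelity(dataset, D, Xa, i)
    return total


def _class_fidelity(
    dataset: LabeledDataset, D: StructuredDictionary, Xa: np.ndarray, i: int
) -> float:
    """r(A_i, D, X_i) for 0-based class index i."""
    Ai = dataset.A[:, dataset.class_slices[i]]
    Xi = Xa[:, dataset.class_slices[i]]
    val = float(np.sum((Ai - D.D @ Xi) ** 2))
    Di = D.D[:, D.class_blocks[i]]
    Xii = Xi[D.class_blocks[i], :]
    val += float(np.sum((Ai - Di @ Xii) ** 2))
    for j in range(D.c):
        if j == i:
            continue
        Dj = D.D[:, D.class_blocks[j]]
        Xij = Xi[D.class_blocks[j], :]
        val += float(np.sum((Dj @ Xij) ** 2))
    return val


def fddl_objective(
    dataset: LabeledDataset, D: StructuredDictionary, X, hyper: FDDLHyperparams
) -> float:
    """The full learning objective J(D, X)."""
    Xa = _coef_array(X)
    return (
        fidelity_term(dataset, D, Xa)
        + hyper.lambda1 * float(np.sum(np.abs(Xa)))
        + hyper.lambda2 * discrimination_term(Xa, dataset, hyper.eta)
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _normalize_atoms(D: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(D, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm atom cannot be normalized")
    return D / norms


def init_dictionary(
    dataset: LabeledDataset,
    atoms_per_class: int,
    seed: int,
    method: str = "sample",
) -> StructuredDictionary:
    """Seeded initial dictionary.

    ``sample``: atoms_per_class distinct training columns per class (requires
    atoms_per_class <= n_i).  ``svd``: top left-singular vectors of each A_i.
    Atoms are unit-normalized either way.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for i in range(1, dataset.c + 1):
        Ai = dataset.class_samples(i)
        ni = Ai.shape[1]
        if method == "sample":
            if atoms_per_class > ni:
                raise ValueError(
                    f"atoms_per_class={atoms_per_class} exceeds class {i} size {ni}"
                )
            cols = rng.choice(ni, size=atoms_per_class, replace=False)
            blocks.append(_normalize_atoms(Ai[:, np.sort(cols)].copy()))
        elif method == "svd":
            if atoms_per_class > min(Ai.shape):
                raise ValueError("atoms_per_class exceeds rank bound of class block")
            U, _, _ = scipy.linalg.svd(Ai, full_matrices=False)
            blocks.append(U[:, :atoms_per_class].copy())
        else:
            raise ValueError(f"unknown init method {method!r}")
    D = np.hstack(blocks)
    K = atoms_per_class * dataset.c
    starts = range(0, K + 1, atoms_per_class)
    class_blocks = [slice(a, b) for a, b in zip(starts, list(starts)[1:])]
    return StructuredDictionary(D=D, class_blocks=class_blocks, c=dataset.c)


def zero_coefficients(D: StructuredDictionary, dataset: LabeledDataset) -> CodingCoefficients:
    return CodingCoefficients(
        X=np.zeros((D.K, dataset.N)),
        class_cols=list(dataset.class_slices),
        row_blocks=list(D.class_blocks),
    )


# ---------------------------------------------------------------------------
# X step: block proximal gradient
# ---------------------------------------------------------------------------

def soft_threshold(Z: np.ndarray, thresh: float) -> np.ndarray:
    """Elementwise soft threshold; exactly-threshold magnitudes map to 0."""
    return np.sign(Z) * np.maximum(np.abs(Z) - thresh, 0.0)


def _block_smooth_value(
    dataset: LabeledDataset,
    D: StructuredDictionary,
    Xa: np.ndarray,
    i: int,
    hyper: FDDLHyperparams,
) -> float:
    """Smooth part of J restricted to block X_i (fidelity_i + lambda2 f(X))."""
    val = _class_fidelity(dataset, D, Xa, i)
    if hyper.lambda2 > 0:
        val += hyper.lambda2 * discrimination_term(Xa, dataset, hyper.eta)
    return val


def _block_smooth_grad(
    dataset: LabeledDataset,
    D: StructuredDictionary,
    Xa: np.ndarray,
    i: int,
    hyper: FDDLHyperparams,
) -> np.ndarray:
    """Gradient of the smooth part w.r.t. X_i.

    Fidelity: 2 D^T (D X_i - A_i), plus 2 D_i^T (D_i X_i^i - A_i) on the
    class-i rows and 2 D_j^T D_j X_i^j on the other row blocks.  Fisher
    penalty (accounting for the dependence of m_i and m on X_i):
    2 (x_k - m_i) - 2 (m_i - m) + 2 eta x_k per column.
    """
    cols = dataset.class_slices[i]
    Ai = dataset.A[:, cols]
    Xi = Xa[:, cols]
    G = 2.0 * (D.D.T @ (D.D @ Xi - Ai))
    for j in range(D.c):
        rows = D.class_blocks[j]
        Dj = D.D[:, rows]
        if j == i:
            G[rows, :] += 2.0 * (Dj.T @ (Dj @ Xi[rows, :] - Ai))
        else:
            G[rows, :] += 2.0 * (Dj.T @ (Dj @ Xi[rows, :]))
    if hyper.lambda2 > 0:
        m = Xa.mean(axis=1)
        mi = Xi.mean(axis=1)
        G += hyper.lambda2 * (
            2.0 * (Xi - mi[:, None])
            - 2.0 * (mi - m)[:, None]
            + 2.0 * hyper.eta * Xi
        )
    return G


def update_coefficients(
    dataset: LabeledDataset,
    D: StructuredDictionary,
    X: CodingCoefficients,
    hyper: FDDLHyperparams,
    max_inner: int = 50,
    inner_tol: float = 1e-10,
) -> CodingCoefficients:
    """One pass of block proximal-gradient updates of X, class by class.

    Each class block runs ISTA with backtracking on the smooth part
    (fidelity + lambda2 * Fisher penalty, quadratic in X_i) and soft
    thresholding at lambda1 * step for the l1 part; the restricted objective
    is non-increasing across inner iterations, hence so is J.
    """
    Xa = _coef_array(X).copy()
    smax_D = scipy.linalg.svdvals(D.D)[0] if D.K else 0.0
    smax_blocks = max(
        scipy.linalg.svdvals(D.D[:, bl])[0] for bl in D.class_blocks
    )
    # curvature bound of the smooth part; backtracking guards the slack
    L0 = 2.0 * smax_D**2 + 2.0 * smax_blocks**2 + hyper.lambda2 * (4.0 + 2.0 * hyper.eta)
    for i in range(dataset.c):
        cols = dataset.class_slices[i]
        t = 1.0 / max(L0, 1e-12)
        f_cur = _block_smooth_value(dataset, D, Xa, i, hyper)
        obj_cur = f_cur + hyper.lambda1 * float(np.sum(np.abs(Xa[:, cols])))
        for _ in range(max_inner):
            Xi = Xa[:, cols].copy()
            G = _block_smooth_grad(dataset, D, Xa, i, hyper)
            while True:
                Z = soft_threshold(Xi - t * G, t * hyper.lambda1)
                Xa[:, cols] = Z
                f_new = _block_smooth_value(dataset, D, Xa, i, hyper)
                if not np.isfinite(f_new):
                    Xa[:, cols] = Xi
                    raise FloatingPointError("non-finite objective in X update")
                diff = Z - Xi
                quad = (
                    f_cur
                    + float(np.sum(G * diff))
                    + float(np.sum(diff**2)) / (2.0 * t)
                )
                if f_new <= quad + 1e-12 * max(1.0, abs(f_cur)):
                    break
                Xa[:, cols] = Xi
                t *= 0.5
                if t < 1e-18:
                    raise FloatingPointError("step-halving exhausted in X update")
            obj_new = f_new + hyper.lambda1 * float(np.sum(np.abs(Z)))
            if obj_cur - obj_new <= inner_tol * max(1.0, abs(obj_cur)):
                f_cur, obj_cur = f_new, obj_new
                break
            f_cur, obj_cur = f_new, obj_new
    return CodingCoefficients(
        X=Xa, class_cols=list(dataset.class_slices), row_blocks=list(D.class_blocks)
    )


# ---------------------------------------------------------------------------
# D step: atom-wise exact updates
# ---------------------------------------------------------------------------

def update_dictionary(
    dataset: LabeledDataset, D: StructuredDictionary, X: CodingCoefficients
) -> StructuredDictionary:
    """Atom-by-atom closed-form dictionary update with re-normalization.

    For class i the objective terms involving D_i form a stacked
    least-squares problem ||Ybig - D_i Zbig||_F^2; for a unit-norm atom with
    fixed coefficient row z, ||d z||_F^2 is constant, so the minimizer is
    d = E z^T / ||E z^T|| with E the residual excluding that atom — an exact
    constrained minimization, hence monotone.  Dead atoms (all-zero rows of
    Zbig) are re-seeded from the worst-reconstructed sample of their class.
    """
    Xa = _coef_array(X)
    Dnew = D.D.copy()
    for i in range(D.c):
        rows_i = D.class_blocks[i]
        cols_i = dataset.class_slices[i]
        Ai = dataset.A[:, cols_i]
        Xi = Xa[:, cols_i]
        # residual of A_i over all other sub-dictionaries
        other = Ai - Dnew @ Xi + Dnew[:, rows_i] @ Xi[rows_i, :]
        Y_parts = [other, Ai]
        Z_parts = [Xi[rows_i, :], Xi[rows_i, :]]
        for j in range(D.c):
            if j == i:
                continue
            cols_j = dataset.class_slices[j]
            Aj = dataset.A[:, cols_j]
            Xj = Xa[:, cols_j]
            other_j = Aj - Dnew @ Xj + Dnew[:, rows_i] @ Xj[rows_i, :]
            Y_parts.extend([other_j, np.zeros_like(other_j)])
            Z_parts.extend([Xj[rows_i, :], Xj[rows_i, :]])
        Ybig = np.hstack(Y_parts)
        Zbig = np.hstack(Z_parts)
        Di = Dnew[:, rows_i]
        E = Ybig - Di @ Zbig
        for k in range(Di.shape[1]):
            z = Zbig[k, :]
            if not np.any(z):
                # dead atom: re-seed from the worst-reconstructed class sample
                resid = Ai - Dnew @ Xi
                worst = int(np.argmax(np.sum(resid**2, axis=0)))
                cand = Ai[:, worst]
                nrm = np.linalg.norm(cand)
                if nrm > 0:
                    Di[:, k] = cand / nrm
                continue
            Ek = E + np.outer(Di[:, k], z)
            v = Ek @ z
            nv = np.linalg.norm(v)
            if nv > 1e-12:
                Di[:, k] = v / nv
            E = Ek - np.outer(Di[:, k], z)
        Dnew[:, rows_i] = Di
    return StructuredDictionary(D=Dnew, class_blocks=list(D.class_blocks), c=D.c)


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

def fddl_fit(
    dataset: LabeledDataset, hyper: FDDLHyperparams
) -> tuple[StructuredDictionary, CodingCoefficients, list[float]]:
    """Alternating minimization of J(D, X) from a seeded initialization.

    The trace records the objective after every half-step (X update, then D
    update); iteration stops when the relative objective change over a full
    outer iteration drops below ``hyper.tol`` or after
    ``hyper.max_outer_iter`` iterations.
    """
    D = init_dictionary(dataset, hyper.atoms_per_class, hyper.seed, hyper.init)
    X = zero_coefficients(D, dataset)
    trace = [fddl_objective(dataset, D, X, hyper)]
    prev = trace[0]
    for _ in range(hyper.max_outer_iter):
        X = update_coefficients(dataset, D, X, hyper)
        trace.append(fddl_objective(dataset, D, X, hyper))
        D = update_dictionary(dataset, D, X)
        cur = fddl_objective(dataset, D, X, hyper)
        trace.append(cur)
        if abs(prev - cur) <= hyper.tol * max(1.0, abs(prev)):
            break
        prev = cur
    return D, X, trace


# ---------------------------------------------------------------------------
# test-time coding and reconstruction
# ---------------------------------------------------------------------------

def code_samples(
    D: StructuredDictionary,
    samples: np.ndarray,
    lambda1: float,
    ridge_eta: float = 0.0,
    max_iter: int = 20000,
    tol: float = 1e-6,
    accelerate: bool = True,
) -> CodingCoefficients:
    """l1 sparse coding of (unit-normalized) samples over the full dictionary.

    Solves min_x ||a - D x||^2 + lambda1 ||x||_1 (+ ridge_eta ||x||^2) per
    column by proximal gradient at the fixed safe step 1/L, with
    L = 2 smax(D)^2 + 2 ridge_eta; ``accelerate`` enables Nesterov momentum
    (FISTA) with a restart whenever the momentum fights the descent
    direction.  Stops when the subgradient optimality residual (the KKT
    conditions of the lasso) drops below ``tol``.  Deterministic; if the
    iteration cap is reached first, a warning is emitted and the best
    iterate returned.
    """
    A = np.atleast_2d(np.asarray(samples, dtype=float))
    if A.shape[0] != D.p:
        raise ValueError(f"sample dimension {A.shape[0]} != dictionary rows {D.p}")
    L = 2.0 * scipy.linalg.svdvals(D.D)[0] ** 2 + 2.0 * ridge_eta
    t = 1.0 / max(L, 1e-12)
    X = np.zeros((D.K, A.shape[1]))
    Z = X  # extrapolated point
    theta = 1.0
    DtA = D.D.T @ A
    DtD = D.D.T @ D.D

    def grad(P):
        G = 2.0 * (DtD @ P - DtA)
        if ridge_eta:
            G += 2.0 * ridge_eta * P
        return G

    converged = False
    for it in range(max_iter):
        if it % 10 == 0 and _lasso_kkt_residual(X, grad(X), lambda1) <= tol:
            converged = True
            break
        X_new = soft_threshold(Z - t * grad(Z), t * lambda1)
        if accelerate:
            if float(np.sum((Z - X_new) * (X_new - X))) > 0.0:
                theta = 1.0  # gradient restart
            theta_new = (1.0 + np.sqrt(1.0 + 4.0 * theta**2)) / 2.0
            Z = X_new + ((theta - 1.0) / theta_new) * (X_new - X)
            theta = theta_new
        else:
            Z = X_new
        X = X_new
    if not converged and _lasso_kkt_residual(X, grad(X), lambda1) > tol:
        warnings.warn("sparse coding hit the iteration cap before convergence")
    return CodingCoefficients.unpartitioned(X, list(D.class_blocks))


def _lasso_kkt_residual(X: np.ndarray, G: np.ndarray, lambda1: float) -> float:
    """Max violation of the l1 subgradient optimality conditions:
    |g_i + lambda1 sign(x_i)| on the support, max(|g_i| - lambda1, 0) off it."""
    on = X != 0
    res_on = np.abs(G + lambda1 * np.sign(X))[on]
    res_off = np.maximum(np.abs(G[~on]) - lambda1, 0.0)
    worst = 0.0
    if res_on.size:
        worst = float(res_on.max())
    if res_off.size:
        worst = max(worst, float(res_off.max()))
    return worst


def reconstruct(D: StructuredDictionary, X) -> np.ndarray:
    """Reconstructed signals B = D X (p x N)."""
    return D.D @ _coef_array(X)
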