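"""Regularized extreme learning machine (ELM).

A single-hidden-layer network whose hidden parameters (input weights a_i and
biases b_i) are drawn at random and never trained; only the output weights
beta are fitted, in closed form, as the ridge solution of

    min_beta ||beta||^2 + C ||H beta - Y||^2,

where H is the N x m hidden-layer output matrix H[j, i] = g(a_i^T x_j + b_i).
Two algebraically equivalent forms of the solution are used depending on
which Gram matrix is smaller:

    beta = (I/C + H^T H)^{-1} H^T Y        (N > m)
    beta = H^T (I/C + H H^T)^{-1} Y        (N <= m)

The ridge strength C is selected on a grid by closed-form leave-one-out
cross-validation: the PRESS (predicted residual sum of squares) statistic,
computed from the hat matrix of the ridge smoother without any retraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

Activation = Callable[[np.ndarray], np.ndarray]

ACTIVATIONS: dict[str, Activation] = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "rbf": lambda z: np.exp(-(z**2)),
}


@dataclass
class ELMModel:
    """A trained ELM: frozen random hidden layer plus fitted output weights.

    ``input_scale`` is the per-feature max-abs divisor fitted on the
    training features (None = no scaling): uniform [-1, 1] hidden weights
    presume inputs of order one, and without this rescaling a sigmoid layer
    saturates on large-scale features and the random-feature expansion
    degrades.
    """

    W_in: np.ndarray  # m x p input weights, rows a_i
    b: np.ndarray  # m biases
    activation: str
    beta: np.ndarray  # m x q output weights
    C: float
    m: int
    seed: int
    input_scale: np.ndarray | None = None

    def hidden(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if self.input_scale is not None:
            features = features / self.input_scale
        return hidden_output(self.W_in, self.b, features, ACTIVATIONS[self.activation])


def init_hidden(p: int, m: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random hidden parameters, i.i.d. uniform on [-1, 1], seeded."""
    rng = np.random.default_rng(seed)
    W_in = rng.uniform(-1.0, 1.0, size=(m, p))
    b = rng.uniform(-1.0, 1.0, size=m)
    return W_in, b


def hidden_output(
    W_in: np.ndarray, b: np.ndarray, features: np.ndarray, g: Activation
) -> np.ndarray:
    """Hidden-layer output matrix: H[j, i] = g(a_i . x_j + b_i), N x m."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return g(features @ W_in.T + b[None, :])


def solve_output_weights(H: np.ndarray, Y: np.ndarray, C: float) -> np.ndarray:
    """Closed-form ridge output weights, picking the smaller Gram system.

    Both branches are symmetric positive-definite solves (never explicit
    inverses); at N = m they coincide and the dual form is used.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in H or Y")
    N, m = H.shape
    if N > m:
        gram = H.T @ H + np.eye(m) / C
        return scipy.linalg.solve(gram, H.T @ Y, assume_a="pos")
    gram = H @ H.T + np.eye(N) / C
    return H.T @ scipy.linalg.solve(gram, Y, assume_a="pos")


def _hat_diag_and_fit(H: np.ndarray, Y: np.ndarray, C: float):
    """Diagonal of the ridge smoother S = H (I/C + H^T H)^{-1} H^T and the
    in-sample fit S Y, computed through the smaller Gram matrix."""
    N, m = H.shape
    if N > m:
        gram = H.T @ H + np.eye(m) / C
        T = scipy.linalg.solve(gram, H.T, assume_a="pos")  # m x N
        hat_diag = np.einsum("ij,ji->i", H, T)
        fit = H @ (T @ Y)
    else:
        gram = H @ H.T + np.eye(N) / C
        K_inv = scipy.linalg.solve(gram, np.eye(N), assume_a="pos")
        S = H @ H.T @ K_inv
        hat_diag = np.diag(S).copy()
        fit = S @ Y
    return hat_diag, fit


def press_loo_mse(H: np.ndarray, Y: np.ndarray, C: float) -> float:
    """Leave-one-out MSE of the ridge fit, in closed form.

    For a linear smoother the LOO residual of sample j is
    (y_j - yhat_j) / (1 - hat_jj); the PRESS criterion averages its square
    over samples and output dimensions.  No model is retrained.
    """
    H = np.asarray(H, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != H.shape[0]:
        raise ValueError("H and Y row counts differ")
    hat_diag, fit = _hat_diag_and_fit(H, Y, C)
    if np.any(hat_diag >= 1.0 - 1e-12):
        raise ValueError("degenerate leverage: hat_jj ~ 1")
    loo_resid = (Y - fit) / (1.0 - hat_diag)[:, None]
    return float(np.mean(loo_resid**2))


def select_C(H: np.ndarray, Y: np.ndarray, C_grid: Sequence[float]) -> float:
    """Grid value of C minimizing the PRESS LOO MSE.

    Ties are broken toward larger C (stronger regularization).
    """
    if len(C_grid) == 0:
        raise ValueError("empty C grid")
    best_C, best_mse = None, np.inf
    for C in sorted(C_grid):
        mse = press_loo_mse(H, Y, C)
        if mse <= best_mse:  # <= so larger C wins ties on the ascending scan
            best_C, best_mse = C, mse
    return float(best_C)


def elm_train(
    features: np.ndarray,
    Y: np.ndarray,
    m: int,
    C_grid: Sequence[float],
    seed: int,
    activation: str = "sigmoid",
    scale_inputs: bool = True,
) -> ELMModel:
    """Fit an ELM: random hidden layer, PRESS-selected C, closed-form beta.

    With ``scale_inputs`` (default) each feature is divided by its training
    max-abs before the hidden layer, keeping the pre-activations in the
    informative range of the sigmoid; the divisor is stored on the model
    and re-applied at prediction.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    scale = None
    if scale_inputs:
        scale = np.abs(features).max(axis=0)
        scale[scale == 0] = 1.0
        features = features / scale
    g = ACTIVATIONS[activation]
    W_in, b = init_hidden(features.shape[1], m, seed)
    H = hidden_output(W_in, b, features, g)
    C = select_C(H, Y, C_grid)
    beta = solve_output_weights(H, Y, C)
    return ELMModel(
        W_in=W_in, b=b, activation=activation, beta=beta, C=C, m=m, seed=seed,
        input_scale=scale,
    )


def elm_predict(model: ELMModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Network scores H beta and 1-based argmax labels (ties -> lowest class)."""
    scores = model.hidden(features) @ model.beta
    labels = np.argmax(scores, axis=1) + 1
    return scores, labels
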