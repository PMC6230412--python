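"""Motor-imagery EEG front end: segment extraction, band-pass filtering,
common spatial patterns (CSP) and log-variance features.

The processing chain is the standard offline sensorimotor-rhythm recipe:
cut the post-cue window, band-pass to the mu/beta range (8-30 Hz) with a
zero-phase Butterworth filter, learn CSP spatial filters on the training
trials, and describe each trial by the normalized log variance of its
spatially filtered signals.  Multi-class data are handled one-vs-rest, one
binary CSP per class with the filter blocks concatenated.

Filtering is zero-phase (``sosfiltfilt``), which doubles the effective
filter order; this is an offline pipeline, so the non-causality is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass

from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.signal

from .datasets import load_matrix, load_sidecar, save_matrix, save_sidecar


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG: ``data`` is trials x channels x samples.

    ``fs`` is the sampling rate in Hz; ``t0`` the time (seconds, relative to
    the task cue) of the first sample; ``labels`` the 1-based class of each
    trial.
    """

    data: np.ndarray
    fs: float
    t0: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class CSPModel:
    """Fitted CSP spatial filters.

    ``filters`` has one spatial filter per row.  In binary mode there are
    ``2 * n_pairs`` rows (the extremes of the eigenvalue spectrum); in
    one-vs-rest mode one such block per class, concatenated in ``class_order``.
    ``full_filters`` keeps the complete (unkept) filter set of each binary
    problem, which simultaneously diagonalizes the class covariances.
    """

    filters: np.ndarray
    n_pairs: int
    mode: str  # "binary" | "one-vs-rest"
    class_order: np.ndarray
    eigenvalues: list[np.ndarray]
    full_filters: list[np.ndarray]

    @property
    def n_blocks(self) -> int:
        return 1 if self.mode == "binary" else len(self.class_order)

    @property
    def block_size(self) -> int:
        return self.filters.shape[0] // self.n_blocks


def save_epochs(eeg: EpochedEEG, prefix: str | Path) -> None:
    """Write epochs as ``<prefix>.bin`` (trials*channels x samples container),
    ``<prefix>.labels.txt`` and a ``<prefix>.json`` sidecar with the shape,
    sampling rate and cue-relative start time."""
    prefix = Path(prefix)
    flat = eeg.data.reshape(eeg.n_trials * eeg.n_channels, eeg.n_samples)
    save_matrix(prefix.with_suffix(".bin"), flat)
    np.savetxt(prefix.with_suffix(".labels.txt"), eeg.labels[:, None], fmt="%d")
    save_sidecar(
        prefix.with_suffix(".json"),
        {
            "trials": eeg.n_trials,
            "channels": eeg.n_channels,
            "samples": eeg.n_samples,
            "fs": eeg.fs,
            "t0": eeg.t0,
        },
    )


def load_epochs(prefix: str | Path) -> EpochedEEG:
    prefix = Path(prefix)
    meta = load_sidecar(prefix.with_suffix(".json"))
    flat = load_matrix(prefix.with_suffix(".bin"))
    data = flat.reshape(meta["trials"], meta["channels"], meta["samples"])
    labels = np.loadtxt(prefix.with_suffix(".labels.txt"), dtype=int).reshape(-1)
    return EpochedEEG(data=data, fs=meta["fs"], t0=meta["t0"], labels=labels)


def extract_segment(eeg: EpochedEEG, t_start: float, t_end: float) -> EpochedEEG:
    """Cut a cue-relative time window out of every trial.

    The returned epoch has ``round((t_end - t_start) * fs)`` samples and its
    ``t0`` equals ``t_start``.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    eps = 0.5 / eeg.fs  # half-sample slack against float rounding
    if t_start < eeg.t0 - eps or t_end > eeg.t0 + eeg.duration + eps:
        raise ValueError(
            f"segment [{t_start}, {t_end}] outside recorded window "
            f"[{eeg.t0}, {eeg.t0 + eeg.duration}]"
        )
    start = int(round((t_start - eeg.t0) * eeg.fs))
    n_out = int(round((t_end - t_start) * eeg.fs))
    if start + n_out > eeg.n_samples:
        raise ValueError("segment extends past the last recorded sample")
    return EpochedEEG(
        data=eeg.data[:, :, start : start + n_out].copy(),
        fs=eeg.fs,
        t0=t_start,
        labels=eeg.labels.copy(),
    )


def bandpass_epochs(
    eeg: EpochedEEG, low: float, high: float, order: int = 5
) -> EpochedEEG:
    """Zero-phase Butterworth band-pass of every channel of every trial.

    Forward-backward filtering (on second-order sections for numerical
    stability) gives zero phase distortion at the cost of squaring the
    magnitude response.
    """
    nyq = eeg.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) invalid for fs={eeg.fs}")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=eeg.fs, output="sos")
    # forward-backward per biquad with Gustafsson initial conditions: exactly
    # time-reversal symmetric (unlike pad-based filtfilt) and numerically
    # stable through the second-order cascade
    filtered = eeg.data
    for section in sos:
        filtered = scipy.signal.filtfilt(
            section[:3], section[3:], filtered, axis=-1, method="gust"
        )
    return EpochedEEG(data=filtered, fs=eeg.fs, t0=eeg.t0, labels=eeg.labels.copy())


def bandpass_response(
    low: float, high: float, order: int, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """Magnitude response of the zero-phase filter (|H|^2 of the one-pass
    design) at the given frequencies — the analytic oracle for the gain a
    sinusoid experiences under :func:`bandpass_epochs`."""
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = scipy.signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h) ** 2


def _trial_covariances(data: np.ndarray, shrinkage: float) -> np.ndarray:
    """Per-trial spatial covariance, trace-normalized, with diagonal shrinkage
    Sigma <- (1-g) Sigma + g tr(Sigma)/ch I for conditioning."""
    trials, ch, _ = data.shape
    covs = np.einsum("tcs,tds->tcd", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("trial with zero total variance")
    covs /= traces[:, None, None]
    eye = np.eye(ch)
    # after trace normalization tr(Sigma) = 1
    return (1.0 - shrinkage) * covs + shrinkage * (1.0 / ch) * eye


def _binary_csp(cov_a: np.ndarray, cov_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve cov_a w = lambda (cov_a + cov_b) w.

    Returns (W, eigvals) with filters as rows, sorted by descending
    eigenvalue; eigenvectors are B-normalized, so W (cov_a + cov_b) W^T = I.
    """
    composite = cov_a + cov_b
    try:
        vals, vecs = scipy.linalg.eigh(cov_a, composite)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("class covariance not positive definite") from exc
    order = np.argsort(vals, kind="stable")[::-1]
    return vecs[:, order].T, vals[order]


def csp_fit(eeg: EpochedEEG, n_pairs: int = 3, shrinkage: float = 1e-6) -> CSPModel:
    """Learn CSP spatial filters from labeled trials.

    Binary data yield one filter bank: the generalized eigenproblem of the
    two mean (trace-normalized, shrunk) spatial covariances, keeping the
    ``n_pairs`` filters from each end of the eigenvalue spectrum.  With more
    than two classes a binary CSP is fitted per class against the pooled
    rest and the kept blocks are concatenated.
    """
    classes = np.unique(eeg.labels)
    if classes.size < 2:
        raise ValueError("CSP needs at least two classes")
    counts = {int(k): int(np.sum(eeg.labels == k)) for k in classes}
    thin = [k for k, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"class(es) with fewer than 2 trials: {thin}")
    if 2 * n_pairs > eeg.n_channels:
        raise ValueError("2 * n_pairs exceeds channel count")

    covs = _trial_covariances(eeg.data, shrinkage)
    class_covs = {int(k): covs[eeg.labels == k].mean(axis=0) for k in classes}

    if classes.size == 2:
        a, b = int(classes[0]), int(classes[1])
        w_full, vals = _binary_csp(class_covs[a], class_covs[b])
        kept = np.vstack([w_full[:n_pairs], w_full[-n_pairs:]])
        return CSPModel(
            filters=kept,
            n_pairs=n_pairs,
            mode="binary",
            class_order=classes.copy(),
            eigenvalues=[vals],
            full_filters=[w_full],
        )

    blocks, eigs, fulls = [], [], []
    for k in classes:
        rest = covs[eeg.labels != k].mean(axis=0)
        w_full, vals = _binary_csp(class_covs[int(k)], rest)
        blocks.append(np.vstack([w_full[:n_pairs], w_full[-n_pairs:]]))
        eigs.append(vals)
        fulls.append(w_full)
    return CSPModel(
        filters=np.vstack(blocks),
        n_pairs=n_pairs,
        mode="one-vs-rest",
        class_order=classes.copy(),
        eigenvalues=eigs,
        full_filters=fulls,
    )


def split_trials(
    eeg: EpochedEEG, test_fraction: float = 0.5, seed: int = 0
) -> tuple[EpochedEEG, EpochedEEG]:
    """Seeded stratified train/test split of trials (default 1:1)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(eeg.labels):
        idx = np.flatnonzero(eeg.labels == cls)
        rng.shuffle(idx)
        n_test = min(max(int(round(test_fraction * idx.size)), 1), idx.size - 1)
        test_idx.extend(idx[:n_test].tolist())
    mask = np.zeros(eeg.n_trials, dtype=bool)
    mask[test_idx] = True
    mk = lambda sel: EpochedEEG(
        data=eeg.data[sel].copy(), fs=eeg.fs, t0=eeg.t0, labels=eeg.labels[sel].copy()
    )
    return mk(~mask), mk(mask)


def csp_features(model: CSPModel, eeg: EpochedEEG) -> np.ndarray:
    """Normalized log-variance features, trials x n_filters.

    Per trial and per filter block: project onto the spatial filters, take
    each projection's variance v_k and emit log(v_k / sum_k v_k) within the
    block.  Invariant to global per-trial scaling.
    """
    if eeg.n_channels != model.filters.shape[1]:
        raise ValueError("channel count does not match the fitted model")
    proj = np.einsum("fc,tcs->tfs", model.filters, eeg.data)
    var = proj.var(axis=-1)
    if np.any(var <= 0):
        raise ValueError("zero-variance projected trial")
    bs = model.block_size
    feats = np.empty_like(var)
    for b in range(model.n_blocks):
        block = var[:, b * bs : (b + 1) * bs]
        feats[:, b * bs : (b + 1) * bs] = np.log(block / block.sum(axis=1, keepdims=True))
    return feats
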