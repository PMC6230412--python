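"""Seeded synthetic-data generators.

Two fixtures cover the two halves of the pipeline:

* Gaussian class clusters with controllable separation, for the generic
  dictionary-learning + ELM core.
* Oscillatory multichannel "EEG" whose class information is band-limited
  (mu/beta range) variance modulation on a per-class subset of channels —
  precisely the structure the CSP front end assumes in sensorimotor-rhythm
  motor imagery.

Both generators are pure functions of their spec (including the seed).
They make no attempt to mimic real EEG artifacts, nonstationarity or
inter-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import EpochedEEG, bandpass_epochs
from .datasets import LabeledDataset


@dataclass
class GaussianSpec:
    """Isotropic Gaussian class clusters along a random direction.

    Class i's mean sits at ``mean_separation * sd * i`` along a seeded random
    unit direction, so adjacent class means are ``mean_separation`` within-
    class standard deviations apart.
    """

    p: int = 10
    c: int = 2
    n_per_class: tuple[int, ...] = (60, 60)
    mean_separation: float = 4.0
    sd: float = 1.0
    seed: int = 0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.mean_separation < 0:
            raise ValueError("mean_separation must be nonnegative")
        if len(self.n_per_class) != self.c:
            raise ValueError("n_per_class must list one count per class")
        if any(n < 1 for n in self.n_per_class) or self.p < 1:
            raise ValueError("all counts must be positive")


def make_gaussian_classes(spec: GaussianSpec) -> LabeledDataset:
    rng = np.random.default_rng(spec.seed)
    direction = rng.normal(size=spec.p)
    direction /= np.linalg.norm(direction)
    cols = []
    labels = []
    for i in range(1, spec.c + 1):
        n = spec.n_per_class[i - 1]
        mean = spec.mean_separation * spec.sd * i * direction
        cols.append(mean[:, None] + spec.sd * rng.normal(size=(spec.p, n)))
        labels.extend([i] * n)
    A = np.hstack(cols)
    return LabeledDataset.from_arrays(A, np.array(labels), normalize=spec.normalize)


@dataclass
class MIEEGSpec:
    """Two- or four-class oscillatory EEG with planted CSP structure.

    Every trial is broadband Gaussian noise on all channels plus a
    band-limited (``carrier_band``) oscillatory component.  On the trial
    class's ``active_channels`` the oscillation's variance is
    ``modulation_depth`` times the baseline; everywhere else it is baseline.
    The trial starts at the cue (t0 = 0).
    """

    n_trials_per_class: int = 60
    channels: int = 10
    fs: float = 250.0
    duration_s: float = 3.0
    carrier_band: tuple[float, float] = (8.0, 30.0)
    active_channels: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: {1: (0, 1), 2: (2, 3)}
    )
    modulation_depth: float = 3.0
    noise_sd: float = 1.0
    baseline_band_var: float = 1.0
    filter_order: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.carrier_band
        if not 0 < low < high < self.fs / 2:
            raise ValueError("carrier_band must lie inside (0, fs/2)")
        if self.modulation_depth <= 1:
            raise ValueError("modulation_depth must exceed 1")
        for cls, chans in self.active_channels.items():
            if any(ch < 0 or ch >= self.channels for ch in chans):
                raise ValueError(f"active channel out of range for class {cls}")

    @property
    def classes(self) -> list[int]:
        return sorted(self.active_channels)


def band_limited_noise(
    n_trials: int, channels: int, samples: int, spec: MIEEGSpec, rng: np.random.Generator
) -> np.ndarray:
    """White noise pushed through the analysis-band Butterworth filter and
    rescaled to exactly unit variance per trial-channel.  Reusing the CSP
    front end's zero-phase filter keeps the spectra consistent with the band
    the pipeline later analyzes.  Synthesis is padded by one second per side
    and cropped to the stationary interior, so filter edge transients do not
    leak broadband power into the nominally band-limited component."""
    pad = int(round(spec.fs))
    white = rng.normal(size=(n_trials, channels, samples + 2 * pad))
    carrier = EpochedEEG(
        data=white, fs=spec.fs, t0=0.0, labels=np.ones(n_trials, dtype=int)
    )
    low, high = spec.carrier_band
    filtered = bandpass_epochs(carrier, low, high, order=spec.filter_order).data
    filtered = filtered[:, :, pad : pad + samples]
    sd = filtered.std(axis=-1, keepdims=True)
    return filtered / sd


def make_mi_eeg(spec: MIEEGSpec) -> EpochedEEG:
    """Generate balanced, class-interleaved epochs with planted band power."""
    rng = np.random.default_rng(spec.seed)
    samples = int(round(spec.duration_s * spec.fs))
    classes = spec.classes
    n_total = spec.n_trials_per_class * len(classes)
    labels = np.tile(classes, spec.n_trials_per_class)  # interleaved, balanced
    osc = band_limited_noise(n_total, spec.channels, samples, spec, rng)
    amp = np.full((n_total, spec.channels, 1), np.sqrt(spec.baseline_band_var))
    boost = np.sqrt(spec.modulation_depth * spec.baseline_band_var)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        for ch in spec.active_channels[cls]:
            amp[idx, ch, 0] = boost
    noise = spec.noise_sd * rng.normal(size=(n_total, spec.channels, samples))
    return EpochedEEG(data=amp * osc + noise, fs=spec.fs, t0=0.0, labels=labels)
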