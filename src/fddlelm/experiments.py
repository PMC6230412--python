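"""Canonical synthetic-fixture experiments.

These reproduce, at desk scale, the two recovery studies the package is
validated on: Gaussian cluster classification with the generic core, and
planted band-power motor-imagery classification with the full EEG chain.
Both are pure functions of the master seed.  Problem sizes and the fixed
hyper-parameters are documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .csp import bandpass_epochs, csp_features, csp_fit, extract_segment, split_trials
from .datasets import FDDLHyperparams, LabeledDataset, RunConfig
from .pipeline import accuracy, fddl_elm_fit, fddl_elm_predict, train_test_split
from .synth import GaussianSpec, MIEEGSpec, make_gaussian_classes, make_mi_eeg

_C_GRID = RunConfig().C_grid


def gaussian_recovery(seed: int = 0, n_seeds: int = 10) -> list[float]:
    """Test accuracy of FDDL-ELM on 4-sigma-separated Gaussian clusters.

    Per repetition: 120 samples/class (p=10), split 1:1 into train/test
    (60/class each side); dictionary of 30 atoms/class, lambda1 = lambda2 =
    0.01, 500 hidden nodes, PRESS-selected C.
    """
    accs = []
    for s in range(seed, seed + n_seeds):
        ds = make_gaussian_classes(
            GaussianSpec(p=10, c=2, n_per_class=(120, 120), mean_separation=4.0,
                         sd=1.0, seed=s, normalize=False)
        )
        train, test = train_test_split(ds, 0.5, seed=s)
        hyper = FDDLHyperparams(
            lambda1=0.01, lambda2=0.01, atoms_per_class=30, max_outer_iter=15,
            seed=s,
        )
        model = fddl_elm_fit(train, hyper, 500, _C_GRID, seed=s)
        _, pred = fddl_elm_predict(model, test.A)
        accs.append(accuracy(pred, test.labels))
    return accs


def mieeg_recovery(seed: int = 0, n_seeds: int = 10) -> list[float]:
    """Test accuracy of the full EEG chain on planted band-power data.

    Per repetition: 60 trials/class (10 channels, 250 Hz, modulation depth
    3), 0.5-2.5 s segment, 8-30 Hz fifth-order band-pass, 3 CSP pairs fit
    on the training half of a 1:1 trial split; FDDL-ELM on the log-variance
    features (15 atoms/class, lambda1 = lambda2 = 0.01, 50 hidden nodes).
    """
    accs = []
    for s in range(seed, seed + n_seeds):
        eeg = make_mi_eeg(MIEEGSpec(seed=s))
        filt = bandpass_epochs(extract_segment(eeg, 0.5, 2.5), 8.0, 30.0, order=5)
        train_eeg, test_eeg = split_trials(filt, 0.5, seed=s)
        csp = csp_fit(train_eeg, n_pairs=3)
        f_train = csp_features(csp, train_eeg)
        f_test = csp_features(csp, test_eeg)
        train = LabeledDataset.from_arrays(f_train.T, train_eeg.labels)
        hyper = FDDLHyperparams(
            lambda1=0.01, lambda2=0.01, atoms_per_class=15, max_outer_iter=15,
            seed=s,
        )
        model = fddl_elm_fit(train, hyper, 50, _C_GRID, seed=s)
        _, pred = fddl_elm_predict(model, f_test.T)
        accs.append(accuracy(pred, test_eeg.labels))
    return accs
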