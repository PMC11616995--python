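"""Shared fixtures: small synthetic datasets that exercise every stage."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from braillemvpa import (Epochs, EffectSpec, default_montage,
                         generate_eeg_session_schedule, synthesize_eeg_epochs)


@pytest.fixture(scope="session")
def montage16():
    return {k: v for k, v in list(default_montage(63).items())[:16]}


@pytest.fixture(scope="session")
def montage8(montage16):
    return {k: v for k, v in list(montage16.items())[:8]}


def make_epochs(n_letters=4, reps=20, n_channels=8, sfreq=100.0,
                window=(-100.0, 390.0), sensory_snr=0.25,
                perceptual_snr=0.2, seed=0, montage=None, **spec_kw):
    """Small synthetic session covering the letter x hand design."""
    from braillemvpa.containers import LETTERS
    letters = LETTERS[:n_letters]
    sched = generate_eeg_session_schedule(
        composition=(2 * n_letters * reps, max(1, n_letters * reps // 6)),
        seed=seed, letters=letters)
    if montage is None:
        montage = {k: v for k, v in
                   list(default_montage(63).items())[:n_channels]}
    spec = EffectSpec(sensory_snr=sensory_snr, perceptual_snr=perceptual_snr,
                      seed=seed, **spec_kw)
    geom = spec.letter_geometry
    if geom is None and n_letters != 8:
        from braillemvpa import default_letter_geometry
        spec.letter_geometry = default_letter_geometry(letters)
    return synthesize_eeg_epochs(sched, spec, n_channels=n_channels,
                                 sfreq=sfreq, epoch_window_ms=window,
                                 montage=montage)


@pytest.fixture(scope="session")
def planted_epochs():
    """Two-code session: sensory from 80 ms, perceptual from 180 ms."""
    return make_epochs(seed=11)


@pytest.fixture(scope="session")
def null_epochs():
    """Noise-only session (no letter information)."""
    return make_epochs(sensory_snr=0.0, perceptual_snr=0.0, seed=12)


def toy_epochs(data, times=None, montage=None, letters=("B", "C"),
               hands=("left", "right")):
    """Epochs directly from an array, cycling letter/hand labels."""
    data = np.asarray(data, dtype=float)
    n, c, t = data.shape
    if times is None:
        times = np.arange(t, dtype=float)
    conds = [(l, h) for l in letters for h in hands]
    lab = pd.DataFrame([{"letter": conds[i % len(conds)][0],
                         "hand": conds[i % len(conds)][1],
                         "kind": "regular", "session": 0}
                        for i in range(n)])
    names = [f"ch{i}" for i in range(c)]
    if montage is None:
        montage = {nm: np.array([i, 0.0, 0.0]) for i, nm in enumerate(names)}
    return Epochs(data=data, times=np.asarray(times, dtype=float),
                  channel_names=names, labels=lab, montage=montage)
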