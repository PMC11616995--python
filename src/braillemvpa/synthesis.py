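"""Synthetic neural and behavioral data with planted sensory/perceptual codes.

The generator emulates the statistical structure of the braille-letter
study: channel-space EEG epochs in which a *hand-dependent* (sensory) letter
code switches on at an early latency and a *hand-independent* (perceptual)
letter code at a later latency; run-wise ROI pattern vectors mixing the two
codes; and 1-7 similarity ratings driven by a latent letter geometry.  It
targets statistical structure, not biophysical realism: there are no
leadfields and no hemodynamic convolution.

The generative model for an epoch at time t is

    x(t) = noise(t) + 1[t in sensory window] * a_s * P[hand, letter]
                    + 1[t in perceptual window] * a_p * Q[letter]

with P patterns drawn independently per (hand, letter), Q patterns per
letter (shared across hands) with pairwise distances shaped to a latent
letter geometry, and spatially correlated, temporally white (optionally
AR(1)) Gaussian noise.

The default letter geometry is the pin-overlap (Hamming) distance between
the 6-dot braille codes of the eight letters — the natural planted geometry
for this stimulus set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import Epochs, HANDS, LETTERS, PatternSet, Ratings, letter_pairs
from .design import TrialSchedule

#: 6-pin braille codes (dots 1-2-3 left column, 4-5-6 right column).
BRAILLE_DOTS: dict[str, tuple[int, ...]] = {
    "B": (1, 1, 0, 0, 0, 0),
    "C": (1, 0, 0, 1, 0, 0),
    "D": (1, 0, 0, 1, 1, 0),
    "L": (1, 1, 1, 0, 0, 0),
    "M": (1, 0, 1, 1, 0, 0),
    "N": (1, 0, 1, 1, 1, 0),
    "V": (1, 1, 1, 0, 0, 1),
    "Z": (1, 0, 1, 0, 1, 1),
    # catch letters, never part of the geometry
    "E": (1, 0, 0, 0, 1, 0),
    "O": (1, 0, 1, 0, 1, 0),
}

#: 63-channel subset of the standard 10-10 system (EASYCAP-style layout).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10", "AF7",
    "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT9", "FT7", "FC3", "FC4",
    "FT8", "FT10", "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4",
)

#: ROI-wise fraction of hand-dependent code, emulating the expected pattern:
#: tactile stream hand-dependent, sighted-reading stream hand-independent,
#: LOC carrying both.
DEFAULT_ROI_MIX: dict[str, float] = {
    "S1": 1.0, "S2": 1.0, "aIPS": 1.0, "pIPS": 1.0, "insula": 1.0,
    "EVC": 0.0, "V4": 0.0, "LOC": 0.5, "LFA": 0.0, "VWFA": 0.0,
}


def default_letter_geometry(letters: tuple[str, ...] = LETTERS) -> np.ndarray:
    """Pairwise Hamming distance between braille dot codes (L x L)."""
    dots = np.array([BRAILLE_DOTS[l] for l in letters], dtype=float)
    return np.abs(dots[:, None, :] - dots[None, :, :]).sum(axis=2)


def default_montage(n_channels: int = 63) -> dict[str, np.ndarray]:
    """Channel name -> 3D position (meters) from the standard 10-10 layout."""
    if n_channels > len(DEFAULT_CHANNELS):
        raise ValueError(f"at most {len(DEFAULT_CHANNELS)} channels available")
    import mne
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mont = mne.channels.make_standard_montage("standard_1020")
    pos = mont.get_positions()["ch_pos"]
    names = DEFAULT_CHANNELS[:n_channels]
    return {name: np.asarray(pos[name], dtype=float) for name in names}


def spatial_noise_covariance(montage: Mapping[str, np.ndarray],
                             length_scale_m: float = 0.05) -> np.ndarray:
    """Unit-variance covariance with exponential falloff by sensor distance."""
    xyz = np.array(list(montage.values()), dtype=float)
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
    cov = np.exp(-d / length_scale_m)
    # guarantee positive-definiteness against rounding
    return cov + 1e-9 * np.eye(len(xyz))


@dataclass
class EffectSpec:
    """Parameters of the planted sensory and perceptual letter codes.

    ``sensory_onset_ms``/``perceptual_onset_ms`` are the latencies at which
    the hand-dependent and hand-independent codes switch on; each stays on
    for ``effect_duration_ms``.  ``sensory_snr``/``perceptual_snr`` are
    pattern amplitudes relative to the unit per-channel noise SD.  Defaults
    plant the sensory code at 80 ms and the perceptual code at 180 ms with
    amplitudes that put desk-scale decoding in the dynamic range between
    chance and ceiling.
    """

    sensory_onset_ms: float = 80.0
    perceptual_onset_ms: float = 180.0
    sensory_snr: float = 0.25
    perceptual_snr: float = 0.2
    effect_duration_ms: float = 420.0
    noise_covariance: np.ndarray | None = None
    letter_geometry: np.ndarray | None = None
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensory_onset_ms > self.perceptual_onset_ms:
            warnings.warn("sensory onset is later than perceptual onset; "
                          "defaults place sensory first", stacklevel=2)
        if self.noise_covariance is not None:
            _check_pd(np.asarray(self.noise_covariance))
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 coefficient must lie in [0, 1)")

    def with_seed(self, seed: int) -> "EffectSpec":
        return replace(self, seed=int(seed))


def _check_pd(cov: np.ndarray) -> np.ndarray:
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("noise covariance must be square")
    if not np.allclose(cov, cov.T):
        raise ValueError("noise covariance must be symmetric")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("noise covariance must be positive-definite") from err


def geometry_embedding(geometry: np.ndarray, n_dim: int | None = None
                       ) -> np.ndarray:
    """Classical multidimensional-scaling embedding of a letter geometry.

    The geometry is interpreted as squared Euclidean dissimilarity (the
    Hamming distance between binary dot codes is exactly the squared
    Euclidean distance between them); negative eigenvalues of the
    double-centered matrix are clipped.  Returns (L, m) coordinates.
    """
    D = np.asarray(geometry, dtype=float)
    L = D.shape[0]
    J = np.eye(L) - np.ones((L, L)) / L
    B = -0.5 * J @ D @ J
    w, V = np.linalg.eigh(B)
    keep = w > max(1e-12, 1e-10 * abs(w).max(initial=1.0))
    w, V = w[keep][::-1], V[:, keep][:, ::-1]
    if n_dim is not None:
        w, V = w[:n_dim], V[:, :n_dim]
    if w.size == 0:  # degenerate geometry (all-equal): a single point
        return np.zeros((L, 1))
    return V * np.sqrt(w)


def _unit_patterns(raw: np.ndarray) -> np.ndarray:
    """Scale patterns to RMS amplitude 1 per channel (norm sqrt(d))."""
    d = raw.shape[-1]
    norms = np.linalg.norm(raw, axis=-1, keepdims=True)
    norms = np.where(norms == 0, 1.0, norms)
    return raw / norms * np.sqrt(d)


def make_letter_codes(rng: np.random.Generator, n_features: int,
                      geometry: np.ndarray,
                      letters: tuple[str, ...] = LETTERS,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw hand-dependent P (2, L, d) and geometry-shaped Q (L, d) codes.

    P patterns are independent spherical Gaussian draws per (hand, letter),
    RMS-normalized.  Q patterns embed the latter geometry via classical MDS
    and a random orthonormal basis, globally rescaled so the mean pattern
    norm is sqrt(d); relative letter distances follow the geometry exactly
    (up to clipped negative eigenvalues).
    """
    L = len(letters)
    P = _unit_patterns(rng.normal(size=(len(HANDS), L, n_features)))
    coords = geometry_embedding(geometry)
    m = coords.shape[1]
    if m > n_features:
        raise ValueError("feature count too small for the letter geometry")
    basis, _ = np.linalg.qr(rng.normal(size=(n_features, m)))
    Q = coords @ basis.T
    mean_norm = np.linalg.norm(Q, axis=1).mean()
    if mean_norm > 0:
        Q = Q / mean_norm * np.sqrt(n_features)
    return P, Q


def _draw_noise(rng: np.random.Generator, chol: np.ndarray, n_trials: int,
                n_samples: int, ar1: float) -> np.ndarray:
    d = chol.shape[0]
    z = rng.standard_normal((n_trials, d, n_samples))
    if ar1 > 0.0:
        # stationary AR(1) over time per channel
        out = np.empty_like(z)
        out[..., 0] = z[..., 0]
        c = np.sqrt(1.0 - ar1 * ar1)
        for t in range(1, n_samples):
            out[..., t] = ar1 * out[..., t - 1] + c * z[..., t]
        z = out
    return np.einsum("ij,njt->nit", chol, z)


def synthesize_eeg_epochs(schedule: TrialSchedule, spec: EffectSpec,
                          n_channels: int = 63, sfreq: float = 1000.0,
                          epoch_window_ms: tuple[float, float] = (-100.0, 999.0),
                          montage: Mapping[str, np.ndarray] | None = None,
                          session: int = 0) -> Epochs:
    """Synthesize one session of epoched channel-space data from a schedule.

    One epoch per non-null trial; catch trials carry noise only and are
    flagged in the labels.  The default window of (-100, 999) ms at 1 kHz
    yields 1100 samples per epoch.
    """
    if schedule.modality != "eeg":
        raise ValueError("EEG epoch synthesis expects an EEG schedule")
    w0, w1 = epoch_window_ms
    if not (w0 <= 0.0 <= w1):
        raise ValueError("epoch window must contain the stimulus onset (0 ms)")
    dt = 1000.0 / sfreq
    times = np.arange(w0, w1 + dt / 2, dt)

    if montage is None:
        montage = default_montage(n_channels)
    names = list(montage.keys())
    if len(names) != n_channels:
        raise ValueError("montage size does not match channel count")

    cov = (np.asarray(spec.noise_covariance, dtype=float)
           if spec.noise_covariance is not None
           else spatial_noise_covariance(montage))
    if cov.shape[0] != n_channels:
        raise ValueError("noise covariance does not match channel count")
    chol = _check_pd(cov)

    geometry = (np.asarray(spec.letter_geometry, dtype=float)
                if spec.letter_geometry is not None
                else default_letter_geometry())

    letters = tuple(sorted(set(
        schedule.entries.loc[schedule.entries["kind"] == "regular", "letter"])))
    if geometry.shape[0] != len(letters):
        raise ValueError("letter geometry does not match the letter set")

    ss = np.random.SeedSequence(spec.seed)
    code_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    P, Q = make_letter_codes(code_rng, n_channels, geometry, letters)

    trials = schedule.entries[schedule.entries["kind"] != "null"]
    n_trials = len(trials)
    data = _draw_noise(noise_rng, chol, n_trials, times.size, spec.ar1)

    sens = ((times >= spec.sensory_onset_ms)
            & (times < spec.sensory_onset_ms + spec.effect_duration_ms))
    perc = ((times >= spec.perceptual_onset_ms)
            & (times < spec.perceptual_onset_ms + spec.effect_duration_ms))

    letter_idx = {l: i for i, l in enumerate(letters)}
    hand_idx = {h: i for i, h in enumerate(HANDS)}
    for row, (_, tr) in enumerate(trials.iterrows()):
        if tr["kind"] != "regular":
            continue
        li = letter_idx[tr["letter"]]
        hi = hand_idx[tr["hand"]]
        data[row, :, sens] += spec.sensory_snr * P[hi, li]
        data[row, :, perc] += spec.perceptual_snr * Q[li]

    labels = pd.DataFrame({
        "letter": trials["letter"].to_numpy(),
        "hand": trials["hand"].to_numpy(),
        "kind": trials["kind"].to_numpy(),
        "session": session,
    })
    return Epochs(data=data, times=times, channel_names=names, labels=labels,
                  montage=dict(montage),
                  meta={"letters": letters, "seed": int(spec.seed),
                        "sfreq": float(sfreq)})


def synthesize_roi_patterns(n_runs: int, spec: EffectSpec,
                            n_features: int = 100,
                            mix: Mapping[str, float] | float | None = None,
                            amplitude: float = 1.0,
                            letters: tuple[str, ...] = LETTERS,
                            ) -> dict[str, PatternSet]:
    """Run-wise t-value-like condition patterns per named ROI.

    Each ROI mixes a hand-dependent code P and a hand-independent code Q:
    ``pattern = amplitude * (mix * P[hand, letter] + (1 - mix) * Q[letter])
    + noise`` per run, with iid unit Gaussian feature noise.  ``mix=1``
    yields a purely sensory ROI (within-hand decodable only), ``mix=0`` a
    purely perceptual ROI (within ~ across).
    """
    if n_runs < 5:
        raise ValueError("at least 5 runs are needed to form 5 pseudo-runs")
    if mix is None:
        mix = DEFAULT_ROI_MIX
    if not isinstance(mix, Mapping):
        mix = {"roi": float(mix)}
    for name, m in mix.items():
        if not (0.0 <= m <= 1.0):
            raise ValueError(f"mix for ROI {name!r} must lie in [0, 1]")

    geometry = (np.asarray(spec.letter_geometry, dtype=float)
                if spec.letter_geometry is not None
                else default_letter_geometry(letters))
    conditions = [(l, h) for l in letters for h in HANDS]
    ss = np.random.SeedSequence(spec.seed)
    out: dict[str, PatternSet] = {}
    for (name, m), child in zip(sorted(mix.items()), ss.spawn(len(mix))):
        code_rng, noise_rng = (np.random.default_rng(s) for s in child.spawn(2))
        P, Q = make_letter_codes(code_rng, n_features, geometry, letters)
        signal = np.stack([
            amplitude * (m * P[HANDS.index(h), letters.index(l)]
                         + (1.0 - m) * Q[letters.index(l)])
            for l, h in conditions])                      # (C, d)
        noise = noise_rng.standard_normal((n_runs, len(conditions), n_features))
        out[name] = PatternSet(data=signal[None] + noise,
                               conditions=conditions, roi=name,
                               meta={"mix": float(m),
                                     "amplitude": float(amplitude),
                                     "seed": int(spec.seed)})
    return out


def synthesize_similarity_ratings(letter_geometry: np.ndarray | None = None,
                                  n_participants: int = 19,
                                  noise_sd: float = 1.0,
                                  seed: int = 0,
                                  letters: tuple[str, ...] = LETTERS,
                                  ) -> Ratings:
    """1-7 similarity ratings from a monotone rescaling of a latent geometry.

    Each participant's rating of a pair is the latent dissimilarity mapped
    linearly onto [1, 7], plus Gaussian noise, rounded to integers and
    clipped to the scale.  With ``noise_sd=0`` the participant-average RDM
    rank-correlates perfectly with the latent geometry.
    """
    if n_participants < 1:
        raise ValueError("at least one participant is required")
    geometry = (np.asarray(letter_geometry, dtype=float)
                if letter_geometry is not None
                else default_letter_geometry(letters))
    pairs = letter_pairs(letters)
    idx = {l: i for i, l in enumerate(letters)}
    latent = np.array([geometry[idx[a], idx[b]] for a, b in pairs])
    lo, hi = latent.min(), latent.max()
    if hi > lo:
        scaled = 1.0 + 6.0 * (latent - lo) / (hi - lo)
    else:  # degenerate: all pairs equally dissimilar
        scaled = np.full_like(latent, 4.0)
    rng = np.random.default_rng(seed)
    vals = scaled[None, :] + rng.normal(0.0, noise_sd,
                                        size=(n_participants, latent.size))
    vals = np.clip(np.rint(vals), 1, 7).astype(int)
    return Ratings(values=vals, pairs=pairs, letters=letters)
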