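"""Preprocessing between raw epochs/patterns and the decoder.

Three steps: baseline correction against the prestimulus window,
multivariate noise normalization (whitening by an inverse-square-root of a
shrinkage-regularized channel covariance, estimated within condition per
time point and averaged), and pseudo-trial / pseudo-run binning, which
averages disjoint random subsets of trials (runs) within a condition to
raise SNR before classification.

Noise normalization is applied once to the full epoch set, mirroring its
place in the source procedure as a preprocessing step before any
cross-validation; see the methods note for the leakage discussion.
"""
from __future__ import annotations

import numpy as np

from .containers import Epochs, HANDS, PatternSet, PseudoTrials


def baseline_correct(epochs: Epochs,
                     window_ms: tuple[float, float] = (-100.0, 0.0)) -> Epochs:
    """Subtract the per-trial, per-channel mean over the baseline window.

    The window is half-open, [start, stop): the default (-100, 0) covers the
    100-ms prestimulus interval and excludes the stimulus-onset sample.
    """
    w0, w1 = window_ms
    mask = (epochs.times >= w0) & (epochs.times < w1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy(data=epochs.data - base)


def _condition_groups(epochs: Epochs) -> list[np.ndarray]:
    lab = epochs.labels
    reg = lab["kind"] == "regular"
    groups = []
    for (_, _), idx in lab[reg].groupby(["letter", "hand"],
                                        observed=True).groups.items():
        groups.append(np.asarray(idx))
    return groups


def _ledoit_wolf_cov(X: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance of (n, d) demeaned observations."""
    from sklearn.covariance import ledoit_wolf
    cov, _ = ledoit_wolf(X, assume_centered=True)
    return cov


def estimate_noise_covariance(epochs: Epochs,
                              shrinkage: str | float = "lw") -> np.ndarray:
    """Channel covariance, estimated within condition per time point and
    averaged across time points and conditions.

    ``shrinkage='lw'`` applies analytic Ledoit-Wolf shrinkage toward scaled
    identity per time point; ``'none'`` uses the empirical covariance; a
    float in [0, 1) mixes empirical covariance with scaled identity at that
    fixed intensity.
    """
    groups = _condition_groups(epochs)
    if not groups or min(len(g) for g in groups) < 2:
        raise ValueError("noise covariance needs >= 2 trials per condition")
    d = epochs.n_channels
    total = np.zeros((d, d))
    count = 0
    for idx in groups:
        X = epochs.data[idx]                       # (n, d, T)
        X = X - X.mean(axis=0, keepdims=True)      # demean within condition
        if shrinkage == "lw":
            for t in range(epochs.n_samples):
                total += _ledoit_wolf_cov(X[:, :, t])
            count += epochs.n_samples
        else:
            n = X.shape[0]
            emp = np.einsum("ndt,net->de", X, X) / ((n - 1) * epochs.n_samples)
            if shrinkage != "none":
                s = float(shrinkage)
                if not (0.0 <= s < 1.0):
                    raise ValueError("shrinkage intensity must lie in [0, 1)")
                emp = (1.0 - s) * emp + s * (np.trace(emp) / d) * np.eye(d)
            total += emp
            count += 1
    return total / count


def _inverse_sqrt(cov: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(cov)
    if w.min() <= 1e-12 * max(w.max(), 1.0):
        raise np.linalg.LinAlgError(
            "noise covariance is singular; enable shrinkage or supply more "
            "trials")
    return (V / np.sqrt(w)) @ V.T


def noise_normalize(epochs: Epochs, shrinkage: str | float = "lw",
                    return_operator: bool = False):
    """Whiten channel patterns by the inverse square root of the noise
    covariance (multivariate noise normalization).

    Output shape is unchanged; with frozen covariance the transform is
    invertible, and applying it twice equals applying the covariance inverse
    once.
    """
    cov = estimate_noise_covariance(epochs, shrinkage=shrinkage)
    W = _inverse_sqrt(cov)
    out = epochs.copy(data=np.einsum("ij,njt->nit", W, epochs.data))
    out.meta["noise_whitener"] = W
    if return_operator:
        return out, W
    return out


def bin_pseudotrials(trials: np.ndarray, bin_size: int,
                     rng: np.random.Generator | int | None = None
                     ) -> PseudoTrials:
    """Average disjoint random subsets of ``bin_size`` trials each.

    ``trials`` is (n_trials, ...features); the result holds
    floor(n/bin_size) pseudo-trials, each the arithmetic mean of its
    recorded member trials; leftover trials are dropped.
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    trials = np.asarray(trials)
    n = trials.shape[0]
    if n < bin_size:
        raise ValueError("fewer trials than the bin size")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_pseudo = n // bin_size
    perm = rng.permutation(n)[:n_pseudo * bin_size]
    membership = perm.reshape(n_pseudo, bin_size)
    data = trials[membership].mean(axis=1)
    return PseudoTrials(data=data, membership=membership, bin_size=bin_size)


def make_pseudotrial_array(epochs: Epochs, n_pseudo: int = 5,
                           bin_size: int | None = None,
                           rng: np.random.Generator | int | None = None,
                           ) -> tuple[np.ndarray, tuple[str, ...], dict]:
    """Bin every condition of an epoch set into pseudo-trials.

    Returns ``(array, letters, membership)`` with ``array`` shaped
    (n_letters, n_hands, n_pseudo, n_channels, n_samples).  The default
    bin size is floor(n_per_condition / n_pseudo) — 34 for the 170
    repetitions of a single session, 68 for the 340 of two pooled sessions,
    5 pseudo-trials either way.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    reg = epochs.regular()
    letters = tuple(sorted(set(reg.labels["letter"])))
    arr = None
    membership: dict[tuple[str, str], np.ndarray] = {}
    for li, letter in enumerate(letters):
        for hi, hand in enumerate(HANDS):
            idx = np.flatnonzero((reg.labels["letter"] == letter)
                                 & (reg.labels["hand"] == hand))
            if idx.size == 0:
                raise ValueError(f"condition {letter}/{hand} has no trials")
            bs = bin_size if bin_size is not None else idx.size // n_pseudo
            pt = bin_pseudotrials(reg.data[idx], bs, rng)
            if pt.n_pseudo < n_pseudo:
                raise ValueError(
                    f"condition {letter}/{hand}: cannot form {n_pseudo} "
                    f"pseudo-trials from {idx.size} trials at bin size {bs}")
            if arr is None:
                arr = np.empty((len(letters), len(HANDS), n_pseudo)
                               + pt.data.shape[1:])
            arr[li, hi] = pt.data[:n_pseudo]
            membership[(letter, hand)] = idx[pt.membership[:n_pseudo]]
    return arr, letters, membership


def bin_pseudoruns(pattern_set: PatternSet, seed: int | np.random.Generator = 0,
                   n_pseudo: int = 5,
                   ) -> tuple[np.ndarray, tuple[str, ...], dict]:
    """Bin run-wise pattern vectors into exactly five pseudo-runs.

    Bin size follows the run count: 10 runs -> bins of 2, 25 runs -> bins
    of 5, otherwise floor(n_runs / 5); leftover runs are dropped.  Returns
    ``(array, letters, membership)`` with ``array`` shaped
    (n_letters, n_hands, n_pseudo, n_features).
    """
    n_runs = pattern_set.n_runs
    if n_runs < n_pseudo:
        raise ValueError(f"at least {n_pseudo} runs are required")
    bin_size = n_runs // n_pseudo
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    letters = tuple(sorted({l for l, _ in pattern_set.conditions}))
    cond_idx = {c: i for i, c in enumerate(pattern_set.conditions)}
    arr = np.empty((len(letters), len(HANDS), n_pseudo,
                    pattern_set.n_features))
    membership: dict[tuple[str, str], np.ndarray] = {}
    for li, letter in enumerate(letters):
        for hi, hand in enumerate(HANDS):
            runs = pattern_set.data[:, cond_idx[(letter, hand)], :]
            pt = bin_pseudotrials(runs, bin_size, rng)
            arr[li, hi] = pt.data[:n_pseudo]
            membership[(letter, hand)] = pt.membership[:n_pseudo]
    return arr, letters, membership
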