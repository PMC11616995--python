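"""Shared in-memory containers for the decoding pipeline.

The containers are thin dataclasses around numpy arrays plus the label
metadata that downstream stages need: epoched channel-space data, run-wise
condition pattern vectors, pseudo-trial averages, pairwise decoding results,
representational dissimilarity matrices, and behavioral similarity ratings.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: The eight letters entering all analyses.
LETTERS: tuple[str, ...] = ("B", "C", "D", "L", "M", "N", "V", "Z")
#: Vigilance-target letters; their trials are carried but excluded from decoding.
CATCH_LETTERS: tuple[str, ...] = ("E", "O")
HANDS: tuple[str, str] = ("left", "right")
#: Chance level for pairwise classification, in percent.
CHANCE = 50.0


def letter_pairs(letters: tuple[str, ...] = LETTERS) -> list[tuple[str, str]]:
    """All unordered letter pairs, row-major over the lower triangle."""
    return [(letters[i], letters[j])
            for i in range(len(letters)) for j in range(i)]


@dataclass
class Epochs:
    """Trials x channels x samples tensor with per-trial labels.

    ``data`` has shape (n_trials, n_channels, n_samples); ``times`` is the
    per-sample latency in ms (uniform, strictly increasing); ``labels`` has
    one row per trial with columns ``letter``, ``hand``, ``kind`` and
    ``session``; ``montage`` maps channel names to 3D positions in meters.
    """

    data: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    labels: pd.DataFrame
    montage: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length does not match data")
        dt = np.diff(self.times)
        if self.times.size > 1 and (dt <= 0).any():
            raise ValueError("time axis must be strictly increasing")
        if self.times.size > 2 and not np.allclose(dt, dt[0]):
            raise ValueError("time axis must have a uniform step")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label table length must equal trial count")

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
    def sfreq(self) -> float:
        """Sampling rate in Hz."""
        if self.times.size < 2:
            return float("nan")
        return 1000.0 / float(self.times[1] - self.times[0])

    def copy(self, data: np.ndarray | None = None) -> "Epochs":
        return Epochs(
            data=self.data.copy() if data is None else data,
            times=self.times.copy(),
            channel_names=list(self.channel_names),
            labels=self.labels.copy(),
            montage={k: np.asarray(v).copy() for k, v in self.montage.items()},
            meta=dict(self.meta),
        )

    def regular(self) -> "Epochs":
        """Subset to regular (non-catch) trials."""
        keep = (self.labels["kind"] == "regular").to_numpy()
        return Epochs(
            data=self.data[keep],
            times=self.times.copy(),
            channel_names=list(self.channel_names),
            labels=self.labels.loc[keep].reset_index(drop=True),
            montage=dict(self.montage),
            meta=dict(self.meta),
        )


@dataclass
class PatternSet:
    """Per-ROI activation patterns: runs x conditions x features (t-values)."""

    data: np.ndarray
    conditions: list[tuple[str, str]]  # (letter, hand) per condition column
    roi: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("pattern data must be runs x conditions x features")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("condition labels do not match data")

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[2]


@dataclass
class PseudoTrials:
    """Pseudo-trial averages for one condition plus binning provenance.

    ``data`` has shape (n_pseudo, ...) and ``membership`` records, per
    pseudo-trial, the source-trial indices that were averaged (disjoint
    within one binning iteration; leftovers are dropped).
    """

    data: np.ndarray
    membership: np.ndarray
    bin_size: int

    @property
    def n_pseudo(self) -> int:
        return self.data.shape[0]


@dataclass
class DecodingResult:
    """Pairwise accuracy matrices for one classification scheme.

    ``accuracies`` is (L, L) in percent (diagonal NaN) or, for time- or
    ROI-resolved results, (n_points, L, L) with ``axis_values`` holding the
    time axis in ms (or ROI names). Matrices are symmetric; hands (within
    scheme) or train-test directions (across scheme) are averaged.
    """

    scheme: str  # within | across | difference
    accuracies: np.ndarray
    letters: tuple[str, ...] = LETTERS
    axis_values: np.ndarray | list | None = None
    n_folds: int = 5
    n_iterations: int = 1
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.scheme not in ("within", "across", "difference"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def resolved(self) -> bool:
        return self.accuracies.ndim == 3

    def pair_matrix(self) -> np.ndarray:
        """(L, L) matrix averaged over any leading axis."""
        if self.resolved:
            return np.nanmean(self.accuracies, axis=0)
        return self.accuracies

    def timecourse(self) -> np.ndarray:
        """Accuracy averaged over condition pairs, one value per point."""
        acc = self.accuracies if self.resolved else self.accuracies[None]
        L = acc.shape[-1]
        iu = np.triu_indices(L, k=1)
        tc = acc[:, iu[0], iu[1]].mean(axis=1)
        return tc if self.resolved else tc[0]

    def grand_mean(self) -> float:
        """Grand-average accuracy over pairs (and time points / ROIs)."""
        return float(np.mean(self.timecourse()))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (scheme, pair, axis value, accuracy)."""
        acc = self.accuracies if self.resolved else self.accuracies[None]
        axis = (self.axis_values if self.axis_values is not None
                else np.arange(acc.shape[0]))
        rows = []
        L = len(self.letters)
        for t, av in enumerate(np.asarray(axis, dtype=object)):
            for i in range(L):
                for j in range(i):
                    rows.append({
                        "scheme": self.scheme,
                        "letter_a": self.letters[j],
                        "letter_b": self.letters[i],
                        "axis": av,
                        "accuracy": acc[t, i, j],
                    })
        return pd.DataFrame(rows)


@dataclass
class RDM:
    """8x8 representational dissimilarity matrix; diagonal undefined (NaN)."""

    values: np.ndarray
    letters: tuple[str, ...] = LETTERS
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.letters)
        if self.values.shape != (n, n):
            raise ValueError("RDM must be square over the letter set")
        offdiag = ~np.eye(n, dtype=bool)
        v = self.values[offdiag]
        if not np.allclose(self.values[offdiag],
                           self.values.T[offdiag], equal_nan=True):
            raise ValueError("RDM must be symmetric")
        np.fill_diagonal(self.values, np.nan)

    def lower_triangle(self) -> np.ndarray:
        """The C(L,2) below-diagonal entries, row-major."""
        n = len(self.letters)
        il = np.tril_indices(n, k=-1)
        return self.values[il]


@dataclass
class Ratings:
    """Pairwise perceived-similarity ratings on the integer 1-7 scale.

    ``values`` is (n_participants, n_pairs); ``pairs`` maps each column to
    an unordered letter pair. 1 = very similar, 7 = very different.
    """

    values: np.ndarray
    pairs: list[tuple[str, str]]
    letters: tuple[str, ...] = LETTERS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("ratings must be participants x pairs")
        if self.values.shape[1] != len(self.pairs):
            raise ValueError("pair index does not match rating columns")
        if ((self.values < 1) | (self.values > 7)).any():
            raise ValueError("ratings must lie on the 1-7 scale")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]


@dataclass
class AccuracyMap:
    """Searchlight accuracy map: volumetric voxel grid or sensor x time bins."""

    kind: str  # "volume" | "sensor"
    data: np.ndarray
    affine: np.ndarray | None = None
    channel_names: list[str] | None = None
    bin_starts_ms: np.ndarray | None = None
    bin_ms: float | None = None
    scheme: str = "across"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("volume", "sensor"):
            raise ValueError("map kind must be 'volume' or 'sensor'")
        self.data = np.asarray(self.data, dtype=float)
        finite = self.data[np.isfinite(self.data)]
        if finite.size and ((finite < 0) | (finite > 100)).any():
            raise ValueError("accuracies must lie in [0, 100]")
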