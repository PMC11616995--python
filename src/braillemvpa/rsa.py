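"""Representational similarity analysis linking decoding and behavior.

Pairwise classification accuracy is a dissimilarity measure (two letters
decode better the more dissimilar their neural patterns), so decoding
results arrange directly into 8 x 8 representational dissimilarity matrices
(RDMs), as do participant-averaged 1-7 similarity ratings.  Neural and
behavioral measurement spaces are then related by Spearman rank correlation
over the 28 lower-triangle entries (diagonal excluded; ties get average
ranks).  RDMs are averaged over hands (the decoding stage already does
this); the group pipeline keeps neural RDMs subject-specific and the
behavioral RDM participant-averaged, one correlation per subject and ROI or
time point.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import DecodingResult, RDM, Ratings, letter_pairs

__all__ = ["accuracies_to_rdm", "rdms_over_axis", "ratings_to_rdm",
           "rdm_correlation", "rdm_timecourse_correlation"]


def accuracies_to_rdm(result: DecodingResult, index: int | None = None
                      ) -> RDM:
    """RDM from a decoding result's pair accuracy matrix.

    For time- or ROI-resolved results, ``index`` selects the point; without
    it, the matrices are averaged over the leading axis.  Accuracies enter
    as-is (percent, hands/directions already averaged).
    """
    if result.resolved and index is not None:
        mat = result.accuracies[index]
    else:
        mat = result.pair_matrix()
    if np.isnan(mat[~np.eye(mat.shape[0], dtype=bool)]).any():
        raise ValueError("decoding result has missing letter pairs")
    src = result.scheme if index is None else f"{result.scheme}@{index}"
    return RDM(values=mat.copy(), letters=result.letters, source=src)


def rdms_over_axis(result: DecodingResult) -> list[RDM]:
    """One RDM per time point (or ROI) of a resolved decoding result."""
    if not result.resolved:
        return [accuracies_to_rdm(result)]
    return [accuracies_to_rdm(result, i)
            for i in range(result.accuracies.shape[0])]


def ratings_to_rdm(ratings: Ratings) -> RDM:
    """Participant-averaged similarity ratings arranged as an RDM."""
    mean = np.asarray(ratings.values, dtype=float).mean(axis=0)
    n = len(ratings.letters)
    idx = {l: i for i, l in enumerate(ratings.letters)}
    values = np.full((n, n), np.nan)
    for (a, b), v in zip(ratings.pairs, mean):
        values[idx[a], idx[b]] = v
        values[idx[b], idx[a]] = v
    expected = set(map(frozenset, letter_pairs(ratings.letters)))
    got = set(frozenset(p) for p in ratings.pairs)
    if got != expected:
        raise ValueError("ratings do not cover every letter pair exactly once")
    return RDM(values=values, letters=ratings.letters, source="behavior")


def rdm_correlation(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman's R over the lower-triangle entries of two RDMs.

    Returns NaN when either triangle has zero variance (rank correlation
    undefined).
    """
    if rdm_a.values.shape != rdm_b.values.shape:
        raise ValueError("RDM dimensions do not match")
    a = rdm_a.lower_triangle()
    b = rdm_b.lower_triangle()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r, _ = sps.spearmanr(a, b)
    return float(r)


def rdm_timecourse_correlation(behavior: RDM, result: DecodingResult
                               ) -> np.ndarray:
    """Spearman R between a behavioral RDM and each time point's neural RDM."""
    return np.asarray([rdm_correlation(behavior, rdm)
                       for rdm in rdms_over_axis(result)])


def group_rsa(behavior: RDM,
              subject_results: list[DecodingResult]) -> pd.DataFrame:
    """One correlation (time course) per subject against the group-average
    behavioral RDM; tidy output (subject, axis, R)."""
    rows = []
    for s, res in enumerate(subject_results):
        rs = rdm_timecourse_correlation(behavior, res)
        axis = (res.axis_values if res.axis_values is not None
                else np.arange(rs.size))
        for av, r in zip(np.asarray(axis, dtype=object), rs):
            rows.append({"subject": s, "scheme": res.scheme,
                         "axis": av, "R": r})
    return pd.DataFrame(rows)
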