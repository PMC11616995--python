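"""Pairwise SVM decoding of letter identity, within and across hands.

For every pair of letters, a linear C-SVC is trained on pseudo-trial
patterns and evaluated with leave-one-pseudo-trial-out cross-validation
(five folds by default).  Two schemes index different representations:

* **within-hand** — train and test on the same hand; sensitive to both
  hand-dependent (sensory) and hand-independent (perceptual) letter codes;
* **across-hand** — train on one hand, test on the other (both directions);
  sensitive only to hand-independent codes.

Their entrywise difference (within - across) isolates the hand-dependent
component.  Accuracies are reported in percent against a 50% chance level
and aggregated into symmetric letter x letter matrices (diagonal
undefined), per time point for EEG or per ROI for fMRI patterns.
"""
from __future__ import annotations

import numpy as np

from ._svm import DEFAULT_C, ENGINES
from .containers import CHANCE, DecodingResult, Epochs, PatternSet
from .preprocess import bin_pseudoruns, make_pseudotrial_array

__all__ = [
    "pairwise_cv_decode", "within_hand_decode", "across_hand_decode",
    "sensory_score", "time_resolved_decode", "roi_decode",
]


def _pair_indices(n_letters: int) -> np.ndarray:
    """(P, 2) lower-triangle letter index pairs, row-major."""
    out = [(i, j) for i in range(n_letters) for j in range(i)]
    return np.asarray(out, dtype=int)


def _as_timed(pseudo: np.ndarray) -> tuple[np.ndarray, bool]:
    if pseudo.ndim == 4:          # (L, H, n_pseudo, d)
        return pseudo[..., None], False
    if pseudo.ndim == 5:          # (L, H, n_pseudo, d, T)
        return pseudo, True
    raise ValueError("pseudo-trial array must be (L, H, n_pseudo, d[, T])")


def _decode_pairs_folds(Xa: np.ndarray, Xb: np.ndarray,
                        Ta: np.ndarray, Tb: np.ndarray,
                        C: float, engine: str, tol: float) -> np.ndarray:
    """Fold-wise pairwise decoding.

    ``Xa``/``Xb`` are (P, n_pseudo, d, T) training-side pseudo-trials of
    the two letters; ``Ta``/``Tb`` the test side (may be the same arrays
    within-hand or the other hand's across-hand).  Fold f trains on
    training-side pseudo-trials != f and tests on test-side pseudo-trial f.
    Returns (T, P) percent accuracy averaged over folds.
    """
    solver = ENGINES[engine]
    P, n_pseudo, d, T = Xa.shape
    train_idx = np.stack([np.delete(np.arange(n_pseudo), f)
                          for f in range(n_pseudo)])        # (F, n_pseudo-1)
    n_tr = n_pseudo - 1
    y = np.concatenate([np.ones(n_tr), -np.ones(n_tr)])

    # (P, F, n_tr, d, T) per letter -> problems (T, P, F, 2*n_tr, d)
    Atr = Xa[:, train_idx]
    Btr = Xb[:, train_idx]
    Xtr = np.concatenate([Atr, Btr], axis=2)                # (P,F,2n_tr,d,T)
    Xte = np.stack([Ta, Tb], axis=2)                        # (P,F,2,d,T)
    Xtr = np.moveaxis(Xtr, -1, 0).reshape(T * P * n_pseudo, 2 * n_tr, d)
    Xte = np.moveaxis(Xte, -1, 0).reshape(T * P * n_pseudo, 2, d)
    dec = solver(Xtr, y, Xte, C=C) if engine != "batched" else \
        solver(Xtr, y, Xte, C=C, tol=tol)
    correct = np.stack([dec[:, 0] > 0, dec[:, 1] <= 0], axis=1)
    acc = correct.mean(axis=1).reshape(T, P, n_pseudo).mean(axis=2)
    return 100.0 * acc


def _pair_matrix(acc_tp: np.ndarray, n_letters: int) -> np.ndarray:
    """(T, P) pair accuracies -> (T, L, L) symmetric matrices, NaN diagonal."""
    pairs = _pair_indices(n_letters)
    T = acc_tp.shape[0]
    mat = np.full((T, n_letters, n_letters), np.nan)
    mat[:, pairs[:, 0], pairs[:, 1]] = acc_tp
    mat[:, pairs[:, 1], pairs[:, 0]] = acc_tp
    return mat


def _squeeze_result(mat: np.ndarray, timed: bool) -> np.ndarray:
    return mat if timed else mat[0]


def pairwise_cv_decode(train_a: np.ndarray, train_b: np.ndarray,
                       test_a: np.ndarray | None = None,
                       test_b: np.ndarray | None = None,
                       C: float = DEFAULT_C, engine: str = "batched",
                       tol: float = 1e-4) -> float:
    """Leave-one-pseudo-trial-out CV accuracy (%) for one letter pair.

    ``train_a``/``train_b`` are (n_pseudo, d) pseudo-trials of the two
    classes on the training side; ``test_a``/``test_b`` the test side
    (defaults to the training side, i.e. within-hand).  Each fold trains a
    linear C-SVC on the remaining pseudo-trials of both classes and tests
    on the held-out test-side pseudo-trial of each class.
    """
    train_a = np.asarray(train_a, dtype=float)
    train_b = np.asarray(train_b, dtype=float)
    if test_a is None:
        test_a = train_a
    if test_b is None:
        test_b = train_b
    test_a = np.asarray(test_a, dtype=float)
    test_b = np.asarray(test_b, dtype=float)
    if train_a.shape != train_b.shape or test_a.shape != test_b.shape:
        raise ValueError("class arrays must have matching shapes")
    if train_a.shape[1] != test_a.shape[1]:
        raise ValueError("train/test feature dimensionality mismatch")
    if train_a.shape[0] != test_a.shape[0]:
        raise ValueError("train and test sides need equal pseudo-trial counts")
    acc = _decode_pairs_folds(train_a[None, :, :, None],
                              train_b[None, :, :, None],
                              test_a[None, :, :, None],
                              test_b[None, :, :, None],
                              C=C, engine=engine, tol=tol)
    return float(acc[0, 0])


def _decode_scheme(pseudo: np.ndarray, scheme: str, C: float, engine: str,
                   tol: float, chunk_t: int = 64) -> np.ndarray:
    """Decode all pairs in one scheme.

    Returns (T, n_sides, P) with sides = hands (within) or train-test
    directions (across).
    """
    timed_pseudo, _ = _as_timed(pseudo)
    L, H, n_pseudo, d, T = timed_pseudo.shape
    if H != 2:
        raise ValueError("both hands must be present")
    pairs = _pair_indices(L)
    out = np.empty((T, 2, len(pairs)))
    for t0 in range(0, T, chunk_t):
        sl = slice(t0, min(t0 + chunk_t, T))
        block = timed_pseudo[..., sl]
        A = block[pairs[:, 0]]                  # (P, H, n_pseudo, d, Tc)
        B = block[pairs[:, 1]]
        for side in range(2):
            tr_h = side
            te_h = side if scheme == "within" else 1 - side
            out[sl, side] = _decode_pairs_folds(
                A[:, tr_h], B[:, tr_h], A[:, te_h], B[:, te_h],
                C=C, engine=engine, tol=tol)
    return out


def _make_result(acc_tsp: np.ndarray, scheme: str, letters, timed: bool,
                 axis_values, n_iterations: int) -> DecodingResult:
    side_key = "per_hand" if scheme == "within" else "per_direction"
    mean_tp = acc_tsp.mean(axis=1)
    mat = _pair_matrix(mean_tp, len(letters))
    return DecodingResult(
        scheme=scheme,
        accuracies=_squeeze_result(mat, timed),
        letters=tuple(letters),
        axis_values=axis_values,
        n_iterations=n_iterations,
        extra={side_key: _squeeze_result(
            np.stack([_pair_matrix(acc_tsp[:, s], len(letters))
                      for s in range(2)], axis=1),
            True) if timed else np.stack(
                [_pair_matrix(acc_tsp[:, s], len(letters))[0]
                 for s in range(2)])},
    )


def within_hand_decode(pseudo: np.ndarray, letters=None,
                       axis_values=None, C: float = DEFAULT_C,
                       engine: str = "batched", tol: float = 1e-4
                       ) -> DecodingResult:
    """Within-hand pairwise decoding of a pseudo-trial array.

    ``pseudo`` is (L, 2, n_pseudo, d[, T]).  Every letter pair is decoded
    per hand (28 pairs per hand for 8 letters) and accuracies are averaged
    across condition pairs and hands.
    """
    timed = np.asarray(pseudo).ndim == 5
    L = pseudo.shape[0]
    if letters is None:
        letters = tuple(f"L{i}" for i in range(L))
    acc = _decode_scheme(np.asarray(pseudo, dtype=float), "within",
                         C, engine, tol)
    return _make_result(acc, "within", letters, timed, axis_values, 1)


def across_hand_decode(pseudo: np.ndarray, letters=None,
                       axis_values=None, C: float = DEFAULT_C,
                       engine: str = "batched", tol: float = 1e-4
                       ) -> DecodingResult:
    """Across-hand pairwise decoding: train on one hand, test on the other.

    Uses the same fivefold partition skeleton as within-hand decoding, with
    the held-out fold drawn from the other hand; accuracies are averaged
    across condition pairs and the two train-test directions.
    """
    timed = np.asarray(pseudo).ndim == 5
    L = pseudo.shape[0]
    if letters is None:
        letters = tuple(f"L{i}" for i in range(L))
    acc = _decode_scheme(np.asarray(pseudo, dtype=float), "across",
                         C, engine, tol)
    return _make_result(acc, "across", letters, timed, axis_values, 1)


def sensory_score(within: DecodingResult,
                  across: DecodingResult) -> DecodingResult:
    """Within-hand minus across-hand accuracy, entrywise.

    The difference removes the hand-independent (perceptual) component and
    isolates hand-dependent (sensory) letter information; downstream it is
    compared against 0 rather than chance.
    """
    if within.scheme != "within" or across.scheme != "across":
        raise ValueError("expected a (within, across) result pair")
    if within.accuracies.shape != across.accuracies.shape:
        raise ValueError("result shapes do not match")
    if within.letters != across.letters:
        raise ValueError("letter sets do not match")
    return DecodingResult(
        scheme="difference",
        accuracies=within.accuracies - across.accuracies,
        letters=within.letters,
        axis_values=within.axis_values,
        n_iterations=min(within.n_iterations, across.n_iterations),
    )


def time_resolved_decode(epochs: Epochs, n_iterations: int = 100,
                         seed: int | np.random.Generator = 0,
                         schemes: tuple[str, ...] = ("within", "across",
                                                     "difference"),
                         n_pseudo: int = 5, bin_size: int | None = None,
                         C: float = DEFAULT_C, engine: str = "batched",
                         tol: float = 1e-4
                         ) -> dict[str, DecodingResult]:
    """Time-resolved decoding: the full scheme at every sample.

    Trials are randomly assigned to pseudo-trials ``n_iterations`` times
    (100 in the reference procedure); accuracies are averaged over
    condition pairs, folds, iterations, and hands (within) or train-test
    directions (across).  Expects preprocessed (baseline-corrected,
    noise-normalized) epochs.
    """
    if n_iterations < 1:
        raise ValueError("at least one iteration is required")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    want_diff = "difference" in schemes
    base = [s for s in schemes if s != "difference"]
    if want_diff:
        for s in ("within", "across"):
            if s not in base:
                base.append(s)
    sums: dict[str, np.ndarray] = {}
    letters: tuple[str, ...] = ()
    for _ in range(n_iterations):
        pseudo, letters, _ = make_pseudotrial_array(
            epochs, n_pseudo=n_pseudo, bin_size=bin_size, rng=rng)
        for scheme in base:
            acc = _decode_scheme(pseudo, scheme, C, engine, tol)
            sums[scheme] = sums.get(scheme, 0.0) + acc
    results: dict[str, DecodingResult] = {}
    for scheme in base:
        acc = sums[scheme] / n_iterations
        results[scheme] = _make_result(acc, scheme, letters, True,
                                       epochs.times.copy(), n_iterations)
    if want_diff:
        results["difference"] = sensory_score(results["within"],
                                              results["across"])
    return {s: results[s] for s in schemes if s in results}


def roi_decode(pattern_sets: dict[str, PatternSet],
               seed: int | np.random.Generator = 0, n_iterations: int = 1,
               schemes: tuple[str, ...] = ("within", "across", "difference"),
               C: float = DEFAULT_C, engine: str = "batched",
               tol: float = 1e-4
               ) -> dict[str, dict[str, DecodingResult]]:
    """ROI-wise decoding of run-wise condition patterns.

    Runs are binned into five pseudo-runs per condition (re-randomized over
    iterations when ``n_iterations > 1``; the reference fMRI procedure
    names a single binning), then the within/across/difference schemes run
    per ROI.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out: dict[str, dict[str, DecodingResult]] = {}
    for roi in sorted(pattern_sets):
        ps = pattern_sets[roi]
        want_diff = "difference" in schemes
        base = [s for s in schemes if s != "difference"]
        if want_diff:
            for s in ("within", "across"):
                if s not in base:
                    base.append(s)
        sums: dict[str, np.ndarray] = {}
        letters: tuple[str, ...] = ()
        for _ in range(n_iterations):
            pseudo, letters, _ = bin_pseudoruns(ps, rng)
            for scheme in base:
                acc = _decode_scheme(pseudo, scheme, C, engine, tol)
                sums[scheme] = sums.get(scheme, 0.0) + acc
        roi_res: dict[str, DecodingResult] = {}
        for scheme in base:
            roi_res[scheme] = _make_result(sums[scheme] / n_iterations,
                                           scheme, letters, False, [roi],
                                           n_iterations)
        if want_diff:
            roi_res["difference"] = sensory_score(roi_res["within"],
                                                  roi_res["across"])
        out[roi] = {s: roi_res[s] for s in schemes if s in roi_res}
    return out


def grand_average(results: list[DecodingResult]) -> float:
    """Mean accuracy over a set of results (subjects), pairs, and points."""
    return float(np.mean([r.grand_mean() for r in results]))


def chance_level() -> float:
    return CHANCE
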