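"""Inference for decoding time courses: signed-rank tests, FDR control,
onset-latency detection, and participant-level bootstrap inference.

Group-level significance at each time point (or ROI) is a one-tailed
Wilcoxon signed-rank test against chance (50% for pairwise accuracy, 0 for
difference scores and correlations), corrected across tests with the
Benjamini-Hochberg false-discovery-rate procedure at q = 0.05.  An onset
latency is the earliest post-stimulus time point beginning a run of k
consecutive FDR-significant points (k = 50 at the 1-ms resolution of the
reference design).  Uncertainty on onsets comes from resampling the
participant pool with replacement (1000 resamples), recomputing the full
group trace and onset per resample, and taking percentile intervals.

Zeros are handled by the Pratt policy (ranked with the rest, then
discarded); ties get average ranks.  The exact permutation null of the
signed-rank statistic is used up to n = 25 non-zero differences, a
continuity-corrected normal approximation above.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_signed_rank", "fdr_bh", "onset_latency",
    "SignificanceTrace", "group_significance_trace", "LatencyEstimate",
    "bootstrap_onset_ci", "LatencyDifference", "bootstrap_latency_difference",
]

EXACT_N_MAX = 25


def _wplus_survival(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Exact null distribution of the signed-rank statistic.

    ``doubled_ranks`` are 2x the (possibly half-integer, tie-averaged)
    ranks of the non-zero differences.  Returns ``sf`` with
    ``sf[s] = P(2*W+ >= s)`` under independent fair sign flips — identical
    to full enumeration of all 2^n sign patterns.
    """
    total = int(sum(doubled_ranks))
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])


@lru_cache(maxsize=64)
def _no_tie_survival(n: int) -> np.ndarray:
    return _wplus_survival(tuple(2 * r for r in range(1, n + 1)))


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    """Pratt signed-rank statistic of a 1D difference vector.

    Zeros are ranked together with the non-zero differences and then
    discarded.  Returns (W+, doubled ranks of the non-zero entries).
    """
    d = np.asarray(d, dtype=float)
    ranks = sps.rankdata(np.abs(d), method="average")
    nz = d != 0
    wplus = float(ranks[d > 0].sum())
    return wplus, np.rint(2 * ranks[nz]).astype(int)


def _tail_p(sf: np.ndarray, doubled_w: int, tail: str) -> float:
    pg = float(sf[min(doubled_w, len(sf) - 1)])
    total = len(sf) - 2                       # sum of doubled ranks
    # P(W <= w) = P(W' >= total - w) by symmetry of the flip distribution
    pl = float(sf[min(max(total - doubled_w, 0), len(sf) - 1)])
    if tail == "greater":
        return pg
    if tail == "less":
        return pl
    if tail == "two_sided":
        return min(1.0, 2.0 * min(pg, pl))
    raise ValueError(f"unknown tail {tail!r}")


def _normal_p(wplus: float, doubled_ranks: np.ndarray, tail: str) -> float:
    r = doubled_ranks / 2.0
    mean = r.sum() / 2.0
    sd = np.sqrt((r ** 2).sum() / 4.0)
    if sd == 0:
        return 1.0
    if tail == "greater":
        return float(sps.norm.sf((wplus - mean - 0.5) / sd))
    if tail == "less":
        return float(sps.norm.cdf((wplus - mean + 0.5) / sd))
    z = (abs(wplus - mean) - 0.5) / sd
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def _wilcoxon_1d(d: np.ndarray, tail: str, mode: str) -> float:
    wplus, dranks = _signed_rank_stat(d)
    n = len(dranks)
    if n == 0:
        # degenerate: every value equals the hypothesized median
        return 1.0
    if mode == "exact" or (mode == "auto" and n <= EXACT_N_MAX):
        sf = _wplus_survival(tuple(sorted(dranks)))
        return _tail_p(sf, int(round(2 * wplus)), tail)
    return _normal_p(wplus, dranks, tail)


def wilcoxon_signed_rank(values: np.ndarray, mu: float = 50.0,
                         tail: str = "greater", axis: int = 0,
                         mode: str = "auto") -> float | np.ndarray:
    """Wilcoxon signed-rank test of H0: median(values) = mu.

    ``values`` may be 1D (one test) or 2D, in which case one test runs per
    column along ``axis``.  ``tail='greater'`` tests for a median above
    ``mu`` (the above-chance test); ``'two_sided'`` is available by flag.
    ``mode`` selects the exact permutation null (``n <= 25`` by default) or
    the continuity-corrected normal approximation.  If every value equals
    ``mu`` the test is degenerate and p = 1 is returned.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        if values.size < 5:
            raise ValueError("signed-rank test requires n >= 5")
        return _wilcoxon_1d(values - mu, tail, mode)
    if values.ndim != 2:
        raise ValueError("values must be 1D or 2D")
    values = np.moveaxis(values, axis, 0)
    if values.shape[0] < 5:
        raise ValueError("signed-rank test requires n >= 5")
    return np.asarray([_wilcoxon_1d(values[:, t] - mu, tail, mode)
                       for t in range(values.shape[1])])


def _fast_group_pvals(tcs: np.ndarray, mu: float, tail: str) -> np.ndarray:
    """Vectorized per-column signed-rank p-values for (n, T) data.

    Uses tie-averaged ranks with the no-tie exact reference distribution
    for n <= 25 (ties, e.g. from bootstrap-duplicated subjects, are
    approximated by rounding the doubled statistic), the normal
    approximation above.  Intended for the bootstrap inner loop.
    """
    d = tcs - mu
    n, T = d.shape
    absd = np.abs(d)
    ranks = sps.rankdata(absd, method="average", axis=0)
    zero = d == 0
    wplus = np.where(d > 0, ranks, 0.0).sum(axis=0)
    if n <= EXACT_N_MAX:
        sf = _no_tie_survival(n)
        # Pratt: zero ranks are discarded; with zeros present the no-tie
        # table is only a reference -- exact handling goes per column
        has_zero = zero.any(axis=0)
        idx = np.clip(np.rint(2 * wplus).astype(int), 0, len(sf) - 1)
        if tail == "greater":
            p = sf[idx]
        else:
            total = n * (n + 1)
            pl = sf[np.clip(total - idx, 0, len(sf) - 1)]
            p = (pl if tail == "less"
                 else np.minimum(1.0, 2.0 * np.minimum(sf[idx], pl)))
        if has_zero.any():
            for t in np.flatnonzero(has_zero):
                p[t] = _wilcoxon_1d(d[:, t], tail, "auto")
        return p
    mean = ranks.sum(axis=0) / 2.0
    sd = np.sqrt((ranks ** 2).sum(axis=0) / 4.0)
    sd = np.where(sd == 0, np.inf, sd)
    if tail == "greater":
        return sps.norm.sf((wplus - mean - 0.5) / sd)
    if tail == "less":
        return sps.norm.cdf((wplus - mean + 0.5) / sd)
    return np.minimum(1.0, 2.0 * sps.norm.sf(
        (np.abs(wplus - mean) - 0.5) / sd))


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions at FDR level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value array")
    if not np.isfinite(pvals).all() or (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("p-values must be finite and in (0, 1]")
    reject, _, _, _ = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape)


@dataclass
class SignificanceTrace:
    """Per-point raw p-values and FDR decisions for a group test."""

    times: np.ndarray
    pvals: np.ndarray
    significant: np.ndarray
    chance: float
    tail: str
    q: float


def group_significance_trace(subject_tcs: np.ndarray, times: np.ndarray,
                             chance: float = 50.0, tail: str = "greater",
                             q: float = 0.05, mode: str = "auto"
                             ) -> SignificanceTrace:
    """Wilcoxon + FDR across time points for (n_subjects, T) time courses."""
    subject_tcs = np.asarray(subject_tcs, dtype=float)
    if subject_tcs.ndim != 2:
        raise ValueError("expected (n_subjects, n_points) time courses")
    pvals = np.clip(wilcoxon_signed_rank(subject_tcs, mu=chance, tail=tail,
                                         mode=mode),
                    np.nextafter(0, 1), 1.0)
    return SignificanceTrace(times=np.asarray(times, dtype=float),
                             pvals=pvals, significant=fdr_bh(pvals, q),
                             chance=chance, tail=tail, q=q)


def onset_latency(significant: np.ndarray | SignificanceTrace,
                  times: np.ndarray | None = None, k: int = 50) -> float:
    """Earliest post-stimulus time starting k consecutive significant points.

    Returns the onset in ms, or NaN when no such run exists.  Only runs
    beginning at t >= 0 count; the run must fit within the trace.
    """
    if k < 1:
        raise ValueError("the run criterion k must be >= 1")
    if isinstance(significant, SignificanceTrace):
        times = significant.times
        significant = significant.significant
    if times is None:
        raise ValueError("times are required")
    sig = np.asarray(significant, dtype=bool)
    times = np.asarray(times, dtype=float)
    post = np.flatnonzero(times >= 0)
    if post.size < k:
        return float("nan")
    b = sig[post].astype(int)
    runs = np.convolve(b, np.ones(k, dtype=int), mode="valid")
    hit = np.flatnonzero(runs == k)
    if hit.size == 0:
        return float("nan")
    return float(times[post[hit[0]]])


@dataclass
class LatencyEstimate:
    """Onset latency with a bootstrap percentile confidence interval."""

    onset_ms: float
    ci_low_ms: float
    ci_high_ms: float
    n_boot: int
    criterion_k: int
    n_undefined: int = 0
    boot_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))


def _boot_onsets(tcs: np.ndarray, times: np.ndarray, idx: np.ndarray,
                 k: int, chance: float, tail: str, q: float) -> np.ndarray:
    out = np.empty(idx.shape[0])
    for b in range(idx.shape[0]):
        p = _fast_group_pvals(tcs[idx[b]], chance, tail)
        sig = fdr_bh(np.clip(p, np.nextafter(0, 1), 1.0), q)
        out[b] = onset_latency(sig, times, k=k)
    return out


def bootstrap_onset_ci(subject_tcs: np.ndarray, times: np.ndarray,
                       n_boot: int = 1000, seed: int = 0, k: int = 50,
                       chance: float = 50.0, tail: str = "greater",
                       q: float = 0.05) -> LatencyEstimate:
    """95% percentile CI for an onset latency by resampling participants.

    The participant pool is sampled with replacement ``n_boot`` times; the
    group trace (Wilcoxon + FDR) and its onset are recomputed per resample.
    Resamples without a defined onset are excluded from the percentile
    computation and counted in ``n_undefined``.
    """
    tcs = np.asarray(subject_tcs, dtype=float)
    if tcs.ndim != 2 or tcs.shape[0] < 2:
        raise ValueError("bootstrap needs >= 2 subject time courses")
    times = np.asarray(times, dtype=float)
    trace = group_significance_trace(tcs, times, chance=chance, tail=tail,
                                     q=q)
    onset = onset_latency(trace, k=k)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, tcs.shape[0], size=(n_boot, tcs.shape[0]))
    onsets = _boot_onsets(tcs, times, idx, k, chance, tail, q)
    defined = onsets[~np.isnan(onsets)]
    n_undef = int(np.isnan(onsets).sum())
    if defined.size == 0:
        lo = hi = float("nan")
    else:
        lo, hi = np.percentile(defined, [2.5, 97.5])
    return LatencyEstimate(onset_ms=onset, ci_low_ms=float(lo),
                           ci_high_ms=float(hi), n_boot=n_boot,
                           criterion_k=k, n_undefined=n_undef,
                           boot_onsets=onsets)


@dataclass
class LatencyDifference:
    """Bootstrap test of an onset-latency difference (b minus a)."""

    diff_ms: float
    ci_low_ms: float
    ci_high_ms: float
    p: float
    n_boot: int
    n_undefined: int


def bootstrap_latency_difference(tc_a: np.ndarray, tc_b: np.ndarray,
                                 times: np.ndarray, n_boot: int = 1000,
                                 seed: int = 0, k: int = 50,
                                 chance_a: float = 50.0,
                                 chance_b: float = 50.0,
                                 tail: str = "greater",
                                 q: float = 0.05) -> LatencyDifference:
    """Paired bootstrap of the onset difference onset(b) - onset(a).

    The same resampled participants enter both conditions.  The one-tailed
    p-value is the proportion of resampled differences that are <= 0 (the
    test that condition b starts later than condition a); resamples where
    either onset is undefined are excluded and counted.
    """
    a = np.asarray(tc_a, dtype=float)
    b = np.asarray(tc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("both conditions need the same subject pool")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.shape[0], size=(n_boot, a.shape[0]))
    on_a = _boot_onsets(a, times, idx, k, chance_a, tail, q)
    on_b = _boot_onsets(b, times, idx, k, chance_b, tail, q)
    diffs = on_b - on_a
    ok = ~np.isnan(diffs)
    n_undef = int((~ok).sum())
    point_a = onset_latency(group_significance_trace(
        a, times, chance=chance_a, tail=tail, q=q), k=k)
    point_b = onset_latency(group_significance_trace(
        b, times, chance=chance_b, tail=tail, q=q), k=k)
    if ok.sum() == 0:
        return LatencyDifference(diff_ms=point_b - point_a,
                                 ci_low_ms=float("nan"),
                                 ci_high_ms=float("nan"), p=float("nan"),
                                 n_boot=n_boot, n_undefined=n_undef)
    d = diffs[ok]
    lo, hi = np.percentile(d, [2.5, 97.5])
    p = float((d <= 0).mean())
    return LatencyDifference(diff_ms=float(point_b - point_a),
                             ci_low_ms=float(lo), ci_high_ms=float(hi),
                             p=p, n_boot=n_boot, n_undefined=n_undef)
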