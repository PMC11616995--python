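"""Experiment schedules for the braille-letter paradigm.

The paradigm presents 8 braille letters (B, C, D, L, M, N, V, Z) to the left
or right index finger — 16 experimental conditions — plus rare catch letters
(E, O) requiring a foot response, and (in the fMRI variant) null trials with
no stimulation.  One fMRI run holds 80 regular, 5 catch, and 22 null trials
(107 total; 500-ms stimulus, 2500-ms ISI).  One EEG session holds 2720
regular and 541 catch trials (3261 total; 500-ms stimulus; 500-ms ISI after
regular trials, 1100-ms after catch trials).

Catch and null placement rules ("a catch trial roughly every 20 regular
trials", "every third to fifth trial a null trial", "every fifth to seventh
trial a catch trial") cannot always coexist exactly with the printed totals;
the printed totals are authoritative here and the gap rules are honored
best-effort, with any soft violations recorded in the schedule metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .containers import CATCH_LETTERS, HANDS, LETTERS

SCHEDULE_COLUMNS = ["index", "kind", "letter", "hand",
                    "onset_s", "duration_s", "isi_s"]

#: Printed fMRI composition: (regular, catch, null) trials per run.
FMRI_COMPOSITION = (80, 5, 22)
#: Printed EEG composition: (regular, catch) trials per session.
EEG_COMPOSITION = (2720, 541)

FMRI_STIM_S = 0.5
FMRI_ISI_S = 2.5
EEG_STIM_S = 0.5
EEG_ISI_S = 0.5
EEG_CATCH_ISI_S = 1.1

#: Localizer block: 18 letter presentations of 500 ms on + 300 ms off.
LOCALIZER_BLOCK_S = 18 * (0.5 + 0.3)


@dataclass
class TrialSchedule:
    """Ordered trial sequence for one run (fMRI) or session (EEG)."""

    entries: pd.DataFrame
    modality: str  # "fmri" | "eeg"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in ("fmri", "eeg"):
            raise ValueError("modality must be 'fmri' or 'eeg'")
        missing = set(SCHEDULE_COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"schedule missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[str, int]:
        return self.entries["kind"].value_counts().to_dict()

    def condition_counts(self) -> pd.Series:
        reg = self.entries[self.entries["kind"] == "regular"]
        return reg.groupby(["letter", "hand"], observed=True).size()

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, modality: str) -> "TrialSchedule":
        df = pd.read_csv(path, sep="\t", keep_default_na=True)
        return cls(entries=df, modality=modality)


def _balanced_conditions(n_regular: int, rng: np.random.Generator,
                         letters: tuple[str, ...] = LETTERS,
                         ) -> list[tuple[str, str]]:
    """Shuffled regular conditions, each letter x hand appearing equally."""
    n_cond = len(letters) * len(HANDS)
    if n_regular % n_cond != 0:
        raise ValueError(
            f"regular trial count {n_regular} is not divisible by the "
            f"{n_cond} conditions; condition balance is impossible")
    reps = n_regular // n_cond
    conds = [(let, hand) for let in letters for hand in HANDS] * reps
    perm = rng.permutation(len(conds))
    return [conds[i] for i in perm]


def _spread_insertions(n_base: int, n_insert: int,
                       rng: np.random.Generator) -> list[int]:
    """Positions (in the base sequence) after which to insert one item each,
    spread roughly evenly with random jitter within each segment."""
    if n_insert == 0:
        return []
    edges = np.linspace(0, n_base, n_insert + 1)
    pos = []
    for k in range(n_insert):
        lo, hi = int(edges[k]), int(edges[k + 1])
        hi = max(hi, lo + 1)
        pos.append(int(rng.integers(lo, hi)))
    return sorted(pos)


def _assemble(records: list[dict], stim_s: float,
              isi_for: dict[str, float]) -> pd.DataFrame:
    onset = 0.0
    rows = []
    for i, rec in enumerate(records):
        isi = isi_for[rec["kind"]]
        rows.append({"index": i, "kind": rec["kind"],
                     "letter": rec.get("letter"), "hand": rec.get("hand"),
                     "onset_s": round(onset, 6), "duration_s": stim_s,
                     "isi_s": isi})
        onset += stim_s + isi
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def generate_fmri_run_schedule(composition: tuple[int, int, int] = FMRI_COMPOSITION,
                               seed: int = 0,
                               letters: tuple[str, ...] = LETTERS,
                               stim_s: float = FMRI_STIM_S,
                               isi_s: float = FMRI_ISI_S) -> TrialSchedule:
    """One fMRI run: balanced regular trials, interspersed catch and null trials.

    Defaults reproduce the printed composition of 80 regular + 5 catch +
    22 null = 107 trials, with every condition repeated 5 times, a catch
    trial roughly every 20 regular trials, and null trials at gaps of 3-5
    stimulus trials (best-effort; totals are exact).
    """
    n_reg, n_catch, n_null = composition
    rng = np.random.default_rng(seed)
    regs = _balanced_conditions(n_reg, rng, letters)

    records = [{"kind": "regular", "letter": l, "hand": h} for l, h in regs]
    # catch trials: one per roughly-equal segment of the regular sequence
    for pos in reversed(_spread_insertions(n_reg, n_catch, rng)):
        records.insert(pos, {"kind": "catch",
                             "letter": str(rng.choice(CATCH_LETTERS)),
                             "hand": str(rng.choice(HANDS))})
    # null trials: after every 3rd-5th stimulus trial while they last
    soft_violation = False
    out: list[dict] = []
    remaining = n_null
    queue = list(records)
    while queue:
        gap = int(rng.integers(3, 6))
        take = queue[:gap]
        queue = queue[gap:]
        out.extend(take)
        if remaining > 0 and queue:
            out.append({"kind": "null"})
            remaining -= 1
    if remaining > 0:
        # printed totals win: top up at random stimulus positions
        soft_violation = True
        for _ in range(remaining):
            out.insert(int(rng.integers(0, len(out) + 1)), {"kind": "null"})
    entries = _assemble(out, stim_s, {"regular": isi_s, "catch": isi_s,
                                      "null": isi_s})
    return TrialSchedule(entries=entries, modality="fmri",
                         meta={"composition": tuple(composition),
                               "seed": int(seed),
                               "null_gap_range": (3, 5),
                               "soft_gap_violation": soft_violation})


def generate_eeg_session_schedule(composition: tuple[int, int] = EEG_COMPOSITION,
                                  seed: int = 0,
                                  letters: tuple[str, ...] = LETTERS,
                                  stim_s: float = EEG_STIM_S,
                                  isi_s: float = EEG_ISI_S,
                                  catch_isi_s: float = EEG_CATCH_ISI_S,
                                  ) -> TrialSchedule:
    """One EEG session: balanced regular trials with interspersed catch trials.

    Defaults reproduce the printed composition of 2720 regular + 541 catch =
    3261 trials (170 repetitions per condition).  The printed catch spacing
    of 5-7 regular trials admits at most ~453 catch trials for 2720 regular
    trials, which contradicts the printed total of 541; the totals are
    treated as authoritative and catch trials are spread as evenly as the
    counts allow (each separated by at least one regular trial whenever
    regular >= catch), with the realized gap range recorded in metadata.
    """
    n_reg, n_catch = composition
    rng = np.random.default_rng(seed)
    regs = _balanced_conditions(n_reg, rng, letters)
    records = [{"kind": "regular", "letter": l, "hand": h} for l, h in regs]

    gap_lo = gap_hi = None
    if n_catch > 0:
        if n_reg == 0:
            raise ValueError("catch trials require regular trials between them")
        base = n_reg // n_catch
        extra = n_reg - base * n_catch
        gaps = np.full(n_catch, base, dtype=int)
        bump = rng.choice(n_catch, size=extra, replace=False)
        gaps[bump] += 1
        if base < 1:
            # more catches than regulars: cannot separate each catch
            gaps = np.maximum(gaps, 0)
        gap_lo, gap_hi = int(gaps.min()), int(gaps.max())
        out: list[dict] = []
        ri = 0
        for g in gaps:
            out.extend(records[ri:ri + g])
            ri += g
            out.append({"kind": "catch",
                        "letter": str(rng.choice(CATCH_LETTERS)),
                        "hand": str(rng.choice(HANDS))})
        out.extend(records[ri:])
        records = out

    entries = _assemble(records, stim_s, {"regular": isi_s,
                                          "catch": catch_isi_s})
    return TrialSchedule(entries=entries, modality="eeg",
                         meta={"composition": tuple(composition),
                               "seed": int(seed),
                               "target_gap_range": (5, 7),
                               "realized_gap_range": (gap_lo, gap_hi)})
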