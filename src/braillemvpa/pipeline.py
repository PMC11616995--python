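"""End-to-end orchestration: simulate -> preprocess -> decode -> searchlight
-> rsa -> stats -> report.

A :class:`RunConfig` carries every knob with its active value; the
reference values of the emulated design (trial counts, 1-kHz epoching,
100 binning iterations, k = 50, 1000 bootstraps) are recorded beside the
active configuration in every serialized config and manifest, so a scaled
desk run stays self-describing.  One master seed drives all stochastic
stages through a documented ``numpy.random.SeedSequence`` splitting scheme
(per-subject child sequences, spawned in subject order, further split per
stage); a rerun with the same config is bit-identical for deterministic
stages, and every output file is content-hashed into the run manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .containers import CHANCE, LETTERS
from .decoding import roi_decode, time_resolved_decode
from .design import generate_eeg_session_schedule, generate_fmri_run_schedule
from .preprocess import baseline_correct, noise_normalize
from .rsa import ratings_to_rdm, rdm_correlation, \
    rdm_timecourse_correlation
from .searchlight import sensor_searchlight, volume_searchlight
from .stats import bootstrap_latency_difference, bootstrap_onset_ci, \
    fdr_bh, group_significance_trace, wilcoxon_signed_rank
from .synthesis import DEFAULT_ROI_MIX, EffectSpec, synthesize_eeg_epochs, \
    synthesize_roi_patterns, synthesize_similarity_ratings

log = logging.getLogger("braillemvpa")

#: Reference values of the emulated design, recorded beside active knobs.
REFERENCE_DESIGN = {
    "eeg_reps_per_condition": 170,
    "eeg_sfreq_hz": 1000.0,
    "epoch_window_ms": [-100.0, 999.0],
    "n_channels": 63,
    "pseudo_trial_iterations": 100,
    "fmri_runs": [10, 25],
    "n_pseudo": 5,
    "onset_criterion_k": 50,
    "n_bootstraps": 1000,
    "fdr_q": 0.05,
    "svm_C": 1.0,
    "searchlight_radius_voxels": 4,
    "searchlight_k_channels": 4,
    "searchlight_bin_ms": 10.0,
    "n_subjects": {"fmri": 15, "eeg": 11, "behavior": 19},
}

STAGES = ("simulate", "preprocess", "decode", "searchlight", "rsa",
          "stats", "report")


@dataclass
class RunConfig:
    """Every knob of one end-to-end run.

    Defaults are a scaled desk run (fewer subjects and repetitions, 100-Hz
    sampling, a shorter window, a proportionally scaled onset criterion)
    that finishes in minutes on one CPU while exercising every stage; see
    ``REFERENCE_DESIGN`` for the emulated study's own values.
    """

    seed: int = 0
    outdir: str = "results/run"

    # cohort sizes
    n_subjects_eeg: int = 6
    n_subjects_fmri: int = 6
    n_participants_behavior: int = 19

    # EEG design / synthesis
    eeg_reps_per_condition: int = 40
    eeg_sfreq_hz: float = 100.0
    epoch_window_ms: list = field(default_factory=lambda: [-100.0, 490.0])
    n_channels: int = 63
    sensory_onset_ms: float = 80.0
    perceptual_onset_ms: float = 180.0
    sensory_snr: float = 0.25
    perceptual_snr: float = 0.2
    effect_duration_ms: float = 420.0
    noise_ar1: float = 0.0

    # fMRI synthesis
    fmri_runs: int = 10
    fmri_features: int = 60
    fmri_amplitude: float = 0.6
    roi_mix: dict = field(default_factory=lambda: dict(DEFAULT_ROI_MIX))

    # behavior
    rating_noise_sd: float = 1.0

    # preprocessing
    baseline_window_ms: list = field(default_factory=lambda: [-100.0, 0.0])
    shrinkage: str | float = "lw"

    # decoding
    svm_C: float = 1.0
    engine: str = "batched"
    n_iterations: int = 3
    n_pseudo: int = 5

    # searchlight
    searchlight_enabled: bool = True
    searchlight_k_channels: int = 4
    searchlight_bin_ms: float = 10.0
    searchlight_include_center: bool = False
    volume_grid: int = 8
    volume_radius: float = 2.0

    # stats
    fdr_q: float = 0.05
    onset_criterion_k: int = 5
    n_bootstraps: int = 200
    tail: str = "greater"

    def effect_spec(self, seed: int) -> EffectSpec:
        return EffectSpec(
            sensory_onset_ms=self.sensory_onset_ms,
            perceptual_onset_ms=self.perceptual_onset_ms,
            sensory_snr=self.sensory_snr,
            perceptual_snr=self.perceptual_snr,
            effect_duration_ms=self.effect_duration_ms,
            ar1=self.noise_ar1, seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference_design"] = dict(REFERENCE_DESIGN)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("reference_design", None)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def _subject_seeds(cfg: RunConfig, n: int, label: str) -> list[int]:
    """Stable per-subject seeds: one spawn level per cohort label."""
    salt = int(hashlib.sha256(label.encode()).hexdigest()[:7], 16)
    ss = np.random.SeedSequence([cfg.seed, salt])
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _paths(cfg: RunConfig) -> dict[str, Path]:
    out = Path(cfg.outdir)
    return {
        "root": out,
        "schedules": out / "schedules",
        "epochs": out / "epochs",
        "patterns": out / "patterns",
        "decoding": out / "decoding",
        "searchlight": out / "searchlight",
        "rsa": out / "rsa",
        "stats": out / "stats",
    }


def stage_simulate(cfg: RunConfig) -> list[Path]:
    """Schedules, raw synthetic epochs and ROI patterns, ratings."""
    p = _paths(cfg)
    written: list[Path] = []
    for d in p.values():
        d.mkdir(parents=True, exist_ok=True)

    sched_fmri = generate_fmri_run_schedule(seed=cfg.seed)
    f = p["schedules"] / "fmri_run.tsv"
    sched_fmri.to_tsv(f)
    written.append(f)

    reps = cfg.eeg_reps_per_condition
    composition = (16 * reps, max(1, round(16 * reps * 541 / 2720)))
    eeg_seeds = _subject_seeds(cfg, cfg.n_subjects_eeg, "eeg")
    for s, seed in enumerate(eeg_seeds):
        sched = generate_eeg_session_schedule(composition=composition,
                                              seed=seed)
        f = p["schedules"] / f"eeg_session_sub{s:02d}.tsv"
        sched.to_tsv(f)
        written.append(f)
        spec = cfg.effect_spec(seed)
        epochs = synthesize_eeg_epochs(
            sched, spec, n_channels=cfg.n_channels, sfreq=cfg.eeg_sfreq_hz,
            epoch_window_ms=tuple(cfg.epoch_window_ms))
        f = p["epochs"] / f"sub{s:02d}_raw.h5"
        bio.save_epochs(epochs, f)
        written.append(f)

    fmri_seeds = _subject_seeds(cfg, cfg.n_subjects_fmri, "fmri")
    for s, seed in enumerate(fmri_seeds):
        sets = synthesize_roi_patterns(
            cfg.fmri_runs, cfg.effect_spec(seed),
            n_features=cfg.fmri_features, mix=cfg.roi_mix,
            amplitude=cfg.fmri_amplitude)
        f = p["patterns"] / f"sub{s:02d}_patterns.h5"
        bio.save_pattern_sets(sets, f)
        written.append(f)

    ratings = synthesize_similarity_ratings(
        n_participants=cfg.n_participants_behavior,
        noise_sd=cfg.rating_noise_sd,
        seed=_subject_seeds(cfg, 1, "behavior")[0])
    f = p["root"] / "ratings.csv"
    bio.save_ratings(ratings, f)
    written.append(f)
    return written


def stage_preprocess(cfg: RunConfig) -> list[Path]:
    """Baseline correction and multivariate noise normalization."""
    p = _paths(cfg)
    written = []
    for s in range(cfg.n_subjects_eeg):
        epochs = bio.load_epochs(p["epochs"] / f"sub{s:02d}_raw.h5")
        epochs = baseline_correct(epochs, tuple(cfg.baseline_window_ms))
        epochs = noise_normalize(epochs, shrinkage=cfg.shrinkage)
        f = p["epochs"] / f"sub{s:02d}_preproc.h5"
        bio.save_epochs(epochs, f)
        written.append(f)
    return written


def stage_decode(cfg: RunConfig) -> list[Path]:
    """Time-resolved EEG decoding per subject, ROI decoding per subject."""
    p = _paths(cfg)
    written = []
    seeds = _subject_seeds(cfg, cfg.n_subjects_eeg, "eeg-decode")
    for s in range(cfg.n_subjects_eeg):
        epochs = bio.load_epochs(p["epochs"] / f"sub{s:02d}_preproc.h5")
        results = time_resolved_decode(
            epochs, n_iterations=cfg.n_iterations, seed=seeds[s],
            n_pseudo=cfg.n_pseudo, C=cfg.svm_C, engine=cfg.engine)
        frames = [r.to_frame() for r in results.values()]
        f = p["decoding"] / f"sub{s:02d}_timecourse.tsv"
        pd.concat(frames).to_csv(f, sep="\t", index=False)
        written.append(f)

    roi_rows = []
    pair_frames = []
    seeds = _subject_seeds(cfg, cfg.n_subjects_fmri, "fmri-decode")
    for s in range(cfg.n_subjects_fmri):
        sets = bio.load_pattern_sets(p["patterns"] / f"sub{s:02d}_patterns.h5")
        per_roi = roi_decode(sets, seed=seeds[s], C=cfg.svm_C,
                             engine=cfg.engine)
        for roi, res in per_roi.items():
            for scheme, r in res.items():
                roi_rows.append({"subject": s, "roi": roi, "scheme": scheme,
                                 "accuracy": r.grand_mean()})
                pf = r.to_frame()
                pf["axis"] = roi
                pf["subject"] = s
                pair_frames.append(pf)
    f = p["decoding"] / "roi_accuracies.tsv"
    pd.DataFrame(roi_rows).to_csv(f, sep="\t", index=False)
    written.append(f)
    f = p["decoding"] / "roi_pair_accuracies.tsv"
    pd.concat(pair_frames).to_csv(f, sep="\t", index=False)
    written.append(f)
    return written


def stage_searchlight(cfg: RunConfig) -> list[Path]:
    """Sensor-space searchlight (subject 0) and a small volumetric map."""
    if not cfg.searchlight_enabled:
        return []
    p = _paths(cfg)
    written = []
    epochs = bio.load_epochs(p["epochs"] / "sub00_preproc.h5")
    seeds = _subject_seeds(cfg, 2, "searchlight")
    maps = sensor_searchlight(
        epochs, k=cfg.searchlight_k_channels, bin_ms=cfg.searchlight_bin_ms,
        include_center=cfg.searchlight_include_center, seed=seeds[0],
        schemes=("across",), n_pseudo=cfg.n_pseudo, C=cfg.svm_C,
        engine=cfg.engine)
    f = p["searchlight"] / "sensor_across.tsv"
    bio.save_accuracy_map(maps["across"], f)
    written.append(f)

    # small volumetric demonstration: one signal block in a cubic grid
    g = cfg.volume_grid
    rng = np.random.default_rng(seeds[1])
    spec = cfg.effect_spec(seeds[1])
    sets = synthesize_roi_patterns(cfg.fmri_runs, spec,
                                   n_features=(g // 2) ** 3,
                                   mix={"block": 0.0},
                                   amplitude=cfg.fmri_amplitude)
    n_vox = g ** 3
    vols = rng.standard_normal((cfg.fmri_runs, 16, n_vox))
    block = np.zeros((g, g, g), dtype=bool)
    block[:g // 2, :g // 2, :g // 2] = True
    vols[:, :, block.ravel()] = sets["block"].data
    vols = vols.reshape(cfg.fmri_runs, 16, g, g, g)
    maps = volume_searchlight(vols, sets["block"].conditions,
                              mask=np.ones((g, g, g), dtype=bool),
                              radius=cfg.volume_radius, seed=seeds[1],
                              schemes=("across",), C=cfg.svm_C,
                              engine=cfg.engine)
    # uncompressed NIfTI: gzip headers embed timestamps, which would break
    # the bit-identical-rerun guarantee of the manifest hashes
    f = p["searchlight"] / "volume_across.nii"
    bio.save_accuracy_map(maps["across"], f)
    written.append(f)
    from .searchlight import cluster_report
    f = p["searchlight"] / "volume_clusters.json"
    bio.save_json({"threshold_accuracy": 55.0,
                   "clusters": cluster_report(maps["across"],
                                              threshold=55.0)}, f)
    written.append(f)
    return written


def _load_subject_results(cfg: RunConfig):
    """Rebuild per-subject pair-accuracy matrices from the decoding TSVs."""
    from .containers import DecodingResult
    p = _paths(cfg)
    out = []
    for s in range(cfg.n_subjects_eeg):
        df = pd.read_csv(p["decoding"] / f"sub{s:02d}_timecourse.tsv",
                         sep="\t")
        subj = {}
        for scheme, grp in df.groupby("scheme"):
            times = np.sort(grp["axis"].unique())
            L = len(LETTERS)
            idx = {l: i for i, l in enumerate(LETTERS)}
            acc = np.full((times.size, L, L), np.nan)
            tpos = {t: i for i, t in enumerate(times)}
            for _, row in grp.iterrows():
                i, j = idx[row["letter_b"]], idx[row["letter_a"]]
                t = tpos[row["axis"]]
                acc[t, i, j] = acc[t, j, i] = row["accuracy"]
            subj[scheme] = DecodingResult(scheme=scheme, accuracies=acc,
                                          axis_values=times)
        out.append(subj)
    return out


def stage_rsa(cfg: RunConfig) -> list[Path]:
    """Behavioral RDM and subject-wise neural-behavior correlations."""
    p = _paths(cfg)
    written = []
    ratings = bio.load_ratings(p["root"] / "ratings.csv")
    behavior = ratings_to_rdm(ratings)
    f = p["rsa"] / "behavior_rdm.csv"
    bio.save_rdm(behavior, f)
    written.append(f)

    rows = []
    for s, subj in enumerate(_load_subject_results(cfg)):
        for scheme in ("within", "across"):
            rs = rdm_timecourse_correlation(behavior, subj[scheme])
            for t, r in zip(subj[scheme].axis_values, rs):
                rows.append({"subject": s, "scheme": scheme,
                             "time_ms": t, "R": r})
    f = p["rsa"] / "eeg_behavior_rsa.tsv"
    pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
    written.append(f)

    from .containers import RDM
    pair_df = pd.read_csv(p["decoding"] / "roi_pair_accuracies.tsv",
                          sep="\t")
    idx = {l: i for i, l in enumerate(LETTERS)}
    roi_rows = []
    for (subj, roi, scheme), grp in pair_df.groupby(
            ["subject", "axis", "scheme"]):
        if scheme == "difference":
            continue
        L = len(LETTERS)
        mat = np.full((L, L), np.nan)
        for _, row in grp.iterrows():
            i, j = idx[row["letter_b"]], idx[row["letter_a"]]
            mat[i, j] = mat[j, i] = row["accuracy"]
        r = rdm_correlation(behavior, RDM(values=mat, source=roi))
        roi_rows.append({"subject": subj, "roi": roi, "scheme": scheme,
                         "R": r})
    f = p["rsa"] / "fmri_behavior_rsa.tsv"
    pd.DataFrame(roi_rows).to_csv(f, sep="\t", index=False)
    written.append(f)
    return written


def stage_stats(cfg: RunConfig) -> list[Path]:
    """Group inference: significance traces, onsets, bootstrap CIs."""
    p = _paths(cfg)
    written = []
    subjects = _load_subject_results(cfg)
    times = subjects[0]["within"].axis_values
    tcs = {scheme: np.stack([s[scheme].timecourse() for s in subjects])
           for scheme in ("within", "across", "difference")}

    rows = []
    summary: dict = {"onsets_ms": {}, "latency_differences": {}}
    for scheme, tc in tcs.items():
        chance = CHANCE if scheme != "difference" else 0.0
        trace = group_significance_trace(tc, times, chance=chance,
                                         tail=cfg.tail, q=cfg.fdr_q)
        est = bootstrap_onset_ci(tc, times, n_boot=cfg.n_bootstraps,
                                 seed=cfg.seed, k=cfg.onset_criterion_k,
                                 chance=chance, tail=cfg.tail, q=cfg.fdr_q)
        summary["onsets_ms"][scheme] = {
            "onset": est.onset_ms, "ci": [est.ci_low_ms, est.ci_high_ms],
            "n_undefined": est.n_undefined}
        for t, pv, sig in zip(times, trace.pvals, trace.significant):
            rows.append({"scheme": scheme, "time_ms": t, "p": pv,
                         "significant": bool(sig)})
    f = p["stats"] / "significance.tsv"
    pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
    written.append(f)

    ld = bootstrap_latency_difference(
        tcs["within"], tcs["across"], times, n_boot=cfg.n_bootstraps,
        seed=cfg.seed, k=cfg.onset_criterion_k, chance_a=CHANCE,
        chance_b=CHANCE, tail=cfg.tail, q=cfg.fdr_q)
    summary["latency_differences"]["across_minus_within"] = {
        "diff_ms": ld.diff_ms, "ci": [ld.ci_low_ms, ld.ci_high_ms],
        "p": ld.p, "n_undefined": ld.n_undefined}

    roi_df = pd.read_csv(p["decoding"] / "roi_accuracies.tsv", sep="\t")
    roi_rows = []
    for scheme, grp in roi_df.groupby("scheme"):
        chance = CHANCE if scheme != "difference" else 0.0
        wide = grp.pivot(index="subject", columns="roi", values="accuracy")
        pv = wilcoxon_signed_rank(wide.to_numpy(), mu=chance, tail=cfg.tail)
        sig = fdr_bh(np.clip(pv, np.nextafter(0, 1), 1.0), q=cfg.fdr_q)
        for roi, pp, ss in zip(wide.columns, pv, sig):
            roi_rows.append({"scheme": scheme, "roi": roi, "p": pp,
                             "significant": bool(ss),
                             "mean_accuracy": wide[roi].mean()})
    f = p["stats"] / "roi_stats.tsv"
    pd.DataFrame(roi_rows).to_csv(f, sep="\t", index=False)
    written.append(f)

    summary["run"] = {"seed": cfg.seed, "n_boot": cfg.n_bootstraps,
                      "q": cfg.fdr_q, "k": cfg.onset_criterion_k,
                      "tail": cfg.tail}
    f = p["stats"] / "summary.json"
    bio.save_json(summary, f)
    written.append(f)
    return written


def stage_report(cfg: RunConfig) -> list[Path]:
    """Condense the run into one JSON report."""
    p = _paths(cfg)
    # the output location is not part of the scientific configuration
    report: dict = {"config": {k: v for k, v in cfg.to_dict().items()
                               if k != "outdir"}}
    with open(p["stats"] / "summary.json") as f:
        report["stats"] = json.load(f)
    roi_df = pd.read_csv(p["stats"] / "roi_stats.tsv", sep="\t")
    report["roi"] = roi_df.to_dict(orient="records")
    rsa_df = pd.read_csv(p["rsa"] / "eeg_behavior_rsa.tsv", sep="\t")
    peak = (rsa_df.groupby(["scheme", "time_ms"])["R"].mean()
            .groupby("scheme").max())
    report["rsa_peak_R"] = peak.to_dict()
    f = p["root"] / "report.json"
    bio.save_json(report, f)
    return [f]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "decode": stage_decode,
    "searchlight": stage_searchlight,
    "rsa": stage_rsa,
    "stats": stage_stats,
    "report": stage_report,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline stages in order and write a hashed manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r}")
        t0 = time.perf_counter()
        log.info("stage %s: starting", name)
        try:
            files = _STAGE_FUNCS[name](cfg)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        dt = time.perf_counter() - t0
        log.info("stage %s: done in %.1fs (%d files)", name, dt, len(files))
        manifest["stages"][name] = {
            "seconds": round(dt, 3),
            "outputs": {str(f.relative_to(out)): _sha256(f)
                        for f in dict.fromkeys(files)},
        }
    bio.save_json(manifest, out / "manifest.json")
    return manifest
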