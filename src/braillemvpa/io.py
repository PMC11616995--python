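"""File containers: HDF5 epochs/patterns, NIfTI accuracy maps, TSV/CSV tables.

All writers are deterministic (HDF5 object timestamps disabled) so that
pipeline reruns with the same configuration hash identically.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import AccuracyMap, Epochs, PatternSet, Ratings, RDM

_STR = h5py.string_dtype(encoding="utf-8")


def _h5_create(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def save_epochs(epochs: Epochs, path) -> None:
    """Write an Epochs container to HDF5 (data, time axis, labels, montage)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as f:
        _h5_create(f, "data", epochs.data)
        _h5_create(f, "time_ms", epochs.times)
        _h5_create(f, "channel_names",
                   np.asarray(epochs.channel_names, dtype=_STR))
        lab = f.create_group("labels")
        for col in ("letter", "hand", "kind"):
            vals = epochs.labels[col].fillna("").astype(str).to_numpy()
            _h5_create(lab, col, vals.astype(_STR))
        _h5_create(lab, "session",
                   epochs.labels.get("session",
                                     pd.Series(np.zeros(len(epochs.labels)))
                                     ).to_numpy().astype(int))
        if epochs.montage:
            mont = f.create_group("montage")
            _h5_create(mont, "names",
                       np.asarray(list(epochs.montage), dtype=_STR))
            _h5_create(mont, "positions",
                       np.asarray(list(epochs.montage.values()), dtype=float))
        f.attrs["meta"] = json.dumps(
            {k: v for k, v in epochs.meta.items()
             if isinstance(v, (str, int, float, bool, list, tuple))})


def load_epochs(path) -> Epochs:
    """Read an Epochs container; malformed files raise an informative error."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["time_ms"][()]
            chans = [c.decode() if isinstance(c, bytes) else str(c)
                     for c in f["channel_names"][()]]
            lab = {col: [v.decode() if isinstance(v, bytes) else str(v)
                         for v in f["labels"][col][()]]
                   for col in ("letter", "hand", "kind")}
            labels = pd.DataFrame(lab)
            labels["session"] = f["labels"]["session"][()]
            montage = {}
            if "montage" in f:
                names = [n.decode() if isinstance(n, bytes) else str(n)
                         for n in f["montage"]["names"][()]]
                pos = f["montage"]["positions"][()]
                montage = {n: pos[i] for i, n in enumerate(names)}
            meta = json.loads(f.attrs.get("meta", "{}"))
    except OSError as err:
        raise OSError(
            f"{path} is not a readable HDF5 epochs container "
            f"(truncated or wrong format): {err}") from err
    labels = labels.replace({"": None})
    return Epochs(data=data, times=times, channel_names=chans, labels=labels,
                  montage=montage, meta=meta)


def save_pattern_sets(pattern_sets: dict[str, PatternSet], path) -> None:
    """Write per-ROI run-wise condition patterns to one HDF5 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as f:
        for roi, ps in sorted(pattern_sets.items()):
            g = f.create_group(roi)
            _h5_create(g, "data", ps.data)
            _h5_create(g, "letters",
                       np.asarray([l for l, _ in ps.conditions], dtype=_STR))
            _h5_create(g, "hands",
                       np.asarray([h for _, h in ps.conditions], dtype=_STR))


def load_pattern_sets(path) -> dict[str, PatternSet]:
    path = Path(path)
    out: dict[str, PatternSet] = {}
    try:
        with h5py.File(path, "r") as f:
            for roi in f:
                g = f[roi]
                letters = [v.decode() if isinstance(v, bytes) else str(v)
                           for v in g["letters"][()]]
                hands = [v.decode() if isinstance(v, bytes) else str(v)
                         for v in g["hands"][()]]
                out[roi] = PatternSet(data=g["data"][()],
                                      conditions=list(zip(letters, hands)),
                                      roi=roi)
    except OSError as err:
        raise OSError(f"{path} is not a readable HDF5 pattern container: "
                      f"{err}") from err
    return out


def save_accuracy_map(amap: AccuracyMap, path) -> None:
    """Volumetric maps as float32 NIfTI (NaN background); sensor maps as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if amap.kind == "volume":
        import nibabel as nib
        img = nib.Nifti1Image(amap.data.astype(np.float32), amap.affine)
        nib.save(img, path)
    else:
        rows = []
        for ci, chan in enumerate(amap.channel_names):
            for bi, start in enumerate(amap.bin_starts_ms):
                rows.append({"channel": chan, "bin_start_ms": start,
                             "accuracy": amap.data[ci, bi]})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_volume_map(path) -> AccuracyMap:
    import nibabel as nib
    img = nib.load(path)
    return AccuracyMap(kind="volume", data=np.asarray(img.dataobj,
                                                      dtype=float),
                       affine=img.affine)


def save_rdm(rdm: RDM, path) -> None:
    """Letter-labeled CSV; the undefined diagonal is left empty."""
    df = pd.DataFrame(rdm.values, index=list(rdm.letters),
                      columns=list(rdm.letters))
    df.to_csv(path)


def load_rdm(path, source: str = "") -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(values=df.to_numpy(dtype=float),
               letters=tuple(df.index), source=source)


def save_ratings(ratings: Ratings, path) -> None:
    cols = [f"{a}-{b}" for a, b in ratings.pairs]
    pd.DataFrame(ratings.values, columns=cols).to_csv(path, index_label="participant")


def load_ratings(path) -> Ratings:
    df = pd.read_csv(path, index_col=0)
    pairs = [tuple(c.split("-")) for c in df.columns]
    letters = tuple(sorted({l for p in pairs for l in p}))
    return Ratings(values=df.to_numpy(dtype=int), pairs=pairs,
                   letters=letters)


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_json_default)
        f.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
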