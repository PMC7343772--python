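"""Text-based serialization for recordings, epochs and pipeline artifacts.

The canonical on-disk signal format is a tab-delimited matrix (rows =
samples, columns = channels, header = channel names) plus a JSON sidecar
carrying the sampling rate, epoch geometry, trial labels and event onsets.
EDF files can additionally be *read* through MNE when it is installed;
export is text-only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityTensor
from .preprocess import EpochSet, Recording

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_recording",
    "load_recording",
    "read_edf",
    "save_connectivity",
    "load_connectivity",
]


def save_epochs(ep: EpochSet, stem: str | Path) -> tuple[Path, Path]:
    """Write an epoch set as ``<stem>.tsv`` (trials concatenated sample-wise)
    plus ``<stem>.json`` sidecar. Returns both paths."""
    stem = Path(stem)
    flat = ep.data.transpose(0, 2, 1).reshape(-1, ep.n_channels)
    df = pd.DataFrame(flat, columns=ep.channels)
    tsv = stem.with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "fs": ep.fs,
        "origin_ms": ep.origin_ms,
        "n_trials": ep.n_trials,
        "samples_per_trial": ep.n_samples,
        "channels": ep.channels,
        "band": ep.band,
        "labels": None if ep.labels is None else [str(x) for x in ep.labels],
        # one event per trial at 0 ms relative to each trial's onset
        "events": [
            {"label": str(ep.labels[t]) if ep.labels is not None else "",
             "onset_ms": t * ep.n_samples * 1000.0 / ep.fs - ep.origin_ms}
            for t in range(ep.n_trials)
        ],
    }
    js = stem.with_suffix(".json")
    js.write_text(json.dumps(sidecar, indent=1))
    return tsv, js


def load_epochs(stem: str | Path) -> EpochSet:
    """Inverse of :func:`save_epochs`."""
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
    n_tr, n_s = meta["n_trials"], meta["samples_per_trial"]
    data = df.to_numpy(dtype=float).reshape(n_tr, n_s, len(meta["channels"])).transpose(0, 2, 1)
    return EpochSet(
        data=data,
        fs=meta["fs"],
        origin_ms=meta["origin_ms"],
        channels=list(meta["channels"]),
        labels=np.asarray(meta["labels"]) if meta.get("labels") else None,
        band=meta.get("band"),
    )


def save_recording(rec: Recording, stem: str | Path, events: list[dict] | None = None) -> Path:
    """Write a continuous recording as TSV + JSON sidecar
    (events as ``{"label": ..., "onset_ms": ...}`` records)."""
    stem = Path(stem)
    pd.DataFrame(rec.data.T, columns=rec.channels).to_csv(
        stem.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6g"
    )
    meta = {"fs": rec.fs, "channels": rec.channels, "reference": rec.reference,
            "events": events or []}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".tsv")


def load_recording(path: str | Path) -> tuple[Recording, list[dict]]:
    """Read a recording from ``.tsv``+``.json`` or from an ``.edf`` file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    stem = path.with_suffix("")
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
    rec = Recording(
        data=df.to_numpy(dtype=float).T,
        fs=meta["fs"],
        channels=list(meta["channels"]),
        reference=meta.get("reference", "unknown"),
    )
    return rec, meta.get("events", [])


def read_edf(path: str | Path) -> tuple[Recording, list[dict]]:
    """Read an EDF recording via MNE (optional dependency).

    Annotations become events; data are converted to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    events = [
        {"label": str(desc), "onset_ms": float(onset) * 1000.0}
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    rec = Recording(data=data_uv, fs=float(raw.info["sfreq"]), channels=list(raw.ch_names))
    return rec, events


def save_connectivity(tensor: ConnectivityTensor, out_dir: str | Path) -> Path:
    """Write one stacked-matrix TSV per (condition, subject, band) plus a
    JSON manifest describing the layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for (cond, subj, band), mats in tensor.values.items():
        name = f"{cond}_s{subj:03d}_{band}.tsv"
        w, n, _ = mats.shape
        np.savetxt(out / name, mats.reshape(w * n, n), fmt="%.6g", delimiter="\t")
        entries.append({"condition": cond, "subject": subj, "band": band, "file": name,
                        "n_windows": w, "n_nodes": n})
    manifest = {
        "method": tensor.method,
        "bands": list(tensor.bands),
        "conditions": list(tensor.conditions),
        "channels": tensor.channels,
        "layout": "windows stacked row-wise: rows w*n..(w+1)*n-1 are window w+1",
        "entries": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_connectivity(in_dir: str | Path) -> ConnectivityTensor:
    """Inverse of :func:`save_connectivity`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    values = {}
    for e in manifest["entries"]:
        flat = np.loadtxt(in_dir / e["file"], delimiter="\t", ndmin=2)
        values[(e["condition"], e["subject"], e["band"])] = flat.reshape(
            e["n_windows"], e["n_nodes"], e["n_nodes"]
        )
    return ConnectivityTensor(
        values=values,
        method=manifest["method"],
        bands=tuple(manifest["bands"]),
        conditions=tuple(manifest["conditions"]),
        channels=list(manifest["channels"]),
    )
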