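"""File formats: TSV tables, HDF5 arrays, JSON/YAML configs, WAV audio, EDF.

Raw recordings and high-gamma responses persist to HDF5 with dimension
labels and a provenance attribute (config hash). Real electrophysiology in
EDF is ingested through mne when available.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import HighGammaResponse, RawRecording

__all__ = [
    "read_table", "write_table", "write_high_gamma", "read_high_gamma",
    "write_recording", "read_recording", "read_edf", "write_wav",
    "load_config", "dump_config", "config_hash",
]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_config(cfg: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True, default=str))


def write_high_gamma(hg: HighGammaResponse, path, provenance: str = "") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=hg.values, compression="gzip")
        f.create_dataset("times", data=hg.times)
        f.create_dataset("trial_index", data=np.asarray(hg.trial_index, dtype=np.int64))
        f.create_dataset("electrode_ids",
                         data=np.array(hg.electrode_ids, dtype=h5py.string_dtype()))
        if hg.baseline_power is not None:
            f.create_dataset("baseline_power", data=hg.baseline_power)
        f.attrs["task"] = hg.task
        f.attrs["time_step"] = hg.time_step
        f.attrs["baseline_window"] = hg.baseline_window
        f.attrs["dims"] = "trials x electrodes x time"
        f.attrs["provenance"] = provenance


def read_high_gamma(path) -> HighGammaResponse:
    with h5py.File(path, "r") as f:
        return HighGammaResponse(
            values=f["values"][()], times=f["times"][()],
            trial_index=f["trial_index"][()],
            electrode_ids=[s.decode() if isinstance(s, bytes) else s
                           for s in f["electrode_ids"][()]],
            task=f.attrs["task"], time_step=float(f.attrs["time_step"]),
            baseline_window=tuple(f.attrs["baseline_window"]),
            baseline_power=f["baseline_power"][()] if "baseline_power" in f else None)


def write_recording(rec: RawRecording, path, provenance: str = "") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.signals, compression="gzip")
        f.create_dataset("electrode_ids",
                         data=np.array(rec.electrode_ids, dtype=h5py.string_dtype()))
        for name, ch in rec.aux.items():
            f.create_dataset(f"aux/{name}", data=ch, compression="gzip")
        f.attrs["fs"] = rec.fs
        f.attrs["participant"] = rec.participant
        f.attrs["provenance"] = provenance


def read_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        aux = {name: f[f"aux/{name}"][()] for name in f.get("aux", {})}
        return RawRecording(signals=f["signals"][()], fs=float(f.attrs["fs"]),
                            electrode_ids=[s.decode() if isinstance(s, bytes) else s
                                           for s in f["electrode_ids"][()]],
                            aux=aux, participant=str(f.attrs["participant"]))


def read_edf(path, aux_channels=("trigger", "microphone", "feedback"),
             participant: str = "") -> RawRecording:
    """Ingest an EDF recording (requires mne). Channels whose names match
    ``aux_channels`` (case-insensitive) become auxiliary channels."""
    import mne  # optional dependency, only needed for real data

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    names = raw.ch_names
    aux_lc = {a.lower() for a in aux_channels}
    aux = {}
    keep, ids = [], []
    for i, name in enumerate(names):
        if name.lower() in aux_lc:
            aux[name.lower()] = data[i]
        else:
            keep.append(i)
            ids.append(name)
    return RawRecording(signals=data[keep], fs=float(raw.info["sfreq"]),
                        electrode_ids=ids, aux=aux,
                        participant=participant or Path(path).stem)


def write_wav(x: np.ndarray, fs: float, path) -> None:
    """Write a mono float signal to 16-bit WAV (peak-normalized)."""
    from scipy.io import wavfile

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    peak = np.max(np.abs(x)) or 1.0
    wavfile.write(path, int(fs), np.asarray(32767 * x / peak, dtype=np.int16))
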