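"""File I/O: BrainVision recordings, HDF5 epoch containers, CSV tables, PNGs.

Recordings go out as BrainVision triplets (.vhdr/.vmrk/.eeg, IEEE float32
multiplexed) — a plain-text header plus raw binary that any EEG toolbox
reads — with a JSON sidecar mapping marker codes back to image ids.
Reading goes through mne, so real BrainVision or EDF recordings drop into
the same pipeline.

The epoch container layout (HDF5):

    data      float32, (trial, channel, time), uV (or z-units downstream)
    time_ms   int32, per-sample time relative to stimulus onset
    channels  variable-length str
    trials/<column>  one dataset per metadata column
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import RawRecording


# -- BrainVision -------------------------------------------------------------

def write_brainvision(rec: RawRecording, basepath) -> Path:
    """Write a BrainVision triplet plus ``<base>_events.json`` sidecar;
    returns the .vhdr path."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    codes = {img: i + 1 for i, img in
             enumerate(dict.fromkeys(img for _, img in rec.events))}
    interval_us = 1e6 / rec.srate
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8",
        f"DataFile={eeg.name}", f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(rec.ch_names)}",
        f"SamplingInterval={interval_us:g}",
        "", "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32",
        "", "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.ch_names):
        header.append(f"Ch{i + 1}={ch},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8", f"DataFile={eeg.name}",
        "", "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for j, (sample, image_id) in enumerate(rec.events):
        code = codes[image_id]
        # BrainVision marker positions are 1-based
        markers.append(f"Mk{j + 2}=Stimulus,S{code:>3},{sample + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    rec.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major

    sidecar = {"participant_id": rec.participant_id,
               "codes": {str(c): img for img, c in codes.items()}}
    (base.parent / f"{base.name}_events.json").write_text(json.dumps(sidecar,
                                                                     indent=1))
    return vhdr


def read_raw(path, sidecar=None) -> RawRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording via mne into a
    RawRecording; stimulus markers become events, decoded through the JSON
    sidecar when present (otherwise image ids are the marker descriptions).
    """
    import mne

    path = Path(path)
    if path.suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format: {path.suffix}")
    if sidecar is None:
        cand = path.parent / f"{path.stem}_events.json"
        sidecar = cand if cand.exists() else None
    code_map, pid = {}, path.stem
    if sidecar is not None:
        doc = json.loads(Path(sidecar).read_text())
        code_map = doc.get("codes", {})
        pid = doc.get("participant_id", pid)
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if "Stimulus" not in desc:
            continue
        code = desc.split("/")[-1].replace("S", "").strip()
        image_id = code_map.get(code.lstrip("0") or code, code_map.get(code, desc))
        events.append((int(round(onset * raw.info["sfreq"])), image_id))
    data_uv = raw.get_data() * 1e6  # mne works in volts
    return RawRecording(data=data_uv.astype(np.float32),
                        srate=raw.info["sfreq"],
                        ch_names=tuple(raw.ch_names), events=events,
                        participant_id=pid)


# -- HDF5 epoch container ----------------------------------------------------

def save_epochs(epochs, path) -> None:
    from .preprocess import EpochSet  # local import to avoid a cycle

    assert isinstance(epochs, EpochSet)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32),
                         compression="gzip")
        f.create_dataset("time_ms", data=np.asarray(epochs.time_ms, np.int32))
        f.create_dataset("channels",
                         data=np.array(epochs.channels, dtype=object),
                         dtype=h5py.string_dtype())
        g = f.create_group("trials")
        for col in epochs.trials.columns:
            vals = epochs.trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                g.create_dataset(col, data=vals.astype(str).astype(object),
                                 dtype=h5py.string_dtype())
            else:
                g.create_dataset(col, data=vals)


def load_epochs(path):
    from .preprocess import EpochSet

    with h5py.File(path, "r") as f:
        data = f["data"][...]
        time_ms = f["time_ms"][...]
        channels = tuple(c.decode() if isinstance(c, bytes) else c
                         for c in f["channels"][...])
        cols = {}
        for col in f["trials"]:
            v = f["trials"][col][...]
            if v.dtype == object or v.dtype.kind in "OS":
                v = np.array([x.decode() if isinstance(x, bytes) else x
                              for x in v])
            cols[col] = v
    return EpochSet(data=data, time_ms=time_ms, channels=channels,
                    trials=pd.DataFrame(cols))


# -- misc --------------------------------------------------------------------

def write_image_png(image: np.ndarray, path) -> None:
    """8-bit grayscale PNG; input in [0, 1]."""
    import imageio.v3 as iio

    arr = np.clip(image, 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))
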