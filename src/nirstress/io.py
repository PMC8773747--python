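"""Readers and writers for recordings, cohorts, and result tables.

The native on-disk form is a wide CSV/TSV table: a time column ``t`` in
seconds plus one column per channel and chromophore (``ch01_hbo`` ...
``ch15_hbr``) for concentration data, or per channel and wavelength
(``ch01_780nm`` ...) for optical-density data. SNIRF (HDF5) files are
readable for interoperability; a processed-concentration SNIRF maps
directly to a :class:`HemoTimeSeries`, a raw/dOD one to an
:class:`OpticalRecording`.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ChannelLayout, HemoTimeSeries, OpticalRecording

_HBO_RE = re.compile(r"^ch(\d+)_hbo$")
_WL_RE = re.compile(r"^ch(\d+)_(\d+)nm$")


def _fs_from_time(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time column is not uniformly sampled")
    return 1.0 / float(dt[0])


def write_hemo_csv(ts: HemoTimeSeries, path, sep: str = ",") -> None:
    cols = {"t": ts.times}
    for c in range(ts.n_channels):
        cols[f"ch{c + 1:02d}_hbo"] = ts.dhbo[c]
    for c in range(ts.n_channels):
        cols[f"ch{c + 1:02d}_hbr"] = ts.dhbr[c]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_hemo_csv(path, layout: ChannelLayout | None = None, sep: str = ",") -> HemoTimeSeries:
    df = pd.read_csv(path, sep=sep)
    if "t" not in df.columns:
        raise ValueError(f"{path}: missing time column 't'")
    hbo_cols = sorted(c for c in df.columns if _HBO_RE.match(c))
    hbr_cols = [c.replace("_hbo", "_hbr") for c in hbo_cols]
    if not hbo_cols or any(c not in df.columns for c in hbr_cols):
        raise ValueError(f"{path}: expected paired chNN_hbo / chNN_hbr columns")
    fs = _fs_from_time(df["t"].to_numpy())
    ts = HemoTimeSeries(
        dhbo=df[hbo_cols].to_numpy().T, dhbr=df[hbr_cols].to_numpy().T, fs_hz=fs
    )
    _check_layout(ts.n_channels, ts.fs_hz, layout, path)
    return ts


def write_optical_csv(rec: OpticalRecording, path, sep: str = ",") -> None:
    cols = {"t": rec.times}
    for w, wl in enumerate(rec.wavelengths_nm):
        for c in range(rec.n_channels):
            cols[f"ch{c + 1:02d}_{int(wl)}nm"] = rec.dod[c, w]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_optical_csv(path, layout: ChannelLayout | None = None, sep: str = ",") -> OpticalRecording:
    df = pd.read_csv(path, sep=sep)
    if "t" not in df.columns:
        raise ValueError(f"{path}: missing time column 't'")
    chan_wl = {}
    for c in df.columns:
        m = _WL_RE.match(c)
        if m:
            chan_wl.setdefault(float(m.group(2)), {})[int(m.group(1))] = c
    if not chan_wl:
        raise ValueError(f"{path}: no chNN_<wavelength>nm columns found")
    wavelengths = tuple(sorted(chan_wl))
    channels = sorted(chan_wl[wavelengths[0]])
    dod = np.stack(
        [
            np.stack([df[chan_wl[wl][ch]].to_numpy() for wl in wavelengths])
            for ch in channels
        ]
    )
    fs = _fs_from_time(df["t"].to_numpy())
    rec = OpticalRecording(dod=dod, fs_hz=fs, wavelengths_nm=wavelengths)
    _check_layout(rec.n_channels, rec.fs_hz, layout, path)
    return rec


def _check_layout(n_channels, fs, layout, path) -> None:
    if layout is None:
        return
    if n_channels != layout.n_channels:
        raise ValueError(
            f"{path}: file has {n_channels} channels, layout expects {layout.n_channels}"
        )
    if not np.isclose(fs, layout.fs_hz, rtol=1e-4):
        raise ValueError(f"{path}: sampling rate {fs:g} Hz != layout {layout.fs_hz} Hz")


def read_snirf(path, layout: ChannelLayout | None = None):
    """Minimal SNIRF reader.

    Returns a :class:`HemoTimeSeries` when the file stores processed
    HbO/HbR concentrations, else an :class:`OpticalRecording` of dOD data.
    Only single-data-block files are supported.
    """
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise ValueError(f"{path}: not a SNIRF file (no /nirs group)")
        nirs = f["nirs"]
        if "data1" not in nirs:
            raise ValueError(f"{path}: no /nirs/data1 block")
        data = nirs["data1"]
        y = np.asarray(data["dataTimeSeries"])  # samples x measurements
        t = np.asarray(data["time"]).ravel()
        fs = _fs_from_time(t) if t.size > 2 else 1.0 / float(t[1] - t[0])
        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),  # numeric, not lexicographic
        )
        if not ml_names:
            raise ValueError(f"{path}: no measurementList entries")
        kinds, chan_of, label_of = [], [], []
        for name in ml_names:
            ml = data[name]
            dtype = int(np.asarray(ml["dataType"])[()])
            src = int(np.asarray(ml["sourceIndex"])[()])
            det = int(np.asarray(ml["detectorIndex"])[()])
            label = ""
            if "dataTypeLabel" in ml:
                raw = np.asarray(ml["dataTypeLabel"])[()]
                label = raw.decode() if isinstance(raw, bytes) else str(raw)
            kinds.append(dtype)
            chan_of.append((src, det))
            label_of.append(label)
        channels = sorted(set(chan_of))
        ch_index = {c: i for i, c in enumerate(channels)}
        if all(k == 99999 for k in kinds):  # processed data
            hbo = np.zeros((len(channels), y.shape[0]))
            hbr = np.zeros_like(hbo)
            for m, (c, label) in enumerate(zip(chan_of, label_of)):
                if label.lower() in ("hbo", "hbo2"):
                    hbo[ch_index[c]] = y[:, m]
                elif label.lower() == "hbr":
                    hbr[ch_index[c]] = y[:, m]
                else:
                    raise ValueError(f"{path}: unsupported processed label {label!r}")
            out = HemoTimeSeries(dhbo=hbo, dhbr=hbr, fs_hz=fs)
            _check_layout(out.n_channels, fs, layout, path)
            return out
        raise ValueError(
            f"{path}: only processed-concentration SNIRF (dataType 99999, "
            "HbO/HbR labels) is supported"
        )


def read_recording(path, fmt: str | None = None, layout: ChannelLayout | None = None):
    """Dispatch on format: 'csv_wide' (hemo or optical sniffed) or 'snirf'."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "snirf" if path.suffix.lower() in (".snirf", ".h5", ".hdf5") else "csv_wide"
    if fmt == "snirf":
        return read_snirf(path, layout)
    if fmt == "csv_wide":
        header = pd.read_csv(path, nrows=0).columns
        if any(_HBO_RE.match(c) for c in header):
            return read_hemo_csv(path, layout)
        return read_optical_csv(path, layout)
    raise ValueError(f"unknown format {fmt!r}; use 'csv_wide' or 'snirf'")
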