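"""Readers and writers for the package's on-disk formats.

Plain-text formats are long-form CSV: intensities as
(subject_id, channel, wavelength_nm, t_s, intensity), hemoglobin series
as (subject_id, channel, t_s, hbo, hhb), the session layout as JSON, and
the feature table as subject_id, group, cit, ch1...ch16.  A minimal
SNIRF (HDF5) continuous-wave reader/writer is provided for instrument
interoperability; each of the 16 channels is stored as its own
source-detector pair with two wavelength measurements.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .preprocess import CHANNELS, N_CHANNELS, HbSeries, RawIntensitySeries, SessionLayout

__all__ = [
    "write_hb_csv",
    "read_hb_csv",
    "write_raw_csv",
    "read_raw_csv",
    "layout_to_json",
    "layout_from_json",
    "write_snirf",
    "read_snirf",
]


def write_hb_csv(series: HbSeries, path) -> None:
    t = series.times
    frames = []
    for c, ch in enumerate(CHANNELS):
        frames.append(
            pd.DataFrame(
                {"subject_id": series.subject_id, "channel": ch, "t_s": t,
                 "hbo": series.hbo[c], "hhb": series.hhb[c]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_hb_csv(path) -> HbSeries:
    df = pd.read_csv(path)
    subject = str(df["subject_id"].iloc[0])
    t = np.sort(df["t_s"].unique())
    if len(t) > 1:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("non-uniform sampling in Hb CSV")
        dt = float(steps[0])
    else:
        raise ValueError("Hb CSV must contain more than one sample")
    hbo = np.empty((N_CHANNELS, len(t)))
    hhb = np.empty((N_CHANNELS, len(t)))
    for c, ch in enumerate(CHANNELS):
        sub = df[df["channel"] == ch].sort_values("t_s")
        if len(sub) != len(t):
            raise ValueError(f"channel {ch} has {len(sub)} samples, expected {len(t)}")
        hbo[c] = sub["hbo"].to_numpy()
        hhb[c] = sub["hhb"].to_numpy()
    return HbSeries(subject_id=subject, hbo=hbo, hhb=hhb, dt=dt)


def write_raw_csv(raw: RawIntensitySeries, path) -> None:
    t = raw.times
    frames = []
    for c, ch in enumerate(CHANNELS):
        for w, wl in enumerate(raw.wavelengths_nm):
            frames.append(
                pd.DataFrame(
                    {"subject_id": raw.subject_id, "channel": ch,
                     "wavelength_nm": wl, "t_s": t, "intensity": raw.data[c, w]}
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_raw_csv(path) -> RawIntensitySeries:
    df = pd.read_csv(path)
    subject = str(df["subject_id"].iloc[0])
    wls = tuple(sorted(df["wavelength_nm"].unique()))
    if len(wls) != 2:
        raise ValueError(f"expected 2 wavelengths, found {len(wls)}")
    t = np.sort(df["t_s"].unique())
    dt = float(np.diff(t)[0])
    data = np.empty((N_CHANNELS, 2, len(t)))
    for c, ch in enumerate(CHANNELS):
        for w, wl in enumerate(wls):
            sub = df[(df["channel"] == ch) & (df["wavelength_nm"] == wl)]
            sub = sub.sort_values("t_s")
            if len(sub) != len(t):
                raise ValueError(f"channel {ch} @ {wl} nm is incomplete")
            data[c, w] = sub["intensity"].to_numpy()
    return RawIntensitySeries(subject_id=subject, data=data, dt=dt, wavelengths_nm=wls)


def layout_to_json(layout: SessionLayout, path) -> None:
    payload = {
        "baseline": list(layout.baseline),
        "blocks": {k: list(v) for k, v in layout.blocks.items()},
        "rests": [list(r) for r in layout.rests],
        "post": None if layout.post is None else list(layout.post),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def layout_from_json(path) -> SessionLayout:
    with open(path) as fh:
        payload = json.load(fh)
    return SessionLayout(
        baseline=tuple(payload["baseline"]),
        blocks={k: tuple(v) for k, v in payload["blocks"].items()},
        rests=tuple(tuple(r) for r in payload.get("rests", [])),
        post=None if payload.get("post") is None else tuple(payload["post"]),
    )


def write_snirf(raw: RawIntensitySeries, path) -> None:
    """Minimal continuous-wave SNIRF: one source-detector pair per channel."""
    import h5py

    t = raw.times
    n_meas = N_CHANNELS * 2
    series = np.empty((raw.n_samples, n_meas))
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=np.bytes_(raw.subject_id))
        meta.create_dataset("MeasurementDate", data=np.bytes_("unknown"))
        meta.create_dataset("MeasurementTime", data=np.bytes_("unknown"))
        meta.create_dataset("LengthUnit", data=np.bytes_("cm"))
        meta.create_dataset("TimeUnit", data=np.bytes_("s"))
        meta.create_dataset("FrequencyUnit", data=np.bytes_("Hz"))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths_nm, float))
        pos = np.zeros((N_CHANNELS, 2))
        pos[:, 0] = np.arange(N_CHANNELS)
        probe.create_dataset("sourcePos2D", data=pos)
        probe.create_dataset("detectorPos2D", data=pos + (0.5, 0.0))
        data = nirs.create_group("data1")
        m = 0
        for c in range(N_CHANNELS):
            for w in range(2):
                series[:, m] = raw.data[c, w]
                ml = data.create_group(f"measurementList{m + 1}")
                ml.create_dataset("sourceIndex", data=np.int32(c + 1))
                ml.create_dataset("detectorIndex", data=np.int32(c + 1))
                ml.create_dataset("wavelengthIndex", data=np.int32(w + 1))
                ml.create_dataset("dataType", data=np.int32(1))  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=np.int32(1))
                m += 1
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=t)


def read_snirf(path) -> RawIntensitySeries:
    """Read the CW amplitude block of a SNIRF file written by this package
    (or any file whose channels map one source-detector pair to one of the
    16 measurement channels)."""
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        subject = "unknown"
        if "metaDataTags" in nirs and "SubjectID" in nirs["metaDataTags"]:
            subject = nirs["metaDataTags"]["SubjectID"][()].decode()
        wls = tuple(float(w) for w in nirs["probe"]["wavelengths"][()])
        data_grp = nirs["data1"]
        series = np.asarray(data_grp["dataTimeSeries"])
        t = np.asarray(data_grp["time"]).ravel()
        dt = float(np.diff(t)[0]) if t.size > 1 else 1.0
        out = np.empty((N_CHANNELS, 2, series.shape[0]))
        m = 1
        while f"measurementList{m}" in data_grp:
            ml = data_grp[f"measurementList{m}"]
            c = int(ml["sourceIndex"][()]) - 1
            w = int(ml["wavelengthIndex"][()]) - 1
            out[c, w] = series[:, m - 1]
            m += 1
    return RawIntensitySeries(subject_id=subject, data=out, dt=dt, wavelengths_nm=wls)
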