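"""File formats: SNIRF (HDF5), the plain CSV dialect, schedules, clinical tables.

The CSV recording dialect is long-format with columns
``time_s, channel_id, wavelength_nm_or_chromophore, value``; an accompanying
``*_events.csv`` sidecar stores the schedule.  SNIRF files carry the probe,
measurement list and stimulus tables, so they round-trip standalone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import EventSchedule, Trial
from .montage import Channel, MontageLayout, hemisphere_from_midpoint, make_default_montage
from .recording import HbRecording, ODRecording, hb_from_ohb_dhb
from .simulate import CLINICAL_COLUMNS

log = logging.getLogger(__name__)

MISSING = "n.a."


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def write_schedule_csv(schedule: EventSchedule, path) -> None:
    df = pd.DataFrame(
        [
            (t.onset_s, t.on_duration_s, t.off_duration_s, t.condition)
            for t in schedule.trials
        ],
        columns=["onset_s", "duration_s", "off_duration_s", "condition"],
    )
    df.to_csv(path, index=False)


def read_schedule_csv(path) -> EventSchedule:
    df = pd.read_csv(path)
    req = {"onset_s", "duration_s", "condition"}
    if not req.issubset(df.columns):
        raise ValueError(f"schedule CSV needs columns {sorted(req)}")
    trials = []
    for i, row in df.iterrows():
        if "off_duration_s" in df.columns:
            off = float(row["off_duration_s"])
        elif i + 1 < len(df):
            off = float(df.loc[i + 1, "onset_s"] - row["onset_s"] - row["duration_s"])
        else:
            off = float(df["duration_s"].iloc[-1])
        trials.append(Trial(float(row["onset_s"]), float(row["duration_s"]),
                            off, str(row["condition"])))
    total = sum(t.on_duration_s + t.off_duration_s for t in trials)
    return EventSchedule(trials=trials, total_duration_s=total)


# ---------------------------------------------------------------------------
# CSV recording dialect
# ---------------------------------------------------------------------------

def _events_sidecar(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_events.csv")


def write_recording_csv(rec: HbRecording | ODRecording, path) -> None:
    path = Path(path)
    t = rec.times
    frames = []
    if isinstance(rec, HbRecording):
        series = {name: rec.chromophore(name) for name in ("OHb", "DHb", "THb")}
    else:
        series = {
            f"{rec.montage.wavelengths[i]:g}": rec.od[:, i, :] for i in range(2)
        }
    for label, arr in series.items():
        for c, cid in enumerate(rec.montage.channel_ids):
            frames.append(pd.DataFrame({
                "time_s": t,
                "channel_id": cid,
                "wavelength_nm_or_chromophore": label,
                "value": arr[c],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    write_schedule_csv(rec.schedule, _events_sidecar(path))


def read_recording_csv(path, montage: MontageLayout | None = None,
                       schedule: EventSchedule | None = None):
    """Read the long-format CSV dialect back into a recording.

    The montage defaults to the built-in one (channel ids must match); the
    schedule comes from the ``*_events.csv`` sidecar unless given.
    """
    path = Path(path)
    df = pd.read_csv(path)
    req = ["time_s", "channel_id", "wavelength_nm_or_chromophore", "value"]
    missing = set(req) - set(df.columns)
    if missing:
        raise ValueError(f"recording CSV is missing columns: {sorted(missing)}")
    for col in ("time_s", "value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ValueError(f"missing value in column {col!r}, row {row}")
        df[col] = vals
    montage = montage or make_default_montage()
    if schedule is None:
        sidecar = _events_sidecar(path)
        if not sidecar.exists():
            raise ValueError("an event schedule is required: sidecar "
                             f"{sidecar.name} not found and none was given")
        schedule = read_schedule_csv(sidecar)

    labels = list(df["wavelength_nm_or_chromophore"].unique())
    times = np.sort(df["time_s"].unique())
    if times.size < 2:
        raise ValueError("recording CSV has fewer than 2 time points")
    fs = 1.0 / float(np.median(np.diff(times)))
    pivot = df.pivot_table(index="channel_id", columns=["wavelength_nm_or_chromophore", "time_s"],
                           values="value")
    order = [cid for cid in montage.channel_ids]
    if set(order) != set(pivot.index):
        raise ValueError("channel ids in CSV do not match the montage")
    pivot = pivot.loc[order]

    if set(labels) >= {"OHb", "DHb"}:
        ohb = pivot["OHb"].to_numpy(float)
        dhb = pivot["DHb"].to_numpy(float)
        return hb_from_ohb_dhb(fs, ohb, dhb, montage, schedule)
    wl_labels = [f"{w:g}" for w in montage.wavelengths]
    if set(labels) >= set(wl_labels):
        od = np.stack([pivot[w].to_numpy(float) for w in wl_labels], axis=1)
        return ODRecording(fs, od, montage, schedule)
    raise ValueError(f"unrecognized series labels in recording CSV: {labels}")


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------

_HB_LABELS = {"OHb": "HbO", "DHb": "HbR", "THb": "HbT"}
_HB_FROM_LABEL = {v: k for k, v in _HB_LABELS.items()}


def write_snirf(rec: HbRecording | ODRecording, path) -> None:
    """Write a recording as a minimal, standard-conforming SNIRF file."""
    montage = rec.montage
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(montage.wavelengths, float))
        probe.create_dataset("sourcePos2D", data=np.array([p for _, p in montage.sources], float))
        probe.create_dataset("detectorPos2D", data=np.array([p for _, p in montage.detectors], float))
        str_dt = h5py.string_dtype()
        probe.create_dataset("sourceLabels", data=[s for s, _ in montage.sources], dtype=str_dt)
        probe.create_dataset("detectorLabels", data=[d for d, _ in montage.detectors], dtype=str_dt)
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data=np.bytes_("cm"))
        meta.create_dataset("TimeUnit", data=np.bytes_("s"))
        meta.create_dataset("FrequencyUnit", data=np.bytes_("Hz"))
        meta.create_dataset(
            "channelDistances_cm",
            data=np.bytes_(",".join(f"{d:g}" for d in montage.distances_cm())),
        )
        src_index = {s: i + 1 for i, (s, _) in enumerate(montage.sources)}
        det_index = {d: i + 1 for i, (d, _) in enumerate(montage.detectors)}

        data = nirs.create_group("data1")
        columns = []
        ml = []
        if isinstance(rec, HbRecording):
            for chrom in ("OHb", "DHb", "THb"):
                arr = rec.chromophore(chrom)
                for c, ch in enumerate(montage.channels):
                    columns.append(arr[c])
                    ml.append((src_index[ch.source_id], det_index[ch.detector_id],
                               1, 99999, _HB_LABELS[chrom]))
        else:
            for w in range(2):
                for c, ch in enumerate(montage.channels):
                    columns.append(rec.od[c, w, :])
                    ml.append((src_index[ch.source_id], det_index[ch.detector_id],
                               w + 1, 1, ""))
        data.create_dataset("dataTimeSeries", data=np.column_stack(columns))
        data.create_dataset("time", data=rec.times)
        for i, (si, di, wi, dtype, label) in enumerate(ml, start=1):
            g = data.create_group(f"measurementList{i}")
            g.create_dataset("sourceIndex", data=si)
            g.create_dataset("detectorIndex", data=di)
            g.create_dataset("wavelengthIndex", data=wi)
            g.create_dataset("dataType", data=dtype)
            if label:
                g.create_dataset("dataTypeLabel", data=np.bytes_(label))

        by_cond: dict[str, list] = {}
        for t in rec.schedule.trials:
            by_cond.setdefault(t.condition, []).append(
                (t.onset_s, t.on_duration_s, 1.0, t.off_duration_s))
        for i, (cond, rows) in enumerate(sorted(by_cond.items()), start=1):
            g = nirs.create_group(f"stim{i}")
            g.create_dataset("name", data=np.bytes_(cond))
            g.create_dataset("data", data=np.asarray(rows, float))
            g.create_dataset(
                "dataLabels",
                data=["starttime", "duration", "amplitude", "off_duration"],
                dtype=str_dt,
            )


def _as_str(x) -> str:
    v = x[()] if isinstance(x, h5py.Dataset) else x
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path):
    """Read a SNIRF file written by this package (Hb or OD series)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        probe = nirs["probe"]
        wavelengths = tuple(float(w) for w in probe["wavelengths"][()])
        spos = probe["sourcePos2D"][()]
        dpos = probe["detectorPos2D"][()]
        slabels = [_as_str(s) for s in probe["sourceLabels"][()]]
        dlabels = [_as_str(d) for d in probe["detectorLabels"][()]]
        sources = [(slabels[i], (float(spos[i][0]), float(spos[i][1]))) for i in range(len(slabels))]
        detectors = [(dlabels[i], (float(dpos[i][0]), float(dpos[i][1]))) for i in range(len(dlabels))]

        data = nirs["data1"]
        series = data["dataTimeSeries"][()]
        time = data["time"][()]
        fs = 1.0 / float(np.median(np.diff(time)))
        ml_names = sorted(
            (k for k in data if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        entries = []
        for k in ml_names:
            g = data[k]
            label = _as_str(g["dataTypeLabel"]) if "dataTypeLabel" in g else ""
            entries.append((int(g["sourceIndex"][()]), int(g["detectorIndex"][()]),
                            int(g["wavelengthIndex"][()]), int(g["dataType"][()]), label))

        # channel list in first-appearance order
        chan_keys = []
        for si, di, _, _, _ in entries:
            key = (si, di)
            if key not in chan_keys:
                chan_keys.append(key)
        channels = []
        for si, di in chan_keys:
            sx, sy = sources[si - 1][1]
            dx, dy = detectors[di - 1][1]
            channels.append(Channel(
                f"{slabels[si - 1]}_{dlabels[di - 1]}", slabels[si - 1], dlabels[di - 1],
                hemisphere_from_midpoint((sx + dx) / 2.0),
            ))
        if "metaDataTags" in nirs and "channelDistances_cm" in nirs["metaDataTags"]:
            dists = [float(v) for v in _as_str(nirs["metaDataTags"]["channelDistances_cm"]).split(",")]
        else:
            dists = [3.0] * len(channels)
        montage = MontageLayout(
            sources=sources, detectors=detectors, channels=channels,
            wavelengths=wavelengths,
            source_detector_distance_cm={c.channel_id: d for c, d in zip(channels, dists)},
        )

        stim_names = [k for k in nirs if k.startswith("stim")]
        if not stim_names:
            raise ValueError("SNIRF file has no stim groups: an event schedule is required")
        trial_rows = []
        for k in stim_names:
            g = nirs[k]
            cond = _as_str(g["name"])
            for row in np.atleast_2d(g["data"][()]):
                off = float(row[3]) if row.size > 3 else float("nan")
                trial_rows.append((float(row[0]), float(row[1]), off, cond))
        trial_rows.sort()
        trials = []
        for i, (onset, dur, off, cond) in enumerate(trial_rows):
            if np.isnan(off):
                if i + 1 < len(trial_rows):
                    off = trial_rows[i + 1][0] - onset - dur
                else:
                    off = dur
            trials.append(Trial(onset, dur, off, cond))
        schedule = EventSchedule(
            trials, sum(t.on_duration_s + t.off_duration_s for t in trials))

        ch_index = {key: i for i, key in enumerate(chan_keys)}
        n_ch, n_t = len(channels), series.shape[0]
        if any(e[3] == 99999 for e in entries):
            arrs = {name: np.zeros((n_ch, n_t)) for name in ("OHb", "DHb", "THb")}
            for col, (si, di, _, _, label) in enumerate(entries):
                chrom = _HB_FROM_LABEL.get(label)
                if chrom:
                    arrs[chrom][ch_index[(si, di)]] = series[:, col]
            return HbRecording(fs, arrs["OHb"], arrs["DHb"], arrs["THb"], montage, schedule)
        od = np.zeros((n_ch, 2, n_t))
        for col, (si, di, wi, _, _) in enumerate(entries):
            od[ch_index[(si, di)], wi - 1] = series[:, col]
        return ODRecording(fs, od, montage, schedule)


def write_recording(rec, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".snirf", ".h5", ".hdf5"):
        write_snirf(rec, path)
    elif path.suffix.lower() == ".csv":
        write_recording_csv(rec, path)
    else:
        raise ValueError(f"unknown recording format {path.suffix!r}")


def read_recording(path, montage=None, schedule=None):
    """Read a recording, recognizing SNIRF and the CSV dialect by extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".snirf", ".h5", ".hdf5"):
        return read_snirf(path)
    if path.suffix.lower() == ".csv":
        return read_recording_csv(path, montage=montage, schedule=schedule)
    raise ValueError(f"unknown recording format {path.suffix!r}")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def write_clinical_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep=MISSING)


def read_clinical_csv(path) -> pd.DataFrame:
    """Read a clinical score table; "n.a." (any case) and blanks are missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    canonical = {c.lower(): c for c in CLINICAL_COLUMNS}
    rename = {}
    for col in df.columns:
        target = canonical.get(col.strip().lower())
        if target:
            rename[col] = target
        else:
            log.warning("ignoring unknown clinical column %r", col)
    df = df.rename(columns=rename)[[c for c in CLINICAL_COLUMNS if c in rename.values()]]
    for col in df.columns:
        if col == "subject_id":
            continue
        raw = df[col].str.strip()
        is_missing = raw.str.lower().isin(("n.a.", "na", "nan", ""))
        vals = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = vals.isna() & ~is_missing
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"malformed numeric {raw.iloc[row]!r} in column {col!r}, row {row}")
        df[col] = vals
    return df
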