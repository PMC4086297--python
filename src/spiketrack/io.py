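"""Plain-text interchange formats for sessions, truth tables and profiles.

A *session* is stored as one directory:

``metadata.json``
    ``{"day": int, "date": str|null, "sampling_rate": float, "m": int,
    "channels": [int, ...]}``
``channel_###.csv``
    One spike per row: ``unit_label,timestamp_s,s000..s{m-1}`` with waveform
    samples in microvolts.  Rows are grouped by unit, timestamps ascending
    within a unit.

Ground truth is a four-column CSV (day, channel, unit_label, identity); a
profile store is a directory with one JSON document per channel.  All floats
are written with Python's shortest round-trip repr, and JSON keys are sorted,
so an unmodified read/write cycle is byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .isih import ISIH
from .tracker import Profile, ProfileDB, UnitSnapshot
from .waveform import SpikeUnit, Waveform

__all__ = [
    "write_session",
    "read_session",
    "write_truth",
    "read_truth",
    "save_profile_db",
    "load_profile_db",
]


def _fmt(v: float) -> str:
    return repr(float(v))


def write_session(
    session: dict[int, list[SpikeUnit]],
    path,
    *,
    day: int | None = None,
    date: str | None = None,
) -> Path:
    """Write one session to a directory (see module docstring for layout)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    units = [u for ulist in session.values() for u in ulist]
    if day is None:
        days = {u.day for u in units}
        if len(days) != 1:
            raise ValueError(f"cannot infer session day from unit days {sorted(days)}")
        day = days.pop()
    ms = {u.m for u in units}
    srs = {u.sampling_rate for u in units}
    if len(ms) > 1 or len(srs) > 1:
        raise ValueError("session mixes waveform lengths or sampling rates")
    m = ms.pop() if ms else 48
    sr = srs.pop() if srs else 30000.0
    meta = {
        "day": int(day),
        "date": date,
        "sampling_rate": float(sr),
        "m": int(m),
        "channels": sorted(int(c) for c in session),
    }
    (path / "metadata.json").write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    header = ["unit_label", "timestamp_s"] + [f"s{j:03d}" for j in range(m)]
    for chan in meta["channels"]:
        with open(path / f"channel_{chan:03d}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for u in sorted(session[chan], key=lambda u: u.unit_label):
                for t, row in zip(u.timestamps, u.waveforms):
                    writer.writerow([u.unit_label, _fmt(t)] + [_fmt(v) for v in row])
    return path


def read_session(path) -> tuple[int, dict[int, list[SpikeUnit]]]:
    """Read a session directory back into per-channel SpikeUnits.

    Malformed rows are rejected with the offending file and line number.
    """
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path}: session metadata missing")
    meta = json.loads(meta_path.read_text())
    m, sr, day = int(meta["m"]), float(meta["sampling_rate"]), int(meta["day"])
    session: dict[int, list[SpikeUnit]] = {}
    for chan in meta["channels"]:
        fname = path / f"channel_{chan:03d}.csv"
        if not fname.exists():
            raise FileNotFoundError(f"{fname}: channel listed in metadata but absent")
        groups: dict[int, list[tuple[float, list[float]]]] = {}
        with open(fname, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or len(header) != m + 2:
                raise ValueError(
                    f"{fname}:1: expected {m + 2} columns "
                    f"(unit_label, timestamp_s, {m} samples), got "
                    f"{0 if header is None else len(header)}"
                )
            for lineno, row in enumerate(reader, start=2):
                if len(row) != m + 2:
                    raise ValueError(f"{fname}:{lineno}: expected {m + 2} fields, got {len(row)}")
                try:
                    lbl = int(row[0])
                    t = float(row[1])
                    samples = [float(v) for v in row[2:]]
                except ValueError as exc:
                    raise ValueError(f"{fname}:{lineno}: unparsable field ({exc})") from None
                bucket = groups.setdefault(lbl, [])
                if bucket and t <= bucket[-1][0]:
                    raise ValueError(
                        f"{fname}:{lineno}: timestamp {t} not strictly ascending "
                        f"within unit {lbl}"
                    )
                bucket.append((t, samples))
        units = [
            SpikeUnit(
                channel_id=int(chan), day=day, unit_label=lbl,
                waveforms=np.array([s for _, s in rows], dtype=float),
                timestamps=np.array([t for t, _ in rows], dtype=float),
                sampling_rate=sr,
            )
            for lbl, rows in sorted(groups.items())
        ]
        session[int(chan)] = units
    return day, session


def write_truth(truth, path) -> Path:
    path = Path(path)
    truth.to_frame().to_csv(path, index=False)
    return path


def read_truth(path):
    from .evaluation import GroundTruth

    frame = pd.read_csv(path)
    required = {"day", "channel", "unit_label", "identity"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: truth table needs columns {sorted(required)}")
    if frame.empty:
        raise ValueError(f"{path}: empty ground truth")
    return GroundTruth.from_frame(frame)


def _snapshot_to_json(s: UnitSnapshot) -> dict:
    return {
        "day": s.day,
        "unit_label": s.unit_label,
        "spike_count": s.spike_count,
        "sampling_rate": s.waveform.sampling_rate,
        "waveform": [float(v) for v in s.waveform.samples],
        "isih": None
        if s.isih is None
        else {
            "probabilities": [float(v) for v in s.isih.probabilities],
            "bin_edges": [float(v) for v in s.isih.bin_edges],
        },
    }


def _snapshot_from_json(d: dict, channel_id: int) -> UnitSnapshot:
    h = d["isih"]
    return UnitSnapshot(
        day=int(d["day"]),
        channel_id=channel_id,
        unit_label=int(d["unit_label"]),
        waveform=Waveform(np.array(d["waveform"], dtype=float), float(d["sampling_rate"])),
        isih=None
        if h is None
        else ISIH(np.array(h["probabilities"]), np.array(h["bin_edges"])),
        spike_count=int(d["spike_count"]),
    )


def save_profile_db(db: ProfileDB, path, config_digest: str | None = None) -> Path:
    """Persist a profile store: one JSON document per channel."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for chan in sorted(db.channels):
        doc = {
            "channel": int(chan),
            "next_id": db.next_id(chan),
            "config_digest": config_digest,
            "profiles": [
                {
                    "profile_id": p.profile_id,
                    "status": p.status,
                    "last_seen_day": p.last_seen_day,
                    "instances": [_snapshot_to_json(s) for s in p.instances],
                }
                for p in db.profiles(chan)
            ],
        }
        (path / f"channel_{chan:03d}.json").write_text(
            json.dumps(doc, sort_keys=True, indent=1) + "\n"
        )
    return path


def load_profile_db(path) -> ProfileDB:
    path = Path(path)
    db = ProfileDB()
    for fname in sorted(path.glob("channel_*.json")):
        doc = json.loads(fname.read_text())
        chan = int(doc["channel"])
        db.channels[chan] = [
            Profile(
                profile_id=int(pd_["profile_id"]),
                channel_id=chan,
                instances=[_snapshot_from_json(s, chan) for s in pd_["instances"]],
                status=pd_["status"],
                last_seen_day=int(pd_["last_seen_day"]),
            )
            for pd_ in doc["profiles"]
        ]
        db.set_next_id(chan, int(doc["next_id"]))
    return db
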