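"""Reading and writing recordings and tables.

Continuous recordings are read through MNE (BioSemi BDF and EDF+); writing
uses a minimal built-in EDF+C writer (16-bit, one-second data records, TAL
annotation channel carrying the stimulus markers), since round-tripping
through a standard format keeps simulated sessions inspectable with any EEG
toolbox.  Schedules and cohort tables are plain CSV.

Stimulus markers are encoded in annotation descriptions of the form
``cpd=4.47;cycle=3;run=1;eye=OS;rate=15;dur=3``.
"""

from __future__ import annotations

import math
from pathlib import Path

import mne
import numpy as np
import pandas as pd

from .synth import ContinuousRecording, StimCondition, StimEvent, StimSchedule

__all__ = [
    "write_edf",
    "read_recording",
    "event_description",
    "parse_event_description",
    "write_schedule_csv",
    "read_schedule_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]


def event_description(ev: StimEvent) -> str:
    c = ev.condition
    return (
        f"cpd={c.spatial_frequency:g};cycle={ev.cycle};run={ev.run};"
        f"eye={ev.eye};rate={c.reversal_rate:g};dur={c.duration:g}"
    )


def parse_event_description(desc: str) -> dict | None:
    """Parse a marker description; returns None for foreign annotations."""
    fields = {}
    for part in desc.split(";"):
        if "=" not in part:
            return None
        k, v = part.split("=", 1)
        fields[k] = v
    try:
        return {
            "cpd": float(fields["cpd"]),
            "cycle": int(fields["cycle"]),
            "run": int(fields["run"]),
            "eye": fields["eye"],
            "rate": float(fields["rate"]),
            "dur": float(fields["dur"]),
        }
    except (KeyError, ValueError):
        return None


def _edf_num(x: float) -> str:
    """Shortest decimal form of ``x`` fitting an 8-char EDF numeric field."""
    for prec in range(6, 0, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{x:.0e}"[:8]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long for EDF header: {text!r}")
    return b.ljust(width)


def write_edf(recording: ContinuousRecording, path: str | Path) -> Path:
    """Write an EDF+C file with the schedule as annotations.

    Signals are stored in uV at 16-bit resolution in one-second records;
    the recording is zero-padded to a whole number of seconds.
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    fs = int(round(fs))
    names = list(recording.channels)
    n_samples = recording.n_samples
    n_records = math.ceil(n_samples / fs)

    data = {}
    phys = {}
    for name in names:
        x = np.zeros(n_records * fs)
        x[:n_samples] = recording.channels[name]
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            lo, hi = lo - 1.0, hi + 1.0
        margin = 1e-3 * (hi - lo)
        # store what the 8-char ASCII header fields will actually say and
        # scale with those exact values, so decoding is self-consistent
        lo = float(_edf_num(lo - margin))
        hi = float(_edf_num(hi + margin))
        data[name] = x
        phys[name] = (lo, hi)

    # Build one TAL block per record: timestamp plus that second's events.
    tals: list[bytes] = []
    per_record_events: dict[int, list[StimEvent]] = {}
    for ev in recording.events.events:
        per_record_events.setdefault(ev.onset_sample // fs, []).append(ev)
    for rec in range(n_records):
        block = f"+{rec}\x14\x14\x00".encode("ascii")
        for ev in per_record_events.get(rec, []):
            onset = ev.onset_sample / fs
            block += (
                f"+{onset:.6f}\x15{ev.condition.duration:.6f}\x14"
                f"{event_description(ev)}\x14\x00"
            ).encode("ascii")
        tals.append(block)
    ann_bytes = max(max(len(t) for t in tals) + 2, 32)
    ann_bytes += ann_bytes % 2
    ann_spr = ann_bytes // 2

    ns = len(names) + 1
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    labels = names + ["EDF Annotations"]
    header += b"".join(_pad(lbl, 16) for lbl in labels)
    header += b"".join(_pad("", 80) for _ in labels)
    header += b"".join(_pad("uV", 8) for _ in names) + _pad("", 8)
    header += b"".join(_pad(_edf_num(phys[n][0]), 8) for n in names) + _pad("-1", 8)
    header += b"".join(_pad(_edf_num(phys[n][1]), 8) for n in names) + _pad("1", 8)
    header += b"".join(_pad("-32768", 8) for _ in labels)
    header += b"".join(_pad("32767", 8) for _ in labels)
    header += b"".join(_pad("", 80) for _ in labels)
    header += b"".join(_pad(str(fs), 8) for _ in names) + _pad(str(ann_spr), 8)
    header += b"".join(_pad("", 32) for _ in labels)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for name in names:
                lo, hi = phys[name]
                seg = data[name][rec * fs : (rec + 1) * fs]
                dig = np.round((seg - lo) / (hi - lo) * 65535.0 - 32768.0)
                fh.write(np.clip(dig, -32768, 32767).astype("<i2").tobytes())
            fh.write(tals[rec].ljust(ann_bytes, b"\x00"))
    return path


def read_recording(
    path: str | Path,
    channels: tuple[str, ...] = ("Oz", "O1", "O2"),
) -> ContinuousRecording:
    """Read a BDF/EDF recording into uV arrays plus its marker schedule.

    Channel picking is case-insensitive; a missing channel raises with its
    name.  Markers are rebuilt from annotations written by
    :func:`write_edf` (foreign annotations are ignored).
    """
    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    lut = {name.lower(): name for name in raw.ch_names}
    picked = {}
    for want in channels:
        actual = lut.get(want.lower())
        if actual is None:
            raise ValueError(f"channel {want!r} not found in {path.name}")
        picked[want] = raw.get_data(picks=[actual])[0] * 1e6  # V -> uV

    events = []
    for onset, _dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        fields = parse_event_description(desc)
        if fields is None:
            continue
        events.append(
            StimEvent(
                onset_sample=int(round(onset * fs)),
                condition=StimCondition(fields["cpd"], fields["rate"], fields["dur"]),
                cycle=fields["cycle"],
                run=fields["run"],
                eye=fields["eye"],
            )
        )
    schedule = StimSchedule(events=tuple(events), sampling_rate=fs)
    return ContinuousRecording(channels=picked, sampling_rate=fs, events=schedule)


def write_schedule_csv(schedule: StimSchedule, path: str | Path) -> Path:
    """CSV columns: onset_sample, cpd, reversal_rate, duration, cycle, run, eye, sampling_rate."""
    df = schedule.to_frame()
    df["sampling_rate"] = schedule.sampling_rate
    df.to_csv(path, index=False)
    return Path(path)


def read_schedule_csv(path: str | Path) -> StimSchedule:
    df = pd.read_csv(path)
    return StimSchedule.from_frame(df, sampling_rate=float(df["sampling_rate"].iloc[0]))


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    """CSV columns: participant_id, group, eye, acuity_raw, age, disease_duration, phenotype."""
    cohort.to_csv(path, index=False)
    return Path(path)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"participant_id": str, "group": str, "eye": str, "phenotype": str}
    )
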