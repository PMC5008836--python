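"""Plain-text readers and writers for recordings, events, score and rating tables.

Storage convention (documented in ``docs/formats.md``): one long-format CSV per
channel (``time_s,value``), a tab-separated events file (``onset,duration,label``)
and a JSON sidecar per recording carrying subject, condition labels, sampling
rates and units.  Time is seconds from recording start.  All writers use
``%.17g`` so a write/read cycle is lossless at full float64 precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

#: canonical channel -> unit mapping (ASCII unit spellings used on disk)
CHANNEL_UNITS = {"HR": "BPM", "SC": "uS", "EMG": "uV"}
_UNIT_ALIASES = {"μS": "uS", "µS": "uS", "μV": "uV", "µV": "uV", "BPM": "BPM",
                 "uS": "uS", "uV": "uV"}

TRIAL_SCORE_COLUMNS = [
    "subject_id", "bandwidth", "posture", "channel", "trial_index",
    "onset_s", "pre_level", "raw_response", "transformed_response",
    "artifact", "artifact_reason",
]
SUBJECT_SUMMARY_COLUMNS = [
    "subject_id", "bandwidth", "posture", "channel", "mean_pre_level",
    "mean_transformed_response", "n_valid_trials",
]
RATING_COLUMNS = [
    "subject_id", "sound_type", "spl", "presentation_index", "dimension",
    "rating",
]


@dataclass
class Channel:
    """One continuous physiological channel on a uniform sample grid.

    Sample ``i`` is the value at time ``i / sampling_rate`` seconds.
    """

    name: str
    sampling_rate: float
    units: str
    samples: np.ndarray

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise DataError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.units = _UNIT_ALIASES.get(self.units, self.units)
        expected = CHANNEL_UNITS.get(self.name)
        if expected is not None and self.units != expected:
            raise DataError(
                f"channel {self.name} must carry units {expected}, got {self.units}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise DataError("channel samples must be one-dimensional")

    @property
    def duration(self) -> float:
        """Duration in seconds (time of the last sample)."""
        return (len(self.samples) - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def __eq__(self, other):
        return (
            isinstance(other, Channel)
            and self.name == other.name
            and self.sampling_rate == other.sampling_rate
            and self.units == other.units
            and np.array_equal(self.samples, other.samples)
        )


def validate_events(events: pd.DataFrame, path=None) -> pd.DataFrame:
    """Check the event-list invariants (non-negative, strictly increasing onsets)."""
    required = {"onset", "duration", "label"}
    missing = required - set(events.columns)
    if missing:
        raise FormatError(f"events table missing columns {sorted(missing)}", path=path)
    onsets = events["onset"].to_numpy(dtype=float)
    if len(onsets) and onsets[0] < 0:
        raise FormatError("event onsets must be non-negative", path=path, line=2)
    bad = np.nonzero(np.diff(onsets) <= 0)[0]
    if bad.size:
        # +3: one for the header line, one for 0- vs 1-based, one for diff offset
        raise FormatError(
            f"event onsets must be strictly increasing "
            f"({onsets[bad[0] + 1]!r} after {onsets[bad[0]]!r})",
            path=path, line=int(bad[0]) + 3)
    return events


@dataclass
class Recording:
    """A multichannel recording for one subject in one condition."""

    subject_id: str
    condition: dict  # {"bandwidth": ..., "posture": ...}
    channels: dict = field(default_factory=dict)  # name -> Channel
    events: pd.DataFrame = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.events is None:
            self.events = pd.DataFrame(columns=["onset", "duration", "label"])
        validate_events(self.events)
        for name, ch in self.channels.items():
            if name != ch.name:
                raise DataError(f"channel key {name!r} does not match Channel.name {ch.name!r}")

    @property
    def duration(self) -> float:
        return min(ch.duration for ch in self.channels.values())

    def __eq__(self, other):
        return (
            isinstance(other, Recording)
            and self.subject_id == other.subject_id
            and self.condition == other.condition
            and set(self.channels) == set(other.channels)
            and all(self.channels[k] == other.channels[k] for k in self.channels)
            and self.events.reset_index(drop=True).equals(
                other.events.reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# recording round trip
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path_prefix) -> list:
    """Write channel CSVs, an events TSV and a JSON sidecar; return the paths."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    sidecar = {
        "subject_id": recording.subject_id,
        "condition": recording.condition,
        "meta": recording.meta,
        "channels": {},
    }
    for name, ch in recording.channels.items():
        p = prefix.with_name(prefix.name + f"_channel-{name}.csv")
        times = ch.times
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("time_s,value\n")
            for t, v in zip(times, ch.samples):
                fh.write(f"{t:.17g},{v:.17g}\n")
        sidecar["channels"][name] = {
            "sampling_rate": ch.sampling_rate,
            "units": ch.units,
            "n_samples": int(len(ch.samples)),
            "path": p.name,
        }
        paths.append(p)
    ev_path = prefix.with_name(prefix.name + "_events.tsv")
    with open(ev_path, "w", encoding="utf-8") as fh:
        fh.write("onset\tduration\tlabel\n")
        for row in recording.events.itertuples(index=False):
            fh.write(f"{row.onset:.17g}\t{row.duration:.17g}\t{row.label}\n")
    paths.append(ev_path)
    sc_path = prefix.with_name(prefix.name + ".json")
    with open(sc_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(sc_path)
    return paths


def _read_events(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["onset", "duration", "label"]:
            raise FormatError(f"unexpected events header {header!r}", path=path, line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("expected 3 tab-separated fields", path=path, line=lineno)
            try:
                onset, duration = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"could not parse number: {exc}", path=path, line=lineno)
            rows.append((onset, duration, parts[2]))
    events = pd.DataFrame(rows, columns=["onset", "duration", "label"])
    # re-run the monotonicity check with file context for precise error lines
    onsets = events["onset"].to_numpy()
    bad = np.nonzero(np.diff(onsets) <= 0)[0]
    if bad.size:
        raise FormatError(
            f"event onsets must be strictly increasing "
            f"({onsets[bad[0] + 1]!r} after {onsets[bad[0]]!r})",
            path=path, line=int(bad[0]) + 3)
    if len(onsets) and onsets[0] < 0:
        raise FormatError("event onsets must be non-negative", path=path, line=2)
    return events


def read_recording(path_prefix) -> Recording:
    """Reload a recording written by :func:`write_recording` (lossless)."""
    prefix = Path(path_prefix)
    sc_path = prefix.with_name(prefix.name + ".json")
    if not sc_path.exists():
        raise FormatError("missing sidecar", path=sc_path)
    with open(sc_path, encoding="utf-8") as fh:
        sidecar = json.load(fh)
    channels = {}
    for name, info in sidecar["channels"].items():
        p = sc_path.with_name(info["path"])
        df = pd.read_csv(p, float_precision="round_trip")
        if list(df.columns) != ["time_s", "value"]:
            raise FormatError(f"unexpected channel header {list(df.columns)!r}", path=p, line=1)
        if len(df) != info["n_samples"]:
            raise FormatError(
                f"sidecar promises {info['n_samples']} samples, file has {len(df)}", path=p)
        fs = float(info["sampling_rate"])
        times = df["time_s"].to_numpy()
        if len(times) > 1:
            step = np.median(np.diff(times))
            if abs(step - 1.0 / fs) > 1e-6 / fs:
                raise FormatError(
                    f"time column step {step:g} s inconsistent with sidecar "
                    f"sampling_rate {fs:g} Hz", path=p)
        channels[name] = Channel(name=name, sampling_rate=fs, units=info["units"],
                                 samples=df["value"].to_numpy())
    events = _read_events(sc_path.with_name(prefix.name + "_events.tsv"))
    return Recording(
        subject_id=sidecar["subject_id"],
        condition=sidecar["condition"],
        channels=channels,
        events=events,
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as CSV at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _require_columns(df, required, path):
    missing = sorted(set(required) - set(df.columns))
    if missing:
        raise FormatError(f"missing required columns {missing}", path=path)


def read_scores_table(path, kind="trial") -> pd.DataFrame:
    """Read a trial-level (``kind='trial'``) or subject-level score table.

    Unknown columns are preserved untouched so externally produced tables can
    carry extra annotations through the pipeline.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if kind == "trial":
        required = ["subject_id", "bandwidth", "posture", "channel",
                    "trial_index", "transformed_response"]
    elif kind == "subject":
        required = ["subject_id", "bandwidth", "posture", "channel",
                    "mean_transformed_response"]
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    _require_columns(df, required, path)
    if "artifact" in df.columns:
        df["artifact"] = df["artifact"].astype(bool)
    else:
        df["artifact"] = False
    return df


def read_ratings_table(path) -> pd.DataFrame:
    """Read a magnitude-estimation rating table (adapter for deposited data)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["subject_id", "sound_type", "spl", "dimension", "rating"], path)
    if (df["rating"] <= 0).any():
        raise FormatError("ratings must be positive (modulus-relative magnitudes)", path=path)
    return df


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
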