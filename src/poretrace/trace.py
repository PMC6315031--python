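"""Core data types and I/O for nanopore current traces.

Unit conventions used throughout the package:

* current — nA
* time — s
* bias — mV
* conductance — nS (so ``G [nS] = 1e3 * I [nA] / V [mV]``)

Sample-index intervals are 0-based and half-open (``[start, end)``),
matching Python slicing, so segments compose without off-by-one bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "LevelSegment",
    "Event",
    "EventAnnotation",
    "GroundTruthAnnotation",
    "blockage_conductance",
    "read_trace",
    "write_trace",
    "read_annotations",
    "write_annotations",
]


def blockage_conductance(blockage_current_nA: float, bias_mV: float) -> float:
    """Convert a blockage current (nA) at a given bias (mV) to nS."""
    if bias_mV == 0:
        raise ValueError("bias must be nonzero to convert current to conductance")
    return 1e3 * blockage_current_nA / bias_mV


@dataclass
class CurrentTrace:
    """A uniformly sampled ionic-current recording.

    Parameters
    ----------
    samples
        Current samples in nA.
    sampling_rate
        Sampling frequency in Hz; must be positive.
    start_time
        Time of the first sample in seconds.
    meta
        Free-form metadata (e.g. ``bias_mV``, ``electrolyte``, ``pore_id``,
        ``lowpass_hz``). Stored but never interpreted by I/O: in particular
        no filter is applied on read even when ``lowpass_hz`` is present.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    def index_to_time(self, index) -> np.ndarray | float:
        return self.start_time + np.asarray(index) / self.sampling_rate

    def time_to_index(self, t) -> np.ndarray | int:
        idx = np.rint((np.asarray(t) - self.start_time) * self.sampling_rate)
        return idx.astype(int) if idx.ndim else int(idx)


@dataclass
class LevelSegment:
    """A piecewise-constant stretch of current within an event.

    ``level_label`` is 0 for open pore, 1 for ssDNA, 2 for dsDNA and
    ``None`` when unassigned (e.g. awaiting noise-based arbitration).
    """

    start: int
    end: int
    mean_current: float
    level_label: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


_KNOWN_CLASSES = ("2", "21", "212")


@dataclass
class Event:
    """A detected translocation excursion with its sub-level structure."""

    segments: list[LevelSegment]
    sampling_rate: float
    baseline_current: float
    event_class: str = "other"
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("event must contain at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end != b.start:
                raise ValueError("segments within an event must be contiguous")

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end

    @property
    def dwell_time(self) -> float:
        """Event duration in seconds."""
        return (self.end - self.start) / self.sampling_rate

    @property
    def blockage_current(self) -> float:
        """Baseline minus the deepest segment mean, in nA."""
        return self.baseline_current - min(s.mean_current for s in self.segments)

    def blockage_conductance(self, bias_mV: float) -> float:
        return blockage_conductance(self.blockage_current, bias_mV)

    @property
    def level_string(self) -> str:
        return "".join(
            "u" if s.level_label is None else str(s.level_label) for s in self.segments
        )


@dataclass
class EventAnnotation:
    """Ground truth for one simulated event."""

    event_id: int
    start: int
    end: int
    event_class: str
    orientation: str = "n/a"  # {"3p_entry", "5p_entry", "n/a"}
    barcode_rel_pos: float = float("nan")
    segment_starts: tuple[int, ...] = ()
    segment_levels: tuple[int, ...] = ()
    segment_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("annotation bounds must satisfy 0 <= start < end")
        if self.segment_fractions and abs(sum(self.segment_fractions) - 1.0) > 1e-9:
            raise ValueError("segment fractions must sum to 1")
        if self.orientation not in ("3p_entry", "5p_entry", "n/a"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class GroundTruthAnnotation:
    """Simulator-emitted truth for all events in a trace."""

    events: list[EventAnnotation]

    def __post_init__(self) -> None:
        ends = 0
        for ev in self.events:
            if ev.start < ends:
                raise ValueError("annotated events must be sorted and non-overlapping")
            ends = ev.end

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

_TEXT_HEADER_KEY = "sampling_rate"


def write_trace(trace: CurrentTrace, path, format: str = "container"):
    """Write a trace to ``path``.

    ``container`` is a chunked HDF5 file (lossless); ``text`` is a
    two-column ``time_s\\tcurrent_nA`` table with ``# key=value`` header
    lines, written at full double precision.
    """
    path = Path(path)
    if format == "container":
        with h5py.File(path, "w") as h5:
            dset = h5.create_dataset(
                "current_nA", data=trace.samples, chunks=True, dtype="f8"
            )
            dset.attrs["sampling_rate_hz"] = trace.sampling_rate
            dset.attrs["start_time_s"] = trace.start_time
            dset.attrs["meta_json"] = json.dumps(trace.meta, sort_keys=True)
    elif format == "text":
        with open(path, "w") as fh:
            fh.write(f"# {_TEXT_HEADER_KEY}={trace.sampling_rate!r}\n")
            fh.write(f"# start_time={trace.start_time!r}\n")
            for key, value in sorted(trace.meta.items()):
                fh.write(f"# meta.{key}={json.dumps(value)}\n")
            fh.write("time_s\tcurrent_nA\n")
            times = trace.times
            for t, i in zip(times, trace.samples):
                fh.write(f"{float(t)!r}\t{float(i)!r}\n")
    else:
        raise ValueError(f"unknown trace format {format!r}")
    return path


def read_trace(path, format: str | None = None) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`.

    When ``format`` is None it is inferred from the file signature. A text
    file whose header does not declare ``sampling_rate`` is rejected, as is
    any non-finite sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "container" if h5py.is_hdf5(path) else "text"
    if format == "container":
        with h5py.File(path, "r") as h5:
            dset = h5["current_nA"]
            samples = dset[()]
            rate = float(dset.attrs["sampling_rate_hz"])
            start = float(dset.attrs.get("start_time_s", 0.0))
            meta = json.loads(dset.attrs.get("meta_json", "{}"))
        return CurrentTrace(samples, rate, start, meta)
    if format != "text":
        raise ValueError(f"unknown trace format {format!r}")

    rate = None
    start = 0.0
    meta: dict = {}
    rows: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    continue
                key, _, value = body.partition("=")
                key = key.strip()
                value = value.strip()
                if key == _TEXT_HEADER_KEY:
                    rate = float(value)
                elif key == "start_time":
                    start = float(value)
                elif key.startswith("meta."):
                    meta[key[5:]] = json.loads(value)
                continue
            first = line.split("\t")[0].split(",")[0]
            if not _looks_numeric(first):
                continue  # column-name row
            fields = line.replace(",", "\t").split("\t")
            rows.append(float(fields[-1]))
    if rate is None:
        raise ValueError(
            f"{path}: text trace header must declare '# {_TEXT_HEADER_KEY}=<Hz>'"
        )
    samples = np.asarray(rows, dtype=float)
    if samples.size == 0:
        raise ValueError(f"{path}: no samples found")
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{path}: non-finite current values")
    return CurrentTrace(samples, rate, start, meta)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# Annotation I/O (TSV sidecar)
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = [
    "event_id",
    "start",
    "end",
    "class",
    "orientation",
    "barcode_rel_pos",
    "segment_starts",
    "segment_levels",
    "segment_fractions",
]


def write_annotations(annotations: GroundTruthAnnotation, path):
    """Write ground-truth annotations as a fixed-column TSV."""
    path = Path(path)
    records = []
    for ev in annotations:
        records.append(
            {
                "event_id": ev.event_id,
                "start": ev.start,
                "end": ev.end,
                "class": ev.event_class,
                "orientation": ev.orientation,
                "barcode_rel_pos": repr(ev.barcode_rel_pos),
                "segment_starts": ",".join(str(s) for s in ev.segment_starts),
                "segment_levels": ",".join(str(s) for s in ev.segment_levels),
                "segment_fractions": ",".join(repr(f) for f in ev.segment_fractions),
            }
        )
    pd.DataFrame.from_records(records, columns=_ANNOT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_annotations(path, on_unsorted: str = "sort") -> GroundTruthAnnotation:
    """Read an annotation TSV.

    ``on_unsorted`` controls what happens when rows are out of order:
    ``"sort"`` reorders them, ``"reject"`` raises. Overlapping events are
    always a validation error.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = set(_ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    events = []
    for _, row in df.iterrows():
        events.append(
            EventAnnotation(
                event_id=int(row["event_id"]),
                start=int(row["start"]),
                end=int(row["end"]),
                event_class=row["class"],
                orientation=row["orientation"] or "n/a",
                barcode_rel_pos=float(row["barcode_rel_pos"])
                if row["barcode_rel_pos"] not in ("", "nan")
                else float("nan"),
                segment_starts=_split(row["segment_starts"], int),
                segment_levels=_split(row["segment_levels"], int),
                segment_fractions=_split(row["segment_fractions"], float),
            )
        )
    starts = [ev.start for ev in events]
    if starts != sorted(starts):
        if on_unsorted == "reject":
            raise ValueError("annotation rows are out of order")
        events.sort(key=lambda ev: ev.start)
    return GroundTruthAnnotation(events)


def _split(text: str, cast) -> tuple:
    text = text.strip()
    if not text:
        return ()
    return tuple(cast(tok) for tok in text.split(","))
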