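"""Session I/O: on-disk representation of behavioural event logs, two-channel
photometry traces, per-neuron calcium matrices and session protocols.

Conventions shared by every module:

* time is in seconds, zero at session start;
* epochs are half-open intervals ``[start, end)``;
* event logs and protocols are plain CSV (inspectable fixtures), traces and
  cell matrices live in a single-file ``.npz`` container (compact numerics).

Event log CSV columns: ``time_s, label, source`` with an optional comment
header ``# session_duration_s=<float>``.  Protocol CSV columns:
``kind, start_s, end_s, name, value`` where ``kind`` is one of ``access``
(value = caloric density, kcal/ml), ``infusion`` (value = rate, ul/min) or
``injection`` (``end_s`` empty, value unused).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EventTrain",
    "RawPhotometry",
    "SessionProtocol",
    "AccessEpoch",
    "InfusionEpoch",
    "Injection",
    "ValidationError",
    "read_event_log",
    "write_event_log",
    "read_trace",
    "write_trace",
    "read_protocol",
    "write_protocol",
    "read_cell_matrix",
    "write_cell_matrix",
]

#: labels accepted in event logs by default
DEFAULT_VOCABULARY = ("lick", "bite")


class ValidationError(ValueError):
    """Raised when an on-disk record violates a container invariant."""


@dataclass(frozen=True)
class EventTrain:
    """Timestamped discrete behavioural events (licks, bites).

    Parameters
    ----------
    timestamps
        Seconds from session start, non-negative and non-decreasing.
    labels
        Per-event label drawn from ``vocabulary``.
    sources
        Per-event source identifier (bottle/sipper id).
    session_duration
        Session length in seconds; all events must fall inside it.
    """

    timestamps: np.ndarray
    labels: np.ndarray
    sources: np.ndarray
    session_duration: float
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        sources = np.asarray(self.sources, dtype=object)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sources", sources)
        if not (len(ts) == len(labels) == len(sources)):
            raise ValidationError("timestamps, labels and sources must have equal length")
        if len(ts) and ts[0] < 0:
            raise ValidationError("timestamps must be non-negative")
        if len(ts) and np.any(np.diff(ts) < 0):
            bad = int(np.argmax(np.diff(ts) < 0)) + 1
            raise ValidationError(f"timestamps must be non-decreasing (violated at event {bad})")
        if self.session_duration < 0:
            raise ValidationError("session_duration must be non-negative")
        if len(ts) and ts[-1] > self.session_duration:
            raise ValidationError("event timestamps exceed session_duration")
        unknown = set(labels) - set(self.vocabulary)
        if unknown:
            raise ValidationError(f"unknown event labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.timestamps)

    def select(self, label: str | None = None, source: str | None = None) -> "EventTrain":
        """Return the sub-train matching ``label`` and/or ``source``."""
        mask = np.ones(len(self), dtype=bool)
        if label is not None:
            mask &= self.labels == label
        if source is not None:
            mask &= self.sources == source
        return EventTrain(
            self.timestamps[mask],
            self.labels[mask],
            self.sources[mask],
            self.session_duration,
            self.vocabulary,
        )


@dataclass(frozen=True)
class RawPhotometry:
    """Paired signal (~470 nm) / isosbestic reference (~405-415 nm) samples
    on one uniform time grid."""

    time: np.ndarray
    signal: np.ndarray
    reference: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        reference = np.asarray(self.reference, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "reference", reference)
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if not (len(time) == len(signal) == len(reference)):
            raise ValidationError("signal and reference must match the time grid length")
        if len(time) > 1:
            dt = np.diff(time)
            if not np.allclose(dt, 1.0 / self.rate, rtol=1e-6, atol=1e-9):
                raise ValidationError("time grid spacing does not match 1/rate")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class AccessEpoch:
    start: float
    end: float
    tastant: str
    caloric_density: float  # kcal/ml


@dataclass(frozen=True)
class InfusionEpoch:
    start: float
    end: float
    rate: float  # ul/min
    solution: str


@dataclass(frozen=True)
class Injection:
    time: float
    compound: str


@dataclass(frozen=True)
class SessionProtocol:
    """Stimulus schedule of a session: lickometer access epochs, intragastric
    infusion epochs and bolus injections."""

    access_epochs: tuple[AccessEpoch, ...] = ()
    infusion_epochs: tuple[InfusionEpoch, ...] = ()
    injections: tuple[Injection, ...] = ()

    def __post_init__(self) -> None:
        for epochs in (self.access_epochs, self.infusion_epochs):
            ordered = sorted(epochs, key=lambda e: e.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise ValidationError("epochs overlap within a category")
        if any(e.caloric_density < 0 for e in self.access_epochs):
            raise ValidationError("caloric densities must be non-negative")
        if any(e.rate < 0 for e in self.infusion_epochs):
            raise ValidationError("infusion rates must be non-negative")


# ---------------------------------------------------------------------------
# event logs

def read_event_log(
    path: str | Path,
    session_duration: float | None = None,
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
) -> EventTrain:
    """Parse a CSV event log into a validated :class:`EventTrain`.

    Malformed rows are reported with their line number.  ``session_duration``
    falls back to a ``# session_duration_s=`` comment line, then to the last
    timestamp.
    """
    path = Path(path)
    times: list[float] = []
    labels: list[str] = []
    sources: list[str] = []
    duration_from_file: float | None = None
    with path.open(newline="") as fh:
        header: list[str] | None = None
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            if row[0].lstrip().startswith("#"):
                text = ",".join(row).lstrip("# ").strip()
                if text.startswith("session_duration_s="):
                    duration_from_file = float(text.split("=", 1)[1])
                continue
            if header is None:
                header = [c.strip() for c in row]
                if header[:3] != ["time_s", "label", "source"]:
                    raise ValidationError(
                        f"{path}:{lineno}: expected header time_s,label,source"
                    )
                continue
            if len(row) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                times.append(float(row[0]))
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad timestamp {row[0]!r}") from exc
            labels.append(row[1].strip())
            sources.append(row[2].strip())
    if session_duration is None:
        session_duration = duration_from_file
    if session_duration is None:
        session_duration = times[-1] if times else 0.0
    return EventTrain(
        np.asarray(times, dtype=float),
        np.asarray(labels, dtype=object),
        np.asarray(sources, dtype=object),
        float(session_duration),
        vocabulary,
    )


def write_event_log(train: EventTrain, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# session_duration_s={train.session_duration!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["time_s", "label", "source"])
        for t, lab, src in zip(train.timestamps, train.labels, train.sources):
            writer.writerow([repr(float(t)), lab, src])


# ---------------------------------------------------------------------------
# traces

def _handle_nan(name: str, values: np.ndarray, nan_policy: str) -> np.ndarray:
    """Strict policy errors on any NaN; lenient interpolates runs of <= 3."""
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size == 0:
        return values
    if nan_policy == "strict":
        raise ValidationError(f"{name} channel contains NaN at sample index {bad[0]}")
    if nan_policy != "lenient":
        raise ValueError(f"unknown nan_policy {nan_policy!r}")
    # find runs of consecutive bad samples
    splits = np.split(bad, np.flatnonzero(np.diff(bad) > 1) + 1)
    if any(len(run) > 3 for run in splits) or bad[0] == 0 or bad[-1] == len(values) - 1:
        raise ValidationError(
            f"{name} channel has a NaN run longer than 3 samples or at an edge"
        )
    out = values.copy()
    good = np.flatnonzero(np.isfinite(values))
    out[bad] = np.interp(bad, good, values[good])
    return out


def read_trace(path: str | Path, nan_policy: str = "strict") -> RawPhotometry:
    """Load a two-channel photometry trace from an ``.npz`` container."""
    with np.load(Path(path), allow_pickle=False) as data:
        rate = float(data["rate"])
        if rate <= 0:
            raise ValidationError("sampling rate must be positive")
        time = np.asarray(data["time"], dtype=float)
        signal = _handle_nan("signal", np.asarray(data["signal"], dtype=float), nan_policy)
        reference = _handle_nan(
            "reference", np.asarray(data["reference"], dtype=float), nan_policy
        )
    if len(signal) != len(reference):
        raise ValidationError("channel length mismatch")
    return RawPhotometry(time, signal, reference, rate)


def write_trace(trace: RawPhotometry, path: str | Path) -> None:
    np.savez(
        Path(path),
        time=trace.time,
        signal=trace.signal,
        reference=trace.reference,
        rate=np.asarray(trace.rate),
    )


def read_cell_matrix(path: str | Path):
    """Load a per-neuron calcium matrix (see :mod:`boutwise.cells`)."""
    from .cells import CellMatrix

    with np.load(Path(path), allow_pickle=False) as data:
        return CellMatrix(
            cell_ids=tuple(str(c) for c in data["cell_ids"]),
            traces=np.asarray(data["traces"], dtype=float),
            time=np.asarray(data["time"], dtype=float),
            rate=float(data["rate"]),
        )


def write_cell_matrix(cells, path: str | Path) -> None:
    np.savez(
        Path(path),
        cell_ids=np.asarray(cells.cell_ids, dtype=str),
        traces=cells.traces,
        time=cells.time,
        rate=np.asarray(cells.rate),
    )


# ---------------------------------------------------------------------------
# protocols

def read_protocol(path: str | Path) -> SessionProtocol:
    access: list[AccessEpoch] = []
    infusions: list[InfusionEpoch] = []
    injections: list[Injection] = []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#") or not row[0].strip():
                continue
            if header is None:
                header = [c.strip() for c in row]
                if header[:5] != ["kind", "start_s", "end_s", "name", "value"]:
                    raise ValidationError(
                        f"{path}:{lineno}: expected header kind,start_s,end_s,name,value"
                    )
                continue
            kind, start_s, end_s, name, value = (c.strip() for c in row[:5])
            if kind == "access":
                access.append(AccessEpoch(float(start_s), float(end_s), name, float(value)))
            elif kind == "infusion":
                infusions.append(InfusionEpoch(float(start_s), float(end_s), float(value), name))
            elif kind == "injection":
                injections.append(Injection(float(start_s), name))
            else:
                raise ValidationError(f"{path}:{lineno}: unknown protocol kind {kind!r}")
    return SessionProtocol(tuple(access), tuple(infusions), tuple(injections))


def write_protocol(protocol: SessionProtocol, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "start_s", "end_s", "name", "value"])
        for e in protocol.access_epochs:
            writer.writerow(["access", repr(e.start), repr(e.end), e.tastant, repr(e.caloric_density)])
        for e in protocol.infusion_epochs:
            writer.writerow(["infusion", repr(e.start), repr(e.end), e.solution, repr(e.rate)])
        for inj in protocol.injections:
            writer.writerow(["injection", repr(inj.time), "", inj.compound, ""])
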