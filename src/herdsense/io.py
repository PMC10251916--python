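"""Reading, validating and writing labelled accelerometer traces.

A trace is one cow's time-ordered stream of 5 Hz tri-axial acceleration
samples, each carrying a behaviour label assigned by a human observer.
The on-disk format is a headered CSV; the column names are configurable
through :class:`CsvDialect` to absorb different logger export dialects,
including the composite ``date,h,min,s,hundredths`` timestamp layout
produced by MSR dataloggers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: The five behaviour classes the classifier distinguishes, in the fixed
#: order used everywhere downstream (feature tensors, confusion matrices).
CLASSES: tuple[str, ...] = (
    "feeding", "moving", "resting", "ruminating", "standing_still")

#: Label for observation spans where the observers could not decide;
#: excluded before modelling, never a model class.
UNCLEAR = "unclear"

#: Nominal sampling interval in seconds (5 Hz).
NOMINAL_PERIOD = 0.2


class ConfigError(ValueError):
    """A column mapping or option does not match the input file."""


class DataIntegrityError(ValueError):
    """The file violates a structural invariant (e.g. time order)."""


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for trace CSV files.

    ``timestamp`` names a single numeric column of seconds.  If
    ``composite_time`` is set, it names (date, hour, minute, second,
    hundredths) columns instead and ``timestamp`` is ignored on read.
    """

    timestamp: str = "timestamp"
    ax: str = "ax"
    ay: str = "ay"
    az: str = "az"
    behaviour: str = "behaviour"
    composite_time: tuple[str, str, str, str, str] | None = None


DEFAULT_DIALECT = CsvDialect()


@dataclass
class LabelledTrace:
    """Time-ordered labelled samples for one cow.

    Attributes
    ----------
    cow_id : str
        Animal identifier.
    t : ndarray of float, shape (n,)
        Timestamps in seconds, strictly increasing, 0.01 s resolution.
    xyz : ndarray of float, shape (n, 3)
        Acceleration on the X (vertical), Y (parallel to ground) and
        Z (orthogonal to the flank) axes, in g-equivalents as read.
    labels : ndarray of str, shape (n,)
        Per-sample behaviour labels.
    meta : dict
        Bookkeeping (e.g. count of skipped unparseable rows).
    """

    cow_id: str
    t: np.ndarray
    xyz: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.xyz) == len(self.labels)):
            raise ValueError("t, xyz and labels must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            i = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise DataIntegrityError(
                f"timestamps not strictly increasing at row {i}")

    def slice(self, start: int, stop: int) -> "LabelledTrace":
        return LabelledTrace(self.cow_id, self.t[start:stop],
                             self.xyz[start:stop], self.labels[start:stop])


@dataclass(frozen=True)
class Run:
    """A maximal span with one behaviour and no internal recording gap.

    ``start``/``stop`` are half-open sample indices into the trace.
    """

    behaviour: str
    start: int
    stop: int

    def __len__(self) -> int:
        return self.stop - self.start


def read_trace(path, dialect: CsvDialect = DEFAULT_DIALECT,
               cow_id: str | None = None) -> LabelledTrace:
    """Read a labelled trace from CSV.

    Rows whose acceleration values fail numeric parsing are logged and
    skipped (their count is reported in ``trace.meta['n_bad_rows']``);
    a missing configured column raises :class:`ConfigError` and
    non-monotone timestamps raise :class:`DataIntegrityError`.
    """
    df = pd.read_csv(path)
    needed = [dialect.ax, dialect.ay, dialect.az, dialect.behaviour]
    needed += (list(dialect.composite_time) if dialect.composite_time
               else [dialect.timestamp])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: configured columns missing from file: {missing}")

    if dialect.composite_time:
        d, h, m, s, c = dialect.composite_time
        day = pd.to_datetime(df[d], errors="coerce")
        secs = (day - day.min()).dt.total_seconds()
        for col, scale in ((h, 3600.0), (m, 60.0), (s, 1.0), (c, 0.01)):
            secs = secs + pd.to_numeric(df[col], errors="coerce") * scale
        t = secs.to_numpy(dtype=float)
    else:
        t = pd.to_numeric(df[dialect.timestamp],
                          errors="coerce").to_numpy(dtype=float)

    xyz = np.column_stack([
        pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        for c in (dialect.ax, dialect.ay, dialect.az)])
    ok = np.isfinite(t) & np.isfinite(xyz).all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        bad_rows = np.flatnonzero(~ok)[:10] + 2  # 1-based incl. header
        log.warning("%s: skipped %d unparseable rows (first at lines %s)",
                    path, n_bad, list(bad_rows))
    labels = df[dialect.behaviour].astype(str).str.strip().to_numpy()
    trace = LabelledTrace(
        cow_id=cow_id or str(path),
        t=np.round(t[ok], 2), xyz=xyz[ok], labels=labels[ok],
        meta={"n_bad_rows": n_bad, "source": str(path)})
    return trace


def write_trace(trace: LabelledTrace, path,
                dialect: CsvDialect = DEFAULT_DIALECT) -> None:
    """Write a trace in the single-timestamp-column CSV dialect."""
    df = pd.DataFrame({
        dialect.timestamp: np.round(trace.t, 2),
        dialect.ax: trace.xyz[:, 0],
        dialect.ay: trace.xyz[:, 1],
        dialect.az: trace.xyz[:, 2],
        dialect.behaviour: trace.labels,
    })
    df.to_csv(path, index=False, float_format="%.6g")


def drop_unclear(trace: LabelledTrace) -> LabelledTrace:
    """Remove samples labelled ``unclear``, preserving order.

    Idempotent; an all-unclear trace yields a valid empty trace.
    """
    keep = trace.labels != UNCLEAR
    out = LabelledTrace(trace.cow_id, trace.t[keep], trace.xyz[keep],
                        trace.labels[keep], dict(trace.meta))
    out.meta["n_unclear_dropped"] = int((~keep).sum()) + \
        trace.meta.get("n_unclear_dropped", 0)
    return out


def contiguous_runs(trace: LabelledTrace, gap_factor: float = 1.5,
                    period: float = NOMINAL_PERIOD) -> list[Run]:
    """Partition a cleaned trace into label-contiguous, gap-free runs.

    A new run starts whenever the behaviour label changes or the
    inter-sample gap exceeds ``gap_factor`` times the nominal sampling
    period (samples dropped by cleaning leave such gaps; windows must
    never bridge them).
    """
    n = len(trace)
    if n == 0:
        return []
    label_change = trace.labels[1:] != trace.labels[:-1]
    time_gap = np.diff(trace.t) > gap_factor * period
    breaks = np.flatnonzero(label_change | time_gap) + 1
    bounds = np.concatenate([[0], breaks, [n]])
    return [Run(str(trace.labels[a]), int(a), int(b))
            for a, b in zip(bounds[:-1], bounds[1:])]


def validate_labels(trace: LabelledTrace, allow_unclear: bool = True) -> None:
    """Raise if the trace carries labels outside the vocabulary."""
    allowed = set(CLASSES) | ({UNCLEAR} if allow_unclear else set())
    bad = sorted(set(trace.labels) - allowed)
    if bad:
        raise DataIntegrityError(f"unknown behaviour labels: {bad}")
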