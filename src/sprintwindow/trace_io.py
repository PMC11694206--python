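"""Read, validate and write 10 Hz match speed traces.

A *speed trace* is one player's record for one match: time in integer
milliseconds since session start and instantaneous speed in km/h, nominally
sampled on a 100 ms grid (10 Hz) by a wearable GNSS unit.  Every downstream
stage (noise filtering, peak detection, peri-peak windowing) assumes this
grid, so this module is where the contract is enforced:

* timestamps are strictly increasing — out-of-order rows are rejected, never
  silently sorted;
* consecutive samples are 100 ms apart within a ±10 ms jitter tolerance;
  larger deviations are *gaps*, which are reported, never interpolated;
* a sample whose speed has been excluded upstream (e.g. an implausible GNSS
  spike) is stored as NaN and written to disk as an empty field, so filtered
  traces round-trip losslessly.

File dialect: comma-separated UTF-8 with header ``t_ms,v_kmh``; session
metadata is a separate CSV with header ``player_id,match_id,position``.
Position codes come from the closed five-element set used for outfield
football players: central defender (CD), fullback (FB), central midfielder
(CM), wide midfielder (WM), forward (FW).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import MetadataError, TraceFormatError, TraceIntegrityError

#: Closed set of outfield playing-position codes.
POSITIONS: tuple[str, ...] = ("CD", "FB", "CM", "WM", "FW")

#: Nominal inter-sample spacing of the 10 Hz grid, in milliseconds.
GRID_MS: int = 100

#: Deviation from the nominal spacing tolerated as device jitter, in ms.
#: Anything larger counts as a gap.
JITTER_MS: int = 10

TRACE_COLUMNS = ("t_ms", "v_kmh")
METADATA_COLUMNS = ("player_id", "match_id", "position")


@dataclass
class SessionRecord:
    """One player-match entry of the session metadata table."""

    player_id: str
    match_id: str
    position: str

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise MetadataError(
                f"unknown position code {self.position!r}; "
                f"expected one of {POSITIONS}"
            )


@dataclass
class SpeedTrace:
    """One player-match 10 Hz speed series with its session metadata.

    ``v_kmh`` may contain NaN for samples marked missing (filtered spikes);
    raw traces read from disk are NaN-free unless the file itself has empty
    speed fields.  Timestamps are integer milliseconds from session start.
    """

    player_id: str
    match_id: str
    position: str
    t_ms: np.ndarray
    v_kmh: np.ndarray
    nominal_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.v_kmh = np.asarray(self.v_kmh, dtype=np.float64)
        if self.position not in POSITIONS:
            raise MetadataError(
                f"unknown position code {self.position!r}; "
                f"expected one of {POSITIONS}"
            )
        if self.t_ms.ndim != 1 or self.v_kmh.ndim != 1:
            raise TraceIntegrityError("t_ms and v_kmh must be 1-D")
        if self.t_ms.size != self.v_kmh.size:
            raise TraceIntegrityError("t_ms and v_kmh lengths differ")
        if self.t_ms.size == 0:
            raise TraceIntegrityError("trace is empty")
        if self.t_ms[0] < 0:
            raise TraceIntegrityError("timestamps must be >= 0")
        if np.any(np.diff(self.t_ms) <= 0):
            raise TraceIntegrityError("timestamps are not strictly increasing")
        finite = np.isfinite(self.v_kmh)
        nan = np.isnan(self.v_kmh)
        if np.any(~finite & ~nan):
            raise TraceIntegrityError("speeds must be finite or NaN (missing)")
        if np.any(self.v_kmh[finite] < 0):
            raise TraceIntegrityError("speeds must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.t_ms.size)

    @property
    def duration_s(self) -> float:
        """Span from first to last sample, in seconds."""
        return float(self.t_ms[-1] - self.t_ms[0]) / 1000.0

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of samples marked missing (NaN speed)."""
        return np.isnan(self.v_kmh)

    def with_speeds(self, v_kmh: np.ndarray) -> "SpeedTrace":
        """Copy of this trace with a replacement speed vector."""
        return replace(self, v_kmh=np.asarray(v_kmh, dtype=np.float64))


@dataclass
class GridReport:
    """Result of checking a trace against the nominal 100 ms grid."""

    n_samples: int
    n_gaps: int
    gap_indices: np.ndarray = field(repr=False)  # i: gap between samples i, i+1
    max_jitter_ms: int
    effective_rate_hz: float


def validate_grid(trace: SpeedTrace) -> GridReport:
    """Report deviations of a trace's time stamps from the 10 Hz grid.

    A *gap* is an inter-sample interval outside ``GRID_MS ± JITTER_MS``;
    ``max_jitter_ms`` is the largest deviation among the non-gap intervals.
    The effective rate is ``(n - 1) / span`` in Hz.  Reporting only — a
    gappy trace is not an error at this layer.
    """
    dt = np.diff(trace.t_ms)
    dev = np.abs(dt - GRID_MS)
    gap_mask = dev > JITTER_MS
    gap_indices = np.flatnonzero(gap_mask)
    max_jitter = int(dev[~gap_mask].max()) if np.any(~gap_mask) else 0
    span_s = trace.duration_s
    rate = (trace.n_samples - 1) / span_s if span_s > 0 else float("nan")
    return GridReport(
        n_samples=trace.n_samples,
        n_gaps=int(gap_indices.size),
        gap_indices=gap_indices,
        max_jitter_ms=max_jitter,
        effective_rate_hz=rate,
    )


def read_trace(path: str | Path | io.TextIOBase, metadata: SessionRecord) -> SpeedTrace:
    """Parse a ``t_ms,v_kmh`` CSV into a validated :class:`SpeedTrace`.

    Rows out of time order are rejected (integrity error), not sorted:
    re-ordering would silently hide an export problem upstream.
    Empty speed fields become NaN (missing sample).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"cannot parse trace CSV: {exc}") from exc
    missing_cols = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TraceFormatError(
            f"trace CSV is missing column(s) {missing_cols}; header must "
            f"name {list(TRACE_COLUMNS)}"
        )
    t = df["t_ms"].to_numpy()
    if np.any(pd.isna(t)):
        raise TraceIntegrityError("t_ms column contains empty values")
    if not np.all(np.equal(np.mod(t, 1), 0)):
        raise TraceIntegrityError("t_ms must be integer milliseconds")
    return SpeedTrace(
        player_id=metadata.player_id,
        match_id=metadata.match_id,
        position=metadata.position,
        t_ms=t.astype(np.int64),
        v_kmh=df["v_kmh"].to_numpy(dtype=np.float64),
    )


def write_trace(trace: SpeedTrace, path: str | Path) -> None:
    """Write a trace in the canonical dialect; NaN speeds become empty fields.

    Speeds are written with ``repr`` precision so that write→read is
    bit-identical on float64 values.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for t, v in zip(trace.t_ms, trace.v_kmh):
            fh.write(f"{int(t)},{'' if np.isnan(v) else repr(float(v))}\n")


def read_metadata(path: str | Path | io.TextIOBase) -> list[SessionRecord]:
    """Parse the ``player_id,match_id,position`` session table."""
    try:
        df = pd.read_csv(path, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"cannot parse metadata CSV: {exc}") from exc
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TraceFormatError(
            f"metadata CSV is missing column(s) {missing_cols}"
        )
    records = [
        SessionRecord(row.player_id, row.match_id, row.position)
        for row in df.itertuples(index=False)
    ]
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.player_id, rec.match_id)
        if key in seen:
            raise MetadataError(f"duplicate player-match entry {key}")
        seen.add(key)
    return records


def write_metadata(records: Iterable[SessionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(METADATA_COLUMNS) + "\n")
        for rec in records:
            fh.write(f"{rec.player_id},{rec.match_id},{rec.position}\n")


def trace_filename(player_id: str, match_id: str) -> str:
    """Canonical file name for one player-match trace."""
    return f"{player_id}_{match_id}.csv"


def read_cohort(traces_dir: str | Path, metadata_path: str | Path) -> list[SpeedTrace]:
    """Read every trace listed in a metadata table from a directory."""
    traces_dir = Path(traces_dir)
    records = read_metadata(metadata_path)
    traces = []
    for rec in records:
        path = traces_dir / trace_filename(rec.player_id, rec.match_id)
        if not path.exists():
            raise TraceFormatError(f"trace file not found: {path}")
        traces.append(read_trace(path, rec))
    return traces
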