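"""Noise filtering, sprint-bout segmentation and match-peak-speed validation.

Raw 10 Hz GNSS speed feeds contain occasional implausible spikes, so the
highest raw sample of a match cannot be trusted as the player's match peak
speed.  The validation scheme implemented here works on the raw (untreated)
speed series:

1. samples faster than a physiological cap (default 44.45 km/h, beyond any
   recorded human running speed) are marked missing;
2. the match peak speed is the fastest *corroborated* candidate: a candidate
   peak is only accepted if another effort reached within a margin (default
   1 km/h) of it elsewhere in the same match — e.g. 32.7 km/h is a valid
   peak only if some other effort reached >= 31.7 km/h;
3. the peak must exceed the sprint threshold (default > 25.2 km/h).

"Another effort" is operationalized as a corroborating sample at or above
(candidate − margin) lying outside the candidate's own contiguous run above
that level, i.e. the speed must drop below (candidate − margin) somewhere
between the two.  This is the weakest reading that excludes samples of the
same sprint without imposing an arbitrary time gap.  If the global maximum
fails corroboration it is demoted and the next-highest bout maximum is
tested with the margin recomputed for that candidate, so a single spurious
(sub-cap) spike cannot void a whole player-match.

Sprints are additionally typed as *explosive* (sprint threshold reached
without passing through the high-speed-running band, 19.8–25.2 km/h, during
the preceding 0.5 s) or *leading* (reached via the band).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError, SprintWindowError
from .trace_io import SpeedTrace


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds governing noise filtering and peak validation.

    All speeds in km/h.  Defaults are the conventional elite-football values:
    sprint threshold 25.2 km/h (7 m/s), high-speed running 19.8–25.2 km/h
    (5.5–7 m/s), implausible-speed cap 44.45 km/h.
    """

    v_cap_kmh: float = 44.45
    sprint_threshold_kmh: float = 25.2
    hsr_band_kmh: tuple[float, float] = (19.8, 25.2)
    corroboration_margin_kmh: float = 1.0
    lookback_s: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.hsr_band_kmh
        if not (self.v_cap_kmh > self.sprint_threshold_kmh > lo > 0):
            raise ConfigError(
                "expected v_cap > sprint_threshold > HSR lower bound > 0, got "
                f"{self.v_cap_kmh} / {self.sprint_threshold_kmh} / {lo}"
            )
        if hi < lo:
            raise ConfigError("HSR band upper bound below lower bound")
        if self.corroboration_margin_kmh <= 0:
            raise ConfigError("corroboration margin must be > 0")
        if self.lookback_s <= 0:
            raise ConfigError("lookback must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        """Load from JSON or ``key=value`` lines; unknown keys rejected."""
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = json.loads(value.strip())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown filter config key(s): {sorted(unknown)}")
        if "hsr_band_kmh" in data:
            data["hsr_band_kmh"] = tuple(data["hsr_band_kmh"])
        return cls(**data)


@dataclass
class FilterResult:
    """A spike-filtered trace plus an account of what was removed."""

    trace: SpeedTrace
    n_removed: int
    removed_indices: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class Bout:
    """Maximal contiguous run of samples at or above a threshold."""

    start: int  # first sample index (inclusive)
    end: int  # last sample index (inclusive)
    v_max_kmh: float
    t_max_ms: int
    i_max: int  # index of the (first) maximal sample


@dataclass(frozen=True)
class PeakEvent:
    """A validated match peak speed with its corroborating evidence."""

    peak_kmh: float
    t_peak_ms: int
    i_peak: int
    corroborating_kmh: float
    corroborating_t_ms: int
    i_corroborating: int
    candidate_rank: int  # 1 = the global post-filter maximum
    above_sprint_threshold: bool = True
    corroborated: bool = True


def filter_speeds(trace: SpeedTrace, cfg: FilterConfig) -> FilterResult:
    """Mark implausibly fast samples (> cap) as missing.

    Removed samples become NaN, never interpolated: fabricating a value
    where the device glitched could fabricate a peak.
    """
    with np.errstate(invalid="ignore"):
        spikes = trace.v_kmh > cfg.v_cap_kmh
    removed = np.flatnonzero(spikes)
    v = trace.v_kmh.copy()
    v[removed] = np.nan
    return FilterResult(
        trace=trace.with_speeds(v),
        n_removed=int(removed.size),
        removed_indices=removed,
    )


def segment_bouts(trace: SpeedTrace, threshold_kmh: float) -> list[Bout]:
    """Split a trace into maximal contiguous runs of samples >= threshold.

    Missing (NaN) samples never belong to a bout, so a filtered spike splits
    a run.  Bouts are returned in time order; the list is empty if no sample
    reaches the threshold.
    """
    with np.errstate(invalid="ignore"):
        above = trace.v_kmh >= threshold_kmh  # NaN compares False
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    bouts = []
    for s, e in zip(idx[starts], idx[ends]):
        seg = trace.v_kmh[s : e + 1]
        local = int(np.nanargmax(seg))
        bouts.append(
            Bout(
                start=int(s),
                end=int(e),
                v_max_kmh=float(seg[local]),
                t_max_ms=int(trace.t_ms[s + local]),
                i_max=s + local,
            )
        )
    return bouts


def _contiguous_run(above: np.ndarray, i: int) -> tuple[int, int]:
    """Bounds (inclusive) of the True-run of ``above`` containing index i."""
    lo = i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    return lo, hi


def find_match_peak(trace: SpeedTrace, cfg: FilterConfig) -> Optional[PeakEvent]:
    """Identify the valid match peak speed, or ``None`` if no candidate holds.

    Candidates are the sprint-bout maxima in descending order of speed
    (ties broken by earlier occurrence).  Each candidate ``c`` is accepted
    iff some sample at or above ``c − margin`` lies outside the candidate's
    own contiguous run above that level.  The corroborating sample is not
    itself required to exceed the sprint threshold.  Run on a spike-filtered
    trace (see :func:`filter_speeds`).
    """
    bouts = segment_bouts(trace, cfg.sprint_threshold_kmh)
    candidates = [b for b in bouts if b.v_max_kmh > cfg.sprint_threshold_kmh]
    candidates.sort(key=lambda b: (-b.v_max_kmh, b.t_max_ms))
    v = trace.v_kmh
    for rank, cand in enumerate(candidates, start=1):
        # tiny slack so decimal speeds exactly at the margin boundary
        # (e.g. a 31.7 witness for a 32.7 candidate at margin 1.0) are not
        # lost to binary float representation
        level = cand.v_max_kmh - cfg.corroboration_margin_kmh - 1e-9
        with np.errstate(invalid="ignore"):
            above = v >= level
        lo, hi = _contiguous_run(above, cand.i_max)
        outside = above.copy()
        outside[lo : hi + 1] = False
        witnesses = np.flatnonzero(outside)
        if witnesses.size == 0:
            continue
        # report the fastest corroborating sample (earliest on ties)
        j = int(witnesses[np.argmax(v[witnesses])])
        return PeakEvent(
            peak_kmh=cand.v_max_kmh,
            t_peak_ms=cand.t_max_ms,
            i_peak=cand.i_max,
            corroborating_kmh=float(v[j]),
            corroborating_t_ms=int(trace.t_ms[j]),
            i_corroborating=j,
            candidate_rank=rank,
        )
    return None


def classify_sprint(trace: SpeedTrace, bout: Bout, cfg: FilterConfig) -> str:
    """Type a sprint bout as ``"explosive"`` or ``"leading"``.

    Explosive: the sprint threshold was reached without any sample in the
    high-speed-running band during the preceding ``lookback_s`` (default
    0.5 s, i.e. the 5 samples before the first super-threshold sample).
    Leading: the band was passed through.
    """
    seg = trace.v_kmh[bout.start : bout.end + 1]
    with np.errstate(invalid="ignore"):
        over = seg > cfg.sprint_threshold_kmh
    if not np.any(over):
        raise SprintWindowError(
            "bout never exceeds the sprint threshold; cannot classify"
        )
    i_first = bout.start + int(np.argmax(over))
    t_first = trace.t_ms[i_first]
    lookback_ms = round(cfg.lookback_s * 1000)
    window = (trace.t_ms >= t_first - lookback_ms) & (trace.t_ms < t_first)
    lo, hi = cfg.hsr_band_kmh
    vals = trace.v_kmh[window]
    with np.errstate(invalid="ignore"):
        in_band = (vals >= lo) & (vals <= hi)
    return "leading" if np.any(in_band) else "explosive"
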