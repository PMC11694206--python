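"""Peri-peak window extraction and per-second reduction.

The unit of analysis is the 20-second window centred on one match peak
speed: 10 s before to 10 s after, on the trace's own 100 ms grid, giving
exactly 201 slots at deci-second offsets −100..+100 (slot 0 = the peak
sample).  Slots falling outside the trace, in a timing gap, or on a
filtered sample are retained as *missing* rather than dropped or
interpolated — a window near the final whistle is simply truncated, and
per-interval statistics later use whatever n is available at each offset.

The window is reduced to 21 per-second values (offsets −10..+10 s).  The
default reduction is the *instantaneous* sample at each integer-second
offset; a *block-mean* alternative averages the 10 slots of each second,
sign-symmetrically about the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peak_detection import PeakEvent
from .trace_io import GRID_MS, JITTER_MS, SpeedTrace

#: Window half-width in deci-seconds (slots), i.e. 10 s at 10 Hz.
HALF_WIDTH_DS: int = 100

#: Total number of window slots: −100..+100 inclusive.
N_SLOTS: int = 2 * HALF_WIDTH_DS + 1

#: Per-second profile offsets, in seconds.
PROFILE_OFFSETS: tuple[int, ...] = tuple(range(-10, 11))


@dataclass
class PeakWindow:
    """201-slot peri-peak speed vector for one player-match.

    ``speeds[k]`` holds the sample nearest to ``t_peak + 100·(k−100) ms``
    (within the grid jitter tolerance); ``missing[k]`` is True where no such
    sample exists or the sample was filtered.
    """

    player_id: str
    match_id: str
    position: str
    peak: PeakEvent
    offsets_ds: np.ndarray = field(repr=False)  # −100..+100
    speeds_kmh: np.ndarray = field(repr=False)
    missing: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.speeds_kmh.size != N_SLOTS or self.missing.size != N_SLOTS:
            raise ValueError(f"a peak window has exactly {N_SLOTS} slots")

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    @property
    def truncated(self) -> bool:
        """True if any slot is missing (boundary, gap or filtered sample)."""
        return bool(self.missing.any())


@dataclass
class PerSecondProfile:
    """Speeds at the 21 integer-second offsets of one window (0 = peak)."""

    player_id: str
    match_id: str
    position: str
    values_kmh: np.ndarray = field(repr=False)  # length 21, NaN where unavailable
    available: np.ndarray = field(repr=False)
    mode: str = "instant"

    def value(self, offset_s: int) -> float:
        """Speed at an integer-second offset (NaN if unavailable)."""
        return float(self.values_kmh[offset_s + 10])

    def is_available(self, offset_s: int) -> bool:
        return bool(self.available[offset_s + 10])


def extract_window(trace: SpeedTrace, peak: PeakEvent) -> PeakWindow:
    """Extract the 20 s window around a validated peak.

    Slot k holds the sample whose timestamp is nearest to
    ``t_peak + 100·k ms`` within ±10 ms; no resampling is performed, so the
    window inherits the trace's own grid anchored at the peak sample.
    Always returns 201 slots; unmatched slots are missing.
    """
    targets = peak.t_peak_ms + GRID_MS * np.arange(-HALF_WIDTH_DS, HALF_WIDTH_DS + 1)
    t = trace.t_ms
    pos = np.searchsorted(t, targets)
    left = np.clip(pos - 1, 0, t.size - 1)
    right = np.clip(pos, 0, t.size - 1)
    d_left = np.abs(t[left] - targets)
    d_right = np.abs(t[right] - targets)
    nearest = np.where(d_right <= d_left, right, left)
    matched = np.abs(t[nearest] - targets) <= JITTER_MS
    speeds = np.where(matched, trace.v_kmh[nearest], np.nan)
    missing = ~matched | np.isnan(speeds)
    speeds = np.where(missing, np.nan, speeds)
    return PeakWindow(
        player_id=trace.player_id,
        match_id=trace.match_id,
        position=trace.position,
        peak=peak,
        offsets_ds=np.arange(-HALF_WIDTH_DS, HALF_WIDTH_DS + 1),
        speeds_kmh=speeds,
        missing=missing,
    )


def per_second_profile(window: PeakWindow, mode: str = "instant") -> PerSecondProfile:
    """Reduce a window to its 21 per-second values.

    ``mode="instant"`` (default): the value at offset k seconds is the
    single slot at 10·k deci-seconds.  ``mode="block_mean"``: the mean of
    the 10 slots of that second, taken sign-symmetrically about the peak —
    for k > 0 the slots in (k−1, k] s, for k < 0 the mirror image, and for
    k = 0 the peak slot alone; the mean is over the non-missing slots of
    the block and the offset is unavailable only if the whole block is
    missing.  Both modes agree exactly on constant windows.
    """
    values = np.full(len(PROFILE_OFFSETS), np.nan)
    if mode == "instant":
        slots = HALF_WIDTH_DS + 10 * np.asarray(PROFILE_OFFSETS)
        values = window.speeds_kmh[slots].copy()
    elif mode == "block_mean":
        for i, k in enumerate(PROFILE_OFFSETS):
            if k == 0:
                block = window.speeds_kmh[HALF_WIDTH_DS : HALF_WIDTH_DS + 1]
            elif k > 0:
                a = HALF_WIDTH_DS + 10 * (k - 1) + 1
                block = window.speeds_kmh[a : a + 10]
            else:
                a = HALF_WIDTH_DS + 10 * k
                block = window.speeds_kmh[a : a + 10]
            if np.any(~np.isnan(block)):
                values[i] = np.nanmean(block)
    else:
        raise ValueError(f"unknown per-second mode {mode!r}")
    return PerSecondProfile(
        player_id=window.player_id,
        match_id=window.match_id,
        position=window.position,
        values_kmh=values,
        available=~np.isnan(values),
        mode=mode,
    )


def speed_changes_01s(window: PeakWindow) -> np.ndarray:
    """The 200 consecutive 0.1 s speed deltas of a window.

    ``delta[j] = speed[j+1] − speed[j]``; NaN where either slot is missing.
    On a gap-free window the deltas telescope to
    ``speed(+10 s) − speed(−10 s)``.
    """
    return np.diff(window.speeds_kmh)
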