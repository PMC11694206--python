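"""Seeded synthetic 10 Hz match speed traces with ground truth.

The study conditions this generator emulates — since real club GNSS data
are proprietary — are ~90-minute outfield traces of intermittent
locomotion, punctuated by a handful of sprints reached from flying starts
(~5–10 km/h ten seconds before the peak), with position-dependent peak
speeds around 29–32 km/h, deceleration faster than acceleration after the
peak (but no full stop), autocorrelated GNSS observation noise, occasional
implausible spike artifacts (> 44.45 km/h) and, optionally, timing gaps.

Model, in three layers:

1. **baseline** — a semi-Markov locomotor state process (stand / walk /
   jog / run) with geometric dwell times on the 0.1 s grid, smoothed with a
   short moving average to emulate inertia;
2. **sprint events** — mono-exponential speed profiles overlaid on the
   baseline: a rise from the flying-start speed to the target peak over
   ``rise_s`` seconds with time constant ``tau_acc_s`` (normalized so the
   peak sample attains the target exactly), then a decay toward a non-zero
   floor with the faster constant ``tau_dec_s``;  one event carries the
   match peak and a second event is placed within the corroboration margin
   below it so the peak-validity rule holds by construction;
3. **observation layer** — AR(1) Gaussian noise (GNSS Doppler speed noise
   is autocorrelated, not white), spike artifacts and gap deletions.

Everything is driven by one :class:`numpy.random.Generator`; the same seed
reproduces a trace bit-for-bit.  Cohort generation derives per-trace seeds
by hashing (master seed, player, match), so regenerating a cohort is stable
under roster edits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal

from . import reference
from .errors import ConfigError
from .trace_io import (
    POSITIONS,
    SessionRecord,
    SpeedTrace,
    trace_filename,
    write_metadata,
    write_trace,
)


@dataclass(frozen=True)
class LocomotorState:
    """One baseline locomotion mode: a mean speed and a mean dwell time."""

    name: str
    mean_kmh: float
    dwell_mean_s: float
    weight: float  # relative propensity when choosing the next state


#: Default intermittent-locomotion repertoire.  Mean speeds stay below the
#: high-speed-running band so only injected sprint events can produce peaks.
DEFAULT_STATES: tuple[LocomotorState, ...] = (
    LocomotorState("stand", 0.3, 4.0, 0.25),
    LocomotorState("walk", 4.5, 6.0, 0.35),
    LocomotorState("jog", 9.0, 5.0, 0.30),
    LocomotorState("run", 14.5, 3.0, 0.10),
)


@dataclass
class SimConfig:
    """Full parameterization of the synthetic match generator.

    Defaults are the emulated study conditions: 90-minute traces at 10 Hz,
    per-position peak-speed targets from the published per-position peak
    means/SDs, flying starts around 9 km/h, a ~5 s acceleration with
    ``tau_acc_s`` = 1.5 s and a faster deceleration (``tau_dec_s`` = 0.9 s)
    to a ~7 km/h floor, 0.25 km/h AR(1) observation noise and on average
    two implausible spikes per trace.  Gap injection is off by default.
    """

    duration_s: float = 5400.0
    rate_hz: float = 10.0
    states: tuple[LocomotorState, ...] = DEFAULT_STATES
    n_sprints: int = 5
    peak_targets_kmh: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(reference.PEAK_SPEEDS)
    )
    flying_start_mean_kmh: float = 9.0
    flying_start_sd_kmh: float = 2.0
    rise_s: float = 5.0
    decay_s: float = 5.0
    tau_acc_s: float = 1.5
    tau_dec_s: float = 0.9
    post_sprint_floor_kmh: float = 7.0
    noise_sd_kmh: float = 0.25
    noise_ar1_rho: float = 0.85
    spike_rate_per_trace: float = 2.0
    spike_range_kmh: tuple[float, float] = (45.0, 60.0)
    gap_rate_per_trace: float = 0.0
    gap_max_samples: int = 20

    def __post_init__(self) -> None:
        if not self.tau_dec_s < self.tau_acc_s:
            raise ConfigError(
                "deceleration must be faster than acceleration "
                f"(tau_dec {self.tau_dec_s} >= tau_acc {self.tau_acc_s})"
            )
        if min(self.tau_dec_s, self.tau_acc_s) <= 0:
            raise ConfigError("time constants must be positive")
        if self.noise_sd_kmh < 0 or self.flying_start_sd_kmh < 0:
            raise ConfigError("SDs must be >= 0")
        if not 0 <= self.noise_ar1_rho < 1:
            raise ConfigError("AR(1) rho must be in [0, 1)")
        for pos, (mean, sd) in self.peak_targets_kmh.items():
            if mean <= 25.2:
                raise ConfigError(
                    f"peak target for {pos} must exceed the 25.2 km/h sprint "
                    f"threshold, got {mean}"
                )
            if sd < 0:
                raise ConfigError("peak target SD must be >= 0")
        if self.n_sprints < 2:
            raise ConfigError(
                "need >= 2 sprint events (the match peak and its corroborating effort)"
            )
        if self.spike_range_kmh[0] <= 44.45:
            raise ConfigError("spike magnitudes must exceed the 44.45 km/h cap")
        if self.duration_s < 2 * self.n_sprints * (self.rise_s + self.decay_s + 30):
            raise ConfigError("trace too short for the requested sprint count")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load overrides from a JSON object; unknown keys rejected."""
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown simulator config key(s): {sorted(unknown)}")
        if "states" in data:
            data["states"] = tuple(LocomotorState(**s) for s in data["states"])
        if "peak_targets_kmh" in data:
            data["peak_targets_kmh"] = {
                k: tuple(v) for k, v in data["peak_targets_kmh"].items()
            }
        if "spike_range_kmh" in data:
            data["spike_range_kmh"] = tuple(data["spike_range_kmh"])
        return cls(**data)


@dataclass
class GroundTruth:
    """What was injected into one simulated trace."""

    position: str
    seed: int
    sprint_t_peak_ms: list[int]
    sprint_peak_kmh: list[float]
    match_peak_kmh: float  # noise-free maximum over injected sprints
    match_peak_t_ms: int
    spike_indices: list[int]  # indices into the emitted trace
    gap_spans_ms: list[tuple[int, int]]  # [t_first_removed, t_last_removed]


def _baseline(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Piecewise semi-Markov locomotor baseline, smoothed over ~1.5 s."""
    states = cfg.states
    weights = np.array([s.weight for s in states], dtype=float)
    out = np.empty(n)
    i = 0
    current = int(rng.choice(len(states), p=weights / weights.sum()))
    while i < n:
        st = states[current]
        dwell = int(rng.geometric(1.0 / max(st.dwell_mean_s * cfg.rate_hz, 1.0)))
        j = min(i + dwell, n)
        out[i:j] = st.mean_kmh
        i = j
        w = weights.copy()
        w[current] = 0.0
        current = int(rng.choice(len(states), p=w / w.sum()))
    kernel = np.ones(15) / 15.0
    return np.convolve(out, kernel, mode="same")


def _sprint_profile(
    cfg: SimConfig, v_start: float, v_peak: float
) -> tuple[np.ndarray, int]:
    """Noise-free sprint overlay; returns (profile, index of its peak sample).

    Rise: ``v_start + (v_peak − v_start)·(1 − e^(−t/τ_acc)) / (1 − e^(−T/τ_acc))``
    so the last rise sample equals ``v_peak`` exactly.  Decay: mirrored
    mono-exponential toward the post-sprint floor with the faster
    ``τ_dec``, so the profile never returns to a standstill.
    """
    dt = 1.0 / cfg.rate_hz
    n_rise = int(round(cfg.rise_s * cfg.rate_hz))
    n_decay = int(round(cfg.decay_s * cfg.rate_hz))
    t_rise = np.arange(n_rise + 1) * dt
    norm = 1.0 - np.exp(-cfg.rise_s / cfg.tau_acc_s)
    rise = v_start + (v_peak - v_start) * (1.0 - np.exp(-t_rise / cfg.tau_acc_s)) / norm
    t_dec = np.arange(1, n_decay + 1) * dt
    floor = min(cfg.post_sprint_floor_kmh, v_peak)
    decay = floor + (v_peak - floor) * np.exp(-t_dec / cfg.tau_dec_s)
    return np.concatenate([rise, decay]), n_rise


def _overlay(base: np.ndarray, profile: np.ndarray, start: int, fade: int = 10) -> None:
    """Blend a sprint profile into the baseline with linear cross-fades."""
    n = base.size
    end = start + profile.size  # exclusive
    lo = max(start - fade, 0)
    hi = min(end + fade, n)
    base[start:end] = profile[: max(0, min(end, n) - start)]
    # fade-in from baseline to the profile's first value
    for k, i in enumerate(range(lo, start)):
        w = (k + 1) / (start - lo + 1)
        base[i] = (1 - w) * base[i] + w * profile[0]
    # fade-out from the profile's last value back to baseline
    for k, i in enumerate(range(min(end, n), hi)):
        w = 1.0 - (k + 1) / (hi - end + 1)
        base[i] = (1 - w) * base[i] + w * profile[-1]


def _ar1_noise(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_sd_kmh == 0:
        return np.zeros(n)
    rho = cfg.noise_ar1_rho
    w = rng.normal(0.0, cfg.noise_sd_kmh * np.sqrt(1 - rho**2), n)
    w[0] = rng.normal(0.0, cfg.noise_sd_kmh)  # stationary start
    return signal.lfilter([1.0], [1.0, -rho], w)


def simulate_trace(
    cfg: SimConfig,
    position: str,
    seed: int,
    player_id: str = "P00",
    match_id: str = "M0",
) -> tuple[SpeedTrace, GroundTruth]:
    """Generate one player-match trace plus its ground truth.

    Sprint events are placed in the interiors of equal segments of the
    match so they never overlap and every peri-peak window fits inside the
    trace.  One event carries the match peak (drawn from the position's
    target distribution); a second reaches within the corroboration margin
    below it (0.2–0.7 km/h), guaranteeing a valid peak; the rest stay at
    least 1.2 km/h below so they cannot displace it.
    """
    if position not in POSITIONS:
        raise ConfigError(f"unknown position {position!r}")
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.rate_hz))
    v = _baseline(cfg, n, rng)

    # --- sprint schedule -------------------------------------------------
    pad = int((cfg.rise_s + cfg.decay_s + 12) * cfg.rate_hz)
    seg = n // cfg.n_sprints
    peak_indices = []
    for s in range(cfg.n_sprints):
        lo, hi = s * seg + pad, (s + 1) * seg - pad
        peak_indices.append(int(rng.integers(lo, hi)))

    mean, sd = cfg.peak_targets_kmh[position]
    v_peak = max(float(rng.normal(mean, sd)), 25.5)
    order = rng.permutation(cfg.n_sprints)
    main, corroborator = int(order[0]), int(order[1])
    peaks = np.empty(cfg.n_sprints)
    peaks[main] = v_peak
    peaks[corroborator] = v_peak - float(rng.uniform(0.2, 0.7))
    for s in range(cfg.n_sprints):
        if s not in (main, corroborator):
            peaks[s] = float(rng.uniform(25.5, max(25.6, v_peak - 1.2)))

    n_rise = int(round(cfg.rise_s * cfg.rate_hz))
    sprint_t_ms, sprint_v = [], []
    for s in range(cfg.n_sprints):
        v_start = float(
            np.clip(rng.normal(cfg.flying_start_mean_kmh, cfg.flying_start_sd_kmh),
                    0.5, peaks[s] - 5.0)
        )
        profile, _ = _sprint_profile(cfg, v_start, float(peaks[s]))
        _overlay(v, profile, peak_indices[s] - n_rise)
        sprint_t_ms.append(peak_indices[s] * 100)
        sprint_v.append(float(peaks[s]))

    # --- observation layer ------------------------------------------------
    v = np.clip(v + _ar1_noise(cfg, n, rng), 0.0, None)
    # re-pin the injected peak samples so the noise-free targets are attained
    for idx, val in zip(peak_indices, peaks):
        v[idx] = val

    t_ms = np.arange(n, dtype=np.int64) * 100

    # protected neighbourhoods: sprints (plus their windows) and trace edges
    protected = np.zeros(n, dtype=bool)
    protected[:200] = protected[-200:] = True
    for idx in peak_indices:
        protected[max(idx - 160, 0) : idx + 160] = True

    # --- gap deletions ----------------------------------------------------
    gap_spans: list[tuple[int, int]] = []
    keep = np.ones(n, dtype=bool)
    n_gaps = int(rng.poisson(cfg.gap_rate_per_trace)) if cfg.gap_rate_per_trace > 0 else 0
    taken = protected.copy()
    for _ in range(n_gaps):
        for _attempt in range(100):
            length = int(rng.integers(1, cfg.gap_max_samples + 1))
            start = int(rng.integers(200, n - 200 - length))
            if not taken[start - 2 : start + length + 2].any():
                keep[start : start + length] = False
                taken[start - 2 : start + length + 2] = True
                gap_spans.append((int(t_ms[start]), int(t_ms[start + length - 1])))
                break
    t_ms, v, protected = t_ms[keep], v[keep], protected[keep]

    # --- spike artifacts --------------------------------------------------
    n_spikes = int(rng.poisson(cfg.spike_rate_per_trace)) if cfg.spike_rate_per_trace > 0 else 0
    open_idx = np.flatnonzero(~protected)
    n_spikes = min(n_spikes, open_idx.size)
    spike_indices = sorted(
        int(i) for i in rng.choice(open_idx, size=n_spikes, replace=False)
    )
    for i in spike_indices:
        v[i] = float(rng.uniform(*cfg.spike_range_kmh))

    trace = SpeedTrace(
        player_id=player_id,
        match_id=match_id,
        position=position,
        t_ms=t_ms,
        v_kmh=v,
        nominal_rate_hz=cfg.rate_hz,
    )
    i_best = int(np.argmax(sprint_v))
    truth = GroundTruth(
        position=position,
        seed=seed,
        sprint_t_peak_ms=sprint_t_ms,
        sprint_peak_kmh=sprint_v,
        match_peak_kmh=float(sprint_v[i_best]),
        match_peak_t_ms=int(sprint_t_ms[i_best]),
        spike_indices=spike_indices,
        gap_spans_ms=sorted(gap_spans),
    )
    return trace, truth


def derive_seed(master_seed: int, player_id: str, match_id: str) -> int:
    """Stable 31-bit per-trace seed from the master seed and identifiers."""
    digest = hashlib.sha256(f"{master_seed}|{player_id}|{match_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_cohort(
    cfg: SimConfig,
    roster: Sequence[SessionRecord],
    seed: int,
    out_dir: Optional[str | Path] = None,
) -> list[tuple[SpeedTrace, GroundTruth]]:
    """Simulate one trace per roster entry; optionally write the file set.

    When ``out_dir`` is given, emits one trace CSV per player-match in the
    canonical dialect, a ``metadata.csv`` and a ``ground_truth.json``.
    Regeneration with the same master seed yields an identical file set.
    """
    results = []
    for rec in roster:
        trace_seed = derive_seed(seed, rec.player_id, rec.match_id)
        results.append(
            simulate_trace(
                cfg,
                rec.position,
                trace_seed,
                player_id=rec.player_id,
                match_id=rec.match_id,
            )
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for trace, _truth in results:
            write_trace(trace, out_dir / trace_filename(trace.player_id, trace.match_id))
        write_metadata(roster, out_dir / "metadata.csv")
        truths = {
            trace_filename(t.player_id, t.match_id): asdict(truth)
            for t, truth in results
        }
        (out_dir / "ground_truth.json").write_text(
            json.dumps(truths, indent=1, sort_keys=True), encoding="utf-8"
        )
    return results


def study_roster() -> list[SessionRecord]:
    """Deterministic 90-entry roster reproducing the study's cohort shape.

    20 players (4 CD, 3 FB, 5 CM, 5 WM, 3 FW) over 6 matches would give 120
    player-matches; absences reduce the per-position observation counts to
    (CD 20, FB 10, CM 19, WM 24, FW 17), summing to 90.  Absences are
    spread evenly over each position's player-match slots.
    """
    squads = {"CD": 4, "FB": 3, "CM": 5, "WM": 5, "FW": 3}
    matches = [f"M{m}" for m in range(1, 7)]
    roster: list[SessionRecord] = []
    for pos, n_players in squads.items():
        slots = [
            (f"{pos}{p:02d}", match)
            for p in range(1, n_players + 1)
            for match in matches
        ]
        n_keep = reference.POSITION_COUNTS[pos]
        n_drop = len(slots) - n_keep
        dropped = {(i * len(slots)) // n_drop for i in range(n_drop)} if n_drop else set()
        for i, (player, match) in enumerate(slots):
            if i not in dropped:
                roster.append(SessionRecord(player, match, pos))
    return roster
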