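"""Assemble the analysis products and drive the end-to-end pipeline.

The report mirrors the standard presentation of peri-peak analyses:

* a **position summary** — per position × integer-second offset: mean, SD
  and n of the available window values, with offset 0 the match peak row;
* a **consecutive-interval table** — the 18 paired mean differences with
  effect sizes and magnitude labels;
* a **position-comparison matrix** — pairwise independent mean differences
  between the positions' peak speeds (upper triangle, sign convention:
  difference = column-position mean − row-position mean, so a negative
  value means the row position is faster);
* long-format exports of every retained window and of the 0.1 s speed
  deltas, suitable for plotting;
* run metadata: configuration, per-stage exclusion counters, and the ids
  of player-matches that produced no valid peak.

All outputs are plain CSV plus a JSON sidecar, written deterministically,
so a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .effect_stats import (
    GroupDiff,
    IntervalDiff,
    consecutive_interval_diffs,
    independent_mean_diff,
    interval_diffs_to_frame,
)
from .errors import InsufficientDataError
from .peak_detection import FilterConfig, filter_speeds, find_match_peak
from .trace_io import POSITIONS, SpeedTrace, read_cohort
from .windowing import (
    PeakWindow,
    PerSecondProfile,
    PROFILE_OFFSETS,
    extract_window,
    per_second_profile,
    speed_changes_01s,
)


@dataclass
class AnalysisReport:
    """Everything one pipeline run produces."""

    position_summary: pd.DataFrame
    interval_diffs: list[IntervalDiff]
    position_comparisons: pd.DataFrame
    windows: list[PeakWindow] = field(repr=False)
    profiles: list[PerSecondProfile] = field(repr=False)
    window_long: pd.DataFrame = field(repr=False)
    deltas_long: pd.DataFrame = field(repr=False)
    metadata: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def save(self, out_dir: str | Path) -> None:
        """Write the report as diff-able CSVs plus a JSON run sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary = self.position_summary.copy()
        summary.index = [("peak" if o == 0 else str(o)) for o in summary.index]
        summary.index.name = "offset_s"
        summary.columns = [f"{pos}_{stat}" for pos, stat in summary.columns]
        summary.to_csv(out / "position_summary.csv")
        interval_diffs_to_frame(self.interval_diffs).to_csv(
            out / "interval_diffs.csv", index=False
        )
        self.position_comparisons.to_csv(out / "position_comparisons.csv", index=False)
        self.window_long.to_csv(out / "windows_long.csv", index=False)
        self.deltas_long.to_csv(out / "deltas_01s.csv", index=False)
        (out / "run.json").write_text(
            json.dumps(self.metadata, indent=1, sort_keys=True), encoding="utf-8"
        )


def build_position_summary(
    profiles: Iterable[PerSecondProfile],
    peaks_kmh: Optional[dict[tuple[str, str], float]] = None,
) -> pd.DataFrame:
    """Per position × offset table of mean, SD and n of available values.

    Rows are integer offsets −10..+10 (0 = the match peak row); columns a
    MultiIndex (position, {mean, sd, n}).  Only positions present among the
    profiles get columns.  SD is the sample SD (ddof=1), defined as 0 for a
    single observation.
    """
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("no windows to summarize")
    positions = [p for p in POSITIONS if any(pr.position == p for pr in profiles)]
    cols = pd.MultiIndex.from_product([positions, ("mean", "sd", "n")])
    df = pd.DataFrame(
        index=pd.Index(list(PROFILE_OFFSETS), name="offset_s"), columns=cols, dtype=float
    )
    for pos in positions:
        values = np.vstack(
            [pr.values_kmh for pr in profiles if pr.position == pos]
        )  # (windows, 21)
        for i, off in enumerate(PROFILE_OFFSETS):
            col = values[:, i]
            col = col[~np.isnan(col)]
            n = col.size
            df.loc[off, (pos, "n")] = n
            df.loc[off, (pos, "mean")] = col.mean() if n else np.nan
            df.loc[off, (pos, "sd")] = col.std(ddof=1) if n > 1 else (0.0 if n else np.nan)
    return df


def build_position_comparisons(
    peaks_by_position: dict[str, Sequence[float]],
    conf: float = 0.95,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise independent comparisons of peak speeds between positions.

    One row per ordered upper-triangle pair in canonical position order
    (CD, FB, CM, WM, FW).  Sign convention: ``mean_diff`` is the column
    position's mean minus the row position's, so a negative difference
    means the row position is faster.  Pairs where either group has fewer
    than 2 peaks are marked unavailable rather than dropped.
    """
    positions = [p for p in POSITIONS if p in peaks_by_position]
    rows = []
    for i, row_pos in enumerate(positions):
        for col_pos in positions[i + 1 :]:
            x = np.asarray(peaks_by_position[row_pos], dtype=float)
            y = np.asarray(peaks_by_position[col_pos], dtype=float)
            entry = {"row": row_pos, "col": col_pos, "n_row": x.size, "n_col": y.size}
            try:
                gd: GroupDiff = independent_mean_diff(x, y, conf=conf, equal_var=equal_var)
            except InsufficientDataError:
                entry.update(
                    available=False, mean_diff_kmh=np.nan, ci_low=np.nan,
                    ci_high=np.nan, d=np.nan, d_ci_low=np.nan, d_ci_high=np.nan,
                    magnitude="",
                )
            else:
                entry.update(
                    available=True,
                    mean_diff_kmh=gd.mean_diff_kmh,
                    ci_low=gd.ci_low,
                    ci_high=gd.ci_high,
                    d=gd.d,
                    d_ci_low=gd.d_ci_low,
                    d_ci_high=gd.d_ci_high,
                    magnitude=gd.magnitude,
                )
            rows.append(entry)
    return pd.DataFrame(rows)


def _window_long(windows: Sequence[PeakWindow]) -> pd.DataFrame:
    frames = []
    for w in windows:
        frames.append(
            pd.DataFrame(
                {
                    "player_id": w.player_id,
                    "match_id": w.match_id,
                    "position": w.position,
                    "offset_ds": w.offsets_ds,
                    "v_kmh": w.speeds_kmh,
                    "missing": w.missing.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _deltas_long(windows: Sequence[PeakWindow]) -> pd.DataFrame:
    frames = []
    for w in windows:
        deltas = speed_changes_01s(w)
        frames.append(
            pd.DataFrame(
                {
                    "player_id": w.player_id,
                    "match_id": w.match_id,
                    "position": w.position,
                    "offset_ds": w.offsets_ds[:-1],
                    "delta_kmh": deltas,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    traces: Iterable[SpeedTrace],
    cfg: Optional[FilterConfig] = None,
    per_second_mode: str = "instant",
    log=None,
) -> AnalysisReport:
    """Run filtering → peak validation → windowing → statistics.

    Deterministic given its inputs.  Traces without a valid match peak are
    excluded from every table and listed in the run metadata; if no trace
    yields a peak the report is empty (tables have no rows) but this is not
    an error.
    """
    cfg = cfg or FilterConfig()
    log = log or (lambda msg: print(msg, file=sys.stderr))

    windows: list[PeakWindow] = []
    profiles: list[PerSecondProfile] = []
    n_spikes_removed = 0
    invalid: list[str] = []
    n_traces = 0
    for trace in traces:
        n_traces += 1
        filt = filter_speeds(trace, cfg)
        n_spikes_removed += filt.n_removed
        peak = find_match_peak(filt.trace, cfg)
        key = f"{trace.player_id}/{trace.match_id}"
        if peak is None:
            invalid.append(key)
            continue
        window = extract_window(filt.trace, peak)
        windows.append(window)
        profiles.append(per_second_profile(window, mode=per_second_mode))
    log(
        f"pipeline: {n_traces} traces, {n_spikes_removed} spike samples removed, "
        f"{len(invalid)} without a valid peak, {len(windows)} windows retained"
    )

    if windows:
        summary = build_position_summary(profiles)
        peaks_by_pos: dict[str, list[float]] = {}
        for w in windows:
            peaks_by_pos.setdefault(w.position, []).append(w.peak.peak_kmh)
        comparisons = build_position_comparisons(peaks_by_pos)
        try:
            diffs = consecutive_interval_diffs(profiles)
        except InsufficientDataError:
            diffs = []
        window_long = _window_long(windows)
        deltas_long = _deltas_long(windows)
    else:
        log("pipeline: no valid peak in any trace; emitting empty report")
        summary = pd.DataFrame()
        comparisons = pd.DataFrame()
        diffs = []
        window_long = pd.DataFrame()
        deltas_long = pd.DataFrame()

    metadata = {
        "n_traces": n_traces,
        "n_spike_samples_removed": n_spikes_removed,
        "n_traces_without_valid_peak": len(invalid),
        "traces_without_valid_peak": invalid,
        "n_windows": len(windows),
        "n_truncated_windows": sum(w.truncated for w in windows),
        "per_second_mode": per_second_mode,
        "filter_config": {
            "v_cap_kmh": cfg.v_cap_kmh,
            "sprint_threshold_kmh": cfg.sprint_threshold_kmh,
            "hsr_band_kmh": list(cfg.hsr_band_kmh),
            "corroboration_margin_kmh": cfg.corroboration_margin_kmh,
            "lookback_s": cfg.lookback_s,
        },
    }
    return AnalysisReport(
        position_summary=summary,
        interval_diffs=diffs,
        position_comparisons=comparisons,
        windows=windows,
        profiles=profiles,
        window_long=window_long,
        deltas_long=deltas_long,
        metadata=metadata,
    )


def run_pipeline_from_files(
    traces_dir: str | Path,
    metadata_path: str | Path,
    cfg: Optional[FilterConfig] = None,
    per_second_mode: str = "instant",
) -> AnalysisReport:
    """File-system entry point: read a cohort, then :func:`run_pipeline`."""
    traces = read_cohort(traces_dir, metadata_path)
    return run_pipeline(traces, cfg=cfg, per_second_mode=per_second_mode)
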