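"""Published reference summary statistics for elite match peak speeds.

A published study of elite male footballers (20 outfield players, six
first-division matches, 90 player-match observations) reports, per playing
position, the mean ± SD speed at every integer-second offset of the
20-second peri-peak window, plus the paired mean differences between
consecutive one-second intervals with classified effect sizes.  The raw
club GNSS data behind those tables are proprietary and undeposited, so this
module transcribes the printed summary statistics themselves.

They serve two purposes here:

* **simulator calibration** — the per-position peak-speed and flying-start
  distributions of :mod:`sprintwindow.synthetic_data` default to these
  values, so a simulated cohort reproduces realistic match conditions;
* **reconciliation checks** — the pre-peak consecutive-interval differences
  can be recovered from the per-position means by n-weighted pooling, and
  the between-position peak differences from the peak row, which gives the
  pipeline's aggregation arithmetic published numbers to be checked against.
"""

from __future__ import annotations


import pandas as pd

from .trace_io import POSITIONS

#: Number of valid match peak speeds per position (sums to 90).
POSITION_COUNTS: dict[str, int] = {"CD": 20, "FB": 10, "CM": 19, "WM": 24, "FW": 17}

#: Mean ± SD speed (km/h) per position at each integer-second offset of the
#: peri-peak window; offset 0 is the match peak speed itself.
#: Rows: offset −10..+10; per position a (mean, sd) pair.
PER_SECOND_SUMMARY: dict[int, dict[str, tuple[float, float]]] = {
    -10: {"CD": (5.11, 3.60), "FB": (7.40, 4.09), "CM": (8.02, 4.94), "WM": (8.30, 5.43), "FW": (9.21, 6.84)},
    -9: {"CD": (5.53, 4.34), "FB": (8.78, 6.02), "CM": (8.54, 4.89), "WM": (8.42, 6.87), "FW": (7.96, 5.34)},
    -8: {"CD": (7.07, 5.08), "FB": (10.03, 7.58), "CM": (9.37, 4.71), "WM": (9.18, 6.94), "FW": (8.88, 5.39)},
    -7: {"CD": (8.18, 5.10), "FB": (11.24, 7.65), "CM": (10.39, 5.15), "WM": (9.47, 6.19), "FW": (8.99, 5.18)},
    -6: {"CD": (9.35, 5.95), "FB": (13.08, 8.57), "CM": (12.59, 5.12), "WM": (10.05, 6.30), "FW": (8.78, 5.10)},
    -5: {"CD": (11.99, 5.69), "FB": (15.07, 9.04), "CM": (16.69, 4.70), "WM": (12.28, 6.66), "FW": (9.45, 5.55)},
    -4: {"CD": (14.59, 7.21), "FB": (18.93, 7.86), "CM": (18.49, 5.10), "WM": (16.40, 6.45), "FW": (12.70, 5.83)},
    -3: {"CD": (18.02, 6.54), "FB": (22.53, 5.32), "CM": (21.20, 5.19), "WM": (21.48, 4.97), "FW": (18.85, 4.59)},
    -2: {"CD": (22.48, 5.50), "FB": (26.57, 3.80), "CM": (24.54, 4.08), "WM": (25.43, 3.27), "FW": (24.03, 2.74)},
    -1: {"CD": (25.75, 5.08), "FB": (29.29, 3.15), "CM": (27.43, 2.95), "WM": (28.67, 2.46), "FW": (27.38, 2.39)},
    0: {"CD": (29.11, 1.64), "FB": (31.64, 1.94), "CM": (30.26, 2.23), "WM": (30.68, 2.61), "FW": (29.83, 1.88)},
    1: {"CD": (25.34, 5.61), "FB": (27.83, 4.97), "CM": (27.68, 3.08), "WM": (26.82, 5.47), "FW": (26.72, 3.62)},
    2: {"CD": (20.14, 6.55), "FB": (20.85, 8.14), "CM": (21.97, 6.63), "WM": (19.12, 8.91), "FW": (20.02, 7.14)},
    3: {"CD": (14.91, 7.63), "FB": (13.74, 7.92), "CM": (15.05, 7.54), "WM": (13.23, 9.56), "FW": (14.78, 6.78)},
    4: {"CD": (12.55, 7.19), "FB": (11.56, 6.55), "CM": (12.27, 6.72), "WM": (10.46, 8.94), "FW": (10.77, 5.21)},
    5: {"CD": (11.07, 6.11), "FB": (11.37, 5.72), "CM": (9.80, 6.00), "WM": (10.13, 8.20), "FW": (9.39, 5.22)},
    6: {"CD": (8.74, 5.84), "FB": (10.66, 4.26), "CM": (9.51, 5.11), "WM": (9.91, 6.60), "FW": (8.74, 5.13)},
    7: {"CD": (7.63, 5.50), "FB": (8.83, 5.40), "CM": (9.15, 4.60), "WM": (9.40, 5.66), "FW": (8.28, 4.48)},
    8: {"CD": (7.59, 5.41), "FB": (7.92, 5.69), "CM": (7.88, 4.24), "WM": (8.39, 5.38), "FW": (7.71, 3.56)},
    9: {"CD": (7.47, 5.09), "FB": (7.65, 6.19), "CM": (6.90, 4.11), "WM": (7.46, 5.75), "FW": (7.41, 3.61)},
    10: {"CD": (7.34, 4.62), "FB": (7.45, 6.31), "CM": (6.58, 4.23), "WM": (7.01, 5.11), "FW": (6.55, 3.01)},
}

#: Per-position match peak speed mean ± SD (km/h) — the offset-0 row.
PEAK_SPEEDS: dict[str, tuple[float, float]] = PER_SECOND_SUMMARY[0]

#: Published consecutive-interval paired differences:
#: pair label → (mean diff, (CI low, CI high), d, (d CI low, d CI high), label).
INTERVAL_EFFECTS: dict[str, tuple[float, tuple[float, float], float, tuple[float, float], str]] = {
    "10-9": (0.15, (-0.10, 0.40), 0.03, (-0.02, 0.07), "unclear"),
    "9-8": (1.03, (0.83, 1.24), 0.18, (0.14, 0.21), "trivial"),
    "8-7": (0.69, (0.46, 0.93), 0.12, (0.08, 0.16), "trivial"),
    "7-6": (1.04, (0.76, 1.32), 0.17, (0.13, 0.22), "trivial"),
    "6-5": (2.40, (2.12, 2.67), 0.37, (0.33, 0.41), "small"),
    "5-4": (3.10, (2.80, 3.40), 0.46, (0.41, 0.51), "small"),
    "4-3": (4.25, (3.99, 4.52), 0.68, (0.64, 0.73), "moderate"),
    "3-2": (4.18, (3.97, 4.38), 0.84, (0.80, 0.88), "moderate"),
    "2-1": (3.13, (2.99, 3.28), 0.80, (0.76, 0.85), "moderate"),
    "1-2": (-6.55, (-6.89, -6.21), -1.04, (-1.10, -0.98), "moderate"),
    "2-3": (-5.72, (-6.02, -5.41), -0.73, (-0.78, -0.68), "moderate"),
    "3-4": (-2.93, (-3.24, -2.62), -0.38, (-0.42, -0.34), "small"),
    "4-5": (-1.06, (-1.31, -0.81), -0.15, (-0.19, -0.12), "trivial"),
    "5-6": (-0.95, (-1.17, -0.73), -0.16, (-0.19, -0.12), "trivial"),
    "6-7": (-0.97, (-1.17, -0.76), -0.18, (-0.22, -0.14), "trivial"),
    "7-8": (-0.65, (-0.84, -0.47), -0.13, (-0.17, -0.09), "trivial"),
    "8-9": (-0.43, (-0.59, -0.27), -0.09, (-0.12, -0.06), "trivial"),
    "9-10": (-0.37, (-0.51, -0.24), -0.08, (-0.11, -0.05), "trivial"),
}

#: Published pre-peak consecutive-interval mean differences (km/h), i.e. the
#: rows of INTERVAL_EFFECTS that n-weighted pooling of the per-position
#: means reproduces (the post-peak rows of the source do not reconcile the
#: same way, presumably due to truncated late-match windows).
PREPEAK_MEAN_DIFFS: dict[str, float] = {
    k: v[0] for k, v in INTERVAL_EFFECTS.items() if int(k.split("-")[0]) > int(k.split("-")[1])
}


def reference_position_summary() -> pd.DataFrame:
    """The per-position per-second summary as a position-summary table.

    Same layout as :func:`sprintwindow.reporting.build_position_summary`:
    rows are integer offsets −10..+10 (0 = peak); columns a MultiIndex
    (position, {mean, sd, n}).  n is the per-position observation count at
    every offset (the published tables report no per-offset attrition).
    """
    offsets = sorted(PER_SECOND_SUMMARY)
    cols = pd.MultiIndex.from_product([POSITIONS, ("mean", "sd", "n")])
    df = pd.DataFrame(index=pd.Index(offsets, name="offset_s"), columns=cols, dtype=float)
    for off in offsets:
        for pos in POSITIONS:
            mean, sd = PER_SECOND_SUMMARY[off][pos]
            df.loc[off, (pos, "mean")] = mean
            df.loc[off, (pos, "sd")] = sd
            df.loc[off, (pos, "n")] = POSITION_COUNTS[pos]
    return df


def flying_start_speeds() -> dict[str, float]:
    """Per-position mean speed 5 s before the peak (flying-start region)."""
    return {pos: PER_SECOND_SUMMARY[-5][pos][0] for pos in POSITIONS}
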