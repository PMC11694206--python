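"""Estimation statistics for peri-peak speed comparisons.

Two designs appear in the pipeline:

* **paired** — the same windows measured at two consecutive one-second
  offsets (intra-individual speed change).  The estimand is the mean
  within-window difference with a 95% t-interval; Cohen's d standardizes by
  the average condition SD, ``s_av = sqrt((SD(a)² + SD(b)²) / 2)`` (the
  estimation-statistics convention for repeated measures), not by the SD of
  the differences.
* **independent** — peak speeds of two playing positions.  Pooled-variance
  two-sample t-interval by default, Welch as an option; d standardizes by
  the pooled SD.

Effect sizes are classified into magnitude bands on |d| at cut-points
0.2 / 0.6 / 1.2 / 2.0 / 4.0 → trivial, small, moderate, large, very large,
extremely large.  Whenever the 95% CI of d spans zero (endpoints touching
zero included), the effect is reported as *unclear* instead.

Confidence intervals for d use a normal approximation (documented on each
function); exact noncentral-t intervals are deliberately not the default —
the banding is coarse and the approximation error is far below one band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, MissingPositionError
from .trace_io import POSITIONS
from .windowing import PerSecondProfile

#: |d| upper bounds of the magnitude bands (last band is open-ended).
MAGNITUDE_THRESHOLDS: tuple[float, ...] = (0.2, 0.6, 1.2, 2.0, 4.0)

MAGNITUDE_LABELS: tuple[str, ...] = (
    "trivial",
    "small",
    "moderate",
    "large",
    "very large",
    "extremely large",
)

#: Consecutive one-second interval pairs in report order: pre-peak
#: ("10-9" = −10 s vs −9 s) through post-peak ("9-10" = +9 s vs +10 s);
#: the peak itself separates the two halves and is not an interval.
CONSECUTIVE_PAIRS: tuple[tuple[str, int, int], ...] = tuple(
    (f"{-a}-{-b}", a, b) for a, b in zip(range(-10, -1), range(-9, 0))
) + tuple((f"{a}-{b}", a, b) for a, b in zip(range(1, 10), range(2, 11)))


def classify_effect_size(d: float, ci: tuple[float, float]) -> str:
    """Magnitude band of an effect size given its confidence interval.

    ``unclear`` whenever the CI spans zero (inclusive of endpoints exactly
    at zero — the conservative reading); otherwise the band of |d|, with
    each cut-point belonging to the larger band (|d| = 0.2 is "small").
    """
    lo, hi = ci
    if lo > hi:
        raise ValueError(f"invalid CI ({lo}, {hi})")
    if lo <= 0.0 <= hi:
        return "unclear"
    band = int(np.searchsorted(MAGNITUDE_THRESHOLDS, abs(d), side="right"))
    return MAGNITUDE_LABELS[band]


@dataclass(frozen=True)
class IntervalDiff:
    """Paired mean difference for one consecutive-second interval."""

    pair: str  # e.g. "4-3" (pre-peak) or "1-2" (post-peak)
    n: int
    mean_diff_kmh: float
    ci_low: float
    ci_high: float
    d: float
    d_ci_low: float
    d_ci_high: float
    magnitude: str


@dataclass(frozen=True)
class GroupDiff:
    """Independent mean difference between two groups (y − x)."""

    n_x: int
    n_y: int
    mean_diff_kmh: float
    ci_low: float
    ci_high: float
    d: float
    d_ci_low: float
    d_ci_high: float
    magnitude: str


def _drop_incomplete_pairs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = ~(np.isnan(a) | np.isnan(b))
    return a[keep], b[keep]


def paired_mean_diff(
    a: Sequence[float],
    b: Sequence[float],
    conf: float = 0.95,
    pair: str = "",
) -> IntervalDiff:
    """Paired mean difference b − a with CI, Cohen's d and magnitude label.

    Pairs with a missing member are dropped; at least 2 complete pairs are
    required.  The mean-difference CI is the exact paired t-interval.  d is
    ``mean(b − a) / s_av``; its CI uses the repeated-measures normal
    approximation ``Var(d) ≈ (1/n + d²/(2n)) · 2(1 − r)`` with r the
    Pearson correlation of the paired columns, so a perfectly correlated
    shift has a degenerate (width-0) d interval.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    a, b = _drop_incomplete_pairs(a, b)
    n = a.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete pairs, got {n}")
    diffs = b - a
    md = float(diffs.mean())
    se = float(diffs.std(ddof=1)) / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + conf / 2, n - 1))
    ci = (md - tcrit * se, md + tcrit * se)

    s_av = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    if s_av == 0.0:
        d = 0.0 if md == 0.0 else math.copysign(math.inf, md)
        d_ci = (d, d)
    else:
        d = md / s_av
        if a.std(ddof=1) > 0 and b.std(ddof=1) > 0:
            r = float(np.corrcoef(a, b)[0, 1])
        else:
            r = 0.0
        var_d = max((1 / n + d * d / (2 * n)) * 2 * (1 - r), 0.0)
        z = float(stats.norm.ppf(0.5 + conf / 2))
        half = z * math.sqrt(var_d)
        d_ci = (d - half, d + half)
    return IntervalDiff(
        pair=pair,
        n=n,
        mean_diff_kmh=md,
        ci_low=ci[0],
        ci_high=ci[1],
        d=d,
        d_ci_low=d_ci[0],
        d_ci_high=d_ci[1],
        magnitude=classify_effect_size(d, d_ci),
    )


def independent_mean_diff(
    x: Sequence[float],
    y: Sequence[float],
    conf: float = 0.95,
    equal_var: bool = True,
) -> GroupDiff:
    """Independent mean difference ``mean(y) − mean(x)`` with CI, d, label.

    Default is the classical pooled-variance (equal-variance) two-sample
    t-interval; ``equal_var=False`` switches the mean-difference CI to
    Welch (Satterthwaite df).  d always standardizes by the pooled SD; its
    CI uses the standard large-sample normal approximation
    ``Var(d) ≈ (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"each group needs >= 2 observations, got {n1} and {n2}"
        )
    diff = float(y.mean() - x.mean())
    v1, v2 = float(x.var(ddof=1)), float(y.var(ddof=1))
    df_pooled = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_pooled
    if equal_var:
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = df_pooled
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        num = (v1 / n1 + v2 / n2) ** 2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        df = num / den if den > 0 else df_pooled
    if se > 0:
        tcrit = float(stats.t.ppf(0.5 + conf / 2, df))
        ci = (diff - tcrit * se, diff + tcrit * se)
    else:
        ci = (diff, diff)
    sp = math.sqrt(sp2)
    if sp == 0.0:
        d = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        d_ci = (d, d)
    else:
        d = diff / sp
        var_d = (n1 + n2) / (n1 * n2) + d * d / (2 * df_pooled)
        z = float(stats.norm.ppf(0.5 + conf / 2))
        half = z * math.sqrt(var_d)
        d_ci = (d - half, d + half)
    return GroupDiff(
        n_x=n1,
        n_y=n2,
        mean_diff_kmh=diff,
        ci_low=ci[0],
        ci_high=ci[1],
        d=d,
        d_ci_low=d_ci[0],
        d_ci_high=d_ci[1],
        magnitude=classify_effect_size(d, d_ci),
    )


def consecutive_interval_diffs(
    profiles: Iterable[PerSecondProfile],
    conf: float = 0.95,
) -> list[IntervalDiff]:
    """Paired differences for the 18 consecutive one-second intervals.

    Pairs are matched within player-match windows; each interval uses only
    the windows where both offsets are available, so truncated windows
    contribute to early offsets without biasing late ones.  Differences are
    always (later offset) − (earlier offset): positive while accelerating
    toward the peak, negative while decelerating away from it.  The peak
    offset itself (0 s) is not part of any interval.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise InsufficientDataError("need >= 2 per-second profiles")
    matrix = np.vstack([p.values_kmh for p in profiles])  # (n_windows, 21)
    out = []
    for pair, o_early, o_late in CONSECUTIVE_PAIRS:
        a = matrix[:, o_early + 10]
        b = matrix[:, o_late + 10]
        out.append(paired_mean_diff(a, b, conf=conf, pair=pair))
    return out


def pooled_position_means(summary: pd.DataFrame, offset_s: int) -> float:
    """n-weighted mean speed across the five positions at one offset.

    ``summary`` is a position-summary table (rows: integer offsets −10..+10
    with 0 the peak; columns: MultiIndex (position, {mean, sd, n})), as
    produced by :func:`sprintwindow.reporting.build_position_summary`.
    All five positions must be present with n > 0 at the offset.
    """
    total_n = 0.0
    acc = 0.0
    for pos in POSITIONS:
        if pos not in summary.columns.get_level_values(0):
            raise MissingPositionError(f"position {pos} absent from summary")
        row = summary.loc[offset_s, pos]
        n = float(row["n"])
        if not n > 0 or math.isnan(float(row["mean"])):
            raise MissingPositionError(
                f"position {pos} has no data at offset {offset_s}"
            )
        acc += n * float(row["mean"])
        total_n += n
    return acc / total_n


def interval_diffs_to_frame(diffs: Iterable[IntervalDiff]) -> pd.DataFrame:
    """Long-format table of interval differences (one row per interval)."""
    rows = [
        {
            "pair": d.pair,
            "n": d.n,
            "mean_diff_kmh": d.mean_diff_kmh,
            "ci_low": d.ci_low,
            "ci_high": d.ci_high,
            "d": d.d,
            "d_ci_low": d.d_ci_low,
            "d_ci_high": d.d_ci_high,
            "magnitude": d.magnitude,
        }
        for d in diffs
    ]
    return pd.DataFrame(rows)
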