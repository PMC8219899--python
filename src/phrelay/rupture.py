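"""Rupture-force detection and cohort statistics for steered-MD traces.

In a constant-velocity pulling experiment the opposing force rises
roughly linearly until the ion-coordination bonds break, which shows up
as a sudden, sustained drop.  The detector smooths the trace with a
centered moving average, takes the smoothed maximum as the candidate
rupture, and accepts it only if the smoothed force later stays below
``drop_fraction * max`` for at least ``sustain_ns`` — a monotone ramp
that never drops yields ``detected = False`` rather than an error.

Cohorts are summarized as notched box statistics: notch half-width
``1.57 * IQR / sqrt(n)`` (a 95% confidence interval on the median),
outliers beyond 1.5 IQR from the quartiles, whiskers at the extreme
non-outlier points.  Quartiles use linear interpolation; the convention
is echoed in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ForceTrace:
    """Force-vs-time series for one pulling run (time ns, force kJ/(mol nm))."""

    time_ns: np.ndarray
    force: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time_ns.size < 2:
            raise ValueError("force trace needs at least 2 samples")
        if not (np.diff(self.time_ns) > 0).all():
            raise ValueError("times must be strictly increasing")
        if self.time_ns.size != self.force.size:
            raise ValueError("time and force lengths differ")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ns": self.time_ns, "force": self.force}).to_csv(
            path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, condition: str = "") -> "ForceTrace":
        df = pd.read_csv(path)
        return cls(df["time_ns"].to_numpy(), df["force"].to_numpy(), condition)


@dataclass
class RuptureResult:
    detected: bool
    rupture_force: float | None = None
    rupture_time_ns: float | None = None
    smoothing_window_ns: float = 0.0
    condition: str = ""


def _moving_average(force: np.ndarray, half: int) -> np.ndarray:
    if half <= 0:
        return force.astype(float)
    kernel = np.ones(2 * half + 1)
    csum = np.cumsum(np.concatenate([[0.0], force]))
    n = len(force)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_rupture(trace: ForceTrace, window_ns: float = 0.1,
                   drop_fraction: float = 0.5, sustain_ns: float = 0.5
                   ) -> RuptureResult:
    """Locate the rupture event in one force trace.

    The rupture time is the argmax of the smoothed force, accepted only
    if the smoothed force subsequently stays below
    ``drop_fraction * max`` continuously for at least ``sustain_ns``.
    """
    if window_ns < 0:
        raise ValueError("window_ns must be >= 0")
    if not (0 < drop_fraction < 1):
        raise ValueError("drop_fraction must be in (0, 1)")
    dt = float(np.median(np.diff(trace.time_ns)))
    half = int(round(window_ns / (2 * dt))) if window_ns > 0 else 0
    smooth = _moving_average(trace.force, half)
    imax = int(np.argmax(smooth))
    fmax = float(smooth[imax])
    threshold = drop_fraction * fmax
    below = smooth[imax:] < threshold
    # longest run of consecutive below-threshold samples after the peak
    sustained = False
    run_start = None
    for k, b in enumerate(below):
        if b and run_start is None:
            run_start = k
        elif not b and run_start is not None:
            if (k - run_start) * dt >= sustain_ns:
                sustained = True
                break
            run_start = None
    if run_start is not None and (len(below) - run_start) * dt >= sustain_ns:
        sustained = True
    if not sustained:
        return RuptureResult(False, smoothing_window_ns=window_ns,
                             condition=trace.condition)
    return RuptureResult(True, fmax, float(trace.time_ns[imax]), window_ns,
                         trace.condition)


@dataclass
class NotchedBoxStats:
    """Notched-box summary of one cohort of rupture forces."""

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    notch_half_width: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n_undetected: int = 0
    quartile_method: str = "linear interpolation"

    @classmethod
    def from_values(cls, values: np.ndarray, n_undetected: int = 0
                    ) -> "NotchedBoxStats":
        v = np.sort(np.asarray(values, dtype=float))
        n = len(v)
        q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        outliers = v[(v < lo_fence) | (v > hi_fence)]
        return cls(n, float(med), float(q1), float(q3), float(iqr),
                   float(1.57 * iqr / np.sqrt(n)),
                   float(inside.min()), float(inside.max()), outliers,
                   n_undetected)


def summarize(results: list[RuptureResult],
              min_detected_for_notch: int = 5
              ) -> tuple[dict[str, NotchedBoxStats | None], pd.DataFrame]:
    """Per-condition notched-box stats and pairwise median differences.

    Undetected traces are counted separately and never enter the force
    statistics.  Conditions with zero detections are reported with
    ``None`` stats.  The difference table lists median(a) - median(b)
    for every ordered condition pair.
    """
    by_cond: dict[str, list[float]] = {}
    undet: dict[str, int] = {}
    for r in results:
        by_cond.setdefault(r.condition, [])
        undet.setdefault(r.condition, 0)
        if r.detected:
            by_cond[r.condition].append(r.rupture_force)
        else:
            undet[r.condition] += 1
    stats: dict[str, NotchedBoxStats | None] = {}
    for cond, vals in by_cond.items():
        if not vals:
            stats[cond] = None
            continue
        s = NotchedBoxStats.from_values(np.array(vals), undet[cond])
        if s.n < min_detected_for_notch:
            s.notch_half_width = float("nan")
        stats[cond] = s
    rows = []
    conds = [c for c, s in stats.items() if s is not None]
    for a in conds:
        for b in conds:
            if a == b:
                continue
            rows.append({"condition_a": a, "condition_b": b,
                         "median_difference": stats[a].median - stats[b].median})
    return stats, pd.DataFrame(rows)


def median_difference_ci(values_a: np.ndarray, values_b: np.ndarray,
                         n_boot: int = 2000, ci: float = 95.0,
                         seed: int | None = None) -> tuple[float, float, float]:
    """Bootstrap CI on the difference of cohort medians (a - b)."""
    rng = np.random.default_rng(seed)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    point = float(np.median(a) - np.median(b))
    diffs = (np.median(rng.choice(a, (n_boot, a.size)), axis=1)
             - np.median(rng.choice(b, (n_boot, b.size)), axis=1))
    alpha = (100 - ci) / 2
    return point, float(np.percentile(diffs, alpha)), \
        float(np.percentile(diffs, 100 - alpha))


def pull_coordinate(ca_positions: np.ndarray, ion_position: np.ndarray
                    ) -> np.ndarray:
    """Distance between an ion and the center of mass of anchor C-alpha atoms.

    Feature helper mirroring the pull-coordinate construction used for
    validating synthetic pulling geometries; running steered MD itself is
    outside this package.
    """
    com = np.asarray(ca_positions, dtype=float).mean(axis=-2)
    d = np.asarray(ion_position, dtype=float) - com
    return np.sqrt((d * d).sum(axis=-1))
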