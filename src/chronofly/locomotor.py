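"""Beam-break locomotor activity analysis.

Parses TriKinetics-style monitor files (one row per time bin, one count
column per channel/fly), builds smoothed daily activity profiles and
actogram matrices, and estimates free-running periods with the
Sokolove–Bushell chi-square periodogram, the canonical rhythm test used by
actogram software for this kind of data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schedules import LightSchedule

_MONTHS = [
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
]

#: status flag marking a valid monitor row
VALID_STATUS = 1


@dataclass
class ActivityDataset:
    """Per-fly beam-break counts on a uniform time grid.

    ``counts`` has shape (n_flies, n_bins); the time axis starts at
    ``start`` and advances ``bin_minutes`` per column.  Day boundaries are
    anchored at lights-on of the entrainment schedule, so bin-of-day 0 is
    ZT 0.  ``schedule_segments`` maps 1-based recording days to the light
    regime in force from that day onward.
    """

    fly_ids: list[str]
    counts: np.ndarray
    bin_minutes: float
    start: datetime
    schedule_segments: list[tuple[int, LightSchedule]]
    temperature_label: float = 25.0
    n_malformed_rows: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (fly x bin) array")
        if self.counts.shape[0] != len(self.fly_ids):
            raise ValueError("counts rows must match number of fly ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.schedule_segments:
            raise ValueError("at least one schedule segment is required")
        starts = [d for d, _ in self.schedule_segments]
        if starts != sorted(starts) or starts[0] != 1:
            raise ValueError("schedule segments must start at day 1 and be ordered")

    @property
    def n_flies(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bins_per_day(self) -> int:
        bpd = 1440.0 / self.bin_minutes
        if abs(bpd - round(bpd)) > 1e-9:
            raise ValueError(f"bin_minutes={self.bin_minutes} does not divide 1440")
        return int(round(bpd))

    @property
    def n_days(self) -> int:
        return self.n_bins // self.bins_per_day

    def schedule_on_day(self, day: int) -> LightSchedule:
        """Light schedule in force on a given 1-based recording day."""
        current = self.schedule_segments[0][1]
        for start_day, sched in self.schedule_segments:
            if day >= start_day:
                current = sched
        return current

    def series(self, fly: int | str) -> np.ndarray:
        if isinstance(fly, str):
            fly = self.fly_ids.index(fly)
        return self.counts[fly]


@dataclass
class Periodogram:
    """Chi-square periodogram: test statistics over candidate periods.

    ``qp`` is the normalized folded-variance ratio
    ``N * sum_h (M_h - grand)^2 / sum_i (x_i - grand)^2``, which equals the
    candidate period P for a noiseless periodic series and 0 for a
    constant one.  ``chi2_stat`` is the Sokolove–Bushell test statistic
    ``N * betweenSS / totalSS`` (the ratio weighted by per-column sample
    counts, i.e. qp times the number of folded cycles when they divide
    evenly); under the no-rhythm null it is chi-square with P - 1 degrees
    of freedom, and ``significance_line`` is that distribution's
    ``1 - alpha`` quantile.  Rhythm calls compare ``chi2_stat`` with the
    line.
    """

    candidate_periods_hours: np.ndarray
    qp: np.ndarray
    chi2_stat: np.ndarray
    significance_line: np.ndarray
    alpha: float
    bin_minutes: float

    @property
    def excess(self) -> np.ndarray:
        return self.chi2_stat - self.significance_line


@dataclass
class RhythmicityCall:
    fly_id: str
    rhythmic: bool
    period_hours: float | None
    peak_excess: float


# ---------------------------------------------------------------------------
# Monitor file I/O
# ---------------------------------------------------------------------------

def read_monitor_file(path, schedule_segments=None, temperature_label: float = 25.0,
                      bin_minutes: float | None = None) -> ActivityDataset:
    """Read a tab-delimited TriKinetics-style monitor file.

    The canonical dialect has 42 tab-separated columns: record index, day,
    month name, year, HH:MM:SS, status flag, four monitor-metadata fields,
    then 32 channel counts.  Files with only index/date/time/status
    followed by any number of count columns are also accepted.  Rows whose
    status flag is not ``1`` are counted and excluded.

    The bin axis must be uniform; the first offending row is named
    otherwise.
    """
    rows: list[tuple[datetime, list[int]]] = []
    n_malformed = 0
    n_counts = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"row {lineno}: too few columns for a monitor row")
            try:
                day = int(parts[1])
                month = _MONTHS.index(parts[2][:3].title()) + 1
                year = int(parts[3])
                if year < 100:
                    year += 2000
                hh, mm, ss = (int(x) for x in parts[4].split(":"))
                status = int(parts[5])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"row {lineno}: cannot parse date/time/status") from exc
            if len(parts) == 42:
                count_fields = parts[10:42]
            else:
                count_fields = parts[6:]
            if status != VALID_STATUS:
                n_malformed += 1
                continue
            try:
                counts = [int(c) for c in count_fields]
            except ValueError as exc:
                raise ValueError(f"row {lineno}: non-integer count field") from exc
            if n_counts is None:
                n_counts = len(counts)
            elif len(counts) != n_counts:
                raise ValueError(f"row {lineno}: inconsistent channel count")
            rows.append((datetime(year, month, day, hh, mm, ss), counts))
    if not rows:
        raise ValueError(f"{path}: no valid monitor rows")

    times = [t for t, _ in rows]
    if len(times) > 1:
        step = times[1] - times[0]
        if step <= timedelta(0):
            raise ValueError("row 2: time axis must be strictly increasing")
        for i in range(1, len(times)):
            if times[i] - times[i - 1] != step:
                raise ValueError(
                    f"row {i + 1}: non-uniform bin spacing "
                    f"({times[i] - times[i - 1]} vs {step})"
                )
        inferred_bin = step.total_seconds() / 60.0
    else:
        inferred_bin = bin_minutes if bin_minutes is not None else 5.0
    if bin_minutes is not None and abs(inferred_bin - bin_minutes) > 1e-9:
        raise ValueError(
            f"bin spacing {inferred_bin} min does not match requested {bin_minutes}"
        )

    counts = np.array([c for _, c in rows], dtype=np.int64).T
    fly_ids = [f"ch{j + 1:02d}" for j in range(counts.shape[0])]
    if schedule_segments is None:
        schedule_segments = [(1, LightSchedule(12.0, 12.0))]
    return ActivityDataset(
        fly_ids=fly_ids,
        counts=counts,
        bin_minutes=inferred_bin,
        start=times[0],
        schedule_segments=list(schedule_segments),
        temperature_label=temperature_label,
        n_malformed_rows=n_malformed,
    )


def write_monitor_file(ds: ActivityDataset, path) -> None:
    """Write a dataset in the 42-column monitor dialect (padding to 32 channels).

    ``read_monitor_file`` followed by ``write_monitor_file`` is a byte-level
    round trip for canonical 32-channel files.
    """
    n_pad = max(0, 32 - ds.n_flies)
    step = timedelta(minutes=ds.bin_minutes)
    with open(path, "w") as fh:
        t = ds.start
        for i in range(ds.n_bins):
            date_part = f"{t.day}\t{_MONTHS[t.month - 1]}\t{t.year % 100:02d}"
            meta = "1\t0\t0\t0"
            row_counts = list(ds.counts[:, i]) + [0] * n_pad
            fh.write(
                f"{i + 1}\t{date_part}\t{t:%H:%M:%S}\t{VALID_STATUS}\t{meta}\t"
                + "\t".join(str(int(c)) for c in row_counts[:32])
                + "\n"
            )
            t += step


# ---------------------------------------------------------------------------
# Profiles and activity levels
# ---------------------------------------------------------------------------

def smooth(series: Sequence[float], factor: int) -> np.ndarray:
    """Centered moving average of window ``2*factor + 1`` bins.

    At the edges the window shrinks symmetrically so the average stays
    centered; ``factor=0`` is the identity.  This mirrors the display
    smoothing applied to activity histograms before plotting.
    """
    if factor < 0:
        raise ValueError(f"smoothing factor must be >= 0, got {factor}")
    x = np.asarray(series, dtype=float)
    if factor == 0 or x.size == 0:
        return x.copy()
    n = x.size
    out = np.empty(n)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    for i in range(n):
        half = min(factor, i, n - 1 - i)
        out[i] = (csum[i + half + 1] - csum[i - half]) / (2 * half + 1)
    return out


def _check_day_range(ds: ActivityDataset, day_range: tuple[int, int]) -> tuple[int, int]:
    d0, d1 = day_range
    if d0 < 1 or d1 > ds.n_days or d0 > d1:
        raise ValueError(
            f"day range {day_range} outside recorded days 1..{ds.n_days}"
        )
    return d0, d1


def daily_profile(ds: ActivityDataset, day_range: tuple[int, int],
                  smooth_factor: int = 2) -> pd.DataFrame:
    """Mean +/- SEM activity per bin-of-day across fly-days.

    Days are 1-based and the range is inclusive (e.g. ``(1, 10)`` uses the
    first ten recorded days, dropping a survival-control tail).  Each fly's
    selected stretch is smoothed before folding into days; the SEM is taken
    across all contributing fly-days.

    Returns a frame with columns ``bin_of_day, zt_hours, mean, sem, n``.
    """
    d0, d1 = _check_day_range(ds, day_range)
    bpd = ds.bins_per_day
    sl = slice((d0 - 1) * bpd, d1 * bpd)
    n_days = d1 - d0 + 1
    per_day = np.empty((ds.n_flies * n_days, bpd))
    for f in range(ds.n_flies):
        sm = smooth(ds.counts[f, sl], smooth_factor)
        per_day[f * n_days:(f + 1) * n_days] = sm.reshape(n_days, bpd)
    mean = per_day.mean(axis=0)
    n = per_day.shape[0]
    sem = per_day.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(bpd)
    return pd.DataFrame({
        "bin_of_day": np.arange(bpd),
        "zt_hours": np.arange(bpd) * ds.bin_minutes / 60.0,
        "mean": mean,
        "sem": sem,
        "n": n,
    })


def total_daily_activity(ds: ActivityDataset, day_range: tuple[int, int]) -> pd.DataFrame:
    """Average beam-break total per 24 h for each fly over the given days.

    Raw (unsmoothed) counts are summed within each day and averaged over
    days, yielding one activity-level point per fly.
    """
    d0, d1 = _check_day_range(ds, day_range)
    bpd = ds.bins_per_day
    sl = ds.counts[:, (d0 - 1) * bpd:d1 * bpd]
    daily = sl.reshape(ds.n_flies, d1 - d0 + 1, bpd).sum(axis=2)
    return pd.DataFrame({
        "fly_id": ds.fly_ids,
        "counts_per_24h": daily.mean(axis=1),
    })


def actogram_matrix(series: Sequence[float], bins_per_day: int,
                    double_plot: bool = True) -> np.ndarray:
    """Day x bin raster of raw counts for actogram plotting.

    With ``double_plot`` row *d* holds days *d* and *d+1* side by side
    (the conventional double-plotted actogram); the final row's right half
    is zero-padded.
    """
    x = np.asarray(series, dtype=float)
    if x.size < bins_per_day:
        raise ValueError("need at least one full day of data")
    n_days = x.size // bins_per_day
    days = x[: n_days * bins_per_day].reshape(n_days, bins_per_day)
    if not double_plot:
        return days
    out = np.zeros((n_days, 2 * bins_per_day))
    out[:, :bins_per_day] = days
    out[:-1, bins_per_day:] = days[1:]
    return out


# ---------------------------------------------------------------------------
# Chi-square periodogram and rhythmicity
# ---------------------------------------------------------------------------

def chi_square_periodogram(series: Sequence[float],
                           period_range_hours: tuple[float, float] = (16.0, 32.0),
                           alpha: float = 0.05,
                           bin_minutes: float = 5.0) -> Periodogram:
    """Sokolove–Bushell chi-square periodogram on raw counts.

    For a candidate period of P bins the series is folded into P columns
    with column means M_h and grand mean M̄.  Two scalings of the folded
    variance ratio are computed per candidate (see :class:`Periodogram`):
    the normalized ``qp`` with closed form Qp(P) = P on a noiseless
    P-periodic series, and the chi-square-distributed test statistic used
    for significance, with its pointwise ``1 - alpha`` chi-square line.
    Candidate periods run at the native bin resolution.  A zero-variance
    series yields both statistics 0 everywhere.

    The periodogram runs on raw, unsmoothed counts: display smoothing
    correlates neighbouring bins and inflates the statistic.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    lo, hi = period_range_hours
    if not 0 < lo <= hi:
        raise ValueError(f"invalid period range {period_range_hours}")
    bins_per_hour = 60.0 / bin_minutes
    p_lo = int(np.ceil(lo * bins_per_hour - 1e-9))
    p_hi = int(np.floor(hi * bins_per_hour + 1e-9))
    if p_lo < 2:
        raise ValueError("period range must span at least 2 bins")
    if 2 * p_hi > n:
        raise ValueError(
            f"series of {n} bins cannot support periods up to "
            f"{p_hi} bins (need >= 2 cycles)"
        )
    grand = x.mean()
    denom = np.sum((x - grand) ** 2)
    periods = np.arange(p_lo, p_hi + 1)
    qp = np.zeros(periods.size)
    chi2_stat = np.zeros(periods.size)
    if denom > 0:
        idx = np.arange(n)
        for j, p in enumerate(periods):
            col_sums = np.bincount(idx % p, weights=x, minlength=p)
            col_n = np.bincount(idx % p, minlength=p)
            col_means = col_sums / col_n
            dev2 = (col_means - grand) ** 2
            qp[j] = n * np.sum(dev2) / denom
            chi2_stat[j] = n * np.sum(col_n * dev2) / denom
    sig = stats.chi2.ppf(1.0 - alpha, periods - 1)
    return Periodogram(
        candidate_periods_hours=periods / bins_per_hour,
        qp=qp,
        chi2_stat=chi2_stat,
        significance_line=sig,
        alpha=alpha,
        bin_minutes=bin_minutes,
    )


def classify_rhythmicity(pg: Periodogram, fly_id: str = "",
                         correction: str = "bonferroni") -> RhythmicityCall:
    """Call a fly rhythmic when the periodogram peak clears the chi-square line.

    The period estimate is the candidate period at the maximal excess
    (test statistic minus threshold); exact ties are broken toward the
    period closest to 24 h.  By default the threshold is
    Bonferroni-corrected across the scanned candidate periods: a
    day-resolution scan covers ~200 correlated candidates, and an
    uncorrected pointwise line mislabels essentially every noise series as
    rhythmic.  ``correction="none"`` gives the liberal pointwise rule.
    """
    if correction == "bonferroni":
        p_bins = np.round(
            pg.candidate_periods_hours * 60.0 / pg.bin_minutes).astype(int)
        line = stats.chi2.ppf(1.0 - pg.alpha / pg.qp.size, p_bins - 1)
    elif correction == "none":
        line = pg.significance_line
    else:
        raise ValueError(f"unknown correction {correction!r}")
    excess = pg.chi2_stat - line
    peak = float(np.max(excess))
    if peak <= 0:
        return RhythmicityCall(fly_id, False, None, peak)
    tied = np.flatnonzero(excess == np.max(excess))
    best = tied[np.argmin(np.abs(pg.candidate_periods_hours[tied] - 24.0))]
    return RhythmicityCall(
        fly_id, True, float(pg.candidate_periods_hours[best]), peak
    )


def free_running_summary(calls: Iterable[RhythmicityCall],
                         group_labels: Iterable[str]) -> pd.DataFrame:
    """Per-group rhythmicity and free-running-period statistics.

    Percent rhythmic is over all flies in the group; period mean and SD are
    over the rhythmic flies only (NaN when none are rhythmic).
    """
    calls = list(calls)
    labels = list(group_labels)
    if len(calls) != len(labels):
        raise ValueError("one group label per call is required")
    if not calls:
        raise ValueError("at least one rhythmicity call is required")
    df = pd.DataFrame({
        "group": labels,
        "rhythmic": [c.rhythmic for c in calls],
        "period": [c.period_hours if c.rhythmic else np.nan for c in calls],
    })
    rows = []
    for group, sub in df.groupby("group", sort=True):
        per = sub.loc[sub["rhythmic"], "period"]
        rows.append({
            "group": group,
            "n": len(sub),
            "percent_rhythmic": 100.0 * sub["rhythmic"].mean(),
            "mean_period": per.mean() if len(per) else np.nan,
            "sd_period": per.std(ddof=1) if len(per) > 1 else (0.0 if len(per) == 1 else np.nan),
        })
    return pd.DataFrame(rows)
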