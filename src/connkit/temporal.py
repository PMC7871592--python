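"""Metric time courses and the slope-of-linear-interpolation summary.

To compare how coupling evolves within a session across metrics with
different native bin sizes (10-s bins for power/coherence, 1-min bins for
wPLI/PAC/GC), each metric is evaluated independently per bin and the change
over time is summarised as the slope of an ordinary least-squares line.
The abscissa is the bin midpoint in minutes, so slopes are in metric units
per minute regardless of bin size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricTimeCourse", "slope", "metric_timecourse"]


@dataclass
class MetricTimeCourse:
    bin_starts_s: np.ndarray
    values: np.ndarray
    slope_per_min: float
    intercept: float
    metric: str = ""


def slope(values, bin_starts_s=None, bin_s: float = 60.0) -> tuple[float, float]:
    """OLS slope (per minute) and intercept of a per-bin metric series.

    Non-finite bins are dropped; at least two finite bins are required.
    """
    values = np.asarray(values, dtype=float)
    if bin_starts_s is None:
        bin_starts_s = np.arange(values.size) * bin_s
    bin_starts_s = np.asarray(bin_starts_s, dtype=float)
    mid_min = (bin_starts_s + bin_s / 2.0) / 60.0
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError("need >= 2 finite bins for a slope")
    b, a = np.polyfit(mid_min[ok], values[ok], 1)
    return float(b), float(a)


def metric_timecourse(
    metric_fn,
    n_samples: int,
    rate_hz: float,
    bin_s: float,
    metric: str = "",
) -> MetricTimeCourse:
    """Evaluate ``metric_fn(start_sample, stop_sample) -> float`` per bin.

    The callable computes the metric on one time bin of the underlying
    record; bins are non-overlapping and a trailing partial bin is dropped.
    """
    nbin = int(round(bin_s * rate_hz))
    n_bins = n_samples // nbin
    if n_bins < 2:
        raise ValueError(f"record covers {n_bins} bins of {bin_s}s; need >= 2")
    starts = np.arange(n_bins) * nbin
    values = np.array([metric_fn(int(s), int(s + nbin)) for s in starts], dtype=float)
    b, a = slope(values, starts / rate_hz, bin_s=bin_s)
    return MetricTimeCourse(
        bin_starts_s=starts / rate_hz,
        values=values,
        slope_per_min=b,
        intercept=a,
        metric=metric,
    )
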