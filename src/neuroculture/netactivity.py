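"""Population structure: mean rates, network bursts, synchrony, activity classes.

The population rate is the unweighted mean of per-channel rate series
over active channels.  Network bursts are maximal epochs where that
rate exceeds max(factor × median, absolute floor); synchrony is the
zero-lag Pearson correlation between binned rates (peak lagged
cross-correlation available as a secondary statistic).  Cells are
classified into the four activity categories — spiking, bursting,
spiking-and-bursting, none — from where their events fall relative to
the network bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NetworkBurst, RateSeries, SpikeTrain

__all__ = [
    "PopulationRate",
    "population_rate",
    "detect_network_bursts",
    "inter_burst_intervals",
    "SynchronyMatrix",
    "synchrony",
    "classify_activity",
    "classification_summary",
    "ACTIVITY_CLASSES",
]

ACTIVITY_CLASSES = ("spiking", "bursting", "spiking_and_bursting", "none")


@dataclass
class PopulationRate:
    """Mean rate across active channels, with the criterion used."""

    series: RateSeries
    active_channels: list[str]
    activity_threshold: float


def population_rate(
    trains: dict | list[SpikeTrain],
    bin_width: float = 0.1,
    activity_threshold: float = 0.1,
) -> PopulationRate:
    """Unweighted mean rate over channels with mean rate >= threshold (Hz).

    An "active channel" is one whose whole-recording mean rate reaches
    ``activity_threshold`` (0.1 Hz by default).  Raises if no channel
    qualifies.
    """
    from .mea import compute_rate

    if isinstance(trains, dict):
        trains = list(trains.values())
    active = [tr for tr in trains if tr.mean_rate >= activity_threshold]
    if not active:
        raise ValueError("no active channels at the given activity threshold")
    series = [compute_rate(tr, bin_width) for tr in active]
    n = max(s.n_bins for s in series)
    mat = np.zeros((len(series), n))
    for i, s in enumerate(series):
        mat[i, : s.n_bins] = s.values
    mean = RateSeries(values=mat.mean(axis=0), bin_width=bin_width)
    return PopulationRate(
        series=mean,
        active_channels=[tr.channel_id for tr in active],
        activity_threshold=activity_threshold,
    )


def detect_network_bursts(
    pop: PopulationRate,
    rate_threshold_factor: float = 5.0,
    min_duration: float = 0.1,
    merge_gap: float = 0.2,
    rate_floor: float = 1.0,
    trains: dict | list[SpikeTrain] | None = None,
) -> list[NetworkBurst]:
    """Threshold the population rate into sharply delineated burst epochs.

    The threshold is max(factor × median population rate, ``rate_floor``
    Hz).  Supra-threshold epochs separated by less than ``merge_gap``
    are merged, then epochs shorter than ``min_duration`` are dropped.
    When spike trains are supplied, burst edges are refined to the
    first/last spike inside each epoch and per-burst participation
    (fraction of supplied channels with >= 1 spike inside) is filled in.
    Silent input yields an empty list.
    """
    values = pop.series.values
    bw = pop.series.bin_width
    threshold = max(rate_threshold_factor * float(np.median(values)), rate_floor)
    above = values > threshold
    if not np.any(above):
        return []
    # maximal runs of supra-threshold bins, expanded by one bin on each
    # side: a burst edge falling inside a bin can leave that partial bin
    # sub-threshold even though it holds the first/last burst spikes
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(int), [0]])))
    starts = np.maximum(edges[::2] - 1, 0) * bw
    ends = np.minimum(edges[1::2] + 1, above.size) * bw
    # merge runs separated by < merge_gap
    merged: list[list[float]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    if isinstance(trains, dict):
        trains = list(trains.values())
    pooled = None
    if trains:
        all_times = [tr.times for tr in trains if tr.times.size]
        pooled = np.sort(np.concatenate(all_times)) if all_times else np.empty(0)

    bursts: list[NetworkBurst] = []
    for s, e in merged:
        if pooled is not None and pooled.size:
            inside = pooled[(pooled >= s) & (pooled <= e)]
            if inside.size == 0:
                continue
            s, e = float(inside[0]), float(inside[-1])
            if e <= s:
                e = s + 1e-6
        if e - s < min_duration:
            continue
        part = float("nan")
        if trains:
            with_spike = sum(
                1 for tr in trains if np.any((tr.times >= s) & (tr.times <= e))
            )
            part = with_spike / len(trains)
        bursts.append(NetworkBurst(start=s, end=e, participation=part))
    return bursts


def inter_burst_intervals(
    bursts: list[NetworkBurst], convention: str = "end_to_start"
) -> np.ndarray:
    """Gaps between successive bursts (end-to-start by default)."""
    if len(bursts) < 2:
        return np.empty(0)
    starts = np.array([b.start for b in bursts])
    ends = np.array([b.end for b in bursts])
    if convention == "end_to_start":
        return starts[1:] - ends[:-1]
    if convention == "start_to_start":
        return np.diff(starts)
    raise ValueError("convention must be 'end_to_start' or 'start_to_start'")


@dataclass
class SynchronyMatrix:
    """Pairwise rate correlations; NaN marks undefined (constant) pairs."""

    matrix: np.ndarray
    channel_ids: list[str]
    lags: np.ndarray | None = None  # peak-correlation lags (s), if lagged

    @property
    def mean_pairwise(self) -> float:
        """Mean of finite off-diagonal coefficients."""
        m = self.matrix
        off = m[~np.eye(m.shape[0], dtype=bool)]
        off = off[np.isfinite(off)]
        return float(off.mean()) if off.size else float("nan")


def synchrony(
    series: list[RateSeries],
    max_lag: float | None = None,
) -> SynchronyMatrix:
    """Pairwise correlation between rate series.

    Zero-lag Pearson correlation by default.  With ``max_lag`` set, the
    peak normalized cross-correlation within ±max_lag is reported
    instead, together with the lag (in seconds) at which it peaks.
    Constant series give NaN entries, excluded from the matrix mean.
    """
    if len(series) < 2:
        raise ValueError("need at least two series")
    n = min(s.n_bins for s in series)
    if len({round(s.bin_width, 12) for s in series}) != 1:
        raise ValueError("all series must share a bin width")
    bw = series[0].bin_width
    mat = np.vstack([s.values[:n] for s in series])
    ids = [s.channel_id for s in series]
    k = mat.shape[0]
    sd = mat.std(axis=1)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    lags = np.zeros((k, k)) if max_lag is not None else None
    max_shift = int(round(max_lag / bw)) if max_lag is not None else 0
    centered = mat - mat.mean(axis=1, keepdims=True)
    for i in range(k):
        for j in range(i + 1, k):
            if sd[i] == 0 or sd[j] == 0:
                continue
            if max_lag is None:
                r = float(np.dot(centered[i], centered[j]) / (n * sd[i] * sd[j]))
            else:
                best_r, best_lag = -np.inf, 0
                for shift in range(-max_shift, max_shift + 1):
                    if shift >= 0:
                        a, b = centered[i, shift:], centered[j, : n - shift]
                    else:
                        a, b = centered[i, :shift], centered[j, -shift:]
                    if a.size < 2 or a.std() == 0 or b.std() == 0:
                        continue
                    r_s = float(np.corrcoef(a, b)[0, 1])
                    if r_s > best_r:
                        best_r, best_lag = r_s, shift
                r = best_r if np.isfinite(best_r) else np.nan
                # positive lag: series j is delayed relative to series i
                lags[i, j] = -best_lag * bw
                lags[j, i] = best_lag * bw
            out[i, j] = out[j, i] = r
    return SynchronyMatrix(matrix=out, channel_ids=ids, lags=lags)


def classify_activity(
    events: dict[str, np.ndarray],
    bursts: list[NetworkBurst],
    min_iso_events: int = 3,
    min_burst_frac: float = 0.5,
) -> dict[str, str]:
    """Assign each cell one of the four activity classes.

    A cell meets the *burst* criterion when at least ``min_burst_frac``
    of the network bursts contain one of its events; it meets the
    *spiking* criterion when it has at least ``min_iso_events`` events
    outside all bursts.  Burst-only ⇒ 'bursting', spiking-only ⇒
    'spiking', both ⇒ 'spiking_and_bursting', neither ⇒ 'none'.
    """
    n_bursts = len(bursts)
    classes: dict[str, str] = {}
    for cell, times in events.items():
        times = np.asarray(times, dtype=np.float64)
        if times.size == 0:
            classes[cell] = "none"
            continue
        in_any = np.zeros(times.size, dtype=bool)
        hit = 0
        for b in bursts:
            inside = (times >= b.start) & (times <= b.end)
            in_any |= inside
            hit += bool(np.any(inside))
        burst_ok = n_bursts > 0 and (hit / n_bursts) >= min_burst_frac
        iso_ok = int(np.sum(~in_any)) >= min_iso_events
        if burst_ok and iso_ok:
            classes[cell] = "spiking_and_bursting"
        elif burst_ok:
            classes[cell] = "bursting"
        elif iso_ok:
            classes[cell] = "spiking"
        else:
            classes[cell] = "none"
    return classes


def _pct(count: int, total: int) -> float:
    """Percentage, rounded half-up to the nearest integer."""
    if total == 0:
        return 0.0
    return float(np.floor(100.0 * count / total + 0.5))


def classification_summary(
    counts: dict[str, dict[str, int]] | None = None,
    classes_by_group: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Activity-pattern overview table, one row per cell-type group.

    Accepts either raw per-group class counts or per-group cell→class
    mappings.  Columns: group, total, then count and integer-rounded
    percentage for each of spiking / bursting / spiking-and-bursting /
    no-activity, mirroring the standard overview-table layout.
    """
    if counts is None:
        if classes_by_group is None:
            raise ValueError("provide counts or classes_by_group")
        counts = {
            g: {c: sum(1 for v in m.values() if v == c) for c in ACTIVITY_CLASSES}
            for g, m in classes_by_group.items()
        }
    rows = []
    for group, c in counts.items():
        c = {k: int(c.get(k, 0)) for k in ACTIVITY_CLASSES}
        total = sum(c.values())
        row: dict[str, object] = {"group": group, "total": total}
        for cls in ACTIVITY_CLASSES:
            row[cls] = c[cls]
            row[f"{cls}_pct"] = _pct(c[cls], total)
        rows.append(row)
    return pd.DataFrame(rows)
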