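"""MEA signal pipeline: filter, detect, sort, bin, normalize.

Raw multichannel traces are high-pass filtered (Bessel 4th order,
400 Hz cutoff by default, applied causally as acquisition software
does), spikes are detected at negative-going crossings of a
mean − k·SD threshold (k = 5 by default) and timestamped at the local
trough, optionally sorted by threshold polylines drawn through
waveform space, binned into 100 ms rates (count × 10 ⇒ Hz), and
normalized: spline-smoothed, re-binned to 10 s averages, and scaled so
the mean of the first ten 10 s bins (the first 100 s) is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import make_smoothing_spline

from .containers import FilteredRecording, RateSeries, RawRecording, SpikeEvent, SpikeTrain

__all__ = [
    "highpass_filter",
    "detect_spikes",
    "ThresholdPolyline",
    "sort_spikes",
    "propose_polylines",
    "events_to_trains",
    "compute_rate",
    "normalize_rate",
]


def highpass_filter(
    raw: RawRecording,
    order: int = 4,
    cutoff: float = 400.0,
    zero_phase: bool = False,
) -> FilteredRecording:
    """Bessel high-pass filter, applied per channel.

    Causal (single-pass) by default, matching online acquisition;
    ``zero_phase=True`` switches to forward-backward filtering.  The
    filter is magnitude-normalized so the −3 dB point sits at
    ``cutoff``.
    """
    nyquist = raw.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyquist:g}) Hz")
    sos = signal.bessel(
        order, cutoff, btype="highpass", fs=raw.sampling_rate, output="sos", norm="mag"
    )
    fn = signal.sosfiltfilt if zero_phase else signal.sosfilt
    filtered = fn(sos, raw.samples, axis=1)
    return FilteredRecording(
        samples=filtered.astype(raw.samples.dtype, copy=False),
        sampling_rate=raw.sampling_rate,
        channel_ids=list(raw.channel_ids),
        unit=raw.unit,
        filter_type="bessel",
        filter_order=order,
        filter_cutoff_hz=cutoff,
        filter_mode="highpass",
        zero_phase=zero_phase,
    )


def detect_spikes(
    filtered: FilteredRecording,
    k: float | dict[str, float] = 5.0,
    dead_time: float = 0.001,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
    robust_sd: bool = False,
) -> list[SpikeEvent]:
    """Threshold detection at mean − k·SD, per channel.

    Events are negative-going crossings of the per-channel threshold,
    timestamped at the local trough; crossings within ``dead_time`` of
    the previous event are suppressed.  A waveform snippet of
    ``pre_ms`` before to ``post_ms`` after the trough is attached to
    each event (events too close to the recording edges for a full
    snippet are dropped).  ``k`` may be a single multiplier or a
    per-channel mapping (mirroring per-channel manual threshold
    adjustment); ``robust_sd`` estimates the SD from the median
    absolute deviation, useful on burst-dense channels.  Channels with
    zero variance yield no events.
    """
    fs = filtered.sampling_rate
    if filtered.n_samples < fs:  # need >= 1 s to estimate mean and SD
        raise ValueError("recording must be at least 1 s long")
    pre = int(round(pre_ms * 1e-3 * fs))
    post = int(round(post_ms * 1e-3 * fs))
    dead = max(1, int(round(dead_time * fs)))
    wf_times = (np.arange(pre + post + 1) - pre) / fs * 1e3  # ms rel. trough

    events: list[SpikeEvent] = []
    for ch, row in zip(filtered.channel_ids, filtered.samples):
        row = np.asarray(row, dtype=np.float64)
        mu = row.mean()
        if robust_sd:
            sd = 1.4826 * np.median(np.abs(row - np.median(row)))
        else:
            sd = row.std()
        if sd == 0:
            continue  # flat channel: flagged by absence
        k_ch = k.get(ch, 5.0) if isinstance(k, dict) else k
        thr = mu - k_ch * sd
        below = row < thr
        crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
        last_trough = -np.inf
        for c in crossings:
            # trough: local minimum from the crossing to re-crossing (or +2 ms)
            end = c
            limit = min(row.size, c + 2 * post)
            while end < limit and row[end] < thr:
                end += 1
            trough = c + int(np.argmin(row[c:max(end, c + 1)]))
            # suppress re-crossings belonging to the previous event's
            # waveform complex: a large spike's filtered waveform can
            # re-cross threshold (post-lobe undershoot) within its own
            # snippet window, which is not a separate spike
            if trough - last_trough < dead or c - last_trough < max(dead, post):
                continue
            last_trough = trough
            if trough - pre < 0 or trough + post + 1 > row.size:
                continue
            events.append(
                SpikeEvent(
                    channel_id=ch,
                    time=trough / fs,
                    waveform=row[trough - pre : trough + post + 1].copy(),
                    waveform_times=wf_times,
                )
            )
    return events


@dataclass
class ThresholdPolyline:
    """A line drawn through waveform space for manual spike sorting.

    Vertices are (time-offset ms relative to the trough, amplitude)
    pairs with strictly increasing time offsets.  A waveform *crosses*
    the polyline when it dips below the line at any sample within the
    line's time span (crossing = below convention).
    """

    vertices: np.ndarray  # (n, 2): time-offset ms, amplitude
    label: str = "unit1"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 2:
            raise ValueError("polyline needs at least two vertices")
        if not np.all(np.diff(self.vertices[:, 0]) > 0):
            raise ValueError("vertex time-offsets must be strictly increasing")

    def crosses(self, waveform: np.ndarray, waveform_times: np.ndarray) -> bool:
        t0, t1 = self.vertices[0, 0], self.vertices[-1, 0]
        mask = (waveform_times >= t0) & (waveform_times <= t1)
        if not np.any(mask):
            return False
        line = np.interp(waveform_times[mask], self.vertices[:, 0], self.vertices[:, 1])
        return bool(np.any(waveform[mask] <= line))


def sort_spikes(
    events: list[SpikeEvent],
    polylines: list[ThresholdPolyline],
    residual_label: str = "residual",
) -> list[SpikeEvent]:
    """Label each event by the first polyline its waveform crosses.

    Polylines are tested in the given order; events crossing none get
    the residual label.  With no polylines every event shares one
    label.  Events are relabeled in place and returned.
    """
    if not polylines:
        for ev in events:
            ev.label = "unit1"
        return events
    for pl in polylines:
        if events:
            wt = events[0].waveform_times
            if pl.vertices[0, 0] < wt[0] - 1e-9 or pl.vertices[-1, 0] > wt[-1] + 1e-9:
                raise ValueError(f"polyline {pl.label!r} lies outside the waveform window")
    for ev in events:
        ev.label = residual_label
        for pl in polylines:
            if pl.crosses(ev.waveform, ev.waveform_times):
                ev.label = pl.label
                break
    return events


def propose_polylines(
    events: list[SpikeEvent], min_events: int = 20
) -> list[ThresholdPolyline]:
    """Propose a sorting polyline from the trough-amplitude distribution.

    When the per-event trough amplitudes are bimodal, a horizontal line
    at the midpoint between the two modes separates the deeper
    population; unimodal distributions yield no polylines.  A stand-in
    for drawing the line by eye.
    """
    if len(events) < min_events:
        return []
    amps = np.array([ev.trough_amplitude for ev in events])
    if np.ptp(amps) <= 0:
        return []
    from sklearn.mixture import GaussianMixture

    x = amps.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=0).fit(x)
    gm2 = GaussianMixture(2, n_init=3, random_state=0).fit(x)
    if gm2.bic(x) >= gm1.bic(x):
        return []  # not convincingly bimodal
    m1, m2 = np.sort(gm2.means_.ravel())
    sds = np.sqrt(gm2.covariances_.ravel())
    if (m2 - m1) < 2.0 * sds.mean():
        return []  # modes overlap too much to draw a line between them
    split = 0.5 * (m1 + m2)
    wt = events[0].waveform_times
    verts = np.array([[wt[0], split], [wt[-1], split]])
    return [ThresholdPolyline(vertices=verts, label="unit1")]


def events_to_trains(
    events: list[SpikeEvent], duration: float
) -> dict[tuple[str, str], SpikeTrain]:
    """Group labeled events into per-(channel, unit) spike trains."""
    grouped: dict[tuple[str, str], list[float]] = {}
    for ev in events:
        key = (ev.channel_id, ev.label or "unit1")
        grouped.setdefault(key, []).append(ev.time)
    return {
        key: SpikeTrain(times=np.array(ts), duration=duration, channel_id=key[0], unit=key[1])
        for key, ts in grouped.items()
    }


def compute_rate(train: SpikeTrain, bin_width: float = 0.1) -> RateSeries:
    """Bin spike counts and convert to Hz (count / bin width).

    With the default 100 ms bins this is the count multiplied by 10.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(int(np.ceil(train.duration / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(train.times, bins=edges)
    return RateSeries(
        values=counts / bin_width,
        bin_width=bin_width,
        channel_id=train.channel_id,
    )


def normalize_rate(
    series: RateSeries,
    target_bin: float = 10.0,
    baseline_bins: int = 10,
    lam: float | None = 1.0,
) -> RateSeries:
    """Smooth, re-bin to 10 s averages, scale first-100-s mean to 1.

    The rate is smoothed with a cubic smoothing spline (``lam`` is the
    roughness weight in time-in-seconds units; the mild default of 1
    suppresses bin-to-bin counting noise and reproduces constants
    exactly, and None lets generalized cross-validation choose it),
    averaged over non-overlapping ``target_bin``-second intervals,
    and divided by the mean of the first ``baseline_bins`` such
    intervals, making the output dimensionless with a first-100-s mean
    of exactly 1.  Series already at the target bin width pass through
    unsmoothed (so normalization is idempotent).  A silent baseline
    (first-100-s mean of 0) cannot be normalized and is rejected.
    """
    need = target_bin * baseline_bins
    if series.duration < need - 1e-9:
        raise ValueError(f"series must span at least {need:g} s to normalize")
    if abs(series.bin_width - target_bin) < 1e-12:
        coarse = series.values.copy()
    else:
        x = series.bin_midpoints()
        y = series.values
        if np.ptp(y) == 0:
            smooth = y.astype(np.float64)
        else:
            spline = make_smoothing_spline(x, y, lam=lam)
            smooth = np.clip(spline(x), 0.0, None)
        per = int(round(target_bin / series.bin_width))
        if abs(per * series.bin_width - target_bin) > 1e-9:
            raise ValueError("target_bin must be a multiple of the series bin width")
        n_coarse = smooth.size // per
        coarse = smooth[: n_coarse * per].reshape(n_coarse, per).mean(axis=1)
    n_raw = int(round(need / series.bin_width))
    if series.values[:n_raw].mean() <= 0:
        raise ValueError("cannot normalize a silent baseline (first-100-s mean is 0)")
    baseline = coarse[:baseline_bins].mean()
    if baseline <= 0:
        raise ValueError("cannot normalize a silent baseline (first-100-s mean is 0)")
    return RateSeries(
        values=coarse / baseline,
        bin_width=target_bin,
        start_time=series.start_time,
        channel_id=series.channel_id,
        normalized=True,
    )
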