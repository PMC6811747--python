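"""Core data containers shared across the pipeline.

The central currency of the package is the spike train and its binned
rate series; raw multichannel voltage matrices enter at one end and
summary statistics (bursts, synchrony, dose fits) leave at the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawRecording",
    "FilteredRecording",
    "SpikeEvent",
    "SpikeTrain",
    "RateSeries",
    "NetworkBurst",
    "ROITrace",
]


@dataclass
class RawRecording:
    """Multichannel extracellular voltage recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage samples, in ``unit`` (microvolts by default).
    sampling_rate : float
        Samples per second (Hz).
    channel_ids : list of str
        One identifier per channel.
    unit : str
        Physical unit of the samples.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[str]
    unit: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def time(self) -> np.ndarray:
        """Sample times in seconds (starting at 0)."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class FilteredRecording(RawRecording):
    """Recording after filtering, with the filter descriptor attached."""

    filter_type: str = "bessel"
    filter_order: int = 4
    filter_cutoff_hz: float = 400.0
    filter_mode: str = "highpass"
    zero_phase: bool = False


@dataclass
class SpikeEvent:
    """A single detected extracellular spike.

    ``time`` is the trough time in seconds.  ``waveform`` is the voltage
    snippet around the trough (fixed window per run); ``waveform_times``
    are the snippet sample offsets relative to the trough, in
    milliseconds.  ``label`` is the sorted-unit tag (None = unsorted).
    """

    channel_id: str
    time: float
    waveform: np.ndarray
    waveform_times: np.ndarray
    label: str | None = None

    @property
    def trough_amplitude(self) -> float:
        return float(np.min(self.waveform))


@dataclass
class SpikeTrain:
    """Ordered event times for one (channel, unit)."""

    times: np.ndarray
    duration: float
    channel_id: str = "ch0"
    unit: str | None = None

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=np.float64))
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def mean_rate(self) -> float:
        """Mean firing rate over the recording, Hz."""
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


@dataclass
class RateSeries:
    """Binned firing rate: ``values[i]`` is the rate over bin ``i``.

    ``values`` are in Hz for raw series and dimensionless after
    normalization (``normalized`` flag).
    """

    values: np.ndarray
    bin_width: float
    start_time: float = 0.0
    channel_id: str = "ch0"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def bin_midpoints(self) -> np.ndarray:
        return self.start_time + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class NetworkBurst:
    """A network-wide burst epoch.

    ``participation`` is the fraction of active channels with at least
    one spike inside the window (NaN when spike trains were not given).
    """

    start: float
    end: float
    participation: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("burst end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ROITrace:
    """Calcium fluorescence time series for one ROI.

    ``raw`` holds the as-measured values; ``corrected`` (baseline
    subtracted) and ``normalized`` (0-to-1 scaled) are filled in by the
    calcium module.  ``channel_identity`` carries the dual-fluorescence
    cell-type call when available.
    """

    roi_id: str
    frame_interval: float
    raw: np.ndarray
    corrected: np.ndarray | None = None
    normalized: np.ndarray | None = None
    cfp_value: float | None = None
    gfp_value: float | None = None
    channel_identity: str | None = None
    true_transient_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_transient_amplitude: float = float("nan")

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.raw.size

    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval
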