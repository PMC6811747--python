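"""Intracellular (patch-clamp) step-family analysis.

Voltage-clamp families yield the fast inward sodium current I_Na per
step — measured as the local minimum within 30 ms of step onset minus
the mean current over the last 30 ms of the step — and the resulting
current–voltage (IV) curve.  Current-clamp families yield the spike
threshold (rheobase): the smallest injected current evoking an action
potential.  An action potential is defined operationally as an upstroke
of at least ``min_dvdt`` mV/ms whose peak exceeds ``min_peak`` mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "StepTraceFamily",
    "IVCurve",
    "APCriterion",
    "extract_ina",
    "build_iv",
    "spike_threshold",
    "count_spontaneous_spikes",
]


@dataclass
class StepTraceFamily:
    """A family of step responses from one cell.

    mode : 'voltage_clamp' (command in mV, response in pA) or
        'current_clamp' (command in pA, response in mV).
    levels : per-step command level, strictly increasing.
    traces : (n_steps, n_samples) response matrix.
    onset, offset : step start/end in seconds within each sweep.
    """

    mode: str
    levels: np.ndarray
    traces: np.ndarray
    sampling_rate: float
    onset: float
    offset: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if self.mode not in ("voltage_clamp", "current_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.traces.ndim != 2 or self.traces.shape[0] != self.levels.size:
            raise ValueError("traces must be (n_steps, n_samples)")
        if self.levels.size > 1 and not np.all(np.diff(self.levels) > 0):
            raise ValueError("levels must be strictly increasing")
        if not 0 <= self.onset < self.offset:
            raise ValueError("need 0 <= onset < offset")

    @property
    def n_steps(self) -> int:
        return self.levels.size

    def time(self) -> np.ndarray:
        return np.arange(self.traces.shape[1]) / self.sampling_rate


@dataclass
class IVCurve:
    """I_Na per command voltage, plus the voltage of the largest inward current."""

    voltages_mV: np.ndarray
    ina_pA: np.ndarray

    def __post_init__(self) -> None:
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=np.float64)
        self.ina_pA = np.asarray(self.ina_pA, dtype=np.float64)
        if self.voltages_mV.shape != self.ina_pA.shape:
            raise ValueError("voltages and currents must have equal length")

    @property
    def peak_voltage_mV(self) -> float:
        """Command voltage at the most-negative (largest inward) I_Na."""
        return float(self.voltages_mV[np.argmin(self.ina_pA)])


@dataclass
class APCriterion:
    """Operational action-potential definition.

    min_dvdt : minimum upstroke slope, mV/ms.
    min_peak : minimum peak membrane voltage, mV.
    """

    min_dvdt: float = 10.0
    min_peak: float = -10.0


def extract_ina(
    trace: np.ndarray,
    sampling_rate: float,
    onset: float,
    offset: float,
    window: float = 0.030,
) -> float:
    """I_Na of one voltage-clamp sweep, in the trace's current units.

    The local minimum of the evoked current within ``window`` (30 ms by
    default) of step onset, minus the mean current over the last
    ``window`` of the step.  Negative values denote a net inward
    transient.  The early and late windows must not overlap.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if offset - onset < 2 * window:
        raise ValueError(
            f"step of {offset - onset:.4f}s too short for non-overlapping "
            f"{window * 1e3:.0f} ms windows"
        )
    i0 = int(round(onset * sampling_rate))
    i1 = int(round((onset + window) * sampling_rate))
    j0 = int(round((offset - window) * sampling_rate))
    j1 = int(round(offset * sampling_rate))
    early_min = float(np.min(trace[i0 : i1 + 1]))
    late_mean = float(np.mean(trace[j0:j1]))
    return early_min - late_mean


def build_iv(family: StepTraceFamily, window: float = 0.030) -> IVCurve:
    """IV curve of a voltage-clamp family: extract_ina per step."""
    if family.mode != "voltage_clamp":
        raise ValueError("build_iv requires a voltage-clamp family")
    ina = np.array(
        [
            extract_ina(tr, family.sampling_rate, family.onset, family.offset, window)
            for tr in family.traces
        ]
    )
    return IVCurve(voltages_mV=family.levels, ina_pA=ina)


def _detect_aps(
    trace: np.ndarray, sampling_rate: float, criterion: APCriterion
) -> np.ndarray:
    """Indices of action-potential peaks in a membrane-voltage trace."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < 3:
        return np.empty(0, dtype=int)
    peaks, _ = find_peaks(trace, height=criterion.min_peak)
    if peaks.size == 0:
        return peaks
    # upstroke slope over the 2 ms preceding each candidate peak
    dvdt = np.gradient(trace) * sampling_rate / 1e3  # mV/ms
    pre = max(1, int(round(0.002 * sampling_rate)))
    keep = [
        p for p in peaks if np.max(dvdt[max(0, p - pre) : p + 1]) >= criterion.min_dvdt
    ]
    return np.asarray(keep, dtype=int)


def spike_threshold(
    family: StepTraceFamily, criterion: APCriterion | None = None
) -> float | None:
    """Smallest current step (pA) whose response contains an action potential.

    Returns None if no step evokes a spike.
    """
    if family.mode != "current_clamp":
        raise ValueError("spike_threshold requires a current-clamp family")
    criterion = criterion or APCriterion()
    for level, trace in zip(family.levels, family.traces):
        if _detect_aps(trace, family.sampling_rate, criterion).size:
            return float(level)
    return None


def count_spontaneous_spikes(
    trace: np.ndarray,
    sampling_rate: float,
    criterion: APCriterion | None = None,
) -> tuple[int, np.ndarray]:
    """Action-potential count and peak times (s) in a free-running Vm trace."""
    criterion = criterion or APCriterion()
    idx = _detect_aps(np.asarray(trace, dtype=np.float64), sampling_rate, criterion)
    return idx.size, idx / sampling_rate
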