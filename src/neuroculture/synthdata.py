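"""Synthetic cultured-network data with retained ground truth.

Generates the full range of signals the analysis pipeline consumes:

* spike trains from bursting, tonic, or mixed (coculture-like)
  populations — bursting networks emit synchronized bursts separated by
  inter-burst intervals drawn from a configurable range (2–10 s by
  default, the range observed in Chx10-like cultures), tonic
  populations fire independent Poisson trains (HB9-like), and mixtures
  entrain tonic units into the network bursts;
* pharmacological wash-in modulation (baseline / linear ramp / steady
  state) with saturable Hill-type spike thinning;
* rendered multielectrode-array voltage traces (biphasic spike
  waveforms over Gaussian noise, 60 electrodes at 20 kHz by default);
* calcium indicator ROI traces with photobleach drift;
* patch-clamp voltage- and current-step families.

Every generator keeps its ground truth (true spike times, phenotypes,
burst windows, applied drug effect) so downstream recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import RawRecording, ROITrace
from .patch import StepTraceFamily

__all__ = [
    "NetworkSimConfig",
    "SimGroundTruth",
    "MEARenderConfig",
    "DrugProtocol",
    "CalciumSimConfig",
    "PatchSimConfig",
    "simulate_spike_trains",
    "apply_drug_protocol",
    "render_mea",
    "simulate_calcium",
    "simulate_patch_family",
    "simulate_membrane_trace",
]

PHENOTYPES = ("burster", "tonic", "mixture")


# ---------------------------------------------------------------------------
# configs


@dataclass
class NetworkSimConfig:
    """Population spiking model.

    mixture_ratio is the tonic:burster unit ratio for phenotype
    'mixture' (default 2.5, i.e. 5:2).  burst_participation is the
    probability that a bursting unit fires in any given burst;
    entrainment is the probability that a tonic unit of a mixture joins
    a given burst.  silent_fraction silences units outright (they keep
    their slot but emit nothing), emulating inactive cells.
    """

    n_units: int = 20
    phenotype: str = "burster"
    mixture_ratio: float = 2.5
    duration: float = 120.0
    ibi_range: tuple[float, float] = (2.0, 10.0)
    burst_duration: float = 1.0
    within_burst_rate: float = 50.0
    burst_participation: float = 0.9
    tonic_rate: float = 2.0
    entrainment: float = 0.9
    silent_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")
        if not (0 < self.ibi_range[0] <= self.ibi_range[1]):
            raise ValueError("ibi_range must satisfy 0 < min <= max")
        for name in ("within_burst_rate", "tonic_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("burst_participation", "entrainment", "silent_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")


@dataclass
class SimGroundTruth:
    """Generator-side record: the oracle for every recovery test.

    unit_times : per-unit spike time arrays (seconds).
    phenotypes : per-unit label in {'burster','tonic','silent'}.
    burst_windows : sorted, non-overlapping (start, end) pairs.
    joined_bursts : per-unit set of burst indices the unit fired in.
    drug_effect : parameters of the applied protocol, if any.
    """

    unit_times: list[np.ndarray]
    phenotypes: list[str]
    burst_windows: list[tuple[float, float]]
    duration: float
    joined_bursts: list[set[int]] = field(default_factory=list)
    drug_effect: dict | None = None

    @property
    def n_units(self) -> int:
        return len(self.unit_times)

    def pooled_times(self) -> np.ndarray:
        if not self.unit_times:
            return np.empty(0)
        return np.sort(np.concatenate(self.unit_times))

    def inter_burst_intervals(self, convention: str = "end_to_start") -> np.ndarray:
        """Gaps between successive burst windows."""
        w = self.burst_windows
        if len(w) < 2:
            return np.empty(0)
        starts = np.array([s for s, _ in w])
        ends = np.array([e for _, e in w])
        if convention == "end_to_start":
            return starts[1:] - ends[:-1]
        if convention == "start_to_start":
            return np.diff(starts)
        raise ValueError("convention must be 'end_to_start' or 'start_to_start'")


@dataclass
class MEARenderConfig:
    """Rendering of spike trains into extracellular voltage traces.

    Waveforms are fixed biphasic (negative-then-positive) templates;
    ``amplitude`` is the trough depth in multiples of ``noise_sd``.
    Each unit projects to exactly one electrode (round-robin when no
    explicit assignment is given), which keeps the sorting ground truth
    unambiguous.
    """

    n_electrodes: int = 60
    sampling_rate: float = 20_000.0
    noise_sd: float = 3.0  # uV
    amplitude: float | np.ndarray = 8.0  # per unit, in units of noise_sd
    waveform_width_ms: float = 2.4
    unit_electrode: list[int] | None = None
    # calibrate amplitudes to the acquisition high-pass: the template
    # trough *after* a causal Bessel filter of this order/cutoff equals
    # amplitude x noise_sd (the filter disperses fast transients, so an
    # uncalibrated trough would read ~40% smaller post-filter)
    calibrate_to_filter: bool = True
    calibration_cutoff_hz: float = 400.0
    calibration_order: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.n_electrodes <= 0:
            raise ValueError("sampling_rate and n_electrodes must be positive")
        if np.any(np.asarray(self.amplitude) <= 0):
            raise ValueError("amplitudes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class DrugProtocol:
    """Wash-in timeline and saturable suppression model.

    dose(t) is 0 during the baseline, ramps linearly to ``final_dose``
    over the ramp window, and is constant thereafter.  The survival
    probability of a spike at time t is 1 − efficacy·d/(d+EC50).
    target 'burst_coupling' additionally de-synchronizes surviving
    burst spikes (they are re-jittered to tonic-like times with
    probability equal to the momentary suppression); 'tonic_rate' thins
    only; 'none' leaves spikes untouched.
    """

    name: str = "CNQX"
    final_dose: float = 20.0  # uM
    baseline_s: float = 120.0
    ramp_s: float = 120.0
    steady_s: float = 240.0
    efficacy: float = 0.6
    ec50: float = 2.0  # uM
    target: str = "burst_coupling"

    def validate(self) -> None:
        if min(self.baseline_s, self.ramp_s, self.steady_s) <= 0:
            raise ValueError("all protocol durations must be positive")
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError("efficacy must lie in [0, 1]")
        if self.final_dose < 0 or self.ec50 <= 0:
            raise ValueError("final_dose must be >= 0 and ec50 > 0")
        if self.target not in ("burst_coupling", "tonic_rate", "none"):
            raise ValueError("unknown drug target")

    @property
    def total_duration(self) -> float:
        return self.baseline_s + self.ramp_s + self.steady_s

    def dose(self, t: float | np.ndarray) -> np.ndarray:
        """Dose (uM) at time(s) t seconds from recording start."""
        t = np.asarray(t, dtype=np.float64)
        ramp_frac = np.clip((t - self.baseline_s) / self.ramp_s, 0.0, 1.0)
        return self.final_dose * ramp_frac

    def survival(self, t: float | np.ndarray) -> np.ndarray:
        """Per-spike survival probability at time(s) t."""
        d = self.dose(t)
        return 1.0 - self.efficacy * d / (d + self.ec50)


@dataclass
class CalciumSimConfig:
    """Indicator-transient model for ROI traces.

    Each calcium event contributes an instant-rise, exponentially
    decaying transient of ``amplitude`` (a.u.).  ``bleach_drift`` is
    the fractional baseline decay over the whole recording.  The
    0.15 s default frame interval matches time-lapse imaging at a
    150 ms interval.
    """

    decay_s: float = 1.0
    amplitude: float = 1.0
    bleach_drift: float = 0.2
    frame_interval: float = 0.15
    noise_sd: float = 0.02
    baseline: float = 100.0
    cfp_high: float = 500.0
    gfp_high: float = 500.0
    channel_background: float = 20.0

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.decay_s <= self.frame_interval:
            raise ValueError("decay constant must exceed the frame interval")
        if not 0.0 <= self.bleach_drift < 1.0:
            raise ValueError("bleach_drift must lie in [0, 1)")


@dataclass
class PatchSimConfig:
    """Step families for one model cell.

    Voltage clamp: steps ``vstep_range`` in ``vstep_increment`` from a
    holding potential, each carrying a leak plateau plus a fast
    transient inward current whose peak follows a Boltzmann activation
    times driving force (largest inward current near 0 mV with the
    defaults, as for voltage-gated Na+ current).  Current clamp: 10 pA
    steps from −10 to 130 pA; responses spike iff the step reaches
    ``rheobase_pA``.
    """

    # voltage clamp
    holding_mV: float = -80.0
    vstep_range: tuple[float, float] = (-100.0, 150.0)
    vstep_increment: float = 10.0
    vstep_duration_s: float = 0.100
    peak_amplitude_pA: float = 500.0
    time_to_peak_ms: float = 5.0
    decay_ms: float = 5.0
    activation_midpoint_mV: float = -15.0
    activation_slope_mV: float = 5.0
    reversal_mV: float = 60.0
    leak_pA_per_mV: float = 0.5
    # current clamp
    istep_range: tuple[float, float] = (-10.0, 130.0)
    istep_increment: float = 10.0
    istep_duration_s: float = 1.0
    rheobase_pA: float = 20.0
    membrane_R_GOhm: float = 0.787
    membrane_tau_s: float = 0.018
    resting_mV: float = -70.0
    # common
    sampling_rate: float = 20_000.0
    pre_s: float = 0.020
    post_s: float = 0.020

    def validate(self) -> None:
        if self.time_to_peak_ms >= 30.0:
            raise ValueError("time_to_peak must be below 30 ms")
        if self.vstep_increment <= 0 or self.istep_increment <= 0:
            raise ValueError("step increments must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def transient_peak_pA(self, v_mV: float | np.ndarray) -> np.ndarray:
        """Peak transient current at command voltage v (negative = inward)."""
        v = np.asarray(v_mV, dtype=np.float64)
        m = 1.0 / (1.0 + np.exp(-(v - self.activation_midpoint_mV) / self.activation_slope_mV))
        scale = self.reversal_mV - self.activation_midpoint_mV
        return -self.peak_amplitude_pA * m * (self.reversal_mV - v) / scale


# ---------------------------------------------------------------------------
# spike-train generator


def _draw_burst_windows(cfg: NetworkSimConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    lo, hi = cfg.ibi_range
    windows: list[tuple[float, float]] = []
    t = rng.uniform(lo, hi)
    while t + cfg.burst_duration <= cfg.duration:
        windows.append((t, t + cfg.burst_duration))
        t = t + cfg.burst_duration + rng.uniform(lo, hi)
    return windows


def _poisson_times(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    span = t1 - t0
    if rate <= 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return np.sort(t0 + rng.uniform(0.0, span, size=n))


def simulate_spike_trains(config: NetworkSimConfig) -> SimGroundTruth:
    """Simulate a population per the configured phenotype.

    Bursting units fire inhomogeneous-Poisson spikes confined to shared
    burst windows (per-burst participation sampled independently);
    tonic units fire homogeneous Poisson trains; mixtures combine both,
    with tonic units entrained into bursts.  Identical seeds give
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.duration <= 0 or config.n_units == 0:
        return SimGroundTruth([], [], [], max(config.duration, 0.0), [])

    if config.phenotype == "burster":
        roles = ["burster"] * config.n_units
    elif config.phenotype == "tonic":
        roles = ["tonic"] * config.n_units
    else:
        r = config.mixture_ratio
        n_tonic = int(round(config.n_units * r / (1.0 + r)))
        roles = ["tonic"] * n_tonic + ["burster"] * (config.n_units - n_tonic)

    silent = rng.random(config.n_units) < config.silent_fraction

    windows: list[tuple[float, float]] = []
    if config.phenotype in ("burster", "mixture"):
        windows = _draw_burst_windows(config, rng)

    unit_times: list[np.ndarray] = []
    phenotypes: list[str] = []
    joined: list[set[int]] = []
    for u, role in enumerate(roles):
        if silent[u]:
            unit_times.append(np.empty(0))
            phenotypes.append("silent")
            joined.append(set())
            continue
        spikes: list[np.ndarray] = []
        joined_u: set[int] = set()
        if role == "burster":
            for b, (s, e) in enumerate(windows):
                if rng.random() < config.burst_participation:
                    ts = _poisson_times(config.within_burst_rate, s, e, rng)
                    if ts.size:
                        spikes.append(ts)
                        joined_u.add(b)
        else:  # tonic
            spikes.append(_poisson_times(config.tonic_rate, 0.0, config.duration, rng))
            if config.phenotype == "mixture":
                for b, (s, e) in enumerate(windows):
                    if rng.random() < config.entrainment:
                        ts = _poisson_times(config.within_burst_rate, s, e, rng)
                        if ts.size:
                            spikes.append(ts)
                            joined_u.add(b)
        times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        unit_times.append(times)
        phenotypes.append(role)
        joined.append(joined_u)

    return SimGroundTruth(unit_times, phenotypes, windows, config.duration, joined)


# ---------------------------------------------------------------------------
# drug modulation


def apply_drug_protocol(
    truth: SimGroundTruth, protocol: DrugProtocol, seed: int = 0
) -> SimGroundTruth:
    """Thin (and optionally de-synchronize) spikes along a wash-in timeline.

    Each spike at time t survives with probability
    ``1 − efficacy·dose(t)/(dose(t)+EC50)``; dose is 0 throughout the
    baseline, so baseline activity is untouched.  With target
    'burst_coupling', each surviving spike inside a burst window is
    additionally moved to a tonic-like (uniform within ±2 s) time with
    probability equal to the momentary suppression, emulating units
    that fall out of the network bursts and fire tonically.
    """
    protocol.validate()
    if truth.duration < protocol.total_duration - 1e-9:
        raise ValueError("ground truth does not cover the protocol timeline")
    rng = np.random.default_rng(seed)
    out_times: list[np.ndarray] = []
    windows = truth.burst_windows
    for times in truth.unit_times:
        if times.size == 0 or protocol.target == "none":
            out_times.append(times.copy())
            continue
        surv = protocol.survival(times)
        keep = rng.random(times.size) < surv
        kept = times[keep]
        if protocol.target == "burst_coupling" and kept.size and windows:
            suppression = 1.0 - protocol.survival(kept)
            in_burst = np.zeros(kept.size, dtype=bool)
            for s, e in windows:
                in_burst |= (kept >= s) & (kept <= e)
            jitter = in_burst & (rng.random(kept.size) < suppression)
            if np.any(jitter):
                kept = kept.copy()
                kept[jitter] = np.clip(
                    kept[jitter] + rng.uniform(-2.0, 2.0, size=int(jitter.sum())),
                    0.0,
                    truth.duration,
                )
        out_times.append(np.sort(kept))
    return SimGroundTruth(
        out_times,
        list(truth.phenotypes),
        list(truth.burst_windows),
        truth.duration,
        [set(j) for j in truth.joined_bursts],
        drug_effect={
            "name": protocol.name,
            "final_dose": protocol.final_dose,
            "efficacy": protocol.efficacy,
            "ec50": protocol.ec50,
            "target": protocol.target,
            "baseline_s": protocol.baseline_s,
            "ramp_s": protocol.ramp_s,
            "steady_s": protocol.steady_s,
        },
    )


# ---------------------------------------------------------------------------
# MEA rendering


def biphasic_template(
    sampling_rate: float, width_ms: float = 2.4, amplitude: float = 1.0
) -> tuple[np.ndarray, int]:
    """Biphasic (negative-then-positive) waveform template.

    Returns (samples, trough_index); trough depth equals ``amplitude``.
    """
    n = max(3, int(round(width_ms * 1e-3 * sampling_rate)))
    t = np.arange(n) / sampling_rate * 1e3  # ms
    # fast biphasic shape (sub-ms lobes, as extracellular spikes are);
    # width_ms sets the window length, not the lobe speed
    neg = np.exp(-0.5 * ((t - 0.4) / 0.08) ** 2)
    pos = 0.25 * np.exp(-0.5 * ((t - 1.1) / 0.3) ** 2)
    w = -neg + pos
    w *= amplitude / abs(w.min())
    return w, int(np.argmin(w))


def render_mea(truth: SimGroundTruth, config: MEARenderConfig) -> RawRecording:
    """Render ground-truth spike trains into a noisy voltage recording.

    Gaussian noise of the configured SD on every electrode, plus each
    unit's biphasic template inserted so that the template trough falls
    at the spike time on the unit's electrode.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = int(round(truth.duration * fs))
    amps = np.broadcast_to(np.asarray(config.amplitude, dtype=np.float64), (truth.n_units,))
    assignment = config.unit_electrode
    if assignment is None:
        assignment = [u % config.n_electrodes for u in range(truth.n_units)]
    if len(assignment) != truth.n_units:
        raise ValueError("unit_electrode must list one electrode per unit")

    data = rng.standard_normal((config.n_electrodes, n_samples)).astype(np.float32)
    data *= np.float32(config.noise_sd)

    gain = 1.0
    if config.calibrate_to_filter:
        from scipy import signal as _signal

        w0, _ = biphasic_template(fs, config.waveform_width_ms, 1.0)
        sos = _signal.bessel(
            config.calibration_order,
            config.calibration_cutoff_hz,
            btype="highpass",
            fs=fs,
            output="sos",
            norm="mag",
        )
        pad = np.zeros(w0.size * 4)
        resp = _signal.sosfilt(sos, np.concatenate([pad, w0, pad]))
        gain = 1.0 / abs(resp.min())

    for u, times in enumerate(truth.unit_times):
        if times.size == 0:
            continue
        if np.any(times > truth.duration) or np.any(times < 0):
            raise ValueError(f"unit {u} has spike times outside the recording")
        w, trough = biphasic_template(
            fs, config.waveform_width_ms, gain * amps[u] * config.noise_sd
        )
        ch = assignment[u]
        for t in times:
            i0 = int(round(t * fs)) - trough
            j0, j1 = max(i0, 0), min(i0 + w.size, n_samples)
            if j1 > j0:
                data[ch, j0:j1] += w[j0 - i0 : j1 - i0].astype(np.float32)

    ids = [f"el{i:02d}" for i in range(config.n_electrodes)]
    return RawRecording(samples=data, sampling_rate=fs, channel_ids=ids, unit="uV")


# ---------------------------------------------------------------------------
# calcium rendering


def simulate_calcium(
    truth: SimGroundTruth, config: CalciumSimConfig, seed: int = 0
) -> list[ROITrace]:
    """Render per-unit calcium indicator traces.

    trace = baseline·exp(−drift·t/T) + Σ transients + noise, with one
    instant-rise exponential transient per calcium event.  Bursting
    units get one event per joined burst (at their first spike inside
    it); tonic units get one event per spike.  Channel fluorescence
    values are assigned from the phenotype (burster ⇒ CFP-high,
    Chx10-like; tonic ⇒ GFP-high, HB9-like), with CFP-to-GFP crosstalk:
    CFP-positive cells also read high on the GFP channel.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    T = truth.duration
    n_frames = max(int(np.floor(T / config.frame_interval)), 1)
    t = np.arange(n_frames) * config.frame_interval
    traces: list[ROITrace] = []
    for u, times in enumerate(truth.unit_times):
        role = truth.phenotypes[u]
        if role == "burster" or (role == "tonic" and truth.joined_bursts[u]):
            events = []
            for b in sorted(truth.joined_bursts[u]):
                s, e = truth.burst_windows[b]
                inside = times[(times >= s) & (times <= e)]
                if inside.size:
                    events.append(inside[0])
            if role == "tonic":  # entrained: tonic background events too
                outside = times.copy()
                for s, e in truth.burst_windows:
                    outside = outside[(outside < s) | (outside > e)]
                events.extend(outside.tolist())
            events = np.sort(np.asarray(events))
        else:
            events = times
        denom = T if T > 0 else 1.0
        sig = config.baseline * np.exp(-config.bleach_drift * t / denom)
        for te in events:
            mask = t >= te
            sig[mask] += config.amplitude * np.exp(-(t[mask] - te) / config.decay_s)
        if config.noise_sd > 0:
            sig = sig + rng.normal(0.0, config.noise_sd, size=n_frames)
        is_cfp = role == "burster"
        is_gfp = role == "tonic"
        traces.append(
            ROITrace(
                roi_id=f"roi_{u:03d}",
                frame_interval=config.frame_interval,
                raw=sig,
                cfp_value=config.cfp_high if is_cfp else config.channel_background,
                gfp_value=(
                    config.gfp_high
                    if (is_gfp or is_cfp)  # CFP bleeds into the GFP channel
                    else config.channel_background
                ),
                true_transient_times=np.asarray(events, dtype=np.float64),
                true_transient_amplitude=config.amplitude,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# patch-clamp rendering


def _alpha_kernel(t: np.ndarray, ttp: float, decay: float) -> np.ndarray:
    """Unit-peak transient: linear-ish rise to peak at ttp, exp decay after."""
    out = np.zeros_like(t)
    rise = (t >= 0) & (t < ttp)
    out[rise] = t[rise] / ttp
    fall = t >= ttp
    out[fall] = np.exp(-(t[fall] - ttp) / decay)
    return out


def simulate_patch_family(config: PatchSimConfig, mode: str = "voltage_clamp",
                          seed: int | None = None) -> StepTraceFamily:
    """Simulate a voltage- or current-clamp step family.

    Voltage-clamp sweeps: leak plateau (leak slope × step size) plus a
    fast inward transient peaking ``time_to_peak_ms`` after onset with
    voltage-dependent amplitude (``transient_peak_pA``).  Current-clamp
    sweeps: RC charging toward V∞ = resting + R·I, with stereotyped
    action potentials inserted iff the step reaches the rheobase.
    Noise-free unless a seed is given.
    """
    config.validate()
    fs = config.sampling_rate
    rng = np.random.default_rng(seed) if seed is not None else None
    if mode == "voltage_clamp":
        lo, hi = config.vstep_range
        levels = np.arange(lo, hi + 0.5 * config.vstep_increment, config.vstep_increment)
        onset, dur = config.pre_s, config.vstep_duration_s
        n = int(round((config.pre_s + dur + config.post_s) * fs))
        t = np.arange(n) / fs
        traces = np.zeros((levels.size, n))
        for i, v in enumerate(levels):
            step = (t >= onset) & (t < onset + dur)
            leak = config.leak_pA_per_mV * (v - config.holding_mV)
            traces[i, step] += leak
            peak = config.transient_peak_pA(v)
            k = _alpha_kernel(t - onset, config.time_to_peak_ms * 1e-3, config.decay_ms * 1e-3)
            k[~step] = 0.0
            traces[i] += peak * k
            if rng is not None:
                traces[i] += rng.normal(0.0, 2.0, size=n)
        return StepTraceFamily("voltage_clamp", levels, traces, fs, onset, onset + dur)
    if mode == "current_clamp":
        lo, hi = config.istep_range
        levels = np.arange(lo, hi + 0.5 * config.istep_increment, config.istep_increment)
        onset, dur = config.pre_s, config.istep_duration_s
        n = int(round((config.pre_s + dur + config.post_s) * fs))
        t = np.arange(n) / fs
        traces = np.full((levels.size, n), config.resting_mV)
        for i, amp in enumerate(levels):
            step = (t >= onset) & (t < onset + dur)
            dv = config.membrane_R_GOhm * amp  # GOhm * pA = mV
            charge = 1.0 - np.exp(-(t[step] - onset) / config.membrane_tau_s)
            traces[i, step] += dv * charge
            if amp >= config.rheobase_pA:
                spike_times = np.arange(onset + 0.030, onset + dur - 0.010, 0.100)
                traces[i] = _insert_aps(traces[i], spike_times, fs)
            if rng is not None:
                traces[i] += rng.normal(0.0, 0.3, size=n)
        return StepTraceFamily("current_clamp", levels, traces, fs, onset, onset + dur)
    raise ValueError("mode must be 'voltage_clamp' or 'current_clamp'")


def _ap_template(fs: float) -> tuple[np.ndarray, int]:
    """Stereotyped action potential: fast rise to +30 mV, repolarizing fall.

    Returned as an additive waveform normalized to raise the membrane
    to +30 mV at its peak when added near rest; peak index returned.
    """
    rise_n = max(2, int(round(0.0008 * fs)))
    fall_n = max(2, int(round(0.0025 * fs)))
    rise = np.linspace(0.0, 1.0, rise_n, endpoint=False)
    fall = np.exp(-np.arange(fall_n) / (0.0008 * fs))
    w = np.concatenate([rise, fall])
    return w, rise_n


def _insert_aps(trace: np.ndarray, spike_times: np.ndarray, fs: float) -> np.ndarray:
    out = trace.copy()
    w, peak_i = _ap_template(fs)
    for ts in np.atleast_1d(spike_times):
        i0 = int(round(ts * fs)) - peak_i
        j0, j1 = max(i0, 0), min(i0 + w.size, out.size)
        if j1 <= j0:
            continue
        local = out[j0:j1]
        # scale so the AP peak reaches +30 mV from the local membrane level
        height = 30.0 - trace[min(max(i0 + peak_i, 0), out.size - 1)]
        out[j0:j1] = local + height * w[j0 - i0 : j1 - i0]
    return out


def simulate_membrane_trace(
    spike_times: np.ndarray,
    duration: float,
    sampling_rate: float = 10_000.0,
    resting_mV: float = -55.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Free-running membrane voltage with stereotyped APs at given times."""
    n = int(round(duration * sampling_rate))
    trace = np.full(n, resting_mV)
    trace = _insert_aps(trace, np.asarray(spike_times, dtype=np.float64), sampling_rate)
    if noise_sd > 0:
        trace = trace + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return trace
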