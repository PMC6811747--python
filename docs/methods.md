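# Methods

This note records the models behind each stage, the parameters that
matter, and the choices made where the procedure was genuinely open.

## Synthetic network model

The generator is phenomenological, not biophysical: it reproduces the
*statistics* that the analysis consumes, with ground truth retained.

**Bursting networks.** Burst windows are laid down sequentially: each
window lasts `burst_duration` (default 1 s) and the gap to the next
window is drawn uniformly from `ibi_range` (default 2–10 s, the
inter-burst interval range typical of rhythmogenic V2a cultures).
Within a window, each unit participates with probability
`burst_participation` (0.9) and, if participating, fires a homogeneous
Poisson train at `within_burst_rate` (50 Hz) confined to the window.
No spikes occur outside windows, mirroring sharply delineated bursting.
Burst duration and within-burst rate are free parameters of this
package — realistic round numbers, not literature values.

**Tonic populations.** Independent homogeneous Poisson trains at
`tonic_rate` (2 Hz), uncorrelated across units.

**Cocultures.** Units are split tonic:burster at `mixture_ratio`
(default 2.5, i.e. 5:2 — the plating ratio that motivates the
scenario). Each tonic unit joins each burst with probability
`entrainment` (0.9), adding a within-burst Poisson volley on top of
its tonic background; this produces the "tonic unit recruited into
network bursts" phenotype. `silent_fraction` converts units into
inactive cells so classification has a true "none" class.

**Drug wash-in.** dose(t) is 0 for the baseline (120 s), rises
linearly over the ramp (120 s) to `final_dose`, and is constant for
the steady state (240 s). Chamber mixing kinetics are unknown, so the
linear ramp is the simplest timeline consistent with the 2–4 min
wash-in analysis window. Each spike at time t survives with
probability 1 − efficacy·d(t)/(d(t)+EC50) — a saturable Hill-type
survival so a finite efficacy (default 0.6, chosen so saturating doses
leave ~40% of baseline activity) can be dialled independently of dose.
For `target="burst_coupling"` a surviving burst spike is additionally
re-jittered to a tonic-like time (uniform ±2 s) with probability equal
to the momentary suppression, emulating units that fall out of the
network rhythm and fire tonically before silencing.

**MEA rendering.** Each unit projects to exactly one electrode
(round-robin), keeping sorting ground truth unambiguous; multi-electrode
spread is deliberately not modelled. Electrode traces are Gaussian
noise (`noise_sd`, default 3 µV) plus a fixed biphasic
(negative-then-positive) template per spike, with sub-millisecond
lobes as real extracellular spikes have. Amplitude is specified in
multiples of the noise SD **as seen through the acquisition filter**:
a causal Bessel high-pass disperses a fast transient and shrinks its
trough by roughly 40% even though its magnitude response at the
waveform's dominant frequencies is near unity, so templates are scaled
such that the post-filter trough equals `amplitude × noise_sd`. An
"8σ unit" therefore means 8σ where detection happens, which is the
only scale at which amplitude statements are well defined.

**Calcium traces.** trace = baseline·exp(−drift·t/T) + Σ transients +
noise. Each calcium event contributes an instant-rise exponential
decay (`decay_s` = 1 s, amplitude 1 a.u.); bursting units get one
event per joined burst, tonic units one per spike. The frame interval
defaults to 0.15 s (time-lapse at a 150 ms interval). Channel
fluorescence is assigned from phenotype with CFP→GFP crosstalk built
in, so the identity rule has something real to disambiguate.

**Patch families.** Voltage-clamp sweeps hold at −80 mV and step
−100…+150 mV in 10 mV increments (the conventional reading of a
protocol whose printed units mix pA and mV); each sweep carries a
linear leak plateau plus a fast inward transient peaking 5 ms after
onset whose amplitude follows a Boltzmann activation times driving
force — with the default midpoint (−15 mV), slope (5 mV) and reversal
(+60 mV) the largest inward current falls at 0 mV on the 10 mV grid,
matching the ~0 mV peak of voltage-gated Na⁺ IV curves in young
cultured neurons. Current-clamp sweeps are RC charging
(R = 0.787 GΩ, τ = 18 ms) with stereotyped action potentials inserted
iff the step reaches `rheobase_pA` (default 20 pA).

## MEA pipeline

* **Filtering** is a causal (single-pass) Bessel 4th-order high-pass,
  magnitude-normalized so the −3 dB point sits at the 400 Hz cutoff;
  causal because that is what acquisition software applies online.
  Zero-phase filtering is available (`zero_phase=True`) but not the
  default.
* **Detection** thresholds each channel at mean − k·SD (k = 5),
  one-sided — "below the mean" is read literally; absolute-value
  detection is rejected. Events are timestamped at the trough of each
  below-threshold excursion. The SD is estimated over the whole
  recording; a MAD-based robust option exists for burst-dense
  channels, and k can be overridden per channel (the analogue of
  manually adjusted thresholds). Crossings within the dead time
  (1 ms) of the previous trough are suppressed, as are re-crossings
  within the waveform post-window (2 ms): a large spike's filtered
  waveform can re-cross threshold on its post-lobe undershoot, and
  that undershoot belongs to the same spike, not a new one.
* **Waveform window** is 1 ms before to 2 ms after the trough —
  enough to cover a biphasic extracellular waveform at 20 kHz; events
  whose window would overrun the recording edge are dropped.
* **Sorting** labels an event by the first threshold polyline its
  waveform dips below (crossing = below), with a residual class for
  events crossing none — a faithful mechanization of drawing a line
  through visually similar waveforms. The automatic proposal fits 1-
  and 2-component Gaussian mixtures to the trough amplitudes and, when
  the 2-component fit wins by BIC with well-separated means, places a
  horizontal line at the midpoint between them. Manual polylines
  remain the canonical input.
* **Rates** are counts per 100 ms bin × 10 ⇒ Hz. **Normalization**
  smooths the rate with a cubic smoothing spline (roughness weight 1.0
  in time-in-seconds units — mild, reproduces constants exactly;
  GCV selection available), averages over non-overlapping 10 s
  intervals, and divides by the mean of the first ten intervals, so
  the first 100 s average exactly 1. Series already at 10 s bins pass
  through unsmoothed, making normalization idempotent. A silent first
  100 s cannot be normalized and is rejected.

## Network bursts, synchrony, classification

The burst detector is this package's own (the phenomenon was
originally assessed by eye): threshold = max(5 × median population
rate, 1 Hz floor) on 100 ms bins; supra-threshold runs are expanded by
one bin per side (a burst edge inside a bin leaves that partial bin
sub-threshold), merged across gaps < 200 ms, refined to the
first/last pooled spike inside each epoch, and dropped if shorter than
100 ms. The median is a robust quiescence estimate — for a bursting
culture it sits near zero, so the absolute floor carries the
threshold. Inter-burst intervals are reported end-to-start by default
(start-to-start available) since the quiescent gap is what "interval
between bursts" most naturally means.

"Active channel" means mean rate ≥ 0.1 Hz over the recording.
Synchrony is zero-lag Pearson correlation between 100 ms-binned rates;
the peak cross-correlation within ±max_lag (with its lag) is a
secondary output. Constant series give undefined (NaN) pairs excluded
from the matrix mean.

Classification: a cell meets the burst criterion when ≥ 50% of
network bursts contain at least one of its events, and the spiking
criterion when ≥ 3 events fall outside all bursts; the four classes
follow from the two criteria. Both thresholds are config-exposed;
they are this package's operationalization of a classification
originally done by eye. The summary table reports counts and
percentages rounded half-up to integers.

## Dose–response model

The canonical fit is `dose ~ 1 + normalized rate + (1|electrode)` —
dose as the response, kept in that orientation even though it is
unconventional (it asks "what dose is consistent with this activity
level", which makes the slope a sensitivity in µM per unit rate); the
conventional rate-on-dose OLS is attached to every result as a
clearly-labeled secondary output. Bins outside the wash-in window
(midpoints in [120 s, 240 s)) are excluded. Estimation is maximum
likelihood (not REML) so nested-model likelihoods are comparable;
inference on β₁ is a Wald normal-approximation test (the null
calibration sits at ~5% for 20 electrodes × 12 bins; see the test
suite). Dose is assigned at each 10 s bin midpoint under the linear
ramp. σ_u on the boundary (zero) is a legitimate outcome and is
reported as such; `force_ols=True` gives the exact σ_u → 0 limit.
Pooling across trials relabels electrodes uniquely; per-trial fits are
available by fitting experiments singly.

## Calcium processing

The baseline is a cubic smoothing spline fit to the trace in
frame-index units, made robust in two ways: the trace is extended by
odd (point) reflection at both ends before fitting (a natural spline's
free-end conditions otherwise bias the boundary), and the fit is
iterated (≤ 4 times) with frames whose positive residual exceeds 2
robust SDs masked out, the mask dilated 12 frames forward so the
sub-threshold decay tail of a transient does not pull the baseline up.
The default roughness weight (λ = 400) was calibrated against the
package's own acceptance yardsticks: a constant and a 100-frame-period
sinusoid must be absorbed into the baseline (residual < 5%) while a
few-frame transient passes through with < 5% amplitude loss. The
often-quoted smoothing parameter 0.0001 belongs to a specific tool's
p·fidelity + (1−p)·roughness convention; `matlab_smoothing_to_lam`
converts it ((1−p)/p ≈ 10⁴ at unit frame spacing), but the conversion
is convention-dependent, which is why the default is calibrated rather
than translated.

Normalization to [0, 1] is (x − min)/(max − min); constant traces map
to zeros by declared contract. Event detection takes local maxima
above 5 robust SDs with at least one indicator decay constant between
events and a prominence requirement equal to the height threshold (so
noise bumps riding a decay tail are not events). Identity: CFP above
threshold ⇒ Chx10 regardless of GFP (CFP emission registers on the
GFP channel, so GFP positivity is uninformative for CFP⁺ cells); GFP
above threshold with CFP below ⇒ HB9; otherwise unlabeled. The
positivity thresholds are inputs — nothing in the data fixes them —
and the midpoint between background and labeled-cell levels is the
sensible default. Pixel membership is pixel-center-in-polygon under
the even-odd rule.

## Patch analysis

I_Na = min(trace over [onset, onset+30 ms]) − mean(trace over the last
30 ms of the step); "local minimum within 30 ms" is read as the global
minimum over that window, which is robust to multi-trough traces. The
two windows must not overlap (steps ≥ 60 ms). The action-potential
criterion — upstroke ≥ 10 mV/ms and peak ≥ −10 mV — is an
operational definition chosen here; rheobase is the smallest step
whose response contains one. Leak subtraction beyond the two-window
rule (P/N protocols) is deliberately out of scope.

## Problem sizes and determinism

All simulations are deterministic under their seeds (verified
bit-identical in the suite). Default study conditions: 20 units,
120 s for phenotype comparisons; 60 channels × 60 s at 20 kHz for the
detection round trip; 20 electrodes × 12 wash-in bins for the mixed
model, with 100 replicates for slope coverage and 200 for null
calibration; 800-frame calcium traces with three transients. These
sizes keep every check at desk scale while leaving the statistics
comfortably clear of their thresholds.

## What passing on synthetic data does and does not show

The generator's spikes are Poisson with stationary rates, one unit per
electrode, fixed waveforms, and Gaussian noise. Real recordings add
waveform drift, electrode crosstalk, overlapping units, non-Poisson
burst microstructure (adaptation, intra-burst oscillation), movement
and perfusion artifacts, and calcium indicator nonlinearity/saturation
— none of which are modelled. Recovery rates measured here are
therefore upper bounds on real-data performance: they verify that the
implementations are correct and well-calibrated, not that the
thresholds are optimal for any particular preparation. The LME
recovery shows calibration when the model is true; with real rate
series the dose-as-response orientation inherits whatever measurement
error the rates carry. Known further limitations: no conductance-based
network model, no astrocyte calcium waves, no streaming detection, no
stimulation-artifact blanking, no automatic ROI segmentation, and no
motion correction.
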