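# Methods

This note documents the models, parameters and numerical choices behind the
package, and what the simulation studies do and do not establish.

## Generative model

**Acquisition.** The default montage is a mirror-symmetric two-row occipital
grid of 8 sources and 7 detectors forming 22 channels (11 per hemisphere, no
midline channels), sampled at 10.2 Hz at 760/850 nm.  The montage geometry
is synthetic: it satisfies the optode/channel counts and left–right symmetry
of a real occipital array, with hemisphere labels derived from the sign of
the channel-midpoint x-coordinate and a nominal 3 cm source–detector
separation for every channel.  The event schedule interleaves 20 patterned
stimulus (STIM) and 20 zero-contrast mock (MOCK) trials, 5 s on / 10 s off,
by a uniform seeded shuffle with no run-length constraint — a 10-minute
block.  Recordings carry a 5 s pre/post roll so the full peri-stimulus
window of every trial is in-bounds.

**Evoked response.** Each STIM trial contributes a double-gamma kernel
convolved with the stimulus boxcar, renormalized to unit single-trial peak.
Kernel defaults: peak delay 5 s, dispersion 0.6 s; undershoot delay 11 s,
dispersion 0.8 s, ratio 1/6.  This is deliberately more compact than the
canonical adult fMRI kernel: with a 10 s rest the response must return near
baseline before the next trial, which matches pediatric visual fNIRS
waveforms and keeps inter-trial overlap ≲2% of the peak.  DHb is −1/3 of
the OHb amplitude lagged by 1 s; THb is computed as OHb + DHb exactly.
MOCK trials evoke exactly nothing in the generative model.

**Group structure.** Per-channel OHb amplitude =
subject amplitude × hemisphere gain × channel jitter.  Defaults:

| parameter | TD | fASD | meaning |
|---|---|---|---|
| `ohb_amplitude` | 3.2e−5 M | 1.8e−5 M | left-hemisphere single-trial OHb peak |
| `between_subject_sd` | 0.9e−5 M | 0.9e−5 M | subject-level amplitude SD |
| `lateralization` λ | 1.5 | 1.0 | right-hemisphere gain (λ>1 → rightward) |
| `lateralization_sd_log` | 0.10 | 0.35 | between-subject SD of log λ |
| `channel_amp_sd_frac` | 0.10 | 0.10 | per-channel amplitude jitter |

With equal hemisphere counts the ground-truth laterality index is
LI = (1−λ)/(1+λ): ≈ −0.2 for TD, ≈ 0 but highly variable for fASD.  The
amplitude separation (Cohen's d ≈ 1.5) and the lateralization loss are set
so the simulated cohort reproduces the qualitative pattern the pipeline is
meant to detect — a clearly significant amplitude reduction and LI
difference at n = 13 vs 12 after FDR adjustment.

**Noise.**  Sinusoids at 1.1 Hz (cardiac, 2e−6 M), 0.3 Hz (respiratory,
1e−6 M) and 0.1 Hz (Mayer, 1e−6 M) with seeded random phases per channel;
first-order random-walk drift (step SD 1e−8 M ≈ 0.02 OD wander over 10
min); white noise 2.5e−7 M (≈5 mOD at 850 nm) — the white/drift levels
correspond to a good continuous-wave instrument, while the in-band Mayer
wave is what actually limits single-trial SNR.  DHb receives independent
draws scaled by 0.4.  Motion artifacts are injected in optical-density
space at Poisson times (1.2 events/min): 50% spikes (1–3 samples, 4 OD) and
50% baseline steps (2 OD), hitting all channels with random per-channel
sign and ±20% magnitude jitter.  The exact event list is returned so the
detector can be scored.

**Clinical scores.** Only the fASD group gets a clinical table (subject_id,
age, ADOS_TOT, ADOS_comp, AQ_tot, nv_IQ, VABS_tot; missing cells serialize
as "n.a.").  AQ is a monotone function of the true laterality index,
AQ = 60 + 120·LI + N(0, 8) — subjects with a weaker rightward bias score
higher — giving a population Spearman ρ ≈ 0.9 at the default LI spread; AQ
is left unrounded so a noise-free clinical model is exactly monotone.  The
other scores are drawn independently of the imaging truth (means/SDs taken
from the embedded reference table).

## Preprocessing

Order: detect → correct motion on ΔOD → zero-phase band-pass → MBLL
inversion (zero-phase so peak latencies carry no filter delay).  Defaults:
Butterworth order 3, band 0.01–0.5 Hz; DPF 6.0 at both wavelengths;
extinction coefficients from the standard hemoglobin compilation
(760 nm: 586 / 1548.52; 850 nm: 1058 / 691.32 cm⁻¹ M⁻¹).  Channels with
zero robust SD are flagged dead, kept in the arrays, excluded from all
averaging and reported in the log.

**Detection.** A sample is flagged when the 1 s sliding-window peak-to-peak
excursion exceeds 1.0 OD or the local SD exceeds 6× the channel's
MAD-based robust SD; flags are OR-ed across wavelengths and merged into
intervals.  Each interval is classified spike vs baseline shift by a local
linear extrapolation across the interval (threshold 0.4 OD), computed on
clean samples only.  The thresholds sit well above the steepest evoked
excursions (≲0.6 OD/s·win in the strongest channels), so a noiseless
recording is never flagged.

**Correction.**  Head motion hits all channels at once, so correction works
on the union of the per-channel masks.  Baseline steps cannot be separated
from the evoked response and slow drift by local flank means at the
fidelity we require, so step sizes are estimated by regression: per series,
a design with a cosine drift basis (12 terms), harmonic regressors at the
dominant physiological frequencies (found on the residual of a first pass
and refined to phase-lock over the whole recording), a trial-locked
piecewise-linear FIR basis per condition (signal-agnostic), and one step
regressor per detected interval, with masked samples excluded from the fit.
Step coefficients are then refined by generalized least squares in the
difference domain — differencing consecutive clean samples whitens the
random-walk drift, a gap of g samples gets variance σ_d²·g + 2σ_w², and
adjacent differences share an endpoint, giving a symmetric tridiagonal
system solved in O(n); the drift/white ratio is estimated from unit-lag
residual differences and shared across series.  Steps larger than 0.05 OD
are subtracted; masked intervals are filled with the model prediction
(which reconstructs the response shape far better than interpolation over
a steep rise).  A spike interval's step estimate is ≈0, so classification
errors cannot leave a genuine step uncorrected, and a second pass with the
same mask estimates no step above threshold — the correction is idempotent.
Without a schedule the corrector falls back to local linear re-levelling
plus cubic-spline interpolation anchored on clean flanks.

On 200 seeded default simulations this yields 100% detection of injected
(event, channel) pairs, no false flags, and a corrected-series RMS error
≈4.5% of the clean-signal RMS, dominated by residual step-size error of a
few ×0.01 OD per shift.

## Response metrics

Epochs −2…15 s around onset, baseline −2…0 s, peak search 0…15 s (covering
the 5 s stimulus and the 10 s rest; per-trial baseline-mean subtraction).
Peaks: maximum for OHb/THb, signed minimum for DHb, ties to the earliest
sample.  The best channel is selected on the OHb STIM peak (lowest channel
index on ties) and the MOCK readout is taken from that same channel.
Hemisphere peaks are read literally as the mean of per-channel
block-average maxima, not the maximum of the mean trace; midline channels
(none in the default montage) are excluded.  LI uses the exact formula and
raises on a zero denominator rather than returning NaN.  Each subject
contributes one value per metric per condition.

A caveat inherent to window-maximum statistics: under noise the MOCK
"amplitude" is strictly positive (the max of a zero-mean trace), so the
meaningful null checks are the exact zero in the noiseless case and the
mock ≪ stim ordering at default SNR — both tested.

## Statistics

Welch t is the default for between-group tests (n = 13 vs 12 need not share
a variance); Student is available by flag.  The mixed ANOVA is the
classical split-plot sums-of-squares decomposition (documented term by term
in the docstring) with hemisphere within and group between; with two
within-levels the sphericity question does not arise.  Degenerate cells
(F with zero effect SS → F = 0, p = 1; zero error MS with positive effect
SS → p = 0) are handled explicitly, and a pingouin cross-check pins the
implementation in the tests.  Spearman uses average ranks with pairwise
deletion of missing values (n reported per correlation).  BH-FDR is the
step-up procedure applied within five families — reliability, amplitude,
latency, lateralization, correlations — mirroring the results subsections;
identical paired samples define t = 0, p = 1, while constant non-zero
differences raise.  Tests whose inputs are degenerate (e.g. latency
quantized to the sample grid in a tiny cohort) are skipped with a warning
rather than aborting the run.

## Validation studies and problem sizes

* **Recovery** — 100 subjects (alternating TD-like and fASD-like
  parameters) through the complete chain: LI bias ≈ 0.001, RMSE ≈ 0.005
  (bounds tested: |bias| ≤ 0.05, RMSE < 0.15); noiseless channel-average
  OHb amplitude within 5% (residual ≈3%, from trial overlap and baseline
  pickup of the previous trial's undershoot).
* **Power** — 100 replicated 13+12 cohorts through the complete chain:
  adjusted-significance rates ≈95–100% for the amplitude reduction, the
  LI difference and the LI–AQ correlation.
* **Type-I calibration** — 1000 replicates per elemental test on
  subject-level metric tables drawn from a null generative model (identical
  distributions across groups and conditions, clinical scores independent
  of imaging).  Re-simulating full recordings 1000× would only add Monte
  Carlo noise to a property of the tests themselves; the full chain is
  already exercised by the recovery and power studies.
* **Artifacts** — 200 seeded single-subject simulations at default
  settings, scored against the simulator's injected-event list and
  pre-artifact series.

## Limitations

The simulator is a statistical stand-in, not a biophysical model: it does
not include scalp/systemic contamination shared across channels,
channel-distance-dependent sensitivity, heart-rate variability (tones are
fixed-frequency), gaze-dependent response fluctuations, or partial-volume
errors in the MBLL (a fixed DPF at both wavelengths).  Passing recovery and
power tests therefore demonstrate that the analysis is correct and
well-calibrated under its own assumptions — not that real recordings meet
those assumptions.  The design-informed step correction assumes the event
schedule is known and trustworthy; with real data whose schedule is
misaligned, the FIR regressors would absorb less of the response and step
estimates would degrade toward the schedule-free fallback.  Hemisphere
summaries assume the montage's left/right labels are correct, and the
published TD age summary is not reproducible from integer-year ages, so
only the fASD demographic summary is used as a fixed reference.
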