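"""Forward simulation of visually-evoked fNIRS recordings.

The generative model: each STIM trial evokes a hemodynamic response obtained
by convolving the stimulus boxcar with a canonical double-gamma kernel and
renormalizing so the single-trial peak equals the per-channel amplitude.
OHb rises, DHb dips at -1/3 of the OHb amplitude with a ~1 s lag, and
THb = OHb + DHb exactly.  MOCK (zero-contrast) trials evoke no response.
Right-hemisphere channels are scaled by a lateralization gain lambda, so the
ground-truth laterality index is LI = (1 - lambda) / (1 + lambda) when
per-channel jitter is off.  On top of the evoked signal the simulator adds
physiological oscillations (cardiac, respiratory, Mayer waves), random-walk
drift and white noise, and — in optical-density space — spike and
baseline-shift motion artifacts at Poisson times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .events import MOCK, STIM, EventSchedule
from .mbll import mbll_forward
from .montage import LEFT, MIDLINE, RIGHT, MontageLayout
from .recording import HbRecording, ODRecording, hb_from_ohb_dhb


# ---------------------------------------------------------------------------
# canonical response kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelParams:
    """Double-gamma hemodynamic kernel parameters (seconds).

    Defaults give a unit-peak response peaking near 4.5 s with an undershoot
    about 1/6 of the peak and a return to baseline within ~12 s — a compact
    visual response compatible with a 10 s inter-stimulus rest, so that
    consecutive trials overlap only marginally.
    """

    peak_delay_s: float = 5.0
    undershoot_delay_s: float = 11.0
    peak_dispersion_s: float = 0.6
    undershoot_dispersion_s: float = 0.8
    undershoot_ratio: float = 1.0 / 6.0


def _raw_double_gamma(t: np.ndarray, p: KernelParams) -> np.ndarray:
    main = gamma_dist.pdf(t, a=p.peak_delay_s / p.peak_dispersion_s, scale=p.peak_dispersion_s)
    under = gamma_dist.pdf(
        t, a=p.undershoot_delay_s / p.undershoot_dispersion_s, scale=p.undershoot_dispersion_s
    )
    return main - p.undershoot_ratio * under


def canonical_response_kernel(t: np.ndarray, params: KernelParams | None = None) -> np.ndarray:
    """Unit-peak double-gamma response evaluated on the time grid ``t`` (s).

    The kernel is 0 at t = 0, rises to a single maximum normalized to 1.0,
    and decays back toward 0 with a small undershoot.
    """
    params = params or KernelParams()
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        return np.zeros(0)
    if np.any(t < 0):
        raise ValueError("kernel time grid must be non-negative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("kernel time grid must be strictly increasing")
    dense = np.arange(0.0, max(32.0, float(t[-1]) + 1.0), 1e-3)
    peak = _raw_double_gamma(dense, params).max()
    if peak <= 0:
        raise ValueError("kernel parameters give a non-positive peak")
    return _raw_double_gamma(t, params) / peak


# ---------------------------------------------------------------------------
# simulation configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Generative parameters for one subject group.

    Amplitudes are molar concentration changes; the defaults put the
    channel-level OHb peak a little above 3e-5 M so that figures read
    naturally on a 1e-5 scale.  ``lateralization`` multiplies right-hemisphere
    amplitudes (lambda > 1 = rightward dominance); midline channels, if any,
    get the mean of the two hemisphere gains.
    """

    sampling_rate: float = 10.2
    ohb_amplitude: float = 3.2e-5
    dhb_ratio: float = -1.0 / 3.0
    dhb_lag_s: float = 1.0
    between_subject_sd: float = 0.9e-5
    channel_amp_sd_frac: float = 0.10
    lateralization: float = 1.5
    lateralization_sd_log: float = 0.10
    cardiac_hz: float = 1.1
    cardiac_amp: float = 2.0e-6
    resp_hz: float = 0.3
    resp_amp: float = 1.0e-6
    mayer_hz: float = 0.1
    mayer_amp: float = 1.0e-6
    drift_step_sd: float = 1.0e-8
    white_sd: float = 2.5e-7
    dhb_noise_frac: float = 0.4
    artifact_rate_per_min: float = 1.2
    spike_mag_od: float = 4.0
    shift_mag_od: float = 2.0
    pre_roll_s: float = 5.0
    post_roll_s: float = 5.0
    kernel: KernelParams = field(default_factory=KernelParams)

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.lateralization <= 0:
            raise ValueError("lateralization gain must be positive")
        for name in (
            "between_subject_sd", "channel_amp_sd_frac", "lateralization_sd_log",
            "cardiac_amp", "resp_amp", "mayer_amp", "drift_step_sd", "white_sd",
            "artifact_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def noiseless(self) -> "SimulationConfig":
        """Copy with every stochastic term switched off (for oracle tests)."""
        return replace(
            self,
            between_subject_sd=0.0,
            channel_amp_sd_frac=0.0,
            lateralization_sd_log=0.0,
            cardiac_amp=0.0,
            resp_amp=0.0,
            mayer_amp=0.0,
            drift_step_sd=0.0,
            white_sd=0.0,
            artifact_rate_per_min=0.0,
        )


def td_default_config() -> SimulationConfig:
    """Default generative parameters for the typically-developing group."""
    return SimulationConfig()


def asd_default_config() -> SimulationConfig:
    """Default generative parameters for the ASD group: reduced OHb
    amplitude and no systematic lateralization, with larger between-subject
    variability of the lateralization gain."""
    return SimulationConfig(
        ohb_amplitude=1.8e-5,
        lateralization=1.0,
        lateralization_sd_log=0.35,
    )


@dataclass
class GroundTruth:
    """True per-channel amplitudes and derived laterality for one subject."""

    ohb_amp: np.ndarray          # (n_channels,)
    dhb_amp: np.ndarray          # (n_channels,)
    peak_left: float
    peak_right: float
    li: float
    seed: int

    def validate(self) -> None:
        denom = self.peak_left + self.peak_right
        expected = (self.peak_left - self.peak_right) / denom if denom != 0 else 0.0
        if abs(self.li - expected) > 1e-12:
            raise ValueError("ground-truth LI inconsistent with hemisphere peaks")


# ---------------------------------------------------------------------------
# single-subject simulation
# ---------------------------------------------------------------------------

def _trial_response(on_s: float, fs: float, params: KernelParams) -> np.ndarray:
    """Unit-peak response to one ``on_s``-second stimulus at sampling rate fs."""
    dt = 1.0 / fs
    t_kernel = np.arange(0.0, 32.0, dt)
    kernel = canonical_response_kernel(t_kernel, params)
    boxcar = np.ones(max(1, int(round(on_s * fs))))
    resp = np.convolve(boxcar, kernel)
    peak = resp.max()
    if peak <= 0:
        raise ValueError("degenerate trial response")
    return resp / peak


def _sinusoid(rng, amp, hz, t, n_ch):
    if amp == 0:
        return 0.0
    phases = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
    return amp * np.sin(2 * np.pi * hz * t[None, :] + phases)


def simulate_subject(
    montage: MontageLayout,
    schedule: EventSchedule,
    config: SimulationConfig,
    seed: int,
) -> tuple[HbRecording, GroundTruth]:
    """Simulate one subject's recording; returns the Hb series and the truth.

    The recording spans ``pre_roll_s + total_duration + post_roll_s`` seconds
    and the returned schedule has its onsets shifted by ``pre_roll_s`` so the
    whole peri-stimulus window of every trial lies inside the recording.
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n_ch = montage.n_channels
    duration = config.pre_roll_s + schedule.total_duration_s + config.post_roll_s
    n_t = int(round(duration * fs))
    t = np.arange(n_t) / fs
    shifted = schedule.shifted(config.pre_roll_s)

    # subject- and channel-level true amplitudes
    amp_subj = config.ohb_amplitude + rng.normal(0.0, config.between_subject_sd)
    amp_subj = max(amp_subj, 0.15 * config.ohb_amplitude)
    lam = config.lateralization * np.exp(rng.normal(0.0, config.lateralization_sd_log))
    gains = np.ones(n_ch)
    hemis = montage.hemisphere_labels()
    for i, h in enumerate(hemis):
        if h == RIGHT:
            gains[i] = lam
        elif h == MIDLINE:
            gains[i] = (1.0 + lam) / 2.0
    jitter = 1.0 + rng.normal(0.0, config.channel_amp_sd_frac, size=n_ch)
    ohb_amp = np.clip(amp_subj * gains * jitter, 0.05 * config.ohb_amplitude, None)
    dhb_amp = config.dhb_ratio * ohb_amp

    # evoked signal: unit-peak trial response placed at each STIM onset
    unit = np.zeros(n_t)
    if schedule.count(STIM):
        on_s = shifted.trials[0].on_duration_s
        resp = _trial_response(on_s, fs, config.kernel)
        for tr in shifted.trials:
            if tr.condition != STIM:
                continue
            i0 = int(round(tr.onset_s * fs))
            i1 = min(n_t, i0 + resp.size)
            unit[i0:i1] += resp[: i1 - i0]
    lag = int(round(config.dhb_lag_s * fs))
    unit_lagged = np.concatenate([np.zeros(lag), unit[: n_t - lag]]) if lag else unit

    ohb = ohb_amp[:, None] * unit[None, :]
    dhb = dhb_amp[:, None] * unit_lagged[None, :]

    # physiological noise, drift, white noise (independent draws per species)
    for arr, scale in ((ohb, 1.0), (dhb, config.dhb_noise_frac)):
        arr += scale * _sinusoid(rng, config.cardiac_amp, config.cardiac_hz, t, n_ch)
        arr += scale * _sinusoid(rng, config.resp_amp, config.resp_hz, t, n_ch)
        arr += scale * _sinusoid(rng, config.mayer_amp, config.mayer_hz, t, n_ch)
        if config.drift_step_sd > 0:
            arr += scale * np.cumsum(
                rng.normal(0.0, config.drift_step_sd, size=(n_ch, n_t)), axis=1
            )
        if config.white_sd > 0:
            arr += scale * rng.normal(0.0, config.white_sd, size=(n_ch, n_t))

    left = montage.channel_indices(LEFT)
    right = montage.channel_indices(RIGHT)
    peak_left = float(np.mean(ohb_amp[left])) if left else float("nan")
    peak_right = float(np.mean(ohb_amp[right])) if right else float("nan")
    denom = peak_left + peak_right
    li = (peak_left - peak_right) / denom if denom != 0 else 0.0
    truth = GroundTruth(
        ohb_amp=ohb_amp, dhb_amp=dhb_amp,
        peak_left=peak_left, peak_right=peak_right, li=float(li), seed=seed,
    )
    truth.validate()
    rec = hb_from_ohb_dhb(fs, ohb, dhb, montage, shifted)
    return rec, truth


# ---------------------------------------------------------------------------
# motion artifacts (optical-density space)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectedArtifact:
    sample: int
    width: int           # samples affected (1 for a step)
    kind: str            # "spike" | "shift"


def inject_motion_artifacts(
    od: np.ndarray,
    sampling_rate: float,
    rate_per_min: float,
    spike_mag_od: float,
    shift_mag_od: float,
    seed: int,
) -> tuple[np.ndarray, list[InjectedArtifact]]:
    """Add seeded spike and baseline-shift artifacts at Poisson times.

    Events are drawn globally (head motion hits all channels at once) and
    applied to every channel and wavelength with a random sign and a modest
    magnitude jitter.  Returns the contaminated copy and the exact event list.
    """
    if rate_per_min < 0:
        raise ValueError("artifact rate must be non-negative")
    od = np.array(od, dtype=float, copy=True)
    squeeze = od.ndim == 2
    if squeeze:
        od = od[np.newaxis, ...]
    n_t = od.shape[-1]
    flat = od.reshape(-1, n_t)
    rng = np.random.default_rng(seed)
    events: list[InjectedArtifact] = []
    if rate_per_min == 0 or n_t == 0:
        return (flat.reshape(od.shape)[0] if squeeze else od), events
    duration_min = n_t / sampling_rate / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    samples = np.sort(rng.integers(0, n_t, size=n_events))
    for s in samples:
        kind = "spike" if rng.random() < 0.5 else "shift"
        signs = rng.choice([-1.0, 1.0], size=flat.shape[0])
        scale = rng.uniform(0.8, 1.2, size=flat.shape[0])
        if kind == "spike":
            width = int(rng.integers(1, 4))
            end = min(n_t, s + width)
            flat[:, s:end] += (signs * scale * spike_mag_od)[:, None]
            events.append(InjectedArtifact(int(s), end - int(s), "spike"))
        else:
            flat[:, s:] += (signs * scale * shift_mag_od)[:, None]
            events.append(InjectedArtifact(int(s), 1, "shift"))
    out = flat.reshape(od.shape)
    return (out[0] if squeeze else out), events


def subject_od_recording(sub: "SubjectSim", config: SimulationConfig) -> ODRecording:
    """The measured (artifact-laden) optical-density recording for a
    simulated subject: MBLL forward model plus motion artifacts at the
    configured rate, seeded from the subject's own seed."""
    hb = sub.recording
    od_clean = mbll_forward(hb.ohb, hb.dhb, hb.montage.distances_cm(),
                            hb.montage.wavelengths)
    od_dirty, _events = inject_motion_artifacts(
        od_clean, config.sampling_rate, config.artifact_rate_per_min,
        config.spike_mag_od, config.shift_mag_od, seed=sub.truth.seed + 1_000_003)
    return ODRecording(config.sampling_rate, od_dirty, hb.montage, hb.schedule)


def simulate_od_subject(
    montage: MontageLayout,
    schedule: EventSchedule,
    config: SimulationConfig,
    seed: int,
    dpf=None,
) -> tuple[ODRecording, GroundTruth, list[InjectedArtifact], np.ndarray]:
    """Full forward model: Hb -> optical density -> motion artifacts.

    Returns the contaminated OD recording, the ground truth, the injected
    artifact list, and the clean (pre-artifact) OD array for validation.
    """
    hb, truth = simulate_subject(montage, schedule, config, seed)
    od_clean = mbll_forward(
        hb.ohb, hb.dhb, montage.distances_cm(), montage.wavelengths, dpf=dpf
    )
    od_dirty, events = inject_motion_artifacts(
        od_clean,
        config.sampling_rate,
        config.artifact_rate_per_min,
        config.spike_mag_od,
        config.shift_mag_od,
        seed=seed + 1_000_003,
    )
    rec = ODRecording(config.sampling_rate, od_dirty, montage, hb.schedule)
    return rec, truth, events, od_clean


# ---------------------------------------------------------------------------
# cohort simulation with clinical scores
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ["subject_id", "age", "ADOS_TOT", "ADOS_comp", "AQ_tot", "nv_IQ", "VABS_tot"]


@dataclass
class ClinicalModel:
    """Score-generation parameters for the simulated ASD group.

    AQ is generated as a monotone increasing function of the true laterality
    index plus Gaussian noise: subjects with a weaker rightward bias (LI
    closer to zero or positive) receive higher autistic-trait scores.  The
    remaining scores are drawn independently of the imaging truth.
    """

    aq_intercept: float = 60.0
    aq_slope: float = 120.0
    aq_noise_sd: float = 8.0
    ados_tot_mean: float = 11.6
    ados_tot_sd: float = 2.7
    ados_comp_mean: float = 5.4
    ados_comp_sd: float = 1.0
    nviq_mean: float = 104.0
    nviq_sd: float = 14.0
    vabs_mean: float = 84.0
    vabs_sd: float = 11.0
    age_range_years: tuple[int, int] = (3, 6)


@dataclass
class SubjectSim:
    subject_id: str
    group: str
    recording: HbRecording
    truth: GroundTruth


def simulate_cohort(
    n_td: int,
    n_asd: int,
    config_td: SimulationConfig | None = None,
    config_asd: SimulationConfig | None = None,
    clinical_model: ClinicalModel | None = None,
    seed: int = 0,
    schedule: EventSchedule | None = None,
    montage: MontageLayout | None = None,
    n_stim: int = 20,
    n_mock: int = 20,
    on_s: float = 5.0,
    off_s: float = 10.0,
) -> tuple[list[SubjectSim], pd.DataFrame]:
    """Simulate a two-group cohort plus a clinical table for the ASD group.

    Each subject gets an independent pseudo-random trial interleaving and an
    independent recording seed, all derived from the master seed.
    """
    from .montage import make_default_montage
    from .events import generate_event_schedule

    if n_td < 1 or n_asd < 1:
        raise ValueError("both groups need at least one subject")
    config_td = config_td or td_default_config()
    config_asd = config_asd or asd_default_config()
    clinical_model = clinical_model or ClinicalModel()
    montage = montage or make_default_montage()
    rng = np.random.default_rng(seed)

    subjects: list[SubjectSim] = []
    specs = [("TD", config_td, f"TD{i + 1:02d}") for i in range(n_td)]
    specs += [("ASD", config_asd, f"ASD{i + 1:02d}") for i in range(n_asd)]
    for group, cfg, sid in specs:
        sched_seed = int(rng.integers(0, 2**31 - 1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sched = schedule if schedule is not None else generate_event_schedule(
            n_stim, n_mock, on_s, off_s, seed=sched_seed
        )
        rec, truth = simulate_subject(montage, sched, cfg, sub_seed)
        subjects.append(SubjectSim(sid, group, rec, truth))

    rows = []
    lo, hi = clinical_model.age_range_years
    for sub in subjects:
        if sub.group != "ASD":
            continue
        aq = (
            clinical_model.aq_intercept
            + clinical_model.aq_slope * sub.truth.li
            + (rng.normal(0.0, clinical_model.aq_noise_sd) if clinical_model.aq_noise_sd > 0 else 0.0)
        )
        rows.append({
            "subject_id": sub.subject_id,
            "age": int(rng.integers(lo, hi + 1)),
            "ADOS_TOT": round(float(rng.normal(clinical_model.ados_tot_mean, clinical_model.ados_tot_sd)), 0),
            "ADOS_comp": round(float(rng.normal(clinical_model.ados_comp_mean, clinical_model.ados_comp_sd)), 0),
            "AQ_tot": float(aq),
            "nv_IQ": round(float(rng.normal(clinical_model.nviq_mean, clinical_model.nviq_sd)), 0),
            "VABS_tot": round(float(rng.normal(clinical_model.vabs_mean, clinical_model.vabs_sd)), 0),
        })
    clinical = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    return subjects, clinical
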