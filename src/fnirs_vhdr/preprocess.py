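"""Optical-density preprocessing: motion artifacts, filtering, MBLL inversion.

Processing order follows the common convention for continuous-wave NIRS:
detect and correct motion artifacts on the optical-density series, band-pass
filter, then invert the modified Beer–Lambert law to concentrations.
Filtering is zero-phase so peak latencies are not biased by filter delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .mbll import mbll_inverse
from .recording import HbRecording, ODRecording, hb_from_ohb_dhb

log = logging.getLogger(__name__)

SPIKE = "spike"
SHIFT = "shift"


@dataclass
class ArtifactMask:
    """Per-channel artifact intervals: (start, end, kind), end exclusive."""

    intervals: list[list[tuple[int, int, str]]]
    n_samples: int

    def __post_init__(self):
        for ch_intervals in self.intervals:
            prev_end = 0
            for start, end, kind in sorted(ch_intervals):
                if start < 0 or end > self.n_samples or start >= end:
                    raise ValueError("artifact interval outside recording")
                if start < prev_end:
                    raise ValueError("overlapping artifact intervals")
                if kind not in (SPIKE, SHIFT):
                    raise ValueError(f"unknown artifact kind {kind!r}")
                prev_end = end

    @property
    def n_channels(self) -> int:
        return len(self.intervals)

    def flagged_fraction(self) -> float:
        if not self.intervals or self.n_samples == 0:
            return 0.0
        total = sum(end - start for ch in self.intervals for start, end, _ in ch)
        return total / (self.n_samples * len(self.intervals))

    def channel_flags(self, channel: int) -> np.ndarray:
        flags = np.zeros(self.n_samples, dtype=bool)
        for start, end, _ in self.intervals[channel]:
            flags[start:end] = True
        return flags


@dataclass
class PreprocessParams:
    """Tunable preprocessing parameters (all overridable from config)."""

    band_low_hz: float = 0.01
    band_high_hz: float = 0.5
    filter_order: int = 3
    dpf: dict = field(default_factory=lambda: {760.0: 6.0, 850.0: 6.0})
    motion_window_s: float = 1.0
    amp_thresh_od: float = 1.0
    std_thresh: float = 6.0
    shift_offset_thresh_od: float = 0.4
    step_sub_thresh_od: float = 0.05


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) with end exclusive."""
    if not flags.any():
        return []
    padded = np.concatenate([[False], flags, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _level_offset(x: np.ndarray, start: int, end: int, fs: float,
                  flags: np.ndarray | None = None) -> float:
    """Baseline level change across [start, end): post level minus the value
    extrapolated from a linear fit on clean pre-interval samples.  Samples
    marked in ``flags`` (other artifacts) are excluded from both windows."""
    n = x.size
    pre_n = max(3, int(round(1.5 * fs)))
    post_n = max(3, int(round(0.5 * fs)))
    ti = np.arange(max(0, start - 4 * pre_n), start)
    tj = np.arange(end, min(n, end + 4 * post_n))
    if flags is not None:
        ti = ti[~flags[ti]]
        tj = tj[~flags[tj]]
    ti = ti[-pre_n:]
    tj = tj[:post_n]
    if ti.size < 3 or tj.size < 1:
        return 0.0
    # linear extrapolation from the pre window (closed-form fit)
    t0 = ti.mean()
    x0 = x[ti].mean()
    slope = np.dot(ti - t0, x[ti] - x0) / np.dot(ti - t0, ti - t0)
    return float(np.mean(x[tj] - (x0 + slope * (tj - t0))))


def detect_motion(
    od: np.ndarray,
    sampling_rate: float,
    window_s: float = 1.0,
    amp_thresh: float = 1.0,
    std_thresh: float = 6.0,
    shift_offset_thresh: float = 0.4,
) -> ArtifactMask:
    """Flag motion-contaminated samples on optical-density series.

    ``od`` is (n_channels, n_wavelengths, n_samples) or (n_channels,
    n_samples).  A sample is flagged when, within a sliding window, the
    peak-to-peak excursion exceeds ``amp_thresh`` OD, or the local SD exceeds
    ``std_thresh`` times the channel's robust (MAD-based) SD.  Flags are
    OR-ed across wavelengths and merged into intervals classified as spike
    or baseline shift.
    """
    if window_s <= 0 or amp_thresh <= 0 or std_thresh <= 0:
        raise ValueError("window and thresholds must be positive")
    od = np.asarray(od, dtype=float)
    if od.ndim == 2:
        od = od[:, np.newaxis, :]
    n_ch, n_wl, n_t = od.shape
    win = max(2, int(round(window_s * sampling_rate)))
    intervals: list[list[tuple[int, int, str]]] = []
    for c in range(n_ch):
        flags = np.zeros(n_t, dtype=bool)
        for w in range(n_wl):
            x = od[c, w]
            p2p = maximum_filter1d(x, win) - minimum_filter1d(x, win)
            flags |= p2p > amp_thresh
            robust = 1.4826 * np.median(np.abs(x - np.median(x)))
            if robust > 0:
                mu = uniform_filter1d(x, win)
                local_sd = np.sqrt(np.maximum(uniform_filter1d(x * x, win) - mu * mu, 0.0))
                flags |= local_sd > std_thresh * robust
        ch_intervals = []
        for start, end in _runs(flags):
            offset = max(
                (abs(_level_offset(od[c, w], start, end, sampling_rate, flags))
                 for w in range(n_wl)),
                default=0.0,
            )
            kind = SHIFT if offset > shift_offset_thresh else SPIKE
            ch_intervals.append((int(start), int(end), kind))
        intervals.append(ch_intervals)
    return ArtifactMask(intervals=intervals, n_samples=n_t)


# ---------------------------------------------------------------------------
# correction
# ---------------------------------------------------------------------------

def _projected_power(flat: np.ndarray, fs: float, freq: float) -> float:
    """Total squared projection of all series onto a complex tone at ``freq``."""
    t = np.arange(flat.shape[-1]) / fs
    tone = np.exp(-2j * np.pi * freq * t)
    return float(np.sum(np.abs(flat @ tone) ** 2))


def _physio_freqs(od: np.ndarray, fs: float, n_freqs: int = 6,
                  fmin: float = 0.03, fmax: float = 2.0,
                  min_sep: float = 0.02) -> tuple[float, ...]:
    """Dominant physiological frequencies from the channel-averaged
    periodogram (cardiac, respiratory, Mayer-type oscillations), refined so
    that a harmonic regressor stays phase-locked over the whole recording."""
    from scipy.optimize import minimize_scalar
    from scipy.signal import welch

    flat = od.reshape(-1, od.shape[-1])
    n_t = flat.shape[-1]
    nperseg = min(4096, n_t)
    f, pxx = welch(flat, fs=fs, nperseg=nperseg, detrend="linear", axis=-1)
    power = pxx.mean(axis=0)
    sel = (f >= fmin) & (f <= fmax)
    f, power = f[sel], power[sel]
    coarse: list[float] = []
    for i in np.argsort(power)[::-1]:
        if len(coarse) >= n_freqs:
            break
        if all(abs(f[i] - g) >= min_sep for g in coarse):
            coarse.append(float(f[i]))
    half = fs / nperseg  # one coarse bin
    subset = flat[:: max(1, flat.shape[0] // 8)]  # refinement needs few series
    refined = []
    for f0 in coarse:
        res = minimize_scalar(
            lambda fq: -_projected_power(subset, fs, fq),
            bounds=(max(fmin, f0 - half), f0 + half),
            method="bounded",
            options={"xatol": 1e-6},
        )
        refined.append(float(res.x))
    return tuple(sorted(refined))


def _relevel_design(n_t: int, fs: float, schedule, step_starts,
                    physio_freqs=(), fir_span_s: float = 17.0,
                    fir_dt_s: float = 1.0) -> tuple[np.ndarray, int]:
    """Design matrix for step re-levelling.

    Columns: a cosine drift basis, harmonic regressors at the dominant
    physiological frequencies, a trial-locked piecewise-linear FIR basis per
    condition (signal-agnostic — it absorbs whatever peri-stimulus waveform
    the data carry), and one unit-step regressor per detected artifact
    interval.
    """
    t = np.arange(n_t) / fs
    span = t[-1] if n_t > 1 else 1.0
    cols = [np.ones(n_t)]
    for k in range(1, 13):
        cols.append(np.cos(np.pi * k * t / span))
    for fq in physio_freqs:
        cols.append(np.sin(2 * np.pi * fq * t))
        cols.append(np.cos(2 * np.pi * fq * t))
    # tent (piecewise-linear interpolating) basis time-locked to trial onsets
    delta = max(1, int(round(fir_dt_s * fs)))
    tent = 1.0 - np.abs(np.arange(-delta + 1, delta)) / delta
    n_knots = int(round(fir_span_s / fir_dt_s))
    conditions = sorted({tr.condition for tr in schedule.trials})
    for cond in conditions:
        impulses = np.zeros(n_t)
        for tr in schedule.trials:
            if tr.condition != cond:
                continue
            i0 = int(round(tr.onset_s * fs))
            if 0 <= i0 < n_t:
                impulses[i0] = 1.0
        base = np.convolve(impulses, tent)[delta - 1: delta - 1 + n_t]
        for k in range(n_knots):
            shift = k * delta
            col = np.zeros(n_t)
            col[shift:] = base[: n_t - shift]
            cols.append(col)
    n_fixed = len(cols)
    for p in step_starts:
        u = np.zeros(n_t)
        u[p:] = 1.0
        cols.append(u)
    return np.column_stack(cols), n_fixed


def _fast_lstsq(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """QR-based least squares (faster than the SVD driver for tall systems)."""
    from scipy.linalg import lstsq as sp_lstsq

    beta, *_ = sp_lstsq(X, Y, cond=1e-10, lapack_driver="gelsy", check_finite=False)
    return beta


def _gls_step_refine(y_block: np.ndarray, X: np.ndarray, n_fixed: int,
                     beta: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Refine step-size estimates by generalized least squares in the
    difference domain.

    Differences between consecutive clean samples turn the slow random-walk
    component of the noise into white increments, so a step is estimated
    with the statistically appropriate weight: a difference spanning a
    masked gap of g samples has variance ``sd2 * g + 2 * sw2`` (drift
    accumulation plus measurement noise at both ends), and adjacent
    differences share an endpoint (covariance ``-sw2``), giving a symmetric
    tridiagonal system solved in O(n).  The fixed part of the model (drift,
    physiological harmonics, trial-locked response) is removed using its
    ordinary-least-squares fit; only the step coefficients are re-estimated.

    Returns the refined step matrix with shape (n_steps, n_series).
    """
    from scipy.linalg import solveh_banded

    n_steps = X.shape[1] - n_fixed
    n_series = y_block.shape[1]
    k = np.flatnonzero(keep)
    gaps = np.diff(k)
    unit = gaps == 1
    # differences between consecutive kept samples; the intercept column
    # vanishes here, so the whole remaining design is re-estimated jointly
    A = X[k[1:], 1:] - X[k[:-1], 1:]
    B = y_block[k[1:]] - y_block[k[:-1]]
    full_resid = y_block - X @ beta
    D = full_resid[k[1:]] - full_resid[k[:-1]]
    du = D[unit]
    if du.shape[0] < 10:
        return beta[n_fixed:].copy()
    g0 = du.var(axis=0)
    g1 = (du[:-1] * du[1:]).mean(axis=0) - du[:-1].mean(axis=0) * du[1:].mean(axis=0)
    sw2 = np.maximum(-g1, 1e-12)
    sd2 = np.maximum(g0 - 2 * sw2, 1e-3 * sw2)
    # the GLS estimate depends on the covariance only through the drift/white
    # ratio, which is shared across channels up to gain; use the median
    ratio = float(np.median(sd2 / sw2))
    ab = np.zeros((2, gaps.size))
    ab[1] = ratio * gaps + 2.0
    ab[0, 1:] = -1.0
    sol = solveh_banded(ab, np.column_stack([A, B]), lower=False)
    SiA = sol[:, : A.shape[1]]
    SiB = sol[:, A.shape[1]:]
    G = A.T @ SiA
    H = A.T @ SiB
    coef, *_ = np.linalg.lstsq(G, H, rcond=None)
    out = coef[n_fixed - 1:]
    # a step whose interval touches a recording edge has no crossing
    # difference row; it is unidentified here and keeps its anchored
    # least-squares estimate
    unseen = np.abs(A[:, n_fixed - 1:]).sum(axis=0) < 1e-9
    out[unseen] = beta[n_fixed:][unseen]
    return out


def _interpolate_intervals(y: np.ndarray, ch_intervals, fs: float,
                           flags: np.ndarray | None = None) -> np.ndarray:
    """Cubic-spline interpolation of masked intervals, anchored on flanking
    clean samples only (samples inside any other interval are skipped)."""
    n = y.size
    flank = max(3, int(round(1.0 * fs)))
    for start, end, _kind in sorted(ch_intervals):
        pre = np.arange(max(0, start - 4 * flank), start)
        post = np.arange(end, min(n, end + 4 * flank))
        if flags is not None:
            pre = pre[~flags[pre]]
            post = post[~flags[post]]
        anchors = np.concatenate([pre[-flank:], post[:flank]])
        if anchors.size >= 2:
            if pre.size >= 4 and post.size >= 4:
                interp = CubicSpline(anchors, y[anchors])
            else:
                interp = lambda t: np.interp(t, anchors, y[anchors])  # noqa: E731
            y[start:end] = interp(np.arange(start, end))
        elif anchors.size == 1:
            y[start:end] = y[anchors[0]]
    return y


def correct_motion(
    od: np.ndarray,
    mask: ArtifactMask,
    sampling_rate: float,
    shift_offset_thresh: float = 0.4,
    schedule=None,
    step_sub_thresh: float = 0.05,
) -> np.ndarray:
    """Remove baseline steps at detected shifts and repair masked intervals;
    unmasked samples are only re-levelled, never reshaped.

    Head motion hits every channel at once, so correction works on the union
    of the per-channel masks.  When the event schedule is available, step
    sizes are estimated per series by least squares against a design holding
    a cosine drift basis, data-driven physiological harmonics, a trial-locked
    FIR basis and one step regressor per interval (masked samples excluded
    from the fit), then refined by difference-domain GLS; masked intervals
    are filled with the model prediction.  Without a schedule the step size
    falls back to a local linear extrapolation and masked intervals are
    spline-interpolated.  Only estimated steps exceeding ``step_sub_thresh``
    are removed, so correcting twice with the same mask changes nothing the
    second time.
    """
    od = np.asarray(od, dtype=float)
    squeeze = od.ndim == 2
    arr = np.array(od[:, np.newaxis, :] if squeeze else od, dtype=float, copy=True)
    n_ch, n_wl, n_t = arr.shape
    if mask.n_channels != n_ch or mask.n_samples != n_t:
        raise ValueError("mask does not match the series")
    for c in range(n_ch):
        flagged = sum(end - start for start, end, _ in mask.intervals[c])
        if mask.intervals[c] and flagged >= n_t:
            raise ValueError("artifact mask covers the entire channel")

    # union mask across channels: global motion, one shared design
    flags = np.zeros(n_t, dtype=bool)
    for c in range(n_ch):
        flags |= mask.channel_flags(c)
    if not flags.any():
        return arr[:, 0, :] if squeeze else arr
    if flags.all():
        raise ValueError("artifact mask covers the entire recording")
    union: list[tuple[int, int, str]] = []
    for start, end in _runs(flags):
        kinds = {
            kind
            for c in range(n_ch)
            for a, b, kind in mask.intervals[c]
            if a < end and b > start
        }
        union.append((int(start), int(end), SHIFT if SHIFT in kinds else SPIKE))
    keep = ~flags
    starts = tuple(s for s, _e, _k in union)

    if schedule is not None:
        y_block = arr.reshape(n_ch * n_wl, n_t).T
        # pass 1: fit drift + response + steps, then pick physiological
        # frequencies from the residuals — with the steps in the model,
        # neither evoked harmonics nor baseline jumps pollute the
        # cardiac/respiratory/Mayer peaks
        def anchored_fit(X, n_fixed):
            # differential OD starts at baseline 0: pseudo-observations pin
            # the fixed-part prediction at t=0 to zero, which identifies a
            # step whose interval touches the start of the recording
            anchor = np.repeat(X[0:1], 20, axis=0)
            anchor[:, n_fixed:] = 0.0
            Xa = np.vstack([X[keep], anchor])
            Ya = np.vstack([y_block[keep], np.zeros((20, y_block.shape[1]))])
            return _fast_lstsq(Xa, Ya)

        X0, nf0 = _relevel_design(n_t, sampling_rate, schedule, starts)
        beta0 = anchored_fit(X0, nf0)
        resid = y_block - X0 @ beta0
        resid[~keep] = 0.0
        physio = _physio_freqs(resid.T.reshape(arr.shape), sampling_rate)
        # pass 2: full design, then difference-domain GLS for the steps
        X, n_fixed = _relevel_design(n_t, sampling_rate, schedule, starts, physio)
        beta = anchored_fit(X, n_fixed)
        steps = _gls_step_refine(y_block, X, n_fixed, beta, keep)
        # one step regressor per interval: a spike's step estimate is ~0 and
        # falls below the threshold, so misclassification cannot leave a
        # genuine baseline step uncorrected
        for col, (c, w) in enumerate((c, w) for c in range(n_ch) for w in range(n_wl)):
            y = arr[c, w]
            removed = np.abs(steps[:, col]) > step_sub_thresh
            for k, p in enumerate(starts):
                if removed[k]:
                    y[p:] -= steps[k, col]
            # fill masked intervals with the model prediction (drift +
            # physiological harmonics + trial-locked response + any step
            # terms left in place), which reconstructs the response shape
            # far better than interpolation over a steep rise
            pred = X[:, :n_fixed] @ beta[:n_fixed, col]
            for k, p in enumerate(starts):
                if not removed[k]:
                    pred[p:] += steps[k, col]
            for a, b, _kind in union:
                y[a:b] = pred[a:b]
            arr[c, w] = y
    else:
        for c in range(n_ch):
            for w in range(n_wl):
                y = arr[c, w]
                for start, end, kind in union:
                    if kind != SHIFT:
                        continue
                    offset = _level_offset(y, start, end, sampling_rate, flags)
                    if abs(offset) > shift_offset_thresh:
                        y[end:] -= offset
                arr[c, w] = _interpolate_intervals(y, union, sampling_rate, flags)
    return arr[:, 0, :] if squeeze else arr


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bandpass(
    series: np.ndarray,
    low_hz: float,
    high_hz: float,
    sampling_rate: float,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    ``low_hz`` may be 0, in which case only the low-pass branch is applied.
    """
    nyq = sampling_rate / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for sampling rate {sampling_rate} Hz"
        )
    x = np.asarray(series, dtype=float)
    if low_hz > 0:
        sos = butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")
    else:
        sos = butter(order, high_hz / nyq, btype="lowpass", output="sos")
    return sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# full preprocessing chain
# ---------------------------------------------------------------------------

def preprocess_od(
    rec: ODRecording,
    params: PreprocessParams | None = None,
) -> tuple[HbRecording, ArtifactMask]:
    """detect -> correct motion on dOD -> band-pass -> MBLL inversion.

    Channels whose robust SD is zero (dead channels) are kept in the arrays
    but flagged unusable and reported in the log.
    """
    params = params or PreprocessParams()
    fs = rec.sampling_rate
    mask = detect_motion(
        rec.od, fs,
        window_s=params.motion_window_s,
        amp_thresh=params.amp_thresh_od,
        std_thresh=params.std_thresh,
        shift_offset_thresh=params.shift_offset_thresh_od,
    )
    corrected = correct_motion(rec.od, mask, fs, params.shift_offset_thresh_od,
                               schedule=rec.schedule,
                               step_sub_thresh=params.step_sub_thresh_od)
    filtered = bandpass(corrected, params.band_low_hz, params.band_high_hz, fs,
                        order=params.filter_order)
    dpf = [params.dpf[float(w)] for w in rec.montage.wavelengths]
    ohb, dhb = mbll_inverse(
        filtered, rec.montage.distances_cm(), rec.montage.wavelengths, dpf=dpf
    )
    # dead-channel screen on the raw OD series
    robust_sd = 1.4826 * np.median(
        np.abs(rec.od - np.median(rec.od, axis=-1, keepdims=True)), axis=-1
    ).max(axis=1)
    usable = robust_sd > 0
    for idx in np.flatnonzero(~usable):
        log.warning("channel %s is flat; excluded from averaging",
                    rec.montage.channel_ids[idx])
    return (
        hb_from_ohb_dhb(fs, ohb, dhb, rec.montage, rec.schedule, usable=usable),
        mask,
    )
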