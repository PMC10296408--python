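"""Event-related response metrics: epoching, block averages, peaks, laterality.

Readouts per subject and condition: channel-average and best-channel peak
amplitude/latency per chromophore (max for OHb/THb, min for DHb), hemisphere
peaks (the mean over each hemisphere's channels of the per-channel maximum of
the block-averaged OHb trace), and the laterality index

    LI = (peak_left - peak_right) / (peak_left + peak_right),

so negative LI means rightward dominance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import MOCK, STIM, EventSchedule
from .montage import LEFT, RIGHT, MontageLayout
from .recording import CHROMOPHORES, HbRecording

log = logging.getLogger(__name__)

#: default peri-stimulus windows, seconds relative to stimulus onset
DEFAULT_PRE_S = 2.0
DEFAULT_POST_S = 15.0
DEFAULT_BASELINE = (-2.0, 0.0)
DEFAULT_SEARCH = (0.0, 15.0)


@dataclass
class EpochSet:
    """Baseline-corrected trials: {(condition, chromophore): (C, trials, T)}."""

    data: dict[tuple[str, str], np.ndarray]
    times: np.ndarray            # seconds relative to onset, length T
    pre_s: float
    post_s: float
    baseline: tuple[float, float]
    montage: MontageLayout
    usable: np.ndarray

    def conditions(self) -> list[str]:
        return sorted({c for c, _ in self.data})

    def n_trials(self, condition: str) -> int:
        return self.data[(condition, "OHb")].shape[1]


def epoch_trials(
    hb: HbRecording,
    schedule: EventSchedule | None = None,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
) -> EpochSet:
    """Cut each trial at onset-pre_s .. onset+post_s and baseline-correct.

    The baseline window is expressed relative to onset and must lie within
    [-pre_s, 0].  Trials whose window exceeds the recording bounds are
    dropped with a warning; an error is raised if nothing remains.
    """
    schedule = schedule or hb.schedule
    if pre_s < 0 or post_s <= 0:
        raise ValueError("epoch window must have pre_s >= 0 and post_s > 0")
    b0, b1 = baseline
    if not (-pre_s - 1e-9 <= b0 < b1 <= 1e-9):
        raise ValueError("baseline window must lie within [-pre_s, 0]")
    fs = hb.sampling_rate
    n_t = hb.n_samples
    n_len = int(round((pre_s + post_s) * fs)) + 1
    times = np.arange(n_len) / fs - pre_s
    bmask = (times >= b0 - 1e-9) & (times <= b1 + 1e-9)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")

    starts: dict[str, list[int]] = {}
    for tr in schedule.trials:
        i0 = int(round((tr.onset_s - pre_s) * fs))
        if i0 < 0 or i0 + n_len > n_t:
            log.warning("trial at %.1f s exceeds recording bounds; dropped", tr.onset_s)
            continue
        starts.setdefault(tr.condition, []).append(i0)
    if not starts:
        raise ValueError("all trials fall outside the recording")

    data = {}
    idx = np.arange(n_len)
    for cond, i0s in starts.items():
        gather = np.asarray(i0s)[:, None] + idx[None, :]           # (trials, T)
        for chrom in CHROMOPHORES:
            series = hb.chromophore(chrom)
            ep = series[:, gather]                                  # (C, trials, T)
            ep = ep - ep[:, :, bmask].mean(axis=2, keepdims=True)
            data[(cond, chrom)] = ep
    return EpochSet(
        data=data, times=times, pre_s=pre_s, post_s=post_s,
        baseline=baseline, montage=hb.montage, usable=hb.usable.copy(),
    )


def block_average(
    epochs: EpochSet, condition: str, chromophore: str = "OHb"
) -> tuple[np.ndarray, np.ndarray]:
    """Point-wise mean and standard error across trials, per channel."""
    key = (condition, chromophore)
    if key not in epochs.data:
        raise ValueError(f"no trials for condition {condition!r}")
    ep = epochs.data[key]
    n = ep.shape[1]
    if n < 1:
        raise ValueError(f"no trials for condition {condition!r}")
    mean = ep.mean(axis=1)
    sem = ep.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem


def extract_peak(
    trace: np.ndarray,
    times: np.ndarray,
    chromophore: str,
    search_window: tuple[float, float] = DEFAULT_SEARCH,
) -> tuple[float, float]:
    """Peak amplitude and latency of an averaged trace.

    The peak is the maximum for OHb/THb and the minimum for DHb, searched
    within ``search_window`` (seconds from onset); ties break to the earliest
    time.  Latency is reported relative to stimulus onset.
    """
    if chromophore not in CHROMOPHORES:
        raise ValueError(f"unknown chromophore {chromophore!r}")
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    w0, w1 = search_window
    sel = (times >= w0 - 1e-9) & (times <= w1 + 1e-9)
    if not sel.any():
        raise ValueError("empty peak-search window")
    seg = trace[sel]
    tseg = times[sel]
    i = int(np.argmin(seg)) if chromophore == "DHb" else int(np.argmax(seg))
    return float(seg[i]), float(tseg[i])


def _usable_indices(epochs: EpochSet) -> np.ndarray:
    idx = np.flatnonzero(epochs.usable)
    if idx.size == 0:
        raise ValueError("no usable channels")
    return idx


def channel_average_response(
    epochs: EpochSet,
    condition: str,
    search_window: tuple[float, float] = DEFAULT_SEARCH,
) -> dict[str, tuple[float, float]]:
    """Average block-averaged traces across usable channels, then take peaks."""
    idx = _usable_indices(epochs)
    out = {}
    for chrom in CHROMOPHORES:
        mean, _ = block_average(epochs, condition, chrom)
        grand = mean[idx].mean(axis=0)
        out[chrom] = extract_peak(grand, epochs.times, chrom, search_window)
    return out


def best_channel_response(
    epochs: EpochSet,
    condition: str,
    search_window: tuple[float, float] = DEFAULT_SEARCH,
    selection_condition: str = STIM,
) -> tuple[str, dict[str, tuple[float, float]]]:
    """Peaks from the channel with the highest OHb response.

    The channel is selected on the OHb peak of ``selection_condition``
    (STIM by default, so MOCK readouts come from the same channel that wins
    on stimulation); ties break to the lowest channel index.
    """
    idx = _usable_indices(epochs)
    sel_cond = selection_condition if (selection_condition, "OHb") in epochs.data else condition
    mean, _ = block_average(epochs, sel_cond, "OHb")
    peaks = [extract_peak(mean[c], epochs.times, "OHb", search_window)[0] for c in idx]
    best = idx[int(np.argmax(peaks))]
    out = {}
    for chrom in CHROMOPHORES:
        cmean, _ = block_average(epochs, condition, chrom)
        out[chrom] = extract_peak(cmean[best], epochs.times, chrom, search_window)
    return epochs.montage.channel_ids[best], out


def hemisphere_peaks(
    epochs: EpochSet,
    condition: str = STIM,
    search_window: tuple[float, float] = DEFAULT_SEARCH,
) -> tuple[float, float]:
    """Mean over each hemisphere's channels of the per-channel OHb maximum.

    Midline channels are excluded.  Read literally as the average of
    per-channel maxima, not the maximum of the averaged trace.
    """
    mean, _ = block_average(epochs, condition, "OHb")
    w0, w1 = search_window
    sel = (epochs.times >= w0 - 1e-9) & (epochs.times <= w1 + 1e-9)
    maxima = mean[:, sel].max(axis=1)
    out = []
    for hemi in (LEFT, RIGHT):
        idx = [i for i in epochs.montage.channel_indices(hemi) if epochs.usable[i]]
        if not idx:
            raise ValueError(f"no usable channels in the {hemi} hemisphere")
        out.append(float(np.mean(maxima[idx])))
    return out[0], out[1]


def laterality_index(peak_left: float, peak_right: float) -> float:
    """(peak_left - peak_right) / (peak_left + peak_right)."""
    denom = peak_left + peak_right
    if denom == 0:
        raise ZeroDivisionError("laterality index undefined: peak_left + peak_right = 0")
    return (peak_left - peak_right) / denom


# ---------------------------------------------------------------------------
# per-subject summary
# ---------------------------------------------------------------------------

@dataclass
class SubjectResponse:
    """One subject's vHDR readouts for a single condition."""

    condition: str
    channel_average: dict[str, tuple[float, float]]   # chrom -> (amp, latency)
    best_channel_id: str
    best_channel: dict[str, tuple[float, float]]
    peak_left: float
    peak_right: float
    li: float


def compute_subject_response(
    hb: HbRecording,
    condition: str,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    search_window: tuple[float, float] = DEFAULT_SEARCH,
    epochs: EpochSet | None = None,
) -> SubjectResponse:
    epochs = epochs or epoch_trials(hb, pre_s=pre_s, post_s=post_s, baseline=baseline)
    avg = channel_average_response(epochs, condition, search_window)
    best_id, best = best_channel_response(epochs, condition, search_window)
    pl, pr = hemisphere_peaks(epochs, condition, search_window)
    return SubjectResponse(
        condition=condition,
        channel_average=avg,
        best_channel_id=best_id,
        best_channel=best,
        peak_left=pl,
        peak_right=pr,
        li=laterality_index(pl, pr),
    )


def subject_metrics_table(
    subject_id: str,
    group: str,
    hb: HbRecording,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    search_window: tuple[float, float] = DEFAULT_SEARCH,
) -> pd.DataFrame:
    """Tidy metric rows (subject_id, group, condition, chromophore, metric, value)."""
    epochs = epoch_trials(hb, pre_s=pre_s, post_s=post_s, baseline=baseline)
    rows = []
    for cond in epochs.conditions():
        resp = compute_subject_response(hb, cond, epochs=epochs, search_window=search_window)
        for chrom in CHROMOPHORES:
            a, l = resp.channel_average[chrom]
            rows.append((subject_id, group, cond, chrom, "avg_amp", a))
            rows.append((subject_id, group, cond, chrom, "avg_lat", l))
            a, l = resp.best_channel[chrom]
            rows.append((subject_id, group, cond, chrom, "best_amp", a))
            rows.append((subject_id, group, cond, chrom, "best_lat", l))
        rows.append((subject_id, group, cond, "OHb", "peak_left", resp.peak_left))
        rows.append((subject_id, group, cond, "OHb", "peak_right", resp.peak_right))
        rows.append((subject_id, group, cond, "OHb", "LI", resp.li))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "condition", "chromophore", "metric", "value"]
    )
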