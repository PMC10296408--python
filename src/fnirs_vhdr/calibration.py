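"""Simulation studies: parameter recovery, power, type-I calibration, artifacts.

These routines drive the full signal chain (simulate -> OD -> artifacts ->
preprocess -> metrics -> stats) for the recovery and power studies, and a
subject-level null generative model for the large-replicate type-I / FDR
calibration, where re-simulating full recordings would add nothing but noise
to the estimate of a property of the tests themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import generate_event_schedule
from .metrics import laterality_index, subject_metrics_table
from .montage import make_default_montage
from .preprocess import PreprocessParams, preprocess_od
from .simulate import (
    ClinicalModel,
    SimulationConfig,
    asd_default_config,
    simulate_cohort,
    simulate_od_subject,
    td_default_config,
)
from .stats import StatsConfig, independent_t, mixed_anova, paired_t, run_full_stats, spearman


# ---------------------------------------------------------------------------
# full-chain single-subject processing
# ---------------------------------------------------------------------------

def process_subject(
    montage, schedule, config: SimulationConfig, seed: int,
    params: PreprocessParams | None = None,
):
    """Simulate one subject through the complete chain; return (truth, hb)."""
    od_rec, truth, _events, _clean = simulate_od_subject(montage, schedule, config, seed)
    hb, _mask = preprocess_od(od_rec, params)
    return truth, hb


def recovery_study(
    n_subjects: int = 100,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Estimated vs true LI (and OHb amplitude) over simulated subjects.

    Alternates TD-like and ASD-like generative parameters so the LI range is
    representative of both groups.
    """
    montage = make_default_montage()
    rng = np.random.default_rng(seed)
    rows = []
    cfgs = [td_default_config(), asd_default_config()] if config is None else [config]
    for i in range(n_subjects):
        cfg = cfgs[i % len(cfgs)]
        sched = generate_event_schedule(20, 20, 5.0, 10.0, seed=int(rng.integers(0, 2**31 - 1)))
        truth, hb = process_subject(montage, sched, cfg, int(rng.integers(0, 2**31 - 1)))
        metrics = subject_metrics_table(f"S{i:03d}", "X", hb)
        stim = metrics[metrics.condition == "STIM"].set_index(["chromophore", "metric"])["value"]
        est_li = float(stim.loc[("OHb", "LI")])
        est_amp = float(stim.loc[("OHb", "avg_amp")])
        rows.append({
            "subject": i,
            "true_li": truth.li, "est_li": est_li,
            "true_amp": float(np.mean(truth.ohb_amp)), "est_amp": est_amp,
        })
    return pd.DataFrame(rows)


def process_cohort(
    subjects,
    config_td: SimulationConfig | None = None,
    config_asd: SimulationConfig | None = None,
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Push already-simulated subjects through OD conversion, artifact
    injection, preprocessing and metric extraction (keeps the clinical table's
    link to each subject's ground truth intact)."""
    from .simulate import subject_od_recording

    config_td = config_td or td_default_config()
    config_asd = config_asd or asd_default_config()
    frames = []
    for sub in subjects:
        cfg = config_td if sub.group == "TD" else config_asd
        od_rec = subject_od_recording(sub, cfg)
        processed, _mask = preprocess_od(od_rec, params)
        frames.append(subject_metrics_table(sub.subject_id, sub.group, processed))
    return pd.concat(frames, ignore_index=True)


def cohort_metrics(
    n_td: int, n_asd: int, seed: int,
    config_td: SimulationConfig | None = None,
    config_asd: SimulationConfig | None = None,
    clinical_model: ClinicalModel | None = None,
    params: PreprocessParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort through the full chain; return (metrics, clinical)."""
    montage = make_default_montage()
    subjects, clinical = simulate_cohort(
        n_td, n_asd, config_td, config_asd, clinical_model, seed=seed, montage=montage
    )
    metrics = process_cohort(subjects, config_td, config_asd, params)
    return metrics, clinical


def power_study(
    n_reps: int = 100,
    seed: int = 0,
    n_td: int = 13,
    n_asd: int = 12,
    config_td: SimulationConfig | None = None,
    config_asd: SimulationConfig | None = None,
    stats_config: StatsConfig | None = None,
) -> dict[str, float]:
    """Fraction of replicates where the key group effects reach adjusted
    significance: OHb amplitude reduction, LI group difference, LI–AQ
    correlation.  Each replicate simulates a full cohort through the chain."""
    montage = make_default_montage()
    config_td = config_td or td_default_config()
    config_asd = config_asd or asd_default_config()
    stats_config = stats_config or StatsConfig()
    rng = np.random.default_rng(seed)
    hits = {"amplitude_OHb": 0, "LI_group": 0, "LI_AQ_corr": 0}
    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        subjects, clinical = simulate_cohort(
            n_td, n_asd, config_td, config_asd, seed=rep_seed, montage=montage
        )
        metrics = process_cohort(subjects, config_td, config_asd)
        res = run_full_stats(metrics, clinical, stats_config).set_index("test")
        alpha = stats_config.alpha
        if res.loc["amplitude_avg_OHb", "p_adj"] < alpha:
            hits["amplitude_OHb"] += 1
        if res.loc["LI_group", "p_adj"] < alpha:
            hits["LI_group"] += 1
        if res.loc["corr_LI_AQ_tot", "p_adj"] < alpha:
            hits["LI_AQ_corr"] += 1
    return {k: v / n_reps for k, v in hits.items()}


# ---------------------------------------------------------------------------
# null generative model at the subject-metric level
# ---------------------------------------------------------------------------

def null_metric_tables(
    n_td: int = 13, n_asd: int = 12, rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level metric and clinical tables with no true effect anywhere.

    Amplitudes, latencies and hemisphere peaks are drawn from identical
    distributions for both groups and both conditions; clinical scores are
    independent of the imaging metrics.
    """
    rng = rng or np.random.default_rng()
    rows = []
    clinical_rows = []
    for g, n in (("TD", n_td), ("ASD", n_asd)):
        for i in range(n):
            sid = f"{g}{i + 1:02d}"
            for cond in ("STIM", "MOCK"):
                for chrom in ("THb", "OHb", "DHb"):
                    for kind in ("avg", "best"):
                        rows.append((sid, g, cond, chrom, f"{kind}_amp", rng.normal(2e-5, 5e-6)))
                        rows.append((sid, g, cond, chrom, f"{kind}_lat", rng.normal(7.0, 1.0)))
                pl = rng.normal(2e-5, 5e-6)
                pr = rng.normal(2e-5, 5e-6)
                rows.append((sid, g, cond, "OHb", "peak_left", pl))
                rows.append((sid, g, cond, "OHb", "peak_right", pr))
                rows.append((sid, g, cond, "OHb", "LI", laterality_index(pl, pr)))
            if g == "ASD":
                clinical_rows.append({
                    "subject_id": sid, "age": int(rng.integers(3, 7)),
                    "ADOS_TOT": rng.normal(11.6, 2.7), "ADOS_comp": rng.normal(5.4, 1.0),
                    "AQ_tot": rng.normal(60, 20), "nv_IQ": rng.normal(104, 14),
                    "VABS_tot": rng.normal(84, 11),
                })
    metrics = pd.DataFrame(
        rows, columns=["subject_id", "group", "condition", "chromophore", "metric", "value"])
    return metrics, pd.DataFrame(clinical_rows)


def type_i_error_rates(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05,
                       n_td: int = 13, n_asd: int = 12) -> dict[str, float]:
    """Monte-Carlo type-I error of every implemented test under the null."""
    rng = np.random.default_rng(seed)
    rej = {k: 0 for k in (
        "paired_t", "welch_t", "student_t", "spearman",
        "anova_group", "anova_hemisphere", "anova_interaction",
    )}
    for _ in range(n_reps):
        x = rng.normal(size=n_td)
        y = rng.normal(size=n_td)
        if paired_t(x, y).p < alpha:
            rej["paired_t"] += 1
        g1, g2 = rng.normal(size=n_td), rng.normal(size=n_asd)
        if independent_t(g1, g2, welch=True).p < alpha:
            rej["welch_t"] += 1
        if independent_t(g1, g2, welch=False).p < alpha:
            rej["student_t"] += 1
        if spearman(rng.normal(size=n_asd), rng.normal(size=n_asd)).p < alpha:
            rej["spearman"] += 1
        table = pd.DataFrame({
            "subject": np.repeat(np.arange(n_td + n_asd), 2),
            "group": np.repeat(["A"] * n_td + ["B"] * n_asd, 2),
            "hemisphere": ["left", "right"] * (n_td + n_asd),
            "value": rng.normal(size=2 * (n_td + n_asd)),
        })
        for res in mixed_anova(table):
            key = "anova_" + res.name.split("_")[-1]
            if res.p < alpha:
                rej[key] += 1
    return {k: v / n_reps for k, v in rej.items()}


def familywise_null_rates(n_reps: int = 1000, seed: int = 0,
                          alpha: float = 0.05) -> dict[str, float]:
    """Per-family probability of any BH-adjusted rejection under the global
    null — bounded by alpha when the FDR adjustment behaves."""
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for _ in range(n_reps):
        metrics, clinical = null_metric_tables(rng=rng)
        res = run_full_stats(metrics, clinical)
        for fam, sub in res.groupby("family"):
            if (sub["p_adj"] < alpha).any():
                counts[fam] = counts.get(fam, 0) + 1
            else:
                counts.setdefault(fam, counts.get(fam, 0))
    return {k: v / n_reps for k, v in counts.items()}


# ---------------------------------------------------------------------------
# motion-artifact handling study
# ---------------------------------------------------------------------------

@dataclass
class ArtifactStudyResult:
    sensitivity: float          # fraction of injected (event, channel) pairs hit
    false_flag_fraction: float  # flagged samples outside true artifact windows
    rms_error_ratio: float      # RMS(corrected - clean) / RMS(clean)


def artifact_study(n_seeds: int = 200, seed: int = 0,
                   config: SimulationConfig | None = None) -> ArtifactStudyResult:
    """Detection sensitivity and correction fidelity on default simulations.

    Each replicate simulates a default subject, injects artifacts at the
    configured rate, runs detection + correction, and compares against the
    simulator's injected-event list and clean OD series.
    """
    from .preprocess import correct_motion, detect_motion

    config = config or td_default_config()
    params = PreprocessParams()
    montage = make_default_montage()
    rng = np.random.default_rng(seed)
    hit = total = 0
    false_flag_num = false_flag_den = 0
    sq_err = sq_clean = 0.0
    pad = int(round(config.sampling_rate * 0.5))
    for _ in range(n_seeds):
        sched = generate_event_schedule(20, 20, 5.0, 10.0,
                                        seed=int(rng.integers(0, 2**31 - 1)))
        od_rec, _tr, events, od_clean = simulate_od_subject(
            montage, sched, config, int(rng.integers(0, 2**31 - 1)))
        mask = detect_motion(
            od_rec.od, config.sampling_rate,
            window_s=params.motion_window_s, amp_thresh=params.amp_thresh_od,
            std_thresh=params.std_thresh,
            shift_offset_thresh=params.shift_offset_thresh_od)
        n_t = od_rec.n_samples
        truth_flags = np.zeros(n_t, dtype=bool)
        for ev in events:
            truth_flags[max(0, ev.sample - pad): min(n_t, ev.sample + ev.width + pad)] = True
        for c in range(montage.n_channels):
            flags = mask.channel_flags(c)
            for ev in events:
                total += 1
                if flags[ev.sample: ev.sample + ev.width].any():
                    hit += 1
            false_flag_num += int((flags & ~truth_flags).sum())
            false_flag_den += n_t
        corrected = correct_motion(od_rec.od, mask, config.sampling_rate,
                                   params.shift_offset_thresh_od,
                                   schedule=od_rec.schedule,
                                   step_sub_thresh=params.step_sub_thresh_od)
        sq_err += float(np.sum((corrected - od_clean) ** 2))
        sq_clean += float(np.sum(od_clean ** 2))
    return ArtifactStudyResult(
        sensitivity=hit / total if total else 1.0,
        false_flag_fraction=false_flag_num / false_flag_den if false_flag_den else 0.0,
        rms_error_ratio=float(np.sqrt(sq_err / sq_clean)) if sq_clean else 0.0,
    )
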