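"""Group statistics: t-tests, split-plot ANOVA, Spearman, BH-FDR.

The analysis plan for a two-group visual fNIRS cohort:

* stim-vs-mock paired t-tests per chromophore, per group, for both the
  channel-average and best-channel amplitude (response reliability);
* between-group comparisons of amplitude and latency (Welch by default);
* a two-way mixed ANOVA with hemisphere as the within-subject factor and
  group as the between-subject factor, on the hemisphere OHb peaks;
* a between-group t-test on the laterality index;
* Spearman correlations of LI and OHb amplitude with the clinical scores
  (AQ_tot, VABS_tot, ADOS_TOT, nv_IQ), pairwise-deleting missing values;
* Benjamini–Hochberg FDR adjustment within each test family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

CLINICAL_SCORES = ["AQ_tot", "VABS_tot", "ADOS_TOT", "nv_IQ"]


@dataclass
class StatResult:
    """A single test outcome; ``p_adj`` is filled in by the FDR pass."""

    name: str
    family: str
    statistic: float
    df: float | tuple
    p: float
    p_adj: float | None = None
    direction: str = ""
    n: tuple | int = 0

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")

    def as_row(self) -> dict:
        df = self.df if not isinstance(self.df, tuple) else "/".join(str(d) for d in self.df)
        n = self.n if not isinstance(self.n, tuple) else "/".join(str(v) for v in self.n)
        return {
            "test": self.name, "family": self.family, "statistic": self.statistic,
            "df": df, "p": self.p, "p_adj": self.p_adj,
            "direction": self.direction, "n": n,
        }


# ---------------------------------------------------------------------------
# elemental tests
# ---------------------------------------------------------------------------

def paired_t(x, y, name: str = "paired_t", family: str = "") -> StatResult:
    """Classical paired t-test on the differences, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # identical pairs: no effect, by convention t = 0, p = 1
            return StatResult(name, family, 0.0, n - 1, 1.0, direction="", n=n)
        raise ValueError("paired differences have zero variance; t is undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult(name, family, float(t), n - 1, float(p),
                      direction="x>y" if t > 0 else "x<y", n=n)


def independent_t(g1, g2, welch: bool = True,
                  name: str = "independent_t", family: str = "") -> StatResult:
    """Two-sample t-test, Welch by default (Student with ``welch=False``)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    n1, n2 = g1.size, g2.size
    if welch:
        se2 = v1 / n1 + v2 / n2
        t = (g1.mean() - g2.mean()) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(name, family, float(t), float(df), float(p),
                      direction="g1>g2" if t > 0 else "g1<g2", n=(n1, n2))


def mixed_anova(table: pd.DataFrame, name_prefix: str = "anova",
                family: str = "") -> list[StatResult]:
    """Two-way mixed (split-plot) ANOVA: hemisphere within, group between.

    ``table`` needs columns subject, group, hemisphere, value with exactly two
    hemisphere levels.  Subjects missing a hemisphere are dropped with a
    warning.  The classical sums-of-squares decomposition, with k = 2
    within-subject levels, N subjects in g groups of sizes n_g:

        SS_between_subj = k * sum_s (mean_s - grand)^2
        SS_group        = k * sum_g n_g (mean_g - grand)^2
        SS_subj(group)  = SS_between_subj - SS_group           df = N - g
        SS_within       = sum (x - mean_subject)^2
        SS_hemi         = N * sum_h (mean_h - grand)^2          df = k - 1
        SS_gxh          = sum_{g,h} n_g (cell - mean_g - mean_h + grand)^2
        SS_error        = SS_within - SS_hemi - SS_gxh          df = (N-g)(k-1)

    F_group = MS_group / MS_subj(group); the within effects are tested
    against MS_error.
    """
    req = {"subject", "group", "hemisphere", "value"}
    if not req.issubset(table.columns):
        raise ValueError(f"mixed_anova table needs columns {sorted(req)}")
    hemis = sorted(table["hemisphere"].unique())
    if len(hemis) != 2:
        raise ValueError("exactly two hemisphere levels are required")
    wide = table.pivot_table(index=["subject", "group"], columns="hemisphere",
                             values="value", aggfunc="mean")
    incomplete = wide.isna().any(axis=1)
    for subj, _grp in wide.index[incomplete]:
        log.warning("subject %s lacks a hemisphere measurement; dropped", subj)
    wide = wide[~incomplete]
    groups = wide.index.get_level_values("group")
    g_levels = sorted(set(groups))
    if len(g_levels) < 2 or any((groups == g).sum() < 2 for g in g_levels):
        raise ValueError("need at least 2 groups with >= 2 subjects each")

    x = wide.to_numpy()                       # (N, 2)
    n_subj, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    hemi_means = x.mean(axis=0)
    ss_between_subj = k * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    ss_gxh = 0.0
    for g in g_levels:
        sel = groups == g
        ng = sel.sum()
        gmean = x[sel].mean()
        ss_group += k * ng * (gmean - grand) ** 2
        cell = x[sel].mean(axis=0)
        ss_gxh += ng * np.sum((cell - gmean - hemi_means + grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_within = np.sum((x - subj_means[:, None]) ** 2)
    ss_hemi = n_subj * np.sum((hemi_means - grand) ** 2)
    ss_error = max(ss_within - ss_hemi - ss_gxh, 0.0)

    g = len(g_levels)
    df_group, df_subj = g - 1, n_subj - g
    df_hemi = k - 1
    df_err = (n_subj - g) * (k - 1)

    def f_result(label, ss_eff, df_eff, ss_err, df_err_):
        if ss_eff <= 0:
            return StatResult(f"{name_prefix}_{label}", family, 0.0,
                              (df_eff, df_err_), 1.0, n=n_subj)
        ms_err = ss_err / df_err_ if df_err_ > 0 else 0.0
        if ms_err == 0:
            return StatResult(f"{name_prefix}_{label}", family, float("inf"),
                              (df_eff, df_err_), 0.0, n=n_subj)
        f = (ss_eff / df_eff) / ms_err
        p = sps.f.sf(f, df_eff, df_err_)
        return StatResult(f"{name_prefix}_{label}", family, float(f),
                          (df_eff, df_err_), float(p), n=n_subj)

    return [
        f_result("group", ss_group, df_group, ss_subj_within, df_subj),
        f_result("hemisphere", ss_hemi, df_hemi, ss_error, df_err),
        f_result("interaction", ss_gxh, df_group * df_hemi, ss_error, df_err),
    ]


def spearman(x, y, name: str = "spearman", family: str = "") -> StatResult:
    """Spearman rank correlation with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("Spearman correlation needs at least 3 complete pairs")
    rho, p = sps.spearmanr(x[ok], y[ok])
    return StatResult(name, family, float(rho), int(ok.sum()) - 2, float(p),
                      direction="positive" if rho > 0 else "negative", n=int(ok.sum()))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    With m p-values sorted ascending, p_adj(i) = min_{j >= i} p(j) * m / j,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def demographic_summary(ages) -> tuple[float, float, float, float]:
    """Median and sample SD (n-1) of ages; also rounded to 2 dp for reporting."""
    a = np.asarray(ages, dtype=float)
    if a.size == 0:
        raise ValueError("no ages provided")
    median = float(np.median(a))
    if a.size < 2:
        raise ValueError("sample SD needs at least 2 values")
    sd = float(a.std(ddof=1))
    return median, sd, round(median, 2), round(sd, 2)


# ---------------------------------------------------------------------------
# full statistical plan
# ---------------------------------------------------------------------------

@dataclass
class StatsConfig:
    welch: bool = True
    alpha: float = 0.05
    groups: tuple[str, str] = ("TD", "ASD")
    conditions: tuple[str, str] = ("STIM", "MOCK")


def _pivot_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Tidy (subject_id, group, condition, chromophore, metric, value) -> wide."""
    req = {"subject_id", "group", "condition", "chromophore", "metric", "value"}
    missing = req - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table is missing columns: {sorted(missing)}")
    wide = metrics.pivot_table(
        index=["subject_id", "group"],
        columns=["condition", "chromophore", "metric"],
        values="value",
    )
    return wide


def _col(wide, cond, chrom, metric):
    try:
        return wide[(cond, chrom, metric)]
    except KeyError:
        raise ValueError(f"metrics table lacks {cond}/{chrom}/{metric}") from None


def run_full_stats(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    config: StatsConfig | None = None,
) -> pd.DataFrame:
    """Execute the full plan and return one results table.

    Families for FDR adjustment: reliability, amplitude, latency,
    lateralization, correlations.  Rows report the raw and adjusted p.
    """
    config = config or StatsConfig()
    wide = _pivot_metrics(metrics)
    groups = wide.index.get_level_values("group")
    g_td, g_asd = config.groups
    stim, mock = config.conditions
    results: list[StatResult] = []

    # reliability: stim vs mock, paired within subject
    for grp in (g_td, g_asd):
        sel = groups == grp
        for kind in ("avg", "best"):
            for chrom in ("THb", "OHb", "DHb"):
                x = _col(wide, stim, chrom, f"{kind}_amp")[sel]
                y = _col(wide, mock, chrom, f"{kind}_amp")[sel]
                try:
                    results.append(paired_t(
                        x, y, name=f"reliability_{grp}_{kind}_{chrom}", family="reliability"))
                except ValueError as exc:
                    log.warning("skipping reliability_%s_%s_%s: %s", grp, kind, chrom, exc)

    # amplitude and latency: TD vs ASD on the stimulation condition
    td_sel, asd_sel = groups == g_td, groups == g_asd
    for kind in ("avg", "best"):
        for chrom in ("THb", "OHb", "DHb"):
            for fam, metric in (("amplitude", "amp"), ("latency", "lat")):
                v = _col(wide, stim, chrom, f"{kind}_{metric}")
                try:
                    results.append(independent_t(
                        v[td_sel], v[asd_sel], welch=config.welch,
                        name=f"{fam}_{kind}_{chrom}", family=fam))
                except ValueError as exc:
                    log.warning("skipping %s_%s_%s: %s", fam, kind, chrom, exc)

    # lateralization: mixed ANOVA on hemisphere peaks + LI group test
    pl = _col(wide, stim, "OHb", "peak_left")
    pr = _col(wide, stim, "OHb", "peak_right")
    long = pd.DataFrame({
        "subject": np.repeat(wide.index.get_level_values("subject_id"), 2),
        "group": np.repeat(groups, 2),
        "hemisphere": ["left", "right"] * len(wide),
        "value": np.column_stack([pl, pr]).ravel(),
    })
    results.extend(mixed_anova(long, name_prefix="hemi_anova", family="lateralization"))
    li = _col(wide, stim, "OHb", "LI")
    results.append(independent_t(
        li[td_sel], li[asd_sel], welch=config.welch,
        name="LI_group", family="lateralization"))

    # correlations with clinical scores (ASD group)
    if clinical is not None and len(clinical):
        cl = clinical.set_index("subject_id")
        asd_ids = wide.index.get_level_values("subject_id")[asd_sel]
        common = [s for s in asd_ids if s in cl.index]
        li_asd = li[asd_sel]
        li_map = dict(zip(asd_ids, li_asd))
        amp_asd = _col(wide, stim, "OHb", "avg_amp")[asd_sel]
        amp_map = dict(zip(asd_ids, amp_asd))
        for metric_name, mapping in (("LI", li_map), ("OHb_avg_amp", amp_map)):
            for score in CLINICAL_SCORES:
                if score not in cl.columns:
                    continue
                xs = np.array([mapping[s] for s in common])
                ys = pd.to_numeric(cl.loc[common, score], errors="coerce").to_numpy(float)
                try:
                    results.append(spearman(
                        xs, ys, name=f"corr_{metric_name}_{score}", family="correlations"))
                except ValueError as exc:
                    log.warning("skipping correlation %s vs %s: %s", metric_name, score, exc)

    # BH-FDR within each family
    out = pd.DataFrame([r.as_row() for r in results])
    out["p_adj"] = out["p"].astype(float)
    for fam, idx in out.groupby("family").groups.items():
        out.loc[idx, "p_adj"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out
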