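"""Serial-biomarker response and survival statistics.

Implements the analysis grid for a serial multimodal imaging cohort:
percent changes from baseline, metabolism/perfusion mismatch ratios,
baseline Spearman correlations, Wilcoxon rank-sum comparisons between
pathological responders (RCB 0/I) and non-responders (RCB II/III) with
Benjamini-Hochberg correction per analysis family, univariate Cox
proportional-hazards regressions of recurrence-free survival on percent
change (hazard ratio per 5%-change unit, Wald test, Efron ties), and
Kaplan-Meier curves dichotomized at the third quartile of percent
change with log-rank comparison.

All tests are two-sided; significance level 0.05 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .core import ALL_METRICS, LesionMetrics, MpqError, TIMEPOINTS

log = logging.getLogger("mpq.stats")


@dataclass
class StatResult:
    """One test result with multiple-comparison bookkeeping."""

    metric: str
    analysis: str                 # "spearman" | "wilcoxon" | "cox" | "logrank"
    timepoint: Optional[str] = None
    estimate: Optional[float] = None   # rho, HR, or chi-square
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    statistic: Optional[float] = None
    p_raw: Optional[float] = None
    p_adjusted: Optional[float] = None
    family: Optional[str] = None
    n: int = 0
    n_events: Optional[int] = None
    note: str = ""

    @property
    def ok(self) -> bool:
        return self.p_raw is not None and self.note == ""


# ------------------------------------------------------------- change & ratios

def percent_change(baseline: Optional[float], followup: Optional[float]) -> Optional[float]:
    """100 * (followup - baseline)/baseline; None when undefined.

    A missing or zero baseline (or missing follow-up) yields a missing
    marker rather than an exception — per-metric Ns shrink accordingly.
    """
    if baseline is None or followup is None:
        return None
    if not np.isfinite(baseline) or not np.isfinite(followup):
        return None
    if baseline == 0:
        log.info("percent_change: zero baseline, change undefined")
        return None
    return 100.0 * (followup - baseline) / baseline


def mismatch_ratios(metrics: LesionMetrics) -> LesionMetrics:
    """Fill the five metabolism/perfusion ratio fields in place.

    Ratios: MRFDG/peak PE, MRFDG/peak SER, MRFDG/K1, SUVmax/peak PE,
    SUVmax/peak SER. A missing or non-positive denominator makes that
    ratio missing; the others are still computed.
    """
    def ratio(num: Optional[float], den: Optional[float]) -> Optional[float]:
        if num is None or den is None or den <= 0:
            return None
        return num / den

    metrics.mrfdg_peak_pe = ratio(metrics.mrfdg, metrics.peak_pe)
    metrics.mrfdg_peak_ser = ratio(metrics.mrfdg, metrics.peak_ser)
    metrics.mrfdg_k1 = ratio(metrics.mrfdg, metrics.k1)
    metrics.suvmax_peak_pe = ratio(metrics.suvmax, metrics.peak_pe)
    metrics.suvmax_peak_ser = ratio(metrics.suvmax, metrics.peak_ser)
    return metrics


# ------------------------------------------------------------------- inference

def _complete_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x: Sequence[float], y: Sequence[float], metric: str = "") -> StatResult:
    """Spearman rank correlation with pairwise-complete deletion.

    Average ranks for ties; two-sided p from the t approximation.
    Fewer than 3 complete pairs or a constant margin yields a flagged
    (undefined) result.
    """
    xs, ys = _complete_pairs(x, y)
    if xs.size < 3:
        return StatResult(metric, "spearman", n=int(xs.size), note="fewer than 3 complete pairs")
    if np.unique(xs).size == 1 or np.unique(ys).size == 1:
        return StatResult(metric, "spearman", n=int(xs.size), note="constant input, rho undefined")
    rho, p = sps.spearmanr(xs, ys)
    return StatResult(metric, "spearman", estimate=float(rho), p_raw=float(p), n=int(xs.size))


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    metric: str = "",
    timepoint: Optional[str] = None,
    exact_max_n: int = 20,
) -> StatResult:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Exact null distribution when the combined sample is small (<= 20)
    and tie-free; otherwise the normal approximation with continuity
    and tie correction. Identical values throughout both groups give
    p = 1 (no evidence of a shift).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n = a.size + b.size
    if a.size == 0 or b.size == 0:
        return StatResult(metric, "wilcoxon", timepoint, n=int(n), note="empty group")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        return StatResult(
            metric, "wilcoxon", timepoint, estimate=float(a.size * b.size / 2),
            statistic=float(a.size * b.size / 2), p_raw=1.0, n=int(n),
        )
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (n <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        metric, "wilcoxon", timepoint,
        estimate=float(res.statistic), statistic=float(res.statistic),
        p_raw=float(res.pvalue), n=int(n),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise MpqError("bh_adjust: empty family")
    if np.any((p < 0) | (p > 1)):
        raise MpqError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_bh(results: list[StatResult], family: str) -> None:
    """Attach BH-adjusted p-values to the testable results of one family."""
    testable = [r for r in results if r.p_raw is not None]
    if not testable:
        return
    adjusted = bh_adjust([r.p_raw for r in testable])
    for r, padj in zip(testable, adjusted):
        r.p_adjusted = float(padj)
        r.family = family
    for r in results:
        if r.p_raw is None:
            r.family = family


def cox_univariate(
    change: Sequence[float],
    rfs_time: Sequence[float],
    rfs_event: Sequence[bool],
    unit_percent: float = 5.0,
    metric: str = "",
    timepoint: Optional[str] = None,
) -> StatResult:
    """Univariate Cox PH of RFS on percent change, HR per ``unit_percent``.

    Efron partial-likelihood tie handling; Wald test and 95% Wald CI.
    Rows with a missing covariate are dropped (per-metric N). Requires
    at least one event and a non-constant covariate; monotone-likelihood
    failures are returned flagged, not raised.
    """
    x = np.asarray(change, dtype=float)
    t = np.asarray(rfs_time, dtype=float)
    e = np.asarray(rfs_event, dtype=bool)
    keep = np.isfinite(x) & np.isfinite(t)
    x, t, e = x[keep], t[keep], e[keep]
    n, n_events = int(x.size), int(e.sum())
    if n_events < 1:
        return StatResult(metric, "cox", timepoint, n=n, n_events=0, note="no events")
    if np.unique(x).size == 1:
        return StatResult(metric, "cox", timepoint, n=n, n_events=n_events,
                          note="constant covariate")
    df = pd.DataFrame({"x": x / unit_percent, "t": t, "e": e.astype(int)})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="t", event_col="e", show_progress=False)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        return StatResult(metric, "cox", timepoint, n=n, n_events=n_events,
                          note=f"non-convergence: {type(exc).__name__}")
    row = cph.summary.loc["x"]
    return StatResult(
        metric, "cox", timepoint,
        estimate=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        statistic=float(row["z"]),
        p_raw=float(row["p"]),
        n=n, n_events=n_events,
    )


@dataclass
class KmResult:
    """Q3-dichotomized Kaplan-Meier comparison for one metric."""

    metric: str
    q3: float
    # "larger decrease": percent change <= Q3 (more negative / smaller).
    curve_larger_decrease: Optional[pd.DataFrame]
    curve_smaller_decrease: Optional[pd.DataFrame]
    test: StatResult = field(default_factory=lambda: StatResult("", "logrank"))


def km_logrank_q3(
    change: Sequence[float],
    rfs_time: Sequence[float],
    rfs_event: Sequence[bool],
    metric: str = "",
    timepoint: Optional[str] = None,
) -> KmResult:
    """Kaplan-Meier curves split at the third quartile of percent change.

    Q3 uses linear interpolation between order statistics. The group
    with change <= Q3 is labelled the "larger decrease" group (percent
    changes are predominantly negative under tumor response); both
    curves carry explicit labels. Log-rank chi-square compares them.
    Degenerate splits (all values equal, a group of < 2, or no events)
    are flagged, not raised.
    """
    x = np.asarray(change, dtype=float)
    t = np.asarray(rfs_time, dtype=float)
    e = np.asarray(rfs_event, dtype=bool)
    keep = np.isfinite(x) & np.isfinite(t)
    x, t, e = x[keep], t[keep], e[keep]
    flagged = StatResult(metric, "logrank", timepoint, n=int(x.size), n_events=int(e.sum()))
    if x.size < 4:
        flagged.note = "too few patients for a Q3 split"
        return KmResult(metric, float("nan"), None, None, flagged)
    q3 = float(np.percentile(x, 75, method="linear"))
    lower = x <= q3
    if np.unique(x).size == 1 or lower.all() or (~lower).sum() < 2 or lower.sum() < 2:
        flagged.note = "degenerate Q3 split"
        return KmResult(metric, q3, None, None, flagged)
    if not e.any():
        flagged.note = "no events; curves are flat, log-rank undefined"

    def km_curve(sel: np.ndarray, label: str) -> pd.DataFrame:
        kmf = KaplanMeierFitter(label=label)
        kmf.fit(t[sel], event_observed=e[sel])
        out = kmf.survival_function_.reset_index()
        out.columns = ["time_years", "survival"]
        out["group"] = label
        return out

    curve_lo = km_curve(lower, f"{metric} change <= Q3 (larger decrease)")
    curve_hi = km_curve(~lower, f"{metric} change > Q3 (smaller decrease)")
    if flagged.note:
        return KmResult(metric, q3, curve_lo, curve_hi, flagged)
    lr = logrank_test(t[lower], t[~lower], e[lower], e[~lower])
    test = StatResult(
        metric, "logrank", timepoint,
        estimate=float(lr.test_statistic), statistic=float(lr.test_statistic),
        p_raw=float(lr.p_value), n=int(x.size), n_events=int(e.sum()),
    )
    return KmResult(metric, q3, curve_lo, curve_hi, test)


# ------------------------------------------------------------------ full grid

@dataclass
class AnalysisReport:
    """Every analysis the serial-cohort study grid produces."""

    spearman_baseline: pd.DataFrame
    wilcoxon: list[StatResult]
    cox: list[StatResult]
    km: dict[str, KmResult]
    group_summary: pd.DataFrame        # mean (SD) and median (IQR) per group
    cox_summary: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def results_frame(self) -> pd.DataFrame:
        rows = [vars(r) for r in self.wilcoxon + self.cox] + [
            vars(k.test) for k in self.km.values()
        ]
        return pd.DataFrame(rows)


def _metric_columns(cohort: pd.DataFrame, timepoint: str) -> list[str]:
    prefix = "pct_"
    suffix = f"_{timepoint}"
    metrics = []
    for col in cohort.columns:
        if col.startswith(prefix) and col.endswith(suffix):
            metrics.append(col[len(prefix):-len(suffix)])
    order = {m: i for i, m in enumerate(ALL_METRICS)}
    return sorted(metrics, key=lambda m: order.get(m, len(order)))


def run_full_analysis(
    cohort: pd.DataFrame, config: Optional[AnalysisConfig] = None
) -> AnalysisReport:
    """Run the complete analysis grid on a cohort table.

    Baseline Spearman correlations (all pairs of ``*_baseline`` columns),
    per-metric Wilcoxon responder comparisons at mid and post (BH family
    per timepoint), per-metric Cox PH at mid and post (BH family per
    timepoint), and Q3-dichotomized KM/log-rank for the configured
    metrics. Deterministic given the cohort table. Insufficient data
    produces flagged results and notes, never an exception.
    """
    config = config or AnalysisConfig()
    for col in ("responder", "rfs_time_years", "rfs_event"):
        if col not in cohort.columns:
            raise MpqError(f"cohort table lacks outcome column {col!r}")
    notes: list[str] = []

    # Baseline Spearman matrix.
    base_cols = [c for c in cohort.columns if c.endswith("_baseline")]
    spearman_rows = []
    for i, ci in enumerate(base_cols):
        for cj in base_cols[i + 1:]:
            r = spearman(cohort[ci], cohort[cj], metric=f"{ci[:-9]}~{cj[:-9]}")
            spearman_rows.append({
                "pair": r.metric, "rho": r.estimate, "p": r.p_raw, "n": r.n,
                "note": r.note,
            })
    spearman_df = pd.DataFrame(
        spearman_rows, columns=["pair", "rho", "p", "n", "note"]
    )

    resp = cohort["responder"].astype(bool)
    if resp.sum() < 2 or (~resp).sum() < 2:
        notes.append("insufficient data: fewer than 2 patients per response group")

    wilcoxon_results: list[StatResult] = []
    cox_results: list[StatResult] = []
    summary_rows = []
    for tp in ("mid", "post"):
        metrics = _metric_columns(cohort, tp)
        tp_wilcoxon = []
        tp_cox = []
        for m in metrics:
            col = cohort[f"pct_{m}_{tp}"]
            a = col[resp].to_numpy(float)
            b = col[~resp].to_numpy(float)
            if resp.sum() >= 2 and (~resp).sum() >= 2:
                w = wilcoxon_rank_sum(a, b, metric=m, timepoint=tp)
            else:
                w = StatResult(m, "wilcoxon", tp, n=int(np.isfinite(col).sum()),
                               note="insufficient group sizes")
            tp_wilcoxon.append(w)
            c = cox_univariate(
                col, cohort["rfs_time_years"], cohort["rfs_event"],
                unit_percent=config.cox_unit_percent, metric=m, timepoint=tp,
            )
            tp_cox.append(c)

            af, bf = a[np.isfinite(a)], b[np.isfinite(b)]
            summary_rows.append({
                "metric": m, "timepoint": tp,
                "responder_n": af.size, "nonresponder_n": bf.size,
                "responder_mean": af.mean() if af.size else np.nan,
                "responder_sd": af.std(ddof=1) if af.size > 1 else np.nan,
                "nonresponder_mean": bf.mean() if bf.size else np.nan,
                "nonresponder_sd": bf.std(ddof=1) if bf.size > 1 else np.nan,
                "responder_median": np.median(af) if af.size else np.nan,
                "responder_iqr": np.subtract(*np.percentile(af, [75, 25])) if af.size else np.nan,
                "nonresponder_median": np.median(bf) if bf.size else np.nan,
                "nonresponder_iqr": np.subtract(*np.percentile(bf, [75, 25])) if bf.size else np.nan,
                "p_wilcoxon": w.p_raw,
            })
        apply_bh(tp_wilcoxon, family=f"wilcoxon_{tp}")
        apply_bh(tp_cox, family=f"cox_{tp}")
        wilcoxon_results.extend(tp_wilcoxon)
        cox_results.extend(tp_cox)

    # Attach adjusted Wilcoxon p to the summary table.
    padj = {(r.metric, r.timepoint): r.p_adjusted for r in wilcoxon_results}
    for row in summary_rows:
        row["p_wilcoxon_adjusted"] = padj.get((row["metric"], row["timepoint"]))
    group_summary = pd.DataFrame(summary_rows)

    cox_summary = pd.DataFrame([
        {
            "metric": r.metric, "timepoint": r.timepoint, "n": r.n,
            "n_events": r.n_events, "hr_per_5pct": r.estimate,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p": r.p_raw, "p_adjusted": r.p_adjusted, "note": r.note,
        }
        for r in cox_results
    ])

    km_results: dict[str, KmResult] = {}
    tp = "mid"
    for m in config.km_metrics:
        col = f"pct_{m}_{tp}"
        if col not in cohort.columns:
            continue
        km_results[m] = km_logrank_q3(
            cohort[col], cohort["rfs_time_years"], cohort["rfs_event"],
            metric=m, timepoint=tp,
        )

    return AnalysisReport(
        spearman_baseline=spearman_df,
        wilcoxon=wilcoxon_results,
        cox=cox_results,
        km=km_results,
        group_summary=group_summary,
        cox_summary=cox_summary,
        notes=notes,
    )
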