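"""Evaluation of a reserve-prediction stream against the protocol reference.

The reference ("ground truth") reserve at each 1 Hz tick is the pressure
ratio on the LBNP staircase,

    CRM_GT(t) = 1 - P(t) / P_endpoint,

clipped to [0, 1].  Prediction quality is summarized per subject by

* performance error PE(t) = (pred(t) - gt(t)) / gt(t) on the fraction scale
  (positive = over-prediction), with ticks where the reference is 0
  discarded; its median (MDPE, signed bias) and median absolute value
  (MDAPE, unsigned error), reported in percent;
* the median 30-s rolling coefficient of variation of the smoothed stream
  (a localized noise measure);
* a 3x3 triage-zone confusion matrix (rows = reference zone, normalized to
  sum 1) with one-vs-rest accuracy/precision/recall/specificity per zone;
* the early-warning times of the detector battery.

PE and zone agreement are computed on the raw 1 Hz predictions: the trailing
smoothing filter exists to stabilize the display and detectors and lags the
reference staircase at stage transitions, which would charge the predictor
for filter delay.  Both entry points accept ``use="smoothed"`` to evaluate
the displayed stream instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import DetectionEvent, ZONE_LABELS, ZoneConfig, zone_codes
from .engine import CRMSeries
from .errors import EvaluationError
from .protocol import LBNPProtocol, reserve_fraction

__all__ = [
    "GroundTruthSeries", "PerformanceErrorSeries", "SubjectReport",
    "ground_truth", "performance_error", "mdpe_mdape", "rolling_cv",
    "zone_confusion", "evaluate_subject", "cohort_summary", "detection_time_stats",
]


@dataclass
class GroundTruthSeries:
    """Protocol-derived reserve reference, fraction in [0, 1] at 1 Hz."""

    times: np.ndarray
    crm_gt: np.ndarray


@dataclass
class PerformanceErrorSeries:
    """Signed relative errors on ticks with a positive reference."""

    times: np.ndarray
    pe: np.ndarray


@dataclass
class SubjectReport:
    """Per-subject evaluation summary."""

    subject_id: str
    mdpe: float                      # percent, signed
    mdape: float                     # percent
    median_cv: float                 # percent
    confusion: np.ndarray            # 3x3 row-normalized (NaN rows lack support)
    confusion_counts: np.ndarray     # 3x3 raw tick counts
    per_zone_metrics: pd.DataFrame   # accuracy/precision/recall/specificity per zone
    detection_events: list[DetectionEvent] = field(default_factory=list)


# -- reference and errors ---------------------------------------------------

def ground_truth(protocol: LBNPProtocol, times: np.ndarray,
                 interpolate: bool = False) -> GroundTruthSeries:
    """Reserve reference on the protocol staircase (optionally interpolated)."""
    t = np.asarray(times, dtype=float)
    return GroundTruthSeries(times=t, crm_gt=reserve_fraction(protocol, t, interpolate))


def _align(pred: CRMSeries, gt: GroundTruthSeries, use: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if use not in ("raw", "smoothed"):
        raise EvaluationError(f"use must be 'raw' or 'smoothed', got {use!r}")
    values = pred.raw if use == "raw" else pred.smoothed
    common, ip, ig = np.intersect1d(np.round(pred.times, 6), np.round(gt.times, 6),
                                    return_indices=True)
    if common.size == 0:
        raise EvaluationError("prediction and ground truth share no time ticks")
    return common, values[ip], gt.crm_gt[ig]


def performance_error(pred: CRMSeries, gt: GroundTruthSeries,
                      use: str = "raw") -> PerformanceErrorSeries:
    """PE = (pred - gt) / gt on the common fraction scale.

    Ticks where the reference is 0 and ticks with missing predictions are
    dropped.
    """
    t, p, g = _align(pred, gt, use)
    keep = (g > 0) & np.isfinite(p)
    if not np.any(keep):
        raise EvaluationError("no ticks with positive reference and a prediction")
    pe = (p[keep] / 100.0 - g[keep]) / g[keep]
    return PerformanceErrorSeries(times=t[keep], pe=pe)


def mdpe_mdape(pe: PerformanceErrorSeries) -> tuple[float, float]:
    """Median and median-absolute performance error, in percent."""
    if len(pe.pe) == 0:
        raise EvaluationError("empty performance-error series")
    return float(np.median(pe.pe) * 100.0), float(np.median(np.abs(pe.pe)) * 100.0)


def rolling_cv(values: np.ndarray, window: int = 30, mean_floor: float = 1.0) -> float:
    """Median coefficient of variation (std/mean x 100) over trailing windows.

    Windows containing missing values or with mean below ``mean_floor``
    (percent-units; guards the division) are excluded.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    mean = s.rolling(window, min_periods=window).mean()
    sd = s.rolling(window, min_periods=window).std(ddof=1)
    cv = (sd / mean * 100.0).where(mean >= mean_floor)
    cv = cv.dropna()
    if cv.empty:
        raise EvaluationError("no valid windows for the rolling CV")
    return float(cv.median())


# -- zone agreement ---------------------------------------------------------

def zone_confusion(pred: CRMSeries, gt: GroundTruthSeries,
                   zones: ZoneConfig = ZoneConfig(), use: str = "raw",
                   ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """3x3 zone confusion (rows = reference zone) plus one-vs-rest metrics.

    Returns ``(row_normalized, counts, metrics)``; a reference zone with no
    ticks yields a NaN row and NaN metrics rather than zeros.
    """
    _, p, g = _align(pred, gt, use)
    keep = np.isfinite(p)
    pc = zone_codes(p[keep], zones)
    gc = zone_codes(100.0 * g[keep], zones)
    counts = np.zeros((3, 3))
    for gz, pz in zip(gc, pc):
        counts[gz, pz] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, counts / row_sums, np.nan)
    total = counts.sum()
    rows = []
    for z in range(3):
        tp = counts[z, z]
        fn = counts[z].sum() - tp
        fp = counts[:, z].sum() - tp
        tn = total - tp - fn - fp
        if counts[z].sum() == 0:
            rows.append({"zone": ZONE_LABELS[z], "accuracy": np.nan, "precision": np.nan,
                         "recall": np.nan, "specificity": np.nan})
            continue
        rows.append({
            "zone": ZONE_LABELS[z],
            "accuracy": (tp + tn) / total if total else np.nan,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
            "recall": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        })
    return norm, counts, pd.DataFrame(rows).set_index("zone")


# -- per-subject and cohort reports -----------------------------------------

def evaluate_subject(subject_id: str, pred: CRMSeries, protocol: LBNPProtocol,
                     zones: ZoneConfig = ZoneConfig(),
                     detection_events: list[DetectionEvent] | None = None,
                     interpolate_gt: bool = False) -> SubjectReport:
    """Assemble the full per-subject evaluation."""
    gt = ground_truth(protocol, pred.times, interpolate=interpolate_gt)
    mdpe, mdape = mdpe_mdape(performance_error(pred, gt, use="raw"))
    median_cv = rolling_cv(pred.smoothed)
    norm, counts, metrics = zone_confusion(pred, gt, zones, use="raw")
    return SubjectReport(subject_id=subject_id, mdpe=mdpe, mdape=mdape,
                         median_cv=median_cv, confusion=norm, confusion_counts=counts,
                         per_zone_metrics=metrics,
                         detection_events=detection_events or [])


def cohort_summary(reports: list[SubjectReport]) -> dict[str, pd.DataFrame]:
    """Aggregate subject reports: scalar metrics, mean confusion, detections.

    Returns a dict of tables: ``metrics`` (per-metric median and mean +- SD),
    ``confusion_mean`` (subject-averaged row-normalized matrix),
    ``zone_metrics`` (per-zone medians of the one-vs-rest metrics) and
    ``detections`` (per-method early-time mean +- SD and non-flag counts).
    """
    if not reports:
        raise EvaluationError("cohort summary needs at least one subject")
    scalars = pd.DataFrame({
        "subject_id": [r.subject_id for r in reports],
        "mdpe_pct": [r.mdpe for r in reports],
        "mdape_pct": [r.mdape for r in reports],
        "median_cv_pct": [r.median_cv for r in reports],
    }).set_index("subject_id")
    metrics = pd.DataFrame({
        "median": scalars.median(),
        "mean": scalars.mean(),
        "sd": scalars.std(ddof=1) if len(reports) > 1 else np.nan,
    })
    confusion_mean = pd.DataFrame(
        np.nanmean(np.stack([r.confusion for r in reports]), axis=0),
        index=[f"gt_{z}" for z in ZONE_LABELS],
        columns=[f"pred_{z}" for z in ZONE_LABELS])
    zone_metrics = (pd.concat([r.per_zone_metrics for r in reports])
                    .groupby(level=0, sort=False).median()
                    .reindex(list(ZONE_LABELS)))
    det_rows = []
    methods: dict[str, list[DetectionEvent]] = {}
    for r in reports:
        for e in r.detection_events:
            methods.setdefault(e.method, []).append(e)
    for method, events in methods.items():
        early = np.array([e.early_minutes for e in events])
        det_rows.append({
            "method": method,
            "n_subjects": len(events),
            "n_not_flagged": sum(not e.flagged for e in events),
            "early_min_mean": float(early.mean()),
            "early_min_sd": float(early.std(ddof=1)) if len(early) > 1 else np.nan,
            "early_min_median": float(np.median(early)),
        })
    detections = pd.DataFrame(det_rows).set_index("method") if det_rows else pd.DataFrame()
    return {"metrics": metrics, "confusion_mean": confusion_mean,
            "zone_metrics": zone_metrics, "detections": detections,
            "subjects": scalars}


# -- optional inferential statistics ----------------------------------------

def detection_time_stats(early_by_method: dict[str, np.ndarray]) -> pd.DataFrame:
    """Off-the-shelf comparison of detector early times across methods.

    Delegates to standard routines: Shapiro-Wilk normality per method, a
    Friedman test across methods, and repeated-measures ANOVA when all
    methods pass normality.  Returns one row per test with its statistic and
    p-value; nothing here is re-implemented.
    """
    from scipy import stats as sps

    rows = []
    normal = True
    for method, x in early_by_method.items():
        x = np.asarray(x, dtype=float)
        if len(x) >= 3 and np.ptp(x) > 0:
            w, p = sps.shapiro(x)
            normal &= p >= 0.05
            rows.append({"test": f"shapiro[{method}]", "statistic": w, "p_value": p})
    arrays = [np.asarray(v, float) for v in early_by_method.values()]
    if len(arrays) >= 3 and len({len(a) for a in arrays}) == 1:
        stat, p = sps.friedmanchisquare(*arrays)
        rows.append({"test": "friedman", "statistic": stat, "p_value": p})
        if normal:
            try:
                from statsmodels.stats.anova import AnovaRM
                long = pd.concat([
                    pd.DataFrame({"subject": np.arange(len(a)), "method": m, "early": a})
                    for m, a in early_by_method.items()])
                res = AnovaRM(long, "early", "subject", within=["method"]).fit()
                rows.append({"test": "rm_anova",
                             "statistic": float(res.anova_table["F Value"].iloc[0]),
                             "p_value": float(res.anova_table["Pr > F"].iloc[0])})
            except Exception:  # pragma: no cover - degenerate designs
                pass
    return pd.DataFrame(rows)
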