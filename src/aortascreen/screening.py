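"""Screening classification against the 30 mm threshold and cohort metrics.

An abdominal aorta with maximum diameter strictly greater than the threshold
(default 30 mm) is classified aneurysmal (AAA); AAA is the positive class of
the confusion matrix. Summary statistics follow the usual screening-report
structure: mean, sample SD, median, IQR, 5th/95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

AAA = "AAA"
CONTROL = "control"


@dataclass
class ScreeningConfig:
    threshold_mm: float = 30.0
    rounding: int = 0  # decimal places for reported percentages
    percentile_method: str = "linear"

    def __post_init__(self):
        if self.threshold_mm <= 0:
            raise ValidationError("threshold must be positive")


def classify(diameter_mm: float, cfg: ScreeningConfig | None = None) -> str:
    """AAA iff diameter strictly exceeds the threshold; ties are control."""
    cfg = cfg or ScreeningConfig()
    if diameter_mm < 0:
        raise ValidationError(f"negative diameter: {diameter_mm}")
    return AAA if diameter_mm > cfg.threshold_mm else CONTROL


def cohort_metrics(predicted: list[str], truth: list[str],
                   cfg: ScreeningConfig | None = None) -> dict:
    """Confusion counts and accuracy/sensitivity/specificity (percent).

    AAA is the positive class. Rates with zero denominators are reported as
    None (undefined), never as 0.
    """
    cfg = cfg or ScreeningConfig()
    if len(predicted) != len(truth):
        raise ValidationError(f"length mismatch: {len(predicted)} predictions, {len(truth)} truths")
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    tp = int(np.sum((pred == AAA) & (true == AAA)))
    fn = int(np.sum((pred == CONTROL) & (true == AAA)))
    tn = int(np.sum((pred == CONTROL) & (true == CONTROL)))
    fp = int(np.sum((pred == AAA) & (true == CONTROL)))
    total = tp + fp + tn + fn

    def rate(num, den):
        if den == 0:
            return None, None
        raw = 100.0 * num / den
        return raw, round(raw, cfg.rounding) if cfg.rounding > 0 else int(round(raw))

    acc_raw, acc = rate(tp + tn, total)
    sens_raw, sens = rate(tp, tp + fn)
    spec_raw, spec = rate(tn, tn + fp)
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn, "total": total,
        "accuracy_pct": acc, "sensitivity_pct": sens, "specificity_pct": spec,
        "accuracy_pct_raw": acc_raw, "sensitivity_pct_raw": sens_raw,
        "specificity_pct_raw": spec_raw,
    }


def summarize(values) -> dict:
    """Mean, sample SD (n-1), median, IQR (p75-p25), p5, p95.

    Percentiles use linear interpolation between order statistics.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("cannot summarize an empty list")
    p5, p25, p50, p75, p95 = np.percentile(v, [5, 25, 50, 75, 95], method="linear")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(p50),
        "IQR": float(p75 - p25),
        "p5": float(p5),
        "p95": float(p95),
    }


def error_stats(predicted, manual, true_class=None) -> dict:
    """Absolute-error summaries of automatic vs manual diameters.

    Per-case |predicted - manual| is summarized overall and, when
    ``true_class`` labels are given, stratified by class.
    """
    p = np.asarray(list(predicted), dtype=float)
    m = np.asarray(list(manual), dtype=float)
    if p.shape != m.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {m.shape}")
    err = np.abs(p - m)
    out = {"all": summarize(err)}
    if true_class is not None:
        tc = np.asarray(list(true_class))
        if tc.shape != p.shape:
            raise ValidationError("true_class length mismatch")
        for cls in (AAA, CONTROL):
            sel = tc == cls
            if sel.any():
                out[cls] = summarize(err[sel])
    return out


@dataclass
class CohortReport:
    table: pd.DataFrame  # per-case rows
    metrics: dict | None  # confusion counts + rates, None without truth
    diameter_stats: dict  # per class and overall
    error_summary: dict | None  # abs-error stats, None without manual diameters
    config: ScreeningConfig = field(default_factory=ScreeningConfig)
    n_failures: int = 0

    def to_json_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "diameter_stats": self.diameter_stats,
            "error_stats": self.error_summary,
            "threshold_mm": self.config.threshold_mm,
            "n_cases": int(len(self.table)),
            "n_failures": int(self.n_failures),
        }


def build_cohort_report(df: pd.DataFrame, cfg: ScreeningConfig | None = None,
                        n_failures: int = 0) -> CohortReport:
    """Assemble the cohort screening report from per-case measurements.

    ``df`` needs ``case_id`` and ``predicted_diameter_mm``; optional
    ``manual_diameter_mm`` enables the confusion matrix (true class from the
    same threshold applied to the manual measurement) and error statistics.
    """
    cfg = cfg or ScreeningConfig()
    df = df.copy()
    df["predicted_class"] = [classify(d, cfg) for d in df["predicted_diameter_mm"]]
    has_manual = "manual_diameter_mm" in df.columns and df["manual_diameter_mm"].notna().any()
    metrics = None
    error_summary = None
    if has_manual:
        valid = df["manual_diameter_mm"].notna()
        df.loc[valid, "true_class"] = [classify(d, cfg) for d in df.loc[valid, "manual_diameter_mm"]]
        df.loc[valid, "abs_error_mm"] = (df.loc[valid, "predicted_diameter_mm"]
                                         - df.loc[valid, "manual_diameter_mm"]).abs()
        sub = df[valid]
        metrics = cohort_metrics(list(sub["predicted_class"]), list(sub["true_class"]), cfg)
        error_summary = error_stats(sub["predicted_diameter_mm"], sub["manual_diameter_mm"],
                                    sub["true_class"])
    diameter_stats = {"all": summarize(df["predicted_diameter_mm"])}
    for cls in (AAA, CONTROL):
        sel = df["predicted_class"] == cls
        if sel.any():
            diameter_stats[cls] = summarize(df.loc[sel, "predicted_diameter_mm"])
    return CohortReport(table=df, metrics=metrics, diameter_stats=diameter_stats,
                        error_summary=error_summary, config=cfg, n_failures=n_failures)


def bland_altman_table(predicted, manual) -> pd.DataFrame:
    """Per-case (mean, difference) pairs for external Bland-Altman plotting."""
    p = np.asarray(list(predicted), dtype=float)
    m = np.asarray(list(manual), dtype=float)
    if p.shape != m.shape:
        raise ValidationError("length mismatch")
    return pd.DataFrame({"mean_mm": (p + m) / 2.0, "difference_mm": p - m})
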