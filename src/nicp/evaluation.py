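"""Agreement and diagnostic metrics for the nICP estimate.

Agreement between the non-invasive estimate and the invasive reference is
summarized the way method-comparison studies report it: Bland-Altman bias
and limits of agreement (bias ± Z·SD of the paired differences, Z = 1.96),
Pearson correlation, determination coefficient and RMSE. Diagnostic power
for intracranial hypertension (reference ICP >= 15 mmHg) is summarized by
the ROC curve, its AUC, and sensitivity/specificity both at the matched
15 mmHg cut-off on the estimate and at the Youden-optimal point. Differences
are always estimate minus reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .config import AnalysisConfig

__all__ = [
    "AgreementResult",
    "RocResult",
    "PatientRow",
    "PerPatientReport",
    "bland_altman",
    "agreement_stats",
    "evaluate_pooled",
    "roc_analysis",
    "per_patient_report",
]


@dataclass
class AgreementResult:
    """Bland-Altman and correlation summary of est vs ref (mmHg)."""

    bias_mmhg: float
    sd_mmhg: float
    loa_low_mmhg: float
    loa_high_mmhg: float
    r: float
    r_squared: float
    rmse_mmhg: float
    n: int
    p_value: float = float("nan")
    variance_explained: float = float("nan")  # regression-fit R2, auxiliary

    def to_dict(self) -> dict[str, float]:
        return {
            "bias_mmhg": self.bias_mmhg,
            "sd_mmhg": self.sd_mmhg,
            "loa_low_mmhg": self.loa_low_mmhg,
            "loa_high_mmhg": self.loa_high_mmhg,
            "r": self.r,
            "r_squared": self.r_squared,
            "rmse_mmhg": self.rmse_mmhg,
            "n": self.n,
            "p_value": self.p_value,
            "variance_explained": self.variance_explained,
        }


@dataclass
class RocResult:
    """ROC summary for hypertension detection at a given reference threshold."""

    auc: float
    sensitivity_pct: float
    specificity_pct: float
    operating_threshold_mmhg: float
    youden_threshold_mmhg: float
    youden_sensitivity_pct: float
    youden_specificity_pct: float
    curve: list[tuple[float, float]] = field(default_factory=list)  # (fpr, tpr)

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "operating_threshold_mmhg": self.operating_threshold_mmhg,
            "youden_threshold_mmhg": self.youden_threshold_mmhg,
            "youden_sensitivity_pct": self.youden_sensitivity_pct,
            "youden_specificity_pct": self.youden_specificity_pct,
        }
        return d


def _as_arrays(est, ref) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be 1-D sequences of equal length")
    return est, ref


def bland_altman(est, ref, z: float = 1.96) -> tuple[float, float, float, float]:
    """Bias, SD of differences (n-1), and limits of agreement.

    Differences are ``est - ref``; LoA = bias ± z·SD.
    """
    est, ref = _as_arrays(est, ref)
    if est.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = est - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - z * sd, bias + z * sd


def agreement_stats(est, ref) -> tuple[float, float, float]:
    """Pearson r, its square, and RMSE of est against ref."""
    est, ref = _as_arrays(est, ref)
    if est.size < 3:
        raise ValueError("agreement stats need at least 3 pairs")
    if np.ptp(ref) == 0:
        raise ValueError("zero-variance reference; correlation undefined")
    r = float(stats.pearsonr(est, ref).statistic)
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    return r, r * r, rmse


def evaluate_pooled(est, ref, cfg: AnalysisConfig) -> AgreementResult:
    """Full agreement summary: Bland-Altman + correlation + RMSE."""
    est, ref = _as_arrays(est, ref)
    bias, sd, lo, hi = bland_altman(est, ref, cfg.loa_z)
    r, r2, rmse = agreement_stats(est, ref)
    p = float(stats.pearsonr(est, ref).pvalue)
    ss_res = float(np.sum((ref - est) ** 2))
    ss_tot = float(np.sum((ref - np.mean(ref)) ** 2))
    return AgreementResult(
        bias_mmhg=bias,
        sd_mmhg=sd,
        loa_low_mmhg=lo,
        loa_high_mmhg=hi,
        r=r,
        r_squared=r2,
        rmse_mmhg=rmse,
        n=int(est.size),
        p_value=p,
        variance_explained=1.0 - ss_res / ss_tot,
    )


def roc_analysis(est, ref, threshold_mmhg: float, cfg: AnalysisConfig | None = None) -> RocResult:
    """ROC of the continuous estimate against ``ref >= threshold`` labels.

    The curve is swept over all distinct estimate values; AUC by trapezoid.
    The reported operating point applies the matched threshold to the
    estimate (``est >= threshold_mmhg``); the Youden-optimal point (max
    TPR - FPR) is recorded alongside.
    """
    est, ref = _as_arrays(est, ref)
    labels = ref >= threshold_mmhg
    pos, neg = int(labels.sum()), int((~labels).sum())
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present in the reference")
    fpr, tpr, thr = _sk_roc_curve(labels, est)
    auc = float(np.trapezoid(tpr, fpr))
    pred = est >= threshold_mmhg
    sens = 100.0 * float(np.sum(pred & labels)) / pos
    spec = 100.0 * float(np.sum(~pred & ~labels)) / neg
    j = int(np.argmax(tpr - fpr))
    return RocResult(
        auc=auc,
        sensitivity_pct=sens,
        specificity_pct=spec,
        operating_threshold_mmhg=float(threshold_mmhg),
        youden_threshold_mmhg=float(thr[j]),
        youden_sensitivity_pct=100.0 * float(tpr[j]),
        youden_specificity_pct=100.0 * float(1.0 - fpr[j]),
        curve=list(zip(fpr.tolist(), tpr.tolist())),
    )


@dataclass
class PatientRow:
    patient_id: str
    n: int
    included: bool
    agreement: AgreementResult | None
    roc: RocResult | None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "n": self.n,
            "included": self.included,
            "agreement": self.agreement.to_dict() if self.agreement else None,
            "roc": self.roc.to_dict() if self.roc else None,
        }


@dataclass
class PerPatientReport:
    """Per-patient metric table plus mean ± SD and 95% CI summaries."""

    rows: list[PatientRow]
    summary: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {"rows": [r.to_dict() for r in self.rows], "summary": self.summary}


_SUMMARY_METRICS = (
    ("bias_mmhg", lambda row: row.agreement.bias_mmhg if row.agreement else None),
    ("loa_low_mmhg", lambda row: row.agreement.loa_low_mmhg if row.agreement else None),
    ("loa_high_mmhg", lambda row: row.agreement.loa_high_mmhg if row.agreement else None),
    ("rmse_mmhg", lambda row: row.agreement.rmse_mmhg if row.agreement else None),
    ("r", lambda row: row.agreement.r if row.agreement else None),
    ("auc", lambda row: row.roc.auc if row.roc else None),
    ("sensitivity_pct", lambda row: row.roc.sensitivity_pct if row.roc else None),
    ("specificity_pct", lambda row: row.roc.specificity_pct if row.roc else None),
)

MIN_PATIENT_OBSERVATIONS = 100  # per-patient summary requires > 100 windows


def per_patient_report(
    est: np.ndarray, ref: np.ndarray, patient_ids: np.ndarray, cfg: AnalysisConfig
) -> PerPatientReport:
    """Evaluate each patient's test observations individually.

    Patients with 100 or fewer observations are excluded from the summary
    (rule: strictly more than 100). Metrics undefined for a patient
    (constant reference -> no r; single-class reference -> no ROC) are
    computed as None and excluded from that metric's summary only.
    """
    est = np.asarray(est, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    patient_ids = np.asarray(patient_ids)
    rows: list[PatientRow] = []
    for pid in sorted(set(patient_ids.tolist())):
        m = patient_ids == pid
        e, r_ = est[m], ref[m]
        n = int(m.sum())
        agreement: AgreementResult | None = None
        roc: RocResult | None = None
        if n >= 3 and np.ptp(r_) > 0:
            agreement = evaluate_pooled(e, r_, cfg)
        try:
            roc = roc_analysis(e, r_, cfg.hypertension_threshold_mmhg, cfg)
        except ValueError:
            roc = None
        rows.append(
            PatientRow(
                patient_id=str(pid),
                n=n,
                included=n > MIN_PATIENT_OBSERVATIONS,
                agreement=agreement,
                roc=roc,
            )
        )

    summary: dict[str, dict[str, float]] = {}
    included = [row for row in rows if row.included]
    for name, getter in _SUMMARY_METRICS:
        vals = [getter(row) for row in included]
        vals = np.array([v for v in vals if v is not None], dtype=np.float64)
        if vals.size == 0:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        half = 1.96 * sd / np.sqrt(vals.size)
        summary[name] = {
            "mean": mean,
            "sd": sd,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "n_patients": int(vals.size),
        }
    return PerPatientReport(rows=rows, summary=summary)
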