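"""Volumes, extent of resection, GTR classification and cohort statistics.

The clinical quantities of interest:

* tumor volume — foreground voxel count times voxel volume, mm^3;
* extent of resection (EOR) — 100 * (pre - post) / pre percent, not
  clamped (a postoperative volume larger than the preoperative one yields
  a negative EOR rather than being censored);
* gross total resection (GTR) — EOR exactly 100%, i.e. zero residual
  volume;
* GTR detection quality — a 2x2 confusion matrix of predicted vs true GTR
  with accuracy / sensitivity / specificity / PPV / NPV, where GTR present
  is the positive class (sensitivity = GTR-detection rate);
* volume agreement — Pearson product-moment correlation, and per-patient
  absolute EOR differences summarized as mean ± SD and median (IQR).

Rates are kept unrounded internally; rounding to two decimals happens only
when reports are written.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import summarize


@dataclass(frozen=True)
class ResectionReport:
    """Volumetric outcome of one patient."""

    patient_id: str
    preop_volume_mm3: float
    postop_volume_mm3: float

    def __post_init__(self) -> None:
        if self.preop_volume_mm3 <= 0:
            raise ValueError(
                f"{self.patient_id}: preoperative volume must be positive "
                f"(got {self.preop_volume_mm3}); EOR is undefined otherwise"
            )
        if self.postop_volume_mm3 < 0:
            raise ValueError(f"{self.patient_id}: negative postoperative volume")

    @property
    def eor_percent(self) -> float:
        return extent_of_resection(self.preop_volume_mm3, self.postop_volume_mm3)

    @property
    def gtr(self) -> bool:
        return classify_gtr(self)


@dataclass(frozen=True)
class ConfusionReport:
    """2x2 confusion counts and derived rates (percent, NaN on 0/0)."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @staticmethod
    def _rate(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    @property
    def accuracy(self) -> float:
        return self._rate(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._rate(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
        }


def mask_volume_mm3(mask) -> float:
    """Foreground voxel count x voxel volume (product of spacings), mm^3."""
    if isinstance(mask, np.ndarray):
        data, spacing = mask, np.ones(3)
    else:
        data = np.asarray(mask.data)
        spacing = mask.spacing if hasattr(mask, "spacing") else np.ones(3)
    return float(data.astype(bool).sum()) * float(np.prod(spacing))


def extent_of_resection(pre_mm3: float, post_mm3: float) -> float:
    """EOR percent, 100 * (pre - post) / pre; negative if post > pre."""
    if pre_mm3 <= 0:
        raise ValueError(f"EOR undefined for non-positive preoperative volume {pre_mm3}")
    return 100.0 * (pre_mm3 - post_mm3) / pre_mm3


def classify_gtr(report: ResectionReport) -> bool:
    """Gross total resection: EOR of exactly 100% (zero residual volume)."""
    return report.postop_volume_mm3 == 0.0


def confusion_stats(
    predicted_gtr: Sequence[bool], true_gtr: Sequence[bool]
) -> ConfusionReport:
    """Confusion counts with GTR-present as the positive class."""
    pred = np.asarray(predicted_gtr, dtype=bool)
    true = np.asarray(true_gtr, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return ConfusionReport(
        tp=int(np.sum(pred & true)),
        fn=int(np.sum(~pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN (with a warning) if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need equal-length 1D sequences, got {x.shape} / {y.shape}")
    if x.size < 2:
        raise ValueError("correlation needs at least two observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        warnings.warn("pearson_r: zero variance in an input; returning NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def eor_error_summary(
    auto: Sequence[ResectionReport], manual: Sequence[ResectionReport]
) -> dict:
    """Per-patient |EOR_auto - EOR_manual| with mean ± SD and median (IQR)."""
    auto_by_id = {r.patient_id: r for r in auto}
    manual_by_id = {r.patient_id: r for r in manual}
    if set(auto_by_id) != set(manual_by_id):
        missing = set(auto_by_id) ^ set(manual_by_id)
        raise ValueError(f"unmatched patient ids: {sorted(missing)[:5]}")
    ids = sorted(auto_by_id)
    diffs = [abs(auto_by_id[p].eor_percent - manual_by_id[p].eor_percent) for p in ids]
    out = summarize(diffs)
    out["per_patient"] = dict(zip(ids, diffs))
    return out
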