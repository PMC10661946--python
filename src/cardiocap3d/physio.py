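"""Cardiac physiology formulas and correlation reporting.

Echo and ECG summary formulas, developmental-stage differentials, and the
Pearson correlation report used to relate pruning abundance to network
morphometry across volumes of interest.

Unit note: the rate-corrected interval formulas ``QRSc = QRS +
0.0125·(1−RR)`` and ``QTc = QT + 0.0154·(1−RR)`` only make dimensional
sense with RR in seconds (neonatal mouse RR ≈ 0.1–0.2 s, so 1−RR stays
positive); this module takes all ECG durations in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EchoRecord",
    "EcgRecord",
    "CorrelationReport",
    "lv_strain",
    "qrs_corrected",
    "qt_corrected",
    "stage_differential",
    "pearson_report",
]

_QRS_RATE_COEF = 0.0125
_QT_RATE_COEF = 0.0154


@dataclass
class EchoRecord:
    """Left-ventricular wall thickness pair (mm) at one developmental stage."""

    lvw_thickness_systole: float
    lvw_thickness_diastole: float
    stage: str = ""

    def __post_init__(self) -> None:
        if self.lvw_thickness_systole <= 0 or self.lvw_thickness_diastole <= 0:
            raise ValueError("wall thicknesses must be positive")


@dataclass
class EcgRecord:
    """ECG interval durations in seconds."""

    qrs_s: float
    qt_s: float
    rr_s: float

    def __post_init__(self) -> None:
        if min(self.qrs_s, self.qt_s, self.rr_s) <= 0:
            raise ValueError("ECG intervals must be positive")


@dataclass
class CorrelationReport:
    x_label: str
    y_label: str
    r: float
    p_two_sided: float
    n: int


def lv_strain(record: EchoRecord) -> float:
    """LV wall strain %: 100 × (systolic − diastolic) / systolic thickness.

    Negative when the wall is thicker in diastole; returned unclamped.
    """
    sys_, dia = record.lvw_thickness_systole, record.lvw_thickness_diastole
    return 100.0 * (sys_ - dia) / sys_


def qrs_corrected(record: EcgRecord) -> float:
    """Heart-rate-corrected QRS duration (s)."""
    return record.qrs_s + _QRS_RATE_COEF * (1.0 - record.rr_s)


def qt_corrected(record: EcgRecord) -> float:
    """Heart-rate-corrected QT interval (s)."""
    return record.qt_s + _QT_RATE_COEF * (1.0 - record.rr_s)


def stage_differential(value_p1: float, value_p7: float, mode: str = "absolute") -> float:
    """Differential between stages: Δ = P7 − P1, or %Δ = 100·(P7−P1)/P1."""
    if mode == "absolute":
        return value_p7 - value_p1
    if mode == "percent":
        if value_p1 == 0:
            raise ValueError("percent differential undefined for zero baseline")
        return 100.0 * (value_p7 - value_p1) / value_p1
    raise ValueError(f"unknown mode {mode!r}; use 'absolute' or 'percent'")


def pearson_report(
    x, y, x_label: str = "x", y_label: str = "y"
) -> CorrelationReport:
    """Pearson r with a two-sided p-value (t transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationReport(x_label, y_label, float(res.statistic), float(res.pvalue), n)
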