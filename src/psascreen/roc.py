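"""Empirical ROC curves of PSA for predicting a malignant biopsy.

Curves are empirical step functions with grouped tie handling (one vertex
per distinct score, ties contribute diagonal segments) and endpoints
(0, 0) and (1, 1); the AUC is the trapezoidal integral of the stored
points, which equals the Mann-Whitney probability that a random cancer
case outranks a random benign case (ties counted half). No smoothing or
parametric fit is applied.

The main stratification of interest is by percent free PSA: curves for the
fPSA <= t vs fPSA > t subgroups at t = 18% or 21%, per age group or pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import GROUP_LABELS, PatientRecord, assign_age_group

__all__ = ["RocCurve", "StratifiedRoc", "roc_curve", "stratified_roc", "roc_by_group"]


@dataclass(frozen=True)
class RocCurve:
    """Ordered (FPR, TPR) vertices including (0,0) and (1,1), and their AUC."""

    points: np.ndarray  # shape (k, 2), columns (fpr, tpr)
    auc: float
    label: str = ""

    def __post_init__(self) -> None:
        pts = self.points
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an array of (fpr, tpr) pairs")
        if np.any(np.diff(pts, axis=0) < -1e-12):
            raise ValueError("ROC points must be non-decreasing in both coordinates")


def _scores(records: Sequence[PatientRecord], score) -> np.ndarray:
    if callable(score):
        return np.array([float(score(r)) for r in records])
    return np.array([float(getattr(r, score)) for r in records])


def roc_curve(
    records: Sequence[PatientRecord],
    score: str | Callable[[PatientRecord], float] = "psa",
    label: str = "",
) -> RocCurve:
    """Empirical ROC of ``score`` (default PSA) against the biopsy outcome.

    Decisions are score >= threshold with thresholds swept over the
    distinct observed scores. Requires at least one malignant and one
    benign record.
    """
    y = np.array([r.malignant for r in records], dtype=int)
    if y.size == 0 or y.all() or not y.any():
        missing = "malignant" if not y.any() else "benign"
        raise ValueError(f"ROC needs both classes; no {missing} records present")
    s = _scores(records, score)
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=pts, auc=auc, label=label)


@dataclass(frozen=True)
class StratifiedRoc:
    """ROC curves of the two fPSA strata; a degenerate stratum is ``None``."""

    split: float  # percent free PSA
    low: RocCurve | None  # records with fPSA% <= split
    high: RocCurve | None  # records with fPSA% > split
    n_low: int
    n_high: int


def stratified_roc(
    records: Sequence[PatientRecord],
    fpsa_split: float,
    score: str | Callable[[PatientRecord], float] = "psa",
) -> StratifiedRoc:
    """ROC curves of PSA within the fPSA <= split and fPSA > split strata.

    A stratum that is empty or single-class yields ``None`` for that curve
    with a warning rather than an error.
    """
    low = [r for r in records if r.fpsa_pct <= fpsa_split]
    high = [r for r in records if r.fpsa_pct > fpsa_split]
    curves: list[RocCurve | None] = []
    for sub, name in [(low, f"fPSA<={fpsa_split:g}%"), (high, f"fPSA>{fpsa_split:g}%")]:
        try:
            curves.append(roc_curve(sub, score, label=name))
        except ValueError as exc:
            warnings.warn(f"stratum {name}: {exc}", RuntimeWarning, stacklevel=2)
            curves.append(None)
    return StratifiedRoc(split=fpsa_split, low=curves[0], high=curves[1],
                         n_low=len(low), n_high=len(high))


def roc_by_group(
    records: Sequence[PatientRecord],
    fpsa_split: float,
    include_pooled: bool = True,
) -> dict[str, StratifiedRoc]:
    """Per-age-group stratified ROC curves, optionally plus a pooled entry."""
    out: dict[str, StratifiedRoc] = {}
    for lab in GROUP_LABELS:
        sub = [r for r in records if assign_age_group(r.age).label == lab]
        if sub:
            out[lab] = stratified_roc(sub, fpsa_split)
    if include_pooled:
        out["total"] = stratified_roc(list(records), fpsa_split)
    return out
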