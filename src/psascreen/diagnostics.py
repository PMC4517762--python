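"""Diagnostic performance of a biopsy rule against the biopsy outcome.

Confusion matrices, sensitivity/specificity/PPV/NPV with exact
(Clopper-Pearson) confidence intervals, a bridge that reconstructs
predictive values from rounded published rates, and tumor-recognition
tables stratified by Gleason category and pathological stage.

Metrics with a zero denominator are reported as ``None`` (undefined), never
silently as zero, so that downstream grid-search comparisons are not
corrupted by degenerate scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._util import pct, round_half_away
from .cohort import (
    GROUP_LABELS,
    BiopsyGS,
    PathStage,
    PatientRecord,
    assign_age_group,
)
from .rules import BiopsyRule, indicates_biopsy

__all__ = [
    "ConfusionMatrix",
    "Estimate",
    "DiagnosticSummary",
    "confusion",
    "clopper_pearson",
    "metrics",
    "metrics_by_group",
    "predictive_values_from_rates",
    "recognition_table",
    "RECOGNITION_CATEGORIES",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of rule decision vs biopsy truth (malignant = positive)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_malignant(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class Estimate:
    """A proportion with its exact two-sided confidence interval."""

    point: float
    ci_low: float
    ci_high: float

    def as_pct(self) -> tuple[float, float, float]:
        return pct(self.point), pct(self.ci_low), pct(self.ci_high)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV; ``None`` marks an undefined metric."""

    sensitivity: Estimate | None
    specificity: Estimate | None
    ppv: Estimate | None
    npv: Estimate | None


def confusion(records: Sequence[PatientRecord], rule: BiopsyRule) -> ConfusionMatrix:
    """Cross-tabulate the rule's biopsy indication against the outcome."""
    if not records:
        raise ValueError("cannot build a confusion matrix from an empty cohort")
    tp = fp = tn = fn = 0
    for rec in records:
        flagged = indicates_biopsy(rule, rec)
        if rec.malignant:
            tp += flagged
            fn += not flagged
        else:
            fp += flagged
            tn += not flagged
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact equal-tailed binomial confidence interval (beta quantiles).

    The lower bound is 0 when ``successes`` is 0 and the upper bound is 1
    when ``successes`` equals ``trials``.
    """
    if trials < 1 or not (0 <= successes <= trials):
        raise ValueError(f"need 0 <= successes <= trials, trials >= 1; got {successes}/{trials}")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def _estimate(successes: int, trials: int, level: float) -> Estimate | None:
    if trials == 0:
        return None
    lo, hi = clopper_pearson(successes, trials, level)
    return Estimate(point=successes / trials, ci_low=lo, ci_high=hi)


def metrics(cm: ConfusionMatrix, ci_level: float = 0.95) -> DiagnosticSummary:
    """Point estimates and exact CIs for the four standard metrics.

    Any metric whose denominator is zero comes back as ``None``.
    """
    return DiagnosticSummary(
        sensitivity=_estimate(cm.tp, cm.tp + cm.fn, ci_level),
        specificity=_estimate(cm.tn, cm.tn + cm.fp, ci_level),
        ppv=_estimate(cm.tp, cm.tp + cm.fp, ci_level),
        npv=_estimate(cm.tn, cm.tn + cm.fn, ci_level),
    )


def metrics_by_group(
    records: Sequence[PatientRecord], rule: BiopsyRule, ci_level: float = 0.95
) -> dict[str, DiagnosticSummary]:
    """One :class:`DiagnosticSummary` per age group plus ``"total"``."""
    out: dict[str, DiagnosticSummary] = {}
    for label in GROUP_LABELS:
        sub = [r for r in records if assign_age_group(r.age).label == label]
        if sub:
            out[label] = metrics(confusion(sub, rule), ci_level)
    out["total"] = metrics(confusion(list(records), rule), ci_level)
    return out


def predictive_values_from_rates(
    sens_pct: float, spec_pct: float, n_malignant: int, n_benign: int
) -> tuple[float, float]:
    """Reconstruct PPV/NPV (percent, 1 decimal) from rounded published rates.

    Published tables often print sensitivity and specificity rounded to one
    decimal alongside predictive values. Given the stratum sizes, the
    underlying integer counts are recovered as ``tp = round(sens *
    n_malignant)`` and ``tn = round(spec * n_benign)`` (ties away from
    zero), the complements fill in fn/fp, and PPV/NPV follow from the
    counts. This is the documented bridge from printed rates to printed
    predictive values.
    """
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("rates must be percentages in [0, 100]")
    if n_malignant < 1 or n_benign < 1:
        raise ValueError("stratum sizes must be >= 1")
    tp = int(round_half_away(sens_pct / 100.0 * n_malignant, 0))
    tn = int(round_half_away(spec_pct / 100.0 * n_benign, 0))
    fn = n_malignant - tp
    fp = n_benign - tn
    if min(tp, tn, fn, fp) < 0:
        raise ValueError("reconstruction yielded negative counts")
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    summary = metrics(cm)
    if summary.ppv is None or summary.npv is None:
        raise ValueError("reconstructed counts leave PPV or NPV undefined")
    return pct(summary.ppv.point), pct(summary.npv.point)


#: Categories of the tumor-recognition table: biopsy Gleason strata plus
#: pathological stage of the prostatectomy specimen.
RECOGNITION_CATEGORIES = (
    BiopsyGS.GS6.value,
    BiopsyGS.GS7_34.value,
    BiopsyGS.GS7_43.value,
    BiopsyGS.GS8.value,
    BiopsyGS.GS9.value,
    BiopsyGS.GS10.value,
    PathStage.ORGAN_CONFINED.value,
    PathStage.EXTRAPROSTATIC.value,
)


def recognition_table(records: Sequence[PatientRecord], rule: BiopsyRule) -> pd.DataFrame:
    """Fraction of tumors in each category that the rule flags for biopsy.

    Rows are the Gleason/stage categories, columns the age groups plus
    ``"total"``; cells hold the flagged fraction in [0, 1] or NaN when the
    category is empty in that group ("no data"). Denominators exclude
    records with a missing category.
    """
    cols = list(GROUP_LABELS) + ["total"]
    table = pd.DataFrame(index=list(RECOGNITION_CATEGORIES), columns=cols, dtype=float)

    def tally(sub: Sequence[PatientRecord], col: str) -> None:
        for cat in RECOGNITION_CATEGORIES:
            members = [
                r
                for r in sub
                if (r.biopsy_gs is not None and r.biopsy_gs.value == cat)
                or (r.rp is not None and r.rp.stage is not None and r.rp.stage.value == cat)
            ]
            if not members:
                table.loc[cat, col] = np.nan
                continue
            flagged = sum(indicates_biopsy(rule, r) for r in members)
            table.loc[cat, col] = flagged / len(members)

    for label in GROUP_LABELS:
        tally([r for r in records if assign_age_group(r.age).label == label], label)
    tally(list(records), "total")
    return table
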