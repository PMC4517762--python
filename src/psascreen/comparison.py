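"""Old-vs-new biopsy rule comparison: reduction, NNS, Fisher's exact test.

Both rules are applied to the same cohort; the comparison reports, per age
group and pooled, the flagged (biopsy) fractions under each rule, their
difference with a 95% CI, the number needed to screen to avoid one biopsy
(the reciprocal of the difference, with a CI obtained by reciprocating and
swapping the difference CI endpoints), and a two-sided Fisher exact
p-value on the 2x2 table (flagged, unflagged) x (old rule, new rule).

The default difference CI is the unpaired two-proportion Wald interval,
treating the two rule applications as independent margins even though
they are paired on the same patients — this mirrors the conventional
presentation in the screening literature this package re-implements. A
paired (discordant-pair) interval is available via ``ci_method="paired"``
and is the statistically preferable choice when both decisions come from
the same men; it is narrower because the two decisions are highly
positively correlated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import norm
from statsmodels.stats.proportion import confint_proportions_2indep

from ._util import round_half_away
from .cohort import GROUP_LABELS, PatientRecord, assign_age_group
from .rules import BiopsyRule, flags

__all__ = [
    "ReductionRow",
    "ComparisonResult",
    "biopsy_reduction",
    "nns",
    "fisher_exact_2x2",
    "compare_rules",
]


@dataclass(frozen=True)
class ReductionRow:
    """Flagged fractions and their difference (old minus new) in one stratum."""

    group_label: str
    n: int
    n_flagged_old: int
    n_flagged_new: int
    difference: float  # frac_old - frac_new
    diff_ci: tuple[float, float]

    @property
    def frac_old(self) -> float:
        return self.n_flagged_old / self.n

    @property
    def frac_new(self) -> float:
        return self.n_flagged_new / self.n


def _diff_ci_wald(k_old: int, k_new: int, n: int, level: float) -> tuple[float, float]:
    lo, hi = confint_proportions_2indep(
        k_old, n, k_new, n, method="wald", compare="diff", alpha=1 - level, correction=False
    )
    return float(lo), float(hi)


def _diff_ci_paired(
    flagged_old: np.ndarray, flagged_new: np.ndarray, level: float
) -> tuple[float, float]:
    """Wald interval for the paired difference via the discordant proportions."""
    n = flagged_old.size
    p10 = float(np.mean(flagged_old & ~flagged_new))
    p01 = float(np.mean(~flagged_old & flagged_new))
    d = p10 - p01
    se = math.sqrt(max(p10 + p01 - d * d, 0.0) / n)
    z = norm.ppf(0.5 + level / 2)
    return d - z * se, d + z * se


def biopsy_reduction(
    records: Sequence[PatientRecord],
    rule_old: BiopsyRule,
    rule_new: BiopsyRule,
    ci_level: float = 0.95,
    ci_method: str = "wald",
) -> list[ReductionRow]:
    """Per-group and pooled biopsy-fraction difference with CI.

    ``ci_method`` is ``"wald"`` (unpaired two-proportion, the default) or
    ``"paired"`` (discordant-pair interval). Empty age groups are omitted
    with a warning.
    """
    if ci_method not in ("wald", "paired"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    f_old = flags(rule_old, records)
    f_new = flags(rule_new, records)
    group_of = np.array([assign_age_group(r.age).label for r in records])

    rows: list[ReductionRow] = []
    for label in list(GROUP_LABELS) + ["total"]:
        mask = np.ones(len(records), dtype=bool) if label == "total" else group_of == label
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"age group {label}: no records, row omitted", RuntimeWarning,
                          stacklevel=2)
            continue
        k_old = int(f_old[mask].sum())
        k_new = int(f_new[mask].sum())
        if ci_method == "wald":
            ci = _diff_ci_wald(k_old, k_new, n, ci_level)
        else:
            ci = _diff_ci_paired(f_old[mask], f_new[mask], ci_level)
        rows.append(
            ReductionRow(
                group_label=label,
                n=n,
                n_flagged_old=k_old,
                n_flagged_new=k_new,
                difference=(k_old - k_new) / n,
                diff_ci=ci,
            )
        )
    return rows


def nns(
    difference: float, ci: tuple[float, float] | None = None
) -> tuple[float | None, tuple[float, float] | None]:
    """Number needed to screen to avoid one biopsy: 1/difference, 1 decimal.

    The CI reciprocates the difference CI with endpoints swapped; a lower
    difference bound <= 0 gives an infinite upper NNS bound. A difference
    <= 0 has no defined NNS and returns ``(None, None)``.
    """
    if difference <= 0:
        return None, None
    value = round_half_away(1.0 / difference, 1)
    if ci is None:
        return value, None
    lo, hi = ci
    nns_lo = round_half_away(1.0 / hi, 1) if hi > 0 else math.inf
    nns_hi = round_half_away(1.0 / lo, 1) if lo > 0 else math.inf
    return value, (nns_lo, nns_hi)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Point-probability definition: the sum of the probabilities of all
    tables with the same margins whose probability does not exceed the
    observed one. The degenerate all-zero (or empty-margin) table returns
    1.0 with a warning.
    """
    cells = (a, b, c, d)
    if any(v < 0 or v != int(v) for v in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        warnings.warn("degenerate 2x2 table (an empty margin): p = 1.0",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    _, p = _scipy_fisher([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


@dataclass(frozen=True)
class ComparisonResult:
    """One comparison row: reduction, NNS and Fisher p for one stratum."""

    group_label: str
    n: int
    frac_old: float
    frac_new: float
    difference: float
    diff_ci: tuple[float, float]
    nns: float | None
    nns_ci: tuple[float, float] | None
    fisher_p: float


def compare_rules(
    records: Sequence[PatientRecord],
    rule_old: BiopsyRule,
    rule_new: BiopsyRule,
    ci_level: float = 0.95,
    ci_method: str = "wald",
) -> list[ComparisonResult]:
    """Full comparison rows per age group and pooled.

    The Fisher test contrasts the flagged/unflagged split under the two
    rules as two independent margins of the same cohort.
    """
    rows = biopsy_reduction(records, rule_old, rule_new, ci_level, ci_method)
    out: list[ComparisonResult] = []
    for row in rows:
        value, value_ci = nns(row.difference, row.diff_ci)
        p = fisher_exact_2x2(
            row.n_flagged_old,
            row.n - row.n_flagged_old,
            row.n_flagged_new,
            row.n - row.n_flagged_new,
        )
        out.append(
            ComparisonResult(
                group_label=row.group_label,
                n=row.n,
                frac_old=row.frac_old,
                frac_new=row.frac_new,
                difference=row.difference,
                diff_ci=row.diff_ci,
                nns=value,
                nns_ci=value_ci,
                fisher_p=p,
            )
        )
    return out
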