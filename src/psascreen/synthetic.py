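"""Seeded synthetic screening cohorts emulating the source population.

Because the patient-level biobank data behind the published summary tables
are unavailable, this module generates cohorts whose per-age-group
structure — size, malignancy prevalence, PSA and fPSA% distributions,
biopsy Gleason mix, prostatectomy pathology mix — matches those published
summaries, so that every downstream stage (diagnostics, ROC, grid search,
rule comparison) is exercisable and testable.

Model
-----
Within each age group, biopsy outcome is Bernoulli with the published
prevalence. Conditional on outcome:

* PSA is log-normal. The published tables pool benign and malignant cases,
  so the two status-specific location parameters and a shared log-scale are
  calibrated such that the benign/malignant *mixture* reproduces the
  published pooled quartiles (q25, median, q75), with an additional soft
  target on the malignant exceedance of the historical low-fPSA cut-off
  (P[PSA_mal >= cut-off] ~ 0.97) so that historical-rule sensitivities land
  in the published 93-97% range. Sharing the log-scale within a group makes
  the malignant distribution stochastically dominate the benign one, which
  spec validation checks. Medians/IQRs, not means, are the targets: the
  published means (e.g. 28.6 ng/mL with SD 225 in the oldest group) are
  outlier-driven and unreachable for a two-parameter log-normal.
* fPSA%/100 is logit-normal, calibrated the same way against the pooled
  fPSA quartiles with a soft separation target P[fPSA_mal <= 18%] ~ 0.90
  (cancers have lower free-PSA fractions; the direction is implied by the
  fPSA < 18% biopsy criterion, the magnitude is a documented choice, not a
  claim about the unpublished truth).
* Biopsy Gleason categories are drawn for malignant records only, from the
  published per-group mix; the published "GS >= 8" mass is split 70/25/5
  over GS 8/9/10 in the three older groups and left entirely on GS 8 in
  the youngest (whose published recognition tables report no GS 9/10
  cases). A small published fraction of cancers has a missing category.
* Prostate volume is log-normal matched to the pooled quartiles (not
  status-specific; the package carries the column without modelling it).
* A ``rp_fraction`` share of malignant records (default 758/1218) carries
  prostatectomy pathology drawn from the published per-group category
  frequencies.

One named generator stream per age group hangs off the single global seed,
so adding or reordering groups never reshuffles the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit
from scipy.stats import norm

from . import reference as ref
from .cohort import (
    AGE_GROUPS,
    GROUP_LABELS,
    BiopsyGS,
    Margin,
    Outcome,
    PathStage,
    PatientRecord,
    RPPathology,
    RpGS,
)
from .rules import OLD_LOW_CUTOFFS, BiopsyRule

__all__ = [
    "GroupParams",
    "RpParams",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "separable_fixture",
]

_GLEASON_CATS = (BiopsyGS.GS6, BiopsyGS.GS7_34, BiopsyGS.GS7_43,
                 BiopsyGS.GS8, BiopsyGS.GS9, BiopsyGS.GS10)

#: How the published "GS >= 8" biopsy mass is split over GS 8 / 9 / 10.
_GS8PLUS_SPLIT = {
    "<=49": (1.0, 0.0, 0.0),
    "50-59": (0.70, 0.25, 0.05),
    "60-69": (0.70, 0.25, 0.05),
    ">=70": (0.70, 0.25, 0.05),
}

#: Soft calibration targets for the status-conditional separation.
_PSA_SENS_TARGET = 0.97  # P[PSA_mal >= historical low-fPSA cut-off]
_FPSA_SEP_TARGET = 0.90  # P[fPSA_mal <= 18%]

#: Default relative tolerance for the large-sample median/IQR calibration.
CALIBRATION_RTOL = 0.05


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one age group."""

    n: int
    prevalence: float
    psa_logmu_benign: float
    psa_logsigma_benign: float
    psa_logmu_malignant: float
    psa_logsigma_malignant: float
    fpsa_mu_benign: float
    fpsa_sigma_benign: float
    fpsa_mu_malignant: float
    fpsa_sigma_malignant: float
    gleason_probs: tuple[float, ...]  # over GS<=6, 7(3+4), 7(4+3), 8, 9, 10
    gleason_missing: float
    volume_logmu: float
    volume_logsigma: float
    age_mean: float
    age_sd: float

    def validate(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        for name in ("psa_logsigma_benign", "psa_logsigma_malignant",
                     "fpsa_sigma_benign", "fpsa_sigma_malignant",
                     "volume_logsigma", "age_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.gleason_probs) != len(_GLEASON_CATS):
            raise ValueError("gleason_probs must have six entries")
        if any(p < 0 for p in self.gleason_probs) or not (0 <= self.gleason_missing < 1):
            raise ValueError("gleason probabilities must be non-negative")
        if not math.isclose(sum(self.gleason_probs), 1.0, abs_tol=1e-9):
            raise ValueError("gleason_probs must sum to 1")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        # stochastic dominance of malignant over benign PSA, checked on a grid
        xs = np.geomspace(0.05, 500.0, 200)
        cdf_m = norm.cdf((np.log(xs) - self.psa_logmu_malignant) / self.psa_logsigma_malignant)
        cdf_b = norm.cdf((np.log(xs) - self.psa_logmu_benign) / self.psa_logsigma_benign)
        if np.any(cdf_m > cdf_b + 1e-9):
            raise ValueError("malignant PSA distribution must stochastically dominate benign")


@dataclass(frozen=True)
class RpParams:
    """Category probabilities for prostatectomy pathology in one group.

    Each vector includes an explicit trailing "missing" probability.
    """

    gs_probs: tuple[float, ...]  # GS<=6, GS7(3+4), GS7(4+3), GS>=8, missing
    stage_probs: tuple[float, ...]  # <=pT2c, >=pT3a, missing
    margin_probs: tuple[float, ...]  # R0, R1, missing

    def validate(self) -> None:
        for name, probs, k in [("gs_probs", self.gs_probs, 5),
                               ("stage_probs", self.stage_probs, 3),
                               ("margin_probs", self.margin_probs, 3)]:
            if len(probs) != k or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be {k} non-negative probabilities")
            if not math.isclose(sum(probs), 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} must sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Full generative specification: one :class:`GroupParams` per group."""

    groups: Mapping[str, GroupParams]
    seed: int = 0
    rp_fraction: float = 758 / 1218
    rp_params: Mapping[str, RpParams] | None = None

    def validate(self) -> None:
        missing = [g for g in GROUP_LABELS if g not in self.groups]
        if missing:
            raise ValueError(f"spec lacks group(s): {missing}")
        for gp in self.groups.values():
            gp.validate()
        if not (0.0 <= self.rp_fraction <= 1.0):
            raise ValueError("rp_fraction must be in [0, 1]")
        if self.rp_params is not None:
            for rp in self.rp_params.values():
                rp.validate()


# ---------------------------------------------------------------------------
# calibration: match pooled quartiles + a soft separation target
# ---------------------------------------------------------------------------

def _calibrate_mixture(
    quartiles: Sequence[float],
    prevalence: float,
    sep_point: float,
    sep_prob: float,
    sep_upper_tail: bool,
) -> tuple[float, float, float]:
    """Solve for (mu_benign, mu_malignant, shared sigma) on a transformed
    scale so that the two-component normal mixture hits the pooled
    quartiles, with a soft separation constraint on the malignant
    component: P[X_mal >= sep_point] = sep_prob (upper tail) or
    P[X_mal <= sep_point] = sep_prob (lower tail).

    ``quartiles`` and ``sep_point`` are already on the transformed
    (log / logit) scale. Sharing sigma guarantees stochastic ordering of
    the two components. Three unknowns against four residuals: the
    quartile residuals are weighted 3x so the printed targets dominate.
    """
    q25, q50, q75 = quartiles

    def residuals(x):
        mu_b, mu_m, log_s = x
        s = math.exp(log_s)
        mix_cdf = lambda v: (1 - prevalence) * norm.cdf((v - mu_b) / s) + prevalence * norm.cdf(
            (v - mu_m) / s
        )
        tail = 1 - norm.cdf((sep_point - mu_m) / s) if sep_upper_tail else norm.cdf(
            (sep_point - mu_m) / s
        )
        return [
            3.0 * (mix_cdf(q25) - 0.25),
            3.0 * (mix_cdf(q50) - 0.50),
            3.0 * (mix_cdf(q75) - 0.75),
            1.0 * (tail - sep_prob),
        ]

    spread = max(q75 - q25, 1e-3)
    x0 = [q50 - 0.3 * spread, q50 + 0.3 * spread, math.log(spread / 1.35)]
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    mu_b, mu_m, log_s = sol.x
    if mu_m < mu_b:  # enforce the documented ordering of the components
        mu_b, mu_m = mu_m, mu_b
    return float(mu_b), float(mu_m), float(math.exp(log_s))


def _lognormal_from_quartiles(q25: float, med: float, q75: float) -> tuple[float, float]:
    """Log-normal (logmu, logsigma) matching median and IQR ratio."""
    z75 = norm.ppf(0.75)
    sigma = math.log(q75 / q25) / (2 * z75)
    return math.log(med), sigma


@lru_cache(maxsize=1)
def _default_groups() -> tuple[dict[str, GroupParams], dict[str, RpParams]]:
    groups: dict[str, GroupParams] = {}
    rp_params: dict[str, RpParams] = {}
    for gi, label in enumerate(GROUP_LABELS):
        n = ref.GROUP_SIZES[label]
        prev = ref.MALIGNANT_COUNTS[label] / n

        psa_q = np.log(np.asarray(ref.PSA_QUARTILES[label], dtype=float))
        mu_b, mu_m, s = _calibrate_mixture(
            psa_q, prev,
            sep_point=math.log(OLD_LOW_CUTOFFS[gi]),
            sep_prob=_PSA_SENS_TARGET,
            sep_upper_tail=True,
        )

        fpsa_q = logit(np.asarray(ref.FPSA_QUARTILES[label], dtype=float) / 100.0)
        fmu_lo, fmu_hi, fs = _calibrate_mixture(
            fpsa_q, prev,
            sep_point=float(logit(0.18)),
            sep_prob=_FPSA_SEP_TARGET,
            sep_upper_tail=False,
        )
        # malignant mean sits BELOW benign on the logit scale
        fmu_m, fmu_b = fmu_lo, fmu_hi

        gs_pct = ref.BIOPSY_GLEASON_PCT[label]
        missing = gs_pct[4] / 100.0
        base = np.array(gs_pct[:4], dtype=float)
        base = base / base.sum()
        split = _GS8PLUS_SPLIT[label]
        gleason = (base[0], base[1], base[2],
                   base[3] * split[0], base[3] * split[1], base[3] * split[2])

        vol_mu, vol_sigma = _lognormal_from_quartiles(*ref.VOLUME_QUARTILES[label])
        age_mean, age_sd = ref.AGE_MEAN_SD[label]

        groups[label] = GroupParams(
            n=n,
            prevalence=prev,
            psa_logmu_benign=mu_b,
            psa_logsigma_benign=s,
            psa_logmu_malignant=mu_m,
            psa_logsigma_malignant=s,
            fpsa_mu_benign=fmu_b,
            fpsa_sigma_benign=fs,
            fpsa_mu_malignant=fmu_m,
            fpsa_sigma_malignant=fs,
            gleason_probs=tuple(float(p) for p in gleason),
            gleason_missing=missing,
            volume_logmu=vol_mu,
            volume_logsigma=vol_sigma,
            age_mean=age_mean,
            age_sd=age_sd,
        )

        def _normed(pcts: Sequence[float]) -> tuple[float, ...]:
            arr = np.asarray(pcts, dtype=float)
            return tuple(float(p) for p in arr / arr.sum())

        rp_params[label] = RpParams(
            gs_probs=_normed(ref.RP_GLEASON_PCT[label]),
            stage_probs=_normed(ref.RP_STAGE_PCT[label]),
            margin_probs=_normed(ref.RP_MARGIN_PCT[label]),
        )
    return groups, rp_params


def default_spec(seed: int = 0) -> CohortSpec:
    """The calibrated default specification.

    Group sizes, prevalences and category mixes are taken directly from the
    published summaries; the PSA / fPSA location-scale parameters are
    solved at call time by :func:`_calibrate_mixture` (cached) so that the
    pooled per-group mixtures reproduce the published medians and IQRs
    within :data:`CALIBRATION_RTOL`.
    """
    groups, rp_params = _default_groups()
    spec = CohortSpec(groups=dict(groups), seed=seed, rp_params=dict(rp_params))
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _group_rng(seed: int, group_index: int) -> np.random.Generator:
    # one named stream per group: independent of how many groups are drawn
    return np.random.default_rng(np.random.SeedSequence([int(seed), 1000 + group_index]))


def _sample_ages(rng: np.random.Generator, gp: GroupParams, lower: int, upper: int | None, n: int) -> np.ndarray:
    hi = upper if upper is not None else 90
    ages = rng.normal(gp.age_mean, gp.age_sd, size=n)
    ages = np.clip(np.floor(ages), max(lower, 18), hi)
    return ages.astype(int)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort; deterministic given ``spec.seed``."""
    spec.validate()
    records: list[PatientRecord] = []
    for gi, group in enumerate(AGE_GROUPS):
        gp = spec.groups[group.label]
        rng = _group_rng(spec.seed, gi)
        n = gp.n
        ages = _sample_ages(rng, gp, group.lower, group.upper, n)
        malignant = rng.random(n) < gp.prevalence

        psa_mu = np.where(malignant, gp.psa_logmu_malignant, gp.psa_logmu_benign)
        psa_sigma = np.where(malignant, gp.psa_logsigma_malignant, gp.psa_logsigma_benign)
        psa = np.exp(rng.normal(psa_mu, psa_sigma))

        f_mu = np.where(malignant, gp.fpsa_mu_malignant, gp.fpsa_mu_benign)
        f_sigma = np.where(malignant, gp.fpsa_sigma_malignant, gp.fpsa_sigma_benign)
        fpsa = 100.0 * expit(rng.normal(f_mu, f_sigma))

        volume = np.exp(rng.normal(gp.volume_logmu, gp.volume_logsigma, size=n))

        gs_probs = np.array(gp.gleason_probs) * (1 - gp.gleason_missing)
        gs_support = list(_GLEASON_CATS) + [None]
        gs_p = np.append(gs_probs, gp.gleason_missing)
        gs_idx = rng.choice(len(gs_support), size=n, p=gs_p)

        rp_draw = rng.random(n) < spec.rp_fraction
        rp_spec = (spec.rp_params or {}).get(group.label)
        gs_cats = list(RpGS) + [None]
        stage_cats = list(PathStage) + [None]
        margin_cats = list(Margin) + [None]

        for i in range(n):
            is_mal = bool(malignant[i])
            rp = None
            if is_mal and rp_draw[i] and rp_spec is not None:
                rp = RPPathology(
                    rp_gs=gs_cats[rng.choice(5, p=rp_spec.gs_probs)],
                    stage=stage_cats[rng.choice(3, p=rp_spec.stage_probs)],
                    margin=margin_cats[rng.choice(3, p=rp_spec.margin_probs)],
                )
            records.append(
                PatientRecord(
                    patient_id=f"{group.label}-{i:05d}",
                    age=int(ages[i]),
                    psa=float(psa[i]),
                    fpsa_pct=float(min(fpsa[i], 100.0)),
                    outcome=Outcome.MALIGNANT if is_mal else Outcome.BENIGN,
                    biopsy_gs=gs_support[gs_idx[i]] if is_mal else None,
                    prostate_volume=float(volume[i]),
                    rp=rp,
                )
            )
    return records


# ---------------------------------------------------------------------------
# planted-rule fixture for grid-search recovery
# ---------------------------------------------------------------------------

def separable_fixture(
    rule: BiopsyRule,
    n_per_group: int,
    seed: int,
    *,
    fpsa_thresholds: Sequence[float] = (15.0, 18.0, 21.0),
    high_fpsa_cutoffs: Sequence[float] = (5.0, 6.0, math.inf),
    sensitivity_floor: float = 0.88,
) -> list[PatientRecord]:
    """Construct a cohort on which ``rule`` is the unique grid-search winner.

    Within each age group the records are placed so that, over the scenario
    grid spanned by ``fpsa_thresholds`` x PSA cut-offs x
    ``high_fpsa_cutoffs``:

    * the planted rule attains sensitivity 1 and specificity 1;
    * every scenario with a higher low-stratum cut-off, a lower fPSA
      threshold, or a higher high-stratum cut-off than planted loses a
      block of >= (1 - floor) of the malignant records and becomes
      infeasible;
    * every other differing scenario flags at least one benign sentinel
      record and therefore has strictly lower specificity.

    Malignant blocks must each exceed ``1 - sensitivity_floor`` of the
    group's cancers, so the construction requires ``sensitivity_floor >
    2/3``. The ``seed`` jitters the placed PSA values within the open
    interval to the neighbouring grid points (malignant at or above the
    planted cut-off, benign strictly below it), so different seeds give
    different cohorts with identical recovery guarantees.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    if n_per_group < 6:
        raise ValueError("n_per_group must be >= 6 to place all sentinel blocks")
    if not (2 / 3 < sensitivity_floor <= 1):
        raise ValueError("construction requires sensitivity_floor in (2/3, 1]")
    thresholds = sorted(fpsa_thresholds)
    records: list[PatientRecord] = []
    for gi, group in enumerate(AGE_GROUPS):
        gr = rule.groups[group.label]
        t, low, high = gr.fpsa_threshold, gr.psa_cutoff_low_fpsa, gr.psa_cutoff_high_fpsa
        if t not in thresholds:
            raise ValueError(f"planted fPSA threshold {t} not on the grid {thresholds}")
        smaller_t = [x for x in thresholds if x < t]
        larger_t = [x for x in thresholds if x > t]
        finite_high = high if math.isfinite(high) else max(
            h for h in high_fpsa_cutoffs if math.isfinite(h)
        )
        if math.isfinite(high) and low >= high:
            raise ValueError(
                f"infeasible construction: planted low cut-off {low} is not "
                f"strictly below the high cut-off {high}"
            )

        age = group.lower + 1 if group.upper is None else (group.lower + group.upper) // 2
        fpsa_lowest = thresholds[0] - 1.0
        eps = 0.01

        # malignant blocks: losing any one drops sensitivity below the floor
        mal_blocks: list[tuple[float, float]] = [(fpsa_lowest, low)]
        if smaller_t:
            # in the low stratum for the planted threshold only
            mal_blocks.append((t - 0.25, low))
        if math.isfinite(high):
            # in the high stratum for every threshold <= t
            mal_blocks.append((t + 0.25, high))

        # benign sentinels: flagged by any feasible deviation, not by planted
        ben_blocks: list[tuple[float, float]] = [(fpsa_lowest, low - eps)]
        if larger_t:
            ben_blocks.append((t + 0.25, low))
        ben_blocks.append((t + 0.25, (high - eps) if math.isfinite(high) else finite_high))

        n_mal = n_per_group // 2
        n_ben = n_per_group - n_mal
        mal_counts = _split_evenly(n_mal, len(mal_blocks))
        ben_counts = _split_evenly(n_ben, len(ben_blocks))

        # jitter < half the 0.5 ng/mL grid step keeps every record on the
        # intended side of every grid cut-off
        idx = 0
        for (fp, psa), count in zip(mal_blocks, mal_counts):
            for _ in range(count):
                records.append(
                    PatientRecord(
                        patient_id=f"fix{seed}-{group.label}-m{idx}",
                        age=age, psa=psa + 0.24 * rng.random(), fpsa_pct=fp,
                        outcome=Outcome.MALIGNANT, biopsy_gs=BiopsyGS.GS6,
                    )
                )
                idx += 1
        for (fp, psa), count in zip(ben_blocks, ben_counts):
            for _ in range(count):
                records.append(
                    PatientRecord(
                        patient_id=f"fix{seed}-{group.label}-b{idx}",
                        age=age, psa=max(psa - 0.2 * rng.random(), 0.0), fpsa_pct=fp,
                        outcome=Outcome.BENIGN,
                    )
                )
                idx += 1
    return records


def _split_evenly(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]
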