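"""Published per-age-group summary statistics of the source screening cohort.

The patient-level data of the biopsy cohort that motivated this package
(2225 men biopsied in an Austrian PSA early-detection program, 1995-2012)
are not publicly available. What is available are its published summary
tables: per-age-group sample sizes, malignancy prevalence, PSA / fPSA% /
prostate-volume medians and IQRs, biopsy Gleason mix, prostatectomy
pathology mix, the diagnostic performance of the historical and revised
rules (rounded to one decimal), and the per-group biopsy-reduction
fractions.

Those summaries serve two roles here:

* calibration targets for the synthetic cohort generator
  (:mod:`psascreen.synthetic`), and
* inputs to reconstruction arithmetic — e.g. recovering predictive values
  from rounded rates, or the number needed to screen from reduction
  fractions — that can be checked against the published numbers.

All dictionaries are keyed by the age-group labels of
:data:`psascreen.cohort.GROUP_LABELS`.
"""

from __future__ import annotations

from .cohort import GROUP_LABELS

# --- cohort structure ------------------------------------------------------

#: Patients per age group (sums to 2225).
GROUP_SIZES = dict(zip(GROUP_LABELS, (178, 597, 962, 488)))

#: Malignant biopsies per age group (sums to 1218).
MALIGNANT_COUNTS = dict(zip(GROUP_LABELS, (61, 295, 524, 338)))

#: Benign biopsies per age group (sums to 1007).
BENIGN_COUNTS = {g: GROUP_SIZES[g] - MALIGNANT_COUNTS[g] for g in GROUP_LABELS}

#: Age mean / SD within each group (years).
AGE_MEAN_SD = dict(zip(GROUP_LABELS, ((45.4, 3.2), (55.3, 2.6), (64.5, 2.8), (74.2, 3.9))))

#: Pooled PSA (ng/mL) quartiles (q25, median, q75) per group.
PSA_QUARTILES = dict(
    zip(GROUP_LABELS, ((2.0, 2.8, 4.4), (3.1, 4.5, 6.5), (4.0, 5.6, 7.9), (4.7, 7.1, 11.8)))
)

#: Pooled fPSA% quartiles (q25, median, q75) per group.
FPSA_QUARTILES = dict(
    zip(GROUP_LABELS, ((9.0, 12.7, 15.1), (10.2, 13.9, 17.4), (10.0, 14.9, 21.0), (9.2, 15.0, 22.8)))
)

#: Pooled prostate volume (mL) quartiles (q25, median, q75) per group.
VOLUME_QUARTILES = dict(
    zip(GROUP_LABELS, ((20.0, 26.0, 35.0), (26.0, 35.0, 45.0), (30.0, 41.0, 61.0), (26.0, 40.0, 61.5)))
)

#: Biopsy Gleason mix among malignant records, as published percents of the
#: group's malignant count: (GS<=6, GS7(3+4), GS7(4+3), GS>=8, missing).
BIOPSY_GLEASON_PCT = dict(
    zip(
        GROUP_LABELS,
        (
            (75.4, 19.7, 3.3, 1.6, 0.0),
            (68.5, 20.7, 4.4, 5.8, 0.7),
            (55.5, 26.0, 5.2, 12.4, 1.0),
            (39.3, 29.3, 7.1, 22.8, 1.5),
        ),
    )
)

# --- prostatectomy sub-cohort ---------------------------------------------

#: Radical prostatectomies per age group (sums to 758 of the 1218 cancers).
RP_COUNTS = dict(zip(GROUP_LABELS, (54, 246, 371, 87)))

#: Prostatectomy Gleason mix, percents of the group's RP count:
#: (GS<=6, GS7(3+4), GS7(4+3), GS>=8, missing).
RP_GLEASON_PCT = dict(
    zip(
        GROUP_LABELS,
        (
            (79.6, 14.8, 3.7, 1.9, 0.0),
            (71.5, 19.9, 4.9, 3.3, 0.4),
            (58.5, 26.7, 5.9, 8.1, 0.8),
            (49.4, 27.6, 5.7, 13.8, 3.4),
        ),
    )
)

#: Pooled prostatectomy Gleason mix, percents of 758: (GS<=6, GS7(3+4),
#: GS7(4+3), GS>=8, missing).
RP_GLEASON_PCT_TOTAL = (63.2, 23.7, 5.4, 6.7, 0.9)

#: Pathological stage mix per group, percents: (<=pT2c, >=pT3a, missing).
RP_STAGE_PCT = dict(
    zip(
        GROUP_LABELS,
        ((88.9, 9.3, 1.9), (81.3, 17.9, 0.8), (70.1, 27.2, 2.7), (54.0, 35.6, 10.3)),
    )
)

#: Surgical margin mix per group, percents: (R0, R1, missing).
RP_MARGIN_PCT = dict(
    zip(
        GROUP_LABELS,
        ((77.8, 16.7, 5.6), (76.4, 19.1, 4.5), (69.3, 23.7, 7.0), (56.3, 25.3, 18.4)),
    )
)

# --- published rule performance (rounded to one decimal) -------------------

#: Historical rule: (sensitivity %, specificity %, PPV %, NPV %) per group.
OLD_RULE_RATES = dict(
    zip(
        GROUP_LABELS,
        (
            (93.4, 7.7, 34.5, 69.2),
            (96.9, 4.0, 49.4, 50.0),
            (96.4, 4.6, 54.7, 51.3),
            (93.5, 6.0, 69.1, 29.0),
        ),
    )
)

#: Revised rule: (sensitivity %, specificity %, PPV %, NPV %) per group.
NEW_RULE_RATES = dict(
    zip(
        GROUP_LABELS,
        (
            (88.5, 25.6, 38.3, 81.1),
            (93.2, 11.3, 50.6, 63.0),
            (90.8, 17.8, 56.9, 61.9),
            (88.5, 32.7, 74.8, 55.7),
        ),
    )
)

#: Published biopsy-reduction fractions (revised vs historical rule),
#: per group and pooled, as proportions.
BIOPSY_REDUCTION = {"<=49": 0.109, "50-59": 0.057, "60-69": 0.072, ">=70": 0.090, "total": 0.075}

#: Published number needed to screen to avoid one biopsy, per group and
#: pooled. The 50-59 and 60-69 entries are internally inconsistent with the
#: one-decimal reduction fractions above (1/0.057 = 17.5, 1/0.072 = 13.9);
#: they are kept verbatim for reference but cannot be reproduced from the
#: printed reductions.
NNS = {"<=49": 9.2, "50-59": 17.4, "60-69": 13.8, ">=70": 11.1, "total": 13.3}
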