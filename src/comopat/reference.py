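"""Published reference tables for an older lung-cancer comorbidity cohort.

These are the summary tables of a published 2018 electronic-medical-record
study of 1510 lung-cancer patients aged 65+ drawn from tertiary hospitals in
Jilin Province, Northeast China.  The raw records of that cohort are not
public; what survives are its marginal summaries: the demographic breakdown,
the per-disease case counts for the 31 comorbidity categories it reported,
and the 41 association rules it mined at thresholds support > 0.01,
confidence > 0.5, lift > 2.

This module packages those summaries as plain data.  They serve two roles:

* calibration — :func:`default_marginals` and the demographic proportions are
  the default parameters of :class:`comopat.synthetic.CohortConfig`, so a
  simulated cohort has the same marginal structure as the reference one;
* fixtures — :func:`published_rules` returns the 41 rules as
  :class:`~comopat.mining.AssociationRule` objects so summary statistics and
  itemset-deduplication behaviour can be checked against the published values.

The reference comorbidity-count histogram is known to be internally
inconsistent (its rows sum to 1530, not 1510); the per-disease counts are
therefore the quantity the synthetic generator targets.
"""

from __future__ import annotations

COHORT_SIZE: int = 1510

#: (age band lower, upper inclusive) -> proportion of the cohort
AGE_BAND_PROPORTIONS: dict[tuple[int, int], float] = {
    (65, 74): 0.744,
    (75, 84): 0.218,
    (85, 95): 0.038,
}

MALE_FRACTION: float = 909 / 1510  # 60.2%

NATIONALITY_PROPORTIONS: dict[str, float] = {
    "Han": 1416 / 1510,
    "Korean": 68 / 1510,
    "Other": 25 / 1510,
}

OCCUPATION_PROPORTIONS: dict[str, float] = {
    "Farmer": 246 / 1510,
    "Retired": 337 / 1510,
    "Unemployed": 84 / 1510,
    "Worker": 55 / 1510,
    "Staff": 23 / 1510,
    "Other": 33 / 1510,
    "": 732 / 1510,  # unspecified
}

MARITAL_PROPORTIONS: dict[str, float] = {
    "Unmarried": 9 / 1510,
    "Married": 1375 / 1510,
    "Widowed": 59 / 1510,
    "Divorced": 11 / 1510,
    "Other": 56 / 1510,
}

#: number of comorbidities -> patient count ("4+" pools four or more).
#: NB: the column sums to 1530, 20 more than the cohort size — an
#: inconsistency in the published table itself, preserved verbatim here.
COMORBIDITY_COUNT_TABLE: dict[str, int] = {
    "0": 339,
    "1": 230,
    "2": 262,
    "3": 203,
    "4+": 496,
}

#: (category label, all cases n, single-comorbidity %, multiple-comorbidity %)
DISEASE_TABLE: list[tuple[str, int, float, float]] = [
    ("Pneumonia", 299, 11.7, 88.3),
    ("Cerebral infarction", 230, 10.9, 89.1),
    ("Hypertension", 202, 8.4, 91.6),
    ("Pleural conditions", 174, 11.5, 88.5),
    ("Heart failure", 112, 0.0, 100.0),
    ("Atherosclerotic heart disease", 102, 3.9, 96.1),
    ("Disorders of glycoprotein metabolism", 98, 1.0, 99.0),
    ("Type 2 diabetes mellitus", 93, 10.8, 89.2),
    ("Emphysema", 90, 4.4, 95.6),
    ("Cardiac arrhythmias", 70, 1.4, 98.6),
    ("Chronic ischemic heart disease", 69, 0.0, 100.0),
    ("Pericardium diseases", 65, 10.8, 89.2),
    ("Cyst of kidney", 65, 1.5, 98.5),
    ("Pulmonary collapse", 62, 4.8, 95.2),
    ("Anemias", 59, 3.4, 96.6),
    ("Respiratory failure", 51, 7.8, 92.2),
    ("Hypokalemia", 42, 0.0, 100.0),
    ("Chronic obstructive pulmonary disease", 41, 7.3, 92.7),
    ("Cholelithiasis", 41, 2.4, 97.6),
    ("Hyponatremia", 36, 5.6, 94.4),
    ("Fatty liver", 30, 0.0, 100.0),
    ("Thyroid nodule", 29, 3.4, 96.6),
    ("Angina pectoris", 29, 0.0, 100.0),
    ("Ischemic cardiomyopathy", 28, 3.6, 96.4),
    ("Hyperplasia of the prostate", 28, 3.6, 96.4),
    ("Disorders of calcium metabolism", 27, 0.0, 100.0),
    ("Atrial fibrillation and flutter", 27, 3.7, 96.3),
    ("Degenerative diseases of the nervous system", 24, 0.0, 100.0),
    ("Interstitial pulmonary diseases", 22, 13.6, 86.4),
    ("Chronic sinusitis", 21, 4.8, 95.2),
    ("Calculus of the kidney", 21, 0.0, 100.0),
]

#: the 41 published association rules: (rule number, LHS labels, RHS label,
#: support, confidence, lift) — metrics as printed, rounded to 2 decimals.
PUBLISHED_RULE_TABLE: list[tuple[int, tuple[str, ...], str, float, float, float]] = [
    (1, ("Degenerative diseases of the nervous system",), "Cerebral infarction", 0.02, 0.71, 2.60),
    (2, ("Disorders of calcium metabolism",), "Disorders of glycoprotein metabolism", 0.02, 0.56, 4.78),
    (3, ("Ischemic cardiomyopathy",), "Heart failure", 0.02, 0.61, 4.58),
    (4, ("Angina pectoris",), "Atherosclerotic heart disease", 0.02, 0.55, 4.57),
    (5, ("Angina pectoris",), "Heart failure", 0.02, 0.69, 5.20),
    (6, ("Anemias",), "Disorders of glycoprotein metabolism", 0.04, 0.53, 4.53),
    (7, ("Chronic ischemic heart disease",), "Heart failure", 0.05, 0.62, 4.70),
    (8, ("Atherosclerotic heart disease",), "Heart failure", 0.06, 0.51, 3.84),
    (9, ("Atherosclerotic heart disease", "Ischemic cardiomyopathy"), "Heart failure", 0.01, 0.92, 6.96),
    (10, ("Ischemic cardiomyopathy", "Heart failure"), "Atherosclerotic heart disease", 0.01, 0.71, 5.84),
    (11, ("Ischemic cardiomyopathy", "Heart failure"), "Hypertension", 0.01, 0.59, 2.46),
    (12, ("Hypertension", "Ischemic cardiomyopathy"), "Heart failure", 0.01, 0.83, 6.28),
    (13, ("Anemias", "Hyponatremia"), "Disorders of glycoprotein metabolism", 0.01, 0.60, 5.17),
    (14, ("Disorders of glycoprotein metabolism", "Hyponatremia"), "Anemias", 0.01, 0.60, 8.58),
    (15, ("Angina pectoris", "Chronic ischemic heart disease"), "Pneumonia", 0.01, 0.90, 2.54),
    (16, ("Angina pectoris", "Pneumonia"), "Chronic ischemic heart disease", 0.01, 0.53, 6.48),
    (17, ("Angina pectoris", "Atherosclerotic heart disease"), "Heart failure", 0.01, 0.69, 5.18),
    (18, ("Angina pectoris", "Heart failure"), "Atherosclerotic heart disease", 0.01, 0.55, 4.55),
    (19, ("Hypertension", "Angina pectoris"), "Heart failure", 0.01, 0.82, 6.17),
    (20, ("Angina pectoris", "Pneumonia"), "Heart failure", 0.01, 0.65, 4.88),
    (21, ("Anemias", "Hypokalemia"), "Disorders of glycoprotein metabolism", 0.01, 0.69, 5.92),
    (22, ("Disorders of glycoprotein metabolism", "Hypokalemia"), "Anemias", 0.01, 0.58, 8.28),
    (23, ("Hypokalemia", "Pleural conditions"), "Disorders of glycoprotein metabolism", 0.01, 0.64, 5.54),
    (24, ("Anemias", "Pleural conditions"), "Disorders of glycoprotein metabolism", 0.01, 0.56, 4.84),
    (25, ("Pericardium diseases", "Pneumonia"), "Pleural conditions", 0.02, 0.52, 2.51),
    (26, ("Atherosclerotic heart disease", "Cardiac arrhythmias"), "Heart failure", 0.02, 0.67, 5.02),
    (27, ("Cardiac arrhythmias", "Heart failure"), "Atherosclerotic heart disease", 0.02, 0.58, 4.83),
    (28, ("Type 2 diabetes mellitus", "Chronic ischemic heart disease"), "Heart failure", 0.01, 0.73, 5.53),
    (29, ("Type 2 diabetes mellitus", "Heart failure"), "Chronic ischemic heart disease", 0.01, 0.52, 6.41),
    (30, ("Chronic ischemic heart disease", "Pleural conditions"), "Heart failure", 0.01, 0.59, 4.43),
    (31, ("Hypertension", "Chronic ischemic heart disease"), "Heart failure", 0.02, 0.67, 5.02),
    (32, ("Chronic ischemic heart disease", "Cerebral infarction"), "Heart failure", 0.01, 0.50, 3.77),
    (33, ("Chronic ischemic heart disease", "Pneumonia"), "Heart failure", 0.02, 0.53, 4.00),
    (34, ("Heart failure", "Pneumonia"), "Chronic ischemic heart disease", 0.02, 0.55, 6.71),
    (35, ("Type 2 diabetes mellitus", "Atherosclerotic heart disease"), "Heart failure", 0.01, 0.53, 3.99),
    (36, ("Type 2 diabetes mellitus", "Heart failure"), "Hypertension", 0.02, 0.62, 2.59),
    (37, ("Atherosclerotic heart disease", "Pleural conditions"), "Heart failure", 0.02, 0.59, 4.45),
    (38, ("Hypertension", "Atherosclerotic heart disease"), "Heart failure", 0.03, 0.67, 5.02),
    (39, ("Hypertension", "Heart failure"), "Atherosclerotic heart disease", 0.03, 0.50, 4.14),
    (40, ("Atherosclerotic heart disease", "Cerebral infarction"), "Heart failure", 0.02, 0.50, 3.77),
    (41, ("Heart failure", "Cerebral infarction"), "Atherosclerotic heart disease", 0.02, 0.58, 4.77),
]


def default_marginals() -> dict[str, float]:
    """Reference per-disease marginal prevalences (case count / cohort size)."""
    return {label: n / COHORT_SIZE for label, n, _, _ in DISEASE_TABLE}


def disease_counts() -> dict[str, int]:
    """Reference per-disease patient counts for the 31 comorbidity categories."""
    return {label: n for label, n, _, _ in DISEASE_TABLE}


def published_rules() -> list:
    """The 41 published rules as :class:`~comopat.mining.AssociationRule`.

    Metrics carry the printed two-decimal precision; patient counts behind
    them were not published, so the count fields are left at ``None``.
    """
    from .mining import AssociationRule

    return [
        AssociationRule(
            lhs=frozenset(lhs), rhs=rhs,
            support=sup, confidence=conf, lift=lift,
        )
        for _, lhs, rhs, sup, conf, lift in PUBLISHED_RULE_TABLE
    ]


def comorbidity_count_proportions() -> dict[str, float]:
    """Comorbidity-count histogram rows as proportions of the cohort size.

    Uses the cohort size (1510) as the denominator even though the published
    rows sum to 1530; this reproduces the published percentages.
    """
    return {k: v / COHORT_SIZE for k, v in COMORBIDITY_COUNT_TABLE.items()}
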