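"""ICD-10 code -> morbidity-category catalog.

Maps raw ICD-10 diagnosis codes to the comorbidity category labels used
throughout the pipeline, and identifies the index disease (lung cancer, C34)
that defines cohort eligibility but is excluded from the comorbidity
transactions.  Codes are matched by exact string equality; no hierarchy
collapsing is performed — in particular I25 (chronic ischemic heart disease)
and its children I25.1 / I25.5 are three distinct categories, as the
reference rule set treats them.

Only ten category codes are documented by the reference study; the remaining
categories carry one representative ICD-10 code each, chosen as the code a
coder would most plausibly use for that label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path


class CatalogError(ValueError):
    """Raised for an ill-formed disease catalog."""


#: ICD-10 chapter tag inferred from the code's leading letter(s).
_CHAPTER_BY_LETTER = {
    "C": "Neoplasms",
    "D": "Blood",
    "E": "Endocrine/metabolic",
    "G": "Nervous",
    "I": "Circulatory",
    "J": "Respiratory",
    "K": "Digestive",
    "N": "Genitourinary",
}

#: (icd10 code, category label); the first ten codes are documented by the
#: reference rule set, the rest are representative assignments.
_DEFAULT_ENTRIES: list[tuple[str, str]] = [
    ("J18", "Pneumonia"),
    ("I63", "Cerebral infarction"),
    ("I10", "Hypertension"),
    ("I50", "Heart failure"),
    ("I25", "Chronic ischemic heart disease"),
    ("I25.1", "Atherosclerotic heart disease"),
    ("I25.5", "Ischemic cardiomyopathy"),
    ("I20", "Angina pectoris"),
    ("E11", "Type 2 diabetes mellitus"),
    ("I31", "Pericardium diseases"),
    ("J94", "Pleural conditions"),
    ("E77", "Disorders of glycoprotein metabolism"),
    ("J43", "Emphysema"),
    ("I49", "Cardiac arrhythmias"),
    ("N28.1", "Cyst of kidney"),
    ("J98.1", "Pulmonary collapse"),
    ("D64", "Anemias"),
    ("J96", "Respiratory failure"),
    ("E87.6", "Hypokalemia"),
    ("J44", "Chronic obstructive pulmonary disease"),
    ("K80", "Cholelithiasis"),
    ("E87.1", "Hyponatremia"),
    ("K76.0", "Fatty liver"),
    ("E04.1", "Thyroid nodule"),
    ("N40", "Hyperplasia of the prostate"),
    ("E83.5", "Disorders of calcium metabolism"),
    ("I48", "Atrial fibrillation and flutter"),
    ("G31", "Degenerative diseases of the nervous system"),
    ("J84", "Interstitial pulmonary diseases"),
    ("J32", "Chronic sinusitis"),
    ("N20.0", "Calculus of the kidney"),
]

INDEX_CODE = "C34"  # malignant neoplasm of bronchus and lung
INDEX_LABEL = "Lung cancer"


def chapter_of_code(code: str) -> str:
    """ICD-10 chapter tag for a code (falls back to the leading letter)."""
    letter = code[:1].upper()
    return _CHAPTER_BY_LETTER.get(letter, letter or "?")


@dataclass(frozen=True)
class DiseaseCatalog:
    """Mapping of ICD-10 codes to morbidity categories plus the index codes.

    Parameters
    ----------
    code_to_category
        Exact-match mapping of ICD-10 code to category label.  Several codes
        may map to one category; every code maps to exactly one.
    index_codes
        Codes identifying the index disease (lung cancer); disjoint from the
        comorbidity mapping.
    """

    code_to_category: dict[str, str]
    index_codes: frozenset[str] = field(default_factory=lambda: frozenset({INDEX_CODE}))

    def __post_init__(self) -> None:
        overlap = self.index_codes & set(self.code_to_category)
        if overlap:
            raise CatalogError(f"index codes also mapped as comorbidities: {sorted(overlap)}")

    @property
    def categories(self) -> list[str]:
        """Distinct comorbidity category labels, in catalog order."""
        seen: dict[str, None] = {}
        for label in self.code_to_category.values():
            seen.setdefault(label)
        return list(seen)

    def category_of(self, code: str) -> str | None:
        return self.code_to_category.get(code)

    def is_index(self, code: str) -> bool:
        return code in self.index_codes

    def code_of(self, category: str) -> str | None:
        """First code mapping to a category (categories have one by default)."""
        for code, label in self.code_to_category.items():
            if label == category:
                return code
        return None

    def chapter_of(self, category: str) -> str:
        code = self.code_of(category)
        return chapter_of_code(code) if code else "?"

    @classmethod
    def default(cls) -> "DiseaseCatalog":
        """The packaged catalog covering the 31 reference categories."""
        return cls(code_to_category=dict(_DEFAULT_ENTRIES))

    @classmethod
    def from_csv(cls, path: str | Path, index_codes: set[str] | None = None) -> "DiseaseCatalog":
        """Read a two-column ``icd10_code,category`` CSV catalog."""
        mapping: dict[str, str] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"icd10_code", "category"} <= set(reader.fieldnames):
                raise CatalogError("catalog CSV must have columns icd10_code,category")
            for row in reader:
                code = row["icd10_code"].strip()
                if code in mapping and mapping[code] != row["category"].strip():
                    raise CatalogError(f"code {code} mapped to two categories")
                mapping[code] = row["category"].strip()
        return cls(code_to_category=mapping,
                   index_codes=frozenset(index_codes or {INDEX_CODE}))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["icd10_code", "category"])
            for code, label in self.code_to_category.items():
                writer.writerow([code, label])
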