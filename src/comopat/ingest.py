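"""EMR ingestion: parsing, eligibility filtering and transaction building.

The pipeline's unit of analysis is the *transaction*: the set of comorbidity
categories recorded for one eligible patient.  This module reads raw EMR
rows, applies the cohort eligibility rules (lung-cancer diagnosis, age >= 65,
complete gender/hospital/case-number, first occurrence of each composite
primary key), maps ICD-10 codes to categories through a
:class:`~comopat.catalog.DiseaseCatalog`, and summarises the resulting
comorbidity-count distribution.

Eligibility exclusions are counted by reason with a fixed precedence so the
exclusion report is deterministic: missing mandatory field, then no index
code, then under-age, then duplicate primary key; the first matching reason
wins.  Record counts are conserved exactly:
``n_input = n_kept + sum(exclusion counts)``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .catalog import DiseaseCatalog

REQUIRED_COLUMNS = ("case_number", "gender", "age", "hospital", "icd10_codes")
OPTIONAL_COLUMNS = ("nationality", "occupation", "marital_status")

MANDATORY_FIELDS = ("case_number", "gender", "hospital")


class SchemaError(ValueError):
    """Input file does not have the expected columns."""


@dataclass(frozen=True)
class DiagnosisRecord:
    """One raw EMR row: a patient's demographics and diagnosis codes.

    ``None`` marks a missing mandatory cell; such records survive parsing and
    are removed (and counted) by :func:`filter_cohort`.
    """

    case_number: str | None
    gender: str | None
    age: int | None
    hospital: str | None
    icd10_codes: tuple[str, ...]
    nationality: str | None = None
    occupation: str | None = None
    marital_status: str | None = None

    @property
    def primary_key(self) -> tuple[str | None, str | None, int | None]:
        """Composite deduplication key: (case number, gender, age)."""
        return (self.case_number, self.gender, self.age)


@dataclass
class ExclusionReport:
    """Counts of records removed by :func:`filter_cohort`, by reason."""

    n_input: int = 0
    n_kept: int = 0
    missing_field: int = 0
    no_index_code: int = 0
    under_age: int = 0
    duplicate_key: int = 0

    @property
    def n_excluded(self) -> int:
        return self.missing_field + self.no_index_code + self.under_age + self.duplicate_key

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "missing_field": self.missing_field,
            "no_index_code": self.no_index_code,
            "under_age": self.under_age,
            "duplicate_key": self.duplicate_key,
        }


@dataclass(frozen=True)
class TransactionDB:
    """Per-patient comorbidity sets keyed by the composite primary key.

    Patients with zero comorbidities are present with an empty set; they
    count in every support denominator.
    """

    transactions: dict[str, frozenset[str]]
    unknown_codes: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.transactions)

    @property
    def items(self) -> set[str]:
        out: set[str] = set()
        for t in self.transactions.values():
            out |= t
        return out

    def item_counts(self) -> Counter:
        """Number of patients carrying each category."""
        c: Counter = Counter()
        for t in self.transactions.values():
            c.update(t)
        return c

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]]) -> "TransactionDB":
        """Build from bare item sets, assigning synthetic keys ``t0, t1, ...``."""
        return cls(transactions={f"t{i}": frozenset(s) for i, s in enumerate(sets)})

    def to_basket_text(self, path: str | Path) -> None:
        """Write one-line-per-patient basket text: ``key<TAB>item1,item2``."""
        with open(path, "w") as fh:
            for key, items in self.transactions.items():
                fh.write(f"{key}\t{','.join(sorted(items))}\n")

    @classmethod
    def from_basket_text(cls, path: str | Path) -> "TransactionDB":
        transactions: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, _, items = line.partition("\t")
                transactions[key] = frozenset(i for i in items.split(",") if i)
        return cls(transactions=transactions)


def _clean(value: object) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def read_emr(path: str | Path, delimiter: str = ",", code_delimiter: str = ";") -> list[DiagnosisRecord]:
    """Parse an EMR CSV into :class:`DiagnosisRecord` objects.

    Blank mandatory cells are preserved as ``None`` rather than dropped here,
    so the exclusion report downstream can account for them.  Diagnosis codes
    are split on ``code_delimiter``.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                        na_values=[""])
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    records: list[DiagnosisRecord] = []
    for row in frame.itertuples(index=False):
        age_text = _clean(getattr(row, "age"))
        try:
            age = int(age_text) if age_text is not None else None
        except ValueError as exc:
            raise SchemaError(f"non-integer age value {age_text!r}") from exc
        codes_text = _clean(getattr(row, "icd10_codes")) or ""
        codes = tuple(c.strip() for c in codes_text.split(code_delimiter) if c.strip())
        records.append(DiagnosisRecord(
            case_number=_clean(getattr(row, "case_number")),
            gender=_clean(getattr(row, "gender")),
            age=age,
            hospital=_clean(getattr(row, "hospital")),
            icd10_codes=codes,
            nationality=_clean(getattr(row, "nationality", None)),
            occupation=_clean(getattr(row, "occupation", None)),
            marital_status=_clean(getattr(row, "marital_status", None)),
        ))
    return records


def write_emr(records: Iterable[DiagnosisRecord], path: str | Path,
              delimiter: str = ",", code_delimiter: str = ";") -> None:
    """Write records back out in the EMR CSV schema (inverse of :func:`read_emr`)."""
    rows = []
    for r in records:
        rows.append({
            "case_number": r.case_number or "",
            "gender": r.gender or "",
            "age": "" if r.age is None else r.age,
            "hospital": r.hospital or "",
            "nationality": r.nationality or "",
            "occupation": r.occupation or "",
            "marital_status": r.marital_status or "",
            "icd10_codes": code_delimiter.join(r.icd10_codes),
        })
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS[:4]) + list(OPTIONAL_COLUMNS) + ["icd10_codes"]).to_csv(
        path, sep=delimiter, index=False)


def filter_cohort(records: Iterable[DiagnosisRecord], catalog: DiseaseCatalog,
                  min_age: int = 65) -> tuple[list[DiagnosisRecord], ExclusionReport]:
    """Apply the eligibility rules and deduplicate on the composite key.

    A record is kept iff it has non-missing case number, gender and hospital;
    carries at least one index (lung-cancer) code; is aged ``min_age`` or
    older; and is the first occurrence of its (case number, gender, age) key.
    Filtering is idempotent.
    """
    report = ExclusionReport()
    kept: list[DiagnosisRecord] = []
    seen_keys: set[tuple] = set()
    for rec in records:
        report.n_input += 1
        if rec.case_number is None or rec.gender is None or rec.hospital is None or rec.age is None:
            report.missing_field += 1
            continue
        if not any(catalog.is_index(code) for code in rec.icd10_codes):
            report.no_index_code += 1
            continue
        if rec.age < min_age:
            report.under_age += 1
            continue
        if rec.primary_key in seen_keys:
            report.duplicate_key += 1
            continue
        seen_keys.add(rec.primary_key)
        kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def build_transactions(records: Iterable[DiagnosisRecord], catalog: DiseaseCatalog) -> TransactionDB:
    """Map each filtered record to its set of comorbidity categories.

    Index (lung-cancer) codes are excluded; codes absent from the catalog are
    dropped and tallied in ``unknown_codes``; repeated codes collapse under
    set semantics.  Patients whose only diagnosis is the index disease yield
    an empty transaction.
    """
    transactions: dict[str, frozenset[str]] = {}
    unknown: Counter = Counter()
    for rec in records:
        key = f"{rec.case_number}|{rec.gender}|{rec.age}"
        items: set[str] = set()
        for code in rec.icd10_codes:
            if catalog.is_index(code):
                continue
            label = catalog.category_of(code)
            if label is None:
                unknown[code] += 1
            else:
                items.add(label)
        transactions[key] = frozenset(items)
    return TransactionDB(transactions=transactions, unknown_codes=dict(unknown))


@dataclass
class DistributionSummary:
    """Comorbidity-count distribution plus per-disease burden summaries."""

    histogram: pd.DataFrame  # columns: n_comorbidities, count, proportion
    per_disease: pd.DataFrame  # disease, n_cases, single_pct, multiple_pct, mean_comorbidities


def comorbidity_distribution(tdb: TransactionDB, include_self: bool = True) -> DistributionSummary:
    """Summarise comorbidity burden across the cohort.

    Returns the histogram of per-patient comorbidity counts (proportions sum
    to 1) and, per disease D: the number of carriers, the percentage of
    carriers whose D is their only comorbidity versus one of several, and the
    mean comorbidity count among carriers.  With ``include_self=True``
    (default) the mean counts the full transaction size, i.e. D itself is one
    of the comorbidities being averaged; ``False`` averages the count of
    *other* comorbidities.
    """
    sizes = [len(t) for t in tdb.transactions.values()]
    n = len(sizes)
    hist = Counter(sizes)
    max_size = max(hist) if hist else 0
    rows = [{"n_comorbidities": k, "count": hist.get(k, 0),
             "proportion": hist.get(k, 0) / n if n else 0.0}
            for k in range(max_size + 1)]
    histogram = pd.DataFrame(rows, columns=["n_comorbidities", "count", "proportion"])

    per_disease_rows = []
    counts = tdb.item_counts()
    for disease in sorted(counts, key=lambda d: (-counts[d], d)):
        carrier_sizes = [len(t) for t in tdb.transactions.values() if disease in t]
        n_cases = len(carrier_sizes)
        single = sum(1 for s in carrier_sizes if s == 1)
        mean_size = sum(carrier_sizes) / n_cases
        per_disease_rows.append({
            "disease": disease,
            "n_cases": n_cases,
            "single_pct": 100.0 * single / n_cases,
            "multiple_pct": 100.0 * (n_cases - single) / n_cases,
            "mean_comorbidities": mean_size if include_self else mean_size - 1,
        })
    per_disease = pd.DataFrame(
        per_disease_rows,
        columns=["disease", "n_cases", "single_pct", "multiple_pct", "mean_comorbidities"])
    return DistributionSummary(histogram=histogram, per_disease=per_disease)


def blank_field(record: DiagnosisRecord, fieldname: str) -> DiagnosisRecord:
    """Return a copy of ``record`` with one mandatory field set missing."""
    if fieldname not in MANDATORY_FIELDS:
        raise ValueError(f"not a blankable mandatory field: {fieldname}")
    return replace(record, **{fieldname: None})
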