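"""Synthetic EMR cohort generator with analytically known rule metrics.

No real patient records ship with this package, so the whole pipeline is
exercised on simulated cohorts whose statistical structure is known exactly.
The generative model is deliberately minimal:

* each patient receives the lung-cancer index code (C34), an age drawn
  uniformly within an age band, a gender, a hospital, and demographic strings
  sampled from the reference cohort's proportions;
* comorbidities start as independent Bernoulli draws at configured marginal
  prevalences;
* *planted dependencies* then rewrite targets in list order: when all of a
  dependency's source diseases are present, the target is redrawn as
  Bernoulli(conditional_prob), overriding its marginal draw.

Because the only dependence is through these explicit overrides, the exact
population-level support, confidence and lift of any candidate rule can be
computed in closed form by propagating the joint distribution of the involved
diseases through the override sequence (:func:`expected_rule_metrics`) —
giving every mining test an analytic oracle.

Data-quality defects are injectable on top: a fraction of records with one
mandatory field blanked, and a fraction re-emitted with an identical primary
key.  Corruption draws happen after the disease draws, so toggling corruption
never changes the disease pattern of the clean records; duplicates clone only
uncorrupted records, keeping the downstream exclusion accounting exact.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import reference
from .catalog import INDEX_CODE, DiseaseCatalog
from .ingest import DiagnosisRecord, write_emr

_ENUMERATION_LIMIT = 20  # diseases in a dependency closure we will enumerate


class CohortConfigError(ValueError):
    """A cohort configuration violates one of its invariants."""


class UnknownLabelError(KeyError):
    """A queried disease label is not in the configuration."""


class UnsupportedConfigError(ValueError):
    """The dependency structure is too large for exact enumeration."""


@dataclass(frozen=True)
class PlantedDependency:
    """One conditional override: P(target present | all sources present).

    When every label in ``source_set`` is present, the target's marginal draw
    is replaced by Bernoulli(``conditional_prob``); otherwise the marginal
    draw stands.  ``conditional_prob`` may be below the target's marginal
    (the override replaces, it does not take a maximum).
    """

    source_set: frozenset[str]
    target: str
    conditional_prob: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_set", frozenset(self.source_set))
        if self.target in self.source_set:
            raise CohortConfigError(f"planted_rules: target {self.target!r} is in its own source set")
        if not self.source_set:
            raise CohortConfigError("planted_rules: empty source set")
        if not 0.0 <= self.conditional_prob <= 1.0:
            raise CohortConfigError("planted_rules: conditional_prob outside [0, 1]")


def _default_age_bands() -> tuple[tuple[tuple[int, int], float], ...]:
    return tuple(reference.AGE_BAND_PROPORTIONS.items())


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults reproduce the reference cohort's structure: n = 1510, age bands
    65-74 / 75-84 / 85+ at 74.4 / 21.8 / 3.8 %, 60.2 % male, and the 31
    reference disease marginals (case counts / 1510).
    """

    n_patients: int = reference.COHORT_SIZE
    age_distribution: tuple[tuple[tuple[int, int], float], ...] = field(
        default_factory=_default_age_bands)
    male_fraction: float = reference.MALE_FRACTION
    disease_marginals: Mapping[str, float] = field(default_factory=reference.default_marginals)
    planted_rules: tuple[PlantedDependency, ...] = ()
    missing_field_rate: float = 0.0
    duplicate_key_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_distribution",
                           tuple((tuple(b), p) for b, p in self.age_distribution))
        object.__setattr__(self, "disease_marginals", dict(self.disease_marginals))
        object.__setattr__(self, "planted_rules", tuple(self.planted_rules))
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise CohortConfigError("n_patients must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise CohortConfigError("male_fraction outside [0, 1]")
        for rate_name in ("missing_field_rate", "duplicate_key_rate"):
            if not 0.0 <= getattr(self, rate_name) <= 1.0:
                raise CohortConfigError(f"{rate_name} outside [0, 1]")
        if abs(sum(p for _, p in self.age_distribution) - 1.0) > 1e-9:
            raise CohortConfigError("age_distribution proportions must sum to 1")
        for (lo, hi), p in self.age_distribution:
            if lo > hi or not 0.0 <= p <= 1.0:
                raise CohortConfigError("age_distribution has an invalid band")
        for label, p in self.disease_marginals.items():
            if not 0.0 <= p <= 1.0:
                raise CohortConfigError(f"disease_marginals[{label!r}] outside [0, 1]")
        targets_so_far: list[frozenset[str]] = []
        sources_so_far: set[str] = set()
        for rule in self.planted_rules:
            for label in rule.source_set | {rule.target}:
                if label not in self.disease_marginals:
                    raise CohortConfigError(f"planted_rules references unknown disease {label!r}")
            if rule.target in sources_so_far:
                raise CohortConfigError(
                    f"planted_rules: target {rule.target!r} already used as a source "
                    "of an earlier dependency (overrides must form a forward chain)")
            sources_so_far |= rule.source_set
            targets_so_far.append(rule.source_set)

    @property
    def labels(self) -> list[str]:
        return list(self.disease_marginals)


def catalog_for(config: CohortConfig, base: DiseaseCatalog | None = None) -> DiseaseCatalog:
    """A catalog covering every disease label of ``config``.

    Labels known to the packaged default catalog keep their ICD-10 codes;
    any other label doubles as its own code (the generator writes the label
    string into the diagnosis list in that case).
    """
    base = base or DiseaseCatalog.default()
    mapping = dict(base.code_to_category)
    known = set(mapping.values())
    for label in config.labels:
        if label not in known:
            mapping[label] = label
    return DiseaseCatalog(code_to_category=mapping, index_codes=base.index_codes)


def _sample_categorical(rng: np.random.Generator, table: Mapping[str, float], size: int) -> np.ndarray:
    keys = list(table)
    probs = np.array([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(keys, dtype=object), size=size, p=probs)


def generate_cohort(config: CohortConfig) -> list[DiagnosisRecord]:
    """Draw a synthetic cohort; reproducible for a fixed ``rng_seed``.

    Returns ``n_patients`` base records (every one aged >= 65 within its band
    and carrying the C34 index code) followed by any duplicate-key rows.
    Records selected for corruption have exactly one of case number, gender
    or hospital blanked.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients
    labels = config.labels
    cat = catalog_for(config)
    code_of = {label: cat.code_of(label) for label in labels}

    # demographics
    bands = [b for b, _ in config.age_distribution]
    band_probs = np.array([p for _, p in config.age_distribution])
    band_idx = rng.choice(len(bands), size=n, p=band_probs / band_probs.sum())
    ages = np.array([rng.integers(bands[i][0], bands[i][1] + 1) for i in band_idx])
    genders = np.where(rng.random(n) < config.male_fraction, "male", "female")
    hospitals = np.array([f"H{h:02d}" for h in rng.integers(1, 21, size=n)])
    nationality = _sample_categorical(rng, reference.NATIONALITY_PROPORTIONS, n)
    occupation = _sample_categorical(rng, reference.OCCUPATION_PROPORTIONS, n)
    marital = _sample_categorical(rng, reference.MARITAL_PROPORTIONS, n)

    # disease draws: independent marginals, then overrides in list order
    probs = np.array([config.disease_marginals[label] for label in labels])
    present = rng.random((n, len(labels))) < probs
    col = {label: j for j, label in enumerate(labels)}
    for rule in config.planted_rules:
        mask = np.ones(n, dtype=bool)
        for src in rule.source_set:
            mask &= present[:, col[src]]
        present[mask, col[rule.target]] = rng.random(int(mask.sum())) < rule.conditional_prob

    records: list[DiagnosisRecord] = []
    for i in range(n):
        codes = [INDEX_CODE] + [code_of[label] for label in labels if present[i, col[label]]]
        records.append(DiagnosisRecord(
            case_number=f"P{i:06d}",
            gender=str(genders[i]),
            age=int(ages[i]),
            hospital=str(hospitals[i]),
            icd10_codes=tuple(codes),
            nationality=str(nationality[i]),
            occupation=str(occupation[i]) or None,
            marital_status=str(marital[i]),
        ))

    # corruption draws come last so the clean records' disease patterns are
    # unchanged when corruption rates are toggled
    n_missing = int(round(config.missing_field_rate * n))
    corrupted_idx = rng.choice(n, size=n_missing, replace=False) if n_missing else np.array([], dtype=int)
    from .ingest import MANDATORY_FIELDS, blank_field
    for i in corrupted_idx:
        records[i] = blank_field(records[i], MANDATORY_FIELDS[rng.integers(len(MANDATORY_FIELDS))])

    n_dupes = int(round(config.duplicate_key_rate * n))
    clean_idx = np.setdiff1d(np.arange(n), corrupted_idx)
    if n_dupes:
        if n_dupes > len(clean_idx):
            n_dupes = len(clean_idx)
        for i in rng.choice(clean_idx, size=n_dupes, replace=False):
            records.append(records[int(i)])
    return records


# ---------------------------------------------------------------------------
# analytic oracle


def _dependency_closure(config: CohortConfig, seed_labels: Iterable[str]) -> list[str]:
    """All diseases whose joint law must be enumerated to answer a query."""
    involved = set(seed_labels)
    changed = True
    while changed:
        changed = False
        for rule in config.planted_rules:
            if rule.target in involved and not rule.source_set <= involved:
                involved |= rule.source_set
                changed = True
    return sorted(involved)


def joint_distribution(config: CohortConfig, labels: Sequence[str]) -> dict[tuple[bool, ...], float]:
    """Exact joint law of ``labels`` under the generative model.

    Starts from the independent-marginal product law and applies each planted
    override in list order as an exact distribution transform (conditional
    redraw of the target bit).  Only overrides whose target is among
    ``labels`` act; ``labels`` must be closed under dependency sources.
    """
    for label in labels:
        if label not in config.disease_marginals:
            raise UnknownLabelError(label)
    if len(labels) > _ENUMERATION_LIMIT:
        raise UnsupportedConfigError(
            f"dependency closure has {len(labels)} diseases; enumeration limit is {_ENUMERATION_LIMIT}")
    idx = {label: j for j, label in enumerate(labels)}
    marg = [config.disease_marginals[label] for label in labels]

    dist: dict[tuple[bool, ...], float] = {}
    for assignment in itertools.product([False, True], repeat=len(labels)):
        p = 1.0
        for j, bit in enumerate(assignment):
            p *= marg[j] if bit else 1.0 - marg[j]
        if p:
            dist[assignment] = p

    for rule in config.planted_rules:
        if rule.target not in idx:
            continue
        if not rule.source_set <= set(labels):
            raise UnsupportedConfigError(
                f"labels not closed under dependencies: sources of {rule.target!r} missing")
        t = idx[rule.target]
        c = rule.conditional_prob
        new: dict[tuple[bool, ...], float] = {}
        for assignment, p in dist.items():
            if all(assignment[idx[s]] for s in rule.source_set):
                on = assignment[:t] + (True,) + assignment[t + 1:]
                off = assignment[:t] + (False,) + assignment[t + 1:]
                if c:
                    new[on] = new.get(on, 0.0) + p * c
                if c < 1.0:
                    new[off] = new.get(off, 0.0) + p * (1.0 - c)
            else:
                new[assignment] = new.get(assignment, 0.0) + p
        dist = new
    return dist


def expected_rule_metrics(config: CohortConfig, lhs: Iterable[str], rhs: str) -> tuple[float, float, float]:
    """Population-level (support, confidence, lift) of rule lhs => rhs.

    Computed exactly by enumerating the joint distribution of the diseases in
    the dependency closure of ``lhs`` and ``rhs``.
    """
    lhs = frozenset(lhs)
    if not lhs or rhs in lhs:
        raise ValueError("lhs must be non-empty and must not contain rhs")
    labels = _dependency_closure(config, lhs | {rhs})
    dist = joint_distribution(config, labels)
    idx = {label: j for j, label in enumerate(labels)}

    def prob(event: frozenset[str]) -> float:
        return sum(p for a, p in dist.items() if all(a[idx[e]] for e in event))

    p_x = prob(lhs)
    p_y = prob(frozenset({rhs}))
    p_xy = prob(lhs | {rhs})
    if p_x == 0.0:
        raise UnsupportedConfigError("P(lhs) = 0: confidence undefined")
    if p_y == 0.0:
        raise UnsupportedConfigError("P(rhs) = 0: lift undefined")
    return p_xy, p_xy / p_x, p_xy / (p_x * p_y)


def expected_pareto_head_size(config: CohortConfig, threshold: float = 0.80) -> int:
    """Head size the rank-frequency stage is expected to report.

    Uses expected case counts (proportional to marginals) under the
    disease-instance denominator; only meaningful when no planted dependency
    rewrites the queried marginals.  Ties break lexicographically, matching
    the ranking stage.
    """
    items = sorted(config.disease_marginals.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(p for _, p in items)
    cum = 0.0
    for k, (_, p) in enumerate(items, start=1):
        cum += p / total
        if cum >= threshold - 1e-12:
            return k
    return len(items)


# ---------------------------------------------------------------------------
# file output


def write_cohort(config: CohortConfig, outdir: str | Path,
                 stem: str = "cohort") -> tuple[Path, Path]:
    """Generate a cohort and write the EMR CSV plus a JSON manifest.

    The manifest records the full configuration and, for every planted
    dependency, the analytic support/confidence/lift of its induced rule —
    the ground truth downstream recovery is judged against.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(config)
    csv_path = outdir / f"{stem}.csv"
    write_emr(records, csv_path)

    expected = []
    for rule in config.planted_rules:
        sup, conf, lift = expected_rule_metrics(config, rule.source_set, rule.target)
        expected.append({
            "lhs": sorted(rule.source_set), "rhs": rule.target,
            "conditional_prob": rule.conditional_prob,
            "expected_support": sup, "expected_confidence": conf, "expected_lift": lift,
        })
    manifest = {
        "n_patients": config.n_patients,
        "rng_seed": config.rng_seed,
        "male_fraction": config.male_fraction,
        "age_distribution": [[list(b), p] for b, p in config.age_distribution],
        "disease_marginals": dict(config.disease_marginals),
        "missing_field_rate": config.missing_field_rate,
        "duplicate_key_rate": config.duplicate_key_rate,
        "planted_rules": expected,
    }
    manifest_path = outdir / f"{stem}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return csv_path, manifest_path


def config_from_dict(raw: Mapping) -> CohortConfig:
    """Build a :class:`CohortConfig` from a plain mapping (YAML/JSON)."""
    kwargs = dict(raw)
    if "age_distribution" in kwargs:
        kwargs["age_distribution"] = tuple(
            ((int(b[0]), int(b[1])), float(p)) for b, p in kwargs["age_distribution"])
    if "planted_rules" in kwargs:
        kwargs["planted_rules"] = tuple(
            PlantedDependency(source_set=frozenset(r["source_set"]), target=r["target"],
                              conditional_prob=float(r["conditional_prob"]))
            for r in kwargs["planted_rules"])
    return CohortConfig(**kwargs)
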