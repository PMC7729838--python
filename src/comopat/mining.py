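"""Association-rule mining over comorbidity transactions.

Implements level-wise Apriori frequent-itemset search and rule generation
with the three classical interestingness measures, over per-patient
comorbidity sets:

* support(X => Y)    = P(X, Y), the fraction of patients with all of X and Y;
* confidence(X => Y) = P(Y | X) = support / P(X);
* lift(X => Y)       = P(X, Y) / (P(X) P(Y)), the co-occurrence enrichment
  over independence.

All three thresholds are *strict* (support > s, confidence > c, lift > l),
and every denominator counts all eligible patients, including those with
zero comorbidities.  Metrics are computed from integer patient counts with a
single division each, so the identities confidence = support / P(X) and
lift = confidence / P(Y) hold to machine precision on every emitted rule.

Rules have a single-item consequent.  Because several rules can share the
same combined itemset (X u {Y}) while splitting it differently, a
deduplication pass (:func:`dedupe_by_itemset`) keeps one rule per itemset —
the highest-confidence split — mirroring how a published rule table is
pruned for display.

:func:`brute_force_rules` is an intentionally naive exhaustive enumeration
used as the testing oracle for the Apriori path; it never feeds results to
it.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ingest import TransactionDB

_BRUTE_FORCE_ITEM_LIMIT = 20


class MetricUndefinedError(ZeroDivisionError):
    """P(lhs) or P(rhs) is zero, so confidence or lift is undefined."""


@dataclass(frozen=True)
class MiningThresholds:
    """Strict lower bounds on the three rule metrics plus the itemset cap.

    Defaults are the reference study's operating point: support > 0.01,
    confidence > 0.5, lift > 2, itemsets of at most 3 diseases (dyads and
    triads).
    """

    min_support: float = 0.01
    min_confidence: float = 0.5
    min_lift: float = 2.0
    max_itemset_size: int = 3

    def __post_init__(self) -> None:
        if min(self.min_support, self.min_confidence, self.min_lift) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_itemset_size < 2:
            raise ValueError("max_itemset_size must be at least 2")


@dataclass(frozen=True)
class Itemset:
    items: frozenset[str]
    support: float
    count: int = 0  # patients containing all items


@dataclass(frozen=True)
class AssociationRule:
    """A mined rule lhs => rhs with its support, confidence and lift.

    The integer patient counts behind the metrics are carried when known
    (``n`` patients total, ``count_*`` patients containing the respective
    sets); fixture rules loaded from a printed table leave them ``None``.
    """

    lhs: frozenset[str]
    rhs: str
    support: float
    confidence: float
    lift: float
    n: int | None = None
    count_lhs: int | None = None
    count_rhs: int | None = None
    count_both: int | None = None

    @property
    def itemset(self) -> frozenset[str]:
        return self.lhs | {self.rhs}

    def __str__(self) -> str:  # pragma: no cover - display helper
        lhs = ", ".join(sorted(self.lhs))
        return (f"({lhs}) => ({self.rhs})  sup={self.support:.2f} "
                f"conf={self.confidence:.2f} lift={self.lift:.2f}")


def _contains_count(transactions: Sequence[frozenset[str]], items: frozenset[str]) -> int:
    return sum(1 for t in transactions if items <= t)


def rule_metrics(tdb: TransactionDB, lhs: Iterable[str], rhs: str) -> tuple[float, float, float]:
    """Exact (support, confidence, lift) of lhs => rhs on a transaction set.

    Raises :class:`MetricUndefinedError` when no patient carries lhs (the
    confidence denominator) or rhs (the lift denominator).
    """
    lhs = frozenset(lhs)
    if not lhs:
        raise ValueError("lhs must be non-empty")
    if rhs in lhs:
        raise ValueError("rhs must not be in lhs")
    transactions = list(tdb.transactions.values())
    n = len(transactions)
    if n == 0:
        raise ValueError("empty transaction database")
    c_x = _contains_count(transactions, lhs)
    c_y = _contains_count(transactions, frozenset({rhs}))
    c_xy = _contains_count(transactions, lhs | {rhs})
    if c_x == 0:
        raise MetricUndefinedError("P(lhs) = 0: confidence undefined")
    if c_y == 0:
        raise MetricUndefinedError("P(rhs) = 0: lift undefined")
    return c_xy / n, c_xy / c_x, (c_xy * n) / (c_x * c_y)


# ---------------------------------------------------------------------------
# Apriori


def apriori_frequent_itemsets(tdb: TransactionDB, min_support: float = 0.01,
                              max_itemset_size: int = 3) -> list[Itemset]:
    """Level-wise Apriori search for itemsets with support > ``min_support``.

    Candidates of size k are generated by joining frequent (k-1)-itemsets
    sharing a (k-2)-prefix and pruned by downward closure (every (k-1)-subset
    must itself be frequent).  Supports are counted by intersecting
    per-item transaction-id sets.  Output is sorted by (size, lexicographic
    items).
    """
    n = tdb.n_patients
    if n == 0:
        return []
    per_item: dict[str, set[int]] = {}
    for tid, items in enumerate(tdb.transactions.values()):
        for item in items:
            per_item.setdefault(item, set()).add(tid)

    results: list[Itemset] = []
    level: dict[tuple[str, ...], frozenset[int]] = {}
    for item in sorted(per_item):
        tids = frozenset(per_item[item])
        if len(tids) / n > min_support:
            level[(item,)] = tids

    size = 1
    while level and size <= max_itemset_size:
        for key, tids in sorted(level.items()):
            results.append(Itemset(items=frozenset(key), support=len(tids) / n,
                                   count=len(tids)))
        size += 1
        if size > max_itemset_size:
            break
        frequent_prev = set(level)
        next_level: dict[tuple[str, ...], frozenset[int]] = {}
        keys = sorted(level)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if a[:-1] != b[:-1]:
                    break  # sorted keys: shared prefixes are contiguous
                candidate = a + (b[-1],)
                if any(candidate[:j] + candidate[j + 1:] not in frequent_prev
                       for j in range(len(candidate))):
                    continue
                tids = level[a] & level[b]
                if len(tids) / n > min_support:
                    next_level[candidate] = tids
        level = next_level
    return results


def generate_rules(itemsets: Iterable[Itemset], tdb: TransactionDB,
                   thresholds: MiningThresholds = MiningThresholds()) -> list[AssociationRule]:
    """Emit single-consequent rules from frequent itemsets, strictly filtered.

    For every frequent itemset of size >= 2 and every item y in it, the rule
    (itemset \\ y) => y survives iff support > min_support, confidence >
    min_confidence and lift > min_lift.  Subset supports are available from
    the frequent list itself (downward closure guarantees they were kept).
    """
    n = tdb.n_patients
    count_of = {iset.items: iset.count for iset in itemsets}
    rules: list[AssociationRule] = []
    for iset in itemsets:
        if len(iset.items) < 2 or iset.support <= thresholds.min_support:
            continue
        for rhs in sorted(iset.items):
            lhs = iset.items - {rhs}
            c_x = count_of[lhs]
            c_y = count_of[frozenset({rhs})]
            c_xy = iset.count
            confidence = c_xy / c_x
            lift = (c_xy * n) / (c_x * c_y)
            if confidence > thresholds.min_confidence and lift > thresholds.min_lift:
                rules.append(AssociationRule(
                    lhs=lhs, rhs=rhs, support=c_xy / n, confidence=confidence,
                    lift=lift, n=n, count_lhs=c_x, count_rhs=c_y, count_both=c_xy))
    rules.sort(key=lambda r: (len(r.itemset), tuple(sorted(r.lhs)), r.rhs))
    return rules


def mine_rules(tdb: TransactionDB,
               thresholds: MiningThresholds = MiningThresholds()) -> list[AssociationRule]:
    """Apriori search followed by rule generation (convenience wrapper)."""
    itemsets = apriori_frequent_itemsets(tdb, thresholds.min_support,
                                         thresholds.max_itemset_size)
    return generate_rules(itemsets, tdb, thresholds)


# ---------------------------------------------------------------------------
# exhaustive oracle (tests only)


def brute_force_itemsets(tdb: TransactionDB, min_support: float = 0.01,
                         max_itemset_size: int = 3) -> list[Itemset]:
    """Exhaustive itemset enumeration; testing oracle for the Apriori path."""
    items = sorted(tdb.items)
    if len(items) > _BRUTE_FORCE_ITEM_LIMIT:
        raise ValueError(f"brute force guarded at {_BRUTE_FORCE_ITEM_LIMIT} distinct items")
    transactions = list(tdb.transactions.values())
    n = len(transactions)
    out: list[Itemset] = []
    for size in range(1, max_itemset_size + 1):
        for combo in itertools.combinations(items, size):
            c = _contains_count(transactions, frozenset(combo))
            if n and c / n > min_support:
                out.append(Itemset(items=frozenset(combo), support=c / n, count=c))
    out.sort(key=lambda s: (len(s.items), tuple(sorted(s.items))))
    return out


def brute_force_rules(tdb: TransactionDB,
                      thresholds: MiningThresholds = MiningThresholds()) -> list[AssociationRule]:
    """Exhaustive rule enumeration with the same filtering semantics.

    Enumerates every itemset up to ``max_itemset_size`` and every
    single-item consequent split, computing metrics by direct transaction
    scans — deliberately independent of the Apriori code path.
    """
    items = sorted(tdb.items)
    if len(items) > _BRUTE_FORCE_ITEM_LIMIT:
        raise ValueError(f"brute force guarded at {_BRUTE_FORCE_ITEM_LIMIT} distinct items")
    transactions = list(tdb.transactions.values())
    n = len(transactions)
    rules: list[AssociationRule] = []
    if n == 0:
        return rules
    for size in range(2, thresholds.max_itemset_size + 1):
        for combo in itertools.combinations(items, size):
            itemset = frozenset(combo)
            c_xy = _contains_count(transactions, itemset)
            if c_xy / n <= thresholds.min_support:
                continue
            for rhs in combo:
                lhs = itemset - {rhs}
                c_x = _contains_count(transactions, lhs)
                c_y = _contains_count(transactions, frozenset({rhs}))
                confidence = c_xy / c_x
                lift = (c_xy * n) / (c_x * c_y)
                if confidence > thresholds.min_confidence and lift > thresholds.min_lift:
                    rules.append(AssociationRule(
                        lhs=lhs, rhs=rhs, support=c_xy / n, confidence=confidence,
                        lift=lift, n=n, count_lhs=c_x, count_rhs=c_y, count_both=c_xy))
    rules.sort(key=lambda r: (len(r.itemset), tuple(sorted(r.lhs)), r.rhs))
    return rules


# ---------------------------------------------------------------------------
# post-processing


@dataclass
class DedupResult:
    """Outcome of same-itemset deduplication."""

    kept: list[AssociationRule]
    dropped: list[AssociationRule]
    n_groups: int


def dedupe_by_itemset(rules: Sequence[AssociationRule]) -> DedupResult:
    """Keep one rule per combined itemset (lhs u rhs).

    Several rules can split the same frequent itemset into different
    antecedent/consequent pairs; for display only the most reliable split is
    kept: maximum confidence, then maximum lift, then lexicographically
    smallest consequent.  Input order is preserved among kept rules.
    """
    best: dict[frozenset[str], AssociationRule] = {}
    order: list[frozenset[str]] = []
    for rule in rules:
        key = rule.itemset
        if key not in best:
            best[key] = rule
            order.append(key)
        else:
            cur = best[key]
            wins = (rule.confidence > cur.confidence
                    or (rule.confidence == cur.confidence and rule.lift > cur.lift)
                    or (rule.confidence == cur.confidence and rule.lift == cur.lift
                        and rule.rhs < cur.rhs))
            if wins:
                best[key] = rule
    kept = [best[k] for k in order]
    kept_ids = {id(r) for r in kept}
    dropped = [r for r in rules if id(r) not in kept_ids]
    return DedupResult(kept=kept, dropped=dropped, n_groups=len(order))


@dataclass(frozen=True)
class RuleSummary:
    """Count and min/max/mean of each metric over a rule list."""

    n_rules: int
    support_min: float = float("nan")
    support_max: float = float("nan")
    support_mean: float = float("nan")
    confidence_min: float = float("nan")
    confidence_max: float = float("nan")
    confidence_mean: float = float("nan")
    lift_min: float = float("nan")
    lift_max: float = float("nan")
    lift_mean: float = float("nan")

    @property
    def empty(self) -> bool:
        return self.n_rules == 0

    def as_dict(self, ndigits: int | None = None) -> dict[str, float | int | None]:
        d: dict[str, float | int | None] = {}
        for k in ("n_rules", "support_min", "support_max", "support_mean",
                  "confidence_min", "confidence_max", "confidence_mean",
                  "lift_min", "lift_max", "lift_mean"):
            v = getattr(self, k)
            if isinstance(v, float) and math.isnan(v):
                d[k] = None  # empty-summary marker
            elif ndigits is not None and isinstance(v, float):
                d[k] = round(v, ndigits)
            else:
                d[k] = v
        return d


def summarize_rules(rules: Sequence[AssociationRule]) -> RuleSummary:
    """Exact min/max and arithmetic mean of each metric (full precision;
    round for display)."""
    if not rules:
        return RuleSummary(n_rules=0)
    sup = [r.support for r in rules]
    conf = [r.confidence for r in rules]
    lift = [r.lift for r in rules]
    return RuleSummary(
        n_rules=len(rules),
        support_min=min(sup), support_max=max(sup), support_mean=sum(sup) / len(sup),
        confidence_min=min(conf), confidence_max=max(conf), confidence_mean=sum(conf) / len(conf),
        lift_min=min(lift), lift_max=max(lift), lift_mean=sum(lift) / len(lift),
    )


# ---------------------------------------------------------------------------
# serialisation


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame([{
        "lhs": "|".join(sorted(r.lhs)),
        "rhs": r.rhs,
        "support": r.support,
        "confidence": r.confidence,
        "lift": r.lift,
    } for r in rules], columns=["lhs", "rhs", "support", "confidence", "lift"])


def write_rules_csv(rules: Sequence[AssociationRule], path: str | Path) -> None:
    rules_to_frame(rules).to_csv(path, index=False)


def write_rules_json(rules: Sequence[AssociationRule], path: str | Path) -> None:
    payload = [{
        "lhs": sorted(r.lhs), "rhs": r.rhs,
        "support": r.support, "confidence": r.confidence, "lift": r.lift,
    } for r in rules]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_rules_csv(path: str | Path) -> list[AssociationRule]:
    frame = pd.read_csv(path)
    return [AssociationRule(
        lhs=frozenset(str(row.lhs).split("|")), rhs=str(row.rhs),
        support=float(row.support), confidence=float(row.confidence), lift=float(row.lift),
    ) for row in frame.itertuples(index=False)]
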