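"""Rank-frequency (Pareto 80-20) analysis of morbidity prevalence.

Diseases are ranked by the number of patients carrying them and the shortest
prefix of the ranking whose cumulative share reaches a threshold (default
80%) is the *Pareto head* — the predominant comorbidities that downstream
network construction focuses on.

Two cumulative denominators are supported, because "covers 80% of the
population" is ambiguous under multimorbidity:

``disease_instances`` (default)
    cumulative share of all disease occurrences (sum of per-disease counts);
    well defined for any cohort.
``patients_with_comorbidity``
    fraction of patients with at least one comorbidity who carry at least
    one of the top-k diseases (union coverage); also ends at 1, but the
    marginal contribution of each rank depends on overlap with earlier ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ingest import TransactionDB

DENOMINATORS = ("disease_instances", "patients_with_comorbidity")


@dataclass(frozen=True)
class ParetoResult:
    """Ranked morbidities with cumulative coverage and the threshold head."""

    ranked: pd.DataFrame  # columns: rank, category, count, cumulative
    threshold: float
    head_size: int
    coverage: float  # achieved cumulative share at the head boundary

    @property
    def head(self) -> list[str]:
        return list(self.ranked["category"].iloc[:self.head_size])


def rank_diseases(tdb: TransactionDB,
                  denominator: str = "disease_instances") -> pd.DataFrame:
    """Rank diseases by patient count (descending, ties lexicographic).

    Returns a frame with ``rank, category, count, cumulative`` where
    ``cumulative`` is the non-decreasing share under the chosen denominator,
    ending at 1.  An all-empty transaction set yields an empty ranking with
    a warning.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    counts = tdb.item_counts()
    if not counts:
        warnings.warn("no comorbidities present; empty ranking", stacklevel=2)
        return pd.DataFrame(columns=["rank", "category", "count", "cumulative"])
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    cumulative: list[float] = []
    if denominator == "disease_instances":
        total = sum(counts.values())
        running = 0
        for _, c in ordered:
            running += c
            cumulative.append(running / total)
    else:
        carriers = [t for t in tdb.transactions.values() if t]
        diseases_so_far: set[str] = set()
        total = len(carriers)
        for label, _ in ordered:
            diseases_so_far.add(label)
            keys_covered = sum(1 for t in carriers if t & diseases_so_far)
            cumulative.append(keys_covered / total)

    return pd.DataFrame({
        "rank": range(1, len(ordered) + 1),
        "category": [label for label, _ in ordered],
        "count": [c for _, c in ordered],
        "cumulative": cumulative,
    })


def pareto_head(ranked: pd.DataFrame, threshold: float = 0.80) -> ParetoResult:
    """Shortest prefix of the ranking whose cumulative share >= threshold.

    The achieved coverage may exceed the threshold (the head boundary rarely
    lands exactly on it).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if ranked.empty:
        return ParetoResult(ranked=ranked, threshold=threshold, head_size=0, coverage=0.0)
    cum = ranked["cumulative"].to_numpy()
    head_size = int((cum >= threshold - 1e-12).argmax()) + 1
    return ParetoResult(ranked=ranked, threshold=threshold,
                        head_size=head_size, coverage=float(cum[head_size - 1]))


def write_ranked_csv(result: ParetoResult, path: str | Path) -> None:
    result.ranked.to_csv(path, index=False)


def plot_pareto(result: ParetoResult, path: str | Path) -> None:
    """Pareto chart: count bars with the cumulative-share line overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(result.ranked)), 4.5))
    ax.bar(result.ranked["category"], result.ranked["count"], color="#4878a8")
    ax.set_ylabel("patients")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    ax2 = ax.twinx()
    ax2.plot(result.ranked["category"], 100 * result.ranked["cumulative"],
             color="#e07b39", marker=".", lw=1.2)
    ax2.axhline(100 * result.threshold, color="grey", ls="--", lw=0.8)
    ax2.set_ylabel("cumulative share (%)")
    ax2.set_ylim(0, 105)
    if result.head_size:
        ax.axvline(result.head_size - 0.5, color="grey", ls=":", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
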