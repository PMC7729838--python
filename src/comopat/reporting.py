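"""Report surfaces: figures, machine-readable tables and the full pipeline.

Every figure written here has a machine-readable twin (CSV/JSON) holding
exactly the plotted numbers, and :func:`run_pipeline` chains all stages —
simulate/ingest -> distribution -> Pareto ranking -> rule mining ->
same-itemset deduplication -> network + communities -> rendering — writing
one ``summary.json`` with every headline quantity.  Running the same
configuration twice produces byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from . import ingest, mining, network, pareto
from .catalog import DiseaseCatalog
from .mining import AssociationRule, MiningThresholds
from .synthetic import CohortConfig, config_from_dict, generate_cohort

logger = logging.getLogger("comopat")


@dataclass
class RuleHeatmapMatrix:
    """Rule-by-morbidity matrix of one metric, with LHS/RHS role markers.

    ``values`` holds the rule's metric in every column participating in the
    rule (NaN elsewhere); ``roles`` holds ``"L"`` for antecedent columns and
    ``"R"`` for the single consequent column.  Direction is an annotation,
    not an arrow: these are co-occurrence patterns, not causal claims.
    """

    metric: str
    values: pd.DataFrame
    roles: pd.DataFrame


def make_heatmaps(rules: Sequence[AssociationRule], metric: str,
                  column_order: Sequence[str] | None = None) -> RuleHeatmapMatrix:
    """Build the rule-by-morbidity matrix for one metric.

    ``rules`` should already be deduplicated.  Rows keep rule order
    (mining sort order); columns follow ``column_order`` when given
    (e.g. Pareto rank), otherwise first appearance across rules.
    """
    if metric not in ("support", "confidence", "lift"):
        raise ValueError("metric must be support, confidence or lift")
    columns: list[str] = list(column_order) if column_order is not None else []
    for rule in rules:
        for label in sorted(rule.lhs) + [rule.rhs]:
            if label not in columns:
                columns.append(label)
    index = [f"#{i + 1} {'+'.join(sorted(r.lhs))}=>{r.rhs}" for i, r in enumerate(rules)]
    values = pd.DataFrame(np.nan, index=index, columns=columns)
    roles = pd.DataFrame("", index=index, columns=columns)
    for row, rule in zip(index, rules):
        v = getattr(rule, metric)
        for label in rule.lhs:
            values.loc[row, label] = v
            roles.loc[row, label] = "L"
        values.loc[row, rule.rhs] = v
        roles.loc[row, rule.rhs] = "R"
    return RuleHeatmapMatrix(metric=metric, values=values, roles=roles)


def render_heatmap(matrix: RuleHeatmapMatrix, path: str | Path) -> None:
    """Render the matrix with a colour scale monotone in the metric."""
    if matrix.values.empty:
        logger.warning("no rules: heatmap %s not rendered", path)
        return
    h = max(3.0, 0.22 * len(matrix.values))
    w = max(5.0, 0.35 * len(matrix.values.columns))
    fig, ax = plt.subplots(figsize=(w, h))
    sns.heatmap(matrix.values, ax=ax, cmap="Blues", annot=matrix.roles.to_numpy(),
                fmt="", linewidths=0.4, linecolor="#dddddd",
                cbar_kws={"label": matrix.metric})
    ax.set_xlabel("morbidity")
    ax.set_ylabel("rule")
    ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_comorbidity_histogram(summary: ingest.DistributionSummary, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    h = summary.histogram
    ax.bar(h["n_comorbidities"], h["count"], color="#4878a8")
    ax2 = ax.twinx()
    ax2.plot(h["n_comorbidities"], 100 * h["proportion"].cumsum(), color="#e07b39", marker=".")
    ax2.set_ylabel("cumulative (%)")
    ax.set_xlabel("number of comorbidities")
    ax.set_ylabel("patients")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mean_comorbidities(summary: ingest.DistributionSummary, path: str | Path,
                            top: int = 10) -> None:
    frame = summary.per_disease.head(top)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(frame["disease"], frame["mean_comorbidities"], color="#4878a8")
    ax.set_ylabel("mean comorbidities among carriers")
    ax.tick_params(axis="x", rotation=60, labelsize=7)
    for label in ax.get_xticklabels():
        label.set_ha("right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``cohort`` (simulate) or ``emr_path`` (read a file) must
    be set.
    """

    cohort: CohortConfig | None = None
    emr_path: str | Path | None = None
    catalog: DiseaseCatalog | None = None
    thresholds: MiningThresholds = field(default_factory=MiningThresholds)
    min_age: int = 65
    pareto_threshold: float = 0.80
    denominator: str = "disease_instances"
    min_cooccurrence: int = 1
    community_seed: int = 0
    resolution: float = 1.0
    mean_count_includes_self: bool = True
    outdir: str | Path = "comopat_out"
    figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw: Mapping = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs and kwargs["cohort"] is not None:
            kwargs["cohort"] = config_from_dict(kwargs["cohort"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = MiningThresholds(**kwargs["thresholds"])
        if "catalog" in kwargs and kwargs["catalog"] is not None:
            kwargs["catalog"] = DiseaseCatalog.from_csv(kwargs["catalog"])
        return cls(**kwargs)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-14s %.3fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict.

    Any stage failure propagates with the stage named in the log.  The
    summary contains the cohort counts, exclusion report, comorbidity-count
    proportions, Pareto head size and coverage, rule counts and metric
    summaries (before and after deduplication), and the community structure.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = config.catalog
    t0 = time.perf_counter()

    if (config.cohort is None) == (config.emr_path is None):
        raise ValueError("set exactly one of cohort (simulate) or emr_path")
    if config.cohort is not None:
        from .synthetic import catalog_for
        catalog = catalog_for(config.cohort, base=catalog)
        records = generate_cohort(config.cohort)
        ingest.write_emr(records, outdir / "cohort.csv")
    else:
        catalog = catalog or DiseaseCatalog.default()
        records = ingest.read_emr(config.emr_path)
    t0 = _stage("load", t0)

    kept, report = ingest.filter_cohort(records, catalog, min_age=config.min_age)
    tdb = ingest.build_transactions(kept, catalog)
    tdb.to_basket_text(outdir / "transactions.txt")
    t0 = _stage("ingest", t0)

    dist = ingest.comorbidity_distribution(tdb, include_self=config.mean_count_includes_self)
    dist.histogram.to_csv(outdir / "comorbidity_histogram.csv", index=False)
    dist.per_disease.to_csv(outdir / "per_disease.csv", index=False)
    t0 = _stage("distribution", t0)

    ranked = pareto.rank_diseases(tdb, denominator=config.denominator)
    head = pareto.pareto_head(ranked, threshold=config.pareto_threshold)
    pareto.write_ranked_csv(head, outdir / "ranked.csv")
    t0 = _stage("pareto", t0)

    rules = mining.mine_rules(tdb, config.thresholds)
    dedup = mining.dedupe_by_itemset(rules)
    mining.write_rules_csv(rules, outdir / "rules.csv")
    mining.write_rules_csv(dedup.kept, outdir / "rules_dedup.csv")
    mining.write_rules_json(dedup.kept, outdir / "rules_dedup.json")
    if not rules:
        logger.warning("no rule passed the thresholds %s", config.thresholds)
    t0 = _stage("mine", t0)

    summary_net: dict = {}
    if head.head:
        net = network.build_network(tdb, head.head,
                                    min_cooccurrence=config.min_cooccurrence,
                                    catalog=catalog)
        partition = network.detect_communities(net, rng_seed=config.community_seed,
                                               resolution=config.resolution)
        chapters = network.chapter_partition(net)
        network.annotate_communities(net, partition)
        net.to_graphml(outdir / "network.graphml")
        net.to_gexf(outdir / "network.gexf")
        net.edge_list_frame().to_csv(outdir / "network_edges.csv", index=False)
        summary_net = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "n_communities": partition.n_communities,
            "modularity_q": partition.modularity_q,
            "communities": [sorted(c) for c in partition.communities()],
            "chapter_partition_q": chapters.modularity_q,
            "n_chapters": chapters.n_communities,
        }
    t0 = _stage("network", t0)

    heatmap_paths = []
    for metric in ("support", "confidence", "lift"):
        matrix = make_heatmaps(dedup.kept, metric,
                               column_order=[c for c in head.head
                                             if any(c in r.itemset for r in dedup.kept)])
        matrix.values.to_csv(outdir / f"heatmap_{metric}.csv")
        if config.figures and not matrix.values.empty:
            render_heatmap(matrix, outdir / f"heatmap_{metric}.png")
            heatmap_paths.append(f"heatmap_{metric}.png")
    if config.figures:
        plot_comorbidity_histogram(dist, outdir / "comorbidity_histogram.png")
        plot_mean_comorbidities(dist, outdir / "mean_comorbidities.png")
        pareto.plot_pareto(head, outdir / "pareto.png")
    t0 = _stage("render", t0)

    summary = {
        "n_records_in": report.n_input,
        "exclusions": report.as_dict(),
        "n_patients": tdb.n_patients,
        "comorbidity_proportions": {
            int(r.n_comorbidities): r.proportion for r in dist.histogram.itertuples(index=False)},
        "share_with_comorbidity": float(
            1.0 - dist.histogram.loc[dist.histogram["n_comorbidities"] == 0, "proportion"].sum()),
        "pareto": {
            "threshold": head.threshold,
            "denominator": config.denominator,
            "head_size": head.head_size,
            "coverage": head.coverage,
            "head": head.head,
        },
        "rules": {
            "n_rules": len(rules),
            "n_after_dedup": len(dedup.kept),
            "n_itemset_groups": dedup.n_groups,
            "summary": mining.summarize_rules(rules).as_dict(),
            "summary_dedup": mining.summarize_rules(dedup.kept).as_dict(),
        },
        "network": summary_net,
        "parameters": {
            "thresholds": {
                "min_support": config.thresholds.min_support,
                "min_confidence": config.thresholds.min_confidence,
                "min_lift": config.thresholds.min_lift,
                "max_itemset_size": config.thresholds.max_itemset_size,
            },
            "min_age": config.min_age,
            "min_cooccurrence": config.min_cooccurrence,
            "community_seed": config.community_seed,
            "resolution": config.resolution,
            "rng_seed": None if config.cohort is None else config.cohort.rng_seed,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
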