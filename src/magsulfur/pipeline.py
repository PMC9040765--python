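"""End-to-end pipeline: load the five input tables, run every analysis
stage, and write a tabular report bundle.

Outputs are TSVs with a header row and a leading provenance comment (tool
version and the SHA-256 of the rule set in force), so reruns on identical
inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import annotations, lineage_metabolism, sulfur_rules, taxonomy, transcription

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_table: Path
    reference_counts: Path
    gene_hits: Path
    ko_table: Path
    tpm_table: Path
    out_dir: Path
    rules_path: Optional[Path] = None
    pathways_path: Optional[Path] = None
    score_threshold: float = annotations.DEFAULT_SCORE_THRESHOLD
    decimals: int = 2

    def validate(self) -> None:
        for p in (
            self.genome_table,
            self.reference_counts,
            self.gene_hits,
            self.ko_table,
            self.tpm_table,
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.score_threshold < 0:
            raise ValueError("score threshold must be non-negative")


@dataclass
class ReportBundle:
    out_dir: Path
    paths: dict[str, Path] = field(default_factory=dict)
    novelty: dict[str, taxonomy.NoveltySummary] = field(default_factory=dict)
    capability_summary: dict[str, sulfur_rules.HabitatSummary] = field(
        default_factory=dict
    )
    partition: Optional[taxonomy.FamilyPartition] = None


def _rules_checksum(rules_path: Optional[Path]) -> str:
    if rules_path is None:
        data = (resources.files("magsulfur") / "data" / "sulfur_rules.yaml").read_bytes()
    else:
        data = Path(rules_path).read_bytes()
    return hashlib.sha256(data).hexdigest()[:16]


def _write(path: Path, df: pd.DataFrame, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(provenance)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run all stages and write the report bundle; returns in-memory results.

    An empty habitat (e.g. no water genomes) simply produces no rows for the
    habitat-specific sections; the rest of the report is complete.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = (
        f"# magsulfur {__version__}; rules sha256:{_rules_checksum(config.rules_path)}\n"
    )
    bundle = ReportBundle(out_dir=out)

    genomes, rejected = taxonomy.load_genome_table(config.genome_table)
    if rejected:
        logger.warning("%d genomes rejected at load", len(rejected))
    ref = taxonomy.ReferenceTaxonCounts.from_tsv(config.reference_counts)
    by_habitat = {
        h: [g for g in genomes if g.habitat == h] for h in ("sediment", "water")
    }

    # --- novelty summaries (per habitat, per rank) ----------------------
    rows = []
    for habitat, members in by_habitat.items():
        if not members:
            logger.info("no %s genomes; skipping novelty section", habitat)
            continue
        for rank in ("phylum", "class", "order", "family"):
            s = taxonomy.novelty_summary(members, ref, rank, config.decimals)
            bundle.novelty[f"{habitat}:{rank}"] = s
            rows.append(
                {
                    "habitat": habitat,
                    "rank": rank,
                    "n_genomes": s.n_genomes,
                    "n_genomes_novel": s.n_genomes_novel,
                    "n_genomes_rare": s.n_genomes_rare,
                    "pct_novel": s.pct_novel,
                    "pct_rare": s.pct_rare,
                    "pct_combined": s.pct_combined,
                    "n_taxa_novel": s.n_taxa_novel,
                    "n_taxa_rare": s.n_taxa_rare,
                    "n_taxa_abundant": s.n_taxa_abundant,
                }
            )
    path = out / "novelty_summary.tsv"
    _write(path, pd.DataFrame(rows), provenance)
    bundle.paths["novelty_summary"] = path

    # --- order-level database enrichment --------------------------------
    rows = []
    order_counts: dict[str, int] = {}
    for g in genomes:
        order_counts[g.taxonomy.order] = order_counts.get(g.taxonomy.order, 0) + 1
    for order in sorted(order_counts):
        enrichment = taxonomy.database_enrichment(order, order_counts[order], ref)
        rows.append(
            {
                "order": order,
                "n_study_genomes": order_counts[order],
                "n_reference_genomes": ref.count("order", order),
                "pct_enrichment": "undefined_novel" if enrichment is None else
                round(enrichment, 4),
            }
        )
    path = out / "database_enrichment.tsv"
    _write(path, pd.DataFrame(rows), provenance)
    bundle.paths["database_enrichment"] = path

    # --- sediment/water family partition --------------------------------
    bundle.partition = taxonomy.shared_family_partition(
        by_habitat["sediment"], by_habitat["water"]
    )
    path = out / "family_partition.tsv"
    _write(
        path,
        pd.DataFrame(
            [
                {
                    "n_water_shared": bundle.partition.n_water_shared,
                    "n_water_specific": bundle.partition.n_water_specific,
                    "n_water_total": bundle.partition.n_water_shared
                    + bundle.partition.n_water_specific,
                }
            ]
        ),
        provenance,
    )
    bundle.paths["family_partition"] = path

    # --- capability calls and summaries ----------------------------------
    ruleset = sulfur_rules.load_ruleset(config.rules_path)
    presence = annotations.load_hits(config.gene_hits, config.score_threshold)
    calls = sulfur_rules.call_collection(genomes, presence, ruleset)
    path = out / "capability_calls.tsv"
    _write(
        path,
        pd.DataFrame(
            [
                {
                    "genome_id": c.genome_id,
                    "capability": c.capability,
                    "direction": c.direction,
                    "evidence": ",".join(sorted(c.evidence)),
                    "suppressed_by": c.suppressed_by or "",
                    "annotations": ",".join(c.annotations),
                }
                for c in calls
            ]
        ),
        provenance,
    )
    bundle.paths["capability_calls"] = path

    bundle.capability_summary = sulfur_rules.summarize_calls(calls, genomes)
    rows = []
    for habitat, summary in bundle.capability_summary.items():
        for cap, stats in summary.per_capability.items():
            rows.append(
                {
                    "habitat": habitat,
                    "capability": cap,
                    "n_genomes": stats.n_genomes,
                    "n_phyla": stats.n_phyla,
                    "n_classes": stats.n_classes,
                    "n_orders": stats.n_orders,
                    "n_families": stats.n_families,
                }
            )
        for label, cp in (
            ("any_reductive", summary.reductive_any),
            ("any_oxidative", summary.oxidative_any),
        ):
            rows.append(
                {
                    "habitat": habitat,
                    "capability": label,
                    "n_genomes": cp.n,
                    "n_phyla": "",
                    "n_classes": "",
                    "n_orders": "",
                    "n_families": f"{cp.n}/{cp.denominator}={cp.pct}%",
                }
            )
    path = out / "capability_summary.tsv"
    _write(path, pd.DataFrame(rows), provenance)
    bundle.paths["capability_summary"] = path

    # --- lineage-level pathway matrix ------------------------------------
    groups = lineage_metabolism.build_lineage_groups(genomes)
    ko_sets = annotations.load_ko_table(config.ko_table)
    pathways = lineage_metabolism.load_pathways(config.pathways_path)
    matrix = lineage_metabolism.lineage_capability_matrix(groups, ko_sets, pathways)
    path = out / "lineage_pathways.tsv"
    with open(path, "w") as fh:
        fh.write(provenance)
        matrix.to_csv(fh, sep="\t", index_label="lineage")
    bundle.paths["lineage_pathways"] = path
    path = out / "lineage_category_summary.tsv"
    _write(path, lineage_metabolism.category_summary(matrix, pathways), provenance)
    bundle.paths["lineage_category_summary"] = path

    # --- transcription ----------------------------------------------------
    abundances = transcription.load_abundances(config.tpm_table)
    genome_phylum = {g.genome_id: g.taxonomy.phylum for g in genomes}
    agg = transcription.aggregate_tpm(
        abundances, transcription.DEFAULT_GENE_GROUPS, genome_phylum
    )
    path = out / "transcription_by_phylum.tsv"
    _write(path, agg.table, provenance)
    bundle.paths["transcription_by_phylum"] = path
    rows = [
        {"sample_id": sample, "group": group, "tpm_total": total}
        for sample, totals in sorted(agg.group_totals.items())
        for group, total in sorted(totals.items())
    ]
    path = out / "transcription_group_totals.tsv"
    _write(path, pd.DataFrame(rows), provenance)
    bundle.paths["transcription_group_totals"] = path

    return bundle
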