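"""Lineage-level metabolic pathway inference from KO annotations.

Genomes are grouped into lineages by a size rule: every order with five or
fewer study genomes forms one order-level group; orders with more than five
genomes split into family-level groups. A pathway is called present in a
lineage when **at least one member genome** carries at least 80% of the
pathway's KOs (the per-genome maximum — KO sets are never pooled across
members). Completeness is compared with exact rational arithmetic, so 8 of
10 KOs is exactly at the threshold and passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .taxonomy import GenomeRecord

#: Orders with more than this many study genomes split into family groups.
ORDER_GROUP_MAX_GENOMES = 5

DEFAULT_THRESHOLD = Fraction(4, 5)


@dataclass(frozen=True)
class PathwayDef:
    """A named KO set with a completeness threshold and a substrate category."""

    name: str
    kos: frozenset[str]
    threshold: Fraction = DEFAULT_THRESHOLD
    category: str = "uncategorized"

    def __post_init__(self) -> None:
        if not self.kos:
            raise ValueError(f"pathway {self.name}: empty KO set")
        if not 0 < self.threshold <= 1:
            raise ValueError(f"pathway {self.name}: threshold must be in (0, 1]")


@dataclass(frozen=True)
class LineageGroup:
    rank: str  # "order" or "family"
    taxon: str
    genome_ids: tuple[str, ...]

    @property
    def key(self) -> tuple[str, str]:
        return (self.rank, self.taxon)


def load_pathways(path=None) -> list[PathwayDef]:
    """Load pathway definitions from YAML; default is the shipped
    illustrative set (real analyses should supply curated KO lists)."""
    if path is None:
        text = (resources.files("magsulfur") / "data" / "pathways.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    out = []
    for d in doc["pathways"]:
        threshold = (
            Fraction(str(d["threshold"])) if "threshold" in d else DEFAULT_THRESHOLD
        )
        out.append(
            PathwayDef(
                name=d["name"],
                kos=frozenset(d["kos"]),
                threshold=threshold,
                category=d.get("category", "uncategorized"),
            )
        )
    return out


def build_lineage_groups(genomes: Sequence[GenomeRecord]) -> list[LineageGroup]:
    """Partition a genome collection into order- or family-level groups.

    Placeholder order/family names are names: genomes in novel lineages group
    under their placeholder. Every genome lands in exactly one group.
    """
    by_order: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        by_order.setdefault(g.taxonomy.order, []).append(g)
    groups: list[LineageGroup] = []
    for order in sorted(by_order):
        members = by_order[order]
        if len(members) <= ORDER_GROUP_MAX_GENOMES:
            groups.append(
                LineageGroup(
                    rank="order",
                    taxon=order,
                    genome_ids=tuple(sorted(g.genome_id for g in members)),
                )
            )
        else:
            by_family: dict[str, list[str]] = {}
            for g in members:
                by_family.setdefault(g.taxonomy.family, []).append(g.genome_id)
            for family in sorted(by_family):
                groups.append(
                    LineageGroup(
                        rank="family",
                        taxon=family,
                        genome_ids=tuple(sorted(by_family[family])),
                    )
                )
    return groups


@dataclass(frozen=True)
class PathwayPresence:
    pathway: str
    present: bool
    best_genome: str
    completeness: Fraction  # of the best genome


def pathway_presence(
    group: LineageGroup,
    ko_sets: Mapping[str, set[str]],
    pathway: PathwayDef,
) -> PathwayPresence:
    """Present iff some member genome covers >= threshold of the pathway KOs.

    The comparison is inclusive and exact-rational: a genome with 8 of 10
    KOs sits exactly at the default 80% threshold and counts as present,
    while 79 of 100 does not.
    """
    if not group.genome_ids:
        raise ValueError(f"empty lineage group {group.key}")
    best_genome = group.genome_ids[0]
    best = Fraction(0)
    for gid in group.genome_ids:
        frac = Fraction(len(pathway.kos & ko_sets.get(gid, set())), len(pathway.kos))
        if frac > best:
            best, best_genome = frac, gid
    return PathwayPresence(
        pathway=pathway.name,
        present=best >= pathway.threshold,
        best_genome=best_genome,
        completeness=best,
    )


def lineage_capability_matrix(
    groups: Sequence[LineageGroup],
    ko_sets: Mapping[str, set[str]],
    pathways: Sequence[PathwayDef],
) -> pd.DataFrame:
    """Boolean lineage x pathway presence matrix.

    Rows are indexed ``rank:taxon``; columns are pathway names.
    """
    index = [f"{g.rank}:{g.taxon}" for g in groups]
    data = {
        p.name: [pathway_presence(g, ko_sets, p).present for g in groups]
        for p in pathways
    }
    return pd.DataFrame(data, index=index)


def category_summary(
    matrix: pd.DataFrame, pathways: Sequence[PathwayDef]
) -> pd.DataFrame:
    """Per substrate category: lineages with >= 1 present pathway, and the
    fraction of all lineages. Backs statements like "x% of lineages can use
    sugars"."""
    rows = []
    n_lineages = len(matrix)
    for category in sorted({p.category for p in pathways}):
        cols = [p.name for p in pathways if p.category == category]
        n_with = int(matrix[cols].any(axis=1).sum()) if n_lineages else 0
        rows.append(
            {
                "category": category,
                "n_lineages": n_with,
                "n_total": n_lineages,
                "fraction": (n_with / n_lineages) if n_lineages else 0.0,
            }
        )
    return pd.DataFrame(rows)
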