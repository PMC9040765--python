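"""GTDB-style taxonomy handling and novelty/rarity classification.

A genome's placement is a seven-rank string (``d__;p__;c__;o__;f__;g__;s__``).
Each taxon is compared against the number of genomes the reference database
holds for it:

* **novel** — no genomes in the reference (count 0), including explicit
  novel-lineage placeholders (``ZNC``/``ZNO``/``ZNF``-style names);
* **rare** (lineage of rare distribution, LRD) — 1 to 5 reference genomes;
* **abundant** — 6 or more reference genomes.

The module also computes summary statistics over a genome collection:
percentages of genomes in novel/rare taxa at a rank, database enrichment of
an order, the mean relative evolutionary divergence (RED) of supplied values,
and the sediment/water shared-family partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._util import percent, round_half_up

logger = logging.getLogger(__name__)

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Prefix used for auto-generated novel-lineage placeholder names per rank.
PLACEHOLDER_CODES: dict[str, str] = {
    "phylum": "ZNP",
    "class": "ZNC",
    "order": "ZNO",
    "family": "ZNF",
    "genus": "ZNG",
    "species": "ZNS",
}

#: A taxon with this many reference genomes or fewer (but at least one) is
#: classified as rare/LRD; zero reference genomes means novel.
RARE_MAX_GENOMES = 5

#: Median RED value used by the reference taxonomy for designating a novel
#: family; exposed as the comparison constant for mean-RED reports.
NOVEL_FAMILY_RED_MEDIAN = 0.77

#: Genomes with contamination above this percentage are rejected at load.
MAX_CONTAMINATION = 10.0


class TaxonomyParseError(ValueError):
    """Raised for malformed taxonomy strings, naming the offending token."""


class EmptyCollectionError(ValueError):
    """Raised when a summary is requested over an empty genome collection."""


class NoRedValuesError(ValueError):
    """Raised when no genome in the collection carries a RED value."""


class NoveltyStatus(str, Enum):
    NOVEL = "novel"
    RARE = "rare"
    ABUNDANT = "abundant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def is_placeholder_name(name: str, rank: str) -> bool:
    """True if *name* is a novel-lineage placeholder token for *rank*."""
    code = PLACEHOLDER_CODES.get(rank)
    if code is None:
        return False
    return name == code or name.startswith(code + "-")


@dataclass(frozen=True)
class RankedTaxonomy:
    """A seven-rank lineage; unnamed trailing ranks hold placeholder names.

    Placeholder names are real names (they group genomes, serialize, and
    classify as novel); they are distinguished only by their ``ZN*`` prefix.
    """

    names: tuple[str, str, str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise TaxonomyParseError(f"expected {len(RANKS)} ranks, got {len(self.names)}")
        seen_placeholder = False
        for rank, name in zip(RANKS, self.names):
            if not name:
                raise TaxonomyParseError(f"empty name at rank {rank}")
            if self.is_placeholder(rank):
                seen_placeholder = True
            elif seen_placeholder:
                raise TaxonomyParseError(
                    f"named rank {rank} ({name!r}) below a placeholder rank"
                )

    # -- rank accessors -------------------------------------------------
    @property
    def domain(self) -> str:
        return self.names[0]

    @property
    def phylum(self) -> str:
        return self.names[1]

    @property
    def class_(self) -> str:
        return self.names[2]

    @property
    def order(self) -> str:
        return self.names[3]

    @property
    def family(self) -> str:
        return self.names[4]

    @property
    def genus(self) -> str:
        return self.names[5]

    @property
    def species(self) -> str:
        return self.names[6]

    def name_at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    def is_placeholder(self, rank: str) -> bool:
        return is_placeholder_name(self.name_at(rank), rank)

    def serialize(self) -> str:
        """Full seven-token ``d__...;s__...`` form; inverts :func:`parse_taxonomy`."""
        return ";".join(p + n for p, n in zip(RANK_PREFIXES, self.names))

    def __str__(self) -> str:
        return self.serialize()


def parse_taxonomy(taxonomy_string: str) -> RankedTaxonomy:
    """Parse a 1-7 token GTDB-style string into a :class:`RankedTaxonomy`.

    Missing or empty trailing ranks become novel placeholders named after the
    deepest named ancestor (e.g. ``ZNF-<order>`` for a missing family), so a
    truncated lineage still yields unique, classifiable taxon names.
    Serializing the result and re-parsing is lossless.
    """
    if not taxonomy_string or not taxonomy_string.strip():
        raise TaxonomyParseError("empty taxonomy string")
    tokens = [t.strip() for t in taxonomy_string.strip().split(";")]
    if len(tokens) > len(RANKS):
        raise TaxonomyParseError(
            f"too many rank tokens ({len(tokens)}) in {taxonomy_string!r}"
        )
    names: list[str] = []
    for i, token in enumerate(tokens):
        prefix = RANK_PREFIXES[i]
        if not token.startswith(prefix):
            raise TaxonomyParseError(
                f"token {token!r} at position {i + 1}: expected prefix {prefix!r}"
            )
        names.append(token[len(prefix):])
    if not names or not names[0]:
        raise TaxonomyParseError(f"domain missing in {taxonomy_string!r}")

    # Fill empty tokens and missing trailing ranks with placeholders carrying
    # the deepest named parent.
    deepest = names[0]
    filled: list[str] = []
    for i, rank in enumerate(RANKS):
        name = names[i] if i < len(names) else ""
        if name and not is_placeholder_name(name, rank):
            # A real name may not appear below a generated placeholder; the
            # dataclass validator enforces this after filling.
            filled.append(name)
            deepest = name
        elif name:
            filled.append(name)
        else:
            filled.append(f"{PLACEHOLDER_CODES[rank]}-{deepest}")
    return RankedTaxonomy(tuple(filled))  # type: ignore[arg-type]


@dataclass(frozen=True)
class GenomeRecord:
    """One metagenome-assembled genome with habitat, taxonomy and QC data."""

    genome_id: str
    habitat: str  # "sediment" or "water"
    taxonomy: RankedTaxonomy
    completeness: float
    contamination: float
    red: Optional[float] = None

    def __post_init__(self) -> None:
        if self.habitat not in ("sediment", "water"):
            raise ValueError(f"{self.genome_id}: unknown habitat {self.habitat!r}")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.genome_id}: completeness out of bounds")
        if not 0.0 <= self.contamination <= 100.0:
            raise ValueError(f"{self.genome_id}: contamination out of bounds")
        if self.red is not None and not 0.0 <= self.red <= 1.0:
            raise ValueError(f"{self.genome_id}: RED must be a 0-1 fraction")


@dataclass
class ReferenceTaxonCounts:
    """(rank, taxon name) -> number of genomes in the reference database.

    Lookups of absent taxa return 0 (the novel case), never an error.
    """

    entries: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (rank, taxon), count in self.entries.items():
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r} for taxon {taxon!r}")
            if count < 0:
                raise ValueError(f"negative reference count for {rank} {taxon!r}")

    def count(self, rank: str, taxon: str) -> int:
        return self.entries.get((rank, taxon), 0)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTaxonCounts":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"rank": str, "taxon": str})
        required = {"rank", "taxon", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"reference counts table needs columns {sorted(required)}")
        entries = {
            (str(r["rank"]), str(r["taxon"])): int(r["count"]) for _, r in df.iterrows()
        }
        return cls(entries)


@dataclass(frozen=True)
class NoveltyCall:
    """Status of one taxon (or one genome's taxon) at one rank."""

    subject: str
    rank: str
    status: NoveltyStatus


def classify_taxon(taxon: str, rank: str, ref: ReferenceTaxonCounts) -> NoveltyCall:
    """Classify one taxon as novel / rare / abundant from its reference count.

    Count 0 (including any placeholder name) is novel; 1-5 is rare; 6 or more
    is abundant. The three statuses are mutually exclusive and exhaustive.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if is_placeholder_name(taxon, rank):
        status = NoveltyStatus.NOVEL
    else:
        n = ref.count(rank, taxon)
        if n == 0:
            status = NoveltyStatus.NOVEL
        elif n <= RARE_MAX_GENOMES:
            status = NoveltyStatus.RARE
        else:
            status = NoveltyStatus.ABUNDANT
    return NoveltyCall(subject=taxon, rank=rank, status=status)


#: Ranks included in a per-genome novelty profile.
PROFILE_RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")


def genome_novelty_profile(
    genome: GenomeRecord, ref: ReferenceTaxonCounts
) -> dict[str, NoveltyStatus]:
    """One status per rank below domain; ranks are classified independently."""
    return {
        rank: classify_taxon(genome.taxonomy.name_at(rank), rank, ref).status
        for rank in PROFILE_RANKS
    }


@dataclass(frozen=True)
class NoveltySummary:
    rank: str
    n_genomes: int
    n_genomes_novel: int
    n_genomes_rare: int
    pct_novel: float
    pct_rare: float
    pct_combined: float
    n_taxa_novel: int
    n_taxa_rare: int
    n_taxa_abundant: int


def novelty_summary(
    genomes: Sequence[GenomeRecord],
    ref: ReferenceTaxonCounts,
    rank: str = "family",
    decimals: int = 2,
) -> NoveltySummary:
    """Genome and distinct-taxon counts per status at *rank*.

    Percentages are 100 * count / total, rounded half-up; the combined
    percentage is computed from the combined count, not from rounded parts.
    """
    if not genomes:
        raise EmptyCollectionError("novelty_summary of an empty genome collection")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    by_status: dict[NoveltyStatus, set[str]] = {s: set() for s in NoveltyStatus}
    n_novel = n_rare = 0
    for g in genomes:
        taxon = g.taxonomy.name_at(rank)
        status = classify_taxon(taxon, rank, ref).status
        by_status[status].add(taxon)
        if status is NoveltyStatus.NOVEL:
            n_novel += 1
        elif status is NoveltyStatus.RARE:
            n_rare += 1
    total = len(genomes)
    return NoveltySummary(
        rank=rank,
        n_genomes=total,
        n_genomes_novel=n_novel,
        n_genomes_rare=n_rare,
        pct_novel=percent(n_novel, total, decimals),
        pct_rare=percent(n_rare, total, decimals),
        pct_combined=percent(n_novel + n_rare, total, decimals),
        n_taxa_novel=len(by_status[NoveltyStatus.NOVEL]),
        n_taxa_rare=len(by_status[NoveltyStatus.RARE]),
        n_taxa_abundant=len(by_status[NoveltyStatus.ABUNDANT]),
    )


def database_enrichment(
    taxon: str,
    study_count: int,
    ref: ReferenceTaxonCounts,
    rank: str = "order",
) -> Optional[float]:
    """Study genomes of a taxon as a percentage of its reference genomes.

    Returns ``None`` when the taxon has no reference genomes (a novel order
    has no defined enrichment).
    """
    if study_count < 0:
        raise ValueError("study_count must be non-negative")
    ref_count = ref.count(rank, taxon)
    if ref_count == 0:
        return None
    return 100.0 * study_count / ref_count


@dataclass(frozen=True)
class MeanRed:
    value: float
    n_used: int
    n_missing: int


def mean_red(genomes: Iterable[GenomeRecord], decimals: int = 2) -> MeanRed:
    """Arithmetic mean of the supplied RED values, to *decimals* places.

    Genomes without a RED value are excluded and their count reported.
    """
    reds = [g.red for g in genomes if g.red is not None]
    n_missing = sum(1 for g in genomes if g.red is None)
    if not reds:
        raise NoRedValuesError("no genome carries a RED value")
    return MeanRed(
        value=round_half_up(sum(reds) / len(reds), decimals),
        n_used=len(reds),
        n_missing=n_missing,
    )


@dataclass(frozen=True)
class FamilyPartition:
    n_water_shared: int
    n_water_specific: int
    shared_families: tuple[str, ...]
    water_specific_families: tuple[str, ...]


def shared_family_partition(
    sediment: Sequence[GenomeRecord], water: Sequence[GenomeRecord]
) -> FamilyPartition:
    """Partition water genomes by whether their family occurs in the sediment.

    ``n_water_shared + n_water_specific`` always equals the water genome
    count.
    """
    sediment_families = {g.taxonomy.family for g in sediment}
    shared: set[str] = set()
    specific: set[str] = set()
    n_shared = n_specific = 0
    for g in water:
        fam = g.taxonomy.family
        if fam in sediment_families:
            n_shared += 1
            shared.add(fam)
        else:
            n_specific += 1
            specific.add(fam)
    return FamilyPartition(
        n_water_shared=n_shared,
        n_water_specific=n_specific,
        shared_families=tuple(sorted(shared)),
        water_specific_families=tuple(sorted(specific)),
    )


def load_genome_table(path) -> tuple[list[GenomeRecord], list[tuple[str, str]]]:
    """Read the genome metadata TSV; returns (records, rejected).

    Rejected rows (contamination above :data:`MAX_CONTAMINATION`) are logged
    with their reason rather than silently dropped. Duplicate genome ids and
    out-of-bound QC values are hard errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"genome_id", "habitat", "taxonomy", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome table missing columns: {sorted(missing)}")
    records: list[GenomeRecord] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gid = row["genome_id"]
        if gid in seen:
            raise ValueError(f"duplicate genome_id {gid!r}")
        seen.add(gid)
        contamination = float(row["contamination"])
        if contamination > MAX_CONTAMINATION:
            reason = f"contamination {contamination} > {MAX_CONTAMINATION}%"
            logger.warning("rejecting genome %s: %s", gid, reason)
            rejected.append((gid, reason))
            continue
        red_cell = row["red"] if "red" in df.columns else ""
        records.append(
            GenomeRecord(
                genome_id=gid,
                habitat=row["habitat"],
                taxonomy=parse_taxonomy(row["taxonomy"]),
                completeness=float(row["completeness"]),
                contamination=contamination,
                red=float(red_cell) if red_cell != "" else None,
            )
        )
    return records, rejected
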