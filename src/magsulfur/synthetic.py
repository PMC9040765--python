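"""Seeded synthetic fixture generation for every pipeline input table.

The generator plants known structure — taxonomy rosters with a chosen
novelty composition, minimal gene complements satisfying chosen capability
rules (plus harmless decoy and sub-threshold noise hits), KO sets at chosen
pathway completeness, and TPM tables with chosen group ratios — and writes
the five input TSVs together with a ground-truth manifest, so every
pipeline stage can be tested against what was planted.

The packaged :func:`headline_fixture` encodes the study conditions of the
spring survey this package models: 516 sediment genomes of which 132 sit in
97 novel families and 208 in 113 rare families; 149 sediment genomes with
at least one reductive or disproportionating sulfur capability (18 sulfate,
104 Asr, 8 Dsr-only, 20 Psr, 11 Phs, and a tetrathionate union of 105 from
73 Otr / 68 Ttr / 36 both); 114 water genomes, 62 in sediment-shared
families and 52 water-specific, 59 of them oxidative; and an Asr:Dsr
transcription ratio of 4.

Planted gene sets are minimal satisfying sets; every plant is verified at
generation time by running the capability rule engine, so a contradictory
plant (e.g. a taxon-excluded capability) fails generation with the conflict
named.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotations import VOCABULARY
from .lineage_metabolism import load_pathways
from .sulfur_rules import RuleSet, call_genome, load_ruleset
from .taxonomy import GenomeRecord, parse_taxonomy

#: Gene complements emitted per plant token. Each satisfies exactly one
#: branch of one shipped rule (or contributes evidence, like "hdr").
PLANT_GENES: dict[str, frozenset[str]] = {
    "sulfate": frozenset(
        {"Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC", "DsrA", "DsrB", "DsrC"}
    ),
    "asr": frozenset({"AsrA", "AsrB", "AsrC"}),
    "hdr": frozenset({"HdrA", "HdrB", "HdrC"}),
    "dsr": frozenset({"DsrA", "DsrB", "DsrC", "DsrK", "DsrM", "DsrJ"}),
    "psr": frozenset({"PsrA", "PsrB", "PsrC"}),
    "phs": frozenset({"PhsA", "PhsB", "PhsC"}),
    "soe": frozenset({"SoeA", "SoeB", "SoeC"}),
    "otr": frozenset({"Otr"}),
    "ttr": frozenset({"TtrA", "TtrB", "TtrC"}),
    "hyd": frozenset({"HydA", "HydB", "HydC", "HydD"}),
    "sox": frozenset({"SoxA", "SoxX", "SoxB", "SoxY", "SoxZ", "SoxC", "SoxD"}),
    "sqr": frozenset({"Sqr"}),
    "dsrabc": frozenset({"DsrA", "DsrB", "DsrC"}),
    "sor": frozenset({"SorA", "SorB"}),
    "tsda": frozenset({"TsdA"}),
    "teth": frozenset({"TetH"}),
}

#: Decoy symbols are accessory subunits referenced by no rule requirement,
#: so adding them above threshold can never create or destroy a call.
DECOY_SYMBOLS: tuple[str, ...] = ("DsrD", "DsrE", "DsrF", "DsrH")


class FixtureGenerationError(ValueError):
    """A planted fact could not be reproduced by the pipeline stage."""


@dataclass(frozen=True)
class FamilySpec:
    """One family in the roster, with its lineage, reference count, and the
    number of sediment/water genomes planted in it."""

    family: str
    order: str
    class_: str
    phylum: str
    ref_count: int
    n_sediment: int = 0
    n_water: int = 0
    domain: str = "Bacteria"

    def taxonomy_string(self) -> str:
        return (
            f"d__{self.domain};p__{self.phylum};c__{self.class_};"
            f"o__{self.order};f__{self.family}"
        )


@dataclass(frozen=True)
class TpmEntry:
    """Plant ``tpm_per_row`` for each (genome index, gene) pair, per sample."""

    genes: tuple[str, ...]
    genome_indices: tuple[int, ...]
    tpm_per_row: float
    habitat: str = "sediment"


@dataclass(frozen=True)
class KoPlant:
    """Give one genome the first *n_kos* KOs of a named default pathway."""

    habitat: str
    genome_index: int
    pathway: str
    n_kos: int


@dataclass
class FixtureConfig:
    name: str
    seed: int
    families: list[FamilySpec]
    #: sediment/water genome index (enumeration order over the roster)
    #: -> plant tokens from :data:`PLANT_GENES`.
    sediment_plants: dict[int, tuple[str, ...]] = field(default_factory=dict)
    water_plants: dict[int, tuple[str, ...]] = field(default_factory=dict)
    #: expected *active* capability calls per planted genome, stated
    #: independently of the rule engine and checked against it.
    expected_sediment: dict[int, frozenset[str]] = field(default_factory=dict)
    expected_water: dict[int, frozenset[str]] = field(default_factory=dict)
    tpm_entries: list[TpmEntry] = field(default_factory=list)
    sample_factors: dict[str, float] = field(default_factory=dict)
    ko_plants: list[KoPlant] = field(default_factory=list)
    #: planted lineage-level pathway facts: (order name, pathway, present).
    expected_lineage_pathways: list[tuple[str, str, bool]] = field(default_factory=list)
    decoy_every: int = 7
    noise_every: int = 3

    def validate(self) -> None:
        names = [f.family for f in self.families]
        if len(names) != len(set(names)):
            raise FixtureGenerationError("duplicate family names in roster")
        for f in self.families:
            if min(f.ref_count, f.n_sediment, f.n_water) < 0:
                raise FixtureGenerationError(f"negative count in {f.family}")
        for plants in (self.sediment_plants, self.water_plants):
            for idx, tokens in plants.items():
                unknown = set(tokens) - set(PLANT_GENES)
                if unknown:
                    raise FixtureGenerationError(
                        f"unknown plant tokens {sorted(unknown)} at index {idx}"
                    )


def _planted_genes(tokens: Sequence[str]) -> set[str]:
    genes: set[str] = set()
    for t in tokens:
        genes |= PLANT_GENES[t]
    return genes


def generate(
    config: FixtureConfig,
    out_dir,
    ruleset: Optional[RuleSet] = None,
    verify: bool = True,
) -> dict[str, Path]:
    """Write the five input tables and the ground-truth manifest.

    Same seed and config give byte-identical outputs. When *verify* is true
    (the default), the capability rule engine is run on every planted genome
    and any mismatch with the config's expected calls aborts generation.
    """
    config.validate()
    if ruleset is None:
        ruleset = load_ruleset()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ---- genome roster ------------------------------------------------
    genome_rows: list[tuple[str, str, str, float, float, float]] = []
    sediment_ids: list[str] = []
    water_ids: list[str] = []
    id_taxonomy: dict[str, str] = {}
    for spec in config.families:
        for habitat, n, ids, prefix in (
            ("sediment", spec.n_sediment, sediment_ids, "ZS"),
            ("water", spec.n_water, water_ids, "ZW"),
        ):
            for _ in range(n):
                gid = f"{prefix}{len(ids):04d}"
                ids.append(gid)
                tax = spec.taxonomy_string()
                id_taxonomy[gid] = tax
                completeness = round(float(rng.uniform(70.0, 99.0)), 2)
                contamination = round(float(rng.uniform(0.0, 9.5)), 2)
                red = round(float(np.clip(rng.normal(0.76, 0.03), 0.5, 0.95)), 3)
                genome_rows.append(
                    (gid, habitat, tax, completeness, contamination, red)
                )

    genomes_path = out / "genomes.tsv"
    with open(genomes_path, "w") as fh:
        fh.write("genome_id\thabitat\ttaxonomy\tcompleteness\tcontamination\tred\n")
        for gid, habitat, tax, comp, cont, red in genome_rows:
            fh.write(f"{gid}\t{habitat}\t{tax}\t{comp:.2f}\t{cont:.2f}\t{red:.3f}\n")

    # ---- reference counts --------------------------------------------
    ref_path = out / "reference_counts.tsv"
    with open(ref_path, "w") as fh:
        fh.write("rank\ttaxon\tcount\n")
        for spec in config.families:
            fh.write(f"family\t{spec.family}\t{spec.ref_count}\n")
        order_counts: dict[str, int] = {}
        for spec in config.families:
            order_counts[spec.order] = order_counts.get(spec.order, 0) + spec.ref_count
        for order, count in order_counts.items():
            fh.write(f"order\t{order}\t{count}\n")

    # ---- gene hits ----------------------------------------------------
    hits_path = out / "gene_hits.tsv"
    planted_presence: dict[str, set[str]] = {}
    vocab = list(VOCABULARY)
    with open(hits_path, "w") as fh:
        fh.write("genome_id\tgene_symbol\tbit_score\n")
        for habitat, ids, plants in (
            ("sediment", sediment_ids, config.sediment_plants),
            ("water", water_ids, config.water_plants),
        ):
            for idx, gid in enumerate(ids):
                genes = sorted(_planted_genes(plants.get(idx, ())))
                presence = set(genes)
                if genes and idx % config.decoy_every == 0:
                    decoy = DECOY_SYMBOLS[idx % len(DECOY_SYMBOLS)]
                    genes.append(decoy)
                    presence.add(decoy)
                for j, gene in enumerate(genes):
                    score = float(np.clip(rng.normal(260.0, 50.0), 110.0, 480.0))
                    fh.write(f"{gid}\t{gene}\t{score:.1f}\n")
                    if j == 0 and idx % 5 == 0:
                        # duplicate hit: set semantics downstream
                        score2 = float(np.clip(rng.normal(260.0, 50.0), 110.0, 480.0))
                        fh.write(f"{gid}\t{gene}\t{score2:.1f}\n")
                if idx % config.noise_every == 1:
                    # sub-threshold noise hit; must never reach a presence set
                    sym = vocab[int(rng.integers(0, len(vocab)))]
                    score = float(rng.uniform(20.0, 95.0))
                    fh.write(f"{gid}\t{sym}\t{score:.1f}\n")
                if presence:
                    planted_presence[gid] = presence

    # ---- KO annotations ----------------------------------------------
    pathways = {p.name: p for p in load_pathways()}
    ko_path = out / "ko_annotations.tsv"
    with open(ko_path, "w") as fh:
        fh.write("genome_id\tko\n")
        for plant in config.ko_plants:
            ids = sediment_ids if plant.habitat == "sediment" else water_ids
            gid = ids[plant.genome_index]
            kos = sorted(pathways[plant.pathway].kos)[: plant.n_kos]
            for ko in kos:
                fh.write(f"{gid}\t{ko}\n")

    # ---- transcript abundances ----------------------------------------
    tpm_path = out / "transcript_tpm.tsv"
    sample_factors = config.sample_factors or {"s1": 1.0}
    with open(tpm_path, "w") as fh:
        fh.write("sample_id\tgenome_id\tgene_symbol\ttpm\n")
        for sample, factor in sample_factors.items():
            for entry in config.tpm_entries:
                ids = sediment_ids if entry.habitat == "sediment" else water_ids
                for gi in entry.genome_indices:
                    for gene in entry.genes:
                        fh.write(
                            f"{sample}\t{ids[gi]}\t{gene}\t{entry.tpm_per_row * factor}\n"
                        )

    # ---- generation-time verification ---------------------------------
    expected_calls: dict[str, list[str]] = {}
    for habitat, ids, expected in (
        ("sediment", sediment_ids, config.expected_sediment),
        ("water", water_ids, config.expected_water),
    ):
        for idx, caps in expected.items():
            expected_calls[ids[idx]] = sorted(caps)
    if verify:
        for gid, caps in expected_calls.items():
            record = GenomeRecord(
                genome_id=gid,
                habitat="sediment" if gid.startswith("ZS") else "water",
                taxonomy=parse_taxonomy(id_taxonomy[gid]),
                completeness=90.0,
                contamination=1.0,
            )
            calls = call_genome(record, planted_presence.get(gid, set()), ruleset)
            active = sorted(c.capability for c in calls if c.active)
            if active != caps:
                raise FixtureGenerationError(
                    f"plant conflict on {gid}: expected active calls {caps}, "
                    f"rule engine produced {active}"
                )

    # ---- manifest ------------------------------------------------------
    def _family_status(spec: FamilySpec) -> str:
        if spec.ref_count == 0:
            return "novel"
        if spec.ref_count <= 5:
            return "rare"
        return "abundant"

    sed_specs = [f for f in config.families if f.n_sediment]
    sed_family_names = {f.family for f in sed_specs}
    manifest = {
        "name": config.name,
        "seed": config.seed,
        "sediment": {
            "n_genomes": len(sediment_ids),
            "n_genomes_by_family_status": {
                status: sum(
                    f.n_sediment for f in sed_specs if _family_status(f) == status
                )
                for status in ("novel", "rare", "abundant")
            },
            "n_families_by_status": {
                status: sum(1 for f in sed_specs if _family_status(f) == status)
                for status in ("novel", "rare", "abundant")
            },
        },
        "water": {
            "n_genomes": len(water_ids),
            "n_shared_family_genomes": sum(
                f.n_water for f in config.families if f.family in sed_family_names
            ),
            "n_specific_genomes": sum(
                f.n_water for f in config.families if f.family not in sed_family_names
            ),
        },
        "expected_active_calls": expected_calls,
        "expected_lineage_pathways": [
            list(t) for t in config.expected_lineage_pathways
        ],
        "tpm": {
            "sample_factors": sample_factors,
            "entries": [
                {
                    "genes": list(e.genes),
                    "n_genomes": len(e.genome_indices),
                    "tpm_per_row": e.tpm_per_row,
                }
                for e in config.tpm_entries
            ],
        },
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return {
        "genomes": genomes_path,
        "reference_counts": ref_path,
        "gene_hits": hits_path,
        "ko_annotations": ko_path,
        "transcript_tpm": tpm_path,
        "manifest": manifest_path,
    }


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def headline_fixture(seed: int = 20220308) -> FixtureConfig:
    """The packaged fixture reproducing the survey's headline counts.

    The seed only affects nuisance values (QC numbers, bit scores, noise);
    all planted counts are fixed by construction.
    """
    families: list[FamilySpec] = []

    # 97 novel families (placeholder names, reference count 0) holding 132
    # sediment genomes: 35 families of 2 plus 62 singletons.
    for i in range(97):
        families.append(
            FamilySpec(
                family=f"ZNF-S{i:03d}",
                order=f"OS{i:03d}",
                class_=f"CS{i % 60:02d}",
                phylum=f"P{(i % 32) + 1:02d}",
                ref_count=0,
                n_sediment=2 if i < 35 else 1,
            )
        )
    # 113 rare (LRD) families (reference counts 1-5) holding 208 sediment
    # genomes: 95 families of 2 plus 18 singletons. The first 18 also hold
    # one water genome each (shared families).
    rare_rng = np.random.default_rng(seed + 1)
    for i in range(113):
        families.append(
            FamilySpec(
                family=f"LF{i:03d}",
                order=f"OL{i:03d}",
                class_=f"CL{i % 60:02d}",
                phylum=f"P{(i % 32) + 1:02d}",
                ref_count=int(rare_rng.integers(1, 6)),
                n_sediment=2 if i < 95 else 1,
                n_water=1 if i < 18 else 0,
            )
        )
    # 44 abundant families (reference count >= 6) holding the remaining 176
    # sediment genomes; the first 22 also hold 2 water genomes each.
    for i in range(44):
        families.append(
            FamilySpec(
                family=f"AF{i:02d}",
                order=f"OA{i:02d}",
                class_=f"CA{i % 20:02d}",
                phylum=f"P{(i % 32) + 1:02d}",
                ref_count=int(rare_rng.integers(6, 200)),
                n_sediment=4,
                n_water=2 if i < 22 else 0,
            )
        )
    # 26 water-specific families of 2 genomes each (52 genomes), abundant in
    # the reference, absent from the sediment roster.
    for i in range(26):
        families.append(
            FamilySpec(
                family=f"WF{i:02d}",
                order=f"OW{i:02d}",
                class_=f"CW{i % 10}",
                phylum=f"WP{i % 6}",
                ref_count=int(rare_rng.integers(6, 60)),
                n_water=2,
            )
        )

    # --- sediment capability plants (genome indices 0..148 reductive) ----
    sediment_plants: dict[int, list[str]] = {}
    expected_sediment: dict[int, set[str]] = {}

    def plant(idx: int, *tokens: str) -> None:
        sediment_plants.setdefault(idx, []).extend(tokens)

    for i in range(104):  # Asr system, with the adjacent Hdr locus
        plant(i, "asr", "hdr")
    for i in range(11):  # PhsABC within Asr carriers -> thiosulfate reduction
        plant(i, "phs")
    for i in range(2, 7):  # SoeABC partner -> disproportionation
        plant(i, "soe")
    for i in range(104, 112):  # Dsr-only sulfite reducers
        plant(i, "dsr")
    for i in range(112, 130):  # complete sulfate reduction pathway
        plant(i, "sulfate")
    plant(103, "psr")
    for i in range(130, 149):  # remaining polysulfide reducers
        plant(i, "psr")
    for i in range(20, 57):  # Otr-only tetrathionate reducers (37)
        plant(i, "otr")
    for i in range(57, 93):  # both Otr and Ttr (36)
        plant(i, "otr", "ttr")
    for i in range(93, 125):  # Ttr-only (32)
        plant(i, "ttr")
    for i in range(119):  # sulfurhydrogenase flag, never counted
        plant(i, "hyd")

    for idx, tokens in sediment_plants.items():
        toks = set(tokens)
        exp: set[str] = set()
        if "asr" in toks:
            exp.add("sulfite_reduction_asr")
        if "phs" in toks:
            exp.add("thiosulfate_reduction")
        if "soe" in toks:
            exp.update({"thiosulfate_disproportionation_phs", "sulfite_oxidation"})
        if "dsr" in toks:
            exp.add("sulfite_reduction_dsr")
        if "sulfate" in toks:
            exp.add("sulfate_reduction")
        if "psr" in toks:
            exp.add("polysulfide_reduction")
        if "otr" in toks or "ttr" in toks:
            exp.add("tetrathionate_reduction")
        if "hyd" in toks:
            exp.add("sulfurhydrogenase")
        expected_sediment[idx] = exp

    # --- water capability plants (59 oxidative genomes) ------------------
    water_plants: dict[int, list[str]] = {}
    expected_water: dict[int, set[str]] = {}

    def wplant(idx: int, *tokens: str) -> None:
        water_plants.setdefault(idx, []).extend(tokens)

    for i in range(14):  # complete SOX systems
        wplant(i, "sox")
    wplant(0, "tsda", "teth")
    wplant(1, "tsda")
    for i in range(14, 53):  # Sqr sulfide oxidizers (39)
        wplant(i, "sqr")
    wplant(14, "dsrabc")  # two of them also run Dsr oxidatively
    wplant(15, "dsrabc")
    for i in range(53, 58):  # SoeABC sulfite oxidizers
        wplant(i, "soe")
    wplant(58, "sor")  # SorAB sulfite oxidizer

    for idx, tokens in water_plants.items():
        toks = set(tokens)
        exp = set()
        if "sox" in toks:
            exp.add("sox_complete")
        if "sqr" in toks:
            exp.add("sulfide_oxidation")
        if "dsrabc" in toks and "sqr" in toks:
            exp.add("sulfur_oxidation_rdsr")
        if "soe" in toks or "sor" in toks:
            exp.add("sulfite_oxidation")
        if "tsda" in toks:
            exp.add("thiosulfate_oxidation_tetrathionate")
        if "teth" in toks:
            exp.add("tetrathionate_hydrolysis")
        expected_water[idx] = exp

    # --- transcription plan: Asr group TPM exactly 4x the Dsr group ------
    tpm_entries = [
        TpmEntry(("AsrA", "AsrB", "AsrC"), tuple(range(104)), 4.0),
        TpmEntry(("DsrA", "DsrB", "DsrC"), tuple(range(104, 112)), 13.0),
        TpmEntry(("Sat", "AprA", "AprB"), tuple(range(112, 130)), 2.5),
        TpmEntry(("PsrA", "PsrB", "PsrC"), tuple(range(130, 149)), 1.0),
    ]
    sample_factors = {"morning": 1.0, "afternoon": 1.5, "evening": 0.75}

    # --- KO plants exercising the 80% boundary ---------------------------
    ko_plants = [
        KoPlant("sediment", 0, "hexose_degradation", 8),   # 8/10 -> present
        KoPlant("sediment", 2, "hexose_degradation", 7),   # 7/10 -> absent
        KoPlant("sediment", 4, "amino_acid_catabolism", 10),
        KoPlant("sediment", 6, "scfa_oxidation", 5),
    ]
    expected_lineage_pathways = [
        ("OS000", "hexose_degradation", True),
        ("OS001", "hexose_degradation", False),
        ("OS002", "amino_acid_catabolism", True),
        ("OS003", "scfa_oxidation", False),
    ]

    return FixtureConfig(
        name="zodletone_headline",
        seed=seed,
        families=families,
        sediment_plants={k: tuple(v) for k, v in sediment_plants.items()},
        water_plants={k: tuple(v) for k, v in water_plants.items()},
        expected_sediment={k: frozenset(v) for k, v in expected_sediment.items()},
        expected_water={k: frozenset(v) for k, v in expected_water.items()},
        tpm_entries=tpm_entries,
        sample_factors=sample_factors,
        ko_plants=ko_plants,
        expected_lineage_pathways=expected_lineage_pathways,
    )


def lineage_grouping_fixture(seed: int = 291) -> FixtureConfig:
    """A roster whose order sizes force 206 order-level and 85 family-level
    lineage groups (small orders of 1-5 genomes; 17 large orders of 5
    families with 2 genomes each)."""
    rng = np.random.default_rng(seed)
    families: list[FamilySpec] = []
    for i in range(206):
        families.append(
            FamilySpec(
                family=f"GF{i:03d}",
                order=f"GO{i:03d}",
                class_=f"GC{i % 40:02d}",
                phylum=f"GP{i % 20:02d}",
                ref_count=int(rng.integers(0, 10)),
                n_sediment=(i % 5) + 1,
            )
        )
    for j in range(17):
        for k in range(5):
            families.append(
                FamilySpec(
                    family=f"BF{j:02d}_{k}",
                    order=f"BO{j:02d}",
                    class_=f"BC{j % 10}",
                    phylum=f"BP{j % 6}",
                    ref_count=int(rng.integers(0, 10)),
                    n_sediment=2,
                )
            )
    return FixtureConfig(name="lineage_grouping", seed=seed, families=families)
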