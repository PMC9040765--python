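import json
from types import SimpleNamespace

import pytest

from magsulfur import annotations, sulfur_rules, taxonomy
from magsulfur.synthetic import generate, headline_fixture


@pytest.fixture(scope="session")
def ruleset():
    return sulfur_rules.load_ruleset()


@pytest.fixture(scope="session")
def headline_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("headline")
    generate(headline_fixture(), out)
    return out


@pytest.fixture(scope="session")
def headline(headline_dir, ruleset):
    """Headline fixture tables loaded once, with capability calls."""
    genomes, rejected = taxonomy.load_genome_table(headline_dir / "genomes.tsv")
    ref = taxonomy.ReferenceTaxonCounts.from_tsv(headline_dir / "reference_counts.tsv")
    presence = annotations.load_hits(headline_dir / "gene_hits.tsv")
    calls = sulfur_rules.call_collection(genomes, presence, ruleset)
    manifest = json.loads((headline_dir / "manifest.json").read_text())
    return SimpleNamespace(
        dir=headline_dir,
        genomes=genomes,
        rejected=rejected,
        sediment=[g for g in genomes if g.habitat == "sediment"],
        water=[g for g in genomes if g.habitat == "water"],
        ref=ref,
        presence=presence,
        calls=calls,
        manifest=manifest,
    )


def make_genome(genome_id, taxonomy_string, habitat="sediment", red=None):
    return taxonomy.GenomeRecord(
        genome_id=genome_id,
        habitat=habitat,
        taxonomy=taxonomy.parse_taxonomy(taxonomy_string),
        completeness=90.0,
        contamination=2.0,
        red=red,
    )
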