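import pytest
from hypothesis import given, settings, strategies as st

from magsulfur.taxonomy import (
    EmptyCollectionError,
    NoRedValuesError,
    NoveltyStatus,
    RANKS,
    RankedTaxonomy,
    ReferenceTaxonCounts,
    TaxonomyParseError,
    classify_taxon,
    database_enrichment,
    genome_novelty_profile,
    mean_red,
    novelty_summary,
    parse_taxonomy,
    shared_family_partition,
)

from conftest import make_genome


class TestParse:
    def test_full_string_round_trips(self):
        s = "d__Bacteria;p__Chloroflexota;c__Anaerolineae;o__Anaerolineales;f__Anaerolineaceae;g__Flexilinea;s__Flexilinea flocculi"
        assert parse_taxonomy(s).serialize() == s

    def test_explicit_novel_family_placeholder(self):
        t = parse_taxonomy(
            "d__Bacteria;p__Chloroflexota;c__Anaerolineae;o__Anaerolineales;f__ZNF-1"
        )
        assert t.family == "ZNF-1"
        assert t.is_placeholder("family")
        assert not t.is_placeholder("order")

    def test_truncated_string_fills_placeholders(self):
        t = parse_taxonomy("d__Archaea")
        assert t.domain == "Archaea"
        for rank in RANKS[1:]:
            assert t.is_placeholder(rank)
        # placeholders carry the deepest named parent
        assert t.phylum == "ZNP-Archaea"

    def test_truncated_round_trip_is_stable(self):
        t = parse_taxonomy("d__Bacteria;p__Bacteroidota;c__Bacteroidia")
        assert parse_taxonomy(t.serialize()) == t

    @pytest.mark.parametrize(
        "bad",
        [
            "",
            "p__Bacteroidota",  # wrong prefix at position 1
            "d__Bacteria;f__TooDeep",  # prefix out of order
            "d__Bacteria;p__A;c__B;o__C;f__D;g__E;s__F;x__G",  # too many
        ],
    )
    def test_malformed_strings_raise(self, bad):
        with pytest.raises(TaxonomyParseError):
            parse_taxonomy(bad)

    def test_named_rank_below_placeholder_rejected(self):
        with pytest.raises(TaxonomyParseError):
            RankedTaxonomy(("Bacteria", "ZNP-Bacteria", "RealClass", "ZNO-x",
                            "ZNF-x", "ZNG-x", "ZNS-x"))

    names = st.text(
        alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789-_",
        min_size=1,
        max_size=12,
    ).filter(lambda s: not s.startswith("ZN"))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(names, min_size=7, max_size=7))
    def test_round_trip_property(self, tokens):
        s = ";".join(p + n for p, n in zip(("d__", "p__", "c__", "o__", "f__", "g__", "s__"), tokens))
        assert parse_taxonomy(s).serialize() == s


class TestClassification:
    @pytest.mark.parametrize(
        "count,expected",
        [
            (0, NoveltyStatus.NOVEL),
            (1, NoveltyStatus.RARE),
            (5, NoveltyStatus.RARE),
            (6, NoveltyStatus.ABUNDANT),
            (500, NoveltyStatus.ABUNDANT),
        ],
    )
    def test_reference_count_boundaries(self, count, expected):
        ref = ReferenceTaxonCounts({("family", "Fam"): count} if count else {})
        assert classify_taxon("Fam", "family", ref).status is expected

    def test_placeholder_always_novel(self):
        ref = ReferenceTaxonCounts({("family", "ZNF-9"): 100})
        assert classify_taxon("ZNF-9", "family", ref).status is NoveltyStatus.NOVEL

    def test_statuses_partition_and_monotone(self):
        """Raising a reference count never moves a taxon toward novel."""
        order = [NoveltyStatus.NOVEL, NoveltyStatus.RARE, NoveltyStatus.ABUNDANT]
        previous = 0
        for count in range(0, 12):
            ref = ReferenceTaxonCounts({("genus", "G"): count})
            status = classify_taxon("G", "genus", ref).status
            assert order.index(status) >= previous
            previous = order.index(status)

    def test_profile_ranks_independent(self):
        ref = ReferenceTaxonCounts(
            {("order", "BigOrder"): 40, ("family", "SmallFam"): 3}
        )
        g = make_genome("g1", "d__Bacteria;p__P;c__C;o__BigOrder;f__SmallFam")
        profile = genome_novelty_profile(g, ref)
        assert profile["family"] is NoveltyStatus.RARE
        assert profile["order"] is NoveltyStatus.ABUNDANT
        assert profile["phylum"] is NoveltyStatus.NOVEL


class TestSummary:
    def _collection(self):
        ref = ReferenceTaxonCounts(
            {("family", "FamRare"): 2, ("family", "FamBig"): 50}
        )
        genomes = (
            [make_genome(f"n{i}", "d__B;p__P;c__C;o__O;f__NewFam") for i in range(3)]
            + [make_genome(f"r{i}", "d__B;p__P;c__C;o__O;f__FamRare") for i in range(2)]
            + [make_genome(f"a{i}", "d__B;p__P;c__C;o__O;f__FamBig") for i in range(5)]
        )
        return genomes, ref

    def test_counts_match_brute_force_tally(self):
        genomes, ref = self._collection()
        s = novelty_summary(genomes, ref, "family")
        # independent tally
        novel = sum(
            1 for g in genomes if ref.count("family", g.taxonomy.family) == 0
        )
        rare = sum(
            1 for g in genomes if 1 <= ref.count("family", g.taxonomy.family) <= 5
        )
        assert (s.n_genomes_novel, s.n_genomes_rare) == (novel, rare)
        assert s.pct_combined == round(100 * (novel + rare) / len(genomes), 2)
        assert s.n_taxa_novel == 1 and s.n_taxa_rare == 1 and s.n_taxa_abundant == 1

    def test_zero_novelty_collection(self):
        ref = ReferenceTaxonCounts({("family", "F"): 99})
        genomes = [make_genome(f"g{i}", "d__B;p__P;c__C;o__O;f__F") for i in range(4)]
        s = novelty_summary(genomes, ref, "family")
        assert s.pct_combined == 0.0

    def test_empty_collection_raises(self):
        with pytest.raises(EmptyCollectionError):
            novelty_summary([], ReferenceTaxonCounts(), "family")


class TestEnrichment:
    def test_simple_percentage(self):
        ref = ReferenceTaxonCounts({("order", "O"): 40})
        assert database_enrichment("O", 10, ref) == 25.0

    def test_novel_order_is_undefined(self):
        assert database_enrichment("NewOrder", 7, ReferenceTaxonCounts()) is None

    def test_zero_study_count(self):
        ref = ReferenceTaxonCounts({("order", "O"): 12})
        assert database_enrichment("O", 0, ref) == 0.0

    def test_negative_study_count_rejected(self):
        with pytest.raises(ValueError):
            database_enrichment("O", -1, ReferenceTaxonCounts())


class TestMeanRed:
    def test_mean_and_missing_count(self):
        genomes = [
            make_genome("a", "d__B", red=0.70),
            make_genome("b", "d__B", red=0.80),
            make_genome("c", "d__B", red=None),
        ]
        result = mean_red(genomes)
        assert result.value == 0.75
        assert result.n_used == 2 and result.n_missing == 1

    def test_no_red_values_raises(self):
        with pytest.raises(NoRedValuesError):
            mean_red([make_genome("a", "d__B")])


class TestFamilyPartition:
    def test_subset_and_disjoint_cases(self):
        sed = [make_genome("s1", "d__B;p__P;c__C;o__O;f__F1")]
        water_same = [make_genome("w1", "d__B;p__P;c__C;o__O;f__F1", habitat="water")]
        water_other = [make_genome("w2", "d__B;p__P;c__C;o__O;f__F2", habitat="water")]
        assert shared_family_partition(sed, water_same).n_water_specific == 0
        assert shared_family_partition(sed, water_other).n_water_shared == 0

    def test_counts_sum_to_water_total(self, headline):
        part = shared_family_partition(headline.sediment, headline.water)
        assert part.n_water_shared + part.n_water_specific == len(headline.water)
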