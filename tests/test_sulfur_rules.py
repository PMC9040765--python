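import numpy as np
import pytest

from magsulfur.annotations import VOCABULARY
from magsulfur.sulfur_rules import (
    RuleSet,
    RuleValidationError,
    UnknownCapabilityError,
    call_genome,
    capability_overlap,
    evaluate_rule,
    load_ruleset,
    parse_expr,
    summarize_calls,
    CapabilityRule,
)
from magsulfur.synthetic import PLANT_GENES

from _oracles import brute_force_calls
from conftest import make_genome

SULFATE_SET = {"Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC", "DsrA", "DsrB", "DsrC"}


def active_names(calls):
    return {c.capability for c in calls if c.active}


class TestEvaluateRule:
    def test_full_sulfate_set_calls_sulfate_reduction(self, ruleset):
        rule = ruleset["sulfate_reduction"]
        call = evaluate_rule(rule, "g", SULFATE_SET)
        assert call is not None and call.evidence == frozenset(SULFATE_SET)

    def test_asr_without_hdr_has_no_locus_annotation(self, ruleset):
        rule = ruleset["sulfite_reduction_asr"]
        call = evaluate_rule(rule, "g", {"AsrA", "AsrB", "AsrC"})
        assert call is not None and call.annotations == ()

    def test_asr_with_hdr_gets_locus_annotation(self, ruleset):
        rule = ruleset["sulfite_reduction_asr"]
        call = evaluate_rule(
            rule, "g", {"AsrA", "AsrB", "AsrC", "HdrA", "HdrB", "HdrC"}
        )
        assert call.annotations == ("asr_hdr_locus",)

    def test_empty_gene_set_calls_nothing(self, ruleset):
        g = make_genome("g", "d__B;p__P;c__C;o__O;f__F")
        assert call_genome(g, set(), ruleset) == []

    def test_taxon_exclusion_blocks_reductive_dsr(self, ruleset):
        rule = ruleset["sulfite_reduction_dsr"]
        genes = {"DsrA", "DsrB", "DsrC", "DsrK", "DsrM", "DsrJ"}
        ok = make_genome("g", "d__B;p__Chloroflexota;c__C;o__O;f__F")
        excluded = make_genome("g", "d__B;p__Proteobacteria;c__C;o__O;f__F")
        assert evaluate_rule(rule, "g", genes, ok.taxonomy) is not None
        assert evaluate_rule(rule, "g", genes, excluded.taxonomy) is None

    def test_unknown_symbol_fails_at_load_time(self):
        with pytest.raises(RuleValidationError, match="unknown gene symbols"):
            RuleSet(
                (
                    CapabilityRule(
                        name="bad", direction="reduction", require=parse_expr("NotAGene")
                    ),
                )
            )


class TestCallGenome:
    def test_sulfate_suppresses_dsr_sulfite_reduction(self, ruleset):
        genes = SULFATE_SET | {"DsrK", "DsrM", "DsrJ"}
        calls = call_genome("g", genes, ruleset)
        by_name = {c.capability: c for c in calls}
        assert by_name["sulfate_reduction"].active
        assert by_name["sulfite_reduction_dsr"].suppressed_by == "sulfate_reduction"
        # suppressed calls are retained but excluded from active counts
        assert "sulfite_reduction_dsr" not in active_names(calls)

    def test_phs_with_soe_disproportionates(self, ruleset):
        genes = {"PhsA", "PhsB", "PhsC", "SoeA", "SoeB", "SoeC"}
        assert "thiosulfate_disproportionation_phs" in active_names(
            call_genome("g", genes, ruleset)
        )

    def test_tetrathionate_otr_branch_evidence(self, ruleset):
        """Partial Ttr fails ALL; the Otr branch alone carries the call."""
        calls = call_genome("g", {"Otr", "TtrA"}, ruleset)
        call = next(c for c in calls if c.capability == "tetrathionate_reduction")
        assert call.active and call.evidence == frozenset({"Otr"})

    def test_apr_reversal_requires_cooccurring_oxidative_call(self, ruleset):
        sat_qmo = {"Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC"}
        # Sat+AprAB+QmoABC alone: reductive machinery, no sulfite oxidation
        assert "sulfite_oxidation" not in active_names(
            call_genome("g", sat_qmo, ruleset)
        )
        # with a sulfide-oxidizing partner the reversal branch applies
        assert "sulfite_oxidation" in active_names(
            call_genome("g", sat_qmo | {"Sqr"}, ruleset)
        )

    def test_evidence_soundness(self, ruleset):
        """Re-evaluating any rule on its own evidence reproduces the call."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            genes = set(
                rng.choice(list(VOCABULARY), size=rng.integers(5, 40), replace=False)
            )
            for call in call_genome("g", genes, ruleset):
                if not call.active:
                    continue
                replay = call_genome("g", set(call.evidence), ruleset)
                assert call.capability in {c.capability for c in replay if c.active}

    def test_monotonicity_for_exclusion_free_rules(self, ruleset):
        """Adding genes never removes a call from an exclusion-free rule."""
        exclusion_free = {
            r.name
            for r in ruleset
            if not r.exclude_capabilities and not r.exclude_taxa and not r.is_gated
            and r.name != "sulfur_oxidation_rdsr"
        }
        rng = np.random.default_rng(5)
        vocab = list(VOCABULARY)
        for _ in range(30):
            genes = set(rng.choice(vocab, size=rng.integers(0, 30), replace=False))
            extra = genes | set(rng.choice(vocab, size=10, replace=False))
            before = active_names(call_genome("g", genes, ruleset)) & exclusion_free
            after = active_names(call_genome("g", extra, ruleset)) & exclusion_free
            assert before <= after

    def test_rdsr_documented_nonmonotone_exception(self, ruleset):
        """Completing the sulfate machinery withdraws the oxidative-Dsr call."""
        genes = {"DsrA", "DsrB", "DsrC", "Sqr"}
        assert "sulfur_oxidation_rdsr" in active_names(call_genome("g", genes, ruleset))
        full = genes | {"Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC"}
        assert "sulfur_oxidation_rdsr" not in active_names(
            call_genome("g", full, ruleset)
        )


class TestBruteForceEquivalence:
    TAXA = [
        "d__B;p__P01;c__C;o__O;f__F",
        "d__B;p__Proteobacteria;c__Gamma;o__O;f__F",
        "d__B;p__Nitrospirota;c__C;o__O;f__F",
        "d__B;p__P02;c__C;o__O;f__Chlorobiaceae",
    ]

    def test_engine_matches_naive_evaluator(self, ruleset):
        """100 seeded random fixtures of up to 50 genomes: the declarative
        engine and a naive per-rule set-inclusion oracle agree on active
        calls and on suppressions."""
        vocab = list(VOCABULARY)
        plant_sets = list(PLANT_GENES.values())
        for seed in range(100):
            rng = np.random.default_rng(seed)
            for i in range(int(rng.integers(1, 51))):
                genes = set(
                    rng.choice(vocab, size=int(rng.integers(0, 25)), replace=False)
                )
                # bias toward rule-relevant complements
                for _ in range(int(rng.integers(0, 3))):
                    genes |= plant_sets[int(rng.integers(0, len(plant_sets)))]
                tax = self.TAXA[int(rng.integers(0, len(self.TAXA)))]
                genome = make_genome(f"g{i}", tax)
                calls = call_genome(genome, genes, ruleset)
                expected_active, expected_suppressed = brute_force_calls(
                    genes, set(genome.taxonomy.names)
                )
                assert active_names(calls) == expected_active, (seed, i, sorted(genes))
                got_suppressed = {
                    c.capability: c.suppressed_by for c in calls if not c.active
                }
                assert got_suppressed == expected_suppressed


class TestSummaries:
    def test_no_calls_gives_zero_percentages(self, ruleset):
        genomes = [make_genome("g1", "d__B;p__P;c__C;o__O;f__F")]
        summary = summarize_calls([], genomes)
        assert summary["sediment"].reductive_any.pct == 0.0
        assert summary["sediment"].oxidative_any.pct == 0.0

    def test_flag_direction_excluded_from_totals(self, ruleset):
        g = make_genome("g1", "d__B;p__P;c__C;o__O;f__F")
        calls = call_genome(g, {"HydA", "HydB", "HydC", "HydD"}, ruleset)
        summary = summarize_calls(calls, [g])
        assert summary["sediment"].reductive_any.n == 0
        assert "sulfurhydrogenase" in summary["sediment"].per_capability

    def test_summary_matches_brute_force_scan(self, ruleset, headline):
        """Counts over (genome x rule) pairs recomputed naively agree."""
        sample = headline.sediment[:50]
        ids = {g.genome_id for g in sample}
        calls = [c for c in headline.calls if c.genome_id in ids]
        summary = summarize_calls(calls, sample)["sediment"]
        reductive = set()
        for g in sample:
            active, _ = brute_force_calls(
                headline.presence.genes(g.genome_id), set(g.taxonomy.names)
            )
            directions = {
                c.direction for c in calls if c.genome_id == g.genome_id and c.active
            }
            if {"reduction", "disproportionation"} & directions:
                reductive.add(g.genome_id)
        assert summary.reductive_any.n == len(reductive)

    def test_overlap_inclusion_exclusion(self, ruleset):
        genomes = (
            [make_genome(f"a{i}", "d__B;p__P;c__C;o__O;f__F") for i in range(2)]
            + [make_genome(f"b{i}", "d__B;p__P;c__C;o__O;f__F") for i in range(3)]
            + [make_genome("ab0", "d__B;p__P;c__C;o__O;f__F")]
        )
        presence = {
            "a0": PLANT_GENES["psr"], "a1": PLANT_GENES["psr"],
            "b0": PLANT_GENES["asr"], "b1": PLANT_GENES["asr"], "b2": PLANT_GENES["asr"],
            "ab0": PLANT_GENES["psr"] | PLANT_GENES["asr"],
        }
        calls = [
            c for g in genomes for c in call_genome(g, presence[g.genome_id], ruleset)
        ]
        o = capability_overlap(
            calls, "polysulfide_reduction", "sulfite_reduction_asr", ruleset
        )
        assert (o.n_a, o.n_b, o.n_both, o.n_union) == (3, 4, 1, 6)
        assert o.n_union == o.n_a + o.n_b - o.n_both

    def test_unknown_capability_rejected(self, ruleset):
        with pytest.raises(UnknownCapabilityError):
            capability_overlap([], "polysulfide_reduction", "nope", ruleset)
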