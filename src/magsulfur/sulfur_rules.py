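"""Declarative sulfur-cycling capability calling over gene presence sets.

A capability (sulfate reduction, Asr-based sulfite reduction, polysulfide
reduction, thiosulfate disproportionation, sulfide oxidation, ...) is a
boolean requirement over gene symbols — combinations of ALL / ANY /
AT_LEAST(k of set) / NOT — plus optional context conditions:

* **taxon exclusions** — lineages known to run a system in the opposite
  direction never receive the call (e.g. the reductive-Dsr rule is withheld
  from phyla that use Dsr oxidatively);
* **capability exclusions** — a call is *suppressed* (retained with the
  suppressing capability recorded, excluded from counts) when a stronger
  capability is active on the same genome (e.g. sulfite-but-not-sulfate
  reduction is suppressed in genomes with the full sulfate pathway);
* **co-occurring oxidative capability** — one branch of the sulfite
  oxidation rule (reversal of the Sat+AprAB+QmoABC machinery) only applies
  in genomes that already carry another oxidative capability, since the same
  genes run reductively otherwise.

Rules are data: the shipped set lives in ``data/sulfur_rules.yaml`` and can
be replaced or edited without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from ._util import percent
from .annotations import VOCABULARY, GenePresence
from .taxonomy import GenomeRecord, RankedTaxonomy

DIRECTIONS = ("reduction", "disproportionation", "oxidation", "flag")

#: Directions counted as "reductive" in summary statistics. Flag-direction
#: capabilities (sulfurhydrogenase) are never counted as respiration.
REDUCTIVE_DIRECTIONS = ("reduction", "disproportionation")


class RuleValidationError(ValueError):
    """A rule references an unknown symbol/capability or the set is cyclic."""


class UnknownCapabilityError(KeyError):
    """A capability name absent from the rule set was requested."""


# ---------------------------------------------------------------------------
# Requirement expression tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    symbol: str


@dataclass(frozen=True)
class All:
    parts: tuple


@dataclass(frozen=True)
class AnyOf:
    parts: tuple


@dataclass(frozen=True)
class AtLeast:
    k: int
    parts: tuple


@dataclass(frozen=True)
class Not:
    part: object


@dataclass(frozen=True)
class OtherOxidativeCall:
    """Satisfied when the genome has another active oxidation-direction call."""


Expr = Union[Gene, All, AnyOf, AtLeast, Not, OtherOxidativeCall]


def parse_expr(obj) -> Expr:
    """Build an expression tree from the YAML rule syntax."""
    if isinstance(obj, str):
        return Gene(obj)
    if isinstance(obj, dict):
        if len(obj) != 1:
            raise RuleValidationError(f"expression node must have one key: {obj!r}")
        key, value = next(iter(obj.items()))
        if key == "all" or key == "and":
            return All(tuple(parse_expr(v) for v in value))
        if key == "any" or key == "or":
            return AnyOf(tuple(parse_expr(v) for v in value))
        if key == "at_least":
            return AtLeast(int(value["k"]), tuple(parse_expr(v) for v in value["of"]))
        if key == "not":
            return Not(parse_expr(value))
        if key == "other_oxidative_call":
            return OtherOxidativeCall()
        raise RuleValidationError(f"unknown expression combinator {key!r}")
    raise RuleValidationError(f"cannot parse expression node {obj!r}")


def expr_symbols(expr: Expr) -> set[str]:
    if isinstance(expr, Gene):
        return {expr.symbol}
    if isinstance(expr, (All, AnyOf, AtLeast)):
        out: set[str] = set()
        for p in expr.parts:
            out |= expr_symbols(p)
        return out
    if isinstance(expr, Not):
        return expr_symbols(expr.part)
    return set()


def expr_is_gated(expr: Expr) -> bool:
    """True if the expression depends on other capability calls."""
    if isinstance(expr, OtherOxidativeCall):
        return True
    if isinstance(expr, (All, AnyOf, AtLeast)):
        return any(expr_is_gated(p) for p in expr.parts)
    if isinstance(expr, Not):
        return expr_is_gated(expr.part)
    return False


def evaluate_expr(
    expr: Expr,
    genes: frozenset[str] | set[str],
    oxidative_context: Optional[Sequence["CapabilityCall"]] = None,
) -> tuple[bool, frozenset[str]]:
    """Evaluate an expression; returns (satisfied, evidence).

    Evidence is the minimal satisfying gene subset under a deterministic
    left-to-right walk: ANY takes its first satisfying branch, AT_LEAST the
    first k satisfying members in listed order. A satisfied gate node
    contributes the evidence of the first active oxidative call, so that the
    evidence set alone reproduces the call.
    """
    if isinstance(expr, Gene):
        ok = expr.symbol in genes
        return ok, frozenset({expr.symbol}) if ok else frozenset()
    if isinstance(expr, All):
        evidence: set[str] = set()
        for p in expr.parts:
            ok, ev = evaluate_expr(p, genes, oxidative_context)
            if not ok:
                return False, frozenset()
            evidence |= ev
        return True, frozenset(evidence)
    if isinstance(expr, AnyOf):
        for p in expr.parts:
            ok, ev = evaluate_expr(p, genes, oxidative_context)
            if ok:
                return True, ev
        return False, frozenset()
    if isinstance(expr, AtLeast):
        evidence = set()
        n = 0
        for p in expr.parts:
            ok, ev = evaluate_expr(p, genes, oxidative_context)
            if ok:
                n += 1
                evidence |= ev
                if n == expr.k:
                    return True, frozenset(evidence)
        return False, frozenset()
    if isinstance(expr, Not):
        ok, _ = evaluate_expr(expr.part, genes, oxidative_context)
        return (not ok), frozenset()
    if isinstance(expr, OtherOxidativeCall):
        if oxidative_context:
            return True, oxidative_context[0].evidence
        return False, frozenset()
    raise TypeError(f"unknown expression node {expr!r}")


# ---------------------------------------------------------------------------
# Rules and calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapabilityRule:
    name: str
    direction: str
    require: Expr
    exclude_taxa: frozenset[str] = frozenset()
    exclude_capabilities: frozenset[str] = frozenset()
    #: (annotation name, expression) pairs recorded as extra evidence tags
    #: when satisfied (e.g. the adjacent Hdr locus of an Asr system).
    annotations: tuple[tuple[str, Expr], ...] = ()

    @property
    def is_gated(self) -> bool:
        return expr_is_gated(self.require)


@dataclass(frozen=True)
class CapabilityCall:
    genome_id: str
    capability: str
    direction: str
    evidence: frozenset[str]
    suppressed_by: Optional[str] = None
    annotations: tuple[str, ...] = ()

    @property
    def active(self) -> bool:
        return self.suppressed_by is None


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[CapabilityRule, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise RuleValidationError("duplicate rule names")
        vocab = set(VOCABULARY)
        for rule in self.rules:
            if rule.direction not in DIRECTIONS:
                raise RuleValidationError(
                    f"rule {rule.name}: unknown direction {rule.direction!r}"
                )
            unknown = expr_symbols(rule.require) - vocab
            for _, expr in rule.annotations:
                unknown |= expr_symbols(expr) - vocab
            if unknown:
                raise RuleValidationError(
                    f"rule {rule.name}: unknown gene symbols {sorted(unknown)}"
                )
            bad_caps = rule.exclude_capabilities - set(names)
            if bad_caps:
                raise RuleValidationError(
                    f"rule {rule.name}: unknown excluded capabilities {sorted(bad_caps)}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        graph = {r.name: r.exclude_capabilities for r in self.rules}
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for dep in graph[node]:
                s = state.get(dep, 0)
                if s == 1:
                    raise RuleValidationError(
                        f"cyclic capability exclusions involving {node!r}"
                    )
                if s == 0:
                    visit(dep)
            state[node] = 2

        for name in graph:
            if state.get(name, 0) == 0:
                visit(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rules)

    def __getitem__(self, name: str) -> CapabilityRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise UnknownCapabilityError(name)

    def __iter__(self):
        return iter(self.rules)


def _rule_from_dict(d: Mapping) -> CapabilityRule:
    return CapabilityRule(
        name=d["name"],
        direction=d["direction"],
        require=parse_expr(d["require"]),
        exclude_taxa=frozenset(d.get("exclude_taxa", ())),
        exclude_capabilities=frozenset(d.get("exclude_capabilities", ())),
        annotations=tuple(
            (a["name"], parse_expr(a["when"])) for a in d.get("annotations", ())
        ),
    )


def load_ruleset(path=None) -> RuleSet:
    """Load a rule set from YAML; with no path, the shipped default set."""
    if path is None:
        text = (resources.files("magsulfur") / "data" / "sulfur_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return RuleSet(tuple(_rule_from_dict(d) for d in doc["rules"]))


def evaluate_rule(
    rule: CapabilityRule,
    genome_id: str,
    genes: set[str] | frozenset[str],
    taxonomy: Optional[RankedTaxonomy] = None,
    oxidative_context: Optional[Sequence[CapabilityCall]] = None,
) -> Optional[CapabilityCall]:
    """Evaluate one rule on one genome; returns a call or None.

    Taxon exclusions match any rank name of the genome's taxonomy.
    Capability exclusions are *not* applied here — they need the full set of
    calls and are the job of :func:`call_genome`.
    """
    if taxonomy is not None and rule.exclude_taxa:
        if rule.exclude_taxa.intersection(taxonomy.names):
            return None
    ok, evidence = evaluate_expr(rule.require, genes, oxidative_context)
    if not ok:
        return None
    tags = tuple(
        name for name, expr in rule.annotations if evaluate_expr(expr, genes)[0]
    )
    return CapabilityCall(
        genome_id=genome_id,
        capability=rule.name,
        direction=rule.direction,
        evidence=evidence,
        annotations=tags,
    )


def call_genome(
    genome: GenomeRecord | str,
    genes: set[str] | frozenset[str],
    ruleset: RuleSet,
) -> list[CapabilityCall]:
    """Evaluate the whole rule set on one genome.

    Gated rules (those referencing co-occurring oxidative capabilities) are
    evaluated after the ungated ones, so the oxidative context is complete.
    Capability exclusions are then applied: a call whose rule excludes an
    active capability is retained but marked ``suppressed_by`` and drops out
    of all counts.
    """
    if isinstance(genome, GenomeRecord):
        genome_id, taxonomy = genome.genome_id, genome.taxonomy
    else:
        genome_id, taxonomy = genome, None

    calls: dict[str, CapabilityCall] = {}
    for rule in ruleset:
        if rule.is_gated:
            continue
        call = evaluate_rule(rule, genome_id, genes, taxonomy)
        if call is not None:
            calls[rule.name] = call
    oxidative_context = [c for c in calls.values() if c.direction == "oxidation"]
    for rule in ruleset:
        if not rule.is_gated:
            continue
        call = evaluate_rule(rule, genome_id, genes, taxonomy, oxidative_context)
        if call is not None:
            calls[rule.name] = call

    # Suppression to a fixpoint: a suppressor that is itself suppressed does
    # not suppress. The exclusion graph is acyclic, so this terminates.
    for _ in range(len(ruleset.rules)):
        changed = False
        for rule in ruleset:
            if rule.name not in calls:
                continue
            call = calls[rule.name]
            suppressor = next(
                (
                    c
                    for c in rule.exclude_capabilities
                    if c in calls and calls[c].active
                ),
                None,
            )
            new_supp = suppressor
            if new_supp != call.suppressed_by:
                calls[rule.name] = CapabilityCall(
                    genome_id=call.genome_id,
                    capability=call.capability,
                    direction=call.direction,
                    evidence=call.evidence,
                    suppressed_by=new_supp,
                    annotations=call.annotations,
                )
                changed = True
        if not changed:
            break
    return [calls[r.name] for r in ruleset if r.name in calls]


def call_collection(
    genomes: Sequence[GenomeRecord],
    presence: GenePresence | Mapping[str, set[str]],
    ruleset: RuleSet,
) -> list[CapabilityCall]:
    """Run the rule set over every genome in a collection."""
    get = presence.genes if isinstance(presence, GenePresence) else (
        lambda gid: presence.get(gid, set())
    )
    out: list[CapabilityCall] = []
    for g in genomes:
        out.extend(call_genome(g, get(g.genome_id), ruleset))
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapabilityStats:
    n_genomes: int
    n_phyla: int
    n_classes: int
    n_orders: int
    n_families: int


@dataclass(frozen=True)
class CountPct:
    n: int
    denominator: int
    pct: float


@dataclass(frozen=True)
class HabitatSummary:
    habitat: str
    n_genomes: int
    per_capability: dict[str, CapabilityStats]
    reductive_any: CountPct
    oxidative_any: CountPct


def summarize_calls(
    calls: Sequence[CapabilityCall],
    genomes: Sequence[GenomeRecord],
    decimals: int = 1,
) -> dict[str, HabitatSummary]:
    """Per-habitat capability counts and the any-reductive / any-oxidative
    genome fractions.

    Only active (unsuppressed) calls count. "Reductive" covers the reduction
    and disproportionation directions; flag capabilities are excluded from
    both totals. Percentages are rounded half-up to *decimals* places.
    """
    by_id = {g.genome_id: g for g in genomes}
    unknown = {c.genome_id for c in calls} - set(by_id)
    if unknown:
        raise ValueError(f"calls reference unknown genomes: {sorted(unknown)[:5]}")
    habitats = sorted({g.habitat for g in genomes})
    out: dict[str, HabitatSummary] = {}
    for habitat in habitats:
        members = [g for g in genomes if g.habitat == habitat]
        member_ids = {g.genome_id for g in members}
        active = [c for c in calls if c.active and c.genome_id in member_ids]
        per_cap: dict[str, CapabilityStats] = {}
        for cap in sorted({c.capability for c in active}):
            gids = {c.genome_id for c in active if c.capability == cap}
            taxa = [by_id[g].taxonomy for g in gids]
            per_cap[cap] = CapabilityStats(
                n_genomes=len(gids),
                n_phyla=len({t.phylum for t in taxa}),
                n_classes=len({t.class_ for t in taxa}),
                n_orders=len({t.order for t in taxa}),
                n_families=len({t.family for t in taxa}),
            )
        n = len(members)
        red = {c.genome_id for c in active if c.direction in REDUCTIVE_DIRECTIONS}
        oxi = {c.genome_id for c in active if c.direction == "oxidation"}
        out[habitat] = HabitatSummary(
            habitat=habitat,
            n_genomes=n,
            per_capability=per_cap,
            reductive_any=CountPct(len(red), n, percent(len(red), n, decimals)),
            oxidative_any=CountPct(len(oxi), n, percent(len(oxi), n, decimals)),
        )
    return out


@dataclass(frozen=True)
class Overlap:
    n_a: int
    n_b: int
    n_both: int
    n_union: int


def capability_overlap(
    calls: Sequence[CapabilityCall],
    capability_a: str,
    capability_b: str,
    ruleset: Optional[RuleSet] = None,
) -> Overlap:
    """Genome counts for two capabilities and their intersection/union.

    Satisfies inclusion-exclusion: ``n_union = n_a + n_b - n_both``.
    """
    if ruleset is not None:
        for cap in (capability_a, capability_b):
            if cap not in ruleset.names:
                raise UnknownCapabilityError(cap)
    a = {c.genome_id for c in calls if c.active and c.capability == capability_a}
    b = {c.genome_id for c in calls if c.active and c.capability == capability_b}
    return Overlap(len(a), len(b), len(a & b), len(a | b))
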