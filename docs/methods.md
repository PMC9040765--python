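# Methods

## Novelty and rarity classification

A genome's lineage is the seven-rank GTDB-style string
`d__;p__;c__;o__;f__;g__;s__`. Missing or empty trailing ranks are filled
with placeholder names (`ZNP-`/`ZNC-`/`ZNO-`/`ZNF-`/`ZNG-`/`ZNS-` followed
by the deepest named ancestor), mirroring the convention of labelling novel
classes/orders/families with ZN-prefixed tokens. Placeholders are ordinary
names downstream — they group genomes and serialize — but they always
classify as novel. A named rank below a placeholder is rejected (no gaps).

Each (rank, taxon) is classified against a reference count table:

* count 0 → **novel**;
* 1 ≤ count ≤ 5 → **rare** (lineage of rare distribution, LRD);
* count ≥ 6 → **abundant**.

The boundary places count 0 in its own class: "five genomes or fewer"
defines rarity only among taxa that exist in the reference at all. Absent
taxa look up as count 0 rather than erroring, which is what makes the novel
case uniform. Raising a reference count can only move a taxon toward
abundant (monotonicity; property-tested).

Report percentages are `100 × count / total` rounded **half-up** to two
decimals (one decimal where a quantity is conventionally printed with one);
combined percentages are computed from the combined count, never by adding
rounded parts. This convention reproduces 340/516 → 65.89 and
149/516 → 28.9 exactly. Mean RED is the arithmetic mean of the supplied
0–1 values (genomes without a value are excluded and counted); the module
exposes 0.77 as the reference median RED for novel-family designation, for
comparison in reports. Genus- and species-level statuses are computed but
excluded from headline summaries, which run phylum through family.

Genomes with contamination > 10 % are rejected at load with a logged
reason; they are reported, not silently dropped.

## Gene presence and the score threshold

Hit tables emulate profile-HMM scan output. A hit survives iff its
alignment bit score is **≥ the threshold** (default 100, inclusive — the
semantics of an hmmscan `-T 100` cutoff). Multi-copy hits collapse to set
membership: all capability logic is presence/absence, since copy number is
not part of any rule. Raising the threshold is monotone-decreasing in
presence sets (property-tested). Symbols are resolved case-insensitively
against a 63-symbol controlled vocabulary with an alias map; both rhodanese
EC activities (2.8.1.1, 2.8.1.3) normalize to the single symbol `Rhd`.
Unknown symbols are collected in a rejects report, never silently kept.
Tree-based confirmation of candidate hits is out of scope, but an optional
boolean `confirmed` column is honored (false rows dropped) so users of a
full phylogenetic-vetting workflow can feed curated hits.

## Capability rules

Rules are data (YAML) compiled to expression trees over ALL / ANY /
AT_LEAST(k of set) / NOT combinators, with three context mechanisms:

* **Taxon exclusions** — the reductive-Dsr rule is withheld from
  Proteobacteria, Nitrospirota (also matched under the legacy spelling
  Nitrospira) and Chlorobiaceae, lineages that run the Dsr system
  oxidatively. Direction cannot be read from the genes alone, so lineage
  context substitutes for a marker.
* **Capability exclusions (suppression)** — `sulfite_reduction_dsr` is
  suppressed when `sulfate_reduction` is active on the same genome (the
  Dsr core is part of the sulfate pathway). Suppressed calls are retained
  with the suppressor recorded, and excluded from all counts: the
  "excluding duplicates" step stays auditable. Suppression is resolved to a
  fixpoint over the (acyclic) exclusion graph.
* **Co-occurring oxidative capability** — sulfite oxidation via reversal of
  Sat+AprAB+QmoABC only applies in genomes that already carry another
  oxidative capability; the same six genes run reductively otherwise. This
  is the one gated branch; gated rules are evaluated in a second pass after
  the ungated oxidative calls are known.

Numerical/structural choices where the underlying biology leaves room:

* **DsrKMJOP completeness**: at least 3 of the 5 membrane-module subunits,
  tolerant to annotation dropout while still demanding a membrane complex;
  editable in the rule file.
* **SOX completeness**: all seven of SoxXA+SoxB+SoxYZ+SoxCD, contrasting a
  "complete" system with partial components; editable.
* **Reverse Dsr** additionally requires a sulfide-oxidizing partner
  (Sqr or FccAB) and the *absence* of the full sulfate machinery — the one
  deliberately non-monotone gene rule, with a dedicated test.
* **Reductive totals** count the reduction and disproportionation
  directions; the sulfurhydrogenase rule is a *flag* (direction neither
  proven reductive nor oxidative) and never enters respiration totals.
  Tetrathionate reduction counts as reductive even for genomes lacking
  downstream thiosulfate/sulfite reduction.
* Evidence is the minimal satisfying subset under a deterministic
  left-to-right walk (ANY takes its first satisfying branch); a gated
  branch folds in the evidence of the gating call, so re-evaluating a rule
  on its own evidence always reproduces the call (property-tested).
* `DsrD/E/F/H` are in the vocabulary but referenced by no shipped rule, so
  users can tighten rules without schema changes.

The engine is tested for exact agreement with an independent brute-force
evaluator (naive per-rule set-inclusion checks) over 100 seeded random
fixtures of up to 50 genomes.

## Lineage grouping and the 80 %-of-KOs rule

Orders with ≤ 5 study genomes form one order-level lineage; larger orders
split into family-level lineages. The grouping is a partition (tested).
A pathway is present in a lineage iff **some single member genome** covers
≥ 80 % of the pathway's KOs; completeness is a `Fraction`, so the 8-of-10
boundary is exact and pooling KO sets across members can never trigger
presence. Whether a fractional threshold should round per pathway is
unstated in the underlying convention; the shipped behaviour is the exact
rational comparison (5.6-of-7 means 6 required). The shipped pathway file
is an illustrative 9-pathway, 10-KO-each set that documents the format;
real analyses should supply curated KO lists.

## Transcription aggregation

TPM rows (sample, genome, gene) are summed per gene group and phylum.
Groups must be disjoint; genes in no group accumulate under `unassigned`,
so per-sample totals are conserved exactly. Both per-sample tables and a
pooled (summed-across-samples) view are emitted, since expression figures
of this kind do not always state which is shown; ratios are invariant to
global rescaling either way. A zero-denominator ratio raises an explicit
`UndefinedRatio` rather than returning a sentinel number.

## Synthetic data

The generator emits all five tables from a seeded config: a family roster
(name, lineage, reference count, genomes per habitat), capability plants
(minimal satisfying gene sets per genome, from a token table), decoy genes,
sub-threshold noise hits, KO plants at chosen completeness, and a TPM plan.
Planted facts are written to a ground-truth manifest, and generation
*verifies itself* by running the rule engine on every planted genome —
a contradictory plant (e.g. reductive Dsr on an excluded phylum) aborts
generation with the conflict named. Decoy symbols are drawn exclusively
from `DsrD/E/F/H`, which no rule references, so decoys can never create or
destroy a call; noise hits are always below threshold.

The packaged `headline_fixture` encodes the study conditions the package
models: 516 sediment genomes (132 across 97 novel families — 35 pairs plus
62 singletons; 208 across 113 rare families with reference counts drawn
uniformly from 1–5; 176 across 44 abundant families), 149 sediment genomes
with at least one reductive/disproportionating capability (104 Asr with
adjacent Hdr loci, 11 of them with PhsABC and 5 of those with SoeABC;
8 Dsr-only; 18 complete sulfate pathways; 20 PsrABC; tetrathionate plants
of 73 Otr and 68 TtrABC overlapping in 36 genomes, union 105), 119 genomes
flagged for sulfurhydrogenase, 114 water genomes (62 in sediment-shared
families, 52 water-specific, 59 oxidative: 14 SOX, 39 Sqr — two also
reverse-Dsr — 5 Soe, 1 SorAB), and a TPM plan whose Asr:Dsr group ratio is
exactly 4 in every sample (per-row values chosen as exact binary/decimal
floats so the ratio is recovered to 1e-9). All of these counts are fixed by
construction; the seed only drives nuisance values (bit scores, QC
percentages, RED jitter, noise placement). The roster sizes keep every
stage in the low seconds on one core.

What the fixture does **not** emulate: real HMM score distributions and
borderline hits, annotation errors correlated with genome completeness,
taxonomically realistic name collisions across ranks, multi-copy biology,
or compositional TPM artifacts. Passing tests therefore demonstrate the
correctness of the decision layer (classification, rule logic, grouping,
aggregation arithmetic), not the upstream annotation quality of any real
dataset.

A second packaged config, `lineage_grouping_fixture`, plants 206 orders of
1–5 genomes plus 17 ten-genome orders of five families each, exercising the
grouping rule at scale (291 lineages).

## Pipeline and determinism

`run_pipeline` loads the five tables, runs every stage, and writes TSV
reports, each with a provenance comment (package version, SHA-256 of the
rule set in force) and both numerator and denominator for every percentage.
Outputs carry no timestamps, so a rerun on identical inputs is
byte-identical — tested, along with byte-identical regeneration of the
synthetic tables from a fixed seed. An empty habitat yields empty sections
for that habitat while the rest of the report completes.

## Known limitations

* Direction resolution for Dsr relies on lineage exclusions and
  co-occurrence, not sequence phylogeny; unusual lineages may be
  mis-directed.
* The rare/novel boundary is tied to one reference release; synonymy across
  releases is not resolved.
* Capability calls are genomic potential, not activity; the transcription
  module reports abundance sums only (no differential testing).
* The Hyd/Shy subunit orthology behind the sulfurhydrogenase flag is
  nominal; the rule matches symbols, not curated orthologs.
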