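# Default dissimilatory sulfur-cycling capability rules.
#
# Each rule is a boolean requirement over gene symbols (all / any /
# at_least{k, of} / not), with optional taxon exclusions (lineages known to
# run the system in the opposite direction), capability exclusions (a call
# suppressed when the named capability is active on the same genome), and
# evidence annotations. Edit or replace this file to tighten criteria; it is
# data, not code.
#
# Directions: reduction, disproportionation, oxidation, flag. Flag rules
# (sulfurhydrogenase) mark gene complements whose respiratory role is
# unresolved; they never count toward reductive or oxidative totals.
version: 1
rules:
  - name: sulfate_reduction
    direction: reduction
    require:
      all: [Sat, AprA, AprB, QmoA, QmoB, QmoC, DsrA, DsrB, DsrC]

  # Sulfite (but not sulfate) reduction: DsrAB+DsrC core plus a membrane
  # module (at least 3 of the DsrKMJOP subunits, tolerant to annotation
  # dropout). Suppressed in sulfate reducers; withheld from lineages that
  # use the Dsr system oxidatively.
  - name: sulfite_reduction_dsr
    direction: reduction
    require:
      and:
        - all: [DsrA, DsrB, DsrC]
        - at_least:
            k: 3
            of: [DsrK, DsrM, DsrJ, DsrO, DsrP]
    exclude_capabilities: [sulfate_reduction]
    exclude_taxa: [Proteobacteria, Nitrospirota, Nitrospira, Chlorobiaceae]

  # Anaerobic sulfite reductase; a complete adjacent HdrABC locus is
  # recorded as evidence, not required.
  - name: sulfite_reduction_asr
    direction: reduction
    require:
      all: [AsrA, AsrB, AsrC]
    annotations:
      - name: asr_hdr_locus
        when:
          all: [HdrA, HdrB, HdrC]

  - name: polysulfide_reduction
    direction: reduction
    require:
      all: [PsrA, PsrB, PsrC]

  # Cytoplasmic sulfurhydrogenase I (HydABCD) / II (ShyABCD): flagged but
  # never counted as respiration.
  - name: sulfurhydrogenase
    direction: flag
    require:
      any:
        - all: [HydA, HydB, HydC, HydD]
        - all: [ShyA, ShyB, ShyC, ShyD]

  # Thiosulfate reduction to sulfide: PhsABC plus a dissimilatory sulfite
  # reductase for the released sulfite.
  - name: thiosulfate_reduction
    direction: reduction
    require:
      and:
        - all: [PhsA, PhsB, PhsC]
        - any:
            - all: [DsrA, DsrB, DsrC]
            - all: [AsrA, AsrB, AsrC]

  # Thiosulfate disproportionation: PhsABC plus a sulfite-oxidizing partner.
  - name: thiosulfate_disproportionation_phs
    direction: disproportionation
    require:
      and:
        - all: [PhsA, PhsB, PhsC]
        - any:
            - all: [AprA, AprB, Sat]
            - all: [SoeA, SoeB, SoeC]
            - SorA

  # Rhodanese-route disproportionation: a rhodanese-like enzyme plus both a
  # sulfite oxidation and a sulfite reduction system.
  - name: thiosulfate_disproportionation_rhd
    direction: disproportionation
    require:
      and:
        - Rhd
        - any:
            - all: [Sat, AprA, AprB]
            - all: [SoeA, SoeB, SoeC]
        - any:
            - all: [DsrA, DsrB, DsrC]
            - all: [AsrA, AsrB, AsrC]

  # Octaheme tetrathionate reductase or the complete Ttr complex.
  - name: tetrathionate_reduction
    direction: reduction
    require:
      any:
        - Otr
        - all: [TtrA, TtrB, TtrC]

  # Complete SOX system (SoxXA + SoxB + SoxYZ + SoxCD).
  - name: sox_complete
    direction: oxidation
    require:
      all: [SoxA, SoxX, SoxB, SoxY, SoxZ, SoxC, SoxD]

  - name: sulfide_oxidation
    direction: oxidation
    require:
      any:
        - all: [FccA, FccB]
        - Sqr

  # Oxidative (reverse) Dsr: the Dsr core in a sulfide-oxidizing genome that
  # lacks the full sulfate-reduction machinery.
  - name: sulfur_oxidation_rdsr
    direction: oxidation
    require:
      and:
        - all: [DsrA, DsrB, DsrC]
        - any:
            - all: [FccA, FccB]
            - Sqr
        - not:
            all: [Sat, AprA, AprB, QmoA, QmoB, QmoC]

  # Sulfite oxidation: reversal of Sat+AprAB+QmoABC (only in genomes with
  # another oxidative capability), or the Soe / Sor dehydrogenases.
  - name: sulfite_oxidation
    direction: oxidation
    require:
      any:
        - and:
            - all: [AprA, AprB, QmoA, QmoB, QmoC, Sat]
            - other_oxidative_call: true
        - all: [SoeA, SoeB, SoeC]
        - all: [SorA, SorB]

  - name: thiosulfate_oxidation_tetrathionate
    direction: oxidation
    require:
      any:
        - TsdA
        - all: [DoxA, DoxD]

  - name: tetrathionate_hydrolysis
    direction: oxidation
    require: TetH
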