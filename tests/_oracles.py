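"""Naive, independent re-implementation of the capability definitions.

Each capability is a hand-written set-inclusion check over plain Python
sets, written without reference to the declarative rule engine, for use as
a brute-force oracle in equivalence tests.
"""

SULFATE_SET = {"Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC", "DsrA", "DsrB", "DsrC"}
DSR_CORE = {"DsrA", "DsrB", "DsrC"}
KMJOP = {"DsrK", "DsrM", "DsrJ", "DsrO", "DsrP"}
ASR = {"AsrA", "AsrB", "AsrC"}
PSR = {"PsrA", "PsrB", "PsrC"}
PHS = {"PhsA", "PhsB", "PhsC"}
SOE = {"SoeA", "SoeB", "SoeC"}
APR_SAT = {"AprA", "AprB", "Sat"}
SAT_QMO = {"Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC"}
HYD = {"HydA", "HydB", "HydC", "HydD"}
SHY = {"ShyA", "ShyB", "ShyC", "ShyD"}
TTR = {"TtrA", "TtrB", "TtrC"}
SOX = {"SoxA", "SoxX", "SoxB", "SoxY", "SoxZ", "SoxC", "SoxD"}
FCC = {"FccA", "FccB"}
SOR = {"SorA", "SorB"}
DOX = {"DoxA", "DoxD"}
DSR_EXCLUDED_TAXA = {"Proteobacteria", "Nitrospirota", "Nitrospira", "Chlorobiaceae"}


def brute_force_calls(genes, taxon_names=frozenset()):
    """Return (active capability names, suppressed -> suppressor map)."""
    genes = set(genes)
    taxon_names = set(taxon_names)
    active = set()

    if SULFATE_SET <= genes:
        active.add("sulfate_reduction")
    if ASR <= genes:
        active.add("sulfite_reduction_asr")
    if PSR <= genes:
        active.add("polysulfide_reduction")
    if HYD <= genes or SHY <= genes:
        active.add("sulfurhydrogenase")
    sulfite_reducer = DSR_CORE <= genes or ASR <= genes
    if PHS <= genes and sulfite_reducer:
        active.add("thiosulfate_reduction")
    if PHS <= genes and (APR_SAT <= genes or SOE <= genes or "SorA" in genes):
        active.add("thiosulfate_disproportionation_phs")
    if "Rhd" in genes and (APR_SAT <= genes or SOE <= genes) and sulfite_reducer:
        active.add("thiosulfate_disproportionation_rhd")
    if "Otr" in genes or TTR <= genes:
        active.add("tetrathionate_reduction")
    if SOX <= genes:
        active.add("sox_complete")
    sulfide_ox = FCC <= genes or "Sqr" in genes
    if sulfide_ox:
        active.add("sulfide_oxidation")
    if DSR_CORE <= genes and sulfide_ox and not SAT_QMO <= genes:
        active.add("sulfur_oxidation_rdsr")
    if "TsdA" in genes or DOX <= genes:
        active.add("thiosulfate_oxidation_tetrathionate")
    if "TetH" in genes:
        active.add("tetrathionate_hydrolysis")

    other_oxidative = active & {
        "sox_complete",
        "sulfide_oxidation",
        "sulfur_oxidation_rdsr",
        "thiosulfate_oxidation_tetrathionate",
        "tetrathionate_hydrolysis",
    }
    if (SAT_QMO <= genes and other_oxidative) or SOE <= genes or SOR <= genes:
        active.add("sulfite_oxidation")

    if (
        DSR_CORE <= genes
        and len(genes & KMJOP) >= 3
        and not (taxon_names & DSR_EXCLUDED_TAXA)
    ):
        active.add("sulfite_reduction_dsr")

    suppressed = {}
    if "sulfite_reduction_dsr" in active and "sulfate_reduction" in active:
        active.discard("sulfite_reduction_dsr")
        suppressed["sulfite_reduction_dsr"] = "sulfate_reduction"
    return active, suppressed
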