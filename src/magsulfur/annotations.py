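"""Gene-hit and KO-annotation loading over a controlled sulfur-gene vocabulary.

Gene hits emulate profile-HMM scan output (genome, gene symbol, alignment bit
score). Hits survive only if their score is at least the threshold (default
100, inclusive, matching the ``-T 100`` convention of hmmscan-style scans),
and duplicate hits collapse to set membership: capability calling downstream
is strictly presence/absence.

KO annotations emulate GhostKOALA output (genome, ``K#####`` orthology id).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical sulfur-gene symbols recognised by the shipped capability rules.
VOCABULARY: tuple[str, ...] = (
    # sulfate reduction / sulfite oxidation (reversal)
    "Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC",
    # dissimilatory sulfite reductase and membrane module / accessories
    "DsrA", "DsrB", "DsrC", "DsrK", "DsrM", "DsrJ", "DsrO", "DsrP",
    "DsrD", "DsrE", "DsrF", "DsrH",
    # anaerobic sulfite reductase and heterodisulfide reductase locus
    "AsrA", "AsrB", "AsrC", "HdrA", "HdrB", "HdrC",
    # polysulfide and thiosulfate reductases
    "PsrA", "PsrB", "PsrC", "PhsA", "PhsB", "PhsC",
    # tetrathionate reduction
    "TtrA", "TtrB", "TtrC", "Otr",
    # cytoplasmic sulfurhydrogenases I and II
    "HydA", "HydB", "HydC", "HydD", "ShyA", "ShyB", "ShyC", "ShyD",
    # rhodanese-like thiosulfate disproportionation
    "Rhd",
    # SOX thiosulfate/sulfur oxidation complex
    "SoxA", "SoxB", "SoxC", "SoxD", "SoxX", "SoxY", "SoxZ",
    # sulfide oxidation
    "FccA", "FccB", "Sqr",
    # sulfite dehydrogenases
    "SoeA", "SoeB", "SoeC", "SorA", "SorB",
    # thiosulfate oxidation to tetrathionate, tetrathionate hydrolysis
    "TsdA", "DoxA", "DoxD", "TetH",
)

#: Extra spellings accepted on input. Case variants of canonical symbols are
#: always accepted; this map covers renamings that case folding cannot.
#: Both rhodanese EC activities (2.8.1.1 thiosulfate sulfurtransferase and
#: 2.8.1.3 thiosulfate--thiol sulfurtransferase) denote one functional role
#: and normalize to the single symbol Rhd.
EXTRA_ALIASES: dict[str, str] = {
    "rhodanese": "Rhd",
    "rhodanase": "Rhd",
    "rhodanese-like": "Rhd",
    "rhodanase-like": "Rhd",
    "ec2.8.1.1": "Rhd",
    "ec2.8.1.3": "Rhd",
    "2.8.1.1": "Rhd",
    "2.8.1.3": "Rhd",
    "fcca": "FccA",
    "fccb": "FccB",
    "sqr": "Sqr",
    "otr": "Otr",
    "teth": "TetH",
    "tsda": "TsdA",
}

_ALIAS_MAP: dict[str, str] = {s.lower(): s for s in VOCABULARY}
_ALIAS_MAP.update({k.lower(): v for k, v in EXTRA_ALIASES.items()})

#: Default inclusive bit-score threshold for accepting a hit.
DEFAULT_SCORE_THRESHOLD = 100.0

_KO_PATTERN = re.compile(r"^K\d{5}$")

_TRUE_TOKENS = {"true", "t", "1", "yes"}
_FALSE_TOKENS = {"false", "f", "0", "no"}


class MalformedRowError(ValueError):
    """A table row failed to parse; the message carries the line number."""


def normalize_symbol(raw: str) -> Optional[str]:
    """Resolve a raw gene token to its canonical symbol, or None if unknown."""
    return _ALIAS_MAP.get(raw.strip().lower())


@dataclass(frozen=True)
class GeneHit:
    genome_id: str
    gene_symbol: str
    bit_score: float

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError(f"{self.genome_id}/{self.gene_symbol}: negative bit score")


@dataclass
class GenePresence:
    """Per-genome sets of gene symbols surviving the score filter.

    ``rejects`` lists (line number, raw symbol) for tokens that could not be
    resolved against the vocabulary; they are reported, never silently kept.
    """

    presence: dict[str, set[str]] = field(default_factory=dict)
    n_discarded_below_threshold: int = 0
    n_dropped_unconfirmed: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def genes(self, genome_id: str) -> set[str]:
        return self.presence.get(genome_id, set())

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.presence


def load_hits(path, threshold: float = DEFAULT_SCORE_THRESHOLD) -> GenePresence:
    """Load a gene-hit TSV and build per-genome presence sets.

    Only hits with ``bit_score >= threshold`` contribute (inclusive: a score
    of exactly 100 survives the default filter). An optional boolean
    ``confirmed`` column is honored: rows marked false are dropped, so users
    running the full tree-confirmation workflow can feed vetted hits.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"genome_id", "gene_symbol", "bit_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    has_confirmed = "confirmed" in df.columns

    result = GenePresence()
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        try:
            score = float(row["bit_score"])
        except ValueError as exc:
            raise MalformedRowError(
                f"line {line}: bad bit_score {row['bit_score']!r}"
            ) from exc
        if score < 0:
            raise MalformedRowError(f"line {line}: negative bit_score {score}")
        if has_confirmed and row["confirmed"] != "":
            token = row["confirmed"].strip().lower()
            if token in _FALSE_TOKENS:
                result.n_dropped_unconfirmed += 1
                continue
            if token not in _TRUE_TOKENS:
                raise MalformedRowError(
                    f"line {line}: bad confirmed flag {row['confirmed']!r}"
                )
        if score < threshold:
            result.n_discarded_below_threshold += 1
            continue
        symbol = normalize_symbol(row["gene_symbol"])
        if symbol is None:
            result.rejects.append((line, row["gene_symbol"]))
            continue
        result.presence.setdefault(row["genome_id"], set()).add(symbol)
    if result.n_discarded_below_threshold:
        logger.info(
            "discarded %d hits below score threshold %.1f",
            result.n_discarded_below_threshold,
            threshold,
        )
    if result.rejects:
        logger.warning(
            "%d hits carried symbols outside the vocabulary: %s",
            len(result.rejects),
            sorted({s for _, s in result.rejects}),
        )
    return result


def load_ko_table(path) -> dict[str, set[str]]:
    """Load a genome -> KO-set mapping; duplicates collapse to set membership."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"genome_id", "ko"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"KO table missing columns: {sorted(missing)}")
    ko_sets: dict[str, set[str]] = {}
    for idx, row in df.iterrows():
        ko = row["ko"].strip()
        if not _KO_PATTERN.match(ko):
            raise MalformedRowError(f"line {idx + 2}: malformed KO id {row['ko']!r}")
        ko_sets.setdefault(row["genome_id"], set()).add(ko)
    return ko_sets
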