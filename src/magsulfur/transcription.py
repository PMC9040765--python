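"""Transcript-abundance (TPM) aggregation over gene groups and phyla.

Metatranscriptome reads pseudoaligned to predicted sulfur-cycling genes
yield one TPM value per (sample, genome, gene). This module sums those
values over named gene groups (e.g. the Asr system genes AsrABC versus the
Dsr core DsrABC) and attributes each group's total to the contributing
phyla. Genes assigned to no group accumulate in an ``unassigned`` bucket so
that per-sample totals are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

UNASSIGNED = "unassigned"

#: Group label for pooled-across-samples views.
POOLED = "pooled"

#: Default gene groups mirroring the main sulfur systems.
DEFAULT_GENE_GROUPS: dict[str, frozenset[str]] = {
    "asr": frozenset({"AsrA", "AsrB", "AsrC"}),
    "dsr": frozenset({"DsrA", "DsrB", "DsrC"}),
    "sulfate_reduction": frozenset({"Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC"}),
    "psr": frozenset({"PsrA", "PsrB", "PsrC"}),
    "phs": frozenset({"PhsA", "PhsB", "PhsC"}),
    "tetrathionate": frozenset({"Otr", "TtrA", "TtrB", "TtrC"}),
    "sulfurhydrogenase": frozenset(
        {"HydA", "HydB", "HydC", "HydD", "ShyA", "ShyB", "ShyC", "ShyD"}
    ),
}


class UndefinedRatio(Exception):
    """Denominator group has zero total TPM; the ratio is undefined."""


def load_abundances(path) -> pd.DataFrame:
    """Read the TPM table; (sample, genome, gene) must be unique after load."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"sample_id": str, "genome_id": str, "gene_symbol": str},
    )
    required = {"sample_id", "genome_id", "gene_symbol", "tpm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    if (df["tpm"] < 0).any():
        raise ValueError("negative TPM values")
    keys = ["sample_id", "genome_id", "gene_symbol"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        offenders = df.loc[dup, keys].head(5).to_records(index=False).tolist()
        raise ValueError(f"duplicate (sample, genome, gene) rows, e.g. {offenders}")
    return df


@dataclass
class TpmAggregation:
    """Long-form (sample, group, phylum) sums plus group totals.

    ``table`` columns: sample_id, group, phylum, tpm_sum. ``group_totals``
    maps sample -> group -> summed TPM; the key :data:`POOLED` holds the
    across-sample sums. Additivity holds by construction: each group total
    equals the sum of its phylum cells.
    """

    table: pd.DataFrame
    group_totals: dict[str, dict[str, float]]

    def total(self, group: str, sample: Optional[str] = None) -> float:
        key = POOLED if sample is None else sample
        return self.group_totals.get(key, {}).get(group, 0.0)


def aggregate_tpm(
    abundances: pd.DataFrame,
    gene_groups: Mapping[str, frozenset[str] | set[str]] = DEFAULT_GENE_GROUPS,
    genome_phylum: Mapping[str, str] | None = None,
) -> TpmAggregation:
    """Sum TPM per (sample, gene group, phylum).

    *genome_phylum* maps every genome id in the table to its phylum name;
    unknown genomes are an error listing the offenders. Gene groups must be
    disjoint (a gene counted twice would break TPM conservation); genes in
    no group are summed under :data:`UNASSIGNED`, never dropped silently.
    """
    if genome_phylum is None:
        raise ValueError("genome_phylum mapping is required")
    symbol_to_group: dict[str, str] = {}
    for group, genes in gene_groups.items():
        for gene in genes:
            if gene in symbol_to_group:
                raise ValueError(
                    f"gene {gene} is in both {symbol_to_group[gene]!r} and {group!r};"
                    " groups must be disjoint"
                )
            symbol_to_group[gene] = group

    unknown = sorted(set(abundances["genome_id"]) - set(genome_phylum))
    if unknown:
        raise ValueError(f"abundances reference unknown genomes: {unknown[:10]}")

    df = abundances.copy()
    df["group"] = df["gene_symbol"].map(lambda s: symbol_to_group.get(s, UNASSIGNED))
    df["phylum"] = df["genome_id"].map(genome_phylum)
    table = (
        df.groupby(["sample_id", "group", "phylum"], as_index=False)["tpm"]
        .sum()
        .rename(columns={"tpm": "tpm_sum"})
        .sort_values(["sample_id", "group", "phylum"], kind="stable")
        .reset_index(drop=True)
    )
    group_totals: dict[str, dict[str, float]] = {}
    for sample, sub in table.groupby("sample_id"):
        group_totals[str(sample)] = sub.groupby("group")["tpm_sum"].sum().to_dict()
    pooled: dict[str, float] = {}
    for totals in group_totals.values():
        for group, v in totals.items():
            pooled[group] = pooled.get(group, 0.0) + v
    group_totals[POOLED] = pooled
    return TpmAggregation(table=table, group_totals=group_totals)


def expression_ratio(
    aggregation: TpmAggregation,
    group_a: str,
    group_b: str,
    sample: Optional[str] = None,
) -> float:
    """Ratio of summed TPM of two gene groups (pooled across samples when
    *sample* is None). Raises :class:`UndefinedRatio` on a zero denominator."""
    num = aggregation.total(group_a, sample)
    den = aggregation.total(group_b, sample)
    if den == 0:
        raise UndefinedRatio(
            f"group {group_b!r} has zero TPM in {sample or POOLED!r}"
        )
    return num / den
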