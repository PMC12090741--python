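"""Community-level rRNA operon (rrn) copy numbers.

The rrn copy number of a genome correlates with maximal growth rate:
copiotrophs (r-strategists) carry many operons, oligotrophs few. At the
community level the trait is summarised as the abundance-weighted mean
copy number over ASVs,

    avg_rrn = sum_i R_i * W_i / sum_i R_i,

where R_i is the read count of ASV_i in a sample and W_i its copy number
assigned from a reference table of taxon -> operons per genome. ASVs
without a reference match are excluded from both sums (renormalisation
rather than imputation) and the matched fraction of reads is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Taxonomic ranks used for reference matching, coarse to fine.
RANKS = ("phylum", "class", "order", "family", "genus")


class NoAssignedReadsError(ValueError):
    """A sample has zero reads with an assigned copy number."""


@dataclass
class RrnReference:
    """Taxon -> rrn copy number lookup (stands in for an operon-count database).

    ``table`` has one row per reference lineage with the columns in
    :data:`RANKS` (empty string = unresolved) plus ``copy_number``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in (*RANKS, "copy_number") if c not in self.table.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        if (self.table["copy_number"] < 1).any():
            raise ValueError("reference copy numbers must be >= 1")

    @classmethod
    def from_tsv(cls, path) -> "RrnReference":
        return cls(pd.read_csv(path, sep="\t", dtype={r: str for r in RANKS}).fillna(""))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AsvTable:
    """ASV x sample integer counts plus per-ASV taxonomic lineage.

    ``counts``: DataFrame indexed by ASV id, one column per sample.
    ``taxonomy``: DataFrame indexed by ASV id with the :data:`RANKS`
    columns; unresolved ranks are empty strings.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.taxonomy.index):
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
            if self.taxonomy.isna().any().any():
                raise ValueError("every ASV needs a taxonomy row")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, counts_path, taxonomy_path) -> "AsvTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str).fillna("")
        if "lineage" in tax.columns:  # semicolon-delimited 7-rank form
            ranks = tax["lineage"].str.split(";", expand=True)
            # kingdom;phylum;class;order;family;genus;species
            tax = pd.DataFrame(
                {r: ranks[i + 1].str.strip() for i, r in enumerate(RANKS)},
                index=tax.index,
            ).fillna("")
        return cls(counts, tax[list(RANKS)])


@dataclass
class CommunityRrnResult:
    """Per-sample community-weighted mean rrn copy number."""

    sample_id: str
    avg_rrn: float
    matched_fraction: float
    flagged: bool = field(default=False)


def assign_rrn_copies(
    table: AsvTable, reference: RrnReference, fallback_depth: str = "phylum"
) -> pd.Series:
    """Assign a copy number to each ASV from the most resolved matching rank.

    Matching walks genus -> family -> order -> class -> phylum, stopping at
    ``fallback_depth``. At the first (most resolved) rank where the ASV is
    resolved and at least one reference lineage carries the same name, the
    mean copy number of all such entries is assigned. ASVs with no match at
    or above ``fallback_depth`` get NaN.
    """
    if reference.table.empty:
        raise ValueError("reference is empty")
    if fallback_depth not in RANKS:
        raise ValueError(f"fallback_depth must be one of {RANKS}")
    stop = RANKS.index(fallback_depth)
    search = [r for r in reversed(RANKS) if RANKS.index(r) >= stop]

    # rank -> name -> mean copy number over matching reference rows
    lookups = {
        r: reference.table[reference.table[r] != ""].groupby(r)["copy_number"].mean()
        for r in search
    }
    out = pd.Series(np.nan, index=table.counts.index, dtype=float)
    for r in search:
        names = table.taxonomy[r]
        hit = out.isna() & (names != "") & names.isin(lookups[r].index)
        out[hit] = lookups[r].reindex(names[hit]).to_numpy()
    return out


def community_avg_rrn(
    table: AsvTable, copies: pd.Series, min_matched: float = 0.5
) -> pd.DataFrame:
    """Abundance-weighted mean copy number per sample.

    Reads of unassigned ASVs are excluded from numerator and denominator.
    Samples whose matched read fraction falls below ``min_matched`` are
    flagged but still reported.

    Raises
    ------
    NoAssignedReadsError
        If any sample has zero reads on assigned ASVs.
    """
    w = copies.reindex(table.counts.index)
    assigned = w.notna().to_numpy()
    c = table.counts.to_numpy(dtype=float)
    total = c.sum(axis=0)
    assigned_reads = c[assigned].sum(axis=0)
    empty = assigned_reads == 0
    if empty.any():
        bad = [s for s, e in zip(table.sample_ids, empty) if e]
        raise NoAssignedReadsError(f"no assigned reads in samples: {bad}")
    num = (c[assigned] * w.to_numpy()[assigned, None]).sum(axis=0)
    avg = num / assigned_reads
    with np.errstate(invalid="ignore"):
        matched = np.where(total > 0, assigned_reads / total, 0.0)
    return pd.DataFrame(
        {
            "avg_rrn": avg,
            "matched_fraction": matched,
            "flagged": matched < min_matched,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
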