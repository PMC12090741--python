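"""Functional-gene qPCR chip quantification.

Wells from a high-throughput qPCR chip (triplicate reactions per
sample x gene over 66 C/N/P-cycling targets plus 16S rRNA) are
quality-controlled, converted to absolute copies via a standard curve,
and normalised to gene copies per 16S copy.

QC retains a well iff its amplification efficiency lies in
[eff_low, eff_high], its negative control did not amplify, and its
threshold cycle CT <= ct_max (defaults 1.8, 2.2, 31 cycles). Copies are
recovered as 10**((ct - intercept)/slope) and replicates pooled by
geometric mean, matching the log scale of CT.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

WELL_COLUMNS = [
    "sample_id",
    "gene_id",
    "replicate",
    "ct",
    "efficiency",
    "neg_control_amplified",
]

#: QC exclusion rules in first-firing order.
QC_RULES = ("efficiency", "neg_control", "ct")


@dataclass
class StandardCurve:
    """CT = intercept + slope * log10(copies); slope < 0."""

    gene_id: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")

    def copies(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def ct(self, copies: float) -> float:
        return self.intercept + self.slope * np.log10(copies)


def load_gene_pathway_map() -> pd.Series:
    """Packaged gene -> pathway map for the 66 chip targets.

    The 48 genes of the well-established carbon-hydrolysis, inorganic
    nitrogen-transformation and phosphorus-solubilization pathways carry
    those labels; the remaining chip targets are labelled ``other``.
    """
    ref = importlib.resources.files("lifehist.data") / "gene_pathways.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")["pathway"]


def qc_filter(
    records: pd.DataFrame,
    eff_low: float = 1.8,
    eff_high: float = 2.2,
    ct_max: float = 31.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well QC.

    Returns (retained wells, exclusion log). The log has one row per
    excluded well with the first rule that fired, in the order
    efficiency -> negative control -> CT; an undetected CT (NaN) fails
    the CT rule.
    """
    r = records.copy()
    eff_bad = (r["efficiency"] < eff_low) | (r["efficiency"] > eff_high)
    neg_bad = r["neg_control_amplified"].astype(bool)
    ct_bad = ~(r["ct"] <= ct_max)  # NaN -> excluded
    rule = np.select(
        [eff_bad, ~eff_bad & neg_bad, ~eff_bad & ~neg_bad & ct_bad],
        QC_RULES,
        default="",
    )
    retained = r[rule == ""].reset_index(drop=True)
    log = r[rule != ""].reset_index(drop=True)
    log["rule"] = rule[rule != ""]
    return retained, log


def absolute_from_ct(
    records: pd.DataFrame, curves: dict[str, StandardCurve] | StandardCurve
) -> pd.DataFrame:
    """Absolute copies per sample x gene from retained wells.

    Per-replicate copies come from the gene's standard curve; the
    reported value is the geometric mean over surviving replicates.
    sample x gene pairs with no retained replicate are absent (NaN after
    pivoting).
    """
    if records.empty:
        raise ValueError("no retained wells")
    r = records.dropna(subset=["ct"]).copy()

    def curve_for(gene: str) -> StandardCurve:
        if isinstance(curves, StandardCurve):
            return curves
        if gene not in curves:
            raise KeyError(f"no standard curve for gene {gene!r}")
        return curves[gene]

    r["log10_copies"] = [
        (row.ct - curve_for(row.gene_id).intercept) / curve_for(row.gene_id).slope
        for row in r.itertuples()
    ]
    # geometric mean = 10 ** mean(log10 copies)
    pooled = 10.0 ** r.groupby(["sample_id", "gene_id"])["log10_copies"].mean()
    return pooled.unstack("gene_id")


def relative_abundance_matrix(
    gene_abs: pd.DataFrame, rrs_abs: pd.Series
) -> pd.DataFrame:
    """Gene copies per 16S rRNA gene copy.

    ``gene_abs``: sample x gene absolute copies. ``rrs_abs``: absolute
    16S copies per sample. Samples without a positive 16S value are
    dropped with a warning.
    """
    rrs = rrs_abs.reindex(gene_abs.index)
    ok = rrs.notna() & (rrs > 0)
    if not ok.all():
        import warnings

        dropped = list(gene_abs.index[~ok])
        warnings.warn(f"dropping samples without 16S quantification: {dropped}")
    return gene_abs.loc[ok].div(rrs[ok], axis=0)


def pathway_sums(matrix: pd.DataFrame, gene_map: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample summed relative abundance for C, N, P pathways and their total.

    ``gene_map`` maps each gene to one of C_hydrolysis, N_transformation,
    P_solubilization or other; the packaged chip map is used by default.
    Total = C + N + P (the ``other`` genes are excluded from the total,
    which covers the well-established pathways only).
    """
    if gene_map is None:
        gene_map = load_gene_pathway_map()
    unmapped = [g for g in matrix.columns if g not in gene_map.index]
    if unmapped:
        raise KeyError(f"genes missing from the pathway map: {unmapped}")
    out = {}
    for pw in ("C_hydrolysis", "N_transformation", "P_solubilization", "other"):
        genes = [g for g in matrix.columns if gene_map[g] == pw]
        out[pw] = matrix[genes].sum(axis=1) if genes else pd.Series(0.0, index=matrix.index)
    df = pd.DataFrame(out)
    df["total"] = df["C_hydrolysis"] + df["N_transformation"] + df["P_solubilization"]
    return df
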