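"""Metagenome-derived genomic traits.

Per-sample traits computed from shotgun reads, coding sequences, and
single-copy marker-gene hit tables:

* GC content mean and variance over quality-filtered reads (the variance,
  on a percent scale, discriminates generalist-rich from specialist-rich
  communities);
* genome equivalents from coverage of universal single-copy marker
  families, and average genome size (AGS) = total read bp / genome
  equivalents;
* codon usage bias (CUB) of ribosomal genes relative to the bulk coding
  background, using a MILC-type log-likelihood-ratio statistic with a
  degrees-of-freedom correction so background-like genes score ~0;
* predicted minimum generation time ``d = exp(b0 + b1 * CUB)`` from a
  linear calibration of ln(doubling time) on CUB, and predicted maximum
  growth rate ``1/d``. Strong ribosomal codon bias (large CUB, b1 < 0)
  marks fast growers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable
from Bio import SeqIO

__all__ = [
    "ReadSet",
    "MarkerProfile",
    "CodingGene",
    "CodingGeneSet",
    "CodonBackground",
    "GrowthCalibration",
    "GenomicTraitResult",
    "SYNONYMOUS_FAMILIES",
    "gc_profile",
    "genome_equivalents",
    "average_genome_size",
    "background_codon_usage",
    "milc",
    "community_cub",
    "fit_growth_calibration",
    "predict_growth",
    "kegg_category_proportions",
]


def _synonymous_families() -> dict[str, tuple[str, ...]]:
    """Multi-codon synonymous families of the bacterial code (table 11).

    Stop codons and single-codon families (Met, Trp) are excluded; only
    families offering a synonymous choice inform codon-usage bias.
    """
    table = CodonTable.unambiguous_dna_by_id[11]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return {
        aa: tuple(sorted(codons))
        for aa, codons in sorted(by_aa.items())
        if len(codons) > 1
    }


SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = _synonymous_families()
_CODON_TO_FAMILY: dict[str, str] = {
    c: aa for aa, codons in SYNONYMOUS_FAMILIES.items() for c in codons
}


@dataclass
class ReadSet:
    """Nucleotide reads (alphabet ACGTN) with their total base count."""

    sequences: list[str]

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences)

    @classmethod
    def from_fasta(cls, path) -> "ReadSet":
        return cls([str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")])


@dataclass
class MarkerProfile:
    """Read bp aligned to one universal single-copy marker family."""

    family_id: str
    family_len: int
    aligned_bp: float

    def __post_init__(self) -> None:
        if self.family_len <= 0:
            raise ValueError("family_len must be positive")
        if self.aligned_bp < 0:
            raise ValueError("aligned_bp must be non-negative")


@dataclass
class CodingGene:
    gene_id: str
    codons: tuple[str, ...]
    role: str  # "ribosomal" | "background"

    @classmethod
    def from_sequence(cls, gene_id: str, seq: str, role: str) -> "CodingGene":
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"{gene_id}: length not divisible by 3")
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        return cls(gene_id, codons, role)


@dataclass
class CodingGeneSet:
    genes: list[CodingGene]

    def by_role(self, role: str) -> list[CodingGene]:
        return [g for g in self.genes if g.role == role]

    @classmethod
    def from_fasta(cls, path) -> "CodingGeneSet":
        """Read genes from FASTA with ``role=ribosomal|background`` in headers."""
        genes = []
        for rec in SeqIO.parse(str(path), "fasta"):
            role = "background"
            for tok in rec.description.split():
                if tok.startswith("role="):
                    role = tok.split("=", 1)[1]
            genes.append(CodingGene.from_sequence(rec.id, str(rec.seq), role))
        return cls(genes)


@dataclass
class CodonBackground:
    """Within-family synonymous codon frequencies pooled over background genes."""

    freqs: dict[str, float]  # codon -> frequency, normalised within family
    missing_families: frozenset[str]  # families with zero observations


@dataclass
class GrowthCalibration:
    """ln(minimum generation time, h) = beta0 + beta1 * CUB."""

    beta0: float
    beta1: float
    r2: float | None = None


@dataclass
class GenomicTraitResult:
    sample_id: str
    gc_mean: float
    gc_var: float
    genome_equivalents: float
    ags: float
    cub: float
    min_gen_time_h: float
    max_growth_rate: float


def gc_profile(
    reads: ReadSet, min_len: int = 0, unit: str = "fraction"
) -> tuple[float, float]:
    """Mean and unbiased sample variance of per-read GC content.

    Per-read GC = (G+C)/(A+C+G+T); N bases are excluded from the
    denominator, and reads with no unambiguous base (or shorter than
    ``min_len``) are excluded from the moments. ``unit="percent"``
    multiplies per-read GC by 100 before taking moments, so the variance
    is on a %^2 scale.
    """
    if unit not in ("fraction", "percent"):
        raise ValueError("unit must be 'fraction' or 'percent'")
    vals = []
    for s in reads.sequences:
        if len(s) < min_len:
            continue
        gc = s.count("G") + s.count("C")
        at = s.count("A") + s.count("T")
        if gc + at == 0:
            continue
        vals.append(gc / (gc + at))
    if len(vals) < 2:
        raise ValueError("need at least 2 usable reads for GC moments")
    x = np.asarray(vals)
    if unit == "percent":
        x = x * 100.0
    return float(x.mean()), float(x.var(ddof=1))


def genome_equivalents(
    profiles: Sequence[MarkerProfile], aggregator: str = "median"
) -> float:
    """Number of genomes in the metagenome from single-copy marker coverage.

    Per-family coverage = aligned_bp / family_len; each family is present
    once per genome, so its pooled coverage counts genomes. The median
    (default) over families is robust to a mis-mapped family.
    """
    if not profiles:
        raise ValueError("no marker profiles")
    cov = np.array([p.aligned_bp / p.family_len for p in profiles])
    if (cov == 0).all():
        raise ValueError("zero coverage in all marker families")
    if aggregator == "median":
        return float(np.median(cov))
    if aggregator == "mean":
        return float(cov.mean())
    raise ValueError("aggregator must be 'median' or 'mean'")


def average_genome_size(total_bp: float, genome_equivalents: float) -> float:
    """AGS (bp) = total read base pairs / genome equivalents."""
    if genome_equivalents <= 0:
        raise ZeroDivisionError("genome_equivalents must be positive")
    return total_bp / genome_equivalents


def background_codon_usage(genes: CodingGeneSet | Iterable[CodingGene]) -> CodonBackground:
    """Pooled within-family codon frequencies of the background gene set.

    Pooling is count-weighted over all background genes (a long gene
    contributes more observations than a short one). Families never
    observed are flagged as missing rather than given frequencies.
    """
    pool = genes.by_role("background") if isinstance(genes, CodingGeneSet) else list(genes)
    if not pool:
        raise ValueError("need at least one background gene")
    counts: Counter[str] = Counter()
    for g in pool:
        counts.update(c for c in g.codons if c in _CODON_TO_FAMILY)
    freqs: dict[str, float] = {}
    missing = []
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        n = sum(counts[c] for c in codons)
        if n == 0:
            missing.append(aa)
            continue
        for c in codons:
            freqs[c] = counts[c] / n
    return CodonBackground(freqs, frozenset(missing))


@lru_cache(maxsize=100_000)
def _null_expectation(freqs: tuple[float, ...], n: int) -> float:
    """Exact E[M_a] for one family under Multinomial(n, freqs).

    M_a is additive over codons and each count is marginally binomial,
    so the expectation is a finite sum of binomial pmf terms.
    """
    o = np.arange(1, n + 1)
    log_o_over_n = np.log(o / n)
    total = 0.0
    for e_c in freqs:
        if e_c <= 0:
            continue
        pmf = stats.binom.pmf(o, n, e_c)
        total += float((pmf * 2.0 * o * (log_o_over_n - math.log(e_c))).sum())
    return total


def milc(
    codons: Sequence[str],
    background: CodonBackground | Mapping[str, float],
    correct: bool = True,
) -> float:
    value, _ = milc_with_length(codons, background, correct)
    return value


def milc_with_length(
    codons: Sequence[str],
    background: CodonBackground | Mapping[str, float],
    correct: bool = True,
) -> tuple[float, int]:
    """MILC statistic of one gene against the background, plus scored length.

    For each synonymous family a with observed codon counts O_c
    (n_a = sum O_c) and background within-family frequencies e_c:

        M_a = 2 * sum_c O_c * ln((O_c / n_a) / e_c)        (0*ln 0 := 0)

    raw = (sum_a M_a) / L with L = sum_a n_a over scored families. With
    ``correct``, the exact null expectation of each M_a under
    Multinomial(n_a, e) — asymptotically the chi-square degrees of
    freedom k_a - 1, but computed exactly from the binomial marginals,

        E[M_a] = sum_c sum_o Binom(o; n_a, e_c) * 2 o ln((o/n_a)/e_c),

    is subtracted (summed over scored families and divided by L), so the
    statistic has expectation 0 for genes drawn from the background at
    any gene length. Families absent from the background (or whose
    observed codons have zero background frequency) are skipped. Families absent from the
    background (or whose observed codons have zero background frequency)
    are skipped.
    """
    e = background.freqs if isinstance(background, CodonBackground) else dict(background)
    fam_counts: dict[str, Counter[str]] = {}
    for c in codons:
        aa = _CODON_TO_FAMILY.get(c)
        if aa is not None:
            fam_counts.setdefault(aa, Counter())[c] += 1
    total = 0.0
    L = 0
    expected = 0.0
    for aa, obs in fam_counts.items():
        codon_list = SYNONYMOUS_FAMILIES[aa]
        if any(c not in e for c in codon_list):
            continue  # family absent from background
        if any(e[c] == 0 and obs[c] > 0 for c in codon_list):
            continue  # observed codon impossible under background
        n_a = sum(obs.values())
        m_a = 2.0 * sum(
            o * math.log((o / n_a) / e[c]) for c, o in obs.items() if o > 0
        )
        total += m_a
        L += n_a
        expected += _null_expectation(
            tuple(e[c] for c in codon_list), n_a
        )
    if L == 0:
        return 0.0, 0
    value = total / L
    if correct:
        value -= expected / L
    return value, L


def community_cub(
    genes: CodingGeneSet, background: CodonBackground | Mapping[str, float]
) -> float:
    """Length-weighted mean corrected MILC over ribosomal genes."""
    ribo = genes.by_role("ribosomal")
    if not ribo:
        raise ValueError("need at least one ribosomal gene")
    num = 0.0
    den = 0
    for g in ribo:
        v, L = milc_with_length(g.codons, background, correct=True)
        num += v * L
        den += L
    if den == 0:
        raise ValueError("no scorable codons in ribosomal genes")
    return num / den


def fit_growth_calibration(
    pairs: Sequence[tuple[float, float]]
) -> GrowthCalibration:
    """OLS of ln(known generation time, h) on CUB.

    Needs >= 3 pairs with positive times; raises on a constant-CUB design.
    Two-point exact interpolation is allowed via the same formula when the
    caller passes exactly the minimum informative design.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 (cub, generation time) pairs")
    cub = np.array([p[0] for p in pairs], dtype=float)
    d = np.array([p[1] for p in pairs], dtype=float)
    if (d <= 0).any():
        raise ValueError("generation times must be positive")
    if np.ptp(cub) == 0:
        raise ValueError("degenerate design: constant CUB")
    y = np.log(d)
    b1, b0 = np.polyfit(cub, y, 1)
    resid = y - (b0 + b1 * cub)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return GrowthCalibration(float(b0), float(b1), r2)


def predict_growth(cub: float, calib: GrowthCalibration) -> tuple[float, float]:
    """(minimum generation time in h, maximum growth rate in 1/h)."""
    if not np.isfinite(cub):
        raise ValueError("cub must be finite")
    d = math.exp(calib.beta0 + calib.beta1 * cub)
    return d, 1.0 / d


def kegg_category_proportions(annotations: pd.DataFrame) -> pd.Series:
    """Per-category fraction of annotated records.

    ``annotations`` has columns ``record_id`` and ``category``. A record
    annotated to m categories contributes 1/m to each; unannotated records
    simply do not appear and are excluded from the denominator.
    """
    if annotations.empty:
        raise ValueError("empty annotation set")
    ann = annotations[["record_id", "category"]].dropna()
    if ann.empty:
        raise ValueError("empty annotation set")
    m = ann.groupby("record_id")["category"].transform("size")
    weights = 1.0 / m
    n_records = ann["record_id"].nunique()
    return weights.groupby(ann["category"]).sum() / n_records
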