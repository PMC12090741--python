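"""Synthetic data with recorded ground truth for every pipeline stage.

Each generator is a pure function of its arguments including the seed and
returns, alongside the data, a :class:`SyntheticTruth` recording the
planted quantities (expected community rrn per sample, genome sizes,
generation time, qPCR abundances, driver coefficients), so downstream
estimators can be tested for recovery without any external data.

The community generator emulates a two-ecosystem (cropland/pristine),
multi-site survey: log-normal taxon abundances (sigma = 1 on the log
scale, a heavy-tailed rank-abundance shape), with the log abundance of
high-rrn ("copiotroph") taxa — those above the reference median copy
number — shifted by a configurable effect in cropland samples plus a
Normal(0, site_sd^2) site random intercept, then multinomial read
sampling at the requested depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metagenome import (
    SYNONYMOUS_FAMILIES,
    CodingGene,
    CodingGeneSet,
    CodonBackground,
    GrowthCalibration,
    MarkerProfile,
    ReadSet,
)
from .qpcr import WELL_COLUMNS, StandardCurve
from .rrn import RANKS, AsvTable, RrnReference

__all__ = [
    "SyntheticTruth",
    "gen_reference",
    "gen_communities",
    "calibrate_effect",
    "gen_metagenome",
    "gen_coding_genes",
    "random_background",
    "gen_qpcr",
    "gen_soil_drivers",
    "random_tree",
]


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside every generated dataset."""

    seed: int | None = None
    true_community_rrn: pd.Series | None = None
    true_effect_rrn: float | None = None
    site_effects: pd.Series | None = None
    true_genome_sizes: list[float] | None = None
    true_ags: float | None = None
    true_gc_mean: float | None = None
    true_gc_var: float | None = None
    true_cub: float | None = None
    true_generation_time_h: float | None = None
    calib_beta0: float | None = None
    calib_beta1: float | None = None
    true_gene_abundance: pd.DataFrame | None = None
    driver_coefs: pd.Series | None = None
    active_predictors: tuple[str, ...] | None = None

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            if v is None:
                continue
            if isinstance(v, pd.Series):
                out[k] = v.to_dict()
            elif isinstance(v, pd.DataFrame):
                out[k] = {c: v[c].to_dict() for c in v.columns}
            elif isinstance(v, tuple):
                out[k] = list(v)
            else:
                out[k] = v
        return out


# ---------------------------------------------------------------------------
# rrn reference and amplicon communities


def gen_reference(
    n_taxa: int, copy_range: tuple[float, float] = (1.0, 15.0), seed: int = 0
) -> RrnReference:
    """Reference table of ``n_taxa`` unique lineages with rrn copy numbers.

    Copy numbers are uniform on ``copy_range`` rounded to the nearest 0.5
    (operon counts in compilations are averages over strains, hence the
    half-integer grid). Lineages form a simple nested hierarchy, unique
    at genus level.
    """
    low, high = copy_range
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not (1 <= low <= high):
        raise ValueError("need 1 <= low <= high")
    rng = np.random.default_rng(seed)
    copies = np.round(rng.uniform(low, high, n_taxa) * 2) / 2
    copies = np.clip(copies, max(1.0, low), high)
    idx = np.arange(n_taxa)
    table = pd.DataFrame(
        {
            "phylum": [f"Phylum{i:02d}" for i in idx // 81],
            "class": [f"Class{i:03d}" for i in idx // 27],
            "order": [f"Order{i:03d}" for i in idx // 9],
            "family": [f"Family{i:04d}" for i in idx // 3],
            "genus": [f"Genus{i:05d}" for i in idx],
            "copy_number": copies,
        }
    )
    return RrnReference(table)


def _base_log_abundance(rng: np.random.Generator, n_taxa: int) -> np.ndarray:
    # first draw of the community stream; calibrate_effect relies on this
    return rng.normal(0.0, 1.0, n_taxa)


def _expected_rrn(base: np.ndarray, shift: float, high: np.ndarray, w: np.ndarray) -> float:
    logp = base + shift * high
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(p @ w)


def gen_communities(
    reference: RrnReference,
    n_sites: int,
    samples_per_site: int,
    effect: float,
    site_sd: float,
    depth: int | Sequence[int],
    seed: int = 0,
) -> tuple[AsvTable, pd.DataFrame, SyntheticTruth]:
    """Two-ecosystem multi-site ASV counts with a planted copiotroph shift.

    Half the sites are cropland, half pristine (``n_sites`` must be
    even). One ASV per reference taxon. ``depth`` may be a scalar or a
    per-sample vector. Truth records the exact expected community rrn of
    every sample computed from the pre-sampling relative abundances, and
    the cropland-minus-pristine mean difference of those expectations.
    """
    if n_sites % 2:
        raise ValueError("n_sites must be even (balanced design)")
    n_samples = n_sites * samples_per_site
    depths = np.broadcast_to(np.asarray(depth, dtype=np.int64), (n_samples,))
    if (depths < 1).any():
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    w = reference.table["copy_number"].to_numpy(dtype=float)
    n_taxa = len(w)
    base = _base_log_abundance(rng, n_taxa)
    high = (w > np.median(w)).astype(float)
    site_effects = rng.normal(0.0, site_sd, n_sites) if site_sd > 0 else np.zeros(n_sites)

    asv_ids = [f"ASV{i:05d}" for i in range(n_taxa)]
    taxonomy = reference.table[list(RANKS)].copy()
    taxonomy.index = pd.Index(asv_ids)

    sample_ids, ecosystems, site_ids, cols, exp_rrn = [], [], [], {}, {}
    half = n_sites // 2
    for s in range(n_sites):
        eco = "cropland" if s < half else "pristine"
        site_id = f"site{s:02d}"
        shift = (effect if eco == "cropland" else 0.0) + site_effects[s]
        logp = base + shift * high
        p = np.exp(logp - logp.max())
        p /= p.sum()
        for r in range(samples_per_site):
            sid = f"{site_id}_s{r}"
            j = len(sample_ids)
            cols[sid] = rng.multinomial(depths[j], p)
            exp_rrn[sid] = float(p @ w)
            sample_ids.append(sid)
            ecosystems.append(eco)
            site_ids.append(site_id)

    counts = pd.DataFrame(cols, index=pd.Index(asv_ids))
    metadata = pd.DataFrame(
        {"ecosystem": ecosystems, "site_id": site_ids},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    rrn_series = pd.Series(exp_rrn)
    is_crop = metadata["ecosystem"] == "cropland"
    truth = SyntheticTruth(
        seed=seed,
        true_community_rrn=rrn_series,
        true_effect_rrn=float(rrn_series[is_crop].mean() - rrn_series[~is_crop].mean()),
        site_effects=pd.Series(site_effects, index=[f"site{s:02d}" for s in range(n_sites)]),
    )
    return AsvTable(counts, taxonomy), metadata, truth


def calibrate_effect(
    reference: RrnReference,
    target_rel_diff: float,
    seed: int = 0,
    max_effect: float = 10.0,
) -> float:
    """Log-abundance effect planting a target relative community-rrn difference.

    Solves, by bisection on the deterministic expected-rrn curve of the
    community that :func:`gen_communities` will draw under the same seed
    (site effects aside), for the effect giving
    (rrn_cropland - rrn_pristine) / rrn_pristine = ``target_rel_diff``.
    """
    if target_rel_diff < 0:
        raise ValueError("target_rel_diff must be >= 0")
    rng = np.random.default_rng(seed)
    w = reference.table["copy_number"].to_numpy(dtype=float)
    base = _base_log_abundance(rng, len(w))
    high = (w > np.median(w)).astype(float)
    r0 = _expected_rrn(base, 0.0, high, w)

    def rel(effect: float) -> float:
        return (_expected_rrn(base, effect, high, w) - r0) / r0

    if target_rel_diff == 0:
        return 0.0
    lo, hi = 0.0, max_effect
    if rel(hi) < target_rel_diff:
        raise ValueError("target difference unreachable within max_effect")
    for _ in range(80):
        mid = (lo + hi) / 2
        if rel(mid) < target_rel_diff:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# metagenome reads and markers

_BASE_LOOKUP = np.frombuffer(b"GCAT", dtype=np.uint8)


def gen_metagenome(
    genome_sizes: Sequence[float],
    marker_families: int = 30,
    marker_len: int = 3000,
    read_len: int = 150,
    n_reads: int = 100_000,
    gc_mean: float = 0.55,
    gc_sd: float = 0.05,
    seed: int = 0,
) -> tuple[ReadSet, list[MarkerProfile], SyntheticTruth]:
    """Reads and single-copy-marker hit table from genomes of known size.

    Each genome carries exactly one copy of every marker family, placed
    in its interior; read starts are uniform along genomes (genome chosen
    proportionally to its length), so pooled per-family coverage counts
    genome sampling depth and AGS = total read bp / median coverage
    recovers the mean genome size. Per-read GC is truncated
    Normal(gc_mean, gc_sd^2) on (0, 1).
    """
    sizes = np.asarray(genome_sizes, dtype=np.int64)
    if len(sizes) == 0:
        raise ValueError("need at least one genome")
    if not 0 < gc_mean < 1:
        raise ValueError("gc_mean must be in (0, 1)")
    if (sizes <= marker_families * marker_len).any():
        raise ValueError("all genome sizes must exceed marker_families * marker_len")
    if read_len > sizes.min():
        raise ValueError("read_len exceeds the smallest genome")
    rng = np.random.default_rng(seed)

    # reads: genome index ~ length-proportional, start uniform in-genome
    span = sizes - read_len + 1
    probs = span / span.sum()
    genome_idx = rng.choice(len(sizes), size=n_reads, p=probs)
    starts = (rng.random(n_reads) * span[genome_idx]).astype(np.int64)

    # per-read GC, truncated normal on (0, 1)
    if gc_sd == 0:
        gcs = np.full(n_reads, gc_mean)
    else:
        gcs = rng.normal(gc_mean, gc_sd, n_reads)
        bad = (gcs <= 0) | (gcs >= 1)
        while bad.any():
            gcs[bad] = rng.normal(gc_mean, gc_sd, bad.sum())
            bad = (gcs <= 0) | (gcs >= 1)

    # each read carries exactly round(gc * read_len) G+C bases at random
    # positions, so the planted per-read GC distribution is reproduced
    # without binomial sampling noise (gc_sd=0 -> variance exactly 0)
    n_gc_all = np.rint(gcs * read_len).astype(np.int64)
    sequences: list[str] = []
    chunk = 20_000
    for i0 in range(0, n_reads, chunk):
        n_gc = n_gc_all[i0 : i0 + chunk, None]
        m = n_gc.shape[0]
        order = np.argsort(rng.random((m, read_len)), axis=1)
        gc_bits = rng.integers(2, size=(m, read_len), dtype=np.uint8)  # G/C
        at_bits = rng.integers(2, size=(m, read_len), dtype=np.uint8)  # A/T
        vals = np.where(np.arange(read_len) < n_gc, gc_bits, 2 + at_bits)
        codes = np.empty((m, read_len), dtype=np.uint8)
        np.put_along_axis(codes, order, vals.astype(np.uint8), axis=1)
        rows = _BASE_LOOKUP[codes]
        sequences.extend(bytes(row).decode("ascii") for row in rows)

    # marker block occupies [read_len, read_len + marker_families*marker_len)
    # in every genome; aligned bp = read overlap with each family interval
    offset = read_len
    aligned = np.zeros(marker_families)
    ends = starts + read_len
    for f in range(marker_families):
        lo = offset + f * marker_len
        hi = lo + marker_len
        ov = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0, None)
        aligned[f] = ov.sum()
    profiles = [
        MarkerProfile(f"marker{f:02d}", marker_len, float(aligned[f]))
        for f in range(marker_families)
    ]
    truth = SyntheticTruth(
        seed=seed,
        true_genome_sizes=[float(s) for s in sizes],
        true_ags=float(sizes.mean()),
        true_gc_mean=gc_mean,
        true_gc_var=gc_sd**2,
    )
    return ReadSet(sequences), profiles, truth


# ---------------------------------------------------------------------------
# coding genes with tunable ribosomal codon bias


def random_background(seed: int = 0, concentration: float = 5.0) -> CodonBackground:
    """Mildly non-uniform within-family codon frequencies (Dirichlet draws)."""
    rng = np.random.default_rng(seed)
    freqs: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        p = rng.dirichlet(np.full(len(codons), concentration))
        for c, v in zip(codons, p):
            freqs[c] = float(v)
    return CodonBackground(freqs, frozenset())


def _tilted(e: np.ndarray, bias: float) -> np.ndarray:
    """Exponentially tilt frequencies toward the preferred (modal) codon."""
    pref = int(np.argmax(e))
    p = e * np.exp(bias * (np.arange(len(e)) == pref))
    return p / p.sum()


def gen_coding_genes(
    background_freqs: CodonBackground | Mapping[str, float],
    bias: float,
    n_ribosomal: int,
    n_background: int,
    gene_len_codons: int = 200,
    calib: GrowthCalibration | None = None,
    seed: int = 0,
) -> tuple[CodingGeneSet, SyntheticTruth]:
    """Background genes from the background codon distribution and
    ribosomal genes from frequencies exponentially tilted toward each
    family's preferred codon with strength ``bias``.

    Amino-acid families are used uniformly within each gene. Truth
    records the asymptotic expected corrected MILC of the ribosomal set
    (the mean within-family 2*KL divergence of tilted vs background
    frequencies) and, when a calibration is given, the generation time it
    implies at that CUB.
    """
    if bias < 0:
        raise ValueError("bias must be >= 0")
    if n_ribosomal < 1:
        raise ValueError("need at least one ribosomal gene")
    e = (
        background_freqs.freqs
        if isinstance(background_freqs, CodonBackground)
        else dict(background_freqs)
    )
    fams = [
        (aa, codons, np.array([e[c] for c in codons]))
        for aa, codons in SYNONYMOUS_FAMILIES.items()
        if all(c in e for c in codons)
    ]
    if not fams:
        raise ValueError("background covers no synonymous family")
    rng = np.random.default_rng(seed)
    n_fam = len(fams)

    def sample_gene(gene_id: str, role: str, tilt: float) -> CodingGene:
        fam_counts = rng.multinomial(gene_len_codons, np.full(n_fam, 1.0 / n_fam))
        codon_list: list[str] = []
        for (aa, codons, ef), m in zip(fams, fam_counts):
            if m == 0:
                continue
            p = _tilted(ef, tilt) if tilt > 0 else ef
            for c, k in zip(codons, rng.multinomial(m, p)):
                codon_list.extend([c] * k)
        perm = rng.permutation(len(codon_list))
        return CodingGene(gene_id, tuple(codon_list[i] for i in perm), role)

    genes = [sample_gene(f"bg{i:04d}", "background", 0.0) for i in range(n_background)]
    genes += [sample_gene(f"ribo{i:04d}", "ribosomal", bias) for i in range(n_ribosomal)]

    # asymptotic expected corrected MILC: mean within-family 2*KL(tilted || background)
    kl = 0.0
    for aa, codons, ef in fams:
        p = _tilted(ef, bias) if bias > 0 else ef
        kl += 2.0 * float(np.sum(p * np.log(p / ef)))
    true_cub = kl / n_fam
    truth = SyntheticTruth(seed=seed, true_cub=true_cub)
    if calib is not None:
        truth.calib_beta0 = calib.beta0
        truth.calib_beta1 = calib.beta1
        truth.true_generation_time_h = math.exp(calib.beta0 + calib.beta1 * true_cub)
    return CodingGeneSet(genes), truth


# ---------------------------------------------------------------------------
# negative-binomial genus counts for differential-abundance calibration


def gen_nb_counts(
    n_genera: int,
    n_samples: int,
    dispersion: float,
    fold_changes: Mapping[int, float] | None = None,
    mean_log_range: tuple[float, float] = (2.0, 7.0),
    size_factor_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Genus x sample NB counts for a two-group design.

    Genus base means are log-uniform over ``mean_log_range`` (natural
    log), per-sample library-size factors log-uniform over
    ``size_factor_range``. ``fold_changes`` maps genus index -> fold
    change applied to the second group ("cropland"); all other genera
    are null. Counts ~ NB(mean = sf * mu, dispersion alpha) via the
    gamma-Poisson mixture.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    fold_changes = dict(fold_changes or {})
    mu = np.exp(rng.uniform(*mean_log_range, n_genera))
    sf = np.exp(rng.uniform(np.log(size_factor_range[0]), np.log(size_factor_range[1]), n_samples))
    half = n_samples // 2
    groups = pd.Series(
        ["pristine"] * half + ["cropland"] * (n_samples - half),
        index=[f"s{j:02d}" for j in range(n_samples)],
    )
    fc = np.ones((n_genera, n_samples))
    for g, f in fold_changes.items():
        fc[g, half:] = f
    mean = mu[:, None] * sf[None, :] * fc
    if dispersion == 0:
        counts = rng.poisson(mean)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=[f"g{i:03d}" for i in range(n_genera)], columns=groups.index)
    truth = SyntheticTruth(seed=seed)
    truth.driver_coefs = pd.Series(
        {f"g{i:03d}": np.log2(f) for i, f in fold_changes.items()}, dtype=float
    )
    return df, groups, truth


# ---------------------------------------------------------------------------
# qPCR plates


def gen_qpcr(
    true_abundance: pd.DataFrame,
    curve: StandardCurve | Mapping[str, StandardCurve],
    frac_bad_eff: float = 0.0,
    frac_neg_amp: float = 0.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Triplicate qPCR wells with planted QC violations.

    CT = intercept + slope*log10(copies) + Normal(0, noise_sd^2). Each
    well independently gets an out-of-spec efficiency (outside
    [1.8, 2.2]) with probability ``frac_bad_eff`` and a negative-control
    amplification flag with probability ``frac_neg_amp``; in-spec wells
    get efficiencies uniform on [1.9, 2.1].
    """
    if (true_abundance.to_numpy() <= 0).any():
        raise ValueError("abundances must be positive")
    for frac in (frac_bad_eff, frac_neg_amp):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def curve_for(gene: str) -> StandardCurve:
        return curve if isinstance(curve, StandardCurve) else curve[gene]

    rows = []
    for sample in true_abundance.index:
        for gene in true_abundance.columns:
            c = curve_for(gene)
            base_ct = c.ct(true_abundance.loc[sample, gene])
            for rep in range(n_replicates):
                ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                if rng.random() < frac_bad_eff:
                    if rng.random() < 0.5:
                        eff = rng.uniform(1.5, 1.79)
                    else:
                        eff = rng.uniform(2.21, 2.5)
                else:
                    eff = rng.uniform(1.9, 2.1)
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": gene,
                        "replicate": rep,
                        "ct": ct,
                        "efficiency": eff,
                        "neg_control_amplified": bool(rng.random() < frac_neg_amp),
                    }
                )
    records = pd.DataFrame(rows, columns=WELL_COLUMNS)
    truth = SyntheticTruth(seed=seed, true_gene_abundance=true_abundance.copy())
    return records, truth


# ---------------------------------------------------------------------------
# soil nutrient drivers


def gen_soil_drivers(
    n_samples: int,
    driver_coefs: Mapping[str, float],
    collinearity: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Multivariate-normal predictors and a linear trait response.

    ``driver_coefs`` maps predictor name -> true coefficient (0 for
    inactive predictors that should still be generated). ``collinearity``
    is the predictor correlation matrix (identity by default, must be
    positive definite). Returns (predictor table, response, truth).
    """
    names = list(driver_coefs)
    k = len(names)
    corr = np.eye(k) if collinearity is None else np.asarray(collinearity, dtype=float)
    if corr.shape != (k, k):
        raise ValueError("correlation matrix shape must match the number of predictors")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix must be positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_samples, k))
    X = z @ chol.T
    beta = np.array([driver_coefs[n] for n in names])
    y = X @ beta + rng.normal(0.0, noise_sd, n_samples)
    idx = pd.Index([f"sample{i:03d}" for i in range(n_samples)], name="sample_id")
    meta = pd.DataFrame(X, columns=names, index=idx)
    truth = SyntheticTruth(
        seed=seed,
        driver_coefs=pd.Series(beta, index=names),
        active_predictors=tuple(n for n in names if driver_coefs[n] != 0),
    )
    return meta, pd.Series(y, index=idx, name="trait"), truth


# ---------------------------------------------------------------------------
# random tree (for UniFrac tests only; not phylogenetically realistic)


def random_tree(leaf_names: Sequence[str], seed: int = 0) -> str:
    """Random bifurcating newick tree with exponential branch lengths."""
    rng = np.random.default_rng(seed)
    names = list(leaf_names)
    if not names:
        raise ValueError("need at least one leaf")
    order = rng.permutation(len(names))
    names = [names[i] for i in order]

    def build(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return leaves[0]
        split = int(rng.integers(1, len(leaves)))
        left, right = build(leaves[:split]), build(leaves[split:])
        bl = rng.exponential(0.5, 2) + 0.05
        return f"({left}:{bl[0]:.6f},{right}:{bl[1]:.6f})"

    return build(names) + ";"
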