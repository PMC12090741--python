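"""Community ecology on ASV tables.

Rarefaction, alpha diversity (Shannon, bias-corrected Chao1), Bray-Curtis
and normalized weighted UniFrac distances, nonmetric multidimensional
scaling, and a self-contained negative-binomial Wald test for responsive
genera (|log2 fold change| > 1 and Benjamini-Hochberg adjusted P < 0.05,
cropland vs pristine).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity
from sklearn.isotonic import isotonic_regression

from .rrn import AsvTable

DEFAULT_RAREFACTION_DEPTH = 33018


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T) or (np.diag(d) != 0).any() or (d < 0).any():
            raise ValueError("not a valid distance matrix")
        self.data = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


@dataclass
class Ordination:
    coordinates: pd.DataFrame  # columns NMDS1, NMDS2, ...
    stress: float
    converged: bool = field(default=True)


def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning. Uses multivariate hypergeometric draws, so the result is an
    exact uniform subsample and deterministic under the seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals >= depth
    if not keep.all():
        import warnings

        warnings.warn(f"dropping samples below depth {depth}: {list(totals.index[~keep])}")
    cols = {}
    for s in table.counts.columns[keep]:
        c = table.counts[s].to_numpy(dtype=np.int64)
        cols[s] = rng.multivariate_hypergeometric(c, depth, method="marginals")
    counts = pd.DataFrame(cols, index=table.counts.index)
    return AsvTable(counts, table.taxonomy.copy())


def alpha_diversity(table: AsvTable, chao1_bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample Shannon (natural log), Chao1, and observed richness.

    Chao1 defaults to the bias-corrected form
    S_obs + F1(F1-1)/(2(F2+1)), which stays defined when doubletons are
    absent; the classic F1^2/(2 F2) form is available via the flag.
    """
    rows = {}
    for s in table.counts.columns:
        c = table.counts[s].to_numpy(dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValueError(f"sample {s!r} has zero reads")
        p = c[c > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        s_obs = int((c > 0).sum())
        f1 = int((c == 1).sum())
        f2 = int((c == 2).sum())
        if chao1_bias_corrected:
            chao1 = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
        else:
            chao1 = s_obs + (f1 * f1 / (2 * f2) if f2 > 0 else 0.0)
        rows[s] = {"shannon": shannon, "chao1": chao1, "observed": s_obs}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on per-sample proportions."""
    x = table.counts.to_numpy(dtype=float).T
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero samples: {bad}")
    p = x / totals[:, None]
    return DistanceMatrix(table.sample_ids, squareform(pdist(p, metric="braycurtis")))


def weighted_unifrac(table: AsvTable, tree: TreeNode | str) -> DistanceMatrix:
    """Normalized weighted UniFrac between all sample pairs.

    d(A,B) = sum_b l_b |p_A(b) - p_B(b)| / sum_b l_b (p_A(b) + p_B(b)),
    where p_X(b) is the proportion of sample X's reads descending from
    branch b. Bounded in [0, 1]. Every ASV must be a tree leaf.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    leaves = {t.name for t in tree.tips()}
    missing = [a for a in table.counts.index if a not in leaves]
    if missing:
        raise ValueError(f"ASVs missing from tree: {missing}")
    counts = table.counts.to_numpy(dtype=float).T
    dm = beta_diversity(
        "weighted_unifrac",
        counts,
        ids=table.sample_ids,
        taxa=list(table.counts.index),
        tree=tree,
        normalized=True,
    )
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data))


def _kruskal_stress1(dissim: np.ndarray, config: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities.

    Disparities are the isotonic (monotone) regression of configuration
    distances on the dissimilarity order, so the value depends on the
    input only through ranks.
    """
    d = pdist(config)
    order = np.argsort(dissim, kind="stable")
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order])
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _smacof_nonmetric(
    dissim: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool]:
    """One SMACOF run: majorization with isotonic disparities.

    The update path depends on the dissimilarities only through their
    rank order, so stress is exactly invariant under strictly monotone
    transforms of the input.
    """
    n = int((1 + math.isqrt(1 + 8 * len(dissim))) // 2)
    order = np.argsort(dissim, kind="stable")
    X = rng.uniform(size=(n, k))
    old = None
    converged = False
    for _ in range(max_iter):
        d = pdist(X)
        dhat = np.empty_like(d)
        dhat[order] = isotonic_regression(d[order])
        denom = float((d**2).sum())
        if denom == 0:
            break
        stress = math.sqrt(((d - dhat) ** 2).sum() / denom)
        if old is not None and (old - stress) < tol * max(old, 1e-12):
            converged = True
            break
        old = stress
        # Guttman transform; coincident points get a tiny distance
        dsq = squareform(np.maximum(d, 1e-8))
        np.fill_diagonal(dsq, 1.0)
        ratio = squareform(dhat) / dsq
        B = -ratio
        B[np.diag_indices(n)] += ratio.sum(axis=1)
        X = (B @ X) / n
    d = pdist(X)
    stress = _kruskal_stress1(dissim, X)
    return X, stress, converged


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> Ordination:
    """Nonmetric MDS by SMACOF majorization with isotonic regression.

    Best of ``n_restarts`` random starts; the returned configuration is
    centred, rotated to principal axes, and sign-fixed so every axis has
    a non-negative coordinate for the first sample — a deterministic
    orientation convention (axis signs are otherwise arbitrary). Stress
    is Kruskal stress-1, and depends on the input dissimilarities only
    through their ranks.
    """
    n = len(dist.ids)
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    rng = np.random.default_rng(seed)
    dissim = dist.condensed()
    best = None
    for _ in range(n_restarts):
        X, stress, conv = _smacof_nonmetric(dissim, k, rng, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, conv)
    coords, _, converged = best
    coords = coords - coords.mean(axis=0)
    # principal-axis rotation
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for j in range(k):
        if coords[0, j] < 0:
            coords[:, j] = -coords[:, j]
    stress = _kruskal_stress1(dist.condensed(), coords)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return Ordination(pd.DataFrame(coords, index=dist.ids, columns=cols), stress, converged)


def aggregate_by_genus(table: AsvTable) -> pd.DataFrame:
    """Sum ASV counts sharing a genus label into a genus x sample table.

    ASVs without a resolved genus are grouped per family as
    ``unclassified_<family>`` (or ``unclassified`` when the family is
    also unresolved).
    """
    genus = table.taxonomy["genus"].copy()
    fam = table.taxonomy["family"]
    unres = genus == ""
    genus[unres] = "unclassified_" + fam[unres]
    genus[genus == "unclassified_"] = "unclassified"
    return table.counts.groupby(genus).sum()


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    For each genus with a finite, nonzero geometric mean across samples,
    form the ratio of its count to that geometric mean; a sample's factor
    is the median ratio. Requires at least one genus nonzero everywhere.
    """
    c = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    ok = np.isfinite(logc).all(axis=1)
    if not ok.any():
        raise ValueError(
            "no genus is nonzero in every sample; consider a pseudo-reference"
        )
    log_gm = logc[ok].mean(axis=1, keepdims=True)
    sf = np.median(np.exp(logc[ok] - log_gm), axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    sf: pd.Series | None = None,
    reference: str | None = None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Negative-binomial Wald test for differential genus abundance.

    A deliberately simple, self-contained procedure: median-of-ratios
    normalization, per-genus method-of-moments NB dispersion shrunk
    halfway (log scale) toward a mean-dispersion trend fitted across
    genera, and a Wald z-test on log2(mu2/mu1) with a delta-method SE
    from the NB variance mu + alpha*mu^2. ``reference`` names the
    baseline group (defaults to the alphabetically first label), so
    log2fc > 0 means enrichment in the other group. A genus is
    ``responsive`` when |log2fc| > ``lfc_threshold`` and BH-adjusted
    p < ``alpha``. Numerical agreement with heavier shrinkage estimators
    is not a goal; calibration on the synthetic null is.
    """
    groups = pd.Series(groups).reindex(counts.columns)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    ref = reference if reference is not None else labels[0]
    if ref not in labels:
        raise ValueError(f"reference {ref!r} not among group labels {labels}")
    other = labels[1] if ref == labels[0] else labels[0]
    idx1 = (groups == ref).to_numpy()
    idx2 = (groups == other).to_numpy()
    if idx1.sum() < 2 or idx2.sum() < 2:
        raise ValueError("need >= 2 samples per group")

    nonzero = counts.sum(axis=1) > 0
    excluded = list(counts.index[~nonzero])
    counts = counts[nonzero]
    if sf is None:
        sf = size_factors(counts)
    sfv = sf.reindex(counts.columns).to_numpy(dtype=float)
    q = counts.to_numpy(dtype=float) / sfv  # normalized counts

    q1, q2 = q[:, idx1], q[:, idx2]
    n1, n2 = q1.shape[1], q2.shape[1]
    mu1, mu2 = q1.mean(axis=1), q2.mean(axis=1)
    base_mean = q.mean(axis=1)

    # method-of-moments dispersion from pooled within-group moments
    s2 = (q1.var(axis=1, ddof=1) * (n1 - 1) + q2.var(axis=1, ddof=1) * (n2 - 1)) / (
        n1 + n2 - 2
    )
    mu_bar = (mu1 * n1 + mu2 * n2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = np.where(mu_bar > 0, (s2 - mu_bar) / mu_bar**2, np.nan)
    disp_raw = np.clip(disp_raw, 1e-8, 10.0)

    # trend: log dispersion on log mean across genera, then shrink halfway
    log_mu = np.log(np.maximum(mu_bar, 1e-8))
    log_disp = np.log(disp_raw)
    if len(log_mu) >= 3 and np.ptp(log_mu) > 0:
        slope, intercept = np.polyfit(log_mu, log_disp, 1)
        trend = intercept + slope * log_mu
    else:
        trend = np.full_like(log_disp, log_disp.mean())
    disp = np.exp(0.5 * (log_disp + trend))

    m1, m2 = mu1 + 0.5, mu2 + 0.5  # pseudo-count before log
    log2fc = np.log2(m2 / m1)
    # Var(mean of q) per group under NB: q_j = c_j/sf_j, Var = mu/sf_j + alpha mu^2
    inv_sf1 = (1.0 / sfv[idx1]).sum()
    inv_sf2 = (1.0 / sfv[idx2]).sum()
    var_mu1 = (m1 * inv_sf1 + disp * m1**2 * n1) / n1**2
    var_mu2 = (m2 * inv_sf2 + disp * m2**2 * n2) / n2**2
    se = np.sqrt(var_mu1 / m1**2 + var_mu2 / m2**2) / np.log(2)
    se = np.maximum(se, 1e-12)
    z = log2fc / se
    # t reference with pooled-sample df: the moment dispersion estimate
    # makes the normal reference anticonservative at realistic group sizes
    p = 2 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)
    padj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "responsive": (np.abs(log2fc) > lfc_threshold) & (padj < alpha),
        },
        index=counts.index.rename("genus"),
    )
    out.attrs["excluded"] = excluded
    out.attrs["reference"] = ref
    out.attrs["contrast"] = f"{other} vs {ref}"
    return out
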