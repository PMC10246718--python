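"""Count-level QC, normalization, discovery clustering and confounder correction.

The processing order is fixed: sample filter (total reads), gene filters
(low-count fraction and coefficient of variation on raw counts), size-factor
normalization, variance-stabilizing transform, then optional surrogate-variable
estimation and nuisance regression. Filters act on raw counts; everything
downstream acts on the transformed scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FilterReport",
    "ExprMatrix",
    "SurrogateSet",
    "filter_samples",
    "filter_genes",
    "high_confidence_counts",
    "size_factors",
    "vst",
    "deg_test",
    "ward_cluster",
    "estimate_surrogates",
    "remove_nuisance",
]


@dataclass
class FilterReport:
    n_input_genes: int
    n_input_samples: int
    samples_removed: dict = field(default_factory=dict)  # id -> total reads
    genes_removed_lowcount: int = 0
    genes_removed_hypervariable: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_genes_removed(self) -> int:
        return self.genes_removed_lowcount + self.genes_removed_hypervariable


@dataclass
class ExprMatrix:
    """Transformed expression (genes x samples) with its size factors."""

    values: pd.DataFrame
    transform: str
    size_factors: pd.Series

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("ExprMatrix contains non-finite values")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class SurrogateSet:
    surrogates: pd.DataFrame  # samples x k
    singular_values: np.ndarray
    perm_quantiles: np.ndarray
    k: int


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative counts")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def filter_samples(counts: pd.DataFrame, min_total: int = 5_000_000):
    """Drop samples whose total read count is below ``min_total`` (default 5e6)."""
    _check_counts(counts)
    totals = counts.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError(
            f"all {counts.shape[1]} samples fall below the total-read threshold {min_total:g}"
        )
    report = FilterReport(
        n_input_genes=counts.shape[0],
        n_input_samples=counts.shape[1],
        samples_removed={s: int(totals[s]) for s in counts.columns[~keep]},
        thresholds={"min_total_reads": min_total},
    )
    return counts.loc[:, keep], report


def filter_genes(
    counts: pd.DataFrame,
    min_reads: int = 10,
    max_low_frac: float = 0.10,
    cv_max: float = 3.0,
):
    """Drop low-coverage and hypervariable genes.

    A gene is removed if its count is below ``min_reads`` in more than
    ``max_low_frac`` of the samples, or if its raw-count coefficient of
    variation (population sd / mean) exceeds ``cv_max``.
    """
    _check_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("gene filtering needs at least 2 samples")
    vals = counts.to_numpy(dtype=float)
    low_frac = (vals < min_reads).mean(axis=1)
    keep_low = low_frac <= max_low_frac
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    keep_cv = cv <= cv_max
    keep = keep_low & keep_cv
    if not keep.any():
        raise ValueError("all genes removed by the abundance/CV filters")
    report = FilterReport(
        n_input_genes=counts.shape[0],
        n_input_samples=counts.shape[1],
        genes_removed_lowcount=int((~keep_low).sum()),
        genes_removed_hypervariable=int((keep_low & ~keep_cv).sum()),
        thresholds={"min_reads": min_reads, "max_low_frac": max_low_frac, "cv_max": cv_max},
    )
    return counts.loc[keep], report


def high_confidence_counts(counts: pd.DataFrame, thresh: int = 30) -> pd.Series:
    """Per-sample number of genes with strictly more than ``thresh`` reads."""
    _check_counts(counts)
    return (counts > thresh).sum(axis=0)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    sf_j = median_i K_ij / geomean_i(K_i.), the median taken over genes with
    strictly positive counts in every sample. If no such gene exists, falls
    back to total-count ratios with a warning.
    """
    _check_counts(counts)
    vals = counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if allpos.any():
        logs = np.log(vals[allpos])
        log_geo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - log_geo, axis=0))
    else:
        warnings.warn(
            "no gene has positive counts in every sample; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = vals.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        sf = totals / np.exp(np.mean(np.log(totals)))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def vst(counts: pd.DataFrame, sf: pd.Series | None = None) -> ExprMatrix:
    """Variance-flattening transform: log2(count / size_factor + 1).

    A monotone shifted-log normalization standing in for model-based
    variance-stabilizing transforms; it flattens the NB mean-variance trend
    sufficiently for correlation- and penalty-based selection downstream.
    """
    _check_counts(counts)
    if sf is None:
        sf = size_factors(counts)
    sf = sf.reindex(counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    values = pd.DataFrame(np.log2(norm + 1.0), index=counts.index, columns=counts.columns)
    return ExprMatrix(values=values, transform="log2(norm+1)", size_factors=sf)


def normalized_counts(expr: ExprMatrix) -> pd.DataFrame:
    """Invert the shifted-log transform back to normalized counts."""
    return 2.0 ** expr.values - 1.0


# ---------------------------------------------------------------------------
# discovery-style DEG + clustering
# ---------------------------------------------------------------------------


def deg_test(
    expr: ExprMatrix,
    labels,
    alpha: float = 0.05,
    min_base_mean: float = 10.0,
) -> pd.DataFrame:
    """Two-class Welch t per gene on the transformed scale with BH correction.

    A gene is flagged differentially expressed when its BH-adjusted p-value is
    below ``alpha`` and its base mean (mean normalized count) exceeds
    ``min_base_mean``.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != expr.values.shape[1]:
        raise ValueError("labels must align with samples")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two classes required, got {list(groups)}")
    a = expr.values.loc[:, labels == groups[0]].to_numpy()
    b = expr.values.loc[:, labels == groups[1]].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    base_mean = normalized_counts(expr).mean(axis=1).to_numpy()
    out = pd.DataFrame(
        {
            "gene_id": expr.values.index,
            "mean_diff": b.mean(axis=1) - a.mean(axis=1),
            "t": t,
            "pvalue": p,
            "padj": padj,
            "base_mean": base_mean,
        }
    ).set_index("gene_id")
    out["is_deg"] = (out["padj"] < alpha) & (out["base_mean"] > min_base_mean)
    return out


def correlation_distance(expr_values: pd.DataFrame) -> np.ndarray:
    """Sample-sample distance 1 - Pearson r across genes (zero-variance -> 1)."""
    x = expr_values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
    n_genes = x.shape[0]
    corr = z.T @ z / n_genes
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    # samples with zero variance carry no correlation information
    dist[~ok, :] = 1.0
    dist[:, ~ok] = 1.0
    np.fill_diagonal(dist, 0.0)
    return dist


def ward_cluster(expr: ExprMatrix, genes=None):
    """Ward-linkage hierarchical clustering on correlation distances.

    Returns ``(linkage_matrix, labels)`` with a two-group cut; the dendrogram
    can be rendered from the linkage matrix directly.
    """
    values = expr.values if genes is None else expr.values.loc[list(genes)]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 genes and 2 samples")
    dist = correlation_distance(values)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="ward")
    labels = fcluster(Z, t=2, criterion="maxclust")
    return Z, pd.Series(labels, index=values.columns, name="cluster")


# ---------------------------------------------------------------------------
# surrogate variables + nuisance regression
# ---------------------------------------------------------------------------


def _class_design(labels) -> np.ndarray:
    labels = np.asarray(labels)
    cats = pd.Categorical(labels)
    dummies = pd.get_dummies(cats, drop_first=True).to_numpy(dtype=float)
    return np.column_stack([np.ones(len(labels)), dummies])


def estimate_surrogates(
    expr: ExprMatrix,
    labels,
    n_sv_max: int = 10,
    n_perm: int = 20,
    seed: int = 0,
) -> SurrogateSet:
    """Estimate latent nuisance factors from class-adjusted residuals.

    Gene-wise regression on (intercept + class) leaves a residual matrix whose
    leading right singular vectors capture structured unmodeled variation
    (batches, library chemistry, ...). The number of surrogates k is chosen by
    permutation parallel analysis: k counts the leading singular values
    exceeding the 95th percentile of the corresponding singular values from
    ``n_perm`` row-wise permutations of the residuals.
    """
    Y = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = Y.shape
    if n_samples < 4:
        raise ValueError("surrogate estimation needs at least 4 samples")
    X = _class_design(labels)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    R = Y - (X @ beta).T

    n_comp = min(n_genes, n_samples)
    sv = np.linalg.svd(R, compute_uv=False)
    # scale-invariant statistic: per-component proportion of total variance,
    # so re-residualization of permuted rows cannot bias the null downward
    prop = sv[:n_comp] ** 2 / np.sum(sv**2)
    rng = np.random.default_rng(seed)
    resid_proj = np.eye(n_samples) - X @ np.linalg.pinv(X)
    perm_prop = np.empty((n_perm, n_comp))
    for b in range(n_perm):
        # permute each gene's residuals independently (destroys shared
        # sample-level structure, keeps gene-wise distributions), then
        # re-residualize so permuted rows live in the same design-orthogonal
        # subspace as the observed residuals
        idx = np.argsort(rng.random((n_genes, n_samples)), axis=1)
        Rp = np.take_along_axis(R, idx, axis=1) @ resid_proj
        sp = np.linalg.svd(Rp, compute_uv=False)
        perm_prop[b] = sp[:n_comp] ** 2 / np.sum(sp**2)
    q95 = np.quantile(perm_prop, 0.95, axis=0)
    exceed = prop > q95
    k = int(np.argmin(exceed)) if not exceed.all() else n_comp
    if k > n_sv_max:
        warnings.warn(f"parallel analysis suggested k={k}; capping at n_sv_max={n_sv_max}")
        k = n_sv_max
    _, _, Vt = np.linalg.svd(R, full_matrices=False)
    sv_df = pd.DataFrame(
        Vt[:k].T, index=expr.values.columns, columns=[f"SV{i + 1}" for i in range(k)]
    )
    return SurrogateSet(surrogates=sv_df, singular_values=sv[:n_comp], perm_quantiles=q95, k=k)


def remove_nuisance(
    expr: ExprMatrix,
    nuisance: pd.DataFrame,
    protect,
) -> ExprMatrix:
    """Regress out nuisance covariates gene-wise while protecting class signal.

    Fits each gene on the joint design [class | nuisance] and subtracts only
    the fitted nuisance component, so class-associated variation (including
    the part collinear with nuisance terms, which the joint fit attributes to
    the protected columns) is preserved. Idempotent for a fixed design.
    """
    Y = expr.values.to_numpy(dtype=float)
    if nuisance.shape[0] != Y.shape[1]:
        raise ValueError("nuisance covariates must align with samples")
    Xp = _class_design(protect)
    Xn = np.asarray(nuisance, dtype=float)
    if Xn.ndim == 1:
        Xn = Xn[:, None]
    X = np.column_stack([Xp, Xn])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = list(range(Xp.shape[1])) + [f"nuisance:{c}" for c in nuisance.columns]
        raise ValueError(f"design matrix rank-deficient (rank {rank} < {X.shape[1]}); columns: {cols}")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    beta_n = beta[Xp.shape[1] :]
    # centered correction: removes nuisance-driven variation but preserves each
    # gene's overall level, so expression scales stay comparable across cohorts
    cleaned = Y - ((Xn - Xn.mean(axis=0)) @ beta_n).T
    values = pd.DataFrame(cleaned, index=expr.values.index, columns=expr.values.columns)
    return ExprMatrix(values=values, transform=expr.transform + "+nuisance_removed", size_factors=expr.size_factors)
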