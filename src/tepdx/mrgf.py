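"""Minimum-redundant gene filtering (MRGF): the feature-selection cascade.

Given preprocessed expression for a training cohort, the cascade runs

1. abundance / hypervariability re-filter (delegated to :mod:`tepdx.preprocess`),
2. greedy correlation pruning (drop one gene of any pair with |r| above a cutoff),
3. cross-validated L1-penalized logistic selection along a regularization path,
4. greedy mRMR (minimum-redundancy maximum-relevance) ranking by mutual
   information, optionally bootstrap-ensembled,
5. incremental feature selection: grow the panel along the ranking and pick the
   size maximizing 10-fold CV accuracy of a default-parameter RBF SVM.

The output panel is an ordered gene list with per-stage provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import ExprMatrix, filter_genes

__all__ = [
    "FeaturePanel",
    "LassoPath",
    "MrgfParams",
    "prune_correlated",
    "cv_lasso_select",
    "mutual_information",
    "mrmr_rank",
    "incremental_select",
    "run_mrgf",
]


@dataclass
class LassoPath:
    lambdas: np.ndarray  # strictly decreasing
    supports: list  # per-lambda arrays of selected gene ids
    cv_deviance: np.ndarray  # mean held-out binomial deviance per lambda
    selected_lambda: float
    coefficients: pd.Series  # nonzero coefficients at the selected lambda


@dataclass
class FeaturePanel:
    genes: list
    stage_sizes: dict  # stage name -> surviving gene count
    cv_accuracy_curve: pd.Series  # k -> mean CV accuracy
    mrmr_scores: pd.DataFrame  # rank, gene_id, relevance, redundancy, score
    lasso_path: LassoPath | None = None

    def __post_init__(self):
        sizes = list(self.stage_sizes.values())
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("stage sizes must be non-increasing along the cascade")


@dataclass
class MrgfParams:
    correlation_cutoff: float = 0.90
    n_lambda: int = 100
    folds: int = 10
    mrmr_bins: int = 10
    n_boot: int = 0
    k_max: int | None = None
    min_reads: int = 10
    max_low_frac: float = 0.10
    cv_max: float = 3.0
    seed: int = 0


def _binary_y(labels) -> np.ndarray:
    """0/1 encoding with OC as the positive class when present."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {list(classes)}")
    if "OC" in classes:
        return (labels == "OC").astype(float)
    if set(classes) == {0, 1}:
        return labels.astype(float)
    return (labels == classes[-1]).astype(float)


# ---------------------------------------------------------------------------
# stage 2: correlation pruning
# ---------------------------------------------------------------------------


def prune_correlated(X: pd.DataFrame, cutoff: float = 0.90) -> list:
    """Greedy elimination of highly inter-correlated genes.

    ``X`` is samples x genes. While any pair has absolute Pearson correlation
    above ``cutoff``, the most correlated pair is examined and the member with
    the larger mean absolute correlation to all remaining genes is dropped.
    No retained pair exceeds the cutoff on exit.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    if X.shape[1] < 2:
        return list(X.columns)
    corr = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(corr.shape[0], dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= cutoff:
            break
        alive_idx = np.flatnonzero(alive)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        gi, gj = alive_idx[i], alive_idx[j]
        mean_i = sub[i].sum() / max(sub.shape[0] - 1, 1)
        mean_j = sub[j].sum() / max(sub.shape[0] - 1, 1)
        drop = gi if mean_i >= mean_j else gj
        alive[drop] = False
    return [g for g, a in zip(X.columns, alive) if a]


# ---------------------------------------------------------------------------
# stage 3: cross-validated LASSO
# ---------------------------------------------------------------------------


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    n = Xs.shape[0]
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    return (X[:, keep] - mean[keep]) / sd[keep], keep


def _fit_path(Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray):
    """L1-logistic coefficients along a descending lambda grid.

    Solves (1/n) sum log-loss + lambda * ||w||_1 with an (effectively)
    unpenalized intercept; liblinear with a large intercept scaling keeps the
    intercept penalty negligible while staying fast at RNA-seq widths.
    """
    n = Xs.shape[0]
    coefs = np.zeros((len(lambdas), Xs.shape[1]))
    intercepts = np.zeros(len(lambdas))
    clf = LogisticRegression(
        l1_ratio=1.0,
        solver="liblinear",
        intercept_scaling=1000.0,
        tol=1e-8,
        max_iter=10000,
    )
    for i, lam in enumerate(lambdas):
        clf.C = 1.0 / (n * lam)
        clf.fit(Xs, y)
        coefs[i] = clf.coef_[0]
        intercepts[i] = clf.intercept_[0]
    return coefs, intercepts


def _deviance(Xs, y, coef, intercept) -> float:
    z = np.clip(Xs @ coef + intercept, -500, 500)
    ll = y * z - np.log1p(np.exp(z))
    return float(-2.0 * ll.mean())


def cv_lasso_select(
    X: pd.DataFrame,
    y,
    n_lambda: int = 100,
    folds: int = 10,
    seed: int = 0,
):
    """Select genes by CV-tuned L1-penalized logistic regression.

    ``X`` is samples x genes. Features are standardized internally (per
    training fold for CV; on the full data for the final support). The lambda
    grid spans four decades below the smallest all-zeroing lambda; the
    selected lambda minimizes mean held-out binomial deviance. Returns
    ``(LassoPath, selected gene ids)``.
    """
    yb = _binary_y(y)
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance features")
    Xs_full, keep = _standardize(Xv)
    genes = np.asarray(X.columns)[keep]
    lambdas = _lambda_grid(Xs_full, yb, n_lambda)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(lambdas)))
    for f, (tr, te) in enumerate(cv.split(Xs_full, yb)):
        if len(np.unique(yb[tr])) < 2:
            raise ValueError("a training fold contains a single class")
        Xtr, keep_f = _standardize(Xv[np.ix_(tr, np.flatnonzero(keep))])
        mean_f = Xv[np.ix_(tr, np.flatnonzero(keep))].mean(axis=0)
        sd_f = Xv[np.ix_(tr, np.flatnonzero(keep))].std(axis=0)
        Xte = (Xv[np.ix_(te, np.flatnonzero(keep))][:, keep_f] - mean_f[keep_f]) / sd_f[keep_f]
        coefs, intercepts = _fit_path(Xtr, yb[tr], lambdas)
        for i in range(len(lambdas)):
            dev[f, i] = _deviance(Xte, yb[te], coefs[i], intercepts[i])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))

    coefs_full, _ = _fit_path(Xs_full, yb, lambdas)
    supports = [list(genes[np.flatnonzero(c)]) for c in coefs_full]
    selected = supports[best]
    nz = np.flatnonzero(coefs_full[best])
    path = LassoPath(
        lambdas=lambdas,
        supports=supports,
        cv_deviance=mean_dev,
        selected_lambda=float(lambdas[best]),
        coefficients=pd.Series(coefs_full[best][nz], index=genes[nz]),
    )
    return path, selected


# ---------------------------------------------------------------------------
# stage 4: mRMR
# ---------------------------------------------------------------------------


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right")


def _plugin_mi(a: np.ndarray, b: np.ndarray) -> float:
    joint = pd.crosstab(a, b).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mutual_information(x, y, bins: int = 10) -> float:
    """Plug-in mutual information (nats) after equal-frequency discretization."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < bins:
        raise ValueError(f"need at least {bins} observations for {bins} bins")
    if np.all(x == x[0]):
        return 0.0
    return max(_plugin_mi(_discretize(x, bins), y), 0.0)


def _greedy_mrmr(rel: np.ndarray, red: np.ndarray, n_select: int):
    """Greedy MID ranking from precomputed relevance and redundancy matrices."""
    p = len(rel)
    selected = [int(np.argmax(rel))]
    scores = [float(rel[selected[0]])]
    remaining = set(range(p)) - set(selected)
    while len(selected) < n_select and remaining:
        cand = np.array(sorted(remaining))
        mean_red = red[np.ix_(cand, selected)].mean(axis=1)
        crit = rel[cand] - mean_red
        j = int(cand[np.argmax(crit)])
        selected.append(j)
        scores.append(float(crit[np.argmax(crit)]))
        remaining.discard(j)
    return selected, scores


def mrmr_rank(
    X: pd.DataFrame,
    y,
    n_select: int | None = None,
    bins: int = 10,
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank genes by greedy minimum-redundancy maximum-relevance (MID scheme).

    The first pick maximizes relevance I(f; y); each later pick maximizes
    relevance minus the mean mutual information with already-selected genes.
    With ``n_boot > 0`` the ranking is repeated on bootstrap resamples and
    aggregated by mean rank (ties broken by full-data relevance).
    Returns a DataFrame ordered by rank with relevance/redundancy provenance.
    """
    yb = _binary_y(y)
    p = X.shape[1]
    if n_select is None:
        n_select = p
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    if n_select > p:
        raise ValueError(f"n_select={n_select} exceeds gene count {p}")
    Xv = X.to_numpy(dtype=float)
    disc = np.column_stack([_discretize(Xv[:, j], bins) for j in range(p)])
    rel = np.array([_plugin_mi(disc[:, j], yb) for j in range(p)])
    red = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            red[i, j] = red[j, i] = _plugin_mi(disc[:, i], disc[:, j])

    if n_boot == 0:
        order, scores = _greedy_mrmr(rel, red, n_select)
    else:
        rng = np.random.default_rng(seed)
        n = Xv.shape[0]
        ranks = np.full((n_boot, p), p + 1.0)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            if len(np.unique(yb[idx])) < 2:
                continue
            disc_b = np.column_stack([_discretize(Xv[idx, j], bins) for j in range(p)])
            rel_b = np.array([_plugin_mi(disc_b[:, j], yb[idx]) for j in range(p)])
            red_b = np.zeros((p, p))
            for i in range(p):
                for j in range(i + 1, p):
                    red_b[i, j] = red_b[j, i] = _plugin_mi(disc_b[:, i], disc_b[:, j])
            order_b, _ = _greedy_mrmr(rel_b, red_b, p)
            for r, g in enumerate(order_b):
                ranks[b, g] = r + 1.0
        mean_rank = ranks.mean(axis=0)
        # ties -> higher single-run (full-data) relevance first
        order = sorted(range(p), key=lambda j: (mean_rank[j], -rel[j]))[:n_select]
        scores = [float(rel[order[0]])]
        for k in range(1, len(order)):
            scores.append(float(rel[order[k]] - red[np.ix_([order[k]], order[:k])].mean()))

    rows = []
    for rank, (g, s) in enumerate(zip(order, scores), start=1):
        redundancy = float(red[np.ix_([g], order[: rank - 1])].mean()) if rank > 1 else 0.0
        rows.append(
            {
                "rank": rank,
                "gene_id": X.columns[g],
                "relevance": float(rel[g]),
                "redundancy": redundancy,
                "score": s,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 5: incremental selection under CV SVM
# ---------------------------------------------------------------------------


def median_heuristic_gamma(X: np.ndarray, max_samples: int = 200, seed: int = 0) -> float:
    """RBF width from the median squared pairwise distance (kernlab-style sigma)."""
    n = X.shape[0]
    if n > max_samples:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(n, max_samples, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


def _cv_svm_accuracy(X: np.ndarray, y: np.ndarray, folds: int, seed: int, cost=1.0, gamma=None) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in cv.split(X, y):
        mean = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mean) / sd
        Xte = (X[te] - mean) / sd
        g = gamma if gamma is not None else median_heuristic_gamma(Xtr, seed=seed)
        clf = SVC(C=cost, gamma=g, kernel="rbf")
        clf.fit(Xtr, y[tr])
        accs.append(float(np.mean(clf.predict(Xte) == y[te])))
    return float(np.mean(accs))


def incremental_select(
    X: pd.DataFrame,
    y,
    ranking,
    k_max: int | None = None,
    folds: int = 10,
    seed: int = 0,
):
    """Pick the panel size maximizing CV accuracy along an mRMR ranking.

    Evaluates stratified ``folds``-fold CV accuracy of a default-parameter RBF
    SVM (cost 1, width from the median-distance heuristic) on the top-k ranked
    genes for k = 1..k_max; returns ``(k_star, accuracy_curve)`` with ties
    resolved toward the smallest k.
    """
    ranking = list(ranking)
    if not ranking:
        raise ValueError("empty ranking")
    if k_max is None:
        k_max = len(ranking)
    k_max = min(k_max, len(ranking))
    yb = _binary_y(y)
    counts = np.bincount(yb.astype(int))
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds minority class size {counts.min()}")
    accs = {}
    for k in range(1, k_max + 1):
        Xk = X.loc[:, ranking[:k]].to_numpy(dtype=float)
        accs[k] = _cv_svm_accuracy(Xk, yb, folds, seed)
    curve = pd.Series(accs, name="cv_accuracy")
    k_star = int(curve.idxmax())  # idxmax takes the first (smallest k) on ties
    return k_star, curve


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------


def run_mrgf(
    expr: ExprMatrix,
    labels,
    params: MrgfParams | None = None,
    counts: pd.DataFrame | None = None,
) -> FeaturePanel:
    """Run the full MRGF cascade on a preprocessed training cohort.

    ``counts`` (raw, aligned with ``expr``) enables stage 1, the re-applied
    abundance/hypervariability filter; if omitted that stage passes all genes
    through. Raises if any stage empties the candidate set.
    """
    params = params or MrgfParams()
    stage_sizes = {"input": expr.values.shape[0]}

    genes = list(expr.values.index)
    if counts is not None:
        filtered, _ = filter_genes(
            counts.loc[genes],
            min_reads=params.min_reads,
            max_low_frac=params.max_low_frac,
            cv_max=params.cv_max,
        )
        genes = list(filtered.index)
    stage_sizes["post_filter"] = len(genes)
    if not genes:
        raise RuntimeError("MRGF stage 'filter' removed every gene")

    X = expr.values.loc[genes].T  # samples x genes
    genes = prune_correlated(X, cutoff=params.correlation_cutoff)
    stage_sizes["post_correlation"] = len(genes)
    if not genes:
        raise RuntimeError("MRGF stage 'correlation pruning' removed every gene")

    path, lasso_genes = cv_lasso_select(
        X.loc[:, genes], labels, n_lambda=params.n_lambda, folds=params.folds, seed=params.seed
    )
    stage_sizes["post_lasso"] = len(lasso_genes)
    if not lasso_genes:
        raise RuntimeError("MRGF stage 'lasso' removed every gene (empty support at best lambda)")

    scores = mrmr_rank(
        X.loc[:, lasso_genes],
        labels,
        bins=params.mrmr_bins,
        n_boot=params.n_boot,
        seed=params.seed,
    )
    ranking = list(scores["gene_id"])
    k_star, curve = incremental_select(
        X, labels, ranking, k_max=params.k_max, folds=params.folds, seed=params.seed
    )
    panel = ranking[:k_star]
    stage_sizes["post_incremental"] = len(panel)

    return FeaturePanel(
        genes=panel,
        stage_sizes=stage_sizes,
        cv_accuracy_curve=curve,
        mrmr_scores=scores,
        lasso_path=path,
    )
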