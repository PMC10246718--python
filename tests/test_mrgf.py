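"""Feature-selection cascade: pruning, LASSO path, mutual information, mRMR,
incremental CV-SVM selection and the assembled MRGF run."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tepdx import mrgf

from .oracles import greedy_mrmr_bruteforce, prox_grad_l1_logistic


def _df(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


# ---------------------------------------------------------------- pruning


def test_prune_drops_one_of_a_duplicated_pair(rng):
    X = rng.normal(size=(60, 5))
    X[:, 1] = X[:, 0]
    kept = mrgf.prune_correlated(_df(X))
    assert len([g for g in kept if g in ("f0", "f1")]) == 1
    assert len(kept) == 4


def test_prune_identity_when_below_cutoff(rng):
    X = rng.normal(size=(200, 8))
    df = _df(X)
    assert mrgf.prune_correlated(df, cutoff=0.9) == list(df.columns)
    with pytest.raises(ValueError):
        mrgf.prune_correlated(df, cutoff=0.0)


def test_prune_leaves_no_admissible_pair_on_planted_blocks(rng):
    # two correlated blocks among independents; verify exhaustively
    n = 150
    base1 = rng.normal(size=n)
    base2 = rng.normal(size=n)
    X = np.column_stack(
        [
            base1,
            base1 + rng.normal(0, 0.1, n),
            base1 + rng.normal(0, 0.1, n),
            base2,
            base2 + rng.normal(0, 0.05, n),
            rng.normal(size=n),
        ]
    )
    df = _df(X)
    kept = mrgf.prune_correlated(df, cutoff=0.9)
    sub = df[kept].corr().abs().to_numpy()
    np.fill_diagonal(sub, 0.0)
    assert sub.max() <= 0.9
    assert "f5" in kept  # the independent never leaves


# ---------------------------------------------------------------- lasso


def test_lasso_lambda_max_support_empty_and_deviance_improves(rng):
    X = _df(rng.normal(size=(80, 10)))
    beta = np.zeros(10)
    beta[:2] = 2.0
    y = (rng.random(80) < 1 / (1 + np.exp(-(X.to_numpy() @ beta)))).astype(int)
    path, _ = mrgf.cv_lasso_select(X, y, n_lambda=30, folds=5, seed=0)
    assert path.supports[0] == []  # definition of lambda_max
    assert np.all(np.diff(path.lambdas) < 0)
    i_sel = int(np.argmin(np.abs(path.lambdas - path.selected_lambda)))
    assert path.cv_deviance[i_sel] <= path.cv_deviance[0]


def test_lasso_selects_the_separating_feature(rng):
    n = 200
    X = rng.normal(size=(n, 51))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += y * 2  # strongly separating
    _, selected = mrgf.cv_lasso_select(_df(X), y, n_lambda=40, folds=10, seed=0)
    assert "f0" in selected


def test_lasso_path_matches_proximal_gradient_oracle(rng):
    n, p = 80, 5
    X = rng.normal(size=(n, p))
    Xs = (X - X.mean(0)) / X.std(0)
    beta = np.array([1.5, -1.0, 0.5, 0.0, 0.0])
    y = (rng.random(n) < 1 / (1 + np.exp(-(Xs @ beta - 0.3)))).astype(float)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    lambdas = np.geomspace(lam_max * 0.9, lam_max * 1e-3, 7)
    coefs, _ = mrgf._fit_path(Xs, y, lambdas)
    for i, lam in enumerate(lambdas):
        w, _ = prox_grad_l1_logistic(Xs, y, lam)
        assert np.max(np.abs(coefs[i] - w)) <= 1e-4


# ---------------------------------------------------------------- mutual information


def test_mi_independence_identity_and_tabulated_value(rng):
    n = 1000
    y = rng.integers(0, 2, n)
    x = rng.normal(size=n)
    assert mrgf.mutual_information(x, y) < 3 / n * np.log(n)  # small-bias null

    ybin = rng.integers(0, 2, 500)
    h = stats.entropy([np.mean(ybin == 0), np.mean(ybin == 1)])
    assert mrgf.mutual_information(ybin.astype(float), ybin, bins=2) == pytest.approx(h, rel=1e-9)

    # joint (0.4, 0.1, 0.1, 0.4) realized exactly at n = 1000
    x2 = np.repeat([0.0, 0.0, 1.0, 1.0], [400, 100, 100, 400])
    y2 = np.repeat([0, 1, 0, 1], [400, 100, 100, 400])
    assert mrgf.mutual_information(x2, y2, bins=2) == pytest.approx(0.1928, abs=5e-4)

    assert mrgf.mutual_information(np.ones(100), y[:100]) == 0.0
    with pytest.raises(ValueError):
        mrgf.mutual_information(np.arange(5), np.arange(5) % 2, bins=10)


# ---------------------------------------------------------------- mRMR


def test_mrmr_relevance_first_and_redundancy_demotes_duplicates(rng):
    n = 400
    y = rng.integers(0, 2, n)
    informative = y + rng.normal(0, 0.5, n)
    weaker = y + rng.normal(0, 1.5, n)
    noise = rng.normal(size=(n, 2))
    X = _df(np.column_stack([informative, informative.copy(), weaker, noise]))
    ranked = mrgf.mrmr_rank(X, y)
    order = list(ranked["gene_id"])
    assert order[0] in ("f0", "f1")  # max relevance first
    dup = "f1" if order[0] == "f0" else "f0"
    assert order.index("f2") < order.index(dup)  # duplicate demoted below weaker independent

    with pytest.raises(ValueError):
        mrgf.mrmr_rank(X, y, n_select=0)


def test_mrmr_matches_exhaustive_greedy_oracle(rng):
    n = 120
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 5))
    X[:, 0] += 0.8 * y
    X[:, 3] += 0.5 * y
    ranked = mrgf.mrmr_rank(_df(X), y, n_select=5)
    oracle = greedy_mrmr_bruteforce(X, y)
    assert list(ranked["gene_id"]) == [f"f{j}" for j in oracle]


def test_mrmr_ensemble_mode_is_deterministic_under_seed(rng):
    n = 150
    y = rng.integers(0, 2, n)
    X = _df(np.column_stack([y + rng.normal(0, 0.8, n), rng.normal(size=(n, 3))]))
    a = mrgf.mrmr_rank(X, y, n_boot=5, seed=7)
    b = mrgf.mrmr_rank(X, y, n_boot=5, seed=7)
    pd.testing.assert_frame_equal(a, b)
    assert a.loc[0, "gene_id"] == "f0"


# ---------------------------------------------------------------- incremental selection


def test_incremental_kmax_one_and_duplicate_tie_break(rng):
    n = 60
    y = np.array([0, 1] * 30)
    sig = y + rng.normal(0, 0.3, n)
    X = _df(np.column_stack([sig, sig, sig]))
    k, curve = mrgf.incremental_select(X, y, ["f0"], folds=5, seed=0)
    assert k == 1 and len(curve) == 1
    k, curve = mrgf.incremental_select(X, y, ["f0", "f1", "f2"], folds=5, seed=0)
    assert k == 1  # identical columns tie -> smallest k
    assert curve.nunique() == 1

    with pytest.raises(ValueError, match="folds"):
        mrgf.incremental_select(X, y, ["f0"], folds=40, seed=0)


def test_incremental_plateaus_quickly_when_signal_is_concentrated(rng):
    n = 120
    y = rng.integers(0, 2, n)
    strong = np.column_stack([y + rng.normal(0, 0.4, n) for _ in range(3)])
    noise = rng.normal(size=(n, 7))
    X = _df(np.column_stack([strong, noise]))
    k, curve = mrgf.incremental_select(X, y, list(X.columns), folds=5, seed=0)
    assert k <= 10
    assert curve.iloc[2] >= 0.85


# ---------------------------------------------------------------- assembled cascade


def test_run_mrgf_stage_sizes_and_null_behavior(small_study, rng):
    from tepdx.config import PipelineConfig
    from tepdx.pipeline import preprocess_cohort

    study = small_study
    expr, meta, _ = preprocess_cohort(study.counts["tr"], study.meta["tr"], PipelineConfig())
    labels = np.where(meta["class"] == "OC", "OC", "control")
    counts = study.counts["tr"].loc[expr.values.index, expr.values.columns]
    panel = mrgf.run_mrgf(expr, labels, mrgf.MrgfParams(n_lambda=30, seed=0), counts=counts)
    sizes = list(panel.stage_sizes.values())
    assert sizes == sorted(sizes, reverse=True)
    assert set(panel.genes) <= set(expr.values.index)
    assert len(panel.genes) == sizes[-1]

    # panel enrichment for true signal genes beats the hypergeometric null
    sig = set(study.truth["tr"]["signal_genes"])
    overlap = len(set(panel.genes) & sig)
    M, n_sig, k = sizes[0], len(sig & set(expr.values.index)), len(panel.genes)
    crit = stats.hypergeom.ppf(0.99, M, n_sig, k)
    assert overlap > crit


def test_run_mrgf_signal_free_data_gives_chance_level_accuracy(rng):
    n, p = 80, 120
    X = pd.DataFrame(
        rng.normal(size=(p, n)),
        index=[f"g{i}" for i in range(p)],
        columns=[f"s{j}" for j in range(n)],
    )
    from tepdx.preprocess import ExprMatrix

    expr = ExprMatrix(X, "t", pd.Series(1.0, index=X.columns))
    labels = np.array(["OC", "control"] * (n // 2))
    # on signal-free data the cascade either halts at the empty lasso support
    # (the contractual failure, naming the stage) or ends at chance accuracy
    try:
        panel = mrgf.run_mrgf(expr, labels, mrgf.MrgfParams(n_lambda=20, folds=5, seed=0))
    except RuntimeError as err:
        assert "lasso" in str(err)
    else:
        acc = panel.cv_accuracy_curve.loc[len(panel.genes)]
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / n)  # within binomial noise
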