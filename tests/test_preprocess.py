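"""QC filters, normalization, DEG/clustering and confounder-correction contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from tepdx import preprocess as pp
from tepdx.simulate import CohortSpec, DistSpec, SimConfig, simulate_cohort

from .oracles import brute_bh


def _counts(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


# ---------------------------------------------------------------- filters


def test_sample_filter_boundary_and_identity():
    base = np.full((3, 4), 2_000_000)
    base[:, 0] = [4_999_999 // 3 + 1, 4_999_999 // 3, 4_999_999 // 3]  # sums to 4,999,999
    df = _counts(base)
    kept, rep = pp.filter_samples(df)
    assert "s0" in rep.samples_removed and kept.shape[1] == 3
    kept2, rep2 = pp.filter_samples(kept)
    assert kept2.equals(kept) and not rep2.samples_removed  # idempotent
    ident, _ = pp.filter_samples(df, min_total=0)
    assert ident.equals(df)
    with pytest.raises(ValueError, match="threshold"):
        pp.filter_samples(df, min_total=10**12)


def test_gene_filter_low_count_fraction_and_cv():
    # 12 samples; gene low (<10 reads) in 2/12 > 10% -> removed
    low = np.full(12, 50)
    low[:2] = 9
    constant = np.full(12, 20)
    spike = np.zeros(12)
    spike[-1] = 1000  # CV = sqrt(11) ~ 3.32
    cv = spike.std() / spike.mean()
    assert cv > 3
    df = _counts(np.vstack([low, constant, spike]).astype(int))
    kept, rep = pp.filter_genes(df)
    assert list(kept.index) == ["g1"]
    assert rep.genes_removed_lowcount >= 1
    kept2, _ = pp.filter_genes(kept)
    assert kept2.equals(kept)  # idempotent


def test_high_confidence_counts_strict_inequality():
    df = _counts([[31, 0], [30, 0], [0, 0]])
    hc = pp.high_confidence_counts(df, thresh=30)
    assert hc["s0"] == 1 and hc["s1"] == 0


# ---------------------------------------------------------------- size factors / vst


def test_size_factors_identical_and_scaled_samples():
    df = _counts([[10, 20], [30, 60], [7, 14]])
    sf = pp.size_factors(df)
    assert sf.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])
    same = _counts([[10, 10], [30, 30]])
    assert pp.size_factors(same).to_numpy() == pytest.approx([1.0, 1.0])


def test_size_factors_recover_simulated_library_sizes():
    cfg = SimConfig(
        n_genes=5000,
        cohorts=(CohortSpec("a", 20, 10, 10, n_batches=1), CohortSpec("b", 5, 5, 0)),
        n_signal_genes=0,
        n_age_genes=0,
        batch_effect_sd=0.0,
        seed=6,
    )
    counts, _, truth = simulate_cohort(cfg, "a")
    sf = pp.size_factors(counts)
    lib = np.array([truth["library_size"][s] for s in counts.columns])
    lib = lib / np.exp(np.mean(np.log(lib)))
    assert np.max(np.abs(sf.to_numpy() / lib - 1)) < 0.10


def test_size_factor_fallback_warns_without_all_positive_gene():
    df = _counts([[0, 5], [5, 0]])
    with pytest.warns(UserWarning, match="total-count"):
        sf = pp.size_factors(df)
    assert sf.to_numpy() == pytest.approx([1.0, 1.0])


def test_vst_zero_maps_to_zero_and_scale_invariance():
    df = _counts([[0, 4], [8, 8]])
    sf = pd.Series([1.0, 1.0], index=df.columns)
    expr = pp.vst(df, sf)
    assert expr.values.iloc[0, 0] == 0.0
    doubled = pp.vst(df * 2, sf * 2)
    assert np.allclose(doubled.values, expr.values)


def test_vst_flattens_mean_variance_trend():
    cfg = SimConfig(
        n_genes=3000,
        cohorts=(CohortSpec("a", 30, 20, 10, n_batches=1), CohortSpec("b", 5, 5, 0)),
        n_signal_genes=0,
        n_age_genes=0,
        batch_effect_sd=0.0,
        seed=10,
    )
    counts, _, _ = simulate_cohort(cfg, "a")
    raw = counts.to_numpy(dtype=float)
    expr = pp.vst(counts)

    def slope(x, y):
        X = np.column_stack([np.ones(len(x)), x])
        return np.linalg.lstsq(X, y, rcond=None)[0][1]

    s_raw = slope(raw.mean(axis=1), raw.std(axis=1))
    t = expr.values.to_numpy()
    s_vst = slope(raw.mean(axis=1), t.std(axis=1))
    assert abs(s_vst) <= 0.25 * abs(s_raw)


# ---------------------------------------------------------------- DEG


def _expr_from(arr):
    df = _counts(arr)
    return pp.ExprMatrix(np.log2(df + 1.0), "log2(norm+1)", pd.Series(1.0, index=df.columns))


def test_deg_flags_respect_alpha_and_base_mean(rng):
    n = 40
    labels = np.array(["a"] * 20 + ["b"] * 20)
    strong = np.where(labels == "b", 200.0, 100.0) + rng.normal(0, 1, n)
    weak_mean = np.where(labels == "b", 8.0, 2.0) + rng.normal(0, 0.1, n)  # base mean ~5
    null = rng.normal(100, 10, n)
    expr = _expr_from(np.vstack([strong, weak_mean, null]))
    table = pp.deg_test(expr, labels)
    assert bool(table.loc["g0", "is_deg"])
    assert not bool(table.loc["g1", "is_deg"])  # significant but base mean too low
    assert table.loc["g1", "padj"] < 0.05


def test_deg_null_labels_yield_no_discoveries(rng):
    Y = rng.normal(100, 10, size=(300, 40))
    labels = np.array(["a", "b"] * 20)
    table = pp.deg_test(_expr_from(Y), labels)
    assert table["is_deg"].sum() <= 2  # BH at 5% on a global null

    with pytest.raises(ValueError, match="two classes"):
        pp.deg_test(_expr_from(Y), np.array(["a"] * 40))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    pvals=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=20)
)
def test_bh_procedure_matches_brute_force(pvals):
    p = np.asarray(pvals)
    fast = multipletests(p, alpha=0.05, method="fdr_bh")[0]
    assert np.array_equal(fast, brute_bh(p, 0.05))


# ---------------------------------------------------------------- clustering


def test_correlation_distance_extremes():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    df = _counts(np.column_stack([x, x, -x, np.full(4, 2.0)]))
    dist = pp.correlation_distance(df)
    assert dist[0, 1] == pytest.approx(0.0, abs=1e-12)  # duplicates
    assert dist[0, 2] == pytest.approx(2.0)  # anti-correlated
    assert dist[0, 3] == pytest.approx(1.0)  # zero-variance sample


def test_ward_cluster_merges_duplicates_first_and_recovers_classes():
    cfg = SimConfig(
        n_genes=800,
        cohorts=(CohortSpec("a", 40, 25, 15), CohortSpec("b", 5, 5, 0)),
        n_signal_genes=40,
        signal_log2fc=DistSpec(3.0, 0.3),
        seed=12,
    )
    counts, meta, truth = simulate_cohort(cfg, "a")
    expr = pp.vst(counts)
    table = pp.deg_test(expr, np.where(meta["class"] == "OC", "OC", "control"))
    degs = table.index[table["is_deg"]]
    assert len(degs) >= 10
    _, labels = pp.ward_cluster(expr, genes=degs)
    y = (meta["class"] == "OC").astype(int)
    assert adjusted_rand_score(y, labels) >= 0.8

    dup = _counts(np.column_stack([[1, 5, 2], [1, 5, 2], [9, 1, 4]]))
    Z, _ = pp.ward_cluster(pp.ExprMatrix(dup.astype(float), "t", pd.Series(1.0, index=dup.columns)))
    assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1} and Z[0, 2] == pytest.approx(0.0, abs=1e-8)


# ---------------------------------------------------------------- surrogates


def test_surrogates_zero_on_pure_noise(rng):
    hits = 0
    labels = np.array(["a", "b"] * 15)
    for i in range(10):
        Y = np.random.default_rng(100 + i).normal(size=(300, 30))
        expr = pp.ExprMatrix(_counts(Y).astype(float), "t", pd.Series(1.0, index=[f"s{j}" for j in range(30)]))
        sv = pp.estimate_surrogates(expr, labels, seed=i)
        hits += sv.k == 0
    assert hits >= 9


def test_surrogates_recover_planted_batch(rng):
    n_genes, n = 400, 40
    batch = np.array([0] * 20 + [1] * 20)
    labels = np.tile(["a", "b"], 20)
    Y = rng.normal(size=(n_genes, n))
    hit = rng.choice(n_genes, n_genes // 3, replace=False)
    shift = rng.normal(0, 1.0, len(hit))
    Y[np.ix_(hit, batch == 1)] += shift[:, None]
    expr = pp.ExprMatrix(_counts(Y).astype(float), "t", pd.Series(1.0, index=[f"s{j}" for j in range(n)]))
    sv = pp.estimate_surrogates(expr, labels, seed=0)
    assert sv.k >= 1
    corr = np.corrcoef(sv.surrogates["SV1"], batch)[0, 1]
    assert abs(corr) >= 0.8


def test_surrogates_exclude_protected_class_signal(rng):
    n_genes, n = 400, 40
    labels = np.array(["a"] * 20 + ["b"] * 20)
    Y = rng.normal(size=(n_genes, n))
    hit = rng.choice(n_genes, 100, replace=False)
    Y[np.ix_(hit, labels == "b")] += 1.5
    expr = pp.ExprMatrix(_counts(Y).astype(float), "t", pd.Series(1.0, index=[f"s{j}" for j in range(n)]))
    sv = pp.estimate_surrogates(expr, labels, seed=1)
    cls = (labels == "b").astype(float)
    for c in sv.surrogates.columns:
        assert abs(np.corrcoef(sv.surrogates[c], cls)[0, 1]) < 0.3


# ---------------------------------------------------------------- nuisance removal


def _expr_noise(rng, n_genes=200, n=50):
    Y = rng.normal(size=(n_genes, n))
    return pp.ExprMatrix(_counts(Y).astype(float), "t", pd.Series(1.0, index=[f"s{j}" for j in range(n)]))


def test_remove_nuisance_no_effect_covariate_is_near_identity(rng):
    expr = _expr_noise(rng)
    labels = np.array(["a", "b"] * 25)
    cov = pd.DataFrame({"x": rng.normal(size=50)})
    out = pp.remove_nuisance(expr, cov, labels)
    # fitted coefficients on an unrelated covariate are O(1/sqrt(n)) noise
    assert np.mean(np.abs(out.values.to_numpy() - expr.values.to_numpy())) < 0.15


def test_remove_nuisance_strips_age_slope_keeps_class_effect(rng):
    n = 80
    age = rng.uniform(30, 70, n)
    labels = np.array(["a"] * 40 + ["b"] * 40)
    slope = 0.05
    class_eff = 2.0
    noise = rng.normal(0, 0.3, size=(100, n))
    Y = noise.copy()
    Y[:50] += slope * (age - age.mean())  # age genes
    Y[50:] += class_eff * (labels == "b")  # class genes
    expr = pp.ExprMatrix(_counts(Y).astype(float), "t", pd.Series(1.0, index=[f"s{j}" for j in range(n)]))
    out = pp.remove_nuisance(expr, pd.DataFrame({"age": age}), labels)

    X = np.column_stack([np.ones(n), age - age.mean()])
    resid_slopes = np.linalg.lstsq(X, out.values.to_numpy()[:50].T, rcond=None)[0][1]
    assert np.max(np.abs(resid_slopes)) < 0.1 * slope

    eff = out.values.to_numpy()[50:, labels == "b"].mean() - out.values.to_numpy()[50:, labels == "a"].mean()
    assert eff == pytest.approx(class_eff, rel=0.1)

    again = pp.remove_nuisance(out, pd.DataFrame({"age": age}), labels)
    assert np.allclose(again.values, out.values, atol=1e-8)  # projection


def test_remove_nuisance_rank_deficiency_names_columns(rng):
    expr = _expr_noise(rng, n_genes=20, n=30)
    labels = np.array(["a", "b"] * 15)
    x = rng.normal(size=30)
    cov = pd.DataFrame({"x": x, "x_copy": x})
    with pytest.raises(ValueError, match="rank-deficient"):
        pp.remove_nuisance(expr, cov, labels)
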