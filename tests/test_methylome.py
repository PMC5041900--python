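"""Core filtering, transforms, precision weights, moderated t, FDR, categories."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ithkit.design import CohortDesign
from ithkit.methylome import (
    CATEGORY_LABELS,
    bh_fdr,
    categorize_region,
    differential_methylation,
    filter_cores,
    fit_moderated,
    hypermethylation_summary,
    logcpm,
    make_design,
    quantile_normalize,
    responder_comparison,
    squeeze_variances,
    top_variance_clustering,
    top_variance_matrix,
    trigamma_inverse,
    voom_weights,
)
from ithkit.simulate import simulate_methylation_counts

from conftest import make_meta


def _cores(index, promoter=True, gene=None):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": 1,
            "end": 100,
            "promoter": promoter,
            "gene": gene,
        },
        index=index,
    )


# ----------------------------------------------------------------------
# filtering + transforms
# ----------------------------------------------------------------------
def test_filter_cores_rules():
    counts = pd.DataFrame(
        {
            "s1": [0, 10, 1, 5],
            "s2": [0, 12, 1, 5],
        },
        index=["zero", "nonprom", "boundary", "ok"],
    )
    cores = _cores(counts.index)
    cores.loc["nonprom", "promoter"] = False
    out, st_ = filter_cores(counts, cores)
    assert list(out.index) == ["boundary", "ok"]  # mean exactly 1.0 is kept
    assert st_ == {"removed_non_promoter": 1, "removed_low_coverage": 1, "kept": 2}


def test_filter_cores_empty_errors():
    counts = pd.DataFrame({"s1": [0], "s2": [0]}, index=["a"])
    with pytest.raises(ValueError, match="no analyzable cores"):
        filter_cores(counts, _cores(counts.index))


def test_logcpm_formula():
    counts = pd.DataFrame({"s1": [0, 10]}, index=["a", "b"])
    lib = pd.Series({"s1": 1_000_000 - 1})
    out = logcpm(counts, lib)
    assert out.loc["a", "s1"] == pytest.approx(-1.0)  # log2(0.5)
    assert out.loc["b", "s1"] == pytest.approx(np.log2(10.5))
    # monotone in counts for fixed library size
    assert out.loc["b", "s1"] > out.loc["a", "s1"]
    with pytest.raises(ValueError, match="positive"):
        logcpm(counts, pd.Series({"s1": 0}))


def test_quantile_normalize_hand_example():
    X = pd.DataFrame({"c1": [1.0, 3.0], "c2": [2.0, 4.0]})
    out = quantile_normalize(X)
    assert out["c1"].tolist() == [1.5, 3.5]
    assert out["c2"].tolist() == [1.5, 3.5]


def test_quantile_normalize_identical_columns_unchanged():
    X = pd.DataFrame({"c1": [5.0, 1.0, 3.0], "c2": [5.0, 1.0, 3.0]})
    out = quantile_normalize(X)
    pd.testing.assert_frame_equal(out, X)


@given(st.integers(0, 2**24 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_quantile_normalize_sorted_columns_identical_even_with_ties(seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.integers(0, 4, size=(11, 4)).astype(float))
    out = quantile_normalize(X).to_numpy()
    ref = np.sort(out[:, 0])
    for c in range(out.shape[1]):
        assert np.array_equal(np.sort(out[:, c]), ref)


def test_quantile_normalize_average_ties_mode():
    X = pd.DataFrame({"c1": [1.0, 1.0, 2.0], "c2": [1.0, 2.0, 3.0]})
    out = quantile_normalize(X, ties="average")
    # rank means are (1, 1.5, 2.5); the tie in c1 shares (1+1.5)/2
    assert out["c1"].tolist() == [1.25, 1.25, 2.5]
    assert out["c2"].tolist() == [1.0, 1.5, 2.5]


# ----------------------------------------------------------------------
# voom weights
# ----------------------------------------------------------------------
def test_voom_weights_homoskedastic_nearly_constant():
    rng = np.random.default_rng(0)
    meta = make_meta(n_patients=7, n_neph=3)
    tumor = [m for m in meta if m.is_tumor]
    X = make_design(tumor, blocked=False)
    G = 5000
    E = pd.DataFrame(
        rng.normal(0, 1, size=(G, len(tumor))) + rng.uniform(3, 10, size=(G, 1)),
        columns=[m.sample_id for m in tumor],
    )
    lib = pd.Series(1e6, index=E.columns)
    W = voom_weights(E, X, lib)
    assert (W > 0).all()
    assert W.std() / W.mean() < 0.10


def test_voom_weights_track_a_noisy_regime():
    """Loci in a high-noise mean band get systematically lower weights."""
    rng = np.random.default_rng(1)
    meta = make_meta(n_patients=7, n_neph=3)
    tumor = [m for m in meta if m.is_tumor]
    X = make_design(tumor, blocked=False)
    n = len(tumor)
    means = np.concatenate([np.full(400, 4.0), np.full(400, 10.0)])
    sds = np.where(means < 7, 2.0, 0.5)
    E = pd.DataFrame(
        rng.normal(means[:, None], sds[:, None], size=(800, n)),
        columns=[m.sample_id for m in tumor],
    )
    W = voom_weights(E, X, pd.Series(1e6, index=E.columns))
    assert W[:400].mean() < W[400:].mean() / 4


def test_voom_weights_fallback_below_min_loci():
    meta = make_meta(n_patients=2, n_neph=1)
    tumor = [m for m in meta if m.is_tumor]
    X = make_design(tumor, blocked=False)
    E = pd.DataFrame(
        np.random.default_rng(0).normal(size=(10, len(tumor))),
        columns=[m.sample_id for m in tumor],
    )
    with pytest.warns(RuntimeWarning, match="unit precision weights"):
        W = voom_weights(E, X, pd.Series(1e6, index=E.columns))
    assert np.all(W == 1.0)


# ----------------------------------------------------------------------
# moderated t
# ----------------------------------------------------------------------
def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma

    for x in (0.1, 1.0, 7.3, 150.0):
        y = float(polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


def test_squeeze_variances_recovers_prior():
    """Sampling s2 ~ s0^2 * F-like prior: moment estimates land near truth."""
    rng = np.random.default_rng(2)
    d0_true, s0_true, df = 8.0, 2.0, 10
    G = 20000
    chi_prior = rng.chisquare(d0_true, G)
    sig2 = d0_true * s0_true / chi_prior
    s2 = sig2 * rng.chisquare(df, G) / df
    s0_hat, d0_hat = squeeze_variances(s2, df)
    assert s0_hat == pytest.approx(s0_true, rel=0.1)
    assert d0_hat == pytest.approx(d0_true, rel=0.2)


def test_moderated_t_with_zero_prior_df_equals_ordinary_t():
    rng = np.random.default_rng(3)
    meta = make_meta(n_patients=4, n_neph=3)
    tumor = [m for m in meta if m.is_tumor]
    X = make_design(tumor, blocked=True)
    E = pd.DataFrame(
        rng.normal(size=(100, len(tumor))), columns=[m.sample_id for m in tumor]
    )
    fit = fit_moderated(E, X, prior=(1.0, 0.0))
    # ordinary per-core OLS t for the treatment coefficient
    import numpy.linalg as la

    Xm = X.to_numpy()
    ci = list(X.columns).index("treat")
    xtx_inv = la.inv(Xm.T @ Xm)
    beta = E.to_numpy() @ Xm @ xtx_inv
    resid = E.to_numpy() - beta @ Xm.T
    s2 = (resid**2).sum(axis=1) / (Xm.shape[0] - Xm.shape[1])
    t_ord = beta[:, ci] / np.sqrt(s2 * xtx_inv[ci, ci])
    assert np.allclose(fit.table["t"].to_numpy(), t_ord, atol=1e-10)


def test_moderated_null_pvalues_uniform():
    rng = np.random.default_rng(4)
    meta = make_meta(n_patients=14, n_neph=3)
    tumor = [m for m in meta if m.is_tumor]
    X = make_design(tumor, blocked=True)
    E = pd.DataFrame(
        rng.normal(5, 1, size=(2000, len(tumor))), columns=[m.sample_id for m in tumor]
    )
    fit = fit_moderated(E, X)
    ks = stats.kstest(fit.table["p"], "uniform")
    assert ks.pvalue > 0.01


def test_moderated_identical_variances_hits_infinite_prior():
    meta = make_meta(n_patients=3, n_neph=3)
    tumor = [m for m in meta if m.is_tumor]
    X = make_design(tumor, blocked=False)
    rng = np.random.default_rng(5)
    base = rng.normal(size=len(tumor))
    # rows are scaled copies of one pattern orthogonalized -> near-identical s2
    E = pd.DataFrame(
        np.tile(base, (50, 1)) + rng.normal(0, 1e-9, size=(50, len(tumor))),
        columns=[m.sample_id for m in tumor],
    )
    fit = fit_moderated(E, X)
    assert np.isinf(fit.d0)
    assert np.isfinite(fit.table["p"]).all()


def test_injected_effect_recovered_by_full_fit():
    """Full-cohort blocked design (14 patients x 4 tumor samples): the injected logFC is estimated within 0.15
    in the vast majority of seeds."""
    hits = 0
    errs = []
    for s in range(40):
        d = CohortDesign(seed=6000 + s)
        counts, cores, meta, truth = simulate_methylation_counts(d)
        dm = differential_methylation(
            counts, cores, meta, lib_sizes=pd.Series(truth.library_sizes)
        )
        core = truth.target_cores["VHL"]
        err = abs(dm.table.loc[core, "logFC"] - 0.87)
        errs.append(err)
        hits += err <= 0.15
    assert hits >= 36  # ~95% of seeds


# ----------------------------------------------------------------------
# BH FDR
# ----------------------------------------------------------------------
def brute_force_bh(p):
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        rank_i = np.sum(p <= pi)
        candidates = []
        for j, pj in enumerate(p):
            rank_j = np.sum(p <= pj)
            if pj >= pi:
                candidates.append(m * pj / rank_j)
        q[i] = min(1.0, min(candidates))
    return q


def test_bh_examples():
    assert bh_fdr([0.02]).tolist() == [0.02]
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_restriction_and_errors():
    p = np.array([0.001, 0.5, 0.9])
    q = bh_fdr(p, restrict_to=[0, 2])
    assert np.isnan(q[1]) and q[0] == pytest.approx(0.002)
    with pytest.raises(ValueError, match="empty restriction"):
        bh_fdr(p, restrict_to=np.zeros(3, bool))
    with pytest.raises(ValueError, match="p-values"):
        bh_fdr([1.2])


@given(st.integers(0, 2**24 - 1))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bh_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    p = np.round(rng.random(int(rng.integers(1, 40))), 3)  # rounding creates ties
    q = bh_fdr(p)
    assert np.allclose(q, brute_force_bh(p))
    assert np.all(q >= p - 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


# ----------------------------------------------------------------------
# top-variance clustering
# ----------------------------------------------------------------------
def test_top_variance_k_all_equals_full_matrix():
    rng = np.random.default_rng(8)
    E = pd.DataFrame(rng.normal(size=(30, 6)))
    full = top_variance_matrix(E, k=30)
    assert set(full.index) == set(E.index)
    d1 = top_variance_clustering(E, k=30)
    from ithkit.phylo import cohort_dendrogram

    d2 = cohort_dendrogram(E.T)
    assert np.allclose(np.sort(d1.linkage[:, 2]), np.sort(d2.linkage[:, 2]))


def test_top_variance_ranking_invariant_to_locus_order():
    rng = np.random.default_rng(9)
    E = pd.DataFrame(rng.normal(size=(50, 6)), index=[f"l{i}" for i in range(50)])
    top1 = set(top_variance_matrix(E, k=10).index)
    perm = rng.permutation(50)
    top2 = set(top_variance_matrix(E.iloc[perm], k=10).index)
    assert top1 == top2


# ----------------------------------------------------------------------
# per-patient quantile categories
# ----------------------------------------------------------------------
def test_categorize_region_hand_quantiles():
    meta = make_meta(n_patients=4, n_neph=1)
    tumor = [m for m in meta if m.is_tumor]
    values = pd.Series(
        dict(zip([m.sample_id for m in tumor], [1.0, 2, 3, 4, 5, 6, 7, 8]))
    )
    table, boundaries, excluded = categorize_region(values, meta)
    assert np.allclose(boundaries, [2.75, 4.5, 6.25])
    assert excluded == []
    # value 5 lands in "Medium to high" -> hypermethylated
    row = table.loc[table["pre_value"] == 5.0].iloc[0]
    assert row["pre_category"] == "Medium to high" and row["pre_hyper"]


def test_categorize_region_degenerate_all_equal():
    meta = make_meta(n_patients=2, n_neph=1)
    tumor = [m for m in meta if m.is_tumor]
    values = pd.Series({m.sample_id: 3.0 for m in tumor})
    table, _b, _e = categorize_region(values, meta)
    assert (table["pre_category"] == CATEGORY_LABELS[0]).all()
    assert not table["pre_hyper"].any()


def test_categorize_region_injected_effect_raises_post_hyper():
    pre_h, post_h = [], []
    for s in range(60):
        d = CohortDesign(n_patients=8, n_cores=100, seed=7000 + s,
                         treatment_logfc={"VHL": 1.5})
        counts, cores, meta, truth = simulate_methylation_counts(d)
        from ithkit.methylome import logcpm as _logcpm

        E = quantile_normalize(_logcpm(counts, pd.Series(truth.library_sizes)))
        table, _b, _e = categorize_region(E.loc[truth.target_cores["VHL"]], meta)
        s_ = hypermethylation_summary(table)
        pre_h.append(s_["pre_pct"])
        post_h.append(s_["post_pct"])
    assert np.median(post_h) >= np.median(pre_h)
    assert np.mean(post_h) > np.mean(pre_h)


def test_responder_comparison():
    deltas = {"P1": 0.5, "P2": 1.0, "P3": 0.6, "P4": 0.9}
    response = {"P1": "good", "P2": "good", "P3": "poor", "P4": "poor"}
    res = responder_comparison(deltas, response)
    assert res["df"] == 2
    x, y = [0.5, 1.0], [0.6, 0.9]
    t_exp, p_exp = stats.ttest_ind(x, y)
    assert res["t"] == pytest.approx(float(t_exp)) and res["p"] == pytest.approx(float(p_exp))
    # label swap negates t and preserves p
    flipped = responder_comparison(deltas, {k: ("poor" if v == "good" else "good")
                                            for k, v in response.items()})
    assert flipped["t"] == pytest.approx(-res["t"]) and flipped["p"] == pytest.approx(res["p"])
    with pytest.raises(ValueError, match=">= 2 patients"):
        responder_comparison({"P1": 0.1, "P2": 0.2}, {"P1": "good", "P2": "poor"})
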