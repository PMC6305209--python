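import numpy as np
import pandas as pd
import pytest

from crossmappability import association as assoc
from crossmappability.annotation import GeneModel
from crossmappability.crossmap import CrossmapResource
from crossmappability.intervals import IntervalSet


def _gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, chrom, strand, "protein_coding",
                     IntervalSet([(start, end)]), IntervalSet())


# ---------------------------------------------------------------------------
# variant filtering / classification
# ---------------------------------------------------------------------------

def test_filter_variants_maf_threshold_inclusive():
    variants = pd.DataFrame(
        dict(variant_id=["v1", "v2", "v3"], chrom=["chr1"] * 3,
             pos=[100, 200, 300], maf=[0.04, 0.05, 0.3])
    )
    kept = assoc.filter_variants(variants)
    assert list(kept["variant_id"]) == ["v2", "v3"]  # 0.05 kept, 0.04 dropped


def test_filter_variants_repeat_regions():
    variants = pd.DataFrame(
        dict(variant_id=["v1", "v2"], chrom=["chr1", "chr1"],
             pos=[150, 500], maf=[0.3, 0.3])
    )
    repeats = {"chr1": IntervalSet([(100, 200)])}
    kept = assoc.filter_variants(variants, repeats)
    assert list(kept["variant_id"]) == ["v2"]


def test_classify_pair():
    gene = _gene("g", "chr1", 10_000_000, 10_001_000)
    assert assoc.classify_pair("chr1", 10_000_000 - 999_999, gene) == "cis"
    assert assoc.classify_pair("chr1", 10_000_000 + 1_000_000, gene) == "cis"  # inclusive
    assert assoc.classify_pair("chr2", 10_000_000, gene) == "trans"
    assert assoc.classify_pair("chr1", 15_000_000, gene) == "other"


# ---------------------------------------------------------------------------
# linear association
# ---------------------------------------------------------------------------

def test_perfect_fit_recovers_slope():
    g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], dtype=float)
    beta, t, p = assoc.linear_association(g, 2.0 * g)
    assert beta == pytest.approx(2.0)
    assert p == pytest.approx(0.0, abs=1e-30)


def test_constant_genotype_is_error():
    with pytest.raises(ValueError):
        assoc.linear_association(np.ones(10), np.random.default_rng(0).normal(size=10))


def test_matches_closed_form_simple_regression():
    rng = np.random.default_rng(5)
    g = rng.binomial(2, 0.3, size=40).astype(float)
    y = 0.7 * g + rng.normal(size=40)
    beta, t, p = assoc.linear_association(g, y)
    # closed-form simple OLS
    gc, yc = g - g.mean(), y - y.mean()
    beta_ref = (gc @ yc) / (gc @ gc)
    resid = yc - beta_ref * gc
    se = np.sqrt((resid @ resid) / (len(g) - 2) / (gc @ gc))
    assert beta == pytest.approx(beta_ref)
    assert t == pytest.approx(beta_ref / se)


def test_null_pvalues_uniform_under_permutation():
    rng = np.random.default_rng(6)
    n = 60
    g = rng.binomial(2, 0.4, size=n).astype(float)
    pvals = []
    for _ in range(400):
        y = rng.normal(size=n)
        pvals.append(assoc.linear_association(g, y)[2])
    from scipy import stats

    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_beta_recovery_with_covariates():
    """Known simulated effect recovered within +-3 SE across seeds."""
    rng = np.random.default_rng(7)
    n, b_true = 200, 0.5
    good = 0
    for _ in range(100):
        g = rng.binomial(2, 0.3, size=n).astype(float)
        C = rng.normal(size=(2, n))
        y = b_true * g + 0.4 * C[0] - 0.2 * C[1] + rng.normal(size=n)
        beta, t, p = assoc.linear_association(g, y, C)
        se = beta / t
        if abs(beta - b_true) <= 3 * se:
            good += 1
    assert good >= 95


def test_vectorized_scan_equals_per_pair_ols():
    rng = np.random.default_rng(8)
    n = 50
    samples = [f"s{i}" for i in range(n)]
    geno = pd.DataFrame(rng.binomial(2, 0.3, size=(3, n)).astype(float),
                        index=["v1", "v2", "v3"], columns=samples)
    expr = pd.DataFrame(rng.normal(size=(4, n)),
                        index=[f"g{i}" for i in range(4)], columns=samples)
    cov = pd.DataFrame(rng.normal(size=(2, n)), index=["c1", "c2"], columns=samples)
    info = pd.DataFrame(dict(variant_id=["v1", "v2", "v3"], chrom=["chr9"] * 3,
                             pos=[100, 200, 300]))
    models = {f"g{i}": _gene(f"g{i}", "chr1", 1000 * i, 1000 * i + 500)
              for i in range(4)}
    scan = assoc.run_trans_scan(geno, info, expr, cov, models)
    assert len(scan) == 12
    for _, row in scan.iterrows():
        beta, t, p = assoc.linear_association(
            geno.loc[row["variant_id"]].to_numpy(),
            expr.loc[row["gene_id"]].to_numpy(),
            cov.to_numpy(),
        )
        assert row["beta"] == pytest.approx(beta)
        assert row["statistic"] == pytest.approx(t)
        assert row["p"] == pytest.approx(p)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def test_bh_closed_form_with_ties():
    # min-step formula: adj_i = min_{j>=i} p_(j) * m / j
    assert assoc.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert assoc.bh_fdr([0.2]) == pytest.approx([0.2])
    assert assoc.bh_fdr([0.5] * 6) == pytest.approx([0.5] * 6)
    assert assoc.bh_fdr([0.001, 0.5, 0.9]) == pytest.approx([0.003, 0.75, 0.9])


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        assoc.bh_fdr([0.5, 1.2])
    with pytest.raises(ValueError):
        assoc.bh_fdr([-0.1])


def test_bh_monotone_in_rank():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=50)
    adj = assoc.bh_fdr(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert np.all(adj <= 1.0)


# ---------------------------------------------------------------------------
# flagging and FDR reassessment
# ---------------------------------------------------------------------------

def _flag_setup():
    models = [
        _gene("cisg", "chr5", 200_000, 205_000),
        _gene("far", "chr5", 2_000_000, 2_005_000),
        _gene("target", "chr1", 100, 5_000),
    ]
    resource = CrossmapResource({("cisg", "target"): 7, ("far", "target"): 3})
    info = pd.DataFrame(dict(variant_id=["v1"], chrom=["chr5"], pos=[400_000]))
    return models, resource, info


def test_flag_trans_eqtls_definition():
    models, resource, info = _flag_setup()
    assoc_df = pd.DataFrame(dict(variant_id=["v1"], gene_id=["target"],
                                 p=[1e-8], eqtl_class=["trans"]))
    out = assoc.flag_trans_eqtls(assoc_df, models, resource, info)
    assert bool(out["crossmappable"][0])  # cisg at 200 kb cross-maps to target


def test_flag_respects_window():
    models, resource, info = _flag_setup()
    # only the gene at 1.6 Mb cross-maps -> outside 1 Mb window, unflagged
    resource = CrossmapResource({("far", "target"): 3})
    info = pd.DataFrame(dict(variant_id=["v1"], chrom=["chr5"], pos=[400_000]))
    assoc_df = pd.DataFrame(dict(variant_id=["v1"], gene_id=["target"], p=[1e-8]))
    out = assoc.flag_trans_eqtls(assoc_df, models, resource, info)
    assert not bool(out["crossmappable"][0])


def test_flag_direction_a_to_b():
    models, _, info = _flag_setup()
    resource = CrossmapResource({("target", "cisg"): 4})  # wrong direction
    assoc_df = pd.DataFrame(dict(variant_id=["v1"], gene_id=["target"], p=[1e-8]))
    assert not bool(
        assoc.flag_trans_eqtls(assoc_df, models, resource, info,
                               direction="a_to_b")["crossmappable"][0]
    )
    assert bool(
        assoc.flag_trans_eqtls(assoc_df, models, resource, info,
                               direction="either")["crossmappable"][0]
    )


def test_flag_unknown_target_is_error():
    models, resource, info = _flag_setup()
    assoc_df = pd.DataFrame(dict(variant_id=["v1"], gene_id=["ghost"], p=[0.5]))
    with pytest.raises(KeyError):
        assoc.flag_trans_eqtls(assoc_df, models, resource, info)


def test_refilter_reassess_hand_example():
    """4 tests, flagged ones carry the smallest p: the filtered significant
    set shrinks below the unflagged members of the original set.

    All 4: BH([0.001, 0.002, 0.03, 0.06]) = [0.004, 0.004, 0.04, 0.06]
    -> v1, v2, v3 significant at alpha=0.05, of which v3 is unflagged.
    Unflagged only: BH([0.03, 0.06]) = [0.06, 0.06] -> none significant.
    """
    df = pd.DataFrame(
        dict(
            variant_id=["v1", "v2", "v3", "v4"],
            gene_id=["g1", "g2", "g3", "g4"],
            p=[0.001, 0.002, 0.030, 0.060],
            crossmappable=[True, True, False, False],
        )
    )
    result = assoc.refilter_and_reassess(df, alpha=0.05)
    assert result.n_original == 3
    unflagged_original = result.original.loc[~result.original["crossmappable"]]
    assert list(unflagged_original["variant_id"]) == ["v3"]
    assert result.n_filtered == 0  # strictly smaller than the unflagged hits


def test_refilter_noop_when_nothing_flagged():
    df = pd.DataFrame(dict(variant_id=list("abcd"), gene_id=list("wxyz"),
                           p=[0.01, 0.2, 0.6, 0.9],
                           crossmappable=[False] * 4))
    result = assoc.refilter_and_reassess(df, alpha=0.05)
    assert result.n_original == result.n_filtered
    assert list(result.original["variant_id"]) == list(result.filtered["variant_id"])


def test_refilter_alpha_zero_empty():
    df = pd.DataFrame(dict(variant_id=["a"], gene_id=["g"], p=[0.001],
                           crossmappable=[False]))
    result = assoc.refilter_and_reassess(df, alpha=0.0)
    assert result.n_original == 0 and result.n_filtered == 0


def test_top_hit_fraction_curve():
    df = pd.DataFrame(
        dict(variant_id=list("abcd"), gene_id=list("wxyz"),
             p=[0.001, 0.002, 0.003, 0.004],
             crossmappable=[True, True, True, False])
    )
    curve, bg = assoc.top_hit_crossmap_fraction(df)
    assert curve[3] == pytest.approx(0.75)
    assert bg == pytest.approx(0.75)
    df["crossmappable"] = False
    curve, bg = assoc.top_hit_crossmap_fraction(df)
    assert np.all(curve == 0) and bg == 0


def test_replication_fraction_paper_style_counts():
    """3 of 28 unflagged and 5 of 16 flagged replicated -> 10.71% / 31.25%."""
    rng = np.random.default_rng(10)
    rows, rep = [], {}
    # 28 unflagged genes: 3 replicate strongly, 25 do not
    for i in range(28):
        vid, gid = f"nv{i}", f"ng{i}"
        rows.append((vid, gid, 1e-6, False))
        rep[(vid, gid)] = 1e-12 if i < 3 else float(rng.uniform(0.5, 1.0))
    # 16 flagged genes: 5 replicate
    for i in range(16):
        vid, gid = f"xv{i}", f"xg{i}"
        rows.append((vid, gid, 1e-6, True))
        rep[(vid, gid)] = 1e-12 if i < 5 else float(rng.uniform(0.5, 1.0))
    disc = pd.DataFrame(rows, columns=["variant_id", "gene_id", "p", "crossmappable"])
    frac = assoc.replication_fraction(disc, rep, alpha=0.05)
    assert frac[False] == pytest.approx(3 / 28)
    assert frac[True] == pytest.approx(5 / 16)


def test_replication_best_variant_per_gene_tiebreak():
    disc = pd.DataFrame(
        dict(variant_id=["vB", "vA", "vC"], gene_id=["g", "g", "g"],
             p=[0.001, 0.001, 0.5], crossmappable=[False, False, False])
    )
    rep = {("vA", "g"): 0.001, ("vB", "g"): 0.9, ("vC", "g"): 0.9}
    # tie on p broken lexicographically: vA chosen, which replicates
    frac = assoc.replication_fraction(disc, rep, alpha=0.05)
    assert frac[False] == 1.0
    assert np.isnan(frac[True])  # empty class reported NA


def test_replication_missing_value_excluded():
    disc = pd.DataFrame(dict(variant_id=["v1", "v2"], gene_id=["g1", "g2"],
                             p=[0.01, 0.01], crossmappable=[False, False]))
    frac = assoc.replication_fraction(disc, {("v1", "g1"): 0.001}, alpha=0.05)
    assert frac[False] == 1.0  # v2/g2 dropped


# ---------------------------------------------------------------------------
# residualization / correlation
# ---------------------------------------------------------------------------

def test_residualize_centers_without_covariates():
    rng = np.random.default_rng(11)
    expr = pd.DataFrame(rng.normal(loc=5.0, size=(3, 30)),
                        index=list("abc"), columns=[f"s{i}" for i in range(30)])
    resid = assoc.residualize(expr)
    assert np.allclose(resid.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(resid.to_numpy(), expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True))


def test_residualize_orthogonal_to_covariates():
    rng = np.random.default_rng(12)
    n = 40
    cov = pd.DataFrame(rng.normal(size=(3, n)), columns=[f"s{i}" for i in range(n)])
    expr = pd.DataFrame(rng.normal(size=(5, n)), columns=cov.columns)
    resid = assoc.residualize(expr, cov)
    dots = resid.to_numpy() @ cov.to_numpy().T
    assert np.max(np.abs(dots)) <= 1e-8 * n


def test_residualize_exact_linear_expression_vanishes():
    rng = np.random.default_rng(13)
    n = 25
    cov = pd.DataFrame(rng.normal(size=(2, n)), columns=[f"s{i}" for i in range(n)])
    expr = pd.DataFrame([3 * cov.iloc[0] - cov.iloc[1] + 2], columns=cov.columns)
    resid = assoc.residualize(expr, cov)
    assert np.allclose(resid.to_numpy(), 0.0, atol=1e-10)


def test_residualize_rank_deficient_error():
    n = 20
    cov = pd.DataFrame(np.ones((2, n)), columns=[f"s{i}" for i in range(n)])
    expr = pd.DataFrame(np.random.default_rng(14).normal(size=(2, n)),
                        columns=cov.columns)
    with pytest.raises(ValueError):
        assoc.residualize(expr, cov)


def test_abs_pearson_values():
    x = np.array([1.0, 2.0, 3.0])
    assert assoc.abs_pearson(x, -2 * x) == pytest.approx(1.0)
    assert assoc.abs_pearson(x, np.array([1.0, 3.0, 2.0])) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        assoc.abs_pearson(x, np.ones(3))


def test_abs_pearson_independent_gaussians_small():
    rng = np.random.default_rng(15)
    n = 2500
    bad = sum(
        assoc.abs_pearson(rng.normal(size=n), rng.normal(size=n)) >= 4 / np.sqrt(n)
        for _ in range(100)
    )
    assert bad <= 3  # P(|r| >= 4/sqrt(n)) well under 1%


# ---------------------------------------------------------------------------
# sampling / rank-sum / quantile groups
# ---------------------------------------------------------------------------

def test_sample_pairs_deterministic_and_distinct():
    pairs = [(f"a{i}", f"b{i}") for i in range(100)]
    w = list(range(1, 101))
    s1 = assoc.sample_pairs(pairs, w, 10, seed=3)
    s2 = assoc.sample_pairs(pairs, w, 10, seed=3)
    assert s1 == s2
    assert len(set(s1)) == 10
    with pytest.raises(ValueError):
        assoc.sample_pairs(pairs, w, 101, seed=0)


def test_sample_pairs_weight_proportional_montecarlo():
    """One pair holding 99% of the weight is drawn ~99% of the time."""
    pairs = ["heavy"] + [f"p{i}" for i in range(99)]
    w = [99 * 99.0] + [1.0] * 99  # heavy pair holds 99% of total weight
    draws = sum(
        assoc.sample_pairs(pairs, w, 1, seed=s)[0] == "heavy" for s in range(2000)
    )
    p = 0.99
    sigma = np.sqrt(2000 * p * (1 - p))
    assert abs(draws - 2000 * p) <= 3 * sigma


def test_sample_pairs_zero_weight_never_drawn():
    pairs = ["a", "b", "c"]
    for s in range(50):
        assert "c" not in assoc.sample_pairs(pairs, [1.0, 1.0, 0.0], 2, seed=s)


def test_rank_sum_exact_enumeration():
    # a=[3,4] vs b=[1,2]: only 1 of C(4,2)=6 rank splits is as extreme
    assert assoc.rank_sum_greater([3, 4], [1, 2]) == pytest.approx(1 / 6)


def test_rank_sum_identical_samples_not_significant():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert assoc.rank_sum_greater(a, list(a)) > 0.4


def test_rank_sum_power_rises_with_shift():
    rng = np.random.default_rng(16)
    rates = []
    for shift in (0.0, 0.5, 1.5):
        rej = 0
        for _ in range(60):
            a = rng.normal(loc=shift, size=30)
            b = rng.normal(size=30)
            if assoc.rank_sum_greater(a, b) < 0.05:
                rej += 1
        rates.append(rej / 60)
    assert rates[0] < 0.2 and rates[1] > rates[0] and rates[2] > 0.95


def test_quantile_groups():
    pairs = pd.DataFrame(
        dict(crossmap_weight=[0.0] * 10 + list(np.arange(1.0, 4001.0)))
    )
    grouped = assoc.quantile_group_pairs(pairs, [2000, 2000])
    assert list(grouped["group"]) == ["0", "1", "2"]
    assert list(grouped["size"]) == [10, 2000, 2000]
    # bounds ordered and non-overlapping: group 1 holds the largest weights
    assert grouped.loc[1, "weight_min"] > grouped.loc[2, "weight_max"]


def test_quantile_groups_all_zero():
    pairs = pd.DataFrame(dict(crossmap_weight=[0.0] * 5))
    grouped = assoc.quantile_group_pairs(pairs, [2000])
    assert list(grouped["group"]) == ["0"] and grouped.loc[0, "size"] == 5


def test_quantile_groups_truncation():
    pairs = pd.DataFrame(dict(crossmap_weight=[1.0, 2.0, 3.0]))
    grouped = assoc.quantile_group_pairs(pairs, [2, 2, 2])
    assert list(grouped["size"]) == [0, 2, 1]
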