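"""Expression profiling and differential expression: CPM filter, TMM,
leading-logFC MDS, conditional-ML dispersion, NB exact test, BH, calls,
and hypergeometric enrichment."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

from holosplit.dge import (
    bh_fdr,
    call_degs,
    classical_mds,
    contrast_table,
    cpm_filter,
    equalize_lib_sizes,
    estimate_common_dispersion,
    hypergeom_enrichment,
    leading_logfc_distance,
    leading_logfc_distance_matrix,
    log_cpm,
    nb_exact_test,
    tmm_factors,
)


def _df(mat, genes=None, samples=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# CPM filter


def test_cpm_filter_keeps_gene_reaching_min_cpm_twice():
    counts = _df([[1, 0, 2], [0, 0, 0], [5, 5, 5]])
    out = cpm_filter(counts, min_cpm=1.0, min_samples=2, lib_sizes=[1e6, 1e6, 1e6])
    assert list(out.index) == ["g0", "g2"]
    assert len(cpm_filter(counts, min_cpm=0.0, min_samples=2, lib_sizes=[1e6] * 3)) == 3


def test_cpm_filter_matches_direct_recount(rng):
    for _ in range(50):
        counts = _df(rng.integers(0, 50, size=(30, 5)))
        libs = counts.sum(axis=0).to_numpy(float)
        if (libs == 0).any():
            continue
        out = cpm_filter(counts, min_cpm=2.0, min_samples=2)
        expected = [
            g
            for g in counts.index
            if (counts.loc[g].to_numpy() * 1e6 / libs >= 2.0).sum() >= 2
        ]
        assert list(out.index) == expected


# ---------------------------------------------------------------------------
# TMM


def test_tmm_identical_columns_unit_factors():
    counts = _df(np.tile([[10], [20], [30], [40]], (1, 4)))
    f = tmm_factors(counts)
    assert np.allclose(f, 1.0)


def test_tmm_pure_depth_change_keeps_factor_near_one():
    gen = np.random.default_rng(2)
    base = gen.integers(5, 500, size=1000)
    counts = _df(np.column_stack([base, base * 2, base, base]))
    f = tmm_factors(counts)
    assert np.allclose(f, 1.0, atol=1e-6)


def test_tmm_composition_change_bracketed():
    # half the genes x4 in one sample: depth normalization absorbs the boost,
    # so the TMM factor falls below 1 (the boosted half inflates the library
    # and deflates the unchanged genes' proportions), bracketed by the two
    # pure M-value extremes log2(1/2.5) and log2(4/2.5)
    gen = np.random.default_rng(3)
    base = gen.integers(20, 500, size=2000)
    boosted = base.copy()
    boosted[:1000] = boosted[:1000] * 4
    counts = _df(np.column_stack([base, base, boosted]))
    f = tmm_factors(counts)
    ratio = counts.sum(axis=0).iloc[2] / counts.sum(axis=0).iloc[0]
    assert 1 / ratio < f.iloc[2] < 4 / ratio
    # the effective (factor x library) correction stays within the x1..x4 band
    assert 1.0 < f.iloc[2] * ratio < 4.0


# ---------------------------------------------------------------------------
# leading logFC distance and MDS


def test_leading_logfc_distance_axioms():
    gen = np.random.default_rng(4)
    lc = _df(gen.normal(5, 2, size=(200, 3)))
    assert leading_logfc_distance(lc, "s0", "s0", top=50) == 0.0
    d01 = leading_logfc_distance(lc, "s0", "s1", top=50)
    d10 = leading_logfc_distance(lc, "s1", "s0", top=50)
    assert d01 == pytest.approx(d10)
    shifted = lc.copy()
    shifted["s1"] = lc["s0"] + 2.0
    assert leading_logfc_distance(shifted, "s0", "s1", top=200) == pytest.approx(2.0)


def test_classical_mds_recovers_euclidean_configurations():
    gen = np.random.default_rng(5)
    pts = gen.normal(size=(7, 2))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    labels = [f"s{i}" for i in range(7)]
    emb = classical_mds(pd.DataFrame(D, index=labels, columns=labels), k=2)
    C = emb.coordinates.to_numpy()
    D2 = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
    assert np.abs(D2 - D).max() < 1e-8
    assert emb.eigenvalues[0] >= emb.eigenvalues[1] > 0


def test_classical_mds_line_and_degenerate_cases():
    xs = np.array([0.0, 1.0, 3.0, 6.0])
    D = np.abs(xs[:, None] - xs[None, :])
    idx = list("abcd")
    emb = classical_mds(pd.DataFrame(D, index=idx, columns=idx), k=1)
    C = emb.coordinates.to_numpy()[:, 0]
    assert np.abs(np.abs(C[:, None] - C[None, :]) - D).max() < 1e-8
    zero = pd.DataFrame(np.zeros((3, 3)), index=list("xyz"), columns=list("xyz"))
    with pytest.warns(UserWarning):
        emb0 = classical_mds(zero, k=2)
    assert np.allclose(emb0.coordinates.to_numpy(), 0)


# ---------------------------------------------------------------------------
# dispersion


def test_dispersion_recovery_small():
    from holosplit import synthio as sy

    cfg = sy.SynthConfig(
        n_genes=500, frac_de=0.0, dispersion=0.2, seed=31,
        groups=(("healthy", 6), ("ga_affected", 6)),
    )
    counts, meta, _ = sy.simulate_counts(cfg)
    phi = estimate_common_dispersion(counts, meta["tissue"].to_numpy())
    assert 0.1 < phi < 0.3


def test_dispersion_identical_counts_tends_to_zero():
    counts = _df(np.full((1, 6), 50))
    phi = estimate_common_dispersion(counts, ["g"] * 6)
    assert phi <= 1e-4
    with pytest.raises(ValueError):
        estimate_common_dispersion(_df(np.zeros((3, 4), dtype=int)), ["g"] * 4)


# ---------------------------------------------------------------------------
# exact test


def _exact_oracle(za, zb, n_a, n_b, phi):
    """Independent enumeration using scipy pmfs at an arbitrary success
    probability (it cancels after conditioning)."""
    t = za + zb
    z = np.arange(t + 1)
    if phi == 0:
        w = binom.pmf(z, t, n_a / (n_a + n_b))
    else:
        ra, rb = n_a / phi, n_b / phi
        w = nbinom.pmf(z, ra, 0.3) * nbinom.pmf(t - z, rb, 0.3)
        w = w / w.sum()
    obs = w[za]
    return float(w[w <= obs * (1 + 1e-9)].sum())


def test_exact_test_most_likely_outcome_has_p_one():
    assert nb_exact_test(10, 10, 2, 2, 0.1) == pytest.approx(1.0, abs=1e-9)


def test_exact_test_matches_enumeration_oracle():
    gen = np.random.default_rng(6)
    for _ in range(200):
        t = int(gen.integers(1, 201))
        za = int(gen.integers(0, t + 1))
        n_a, n_b = int(gen.integers(2, 7)), int(gen.integers(2, 7))
        phi = float(gen.choice([0.0, 0.05, 0.1, 0.5]))
        p = nb_exact_test(za, t - za, n_a, n_b, phi)
        assert p == pytest.approx(_exact_oracle(za, t - za, n_a, n_b, phi), abs=1e-10)
        assert 0 < p <= 1


def test_exact_test_poisson_limit_is_binomial():
    p0 = nb_exact_test(30, 10, 3, 3, 0.0)
    z = np.arange(41)
    w = binom.pmf(z, 40, 0.5)
    expected = w[w <= w[30] * (1 + 1e-9)].sum()
    assert p0 == pytest.approx(float(expected), abs=1e-12)


# ---------------------------------------------------------------------------
# BH


def test_bh_stepup_hand_example():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_fdr([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_statsmodels_and_is_permutation_invariant(pvals):
    from statsmodels.stats.multitest import multipletests

    ours = bh_fdr(pvals)
    ref = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, ref, atol=1e-12)
    perm = np.random.default_rng(0).permutation(len(pvals))
    assert np.allclose(np.asarray(ours)[perm], bh_fdr(np.asarray(pvals)[perm]))
    order = np.argsort(pvals)
    assert (np.diff(np.asarray(ours)[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# significance calls


def test_call_degs_threshold_arithmetic(two_group_null_counts):
    counts, meta = two_group_null_counts
    groups = meta["tissue"].to_numpy()
    res = contrast_table(counts, groups, "healthy", "ga_affected", phi=0.1)
    tab = res.table
    expect = (tab["fdr"] <= 0.01) & (2.0 ** tab["log2_fc"].abs() >= 2.0)
    assert (tab["significant"] == expect).all()


def test_call_degs_venn_partition_consistency():
    idx = [f"g{i}" for i in range(10)]

    def fake(sig):
        t = pd.DataFrame(
            {"log2_fc": 2.0, "pvalue": 0.001, "fdr": 0.001, "significant": False},
            index=idx,
        )
        t.loc[sig, "significant"] = True
        from holosplit.dge import ContrastResult

        return ContrastResult("a", "b", t)

    results = {
        ("h", "a"): fake(["g0", "g1", "g2"]),
        ("h", "u"): fake(["g1", "g2", "g3"]),
        ("a", "u"): fake(["g2"]),
    }
    sets, union, venn = call_degs(results)
    assert union == {"g0", "g1", "g2", "g3"}
    assert sum(venn.values()) == len(union)
    assert venn["111"] == 1  # g2
    assert venn["110"] == 1  # g1
    assert venn["100"] == 1  # g0
    empty_sets, empty_union, _ = call_degs({})
    assert empty_union == set()


# ---------------------------------------------------------------------------
# enrichment


def test_hypergeom_combinatorial_example():
    out = hypergeom_enrichment(
        {"g1", "g2"},
        {"term": [f"g{i}" for i in range(1, 6)]},
        [f"g{i}" for i in range(1, 11)],
    )
    assert out.loc["term", "pvalue"] == pytest.approx(10 / 45)


def test_hypergeom_edge_cases():
    uni = [f"g{i}" for i in range(8)]
    out = hypergeom_enrichment(set(), {"t": uni[:4]}, uni)
    assert (out["pvalue"] == 1.0).all()
    out2 = hypergeom_enrichment({"g0", "g1"}, {"all": uni}, uni)
    assert out2.loc["all", "pvalue"] == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        out3 = hypergeom_enrichment({"g0"}, {"empty": ["nope"]}, uni)
    assert out3.empty


def test_hypergeom_matches_direct_combinatorics(rng):
    for _ in range(50):
        M = int(rng.integers(5, 25))
        uni = [f"g{i}" for i in range(M)]
        K = int(rng.integers(1, M + 1))
        n = int(rng.integers(1, M + 1))
        term = list(rng.choice(uni, size=K, replace=False))
        degs = set(rng.choice(uni, size=n, replace=False))
        k = len(set(term) & degs)
        direct = sum(
            math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
            for x in range(k, min(K, n) + 1)
        )
        out = hypergeom_enrichment(degs, {"t": term}, uni)
        assert out.loc["t", "pvalue"] == pytest.approx(direct, abs=1e-12)
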