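"""Count-based expression profiling and differential expression.

The analysis path mirrors the standard negative-binomial count workflow for
small-replicate RNA-seq designs:

* genes are kept when they reach a minimum CPM in a minimum number of
  libraries (default 1 CPM in 2 libraries);
* compositional normalization by the trimmed mean of M-values (TMM);
* sample profiles are compared by the leading log-fold-change distance (the
  root-mean-square of the ``top`` largest per-gene log2 differences) and
  embedded by classical (Torgerson) metric MDS;
* a common negative-binomial dispersion is estimated by conditional maximum
  likelihood on library-size-equalized pseudo-counts;
* each pairwise tissue contrast is tested with the NB exact test
  (conditioning on the per-gene total, summing the probabilities of all
  outcomes at most as likely as the observed split);
* p-values are adjusted by Benjamini-Hochberg, and genes are called
  significant at FDR <= alpha with fold-change >= the threshold (defaults
  0.01 and 2);
* annotation-term enrichment of a DEG set uses the upper-tail
  hypergeometric test.

Dispersion here is phi in Var(Y) = mu + phi * mu^2 (phi = 0 is Poisson).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, hypergeom


# ---------------------------------------------------------------------------
# filtering and normalization


def cpm(counts: pd.DataFrame, lib_sizes: Sequence[float] | None = None) -> pd.DataFrame:
    libs = np.asarray(lib_sizes if lib_sizes is not None else counts.sum(axis=0), float)
    if (libs <= 0).any():
        raise ValueError("zero library size")
    return counts * 1e6 / libs


def cpm_filter(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    lib_sizes: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` libraries.

    CPM is computed on the original library sizes; callers should keep using
    those sizes downstream (the filter does not recompute them).
    """
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (cpm(counts, lib_sizes) >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    lib_sizes: Sequence[float] | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile.  For each sample, M (log2 count ratio) and A
    (average log2 abundance) are computed over genes nonzero in both sample
    and reference; the ``trim_m``/``trim_a`` most extreme fractions on each
    side are discarded and the factor is 2 to the inverse-variance-weighted
    mean of the surviving M values.  Factors are rescaled to multiply to 1.
    """
    libs = np.asarray(lib_sizes if lib_sizes is not None else counts.sum(axis=0), float)
    y = counts.to_numpy(dtype=float)
    p = cpm(counts, libs)
    f75 = p.quantile(0.75, axis=0).to_numpy()
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(counts.shape[1])
    yr, nr = y[:, ref], libs[ref]
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        ys, ns = y[:, s], libs[s]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(f"sample {counts.columns[s]!r} shares no expressed genes with the reference")
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        # asymptotic inverse variance of M (delta method, binomial sampling)
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = ok.sum()
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        else:
            f = 0.0
        if not np.isfinite(f):
            f = 0.0
        factors[s] = 2.0**f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# MDS of expression profiles


def log_cpm(
    counts: pd.DataFrame,
    lib_sizes: Sequence[float] | None = None,
    norm_factors: Sequence[float] | None = None,
    prior_count: float = 2.0,
) -> pd.DataFrame:
    """log2 CPM with a library-size-scaled prior count to avoid log(0)."""
    libs = np.asarray(lib_sizes if lib_sizes is not None else counts.sum(axis=0), float)
    if norm_factors is not None:
        libs = libs * np.asarray(norm_factors, float)
    prior = prior_count * libs / libs.mean()
    vals = np.log2((counts.to_numpy(float) + prior) / (libs + 2 * prior) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def leading_logfc_distance(
    logcpm: pd.DataFrame, sample_i: str, sample_j: str, top: int = 500
) -> float:
    """Root-mean-square of the ``top`` largest |log2 CPM| differences between
    two samples — the "typical" log2 fold-change separating them."""
    if top > logcpm.shape[0]:
        raise ValueError("top exceeds the number of genes")
    d = np.abs(logcpm[sample_i].to_numpy() - logcpm[sample_j].to_numpy())
    sel = np.sort(d)[-top:]
    return float(np.sqrt(np.mean(sel**2)))


def leading_logfc_distance_matrix(logcpm: pd.DataFrame, top: int = 500) -> pd.DataFrame:
    samples = list(logcpm.columns)
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = leading_logfc_distance(
                logcpm, samples[i], samples[j], top=min(top, logcpm.shape[0])
            )
    return pd.DataFrame(D, index=samples, columns=samples)


@dataclass
class MdsEmbedding:
    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray  # length k, descending
    distance_matrix: pd.DataFrame


def classical_mds(distances: pd.DataFrame, k: int = 2) -> MdsEmbedding:
    """Torgerson metric MDS: double-center -0.5 * J D^2 J and eigendecompose.

    Coordinates use the top-k eigenvectors scaled by the square roots of
    their (non-negative) eigenvalues; if fewer than k eigenvalues are
    positive the embedding is reduced with a warning.
    """
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals[0]))
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning a {n_pos}-dimensional embedding"
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    return MdsEmbedding(
        coordinates=pd.DataFrame(
            coords, index=distances.index, columns=[f"dim{i + 1}" for i in range(k)]
        ),
        eigenvalues=evals[:k],
        distance_matrix=distances,
    )


# ---------------------------------------------------------------------------
# dispersion estimation (conditional maximum likelihood)


def equalize_lib_sizes(
    counts: pd.DataFrame,
    lib_sizes: Sequence[float] | None = None,
    norm_factors: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Pseudo-counts scaled so every library has the common (geometric mean)
    effective size.  Values are non-integral in general."""
    libs = np.asarray(lib_sizes if lib_sizes is not None else counts.sum(axis=0), float)
    if norm_factors is not None:
        libs = libs * np.asarray(norm_factors, float)
    common = np.exp(np.mean(np.log(libs)))
    return counts * (common / libs)


def _group_cond_loglik(pseudo: np.ndarray, group_idx: list[np.ndarray], phi: float) -> float:
    """NB conditional log-likelihood (given per-group totals), summed over
    genes and groups, on equal-library-size pseudo-counts."""
    r = 1.0 / phi
    total = 0.0
    for idx in group_idx:
        y = pseudo[:, idx]
        n = len(idx)
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - y.shape[0] * n * gammaln(r)
            + np.sum(gammaln(n * r) - gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Sequence[str],
    lib_sizes: Sequence[float] | None = None,
    norm_factors: Sequence[float] | None = None,
    phi_bounds: tuple[float, float] = (1e-6, 5.0),
) -> float:
    """Common NB dispersion maximizing the conditional log-likelihood.

    Library sizes are equalized first; groups with a single sample carry no
    conditional information and are ignored.  Returns phi >= 0 (values at
    the lower search bound are effectively Poisson).
    """
    if counts.to_numpy().sum() == 0:
        raise ValueError("all-zero count matrix")
    groups = np.asarray(groups)
    pseudo = equalize_lib_sizes(counts, lib_sizes, norm_factors).to_numpy(float)
    group_idx = [
        np.flatnonzero(groups == g) for g in pd.unique(groups)
        if (groups == g).sum() >= 2
    ]
    if not group_idx:
        raise ValueError("need at least one group with >= 2 samples")

    def neg_ll(log_phi: float) -> float:
        return -_group_cond_loglik(pseudo, group_idx, 10.0**log_phi)

    lo, hi = np.log10(phi_bounds[0]), np.log10(phi_bounds[1])
    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    phi = float(10.0**res.x)
    # a maximum at the lower bound means no evidence of extra-Poisson noise
    if neg_ll(lo) <= res.fun:
        return float(phi_bounds[0])
    return phi


# ---------------------------------------------------------------------------
# NB exact test


def nb_exact_test(
    total_a: float,
    total_b: float,
    n_a: int,
    n_b: int,
    phi: float,
) -> float:
    """Exact NB test of equal means given group totals of equalized libraries.

    With equal library sizes, the group sums are NB with sizes n_a/phi and
    n_b/phi and a common success probability, so conditionally on the grand
    total the split follows a beta-negative-binomial law (binomial in the
    Poisson limit phi = 0).  The p-value sums the probabilities of all
    splits at most as likely as the observed one.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    za, zb = int(round(total_a)), int(round(total_b))
    t = za + zb
    if t == 0:
        return 1.0
    z = np.arange(t + 1)
    if phi == 0:
        logw = binom.logpmf(z, t, n_a / (n_a + n_b))
    else:
        ra, rb = n_a / phi, n_b / phi
        logw = (
            gammaln(z + ra) - gammaln(z + 1)
            + gammaln(t - z + rb) - gammaln(t - z + 1)
        )
    logp = logw - logsumexp(logw)
    obs = logp[za]
    keep = logp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def exact_test_contrast(
    counts: pd.DataFrame,
    groups: Sequence[str],
    group_a: str,
    group_b: str,
    phi: float,
    lib_sizes: Sequence[float] | None = None,
    norm_factors: Sequence[float] | None = None,
) -> pd.Series:
    """Per-gene exact-test p-values for one pairwise contrast."""
    groups = np.asarray(groups)
    idx_a = np.flatnonzero(groups == group_a)
    idx_b = np.flatnonzero(groups == group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both groups must be present")
    pseudo = equalize_lib_sizes(counts, lib_sizes, norm_factors).to_numpy(float)
    za = pseudo[:, idx_a].sum(axis=1)
    zb = pseudo[:, idx_b].sum(axis=1)
    pvals = np.array(
        [nb_exact_test(a, b, len(idx_a), len(idx_b), phi) for a, b in zip(za, zb)]
    )
    return pd.Series(pvals, index=counts.index, name="pvalue")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# significance calls and enrichment


@dataclass
class ContrastResult:
    """Full per-gene table for one pairwise contrast (group_b vs group_a)."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # columns: log2_fc, pvalue, fdr, significant


def contrast_table(
    counts: pd.DataFrame,
    groups: Sequence[str],
    group_a: str,
    group_b: str,
    phi: float,
    lib_sizes: Sequence[float] | None = None,
    norm_factors: Sequence[float] | None = None,
    alpha: float = 0.01,
    min_fold_change: float = 2.0,
    prior_count: float = 2.0,
) -> ContrastResult:
    """Exact-test DGE table for one contrast with BH FDR and significance
    calls (FDR <= alpha and 2^|log2FC| >= min_fold_change).

    log2FC is group_b minus group_a on prior-damped group-mean log2 CPM, so
    it is mildly shrunk toward zero for low counts.
    """
    groups = np.asarray(groups)
    lc = log_cpm(counts, lib_sizes, norm_factors, prior_count=prior_count)
    logfc = (
        lc.loc[:, groups == group_b].mean(axis=1)
        - lc.loc[:, groups == group_a].mean(axis=1)
    )
    pvals = exact_test_contrast(
        counts, groups, group_a, group_b, phi, lib_sizes, norm_factors
    )
    fdr = bh_fdr(pvals.to_numpy())
    sig = (fdr <= alpha) & (2.0 ** np.abs(logfc.to_numpy()) >= min_fold_change)
    table = pd.DataFrame(
        {"log2_fc": logfc, "pvalue": pvals, "fdr": fdr, "significant": sig},
        index=counts.index,
    )
    return ContrastResult(group_a=group_a, group_b=group_b, table=table)


def call_degs(
    results: Mapping[tuple[str, str], ContrastResult]
) -> tuple[dict[tuple[str, str], set[str]], set[str], dict[str, int]]:
    """Per-contrast DEG sets, their union, and the 7-region Venn partition.

    Venn keys are subset signatures like "110" over the contrasts in mapping
    order (1 = gene significant in that contrast).
    """
    sets = {key: set(r.table.index[r.table["significant"]]) for key, r in results.items()}
    union: set[str] = set().union(*sets.values()) if sets else set()
    keys = list(sets)
    venn: dict[str, int] = {}
    for mask in itertools.product((0, 1), repeat=len(keys)):
        if not any(mask):
            continue
        members = union.copy()
        for bit, key in zip(mask, keys):
            members &= sets[key] if bit else (union - sets[key])
        venn["".join(map(str, mask))] = len(members)
    return sets, union, venn


def hypergeom_enrichment(
    deg_set: Iterable[str],
    term_to_genes: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    P(X >= k) with population = universe, K = term genes in the universe,
    n = |DEG set|, k = DEG genes carrying the term.  Terms with no universe
    genes are skipped with a warning.
    """
    uni = set(universe)
    degs = set(deg_set) & uni
    if not set(deg_set) <= uni:
        raise ValueError("DEG set must be a subset of the universe")
    rows = []
    for term, genes in term_to_genes.items():
        K = len(set(genes) & uni)
        if K == 0:
            warnings.warn(f"term {term!r} has no genes in the universe; skipped")
            continue
        k = len(set(genes) & degs)
        p = float(hypergeom.sf(k - 1, len(uni), K, len(degs))) if degs else 1.0
        rows.append({"term": term, "n_term": K, "n_hits": k, "pvalue": min(1.0, p)})
    return pd.DataFrame(rows, columns=["term", "n_term", "n_hits", "pvalue"]).set_index(
        "term"
    )
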