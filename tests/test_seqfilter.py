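"""Quality-filter cascade: GC content, ORF scanning, expression filter,
similarity clustering, assembly statistics, FPKM."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holosplit.seqfilter import (
    Cluster,
    OrfClass,
    TranscriptRecord,
    assembly_stats,
    cluster_by_similarity,
    expression_filter,
    find_orfs,
    fpkm,
    gc_content,
    n50,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


# ---------------------------------------------------------------------------
# gc_content


@pytest.mark.parametrize(
    "seq,expected",
    [("GGCC", 1.0), ("ATAT", 0.0), ("ATGCN", 0.5), ("acgt", 0.5)],
)
def test_gc_content_examples(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


@pytest.mark.parametrize("seq", ["", "NNN", "ACGX"])
def test_gc_content_rejects_degenerate_input(seq):
    with pytest.raises(ValueError):
        gc_content(seq)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(dna)
def test_gc_content_invariant_under_reversal_and_complement(seq):
    assert gc_content(seq) == pytest.approx(gc_content(seq[::-1]))
    assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


# ---------------------------------------------------------------------------
# ORF detection


def _orf_oracle(sequence: str, min_codons: int) -> OrfClass:
    """Plain six-frame enumeration by string slicing: collect every candidate
    ORF span per the classification rules and return the class of the longest
    (class informativeness breaking exact span ties)."""
    seq = sequence.upper()
    candidates: list[tuple[int, OrfClass]] = []
    for s in (seq, reverse_complement(seq)):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            stops = [k for k, c in enumerate(codons) if c in ("TAA", "TAG", "TGA")]
            segments = []
            begin = 0
            for k in stops:
                segments.append((begin, k, True))
                begin = k + 1
            segments.append((begin, len(codons), False))
            for seg_i, (a, b, has_stop) in enumerate(segments):
                open5 = seg_i == 0
                span = (b - a + (1 if has_stop else 0)) * 3
                if open5 and b > a:
                    oc = OrfClass.FIVE_PRIME_PARTIAL if has_stop else OrfClass.INTERNAL
                    if b - a >= min_codons:
                        candidates.append((span, oc))
                atgs = [k for k in range(a, b) if codons[k] == "ATG"]
                if atgs:
                    k0 = atgs[0]
                    oc = OrfClass.COMPLETE if has_stop else OrfClass.THREE_PRIME_PARTIAL
                    span2 = (b - k0 + (1 if has_stop else 0)) * 3
                    if b - k0 >= min_codons:
                        candidates.append((span2, oc))
    if not candidates:
        return OrfClass.NONE
    rank = {
        OrfClass.COMPLETE: 0,
        OrfClass.THREE_PRIME_PARTIAL: 1,
        OrfClass.FIVE_PRIME_PARTIAL: 1,
        OrfClass.INTERNAL: 2,
    }
    return min(candidates, key=lambda c: (-c[0], rank[c[1]]))[1]


@pytest.mark.parametrize(
    "seq,min_codons,expected",
    [
        ("ATGAAATAA", 2, OrfClass.COMPLETE),
        ("AAAAAAAAA", 2, OrfClass.INTERNAL),
        ("ATGAAAAAA", 2, OrfClass.THREE_PRIME_PARTIAL),
        ("ATGTAA", 3, OrfClass.NONE),  # no frame holds three open codons
    ],
)
def test_find_orfs_canonical_cases(seq, min_codons, expected):
    oc, orf = find_orfs(seq, min_codons)
    assert oc is expected
    if expected is OrfClass.NONE:
        assert orf is None
    else:
        assert 0 <= orf.start < orf.end <= len(seq)


def test_find_orfs_agrees_with_six_frame_enumeration_oracle():
    gen = np.random.default_rng(7)
    for _ in range(400):
        length = int(gen.integers(6, 300))
        seq = "".join(gen.choice(list("ACGT"), size=length))
        for min_codons in (2, 5, 20):
            assert find_orfs(seq, min_codons)[0] is _orf_oracle(seq, min_codons), (
                seq,
                min_codons,
            )


def test_find_orfs_reports_reverse_strand_coordinates():
    fwd = "ATGAAACCCTAA"
    rev = reverse_complement(fwd)
    oc, orf = find_orfs(rev, 3)
    assert oc is OrfClass.COMPLETE
    assert orf.strand == "-"
    assert rev[orf.start : orf.end] == reverse_complement(fwd)


# ---------------------------------------------------------------------------
# expression filter


def test_expression_filter_pooled_sum_rule():
    ids = ["a", "b", "c"]
    mat = [[0.2, 0.2, 0.2], [0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]
    assert expression_filter(mat, ids, cutoff=0.5) == ["a", "c"]
    assert expression_filter(mat, ids, cutoff=0.0) == ids
    with pytest.raises(ValueError):
        expression_filter([[-1.0]], ["x"], cutoff=0.5)


# ---------------------------------------------------------------------------
# clustering


def test_cluster_identical_sequences_single_cluster():
    out = cluster_by_similarity({"b": "MKLVVK", "a": "MKLVVK"}, 0.9)
    assert len(out) == 1
    assert out[0].representative_id == "a"  # tie on length -> id ascending
    assert sorted(out[0].member_ids) == ["a", "b"]


def test_cluster_prefix_joins_longest_representative():
    out = cluster_by_similarity({"long": "MKLVVK", "short": "MKLVV"}, 0.9)
    assert len(out) == 1 and out[0].representative_id == "long"


def test_cluster_disjoint_sequences_stay_separate():
    out = cluster_by_similarity({"x": "AAAA", "y": "WWWW"}, 0.5)
    assert len(out) == 2


def test_cluster_invariants_on_random_inputs():
    from holosplit.seqfilter import _ungapped_identity

    gen = np.random.default_rng(11)
    for _ in range(25):
        seqs = {
            f"s{i}": "".join(gen.choice(list("ACDEFG"), size=int(gen.integers(3, 12))))
            for i in range(int(gen.integers(2, 10)))
        }
        thr = float(gen.uniform(0.5, 1.0))
        clusters = cluster_by_similarity(seqs, thr)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(seqs)  # exactly one cluster each
        for c in clusters:
            rep = seqs[c.representative_id]
            for m in c.member_ids:
                assert len(rep) >= len(seqs[m])
                assert _ungapped_identity(rep, seqs[m]) >= thr


# ---------------------------------------------------------------------------
# assembly statistics


def _n50_oracle(lengths):
    ls = sorted(lengths, reverse=True)
    total, cum = sum(ls), 0
    for L in ls:
        cum += L
        if cum >= total / 2:
            return L


@pytest.mark.parametrize(
    "lengths,expected",
    [([6, 5, 4, 3, 2], 5), ([7], 7), ([4, 4, 4], 4)],
)
def test_n50_examples(lengths, expected):
    assert n50(lengths) == expected


def test_n50_matches_brute_force_on_random_multisets(rng):
    for _ in range(300):
        lengths = rng.integers(1, 5000, size=rng.integers(1, 60)).tolist()
        assert n50(lengths) == _n50_oracle(lengths)


def test_assembly_stats_fields():
    recs = [
        TranscriptRecord(id="g1_i1", sequence="ATGC", gene_id="g1"),
        TranscriptRecord(id="g1_i2", sequence="GGGGCC", gene_id="g1"),
        TranscriptRecord(id="g2_i1", sequence="AT", gene_id="g2"),
    ]
    s = assembly_stats(recs)
    assert (s.n_genes, s.n_isoforms, s.total_bp) == (2, 3, 12)
    assert s.mean_bp == pytest.approx(4.0)
    assert s.n50_bp == 6
    assert s.pct_gc == pytest.approx(100 * 8 / 12)
    with pytest.raises(ValueError):
        assembly_stats([])


# ---------------------------------------------------------------------------
# FPKM


def test_fpkm_formula_and_homogeneity():
    out = fpkm([[10]], [1000], [1_000_000])
    assert out[0, 0] == pytest.approx(10.0)
    assert fpkm([[0]], [500], [1000])[0, 0] == 0.0
    a = fpkm([[7]], [800], [123456])
    b = fpkm([[7]], [1600], [123456])
    assert a[0, 0] == pytest.approx(2 * b[0, 0])
    with pytest.raises(ValueError):
        fpkm([[1]], [0], [100])
    with pytest.raises(ValueError):
        fpkm([[0], [0]], [10, 10], None if False else [0, 0])
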