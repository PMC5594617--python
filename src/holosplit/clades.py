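"""Symbiont lineage (clade) typing from marker-gene transcripts.

Divergent dinoflagellate symbiont lineages are distinguished with marker
genes (ITS2, cp23S, psbA): marker transcripts retrieved from the assembly by
e-value and alignment-length cutoffs are placed on a neighbor-joining tree
built from Jukes-Cantor distances together with per-clade reference
sequences; each transcript is assigned the clade of its nearest reference by
patristic distance.  Per-colony clade composition is the FPKM-weighted
proportion of each clade's transcripts, and a colony is called for its
dominant clade when that proportion reaches a threshold (default 0.8),
otherwise "mixed".  Clade-vs-disease-status association uses a Pearson
chi-square test without continuity correction.
"""

from __future__ import annotations

import io as _io
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from skbio import TreeNode

MARKERS = ("ITS2", "cp23S", "psbA")


@dataclass(frozen=True)
class MarkerHit:
    transcript_id: str
    marker: str
    evalue: float
    aln_len: int
    ref_len: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.aln_len > self.ref_len:
            raise ValueError("aln_len cannot exceed ref_len")


@dataclass
class CladeCall:
    colony: str
    proportions: dict[str, float] = field(default_factory=dict)
    dominant: str = "mixed"


def retrieve_markers(
    hits: Sequence[MarkerHit],
    evalue_cutoff: float = 1e-10,
    min_len_frac: float = 0.5,
) -> list[MarkerHit]:
    """Keep hits below the e-value cutoff covering at least ``min_len_frac``
    of the reference length."""
    return [
        h
        for h in hits
        if h.evalue < evalue_cutoff and h.aln_len / h.ref_len >= min_len_frac
    ]


class SaturationError(ValueError):
    pass


_GAPLIKE = set("-.NX?")


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance between two aligned nucleotide sequences.

    Columns where either sequence has a gap or ambiguous base are excluded;
    d = -(3/4) ln(1 - 4p/3) with p the mismatch proportion over the
    comparable columns.  p >= 0.75 is saturated and raises.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a, b = seq_a.upper(), seq_b.upper()
    comparable = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    p = mismatches / comparable
    if p >= 0.75:
        raise SaturationError(f"mismatch proportion {p:.3f} >= 0.75 saturates the JC model")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(alignment: Mapping[str, str]) -> pd.DataFrame:
    ids = list(alignment)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jc_distance(alignment[ids[i]], alignment[ids[j]])
    return pd.DataFrame(D, index=ids, columns=ids)


def neighbor_joining(distances: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in newick form.

    At each step the pair minimizing the Q-criterion is joined (ties broken
    by row order for determinism); branch lengths follow the standard
    formulas, with negative estimates clamped to zero and the deficit moved
    to the sibling branch.  Exactly recovers additive input matrices.
    """
    D = distances.to_numpy(dtype=float).copy()
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [str(t) for t in distances.index]
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D2
    # resolve the final three nodes around a central vertex
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    return f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});"


def patristic_distances(newick: str) -> pd.DataFrame:
    """Tip-to-tip path-length distances of a newick tree."""
    tree = TreeNode.read(_io.StringIO(newick), convert_underscores=False)
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    return pd.DataFrame(dm.data, index=ids, columns=ids)


def assign_clade(
    newick: str,
    reference_labels: Mapping[str, str],
    query_leaves: Sequence[str],
    tie_tol: float = 1e-9,
) -> dict[str, str]:
    """Assign each query leaf the clade of its nearest reference leaf by
    patristic distance; ties between clades give "unassigned"."""
    if not reference_labels:
        raise ValueError("no reference leaves given")
    pat = patristic_distances(newick)
    missing = [q for q in query_leaves if q not in pat.index]
    if missing:
        raise ValueError(f"query leaves absent from tree: {missing[:3]}")
    refs = [r for r in reference_labels if r in pat.index]
    if set(reference_labels.values()) - {reference_labels[r] for r in refs}:
        raise ValueError("every clade needs at least one reference leaf in the tree")
    out: dict[str, str] = {}
    for q in query_leaves:
        d = pat.loc[q, refs]
        best = float(d.min())
        clades = {reference_labels[r] for r in refs if d[r] <= best + tie_tol}
        out[q] = clades.pop() if len(clades) == 1 else "unassigned"
    return out


def clade_composition(
    assignments: Mapping[str, str],
    fpkm: Mapping[str, float],
    colony_of: Mapping[str, str],
    dominance_threshold: float = 0.8,
) -> list[CladeCall]:
    """FPKM-weighted per-colony clade proportions and dominant-clade calls.

    Transcripts assigned "unassigned" are ignored.  A colony whose marker
    FPKM totals zero yields no call (with a warning).  Dominant is the
    argmax clade when its proportion reaches the threshold, else "mixed".
    """
    import warnings

    totals: dict[str, Counter] = {}
    for tid, clade in assignments.items():
        if clade == "unassigned":
            continue
        colony = colony_of[tid]
        totals.setdefault(colony, Counter())[clade] += fpkm[tid]
    calls = []
    for colony in sorted({colony_of[t] for t in assignments}):
        cnt = totals.get(colony, Counter())
        total = sum(cnt.values())
        if total <= 0:
            warnings.warn(f"colony {colony!r} has zero marker FPKM; no call")
            continue
        props = {c: v / total for c, v in sorted(cnt.items())}
        dominant = max(props, key=lambda c: props[c])
        if props[dominant] < dominance_threshold:
            dominant = "mixed"
        calls.append(CladeCall(colony=colony, proportions=props, dominant=dominant))
    return calls


def consensus_calls(
    per_marker_calls: Mapping[str, Sequence[CladeCall]], min_agreement: int = 2
) -> dict[str, str]:
    """Reconcile per-marker dominant calls per colony: the call made by at
    least ``min_agreement`` markers wins, else "unresolved"."""
    by_colony: dict[str, list[str]] = {}
    for calls in per_marker_calls.values():
        for call in calls:
            by_colony.setdefault(call.colony, []).append(call.dominant)
    out = {}
    for colony, votes in by_colony.items():
        label, n = Counter(votes).most_common(1)[0]
        out[colony] = label if n >= min_agreement else "unresolved"
    return out


def chi_square_independence(table: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table, without
    continuity correction; returns (statistic, p) with 1 df."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols, total = obs.sum(axis=1), obs.sum(axis=0), obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal total")
    expected = np.outer(rows, cols) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))
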