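"""Host/symbiont partitioning of a metatranscriptome.

Assembled holobiont transcripts are assigned to the coral host or to the
symbiont/microbial fraction by combining three independent lines of
evidence, in strict precedence order:

1. any symbiont evidence — reciprocal-best-hit orthology to a symbiont
   proteome, or homology to Dinophyceae/Bacteria/Fungi — makes a transcript
   ``non_coral`` (and vetoes coexisting coral evidence);
2. otherwise coral evidence — orthology to coral proteomes or homology to
   Cnidaria — makes it ``coral``;
3. otherwise the transcript is unannotated and a GC-content cutoff decides:
   GC below the cutoff is ``coral``, at or above is ``non_coral``.

The GC cutoff is either a fixed constant (default 0.47, i.e. the "<47%"
convention) or estimated from the data as the density valley between the two
GC peaks that host and symbiont transcripts form.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .io import ParseError

SYMBIONT_GROUPS = frozenset({"dinophyceae", "bacteria", "fungi"})
CORAL_GROUP = "cnidaria"
VALID_METHODS = frozenset({"rbh_coral", "rbh_symbiont", "homology"})
VALID_GROUPS = SYMBIONT_GROUPS | {CORAL_GROUP}


class Label(enum.Enum):
    CORAL = "coral"
    NON_CORAL = "non_coral"


class Basis(enum.Enum):
    ORTHOLOGY = "orthology"
    HOMOLOGY = "homology"
    GC_CUTOFF = "gc_cutoff"


@dataclass(frozen=True)
class PartitionResult:
    label: Label
    basis: Basis
    vetoed: bool = False


@dataclass(frozen=True)
class GcCutoff:
    cutoff: float
    method: str  # "fixed" | "valley"
    peak_low: float | None = None
    peak_high: float | None = None


class GcCutoffError(ValueError):
    pass


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> set[tuple[str, str]]:
    """Reciprocal best hits between two sequence sets.

    Each table needs columns (query, subject, bitscore).  A pair (q, s) is
    returned iff s is q's *unique* top-bitscore hit in ``hits_ab`` and q is
    s's unique top-bitscore hit in ``hits_ba``; ties for the top score on
    either side exclude the pair.
    """

    def unique_best(hits: pd.DataFrame) -> dict[str, str]:
        best: dict[str, str] = {}
        for q, sub in hits.groupby("query"):
            top = sub["bitscore"].max()
            winners = sub.loc[sub["bitscore"] == top, "subject"].unique()
            if len(winners) == 1:
                best[q] = winners[0]
        return best

    fwd = unique_best(hits_ab)
    rev = unique_best(hits_ba)
    return {(q, s) for q, s in fwd.items() if rev.get(s) == q}


def ingest_homology(path_or_df, evalue_cutoff: float = 1e-10) -> pd.DataFrame:
    """Load a homology/orthology evidence table, keeping rows below the
    e-value cutoff and validating method/taxon vocabulary."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        from .io import read_evidence_tsv

        df = read_evidence_tsv(path_or_df)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.method not in VALID_METHODS:
            raise ParseError(f"line {i}: unknown method {row.method!r}")
        if row.taxon_group not in VALID_GROUPS:
            raise ParseError(f"line {i}: unknown taxon group {row.taxon_group!r}")
        if not np.isfinite(row.evalue) or row.evalue < 0:
            raise ParseError(f"line {i}: bad e-value {row.evalue!r}")
    return df[df["evalue"] < evalue_cutoff].reset_index(drop=True)


def estimate_gc_cutoff(
    gc_values: Sequence[float],
    gc_coral: Sequence[float] | None = None,
    gc_noncoral: Sequence[float] | None = None,
    method: str = "fixed",
    fixed_cutoff: float = 0.47,
) -> GcCutoff:
    """Choose the GC cutoff separating host-like from symbiont-like transcripts.

    ``method="fixed"`` returns the configured constant.  ``method="valley"``
    smooths the pooled GC distribution with a Gaussian KDE (Silverman
    bandwidth) and places the cutoff at the minimum-density point between the
    two highest local maxima; the annotated class means must straddle the
    cutoff, otherwise estimation fails.
    """
    if method == "fixed":
        return GcCutoff(cutoff=fixed_cutoff, method="fixed")
    if method != "valley":
        raise ValueError(f"unknown method {method!r}")
    gc = np.asarray(gc_values, dtype=float)
    if gc_coral is None or gc_noncoral is None:
        raise GcCutoffError("valley estimation needs annotated coral/non-coral GC values")
    if len(gc_coral) < 50 or len(gc_noncoral) < 50:
        raise GcCutoffError("valley estimation needs >= 50 annotated values per class")
    if np.ptp(gc) == 0:
        raise GcCutoffError("degenerate GC distribution (all values identical)")
    kde = gaussian_kde(gc, bw_method="silverman")
    grid = np.linspace(gc.min(), gc.max(), 2048)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        raise GcCutoffError(
            "smoothed GC density is unimodal; use method='fixed' instead"
        )
    top2 = sorted(maxima[np.argsort(dens[maxima])[-2:]])
    lo, hi = top2
    between = slice(lo, hi + 1)
    cut_idx = lo + int(np.argmin(dens[between]))
    cutoff = float(grid[cut_idx])
    m_coral = float(np.mean(gc_coral))
    m_non = float(np.mean(gc_noncoral))
    if not m_coral < cutoff < m_non:
        raise GcCutoffError(
            f"valley cutoff {cutoff:.3f} does not separate annotated class means "
            f"({m_coral:.3f} vs {m_non:.3f}); use method='fixed'"
        )
    return GcCutoff(
        cutoff=cutoff,
        method="valley",
        peak_low=float(grid[lo]),
        peak_high=float(grid[hi]),
    )


def classify_transcript(
    evidence_rows: pd.DataFrame | None, gc: float, cutoff: GcCutoff
) -> PartitionResult:
    """Classify one transcript from its evidence rows and GC fraction.

    Precedence: symbiont evidence > coral evidence > GC cutoff.  A
    transcript with both coral and symbiont evidence is ``non_coral`` with
    ``vetoed=True``.
    """
    if not 0 <= gc <= 1:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    has_symb = has_coral = False
    symb_basis = coral_basis = Basis.HOMOLOGY
    if evidence_rows is not None and len(evidence_rows):
        for row in evidence_rows.itertuples(index=False):
            if row.method == "rbh_symbiont" or (
                row.method == "homology" and row.taxon_group in SYMBIONT_GROUPS
            ):
                has_symb = True
                if row.method == "rbh_symbiont":
                    symb_basis = Basis.ORTHOLOGY
            elif row.method == "rbh_coral" or (
                row.method == "homology" and row.taxon_group == CORAL_GROUP
            ):
                has_coral = True
                if row.method == "rbh_coral":
                    coral_basis = Basis.ORTHOLOGY
    if has_symb:
        return PartitionResult(Label.NON_CORAL, symb_basis, vetoed=has_coral)
    if has_coral:
        return PartitionResult(Label.CORAL, coral_basis)
    if gc < cutoff.cutoff:
        return PartitionResult(Label.CORAL, Basis.GC_CUTOFF)
    return PartitionResult(Label.NON_CORAL, Basis.GC_CUTOFF)


def partition_transcripts(
    gc_by_transcript: Mapping[str, float],
    evidence: pd.DataFrame,
    cutoff: GcCutoff,
) -> pd.DataFrame:
    """Classify every transcript; returns a table indexed by transcript id
    with columns label, basis, gc, vetoed."""
    groups = (
        dict(tuple(evidence.groupby("query_id"))) if len(evidence) else {}
    )
    rows = {}
    for tid, gc in gc_by_transcript.items():
        res = classify_transcript(groups.get(tid), gc, cutoff)
        rows[tid] = {
            "label": res.label.value,
            "basis": res.basis.value,
            "gc": gc,
            "vetoed": res.vetoed,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transcript_id"
    return df


def partition_summary(
    results: pd.DataFrame,
    truth: Mapping[str, str] | None = None,
    bins: int = 40,
) -> dict:
    """Counts per label x basis, per-class GC histograms, and (with truth)
    a confusion matrix and accuracy figures.

    Truth labels "host"/"symbiont" correspond to "coral"/"non_coral".
    """
    if results.empty:
        raise ValueError("no partition results")
    out: dict = {
        "n": int(len(results)),
        "counts": results.groupby(["label", "basis"]).size().to_dict(),
    }
    edges = np.linspace(0, 1, bins + 1)
    hists = {}
    for label, sub in results.groupby("label"):
        h, _ = np.histogram(sub["gc"], bins=edges)
        hists[label] = h
    out["gc_histograms"] = hists
    out["bin_edges"] = edges
    if truth is not None:
        to_label = {"host": "coral", "symbiont": "non_coral"}
        true = results.index.map(lambda t: to_label[truth[t]])
        pred = results["label"].to_numpy()
        out["confusion"] = (
            pd.crosstab(pd.Series(true, name="truth"), pd.Series(pred, name="called"))
            .reindex(index=["coral", "non_coral"], columns=["coral", "non_coral"])
            .fillna(0)
            .astype(int)
        )
        out["accuracy"] = float((true == pred).mean())
        annotated = results["basis"] != "gc_cutoff"
        if annotated.any():
            out["accuracy_annotated"] = float(
                (true[annotated.to_numpy()] == pred[annotated.to_numpy()]).mean()
            )
    return out
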