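"""Transcript quality filtering and assembly statistics.

Implements the quality-filtering cascade applied to a de novo assembled
metatranscriptome before host/symbiont separation:

* open-reading-frame (ORF) detection in all six frames, with transcripts
  classified as carrying a complete, 5'-partial, 3'-partial or internal ORF
  (transcripts with no qualifying ORF are discarded);
* a pooled-expression filter keeping transcripts whose FPKM summed over all
  samples reaches a cutoff (default 0.5);
* greedy similarity clustering at a 90% identity threshold, retaining the
  longest sequence of each cluster as its representative;
* standard assembly descriptive statistics (gene/isoform counts, %GC,
  total/mean length, N50).
"""

from __future__ import annotations

import bisect
import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class OrfClass(enum.Enum):
    """Classification of the best ORF found in a transcript."""

    COMPLETE = "complete"
    FIVE_PRIME_PARTIAL = "five_prime_partial"
    THREE_PRIME_PARTIAL = "three_prime_partial"
    INTERNAL = "internal"
    NONE = "none"


@dataclass
class TranscriptRecord:
    """One assembled transcript.

    ``gc_fraction`` is (#G + #C) over non-N bases; ``orf_class`` is filled in
    by :func:`classify_orf` and is ``None`` until then.  ``truth_taxon`` holds
    the generating taxon for synthetic data ("host"/"symbiont") and is absent
    for real data.
    """

    id: str
    sequence: str
    gene_id: str = ""
    truth_taxon: str | None = None
    orf_class: OrfClass | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        if not self.gene_id:
            self.gene_id = self.id

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return gc_content(self.sequence)


@dataclass(frozen=True)
class Orf:
    """ORF coordinates, 0-based half-open on the forward strand."""

    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int
    orf_class: OrfClass

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssemblyStats:
    n_genes: int
    n_isoforms: int
    pct_gc: float
    total_bp: int
    mean_bp: float
    n50_bp: int


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)


def gc_content(sequence: str) -> float:
    """GC fraction of a nucleotide sequence: (#G + #C) / (#A + #C + #G + #T).

    ``N`` bases are excluded from both numerator and denominator.  Raises
    ``ValueError`` on an empty sequence or one consisting only of ``N``.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence contains only N bases")
    return (seq.count("G") + seq.count("C")) / denom


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


_STOP_RE = re.compile(r"(?=(TAA|TAG|TGA))")
_ATG_RE = re.compile(r"(?=ATG)")


def _orfs_in_frame(
    seq: str, frame: int, stop_pos: list[int], atg_pos: list[int]
) -> list[tuple[int, int, bool, bool]]:
    """All candidate ORFs in one forward frame of ``seq``.

    ``stop_pos``/``atg_pos`` are the in-frame stop-codon and ATG start
    positions for this frame, ascending.  Returns (start, end, has_start,
    has_stop) in nucleotide coordinates; the stop codon is included in the
    span.  Candidates are the 5'-open first run (internal or 5'-partial) and
    every first-ATG-anchored run (complete or 3'-partial); a stop-to-stop
    run with no ATG is bounded on both sides and is not an ORF.
    """
    n = len(seq)
    out = []
    run_begin = frame
    frame_end = frame + 3 * ((n - frame) // 3)
    for stop in stop_pos + [None]:  # type: ignore[list-item]
        run_end = stop if stop is not None else frame_end
        if run_begin == frame and run_end > run_begin:
            end = stop + 3 if stop is not None else run_end
            out.append((run_begin, end, False, stop is not None))
        # first in-frame ATG within the run (complete / 3' partial)
        k = bisect.bisect_left(atg_pos, run_begin)
        if k < len(atg_pos) and atg_pos[k] < run_end:
            atg = atg_pos[k]
            if stop is not None:
                out.append((atg, stop + 3, True, True))
            elif run_end > atg:
                out.append((atg, run_end, True, False))
        if stop is not None:
            run_begin = stop + 3
    return out


def find_orfs(sequence: str, min_codons: int = 100) -> tuple[OrfClass, Orf | None]:
    """Find and classify the best ORF across all six reading frames.

    The longest qualifying ORF wins (ties: forward strand first, then lowest
    frame, then leftmost start).  Classification:

    * ``complete`` — starts at ATG and ends at a stop codon;
    * ``five_prime_partial`` — open at the 5' end, ends at a stop codon;
    * ``three_prime_partial`` — starts at ATG, runs off the 3' end;
    * ``internal`` — open at both ends;
    * ``none`` — no ORF of at least ``min_codons`` codons in any frame.

    Codon count excludes the stop codon.  Coordinates are reported 0-based
    half-open on the forward strand with a strand flag.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = sequence.upper()
    best: Orf | None = None
    best_key: tuple | None = None
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        stops_all = [m.start() for m in _STOP_RE.finditer(s)]
        atgs_all = [m.start() for m in _ATG_RE.finditer(s)]
        for frame in range(3):
            stop_pos = [p for p in stops_all if p % 3 == frame]
            atg_pos = [p for p in atgs_all if p % 3 == frame]
            for start, end, has_start, has_stop in _orfs_in_frame(
                s, frame, stop_pos, atg_pos
            ):
                n_codons = (end - start) // 3 - (1 if has_stop else 0)
                if n_codons < min_codons:
                    continue
                if has_start and has_stop:
                    oc = OrfClass.COMPLETE
                elif has_stop:
                    oc = OrfClass.FIVE_PRIME_PARTIAL
                elif has_start:
                    oc = OrfClass.THREE_PRIME_PARTIAL
                else:
                    oc = OrfClass.INTERNAL
                if strand == "-":
                    fstart, fend = len(seq) - end, len(seq) - start
                else:
                    fstart, fend = start, end
                # ties at equal span prefer the more informative class
                rank = {
                    OrfClass.COMPLETE: 0,
                    OrfClass.THREE_PRIME_PARTIAL: 1,
                    OrfClass.FIVE_PRIME_PARTIAL: 1,
                    OrfClass.INTERNAL: 2,
                }[oc]
                key = (-(end - start), rank, strand, frame, fstart)
                if best_key is None or key < best_key:
                    best_key = key
                    best = Orf(fstart, fend, strand, frame, oc)
    if best is None:
        return OrfClass.NONE, None
    return best.orf_class, best


def classify_orf(record: TranscriptRecord, min_codons: int = 100) -> OrfClass:
    """Classify ``record``'s best ORF and store the class on the record."""
    oc, _ = find_orfs(record.sequence, min_codons)
    record.orf_class = oc
    return oc


def expression_filter(
    fpkm: "np.ndarray | Sequence[Sequence[float]]",
    transcript_ids: Sequence[str],
    cutoff: float = 0.5,
) -> list[str]:
    """Keep transcripts whose FPKM summed over pooled samples is >= ``cutoff``."""
    arr = np.asarray(fpkm, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != len(transcript_ids):
        raise ValueError("fpkm must be a transcripts x samples matrix")
    if (arr < 0).any():
        raise ValueError("FPKM values must be non-negative")
    pooled = arr.sum(axis=1)
    return [tid for tid, s in zip(transcript_ids, pooled) if s >= cutoff]


def _ungapped_identity(a: str, b: str) -> float:
    """Best ungapped sliding identity: exact matches over the shorter length."""
    if len(a) < len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    if lb == 0:
        return 0.0
    best = 0
    for offset in range(-(lb - 1), la):
        lo = max(0, offset)
        hi = min(la, offset + lb)
        m = sum(1 for i in range(lo, hi) if a[i] == b[i - offset])
        if m > best:
            best = m
    return best / lb


def cluster_by_similarity(
    sequences: Mapping[str, str], threshold: float = 0.9
) -> list[Cluster]:
    """Greedy incremental clustering of (protein) sequences by identity.

    Sequences are sorted by length descending (ties by id ascending); each
    joins the first existing cluster whose representative shares identity
    >= ``threshold`` (identity = exact matches over the shorter sequence's
    length under the best ungapped sliding offset), else founds a cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[Cluster] = []
    for sid in order:
        seq = sequences[sid]
        for cl in clusters:
            if _ungapped_identity(sequences[cl.representative_id], seq) >= threshold:
                cl.member_ids.append(sid)
                break
        else:
            clusters.append(Cluster(representative_id=sid, member_ids=[sid]))
    return clusters


def n50(lengths: Iterable[int]) -> int:
    """Length of the contig at which cumulative length (sorted descending)
    first reaches half the total assembly length."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("no lengths given")
    total = sum(ls)
    cum = 0
    for L in ls:
        cum += L
        if 2 * cum >= total:
            return L
    raise AssertionError("unreachable")


def assembly_stats(records: Sequence[TranscriptRecord]) -> AssemblyStats:
    """Descriptive statistics over an assembly (or a filtered subset)."""
    if not records:
        raise ValueError("no records")
    lengths = [r.length for r in records]
    total = sum(lengths)
    gc_num = sum(r.sequence.count("G") + r.sequence.count("C") for r in records)
    gc_den = sum(sum(r.sequence.count(b) for b in "ACGT") for r in records)
    return AssemblyStats(
        n_genes=len({r.gene_id for r in records}),
        n_isoforms=len(records),
        pct_gc=100.0 * gc_num / gc_den,
        total_bp=total,
        mean_bp=total / len(records),
        n50_bp=n50(lengths),
    )


def fpkm(
    counts: "np.ndarray | Sequence[Sequence[float]]",
    lengths: Sequence[float],
    lib_sizes: Sequence[float] | None = None,
) -> np.ndarray:
    """Fragments per kilobase of transcript per million mapped reads.

    ``fpkm[g, s] = counts[g, s] / ((lengths[g] / 1e3) * (lib_size[s] / 1e6))``
    with library sizes defaulting to column sums of ``counts``.
    """
    c = np.asarray(counts, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if (L <= 0).any():
        raise ValueError("lengths must be positive")
    libs = c.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, dtype=float)
    if (libs <= 0).any():
        raise ValueError("zero library size")
    return c / (L[:, None] / 1e3) / (libs[None, :] / 1e6)
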