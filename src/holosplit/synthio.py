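"""Synthetic holobiont dataset generator with known ground truth.

Real coral holobiont studies sequence host animal and dinoflagellate symbiont
together; the raw colony data behind such studies is rarely redistributable at
desk scale.  This module generates datasets that reproduce the statistical
structure every downstream stage relies on, with complete truth labels:

* transcript pools for two taxa with distinct unimodal GC distributions
  (host peak near 0.42, symbiont near 0.53) and log-normal lengths, a
  configurable fraction carrying a planted complete ORF;
* sparse homology/orthology evidence (default ~10% of transcripts
  annotatable) with a controllable wrong-taxon error rate;
* negative-binomial count matrices over three tissue groups with planted
  fold-changes for a fraction of genes;
* marker-gene alignments for divergent symbiont lineages (clades) evolved
  from a common ancestor under the Jukes-Cantor model, with per-colony
  clade compositions and marker FPKM values.

Every artifact draws from its own RNG stream spawned deterministically from
the master seed, so stages can be re-run independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqfilter import STOP_CODONS, TranscriptRecord

BASES = np.array(list("ACGT"))

# fixed stream indices so outputs are stable under config extension
_STREAMS = {"transcripts": 0, "evidence": 1, "counts": 2, "markers": 3, "libsizes": 4}

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("healthy", 6),
    ("ga_affected", 6),
    ("ga_unaffected", 6),
)

# desk-scale analogue of the study population: colonies dominated by one
# lineage (C or D) with a single mixed colony
DEFAULT_COLONY_CLADES: tuple[tuple[str, Mapping[str, float]], ...] = tuple(
    [(f"colC{i}", {"C": 1.0}) for i in range(1, 7)]
    + [(f"colD{i}", {"D": 1.0}) for i in range(1, 6)]
    + [("colM1", {"C": 0.5, "D": 0.5})]
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic holobiont dataset.

    GC means/SDs are fractions in [0,1]; lengths are drawn log-normally
    (natural-log parameters, base pairs); ``dispersion`` is the NB dispersion
    phi in Var = mu + phi*mu^2; ``fold_change`` is the planted group-mean
    ratio for differentially expressed genes; ``clade_divergence`` is the
    Jukes-Cantor branch length (substitutions/site) from the lineage common
    ancestor to each clade reference.
    """

    n_host: int = 10_000
    n_symbiont: int = 10_000
    gc_host_mean: float = 0.42
    gc_host_sd: float = 0.03
    gc_symb_mean: float = 0.53
    gc_symb_sd: float = 0.03
    length_log_mean: float = 7.3  # exp(7.3) ~ 1480 bp
    length_log_sd: float = 0.45
    no_orf_fraction: float = 0.1
    planted_orf_min_codons: int = 100
    annotation_sensitivity: float = 0.10
    annotation_error_rate: float = 0.0
    n_genes: int = 2_000
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    frac_de: float = 0.1
    fold_change: float = 4.0
    dispersion: float = 0.1
    lib_size_mean: float = 1e6
    lib_size_cv: float = 0.2
    clade_divergence: float = 0.3
    within_clade_divergence: float = 0.01
    marker_length: int = 600
    n_markers_per_colony: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "gc_host_mean": self.gc_host_mean,
            "gc_host_sd": self.gc_host_sd,
            "gc_symb_mean": self.gc_symb_mean,
            "gc_symb_sd": self.gc_symb_sd,
            "no_orf_fraction": self.no_orf_fraction,
            "annotation_sensitivity": self.annotation_sensitivity,
            "annotation_error_rate": self.annotation_error_rate,
            "frac_de": self.frac_de,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in (
            ("n_host", self.n_host),
            ("n_symbiont", self.n_symbiont),
            ("n_genes", self.n_genes),
            ("marker_length", self.marker_length),
            ("n_markers_per_colony", self.n_markers_per_colony),
        ):
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.clade_divergence < 0 or self.within_clade_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if not self.groups:
            raise ValueError("at least one sample group is required")


@dataclass
class TruthSet:
    """Ground truth for one synthetic dataset."""

    taxon_by_transcript: dict[str, str] = field(default_factory=dict)
    de_genes_by_contrast: dict[tuple[str, str], dict[str, int]] = field(
        default_factory=dict
    )
    clade_by_marker: dict[str, str] = field(default_factory=dict)
    orf_planted: dict[str, bool] = field(default_factory=dict)
    colony_clade: dict[str, str] = field(default_factory=dict)


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed), _STREAMS[stream]])


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


# integer base codes: A=0, C=1, G=2, T=3 (matches BASES order)
_STOP_CODES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA


def _exact_composition(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Random permutation of a base multiset whose GC fraction is exactly
    round(gc * length) / length (G/C and A/T split as evenly as possible)."""
    n_gc = int(round(gc * length))
    n_g = n_gc // 2 + int(rng.integers(0, 2)) * (n_gc % 2)
    n_at = length - n_gc
    n_a = n_at // 2 + int(rng.integers(0, 2)) * (n_at % 2)
    arr = np.concatenate(
        [
            np.zeros(n_a, dtype=np.int8),
            np.ones(n_gc - n_g, dtype=np.int8),
            np.full(n_g, 2, dtype=np.int8),
            np.full(n_at - n_a, 3, dtype=np.int8),
        ]
    )
    return rng.permutation(arr)


def _force_base(
    rng: np.random.Generator, arr: np.ndarray, fixed: np.ndarray, p: int, base: int
) -> None:
    """Set arr[p] = base by swapping with a non-fixed position holding it,
    preserving composition (falls back to overwrite if none exists)."""
    if arr[p] == base:
        fixed[p] = True
        return
    cands = np.flatnonzero((arr == base) & ~fixed)
    if cands.size:
        q = int(rng.choice(cands))
        arr[q] = arr[p]
    arr[p] = base
    fixed[p] = True


def _one_sequence(
    rng: np.random.Generator,
    length: int,
    gc: float,
    plant_orf: bool,
    min_codons: int,
) -> str:
    """One synthetic transcript with GC fraction exactly at the drawn target.

    The sequence is a random permutation of an exact-composition base
    multiset; when an ORF is planted, the ATG and stop codon are swapped in
    and interior in-frame stop codons are removed by composition-preserving
    swaps, so the planted ORF never perturbs the GC fraction.
    """
    arr = _exact_composition(rng, length, gc)
    if not plant_orf:
        return "".join(BASES[arr])
    orf_capacity = (length - 6) // 3
    n_codons = min(orf_capacity, max(min_codons, int(0.7 * orf_capacity)))
    orf_len = 3 * n_codons + 6
    s = int(rng.integers(0, length - orf_len + 1))
    fixed = np.zeros(length, dtype=bool)
    for off, b in enumerate((0, 3, 2)):  # ATG
        _force_base(rng, arr, fixed, s + off, b)
    stop = [(3, 0, 0), (3, 0, 2), (3, 2, 0)][int(rng.integers(0, 3))]
    for off, b in enumerate(stop):
        _force_base(rng, arr, fixed, s + 3 + 3 * n_codons + off, b)
    # clear interior in-frame stop codons by swapping their leading T away
    interior = range(s + 3, s + 3 + 3 * n_codons, 3)
    for _ in range(200):
        bad = [c for c in interior if tuple(arr[c : c + 3]) in _STOP_CODES]
        if not bad:
            break
        for c in bad:
            cands = np.flatnonzero((arr != 3) & ~fixed)
            cands = cands[(cands < c) | (cands >= c + 3)]
            if cands.size:
                q = int(rng.choice(cands))
                arr[c], arr[q] = arr[q], 3
            else:  # degenerate composition: overwrite (negligible GC slip)
                arr[c] = 1
    else:
        for c in interior:
            if tuple(arr[c : c + 3]) in _STOP_CODES:
                arr[c] = 1
    return "".join(BASES[arr])


def simulate_transcripts(cfg: SynthConfig) -> tuple[list[TranscriptRecord], TruthSet]:
    """Generate host and symbiont transcript pools with truth taxon labels.

    Per-sequence target GC is drawn Normal(mean, sd) truncated to [0.2, 0.8];
    bases are i.i.d. at that target.  Lengths are log-normal, floored at a
    length that can hold the planted ORF.  A fraction ``1 - no_orf_fraction``
    of transcripts carries a planted complete ORF of at least
    ``planted_orf_min_codons`` codons.
    """
    rng = _rng(cfg.seed, "transcripts")
    truth = TruthSet()
    records: list[TranscriptRecord] = []
    min_len = 3 * cfg.planted_orf_min_codons + 6
    taxa = [
        ("host", cfg.n_host, cfg.gc_host_mean, cfg.gc_host_sd),
        ("symbiont", cfg.n_symbiont, cfg.gc_symb_mean, cfg.gc_symb_sd),
    ]
    for taxon, n, gc_mean, gc_sd in taxa:
        gcs = np.clip(rng.normal(gc_mean, gc_sd, size=n), 0.2, 0.8)
        lengths = np.maximum(
            np.round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, size=n)),
            min_len,
        ).astype(int)
        plant = rng.random(n) >= cfg.no_orf_fraction
        for i in range(n):
            tid = f"{taxon}_{i:06d}"
            seq = _one_sequence(
                rng, lengths[i], gcs[i], bool(plant[i]), cfg.planted_orf_min_codons
            )
            records.append(TranscriptRecord(id=tid, sequence=seq, truth_taxon=taxon))
            truth.taxon_by_transcript[tid] = taxon
            truth.orf_planted[tid] = bool(plant[i])
    return records, truth


_WRONG_GROUP = {
    "host": ("dinophyceae", "bacteria", "fungi"),
    "symbiont": ("cnidaria",),
}
_TRUE_GROUP = {"host": "cnidaria", "symbiont": "dinophyceae"}
_TRUE_RBH = {"host": "rbh_coral", "symbiont": "rbh_symbiont"}
_WRONG_RBH = {"host": "rbh_symbiont", "symbiont": "rbh_coral"}


def simulate_evidence(
    truth: TruthSet,
    sensitivity: float,
    error_rate: float,
    seed: int,
    rbh_fraction: float = 0.3,
) -> pd.DataFrame:
    """Simulate sparse homology/orthology evidence for annotated transcripts.

    A fraction ``sensitivity`` of transcripts receives one evidence row; with
    probability ``error_rate`` the row carries a wrong taxon group.  Rows are
    split between BLAST-style homology hits and reciprocal-best-hit orthology
    calls.  E-values are drawn below the 1e-10 retrieval threshold.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= error_rate <= 1:
        raise ValueError("sensitivity and error_rate must be in [0, 1]")
    rng = _rng(seed, "evidence")
    rows = []
    for tid, taxon in truth.taxon_by_transcript.items():
        if rng.random() >= sensitivity:
            continue
        wrong = rng.random() < error_rate
        use_rbh = rng.random() < rbh_fraction
        if use_rbh:
            method = _WRONG_RBH[taxon] if wrong else _TRUE_RBH[taxon]
            group = "dinophyceae" if method == "rbh_symbiont" else "cnidaria"
        else:
            method = "homology"
            if wrong:
                group = str(rng.choice(_WRONG_GROUP[taxon]))
            else:
                group = _TRUE_GROUP[taxon]
        evalue = 10.0 ** -rng.uniform(10.5, 60.0)
        aln_len = int(rng.integers(100, 900))
        rows.append(
            {
                "query_id": tid,
                "taxon_group": group,
                "method": method,
                "evalue": evalue,
                "bitscore": float(np.round(rng.uniform(60, 800), 1)),
                "aln_len": aln_len,
                "ref_len": int(aln_len + rng.integers(0, 200)),
            }
        )
    cols = ["query_id", "taxon_group", "method", "evalue", "bitscore", "aln_len", "ref_len"]
    return pd.DataFrame(rows, columns=cols)


def simulate_counts(
    cfg: SynthConfig, truth: TruthSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Simulate an NB gene x sample count matrix over the configured groups.

    Gene baseline relative abundances are log-normal and shared across
    groups; a fraction ``frac_de`` of genes is assigned a target group where
    the mean is multiplied by ``fold_change`` (up) or its inverse (down),
    making the gene differentially expressed in both contrasts involving
    that group.  Counts are NB with dispersion phi (Poisson when phi = 0);
    library sizes are log-normal around ``lib_size_mean`` with the
    configured coefficient of variation.

    Returns (counts, sample metadata, truth).  Healthy samples come from
    distinct colonies; affected/unaffected samples are paired by colony.
    """
    rng = _rng(cfg.seed, "counts")
    if truth is None:
        truth = TruthSet()
    gene_ids = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    group_names = [g for g, _ in cfg.groups]

    q = rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    q /= q.sum()

    mult = np.ones((cfg.n_genes, len(group_names)))
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    target_group = rng.integers(0, len(group_names), size=n_de)
    direction = rng.choice([-1, 1], size=n_de)
    for gi, tg, d in zip(de_idx, target_group, direction):
        mult[gi, tg] = cfg.fold_change if d > 0 else 1.0 / cfg.fold_change

    for a in range(len(group_names)):
        for b in range(a + 1, len(group_names)):
            key = (group_names[a], group_names[b])
            planted: dict[str, int] = {}
            for gi, tg, d in zip(de_idx, target_group, direction):
                if tg == a:
                    planted[gene_ids[gi]] = -int(d)  # up in a means down in b
                elif tg == b:
                    planted[gene_ids[gi]] = int(d)
            truth.de_genes_by_contrast[key] = planted

    lib_rng = _rng(cfg.seed, "libsizes")
    sigma = np.sqrt(np.log1p(cfg.lib_size_cv**2))
    sample_ids, tissues, colonies = [], [], []
    col_counter = 0
    pair_counter: dict[str, int] = {}
    for g, n in cfg.groups:
        for k in range(n):
            sample_ids.append(f"{g}_{k + 1}")
            tissues.append(g)
            if g in ("ga_affected", "ga_unaffected"):
                pair_counter.setdefault(g, 0)
                colonies.append(f"colony_d{k + 1}")
            else:
                col_counter += 1
                colonies.append(f"colony_h{col_counter}")
    lib_sizes = lib_rng.lognormal(
        np.log(cfg.lib_size_mean) - sigma**2 / 2, sigma, size=len(sample_ids)
    )

    counts = np.empty((cfg.n_genes, len(sample_ids)), dtype=np.int64)
    for s, (tissue, lib) in enumerate(zip(tissues, lib_sizes)):
        gidx = group_names.index(tissue)
        mu = lib * q * mult[:, gidx]
        if cfg.dispersion == 0:
            counts[:, s] = rng.poisson(mu)
        else:
            shape = 1.0 / cfg.dispersion
            lam = rng.gamma(shape, mu / shape)
            counts[:, s] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"tissue": tissues, "colony": colonies}, index=pd.Index(sample_ids, name="sample")
    )
    return counts_df, meta, truth


def _evolve_jc(
    rng: np.random.Generator, seq: np.ndarray, branch_length: float
) -> np.ndarray:
    """Evolve an integer-coded sequence along a branch under Jukes-Cantor."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_markers(
    clades: Sequence[str] = ("C", "D"),
    divergence: float = 0.3,
    n_transcripts_per_colony: int = 6,
    seed: int = 0,
    colony_clades: Sequence[tuple[str, Mapping[str, float]]] = DEFAULT_COLONY_CLADES,
    markers: Sequence[str] = ("ITS2", "cp23S", "psbA"),
    marker_length: int = 600,
    within_clade_divergence: float = 0.01,
) -> tuple[dict[str, dict[str, str]], TruthSet, pd.DataFrame]:
    """Simulate aligned marker-gene references and colony marker transcripts.

    For each marker gene an ancestor sequence is drawn and each clade
    reference evolved from it by JC substitution along a branch of length
    ``divergence``.  Each colony's marker transcripts are evolved from their
    clade's reference with small within-clade divergence, the clade being
    drawn per colony composition (exact allocation, largest remainder, so a
    50/50 colony really is half-and-half).  Substitution-only evolution keeps
    all sequences the same length, i.e. naturally aligned.

    Returns (alignments, truth, fpkm) where ``alignments[marker]`` maps
    sequence id -> aligned sequence (references named ``ref_<clade>``),
    ``truth.clade_by_marker`` maps transcript id -> true clade and
    ``truth.colony_clade`` maps colony -> dominant label ("mixed" when no
    clade reaches 80% of the composition), and ``fpkm`` has one row per
    marker transcript (columns: marker, colony, clade, fpkm).
    """
    if len(clades) < 2:
        raise ValueError("at least two clades required")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = _rng(seed, "markers")
    truth = TruthSet()
    alignments: dict[str, dict[str, str]] = {}
    fpkm_rows = []
    for marker in markers:
        ancestor = rng.integers(0, 4, size=marker_length)
        refs = {c: _evolve_jc(rng, ancestor, divergence) for c in clades}
        aln: dict[str, str] = {
            f"ref_{c}": "".join(BASES[refs[c]]) for c in clades
        }
        for colony, comp in colony_clades:
            labels = [c for c in clades if comp.get(c, 0) > 0]
            weights = np.array([comp[c] for c in labels], dtype=float)
            weights /= weights.sum()
            # largest-remainder allocation of transcripts to clades
            raw = weights * n_transcripts_per_colony
            alloc = np.floor(raw).astype(int)
            rem = n_transcripts_per_colony - alloc.sum()
            if rem > 0:
                order = np.argsort(-(raw - alloc))
                alloc[order[:rem]] += 1
            j = 0
            for c, k in zip(labels, alloc):
                for _ in range(k):
                    tid = f"{colony}|{marker}|m{j:02d}"
                    seq = _evolve_jc(rng, refs[c], within_clade_divergence)
                    aln[tid] = "".join(BASES[seq])
                    truth.clade_by_marker[tid] = c
                    fpkm_rows.append(
                        {
                            "transcript_id": tid,
                            "marker": marker,
                            "colony": colony,
                            "fpkm": float(np.round(rng.lognormal(np.log(50), 0.5), 4)),
                        }
                    )
                    j += 1
        alignments[marker] = aln
    for colony, comp in colony_clades:
        total = sum(comp.values())
        best = max(comp, key=lambda c: comp[c])
        truth.colony_clade[colony] = (
            best if comp[best] / total >= 0.8 else "mixed"
        )
    return alignments, truth, pd.DataFrame(fpkm_rows)


def write_dataset(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic dataset and write it as plain-text files."""
    from . import io as hio
    from .seqfilter import fpkm as fpkm_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records, truth = simulate_transcripts(cfg)
    paths["transcripts"] = out / "transcripts.fasta"
    hio.write_fasta(records, paths["transcripts"])

    ev = simulate_evidence(
        truth, cfg.annotation_sensitivity, cfg.annotation_error_rate, cfg.seed
    )
    paths["evidence"] = out / "evidence.tsv"
    hio.write_evidence_tsv(ev, paths["evidence"])

    counts, meta, truth = simulate_counts(cfg, truth)
    paths["counts"] = out / "counts.tsv"
    hio.write_matrix_tsv(counts, paths["counts"])
    paths["samples"] = out / "samples.tsv"
    meta.to_csv(paths["samples"], sep="\t")

    # per-transcript FPKM for the pooled-expression filter: reuse the count
    # model at transcript granularity
    lengths = np.array([r.length for r in records])
    tr_cfg = SynthConfig(
        n_genes=len(records),
        frac_de=0.0,
        dispersion=cfg.dispersion,
        groups=cfg.groups,
        lib_size_mean=cfg.lib_size_mean,
        seed=cfg.seed + 1,
    )
    tcounts, _, _ = simulate_counts(tr_cfg)
    tcounts.index = [r.id for r in records]
    fp = fpkm_matrix(tcounts.to_numpy(), lengths)
    fp_df = pd.DataFrame(fp, index=tcounts.index, columns=tcounts.columns)
    paths["fpkm"] = out / "transcript_fpkm.tsv"
    hio.write_matrix_tsv(fp_df, paths["fpkm"])

    alns, mtruth, mfpkm = simulate_markers(
        divergence=cfg.clade_divergence,
        n_transcripts_per_colony=cfg.n_markers_per_colony,
        seed=cfg.seed,
        marker_length=cfg.marker_length,
        within_clade_divergence=cfg.within_clade_divergence,
    )
    truth.clade_by_marker = mtruth.clade_by_marker
    truth.colony_clade = mtruth.colony_clade
    for marker, aln in alns.items():
        p = out / f"markers_{marker}.afa"
        hio.write_fasta(aln, p)
        paths[f"markers_{marker}"] = p
    paths["marker_fpkm"] = out / "marker_fpkm.tsv"
    mfpkm.to_csv(paths["marker_fpkm"], sep="\t", index=False)

    paths["truth_taxon"] = out / "truth_taxon.tsv"
    pd.Series(truth.taxon_by_transcript, name="taxon").rename_axis(
        "transcript_id"
    ).to_csv(paths["truth_taxon"], sep="\t")
    paths["truth_clades"] = out / "truth_clades.tsv"
    pd.Series(truth.colony_clade, name="dominant_clade").rename_axis("colony").to_csv(
        paths["truth_clades"], sep="\t"
    )
    de_rows = [
        {"contrast": f"{a}_vs_{b}", "gene_id": g, "direction": d}
        for (a, b), genes in truth.de_genes_by_contrast.items()
        for g, d in sorted(genes.items())
    ]
    paths["truth_de"] = out / "truth_de.tsv"
    pd.DataFrame(de_rows, columns=["contrast", "gene_id", "direction"]).to_csv(
        paths["truth_de"], sep="\t", index=False
    )
    return paths
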