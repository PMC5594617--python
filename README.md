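# holosplit

Coral holobiont metatranscriptome analysis: transcript quality filtering,
host/symbiont partitioning, differential gene expression, and symbiont
lineage typing — with a synthetic-data generator so every stage can be
tested against known ground truth.

## The problem

RNA-seq of a coral colony sequences the whole *holobiont*: the coral animal
together with its endosymbiotic dinoflagellates (*Symbiodinium*) and
associated microbes. A de novo assembly of such data is a mixture of
transcripts from all of these organisms, and most of them cannot be
annotated by homology because coral genomic resources are sparse. Before
host gene expression can be analyzed — for example to compare healthy
tissue with growth-anomaly (GA) lesions — the assembly has to be cleaned
and split into host and symbiont fractions, and the symbiont community
itself typed to its major lineages (clades).

`holosplit` implements that post-assembly pipeline for researchers working
on coral (or other host–symbiont) transcriptomes:

1. **Quality filtering** (`holosplit.seqfilter`) — six-frame ORF detection
   (complete / 5′-partial / 3′-partial / internal), a pooled-expression
   filter (transcripts kept when ΣFPKM over samples ≥ 0.5), greedy
   90%-identity clustering retaining the longest sequence per cluster, and
   assembly statistics (N50, %GC, length summaries).
2. **Host/symbiont partitioning** (`holosplit.partition`) — three evidence
   lines in strict precedence: reciprocal-best-hit orthology, BLAST-style
   homology (e-value < 10⁻¹⁰) to Cnidaria vs Dinophyceae/Bacteria/Fungi,
   and, for the unannotated majority, a GC-content cutoff. Any symbiont
   evidence vetoes coral evidence. The cutoff is either fixed (GC < 0.47 ⇒
   host) or estimated as the density valley between the two GC peaks that
   host (≈0.42) and symbiont (≈0.53) transcripts form.
3. **Expression profiling and DGE** (`holosplit.dge`) — CPM filtering
   (≥ 1 CPM in ≥ 2 libraries), TMM normalization, sample ordination by
   classical MDS on the leading-log-fold-change distance
   d(i,j) = √(mean of the top-k largest (log₂CPMᵢ − log₂CPMⱼ)²), a common
   negative-binomial dispersion φ estimated by conditional maximum
   likelihood, the NB exact test for each pairwise tissue contrast
   (conditioning on per-gene totals after library-size equalization),
   Benjamini–Hochberg FDR, significance at FDR ≤ 0.01 and fold-change ≥ 2,
   and hypergeometric term-enrichment of DEG sets.
4. **Clade typing** (`holosplit.clades`) — marker transcripts (ITS2, cp23S,
   psbA) retrieved by e-value and alignment-length cutoffs, Jukes–Cantor
   distances d = −(3/4)·ln(1 − 4p/3), Saitou–Nei neighbor joining, nearest
   reference assignment by patristic distance, FPKM-weighted per-colony
   clade composition with a dominance call (default threshold 0.8, below it
   "mixed"), and a chi-square test of clade vs disease status.
5. **Synthetic data** (`holosplit.synthio`) — generates transcript pools
   with taxon-specific GC distributions, sparse annotation evidence,
   NB-distributed counts with planted fold-changes across three tissue
   groups (healthy / GA-affected / GA-unaffected), and marker-gene
   alignments for divergent clades — all with complete truth labels and
   byte-reproducible from a single seed.

## Worked example

```python
import numpy as np
from holosplit import synthio as sy, partition as pt, dge as dg

cfg = sy.SynthConfig(n_host=3000, n_symbiont=3000, n_genes=2000, seed=42)
records, truth = sy.simulate_transcripts(cfg)
gc = {r.id: r.gc_fraction for r in records}
evidence = pt.ingest_homology(sy.simulate_evidence(truth, 0.10, 0.0, seed=42))
coral = set(evidence.loc[evidence["taxon_group"] == "cnidaria", "query_id"])
symb = set(evidence.loc[evidence["taxon_group"].isin(pt.SYMBIONT_GROUPS), "query_id"])
cutoff = pt.estimate_gc_cutoff(list(gc.values()), [gc[t] for t in coral - symb],
                               [gc[t] for t in symb], method="valley")
results = pt.partition_transcripts(gc, evidence, cutoff)
summary = pt.partition_summary(results, truth.taxon_by_transcript)
print(f"GC valley cutoff: {cutoff.cutoff:.3f}")
print(f"partition accuracy: {summary['accuracy']:.3f} "
      f"(annotated: {summary['accuracy_annotated']:.3f})")

counts, meta, truth = sy.simulate_counts(cfg)
groups = meta["tissue"].to_numpy()
kept = dg.cpm_filter(counts)
factors = dg.tmm_factors(kept)
phi = dg.estimate_common_dispersion(kept, groups, norm_factors=factors.to_numpy())
res = dg.contrast_table(kept, groups, "healthy", "ga_affected", phi,
                        norm_factors=factors.to_numpy())
print(f"common dispersion: {phi:.3f}")
print(f"DEGs (healthy vs GA-affected, FDR<=0.01, FC>=2): "
      f"{int(res.table['significant'].sum())}")
```

prints

```
GC valley cutoff: 0.475
partition accuracy: 0.972 (annotated: 1.000)
common dispersion: 0.100
DEGs (healthy vs GA-affected, FDR<=0.01, FC>=2): 130
```

The estimated valley sits at the midpoint of the two GC peaks (0.42/0.53);
all annotated transcripts are classified correctly, and overall accuracy
reflects only the overlap of the two GC distributions. The dispersion
estimate recovers the generating φ = 0.1, and the DEG count is close to the
~133 genes planted with fold-changes in this contrast (10% of 2,000 genes
spread over three tissue groups, two thirds of which touch this contrast).

The same stages are available from the shell:

```bash
holosplit simulate --seed 1 --out data/
holosplit partition --fasta data/transcripts.fasta --evidence data/evidence.tsv \
    --gc-cutoff auto --out part/
holosplit dge --counts data/counts.tsv --meta data/samples.tsv --out dge/
holosplit run --out full_run/      # entire pipeline + manifest.json
```

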