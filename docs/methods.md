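# Methods

This note documents the models and procedures implemented in `holosplit`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Quality filtering

**ORF detection.** All six reading frames are scanned. Within a frame, the
codon runs bounded by stop codons define the candidates: the 5′-open first
run (class `internal` if it also runs off the 3′ end, `five_prime_partial`
if it ends at a stop), and each run's first in-frame ATG-anchored span
(`complete` if it reaches a stop, `three_prime_partial` if it runs off the
3′ end). A stop-to-stop run with no ATG is bounded on both sides and is not
a candidate. The longest candidate wins; exact span ties prefer the more
informative class (complete, then partial, then internal), then forward
strand, lower frame, leftmost start — making classification deterministic.
Codon counts exclude the stop codon. The minimum ORF length defaults to 100
codons (the published default of the standard transcriptome ORF finder) and
is configurable. Coordinates are reported 0-based half-open on the forward
strand with a strand flag.

**Expression filter.** A transcript is kept when its FPKM summed over all
(pooled) samples is ≥ 0.5. FPKM is count / (kb of transcript × millions of
mapped reads in the library), with library sizes taken as column sums.

**Similarity clustering.** Greedy incremental clustering in length order
(ties by id): a sequence joins the first cluster whose representative
shares ≥ 90% identity, where identity is exact matches over the shorter
sequence's length at the best ungapped sliding offset — the convention of
the widely used greedy clustering tools this mirrors. The representative is
therefore always the longest member. The exact sliding-window identity is
quadratic in sequence length and intended for moderate input sizes; the
full-pipeline driver leaves it off by default (synthetic transcripts are
generated independently, so there is nothing to collapse) while the library
function and CLI expose it.

**N50** is the length of the contig at which the cumulative length of
contigs sorted descending first reaches half the total assembly length —
the standard definition.

## Host/symbiont partitioning

Evidence rows per transcript carry a method (`rbh_coral`, `rbh_symbiont`,
`homology`) and a taxon group (`cnidaria`, `dinophyceae`, `bacteria`,
`fungi`); homology rows are pre-filtered at e-value < 10⁻¹⁰. Reciprocal
best hits require a *unique* top-bitscore hit in both directions; ties
exclude the pair. RBH stands in for full orthology clustering because the
pipeline uses orthology only as a binary host/symbiont signal; multiple
host reference proteomes are treated as a union.

Classification precedence: (1) any symbiont evidence ⇒ `non_coral`, with a
veto flag when coral evidence coexists; (2) else any coral evidence ⇒
`coral`; (3) else GC < cutoff ⇒ `coral`, otherwise `non_coral`. Labeling
high-GC unannotated transcripts `non_coral` is the complement implied by
exclusion from the coral set; a two-way partition is needed downstream.

The GC cutoff is either fixed (default 0.47) or estimated: a Gaussian KDE
with Silverman bandwidth is fitted to all GC values, and the cutoff is the
minimum-density point between the two highest local maxima. The estimate
must separate the annotated class means, and a unimodal density is an
error advising the fixed cutoff. On a balanced two-Gaussian mixture the
valley converges to the component-mean midpoint; with peaks 0.42/0.53 and
SD 0.03 the expected cutoff is 0.475, and the classifier's irreducible
error is the overlap of the two Gaussians (≈3% per class), which is why
partition accuracy on synthetic data sits near 0.97 with annotated
transcripts always correct when the evidence error rate is zero.

## Expression profiling and differential expression

Counts are modeled as negative binomial with Var(Y) = μ + φμ² (φ = 0 is
Poisson). The analysis path is the standard small-replicate count workflow:

* **CPM filter**: keep genes with ≥ 1 CPM in ≥ 2 libraries, computed on the
  original library sizes (which are retained afterwards, not recomputed).
* **TMM factors**: reference = sample whose upper-quartile CPM is closest
  to the mean; per sample, M and A values over genes positive in both
  sample and reference; 30%/5% two-sided trims on M/A ranks; factor =
  2^(inverse-asymptotic-variance weighted mean of surviving M); factors
  rescaled to multiply to 1. This matches the reference R implementation
  to ≈10⁻⁶ (cross-checked in the test suite via Rscript).
* **MDS**: pairwise leading-logFC distance — the root-mean-square of the
  top-500 largest |log₂CPM| differences, log-CPM damped by a
  library-size-scaled prior count of 2 — embedded by classical (Torgerson)
  MDS: eigendecomposition of −½·J·D²·J with coordinates scaled by √λ.
  Requests for more dimensions than positive eigenvalues reduce with a
  warning.
* **Common dispersion**: conditional maximum likelihood on pseudo-counts
  scaled to the geometric-mean effective library size. With equal library
  sizes the per-group sums are sufficient, giving the conditional
  log-likelihood Σ log Γ(yᵢ+1/φ) − n log Γ(1/φ) + log Γ(n/φ) − log Γ(z+n/φ)
  summed over genes and groups; φ is maximized on a log grid with bounded
  scalar optimization, and a maximum at the lower bound is reported as
  (effectively) zero. Simple scaling, rather than full quantile
  adjustment, introduces a bias of order (c−1)/μ per sample — negligible
  at the depth variation simulated here (20% CV).
* **Exact test**: with equalized libraries, group sums are NB with sizes
  n_A/φ and n_B/φ and common success probability, so conditionally on the
  grand total the split is beta-negative-binomial (binomial when φ = 0).
  The p-value sums the probabilities of all splits at most as likely as the
  observed one (with a 10⁻¹⁰ relative tie tolerance). This is the "small-p"
  rejection region; with balanced groups the conditional law is symmetric
  and the choice coincides with tail doubling in practice. Group totals of
  pseudo-counts are rounded to the nearest integer for enumeration.
* **BH FDR** is the usual step-up, and a gene is significant when FDR ≤
  0.01 and 2^|log₂FC| ≥ 2, with log₂FC the difference of prior-damped
  group-mean log-CPMs (mildly shrunk toward zero at low counts; the
  conservative reading of a fold-change threshold). DEG sets per contrast
  are reported with their union and 3-set Venn partition.
* **Enrichment**: upper-tail hypergeometric per annotation term, DEG set
  against a gene universe.

Holobiont-level and host-level analyses are the same operations applied to
different input subsets.

## Clade typing

Marker hits are retained at e-value < 10⁻¹⁰ and alignment covering ≥ 50% of
the reference length. Distances between aligned sequences use the
Jukes–Cantor model, d = −(3/4)·ln(1 − 4p/3), excluding columns where either
sequence has a gap or ambiguity; p ≥ 0.75 is reported as saturation.
Neighbor joining is the Saitou–Nei algorithm (Q-criterion, standard branch
length formulas, deterministic tie-breaking); negative branch-length
estimates are clamped to zero with the deficit moved to the sibling so path
lengths are preserved, and additive matrices are recovered exactly (the
tests verify 10⁻⁹ agreement on random additive matrices, and topology
against an independent NJ implementation). Queries take the clade of their
nearest reference leaf by patristic distance; exact ties are left
unassigned. Colony composition weights each assigned transcript by its
FPKM; the dominant clade requires a proportion ≥ 0.8 (configurable),
otherwise the colony is called "mixed". The three markers are analyzed
independently and reconciled by majority (≥ 2 of 3 agreeing), since a
disagreement-reconciliation rule is not standardized. Clade-vs-status
association uses Pearson's chi-square without continuity correction (1 df).

## Synthetic data

The generator emulates the statistical structure the pipeline depends on,
with full truth labels, one RNG stream per artifact spawned from the master
seed (byte-identical outputs for identical configurations):

* **Transcripts**: per-sequence target GC ~ Normal(mean, sd) truncated to
  [0.2, 0.8] — defaults 0.42/0.53 with SD 0.03 for host/symbiont, matching
  the two GC peaks that host and symbiont transcripts form in real
  holobiont assemblies; lengths log-normal (median ≈ 1.5 kb). Each sequence
  is a random permutation of an exact-composition base multiset, so its
  realized GC equals the drawn target (i.i.d. base draws would add binomial
  noise and inflate the realized SD by ≈10%, breaking the intended
  per-taxon distribution). 90% of transcripts carry a planted complete ORF
  (ATG, ≥100 stop-free codons, stop) inserted by composition-preserving
  swaps; the remaining 10% exercise the ORF filter's negative path (long
  chance ORFs can still occur in them, as in real data).
* **Evidence**: each transcript is annotated with probability equal to the
  sensitivity (default 0.10, the annotatable fraction typical of non-model
  holobiont assemblies), split between homology and RBH rows, with a
  configurable wrong-taxon error rate (default 0) and e-values below the
  retrieval threshold.
* **Counts**: gene baseline abundances log-normal and shared across
  groups; a fraction (default 0.1) of genes gets its mean multiplied by
  the fold-change (default 4) or its inverse in one target tissue group,
  making it differentially expressed in the two contrasts involving that
  group; counts NB via gamma-Poisson with common φ (default 0.1); library
  sizes log-normal around 10⁶ with 20% CV. Defaults use three groups of
  six samples (healthy / GA-affected / GA-unaffected), with affected and
  unaffected samples paired by colony. Group means are deliberately not
  renormalized after planting (balanced up/down directions keep the
  compositional disturbance negligible), so "no planted effect" really
  means equal group means.
* **Markers**: per marker gene, a random ancestor evolves to per-clade
  references by JC substitution (branch length = clade divergence, default
  0.3 substitutions/site); colony transcripts evolve from their clade's
  reference at a small within-clade divergence (default 0.01 — a free
  choice, as real within-colony marker heterogeneity is not well
  characterized). Substitution-only evolution keeps sequences aligned by
  construction. The default colony panel mirrors a small reef population:
  six clade-C colonies, five clade-D, one 50/50 mixed (exact
  largest-remainder allocation so the mixed colony is genuinely balanced).

What the generator does **not** emulate: chimeric or fragmented assembly
artifacts, indels and alignment error in markers, codon structure or
realistic coding statistics beyond the planted ORF, correlated annotation
errors, batch effects, or gene-specific (tagwise) dispersion. Passing the
recovery tests therefore demonstrates that the implementations are correct
under their stated models — not that the pipeline is robust to every
artifact of real sequencing data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which the statistical recovery targets are stable:
20,000 transcripts for partition recovery; 10,000 genes × 12 samples for
null calibration of the exact test; 2,000 genes for DGE power/FDR and
dispersion recovery; 1,000 random additive matrices (≤ 8 taxa) for NJ;
the full-pipeline determinism check uses 2,400 transcripts and 600 genes.
Tolerances: exact-test vs enumeration 10⁻¹⁰; NJ patristic recovery 10⁻⁹;
MDS distance reconstruction 10⁻⁸; TMM vs the R reference 10⁻⁶ (their
pseudo-count adjustment differs slightly from plain scaling). The
dispersion search runs on log₁₀φ ∈ [−6, 0.7]; estimates at the lower
boundary are reported as the boundary value (effectively Poisson).
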