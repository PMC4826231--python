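# Methods

This note documents the models behind each stage of `um_landscape`, the
parameters that matter, the synthetic data used to exercise them, and the
design choices made where the underlying procedures left room.

## Somatic SNV/indel filtering

The rule engine applies a conservative post-calling filter to paired
tumor/normal candidates.  Eight rules are evaluated for every candidate —
never short-circuited — so the rejection reason list is always complete:

| rule | condition for rejection | default |
|---|---|---|
| `dbsnp_not_cosmic` | known population variant not rescued by a somatic database entry | — |
| `normal_contamination` | any variant read in the normal | `normal_alt_max = 0` |
| `normal_low_depth` | reference reads in the normal below minimum | `normal_ref_min = 8` |
| `low_pl` | Phred-scaled wild-type genotype likelihood in the tumor too small | `pl_min = 60` |
| `low_alt_support` | too few tumor variant reads | `tumor_alt_min = 4` |
| `low_clr` | constrained log-likelihood ratio (somatic vs non-somatic) too small | `clr_min = 40` |
| `quality_warning` | caller flagged duplication region, tri-allelic site, or read-tail variants | — |
| `repeat_context` | site inside a short-motif repeat run | — |

Choices worth noting:

- "No variant reads in the normal" is enforced exactly (`normal_alt_reads
  == 0`); there is no tolerance.
- The ≥ 8-read requirement is applied to the normal's *reference* reads
  specifically, not its total depth.
- The repeat-context rule mechanizes what is otherwise a manual curation
  step: a site is flagged when a 1–3 bp motif repeats ≥ 4 consecutive times
  within ±20 bp of it in the reference.  This is a reproducible proxy, not a
  re-implementation of human judgment.
- Quality warnings and the CLR score are consumed as caller-provided
  inputs; the package does not recompute them from reads.
- Indels and SNVs pass through the same rule set.
- Coordinates are 1-based inclusive internally (VCF convention); BED masks
  are converted at the reader boundary only.

## Mutational-signature refitting

A sample's catalogue *M* is the vector of mutation counts over the 96
single-base-substitution classes in trinucleotide context
(pyrimidine-centered; purine-reference SNVs are reverse-complemented).
Exposures *E* ≥ 0 solve

    min_E || M − P E ||²  /  96,

with *P* a fixed 96 × K matrix whose columns are signature probability
distributions.  The objective is taken over raw counts, not proportions,
because exposures are interpreted as mutation counts attributed to each
signature.  The solver is active-set NNLS, whose solution is deterministic;
when two signature columns have cosine similarity above 0.95 a collinearity
warning is emitted because the split between them is poorly identified.
Refitting against a fixed catalogue is the appropriate regime for small
cohorts, where de novo signature extraction is under-powered.

Confidence intervals are a parametric Poisson resample: each bin count is
replaced by a draw from Poisson(observed count), exposures are refit, and
the 5th–95th percentiles over 1,000 replicates (default) form the interval.
Empirically these intervals cover true exposures at close to their nominal
90% rate on simulated catalogues of a few hundred mutations (the test suite
measures this over 200 simulations).

Samples with fewer than 10 total mutations are fitted but flagged
low-confidence.  No exome-versus-genome context-opportunity normalization
is applied; exposures from mixed capture designs are therefore not directly
comparable across designs — a known limitation.

## Copy-number / allelic-imbalance segmentation

Per-locus inputs are tumor and normal coverage plus, at germline
heterozygous loci (defined upstream by a genotype-likelihood cutoff PL ≥
90), the tumor variant-read fraction (BAF).  The segment model is:

- Gaussian log-likelihood on the per-locus log2 tumor/normal coverage
  ratio, with a shared per-chromosome noise scale σ estimated robustly from
  the median absolute successive difference (σ = 1.4826 · MAD / √2, floored
  at 10⁻³).  A 0.5 pseudo-count guards isolated zero-coverage loci.
- Binomial log-likelihood on variant reads at het loci with a segment-level
  allele fraction (MLE = pooled variant / pooled total reads).

Segmentation is top-down recursive bisection — a variant of circular binary
segmentation in which each region is scanned exhaustively for its best
single breakpoint.  Both likelihood terms reduce to prefix sums, so each
candidate split costs O(1) and a chromosome costs O(n log n) in the typical
case.  A split is accepted only if

1. the joint log-likelihood ratio of split vs unsplit exceeds `llr_min`
   (default 90, natural-log units), and
2. the two children differ: copy-number ratio max/min > `ratio_min`
   (default 1.1, orientation-free) **or** minor-allele-frequency difference
   > `maf_diff_min` (default 0.05).

A minimum segment width of 10 loci avoids degenerate splits.  All four
gates are configurable.

Allelic imbalance per segment is a two-sided exact binomial test of pooled
variant reads against 0.5; segments with p < 0.001 are flagged imbalanced.
Pooling across loci is only informative when the variant allele is
consistently phased within a segment (see the generator notes below); with
unphased real data the variant allele switches haplotype from locus to
locus, and the pooled statistic would have to be replaced by per-locus
folding, whose null expectation is below 0.5 and depth-dependent.  The
phased-pool formulation keeps the test exact and unbiased under the null.

Copy numbers are placed on an absolute per-sample scale by one
multiplicative factor chosen so the segment-length-weighted 20th percentile
of copy number across allelically *balanced* segments equals 2.  The
weighted percentile is inf{x : weighted CDF(x) ≥ 0.2}, so the postcondition
holds exactly (to 1e-9 in tests).  When no balanced segment exists — e.g. a
near-tetraploid genome where nearly every segment is imbalanced or shifted —
normalization refuses to guess and requires a manual ploidy factor.

Labels, with δ = 0.3 copies and an LOH bound of MAF < 0.05 (both
configurable): `loss` (cn < 2 − δ), `gain` (cn > 2 + δ), `cn_loh`
(near-diploid, imbalanced, MAF below the LOH bound), `imbalance_only`
(near-diploid, imbalanced, MAF above it), else `neutral`.  An arm-level call
is made when segments sharing one non-neutral label cover ≥ 80% of the arm.
Note that at tumor purity π a true copy-neutral LOH segment has observed
MAF (1 − π)/2, so it is labeled `cn_loh` only for π ≳ 0.9 and
`imbalance_only` below that; reported copy numbers are likewise not
purity-corrected.

## Duplication timing

For mutations on a gained arm, variant reads v at depth d follow the
mixture

    L(v, d) = ρ [ ½ B(v; d, tc/cn) + ½ B(v; d, tc(1 − 1/cn)) ]
              + (1 − ρ) B(v; d, tc/cn),

with ρ the fraction of mutations predating the gain, tc the tumor content
and cn ≥ 3 the arm copy number.  Mutations arising after the gain sit on a
single copy (mean VAF tc/cn); of those predating it, half sit on the
un-duplicated haplotype (same mean) and half were duplicated (mean
tc(1 − 1/cn)).  The ½/½ split is fixed, not estimated.  cn = 2 is rejected
because the two component means coincide and ρ is unidentifiable.

The component means are the simple forms tc/cn and tc(1 − 1/cn).  A fully
purity-adjusted parameterization, tc·k/(tc·cn + 2(1 − tc)) for k mutated
copies, is available behind `purity_adjusted=True` (off by default); with
the default form, tc is best read as an effective scale parameter rather
than a literal purity.

Estimation maximizes the likelihood over a dense (ρ, tc) grid (step 0.01)
refined by Nelder-Mead, with cn enumerated over a candidate set (default
{3, 4}) — three parameters and a cheap likelihood favor robustness over
elegance.  At 500 mutations and depth 60 the refinement stage typically
improves on the raw 0.01 grid by under ~0.3 log-units; the likelihood is
curved enough in tc that this residual grid error is real, which is why the
continuous refinement exists.  Estimates are invariant to observation order,
and below 20 observations a warning is issued.  tc is fitted per arm, not
shared across chromosomes.

The VAF density plot uses a per-mutation-likelihood smoother: density(f) ∝
Σᵢ B(vᵢ; dᵢ, f) on a grid, normalized to integrate to 1 by the trapezoid
rule.  Unlike a VAF histogram this weights each mutation by its read-depth
uncertainty; a late gain shows up as clear bimodality around the two
component means.

## Structural-variant filtering and annotation

Candidate junctions (from any discordant-pair/clipped-read detector) pass
only if **all** of: ≥ 3 junction reads; mean junction-read mismatches ≤ 2;
no end with coverage > 1000× in tumor or normal; normal coverage ≥ 2× at
both ends; neither end in a segmental-duplication region; 20 bp flank
similarity < 90% (the 90% boundary itself is rejected); no matching
breakpoint in another sample (both ends within 100 bp with identical
orientations — 100 bp reflects clipped-read precision; the cohort snapshot
is fixed, making re-runs idempotent); and ≤ 3 bp inserted at the junction.
Flank similarity is consumed as a field, with a helper computing
(20 − edit distance)/20 when sequence is available.

Classes follow chromosomes and breakend orientations: interchromosomal when
the ends differ; otherwise, with ends position-sorted, (+,−) is
deletion-type, (−,+) tandem-duplication-type and (+,+)/(−,−)
inversion-type.  Intrachromosomal translocation-like events are not
distinguished from tandem duplications.

Gene effects use minimal transcript models (exons plus a CDS span).  A
junction fusing the 5′ coding portion of one gene (which portion is 5′
follows from breakend orientation and gene strand) to the 3′ coding portion
of another is a fusion, in frame when the cumulative CDS lengths upstream of
the two junction points agree mod 3.  Fusions involving a transcript without
CDS annotation are labeled truncations.  A deletion confined to one intron
is an intronic deletion; any other genic hit truncates; otherwise
intergenic.  Genes hit by two or more distinct events are reported as
recurrent.

## Driver recurrence and mutual exclusivity

The driver table is a sample-by-gene grid of protein-change strings over
BAP1, EIF1AX, GNA11, GNAQ, PLCB4 and SF3B1; the package ships the
28-sample UM cohort table.  Protein changes are compared verbatim except
that splice annotations are unified case-insensitively.  Hotspots are
identical (gene, change) pairs in ≥ 2 samples; a change query ending at the
codon (e.g. "p.Q209") matches any substitution at that codon.

Mutual exclusivity of a gene set is the number of samples mutated in ≥ 2 of
its genes, with a permutation p-value added by this package (the original
analysis reported the pattern without a statistic): each gene's carriers
are reassigned uniformly at random without replacement, preserving per-gene
counts, and p = (1 + #{permutations with overlap ≤ observed}) / (N + 1).
Small p means fewer co-mutated samples than independence predicts.  Output
labels the statistic as repository-defined.

## Synthetic data

Every generator is a pure function of (parameters, seed) and emulates the
statistical structure its analysis stage assumes:

- **Signature catalogues**: bin counts ~ Poisson((P·E)ⱼ); optional
  realization as concrete SNVs on a uniform-composition synthetic contig,
  so context counting can be exercised end to end.  Uniform base
  composition means context opportunities are approximately uniform, unlike
  a real genome.
- **Timing observations**: pre/post-gain status Bernoulli(ρ), duplication
  Bernoulli(½) among pre-gain mutations, depth Poisson(mean, default 60)
  truncated at 10 to avoid degenerate binomials, variant reads binomial at
  the component mean.  Defaults (depth 60, tc 0.8, cn 3, n of a few
  hundred) match a WGS-scale gained-arm analysis.
- **Coverage/BAF profiles**: tumor coverage Poisson around depth ×
  (purity-blended copy number)/2; normal coverage Poisson(depth); het-locus
  variant reads binomial around the purity-blended minor-allele fraction,
  with the variant allele phased onto the same haplotype throughout a
  segment.  Real unphased data violates that phasing assumption — passing
  closed-loop tests therefore demonstrates correctness of the segmentation
  and testing machinery, not robustness to unphased BAF.
- **SV candidates**: each candidate violates exactly its planned rule class
  (or none), with matching twins planted in a second sample for the
  multi-sample rule.
- **Driver tables**: per-gene Bernoulli carriers at configurable
  frequencies (defaults near the UM cohort's), with at most one
  Gα<sub>q</sub>-pathway mutation per sample when exclusivity is requested.

What the generators do **not** model: sequencing error, mapping artifacts,
GC bias, subclonality, germline contamination of the tumor, or read-level
data of any kind.

## Pipeline, problem sizes and reproducibility

`run_pipeline` wires the stages in dependency order over a synthetic
cohort (default 6 samples, 120 somatic candidates per sample, 400-mutation
signature catalogues, 1,200-locus chromosome profiles, 300 timing
observations, 14 SV candidates per sample) and writes TSV/JSON artifacts
per stage plus a run log recording version, seed and thresholds.  These
sizes keep a full cohort run near one second while leaving each stage
comfortably inside its detection envelope — e.g. a 1.4× coverage-ratio step
needs on the order of 200 loci per flank to clear the LLR-90 gate, and
ρ-recovery to ±0.05 needs a few hundred mutations at depth 60.  Plots are
optional artifacts; every figure has a TSV twin, and tests assert on
tables.  For a fixed configuration (seed included) re-runs are
byte-identical; per-sample seeds are spawned from the master seed, so
results do not depend on stage order or sample count elsewhere in the run.

## Known limitations

- Exposures are reported unthresholded; no sparsity or model selection is
  applied before calling a signature present.
- Copy numbers and MAFs are not purity-corrected; cn-LOH labeling degrades
  below ~90% purity (see above).
- The allelic-imbalance test assumes within-segment phasing of the variant
  allele.
- Whole-genome-doubled samples need a manual ploidy factor.
- Timing assumes a single gain event per arm and no subclonal structure.
- Fusion frame arithmetic uses a single transcript per gene and the coding
  frame at the last base before the junction; splice-mediated frame rescue
  is not modeled.
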