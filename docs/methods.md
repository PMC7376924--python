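# Methods

## The pangenome graph

Input is one Prokka-dialect GFF3 per genome (CDS features plus an embedded
`##FASTA` contig section). Coordinates are 1-based inclusive on disk and
0-based half-open in memory; conversion happens only at the I/O boundary.
Minus-strand genes are reverse complemented at parse time so `dna_seq` is
always the coding strand. CDS whose length is not a multiple of three are
kept and flagged `pseudo`; CDS truncated at contig edges are kept and
flagged `partial` — the correction stages, not the parser, decide their
fate.

Genes are clustered by greedy incremental star clustering on protein
sequences at 98% identity: sequences are processed longest-first (ties
broken lexicographically by gene id, so clustering is deterministic), and
each joins the earliest-founded cluster whose representative it matches at
or above the threshold. A k-mer prefilter (word size 5 for protein, 10 for
DNA) and a length guard (length difference above `(1 - identity) + 0.05`
skips the comparison) mirror the screening of standard greedy clusterers;
the final alignment check carries the correctness contract, which is the
*star property*: every member aligns to its representative at >= the
threshold. Identities are edit-distance based (edlib), with
`identity = 1 - d/alignment_length` for global alignments.

Clusters with at most one gene per genome become single graph nodes;
paralogous clusters are split into one node per gene occurrence and
collapsed back to the maximum per-genome copy number. Occurrences are
grouped by syntenic context: the Jaccard overlap of neighbour-family sets
at graph distance 1, extended to distance 3 on ties, then larger target
support, then node id. The graph itself is always derived from the gene
table (node membership plus per-contig gene order), so edges, supports and
per-genome paths stay mutually consistent through every mutation.

## Correction stages

Stages run in a fixed order: stub trimming, contamination removal,
mistranslation merging, family collapsing, missing-gene refinding. The
rationale for the order is that deletions should precede merges (so
artefact nodes cannot absorb real ones) and refinding should run last, when
node membership is final.

* **Stub trimming.** Nodes of degree <= 1 with support below the trailing
  threshold are removed, for at most `trailing_recursion_depth` (default 2)
  rounds — unbounded recursion could eat genuine rare operons. The
  threshold defaults to `max(2, ceil(0.05 n))` in strict mode and 2 in
  moderate mode; the strict form scales with collection size because
  absolute support loses meaning as n grows.
* **Contamination.** Connected components whose nodes *all* fall below the
  threshold are dissolved by the same recursive degree-<=1 deletion run to
  fixpoint. Restricting to uniformly low-support components is what
  preserves rare genes embedded in the supported graph.
* **Mistranslation merging.** Node pairs within graph distance 3 are
  compared at the DNA level with *infix* alignment (the shorter
  representative searched within the longer). Infix rather than global
  semantics is essential: a frame-shift half aligns to its full-length
  family at ~100% identity over the aligned region but only ~50% global
  identity. Thresholds default to coverage 0.95 and identity 0.99. The
  lower-support node is absorbed (ties: longer representative, then node
  id); a genome left with several members has contig-adjacent copies
  concatenated into one logical gene whose id joins the fragment ids with
  `+`, preserving the audit trail.
* **Family collapsing.** Node pairs sharing a graph neighbour whose protein
  representatives align at >= 70% global identity are merged and flagged
  `diverse_family`; iterated to fixpoint. The shared-neighbour requirement
  is what distinguishes an oversplit family (same syntenic context) from
  genuinely distinct paralogous families.
* **Refinding.** For each (node, genome) absence where a graph neighbour is
  present in the genome, the contig window of +-5000 bp around the
  neighbouring gene is scanned with edit-distance infix alignment, both
  strands, at identity >= 0.99 and coverage >= 0.80 of the query. Up to six
  member alleles are tried as queries (representative first): a single
  representative can be >1% diverged from the target genome while some
  member allele is nearly identical, and using the allele population keeps
  the identity threshold strict without losing genuine hits. Hits become
  `refound` members — they enter the matrix and the graph paths but never
  alter annotations on disk. Windows truncated at contig edges are searched
  as-is and the truncation is logged.

Sensitive mode disables both deletion stages entirely; the removal log of a
sensitive run is empty by construction and this is asserted in the tests.
Polishing is idempotent: a second run changes nothing, which the tests
check on the full pipeline output.

## Structural variants

Every genome path is summarised as its consecutive node triplets, with
orientation canonicalised so (a,b,c) equals (c,b,a); the matrix is
therefore invariant to reverse-complementing whole contigs. By default only
triplets whose centre node has population graph degree > 2 are emitted —
where every genome takes the same path the triplet carries no association
signal — and `--all-triplets` lifts the filter, since whether constant
triplets are useful depends on the downstream tool. Contigs with fewer than
three genes contribute nothing, and no partial (pair) variants are called
at contig ends.

## Gain/loss models

**FMG.** Each gene slot evolves independently along the dated tree as a
two-state chain with gain rate `a` and loss rate `v` (per unit branch
time). Column likelihoods use the Felsenstein pruning recursion with the
closed-form 2x2 transition matrices and the stationary root prior
`(v/(a+v), a/(a+v))`, which makes the likelihood time-reversible. Because
all-absent columns are unobservable, each column likelihood is conditioned
on at least one presence; the conditional likelihood identifies the rates
without knowing the slot count M, which is reported as 1.5x the observed
pangenome by default or profiled on a grid (joint likelihood including the
`M - G` unobserved slots and the binomial assignment term) on request.
Optimisation is L-BFGS-B on log rates from five fixed starting points
scaled by the tree height, so fits are deterministic; estimates at the
parameter bounds are flagged non-converged. Pattern columns are collapsed
to unique patterns before likelihood evaluation.

**IMG.** Genes arise at rate theta per unit branch length, each founding a
new family, and are lost at per-gene rate rho. On a fixed tree the expected
gene frequency spectrum (number of genes in exactly k of n genomes) has a
closed-form subtree recursion: f_v(k) is the probability a gene present at
node v survives in exactly k descendant leaves, combined up the tree by
convolution; gains on a branch of length L contribute with effective weight
`(1 - exp(-rho L))/rho`. Observed spectrum counts are independent Poisson
draws around the expectation (a property of the infinitely-many-genes
assumption), giving an exact likelihood. Two sizes enter the intensity
linearly — theta and the ancestral root pool G0 — and are profiled by
multiplicative fixed-point updates at each rho; rho is optimised on a
deterministic log grid refined by bounded search. G0 is profiled rather
than pinned to the stationary theta/rho because a stationary pool forces
complementary-clade loss mass into the spectrum and misfits lineages whose
ancestor carried few accessory genes (the loss-rate -> 0 limit breaks
entirely under the stationary assumption). The k = n class is excluded from
the fit: persistent core genes are not part of the gain/loss process. The
reported effective pangenome size is the observed core count plus the
equilibrium accessory pool theta/rho.

**Coincident genes.** Pairwise mutual information between presence columns,
with 0.5 pseudo-counts on the 2x2 cells and genome weights proportional to
the inverse neighbourhood size at Hamming fraction < 0.1 (damping clonal
oversampling). The outlier threshold is the upper Tukey fence of the MI
distribution; triangles among outlying pairs are pruned ARACNE-style
(weakest edge dropped); the sign comes from the odds direction of the 2x2
table. Constant columns are excluded with a log line.

## The simulator

The generator emulates the standard simulation design for pangenome
benchmarking, recast at the annotation level (no read simulation or
assembly — the downstream pipeline sees the same error classes either way):

* a Kingman-coalescent genealogy (ultrametric, coalescent time units);
* gene content along the branches: a fixed persistent core (default 200
  families) plus accessory gain at rate 20 and per-gene loss at rate 0.5
  per unit time — with 20 genomes this yields roughly 100 observed
  accessory families, the regime the validation scenarios specify; the
  root's accessory pool is Poisson(gain/loss);
* sequences: random codon sequences per family (length ~ N(900, 150^2) bp,
  min 300), evolving by per-site substitutions at rate 0.001 per unit time
  — within-family divergence well inside the 98% clustering threshold,
  between-family identity at random-sequence levels;
* layout: every family gets a position on a circular gene order shared
  across genomes (synteny); accessory families insert between the first
  and last core genes; each genome's chromosome is the families it carries
  in that order with 50-200 bp random spacers, linearised at a shared
  origin just before the first core gene — mimicking complete assemblies
  rotated to a fixed origin gene, so chromosome ends are core genes rather
  than artificial rare-gene stubs;
* optional duplicated families: a second syntenic slot carried by a
  configurable fraction of genomes (paralog scenarios).

Error injection applies assembly-level errors first, then annotation-level
ones, matching the physical process: fragmentation (cuts at random
intergenic points with probability 0.8, else intragenic; severed pieces >=
150 bp survive as `partial` CDS, smaller pieces lose their annotation),
contamination (Poisson-many 10-kb contigs per genome carrying genes from a
disjoint synthetic contaminant namespace; segments are unique per
insertion, standing in for random windows of a large foreign genome),
annotation dropout (annotation deleted, DNA intact), and frame-shift
splitting (one CDS becomes two adjacent features). Every event is recorded
in the truth object, and genes untouched by any event are byte-identical
before and after.

What the simulator does *not* emulate: real assembly-graph artefacts, read
error profiles, horizontal transfer of homologous (rather than novel)
genes, rearrangement of gene order between genomes, and recurring
contamination from a single foreign species (each contaminant segment is
unique, so contaminant support is always 1). Passing the recovery tests
therefore demonstrates correct behaviour of the graph algorithms under the
modelled error classes, not performance on real assemblies with correlated
errors.

## Problem sizes and determinism

The validation scenarios use 20 genomes x (200 core + ~100 accessory)
families — large enough that every error class appears dozens to hundreds
of times per run while a full pipeline run stays in the tens of seconds —
and the rate-recovery studies use 50-leaf trees with 500 columns (FMG) and
20 clades of 30 leaves (IMG). All randomness flows from a single integer
seed through `numpy` generators (the coalescent sampler receives a derived
seed), and simulator output is byte-identical across runs with the same
seed; graph construction and polishing are fully deterministic, with every
tie broken by an explicit rule (length, support, then lexicographic id).

## Known limitations

* Greedy star clustering guarantees the star property, not a globally
  optimal partition; the threshold-refinement property is verified on
  simulator data, where families are well separated, and can fail on
  adversarial inputs.
* Refinding searches only windows around direct graph neighbours; a gene
  whose DNA lands on an otherwise unannotated contig (or whose family has
  no surviving cluster) cannot be recovered.
* The contamination filter keys on support and connectivity; a contaminant
  shared by enough genomes to exceed the support threshold would survive
  in moderate mode (real recurring contamination is better caught by the
  input QC screen).
* The annotation-conflict audit normalises product strings (lowercase,
  trailing copy-number suffixes stripped) and cannot see through synonyms.
* The QC outlier screen floors the MAD at one count so clonal collections
  (MAD = 0) keep a non-degenerate fence.
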