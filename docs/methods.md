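# Methods

This note records the models, conventions, and numerical choices behind
each `rgenescape` stage, the scope of the synthetic genome generator, and
the known limitations.  All coordinates are 0-based, half-open
internally; GFF3 and VCF files are converted at the I/O boundary.

## Repeat landmarks

**Telomeres.** Terminal tandem arrays of the plant telomere unit
TTTAGGG are detected by regular-expression scanning for maximal tandem
runs: the forward unit near the 3′ terminus and its reverse complement
(CCCTAAA) near the 5′ terminus, each within a 50-kb terminal window.  An
array is reported when it holds ≥10 unit copies.  The motif is a
parameter, so variant conventions for writing the 5′ unit can be supplied
directly.

**Centromeres.** Arrays of the 107-nt grape centromeric monomer are
found by alignment rather than exact matching, since monomer copies
diverge.  A banded semi-global alignment (edlib, infix mode) anchors the
best monomer copy in the sequence; the array is then extended copy by
copy in both directions with prefix-mode alignments, accepting each copy
whose percent identity — alignment columns minus edit distance, over
columns — meets the threshold (default 80%).  An array needs ≥10
accepted copies.  Per-copy identities give the array's mean identity;
indel slack of about 10% of the monomer length per copy is tolerated by
the banded search.

## R-gene classification

A gene is an R-gene candidate when its domain-hit set (from any external
domain scanner, read as a TSV with e-values) contains NB-ARC at the
e-value cutoff (default 1e-5).  The category follows the architecture:
N-terminal TIR, CC, or RPW8 plus optional LRR yield the eight classes
NB, NL, TN, TNL, CN, CNL, RN, RNL ("NBS" is accepted as an alias of NB).
If several N-terminal domains co-occur, precedence TIR > RPW8 > CC
applies and the call is flagged ambiguous.

Protein-composition features support a coherence check of the
categories: DPC (dipeptide composition), CKSAAP(k) (400 amino-acid pairs
separated by k positions, normalised by L−k−1; DPC ≡ CKSAAP(0)), and
KSCTriad(k) (343 triads over the seven conjoint residue classes at
spacing k+1).  Non-canonical residues are dropped before counting.  The
concatenated feature matrix is embedded in 2-D by PCA and category
separation is summarised by the silhouette score; the check requires at
least two categories with ≥3 members each.

## TE enrichment around R genes

Each gene's window is [start − 50 kb, end + 50 kb) clipped to the
chromosome.  The TE proportion of a window is the bp fraction covered by
the union of overlapping TE intervals, per TE class and in total, so
nested or overlapping annotations are never double-counted.  The
background is built by resampling, 100 times, a set of non-R genes equal
in size to the R set (a fixed fraction of all genes can be requested
instead) and profiling their windows the same way.  Enrichment per class
is a two-sided Welch t-test of per-gene R fractions against the pooled
per-gene background fractions.  Stability is assessed by a delete-one
jackknife over R genes: the result is flagged stable when the full test
and every leave-one-out re-test are significant at α = 0.05.  When both
samples are constant the test is declared degenerate with p = 1.
Intact-LTR coverage runs through the same machinery, and for each intact
element the 5′/3′ LTR identity is computed by global alignment
(identity = columns − edit distance over columns); higher identity means
a more recent insertion.

## SV merging, zygosity, and hemizygous genes

Per-haplotype SV calls (DEL, INS, INV read from VCF; other types are
tallied and skipped) are merged by single-linkage clustering of a
compatibility relation: same chromosome and type, position difference
≤1 kb, and length difference ≤25% of the larger length.  Merged position
and length are medians over supporting calls.  An SV supported by one
haplotype of the pair is heterozygous; by both, homozygous.  A
`min_support` filter can drop weakly supported merges.

A gene is called hemizygous when the union of heterozygous SVs covers
strictly more than 10% of its coding (CDS-union) length.  An insertion's
reference footprint is the single base [pos, pos+1), so insertions
cannot trigger the rule.  Homozygous SVs are rejected by precondition;
genes without annotated CDS are skipped with a warning.  Promoters are
strand-aware 2-kb intervals upstream of the transcription start, clipped
at the chromosome edge.  The SV–ASE spatial relation is the Spearman
correlation between per-bin counts of heterozygous SVs and ASE genes
(default 500-kb bins over all chromosomes for fixture-sized genomes;
1-Mb is conventional at full genome scale), requiring ≥10 non-empty
bins.

## Allele-specific expression

Allele counts at heterozygous SNPs are summarised per gene (mean per-SNP
counts per haplotype; genes below a depth or SNP-count floor are
excluded with a reason).  The test is an exact binomial test of the
summed hap1 count against p = 0.5 on the gene's total, corrected across
genes by Benjamini–Hochberg.  A gene shows ASE when fold change between
allele means is ≥2 **and** FDR < 0.05; both conditions are required, so
deep coverage alone never produces a call.

## R-gene clusters

Homology between R proteins is a graph: an edge requires local alignment
(BLOSUM62, gap open −11, extend −1) with ≥40% identity and ≥50% coverage
of both sequences.  Within each connected component and chromosome,
genes are sorted by position and maximal runs spanning ≤1.0 Mb with ≥3
members are emitted greedily left to right; clusters never share
members.  For cross-assembly comparison, each cluster is projected
through a gene-level ortholog map: it is "shared" when ≥50% of its
members have orthologs inside a single cluster of the other assembly,
otherwise assembly-specific.  Ortholog maps naming unknown genes are
rejected.

## Synthetic genome generator

The generator emulates the *statistical* structure the pipeline measures
— densities, effect sizes, category composition, zygosity — not sequence
evolution.  Defaults define the study condition: 4 chromosomes of 2 Mb;
terminal telomere arrays of 20 units at 500 bp from each end; a central
centromere of 30 monomer copies at 5% per-copy substitution; 120
non-overlapping genes, 32 of them R genes (4 per category) on left
chromosome arms with non-R genes on right arms, so background windows
stay ≥2 flanks away from R windows; non-overlapping TE intervals
rejection-sampled to 0.6 coverage near R genes and 0.2 elsewhere; two
planted homolog families (one made assembly-specific by erasing its
homology in the second assembly, one shared); 40 heterozygous SVs (12
coding deletions covering ~23% of a target gene's coding span, 6
promoter deletions, the rest intergenic) plus 8 homozygous SVs including
one gene-covering deletion as a guaranteed hemizygosity negative; and
overdispersed allele counts (negative binomial depth, mean 60, 5
SNPs/gene) with 20 fold-4 effect genes preferring SV-bearing genes so
ASE colocalises with SVs.  All randomness flows from one seed; equal
seeds give byte-identical files, and planted truth is serialised to a
JSON sidecar.  Proteins are random strings (families are mutated copies
of a seed), reads are never simulated, and no claim is made about
biological sequence realism.

## Numerical choices

- Interval arithmetic uses sorted merge of half-open intervals; coverage
  fractions are exact rational counts over window length, computed in
  double precision.
- Alignments use edlib (edit distance, banded) for DNA and Biopython's
  PairwiseAligner (local, BLOSUM62) for proteins.
- Statistical tests come from scipy (Welch t, exact binomial, Spearman)
  and statsmodels (Benjamini–Hochberg); none are reimplemented.
- Degenerate inputs (zero-variance samples, constant feature matrices,
  too few bins or members) raise explicit errors or flagged p = 1
  results instead of propagating NaNs.

## Limitations

- The hemizygosity rule sees only SV–CDS overlap; it does not model
  partial-deletion transcripts or dosage.
- The enrichment test treats pooled background windows as independent
  samples; spatial autocorrelation between overlapping windows is not
  modelled (the jackknife flag is the guard against single-gene
  artefacts).
- ASE ignores mapping bias and SNP-level overdispersion beyond the
  per-gene summation.
- Cluster projection depends entirely on the supplied ortholog map; no
  synteny check is performed.
- The generator's planted effects are large by design so that recovery
  is a correctness check, not a power study; detection thresholds were
  fixed before the fixtures were evaluated.
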