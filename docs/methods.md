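# Methods

`nbsevolve` analyses the evolution of plant NBS (NLR) resistance genes at
desk scale: it classifies domain architectures, types homolog pairs,
assembles cross-species orthologous lineages, categorizes promoter
cis-elements, and runs a simplified expression/co-expression analysis.
Every stage is exercisable on synthetic multi-species fixtures with known
ground truth; this note records the models, the tunable parameters and the
design choices, and what the synthetic experiments do and do not show.

## Domain-architecture classification

A gene's architecture is the ordered string of its domain-class letters
along the protein: N (NB-ARC, Pfam PF00931), T (TIR, PF01582), C
(coiled-coil), L (LRR; the seven Pfam LRR repeat families PF00560,
PF07723, PF07725, PF12799, PF13306, PF08191, PF13855) and R (RPW8,
PF05659). The architecture string is the gene's type name (CNL, NL, CN,
TNC, ...). Genes with at least one N are NBS genes; those with both N and
L form the NBS-LRR subclass, the rest the non-NBS-LRR subclass. Genes
with recognizable domains but no NB-ARC are not NBS candidates and are
reported in a side table (they can still surface in homology results).

Coiled-coils are called from per-residue score tracks: maximal runs of at
least `min_len` = 8 residues (about one confident heptad) scoring ≥ 0.5
become C hits. The 0.5 threshold is the conventional deep-learning
coiled-coil cutoff; only the run-length floor is this package's choice.

Multiple hits of the same class are collapsed into one architecture letter
when their intervals overlap or lie within `gap_max` = 150 residues;
different classes never merge. The gap rule reconciles two facts: LRR
repeat hits arrive as clusters of short intervals that must read as a
single L, while genuinely repeated domains (NN, NNN, CNLCN types) must
keep separate letters. 150 aa sits between observed repeat-cluster gaps
(tens of residues) and inter-domain spacings (hundreds). Merged units are
ordered by interval midpoint, with ties broken by start coordinate and
then alphabetically, so output is deterministic. The merge is an interval
fixed point: merging already-merged units changes nothing, and it is
tested against a brute-force all-pairs oracle.

Domain-hit tables are filtered at E ≤ 1e-10 by default, matching the
similarity-search stage; the HMM search threshold is configurable since
"default parameters" pins down no number.

## Homolog typing and lineage assembly

Similarity-linked gene pairs are typed by a three-way rule: pairs from
different species supported by a collinear block are orthologs; pairs
within one species are homochromosomal or heterochromosomal duplications
according to whether the chromosomes match. Cross-species pairs without
collinearity support carry no relation and are excluded (no fallback is
defined for them). Raw similarity hits are reduced first: self hits
dropped, one best-bitscore hit per directed pair, and cross-species
candidates restricted to reciprocal best hits — an explicit, symmetric
rule imposed where the source procedure is ambiguous.

Ortholog pairs between adjacent species of an ordered species chain
(taken from the species tree's leaf order) are stitched into orthologous
lineages by connected components. A lineage is *complete* when every
chain species contributes a member and *type-conserved* when all members
share one architecture type; a component holding two genes of one species
is a conflict and raises. Census counts are distinct genes per relation
type (a gene participating in two relations counts once in each).

Chromosome lineages are derived, not declared: for each adjacent species
pair, each chromosome maps to the partner chromosome it pairs with most
often across collinear-block anchors (majority vote; ties broken by total
paired-gene count, then lexicographically), and a lineage's chromosome
label is its earliest member's chromosome mapped back to the first
species' coordinates.

## Promoter cis-elements

Elements found within 2,000 bp upstream of the translational start are
binned into three categories — hormone-related, stress-responsive, plant
growth — by a closed element-name map shipped as an editable TSV seeded
from the standard PlantCARE vocabulary (TCA-element → hormone/salicylic
acid, MBS → stress/drought, LTR → stress/low temperature, CAT-box →
growth/meristem, ...). Unmapped names fail loudly rather than defaulting.
Percentages are of the grand total of element *occurrences* (not
element–gene incidences), rounded half-up to one decimal, which is why a
category's function-level percentages sum to that category's share.

## Expression statistics

FPKM = counts × 10⁹ / (gene length in bp × library size), library size
being the column sum. Differential expression is a deliberate desk-scale
stand-in for a count-model tool: Welch's unequal-variance t-test on
log2(FPKM + 1), Benjamini–Hochberg adjustment, and the call rule
p_adj < 0.05 with fold change strictly > 1.5 (strictly < 1/1.5 for down).
Fold change is the ratio of mean treated to mean control FPKM with a 0.01
pseudo-count.

Co-expression modules follow the unsigned weighted-network recipe on
log2(FPKM + 1): adjacency a_ij = |cor(x_i, x_j)|^β with β = 6 (the
classic unsigned default), topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

average-linkage clustering of 1 − TOM, a *static* cut, and a minimum
module size of 30 (smaller clusters stay grey). Static cutting replaces
dynamic tree cut because it is deterministic and directly testable. The
default cut height is 0.9: within-module dissimilarities sit below ~0.5
while unrelated genes sit above ~0.97, and in small designs the null TOM
tail is fat enough that the near-1 cut heights customary for
20,000-gene datasets would sweep the background into one spurious module
(with 500 genes, per-sample FPKM normalization also shares library-size
sampling noise across all genes). A block-size cap is irrelevant at this
scale and ignored with a log message.

Module eigengenes are first principal components of the standardized
member matrix, unit norm, sign-oriented so their correlation with the
members' mean standardized profile is positive; note this orientation
necessarily flips if every member profile is flipped. Module–trait
association is the Pearson correlation of the eigengene with a
treated/control indicator.

## Synthetic data: what it emulates, and what it does not

The genome generator plants: per-species architecture counts (a preset
reproduces the published seven-species type table, 655 genes with the
focal species' 22 + 52 subclass split); orthologous lineages wired
through collinear blocks with non-NBS filler anchors so the chromosome
correspondence is discoverable; incomplete lineages (an end-of-chain
member deleted — deleting a middle member of a three-species chain would
disconnect the chain entirely); type-changed lineages; NB-ARC domain loss
(the gene's emitted hits lose their N, and the recorded truth type changes
accordingly); and same-/different-chromosome duplication pairs. Domain
intervals respect real scale (NB-ARC 150–300 aa, LRR repeats clustered
within the merge gap, inter-domain spacing above it), so the merge
defaults are genuinely exercised. Exon counts and gene lengths are drawn
jointly (length ≈ 1.5 kb + 2 kb × exons + noise) so the exon-count versus
gene-length correlation is a measurable ~0.95. Every output file has its
own random stream derived from the master seed; fixed seed means
byte-identical files. No sequence is emitted, only coordinates, hits and
scores — so nothing here tests alignment, HMM scoring or motif discovery
themselves, only everything downstream of them.

The expression generator draws negative-binomial counts around log-normal
baseline means, with a multiplicative treatment effect on planted
up-regulated genes and shared per-sample factors for planted module
blocks. Defaults emulate a 3 + 3 hormone-treatment design with baseline
means near 1,000 counts and dispersion 0.005 — shot-noise-dominated
variation, as between clonal plantlets under controlled conditions. This
is a deliberate and consequential choice: at field-typical biological
dispersions (0.05–0.2) a 3 + 3 Welch test recovers only a small fraction
of 4× effects, which is precisely why dedicated count models with shared
dispersion estimation exist. Passing recovery tests here therefore shows
the pipeline's logic is correct under low-noise conditions, not that a
Welch test is an adequate DEG caller for noisy field data.

Module-recovery simulations use a 10 + 10 design: with six samples,
correlation estimates among hundreds of genes are dominated by null
spread (sd ≈ 0.45) and no clustering method could be meaningfully
assessed. Planted blocks swing ~1.5-fold (loadings 1.2 on the treatment
contrast, 0.6 on a latent factor; within-block correlations ≈ 0.9 at
dispersion 0.02); stronger swings on 8 % of a 500-gene library would
distort per-sample library sizes and leak planted structure into every
other gene's FPKM. Trait ranking at the study's own 3 + 3 scale is
checked separately with eigengenes computed from planted memberships.

## Numerical choices and degenerate inputs

Coordinates are 1-based inclusive everywhere. Pearson correlations
require length ≥ 3 and non-zero variance and raise otherwise (no silent
NaN); p-values use the exact t-transform with n − 2 df. Genes constant
across samples raise in network construction and get p = 1 in DEG
calling. Zero library sizes, empty element sets and empty architectures
are errors, not defaults. Genes lacking exon features parse with
exon_count 1 plus a warning (single-exon genes are common in this
family). BH adjustment is the standard step-up, capped at 1, and is
order-invariant. Rounding of printed percentages is decimal half-up, not
banker's.

## Problem sizes

Default test and acceptance runs use: 655-gene seven-species fixtures for
classification; 38–66 planted lineages for homology; 500-gene expression
matrices; 20 simulation seeds for DEG calibration and module recovery;
1,000-case oracle sweeps for interval merging and correlation. A full
suite plus the acceptance script completes in well under a minute on one
CPU.

## Known limitations

- The DEG caller is a stand-in; its calibration statement is conditional
  on low dispersion (above).
- Ortholog detection requires collinearity evidence; lineages broken by
  block-level rearrangements are reported as incomplete or unplaced
  rather than rescued by similarity alone.
- The chromosome correspondence is a majority vote per species pair;
  genuine reciprocal translocations produce composite labels rather than
  a second correspondence.
- The cis-element category map is a closed vocabulary; real PlantCARE
  exports contain names that must be added to the map (the failure is
  loud by design).
- Static module cutting trades the adaptivity of dynamic tree cut for
  determinism; deeply nested module structure will be merged or greyed.
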