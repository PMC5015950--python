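# Methods

## Setting and model

`homeoscan` analyzes a nascent allotetraploid whose two subgenomes (the
reference-matching C^a and the non-reference E^a, in the coffee naming
this package uses throughout) diverged recently enough that the
polyploid still behaves as a mosaic of two nearly identical parental
genomes.  Mapped to one progenitor's reference, every fixed
interspecific difference shows up in the polyploid as a
heterozygous-like call — a *homeologous SNP* — because one subgenome
carries the reference allele and the other the alternate.  This gives a
sharp observational signature for each class of genomic change:

| event | DNA-seq vs reference | RNA-seq vs reference | copy number |
|---|---|---|---|
| both homeologs retained and expressed | heterozygous at interspecific positions | heterozygous | 4× |
| exchange/conversion toward C^a | no variant records | no records | 4× |
| exchange/conversion toward E^a | homozygous-alternate | homozygous-alternate | 4× |
| deletion of one homeolog | records lose heterozygosity | follows DNA | 2× (half depth) |
| silencing of one homeolog | heterozygous (DNA intact) | single homeolog's alleles | 4× |

A consequence used everywhere: **only heterozygous-like calls count as
homeologous SNPs**.  A homozygous-alternate record is a fixed difference
from the reference, not evidence of two distinct homeologs; treating it
as an SNP would make any change toward the non-reference subgenome
invisible to both the window scan and the per-gene loss rule, and would
contradict the observed attribution of most losses to the
reference-derived subgenome.  The diploid progenitor's own SNP table is
the opposite case: there, any non-reference call marks an interspecific
difference and counts toward SNP2X.

## Window scan for homeologous SNP deficit

Non-overlapping windows (default 10 kb) tile each chromosome.  A
position is *eligible* when its depth is ≥ 10 and ≤ 2× the genome-wide
mean over covered positions (the floor controls false SNP calls, the
ceiling removes collapsed repeats); a window enters the test only with
≥ 8000 eligible positions.  Each eligible window's SNP proportion is
tested against the genome-wide density p₀ (pooled over all eligible
positions of eligible windows) with the one-sample chi-square form of
the test of proportions with Yates continuity correction, one-sided
toward deficit — the form R's `prop.test(..., alternative="less")`
computes, which our unit tests pin to values frozen from R 4.3.3.
P-values are Benjamini–Hochberg adjusted over the eligible windows only;
ineligible windows are outside the multiple-testing universe and also
terminate runs.  Maximal runs of ≥ 5 consecutive windows with q < 0.01
become HSD regions, so 50 kb is the method's stated resolution floor.
"Highly significant" is operationalized as α = 0.01 on the adjusted
p-value; sidedness, correction and α are all exposed parameters since
only the test family is fixed by the design.

## Per-gene decision tree

For each single-copy gene, counts are taken at *common positions*: CDS
positions passing every depth cutoff of the datasets being compared.
Defaults: polyploid DNA ≥ 12 (both subgenomes must be sampled), polyploid
RNA ≥ 16 (homeolog expression bias can thin one allele's reads),
progenitor RNA ≥ 4.  The polyploid's RNA libraries are pooled read-wise
for the primary call: an allele is present at a position when any
library contributes a supporting read, and a library covering a position
without a variant record contributes reference reads (callers only emit
records where alternate reads exist).

* **Loss** — `SNP4X-D = 0` with `SNP2X ≥ 3`, or `SNP4X-D = 1` with
  `SNP2X ≥ 4` (the ≥ 4-fold drop with at most one residual homeologous
  SNP).  The floor of three SNPs bounds the resolution of any SNP-count
  comparison and absorbs both sequencing error and the fact that real
  progenitor accessions are not the exact parents.
* **Retained** — not loss and both `SNP2X, SNP4X-D ≥ 3`.  The design
  only fixes the loss side of the rule; "comparable counts" is
  operationalized this way, and intermediate patterns are
  `uninformative`.
* **Silenced** (among retained) — ≥ 3 DNA homeologous SNPs at
  RNA-covered common positions with zero RNA SNPs; one RNA SNP is
  tolerated when its position is not in the DNA SNP set (an RNA-only
  artifact, e.g. RNA editing or mapping noise, should not rescue
  expression).
* **Both expressed** — at least 50% of the RNA-covered DNA SNP positions
  recur among RNA SNPs (configurable; full concordance is the typical
  case, and the 50% midpoint separates it cleanly from the 0-or-1 SNP
  silencing pattern).  Genes between the silencing and concordance
  criteria stay `uninformative`.

### Deletion vs homogenization

Losses are split by gene read depth.  Because the vast majority of genes
keep four copies, the 4-copy expectation is estimated robustly from the
data itself: μ₄ = median of per-gene mean depths, σ = 1.4826 × MAD, and
the 99% band μ₄ ± z₀.₉₉₅σ.  The 2-copy band halves the center and
shrinks σ by √2 (depth sums over per-copy contributions, so variance
halves).  A loss gene inside only the 2-copy band is a `deletion`,
inside only the 4-copy band a `homogenization`, otherwise `unresolved`;
the model is flagged unusable (everything `unresolved`) when σ is
degenerate or the bands overlap.  Robust center/scale keeps the ≤ few
percent of true 2-copy genes from biasing the fit — the tests check a 5%
contamination moves μ₄ by < 2%.

### Subgenome attribution

At progenitor-differentiating positions inside the gene (the progenitor
catalog), the alleles the polyploid still carries — DNA alleles for loss
events, expressed RNA alleles for silencing — are matched against each
progenitor.  The event belongs to the subgenome of the progenitor with
the **smaller** shared count (its contribution is the one missing), with
a minimum difference of 3; smaller differences and ties are "ND".  A key
interpretive choice: positions where the polyploid simply matches the
reference produce no variant record but still count as sharing the
reference progenitor's allele — without this, a gene converted to the
reference subgenome would share nothing with anyone and the
smallest-shared rule would be meaningless.  Attribution is exactly
symmetric under relabeling the progenitors.

## GO enrichment

One two-sided Fisher's exact test per term annotated in the reference
group, which is the full set of analyzed genes used as given (test genes
included, so a test set equal to the reference yields p = 1 everywhere).
The two-sided p sums point hypergeometric probabilities ≤ that of the
observed table (the minimum-likelihood convention; the implementation is
scipy's, cross-checked in the tests against exhaustive enumeration over
every admissible table with total ≤ 30).  This convention, and not a
one-sided tail, reproduces the published example p-values to all seven
printed digits.  FDR is BH over the universe of tested terms — the
number of annotated terms, not the number of displayed rows; the
implementation takes the universe size m explicitly, and with m = 230
reproduces the published example FDR column to ~7 digits.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at the study's stated conditions by default: per-bp interspecific
divergence 0.013, DNA depth mean 40×, four polyploid RNA libraries plus
one diploid-progenitor library, 3-kb genes with 80% CDS in two exons
tiled without overlap.  Specifics and deliberate simplifications:

* Interspecific SNPs are Bernoulli per bp at rate `divergence` over the
  whole chromosome (genic and intergenic alike); alleles are random
  distinct bases.  Sequences themselves are not simulated — the analysis
  operates on positions and alleles — though a FASTA writer exists for
  format completeness.
* Depth is negative binomial (dispersion `dna_depth_dispersion`, default
  12) around the mean, multiplied by a per-gene gamma factor
  (CV 5% DNA, 20% RNA) standing in for mappability and expression
  variation; deleted genes halve the mean.  Pure Poisson would
  understate the spread the 2×/4× classifier must tolerate.
* At heterozygous positions the alternate read count is one binomial
  draw per position per library (fraction ½ for DNA; `homeolog_bias`
  for RNA).  Hom-ref draws produce no record, exactly like a caller.
* Event labels: `conversion_to_X` means donor X (the *other* subgenome
  is the lost one); `deletion_X`/`silenced_X` name the affected copy.
  Genes fully inside a homeologous-exchange tract are conversions to the
  tract's donor.  Event sets are disjoint by construction.
* The length distribution of exchange tracts is not fixed by the design;
  tract coordinates are free configuration.
* Not simulated: reads, sequencing error, indels, mapping artifacts,
  paralogy, tissue-specific expression.  Passing recovery tests
  therefore demonstrates correctness of the decision logic under the
  assumed observation model, not robustness to alignment pathology;
  on real data the depth cutoffs and SNP floors carry that burden.

Everything is a deterministic function of (config, seed); identical
seeds give byte-identical output files.

## Problem sizes used in validation

The recovery experiments run 20 independent seeds each: the HSD scan on
two 1-Mb chromosomes carrying 100/60/50-kb exchange tracts; the fate
analysis on 300 genes (two 0.6-Mb chromosomes) with 20 conversions, 12
deletions and 20 silencings; the null check on full two-accession
pipelines over event-free 2 × 300-kb genomes.  These sizes give ~1000
scored events and ~5000 retained genes per experiment, enough to resolve
the ≤ 1% false-call bounds the tests assert.  At these conditions the
package recovers all tract boundaries within one window and classifies
events with ≥ 98% accuracy; the acceptance script reports the exact
numbers for any seed.

## Known limitations

* The single-copy status of genes is an input (simulator flag or GFF
  attribute); deriving it from the data is out of scope.
* The diploid progenitor is represented by an RNA-derived SNP table, so
  SNP2X is only measurable where the progenitor gene is expressed.
* With two accessions observed from one simulated truth, all events are
  shared by construction; accession-specific events would need
  per-accession truths, which the arithmetic (but not the simulator)
  supports.
* Copy-number segmentation (GC-normalized CNA calling) is a separate
  concern handled by dedicated tools and is not reimplemented here.
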