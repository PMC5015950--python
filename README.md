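# homeoscan

Homeolog fate analysis for nascent allopolyploid genomes.

A young allotetraploid carries two complete parental chromosome sets
(subgenomes).  Mapped against one progenitor's reference genome, the
fixed differences between the subgenomes — homeologous SNPs — appear as
constitutive heterozygosity at a roughly constant density.  Departures
from that pattern are the footprints of early polyploid genome
evolution, and `homeoscan` detects and classifies them from standard
variant-calling output:

* **Homeologous SNP deficit (HSD) regions** — tracts where one
  subgenome's sequence has replaced the other's (homeologous crossover
  exchanges), found by a windowed SNP-density scan.
* **Homeolog loss** per gene — collapse of the within-polyploid SNP
  count relative to the between-progenitor count, split by read depth
  into physical **deletion** (2 remaining copies) versus **sequence
  homogenization / gene conversion** (still 4 copies).
* **Homeolog silencing** per gene — homeologous SNPs present in DNA-seq
  but absent from RNA-seq.
* **Subgenome attribution** — which parental subgenome lost its copy or
  its expression, by counting alleles shared with each diploid
  progenitor.
* **GO enrichment** — Fisher's exact over/under-representation of event
  gene sets with Benjamini–Hochberg FDR.

The package was built around the study design used for allotetraploid
coffee (*Coffea arabica*, subgenomes C^a and E^a from *C. canephora* and
*C. eugenioides*, ~1.3% CDS divergence): whole-genome DNA-seq of the
polyploid mapped to the *C. canephora* reference, RNA-seq of the
polyploid and of *C. eugenioides* mapped to a CDS reference, a GFF3 of
single-copy gene models, and per-position depth tracks.  A synthetic
allotetraploid generator with ground-truth event labels makes the whole
pipeline testable without any external data.

## The statistics at the core

For a 10-kb window with $n$ depth-eligible positions ($10 \le$ depth
$\le 2\times$ genome mean; at least 8000 such positions) and $x$
homeologous SNPs, the deficit test is the one-sample test of proportions
with continuity correction against the genome-wide density $p_0$,
one-sided ("less"); window p-values are BH-adjusted and runs of $\ge 5$
consecutive windows with $q < 0.01$ become HSD regions (so 50 kb is the
resolution floor).

Per gene, at CDS positions passing every depth cutoff (DNA $\ge 12$,
polyploid RNA $\ge 16$, progenitor RNA $\ge 4$), three counts are
compared: SNP2X (between the progenitors), SNP4X-D and SNP4X-R (within
the polyploid by DNA and RNA).  Loss requires a $\ge 4$-fold drop with
SNP4X-D $\le 1$ (SNP2X $\ge 3$ when SNP4X-D $= 0$); silencing requires
SNP4X-D $\ge 3$ with SNP4X-R $= 0$ (one discordant RNA SNP tolerated).
Loss mechanism comes from comparing the gene's mean depth to robust 99%
bands around the 4-copy and 2-copy expectations.  Events are attributed
to the subgenome of the progenitor sharing the *fewer* alleles with the
polyploid (difference of $\ge 3$ required).

## Worked example

Recompute the hand-checkable statistics from the published count tables
bundled with the package:

```python
>>> from homeoscan.validation import worked_example_stats
>>> s = worked_example_stats()
>>> s["fisher_p_organelle"]     # GO:0043229, 2x2 = (13, 3977, 53, 3898)
3.610183582467792e-07
>>> s["fisher_fdr_cell"]        # BH over the 230-term universe
0.00013615084682015285
>>> s["loss_union"], s["loss_shared_pct"]     # 174 + 148 losses, 143 shared
(179.0, 80.0)
>>> s["silencing_shared_pct"]   # 80 of 156 silencings shared
51.3
```

The first value is the two-sided Fisher's exact p-value for depletion of
organelle-annotated genes among 66 silenced homeologs; the last two say
that 179 distinct genes show homeolog loss across two accessions (80%
shared — loss events are mostly old and common to the species) while
silenced genes are only ~51% shared (silencing is more recent and
accession-specific).

Run the full pipeline on synthetic data (two accessions observed from
one simulated truth with 3 conversions, 2 deletions, 4 silencings):

```bash
homeoscan run --config examples/two_accessions.yaml --seed 11 --out-dir run_out
```

prints, among other things,

```json
"loss":      {"per_accession": {"ar41": 5, "caturra": 5}, "shared": 5, "union": 5},
"silencing": {"per_accession": {"ar41": 4, "caturra": 4}, "shared": 4, "union": 4}
```

— all 5 simulated losses (3 conversions called `loss_homogenization`, 2
deletions called `loss_deletion`) and all 4 silencings are recovered in
both accessions, with per-gene detail in `run_out/<accession>/gene_fates.tsv`.
The subcommands `simulate`, `scan`, `classify`, `attribute` and `enrich`
expose the individual stages on files (VCF, depth TSV, GFF3, GO TSV).

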