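"""Reading/writing of the standard formats and CDS-level extraction.

Internal coordinates are 0-based half-open everywhere; VCF (1-based) and
GFF3 (1-based inclusive) are converted at the parse/write boundary.
VCF parsing goes through pysam; GFF3 parsing through gffutils.  The
writers target the subset of each format the pipeline itself consumes
(VCF with a single sample and GT:AD:DP, GFF3 with gene + CDS features).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pysam


class VcfParseError(ValueError):
    pass


class GffParseError(ValueError):
    pass


def _open_text(path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class SnpRecord:
    """One variant call at a reference position for one sample.

    ``pos`` is 0-based.  ``allelic_depths`` is ordered (ref, alt1, ...);
    ``genotype`` holds called allele indices (0 = ref).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    total_depth: int
    allelic_depths: tuple[int, ...]
    genotype: tuple[int, ...]
    sample: str = "sample"

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if any(d < 0 for d in self.allelic_depths):
            raise ValueError("allelic depths must be >= 0")

    @property
    def is_het(self) -> bool:
        """Two or more distinct alleles called — a homeologous-SNP-like site."""
        return len(set(self.genotype)) >= 2

    @property
    def has_nonref(self) -> bool:
        return any(g > 0 for g in self.genotype)

    @property
    def called_alleles(self) -> frozenset[str]:
        bases = (self.ref_allele,) + self.alt_alleles
        return frozenset(bases[g] for g in self.genotype)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its CDS footprint on the reference.

    ``cds_intervals`` are 0-based half-open, sorted, non-overlapping.
    ``single_copy`` marks genes usable for SNP analysis (multi-copy CDS
    attract reads from paralogs and are excluded upstream).
    """

    gene_id: str
    chromosome: str
    cds_intervals: tuple[tuple[int, int], ...]
    strand: str = "+"
    single_copy: bool = True

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        prev_end = -1
        for s, e in self.cds_intervals:
            if s < 0 or e <= s:
                raise ValueError(f"bad CDS interval ({s},{e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"CDS intervals unsorted/overlapping in {self.gene_id}")
            prev_end = e

    @property
    def start(self) -> int:
        return self.cds_intervals[0][0]

    @property
    def end(self) -> int:
        return self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_positions(self) -> np.ndarray:
        return np.concatenate([np.arange(s, e) for s, e in self.cds_intervals])

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds_intervals)


@dataclass
class DepthTrack:
    """Per-position read depth, one int array per chromosome."""

    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.depths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.depths

    @property
    def chromosomes(self) -> list[str]:
        return list(self.depths)

    def mean_depth(self, covered_only: bool = True) -> float:
        """Genome-wide mean depth; by default over positions with depth > 0."""
        if not self.depths:
            raise ValueError("empty depth track")
        total = sum(int(a.sum()) for a in self.depths.values())
        if covered_only:
            n = sum(int((a > 0).sum()) for a in self.depths.values())
        else:
            n = sum(a.size for a in self.depths.values())
        if n == 0:
            raise ValueError("depth track has no covered positions")
        return total / n

    def write_tsv(self, path) -> None:
        """chrom / 1-based position / depth, one row per position."""
        with _open_text(path, "wt") as fh:
            for chrom in self.depths:
                arr = self.depths[chrom]
                lines = "\n".join(
                    f"{chrom}\t{i + 1}\t{d}" for i, d in enumerate(arr.tolist())
                )
                fh.write(lines + "\n")

    @classmethod
    def read_tsv(cls, path, chrom_lengths: Mapping[str, int] | None = None) -> "DepthTrack":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}: malformed depth row at line {ln}")
                chrom, pos1, depth = parts
                per_chrom.setdefault(chrom, []).append((int(pos1) - 1, int(depth)))
        depths = {}
        for chrom, rows in per_chrom.items():
            length = (
                chrom_lengths[chrom]
                if chrom_lengths is not None
                else max(p for p, _ in rows) + 1
            )
            arr = np.zeros(length, dtype=np.int32)
            idx = np.array([p for p, _ in rows])
            arr[idx] = np.array([d for _, d in rows], dtype=np.int32)
            depths[chrom] = arr
        return cls(depths)


# ---------------------------------------------------------------------------
# VCF


def parse_vcf(path) -> list[SnpRecord]:
    """Read a (possibly gzipped) VCF into SnpRecords, converting POS to 0-based.

    Multi-allelic records are preserved as single records.  Only the first
    sample column is read.
    """
    records: list[SnpRecord] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot open as VCF ({exc})") from exc
    with vf:
        samples = list(vf.header.samples)
        sample = samples[0] if samples else "sample"
        try:
            for rec in vf:
                alts = tuple(a for a in (rec.alts or ()))
                if samples:
                    call = rec.samples[sample]
                    gt = tuple(g for g in (call.get("GT") or ()) if g is not None)
                    ad = call.get("AD")
                    ad = tuple(int(x) for x in ad) if ad is not None else ()
                    dp = call.get("DP")
                    dp = int(dp) if dp is not None else sum(ad)
                else:  # sites-only VCF
                    gt, ad, dp = (), (), 0
                records.append(
                    SnpRecord(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,
                        ref_allele=rec.ref,
                        alt_alleles=alts,
                        total_depth=dp,
                        allelic_depths=ad,
                        genotype=gt,
                        sample=sample,
                    )
                )
        except (OSError, ValueError) as exc:
            raise VcfParseError(f"{path}: malformed VCF record ({exc})") from exc
    return records


def write_vcf(
    records: Iterable[SnpRecord],
    path,
    contigs: Mapping[str, int],
    sample: str = "sample",
) -> None:
    """Write the VCF v4.2 subset the pipeline uses (GT:AD:DP, one sample)."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in records:
            alt = ",".join(r.alt_alleles) if r.alt_alleles else "."
            gt = "/".join(str(g) for g in r.genotype) if r.genotype else "./."
            ad = ",".join(str(d) for d in r.allelic_depths) if r.allelic_depths else "."
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref_allele}\t{alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{ad}:{r.total_depth}\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def parse_gff(path) -> list[GeneModel]:
    """Read gene + CDS features from a GFF3 into GeneModels.

    CDS (1-based inclusive) are converted to 0-based half-open and grouped
    under their parent gene.  A CDS whose Parent is not a gene feature in
    the file is an error.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GffParseError(f"{path}: cannot parse GFF3 ({exc})") from exc

    gene_features = {g.id: g for g in db.features_of_type("gene")}
    cds_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_features}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents:
            raise GffParseError(f"{path}: CDS {cds.id} has no Parent attribute")
        parent = parents[0]
        if parent not in gene_features:
            raise GffParseError(f"{path}: CDS {cds.id} parent {parent!r} is not a gene")
        cds_by_gene[parent].append((cds.start - 1, cds.end))

    genes = []
    for gid, feat in gene_features.items():
        if feat.strand not in ("+", "-"):
            raise GffParseError(f"{path}: gene {gid} has unknown strand {feat.strand!r}")
        sc = feat.attributes.get("single_copy", ["1"])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                chromosome=feat.seqid,
                cds_intervals=tuple(sorted(cds_by_gene[gid])),
                strand=feat.strand,
                single_copy=sc not in ("0", "false", "False"),
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            sc = "1" if g.single_copy else "0"
            fh.write(
                f"{g.chromosome}\thomeoscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};single_copy={sc}\n"
            )
            for i, (s, e) in enumerate(g.cds_intervals, 1):
                fh.write(
                    f"{g.chromosome}\thomeoscan\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    """Write (chrom, start, end, name) rows as 0-based half-open BED."""
    with _open_text(path, "wt") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# CDS-level extraction


def extract_cds_snps(
    snps: Iterable[SnpRecord], genes: Sequence[GeneModel]
) -> dict[str, list[SnpRecord]]:
    """Assign SNPs to the single-copy gene whose CDS contains them.

    A SNP belongs to a gene iff its position lies in one of the gene's CDS
    intervals (half-open: the start is in, the end is out).  SNPs outside
    every CDS are dropped; genes flagged ``single_copy=False`` receive
    nothing.  Assumes CDS intervals of distinct genes do not overlap.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {g.chromosome for g in genes}:
        ivals = [
            (s, e, g.gene_id)
            for g in genes
            if g.chromosome == chrom and g.single_copy
            for (s, e) in g.cds_intervals
        ]
        ivals.sort()
        starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
        by_chrom[chrom] = (starts, ends, [gid for _, _, gid in ivals])

    out: dict[str, list[SnpRecord]] = {g.gene_id: [] for g in genes if g.single_copy}
    for snp in snps:
        entry = by_chrom.get(snp.chrom)
        if entry is None:
            continue
        starts, ends, gids = entry
        i = int(np.searchsorted(starts, snp.pos, side="right")) - 1
        if i >= 0 and snp.pos < ends[i]:
            out[gids[i]].append(snp)
    return out


def gene_depth_summary(
    depth: DepthTrack, genes: Sequence[GeneModel]
) -> dict[str, float]:
    """Mean read depth over each gene's CDS positions."""
    out = {}
    for g in genes:
        if g.cds_length == 0:
            raise ValueError(f"gene {g.gene_id} has zero CDS length")
        arr = depth[g.chromosome]
        total = sum(int(arr[s:e].sum()) for s, e in g.cds_intervals)
        out[g.gene_id] = total / g.cds_length
    return out
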