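"""Synthetic allotetraploid data with known ground truth.

The generator emulates the observational setting of a nascent
allotetraploid (two subgenomes, here called C^a — the one matching the
reference — and E^a) sequenced as DNA-seq against one progenitor's
genome and as RNA-seq against its CDS set, together with one RNA-seq
library of the other diploid progenitor:

* fixed interspecific differences are scattered along each chromosome at
  a per-bp rate (``divergence``, default 1.3%); at such a position the
  allotetraploid normally looks heterozygous (one allele per subgenome),
  the diploid progenitor looks homozygous-alternate, and the reference
  progenitor matches the reference;
* homeologous exchange tracts and single-gene conversions replace one
  subgenome's sequence by the other's (copy number stays 4x): toward the
  reference subgenome this erases variant records, toward the other it
  turns them homozygous-alternate;
* deletions remove one homeolog (copy number 2x, read depth halved);
* silenced genes keep both DNA copies but express only one homeolog.

Read depth is drawn from a negative binomial around the configured mean
with a per-gene multiplicative gamma factor, so per-gene mean depths are
overdispersed the way mappability makes real coverage.  All outputs are
deterministic functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .variant_io import DepthTrack, GeneModel, SnpRecord, write_gff3, write_vcf

_BASES = np.array(["A", "C", "G", "T"])

RETAINED = "retained_expressed"
EVENT_LABELS = (
    "silenced_Ca",
    "silenced_Ea",
    "conversion_to_Ca",
    "conversion_to_Ea",
    "deletion_Ca",
    "deletion_Ea",
)

# DNA allele state codes along a chromosome
_HET, _REF_ONLY, _ALT_ONLY = 0, 1, 2


class ConfigError(ValueError):
    pass


class HeeRegion(NamedTuple):
    """A homeologous exchange tract: [start, end) replaced by the donor subgenome."""

    chrom: str
    start: int
    end: int
    donor: str  # "Ca" or "Ea"


class GoBias(NamedTuple):
    """Skew a GO term's annotation odds within genes of one truth class."""

    term: str
    label_prefix: str  # matched against truth labels with startswith
    odds_ratio: float


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 200
    gene_length: int = 3_000
    cds_fraction: float = 0.8
    divergence: float = 0.013
    hee_regions: tuple[HeeRegion, ...] = ()
    conversion_genes: int | Mapping[str, str] = 0  # count, or gene_id -> donor
    deletion_genes: int | Mapping[str, str] = 0  # count, or gene_id -> deleted copy
    silenced_genes: int | Mapping[str, str] = 0  # count, or gene_id -> silenced copy
    dna_depth_mean: float = 40.0
    dna_depth_dispersion: float = 12.0
    gene_depth_cv: float = 0.05
    rna_depth_mean: float = 30.0
    rna_depth_dispersion: float = 8.0
    rna_gene_cv: float = 0.2
    n_rna_libraries: int = 4
    diploid_rna_depth_mean: float = 30.0
    homeolog_bias: float = 0.5  # fraction of allotetraploid RNA reads from C^a
    n_go_terms: int = 30
    go_biases: tuple[GoBias, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.divergence < 1:
            raise ConfigError(f"divergence must be in (0,1), got {self.divergence}")
        if min(self.dna_depth_mean, self.rna_depth_mean, self.diploid_rna_depth_mean) <= 0:
            raise ConfigError("depth means must be > 0")
        if not 0 < self.homeolog_bias < 1:
            raise ConfigError("homeolog_bias must be in (0,1)")
        if not 0 < self.cds_fraction <= 1:
            raise ConfigError("cds_fraction must be in (0,1]")
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ConfigError("need at least one chromosome and one gene")
        by_chrom: dict[str, list[HeeRegion]] = {}
        valid = set(self.chromosome_names())
        for reg in self.hee_regions:
            if reg.donor not in ("Ca", "Ea"):
                raise ConfigError(f"unknown donor subgenome {reg.donor!r}")
            if reg.chrom not in valid:
                raise ConfigError(f"HEE region on unknown chromosome {reg.chrom!r}")
            if not 0 <= reg.start < reg.end <= self.chromosome_length:
                raise ConfigError(f"HEE region out of bounds: {reg}")
            by_chrom.setdefault(reg.chrom, []).append(reg)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    raise ConfigError(f"overlapping HEE regions: {a} / {b}")
        for name, mapping in (
            ("conversion_genes", self.conversion_genes),
            ("deletion_genes", self.deletion_genes),
            ("silenced_genes", self.silenced_genes),
        ):
            if isinstance(mapping, int):
                if mapping < 0:
                    raise ConfigError(f"{name} count must be >= 0")
            else:
                for sg in mapping.values():
                    if sg not in ("Ca", "Ea"):
                        raise ConfigError(f"{name}: unknown subgenome {sg!r}")
        explicit = [
            set(m) for m in (self.conversion_genes, self.deletion_genes, self.silenced_genes)
            if not isinstance(m, int)
        ]
        for i, a in enumerate(explicit):
            for b in explicit[i + 1 :]:
                if a & b:
                    raise ConfigError(f"event gene sets overlap: {sorted(a & b)}")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]


def lost_subgenome(label: str) -> str | None:
    """The subgenome whose sequence/expression the event removed.

    A conversion *toward* donor X wipes out the other subgenome's copy, so
    ``conversion_to_Ca`` is an E^a event; deletions and silencings are
    named directly for the affected copy.
    """
    if label.startswith("conversion_to_"):
        return "Ea" if label.endswith("Ca") else "Ca"
    if label.startswith(("deletion_", "silenced_")):
        return label.rsplit("_", 1)[1]
    return None


@dataclass
class TruthSet:
    """Ground truth for one simulated accession universe."""

    config: SimConfig
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    gene_labels: dict[str, str]
    hee_regions: tuple[HeeRegion, ...]
    snp_positions: dict[str, np.ndarray]  # sorted, 0-based
    snp_c_alleles: dict[str, np.ndarray]  # reference-progenitor base
    snp_e_alleles: dict[str, np.ndarray]  # other-progenitor base

    def n_interspecific_snps(self) -> int:
        return sum(len(p) for p in self.snp_positions.values())

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def genes_with_label(self, prefix: str) -> list[str]:
        return sorted(g for g, lab in self.gene_labels.items() if lab.startswith(prefix))

    def progenitor_catalog(self) -> dict[str, dict[int, tuple[str, str]]]:
        """chrom -> pos -> (reference-progenitor allele, other-progenitor allele)."""
        return {
            chrom: {
                int(p): (str(c), str(e))
                for p, c, e in zip(
                    self.snp_positions[chrom],
                    self.snp_c_alleles[chrom],
                    self.snp_e_alleles[chrom],
                )
            }
            for chrom in self.snp_positions
        }

    def dna_state_arrays(self) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        """Per-chromosome DNA allele-state codes and copy-number factors."""
        states = {c: np.zeros(l, dtype=np.int8) for c, l in self.chrom_lengths.items()}
        copy = {c: np.ones(l, dtype=np.float32) for c, l in self.chrom_lengths.items()}
        for reg in self.hee_regions:
            states[reg.chrom][reg.start : reg.end] = (
                _REF_ONLY if reg.donor == "Ca" else _ALT_ONLY
            )
        by_id = self.genes_by_id()
        for gid, label in self.gene_labels.items():
            g = by_id[gid]
            span = slice(g.start, g.end)
            if label == "conversion_to_Ca":
                states[g.chromosome][span] = _REF_ONLY
            elif label == "conversion_to_Ea":
                states[g.chromosome][span] = _ALT_ONLY
            elif label == "deletion_Ca":
                states[g.chromosome][span] = _ALT_ONLY
                copy[g.chromosome][span] = 0.5
            elif label == "deletion_Ea":
                states[g.chromosome][span] = _REF_ONLY
                copy[g.chromosome][span] = 0.5
        return states, copy

    def rna_state(self, label: str) -> int:
        """Which alleles the gene's RNA shows, given its truth label."""
        if label in ("silenced_Ca", "conversion_to_Ea", "deletion_Ca"):
            return _ALT_ONLY
        if label in ("silenced_Ea", "conversion_to_Ca", "deletion_Ea"):
            return _REF_ONLY
        return _HET

    def write_tsv(self, path) -> None:
        rows = [
            {"gene_id": gid, "label": lab, "lost_subgenome": lost_subgenome(lab) or "NA"}
            for gid, lab in sorted(self.gene_labels.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % 2**31, *stream])


# ---------------------------------------------------------------------------
# Truth


def _tile_genes(config: SimConfig) -> list[GeneModel]:
    chroms = config.chromosome_names()
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    cds_total = max(2, int(round(config.cds_fraction * config.gene_length)))
    exon1 = cds_total // 2
    exon2 = cds_total - exon1
    for ci, (chrom, n_on) in enumerate(zip(chroms, per_chrom)):
        if n_on == 0:
            continue
        slot = config.chromosome_length // n_on
        if slot < config.gene_length + 2:
            raise ConfigError(
                f"{n_on} genes of {config.gene_length} bp do not fit on a "
                f"{config.chromosome_length} bp chromosome"
            )
        for i in range(n_on):
            start = i * slot + (slot - config.gene_length) // 2
            end = start + config.gene_length
            if config.cds_fraction >= 1.0:
                cds = ((start, end),)
            else:
                cds = ((start, start + exon1), (end - exon2, end))
            genes.append(
                GeneModel(
                    gene_id=f"{chrom}_g{i + 1:04d}",
                    chromosome=chrom,
                    cds_intervals=cds,
                    strand="+" if (i % 2 == 0) else "-",
                )
            )
    return genes


def simulate_truth(config: SimConfig) -> TruthSet:
    """Lay out gene models, draw interspecific SNPs, and assign event labels."""
    config.validate()
    rng = _rng(config, 11)
    chrom_lengths = {c: config.chromosome_length for c in config.chromosome_names()}
    genes = _tile_genes(config)

    snp_positions, c_alleles, e_alleles = {}, {}, {}
    for chrom, length in chrom_lengths.items():
        pos = np.flatnonzero(rng.random(length) < config.divergence)
        c_idx = rng.integers(0, 4, pos.size)
        e_idx = (c_idx + rng.integers(1, 4, pos.size)) % 4
        snp_positions[chrom] = pos
        c_alleles[chrom] = _BASES[c_idx]
        e_alleles[chrom] = _BASES[e_idx]

    labels = {g.gene_id: RETAINED for g in genes}
    for reg in config.hee_regions:
        for g in genes:
            if g.chromosome == reg.chrom and reg.start <= g.start and g.end <= reg.end:
                labels[g.gene_id] = f"conversion_to_{reg.donor}"

    by_id = {g.gene_id: g for g in genes}

    def _resolve(spec_value, kind: str, free: list[str]) -> dict[str, str]:
        if isinstance(spec_value, int):
            if spec_value > len(free):
                raise ConfigError(
                    f"requested {spec_value} {kind} genes but only {len(free)} available"
                )
            chosen = [free[i] for i in sorted(rng.choice(len(free), spec_value, replace=False))]
            sub = np.where(rng.integers(0, 2, len(chosen)) == 0, "Ca", "Ea")
            return dict(zip(chosen, sub))
        for gid in spec_value:
            if gid not in by_id:
                raise ConfigError(f"{kind} gene {gid!r} not in gene models")
            if labels[gid] != RETAINED:
                raise ConfigError(f"{kind} gene {gid!r} already labeled {labels[gid]}")
        return dict(spec_value)

    free = sorted(gid for gid, lab in labels.items() if lab == RETAINED)
    conversions = _resolve(config.conversion_genes, "conversion", free)
    for gid, donor in conversions.items():
        labels[gid] = f"conversion_to_{donor}"
    free = sorted(gid for gid, lab in labels.items() if lab == RETAINED)
    deletions = _resolve(config.deletion_genes, "deletion", free)
    for gid, sub in deletions.items():
        labels[gid] = f"deletion_{sub}"
    free = sorted(gid for gid, lab in labels.items() if lab == RETAINED)
    silenced = _resolve(config.silenced_genes, "silenced", free)
    for gid, sub in silenced.items():
        labels[gid] = f"silenced_{sub}"

    return TruthSet(
        config=config,
        chrom_lengths=chrom_lengths,
        genes=genes,
        gene_labels=labels,
        hee_regions=tuple(config.hee_regions),
        snp_positions=snp_positions,
        snp_c_alleles=c_alleles,
        snp_e_alleles=e_alleles,
    )


# ---------------------------------------------------------------------------
# Observations


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with the given per-position mean and size ``dispersion``."""
    r = dispersion
    p = r / (r + np.maximum(mean, 1e-9))
    return rng.negative_binomial(r, p).astype(np.int32)


def _gene_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    shape = 1.0 / cv**2
    return rng.gamma(shape, cv**2, n)


def _records_at_snps(
    chrom: str,
    positions: np.ndarray,
    c_all: np.ndarray,
    e_all: np.ndarray,
    states: np.ndarray,
    depth: np.ndarray,
    ref_fraction: float,
    rng: np.random.Generator,
    sample: str,
) -> list[SnpRecord]:
    """Variant records implied by allele states at interspecific positions.

    Heterozygous-state positions get a binomial split of reads between the
    reference-progenitor and other-progenitor alleles; positions where only
    the reference allele remains produce no record (the caller sees plain
    reference sequence).
    """
    out: list[SnpRecord] = []
    dp = depth[positions]
    st = states[positions]
    alt_reads = np.zeros(positions.size, dtype=np.int64)
    het = st == _HET
    alt_reads[het] = rng.binomial(dp[het], 1.0 - ref_fraction)
    alt_reads[st == _ALT_ONLY] = dp[st == _ALT_ONLY]
    for i in range(positions.size):
        if st[i] == _REF_ONLY or dp[i] == 0 or alt_reads[i] == 0:
            continue
        n_alt = int(alt_reads[i])
        n_ref = int(dp[i]) - n_alt
        gt = (1, 1) if n_ref == 0 else (0, 1)
        out.append(
            SnpRecord(
                chrom=chrom,
                pos=int(positions[i]),
                ref_allele=str(c_all[i]),
                alt_alleles=(str(e_all[i]),),
                total_depth=int(dp[i]),
                allelic_depths=(n_ref, n_alt),
                genotype=gt,
                sample=sample,
            )
        )
    return out


def emit_dna_observations(
    truth: TruthSet, config: SimConfig, sample: str = "allo_dna", stream: int = 0
) -> tuple[list[SnpRecord], DepthTrack]:
    """Whole-genome DNA-seq of the allotetraploid vs the reference.

    ``stream`` distinguishes accessions observed from the same truth.
    """
    rng = _rng(config, 21, stream)
    states, copy_factor = truth.dna_state_arrays()
    records: list[SnpRecord] = []
    depths: dict[str, np.ndarray] = {}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in truth.genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, length in truth.chrom_lengths.items():
        mu = np.full(length, config.dna_depth_mean, dtype=np.float64)
        chrom_genes = genes_by_chrom.get(chrom, [])
        factors = _gene_factors(rng, len(chrom_genes), config.gene_depth_cv)
        for g, f in zip(chrom_genes, factors):
            mu[g.start : g.end] *= f
        mu *= copy_factor[chrom]
        depth = _nb_draw(rng, mu, config.dna_depth_dispersion)
        depths[chrom] = depth
        records.extend(
            _records_at_snps(
                chrom,
                truth.snp_positions[chrom],
                truth.snp_c_alleles[chrom],
                truth.snp_e_alleles[chrom],
                states[chrom],
                depth,
                ref_fraction=0.5,
                rng=rng,
                sample=sample,
            )
        )
    return records, DepthTrack(depths)


def _cds_mask(truth: TruthSet, chrom: str) -> np.ndarray:
    mask = np.zeros(truth.chrom_lengths[chrom], dtype=bool)
    for g in truth.genes:
        if g.chromosome == chrom:
            for s, e in g.cds_intervals:
                mask[s:e] = True
    return mask


@dataclass
class RnaObservations:
    """RNA SNP tables: one (records, depth) pair per allotetraploid library
    plus one for the diploid progenitor that is not the reference."""

    allo_libraries: list[tuple[list[SnpRecord], DepthTrack]]
    diploid: tuple[list[SnpRecord], DepthTrack]


def emit_rna_observations(
    truth: TruthSet, config: SimConfig, stream: int = 0
) -> RnaObservations:
    """CDS-restricted RNA-seq observations (genome coordinates).

    Allotetraploid libraries show both alleles at interspecific positions
    of genes expressing both homeologs (read split set by
    ``homeolog_bias``) and only the expressed homeolog's alleles for
    silenced or converted/deleted genes; the diploid progenitor library is
    homozygous-alternate at every covered interspecific position.
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in truth.genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)

    def _one_library(rng: np.random.Generator, mean: float, diploid: bool, sample: str):
        records: list[SnpRecord] = []
        depths: dict[str, np.ndarray] = {}
        for chrom, length in truth.chrom_lengths.items():
            mu = np.zeros(length, dtype=np.float64)
            chrom_genes = genes_by_chrom.get(chrom, [])
            factors = _gene_factors(rng, len(chrom_genes), config.rna_gene_cv)
            states = np.full(length, _REF_ONLY, dtype=np.int8)  # no record off-CDS
            for g, f in zip(chrom_genes, factors):
                st = _ALT_ONLY if diploid else truth.rna_state(truth.gene_labels[g.gene_id])
                for s, e in g.cds_intervals:
                    mu[s:e] = mean * f
                    states[s:e] = st
            depth = np.zeros(length, dtype=np.int32)
            cds = mu > 0
            depth[cds] = _nb_draw(rng, mu[cds], config.rna_depth_dispersion)
            depths[chrom] = depth
            records.extend(
                _records_at_snps(
                    chrom,
                    truth.snp_positions[chrom],
                    truth.snp_c_alleles[chrom],
                    truth.snp_e_alleles[chrom],
                    states,
                    depth,
                    ref_fraction=config.homeolog_bias,
                    rng=rng,
                    sample=sample,
                )
            )
        return records, DepthTrack(depths)

    allo = [
        _one_library(
            _rng(config, 31, stream, i), config.rna_depth_mean, False, f"allo_rna_{i + 1}"
        )
        for i in range(config.n_rna_libraries)
    ]
    diploid = _one_library(
        _rng(config, 41, stream), config.diploid_rna_depth_mean, True, "diploid_rna"
    )
    return RnaObservations(allo_libraries=allo, diploid=diploid)


def emit_annotations(truth: TruthSet, config: SimConfig) -> pd.DataFrame:
    """Gene -> GO term table, optionally skewed within truth classes.

    Each term gets a base annotation rate drawn once; a ``GoBias`` entry
    rescales the odds of that term for genes whose truth label matches the
    prefix (odds ratio < 1 depletes the term in that class).
    """
    rng = _rng(config, 51)
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    # fixed ladder of base annotation rates: term k's rate is known a priori,
    # which lets power studies pick a term of known prevalence
    base = np.linspace(0.05, 0.4, config.n_go_terms)
    gene_ids = [g.gene_id for g in truth.genes]
    prob = np.tile(base, (len(gene_ids), 1))
    for bias in config.go_biases:
        if bias.term not in terms:
            raise ConfigError(f"go_biases term {bias.term!r} not among simulated terms")
        j = terms.index(bias.term)
        for i, gid in enumerate(gene_ids):
            if truth.gene_labels[gid].startswith(bias.label_prefix):
                p = prob[i, j]
                prob[i, j] = bias.odds_ratio * p / (1 - p + bias.odds_ratio * p)
    hits = rng.random(prob.shape) < prob
    rows = [
        {"gene_id": gid, "go_id": terms[j]}
        for i, gid in enumerate(gene_ids)
        for j in np.flatnonzero(hits[i])
    ]
    return pd.DataFrame(rows, columns=["gene_id", "go_id"])


def write_reference_fasta(truth: TruthSet, path, line_width: int = 70) -> None:
    """Reference-progenitor chromosome sequences (random backbone, catalog
    alleles at interspecific positions); provided for format completeness —
    the analysis itself runs on positions and alleles."""
    rng = _rng(truth.config, 61)
    with open(path, "w") as fh:
        for chrom, length in truth.chrom_lengths.items():
            seq = _BASES[rng.integers(0, 4, length)]
            seq[truth.snp_positions[chrom]] = truth.snp_c_alleles[chrom]
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, line_width):
                fh.write(s[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Bundles on disk


@dataclass
class ObservedBundle:
    """Paths of one simulated accession's input files plus the truth."""

    dna_vcf: Path
    dna_depth: Path
    rna_vcfs: list[Path]
    rna_depths: list[Path]
    diploid_vcf: Path
    diploid_depth: Path
    gff3: Path
    go_annotations: Path
    progenitor_catalog: Path
    truth_table: Path
    truth: TruthSet


def write_bundle(
    truth: TruthSet, config: SimConfig, outdir, stream: int = 0
) -> ObservedBundle:
    """Emit all observation files for one accession into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = truth.chrom_lengths

    dna_records, dna_depth = emit_dna_observations(truth, config, stream=stream)
    dna_vcf = outdir / "dna.vcf"
    write_vcf(dna_records, dna_vcf, contigs, sample="allo_dna")
    dna_depth_path = outdir / "dna_depth.tsv"
    dna_depth.write_tsv(dna_depth_path)

    rna = emit_rna_observations(truth, config, stream=stream)
    rna_vcfs, rna_depths = [], []
    for i, (records, depth) in enumerate(rna.allo_libraries, 1):
        vp = outdir / f"rna_allo_lib{i}.vcf"
        dp = outdir / f"rna_allo_lib{i}_depth.tsv"
        write_vcf(records, vp, contigs, sample=f"allo_rna_{i}")
        depth.write_tsv(dp)
        rna_vcfs.append(vp)
        rna_depths.append(dp)
    diploid_vcf = outdir / "rna_diploid.vcf"
    diploid_depth_path = outdir / "rna_diploid_depth.tsv"
    write_vcf(rna.diploid[0], diploid_vcf, contigs, sample="diploid_rna")
    rna.diploid[1].write_tsv(diploid_depth_path)

    gff3 = outdir / "genes.gff3"
    write_gff3(truth.genes, gff3)
    go_path = outdir / "go_annotations.tsv"
    emit_annotations(truth, config).to_csv(go_path, sep="\t", index=False)

    catalog_path = outdir / "progenitor_catalog.tsv"
    with open(catalog_path, "w") as fh:
        fh.write("chrom\tpos\tC_allele\tE_allele\n")
        for chrom in truth.snp_positions:
            for p, c, e in zip(
                truth.snp_positions[chrom],
                truth.snp_c_alleles[chrom],
                truth.snp_e_alleles[chrom],
            ):
                fh.write(f"{chrom}\t{int(p) + 1}\t{c}\t{e}\n")

    truth_path = outdir / "truth_genes.tsv"
    truth.write_tsv(truth_path)

    return ObservedBundle(
        dna_vcf=dna_vcf,
        dna_depth=dna_depth_path,
        rna_vcfs=rna_vcfs,
        rna_depths=rna_depths,
        diploid_vcf=diploid_vcf,
        diploid_depth=diploid_depth_path,
        gff3=gff3,
        go_annotations=go_path,
        progenitor_catalog=catalog_path,
        truth_table=truth_path,
        truth=truth,
    )
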