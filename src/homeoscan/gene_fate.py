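"""Per-gene homeolog fate classification from DNA/RNA SNP concordance.

For every single-copy gene three SNP counts are compared at common,
depth-passing CDS positions:

* ``SNP2X`` — fixed differences between the two diploid progenitors
  (the non-reference progenitor's calls against the reference);
* ``SNP4X-D`` — heterozygous-like (homeologous) SNPs in the
  allotetraploid's DNA-seq;
* ``SNP4X-R`` — homeologous SNPs in the allotetraploid's (pooled)
  RNA-seq.

The decision tree: a collapse of SNP4X-D relative to SNP2X (at least
fourfold, SNP4X-D <= 1) marks homeolog loss; among retained genes,
homeologous SNPs present in DNA but absent from RNA mark homeolog
silencing.  Losses are then split into deletion (gene read depth near
the 2-copy expectation) vs homogenization/conversion (depth near the
4-copy expectation) using a robust coverage model fitted on all genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _ss

from .variant_io import DepthTrack, GeneModel, SnpRecord

logger = logging.getLogger(__name__)

LOSS_FATES = ("loss_deletion", "loss_homogenization", "loss_unresolved")
ALL_FATES = ("retained_expressed", "retained_silenced") + LOSS_FATES + ("uninformative",)


@dataclass(frozen=True)
class DepthThresholds:
    """Depth and SNP-count cutoffs for the per-gene comparisons.

    ``dna_4x_min`` is the minimum allotetraploid DNA depth for a position
    to be compared (high enough that both subgenomes are covered);
    ``rna_4x_min`` / ``rna_2x_min`` are the RNA cutoffs for the
    allotetraploid and the diploid progenitor (the allotetraploid cutoff
    is higher because homeolog expression bias can thin one allele);
    ``min_informative_snps`` is the resolution floor for SNP-count
    comparisons.
    """

    dna_4x_min: int = 12
    rna_4x_min: int = 16
    rna_2x_min: int = 4
    min_informative_snps: int = 3
    both_expressed_concordance: float = 0.5

    def __post_init__(self):
        if min(self.dna_4x_min, self.rna_4x_min, self.rna_2x_min, self.min_informative_snps) < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass
class GeneSnpSummary:
    gene_id: str
    snp2x: int = 0
    snp4x_d: int = 0
    snp4x_r: int = 0
    snp4x_d_rna: int = 0  # DNA homeologous SNPs at RNA-covered common positions
    dna_snp_positions: frozenset[int] = frozenset()
    rna_snp_positions: frozenset[int] = frozenset()
    dna_rna_snp_positions: frozenset[int] = frozenset()
    n_common_dna: int = 0
    n_common_rna: int = 0
    mean_dna_depth: float = float("nan")
    informative: bool = True


@dataclass
class FateCall:
    gene_id: str
    fate: str
    subgenome: str = "NA"  # Ca / Ea / ND / NA; filled by subgenome attribution

    def __post_init__(self):
        if self.fate not in ALL_FATES:
            raise ValueError(f"unknown fate {self.fate!r}")


@dataclass(frozen=True)
class CoverageModel:
    """Expected read-depth bands for 4-copy and 2-copy genes.

    Center and spread are robust (median, MAD-derived sigma) over per-gene
    mean depths, almost all of which come from 4-copy genes; the 2-copy
    band halves the center and shrinks the spread by sqrt(2) (depth is a
    sum of per-copy contributions).  ``usable`` is False when the two 99%
    bands overlap or the spread is degenerate.
    """

    mu4: float
    mu2: float
    ci99_4: tuple[float, float]
    ci99_2: tuple[float, float]
    usable: bool


# ---------------------------------------------------------------------------
# SNP counting


def _positions_of(records: Iterable[SnpRecord], predicate) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        if predicate(r):
            by_chrom.setdefault(r.chrom, []).append(r.pos)
    return {c: np.unique(np.array(p, dtype=np.int64)) for c, p in by_chrom.items()}


def pool_rna_biallelic_positions(
    rna_libs: Sequence[tuple[list[SnpRecord], DepthTrack]],
    min_allele_reads: int = 1,
) -> tuple[dict[str, np.ndarray], DepthTrack]:
    """Pool allotetraploid RNA libraries read-wise.

    Returns per-chromosome positions where the pooled reads carry both
    the reference and an alternate allele (the RNA analogue of a
    homeologous SNP), plus the pooled depth track.  A library with
    coverage but no record at a position contributes reference reads
    there (variants are only recorded when alternate reads exist).
    """
    pooled_depth: dict[str, np.ndarray] = {}
    for _, track in rna_libs:
        for chrom in track.chromosomes:
            if chrom in pooled_depth:
                pooled_depth[chrom] = pooled_depth[chrom] + track[chrom]
            else:
                pooled_depth[chrom] = track[chrom].copy()

    counts: dict[str, dict[int, list[int]]] = {}  # chrom -> pos -> [ref, alt]
    rec_positions: list[dict[str, set[int]]] = []
    for records, _ in rna_libs:
        seen: dict[str, set[int]] = {}
        for r in records:
            ref_reads = r.allelic_depths[0] if r.allelic_depths else 0
            alt_reads = sum(r.allelic_depths[1:]) if len(r.allelic_depths) > 1 else 0
            slot = counts.setdefault(r.chrom, {}).setdefault(r.pos, [0, 0])
            slot[0] += int(ref_reads)
            slot[1] += int(alt_reads)
            seen.setdefault(r.chrom, set()).add(r.pos)
        rec_positions.append(seen)
    # reference reads from libraries that saw no variant at a recorded position
    for (records, track), seen in zip(rna_libs, rec_positions):
        for chrom, pos_map in counts.items():
            if chrom not in track:
                continue
            arr = track[chrom]
            lib_seen = seen.get(chrom, set())
            for pos, slot in pos_map.items():
                if pos not in lib_seen:
                    slot[0] += int(arr[pos])

    biallelic = {
        chrom: np.unique(
            np.array(
                [
                    p
                    for p, (nref, nalt) in pos_map.items()
                    if nref >= min_allele_reads and nalt >= min_allele_reads
                ],
                dtype=np.int64,
            )
        )
        for chrom, pos_map in counts.items()
    }
    return biallelic, DepthTrack(pooled_depth)


def count_gene_snps(
    gene: GeneModel,
    dna_het_pos: np.ndarray,
    diploid_nonref_pos: np.ndarray,
    rna_biallelic_pos: np.ndarray,
    dna_depth: np.ndarray,
    diploid_depth: np.ndarray,
    rna_pooled_depth: np.ndarray,
    thresholds: DepthThresholds = DepthThresholds(),
) -> GeneSnpSummary:
    """SNP counts for one gene at common depth-passing CDS positions.

    Position arrays are chromosome-wide sorted positions of: heterozygous
    allotetraploid DNA calls, non-reference diploid-progenitor calls, and
    pooled-RNA biallelic positions; depth arrays are per-position tracks
    for the same chromosome.
    """
    cds = gene.cds_positions()
    dna_ok = dna_depth[cds] >= thresholds.dna_4x_min
    dip_ok = diploid_depth[cds] >= thresholds.rna_2x_min
    rna_ok = rna_pooled_depth[cds] >= thresholds.rna_4x_min

    common_dna = cds[dna_ok & dip_ok]
    common_rna = cds[dna_ok & rna_ok]

    dna_snp_dna = common_dna[np.isin(common_dna, dna_het_pos)]
    snp2x = int(np.isin(common_dna, diploid_nonref_pos).sum())
    dna_snp_rna = common_rna[np.isin(common_rna, dna_het_pos)]
    rna_snp = common_rna[np.isin(common_rna, rna_biallelic_pos)]

    mean_depth = float(dna_depth[cds].mean()) if cds.size else float("nan")
    return GeneSnpSummary(
        gene_id=gene.gene_id,
        snp2x=snp2x,
        snp4x_d=int(dna_snp_dna.size),
        snp4x_r=int(rna_snp.size),
        snp4x_d_rna=int(dna_snp_rna.size),
        dna_snp_positions=frozenset(int(p) for p in dna_snp_dna),
        rna_snp_positions=frozenset(int(p) for p in rna_snp),
        dna_rna_snp_positions=frozenset(int(p) for p in dna_snp_rna),
        n_common_dna=int(common_dna.size),
        n_common_rna=int(common_rna.size),
        mean_dna_depth=mean_depth,
        informative=common_dna.size > 0,
    )


def summarize_genes(
    genes: Sequence[GeneModel],
    dna_records: Iterable[SnpRecord],
    dna_depth: DepthTrack,
    diploid_records: Iterable[SnpRecord],
    diploid_depth: DepthTrack,
    rna_libs: Sequence[tuple[list[SnpRecord], DepthTrack]],
    thresholds: DepthThresholds = DepthThresholds(),
) -> dict[str, GeneSnpSummary]:
    """Per-gene SNP summaries for all single-copy genes.

    Genes whose chromosome lacks depth data in any required dataset are
    marked uninformative with a warning rather than failing the run.
    """
    dna_het = _positions_of(dna_records, lambda r: r.is_het)
    dip_nonref = _positions_of(diploid_records, lambda r: r.has_nonref)
    rna_biallelic, rna_pooled = pool_rna_biallelic_positions(rna_libs)

    empty = np.empty(0, dtype=np.int64)
    out: dict[str, GeneSnpSummary] = {}
    for gene in genes:
        if not gene.single_copy:
            continue
        chrom = gene.chromosome
        missing = [
            name
            for name, track in (
                ("DNA", dna_depth),
                ("diploid RNA", diploid_depth),
                ("allotetraploid RNA", rna_pooled),
            )
            if chrom not in track
        ]
        if missing:
            logger.warning(
                "gene %s: missing depth data for %s; marked uninformative",
                gene.gene_id,
                ", ".join(missing),
            )
            out[gene.gene_id] = GeneSnpSummary(gene_id=gene.gene_id, informative=False)
            continue
        out[gene.gene_id] = count_gene_snps(
            gene,
            dna_het.get(chrom, empty),
            dip_nonref.get(chrom, empty),
            rna_biallelic.get(chrom, empty),
            dna_depth[chrom],
            diploid_depth[chrom],
            rna_pooled[chrom],
            thresholds,
        )
    return out


# ---------------------------------------------------------------------------
# Decision tree


def classify_homeolog_loss(
    s: GeneSnpSummary, thresholds: DepthThresholds = DepthThresholds()
) -> str:
    """Loss / retained / uninformative from the SNP2X vs SNP4X-D collapse.

    Loss requires at least a fourfold drop with SNP4X-D <= 1 — i.e.
    SNP4X-D = 1 with SNP2X >= 4, or SNP4X-D = 0 with SNP2X >= 3 (the
    resolution floor).  Retention requires both counts at or above the
    floor; anything else is uninformative.
    """
    if not s.informative:
        return "uninformative"
    if (s.snp4x_d == 0 and s.snp2x >= 3) or (s.snp4x_d == 1 and s.snp2x >= 4):
        return "loss"
    if min(s.snp2x, s.snp4x_d) >= thresholds.min_informative_snps:
        return "retained"
    return "uninformative"


def classify_homeolog_silencing(
    s: GeneSnpSummary, thresholds: DepthThresholds = DepthThresholds()
) -> str:
    """Silenced / both_expressed / uninformative for a retained gene.

    Silencing: >= 3 homeologous DNA SNPs at RNA-covered positions with no
    RNA SNP (one tolerated when at a position not seen in the DNA set).
    Both expressed: at least half the RNA-covered DNA SNP positions also
    show up as RNA SNPs.
    """
    n_dna = s.snp4x_d_rna
    if n_dna >= thresholds.min_informative_snps:
        if s.snp4x_r == 0:
            return "silenced"
        if s.snp4x_r == 1 and not (s.rna_snp_positions & s.dna_rna_snp_positions):
            return "silenced"
        concordant = len(s.rna_snp_positions & s.dna_rna_snp_positions)
        if concordant / n_dna >= thresholds.both_expressed_concordance:
            return "both_expressed"
    return "uninformative"


def fit_coverage_model(
    gene_depths: Mapping[str, float], min_genes: int = 100
) -> CoverageModel:
    """Robust 4-copy depth band from per-gene mean depths, halved for 2 copies."""
    depths = np.array(list(gene_depths.values()), dtype=float)
    if depths.size < min_genes:
        raise ValueError(f"need >= {min_genes} genes to fit a coverage model, got {depths.size}")
    mu4 = float(np.median(depths))
    scale = float(1.4826 * np.median(np.abs(depths - mu4)))
    z = float(_ss.norm.ppf(0.995))
    mu2 = mu4 / 2.0
    scale2 = scale / np.sqrt(2.0)
    ci4 = (mu4 - z * scale, mu4 + z * scale)
    ci2 = (mu2 - z * scale2, mu2 + z * scale2)
    usable = scale > 0 and ci2[1] < ci4[0]
    if not usable:
        logger.warning("coverage model unusable (scale=%.4g, bands overlap)", scale)
    return CoverageModel(mu4=mu4, mu2=mu2, ci99_4=ci4, ci99_2=ci2, usable=usable)


def classify_loss_mechanism(mean_depth: float, model: CoverageModel) -> str:
    """Deletion (2-copy band) vs homogenization (4-copy band) vs unresolved."""
    if not model.usable or not np.isfinite(mean_depth):
        return "unresolved"
    in2 = model.ci99_2[0] <= mean_depth <= model.ci99_2[1]
    in4 = model.ci99_4[0] <= mean_depth <= model.ci99_4[1]
    if in2 and not in4:
        return "deletion"
    if in4 and not in2:
        return "homogenization"
    return "unresolved"


def classify_gene(
    s: GeneSnpSummary,
    model: CoverageModel,
    thresholds: DepthThresholds = DepthThresholds(),
) -> FateCall:
    """Full decision tree for one gene; exactly one fate per gene."""
    loss = classify_homeolog_loss(s, thresholds)
    if loss == "loss":
        mech = classify_loss_mechanism(s.mean_dna_depth, model)
        return FateCall(s.gene_id, f"loss_{mech}")
    if loss == "retained":
        sil = classify_homeolog_silencing(s, thresholds)
        if sil == "silenced":
            return FateCall(s.gene_id, "retained_silenced")
        if sil == "both_expressed":
            return FateCall(s.gene_id, "retained_expressed")
    return FateCall(s.gene_id, "uninformative")


def classify_all(
    summaries: Mapping[str, GeneSnpSummary],
    model: CoverageModel,
    thresholds: DepthThresholds = DepthThresholds(),
) -> dict[str, FateCall]:
    return {gid: classify_gene(s, model, thresholds) for gid, s in summaries.items()}


# ---------------------------------------------------------------------------
# Cross-accession comparison


def _fmt_pct(x: float, integer: bool = False) -> float:
    return float(round(x)) if integer else round(x, 1)


def cross_accession_summary(
    fates_by_accession: Mapping[str, Mapping[str, FateCall]],
    event_fates: Sequence[str],
) -> dict:
    """Shared / specific / union accounting of one event class.

    ``event_fates`` selects the fates that constitute the event (e.g. all
    loss fates, or ``("retained_silenced",)``).  All accessions must have
    been analyzed on the same gene universe.
    """
    accs = list(fates_by_accession)
    if len(accs) < 2:
        raise ValueError("need at least two accessions")
    universes = [set(f) for f in fates_by_accession.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("accessions analyzed on different gene universes")
    sets = {
        acc: {g for g, f in fates.items() if f.fate in event_fates}
        for acc, fates in fates_by_accession.items()
    }
    shared = set.intersection(*sets.values())
    union = set.union(*sets.values())
    n_union = len(union)
    return {
        "per_accession": {acc: len(s) for acc, s in sets.items()},
        "shared": len(shared),
        "union": n_union,
        "shared_gene_ids": sorted(shared),
        "union_gene_ids": sorted(union),
        "shared_pct": _fmt_pct(100.0 * len(shared) / n_union, integer=True) if n_union else 0.0,
        "shared_pct_1dp": _fmt_pct(100.0 * len(shared) / n_union) if n_union else 0.0,
        "universe_size": len(universes[0]),
        "union_pct_of_universe": _fmt_pct(100.0 * n_union / len(universes[0])) if universes[0] else 0.0,
    }


def per_library_consistency(
    genes: Sequence[GeneModel],
    rna_libs: Sequence[tuple[list[SnpRecord], DepthTrack]],
    dna_records: Iterable[SnpRecord],
    dna_depth: DepthTrack,
    silenced_gene_ids: Iterable[str],
    thresholds: DepthThresholds = DepthThresholds(),
) -> dict[str, str]:
    """Check pooled silencing calls against each individual RNA library.

    A gene is ``consistent`` when every library independently satisfies
    the silencing rule at its own covered positions, ``inconsistent``
    when some sufficiently covered library expresses the second homeolog,
    and ``not_evaluable`` unless all libraries pass depth filtering with
    enough informative positions.
    """
    if len(rna_libs) < 2:
        raise ValueError("per-library consistency needs >= 2 RNA libraries")
    dna_het = _positions_of(dna_records, lambda r: r.is_het)
    by_id = {g.gene_id: g for g in genes}
    lib_het = [_positions_of(records, lambda r: r.is_het) for records, _ in rna_libs]
    empty = np.empty(0, dtype=np.int64)

    out: dict[str, str] = {}
    for gid in silenced_gene_ids:
        gene = by_id[gid]
        chrom = gene.chromosome
        cds = gene.cds_positions()
        dna_ok = dna_depth[chrom][cds] >= thresholds.dna_4x_min
        verdict = "consistent"
        for (records, track), het in zip(rna_libs, lib_het):
            lib_ok = track[chrom][cds] >= thresholds.rna_4x_min
            common = cds[dna_ok & lib_ok]
            dna_snps = common[np.isin(common, dna_het.get(chrom, empty))]
            if dna_snps.size < thresholds.min_informative_snps:
                verdict = "not_evaluable"
                break
            rna_snps = common[np.isin(common, het.get(chrom, empty))]
            if rna_snps.size == 0:
                continue
            if rna_snps.size == 1 and not np.isin(rna_snps, dna_snps)[0]:
                continue
            verdict = "inconsistent"
        out[gid] = verdict
    return out


def summaries_to_frame(
    summaries: Mapping[str, GeneSnpSummary], fates: Mapping[str, FateCall] | None = None
) -> pd.DataFrame:
    rows = []
    for gid, s in summaries.items():
        row = {
            "gene_id": gid,
            "snp2x": s.snp2x,
            "snp4x_d": s.snp4x_d,
            "snp4x_r": s.snp4x_r,
            "snp4x_d_rna": s.snp4x_d_rna,
            "n_common_dna": s.n_common_dna,
            "n_common_rna": s.n_common_rna,
            "mean_dna_depth": round(s.mean_dna_depth, 3),
        }
        if fates is not None:
            row["fate"] = fates[gid].fate
            row["subgenome"] = fates[gid].subgenome
        rows.append(row)
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
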