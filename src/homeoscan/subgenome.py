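"""Attribute loss/silencing events to a subgenome via shared alleles.

At positions where the two diploid progenitors carry different alleles
(the progenitor catalog), the alleles still present in the
allotetraploid — in its DNA for loss events, in its expressed RNA for
silencing events — are compared against each progenitor.  The event is
attributed to the subgenome derived from the progenitor sharing the
FEWER alleles: that progenitor's contribution is the one that went
missing.  A minimum count difference guards against noise.

Positions where the allotetraploid matches the reference produce no
variant record, yet they count as sharing the reference progenitor's
allele; without that, an event removing the non-reference subgenome
would look like it shares nothing with anyone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_fate import FateCall
from .variant_io import DepthTrack, GeneModel, SnpRecord

__all__ = [
    "ProgenitorCatalog",
    "SharedAlleleCount",
    "pooled_allele_map",
    "count_shared_alleles",
    "attribute_subgenome",
    "attribute_events",
    "subgenome_summary",
]


@dataclass
class ProgenitorCatalog:
    """Progenitor-differentiating positions with both diploid alleles.

    ``c_alleles`` belong to the reference progenitor (subgenome C^a),
    ``e_alleles`` to the other progenitor (subgenome E^a).
    """

    positions: dict[str, np.ndarray]  # sorted, 0-based
    c_alleles: dict[str, np.ndarray]
    e_alleles: dict[str, np.ndarray]

    @classmethod
    def from_truth(cls, truth) -> "ProgenitorCatalog":
        return cls(
            positions={c: p.copy() for c, p in truth.snp_positions.items()},
            c_alleles={c: a.copy() for c, a in truth.snp_c_alleles.items()},
            e_alleles={c: a.copy() for c, a in truth.snp_e_alleles.items()},
        )

    @classmethod
    def read_tsv(cls, path) -> "ProgenitorCatalog":
        df = pd.read_csv(path, sep="\t")
        pos, ca, ea = {}, {}, {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("pos")
            pos[chrom] = sub["pos"].to_numpy(dtype=np.int64) - 1
            ca[chrom] = sub["C_allele"].to_numpy(dtype=str)
            ea[chrom] = sub["E_allele"].to_numpy(dtype=str)
        return cls(pos, ca, ea)

    def in_gene(self, gene: GeneModel) -> Iterator[tuple[int, str, str]]:
        """Catalog entries inside the gene's CDS intervals."""
        if gene.chromosome not in self.positions:
            return
        pos = self.positions[gene.chromosome]
        ca = self.c_alleles[gene.chromosome]
        ea = self.e_alleles[gene.chromosome]
        for s, e in gene.cds_intervals:
            lo, hi = np.searchsorted(pos, [s, e])
            for i in range(lo, hi):
                yield int(pos[i]), str(ca[i]), str(ea[i])

    def ref_base(self, chrom: str, pos: int) -> str | None:
        arr = self.positions.get(chrom)
        if arr is None:
            return None
        i = int(np.searchsorted(arr, pos))
        if i < arr.size and arr[i] == pos:
            return str(self.c_alleles[chrom][i])
        return None


@dataclass(frozen=True)
class SharedAlleleCount:
    gene_id: str
    n_shared_C: int
    n_shared_E: int
    n_informative: int

    def __post_init__(self):
        if max(self.n_shared_C, self.n_shared_E) > self.n_informative:
            raise ValueError("shared counts cannot exceed informative positions")


def pooled_allele_map(
    libs: Sequence[tuple[list[SnpRecord], DepthTrack]],
    catalog: ProgenitorCatalog,
    min_total_depth: int,
) -> dict[str, dict[int, frozenset[str]]]:
    """Observed alleles per catalog position, pooled over libraries.

    A position enters the map only when the summed depth reaches
    ``min_total_depth``.  Alleles with at least one supporting read in
    any library count as present; coverage without a variant record
    contributes the reference (C-progenitor) allele.
    """
    rec_by_pos: dict[str, dict[int, set[str]]] = {}
    lib_rec_pos: list[dict[str, set[int]]] = []
    for records, _ in libs:
        seen: dict[str, set[int]] = {}
        for r in records:
            bases = (r.ref_allele,) + r.alt_alleles
            present = rec_by_pos.setdefault(r.chrom, {}).setdefault(r.pos, set())
            if r.allelic_depths:
                for base, reads in zip(bases, r.allelic_depths):
                    if reads > 0:
                        present.add(base)
            else:
                present.update(bases[g] for g in r.genotype)
            seen.setdefault(r.chrom, set()).add(r.pos)
        lib_rec_pos.append(seen)

    out: dict[str, dict[int, frozenset[str]]] = {}
    for chrom, positions in catalog.positions.items():
        tracks = [t[chrom] if chrom in t else None for _, t in libs]
        if all(t is None for t in tracks):
            continue
        chrom_out: dict[int, frozenset[str]] = {}
        recs = rec_by_pos.get(chrom, {})
        for i, pos in enumerate(positions):
            pos = int(pos)
            total = sum(int(t[pos]) for t in tracks if t is not None)
            if total < min_total_depth:
                continue
            alleles = set(recs.get(pos, ()))
            # a library covering the site without a variant record saw only
            # reference-matching reads
            for t, seen in zip(tracks, lib_rec_pos):
                if t is not None and t[pos] > 0 and pos not in seen.get(chrom, ()):
                    alleles.add(str(catalog.c_alleles[chrom][i]))
                    break
            chrom_out[pos] = frozenset(alleles)
        out[chrom] = chrom_out
    return out


def count_shared_alleles(
    gene: GeneModel,
    allele_map: Mapping[int, frozenset[str]],
    catalog: ProgenitorCatalog,
) -> SharedAlleleCount:
    """Count catalog positions in the gene sharing each progenitor's allele.

    ``allele_map`` holds the allotetraploid's observed alleles at
    depth-passing catalog positions (DNA alleles for loss events,
    expressed RNA alleles for silencing).  A biallelic position
    increments both counters; uncovered positions are skipped.
    """
    n_c = n_e = n_inf = 0
    for pos, c_allele, e_allele in catalog.in_gene(gene):
        alleles = allele_map.get(pos)
        if alleles is None:
            continue
        n_inf += 1
        if c_allele in alleles:
            n_c += 1
        if e_allele in alleles:
            n_e += 1
    return SharedAlleleCount(gene.gene_id, n_c, n_e, n_inf)


def attribute_subgenome(count: SharedAlleleCount, min_diff: int = 3) -> str:
    """Subgenome of the progenitor with the smaller shared-allele count.

    Its alleles are the missing/silenced ones.  Differences below
    ``min_diff`` (ties included) are not determined ("ND").
    """
    if abs(count.n_shared_C - count.n_shared_E) < min_diff:
        return "ND"
    return "Ca" if count.n_shared_C < count.n_shared_E else "Ea"


def attribute_events(
    fates: Mapping[str, FateCall],
    genes: Sequence[GeneModel],
    catalog: ProgenitorCatalog,
    dna_allele_map: Mapping[str, Mapping[int, frozenset[str]]],
    rna_allele_map: Mapping[str, Mapping[int, frozenset[str]]],
    min_diff: int = 3,
) -> dict[str, SharedAlleleCount]:
    """Fill in ``FateCall.subgenome`` for loss and silencing events.

    Loss events read the DNA allele map; silencing events the RNA
    (expressed-allele) map.  Returns the per-gene counts used.
    """
    by_id = {g.gene_id: g for g in genes}
    counts: dict[str, SharedAlleleCount] = {}
    for gid, call in fates.items():
        if call.fate.startswith("loss_"):
            amap = dna_allele_map
        elif call.fate == "retained_silenced":
            amap = rna_allele_map
        else:
            continue
        gene = by_id[gid]
        count = count_shared_alleles(gene, amap.get(gene.chromosome, {}), catalog)
        counts[gid] = count
        call.subgenome = attribute_subgenome(count, min_diff)
    return counts


def subgenome_summary(
    attributions_by_accession: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Per-accession and shared/specific subgenome splits of attributed events.

    Input maps accession -> {gene_id -> "Ca"/"Ea"/"ND"}.  The shared row
    covers genes with an event in every accession; percentages are among
    determined (non-ND) events, displayed as whole percents.
    """
    accs = list(attributions_by_accession)
    rows = []

    def _row(label: str, gene_ids: Iterable[str], source: Mapping[str, str]):
        gene_ids = list(gene_ids)
        ca = sum(source[g] == "Ca" for g in gene_ids)
        ea = sum(source[g] == "Ea" for g in gene_ids)
        nd = sum(source[g] == "ND" for g in gene_ids)
        det = ca + ea
        rows.append(
            {
                "group": label,
                "n_events": len(gene_ids),
                "Ca": ca,
                "Ea": ea,
                "ND": nd,
                "Ca_pct_of_determined": float(round(100.0 * ca / det)) if det else None,
            }
        )

    for acc in accs:
        _row(acc, attributions_by_accession[acc], attributions_by_accession[acc])
    if len(accs) >= 2:
        shared = set.intersection(*(set(attributions_by_accession[a]) for a in accs))
        first = attributions_by_accession[accs[0]]
        _row("shared", shared, first)
        not_shared = set(first) - shared
        _row("not_shared", not_shared, first)
    return pd.DataFrame(rows)
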