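"""End-to-end orchestration: simulate -> scan -> classify -> attribute ->
enrich -> report.

Each accession is an independent observation (its own read-sampling
stream) of the same simulated truth, mirroring a study design where two
accessions of the same allopolyploid are sequenced and compared.  Every
stage persists a TSV so each number in the final report is traceable to
an intermediate file; the report itself only reformats and rounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import enrichment as enr
from . import gene_fate as gf
from . import hsd_scan as hsd
from . import subgenome as sg
from . import synthetic_data as sd
from .variant_io import DepthTrack, GeneModel, SnpRecord, write_bed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    scan_params: hsd.ScanParams = field(default_factory=hsd.ScanParams)
    thresholds: gf.DepthThresholds = field(default_factory=gf.DepthThresholds)
    accessions: tuple[str, ...] = ("acc1", "acc2")
    attribution_min_diff: int = 3
    loss_region_min_genes: int = 3
    coverage_min_genes: int = 100
    enrichment_test: str = "silencing_shared"  # which event set to enrich
    write_files: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = dict(raw.get("simulate", {}))
        if "hee_regions" in sim_raw:
            sim_raw["hee_regions"] = tuple(
                sd.HeeRegion(str(r[0]), int(r[1]), int(r[2]), str(r[3]))
                for r in sim_raw["hee_regions"]
            )
        if "go_biases" in sim_raw:
            sim_raw["go_biases"] = tuple(
                sd.GoBias(str(b[0]), str(b[1]), float(b[2])) for b in sim_raw["go_biases"]
            )
        return cls(
            sim=sd.SimConfig(**sim_raw),
            scan_params=hsd.ScanParams(**raw.get("scan", {})),
            thresholds=gf.DepthThresholds(**raw.get("thresholds", {})),
            accessions=tuple(raw.get("accessions", ("acc1", "acc2"))),
            attribution_min_diff=int(raw.get("attribution_min_diff", 3)),
            loss_region_min_genes=int(raw.get("loss_region_min_genes", 3)),
            coverage_min_genes=int(raw.get("coverage_min_genes", 100)),
            enrichment_test=str(raw.get("enrichment_test", "silencing_shared")),
        )


@dataclass
class AccessionResult:
    accession: str
    windows: list[hsd.WindowStat]
    hsd_regions: list[hsd.HsdRegion]
    genome_density: float
    summaries: dict[str, gf.GeneSnpSummary]
    coverage_model: gf.CoverageModel
    fates: dict[str, gf.FateCall]
    shared_counts: dict[str, sg.SharedAlleleCount]


@dataclass
class PipelineResults:
    config: PipelineConfig
    truth: sd.TruthSet
    accessions: dict[str, AccessionResult]
    joint_universe: set[str]
    loss_summary: dict | None
    silencing_summary: dict | None
    loss_regions: dict[str, pd.DataFrame]
    subgenome_tables: dict[str, pd.DataFrame]
    enrichment_rows: list[enr.EnrichmentRow] | None
    report: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def analyze_accession(
    accession: str,
    truth: sd.TruthSet,
    config: PipelineConfig,
    dna_records: list[SnpRecord],
    dna_depth: DepthTrack,
    rna: sd.RnaObservations,
    catalog: sg.ProgenitorCatalog,
) -> AccessionResult:
    """Scan + classify + attribute for one accession's observations."""
    windows, regions, p0 = hsd.scan(dna_records, dna_depth, config.scan_params)
    summaries = gf.summarize_genes(
        truth.genes,
        dna_records,
        dna_depth,
        rna.diploid[0],
        rna.diploid[1],
        rna.allo_libraries,
        config.thresholds,
    )
    gene_depths = {
        gid: s.mean_dna_depth for gid, s in summaries.items() if s.informative
    }
    model = gf.fit_coverage_model(gene_depths, min_genes=config.coverage_min_genes)
    fates = gf.classify_all(summaries, model, config.thresholds)
    dna_map = sg.pooled_allele_map(
        [(dna_records, dna_depth)], catalog, config.thresholds.dna_4x_min
    )
    rna_map = sg.pooled_allele_map(
        rna.allo_libraries, catalog, config.thresholds.rna_4x_min
    )
    counts = sg.attribute_events(
        fates, truth.genes, catalog, dna_map, rna_map, config.attribution_min_diff
    )
    return AccessionResult(
        accession=accession,
        windows=windows,
        hsd_regions=regions,
        genome_density=p0,
        summaries=summaries,
        coverage_model=model,
        fates=fates,
        shared_counts=counts,
    )


def contiguous_loss_regions(
    fates: Mapping[str, gf.FateCall],
    genes: Sequence[GeneModel],
    min_genes: int = 3,
) -> pd.DataFrame:
    """Runs of consecutive loss genes along each chromosome.

    A retained gene terminates a run; uninformative genes neither extend
    nor break it (a cluster is bounded by genes known to keep both
    homeologs, not by genes we could not classify).
    """
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        run: list[GeneModel] = []

        def _flush(run):
            if len(run) >= min_genes:
                rows.append(
                    {
                        "chrom": chrom,
                        "n_genes": len(run),
                        "first_gene": run[0].gene_id,
                        "last_gene": run[-1].gene_id,
                        "start": run[0].start,
                        "end": run[-1].end,
                        "size_kb": round((run[-1].end - run[0].start) / 1000.0, 1),
                    }
                )

        for g in chrom_genes:
            fate = fates.get(g.gene_id)
            if fate is None or fate.fate == "uninformative":
                continue
            if fate.fate.startswith("loss_"):
                run.append(g)
            else:
                _flush(run)
                run = []
        _flush(run)
    return pd.DataFrame(
        rows, columns=["chrom", "n_genes", "first_gene", "last_gene", "start", "end", "size_kb"]
    )


def run_pipeline(
    config: PipelineConfig, out_dir=None, force: bool = False
) -> PipelineResults:
    """Execute all stages; persists intermediates and a report under out_dir.

    With ``out_dir=None`` everything stays in memory.  With
    ``force=False`` an existing completed run (report.json present) keeps
    its files untouched; with ``force=True`` everything is rewritten
    (deterministically identical for the same config and seed).
    """
    cached = False
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cached = (out_dir / "report.json").exists() and not force

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    truth = _stage("simulate", sd.simulate_truth, config.sim)
    catalog = sg.ProgenitorCatalog.from_truth(truth)

    acc_results: dict[str, AccessionResult] = {}
    for stream, acc in enumerate(config.accessions):
        dna_records, dna_depth = _stage(
            "emit_dna", sd.emit_dna_observations, truth, config.sim, stream=stream
        )
        rna = _stage("emit_rna", sd.emit_rna_observations, truth, config.sim, stream=stream)
        acc_results[acc] = _stage(
            "analyze",
            analyze_accession,
            acc, truth, config, dna_records, dna_depth, rna, catalog,
        )

    # joint gene universe: informative in every accession
    joint = set.intersection(
        *(
            {g for g, f in res.fates.items() if f.fate != "uninformative"}
            for res in acc_results.values()
        )
    )
    joint_fates = {
        acc: {g: res.fates[g] for g in joint} for acc, res in acc_results.items()
    }

    loss_summary = silencing_summary = None
    subgenome_tables: dict[str, pd.DataFrame] = {}
    if len(config.accessions) >= 2:
        loss_summary = _stage(
            "summaries", gf.cross_accession_summary, joint_fates, gf.LOSS_FATES
        )
        silencing_summary = _stage(
            "summaries", gf.cross_accession_summary, joint_fates, ("retained_silenced",)
        )
        for label, fates_sel in (("loss", gf.LOSS_FATES), ("silencing", ("retained_silenced",))):
            attr = {
                acc: {
                    g: f.subgenome
                    for g, f in fates.items()
                    if f.fate in fates_sel
                }
                for acc, fates in joint_fates.items()
            }
            subgenome_tables[label] = sg.subgenome_summary(attr)

    loss_regions = {
        acc: contiguous_loss_regions(
            joint_fates.get(acc, res.fates), truth.genes, config.loss_region_min_genes
        )
        for acc, res in acc_results.items()
    }

    annotations_df = _stage("annotations", sd.emit_annotations, truth, config.sim)
    annotations: dict[str, set[str]] = {}
    for gid, term in zip(annotations_df["gene_id"], annotations_df["go_id"]):
        annotations.setdefault(gid, set()).add(term)

    enrichment_rows = None
    if loss_summary is not None:
        test_sets = {
            "silencing_shared": silencing_summary["shared_gene_ids"],
            "silencing_union": silencing_summary["union_gene_ids"],
            "loss_shared": loss_summary["shared_gene_ids"],
            "loss_union": loss_summary["union_gene_ids"],
        }
        test = test_sets.get(config.enrichment_test, [])
        if test:
            enrichment_rows = _stage(
                "enrich", enr.enrich_groups, test, joint, annotations
            )
        else:
            logger.info("enrichment skipped: empty test set %s", config.enrichment_test)

    report = _build_report(
        config, acc_results, joint, loss_summary, silencing_summary,
        subgenome_tables, loss_regions, enrichment_rows,
    )

    results = PipelineResults(
        config=config,
        truth=truth,
        accessions=acc_results,
        joint_universe=joint,
        loss_summary=loss_summary,
        silencing_summary=silencing_summary,
        loss_regions=loss_regions,
        subgenome_tables=subgenome_tables,
        enrichment_rows=enrichment_rows,
        report=report,
    )
    if out_dir is not None and config.write_files and not cached:
        _persist(results, out_dir)
    return results


def _build_report(
    config, acc_results, joint, loss_summary, silencing_summary,
    subgenome_tables, loss_regions, enrichment_rows,
) -> dict:
    def _strip(summary):
        if summary is None:
            return None
        return {k: v for k, v in summary.items() if not k.endswith("gene_ids")}

    report = {
        "accessions": list(acc_results),
        "n_genes_analyzed": len(joint),
        "hsd": {
            acc: {
                "n_regions": len(res.hsd_regions),
                "region_sizes_kb": [round(r.size_kb, 1) for r in res.hsd_regions],
                "genome_snp_density": round(res.genome_density, 6),
            }
            for acc, res in acc_results.items()
        },
        "loss": _strip(loss_summary),
        "silencing": _strip(silencing_summary),
        "subgenome": {
            label: table.to_dict(orient="records")
            for label, table in subgenome_tables.items()
        },
        "loss_regions": {
            acc: df.to_dict(orient="records") for acc, df in loss_regions.items()
        },
        "enrichment_top": [
            {
                "go_id": r.go_id, "p_value": r.p_value, "fdr": r.fdr,
                "direction": r.direction, "test": r.a, "ref": r.b,
            }
            for r in (enrichment_rows or [])[:10]
        ],
    }
    return report


def _persist(results: PipelineResults, out_dir: Path) -> None:
    for acc, res in results.accessions.items():
        acc_dir = out_dir / acc
        acc_dir.mkdir(exist_ok=True)
        hsd.windows_to_frame(res.windows).to_csv(
            acc_dir / "windows.tsv", sep="\t", index=False
        )
        hsd.regions_to_frame(res.hsd_regions).to_csv(
            acc_dir / "hsd_regions.tsv", sep="\t", index=False
        )
        write_bed(
            [
                (r.chrom, r.start, r.end, f"HSD_{i + 1}")
                for i, r in enumerate(res.hsd_regions)
            ],
            acc_dir / "hsd_regions.bed",
        )
        gf.summaries_to_frame(res.summaries, res.fates).to_csv(
            acc_dir / "gene_fates.tsv", sep="\t", index=False
        )
        results.loss_regions[acc].to_csv(
            acc_dir / "loss_regions.tsv", sep="\t", index=False
        )
    for label, table in results.subgenome_tables.items():
        table.to_csv(out_dir / f"subgenome_{label}.tsv", sep="\t", index=False)
    if results.enrichment_rows is not None:
        enr.enrichment_to_frame(results.enrichment_rows).to_csv(
            out_dir / "enrichment.tsv", sep="\t", index=False
        )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(results.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
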