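"""Worked examples and parameter-recovery experiments.

Two kinds of validation live here.  The worked examples recompute, from
published count tables of the allotetraploid coffee (*Coffea arabica*)
silencing/loss study design this package implements, the statistics a
user can check by hand: Fisher's exact p-values for GO depletion among
silenced homeologs, their BH-adjusted FDR column, and the shared /
union / subgenome arithmetic of the two-accession event comparison.
The recovery experiments run the full machinery on synthetic
allotetraploid data and measure how reliably known homeologous exchange
tracts, conversions, deletions and silencings are recovered.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from . import gene_fate as gf
from . import hsd_scan as hsd
from . import subgenome as sg
from . import synthetic_data as sd
from .pipeline import PipelineConfig, analyze_accession, run_pipeline
from .stats import adjust_pvalues_bh, fisher_exact_2x2

# ---------------------------------------------------------------------------
# Worked-example inputs: GO depletion table among silenced homeologs shared by
# two C. arabica accessions (go_id, test, ref, notAnnotTest, notAnnotRef),
# ordered by p-value.  The test set holds 66 genes; the annotated reference
# universe 7875.  The FDR column was computed over 230 tested terms.

SILENCING_GO_TABLE: tuple[tuple[str, int, int, int, int], ...] = (
    ("GO:0043229", 13, 3977, 53, 3898),
    ("GO:0043226", 13, 3977, 53, 3898),
    ("GO:0043227", 13, 3881, 53, 3994),
    ("GO:0043231", 13, 3881, 53, 3994),
    ("GO:0005623", 24, 5116, 42, 2759),
    ("GO:0044464", 24, 5098, 42, 2777),
    ("GO:0044424", 19, 4510, 47, 3365),
    ("GO:0034641", 2, 1852, 64, 6023),
    ("GO:0005622", 21, 4679, 45, 3196),
    ("GO:0006725", 2, 1720, 64, 6155),
    ("GO:1901360", 2, 1720, 64, 6155),
    ("GO:0046483", 2, 1720, 64, 6155),
    ("GO:0006139", 2, 1720, 64, 6155),
    ("GO:0005634", 2, 1413, 64, 6462),
    ("GO:0044444", 14, 3281, 52, 4594),
    ("GO:0010467", 0, 912, 66, 6963),
    ("GO:0003676", 1, 1146, 65, 6729),
    ("GO:0034645", 0, 860, 66, 7015),
    ("GO:0044249", 0, 860, 66, 7015),
    ("GO:0009059", 0, 860, 66, 7015),
    ("GO:0044271", 0, 860, 66, 7015),
    ("GO:1901576", 0, 861, 66, 7014),
    ("GO:0006807", 7, 2175, 59, 5700),
    ("GO:0005737", 19, 3719, 47, 4156),
    ("GO:0044237", 14, 3065, 52, 4810),
)
GO_TERM_UNIVERSE = 230

# Two-accession event counts (AR41, Caturra, shared) over 9047 analyzed genes,
# and the subgenome split of the shared losses.
ANALYZED_GENES = 9047
LOSS_COUNTS = {"AR41": 174, "Caturra": 148, "shared": 143}
SILENCING_COUNTS = {"AR41": 120, "Caturra": 116, "shared": 80}
SHARED_LOSS_SUBGENOMES = {"Ca": 108, "Ea": 25, "ND": 10}


def _two_accession_fates(
    counts: Mapping[str, int], event_fate: str, universe: int
) -> dict[str, dict[str, gf.FateCall]]:
    """Build fate maps over a synthetic gene universe with the given
    per-accession / shared event counts."""
    genes = [f"g{i:05d}" for i in range(universe)]
    n_a, n_b, n_shared = counts["AR41"], counts["Caturra"], counts["shared"]
    set_a = set(genes[:n_a])  # shared block first
    set_b = set(genes[:n_shared]) | set(genes[n_a : n_a + (n_b - n_shared)])
    out = {}
    for acc, events in (("AR41", set_a), ("Caturra", set_b)):
        out[acc] = {
            g: gf.FateCall(g, event_fate if g in events else "retained_expressed")
            for g in genes
        }
    return out


def worked_example_stats() -> dict[str, float]:
    """Recompute the hand-checkable statistics from the published counts."""
    pvals = [fisher_exact_2x2(a, b, c, d)[0] for _, a, b, c, d in SILENCING_GO_TABLE]
    fdrs = adjust_pvalues_bh(pvals, m=GO_TERM_UNIVERSE)
    by_term = {row[0]: (p, q) for row, p, q in zip(SILENCING_GO_TABLE, pvals, fdrs)}

    loss = gf.cross_accession_summary(
        _two_accession_fates(LOSS_COUNTS, "loss_unresolved", ANALYZED_GENES),
        gf.LOSS_FATES,
    )
    sil = gf.cross_accession_summary(
        _two_accession_fates(SILENCING_COUNTS, "retained_silenced", ANALYZED_GENES),
        ("retained_silenced",),
    )

    shared_attr = {}
    i = 0
    for subg, n in SHARED_LOSS_SUBGENOMES.items():
        for _ in range(n):
            shared_attr[f"g{i:05d}"] = subg
            i += 1
    subg_table = sg.subgenome_summary({"shared_losses": shared_attr})
    ca_pct = float(subg_table.iloc[0]["Ca_pct_of_determined"])

    return {
        "fisher_p_organelle": by_term["GO:0043229"][0],
        "fisher_p_membrane_organelle": by_term["GO:0043227"][0],
        "fisher_p_cell": by_term["GO:0005623"][0],
        "fisher_p_intracellular_part": by_term["GO:0044424"][0],
        "fisher_fdr_organelle": float(by_term["GO:0043229"][1]),
        "fisher_fdr_cell": float(by_term["GO:0005623"][1]),
        "loss_union": float(loss["union"]),
        "loss_shared_pct": float(loss["shared_pct"]),
        "loss_pct_of_analyzed": float(loss["union_pct_of_universe"]),
        "silencing_union": float(sil["union"]),
        "silencing_shared_pct": float(sil["shared_pct_1dp"]),
        "shared_loss_ca_pct": ca_pct,
    }


# ---------------------------------------------------------------------------
# Parameter-recovery experiments on synthetic data


def hsd_scan_config(seed: int) -> sd.SimConfig:
    """Two 1-Mb chromosomes carrying three exchange tracts (100, 60, 50 kb)."""
    return sd.SimConfig(
        n_chromosomes=2,
        chromosome_length=1_000_000,
        n_genes=100,
        hee_regions=(
            sd.HeeRegion("chr01", 200_000, 300_000, "Ca"),
            sd.HeeRegion("chr01", 600_000, 660_000, "Ea"),
            sd.HeeRegion("chr02", 300_000, 350_000, "Ca"),
        ),
        seed=seed,
    )


def hsd_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict[str, float]:
    """Sensitivity and boundary accuracy of HSD region calling.

    For each seed, a genome with three exchange tracts (>= the 50 kb
    resolution floor) is scanned at default thresholds.  A tract counts
    as detected when a called region overlaps it; boundary error is the
    worst per-edge distance in windows among detected tracts.
    """
    params = hsd.ScanParams()
    n_tracts = n_detected = n_false = 0
    worst_boundary = 0.0
    for s in range(n_seeds):
        config = hsd_scan_config(base_seed + s)
        truth = sd.simulate_truth(config)
        records, depth = sd.emit_dna_observations(truth, config)
        _, regions, _ = hsd.scan(records, depth, params)
        matched = set()
        for tract in truth.hee_regions:
            n_tracts += 1
            for i, reg in enumerate(regions):
                if reg.chrom == tract.chrom and reg.start < tract.end and tract.start < reg.end:
                    n_detected += 1
                    matched.add(i)
                    err = max(abs(reg.start - tract.start), abs(reg.end - tract.end))
                    worst_boundary = max(worst_boundary, err / params.window_size)
                    break
        n_false += len(regions) - len(matched)
    return {
        "sensitivity": n_detected / n_tracts,
        "max_boundary_error_windows": worst_boundary,
        "false_regions_total": float(n_false),
        "n_tracts": float(n_tracts),
    }


def fate_config(seed: int) -> sd.SimConfig:
    """300 3-kb genes on two chromosomes with injected events."""
    return sd.SimConfig(
        n_chromosomes=2,
        chromosome_length=600_000,
        n_genes=300,
        conversion_genes=20,
        deletion_genes=12,
        silenced_genes=20,
        seed=seed,
    )


def fate_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict[str, float]:
    """Recovery of simulated conversions, deletions and silencings.

    Runs the per-accession analysis (SNP summaries, coverage model,
    decision tree, subgenome attribution) on default-condition synthetic
    accessions and tallies sensitivity, false-call rates among truly
    retained genes, deletion-vs-homogenization accuracy, and attribution
    accuracy on events with enough informative positions.
    """
    cfg = PipelineConfig()
    tot = {
        "loss_true": 0, "loss_called": 0,
        "sil_true": 0, "sil_called": 0,
        "retained_true": 0, "false_loss": 0, "false_sil": 0,
        "del_called_loss": 0, "del_correct": 0,
        "conv_called_loss": 0, "conv_correct": 0,
        "attr_eligible": 0, "attr_correct": 0,
    }
    for s in range(n_seeds):
        sim = fate_config(base_seed + s)
        cfg_s = dataclasses.replace(cfg, sim=sim)
        truth = sd.simulate_truth(sim)
        records, depth = sd.emit_dna_observations(truth, sim)
        rna = sd.emit_rna_observations(truth, sim)
        catalog = sg.ProgenitorCatalog.from_truth(truth)
        res = analyze_accession("acc", truth, cfg_s, records, depth, rna, catalog)
        for gid, label in truth.gene_labels.items():
            fate = res.fates[gid]
            is_loss_truth = label.startswith(("conversion", "deletion"))
            if is_loss_truth:
                tot["loss_true"] += 1
                if fate.fate.startswith("loss_"):
                    tot["loss_called"] += 1
                    if label.startswith("deletion"):
                        tot["del_called_loss"] += 1
                        tot["del_correct"] += fate.fate == "loss_deletion"
                    else:
                        tot["conv_called_loss"] += 1
                        tot["conv_correct"] += fate.fate == "loss_homogenization"
            elif label.startswith("silenced"):
                tot["sil_true"] += 1
                tot["sil_called"] += fate.fate == "retained_silenced"
            else:
                tot["retained_true"] += 1
                tot["false_loss"] += fate.fate.startswith("loss_")
                tot["false_sil"] += fate.fate == "retained_silenced"
            if is_loss_truth or label.startswith("silenced"):
                count = res.shared_counts.get(gid)
                called_event = fate.fate.startswith("loss_") or fate.fate == "retained_silenced"
                if count is not None and called_event and count.n_informative >= 3:
                    tot["attr_eligible"] += 1
                    tot["attr_correct"] += fate.subgenome == sd.lost_subgenome(label)
    return {
        "loss_sensitivity": tot["loss_called"] / tot["loss_true"],
        "silencing_sensitivity": tot["sil_called"] / tot["sil_true"],
        "false_loss_rate": tot["false_loss"] / tot["retained_true"],
        "false_silencing_rate": tot["false_sil"] / tot["retained_true"],
        "deletion_mechanism_accuracy": tot["del_correct"] / max(tot["del_called_loss"], 1),
        "conversion_mechanism_accuracy": tot["conv_correct"] / max(tot["conv_called_loss"], 1),
        "attribution_accuracy": tot["attr_correct"] / max(tot["attr_eligible"], 1),
        "n_events_total": float(tot["loss_true"] + tot["sil_true"]),
    }


def zero_event_config(seed: int) -> sd.SimConfig:
    return sd.SimConfig(
        n_chromosomes=2, chromosome_length=300_000, n_genes=120, seed=seed
    )


def zero_event_check(n_seeds: int = 20, base_seed: int = 1) -> dict[str, float]:
    """False positives of every kind under event-free simulations."""
    n_regions = n_loss = n_sil = 0
    for s in range(n_seeds):
        cfg = PipelineConfig(sim=zero_event_config(base_seed + s))
        results = run_pipeline(cfg, out_dir=None)
        for res in results.accessions.values():
            n_regions += len(res.hsd_regions)
            n_loss += sum(f.fate.startswith("loss_") for f in res.fates.values())
            n_sil += sum(f.fate == "retained_silenced" for f in res.fates.values())
    return {
        "hsd_regions": float(n_regions),
        "loss_calls": float(n_loss),
        "silencing_calls": float(n_sil),
        "n_seeds": float(n_seeds),
    }
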