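"""Simulator: truth assignment, generating distributions, determinism."""

import filecmp

import numpy as np
import pytest
from scipy.stats import binom

from homeoscan import synthetic_data as sd
from homeoscan.variant_io import gene_depth_summary


class TestSimulateTruth:
    def test_zero_event_config_all_retained(self):
        config = sd.SimConfig(n_chromosomes=1, chromosome_length=60_000, n_genes=10, seed=1)
        truth = sd.simulate_truth(config)
        assert set(truth.gene_labels.values()) == {sd.RETAINED}

    def test_interspecific_snp_count_in_binomial_band(self):
        # per-bp divergence drives a binomial count over the CDS footprint
        config = sd.SimConfig(
            n_chromosomes=2, chromosome_length=600_000, n_genes=300, seed=3
        )
        truth = sd.simulate_truth(config)
        cds_total = sum(g.cds_length for g in truth.genes)
        n_in_cds = 0
        for g in truth.genes:
            pos = truth.snp_positions[g.chromosome]
            for s, e in g.cds_intervals:
                lo, hi = np.searchsorted(pos, [s, e])
                n_in_cds += hi - lo
        lo, hi = binom.ppf([0.005, 0.995], cds_total, config.divergence)
        assert lo <= n_in_cds <= hi

    def test_genes_inside_hee_tract_labeled_converted(self):
        config = sd.SimConfig(
            n_chromosomes=1,
            chromosome_length=300_000,
            n_genes=40,
            hee_regions=(sd.HeeRegion("chr01", 100_000, 150_000, "Ea"),),
            seed=5,
        )
        truth = sd.simulate_truth(config)
        inside = [
            g.gene_id
            for g in truth.genes
            if 100_000 <= g.start and g.end <= 150_000
        ]
        assert inside  # a 50-kb tract covers several genes at this layout
        for gid in inside:
            assert truth.gene_labels[gid] == "conversion_to_Ea"

    def test_gene_models_tile_without_overlap(self, truth):
        for chrom in truth.chrom_lengths:
            genes = sorted(
                (g for g in truth.genes if g.chromosome == chrom), key=lambda g: g.start
            )
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start
            assert genes[-1].end <= truth.chrom_lengths[chrom]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"divergence": 0.0},
            {"dna_depth_mean": -1},
            {"hee_regions": (sd.HeeRegion("chr01", -5, 100, "Ca"),)},
            {"hee_regions": (sd.HeeRegion("chr99", 0, 100, "Ca"),)},
            {
                "hee_regions": (
                    sd.HeeRegion("chr01", 0, 20_000, "Ca"),
                    sd.HeeRegion("chr01", 10_000, 30_000, "Ea"),
                )
            },
            {"conversion_genes": {"chr01_g0001": "Ca"}, "deletion_genes": {"chr01_g0001": "Ea"}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        config = sd.SimConfig(
            n_chromosomes=1, chromosome_length=60_000, n_genes=10, **kwargs
        )
        with pytest.raises(sd.ConfigError):
            sd.simulate_truth(config)

    def test_too_many_event_genes_rejected(self):
        config = sd.SimConfig(
            n_chromosomes=1, chromosome_length=60_000, n_genes=10, silenced_genes=11
        )
        with pytest.raises(sd.ConfigError):
            sd.simulate_truth(config)


class TestDnaObservations:
    def test_deleted_gene_depth_near_half(self, truth, small_config, dna_obs):
        _, depth = dna_obs
        means = gene_depth_summary(depth, truth.genes)
        for gid in truth.genes_with_label("deletion_"):
            assert means[gid] == pytest.approx(small_config.dna_depth_mean / 2, abs=5)
        for gid in truth.genes_with_label(sd.RETAINED):
            assert means[gid] == pytest.approx(small_config.dna_depth_mean, abs=10)

    def test_retained_gene_het_records_with_balanced_alleles(self, truth, dna_obs):
        records, _ = dna_obs
        by_pos = {(r.chrom, r.pos): r for r in records}
        fractions = []
        n_expected = n_found = 0
        for gid in truth.genes_with_label(sd.RETAINED):
            g = truth.genes_by_id()[gid]
            pos = truth.snp_positions[g.chromosome]
            for p in pos[(pos >= g.start) & (pos < g.end)]:
                n_expected += 1
                rec = by_pos.get((g.chromosome, int(p)))
                if rec is not None and rec.is_het:
                    n_found += 1
                    fractions.append(rec.allelic_depths[1] / rec.total_depth)
        assert n_found >= 0.95 * n_expected  # hom miscalls are rare at 40x
        # pooled alternate-allele fraction concentrates at 1/2
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.03)

    def test_tract_converted_to_reference_has_no_records(self):
        config = sd.SimConfig(
            n_chromosomes=1,
            chromosome_length=300_000,
            n_genes=40,
            hee_regions=(sd.HeeRegion("chr01", 100_000, 200_000, "Ca"),),
            seed=9,
        )
        truth = sd.simulate_truth(config)
        records, _ = sd.emit_dna_observations(truth, config)
        assert not any(100_000 <= r.pos < 200_000 for r in records)
        assert any(r.pos < 100_000 for r in records)  # signal outside the tract

    def test_tract_converted_to_other_subgenome_is_homozygous_alt(self):
        config = sd.SimConfig(
            n_chromosomes=1,
            chromosome_length=300_000,
            n_genes=40,
            hee_regions=(sd.HeeRegion("chr01", 100_000, 200_000, "Ea"),),
            seed=9,
        )
        truth = sd.simulate_truth(config)
        records, _ = sd.emit_dna_observations(truth, config)
        inside = [r for r in records if 100_000 <= r.pos < 200_000]
        assert inside
        assert all(r.genotype == (1, 1) for r in inside)


class TestRnaObservations:
    def test_silenced_gene_shows_single_homeolog(self, truth, rna_obs):
        by_id = truth.genes_by_id()
        for gid, label in truth.gene_labels.items():
            if not label.startswith("silenced_"):
                continue
            g = by_id[gid]
            for records, _ in rna_obs.allo_libraries:
                gene_records = [
                    r for r in records if g.start <= r.pos < g.end and r.chrom == g.chromosome
                ]
                if label == "silenced_Ea":  # only the reference homeolog expressed
                    assert gene_records == []
                else:  # only the alternate homeolog expressed
                    assert gene_records and all(r.genotype == (1, 1) for r in gene_records)

    def test_diploid_library_homozygous_alternate_when_covered(self, truth, rna_obs):
        records, depth = rna_obs.diploid
        assert records and all(r.genotype == (1, 1) for r in records)
        # every covered interspecific CDS position produced a record
        recorded = {(r.chrom, r.pos) for r in records}
        for g in truth.genes:
            pos = truth.snp_positions[g.chromosome]
            for s, e in g.cds_intervals:
                lo, hi = np.searchsorted(pos, [s, e])
                for p in pos[lo:hi]:
                    if depth[g.chromosome][int(p)] > 0:
                        assert (g.chromosome, int(p)) in recorded

    def test_expression_bias_recovered(self):
        config = sd.SimConfig(
            n_chromosomes=1,
            chromosome_length=300_000,
            n_genes=60,
            homeolog_bias=0.8,
            seed=13,
        )
        truth = sd.simulate_truth(config)
        rna = sd.emit_rna_observations(truth, config)
        ref_reads = alt_reads = 0
        for records, _ in rna.allo_libraries:
            for r in records:
                ref_reads += r.allelic_depths[0]
                alt_reads += r.allelic_depths[1]
        # mean reference-homeolog read fraction recovers the configured bias
        assert ref_reads / (ref_reads + alt_reads) == pytest.approx(0.8, abs=0.02)


class TestAnnotationsAndDeterminism:
    def test_annotated_genes_exist(self, truth, small_config):
        df = sd.emit_annotations(truth, small_config)
        gene_ids = {g.gene_id for g in truth.genes}
        assert set(df["gene_id"]) <= gene_ids
        assert df["go_id"].str.startswith("GO:").all()

    def test_go_bias_depletes_term(self):
        term = "GO:0000030"  # highest base rate in the ladder
        config = sd.SimConfig(
            n_chromosomes=1,
            chromosome_length=1_200_000,
            n_genes=300,
            silenced_genes=60,
            go_biases=(sd.GoBias(term, "silenced", 0.2),),
            seed=17,
        )
        truth = sd.simulate_truth(config)
        df = sd.emit_annotations(truth, config)
        silenced = set(truth.genes_with_label("silenced"))
        annotated = set(df.loc[df["go_id"] == term, "gene_id"])
        rate_sil = len(annotated & silenced) / len(silenced)
        rate_other = len(annotated - silenced) / (config.n_genes - len(silenced))
        assert rate_sil < rate_other

    def test_same_seed_byte_identical_bundles(self, truth, small_config, bundle, tmp_path):
        other = sd.write_bundle(truth, small_config, tmp_path / "again")
        for a, b in [
            (bundle.dna_vcf, other.dna_vcf),
            (bundle.dna_depth, other.dna_depth),
            (bundle.rna_vcfs[0], other.rna_vcfs[0]),
            (bundle.gff3, other.gff3),
            (bundle.go_annotations, other.go_annotations),
            (bundle.progenitor_catalog, other.progenitor_catalog),
            (bundle.truth_table, other.truth_table),
        ]:
            assert filecmp.cmp(a, b, shallow=False), f"{a.name} differs between runs"
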