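"""Decision tree, SNP counting, coverage model, cross-accession summaries."""

import numpy as np
import pytest

from homeoscan import gene_fate as gf
from homeoscan.variant_io import DepthTrack, GeneModel, SnpRecord


def _summary(snp2x=0, snp4x_d=0, snp4x_r=0, snp4x_d_rna=0,
             dna_rna_pos=(), rna_pos=(), **kw):
    return gf.GeneSnpSummary(
        gene_id="g",
        snp2x=snp2x,
        snp4x_d=snp4x_d,
        snp4x_r=snp4x_r,
        snp4x_d_rna=snp4x_d_rna,
        dna_rna_snp_positions=frozenset(dna_rna_pos),
        rna_snp_positions=frozenset(rna_pos),
        n_common_dna=kw.pop("n_common_dna", 2000),
        **kw,
    )


class TestLossRule:
    @pytest.mark.parametrize(
        "snp2x, snp4x_d, expected",
        [
            (8, 1, "loss"),  # >= fourfold drop with one residual homeologous SNP
            (4, 1, "loss"),  # minimal fourfold case
            (3, 1, "uninformative"),  # drop below fourfold, counts too low
            (3, 0, "loss"),  # null SNP4X-D needs SNP2X >= 3
            (2, 0, "uninformative"),  # below the resolution floor
            (10, 9, "retained"),
            (3, 3, "retained"),
            (10, 2, "uninformative"),  # strong drop but SNP4X-D > 1
        ],
    )
    def test_truth_table(self, snp2x, snp4x_d, expected):
        assert gf.classify_homeolog_loss(_summary(snp2x=snp2x, snp4x_d=snp4x_d)) == expected

    def test_uninformative_gene_stays_uninformative(self):
        s = _summary(snp2x=10, snp4x_d=0, informative=False)
        assert gf.classify_homeolog_loss(s) == "uninformative"


class TestSilencingRule:
    def test_no_rna_snps_is_silenced(self):
        s = _summary(snp4x_d_rna=5, snp4x_r=0, dna_rna_pos=(1, 2, 3, 4, 5))
        assert gf.classify_homeolog_silencing(s) == "silenced"

    def test_one_discordant_rna_snp_tolerated(self):
        s = _summary(snp4x_d_rna=5, snp4x_r=1, dna_rna_pos=(1, 2, 3, 4, 5), rna_pos=(99,))
        assert gf.classify_homeolog_silencing(s) == "silenced"

    def test_one_concordant_rna_snp_not_tolerated(self):
        s = _summary(snp4x_d_rna=5, snp4x_r=1, dna_rna_pos=(1, 2, 3, 4, 5), rna_pos=(3,))
        assert gf.classify_homeolog_silencing(s) == "uninformative"

    def test_full_concordance_is_both_expressed(self):
        pos = (1, 2, 3, 4, 5)
        s = _summary(snp4x_d_rna=5, snp4x_r=5, dna_rna_pos=pos, rna_pos=pos)
        assert gf.classify_homeolog_silencing(s) == "both_expressed"

    def test_too_few_dna_snps_uninformative(self):
        s = _summary(snp4x_d_rna=2, snp4x_r=0, dna_rna_pos=(1, 2))
        assert gf.classify_homeolog_silencing(s) == "uninformative"


class TestCountGeneSnps:
    def _setup(self):
        gene = GeneModel("g1", "chr01", ((0, 50), (60, 100)))
        L = 120
        dna_depth = np.full(L, 40, dtype=np.int32)
        dip_depth = np.full(L, 20, dtype=np.int32)
        rna_depth = np.full(L, 60, dtype=np.int32)
        return gene, dna_depth, dip_depth, rna_depth

    def test_low_dna_depth_position_removed_everywhere(self):
        gene, dna_depth, dip_depth, rna_depth = self._setup()
        dna_depth[10] = 11  # just under the DNA floor of 12
        s = gf.count_gene_snps(
            gene,
            dna_het_pos=np.array([10, 20]),
            diploid_nonref_pos=np.array([10, 20]),
            rna_biallelic_pos=np.array([10, 20]),
            dna_depth=dna_depth,
            diploid_depth=dip_depth,
            rna_pooled_depth=rna_depth,
        )
        assert s.n_common_dna == 89 and s.n_common_rna == 89
        assert s.snp2x == 1 and s.snp4x_d == 1 and s.snp4x_r == 1

    def test_zero_common_positions_uninformative(self):
        gene, dna_depth, dip_depth, rna_depth = self._setup()
        dip_depth[:] = 0
        s = gf.count_gene_snps(
            gene, np.array([20]), np.array([20]), np.array([20]),
            dna_depth, dip_depth, rna_depth,
        )
        assert s.n_common_dna == 0 and s.snp2x == 0

    def test_matches_bruteforce_on_fuzzed_input(self):
        rng = np.random.default_rng(41)
        thresholds = gf.DepthThresholds()
        for _ in range(10):
            gene = GeneModel("g", "chr01", ((0, 200), (250, 400)))
            dna_depth = rng.integers(0, 40, 450).astype(np.int32)
            dip_depth = rng.integers(0, 12, 450).astype(np.int32)
            rna_depth = rng.integers(0, 40, 450).astype(np.int32)
            dna_het = np.unique(rng.integers(0, 450, 60))
            dip_nonref = np.unique(rng.integers(0, 450, 60))
            rna_bi = np.unique(rng.integers(0, 450, 60))
            s = gf.count_gene_snps(
                gene, dna_het, dip_nonref, rna_bi, dna_depth, dip_depth, rna_depth
            )
            cds = [p for a, b in gene.cds_intervals for p in range(a, b)]
            common_dna = [
                p for p in cds
                if dna_depth[p] >= thresholds.dna_4x_min and dip_depth[p] >= thresholds.rna_2x_min
            ]
            common_rna = [
                p for p in cds
                if dna_depth[p] >= thresholds.dna_4x_min and rna_depth[p] >= thresholds.rna_4x_min
            ]
            assert s.n_common_dna == len(common_dna)
            assert s.snp2x == sum(p in set(dip_nonref.tolist()) for p in common_dna)
            assert s.snp4x_d == sum(p in set(dna_het.tolist()) for p in common_dna)
            assert s.snp4x_r == sum(p in set(rna_bi.tolist()) for p in common_rna)
            assert s.snp4x_d_rna == sum(p in set(dna_het.tolist()) for p in common_rna)

    def test_raising_dna_cutoff_never_gains_positions(self):
        rng = np.random.default_rng(42)
        gene = GeneModel("g", "chr01", ((0, 300),))
        dna_depth = rng.integers(0, 40, 300).astype(np.int32)
        other = np.full(300, 50, dtype=np.int32)
        prev = None
        for cutoff in (5, 12, 20, 30):
            s = gf.count_gene_snps(
                gene, np.array([]), np.array([]), np.array([]),
                dna_depth, other, other,
                gf.DepthThresholds(dna_4x_min=cutoff),
            )
            if prev is not None:
                assert s.n_common_dna <= prev
            prev = s.n_common_dna


class TestCoverageModel:
    def test_recovers_simulated_center(self):
        rng = np.random.default_rng(43)
        depths = {f"g{i}": float(d) for i, d in enumerate(rng.normal(40, 1.5, 500))}
        model = gf.fit_coverage_model(depths)
        assert 38 <= model.mu4 <= 42
        assert model.usable

    def test_robust_to_two_copy_contamination(self):
        rng = np.random.default_rng(44)
        clean = rng.normal(40, 1.5, 500)
        contaminated = np.concatenate([clean, rng.normal(20, 1.0, 25)])
        m_clean = gf.fit_coverage_model({f"g{i}": d for i, d in enumerate(clean)})
        m_cont = gf.fit_coverage_model({f"g{i}": d for i, d in enumerate(contaminated)})
        assert abs(m_cont.mu4 - m_clean.mu4) / m_clean.mu4 < 0.02

    def test_degenerate_scale_flagged_unusable(self):
        model = gf.fit_coverage_model({f"g{i}": 40.0 for i in range(200)})
        assert not model.usable
        assert gf.classify_loss_mechanism(20.0, model) == "unresolved"

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValueError):
            gf.fit_coverage_model({"g1": 40.0})


class TestLossMechanism:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(45)
        return gf.fit_coverage_model(
            {f"g{i}": float(d) for i, d in enumerate(rng.normal(40, 1.5, 500))}
        )

    def test_two_copy_depth_is_deletion(self, model):
        assert gf.classify_loss_mechanism(20.0, model) == "deletion"

    def test_four_copy_depth_is_homogenization(self, model):
        assert gf.classify_loss_mechanism(40.0, model) == "homogenization"

    def test_intermediate_depth_unresolved(self, model):
        assert gf.classify_loss_mechanism(30.0, model) == "unresolved"


class TestCrossAccession:
    def _fates(self, n_a, n_b, n_shared, universe=9047, fate="loss_unresolved"):
        genes = [f"g{i}" for i in range(universe)]
        a = set(genes[:n_a])
        b = set(genes[:n_shared]) | set(genes[n_a : n_a + n_b - n_shared])
        return {
            acc: {
                g: gf.FateCall(g, fate if g in s else "retained_expressed")
                for g in genes
            }
            for acc, s in (("A", a), ("B", b))
        }

    def test_loss_counts_union_and_shared_pct(self):
        out = gf.cross_accession_summary(self._fates(174, 148, 143), gf.LOSS_FATES)
        assert out["union"] == 179
        assert out["shared_pct"] == 80.0
        assert out["union_pct_of_universe"] == 2.0

    def test_silencing_counts(self):
        out = gf.cross_accession_summary(
            self._fates(120, 116, 80, fate="retained_silenced"), ("retained_silenced",)
        )
        assert out["union"] == 156
        assert out["shared_pct_1dp"] == 51.3

    def test_disjoint_sets(self):
        out = gf.cross_accession_summary(self._fates(10, 15, 0, universe=200), gf.LOSS_FATES)
        assert out["union"] == 25 and out["shared"] == 0

    def test_mismatched_universe_is_error(self):
        fates = self._fates(5, 5, 2, universe=100)
        del fates["B"]["g0"]
        with pytest.raises(ValueError):
            gf.cross_accession_summary(fates, gf.LOSS_FATES)

    def test_union_matches_inclusion_exclusion_fuzz(self):
        rng = np.random.default_rng(46)
        for _ in range(20):
            n_a, n_b = rng.integers(1, 50, 2)
            n_shared = int(rng.integers(0, min(n_a, n_b) + 1))
            out = gf.cross_accession_summary(
                self._fates(int(n_a), int(n_b), n_shared, universe=200), gf.LOSS_FATES
            )
            assert out["union"] == n_a + n_b - n_shared


class TestPerLibraryConsistency:
    def _inputs(self):
        gene = GeneModel("g1", "chr01", ((0, 100),))
        dna_records = [
            SnpRecord("chr01", p, "A", ("G",), 40, (20, 20), (0, 1)) for p in (10, 20, 30)
        ]
        dna_depth = DepthTrack({"chr01": np.full(100, 40, dtype=np.int32)})
        quiet = ([], DepthTrack({"chr01": np.full(100, 30, dtype=np.int32)}))
        return gene, dna_records, dna_depth, quiet

    def test_all_quiet_libraries_consistent(self):
        gene, dna_records, dna_depth, quiet = self._inputs()
        out = gf.per_library_consistency(
            [gene], [quiet, quiet, quiet], dna_records, dna_depth, ["g1"]
        )
        assert out == {"g1": "consistent"}

    def test_expressing_library_inconsistent(self):
        gene, dna_records, dna_depth, quiet = self._inputs()
        loud = (
            [SnpRecord("chr01", p, "A", ("G",), 30, (15, 15), (0, 1)) for p in (10, 20)],
            DepthTrack({"chr01": np.full(100, 30, dtype=np.int32)}),
        )
        out = gf.per_library_consistency(
            [gene], [quiet, loud], dna_records, dna_depth, ["g1"]
        )
        assert out == {"g1": "inconsistent"}

    def test_shallow_library_not_evaluable(self):
        gene, dna_records, dna_depth, quiet = self._inputs()
        shallow = ([], DepthTrack({"chr01": np.full(100, 5, dtype=np.int32)}))
        out = gf.per_library_consistency(
            [gene], [quiet, shallow], dna_records, dna_depth, ["g1"]
        )
        assert out == {"g1": "not_evaluable"}

    def test_single_library_is_error(self):
        gene, dna_records, dna_depth, quiet = self._inputs()
        with pytest.raises(ValueError):
            gf.per_library_consistency([gene], [quiet], dna_records, dna_depth, ["g1"])


class TestDecisionTreeOnSimulation:
    def test_every_gene_gets_exactly_one_fate(self, truth, small_config, dna_obs, rna_obs):
        records, depth = dna_obs
        summaries = gf.summarize_genes(
            truth.genes, records, depth,
            rna_obs.diploid[0], rna_obs.diploid[1], rna_obs.allo_libraries,
        )
        model = gf.fit_coverage_model(
            {g: s.mean_dna_depth for g, s in summaries.items()}, min_genes=20
        )
        fates = gf.classify_all(summaries, model)
        assert set(fates) == {g.gene_id for g in truth.genes}
        for call in fates.values():
            assert call.fate in gf.ALL_FATES

    def test_silenced_genes_recovered(self, truth, small_config, dna_obs, rna_obs):
        records, depth = dna_obs
        summaries = gf.summarize_genes(
            truth.genes, records, depth,
            rna_obs.diploid[0], rna_obs.diploid[1], rna_obs.allo_libraries,
        )
        model = gf.fit_coverage_model(
            {g: s.mean_dna_depth for g, s in summaries.items()}, min_genes=20
        )
        fates = gf.classify_all(summaries, model)
        for gid in truth.genes_with_label("silenced_"):
            assert fates[gid].fate == "retained_silenced"
        for gid in truth.genes_with_label("deletion_"):
            assert fates[gid].fate == "loss_deletion"
        for gid in truth.genes_with_label("conversion_"):
            assert fates[gid].fate == "loss_homogenization"
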