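"""VCF parsing, the filter cascade, LD pruning, intersection, density."""

import numpy as np
import pytest

import spinpop as sp
from spinpop.datasets import CASCADE_DEMO_SURVIVORS
from spinpop.variants import _maf, _r2_pair

from conftest import make_matrix

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf_text(tmp_path, body):
    path = tmp_path / "t.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVCF:
    def test_genotype_encoding_table(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:20\t1/1:20\t./.:0\n"
        gm = sp.read_vcf(write_vcf_text(tmp_path, body))
        assert gm.dosages[0, 0] == 1
        assert gm.dosages[1, 0] == 2
        assert gm.dosages[2, 0] == -1
        assert gm.depths[0, 0] == 20

    def test_site_classification(self, tmp_path):
        body = ("chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/1:9\n"
                "chr1\t200\t.\tA\tAT\t50\tPASS\t.\tGT:DP\t0/0:9\t0/0:9\t0/1:9\n"
                "chr1\t300\t.\tG\tA,T\t50\tPASS\t.\tGT:DP\t0/1:9\t0/2:9\t0/0:9\n")
        gm = sp.read_vcf(write_vcf_text(tmp_path, body))
        assert list(gm.sites["kind"]) == ["snp", "indel", "multiallelic"]
        assert gm.n_loci == 3
        # multiallelic dosage counts any non-reference allele
        assert gm.dosages[1, 2] == 1

    def test_empty_body(self, tmp_path):
        gm = sp.read_vcf(write_vcf_text(tmp_path, ""))
        assert gm.n_loci == 0
        assert gm.n_samples == 3

    def test_non_diploid_rejected_with_sample_name(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t0\t0/1\n"
        with pytest.raises(sp.variants.VCFParseError, match="S2"):
            sp.read_vcf(write_vcf_text(tmp_path, body))


class TestFilterCascade:
    def test_hand_counted_fixture(self, demo_matrix):
        panel = sp.filter_cascade(demo_matrix)
        assert panel.n_loci == CASCADE_DEMO_SURVIVORS["sites"]
        assert panel.n_samples == CASCADE_DEMO_SURVIVORS["samples"]
        out = panel.extract(demo_matrix)
        assert tuple(out.sites["pos"]) == \
            CASCADE_DEMO_SURVIVORS["site_positions"]

    def test_disabled_thresholds_identity(self, demo_matrix):
        params = sp.FilterParams(min_maf=None, min_qual=None, min_depth=None,
                                 max_site_missing=None,
                                 max_sample_missing=None,
                                 final_min_depth=None,
                                 final_max_site_missing=None,
                                 final_min_maf=None)
        gm = make_matrix([[0, 1], [1, 2], [2, 0]])
        panel = sp.filter_cascade(gm, params)
        assert panel.n_loci == 2 and panel.n_samples == 3

    def test_maf_boundary_half(self):
        # only exactly balanced sites survive a 0.5 MAF floor
        gm = make_matrix([[0, 0, 2], [2, 1, 2], [1, 0, 0], [1, 1, 0]])
        params = sp.FilterParams(min_maf=0.5, min_qual=None, min_depth=None,
                                 max_site_missing=None,
                                 max_sample_missing=None,
                                 final_min_depth=None,
                                 final_max_site_missing=None,
                                 final_min_maf=None)
        panel = sp.filter_cascade(gm, params)
        mafs = _maf(gm.dosages)
        assert set(panel.loci) == set(np.where(mafs == 0.5)[0])

    def test_monotone_provenance_and_idempotence(self, demo_matrix):
        panel = sp.filter_cascade(demo_matrix)
        for step in panel.provenance:
            assert step.loci_out <= step.loci_in
            assert step.samples_out <= step.samples_in
        again = sp.filter_cascade(panel.extract(demo_matrix))
        assert again.n_loci == panel.n_loci
        assert again.n_samples == panel.n_samples

    def test_all_removed_is_empty_panel_not_error(self):
        gm = make_matrix([[0, 0], [0, 0]])  # monomorphic -> MAF filter
        panel = sp.filter_cascade(gm)
        assert panel.n_loci == 0
        assert len(panel.provenance) > 0


class TestLDPrune:
    def test_duplicate_locus_one_survives(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        gm = make_matrix(np.column_stack([col, col, 2 - col]))
        panel = sp.VariantPanel.full(gm)
        pruned = sp.ld_prune(gm, panel, window_snps=10, step=1, r2_max=0.2)
        assert pruned.n_loci == 1  # all three columns are perfectly correlated

    def test_r2_max_one_no_pruning(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        gm = make_matrix(np.column_stack([col, col]))
        pruned = sp.ld_prune(gm, sp.VariantPanel.full(gm), r2_max=1.0)
        assert pruned.n_loci == 2

    def test_independent_loci_survive(self):
        cfg = sp.SimConfig(n_pops=1, n_per_pop=200, n_loci=60,
                           chrom_lengths=(10_000_000,), F=0.01, seed=31)
        gm, _ = sp.simulate_genotypes(cfg)
        pruned = sp.ld_prune(gm, sp.VariantPanel.full(gm))
        assert pruned.n_loci >= 55  # independent loci: r2 ~ 1/n, tiny

    def test_no_surviving_pair_exceeds_threshold(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        sub = gm.take(loci=np.arange(60))
        pruned = sp.ld_prune(sub, sp.VariantPanel.full(sub), window_snps=20,
                             step=5, r2_max=0.3)
        d = pruned.extract(sub).dosages.astype(float)
        for a in range(d.shape[1]):
            for b in range(a + 1, min(a + 20, d.shape[1])):
                assert _r2_pair(d[:, a], d[:, b]) <= 0.3 + 1e-9


class TestCommonSnps:
    def test_self_intersection_idempotent(self, demo_matrix):
        panel = sp.filter_cascade(demo_matrix)
        both = sp.common_snps(demo_matrix, panel, panel)
        assert np.array_equal(np.sort(both.loci), np.sort(panel.loci))

    def test_disjoint_panels_empty(self, demo_matrix):
        a = sp.VariantPanel(np.array([0, 1]), np.arange(5))
        b = sp.VariantPanel(np.array([2, 3]), np.arange(5))
        assert sp.common_snps(demo_matrix, a, b).n_loci == 0

    def test_site_universe_checked(self, demo_matrix):
        bad = sp.VariantPanel(np.array([999]), np.arange(5))
        with pytest.raises(sp.matrix.SiteUniverseError):
            sp.common_snps(demo_matrix, bad, bad)


class TestSnpDensity:
    def test_single_bin(self):
        gm = make_matrix(np.zeros((2, 5)) + np.arange(5) % 2,
                         positions=[100, 200, 300, 400, 500])
        dens = sp.snp_density(gm, sp.VariantPanel.full(gm), bin_bp=1000)
        assert len(dens) == 1
        assert dens["count"].iloc[0] == 5

    def test_bin_totals_conserved(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        panel = sp.VariantPanel.full(gm)
        dens = sp.snp_density(gm, panel, bin_bp=100_000)
        assert dens["count"].sum() == panel.n_loci

    def test_uniform_positions_poisson_bound(self):
        cfg = sp.SimConfig(n_pops=1, n_per_pop=2, n_loci=1000,
                           chrom_lengths=(10_000_000,), F=0.1, seed=17)
        gm, _ = sp.simulate_genotypes(cfg)
        dens = sp.snp_density(gm, sp.VariantPanel.full(gm), bin_bp=1_000_000)
        # lambda = 100 per bin; a 5-sigma Poisson bound
        assert dens["count"].max() < 100 + 5 * 10
        assert dens["count"].min() > 100 - 5 * 10
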