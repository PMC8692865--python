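"""Admixture EM, Evanno delta-K, assignment, PCA and neighbor joining."""

import numpy as np
import pytest

import spinpop as sp
from spinpop.structure import _bipartitions

from conftest import make_matrix


class TestAdmixtureModel:
    def test_k1_closed_form(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        res = sp.AdmixtureModel(gm, K=1).fit()
        assert np.allclose(res.Q, 1.0)
        p, copies = gm.allele_frequencies()
        from scipy.special import xlogy

        expected = float(np.sum(xlogy(copies * p, np.clip(p, 1e-6, None))
                                + xlogy(copies * (1 - p),
                                        np.clip(1 - p, 1e-6, None)))
                         + np.log(2.0) * (gm.dosages == 1).sum())
        assert res.loglik == pytest.approx(expected, rel=1e-6)

    def test_loglik_monotone_and_q_rows_sum_to_one(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        res = sp.AdmixtureModel(gm, K=2).fit(seed=3, max_iter=50)
        path = np.array(res.loglik_path)
        assert (np.diff(path) >= -1e-6 * np.abs(path[:-1])).all()
        assert np.allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
        assert (res.P >= 1e-6).all() and (res.P <= 1 - 1e-6).all()

    def test_recovers_pure_ancestry_labels(self, two_pop_panel):
        gm, truth, _ = two_pop_panel
        res = sp.AdmixtureModel(gm, K=2).fit(seed=5)
        q = sp.align_q(res.Q, truth.Q)
        rmse = np.sqrt(np.mean((q - truth.Q) ** 2))
        assert rmse < 0.05

    def test_k_validation(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        with pytest.raises(ValueError):
            sp.AdmixtureModel(gm, K=0)
        with pytest.raises(ValueError):
            sp.AdmixtureModel(gm, K=gm.n_samples + 1)

    def test_summary_mentions_k_and_convergence(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        res = sp.AdmixtureModel(gm, K=2).fit(seed=1)
        s = res.summary()
        assert "K=2" in s and "log-likelihood" in s


class TestEvanno:
    def _replicates(self, means, sd=10.0):
        d = sd / np.sqrt(2)
        return {k + 1: [m - d, m + d] for k, m in enumerate(means)}

    def test_hand_computed_example(self):
        lls = self._replicates([-1000, -600, -580, -575])
        t = sp.evanno_delta_k(lls)
        dk = dict(zip(t["K"], t["delta_k"]))
        assert dk[2] == pytest.approx(38.0)
        assert dk[3] == pytest.approx(1.5)
        assert sp.best_k(t) == 2

    def test_linear_loglik_gives_zero(self):
        t = sp.evanno_delta_k(self._replicates([-900, -800, -700, -600]))
        assert t["delta_k"].iloc[1] == pytest.approx(0.0)
        assert t["delta_k"].iloc[2] == pytest.approx(0.0)

    def test_invariant_to_constant_shift(self):
        lls = self._replicates([-1000, -600, -580, -575])
        shifted = {k: [v + 12345.0 for v in vals] for k, vals in lls.items()}
        a = sp.evanno_delta_k(lls)["delta_k"].to_numpy()
        b = sp.evanno_delta_k(shifted)["delta_k"].to_numpy()
        np.testing.assert_allclose(a[1:-1], b[1:-1])

    def test_zero_sd_warns_and_reports_inf(self):
        lls = {1: [-1000.0, -1000.0], 2: [-600.0, -600.0],
               3: [-580.0, -580.0]}
        with pytest.warns(RuntimeWarning):
            t = sp.evanno_delta_k(lls)
        assert np.isinf(t["delta_k"].iloc[1])

    def test_requires_consecutive_k(self):
        with pytest.raises(ValueError):
            sp.evanno_delta_k({1: [0, 1], 3: [0, 1], 4: [0, 1]})


class TestAssignment:
    def test_threshold_rule(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        res = sp.AdmixtureModel(gm, K=3).fit(seed=1, max_iter=30)
        res.Q = np.array([[0.80, 0.15, 0.05], [0.60, 0.30, 0.10]]
                         + [[1 / 3, 1 / 3, 1 / 3]] * (gm.n_samples - 2))
        res.model._ids = res.model._ids[:gm.n_samples]
        t = sp.assign_groups(res, threshold=0.75)
        assert t["label"].iloc[0] == "Q1"
        assert t["label"].iloc[1] == "admixed"
        assert (t["label"] == t["best_group"]).iloc[0]


class TestPCA:
    def test_two_clone_clusters(self):
        a = np.tile([0, 2, 0, 2, 0, 2, 0, 2], (5, 1))
        b = np.tile([2, 0, 2, 0, 2, 0, 2, 0], (5, 1))
        gm = make_matrix(np.vstack([a, b]))
        coords, ev = sp.pca(gm, n_components=3)
        assert ev[0] > 0.99
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:5] * pc1[5:] < 0).all()  # clusters on opposite sides

    def test_locus_order_invariance(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        d = gm.dosages
        perm = np.random.default_rng(0).permutation(gm.n_loci)
        coords1, _ = sp.pca(make_matrix(d), n_components=2)
        coords2, _ = sp.pca(make_matrix(d[:, perm]), n_components=2)
        np.testing.assert_allclose(coords1["PC1"], coords2["PC1"],
                                   atol=1e-8)

    def test_separates_simulated_populations(self, two_pop_panel):
        gm, truth, groups = two_pop_panel
        coords, _ = sp.pca(gm, n_components=1)
        pc1 = coords["PC1"].to_numpy()
        side = pc1 > np.median(pc1)
        labels = truth.Q.argmax(axis=1).astype(bool)
        agreement = max((side == labels).mean(), (side != labels).mean())
        assert agreement >= 0.95


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.array([[0, 5, 7], [5, 0, 8], [7, 8, 0]],
                                     float), ["A", "B", "C"])
        tree = sp.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # x_A=(5+7-8)/2=2, x_B=(5+8-7)/2=3, x_C=(7+8-5)/2=5
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(5.0)

    def test_additive_five_taxon_topology_recovered(self):
        from skbio import DistanceMatrix

        # tree: ((A:2,B:3):1,(C:1,D:4):2,E:5)
        paths = {("A", "B"): 5, ("A", "C"): 6, ("A", "D"): 9, ("A", "E"): 8,
                 ("B", "C"): 7, ("B", "D"): 10, ("B", "E"): 9,
                 ("C", "D"): 5, ("C", "E"): 8, ("D", "E"): 11}
        ids = ["A", "B", "C", "D", "E"]
        m = np.zeros((5, 5))
        for (x, y), d in paths.items():
            i, j = ids.index(x), ids.index(y)
            m[i, j] = m[j, i] = d
        tree = sp.nj_tree(DistanceMatrix(m, ids))
        parts = _bipartitions(tree, frozenset(ids))
        assert frozenset({"A", "B"}) in parts or \
            frozenset({"C", "D", "E"}) in parts
        assert frozenset({"C", "D"}) in parts or \
            frozenset({"A", "B", "E"}) in parts

    def test_too_few_taxa_rejected(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.array([[0, 1.], [1., 0]]), ["A", "B"])
        with pytest.raises(ValueError):
            sp.nj_tree(dm)

    def test_clone_pair_full_support_zero_length(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, size=(6, 120)).astype(np.int8)
        dosages = np.vstack([base, base[:1]])  # sample 6 clones sample 0
        gm = make_matrix(dosages)
        tree, support = sp.nj_bootstrap(gm, n_boot=30, seed=2)
        dm = sp.allele_sharing_distance(gm)
        assert dm["S0", "S6"] == 0.0
        clone_part = frozenset({"S0", "S6"})
        if clone_part in support:          # bipartition of the clone pair
            assert support[clone_part] == 1.0

    def test_allele_sharing_distance_definition(self):
        gm = make_matrix(np.array([[0, 2, 1], [2, 2, 1], [0, 0, 2]]))
        dm = sp.allele_sharing_distance(gm)
        assert dm["S0", "S1"] == pytest.approx((2 + 0 + 0) / 2 / 3)
        assert dm["S0", "S2"] == pytest.approx((0 + 2 + 1) / 2 / 3)
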