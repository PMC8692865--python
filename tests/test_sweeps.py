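"""Composite-likelihood sweep scan: drift scale, windows, scores,
regions."""

import numpy as np
import pytest

import spinpop as sp
from spinpop.sweeps import (_GRID, SweepWindow, _hitch_density,
                            _truncnorm_density)

from conftest import make_matrix


class TestEstimateDrift:
    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
        gm = make_matrix(np.vstack([base, base]))
        omega = sp.estimate_drift(gm, None, np.arange(10),
                                  np.arange(10, 20))
        assert omega == pytest.approx(0.0, abs=1e-12)

    def test_allele_relabel_invariance(self, two_pop_panel):
        gm, _, groups = two_pop_panel
        o1 = sp.estimate_drift(gm, None, groups["A"], groups["B"])
        flipped = make_matrix(2 - gm.dosages)
        o2 = sp.estimate_drift(flipped, None, groups["A"], groups["B"])
        assert o1 == pytest.approx(o2, rel=1e-9)

    @staticmethod
    def _one_sided_panel(F, seed, n=50, L=3000):
        """Reference at the ancestral frequency, query drifted by F — the
        configuration under which E[ω] = F/(1-F)."""
        rng = np.random.default_rng(seed)
        p_anc = rng.uniform(0.05, 0.95, L)
        scale = (1 - F) / F
        p_q = rng.beta(p_anc * scale, (1 - p_anc) * scale)
        ref = rng.binomial(2, p_anc, size=(n, L)).astype(np.int8)
        qry = rng.binomial(2, p_q, size=(n, L)).astype(np.int8)
        return make_matrix(np.vstack([ref, qry]),
                           positions=np.arange(1, L + 1) * 100)

    def test_moment_recovery_of_f_over_one_minus_f(self):
        vals = []
        for r in range(10):
            gm = self._one_sided_panel(0.1, 1000 + r)
            vals.append(sp.estimate_drift(gm, None, np.arange(50),
                                          np.arange(50, 100)))
        target = 0.1 / 0.9
        assert abs(np.mean(vals) - target) / target < 0.25

    def test_two_sided_drift_inflates_omega(self):
        """When both populations drift from the ancestor, ω measures the
        total (two-sided) differentiation and exceeds F/(1-F)."""
        cfg = sp.SimConfig(n_pops=2, n_per_pop=50, n_loci=3000,
                           chrom_lengths=(10_000_000,), F=0.1, seed=1003)
        gm, _ = sp.simulate_genotypes(cfg)
        omega = sp.estimate_drift(gm, None, np.arange(50),
                                  np.arange(50, 100))
        assert omega > 2 * 0.1  # at least the two-sided variance scale

    def test_small_groups_rejected(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        with pytest.raises(ValueError):
            sp.estimate_drift(gm, None, np.arange(3), np.arange(3, 20))


class TestWindowScheme:
    def test_100kb_chromosome_window_starts(self):
        rng = np.random.default_rng(0)
        pos = np.sort(np.append(
            rng.choice(np.arange(1, 100_000), 399, replace=False), 100_000))
        gm = make_matrix(rng.integers(0, 3, size=(4, 400)), positions=pos)
        wins = sp.window_scheme(gm)
        starts = sorted(w.start for w in wins)
        assert starts == [0, 10_000, 20_000, 30_000, 40_000, 50_000]

    def test_max_snps_cap_reproducible(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 40_000), 60, replace=False))
        gm = make_matrix(rng.integers(0, 3, size=(4, 60)), positions=pos)
        w1 = sp.window_scheme(gm, size=50_000, step=50_000, max_snps=50,
                              seed=5)
        w2 = sp.window_scheme(gm, size=50_000, step=50_000, max_snps=50,
                              seed=5)
        assert w1[0].n_snps == 50
        assert np.array_equal(w1[0].snp_idx, w2[0].snp_idx)

    def test_snp_containment(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        pos = gm.sites["pos"].to_numpy()
        for w in sp.window_scheme(gm, size=50_000, step=10_000):
            assert ((pos[w.snp_idx] >= w.start)
                    & (pos[w.snp_idx] < w.stop)).all()


class TestXpclrScore:
    def quadrature_oracle(self, dist, p_ref, alt, n, omega, s_grid,
                          rho=1e-8, bw=0.05, grid_points=4001):
        """Independent fine-grid evaluation of the same likelihood
        integrals."""
        from scipy.stats import binom

        x = np.linspace(0, 1, grid_points)

        def tnorm(mu, var):
            sd = max(np.sqrt(max(var, 0.0)), 1e-4)
            f = np.exp(-0.5 * ((x - mu) / sd) ** 2)
            return f / np.trapezoid(f, x)

        L0, Lh = [], []
        for j in range(len(p_ref)):
            pmf = binom.pmf(alt[j], n[j], x)
            f0 = tnorm(p_ref[j], omega * p_ref[j] * (1 - p_ref[j]))
            fh = p_ref[j] * tnorm(1.0, bw ** 2) + \
                (1 - p_ref[j]) * tnorm(0.0, bw ** 2)
            fh = fh / np.trapezoid(fh, x)
            L0.append(np.trapezoid(pmf * f0, x))
            Lh.append(np.trapezoid(pmf * fh, x))
        L0, Lh = np.array(L0), np.array(Lh)
        ll0 = np.log(L0).sum()
        best = -np.inf
        for s in s_grid:
            c = 1 - np.exp(-rho * np.abs(dist) / s)
            best = max(best, np.log(c * L0 + (1 - c) * Lh).sum())
        return max(0.0, 2 * (best - ll0))

    def test_matches_quadrature_oracle(self):
        dist = np.array([-20_000.0, 15_000.0])
        p_ref = np.array([0.35, 0.6])
        alt = np.array([55, 48])
        n = np.array([60, 60])
        s_grid = [1e-3, 1e-2]
        score, s_hat = sp.xpclr_score(dist, p_ref, alt, n, omega=0.1,
                                      s_grid=s_grid)
        oracle = self.quadrature_oracle(dist, p_ref, alt, n, 0.1, s_grid)
        assert score == pytest.approx(oracle, abs=0.05)
        assert s_hat in s_grid

    def test_neutral_nesting_small_s_gives_zero(self):
        dist = np.array([-20_000.0, 15_000.0])
        p_ref = np.array([0.35, 0.6])
        alt = np.array([20, 35])
        n = np.array([60, 60])
        score, _ = sp.xpclr_score(dist, p_ref, alt, n, omega=0.1,
                                  s_grid=[1e-12])
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_score_nonnegative_on_neutral_data(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m = rng.integers(2, 10)
            p_ref = rng.uniform(0.1, 0.9, m)
            n = np.full(m, 40)
            alt = rng.binomial(n, p_ref)
            dist = rng.uniform(-25_000, 25_000, m)
            score, _ = sp.xpclr_score(dist, p_ref, alt, n, omega=0.1)
            assert score >= 0.0

    def test_requires_valid_inputs(self):
        with pytest.raises(ValueError):
            sp.xpclr_score(np.array([0.0, 1.0]), np.array([0.5, 0.5]),
                           np.array([1, 1]), np.array([4, 4]), omega=0.1,
                           s_grid=[])
        with pytest.raises(ValueError):
            sp.xpclr_score(np.array([0.0, 1.0]), np.array([0.5, 0.5]),
                           np.array([1, 1]), np.array([4, 4]), omega=0.0)

    def test_stronger_sweep_never_scores_lower(self):
        """Median score at the swept window is ordered in sweep strength."""
        medians = []
        for strength in (2e4, 1e5, 5e5):
            scores = []
            for r in range(3):
                sweep = sp.SweepSpec("chr1", 5_000_000, strength, 1)
                cfg = sp.SimConfig(n_pops=2, n_per_pop=30, n_loci=1500,
                                   chrom_lengths=(10_000_000,), F=0.1,
                                   sweep=sweep, seed=400 + r)
                gm, _ = sp.simulate_genotypes(cfg)
                wins = sp.scan(gm, None, np.arange(30), np.arange(30, 60),
                               seed=r)
                at = [w.score for w in wins
                      if w.start <= 5_000_000 < w.stop]
                scores.append(max(at) if at else 0.0)
            medians.append(np.median(scores))
        assert medians[0] <= medians[1] + 1e-9
        assert medians[1] <= medians[2] + 1e-9


class TestCallRegions:
    def win(self, chrom, start, stop, score, idx):
        return SweepWindow(chrom, start, stop, np.asarray(idx, int), score)

    def test_overlapping_windows_merge(self):
        pos = np.array([105_000, 115_000, 125_000, 155_000])
        wins = [self.win("chr1", 100_000, 150_000, 9.0, [0, 1, 2]),
                self.win("chr1", 110_000, 160_000, 7.0, [1, 2, 3])]
        regions = sp.call_regions(wins, pos, top_fraction=1.0)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.stop) == (100_000, 160_000)
        assert r.n_snps == 4
        assert r.mean_score == pytest.approx(8.0)

    def test_distant_windows_stay_separate(self):
        pos = np.array([110_000, 310_000])
        wins = [self.win("chr1", 100_000, 150_000, 9.0, [0]),
                self.win("chr1", 300_000, 350_000, 7.0, [1])]
        regions = sp.call_regions(wins, pos, top_fraction=1.0)
        assert len(regions) == 2

    def test_top_one_percent_of_1000_selects_10(self):
        rng = np.random.default_rng(9)
        pos = np.arange(1000) * 1_000_000 + 500
        wins = [self.win("chr1", i * 1_000_000, i * 1_000_000 + 50_000,
                         float(rng.random()), [i]) for i in range(1000)]
        regions = sp.call_regions(wins, pos, top_fraction=0.01,
                                  gap=10_000)
        assert sum(r.n_windows for r in regions) == 10

    def test_region_table_ordinals(self):
        pos = np.array([110_000, 310_000, 110_000])
        wins = [self.win("chr1", 100_000, 150_000, 9.0, [0]),
                self.win("chr1", 300_000, 350_000, 7.0, [1]),
                self.win("chr2", 100_000, 150_000, 8.0, [2])]
        t = sp.regions_table(sp.call_regions(wins, pos, top_fraction=1.0))
        assert list(t["region"]) == ["1.1", "1.2", "2.1"]
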