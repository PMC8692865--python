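"""Recovery and calibration experiments on synthetic panels.

These functions generate data with the synthetic-data module under fixed
study conditions, run the corresponding analysis stage, and measure how well
the known truth is recovered.  They back both the test suite and the
reproduction script, so the numbers they return are always recomputed from
scratch.
"""

from __future__ import annotations

import numpy as np

from . import differentiation, structure, sweeps
from .matrix import derive_seed
from .simulate import SimConfig, SweepSpec, simulate_genotypes


def fst_recovery(F: float, n_per_pop: int = 50, n_loci: int = 5000,
                 n_seeds: int = 10, seed: int = 0) -> dict:
    """Mean allele-level AMOVA Φ across seeded Balding–Nichols panels.

    Returns the mean Φ, the mean Weir–Cockerham θ, and the largest absolute
    deviation of Φ from the simulated drift parameter F.
    """
    phis, wcs = [], []
    for r in range(n_seeds):
        cfg = SimConfig(n_pops=2, n_per_pop=n_per_pop, n_loci=n_loci,
                        chrom_lengths=(50_000_000,), F=F,
                        admix_alpha=None, seed=derive_seed(seed, 1, r))
        gm, truth = simulate_genotypes(cfg)
        groups = {"A": np.arange(n_per_pop),
                  "B": np.arange(n_per_pop, 2 * n_per_pop)}
        res = differentiation.amova(gm, None, groups, n_perm=0)
        phis.append(res.phi)
        wcs.append(differentiation.weir_cockerham_fst(gm, None, groups))
    phis, wcs = np.asarray(phis), np.asarray(wcs)
    return {"F": F, "mean_phi": float(phis.mean()),
            "mean_wc": float(wcs.mean()),
            "max_abs_err_phi": float(np.abs(phis - F).max()),
            "abs_err_mean_phi": float(abs(phis.mean() - F)),
            "n_seeds": n_seeds}


def admixture_recovery(n: int = 100, n_loci: int = 2000, F: float = 0.1,
                       admix_alpha: float = 0.3, seed: int = 7) -> dict:
    """Fit the K=2 admixture model and measure Q recovery after optimal
    label alignment."""
    cfg = SimConfig(n_pops=2, n_per_pop=n // 2, n_loci=n_loci,
                    chrom_lengths=(50_000_000,), F=F,
                    admix_alpha=admix_alpha, seed=seed)
    gm, truth = simulate_genotypes(cfg)
    res = structure.fit_admixture(gm, None, K=2, seed=derive_seed(seed, 2))
    q = structure.align_q(res.Q, truth.Q)
    rmse = float(np.sqrt(np.mean((q - truth.Q) ** 2)))
    return {"rmse": rmse, "converged": bool(res.converged),
            "loglik": res.loglik, "n": n, "n_loci": n_loci}


def evanno_recovery(true_k: int = 2, k_range=(1, 2, 3, 4), n_seeds: int = 10,
                    n_replicates: int = 2, n: int = 100, n_loci: int = 1000,
                    F: float = 0.1, seed: int = 0) -> dict:
    """Fraction of seeds for which ΔK selects the simulated K."""
    hits = 0
    for r in range(n_seeds):
        cfg = SimConfig(n_pops=true_k, n_per_pop=n // true_k, n_loci=n_loci,
                        chrom_lengths=(50_000_000,), F=F,
                        admix_alpha=0.3, seed=derive_seed(seed, 3, r))
        gm, _ = simulate_genotypes(cfg)
        logliks = {}
        for k in k_range:
            model = structure.AdmixtureModel(gm, None, K=k)
            reps = model.fit_replicates(n_replicates=n_replicates,
                                        seed=derive_seed(seed, 4, r, k),
                                        max_iter=200, tol=1e-5)
            logliks[k] = [x.loglik for x in reps]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = structure.evanno_delta_k(logliks)
        if structure.best_k(table) == true_k:
            hits += 1
    return {"hit_rate": hits / n_seeds, "hits": hits, "n_seeds": n_seeds,
            "true_k": true_k}


def _sweep_config(seed: int, with_sweep: bool) -> SimConfig:
    sweep = SweepSpec(chrom="chr1", pos=5_000_000, strength=100_000.0,
                      pop_index=1) if with_sweep else None
    return SimConfig(n_pops=2, n_per_pop=50, n_loci=4000,
                     chrom_lengths=(10_000_000,), F=0.1, admix_alpha=None,
                     sweep=sweep, seed=seed)


def sweep_localization(n_seeds: int = 25, n_null_seeds: int = 10,
                       seed: int = 0) -> dict:
    """Sweep-scan power and null calibration.

    For each seeded replicate a sweep is injected at 5 Mb on a 10 Mb
    chromosome in the query population; the scan's top-scoring merged region
    is checked for containing the sweep position.  Null calibration runs the
    same scan with no sweep and measures the fraction of null windows
    exceeding the 99th percentile of the sweep-run window scores.
    """
    hits = 0
    sweep_scores = []
    for r in range(n_seeds):
        cfg = _sweep_config(derive_seed(seed, 5, r), with_sweep=True)
        gm, truth = simulate_genotypes(cfg)
        ref = np.arange(50)            # population 0 (unswept) as reference
        query = np.arange(50, 100)
        windows = sweeps.scan(gm, None, ref, query,
                              seed=derive_seed(seed, 6, r))
        sweep_scores.extend(w.score for w in windows)
        regions = sweeps.call_regions(windows,
                                      gm.sites["pos"].to_numpy())
        best = max(regions, key=lambda g: g.mean_score)
        if best.start <= 5_000_000 < best.stop:
            hits += 1
    threshold = float(np.percentile(sweep_scores, 99))
    null_scores = []
    for r in range(n_null_seeds):
        cfg = _sweep_config(derive_seed(seed, 7, r), with_sweep=False)
        gm, _ = simulate_genotypes(cfg)
        windows = sweeps.scan(gm, None, np.arange(50), np.arange(50, 100),
                              seed=derive_seed(seed, 8, r))
        null_scores.extend(w.score for w in windows)
    null_scores = np.asarray(null_scores)
    exceed = float((null_scores > threshold).mean()) if len(null_scores) \
        else 0.0
    return {"hit_rate": hits / n_seeds, "hits": hits, "n_seeds": n_seeds,
            "null_exceedance": exceed,
            "score_threshold_99": threshold,
            "n_null_windows": int(len(null_scores))}


def amova_null_calibration(n_replicates: int = 200, n_samples: int = 30,
                           n_loci: int = 200, n_perm: int = 199,
                           alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of the AMOVA permutation test under a true null.

    Panels are simulated with no group structure (labels assigned
    arbitrarily to a single admixed pool), so the rejection rate at level
    ``alpha`` should match ``alpha`` up to binomial noise.
    """
    rejections = 0
    for r in range(n_replicates):
        cfg = SimConfig(n_pops=1, n_per_pop=n_samples, n_loci=n_loci,
                        chrom_lengths=(10_000_000,), F=0.1,
                        admix_alpha=None, seed=derive_seed(seed, 10, r))
        gm, _ = simulate_genotypes(cfg)
        half = n_samples // 2
        groups = {"A": np.arange(half), "B": np.arange(half, n_samples)}
        res = differentiation.amova(gm, None, groups, n_perm=n_perm,
                                    seed=derive_seed(seed, 11, r))
        if res.p_value <= alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_replicates,
            "rejections": rejections, "n_replicates": n_replicates,
            "alpha": alpha, "n_perm": n_perm}


def cascade_demo_counts() -> dict:
    """Run the filter cascade on the hand-counted demo panel and also check
    idempotence on its own output."""
    from .datasets import cascade_demo_matrix
    from .variants import FilterParams, filter_cascade

    gm = cascade_demo_matrix()
    panel = filter_cascade(gm)
    out = panel.extract(gm)
    panel2 = filter_cascade(out)
    idempotent = (panel2.n_loci == panel.n_loci
                  and panel2.n_samples == panel.n_samples)
    return {"sites": panel.n_loci, "samples": panel.n_samples,
            "idempotent": idempotent}
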