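"""Model-based group structure: admixture inference, ΔK, PCA, NJ trees.

The admixture model treats each individual's genome as a mixture over K
source populations with proportions q (rows of Q), and each genotype dosage
as Binomial(2, sum_k q_k p_kl) where p_kl are population allele frequencies.
:class:`AdmixtureModel` maximizes this likelihood by EM with seeded
restarts — the maximum-likelihood counterpart of the classical Bayesian
MCMC clustering, with the same likelihood kernel, deterministic given seeds.

Model selection across K uses the Evanno ΔK second-difference statistic on
replicate log-likelihoods; samples are assigned to a group when their
maximum membership reaches a threshold (default 0.75) and labeled admixed
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .matrix import MISSING, GenotypeMatrix, VariantPanel, derive_seed

_P_EPS = 1e-6


class AdmixtureModel:
    """Binomial admixture likelihood for a dosage matrix.

    Parameters
    ----------
    gm, panel
        Genotype matrix and optional filtered panel.
    K
        Number of source populations.

    Examples
    --------
    >>> model = AdmixtureModel(gm, panel, K=3)
    >>> result = model.fit(seed=42)
    >>> result.Q.shape
    (92, 3)
    """

    def __init__(self, gm: GenotypeMatrix, panel: VariantPanel | None = None,
                 K: int = 2):
        sub = panel.extract(gm) if panel is not None else gm
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > sub.n_samples:
            raise ValueError(f"K={K} exceeds the {sub.n_samples} samples")
        if sub.n_loci == 0:
            raise ValueError("empty panel")
        self.K = K
        self._ids = sub.samples["id"].to_numpy()
        g = sub.dosages.astype(float)
        self._mask = sub.dosages != MISSING
        g[~self._mask] = 0.0
        self._g = g
        # binomial coefficient term: log C(2, g) = log 2 for heterozygotes
        self._logc = float(np.log(2.0) * ((sub.dosages == 1).sum()))

    # -- likelihood pieces --------------------------------------------------

    def loglik(self, Q: np.ndarray, P: np.ndarray) -> float:
        theta = np.clip(Q @ P, _P_EPS, 1 - _P_EPS)
        m, g = self._mask, self._g
        ll = np.where(m, g * np.log(theta) + (2 - g) * np.log1p(-theta), 0.0)
        return float(ll.sum()) + self._logc

    def _em_step(self, Q: np.ndarray, P: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        g, m = self._g, self._mask
        theta = np.clip(Q @ P, _P_EPS, 1 - _P_EPS)
        U = np.where(m, g / theta, 0.0)
        V = np.where(m, (2 - g) / (1 - theta), 0.0)
        A = Q * (U @ P.T + V @ (1 - P).T)             # n x K
        Qn = A / A.sum(axis=1, keepdims=True)
        num = P * (Q.T @ U)                            # K x L  (alt copies)
        den = num + (1 - P) * (Q.T @ V)
        with np.errstate(invalid="ignore", divide="ignore"):
            Pn = np.where(den > 0, num / np.maximum(den, 1e-300), P)
        return Qn, np.clip(Pn, _P_EPS, 1 - _P_EPS)

    def _init(self, seed: int) -> tuple[np.ndarray, np.ndarray]:
        from sklearn.cluster import KMeans

        n, L = self._g.shape
        rng = np.random.default_rng(seed)
        if self.K == 1:
            return np.ones((n, 1)), self._freqs(np.ones((n, 1)))
        coords, _ = pca_from_arrays(self._g, self._mask,
                                    n_components=min(self.K, n - 1, 10))
        km = KMeans(n_clusters=self.K, n_init=4,
                    random_state=seed % (2 ** 31)).fit(coords)
        Q = np.full((n, self.K), 0.1 / max(self.K - 1, 1))
        Q[np.arange(n), km.labels_] = 0.9
        Q += rng.uniform(0, 0.05, size=Q.shape)        # seed perturbation
        Q /= Q.sum(axis=1, keepdims=True)
        P = self._freqs(Q)
        return Q, P

    def _freqs(self, Q: np.ndarray) -> np.ndarray:
        w = Q.T @ (self._mask * 1.0)                  # K x L copies weight
        alt = Q.T @ self._g
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(w > 0, alt / np.maximum(2 * w, 1e-300), 0.5)
        return np.clip(P, _P_EPS, 1 - _P_EPS)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
            replicate: int = 0) -> "AdmixtureResults":
        """Run EM to convergence from a seeded initialization.

        Stops when the relative log-likelihood improvement falls below
        ``tol`` or after ``max_iter`` iterations (the result is then flagged
        as non-converged, not fatal).  The log-likelihood is monotone
        non-decreasing across iterations by the EM construction; this is
        asserted every step.
        """
        if self.K == 1:
            Q = np.ones((self._g.shape[0], 1))
            P = self._freqs(Q)
            ll = self.loglik(Q, P)
            return AdmixtureResults(model=self, K=1, Q=Q, P=P, loglik=ll,
                                    loglik_path=[ll], converged=True,
                                    n_iter=0, seed=seed, replicate=replicate)
        Q, P = self._init(seed)
        ll = self.loglik(Q, P)
        path = [ll]
        converged = False
        for it in range(1, max_iter + 1):
            Q, P = self._em_step(Q, P)
            new = self.loglik(Q, P)
            if new < ll - 1e-6 * max(1.0, abs(ll)):
                raise AssertionError("EM log-likelihood decreased")
            path.append(new)
            if abs(new - ll) <= tol * abs(ll):
                ll = new
                converged = True
                break
            ll = new
        return AdmixtureResults(model=self, K=self.K, Q=Q, P=P, loglik=ll,
                                loglik_path=path, converged=converged,
                                n_iter=len(path) - 1, seed=seed,
                                replicate=replicate)

    def fit_replicates(self, n_replicates: int = 5, seed: int = 0,
                       max_iter: int = 500, tol: float = 1e-6
                       ) -> list["AdmixtureResults"]:
        """Seeded EM restarts (the replicate runs used for ΔK)."""
        return [self.fit(seed=derive_seed(seed, self.K, r), max_iter=max_iter,
                         tol=tol, replicate=r) for r in range(n_replicates)]


@dataclass
class AdmixtureResults:
    """Fitted admixture model: Q, P, log-likelihood and diagnostics."""

    model: AdmixtureModel
    K: int
    Q: np.ndarray
    P: np.ndarray
    loglik: float
    loglik_path: list[float]
    converged: bool
    n_iter: int
    seed: int
    replicate: int = 0

    def q_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q,
                          columns=[f"q{k + 1}" for k in range(self.K)])
        df.insert(0, "sample", self.model._ids)
        return df

    def assign(self, threshold: float = 0.75) -> pd.DataFrame:
        return assign_groups(self, threshold=threshold)

    def summary(self) -> str:
        a = self.assign()
        counts = a["label"].value_counts().to_dict()
        return "\n".join([
            f"Admixture model, K={self.K} "
            f"({'converged' if self.converged else 'NOT converged'} in "
            f"{self.n_iter} EM iterations, seed {self.seed})",
            f"log-likelihood: {self.loglik:.2f}",
            "assignment at 0.75: " + ", ".join(
                f"{k}={v}" for k, v in sorted(counts.items())),
        ])


def fit_admixture(gm: GenotypeMatrix, panel: VariantPanel | None, K: int,
                  seed: int = 0, max_iter: int = 500, tol: float = 1e-6
                  ) -> AdmixtureResults:
    """Functional wrapper: ``AdmixtureModel(gm, panel, K).fit(seed)``."""
    return AdmixtureModel(gm, panel, K).fit(seed=seed, max_iter=max_iter,
                                            tol=tol)


# -- model selection -------------------------------------------------------

def evanno_delta_k(logliks: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno ΔK from replicate log-likelihoods per K.

    ΔK(K) = mean over paired replicates of |L(K+1) − 2L(K) + L(K−1)|,
    divided by the standard deviation of the L(K) replicates.  Defined only
    for interior K; needs at least 3 consecutive K values with at least 2
    replicates each.  A zero replicate standard deviation yields inf with a
    warning.  ΔK is invariant to adding a constant to all log-likelihoods.
    """
    ks = sorted(logliks)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    reps = {k: np.asarray(v, float) for k, v in logliks.items()}
    if min(len(v) for v in reps.values()) < 2:
        raise ValueError("need >= 2 replicates per K")
    rows = []
    for k in ks:
        row = {"K": k, "mean_loglik": reps[k].mean(),
               "sd_loglik": reps[k].std(ddof=1)}
        if k == ks[0] or k == ks[-1]:
            row["delta_k"] = np.nan
            row["second_diff"] = np.nan
        else:
            m = min(len(reps[k - 1]), len(reps[k]), len(reps[k + 1]))
            second = np.abs(reps[k + 1][:m] - 2 * reps[k][:m]
                            + reps[k - 1][:m])
            sd = row["sd_loglik"]
            if sd == 0:
                warnings.warn(f"zero replicate sd at K={k}; delta K is "
                              "infinite", RuntimeWarning, stacklevel=2)
                row["delta_k"] = np.inf if second.mean() > 0 else 0.0
            else:
                row["delta_k"] = second.mean() / sd
            row["second_diff"] = second.mean()
        rows.append(row)
    return pd.DataFrame(rows)


def best_k(delta_table: pd.DataFrame) -> int:
    """argmax ΔK over interior K; ties broken by the raw second
    difference."""
    t = delta_table.dropna(subset=["delta_k"])
    if t.empty:
        raise ValueError("no interior K values")
    t = t.sort_values(["delta_k", "second_diff"], ascending=False)
    return int(t["K"].iloc[0])


def assign_groups(result: AdmixtureResults, threshold: float = 0.75
                  ) -> pd.DataFrame:
    """Label samples by maximum membership vs the assignment threshold."""
    best = result.Q.argmax(axis=1)
    maxq = result.Q.max(axis=1)
    label = np.where(maxq >= threshold,
                     [f"Q{b + 1}" for b in best], "admixed")
    return pd.DataFrame({"sample": result.model._ids,
                         "best_group": [f"Q{b + 1}" for b in best],
                         "membership": maxq, "label": label,
                         "threshold": threshold})


# -- PCA -------------------------------------------------------------------

def pca_from_arrays(g: np.ndarray, mask: np.ndarray, n_components: int = 10
                    ) -> tuple[np.ndarray, np.ndarray]:
    """PCA on a dosage array with a non-missing mask; see :func:`pca`."""
    copies = 2.0 * mask.sum(axis=0)
    alt = (g * mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    p = p[poly]
    x = (g[:, poly] - 2 * p) / np.sqrt(2 * p * (1 - p))
    x[~mask[:, poly]] = 0.0
    n = x.shape[0]
    n_components = min(n_components, n - 1 if n > 1 else 1, x.shape[1])
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    # deterministic sign: largest-magnitude loading positive
    for c in range(n_components):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            coords[:, c] *= -1
    ev = s ** 2
    explained = ev[:n_components] / ev.sum() if ev.sum() > 0 else \
        np.zeros(n_components)
    return coords, explained


def pca(gm: GenotypeMatrix, panel: VariantPanel | None = None,
        n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the dosage matrix with allele-frequency scaling.

    Dosages are centered by 2p̂ and scaled by sqrt(2p̂(1−p̂)); missing
    entries are imputed to the locus mean (0 after centering); monomorphic
    loci are dropped.  Returns sample coordinates and explained-variance
    ratios; component signs follow the largest-magnitude-loading-positive
    convention, so results are deterministic and invariant to locus order.
    """
    sub = panel.extract(gm) if panel is not None else gm
    if sub.n_samples < 2:
        raise ValueError("need at least 2 samples")
    mask = sub.dosages != MISSING
    g = sub.dosages.astype(float)
    g[~mask] = 0.0
    coords, explained = pca_from_arrays(g, mask, n_components)
    df = pd.DataFrame(coords,
                      columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    df.insert(0, "sample", sub.samples["id"].to_numpy())
    return df, explained


# -- label alignment (for recovery experiments) ----------------------------

def align_q(q_est: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Permute the columns of ``q_est`` to best match ``q_true``
    (Hungarian assignment on column RMSE)."""
    K = q_true.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.mean((q_est[:, a] - q_true[:, b]) ** 2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, int)
    perm[cols] = rows
    return q_est[:, perm]


# -- neighbor joining ------------------------------------------------------

def allele_sharing_distance(gm: GenotypeMatrix,
                            panel: VariantPanel | None = None,
                            loci: np.ndarray | None = None):
    """skbio DistanceMatrix of d = 1 − proportion of shared alleles.

    Per locus the shared-allele proportion between dosages x, y is
    1 − |x−y|/2; the distance averages over pairwise-complete loci.
    """
    from skbio import DistanceMatrix

    sub = panel.extract(gm) if panel is not None else gm
    d = sub.dosages if loci is None else sub.dosages[:, loci]
    x = d.astype(float)
    x[d == MISSING] = np.nan
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:])           # broadcast over rows below
        out[i, i + 1:] = out[i + 1:, i] = np.nanmean(diff, axis=1) / 2.0
    ids = [str(s) for s in sub.samples["id"]]
    return DistanceMatrix(out, ids)


def nj_tree(dm):
    """Saitou–Nei neighbor joining on a skbio DistanceMatrix."""
    from skbio.tree import nj

    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    return nj(dm)


def _bipartitions(tree, taxa: frozenset) -> set[frozenset]:
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            parts.add(min(side, taxa - side, key=sorted))
    return parts


def nj_bootstrap(gm: GenotypeMatrix, panel: VariantPanel | None = None,
                 n_boot: int = 200, seed: int = 0):
    """NJ tree with bootstrap support over loci.

    Loci are resampled with replacement ``n_boot`` times; the support of each
    internal bipartition of the full-data tree is the fraction of replicate
    trees containing it.  Supports are attached to internal node names of the
    returned tree.
    """
    sub = panel.extract(gm) if panel is not None else gm
    dm = allele_sharing_distance(sub)
    tree = nj_tree(dm)
    taxa = frozenset(dm.ids)
    main_parts = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            main_parts[node] = min(side, taxa - side, key=sorted)
    counts = {p: 0 for p in main_parts.values()}
    rng = np.random.default_rng(seed)
    L = sub.n_loci
    for _ in range(n_boot):
        resampled = rng.integers(0, L, size=L)
        bdm = allele_sharing_distance(sub, loci=resampled)
        bparts = _bipartitions(nj_tree(bdm), taxa)
        for p in counts:
            if p in bparts:
                counts[p] += 1
    support = {}
    for node, part in main_parts.items():
        frac = counts[part] / n_boot
        node.name = f"{100 * frac:.0f}"
        support[part] = frac
    return tree, support
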