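"""Genetic differentiation: AMOVA, pairwise Fst, Nei distance, gene flow.

The AMOVA partitions squared-Euclidean genetic variance among and within
groups and tests the fixation index Φ by permuting group labels.  By default
the partition is computed at the *allele-copy* level (each diploid sample
contributes two allele copies, so within-individual heterozygosity is part
of the within-group stratum); on Balding–Nichols data this Φ estimates the
simulated drift parameter F directly and agrees with the Weir–Cockerham
moment estimator.  The inter-individual dosage-distance variant (which
reports the larger ΦPT ≈ 2F/(1+F) on the same data) is available as
``level="individual"``.

Nei's (1978) unbiased distance uses per-locus gene identities
J_x = (2n·Σp² − 1)/(2n − 1) within groups and J_xy = Σ p_x p_y between them;
Id = mean(J_xy)/sqrt(mean(J_x)·mean(J_y)) and D = −ln(Id).  Gene flow
follows the island-model inversion Nm = ((1/Fst) − 1)/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, VariantPanel


@dataclass
class AmovaResult:
    table: pd.DataFrame          # source, df, SS, est_var, pct
    phi: float
    p_value: float
    n_permutations: int
    level: str

    def summary(self) -> str:
        lines = ["AMOVA", self.table.to_string(index=False),
                 f"Phi = {self.phi:.4f}   "
                 f"p = {self.p_value:.4f} ({self.n_permutations} "
                 f"permutations, {self.level} level)"]
        return "\n".join(lines)


def _group_matrix(groups: dict[str, np.ndarray], n: int) -> np.ndarray:
    G = np.zeros((len(groups), n))
    for g, (label, idx) in enumerate(groups.items()):
        idx = np.asarray(idx, int)
        if len(idx) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        G[g, idx] = 1.0
    if G.sum() != G.any(axis=0).sum():
        raise ValueError("groups overlap")
    return G


def _sums_of_squares(G: np.ndarray, S: np.ndarray, Qs: np.ndarray,
                     M: np.ndarray, unit_weight: float
                     ) -> tuple[float, float]:
    """(SS_among, SS_within) summed over loci.

    ``S``/``Qs``: per-sample per-locus value sums and squared-value sums;
    ``M``: non-missing indicator; ``unit_weight``: units contributed per
    non-missing sample (2 allele copies or 1 individual).
    """
    Sg = G @ S                     # value sums per group x locus
    Ng = unit_weight * (G @ M)     # unit counts per group x locus
    Qg = G @ Qs
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_w = Qg - np.where(Ng > 0, Sg ** 2 / np.maximum(Ng, 1), 0.0)
    St = S.sum(axis=0)
    Nt = unit_weight * M.sum(axis=0)
    Qt = Qs.sum(axis=0)
    ss_t = Qt - np.where(Nt > 0, St ** 2 / np.maximum(Nt, 1), 0.0)
    ss_within = float(np.nansum(ss_w))
    ss_total = float(np.nansum(ss_t))
    return ss_total - ss_within, ss_within


def amova(gm: GenotypeMatrix, panel: VariantPanel | None,
          groups: dict[str, np.ndarray], n_perm: int = 999,
          seed: int = 0, level: str = "allele") -> AmovaResult:
    """AMOVA with a permutation test of Φ.

    ``groups`` maps labels to sample indices (within the panel's sample
    axis); every group needs at least 2 samples.  ``level`` selects the
    partition units: ``"allele"`` (default, two copies per diploid) or
    ``"individual"`` (squared Euclidean distances between dosage vectors).
    The p-value convention is (1 + #{permuted Φ ≥ observed})/(n_perm + 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sub = panel.extract(gm) if panel is not None else gm
    # restrict to grouped samples so ungrouped ones do not enter the SS
    order = np.concatenate([np.asarray(idx, int) for idx in groups.values()])
    if len(np.unique(order)) != len(order):
        raise ValueError("groups overlap")
    sub = sub.take(samples=order)
    offsets = np.cumsum([0] + [len(idx) for idx in groups.values()])
    groups = {label: np.arange(offsets[k], offsets[k + 1])
              for k, label in enumerate(groups)}
    d = sub.dosages
    M = (d != MISSING).astype(float)
    x = np.where(d != MISSING, d, 0).astype(float)
    if level == "allele":
        S, Qs, w = x, x.copy(), 2.0     # a in {0,1}: sum a = sum a^2 = dosage
    elif level == "individual":
        S, Qs, w = x, x ** 2, 1.0
    else:
        raise ValueError(f"unknown level {level!r}")

    G = _group_matrix(groups, sub.n_samples)
    n_groups = G.shape[0]
    n_units = w * sub.n_samples
    group_units = w * G.sum(axis=1)

    ss_a, ss_w = _sums_of_squares(G, S, Qs, M, w)
    df_a = n_groups - 1
    df_w = n_units - n_groups
    n0 = (n_units - (group_units ** 2).sum() / n_units) / df_a
    var_w = ss_w / df_w
    var_a = (ss_a / df_a - var_w) / n0
    phi = _phi(var_a, var_w)

    rng = np.random.default_rng(seed)
    exceed = 0
    labels = np.argmax(G, axis=0)
    for _ in range(n_perm):
        perm = rng.permutation(sub.n_samples)
        Gp = np.zeros_like(G)
        Gp[labels, perm] = 1.0
        pa, pw = _sums_of_squares(Gp, S, Qs, M, w)
        pvw = pw / df_w
        pva = (pa / df_a - pvw) / n0
        if _phi(pva, pvw) >= phi:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)

    var_a_trunc = max(var_a, 0.0)
    total = var_a_trunc + var_w
    table = pd.DataFrame({
        "source": ["Among groups", "Within groups"],
        "df": [df_a, df_w],
        "SS": [ss_a, ss_w],
        "est_var": [var_a, var_w],
        "pct": [100 * var_a_trunc / total if total > 0 else 0.0,
                100 * var_w / total if total > 0 else 0.0],
    })
    return AmovaResult(table=table, phi=phi, p_value=p,
                       n_permutations=n_perm, level=level)


def _phi(var_a: float, var_w: float) -> float:
    total = max(var_a, 0.0) + var_w
    if total <= 0:
        return 0.0
    return max(var_a, 0.0) / total


def variance_percentages(components: dict[str, float]) -> dict[str, float]:
    """Percent of total variance per component from estimated variance
    components (the bookkeeping behind a printed AMOVA table)."""
    total = sum(max(v, 0.0) for v in components.values())
    return {k: 100.0 * max(v, 0.0) / total for k, v in components.items()}


# -- pairwise statistics ---------------------------------------------------

def weir_cockerham_fst(gm: GenotypeMatrix, panel: VariantPanel | None,
                       groups: dict[str, np.ndarray]) -> float:
    """Weir & Cockerham (1984) θ, ratio-of-sums over loci."""
    sub = panel.extract(gm) if panel is not None else gm
    d = sub.dosages
    r = len(groups)
    if r < 2:
        raise ValueError("need at least two groups")
    n_i, p_i, h_i = [], [], []
    for idx in groups.values():
        idx = np.asarray(idx, int)
        dg = d[idx]
        ok = dg != MISSING
        n = ok.sum(axis=0).astype(float)            # diploids with data
        alt = np.where(ok, dg, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h = np.where(n > 0,
                         np.where(ok, dg == 1, False).sum(axis=0)
                         / np.maximum(n, 1), np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)     # r x L
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    usable = (n_i > 0).all(axis=0)
    n_i, p_i, h_i = n_i[:, usable], p_i[:, usable], h_i[:, usable]
    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    nc = (nsum - (n_i ** 2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / nsum
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / nsum
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        return 0.0
    return float(a[ok].sum() / denom)


def pairwise_fst(gm: GenotypeMatrix, panel: VariantPanel | None,
                 groups: dict[str, np.ndarray], n_perm: int = 0,
                 seed: int = 0) -> pd.DataFrame:
    """Per-pair Φ (allele-level AMOVA) and Weir–Cockerham θ.

    With ``n_perm`` > 0, a permutation p-value accompanies each pair's Φ.
    """
    labels = list(groups)
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            pair = {labels[a]: groups[labels[a]],
                    labels[b]: groups[labels[b]]}
            res = amova(gm, panel, pair, n_perm=max(n_perm, 1), seed=seed)
            wc = weir_cockerham_fst(gm, panel, pair)
            row = {"group_a": labels[a], "group_b": labels[b],
                   "fst_phi": res.phi, "fst_wc": wc}
            if n_perm > 0:
                row["p_value"] = res.p_value
            rows.append(row)
    return pd.DataFrame(rows)


def nei_distance(gm: GenotypeMatrix, panel: VariantPanel | None,
                 groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Nei's (1978) unbiased genetic distance D and identity Id per pair."""
    sub = panel.extract(gm) if panel is not None else gm
    freq, copies = {}, {}
    for label, idx in groups.items():
        idx = np.asarray(idx, int)
        if len(idx) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        p, n = sub.allele_frequencies(idx)
        freq[label], copies[label] = p, n
    labels = list(groups)
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            la, lb = labels[a], labels[b]
            pa, pb = freq[la], freq[lb]
            na, nb = copies[la], copies[lb]
            ok = (na > 1) & (nb > 1) & np.isfinite(pa) & np.isfinite(pb)
            pa, pb, na, nb = pa[ok], pb[ok], na[ok].astype(float), \
                nb[ok].astype(float)
            sum2a = pa ** 2 + (1 - pa) ** 2
            sum2b = pb ** 2 + (1 - pb) ** 2
            jx = (na * sum2a - 1) / (na - 1)
            jy = (nb * sum2b - 1) / (nb - 1)
            jxy = pa * pb + (1 - pa) * (1 - pb)
            identity = jxy.mean() / np.sqrt(jx.mean() * jy.mean())
            if identity <= 0:
                raise ValueError(
                    f"non-positive genetic identity for {la} vs {lb}")
            rows.append({"group_a": la, "group_b": lb,
                         "nei_d": float(-np.log(identity)),
                         "nei_id": float(identity)})
    return pd.DataFrame(rows)


def identity_from_distance(d: float) -> float:
    """Invert D = −ln(Id): Id = exp(−D)."""
    return float(np.exp(-d))


def gene_flow(fst: float) -> float:
    """Island-model gene flow Nm = ((1/Fst) − 1)/4.

    Non-positive Fst means unbounded gene flow and returns +inf rather than
    raising.
    """
    if fst <= 0:
        return float("inf")
    if fst > 1:
        raise ValueError("Fst cannot exceed 1")
    return float((1.0 / fst - 1.0) / 4.0)


def differentiation_table(gm: GenotypeMatrix, panel: VariantPanel | None,
                          groups: dict[str, np.ndarray], n_perm: int = 0,
                          seed: int = 0) -> pd.DataFrame:
    """Combined pairwise table: Φ, Weir–Cockerham θ, D, Id, Nm."""
    fst = pairwise_fst(gm, panel, groups, n_perm=n_perm, seed=seed)
    nei = nei_distance(gm, panel, groups)
    out = fst.merge(nei, on=["group_a", "group_b"])
    out["nm"] = [gene_flow(f) if f > 0 else float("inf")
                 for f in out["fst_phi"]]
    return out
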