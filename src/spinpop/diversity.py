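"""Per-locus and per-group diversity statistics.

Implements the classical marker-diversity estimators for biallelic SNP data:

* gene diversity (expected heterozygosity) ``h = 1 - sum(p_i^2)``
* polymorphic information content (Botstein form)
  ``PIC = 1 - sum(p_j^2) - sum_{j<k} 2 p_j^2 p_k^2``
* number of observed (Na) and effective (Ne = 1/sum p_i^2) alleles
* unbiased gene diversity ``uh = n/(n-1) * h`` where n counts *allele
  copies* (2 x non-missing diploid samples) — the convention that reproduces
  published GenAlEx group tables
* Shannon's information index ``I = -sum(p_i ln p_i)``
* windowed nucleotide diversity π with the per-site unbiased heterozygosity
  ``(n/(n-1)) * 2p(1-p)`` divided by window length in bp (VCFtools
  ``--window-pi`` style).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, VariantPanel


def gene_diversity(freqs: np.ndarray) -> float:
    """Gene diversity GD = 1 - sum(p_i^2) for one locus's allele
    frequencies."""
    p = np.asarray(freqs, dtype=float)
    _check_freqs(p)
    return float(1.0 - np.sum(p ** 2))


def pic(freqs: np.ndarray) -> float:
    """Polymorphic information content, Botstein form.

    PIC = 1 - sum_j p_j^2 - sum_j sum_{k>j} 2 p_j^2 p_k^2.
    For biallelic (p, q): 1 - (p^2+q^2) - 2 p^2 q^2, maximized at 0.375 for
    p = q = 1/2.
    """
    p = np.asarray(freqs, dtype=float)
    _check_freqs(p)
    s2 = np.sum(p ** 2)
    cross = 0.0
    for j in range(len(p)):
        for k in range(j + 1, len(p)):
            cross += 2.0 * p[j] ** 2 * p[k] ** 2
    return float(1.0 - s2 - cross)


def shannon_index(freqs: np.ndarray) -> float:
    """Shannon's information index I = -sum p_i ln p_i (zero terms
    dropped)."""
    p = np.asarray(freqs, dtype=float)
    _check_freqs(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def unbiased_diversity(h: float, n_copies: int) -> float:
    """Finite-sample correction uh = n/(n-1) * h with n = allele copies.

    For a group of N diploid samples, n = 2N, so uh = 2N/(2N-1) * h.
    """
    if n_copies < 2:
        return float("nan")
    return float(n_copies / (n_copies - 1) * h)


def _check_freqs(p: np.ndarray) -> None:
    if (p < -1e-9).any() or (p > 1 + 1e-9).any():
        raise ValueError("allele frequencies must lie in [0,1]")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("allele frequencies must sum to 1")


# -- per-locus tables ------------------------------------------------------

def locus_stats(gm: GenotypeMatrix, panel: VariantPanel | None = None
                ) -> pd.DataFrame:
    """Per-locus GD and PIC over all samples of the panel."""
    sub = panel.extract(gm) if panel is not None else gm
    p, copies = sub.allele_frequencies()
    q = 1.0 - p
    gd = 1.0 - (p ** 2 + q ** 2)
    pic_ = gd - 2.0 * p ** 2 * q ** 2
    out = sub.sites[["chrom", "pos"]].copy()
    out["gd"] = gd
    out["pic"] = pic_
    out["n_copies"] = copies
    return out


def group_summary(gm: GenotypeMatrix, panel: VariantPanel | None,
                  groups: dict[str, np.ndarray],
                  window_bp: int = 1000) -> pd.DataFrame:
    """Mean Na, Ne, h, uh, I and windowed π per group.

    ``groups`` maps a group label to sample indices *within the panel's
    sample axis*.  Group rows are unweighted means over loci.  Two pooled
    rows are also reported: ``all (mean of groups)`` — the unweighted mean
    of the group rows, the convention of published combined rows — and
    ``all (pooled samples)`` computed genome-wide over every sample
    (π convention of the combined row).  Groups of a single sample get
    uh = NaN rather than an error.
    """
    sub = panel.extract(gm) if panel is not None else gm
    rows = []
    for label, idx in groups.items():
        idx = np.asarray(idx, dtype=int)
        if len(idx) == 0:
            raise ValueError(f"group {label!r} is empty")
        rows.append(_one_group_row(sub, label, idx, window_bp))
    table = pd.DataFrame(rows)
    mean_row = table[["na", "ne", "h", "uh", "i"]].mean()
    pooled = _one_group_row(sub, "all (pooled samples)",
                            np.arange(sub.n_samples), window_bp)
    table = pd.concat([
        table,
        pd.DataFrame([{**{"group": "all (mean of groups)",
                          "n_samples": int(table["n_samples"].sum())},
                       **mean_row.to_dict(),
                       "pi": pooled["pi"]}]),
        pd.DataFrame([pooled]),
    ], ignore_index=True)
    return table


def _one_group_row(sub: GenotypeMatrix, label: str, idx: np.ndarray,
                   window_bp: int) -> dict:
    p, copies = sub.allele_frequencies(idx)
    ok = copies > 0
    p, copies = p[ok], copies[ok]
    q = 1.0 - p
    na = (p > 0).astype(float) + (q > 0).astype(float)
    s2 = p ** 2 + q ** 2
    ne = 1.0 / s2
    h = 1.0 - s2
    # the finite-sample correction is meaningless for a single sample
    with np.errstate(divide="ignore", invalid="ignore"):
        if len(idx) < 2:
            uh = np.full_like(h, np.nan)
        else:
            uh = np.where(copies > 1,
                          copies / np.maximum(copies - 1, 1) * h, np.nan)
    i = np.zeros_like(p)
    for arr in (p, q):
        nz = arr > 0
        i[nz] -= arr[nz] * np.log(arr[nz])
    pi_df = pi_windows(sub, None, idx, window_bp=window_bp)
    return {"group": label, "n_samples": int(len(idx)),
            "na": float(na.mean()), "ne": float(ne.mean()),
            "h": float(h.mean()),
            "uh": float(np.nanmean(uh)) if np.isfinite(uh).any() else
            float("nan"),
            "i": float(i.mean()),
            "pi": float(pi_df["pi"].mean()) if len(pi_df) else float("nan")}


def pi_windows(gm: GenotypeMatrix, panel: VariantPanel | None,
               group: np.ndarray | None = None,
               window_bp: int = 1000) -> pd.DataFrame:
    """Nucleotide diversity per half-open window of ``window_bp``.

    Per site, the unbiased heterozygosity (n/(n-1)) * 2p(1-p) with n the
    non-missing allele copies; the window value is the sum over its sites
    divided by the window length in bp.  Only windows containing at least
    one SNP are reported (matching the behavior of the standard windowed-π
    tools); a window with sites but no polymorphism reports π = 0.
    """
    sub = panel.extract(gm) if panel is not None else gm
    idx = np.arange(sub.n_samples) if group is None else np.asarray(group,
                                                                    int)
    p, copies = sub.allele_frequencies(idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = np.where(copies > 1,
                       copies / np.maximum(copies - 1, 1) * 2.0 * p * (1 - p),
                       0.0)
    het = np.nan_to_num(het)
    sites = sub.sites
    win = (sites["pos"].to_numpy() - 1) // window_bp
    df = pd.DataFrame({"chrom": sites["chrom"].to_numpy(), "win": win,
                       "het": het})
    agg = df.groupby(["chrom", "win"], sort=True)["het"].agg(["sum", "size"])
    out = agg.reset_index()
    out["window_start"] = out["win"].astype(int) * window_bp
    out["window_end"] = out["window_start"] + window_bp
    out["n_snps"] = out["size"].astype(int)
    out["pi"] = out["sum"] / float(window_bp)
    return out[["chrom", "window_start", "window_end", "n_snps", "pi"]]
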