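"""VCF input/output and the SNP filter cascade.

The cascade mirrors the standard GBS post-processing sequence for diploid
biallelic SNP panels: drop indels, keep biallelic sites, apply a minor-allele
frequency floor, a site-quality floor, genotype-level depth masking, site and
sample missingness ceilings, and a final stricter depth/missingness/MAF pass.
Every step records (name, parameters, loci in/out, samples in/out) so the
panel carries its own provenance.

Conventions: quality thresholds are "keep if >= Q" (the VCFtools ``--minQ``
convention); depth thresholds mask individual genotypes to missing rather
than dropping sites (``--minDP`` semantics); MAF is computed from non-missing
alleles only; positions are 1-based as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, SiteUniverseError, VariantPanel


class VCFParseError(ValueError):
    pass


# -- reading ---------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    All records are parsed; each site is classified as ``snp``, ``indel`` or
    ``multiallelic``.  Diploid GT fields become alt-allele dosages; half
    calls and ``./.`` become missing.  Non-diploid genotypes raise an error
    naming the offending sample.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise VCFParseError(f"cannot open {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    rows, dosage_cols, depth_cols = [], [], []
    any_depth = False
    for line_no, v in enumerate(vcf, start=1):
        alts = [a for a in (v.ALT or [])]
        if len(alts) > 1:
            kind = "multiallelic"
        elif len(alts) == 1 and (len(v.REF) != 1 or len(alts[0]) != 1
                                 or alts[0] in ("<NON_REF>", "*")):
            kind = "indel"
        elif len(alts) == 1:
            kind = "snp"
        else:
            kind = "indel"  # ALT "." — not a usable SNP candidate
        dose = np.full(n, MISSING, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise VCFParseError(
                    f"non-diploid genotype for sample {sample_ids[i]} at "
                    f"{v.CHROM}:{v.POS}")
            if alleles[0] < 0 or alleles[1] < 0:
                continue  # ./., half calls -> missing
            dose[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        try:
            dp = v.format("DP")
        except Exception:
            dp = None
        if dp is not None:
            any_depth = True
            dp = np.asarray(dp).reshape(n).astype(np.int64)
            dp[dp < 0] = 0
        else:
            dp = np.zeros(n, dtype=np.int64)
        rows.append({"chrom": v.CHROM, "pos": int(v.POS), "ref": v.REF,
                     "alt": ",".join(alts) if alts else ".",
                     "qual": float(v.QUAL) if v.QUAL is not None else np.nan,
                     "kind": kind})
        dosage_cols.append(dose)
        depth_cols.append(dp)
    if not rows:
        sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "qual",
                                      "kind"])
        return GenotypeMatrix(np.zeros((n, 0), dtype=np.int8), sites,
                              pd.DataFrame({"id": sample_ids}),
                              np.zeros((n, 0), dtype=np.int32))
    sites = pd.DataFrame(rows)
    dosages = np.stack(dosage_cols, axis=1)
    depths = np.stack(depth_cols, axis=1).astype(np.int32) if any_depth else None
    return GenotypeMatrix(dosages, sites, pd.DataFrame({"id": sample_ids}),
                          depths)


def write_vcf(gm: GenotypeMatrix, path, contigs=None) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT:DP genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=spinpop\n")
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Read depth">\n')
        ids = "\t".join(gm.samples["id"].astype(str))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + ids + "\n")
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(gm.n_loci):
            s = gm.sites.iloc[j]
            qual = "." if pd.isna(s["qual"]) else f"{s['qual']:g}"
            fields = [str(s["chrom"]), str(int(s["pos"])), ".", str(s["ref"]),
                      str(s["alt"]), qual, "PASS", ".", "GT:DP"]
            for i in range(gm.n_samples):
                d = int(gm.dosages[i, j])
                gt = "./." if d == MISSING else gt_of[d]
                dp = 0 if gm.depths is None else int(gm.depths[i, j])
                fields.append(f"{gt}:{dp}")
            fh.write("\t".join(fields) + "\n")


# -- filter cascade --------------------------------------------------------

@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the filter cascade; ``None`` disables a stage."""

    min_maf: float | None = 0.05
    min_qual: float | None = 20.0
    min_depth: int | None = 10
    max_site_missing: float | None = 0.20
    max_sample_missing: float | None = 0.20
    final_min_depth: int | None = 15
    final_max_site_missing: float | None = 0.20
    final_min_maf: float | None = 0.05


def _maf(dosages: np.ndarray) -> np.ndarray:
    ok = dosages != MISSING
    copies = 2 * ok.sum(axis=0)
    alt = np.where(ok, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / np.maximum(copies, 1), 0.0)
    return np.minimum(p, 1 - p)


def filter_cascade(gm: GenotypeMatrix, params: FilterParams = FilterParams()
                   ) -> VariantPanel:
    """Run the eight-stage filter cascade, recording provenance.

    Stages: (1) drop indels; (2) keep biallelic SNPs; (3) MAF floor;
    (4) site-quality floor; (5) mask genotypes below the depth floor;
    (6) drop sites above the missingness ceiling; (7) drop samples above the
    missingness ceiling; (8) final pass with the stricter depth floor,
    missingness ceiling and recomputed MAF floor.

    An all-removed outcome yields an empty panel with full provenance, not an
    exception.
    """
    if gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    panel = VariantPanel.full(gm)
    kind = gm.sites["kind"].to_numpy()
    qual = gm.sites["qual"].to_numpy(dtype=float)

    def current_dosages() -> np.ndarray:
        d = gm.dosages[np.ix_(panel.sample_idx, panel.loci)].copy()
        if panel.mask is not None:
            d[panel.mask] = MISSING
        return d

    def step(name, params_dict, keep_loci=None, keep_samples=None):
        li, si = panel.n_loci, panel.n_samples
        if keep_loci is not None:
            panel.loci = panel.loci[keep_loci]
            if panel.mask is not None:
                panel.mask = panel.mask[:, keep_loci]
        if keep_samples is not None:
            panel.sample_idx = panel.sample_idx[keep_samples]
            if panel.mask is not None:
                panel.mask = panel.mask[keep_samples]
        panel.record(name, params_dict, li, si)

    # 1. indels out
    step("drop_indels", {}, keep_loci=kind[panel.loci] != "indel")
    # 2. biallelic SNPs only
    step("biallelic_only", {}, keep_loci=kind[panel.loci] == "snp")
    # 3. MAF floor
    if params.min_maf is not None:
        maf = _maf(current_dosages())
        step("min_maf", {"min_maf": params.min_maf},
             keep_loci=maf >= params.min_maf)
    # 4. site quality floor
    if params.min_qual is not None:
        q = qual[panel.loci]
        step("min_qual", {"min_qual": params.min_qual},
             keep_loci=~(q < params.min_qual))  # NaN quality is kept
    # 5. depth masking
    if params.min_depth is not None and gm.depths is not None:
        dp = gm.depths[np.ix_(panel.sample_idx, panel.loci)]
        d = current_dosages()
        panel.mask = (d != MISSING) & (dp < params.min_depth)
        step("mask_low_depth", {"min_depth": params.min_depth})
    # 6. site missingness
    if params.max_site_missing is not None:
        d = current_dosages()
        frac = (d == MISSING).mean(axis=0)
        step("max_site_missing", {"max": params.max_site_missing},
             keep_loci=frac <= params.max_site_missing)
    # 7. sample missingness
    if params.max_sample_missing is not None:
        d = current_dosages()
        frac = (d == MISSING).mean(axis=1) if d.shape[1] else np.zeros(
            d.shape[0])
        step("max_sample_missing", {"max": params.max_sample_missing},
             keep_samples=frac <= params.max_sample_missing)
    # 8. final pass: stricter depth, missingness, MAF recomputed on survivors
    if params.final_min_depth is not None and gm.depths is not None:
        dp = gm.depths[np.ix_(panel.sample_idx, panel.loci)]
        d = current_dosages()
        extra = (d != MISSING) & (dp < params.final_min_depth)
        panel.mask = extra if panel.mask is None else (panel.mask | extra)
        step("final_mask_low_depth", {"min_depth": params.final_min_depth})
    if params.final_max_site_missing is not None:
        d = current_dosages()
        frac = (d == MISSING).mean(axis=0) if d.shape[0] else np.zeros(
            d.shape[1])
        step("final_max_site_missing", {"max": params.final_max_site_missing},
             keep_loci=frac <= params.final_max_site_missing)
    if params.final_min_maf is not None:
        maf = _maf(current_dosages())
        step("final_min_maf", {"min_maf": params.final_min_maf},
             keep_loci=maf >= params.final_min_maf)
    return panel


# -- LD pruning ------------------------------------------------------------

def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns,
    pairwise-complete over samples."""
    x = d.astype(float)
    x[d == MISSING] = np.nan
    L = x.shape[1]
    out = np.zeros((L, L))
    for a in range(L):
        for b in range(a + 1, L):
            out[a, b] = out[b, a] = _r2_pair(x[:, a], x[:, b])
    return out


def _r2_pair(xa: np.ndarray, xb: np.ndarray) -> float:
    ok = ~(np.isnan(xa) | np.isnan(xb))
    if ok.sum() < 2:
        return 0.0
    a, b = xa[ok], xb[ok]
    va, vb = a.var(), b.var()
    if va <= 0 or vb <= 0:
        return 0.0
    c = np.mean((a - a.mean()) * (b - b.mean()))
    return float(c * c / (va * vb))


def ld_prune(gm: GenotypeMatrix, panel: VariantPanel, window_snps: int = 50,
             step: int = 5, r2_max: float = 0.2) -> VariantPanel:
    """Windowed greedy LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window of ``window_snps`` SNPs, while any pair exceeds
    ``r2_max``, one SNP of the worst pair is removed — the lower-MAF SNP,
    then the later position on ties.  The window slides by ``step`` SNPs.
    """
    if panel.n_loci == 0:
        raise ValueError("empty panel")
    sub = panel.extract(gm)
    d = sub.dosages
    order = np.lexsort((sub.sites["pos"].to_numpy(),
                        sub.sites["chrom"].to_numpy().astype(str)))
    maf = _maf(d)
    alive = np.ones(sub.n_loci, dtype=bool)
    chrom = sub.sites["chrom"].to_numpy()
    start = 0
    while start < len(order):
        win = [j for j in order[start:start + window_snps]
               if alive[j] and chrom[j] == chrom[order[start]]]
        while True:
            worst, pair = r2_max, None
            for ai in range(len(win)):
                if not alive[win[ai]]:
                    continue
                for bi in range(ai + 1, len(win)):
                    if not alive[win[bi]]:
                        continue
                    r2 = _r2_pair(*_float_cols(d, win[ai], win[bi]))
                    if r2 > worst:
                        worst, pair = r2, (win[ai], win[bi])
            if pair is None:
                break
            a, b = pair
            if maf[a] < maf[b]:
                drop = a
            elif maf[b] < maf[a]:
                drop = b
            else:  # equal MAF: drop the later position
                drop = max(a, b, key=lambda j: (str(chrom[j]),
                                                sub.sites["pos"].iloc[j]))
            alive[drop] = False
        start += step
    keep = np.where(alive)[0]
    out = VariantPanel(panel.loci[keep], panel.sample_idx.copy(),
                       list(panel.provenance),
                       None if panel.mask is None else panel.mask[:, keep])
    out.record("ld_prune", {"window_snps": window_snps, "step": step,
                            "r2_max": r2_max},
               panel.n_loci, panel.n_samples)
    return out


def _float_cols(d: np.ndarray, a: int, b: int):
    xa = d[:, a].astype(float)
    xb = d[:, b].astype(float)
    xa[d[:, a] == MISSING] = np.nan
    xb[d[:, b] == MISSING] = np.nan
    return xa, xb


# -- panel intersection and density ----------------------------------------

def common_snps(gm: GenotypeMatrix, panel_a: VariantPanel,
                panel_b: VariantPanel) -> VariantPanel:
    """Intersect two panels of the same site universe by
    (chromosome, position, alleles)."""
    for p in (panel_a, panel_b):
        if (p.loci >= gm.n_loci).any():
            raise SiteUniverseError("panel indexes outside the site universe")
    key = gm.sites[["chrom", "pos", "ref", "alt"]]
    ka = set(map(tuple, key.iloc[panel_a.loci].itertuples(index=False)))
    kb = set(map(tuple, key.iloc[panel_b.loci].itertuples(index=False)))
    both = ka & kb
    keep = np.array([j for j in panel_a.loci
                     if tuple(key.iloc[j]) in both], dtype=int)
    samples = np.union1d(panel_a.sample_idx, panel_b.sample_idx)
    out = VariantPanel(keep, samples,
                       list(panel_a.provenance) + list(panel_b.provenance))
    out.record("common_snps", {"n_a": panel_a.n_loci, "n_b": panel_b.n_loci},
               max(panel_a.n_loci, panel_b.n_loci),
               len(samples))
    return out


def snp_density(gm: GenotypeMatrix, panel: VariantPanel,
                bin_bp: int = 1_000_000) -> pd.DataFrame:
    """SNP counts per half-open genomic bin [k*bin, (k+1)*bin) per
    chromosome."""
    if panel.n_loci == 0:
        raise ValueError("empty panel")
    sites = gm.sites.iloc[panel.loci]
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        # 1-based positions: bin k covers positions k*bin+1 .. (k+1)*bin
        bins = (grp["pos"].to_numpy() - 1) // bin_bp
        counts = pd.Series(bins).value_counts().sort_index()
        for k, c in counts.items():
            rows.append({"chrom": chrom, "bin_start": int(k) * bin_bp,
                         "bin_end": (int(k) + 1) * bin_bp, "count": int(c)})
    return pd.DataFrame(rows)
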