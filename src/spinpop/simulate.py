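"""Synthetic GBS genotype panels with known structure, admixture and sweeps.

The generator follows the Balding–Nichols model: each latent population's
allele frequency at a locus is a Beta draw around a shared ancestral
frequency, with the drift parameter ``F`` controlling the expected Fst among
populations.  Individuals receive Dirichlet admixture proportions and
genotypes are binomial draws from their mixed frequencies.  An optional
selective sweep pushes frequencies in one population toward fixation around a
focal position before genotypes are drawn, with exponentially decaying weight
in physical distance — a deterministic, seed-stable stand-in for hitchhiking
that is sufficient to test sweep localization.

Everything is determined by ``SimConfig.seed``: the same config yields
byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, derive_seed


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SweepSpec:
    """A locally swept region: one population's frequencies are pushed toward
    fixation around ``pos`` with weight exp(-distance/strength)."""

    chrom: str
    pos: int
    strength: float       # decay length of the push weight, in bp
    pop_index: int = 0


@dataclass(frozen=True)
class SimConfig:
    n_pops: int = 2
    n_per_pop: int = 50
    n_loci: int = 2000
    # Spinacia-like default map: 6 chromosomes (2n = 2x = 12), 100 Mb each.
    chrom_lengths: tuple[int, ...] = tuple([100_000_000] * 6)
    F: float = 0.10
    admix_alpha: float | None = None   # None => pure block ancestry
    sweep: SweepSpec | None = None
    missing_rate: float = 0.0
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0      # negative-binomial shape; larger=tighter
    qual_mean: float = 60.0
    contaminant_fraction: float = 0.0  # fraction of emitted VCF records that
                                       # are indels/multiallelic
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.F < 1):
            raise ConfigError(f"F must be in (0,1), got {self.F}")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.n_pops < 1:
            raise ConfigError("n_pops must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0,1)")
        if not (0 <= self.contaminant_fraction < 1):
            raise ConfigError("contaminant_fraction must be in [0,1)")
        if self.sweep is not None:
            lens = dict(self._chrom_map())
            if self.sweep.chrom not in lens:
                raise ConfigError(f"sweep chromosome {self.sweep.chrom!r} "
                                  "not in the map")
            if not (1 <= self.sweep.pos <= lens[self.sweep.chrom]):
                raise ConfigError("sweep position outside the chromosome")
            if not (0 <= self.sweep.pop_index < self.n_pops):
                raise ConfigError("sweep population index out of range")

    def _chrom_map(self) -> list[tuple[str, int]]:
        return [(f"chr{i + 1}", int(L))
                for i, L in enumerate(self.chrom_lengths)]

    @property
    def n_samples(self) -> int:
        return self.n_pops * self.n_per_pop


@dataclass
class Truth:
    """Ground truth retained for parameter-recovery tests."""

    Q: np.ndarray                # n_samples x n_pops admixture proportions
    F: float
    ancestral_freqs: np.ndarray  # n_loci
    pop_freqs: np.ndarray        # n_pops x n_loci (post sweep push, if any)
    sweep: SweepSpec | None = None


def _positions(cfg: SimConfig, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random SNP positions, strictly increasing per chromosome,
    loci allocated to chromosomes proportionally to length."""
    lens = np.asarray(cfg.chrom_lengths, float)
    alloc = np.floor(cfg.n_loci * lens / lens.sum()).astype(int)
    while alloc.sum() < cfg.n_loci:
        alloc[int(np.argmax(lens / (alloc + 1)))] += 1
    chroms, positions = [], []
    for (name, L), k in zip(cfg._chrom_map(), alloc):
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, L + 1, dtype=np.int64),
                                 size=k, replace=False))
        chroms.extend([name] * k)
        positions.append(pos)
    return np.asarray(chroms, object), np.concatenate(positions)


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Draw ancestral and per-population allele frequencies.

    Ancestral frequency p ~ Uniform(0.05, 0.95); population frequency
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F), whose variance is F·p(1-p), so the
    expected Fst across loci is about F.

    Returns ``(ancestral, pop_freqs)`` with shapes (L,) and (K, L).
    """
    if rng is None:
        rng = np.random.default_rng(derive_seed(cfg.seed, 0))
    p = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    scale = (1.0 - cfg.F) / cfg.F
    a = np.clip(p * scale, 1e-12, None)
    b = np.clip((1.0 - p) * scale, 1e-12, None)
    pk = rng.beta(a, b, size=(cfg.n_pops, cfg.n_loci))
    return p, np.clip(pk, 0.0, 1.0)


def _push_frequencies(pop_freqs: np.ndarray, chroms: np.ndarray,
                      positions: np.ndarray, sweep: SweepSpec) -> np.ndarray:
    """Push one population's frequencies toward fixation around the sweep.

    The locally major allele is driven toward fixation with weight
    w = exp(-d/strength); other populations are untouched.
    """
    out = pop_freqs.copy()
    on = chroms == sweep.chrom
    d = np.abs(positions[on].astype(float) - sweep.pos)
    w = np.exp(-d / max(sweep.strength, 1e-9))
    p = out[sweep.pop_index, on]
    target = (p >= 0.5).astype(float)
    out[sweep.pop_index, on] = (1.0 - w) * p + w * target
    return out


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, Truth]:
    """Generate a full genotype panel plus its ground-truth record.

    Per sample, the admixture vector q is Dirichlet(admix_alpha) (or a pure
    one-hot block assignment when ``admix_alpha`` is None); the genotype at
    locus l is Binomial(2, sum_k q_k p_kl).  Missing entries are set
    completely at random at ``missing_rate``.  Depth is negative-binomial
    around ``depth_mean``; site quality is exponential-tailed around
    ``qual_mean``.
    """
    rng_freq = np.random.default_rng(derive_seed(cfg.seed, 0))
    rng_geno = np.random.default_rng(derive_seed(cfg.seed, 1))
    rng_meta = np.random.default_rng(derive_seed(cfg.seed, 2))

    anc, pk = simulate_frequencies(cfg, rng_freq)
    chroms, positions = _positions(cfg, rng_freq)
    if cfg.sweep is not None:
        pk = _push_frequencies(pk, chroms, positions, cfg.sweep)

    n = cfg.n_samples
    if cfg.admix_alpha is None:
        Q = np.zeros((n, cfg.n_pops))
        for k in range(cfg.n_pops):
            Q[k * cfg.n_per_pop:(k + 1) * cfg.n_per_pop, k] = 1.0
    else:
        Q = rng_geno.dirichlet([cfg.admix_alpha] * cfg.n_pops, size=n)
    theta = Q @ pk                                   # n x L mixed frequencies
    dosages = rng_geno.binomial(2, np.clip(theta, 0, 1)).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng_geno.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = MISSING

    shape = max(cfg.depth_dispersion, 1e-6)
    depths = rng_meta.negative_binomial(
        shape, shape / (shape + cfg.depth_mean), size=dosages.shape)
    depths = depths.astype(np.int32)
    depths[dosages == MISSING] = 0

    quals = np.round(rng_meta.gamma(4.0, cfg.qual_mean / 4.0,
                                    size=cfg.n_loci), 1)
    ref, alt = _random_alleles(cfg.n_loci, rng_meta)
    sites = pd.DataFrame({
        "chrom": chroms, "pos": positions.astype(np.int64),
        "ref": ref, "alt": alt, "qual": quals,
        "kind": np.repeat("snp", cfg.n_loci),
    })
    pop_of = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)
    samples = pd.DataFrame({
        "id": [f"S{i:04d}" for i in range(n)],
        "species": [f"pop{pop_of[i] + 1}" if cfg.admix_alpha is None
                    else "admixed" for i in range(n)],
    })
    gm = GenotypeMatrix(dosages, sites, samples, depths)
    return gm, Truth(Q=Q, F=cfg.F, ancestral_freqs=anc, pop_freqs=pk,
                     sweep=cfg.sweep)


def _random_alleles(n: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return bases[ref], bases[alt]


def inject_sweep(gm: GenotypeMatrix, truth: Truth, pop_index: int,
                 chrom: str, pos: int, strength: float,
                 seed: int = 0) -> tuple[GenotypeMatrix, Truth]:
    """Re-draw genotypes around ``pos`` after pushing the affected
    population's frequencies toward fixation.

    Only samples with nonzero ancestry in ``pop_index`` and loci on the sweep
    chromosome are touched; the truth record is updated.
    """
    chroms = gm.sites["chrom"].to_numpy()
    if chrom not in set(chroms):
        raise ValueError(f"chromosome {chrom!r} not in the panel")
    positions = gm.sites["pos"].to_numpy()
    if pos < 1:
        raise ValueError("sweep position outside the map")
    spec = SweepSpec(chrom=chrom, pos=pos, strength=strength,
                     pop_index=pop_index)
    pk = _push_frequencies(truth.pop_freqs, chroms, positions, spec)
    rng = np.random.default_rng(derive_seed(seed, 9))
    on = chroms == chrom
    theta = truth.Q @ pk[:, on]
    new = gm.dosages.copy()
    redraw = rng.binomial(2, np.clip(theta, 0, 1)).astype(np.int8)
    keep_missing = new[:, on] == MISSING
    redraw[keep_missing] = MISSING
    # untouched rows: samples with no ancestry in the swept population
    affected = truth.Q[:, pop_index] > 0
    block = new[:, on]
    block[affected] = redraw[affected]
    new[:, on] = block
    gm2 = GenotypeMatrix(new, gm.sites, gm.samples, gm.depths)
    truth2 = dataclasses.replace(truth, pop_freqs=pk, sweep=spec)
    return gm2, truth2


# -- fixture VCF output -----------------------------------------------------

def write_fixture_vcf(gm: GenotypeMatrix, cfg: SimConfig, path) -> int:
    """Write the panel as VCF 4.2, interleaving contaminant records.

    ``cfg.contaminant_fraction`` of the emitted records are indels or
    multiallelic SNPs (with genotypes drawn from the panel's own samples) so
    that the filter cascade has something to remove.  Returns the total
    number of records written.
    """
    from .variants import write_vcf  # local import to avoid a cycle

    if cfg.contaminant_fraction > 0:
        gm = _with_contaminants(gm, cfg)
    write_vcf(gm, path, contigs=cfg._chrom_map())
    return gm.n_loci


def _with_contaminants(gm: GenotypeMatrix, cfg: SimConfig) -> GenotypeMatrix:
    rng = np.random.default_rng(derive_seed(cfg.seed, 3))
    n_snp = gm.n_loci
    n_con = int(round(cfg.contaminant_fraction * n_snp
                      / (1 - cfg.contaminant_fraction)))
    if n_con == 0:
        return gm
    sites = gm.sites
    rows, dos, dep = [], [], []
    bases = "ACGT"
    for j in range(n_con):
        chrom = sites["chrom"].iloc[rng.integers(0, n_snp)]
        on = sites["chrom"] == chrom
        taken = set(sites.loc[on, "pos"])
        while True:
            pos = int(rng.integers(1, int(sites.loc[on, "pos"].max()) + 1000))
            if pos not in taken:
                break
        if rng.random() < 0.5:
            ref = bases[rng.integers(0, 4)]
            alt = ref + bases[rng.integers(0, 4)]
            kind = "indel"
        else:
            ref = bases[rng.integers(0, 4)]
            others = [b for b in bases if b != ref]
            alt = ",".join(rng.permutation(others)[:2])
            kind = "multiallelic"
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "qual": float(np.round(rng.gamma(4, cfg.qual_mean / 4),
                                            1)),
                     "kind": kind})
        dos.append(rng.binomial(2, 0.3, size=gm.n_samples).astype(np.int8))
        dep.append(rng.poisson(cfg.depth_mean,
                               size=gm.n_samples).astype(np.int32))
    all_sites = pd.concat([sites, pd.DataFrame(rows)], ignore_index=True)
    dosages = np.hstack([gm.dosages, np.array(dos).T])
    depths = (np.hstack([gm.depths, np.array(dep).T])
              if gm.depths is not None else None)
    order = np.lexsort((all_sites["pos"].to_numpy(),
                        all_sites["chrom"].to_numpy().astype(str)))
    return GenotypeMatrix(dosages[:, order], all_sites.iloc[order],
                          gm.samples,
                          None if depths is None else depths[:, order])


def write_truth_tsv(truth: Truth, samples: pd.DataFrame, path) -> None:
    """Sidecar TSV with per-sample admixture truth and the sweep, if any."""
    K = truth.Q.shape[1]
    df = pd.DataFrame(truth.Q, columns=[f"q{k + 1}" for k in range(K)])
    df.insert(0, "sample", samples["id"].to_numpy())
    with open(path, "w") as fh:
        if truth.sweep is not None:
            s = truth.sweep
            fh.write(f"#sweep\tchrom={s.chrom}\tpos={s.pos}\t"
                     f"strength={s.strength}\tpop={s.pop_index}\n")
        fh.write(f"#F\t{truth.F}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
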