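"""Core data containers: genotype matrices and filtered variant panels.

The :class:`GenotypeMatrix` is the central exchange object of the package: a
samples × loci table of diploid alt-allele dosages (0, 1, 2, or missing) with
per-site metadata (chromosome, 1-based position, alleles, quality, variant
kind) and per-sample metadata (id, species label, optional collection
coordinates).  A :class:`VariantPanel` is a view onto such a matrix — a locus
and sample subset plus the ordered provenance of every filtering step that
produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "qual", "kind")


class SiteUniverseError(ValueError):
    """Raised when two panels do not reference the same site universe."""


@dataclass(frozen=True)
class FilterStep:
    """One recorded step of a filter cascade."""

    name: str
    params: dict
    loci_in: int
    loci_out: int
    samples_in: int
    samples_out: int

    def as_row(self) -> dict:
        row = {"filter": self.name, "loci_in": self.loci_in,
               "loci_out": self.loci_out, "samples_in": self.samples_in,
               "samples_out": self.samples_out}
        row.update({f"param_{k}": v for k, v in self.params.items()})
        return row


class GenotypeMatrix:
    """Diploid dosage matrix with site and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_loci)`` int8 array; alt-allele dosage 0/1/2,
        ``-1`` for missing.
    sites
        DataFrame with columns ``chrom, pos, ref, alt, qual, kind`` where
        ``kind`` is one of ``snp``, ``indel``, ``multiallelic``.  Positions
        are 1-based and strictly increasing within a chromosome.
    samples
        DataFrame with at least an ``id`` column; optional ``species``,
        ``lat``, ``lon``, ``alt_m``.
    depths
        Optional ``(n_samples, n_loci)`` non-negative int array of
        per-genotype read depth.
    """

    def __init__(self, dosages: np.ndarray, sites: pd.DataFrame,
                 samples: pd.DataFrame, depths: np.ndarray | None = None):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x loci)")
        if dosages.shape[0] < 1:
            raise ValueError("need at least one sample")
        if len(sites) != dosages.shape[1]:
            raise ValueError("sites table does not match dosage loci")
        if len(samples) != dosages.shape[0]:
            raise ValueError("samples table does not match dosage rows")
        for col in SITE_COLUMNS:
            if col not in sites.columns:
                raise ValueError(f"sites table lacks column {col!r}")
        self.dosages = dosages
        self.sites = sites.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        if depths is not None:
            depths = np.asarray(depths)
            if depths.shape != dosages.shape:
                raise ValueError("depths shape mismatch")
            if (depths < 0).any():
                raise ValueError("negative read depth")
        self.depths = depths
        self._check_positions()

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing entries."""
        out = self.dosages.astype(float)
        out[self.missing_mask] = np.nan
        return out

    def _check_positions(self) -> None:
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}")

    # -- subsetting ---------------------------------------------------------

    def take(self, loci: Sequence[int] | None = None,
             samples: Sequence[int] | None = None) -> "GenotypeMatrix":
        """Return a copy restricted to the given locus/sample indices."""
        li = np.arange(self.n_loci) if loci is None else np.asarray(loci, int)
        si = (np.arange(self.n_samples) if samples is None
              else np.asarray(samples, int))
        return GenotypeMatrix(
            self.dosages[np.ix_(si, li)],
            self.sites.iloc[li],
            self.samples.iloc[si],
            None if self.depths is None else self.depths[np.ix_(si, li)],
        )

    def allele_frequencies(self, sample_idx: Sequence[int] | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
        """Alt-allele frequency and non-missing allele-copy count per locus.

        Frequencies are computed from non-missing genotypes only.  Loci with
        no data get frequency NaN and copy count 0.
        """
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        ok = d != MISSING
        copies = 2 * ok.sum(axis=0)
        alt = np.where(ok, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
        return p, copies

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<GenotypeMatrix {self.n_samples} samples x "
                f"{self.n_loci} loci>")


@dataclass
class VariantPanel:
    """A filtered subset of a :class:`GenotypeMatrix` with provenance.

    ``loci`` / ``sample_idx`` index into the *source* matrix; ``mask`` holds
    additional genotype-level missingness introduced by depth filters, on the
    subset's axes (True = masked to missing).
    """

    loci: np.ndarray
    sample_idx: np.ndarray
    provenance: list[FilterStep] = field(default_factory=list)
    mask: np.ndarray | None = None

    @classmethod
    def full(cls, gm: GenotypeMatrix) -> "VariantPanel":
        return cls(np.arange(gm.n_loci), np.arange(gm.n_samples), [])

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.sample_idx)

    def record(self, name: str, params: dict, loci_in: int, samples_in: int
               ) -> None:
        step = FilterStep(name, params, loci_in, self.n_loci,
                          samples_in, self.n_samples)
        if step.loci_out > step.loci_in or step.samples_out > step.samples_in:
            raise AssertionError("filter step increased the panel")
        self.provenance.append(step)

    def extract(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        """Materialize the panel: subset ``gm`` and apply genotype masks."""
        sub = gm.take(self.loci, self.sample_idx)
        if self.mask is not None and self.mask.any():
            d = sub.dosages.copy()
            d[self.mask] = MISSING
            sub = GenotypeMatrix(d, sub.sites, sub.samples, sub.depths)
        return sub

    def provenance_table(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_row() for s in self.provenance])

    def site_key(self, gm: GenotypeMatrix) -> pd.DataFrame:
        s = gm.sites.iloc[self.loci]
        return s[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)


def derive_seed(seed_sequence_or_int, *path: int) -> int:
    """Derive a child seed (< 2**31) from a root seed and an index path.

    One global seed deterministically derives all stage seeds, so a single
    integer reproduces a full pipeline run.
    """
    root = np.random.SeedSequence(seed_sequence_or_int)
    child = np.random.SeedSequence(entropy=root.entropy,
                                   spawn_key=tuple(int(p) for p in path))
    return int(child.generate_state(1, np.uint32)[0] % (2 ** 31))
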