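"""Linkage disequilibrium: pairwise genotypic r² and the decay distance.

Phase is unknown in GBS dosage data, so r² is the squared Pearson
correlation of dosage vectors over pairwise-complete samples, for
same-chromosome SNP pairs within a physical window (default 200 kb).  The
decay curve bins mean r² by distance; the decay distance is where the
monotone-smoothed curve first crosses a threshold (default r² = 0.2),
linearly interpolated between bracketing bin midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, VariantPanel


@dataclass
class LDDecayCurve:
    """Binned LD decay: distance bins, mean r², pair counts."""

    bin_start: np.ndarray
    bin_end: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_start + self.bin_end) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.bin_start,
                             "bin_end": self.bin_end,
                             "mid_bp": self.midpoints,
                             "mean_r2": self.mean_r2,
                             "n_pairs": self.n_pairs})


def pairwise_r2(gm: GenotypeMatrix, panel: VariantPanel | None = None,
                group: np.ndarray | None = None,
                max_dist: int = 200_000, min_samples: int = 4
                ) -> pd.DataFrame:
    """(distance, r²) for every same-chromosome SNP pair within
    ``max_dist``.

    Pairs with fewer than ``min_samples`` pairwise-complete samples, or with
    zero dosage variance at either locus, are skipped.  r² is invariant to
    allele relabeling (x ↔ 2−x).
    """
    sub = panel.extract(gm) if panel is not None else gm
    if group is not None:
        sub = sub.take(samples=np.asarray(group, int))
    if sub.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = sub.dosages.astype(float)
    x[sub.dosages == MISSING] = np.nan
    chrom = sub.sites["chrom"].to_numpy()
    pos = sub.sites["pos"].to_numpy()
    dists, r2s = [], []
    for c in pd.unique(chrom):
        on = np.where(chrom == c)[0]
        p = pos[on]
        for ai in range(len(on)):
            bi = ai + 1
            while bi < len(on) and p[bi] - p[ai] <= max_dist:
                r2 = _r2(x[:, on[ai]], x[:, on[bi]], min_samples)
                if r2 is not None:
                    dists.append(int(p[bi] - p[ai]))
                    r2s.append(r2)
                bi += 1
    return pd.DataFrame({"dist_bp": dists, "r2": r2s})


def _r2(xa: np.ndarray, xb: np.ndarray, min_samples: int) -> float | None:
    ok = ~(np.isnan(xa) | np.isnan(xb))
    if ok.sum() < min_samples:
        return None
    a, b = xa[ok], xb[ok]
    va, vb = a.var(), b.var()
    if va <= 0 or vb <= 0:
        return None
    c = np.mean((a - a.mean()) * (b - b.mean()))
    return float(c * c / (va * vb))


def default_bins(max_dist: int = 200_000, fine_width: int = 1_000,
                 coarse_width: int = 5_000, fine_until: int = 20_000
                 ) -> np.ndarray:
    """Bin edges: 1-kb bins below 20 kb (to resolve the short-range
    crossing), 5-kb bins beyond."""
    fine = np.arange(0, min(fine_until, max_dist) + 1, fine_width)
    coarse = np.arange(fine_until + coarse_width, max_dist + coarse_width,
                       coarse_width)
    return np.concatenate([fine, coarse[coarse <= max_dist + coarse_width]])


def decay_curve(pairs: pd.DataFrame, bins: np.ndarray | None = None,
                bin_bp: int | None = None) -> LDDecayCurve:
    """Mean r² per half-open distance bin; empty bins are omitted."""
    if len(pairs) == 0:
        raise ValueError("no pairs")
    if bins is None:
        if bin_bp is not None:
            top = int(pairs["dist_bp"].max()) + bin_bp
            bins = np.arange(0, top + bin_bp, bin_bp)
        else:
            bins = default_bins(int(pairs["dist_bp"].max()))
    idx = np.digitize(pairs["dist_bp"].to_numpy(), bins) - 1
    starts, ends, means, counts = [], [], [], []
    for b in np.unique(idx):
        if b < 0 or b >= len(bins) - 1:
            continue
        sel = idx == b
        starts.append(bins[b])
        ends.append(bins[b + 1])
        means.append(float(pairs["r2"].to_numpy()[sel].mean()))
        counts.append(int(sel.sum()))
    return LDDecayCurve(np.asarray(starts, float), np.asarray(ends, float),
                        np.asarray(means, float), np.asarray(counts, int))


def decay_distance(curve: LDDecayCurve, threshold: float = 0.2) -> float:
    """Distance where the monotone-smoothed curve first drops below the
    threshold.

    The binned means are smoothed by decreasing isotonic regression
    (weighted by pair counts) before the crossing is located, then linearly
    interpolated between the bracketing bin midpoints.  Returns 0.0 if the
    curve never rises above the threshold, and +inf if it never falls below
    it within the binned range.
    """
    if len(curve.mean_r2) < 2:
        raise ValueError("need at least 2 bins")
    from sklearn.isotonic import IsotonicRegression

    mids = curve.midpoints
    smoothed = IsotonicRegression(increasing=False).fit(
        mids, curve.mean_r2, sample_weight=curve.n_pairs).predict(mids)
    crossing = _first_crossing(mids, smoothed, threshold)
    raw = _first_crossing(mids, curve.mean_r2, threshold)
    if np.isfinite(raw):
        # pooling a late bump must not push the report past the raw
        # crossing by more than one bin width
        width = float(np.max(curve.bin_end - curve.bin_start))
        crossing = min(crossing, raw + width)
    return crossing


def _first_crossing(x: np.ndarray, y: np.ndarray, threshold: float
                    ) -> float:
    if y[0] < threshold:
        return 0.0
    below = np.where(y < threshold)[0]
    if len(below) == 0:
        return float("inf")
    j = below[0]
    x0, x1 = x[j - 1], x[j]
    y0, y1 = y[j - 1], y[j]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - threshold) * (x1 - x0) / (y0 - y1))


def ld_decay_summary(gm: GenotypeMatrix, panel: VariantPanel | None,
                     groups: dict[str, np.ndarray],
                     max_dist: int = 200_000, threshold: float = 0.2
                     ) -> pd.DataFrame:
    """Per-group LD decay distance at the r² threshold."""
    rows = []
    for label, idx in groups.items():
        pairs = pairwise_r2(gm, panel, np.asarray(idx, int),
                            max_dist=max_dist)
        if len(pairs) == 0:
            rows.append({"group": label, "n_pairs": 0,
                         "decay_bp": float("nan")})
            continue
        curve = decay_curve(pairs)
        rows.append({"group": label, "n_pairs": int(len(pairs)),
                     "decay_bp": decay_distance(curve, threshold)})
    return pd.DataFrame(rows)
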