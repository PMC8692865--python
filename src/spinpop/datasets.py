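"""Small hand-built demonstration panels (synthetic).

``cascade_demo_matrix`` is a 12-site, 5-sample panel constructed by hand so
that every stage of the filter cascade removes something, with the survivor
counts (6 sites, 4 samples) established by manual counting before any code
ran against it:

* pos 200, 800 — indels (stage 1)
* pos 400 — triallelic (stage 2)
* pos 500 — monomorphic, minor-allele frequency below the floor (stage 3)
* pos 600 — site quality 10 (stage 4)
* pos 700 — after depth masking (S4 has depth 5) plus S5's missing call,
  2/5 = 40% missing (stage 6)
* sample S5 — missing at 3 of the 6 remaining sites = 50% (stage 7)
* the final pass removes nothing further (all surviving depths are 20).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

M = -1  # missing dosage


def cascade_demo_matrix() -> GenotypeMatrix:
    """The 12-site, 5-sample hand-counted filter-cascade fixture."""
    sites = pd.DataFrame([
        # chrom, pos, ref, alt, qual, kind
        ("chr1", 100, "A", "G", 50.0, "snp"),
        ("chr1", 200, "A", "AT", 50.0, "indel"),
        ("chr1", 300, "C", "T", 50.0, "snp"),
        ("chr1", 400, "G", "A,T", 50.0, "multiallelic"),
        ("chr1", 500, "T", "C", 50.0, "snp"),     # monomorphic
        ("chr1", 600, "A", "C", 10.0, "snp"),     # low quality
        ("chr1", 700, "G", "T", 50.0, "snp"),     # 40% missing after masking
        ("chr1", 800, "CA", "C", 50.0, "indel"),
        ("chr1", 900, "T", "A", 50.0, "snp"),
        ("chr1", 1000, "A", "G", 50.0, "snp"),
        ("chr1", 1100, "C", "G", 50.0, "snp"),
        ("chr1", 1200, "G", "C", 50.0, "snp"),
    ], columns=["chrom", "pos", "ref", "alt", "qual", "kind"])
    #            100 200 300 400 500 600 700 800 900 1000 1100 1200
    dosages = np.array([
        [0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 2],    # S1
        [1, 0, 0, 1, 0, 1, 1, 0, 1, 0, 1, 1],    # S2
        [0, 1, 0, 0, 0, 0, 1, 1, 0, 1, 1, 0],    # S3
        [1, 0, 1, 0, 0, 0, 1, 0, 0, 0, 2, 0],    # S4 (depth 5 at pos 700)
        [0, 0, M, 1, 0, 1, M, 0, M, M, 0, 0],    # S5 (dropped: 50% missing)
    ], dtype=np.int8)
    depths = np.full(dosages.shape, 20, dtype=np.int32)
    depths[3, 6] = 5          # S4 at pos 700: masked by the depth-10 floor
    depths[dosages == M] = 0
    samples = pd.DataFrame({"id": [f"S{i + 1}" for i in range(5)],
                            "species": ["demo"] * 5})
    return GenotypeMatrix(dosages, sites, samples, depths)


CASCADE_DEMO_SURVIVORS = {"sites": 6, "samples": 4,
                          "site_positions": (100, 300, 900, 1000, 1100,
                                             1200)}
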