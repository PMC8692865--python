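# Methods

This note records the models, estimators, numerical choices and known
limitations behind each stage of the pipeline.

## Synthetic panels

The generator uses the Balding–Nichols model: an ancestral allele frequency
p is drawn uniformly on [0.05, 0.95] per locus, and each of K latent
populations receives a Beta(p(1−F)/F, (1−p)(1−F)/F) draw, so the
between-population variance at a locus is F·p(1−p) and the expected Fst
across loci is F.  This model was chosen because it gives a closed-form
target for recovery tests; it is a stand-in for real collections, not a
demographic model.

Individuals get admixture proportions q from a symmetric
Dirichlet(admix_alpha): small alpha concentrates mass near the simplex
corners (nearly pure ancestry with random assignment), large alpha
approaches the uniform mixture (1/K, ..., 1/K).  `admix_alpha=None`
assigns exact one-hot block ancestry — the configuration used by recovery
experiments that need known labels.  Genotypes are Binomial(2, q·P) draws,
so panels are in Hardy–Weinberg proportions within a population.
Missingness is completely at random at `missing_rate` (real GBS missingness
is depth-dependent and therefore not MCAR; passing tests show estimator
correctness under MCAR, not robustness to informative missingness).  Depth
is negative-binomial around `depth_mean` (default 30, dispersion 5), site
quality gamma-tailed around `qual_mean` (default 60) — both exist to
exercise the filters, not to model a sequencer.  The default map is six
chromosomes of 100 Mb, matching the diploid karyotype (2n = 2x = 12) of the
genus the pipeline was built around; experiments that scan densely use a
single 10 Mb chromosome instead, purely to keep simulated SNP density
realistic (hundreds of SNPs per Mb would be unusually dense genome-wide
for GBS).

A sweep is injected at the frequency level: in the affected population
only, each locus's locally major allele is pushed toward fixation with
weight w = exp(−d/strength), d the distance to the focal position and
`strength` the decay length in bp (default in experiments: 100 kb).  This
deterministic push is seed-stable and sufficient for localization tests; it
is not a forward simulation and carries no linkage signal beyond the
frequency distortion itself.

## Filter cascade

Stage order: drop indels → keep biallelic SNPs → MAF ≥ 0.05 → site quality
≥ 20 → mask genotypes with depth < 10 → drop sites > 20% missing → drop
samples > 20% missing → final pass (mask depth < 15, drop sites > 20%
missing, re-apply MAF ≥ 0.05 on the survivors).  Depth thresholds mask
individual genotypes rather than dropping sites (the `--minDP` convention),
and missingness filters act on the masked matrix.  MAF always uses
non-missing alleles only.  Quality filtering keeps sites with QUAL ≥ 20
(the `--minQ` convention).  Re-running the cascade on its own output is a
no-op.  LD pruning is windowed greedy removal (50 SNPs, step 5, r² > 0.2):
within a window, the worse pair's lower-MAF member is removed (later
position on ties — the tie-break is fixed here for determinism, since no
published convention exists).

## Diversity statistics

Per-locus allele frequencies within a group come from non-missing allele
copies (n = 2 × non-missing diploids).  h = 1 − Σp²; uh = n/(n−1) · h with
n in **allele copies** — this reading reproduces published group tables
exactly (h = 0.351 with 33 diploids gives uh = 66/65 · 0.351 = 0.356) where
the per-sample reading does not, and is regression-tested.  Shannon's
I = −Σ p ln p with the conventional minus sign.  PIC uses the Botstein
form, whose biallelic maximum is 0.375 at p = q = 1/2 (gene diversity's
maximum is 0.50 there).  A single-sample group reports uh as missing
rather than applying a meaningless correction.

Windowed π sums the per-site unbiased heterozygosity (n/(n−1))·2p(1−p)
over the SNPs of each half-open window and divides by the window length in
bp (1 kb default).  Only windows containing at least one SNP are reported,
and the group mean averages over those windows — the behavior of the
standard windowed-π tools, which never emit SNP-free windows.  The
combined "all genotypes" row is reported under two labeled conventions:
the unweighted mean of the group rows (the convention of published
combined rows for Na/Ne/h/uh/I) and the pooled-sample computation (the π
convention).

## AMOVA and differentiation

The AMOVA partitions squared-Euclidean sums of squares among and within
groups and estimates variance components by the standard moment equations
with unequal group sizes (n₀ correction).  Two partition levels are
offered:

* **allele** (default): each diploid contributes two allele copies, so
  within-individual heterozygosity is part of the within-group stratum.
  On Balding–Nichols panels E[Φ] ≈ F and Φ agrees with the Weir–Cockerham
  θ estimator within sampling noise.  This is the scale on which the
  island-model inversion Nm = ((1/Fst) − 1)/4 is meaningful, so it is what
  the pipeline reports as Fst.
* **individual**: squared Euclidean distances between dosage vectors, the
  ΦPT convention of spreadsheet AMOVA tools.  Because the within stratum
  then also carries the binomial within-individual variance 2pq, the
  expectation on the same panels is 2F/(1+F) — roughly double at small F.
  The variant is kept for comparability but not used as "Fst".

With missing data, per-locus sums use the available copies and degrees of
freedom come from the full design; this is exact without missing data and
a standard approximation under MCAR.  The permutation test permutes
individual group labels (allele copies move together) and uses
p = (1 + #{Φ_perm ≥ Φ_obs}) / (n_perm + 1), which cannot return zero.  Under
a true null the test is exact: with 199 permutations, p ≤ 0.05 has
probability 0.05, and the calibration experiment checks the rejection
count over 200 null panels against the exact binomial 99% interval.

Nei's unbiased statistics follow the 1978 small-sample form: per locus
J_x = (2n_x Σp² − 1)/(2n_x − 1) within groups, J_xy = Σ p_x p_y between,
I_d = mean(J_xy)/√(mean(J_x)·mean(J_y)), D = −ln I_d.  Loci monomorphic in
a pair are retained (they contribute identity 1), matching the convention
of the standard implementations at printed precision.

## Admixture model

The likelihood is g_il ~ Binomial(2, Σ_k q_ik p_kl) with missing dosages
skipped.  It is maximized by the classical EM for this model (allele-copy
responsibilities), which is monotone in the log-likelihood — asserted at
every iteration.  Initialization: k-means on allele-frequency-scaled PCA
coordinates, membership 0.9 to the assigned cluster, plus a small
seed-dependent perturbation so that replicate restarts differ.
Replicates are the maximum-likelihood counterpart of the replicate MCMC
runs of the classical Bayesian clustering tool; five replicates per K is
the default.  Convergence: relative log-likelihood change below 1e-6
(default) or 500 iterations, in which case the result is flagged
non-converged but returned.  P is clamped to [1e-6, 1 − 1e-6] to keep the
likelihood finite.

Evanno's ΔK = mean over paired replicates of |L(K+1) − 2L(K) + L(K−1)|
divided by the replicate standard deviation of L(K); replicates are paired
by restart index.  ΔK is undefined at the boundary K values and invariant
to adding a constant to all log-likelihoods.  When replicates converge to
identical optima the standard deviation is zero and ΔK is reported as
infinite with a warning; ties among candidates are broken by the raw
second difference.  Assignment uses the 0.75 maximum-membership threshold;
samples below it are labeled admixed.

PCA centers dosages by 2p̂ and scales by √(2p̂(1−p̂)), imputes missing
entries to 0 after centering, drops monomorphic loci, and fixes component
signs by making the largest-magnitude loading positive, so results are
deterministic and invariant to locus order.  Neighbor joining runs on the
allele-sharing distance d = mean |x−y|/2 over pairwise-complete loci;
bootstrap resamples loci with replacement (200 replicates default) and
support is counted per bipartition, so it is robust to replicate-specific
topology differences.

## LD decay

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (phase is unknown in GBS data), for
same-chromosome pairs within 200 kb; pairs with fewer than 4 complete
samples or zero variance are skipped.  Finite samples inflate the null
mean r² to about 1/(n−1), which is visible in the decay curve's tail.
Bins default to 1 kb below 20 kb and 5 kb beyond, to resolve short-range
crossings.  The binned means are smoothed by decreasing isotonic
regression (weighted by pair counts) — assumption-light and deterministic,
since no published functional form is assumed — and the decay distance is
the first crossing below r² = 0.20, linearly interpolated between
bracketing bin midpoints.  Two guards: a curve never above the threshold
reports 0; never below reports +inf.  Because isotonic pooling of a bump
beyond the crossing can drag the pooled mean back above the threshold, the
reported distance is additionally capped at the raw first crossing plus
one bin width.

## Sweep scan

The kernel is a simplified composite-likelihood contrast in the XP-CLR
family; score equality with any external implementation is not claimed,
and validation is by property (nesting, null calibration, localization)
plus a brute-force quadrature oracle.

* Drift scale: ω = mean over loci of (p_q − p_r)²/(p_r(1−p_r)), excluding
  loci fixed in the reference.  When the reference panel tracks the
  ancestral frequency, E[ω] = F/(1−F); when both populations have drifted
  from a common ancestor (as in the symmetric simulator), ω measures the
  total two-sided differentiation — about 2F plus a Jensen inflation from
  the drifted denominator.  The inflated ω simply widens the neutral
  density, which is conservative for sweep detection.
* Neutral model: query frequency density N(p_r, ω·p_r(1−p_r)) truncated to
  [0, 1] and renormalized (standard-deviation floor 1e-4).
* Sweep model at selection parameter s: a locus at distance d from the
  window center escapes with probability c = 1 − exp(−ρd/s), ρ = 1e-8 per
  bp by default; with weight c the neutral density applies, with weight
  1 − c a hitchhiked density concentrated at the boundaries — truncated
  normals at 0 and 1 with bandwidth 0.05 (configurable), weighted by the
  reference frequency of each allele.
* Sampling layer: the observed query alt-allele count enters through a
  binomial likelihood integrated over the frequency density on a 201-point
  trapezoid grid (checked against a 4001-point oracle).
* Score: 2·[max over the s grid (log-spaced, 1e-4 to 1e-1, 10 points) of
  Σ log L(s) − Σ log L(neutral)], truncated at 0.  Since s → 0 collapses
  the sweep model onto the neutral one, the truncation only removes
  numerical noise.

Windows are half-open [k·10 kb, k·10 kb + 50 kb), full-size only; windows
with more than 50 SNPs are downsampled uniformly with a fixed derived
seed, and windows with fewer than 2 usable SNPs are skipped.  Region
calling selects the top 1% of windows genome-wide (per-chromosome cuts are
not implemented; the genome-wide cut is the default reading), merges
selected windows on a chromosome whose gap is below 10 kb, reports the
mean member-window score, and gives both the merged window extent and the
min/max member-SNP positions (the latter explains how a 50-kb window can
yield a much narrower reported region).

## Pipeline

Stages run in methods order — filter → structure → diversity →
differentiation → LD → sweeps — because inferred group labels feed every
later stage.  One global seed derives all stage seeds through a
SeedSequence spawn-key scheme (`derive_seed`), so a single integer
reproduces a run byte-for-byte; this is tested.  The report contains no
computation of its own: every number is re-derivable from the stage TSVs.

## Experiment scales

The recovery experiments use: Fst recovery at F ∈ {0.05, 0.1} with 50
diploids per population, 5,000 loci, 10 seeds; admixture recovery with 100
samples, 2,000 loci, Dirichlet alpha 0.3; Evanno selection over K = 1..4
with 2 matched replicates, 1,000 loci, 10 seeds; sweep localization on a
10 Mb chromosome with 4,000 loci, sweep at 5 Mb, 25 sweep seeds and 10
null seeds; AMOVA calibration with 200 null panels of 30 samples × 200
loci and 199 permutations.  These sizes were chosen as the smallest at
which the asymptotic expectations are clearly separated from sampling
noise.

## Known limitations

No coalescent linkage structure in the simulator (LD-decay distances from
simulated panels are therefore not comparable to empirical decay scales);
MCAR missingness only; admixture inference is maximum-likelihood, so
membership uncertainty is not quantified; the AMOVA supports one grouping
level (no region/population hierarchy); the sweep kernel's scores are
comparable within a scan but not across tools.
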