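# Methods

This note documents the models and procedures implemented in `myrtle`, the
parameters that matter, the numerical choices made where the design was open,
and what the synthetic-data generators do and do not demonstrate.

## NG86 Ka/Ks (`myrtle.kaks`)

For each codon of a pre-aligned pair, the expected number of synonymous
sites is the sum over the three positions of (synonymous single-nucleotide
changes)/3 under the standard genetic code; nonsynonymous sites are the
complement (S + N = 3 × codons). Changes that would create a stop codon are
classed nonsynonymous in site counting. Observed differences are classified
per codon: single-position differences directly, two- and three-position
differences by averaging over all 2 (or 6) mutational orderings, excluding
orderings that pass through a stop codon (if every ordering is blocked, all
orderings are used with stop-touching steps classed nonsynonymous — a
convention that can only arise on pathological input, since valid input
contains no stop codons). Proportions pS = Sd/S and pN = Nd/N (S and N
averaged over the two sequences) are corrected with the Jukes–Cantor map
d = −(3/4)·ln(1 − (4/3)p). p ≥ 3/4 is reported as `status = "saturated"`
rather than raised; ω = Ka/Ks is NaN when Ks = 0.

Conventions deliberately fixed: standard code only, equal pathway weights
(no transition/transversion weighting — classic NG86, not modified NG),
strict validation (equal lengths, multiple of 3, no gaps, no stop codons
anywhere; trim terminal stops upstream). Codons containing `N` in either
sequence are excluded pairwise. Tolerances used in tests: 1e-9 absolute on
counts, 1e-6 on distances.

Known property: the *mean* of per-pair Ks estimates is slightly upward
biased at high divergence (Jensen's inequality on the convex JC transform;
≈ +0.02 at dS = 1.25 with 300-codon pairs), while the per-pair pS estimate
itself is unbiased. This is inherent to averaging JC-corrected distances and
is shared by any faithful implementation.

## WGD dating (`myrtle.wgd`)

A whole-genome duplication appears as a peak in the Ks distribution of
retained paralog pairs. Estimates are filtered to `status == "ok"` and
Ks ∈ [0.01, 5.0] by default — the lower bound removes allelic near-zero
pairs, the upper removes the saturated tail; both are configurable, and
dropped counts are reported per reason. The density is a Gaussian KDE
(Silverman's rule by default, or an absolute bandwidth) evaluated on a
uniform grid of ≥ 512 points over the filter bounds and renormalised to unit
mass; the KDE is implemented directly in numpy so that a zero-variance
sample with an explicit bandwidth is handled. Peaks are local maxima with
prominence ≥ 5% of the density maximum (default), sorted by height, ties
toward lower Ks.

Rates and ages use the standard identity T = Ks/(2r). A per-year rate
interval is calibrated from an ortholog Ks peak and a divergence-time
interval [t_min, t_max]: r_min = Ks/(2 t_max), r_max = Ks/(2 t_min); a
published rate interval can also be supplied directly
(`RateCalibration.from_rates`). Ages propagate the interval:
age_min = Ks/(2 r_max), age_max = Ks/(2 r_min), reported in MY to two
decimals. The identity round-trips (dating then re-calibrating recovers the
rate bounds to 1e-12 relative).

A caveat documented as such: the calibration-time endpoints (74.5, 106.9 MY)
used in examples are back-derived from a published rate interval and are
configuration fixtures, not independently established dates.

## Telomere and centromere annotation (`myrtle.repeats`)

Telomeres: the plant heptamer CCCTAAA (5′, forward) / TTTAGGG (3′, reverse
complement) is scanned in a terminal window (default 10 kb) at each
chromosome end, both orientations in both windows. Exact heptamer matches
are chained into runs; matched units may be separated by up to 3 diverged
units, and a run is accepted when matched copies ≥ 10 (default) and the
diverged fraction ≤ 0.1 (default). The heptamer motif is the only biological
constant here; copy/divergence thresholds are this package's declared
defaults.
Chromosomes shorter than two windows are scanned whole with a warning.

Centromeric satellites: a simplified tandem-repeat finder. Exact 13-mer
self-matches at a lag within [min_period, max_period] = [20, 2000] bp are
collected (integer k-mer hashing, exact, vectorised), lags are clustered
(±3 bp), and seed positions at a consistent lag are chained into candidate
arrays (break at gaps > one period). The consensus monomer is the column
majority over the array cut into period-length frames; edge frames below
50% identity are trimmed; candidates are accepted at mean identity ≥ 0.8
and ≥ 5 copies (defaults). Re-detections of an array at a multiple of its
period are suppressed (smaller periods processed first). This replaces the
full alignment-scoring tandem-repeat recursion; it is adequate for
high-copy, moderately diverged satellites, and is validated against planted
truth rather than against the full algorithm.

Monomer families: greedy centroid clustering in decreasing array length;
an array joins the first family whose representative matches at ≥ 0.8
identity under the best circular rotation (ungapped — tandem monomer phase
is arbitrary), else founds a family. Centromere calls: the genome-wide top
2 families by summed array length are the candidate centromeric repeats;
per chromosome, member arrays within 100 kb are merged and the cluster with
the largest total member length wins (ties: longer span, then leftmost),
at most one call per chromosome, minimum span 1 kb.

## Co-expression modules (`myrtle.coexpression`)

Unsigned weighted network: a_ij = |cor(x_i, x_j)|^β. The soft threshold β is
the lowest candidate power whose degree distribution fits a scale-free
topology with R² ≥ 0.8 (log10 frequency vs log10 mean connectivity over 10
bins), falling back to the argmax-R² power; the scan is deterministic.
Small planted fixtures are not genuinely scale-free, so on noisy inputs the
fallback can land on a high power that sparsifies the network past module
recovery — when the scan reports uniformly poor fits, inspect the R² curve
and set the power explicitly rather than trusting the fallback.
Topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij), TOM_ii = 1. Modules come from average-linkage hierarchical
clustering of 1 − TOM rescaled to [0, 1], a static cut at height 0.25,
discarding clusters below 30 genes to "grey" (unassigned), then iterative
merging of modules whose eigengenes correlate above 1 − 0.25. The static
cut + merge replaces dynamic tree cut: it is simpler, fully deterministic,
and recovers planted structure; it will fragment real nested module
hierarchies more readily than the dynamic variant. Zero-variance genes are
excluded (logged) before network construction.

Module eigengenes are the first right-singular vector of the
gene-standardised module submatrix, scaled to unit sample variance and
sign-aligned with the module mean profile. Module–trait association is
Pearson r with two-sided t-test p (n − 2 df), significance flagged at
|r| > 0.8 and P < 0.001, with no multiple-testing correction — the rule is
applied exactly as stated, against 0/1 sample-group indicators or numeric
covariates. Constant traits give NaN, flagged not significant.

## Metabolite integration (`myrtle.metabolites`)

Clustering: rows are z-scored across samples (abundances span orders of
magnitude), then k-means (k-means++, 10 restarts, fixed seed) is run for
every k in [2, 12] and the Calinski–Harabasz criterion selects k (ties
toward smaller k) — the cascade-selection approach.

Accumulation rate: V[t, n] = (M[t+1, n] − M[t, n])/(T[t+1] − T[t]) over
consecutive fruit stages; times are a strictly increasing schedule in days
after flowering, default (45, 60, 75, 90) — a configurable fixture in which
only the final 75 → 90 interval is externally anchored. The operator is
linear in content and inversely equivariant in time units.

Integration: for each (module, cluster) pair, the mean over member
metabolites of Pearson r between the module eigengene profile and the
metabolite profile, on the shared sample axis; for rates, the eigengene is
reduced to the same intervals by the same finite difference. The unweighted
per-metabolite mean is the most literal "average R"; the per-metabolite
table is always emitted so alternative summaries can be audited.

Anthocyanin: (A530 − 0.25·A657)/fresh weight (g). A650/A666 readings are
stored when present; no chlorophyll computation is performed.

## Synthetic data (`myrtle.simulate`)

All generators are pure functions of (params, seed) and return machine-
readable truth.

*Codon pairs.* The generator targets the NG86 site definition directly:
each codon position of a uniform stop-free ancestor acquires at most one
planted difference with marginal probability p(d)·f, where f is the NG86
site fraction at that position and p(d) = (3/4)(1 − e^{−4d/3}) inverts the
JC map. Synonymous differences are drawn among amino-acid-preserving
changes, nonsynonymous among non-stop amino-acid-changing ones; the change
is assigned to one of the two lineages at random. By construction the
expected NG86-counted divergence equals the requested true_dS/true_dN; this
is an estimator-consistency simulator, not a mechanistic codon model (no
among-site rate variation, no real multiple hits within a codon, no codon
usage bias), so recovery tests demonstrate self-consistency of the counting
chain, not robustness to real evolutionary heterogeneity. Divergences whose
difference probabilities cannot be planted one-per-codon are rejected with
an informative error (well beyond the JC saturation regime).

*Genomes.* Uniform-composition background with a GC knob (default 0.40,
matching a typical Myrtaceae GC content), CCCTAAA×copies at the 5′ end,
TTTAGGG×copies at the 3′ end, and one centromeric array of `copies`
monomers (default length 422; 153 also exercised) with per-base substitution
rate 0.02 placed mid-chromosome. Defaults: 3 chromosomes × 2 Mb, 150
telomere copies, 500 centromere copies.

*Expression.* Gene in module m: loading·latent_m + Normal(0, 0.3) noise,
loadings Uniform(0.5, 1); defaults 4 modules × 50 genes, 50 background
genes, 10 samples. With `trait_locked` the latents are standardised
indicators of disjoint sample groups and the matching 0/1 trait design is
returned. Background genes are unit-variance noise.

*Metabolites.* Metabolite in cluster c: latent time-course c +
Normal(0, 0.1) noise; defaults 60 metabolites, 3 clusters, 6 samples.
A supplied `link` profile replaces cluster 1's latent so integration has a
known ground-truth maximum.

## Problem sizes and numerical notes

Estimator-recovery checks use 200 pairs × 300 codons per divergence level
(the conditions stated for that check). The end-to-end Ks-peak run uses
1200 pairs × 800 codons: the KDE mode of the per-pair Ks distribution sits
systematically below the true divergence for short pairs (the JC transform
skews the sampling distribution, and the shift scales as 1/n_codons), so
longer pairs make the 0.05 mode check statistically meaningful; with these
sizes the measured mode error is ≤ 0.04 across seeds. Repeat-recovery runs
use the generator defaults (3 × 2 Mb plus a 1 Mb chromosome for the 153 bp
monomer). KDE grids are 512 points; density renormalisation uses the
trapezoid rule; all hierarchical clustering is average linkage on condensed
distances; k-means restarts are seeded.

## Known limitations

* NG86 only — no maximum-likelihood codon models, no transition/transversion
  weighting, no alternative genetic codes.
* The tandem-repeat finder needs arrays of ≥ ~5 reasonably homogeneous
  copies and exact 13-mer seeds; highly diverged (> ~15%) or very short
  satellites will be missed.
* The static-cut module detection underperforms dynamic tree cut on nested
  or unevenly sized real modules.
* Synthetic fixtures demonstrate algorithmic correctness and planted-truth
  recovery, not performance on the real sequencing data the pipeline is
  designed to mirror.
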