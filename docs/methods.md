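# Methods notes

This note records the modelling assumptions, numerical choices, and known
limitations behind `seascapegen`, in the order the pipeline runs.

## Data model and quality control

Genotypes are diploid biallelic dosages in {0, 1, 2} with missing calls;
all statistics use pairwise- or locus-complete data, never imputation
(except the PCA outlier scan, which mean-imputes by construction). The QC
cascade runs in a fixed order — sample call rate, locus call rate, minor
allele frequency, one SNP per sequence tag (highest call rate wins, ties
to file order), monomorphic removal — so that reports are comparable
across runs and the filter is idempotent.

Duplicate detection flags sample pairs whose non-missing calls agree at
≥ 0.95 (configurable) and retains the member with the higher call rate;
unrelated individuals agree at ~0.37–0.40 under Binomial(2, 0.5)
genotypes, so the default threshold separates cleanly. The sex-linkage
screen encodes the male-heterogamety pattern: female heterozygosity
exceeding male heterozygosity by > 0.2 while the locus is present in males
at 50% ± 15% of its female presence. Both margins are exposed; they are
pattern thresholds, not estimates, and conservative by design.

Coordinates are geographic degrees; every distance uses a local
equirectangular projection centred on the data. At archipelago scale
(hundreds of km, low latitude) the distortion is well below the raster
discretization error. Rasters are ESRI ASCII grids; the single isotropic
cell size in km is the geometric mean of the N–S and E–W cell edges (they
differ by < 0.5% within 5° of the equator).

## Differentiation statistics

Weir–Cockerham variance components (a, b, c) are computed per locus from
per-population sample sizes, allele frequencies, and heterozygote
fractions; the multi-locus θ is the ratio of sums Σa / Σ(a+b+c) — the
standard aggregation for this estimator (mean-of-ratios is biased for
loci with small denominators). Jost's D uses Nei–Chesser sample-size-
corrected H_S and H_T (both including the observed-heterozygosity terms);
both H_S and H_T are unbiased, so D is zero *in expectation* — not
identically — for identical demes; the per-sample deviation is O(1/n).
The multi-locus D defaults to the arithmetic mean over loci, with the
harmonic-mean variant (positive loci only) exposed because conventions
differ between implementations.

Bootstrap significance resamples loci: the per-pair p-value is the
+1-corrected fraction of 1000 replicates with the statistic ≤ 0 (one-sided
test of differentiation > 0, matching how such tests are reported;
two-sided is an option), followed by Benjamini–Hochberg over all pairs.
Locations need ≥ 8 genotyped individuals to enter pairwise analyses.

## Outlier scans and the neutral panel

Two deliberately simple, fully specified scans replace black-box tools:

* **PCA scan** — loci are centred and scaled by √(2p(1−p)), the top-K
  sample-space axes computed by SVD (K by broken-stick by default), each
  locus regressed on the axes, and the squared z-score norm treated as a
  Mahalanobis distance; a genomic inflation factor (median distance over
  the χ²_K median) rescales the bulk before χ²_K tail probabilities and
  BH q-values.
* **FST scan** — per-locus Weir–Cockerham FST against a central null
  μ·χ²_df/df with df = #demes − 1, where μ is fitted by matching the
  5%-trimmed mean of the observed distribution to the analytically
  trimmed mean of the null, so true outliers do not inflate it.

Only loci flagged by **both** scans (q ≤ 0.05) are removed; the
intersection rule protects against each scan's individual false
positives. Both scans are invariant to sample order and allele-label
flips.

## Spatial admixture

Ancestry proportions minimise ‖X − 2QG‖² over observed entries plus
α·tr(QᵀLQ), where L is the Laplacian of a 10-nearest-neighbour graph on
sample coordinates with heat-kernel weights (bandwidth = median neighbour
distance). α defaults to 0.01; α → 0 recovers plain simplex-constrained
masked NMF. Optimisation alternates projected-gradient steps on Q (rows
projected to the simplex) and G (clipped to [0, 1]) with step sizes from
Lipschitz bounds, which makes the objective provably non-increasing —
chosen over exact alternating least squares precisely for that guarantee.
Ten random restarts (Dirichlet-initialized Q), 10⁴ iteration cap,
relative tolerance 10⁻⁶.

K is selected by masked cross-entropy: 10% of observed entries hidden
uniformly at random, the model fitted on the rest, hidden genotypes scored
by mean negative log Binomial(2, [QG]) probability (floor 10⁻⁹), averaged
over replicates; the per-K mean and spread are both reported because a
flat profile (minimum at K = 1) is itself a finding for weakly structured
data, and with FST of order 0.01 the synthetic study does produce it.

## Directional migration

For each ordered pair a pooled population is formed from the unweighted
mean of the two allele-frequency arrays (sample-size weighting is an
option). Nei's G_ST between each member and the pool is converted through
Nm = (1/G_ST − 1)/4; the entry for direction a→b uses the *sink's*
distance to the pool — a deme receiving much gene flow resembles the
joint migrant pool. This orientation convention is asserted by a literal
transcription oracle in the tests. The matrix is normalized to maximum 1;
asymmetry per pair is called when the two directions' 95% locus-bootstrap
CIs do not overlap — a conservative criterion whose false-positive rate
on symmetric simulations is well under 5%.

## Seascape resistance

Over-water distance is an 8-neighbour shortest path through water cells
(orthogonal step = cell size, diagonal = √2·cell size). Sampling sites are
snapped to the nearest water cell within 3 cells (logged). Effective
resistance uses edge conductance = mean of the two cell conductances,
diagonals scaled by 1/√2, and one grounded sparse-LU solve per focal node;
the implementation is verified against the Laplacian pseudo-inverse
closed form R_ij = L⁺_ii + L⁺_jj − 2L⁺_ij on random graphs to 10⁻⁸.

The paleo scenario clamps water cells in [−210 m, 0) to 1 m depth and
leaves everything else unchanged. The depth-to-resistance transformation
min–max rescales depth per grid (following common resistance-surface
practice); note that per-grid rescaling means clamping is only guaranteed
to lower every cell's resistance when both grids share a depth scale —
`transform_surface(..., depth_range=...)` pins the scale for such
comparisons. Transformation parameters (s ∈ [0.1, 10], m ∈ [1.5, 1000])
and family are fitted by differential evolution with Mantel r² as the
objective. Fitting directly to the reported criterion keeps the
optimization aligned with how the model comparison is scored; a
mixed-effects likelihood objective is noted as future work.

Mantel and partial-Mantel tests permute rows/columns of the first matrix
simultaneously, with the +1 correction (two-sided by default; one-sided
for causal modeling, where the hypotheses are directional). An exact
enumeration mode covers ≤ 8 locations. Causal modeling declares a
candidate supported iff genetic-vs-candidate is significant controlling
every alternative *and* genetic-vs-alternative is non-significant
controlling the candidate, at the 5% level.

## LD effective population size

Burrows composite Δ̂ per locus pair carries the n/(n−1) correction; r̂²
divides Δ̂² by Weir's adjusted heterozygosities π = p(1−p) + D (D the
homozygote excess), the convention under which the published sampling
expectation E[r̂²] = 1/S + 3.19/S² holds (verified by drift-free
simulation; the plain p(1−p) product runs ~2% low). Pairs are weighted by
their pairwise-complete sample size; S is the harmonic mean of pair
sample sizes. The small-sample branch (S < 30) uses the 0.0018 + 0.907/S
+ 4.44/S² expectation and the 0.308/2.08 inversion constants; all
coefficients for the random-mating case sit in one table in the module
docstring. Screening excludes whole loci with MAF < Pcrit; Pcrit is
user-supplied and validated against (1/(2S), 1/S] — no automatic chooser
is provided because the admissible interval does not pick a unique value.

Confidence intervals are a delete-one-**individual** jackknife on the
mean-r̂² scale, transformed through the (monotone) Ne formula. Locus-level
resampling was tried first and understates the standard error by roughly
half: all locus pairs share the same sampled individuals and pedigree, so
pair r̂² values are strongly positively correlated beyond shared loci.
In Wright–Fisher calibration runs (true Ne = 200, S = 50, L = 500) the
individual-level jackknife SE matches the between-replicate standard
deviation and the 95% CI covers the truth in ~90% of replicates, versus
~70% for the locus-level version. Estimation error grows with true Ne as
the drift signal 1/(3Ne) shrinks against fixed sampling noise: at S = 50
and L = 500 the median relative error is ~10–15% at Ne = 100–200 but
~30% at Ne = 500, and estimates at the no-signal boundary return an
infinity sentinel rather than a number.

## Synthetic data

The generator emulates the study design rather than the organism:
Gaussian-cone volcanic islands on a deep (−900 m) channel baseline, an
optional shallow plateau, and −150 m sills between chosen island pairs
(dry or shallow at glacial-maximum sea level, so the paleo clamp converts
them to corridors). Defaults: 100×100 cells, 5 islands, 5 demes × 25
samples, 2000 loci.

Genotypes come from a logit-normal frequency model: ancestral frequency
p₀ ~ U(0.1, 0.9) per locus, deme logit-frequencies multivariate normal
with covariance σ²·exp(−R/ρ) around logit(p₀), genotypes Binomial(2, p).
σ² = 0.09 puts pairwise FST in the 0.005–0.02 range typical of
weakly-structured marine populations; ρ defaults to the median of the
supplied resistance matrix so divergence varies over the matrix's dynamic
range. This model gives direct, tunable control of the
divergence–resistance relationship the IBR tests assume, at trivial cost;
it does **not** model linkage, selection, site-frequency-spectrum realism,
or migration–drift dynamics, so passing recovery tests demonstrates that
the pipeline detects the encoded relationship, not that real data satisfy
it. A coalescent backend (msprime) is the natural extension point for
demographic realism.

The Wright–Fisher module is individual-based: constant N diploids, two
random parents per offspring, free recombination across loci, and — after
finding that independently re-simulated loci destroy the signal — a
**single shared pedigree** for every locus, including redraws of loci that
fixed during the run: the identity disequilibrium that carries the Ne
signal exists only among loci that travelled the same genealogy. The
default run length is 50 generations: composite LD among unlinked loci is
halved by recombination each generation and continuously regenerated by
drift, so it reaches quasi-equilibrium within tens of generations
(census-level drift r̂² matches 1/(3Ne) to ~1% by generation 60);
allele-frequency equilibrium (~4Ne generations) is unnecessary for this
purpose and is not simulated. The returned sample is a cohort of S bred
offspring of the final population — the estimator's model of "a sample
whose parents are the Ne breeders"; drawing S of the N adults without
replacement instead introduces a finite-pool correction ≈ (1 − S/N)/S
that the sampling expectation does not include and visibly deflates CI
coverage at S/N = 0.25.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is reproducible
byte-for-byte. The study-level experiments run at desk scale: 20
archipelago replicates for the model-ranking check, 100 Wright–Fisher
replicates for CI calibration, 500/200 replicates for false-positive
control, and a 100×100 raster (~10⁴ graph nodes) for circuit solves —
sizes chosen so the full closed loop, not a shortcut, runs in a few
minutes on one core. The pipeline caps optimisation budgets (DE
population 8, ≤ 15 generations) accordingly; all budgets are config
knobs.

## Known limitations

* The outlier scans are transparent re-specifications, not
  re-implementations, of the cited selection scans; their exact flagged
  counts on real data will differ even where the consensus rule agrees.
* Mantel-based inference is used because it is the field's reporting
  currency for these comparisons, with its known caveats (autocorrelated
  distance matrices inflate nominal significance; the causal-modeling
  protocol mitigates but does not remove this).
* The LD-Ne machinery assumes a closed, randomly mating population with
  unlinked loci and discrete generations; the chromosome-number
  correction is an empirical regression and shares its domain of
  validity. No mating-system or age-structure corrections are applied.
* Relative migration is comparative, not absolute: entries are scaled to
  the matrix maximum and the island-model Nm transform is used only as a
  monotone link.
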